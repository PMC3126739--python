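# Methods

This note records the models the package implements, the choices made where
the design was genuinely open, and what the built-in validation experiments
do and do not establish.

## The model ladder

All nucleotide models are built from reversible GTR generators
`Q_ij = r_ij * pi_j` (i ≠ j), with the six exchangeabilities `r_AC .. r_GT`
made identifiable by fixing the reference `r_GT = 1` (five free parameters
per matrix) and the generator rescaled so the expected substitution rate at
stationarity is one.  On top of this base the ladder adds, cumulatively and
in any combination the grammar allows:

* **Partitioning** (`GTR112`, `GTR123`): separate matrices for codon
  positions {1,2} vs 3, or for all three positions.
* **Per-partition frequencies** (`+F112`/`+F123`): separate stationary
  frequency sets per group instead of one shared set (3 free parameters per
  set).
* **Gamma rate heterogeneity** (`+G`, `+G112`, `+G123`): Yang's discrete
  approximation with K = 4 equal-probability categories, each category
  represented by its bin mean (computed from the incomplete-gamma identity,
  normalised to mean exactly 1).  One shape per distribution.
* **Rate ratios** (`+CP112`/`+CP123`): per-partition mean rates under the
  random-rates constraint that the position-weighted average rate is one, so
  a model with g groups adds g − 1 free parameters.
* **Context dependence** (`+CD16`, `+CD3`, `+FF16`, `+FF3`; `GTR16C`):
  the third codon position evolves under a GTR matrix selected by its two
  immediate flanking bases — the second position of the same codon and the
  first position of the next codon — read from the sequence at the start of
  the branch (or branch segment).  `CD16` keys one matrix per ordered
  neighbour pair (16 matrices, 80 free exchangeabilities); `CD3` pools the
  pairs by their A+T content (0, 1 or 2 flanking A/T bases; 3 matrices).
  The `FF` variants apply the context matrices only where the parent codon
  prefix is four-fold degenerate (8 prefix families under the standard
  code); all other third positions use a separate independent GTR matrix
  that shares the partition's frequency set.  `GTR16C` is the non-coding
  style full-context model: every column keyed by its neighbours, one shared
  frequency set.
* **Root chains** (`+ROOT0/1/2`): the root sequence is scored (and
  simulated) with first/second positions from their partition frequencies
  and third positions from a zero-order (one extra frequency set),
  first-order (4 sets, conditioned on the same codon's second position) or
  second-order (16 sets, conditioned on both flanking bases) Markov chain.
  `+3F` is accepted as a historical alias for `+ROOT1`.
* **GY94 (+G)**: the 61-sense-codon model with transition factor kappa,
  empirical codon frequencies (F61 averages over the alignment; never-seen
  sense codons get a 0.5 pseudo-count so the generator stays ergodic) and a
  non-synonymous penalty `exp(-d/V)` with `d` the Grantham (1974)
  physicochemical distance, embedded as constant data.  The original
  Goldman–Yang exponential form is used for the amino-acid factor; among-
  codon rate variation multiplies branch lengths per codon site by the
  discrete-gamma category rate.

### Boundary conventions

Columns the context cannot cover fall back to the independent matrix of
their group: the final codon's third position (no succeeding codon) always,
and for `GTR16C` the first and last alignment columns.  Under `ROOT2` the
final codon's third position is scored with the stationary third-position
frequencies.  These conventions affect one or two sites per alignment; the
fallback matrix under pure `CD` schemes is informed by a single site and its
posterior essentially returns the prior.  Parameter *accounting* reports the
context matrices for `CD`/`GTR16C` schemes (16 matrices = 80 free
exchangeabilities, 3 = 15) and additionally the substantive independent
non-degenerate-site matrix for `FF` schemes (so `FF16` counts 85 at the
third position).

## Likelihood

Site-independent models (everything without a context scheme, plus GY94) are
scored by exact Felsenstein pruning with per-column partition models, gamma
categories marginalised per site, missing data (`N`/`-`) marginalised, and
the root chain integrated exactly — `ROOT1` couples the second and third
position of a codon (a per-codon 4×4 sum), `ROOT2` couples consecutive
codons and is handled by a right-to-left transfer DP over codons.

Context-dependent models are scored *conditionally on an augmentation*: an
explicit sequence at every internal (and segment) node.  The log-likelihood
is the root-chain term plus, per branch segment and site, the log transition
probability under the matrix selected from the segment-start (parent)
sequence.  Gamma categories are marginalised per site across the whole tree
(the per-category product of segment probabilities is averaged over
categories), so categories are never augmented.  Branch segmentation splits
each branch of length t into `ceil(t / 0.005)` equal parts by default when
requested; without segmentation the context is frozen along the whole
branch.  Segmentation refines the continuous-time approximation; for
context-free models it is exactly neutral (Chapman–Kolmogorov), which the
tests verify by enumeration.

Transition probabilities come from the symmetric-similarity eigendecomposition
available for every reversible generator; the public `transition_matrix`
primitive uses scipy's scaling-and-squaring `expm` so the two routes
cross-check each other in the tests.

For context-free models the package also provides an exact conditional
augmentation sampler (backward filtering / forward sampling, including the
per-site gamma mixture) returning its own log-density; the identity
`augmented_loglik(a) − log q(a|y) = prune_loglik` holds for every draw and
is asserted to 1e-8 in the tests — the sharpest available consistency check
between the two likelihood routes.

## Priors and MCMC

The extracted source text leaves the prior density formulas blank, so the
package fixes and documents concrete uninformative choices, all overridable
through `PriorConfig`: Dirichlet(1) on every simplex block (frequency sets,
rate-ratio proportions, root-chain rows), independent Exponential(mean 1) on
free exchangeabilities, Uniform(0, 50) on gamma shapes, Exponential(kappa
mean 5, V mean 100) for the codon model, and i.i.d. Exponential(mu) branch
lengths with an Exponential(mean 0.1) hyperprior on mu.  Branch lengths are
fixed at the input tree's values by default (the fixed-topology workflow);
`fix_branch_lengths=False` samples them per branch.

The sampler is Metropolis-within-Gibbs: multiplicative log-normal random
walks on positive scalars and exchangeability vectors (mixed 3:1 with
independence refreshes from the prior, which mix the weakly informed context
matrices), Dirichlet-neighbourhood proposals on simplex blocks, rejection of
proposals outside the support (e.g. alpha ≥ 50).  Step sizes adapt towards a
0.23–0.44 acceptance rate during burn-in and are frozen afterwards.

Data augmentation has a well-known mixing cost: the full conditional of a
substitution matrix given explicit ancestral states is much narrower than
its marginal posterior (every internal transition is effectively observed),
so a chain that alternates one parameter sweep with one augmentation sweep
zigzags, with integrated autocorrelation times an order of magnitude above
the pruning-path sampler's.  Replacing the blocked Gibbs state updates by
exact whole-tree conditional redraws does not help — the bottleneck is the
parameter-given-states step — but several cheap parameter sweeps per
augmentation sweep do.  `run_chain` therefore accepts
``exch_extra_sweeps`` (extra exchangeability-only sweeps per iteration),
which the calibration experiments set to 3.

Augmentations are resampled by blocked Gibbs: within one node, all sites of
one interaction-free phase are drawn simultaneously from their exact full
conditionals (marginalised over gamma categories).  The phases are the three
codon positions for coding layouts (third-position contexts reach only the
two flanking positions; the root chains couple only within/between adjacent
codons across phases) and alignment parity for `GTR16C`.  Ambiguous leaf
positions are latent and resampled the same way, constrained to their
ambiguity set.  The correctness of the phase conditionals is asserted in the
tests against brute-force single-site enumeration (agreement to machine
precision) and, end to end, by a Geweke-style successive-conditional run
that recovers the prior's moments.

## Thermodynamic integration

Model-switch TI integrates `E_beta[log L1 − log L0]` under the power
posterior `prior × L0^(1−beta) × L1^beta` along a 32-point default ladder at
quantiles of Beta(0.3, 1) (dense near 0, where the integrand is steep when
model 0 is the simpler endpoint), by trapezoid quadrature, with per-beta
chains warm-started from the previous beta.  Uncertainty is the per-beta
batch-mean standard error propagated through the quadrature weights;
annealing (0→1) and melting (1→0) runs bracket the burn-in transient and
are averaged for the bidirectional estimate, with a warning when the two
intervals are disjoint.  Log Bayes factors are categorised on the 0/1/3/5
band boundaries.  The harmonic-mean estimator is deliberately absent (it
systematically favours parameter-rich models); a test guards that no such
estimator appears in the public interface.  When two models with identical
flexibility are switched, both endpoints sit at the *other* model's prior
and the integrand swings symmetrically; such comparisons need a ladder dense
near both endpoints (the tests construct one by mirroring the default).

The integrator is generic over a small problem protocol, so the same
quadrature/SE machinery is calibrated on a beta-binomial conjugate toy with
a closed-form log Bayes factor, in both directions, before it is trusted on
phylogenetic switches.  Union-space phylogenetic switches share the data,
the fixed tree and — when a context model is involved — one augmentation,
whose Gibbs updates mix the two engines' candidate weights with weights
(1−beta, beta).  A context model cannot be paired with GY94 (different
latent state spaces); both-prunable pairs (including GY94 vs nucleotide
models) run without augmentation.

## The simulator

The forward simulator is the exact sampling counterpart of the
augmentation-conditional likelihood: root from the root chain, one gamma
category per site for the whole tree, branch-by-branch (segment-by-segment)
evolution with one transition-probability draw per site per segment, matrix
selected from the segment-start sequence.  Simulator and scorer share the
site-to-matrix layout code, so the frozen-context approximation is identical
on both sides; states are recorded at every internal and segment node.

What the simulator does *not* emulate: indels and alignment error (the
generated alignments are gap-free), base-composition ambiguity codes beyond
`N`/`-`, rate drift over time, non-reversible processes, and selection
beyond what the Grantham-penalised codon model encodes.  Tests passing on
simulated data therefore validate the estimators under the model's own
assumptions, not the adequacy of those assumptions for real chloroplast
genes.

## Validation experiments and problem sizes

The built-in experiments (shared by the test suite and
`scripts/acceptance.py`) use desk-scale sizes chosen to finish in minutes
while keeping the checks sharp:

* Pruning vs exhaustive enumeration: 4 taxa, 2 codons, models up to
  `GTR123+G123+CP123+F123`, tolerance 1e-8.
* Augmentation consistency: the conditional-draw identity (exact, 1e-8) and
  a prior-process importance-sampling average over 2000 augmentations on a
  2-taxon, 2-codon instance (3 Monte-Carlo standard errors).
* TI calibration: 20-point ladder, 600 iterations per beta, beta-binomial
  toy, both directions within 3 propagated standard errors.
* Exchangeability recovery: `GTR123+G123+CP123+F123+FF3`, 8 taxa, 400
  codons, 20 replicates with generating values drawn from the inference
  prior (so 95% credibility intervals have exactly 95% expected coverage
  under correct inference), fixed known branch lengths, and reduced chains
  of 1000 iterations (280 burn-in, 3 extra exchangeability sweeps per
  iteration).  Pooled coverage of the 30 generating exchangeabilities per
  replicate is required to reach 90%.  Because all parameters of one
  replicate share one dataset and one chain, misses cluster within
  replicates and the pooled coverage of a finite ensemble is noticeably
  more variable than a binomial count would suggest.

## Known limitations

* The 256-combination both-ends context model (dependence on the
  neighbour pair at both branch ends) is counted but never implemented:
  the parameter cost is out of proportion to any plausible gain in fit.
* Branch segmentation counts are fixed when an augmented tree is built;
  when branch lengths are *sampled*, a segment can temporarily exceed the
  nominal maximum length until the augmentation is rebuilt.
* Model-switch TI with branch-length sampling is not wired (fixed-tree
  comparisons only), and context models cannot be switched against GY94.
* Real-data model comparisons of the kind the method targets are
  cluster-scale by nature; everything here runs at desk scale and the
  absolute log Bayes factors of published analyses are out of reach of the
  bundled experiments.
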