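"""Data-augmented Bayesian MCMC.

A Metropolis-within-Gibbs sampler over model parameters (and optionally
branch lengths) combined with blocked Gibbs resampling of the ancestral
augmentation.  Site-independent models are scored by exact pruning and need
no augmentation; context-dependent models keep explicit sequences at every
internal (and segment) node and update them site-by-site from their full
conditionals, in interaction-free phases (codon positions for third-position
contexts, alignment parity for the all-column context model), so each Gibbs
draw is exact.

Priors: Dirichlet on every simplex block (frequencies, rate-ratio
proportions, root-chain rows), independent Exponentials on free
exchangeabilities, Uniform(0, 50) on gamma shapes, and i.i.d. Exponential
branch lengths given a hyperparameter mu with an Exponential hyperprior.
Proposal step sizes are auto-tuned during burn-in towards a 0.23-0.44
acceptance rate and frozen afterwards; proposals leaving the support are
rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .degeneracy import GeneticCode, STANDARD_CODE
from .likelihood import (AugmentedLikelihood, AugmentedTree, prune_loglik,
                         sample_augmentation)
from .model_core import ContextKind, GY94Spec, ModelSpec, RateRatioScheme
from .parameters import GAMMA_CATEGORIES, ModelParams, slot_names
from .phylo_io import CodingAlignment, PhyloTree

__all__ = ["PriorConfig", "ChainState", "Sampler", "sample_prior", "run_chain",
           "ChainResult", "summarize_posterior", "format_estimate",
           "gibbs_update_node"]


@dataclass
class PriorConfig:
    """Hyperparameters of the prior structure (all positive).

    ``alpha_upper`` bounds the uniform prior on gamma shapes;
    ``branch_length_hyper_mean`` is the mean of the Exponential hyperprior on
    the branch-length prior mean mu.
    """

    frequency_dirichlet_weight: float = 1.0
    exchangeability_prior_mean: float = 1.0
    alpha_upper: float = 50.0
    rate_ratio_dirichlet_weight: float = 1.0
    branch_length_hyper_mean: float = 0.1
    kappa_prior_mean: float = 5.0
    grantham_v_prior_mean: float = 100.0

    def __post_init__(self):
        for f in ("frequency_dirichlet_weight", "exchangeability_prior_mean",
                  "alpha_upper", "rate_ratio_dirichlet_weight",
                  "branch_length_hyper_mean", "kappa_prior_mean",
                  "grantham_v_prior_mean"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class ChainState:
    """Snapshot of a chain: parameter values, branch lengths, bookkeeping."""

    params: ModelParams
    branch_lengths: Optional[np.ndarray] = None
    log_posterior: float = float("nan")
    iteration: int = 0


# ---------------------------------------------------------------------------
# Priors


def _dirichlet_logpdf(x: np.ndarray, a: np.ndarray) -> float:
    return float(gammaln(a.sum()) - gammaln(a).sum() + ((a - 1) * np.log(x)).sum())


def _expon_logpdf(x: float, mean: float) -> float:
    if x <= 0:
        return -np.inf
    return -math.log(mean) - x / mean


def sample_prior(spec: ModelSpec, prior: PriorConfig, rng,
                 tree: Optional[PhyloTree] = None,
                 fix_branch_lengths: bool = True,
                 codon_freqs: Optional[np.ndarray] = None) -> ChainState:
    """Draw a full parameter set (and branch lengths) from the prior."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    params = ModelParams.default(spec, codon_freqs=codon_freqs)
    if spec.gy94:
        from .model_core import discretize_gamma
        gamma = None
        if spec.gy94_gamma:
            gamma = discretize_gamma(rng.uniform(0, prior.alpha_upper),
                                     GAMMA_CATEGORIES)
        params.gy = GY94Spec(kappa=float(rng.exponential(prior.kappa_prior_mean)),
                             V=float(rng.exponential(prior.grantham_v_prior_mean)),
                             codon_freqs=params.gy.codon_freqs, gamma=gamma)
    else:
        for slot in params.exch:
            params.exch[slot] = np.concatenate(
                [rng.exponential(prior.exchangeability_prior_mean, 5), [1.0]])
        w = prior.frequency_dirichlet_weight
        for key in params.freq_keys():
            params.freqs[key] = rng.dirichlet(np.full(4, w))
        for key in params.gamma_keys():
            params.alphas[key] = float(rng.uniform(0, prior.alpha_upper))
        if spec.rate_ratio_scheme == RateRatioScheme.PER_GROUP:
            gw = params.group_weights()
            p = rng.dirichlet(np.full(len(spec.groups),
                                      prior.rate_ratio_dirichlet_weight))
            params.rate_ratios = {g: float(p[i] / gw[g])
                                  for i, g in enumerate(spec.groups)}
        if spec.root.n_sets:
            params.root_freqs = rng.dirichlet(np.full(4, w),
                                              size=spec.root.n_sets)
    params.mu = float(rng.exponential(prior.branch_length_hyper_mean))
    lengths = None
    if tree is not None:
        if fix_branch_lengths:
            lengths = tree.lengths.copy()
        else:
            lengths = np.concatenate(
                [[0.0], rng.exponential(params.mu, tree.n_nodes - 1)])
    return ChainState(params=params, branch_lengths=lengths)


def log_prior(params: ModelParams, prior: PriorConfig,
              branch_lengths: Optional[np.ndarray] = None,
              include_lengths: bool = False) -> float:
    """Joint log prior density of a parameter set."""
    spec = params.spec
    total = 0.0
    if spec.gy94:
        total += _expon_logpdf(params.gy.kappa, prior.kappa_prior_mean)
        total += _expon_logpdf(params.gy.V, prior.grantham_v_prior_mean)
        if params.gy.gamma is not None:
            a = params.gy.gamma.alpha
            total += -math.log(prior.alpha_upper) if 0 < a < prior.alpha_upper else -np.inf
    else:
        for r in params.exch.values():
            for x in r[:5]:
                total += _expon_logpdf(float(x), prior.exchangeability_prior_mean)
        w = prior.frequency_dirichlet_weight
        for pi in params.freqs.values():
            total += _dirichlet_logpdf(pi, np.full(4, w))
        for a in params.alphas.values():
            total += -math.log(prior.alpha_upper) if 0 < a < prior.alpha_upper else -np.inf
        if params.rate_ratios:
            gw = params.group_weights()
            p = np.array([params.rate_ratios[g] * gw[g] for g in spec.groups])
            total += _dirichlet_logpdf(p, np.full(len(p),
                                                  prior.rate_ratio_dirichlet_weight))
        if params.root_freqs is not None:
            for row in params.root_freqs:
                total += _dirichlet_logpdf(row, np.full(4, w))
    if include_lengths and branch_lengths is not None:
        mu = params.mu
        total += _expon_logpdf(mu, prior.branch_length_hyper_mean)
        for t in branch_lengths[1:]:
            total += _expon_logpdf(float(t), mu) if t > 0 else -math.log(mu)
    return total


# ---------------------------------------------------------------------------
# Proposals


def _propose_lognormal(x: np.ndarray, scale: float, rng) -> Tuple[np.ndarray, float]:
    z = rng.normal(0.0, scale, size=np.shape(x))
    new = x * np.exp(z)
    return new, float(np.sum(np.log(new) - np.log(x)))


def _propose_dirichlet(x: np.ndarray, conc: float, rng) -> Tuple[np.ndarray, float]:
    a_fwd = conc * x + 0.5
    y = rng.dirichlet(a_fwd)
    y = np.clip(y, 1e-10, None)
    y = y / y.sum()
    a_bwd = conc * y + 0.5
    log_h = _dirichlet_logpdf(x, a_bwd) - _dirichlet_logpdf(y, a_fwd)
    return y, log_h


def _sample_rows_log(W: np.ndarray, rng) -> np.ndarray:
    W = W - W.max(axis=1, keepdims=True)
    p = np.exp(W)
    p /= p.sum(axis=1, keepdims=True)
    c = np.cumsum(p, axis=1)
    c[:, -1] = 1.0
    return (c > rng.random(W.shape[0])[:, None]).argmax(axis=1)


def gibbs_update_node(engines_weights, node: int, rng) -> None:
    """Resample one node's states from the (possibly tempered) full
    conditional.  ``engines_weights`` is a list of (engine, weight) pairs over
    a shared augmentation; a single pair with weight 1 is the plain sampler.
    """
    engines = [e for e, _ in engines_weights]
    aug = engines[0].aug
    kinds = {e.required_phase_kind() for e in engines} - {None}
    if kinds == {"parity"}:
        phases = ["even", "odd"]
    elif "parity" in kinds and len(kinds) > 1:
        raise NotImplementedError("incompatible context layouts in one chain")
    elif kinds:
        phases = ["p1", "p2", "p3"]
    else:
        phases = ["all"]
    if aug.is_leaf[node]:
        phases = ["all"]
    for phase in phases:
        S = engines[0].phase_sites(phase)
        if aug.is_leaf[node]:
            S = S[aug.free[node, S]]
            if S.size == 0:
                return
            W = np.zeros((S.shape[0], 4))
            for eng, wgt in engines_weights:
                pe = eng.edge_index[node]
                up = aug.states[eng.edge_parent[pe], S].astype(np.int64)
                lp = eng.LP[pe, eng.ids[pe, S], up, :, :]
                mix = logsumexp(lp, axis=2) if eng.K > 1 else lp[:, :, 0]
                W += wgt * mix
        else:
            W = np.zeros((S.shape[0], 4))
            for eng, wgt in engines_weights:
                if wgt != 0.0:
                    W += wgt * eng.candidate_logweights(node, phase)
        draws = _sample_rows_log(W, rng)
        aug.states[node, S] = draws.astype(np.int8)
        touched = []
        if node != 0:
            touched.append(node)
        touched.extend(aug.children[node])
        for eng in engines:
            eng.refresh_edges([eng.edge_index[nd] for nd in touched])


# ---------------------------------------------------------------------------
# The sampler


class Sampler:
    """One model bound to data, with mutable chain internals.

    With ``aln=None`` the chain targets the prior (the likelihood is
    identically zero).  Context-dependent models use the augmentation engine;
    site-independent ones are scored by exact pruning.  ``ll_weight`` tempers
    the likelihood (used by the thermodynamic-integration path).
    """

    def __init__(self, spec: ModelSpec, aln: Optional[CodingAlignment],
                 tree: Optional[PhyloTree], prior: Optional[PriorConfig] = None,
                 code: GeneticCode = STANDARD_CODE,
                 max_segment_length: Optional[float] = None,
                 fix_branch_lengths: bool = True,
                 use_augmentation: Optional[bool] = None,
                 n_categories: int = GAMMA_CATEGORIES,
                 shared_aug: Optional[AugmentedTree] = None):
        self.spec = spec
        self.aln = aln
        self.prior = prior or PriorConfig()
        self.code = code
        self.n_categories = n_categories
        self.fix_branch_lengths = fix_branch_lengths
        self.max_segment_length = max_segment_length
        if aln is not None and tree is None:
            raise ValueError("data without a tree")
        self.tree = tree.copy() if tree is not None else None
        if use_augmentation is None:
            use_augmentation = (aln is not None
                                and not spec.gy94
                                and spec.context.kind != ContextKind.NONE)
        if use_augmentation and spec.gy94:
            raise NotImplementedError("augmentation applies to nucleotide models")
        self.use_aug = use_augmentation
        self.aug: Optional[AugmentedTree] = shared_aug
        if self.use_aug and self.aug is None and aln is not None:
            self.aug = AugmentedTree(self.tree, max_segment_length)
            self.aug.attach_alignment(aln)
        self.engine: Optional[AugmentedLikelihood] = None
        self.ll_weight = 1.0
        self.params: Optional[ModelParams] = None
        self.ll = 0.0
        self._blocks = self._build_blocks()
        self._scales: Dict[str, float] = {}
        self._accept: Dict[str, List[int]] = {}
        self._adapting = True
        for name, kind, _ in self._blocks:
            self._scales[name] = 30.0 if kind in ("freq", "ratio", "root") else 0.2
            self._accept[name] = [0, 0]

    # -- blocks --------------------------------------------------------------

    def _build_blocks(self):
        spec = self.spec
        blocks = []
        if spec.gy94:
            blocks.append(("kappa", "gy_scalar", "kappa"))
            blocks.append(("V", "gy_scalar", "V"))
            if spec.gy94_gamma:
                blocks.append(("alpha[codon]", "gy_alpha", None))
        else:
            for m, slot in enumerate(slot_names(spec)):
                blocks.append((f"exch[{slot}]", "exch", (slot, m)))
            for key in ModelParams.default(spec).freq_keys():
                blocks.append((f"pi[{key}]", "freq", key))
            for key in ModelParams.default(spec).gamma_keys():
                blocks.append((f"alpha[{key}]", "alpha", key))
            if spec.rate_ratio_scheme == RateRatioScheme.PER_GROUP:
                blocks.append(("rate_ratios", "ratio", None))
            for si in range(spec.root.n_sets):
                blocks.append((f"root[{si}]", "root", si))
        if not self.fix_branch_lengths and self.tree is not None:
            for b in range(1, self.tree.n_nodes):
                blocks.append((f"t[{b}]", "length", b))
            blocks.append(("mu", "mu", None))
        return blocks

    # -- state ---------------------------------------------------------------

    def init_state(self, rng, params: Optional[ModelParams] = None) -> ChainState:
        if params is None:
            codon_freqs = None
            if self.spec.gy94 and self.aln is not None:
                from .model_core import observed_codon_frequencies
                codon_freqs = observed_codon_frequencies(self.aln, code=self.code)
            st = sample_prior(self.spec, self.prior, rng, self.tree,
                              self.fix_branch_lengths, codon_freqs)
            params = st.params
            if st.branch_lengths is not None:
                self.tree.lengths = st.branch_lengths
                if self.aug is not None:
                    for b in range(1, self.tree.n_nodes):
                        self.aug.set_branch_length(b, float(st.branch_lengths[b]))
        self.params = params
        if self.use_aug:
            if np.any(self.aug.states < 0):
                self.aug.initialize_states(rng)
            self.engine = AugmentedLikelihood(self.spec, self.params, self.aug,
                                              self.code, self.n_categories)
        self._refresh_ll()
        return self.snapshot()

    def snapshot(self) -> ChainState:
        return ChainState(params=self.params.copy(),
                          branch_lengths=None if self.tree is None
                          else self.tree.lengths.copy(),
                          log_posterior=self.log_posterior())

    def _refresh_ll(self) -> None:
        if self.aln is None:
            self.ll = 0.0
        elif self.use_aug:
            self.ll = self.engine.loglik()
        else:
            self.ll = prune_loglik(self.spec, self.params, self.tree, self.aln,
                                   self.code, self.n_categories)

    def log_prior(self) -> float:
        return log_prior(self.params, self.prior,
                         None if self.tree is None else self.tree.lengths,
                         include_lengths=not self.fix_branch_lengths)

    def log_posterior(self) -> float:
        return self.log_prior() + self.ll_weight * self.ll

    # -- engine refresh plumbing ---------------------------------------------

    def _affected_slots(self, kind: str, payload) -> List[int]:
        names = slot_names(self.spec)
        layout = self.engine.layout
        if kind == "exch":
            return [payload[1]]
        if kind == "freq":
            if self.spec.freq_scheme.value == "shared":
                return list(range(len(names)))
            return [m for m in range(len(names)) if layout.slot_group[m] == payload]
        if kind == "alpha":
            if payload == "shared":
                return list(range(len(names)))
            return [m for m in range(len(names)) if layout.slot_group[m] == payload]
        if kind == "ratio":
            return list(range(len(names)))
        return []

    def _new_ll(self, kind: str, payload) -> float:
        """Likelihood after the already-applied parameter change."""
        if self.aln is None:
            return 0.0
        if not self.use_aug:
            return prune_loglik(self.spec, self.params, self.tree, self.aln,
                                self.code, self.n_categories)
        if kind == "length":
            b = payload
            self.aug.set_branch_length(b, float(self.tree.lengths[b]))
            segs = self.aug.segments_of_branch[b]
            self.engine.refresh_edge_lengths([self.engine.edge_index[s] for s in segs])
        else:
            mult_only = kind in ("alpha", "ratio")
            for m in self._affected_slots(kind, payload):
                self.engine.refresh_slot(m, mult_only=mult_only)
        return self.engine.loglik()

    # -- one Metropolis-within-Gibbs sweep -------------------------------------

    def update_parameters(self, rng) -> None:
        """One full sweep over every parameter block."""
        for name, kind, payload in self._blocks:
            self._update_block(name, kind, payload, rng)

    def update_exchangeabilities(self, rng) -> None:
        """Extra sweep over the exchangeability blocks only (their full
        conditionals given an augmentation are narrow, so additional cheap
        sweeps between augmentation updates speed up marginal mixing)."""
        for name, kind, payload in self._blocks:
            if kind == "exch":
                self._update_block(name, kind, payload, rng)

    def _prior_delta(self, kind, payload, old, new) -> float:
        """log prior(new) - log prior(old) for one block."""
        prior = self.prior
        if kind == "exch":
            return float((old[:5] - new[:5]).sum()
                         / prior.exchangeability_prior_mean)
        if kind in ("freq", "root"):
            w = prior.frequency_dirichlet_weight
            return float((w - 1) * (np.log(new).sum() - np.log(old).sum()))
        if kind == "alpha" or kind == "gy_alpha":
            return 0.0  # uniform within the support (bounds checked earlier)
        if kind == "ratio":
            gw = self.params.group_weights()
            w = prior.rate_ratio_dirichlet_weight
            po = np.array([old[g] * gw[g] for g in self.spec.groups])
            pn = np.array([new[g] * gw[g] for g in self.spec.groups])
            return float((w - 1) * (np.log(pn).sum() - np.log(po).sum()))
        if kind == "gy_scalar":
            mean = (prior.kappa_prior_mean if payload == "kappa"
                    else prior.grantham_v_prior_mean)
            return float((old - new) / mean)
        if kind == "length":
            return float((old - new) / self.params.mu)
        raise AssertionError(kind)

    def _update_block(self, name, kind, payload, rng) -> None:
        prior = self.prior
        scale = self._scales[name]
        p = self.params
        restore = None
        log_h = 0.0
        if kind == "exch":
            slot, _m = payload
            old = p.exch[slot].copy()
            if rng.random() < 0.25:
                # independence refresh from the prior: exact for weakly
                # informed matrices, Hastings cancels the prior ratio
                new5 = rng.exponential(prior.exchangeability_prior_mean, 5)
                log_h = float((new5 - old[:5]).sum()
                              / prior.exchangeability_prior_mean)
            else:
                new5, log_h = _propose_lognormal(old[:5], scale, rng)
            new = np.concatenate([new5, [1.0]])
            p.exch[slot] = new
            restore = ("exch", slot, old)
            d_prior = self._prior_delta(kind, payload, old, new)
        elif kind == "freq":
            old = p.freqs[payload].copy()
            new, log_h = _propose_dirichlet(old, scale, rng)
            p.freqs[payload] = new
            restore = ("freq", payload, old)
            d_prior = self._prior_delta(kind, payload, old, new)
        elif kind == "alpha":
            old = p.alphas[payload]
            if rng.random() < 0.25:
                new, log_h = float(rng.uniform(0, prior.alpha_upper)), 0.0
            else:
                new, log_h = _propose_lognormal(np.array(old), scale, rng)
            if not 0 < float(new) < prior.alpha_upper:
                self._tally(name, False)
                return
            p.alphas[payload] = float(new)
            restore = ("alpha", payload, old)
            d_prior = 0.0
        elif kind == "ratio":
            gw = p.group_weights()
            oldr = dict(p.rate_ratios)
            x = np.array([p.rate_ratios[g] * gw[g] for g in self.spec.groups])
            y, log_h = _propose_dirichlet(x, scale, rng)
            newr = {g: float(y[i] / gw[g])
                    for i, g in enumerate(self.spec.groups)}
            p.rate_ratios = newr
            restore = ("ratio", None, oldr)
            d_prior = self._prior_delta(kind, payload, oldr, newr)
        elif kind == "root":
            old = p.root_freqs[payload].copy()
            new, log_h = _propose_dirichlet(old, scale, rng)
            p.root_freqs[payload] = new
            restore = ("root", payload, old)
            d_prior = self._prior_delta(kind, payload, old, new)
        elif kind == "gy_scalar":
            old = getattr(p.gy, payload)
            new, log_h = _propose_lognormal(np.array(old), scale, rng)
            p.gy = GY94Spec(kappa=float(new) if payload == "kappa" else p.gy.kappa,
                            V=float(new) if payload == "V" else p.gy.V,
                            codon_freqs=p.gy.codon_freqs, gamma=p.gy.gamma)
            restore = ("gy_scalar", payload, old)
            d_prior = self._prior_delta(kind, payload, float(old), float(new))
        elif kind == "gy_alpha":
            from .model_core import discretize_gamma
            old = p.gy.gamma.alpha
            new, log_h = _propose_lognormal(np.array(old), scale, rng)
            if not 0 < float(new) < prior.alpha_upper:
                self._tally(name, False)
                return
            p.gy = GY94Spec(kappa=p.gy.kappa, V=p.gy.V,
                            codon_freqs=p.gy.codon_freqs,
                            gamma=discretize_gamma(float(new), GAMMA_CATEGORIES))
            restore = ("gy_alpha", None, old)
            d_prior = 0.0
        elif kind == "length":
            b = payload
            old = float(self.tree.lengths[b])
            if old == 0.0:
                return
            new, log_h = _propose_lognormal(np.array(old), scale, rng)
            self.tree.lengths[b] = float(new)
            restore = ("length", b, old)
            d_prior = self._prior_delta(kind, payload, old, float(new))
        elif kind == "mu":
            old = p.mu
            new, log_h = _propose_lognormal(np.array(old), scale, rng)
            new = float(new)
            t = self.tree.lengths[1:]
            n = t.shape[0]
            S = float(t.sum())
            hm = prior.branch_length_hyper_mean
            d_prior = ((-n * math.log(new) - S / new - new / hm)
                       - (-n * math.log(old) - S / old - old / hm))
            if math.log(rng.random()) < d_prior + log_h:
                p.mu = new
                self._tally(name, True)
            else:
                self._tally(name, False)
            return
        else:
            raise AssertionError(kind)

        snap = None
        if self.use_aug and self.aln is not None:
            if kind == "length":
                segs = self.aug.segments_of_branch[payload]
                snap = self.engine.snapshot_edges(
                    [self.engine.edge_index[s] for s in segs])
            else:
                aff = self._affected_slots(kind, payload)
                if aff:
                    snap = self.engine.snapshot_slots(aff)
        new_ll = self._new_ll(kind, payload)
        delta = d_prior + self.ll_weight * (new_ll - self.ll) + log_h
        if np.isfinite(delta) and math.log(rng.random()) < delta:
            self.ll = new_ll
            self._tally(name, True)
        else:
            self._undo(restore, snap)
            self._tally(name, False)

    def _undo(self, restore, snap=None) -> None:
        if restore is None:
            return
        kind, key, old = restore
        p = self.params
        if kind == "exch":
            p.exch[key] = old
        elif kind == "freq":
            p.freqs[key] = old
        elif kind == "alpha":
            p.alphas[key] = old
        elif kind == "ratio":
            p.rate_ratios = old
        elif kind == "root":
            p.root_freqs[key] = old
        elif kind == "gy_scalar":
            p.gy = GY94Spec(kappa=old if key == "kappa" else p.gy.kappa,
                            V=old if key == "V" else p.gy.V,
                            codon_freqs=p.gy.codon_freqs, gamma=p.gy.gamma)
        elif kind == "gy_alpha":
            from .model_core import discretize_gamma
            p.gy = GY94Spec(kappa=p.gy.kappa, V=p.gy.V,
                            codon_freqs=p.gy.codon_freqs,
                            gamma=discretize_gamma(old, GAMMA_CATEGORIES))
        elif kind == "length":
            self.tree.lengths[key] = old
            if self.use_aug and self.aln is not None:
                self.aug.set_branch_length(key, old)
        if snap is not None:
            self.engine.restore(snap)

    def _tally(self, name: str, accepted: bool) -> None:
        acc = self._accept[name]
        acc[0] += int(accepted)
        acc[1] += 1
        if self._adapting and acc[1] % 25 == 0:
            rate = acc[0] / acc[1]
            inverted = name.startswith(("pi[", "root[")) or name == "rate_ratios"
            if rate > 0.44:
                self._scales[name] *= (1 / 1.4) if inverted else 1.4
            elif rate < 0.23:
                self._scales[name] *= 1.4 if inverted else (1 / 1.4)
            self._scales[name] = float(np.clip(self._scales[name], 1e-3, 1e6))
            acc[0] = acc[1] = 0

    def freeze_adaptation(self) -> None:
        self._adapting = False

    # -- augmentation --------------------------------------------------------

    def resample_augmentation(self, rng, node: Optional[int] = None) -> None:
        """Gibbs-resample latent states (one node, or a full sweep)."""
        if not self.use_aug:
            return
        nodes = [node] if node is not None else [
            nd for nd in self.aug.topo_order
            if (not self.aug.is_leaf[nd]) or self.aug.free[nd].any()]
        for nd in nodes:
            gibbs_update_node([(self.engine, 1.0)], nd, rng)
        self._refresh_ll()

    def acceptance_rates(self) -> Dict[str, float]:
        return {name: (a[0] / a[1] if a[1] else float("nan"))
                for name, a in self._accept.items()}


# ---------------------------------------------------------------------------
# Chain driver and summaries


@dataclass
class ChainResult:
    samples: pd.DataFrame
    acceptance: Dict[str, float]
    final_state: ChainState
    spec: ModelSpec
    seed: int


def run_chain(spec: ModelSpec, prior: Optional[PriorConfig],
              aln: Optional[CodingAlignment], tree: Optional[PhyloTree],
              n_iter: int, thin: int = 1, burn_in: int = 0, seed: int = 0,
              fix_branch_lengths: bool = True,
              max_segment_length: Optional[float] = None,
              code: GeneticCode = STANDARD_CODE,
              start_params: Optional[ModelParams] = None,
              exch_extra_sweeps: int = 0) -> ChainResult:
    """Run one chain: alternating parameter sweeps and augmentation sweeps.

    Reproducible given the seed; samples are retained after ``burn_in`` at
    spacing ``thin``.  Proposal tuning runs only during burn-in.
    ``exch_extra_sweeps`` adds that many exchangeability-only sweeps per
    iteration, which counteracts the narrow full conditionals of augmented
    chains.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if aln is not None and tree is not None:
        tree.check_taxa(aln)
    rng = np.random.default_rng(seed)
    sampler = Sampler(spec, aln, tree, prior,
                      fix_branch_lengths=fix_branch_lengths,
                      max_segment_length=max_segment_length, code=code)
    sampler.init_state(rng, params=start_params)
    records = []
    for it in range(n_iter):
        if it == burn_in:
            sampler.freeze_adaptation()
        sampler.update_parameters(rng)
        for _ in range(exch_extra_sweeps):
            sampler.update_exchangeabilities(rng)
        sampler.resample_augmentation(rng)
        if it >= burn_in and (it - burn_in) % thin == 0:
            rec = sampler.params.flatten()
            rec["loglik"] = sampler.ll
            rec["log_posterior"] = sampler.log_posterior()
            if not fix_branch_lengths:
                rec["mu"] = sampler.params.mu
                for b in range(1, sampler.tree.n_nodes):
                    rec[f"t[{b}]"] = float(sampler.tree.lengths[b])
            records.append(rec)
    return ChainResult(samples=pd.DataFrame.from_records(records),
                       acceptance=sampler.acceptance_rates(),
                       final_state=sampler.snapshot(), spec=spec, seed=seed)


def summarize_posterior(samples: pd.DataFrame) -> pd.DataFrame:
    """Posterior mean and central 95% credibility interval per parameter."""
    if len(samples) == 0:
        raise ValueError("no samples to summarize")
    out = pd.DataFrame({
        "mean": samples.mean(),
        "lower": samples.quantile(0.025),
        "upper": samples.quantile(0.975),
    })
    return out


def format_estimate(mean: float, lower: float, upper: float) -> str:
    """Render ``mean[lo; hi]`` in the conventional table style, e.g.
    ``0.2396[0.21; 0.28]``."""
    return f"{mean:.4f}[{lower:.2f}; {upper:.2f}]"
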