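"""Forward simulation under every supported model.

The generator is the exact sampling counterpart of the likelihood: the root
sequence is drawn from the chosen root scheme (first/second codon positions
from their frequency sets, third positions from the stationary, zero-,
first- or second-order chain), a gamma rate category is drawn once per site
and kept for the whole tree, and each branch evolves segment by segment with
the per-site transition matrix selected from the segment-start sequence —
flanking-base context, four-fold-degeneracy gating and all.  Within a
segment each site takes one draw from its transition-probability row (exact
given the frozen context), so simulator and scorer share one approximation.

States are recorded at every internal and segment node, which makes the
output directly usable for augmented-likelihood checks and parameter-recovery
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .degeneracy import NUCLEOTIDES, GeneticCode, STANDARD_CODE
from .likelihood import AugmentedTree, _Layout
from .model_core import (GammaScheme, Grouping, ModelSpec, ReversibleEigen,
                         RootOrder, build_gtr_generator, build_gy94_generator)
from .parameters import GAMMA_CATEGORIES, ModelParams, slot_names
from .phylo_io import CodingAlignment, PhyloTree

__all__ = ["SimulationConfig", "SimulatedDataset", "draw_root_sequence",
           "evolve_branch", "simulate_alignment"]


@dataclass
class SimulationConfig:
    """Everything one forward simulation needs (see module docstring)."""

    spec: ModelSpec
    params: ModelParams
    tree: PhyloTree
    n_codons: int
    seed: int
    max_segment_length: Optional[float] = None

    def __post_init__(self):
        if self.n_codons < 2:
            raise ValueError("need at least 2 codons (contexts need a right neighbour)")


@dataclass
class SimulatedDataset:
    """A simulated alignment plus the latent truth that generated it."""

    alignment: CodingAlignment
    true_states: AugmentedTree
    true_params: ModelParams
    seed: int
    site_categories: Optional[np.ndarray] = None


def _sample_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of ``prob_rows``."""
    cum = np.cumsum(prob_rows, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(prob_rows.shape[0])
    return (cum > u[:, None]).argmax(axis=1)


def draw_root_sequence(spec: ModelSpec, params: ModelParams, n_codons: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw a root sequence (integer codes) from the root distribution.

    Codons are laid down left to right; first and second positions are drawn
    before the third positions that may condition on them (the second-order
    chain also conditions on the *next* codon's first position, which exists
    because all position-1 bases are drawn first).
    """
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    n_sites = 3 * n_codons
    if spec.gy94:
        rm = build_gy94_generator(params.gy)
        codons = _sample_rows(np.repeat(params.gy.codon_freqs[None, :], n_codons, 0), rng)
        tri = np.array([[NUCLEOTIDES.index(b) for b in rm.states[c]] for c in codons])
        return tri.reshape(-1).astype(np.int8)
    seq = np.empty(n_sites, dtype=np.int8)
    gop = spec.group_of_position
    if spec.grouping == Grouping.NONCODING:
        pi = params.group_freqs(gop[0])
        if spec.root.order == RootOrder.ORDER0:
            pi = params.root_freqs[0]
        seq[:] = _sample_rows(np.repeat(pi[None, :], n_sites, 0), rng)
        return seq
    s1, s2, s3 = (np.arange(p, n_sites, 3) for p in (0, 1, 2))
    for sel, p in ((s1, 1), (s2, 2)):
        pi = params.group_freqs(gop[p])
        seq[sel] = _sample_rows(np.repeat(pi[None, :], sel.shape[0], 0), rng)
    order = spec.root.order
    pi3 = params.group_freqs(gop[3])
    if order == RootOrder.STATIONARY:
        rows = np.repeat(pi3[None, :], s3.shape[0], 0)
    elif order == RootOrder.ORDER0:
        rows = np.repeat(params.root_freqs[0][None, :], s3.shape[0], 0)
    elif order == RootOrder.ORDER1:
        rows = params.root_freqs[seq[s3 - 1].astype(np.int64)]
    else:  # ORDER2; the final codon has no right neighbour -> stationary
        rows = np.empty((s3.shape[0], 4))
        body = s3[:-1]
        rows[:-1] = params.root_freqs[4 * seq[body - 1].astype(np.int64)
                                      + seq[body + 1].astype(np.int64)]
        rows[-1] = pi3
    seq[s3] = _sample_rows(rows, rng)
    return seq


class _SegmentSampler:
    """Shared machinery: per-slot eigensystems and per-site sampling within a
    segment, with the matrix chosen from the segment-start sequence."""

    def __init__(self, spec: ModelSpec, params: ModelParams, n_sites: int,
                 code: GeneticCode, n_categories: int = GAMMA_CATEGORIES):
        self.spec, self.params = spec, params
        self.layout = _Layout(spec, n_sites, code)
        self.K = n_categories if spec.gamma_scheme != GammaScheme.NONE else 1
        self.eigens, self.mult = [], []
        for m, slot in enumerate(slot_names(spec)):
            g = self.layout.slot_group[m]
            rm = build_gtr_generator(params.exch[slot], params.group_freqs(g))
            self.eigens.append(ReversibleEigen(rm.Q, rm.stationary))
            self.mult.append(params.group_rate(g) * params.gamma_rates(g, self.K))

    def draw_categories(self, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(0, self.K, size=self.layout.n_sites)

    def evolve(self, parent: np.ndarray, t: float, cats: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        if t == 0:
            return parent.copy()
        ids = self.layout.site_ids(parent)
        child = np.empty_like(parent)
        for m in range(self.layout.n_slots):
            msel = ids == m
            if not msel.any():
                continue
            P = self.eigens[m].probs_many(t * self.mult[m])        # (K, 4, 4)
            P = P / P.sum(axis=2, keepdims=True)
            for k in range(self.K):
                sel = msel & (cats == k)
                if not sel.any():
                    continue
                rows = P[k][parent[sel].astype(np.int64)]
                child[sel] = _sample_rows(rows, rng)
        return child


def evolve_branch(parent_sequence, spec: ModelSpec, params: ModelParams,
                  t: float, rng: np.random.Generator,
                  max_segment_length: Optional[float] = None,
                  code: GeneticCode = STANDARD_CODE):
    """Evolve one sequence along a branch of length ``t``.

    The branch is split into equal segments no longer than
    ``max_segment_length`` (whole-branch freezing when None); contexts and
    four-fold-degeneracy masks are recomputed from each segment's start
    sequence.  Accepts and returns a string or an integer-code array.
    """
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    as_str = isinstance(parent_sequence, str)
    if as_str:
        seq = np.array([NUCLEOTIDES.index(b) for b in
                        parent_sequence.upper().replace("U", "T")], dtype=np.int8)
    else:
        seq = np.asarray(parent_sequence, dtype=np.int8).copy()
    sampler = _SegmentSampler(spec, params, seq.shape[0], code)
    cats = sampler.draw_categories(rng)
    n_seg = 1
    if max_segment_length is not None and t > 0:
        n_seg = math.ceil(t / max_segment_length)
    for _ in range(n_seg):
        seq = sampler.evolve(seq, t / n_seg, cats, rng)
    if as_str:
        return "".join(NUCLEOTIDES[c] for c in seq)
    return seq


def simulate_alignment(config: SimulationConfig,
                       code: GeneticCode = STANDARD_CODE) -> SimulatedDataset:
    """Simulate an alignment down the fixed tree; deterministic given the seed.

    Records states at every internal and segment node, so the returned
    :class:`AugmentedTree` is a valid augmentation of the simulated data.
    """
    spec, params = config.spec, config.params
    rng = np.random.default_rng(config.seed)
    n_sites = 3 * config.n_codons
    aug = AugmentedTree(config.tree, config.max_segment_length)
    states = np.empty((aug.n_nodes, n_sites), dtype=np.int8)
    states[0] = draw_root_sequence(spec, params, config.n_codons, rng)
    if spec.gy94:
        cats = _simulate_codon_tree(config, aug, states, rng)
    else:
        sampler = _SegmentSampler(spec, params, n_sites, code)
        cats = sampler.draw_categories(rng)
        for nd in aug.topo_order[1:]:
            states[nd] = sampler.evolve(states[aug.parent[nd]],
                                        float(aug.length[nd]), cats, rng)
    aug.n_sites = n_sites
    aug.states = states
    aug.free = np.zeros_like(states, dtype=bool)
    aug.free[~aug.is_leaf] = True
    leaves = [nd for nd in range(aug.n_nodes) if aug.is_leaf[nd]]
    taxa = [config.tree.names[nd] for nd in leaves]
    aln = CodingAlignment(taxa, states[leaves])
    return SimulatedDataset(aln, aug, params, config.seed, cats)


def _simulate_codon_tree(config, aug, states, rng) -> np.ndarray:
    """Codon-level evolution for the 61-state model (context-free)."""
    gy = config.params.gy
    rm = build_gy94_generator(gy)
    eig = ReversibleEigen(rm.Q, rm.stationary)
    K = GAMMA_CATEGORIES if gy.gamma is not None else 1
    rates = gy.gamma.category_rates if gy.gamma is not None else np.ones(1)
    tri = np.array([[NUCLEOTIDES.index(b) for b in cod] for cod in rm.states])
    lookup = {tuple(row): i for i, row in enumerate(tri)}
    cats = rng.integers(0, K, size=config.n_codons)
    for nd in aug.topo_order[1:]:
        parent_cod = np.array([lookup[tuple(c)] for c in
                               states[aug.parent[nd]].reshape(-1, 3)])
        t = float(aug.length[nd])
        if t == 0:
            states[nd] = states[aug.parent[nd]]
            continue
        P = eig.probs_many(t * rates)
        P = P / P.sum(axis=2, keepdims=True)
        child_cod = np.empty_like(parent_cod)
        for k in range(K):
            sel = cats == k
            if sel.any():
                child_cod[sel] = _sample_rows(P[k][parent_cod[sel]], rng)
        states[nd] = tri[child_cod].reshape(-1)
    return cats
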