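"""Likelihood computation.

Two routes are provided.  Site-independent models (GTR, the codon partition
ladder without contexts, and GY94) get exact Felsenstein-pruning
log-likelihoods.  Context-dependent models condition on an explicit ancestral
augmentation: every internal (and optional segment) node carries a full
nucleotide sequence, branches factor into per-site transition probabilities
whose matrix is selected from the *parent* node's state — the flanking-base
context of a third codon position, optionally gated by four-fold degeneracy
of the parent codon prefix — and the root sequence is scored by the chosen
root Markov chain.

Branch segmentation implements the continuous-time refinement: each branch is
split into equal parts no longer than ``max_segment_length`` (0.005 by
convention) and the context is frozen within a segment and refreshed at
segment nodes.  Without segmentation the context is frozen along the whole
branch.

Gamma rate heterogeneity is marginalised per site across the whole tree: the
per-category product of edge transition probabilities is averaged over the K
equal-probability categories, so no category augmentation is needed.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .degeneracy import GeneticCode, STANDARD_CODE, fourfold_prefix_table
from .model_core import (ContextKind, GammaScheme, Grouping, ModelSpec,
                         ReversibleEigen, RootOrder, build_gtr_generator,
                         build_gy94_generator)
from .parameters import GAMMA_CATEGORIES, ModelParams, slot_names
from .phylo_io import CodingAlignment, PhyloTree

__all__ = ["AugmentedTree", "segment_branches", "AugmentedLikelihood",
           "augmented_loglik", "prune_loglik", "root_log_probability",
           "sample_augmentation"]

_LOG_FLOOR = 1e-300


def _lse(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """Fast log-sum-exp along one axis (no scipy wrapper overhead)."""
    m = a.max(axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.exp(a - m).sum(axis=axis)) + np.squeeze(m, axis=axis)
    return out


# ---------------------------------------------------------------------------
# Augmented tree


class AugmentedTree:
    """A rooted tree with optional branch segmentation and per-node states.

    Nodes ``0..tree.n_nodes-1`` are the original nodes (0 = root); segment
    nodes are appended after them.  ``states`` is an int8 matrix
    (nodes x sites); ``free`` marks entries that are latent (all internal and
    segment states, plus ambiguous leaf positions).
    """

    def __init__(self, tree: PhyloTree, max_segment_length: Optional[float] = None):
        if max_segment_length is not None and max_segment_length <= 0:
            raise ValueError("max_segment_length must be positive")
        self.tree = tree
        self.max_segment_length = max_segment_length
        n = tree.n_nodes
        parent = list(tree.parent)
        length = list(tree.lengths)
        branch_of = list(range(n))           # node -> original branch (child id)
        self.segments_of_branch = {}         # original branch -> [edge child ids]
        for i in range(1, n):
            t = tree.lengths[i]
            m = 1
            if max_segment_length is not None and t > 0:
                m = math.ceil(t / max_segment_length)
            if m == 1:
                self.segments_of_branch[i] = [i]
                continue
            prev = tree.parent[i]
            chain = []
            for _ in range(m - 1):
                parent.append(prev)
                length.append(t / m)
                branch_of.append(i)
                prev = len(parent) - 1
                chain.append(prev)
            parent[i] = prev
            length[i] = t / m
            self.segments_of_branch[i] = chain + [i]
        self.parent = np.array(parent, dtype=int)
        self.length = np.array(length, dtype=float)
        self.branch_of = np.array(branch_of, dtype=int)
        self.n_nodes = self.parent.shape[0]
        self.children: List[List[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            self.children[self.parent[i]].append(i)
        # breadth-first topological order from the root
        order, queue = [], [0]
        while queue:
            nd = queue.pop(0)
            order.append(nd)
            queue.extend(self.children[nd])
        self.topo_order = order
        self.is_leaf = np.array([not self.children[i] for i in range(self.n_nodes)])
        self.states: Optional[np.ndarray] = None
        self.free: Optional[np.ndarray] = None
        self.n_sites = 0

    @property
    def n_segments(self) -> int:
        return self.n_nodes - 1  # one edge per non-root node

    def segment_lengths(self, branch: int) -> np.ndarray:
        return self.length[self.segments_of_branch[branch]]

    def set_branch_length(self, branch: int, t: float) -> None:
        """Re-spread a new total length equally over the branch's segments."""
        segs = self.segments_of_branch[branch]
        self.length[segs] = t / len(segs)

    # -- states -------------------------------------------------------------

    def attach_alignment(self, aln: CodingAlignment) -> None:
        self.tree.check_taxa(aln)
        self.n_sites = aln.n_columns
        self.states = np.full((self.n_nodes, self.n_sites), -1, dtype=np.int8)
        self.free = np.zeros((self.n_nodes, self.n_sites), dtype=bool)
        for i in range(self.n_nodes):
            if self.is_leaf[i]:
                row = aln.row(self.tree.names[i])
                self.states[i] = row
                self.free[i] = row < 0
            else:
                self.free[i] = True

    def initialize_states(self, rng: np.random.Generator) -> None:
        """Fill latent states: internal nodes copy a descendant leaf; remaining
        gaps are drawn uniformly.  A cheap, always-valid starting point."""
        if self.states is None:
            raise ValueError("attach_alignment first")
        for nd in reversed(self.topo_order):
            if not self.is_leaf[nd]:
                self.states[nd] = self.states[self.children[nd][0]]
        missing = self.states < 0
        self.states[missing] = rng.integers(0, 4, size=int(missing.sum()))

    def set_states(self, node: int, values: np.ndarray) -> None:
        self.states[node] = values


def segment_branches(tree: PhyloTree, max_segment_length: float = 0.005) -> AugmentedTree:
    """Split every branch of length t into ``ceil(t / max)`` equal segments
    (zero-length branches stay whole); returns the augmentation scaffold."""
    return AugmentedTree(tree, max_segment_length)


# ---------------------------------------------------------------------------
# Site-to-matrix layout


class _Layout:
    """Maps alignment columns to matrix slots given a parent-node state row."""

    def __init__(self, spec: ModelSpec, n_sites: int, code: GeneticCode):
        self.spec = spec
        self.slots = slot_names(spec)
        self.n_slots = len(self.slots)
        groups = spec.groups
        self.group_slot = {g: i for i, g in enumerate(groups)}
        self.ctx_base = len(groups)
        self.coding = spec.grouping != Grouping.NONCODING
        if self.coding:
            self.pos = np.arange(n_sites) % 3 + 1
        else:
            self.pos = np.zeros(n_sites, dtype=int)
        gop = spec.group_of_position
        self.base_ids = np.array([self.group_slot[gop[p]] for p in self.pos])
        self.slot_group = list(groups) + [spec.context_group] * spec.context.n_contexts
        self.kind = spec.context.kind
        self.n_sites = n_sites
        if self.kind in (ContextKind.CD3, ContextKind.CD16,
                         ContextKind.FF3, ContextKind.FF16):
            s3 = np.arange(2, n_sites, 3)
            self.s3 = s3[:-1]       # the final codon has no right neighbour
            self.fftab = fourfold_prefix_table(code)
        elif self.kind == ContextKind.GTR16C:
            self.interior = np.arange(1, n_sites - 1)

    def ctx_of(self, left: np.ndarray, right: np.ndarray) -> np.ndarray:
        left = left.astype(np.int64)
        right = right.astype(np.int64)
        if self.spec.context.n_contexts == 16:
            return 4 * left + right
        return (((left == 0) | (left == 3)).astype(np.int64)
                + ((right == 0) | (right == 3)).astype(np.int64))

    def site_ids(self, u: np.ndarray) -> np.ndarray:
        """Matrix slot per column, from the branch-start (parent) states."""
        ids = self.base_ids.copy()
        if self.kind == ContextKind.NONE:
            return ids
        if self.kind == ContextKind.GTR16C:
            it = self.interior
            ids[it] = self.ctx_base + self.ctx_of(u[it - 1], u[it + 1])
            return ids
        s3 = self.s3
        ctx = self.ctx_base + self.ctx_of(u[s3 - 1], u[s3 + 1])
        if self.spec.context.fourfold_restricted:
            ffd = self.fftab[4 * u[s3 - 2].astype(np.int64) + u[s3 - 1].astype(np.int64)]
            ids[s3] = np.where(ffd, ctx, ids[s3])
        else:
            ids[s3] = ctx
        return ids


# ---------------------------------------------------------------------------
# Root sequence probability


def root_log_probability(spec: ModelSpec, params: ModelParams,
                         root_states: Sequence[int]) -> float:
    """Log-probability of the root sequence under the model's root scheme.

    First/second codon positions are scored by their partition frequencies;
    third positions by the root scheme (stationary frequencies, or a zero/
    first/second-order Markov chain).  The final codon's third position falls
    back to the stationary (or zero-order) marginal when the scheme needs a
    right neighbour.
    """
    u = np.asarray(root_states, dtype=np.int64)
    if np.any(u < 0):
        raise ValueError("root states must be fully specified")
    n = u.shape[0]
    coding = spec.grouping != Grouping.NONCODING
    pos = np.arange(n) % 3 + 1 if coding else np.zeros(n, dtype=int)
    gop = spec.group_of_position
    logpi = {g: np.log(np.clip(params.group_freqs(g), _LOG_FLOOR, None))
             for g in spec.groups}
    total = 0.0
    order = spec.root.order
    if not coding:
        lp = logpi[gop[0]]
        if order == RootOrder.ORDER0:
            lp = np.log(np.clip(params.root_freqs[0], _LOG_FLOOR, None))
        return float(lp[u].sum())
    for p in (1, 2):
        sel = pos == p
        total += float(logpi[gop[p]][u[sel]].sum())
    s3 = np.arange(2, n, 3)
    stat3 = logpi[gop[3]]
    if order == RootOrder.STATIONARY:
        total += float(stat3[u[s3]].sum())
    elif order == RootOrder.ORDER0:
        rf = np.log(np.clip(params.root_freqs[0], _LOG_FLOOR, None))
        total += float(rf[u[s3]].sum())
    elif order == RootOrder.ORDER1:
        rf = np.log(np.clip(params.root_freqs, _LOG_FLOOR, None))
        total += float(rf[u[s3 - 1], u[s3]].sum())
    else:  # ORDER2
        rf = np.log(np.clip(params.root_freqs, _LOG_FLOOR, None))
        body, last = s3[:-1], s3[-1]
        total += float(rf[4 * u[body - 1] + u[body + 1], u[body]].sum())
        total += float(stat3[u[last]])
    return total


# ---------------------------------------------------------------------------
# Augmentation-conditional likelihood engine


class AugmentedLikelihood:
    """Augmentation-conditional log-likelihood with incremental updates.

    Caches, per edge, the per-site per-gamma-category log transition
    probabilities (``E``), the per-site matrix-slot assignment (``ids``,
    derived from the parent node's states) and the per-edge stack of log
    transition matrices (``LP``).  Parameter changes refresh eigensystems and
    ``LP``; state changes refresh the ``ids``/``E`` rows of adjacent edges.
    Used both directly (scoring) and by the Gibbs augmentation sampler.
    """

    def __init__(self, spec: ModelSpec, params: ModelParams, aug: AugmentedTree,
                 code: GeneticCode = STANDARD_CODE,
                 n_categories: int = GAMMA_CATEGORIES):
        if spec.gy94:
            raise NotImplementedError(
                "the codon model is scored exactly by prune_loglik; "
                "augmentation applies to nucleotide models")
        if aug.states is None:
            raise ValueError("augmented tree has no states attached")
        if np.any(aug.states < 0):
            raise ValueError("augmented states are incomplete; initialize first")
        self.spec = spec
        self.aug = aug
        self.code = code
        self.n_sites = aug.n_sites
        self.layout = _Layout(spec, self.n_sites, code)
        self.K = n_categories if spec.gamma_scheme != GammaScheme.NONE else 1
        # edges in topological order (child node ids)
        self.edge_nodes = np.array([nd for nd in aug.topo_order if nd != 0])
        self.edge_index = {int(nd): e for e, nd in enumerate(self.edge_nodes)}
        self.edge_parent = aug.parent[self.edge_nodes]
        self.n_edges = self.edge_nodes.shape[0]
        self.pendant = aug.is_leaf[self.edge_nodes]
        self.set_params(params)

    # -- parameter-side caches ----------------------------------------------

    def _slot_generator(self, m: int):
        slot = self.layout.slots[m]
        group = self.layout.slot_group[m]
        return build_gtr_generator(self.params.exch[slot],
                                   self.params.group_freqs(group))

    def set_params(self, params: ModelParams) -> None:
        self.params = params
        L = self.layout
        self.mult = np.empty((L.n_slots, self.K))
        self.eigens = []
        for m in range(L.n_slots):
            g = L.slot_group[m]
            self.mult[m] = params.group_rate(g) * params.gamma_rates(g, self.K)
            rm = self._slot_generator(m)
            self.eigens.append(ReversibleEigen(rm.Q, rm.stationary))
        self.LP = np.empty((self.n_edges, L.n_slots, 4, 4, self.K))
        edge_len = self.aug.length[self.edge_nodes]
        for m in range(L.n_slots):
            ts = np.multiply.outer(edge_len, self.mult[m])         # (E, K)
            P = self.eigens[m].probs_many(ts)                      # (E, K, 4, 4)
            self.LP[:, m] = np.log(np.clip(P, _LOG_FLOOR, None)).transpose(0, 2, 3, 1)
        self.ids = np.empty((self.n_edges, self.n_sites), dtype=np.int64)
        self.E = np.zeros((self.n_edges, self.n_sites, self.K))
        self.Tot = np.zeros((self.n_sites, self.K))
        self._tot_dirty = False
        self._su = np.empty((self.n_edges, self.n_sites), dtype=np.int64)
        self._sv = np.empty((self.n_edges, self.n_sites), dtype=np.int64)
        self.refresh_edges(range(self.n_edges))

    def refresh_slot(self, m: int, mult_only: bool = False) -> None:
        """Re-derive one matrix slot after its parameters changed.

        ``mult_only`` skips the eigendecomposition (rate-multiplier changes —
        gamma shapes, rate ratios — leave the generator untouched).
        """
        L = self.layout
        g = L.slot_group[m]
        self.mult[m] = self.params.group_rate(g) * self.params.gamma_rates(g, self.K)
        if not mult_only:
            rm = self._slot_generator(m)
            self.eigens[m] = ReversibleEigen(rm.Q, rm.stationary)
        edge_len = self.aug.length[self.edge_nodes]
        ts = np.multiply.outer(edge_len, self.mult[m])
        P = self.eigens[m].probs_many(ts)
        self.LP[:, m] = np.log(np.clip(P, _LOG_FLOOR, None)).transpose(0, 2, 3, 1)
        e_idx, s_idx = np.nonzero(self.ids == m)
        if e_idx.size:
            self.E[e_idx, s_idx] = self.LP[e_idx, m, self._su[e_idx, s_idx],
                                           self._sv[e_idx, s_idx], :]
            self._tot_dirty = True

    def refresh_edges(self, edges) -> None:
        """Recompute ids and E rows (after state changes on their parents)."""
        st = self.aug.states
        for e in edges:
            u = st[self.edge_parent[e]]
            v = st[self.edge_nodes[e]].astype(np.int64)
            self.ids[e] = self.layout.site_ids(u)
            self._su[e] = u.astype(np.int64)
            self._sv[e] = v
            if not self._tot_dirty:
                self.Tot -= self.E[e]
            self.E[e] = self.LP[e, self.ids[e], self._su[e], v, :]
            if not self._tot_dirty:
                self.Tot += self.E[e]

    def refresh_edge_lengths(self, edges) -> None:
        """Recompute LP and E rows after the edge lengths changed."""
        for e in edges:
            t = self.aug.length[self.edge_nodes[e]]
            for m in range(self.layout.n_slots):
                P = self.eigens[m].probs_many(t * self.mult[m])    # (K, 4, 4)
                self.LP[e, m] = np.log(np.clip(P, _LOG_FLOOR, None)).transpose(1, 2, 0)
        self.refresh_edges(edges)

    # -- proposal snapshot/rollback ------------------------------------------

    def snapshot_slots(self, slots):
        """Cheap rollback state for a proposal touching the given slots."""
        return ("slots", self.E.copy(), self.Tot.copy(), self._tot_dirty,
                [(m, self.LP[:, m].copy(), self.eigens[m], self.mult[m].copy())
                 for m in slots])

    def snapshot_edges(self, edges):
        return ("edges", self.E.copy(), self.Tot.copy(), self._tot_dirty,
                [(e, self.LP[e].copy()) for e in edges])

    def restore(self, snap) -> None:
        kind, E, Tot, dirty, items = snap
        self.E = E
        self.Tot = Tot
        self._tot_dirty = dirty
        if kind == "slots":
            for m, lp, eig, mult in items:
                self.LP[:, m] = lp
                self.eigens[m] = eig
                self.mult[m] = mult
        else:
            for e, lp in items:
                self.LP[e] = lp

    # -- scoring ------------------------------------------------------------

    def totals(self) -> np.ndarray:
        """Per-site per-category sums of edge log-probabilities."""
        if self._tot_dirty:
            self.Tot = self.E.sum(axis=0)
            self._tot_dirty = False
        return self.Tot

    def root_term(self) -> float:
        return root_log_probability(self.spec, self.params, self.aug.states[0])

    def loglik(self, include_pendant: bool = True) -> float:
        """Augmentation-conditional log-likelihood; with
        ``include_pendant=False`` only internal edges and the root term are
        scored (the prior process of the latent states alone)."""
        if include_pendant:
            S = self.totals()
        else:
            S = self.E[~self.pendant].sum(axis=0)                  # (sites, K)
        if self.K == 1:
            site = S[:, 0]
        else:
            site = _lse(S, axis=1) - math.log(self.K)
        return float(site.sum()) + self.root_term()

    # -- Gibbs support -------------------------------------------------------

    def required_phase_kind(self) -> Optional[str]:
        """Which update partition this model needs for valid blocked Gibbs:
        'parity' (neighbour contexts on every column), 'codon' (third-position
        contexts and/or root chains), or None (no cross-site interactions)."""
        if self.layout.kind == ContextKind.GTR16C:
            return "parity"
        if self.layout.kind != ContextKind.NONE:
            return "codon"
        if self.layout.coding and self.spec.root.order in (RootOrder.ORDER1,
                                                           RootOrder.ORDER2):
            return "codon"
        return None

    def phase_sites(self, phase: str) -> np.ndarray:
        n = self.n_sites
        if phase == "all":
            return np.arange(n)
        if phase == "even":
            return np.arange(0, n, 2)
        if phase == "odd":
            return np.arange(1, n, 2)
        return np.arange({"p1": 0, "p2": 1, "p3": 2}[phase], n, 3)

    def candidate_logweights(self, node: int, phase: str) -> np.ndarray:
        """(n_phase_sites, 4) log-weights of candidate states at ``node`` for
        the given phase, marginalised over gamma categories; includes every
        term of the augmented posterior that depends on the candidates."""
        aug, L, K = self.aug, self.layout, self.K
        st = aug.states
        u = st[node]
        S = self.phase_sites(phase)
        n = S.shape[0]
        nsite = self.n_sites
        pe = None if node == 0 else self.edge_index[node]
        ces = [self.edge_index[c] for c in aug.children[node]]

        Tot = self.totals()                                        # (sites, K)
        # mixture term at the phase sites themselves
        base = Tot[S].copy()
        if pe is not None:
            base -= self.E[pe, S]
        for ce in ces:
            base -= self.E[ce, S]
        W_k = np.repeat(base[:, None, :], 4, axis=1)               # (n, 4, K)
        if pe is not None:
            up = st[self.edge_parent[pe], S].astype(np.int64)
            W_k += self.LP[pe, self.ids[pe, S], up, :, :]          # to = candidate
        for ce in ces:
            v = st[self.edge_nodes[ce], S].astype(np.int64)
            W_k += self.LP[ce, self.ids[ce, S], :, v, :]           # from = candidate
        W = _lse(W_k, axis=2) if K > 1 else W_k[:, :, 0]

        # neighbour sites whose child-edge matrix choice depends on the candidate
        ctx_kind = L.kind
        if ces and ctx_kind != ContextKind.NONE:
            if ctx_kind == ContextKind.GTR16C:
                # candidate is the right neighbour of site S-1 ...
                ok = S >= 2
                tt = S[ok] - 1
                if tt.size:
                    idt = (L.ctx_base + 4 * u[tt - 1].astype(np.int64)[:, None]
                           + np.arange(4)[None, :])
                    W[ok] += self._neighbour_mixture(Tot, tt, idt, ces)
                # ... and the left neighbour of site S+1
                ok = S <= nsite - 3
                tt = S[ok] + 1
                if tt.size:
                    idt = (L.ctx_base + 4 * np.arange(4)[None, :]
                           + u[tt + 1].astype(np.int64)[:, None])
                    W[ok] += self._neighbour_mixture(Tot, tt, idt, ces)
            elif phase == "p2":
                t = S + 1
                ok = t != nsite - 1
                tt = t[ok]
                cand = np.arange(4)
                ctx = L.ctx_of(np.repeat(cand[None, :], tt.shape[0], 0),
                               u[tt + 1].astype(np.int64)[:, None])
                idt = L.ctx_base + ctx
                if self.spec.context.fourfold_restricted:
                    ffd = L.fftab[4 * u[tt - 2].astype(np.int64)[:, None] + cand[None, :]]
                    idt = np.where(ffd, idt, L.base_ids[tt][:, None])
                W[ok] += self._neighbour_mixture(Tot, tt, idt, ces)
            elif phase == "p1":
                # previous codon's third position: candidate is its right neighbour
                t = S - 1
                ok = S >= 3
                tt = t[ok]
                if tt.size:
                    ctx = L.ctx_of(u[tt - 1].astype(np.int64)[:, None],
                                   np.repeat(np.arange(4)[None, :], tt.shape[0], 0))
                    idt = L.ctx_base + ctx
                    if self.spec.context.fourfold_restricted:
                        ffd = L.fftab[4 * u[tt - 2].astype(np.int64)
                                      + u[tt - 1].astype(np.int64)][:, None]
                        idt = np.where(ffd, idt, L.base_ids[tt][:, None])
                    W[ok] += self._neighbour_mixture(Tot, tt, idt, ces)
                # own codon's third position: candidate changes the FFD prefix
                if self.spec.context.fourfold_restricted:
                    t2 = S + 2
                    ok2 = t2 != nsite - 1
                    tt2 = t2[ok2]
                    if tt2.size:
                        ctx = L.ctx_of(u[tt2 - 1].astype(np.int64),
                                       u[tt2 + 1].astype(np.int64))[:, None]
                        ffd = L.fftab[4 * np.arange(4)[None, :]
                                      + u[tt2 - 1].astype(np.int64)[:, None]]
                        idt = np.where(ffd, L.ctx_base + ctx, L.base_ids[tt2][:, None])
                        W[ok2] += self._neighbour_mixture(Tot, tt2, idt, ces)

        if node == 0:
            W += self._root_candidate_terms(S, phase)
        return W

    def _neighbour_mixture(self, Tot: np.ndarray, tt: np.ndarray,
                           idt: np.ndarray, ces: List[int]) -> np.ndarray:
        """Per-site gamma-mixture log term at neighbour sites ``tt`` when the
        child-edge matrix ids become ``idt`` (one column per candidate state).
        Candidate-independent edge terms stay inside the mixture (it is
        nonlinear); overall constants cancel in the categorical draw."""
        st = self.aug.states
        K = self.K
        base = Tot[tt].copy()                                      # (n, K)
        for ce in ces:
            base -= self.E[ce, tt]
        M = np.repeat(base[:, None, :], 4, axis=1)                 # (n, 4, K)
        for ce in ces:
            ut = st[self.edge_parent[ce], tt].astype(np.int64)
            vt = st[self.edge_nodes[ce], tt].astype(np.int64)
            M += self.LP[ce, idt, ut[:, None], vt[:, None], :]
        return _lse(M, axis=2) if K > 1 else M[:, :, 0]

    def _root_candidate_terms(self, S: np.ndarray, phase: str) -> np.ndarray:
        """Candidate-dependent root-prior terms (node 0 only)."""
        spec, params, L = self.spec, self.params, self.layout
        u = self.aug.states[0]
        n, nsite = S.shape[0], self.n_sites
        out = np.zeros((n, 4))
        order = spec.root.order
        logpi = {g: np.log(np.clip(params.group_freqs(g), _LOG_FLOOR, None))
                 for g in spec.groups}
        gop = spec.group_of_position
        if not L.coding:
            lp = logpi[gop[0]]
            if order == RootOrder.ORDER0:
                lp = np.log(np.clip(params.root_freqs[0], _LOG_FLOOR, None))
            return out + lp[None, :]
        rf = None
        if params.root_freqs is not None:
            rf = np.log(np.clip(params.root_freqs, _LOG_FLOOR, None))
        if phase == "p3":
            stat3 = logpi[gop[3]]
            if order in (RootOrder.STATIONARY,):
                out += stat3[None, :]
            elif order == RootOrder.ORDER0:
                out += rf[0][None, :]
            elif order == RootOrder.ORDER1:
                out += rf[u[S - 1].astype(np.int64)]
            else:  # ORDER2
                last = S == nsite - 1
                body = ~last
                out[body] += rf[4 * u[S[body] - 1].astype(np.int64)
                                + u[S[body] + 1].astype(np.int64)]
                out[last] += stat3[None, :]
        elif phase == "p2":
            out += logpi[gop[2]][None, :]
            if order == RootOrder.ORDER1:
                out += rf[:, u[S + 1].astype(np.int64)].T
            elif order == RootOrder.ORDER2:
                ok = S + 1 != nsite - 1
                tt = S[ok] + 1
                idx = 4 * np.arange(4)[None, :] + u[tt + 1].astype(np.int64)[:, None]
                out[ok] += rf[idx, u[tt].astype(np.int64)[:, None]]
        elif phase == "p1":
            out += logpi[gop[1]][None, :]
            if order == RootOrder.ORDER2:
                ok = S >= 3
                tt = S[ok] - 1
                idx = 4 * u[tt - 1].astype(np.int64)[:, None] + np.arange(4)[None, :]
                out[ok] += rf[idx, u[tt].astype(np.int64)[:, None]]
        else:  # parity/all phases of ungrouped models handled above
            out += logpi[gop[1]][None, :]
        return out

    def apply_states(self, node: int, sites: np.ndarray, values: np.ndarray) -> None:
        """Write new states for ``sites`` at ``node`` and refresh the caches of
        every adjacent edge (parent edge and child edges)."""
        self.aug.states[node, sites] = values.astype(np.int8)
        touched = []
        if node != 0:
            touched.append(self.edge_index[node])
        touched.extend(self.edge_index[c] for c in self.aug.children[node])
        self.refresh_edges(touched)


def augmented_loglik(spec: ModelSpec, params: ModelParams, aug: AugmentedTree,
                     code: GeneticCode = STANDARD_CODE,
                     n_categories: int = GAMMA_CATEGORIES) -> float:
    """Augmentation-conditional log-likelihood (functional convenience).

    Works for any nucleotide model; context-free specs flow through the same
    code path, which is exercised by the pruning-consistency checks.
    """
    return AugmentedLikelihood(spec, params, aug, code, n_categories).loglik()


# ---------------------------------------------------------------------------
# Exact pruning for site-independent models


def prune_loglik(spec: ModelSpec, params: ModelParams, tree: PhyloTree,
                 aln: CodingAlignment, code: GeneticCode = STANDARD_CODE,
                 n_categories: int = GAMMA_CATEGORIES) -> float:
    """Exact log-likelihood by Felsenstein pruning.

    Supports every site-independent model (all groupings, gamma schemes, rate
    ratios, frequency schemes, root chains) and GY94(+gamma).  Missing data
    are marginalised.  Context-dependent specs must use
    :func:`augmented_loglik`.
    """
    if spec.gy94:
        return _prune_codon(spec, params, tree, aln, code, n_categories)
    if spec.context.kind != ContextKind.NONE:
        raise ValueError("context-dependent models require augmented_loglik "
                         "on an explicit augmentation")
    tree.check_taxa(aln)
    n_sites = aln.n_columns
    coding = spec.grouping != Grouping.NONCODING
    pos = np.arange(n_sites) % 3 + 1 if coding else np.zeros(n_sites, dtype=int)
    groups = list(spec.groups)
    gop = spec.group_of_position
    gidx = np.array([groups.index(gop[p]) for p in pos])
    K = n_categories if spec.gamma_scheme != GammaScheme.NONE else 1
    eigens, mult = [], []
    for g in groups:
        rm = build_gtr_generator(params.exch[g], params.group_freqs(g))
        eigens.append(ReversibleEigen(rm.Q, rm.stationary))
        mult.append(params.group_rate(g) * params.gamma_rates(g, K))
    logLbar = _prune_partials(tree, aln, eigens, mult, gidx, K, 4,
                              _nuc_leaf_partials)
    return _score_root_nucleotide(spec, params, logLbar, n_sites)


def _nuc_leaf_partials(aln: CodingAlignment, taxon: str, K: int) -> np.ndarray:
    row = aln.row(taxon)
    L = np.zeros((row.shape[0], 4))
    L[row < 0] = 1.0
    obs = row >= 0
    L[np.nonzero(obs)[0], row[obs].astype(np.int64)] = 1.0
    return np.repeat(L[:, None, :], K, axis=1)


def _prune_partials(tree, aln, eigens, mult, gidx, K, n_states, leaf_fn):
    """Generic pruning up to the root; returns log of the gamma-averaged root
    partials, shape (n_sites, n_states)."""
    n_groups = len(eigens)
    partial = {}
    logscale = np.zeros((gidx.shape[0], K))
    for i in range(tree.n_nodes - 1, -1, -1):
        if not tree.children[i]:
            Li = leaf_fn(aln, tree.names[i], K)
        else:
            Li = partial.pop(i)
        m = Li.max(axis=2)
        safe = np.where(m > 0, m, 1.0)
        Li = Li / safe[:, :, None]
        logscale += np.where(m > 0, np.log(safe), -np.inf)
        if i == 0:
            root_partial = Li
            break
        t = tree.lengths[i]
        P = np.stack([eigens[g].probs_many(t * mult[g]) for g in range(n_groups)])
        F = np.einsum("skij,skj->ski", P[gidx], Li)
        p = tree.parent[i]
        if p in partial:
            partial[p] = partial[p] * F
        else:
            partial[p] = F
        # fold this child's accumulated scale into the parent and reset
        # (scales are per-site/category and shared multiplicatively)
    with np.errstate(divide="ignore"):
        A = np.log(np.clip(root_partial, _LOG_FLOOR, None)) + logscale[:, :, None]
    if K == 1:
        return A[:, 0, :]
    return logsumexp(A, axis=1) - math.log(K)


def _score_root_nucleotide(spec, params, logLbar, n_sites) -> float:
    coding = spec.grouping != Grouping.NONCODING
    gop = spec.group_of_position
    logpi = {g: np.log(np.clip(params.group_freqs(g), _LOG_FLOOR, None))
             for g in spec.groups}
    order = spec.root.order
    if not coding:
        lp = logpi[gop[0]]
        if order == RootOrder.ORDER0:
            lp = np.log(np.clip(params.root_freqs[0], _LOG_FLOOR, None))
        return float(logsumexp(lp[None, :] + logLbar, axis=1).sum())
    pos = np.arange(n_sites) % 3 + 1
    total = 0.0
    for p in (1, 2):
        if order == RootOrder.ORDER1 and p == 2:
            continue  # folded into the codon-joint term below
        if order == RootOrder.ORDER2:
            continue  # handled by the chain DP below
        sel = pos == p
        total += float(logsumexp(logpi[gop[p]][None, :] + logLbar[sel], axis=1).sum())
    s3 = np.arange(2, n_sites, 3)
    stat3 = logpi[gop[3]]
    if order == RootOrder.STATIONARY:
        total += float(logsumexp(stat3[None, :] + logLbar[s3], axis=1).sum())
    elif order == RootOrder.ORDER0:
        rf = np.log(np.clip(params.root_freqs[0], _LOG_FLOOR, None))
        total += float(logsumexp(rf[None, :] + logLbar[s3], axis=1).sum())
    elif order == RootOrder.ORDER1:
        rf = np.log(np.clip(params.root_freqs, _LOG_FLOOR, None))
        # per codon: sum over (second, third) root states jointly
        B3 = logsumexp(rf[None, :, :] + logLbar[s3][:, None, :], axis=2)  # (c, x2)
        joint = logsumexp(logpi[gop[2]][None, :] + logLbar[s3 - 1] + B3, axis=1)
        total += float(joint.sum())
    else:  # ORDER2: right-to-left chain over codons
        rf = np.log(np.clip(params.root_freqs, _LOG_FLOOR, None))
        lp1, lp2 = logpi[gop[1]], logpi[gop[2]]
        n_codons = n_sites // 3
        c = n_codons - 1
        s1, s2, s3c = 3 * c, 3 * c + 1, 3 * c + 2
        H = (lp1 + logLbar[s1]
             + logsumexp(lp2 + logLbar[s2])
             + logsumexp(stat3 + logLbar[s3c]))
        for c in range(n_codons - 2, -1, -1):
            s1, s2, s3c = 3 * c, 3 * c + 1, 3 * c + 2
            # inner[x2, y'] = log sum_x3 rf[4*x2+y', x3] * Lbar3[x3]
            inner = logsumexp(rf.reshape(4, 4, 4) + logLbar[s3c][None, None, :], axis=2)
            T = logsumexp(inner + H[None, :], axis=1)              # (x2,)
            H = lp1 + logLbar[s1] + logsumexp(lp2 + logLbar[s2] + T)
        total += float(logsumexp(H))
    return total


def _prune_codon(spec, params, tree, aln, code, n_categories) -> float:
    tree.check_taxa(aln)
    gy = params.gy
    rm = build_gy94_generator(gy, code)
    eig = ReversibleEigen(rm.Q, rm.stationary)
    K = n_categories if gy.gamma is not None else 1
    rates = gy.gamma.category_rates if gy.gamma is not None else np.ones(1)
    sense = np.array([[("ACGT".index(b)) for b in cod] for cod in rm.states])
    n_codons = aln.n_codons

    def leaf_fn(a, taxon, KK):
        row = a.row(taxon).reshape(n_codons, 3)
        match = (row[:, None, :] == sense[None, :, :]) | (row[:, None, :] < 0)
        L = np.all(match, axis=2).astype(float)
        resolved = np.all(row >= 0, axis=1)
        bad = resolved & (L.sum(axis=1) == 0)
        if bad.any():
            raise ValueError(
                f"taxon {taxon!r} carries a stop codon at codon "
                f"{int(np.nonzero(bad)[0][0]) + 1}; run validate_coding")
        return np.repeat(L[:, None, :], KK, axis=1)

    gidx = np.zeros(n_codons, dtype=int)
    logLbar = _prune_partials(tree, aln, [eig], [rates], gidx, K, 61, leaf_fn)
    logpi = np.log(np.clip(rm.stationary, _LOG_FLOOR, None))
    return float(logsumexp(logpi[None, :] + logLbar, axis=1).sum())


# ---------------------------------------------------------------------------
# Exact conditional augmentation for context-free models


def sample_augmentation(spec: ModelSpec, params: ModelParams, aug: AugmentedTree,
                        rng: np.random.Generator,
                        n_categories: int = GAMMA_CATEGORIES):
    """Draw all latent states from their exact conditional given the leaves
    (backward filtering / forward sampling), for context-free nucleotide
    models with a per-site root prior.

    Returns the log-density ``log q(a)`` of the drawn augmentation, which
    satisfies the exact identity ``augmented_loglik(a) - log q(a) =
    prune_loglik`` for every draw — the sharp consistency check between the
    two likelihood routes, and a well-mixed starting point for MCMC.
    """
    if spec.gy94 or spec.context.kind != ContextKind.NONE:
        raise ValueError("exact conditional sampling requires a context-free "
                         "nucleotide model")
    if spec.root.order in (RootOrder.ORDER1, RootOrder.ORDER2):
        raise NotImplementedError("root chains couple sites; use Gibbs updates")
    if aug.states is None:
        raise ValueError("attach_alignment first")
    n_sites = aug.n_sites
    coding = spec.grouping != Grouping.NONCODING
    pos = np.arange(n_sites) % 3 + 1 if coding else np.zeros(n_sites, dtype=int)
    groups = list(spec.groups)
    gop = spec.group_of_position
    gidx = np.array([groups.index(gop[p]) for p in pos])
    K = n_categories if spec.gamma_scheme != GammaScheme.NONE else 1
    eigens, mult = [], []
    for g in groups:
        rm = build_gtr_generator(params.exch[g], params.group_freqs(g))
        eigens.append(ReversibleEigen(rm.Q, rm.stationary))
        mult.append(params.group_rate(g) * params.gamma_rates(g, K))
    # per-edge transition matrices, gathered per site: P[node] (sites, K, 4, 4)
    Pedge = {}
    for nd in aug.topo_order[1:]:
        t = float(aug.length[nd])
        stack = np.stack([eigens[g].probs_many(t * mult[g]) for g in range(len(groups))])
        Pedge[nd] = stack[gidx]
    # upward pass
    partial = {}
    logscale = np.zeros((n_sites, K))
    for nd in reversed(aug.topo_order):
        if aug.is_leaf[nd]:
            row = aug.states[nd].copy()
            row[aug.free[nd]] = -1
            L = np.zeros((n_sites, 4))
            L[row < 0] = 1.0
            obs = row >= 0
            L[np.nonzero(obs)[0], row[obs].astype(np.int64)] = 1.0
            L = np.repeat(L[:, None, :], K, axis=1)
        else:
            L = partial[nd]
        m = L.max(axis=2)
        safe = np.where(m > 0, m, 1.0)
        L = L / safe[:, :, None]
        logscale += np.where(m > 0, np.log(safe), -np.inf)
        partial[nd] = L
        if nd == 0:
            continue
        F = np.einsum("skij,skj->ski", Pedge[nd], L)
        p = aug.parent[nd]
        partial[p] = partial[p] * F if p in partial else F
    # per-site per-category data likelihood and category weights
    pi_site = np.empty((n_sites, 4))
    for g in groups:
        sel = gidx == groups.index(g)
        pi_site[sel] = params.group_freqs(g)
    if spec.root.order == RootOrder.ORDER0:
        if coding:
            pi_site[2::3] = params.root_freqs[0]
        else:
            pi_site[:] = params.root_freqs[0]
    root_mass = np.einsum("sx,skx->sk", pi_site, partial[0])
    with np.errstate(divide="ignore"):
        l_log = np.log(np.clip(root_mass, _LOG_FLOOR, None)) + logscale
    wk = np.exp(l_log - l_log.max(axis=1, keepdims=True))
    wk /= wk.sum(axis=1, keepdims=True)
    cum = np.cumsum(wk, axis=1)
    cum[:, -1] = 1.0
    ks = (cum > rng.random(n_sites)[:, None]).argmax(axis=1)
    sites = np.arange(n_sites)
    logq_k = np.zeros((n_sites, K))
    # root draw
    probs = pi_site[:, None, :] * partial[0]                      # (s, K, 4)
    den = probs.sum(axis=2)
    cond = probs / np.clip(den, _LOG_FLOOR, None)[:, :, None]
    pick = cond[sites, ks]
    cc = np.cumsum(pick, axis=1)
    cc[:, -1] = 1.0
    draw = (cc > rng.random(n_sites)[:, None]).argmax(axis=1)
    states = {0: draw}
    logq_k += np.log(np.clip(cond[sites, :, draw], _LOG_FLOOR, None))
    # downward
    for nd in aug.topo_order[1:]:
        xp = states[aug.parent[nd]]
        num = Pedge[nd][sites, :, xp, :] * partial[nd]            # (s, K, 4)
        den = num.sum(axis=2)
        cond = num / np.clip(den, _LOG_FLOOR, None)[:, :, None]
        pick = cond[sites, ks]
        cc = np.cumsum(pick, axis=1)
        cc[:, -1] = 1.0
        draw = (cc > rng.random(n_sites)[:, None]).argmax(axis=1)
        if aug.is_leaf[nd]:
            fixed = ~aug.free[nd]
            draw[fixed] = aug.states[nd, fixed]
        states[nd] = draw
        logq_k += np.log(np.clip(cond[sites, :, draw], _LOG_FLOOR, None))
    for nd, dr in states.items():
        aug.states[nd] = dr.astype(np.int8)
    logq = float(logsumexp(np.log(np.clip(wk, _LOG_FLOOR, None)) + logq_k,
                           axis=1).sum())
    return logq
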