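"""Substitution-model construction: GTR generators, discrete-gamma rates,
neighbour contexts, root schemes, the Goldman-Yang codon model, model
declarations and free-parameter accounting.

The model ladder covered here starts from the site-independent general
time-reversible (GTR) nucleotide model and adds, step by step: per-codon-
position partitioning (groups 112 or 123), per-partition gamma rate
heterogeneity, per-partition mean-rate ratios, per-partition base
frequencies, context dependence of the third codon position on its two
immediate flanking bases (16 contexts, or 3 contexts pooled by A+T content),
optional restriction of the context machinery to four-fold degenerate sites,
and zero/first/second-order Markov chains for the third codon position in the
ancestral root sequence.  The 61-state Goldman-Yang codon model with a
Grantham-distance amino-acid penalty sits alongside as the full codon model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .degeneracy import NUCLEOTIDES, NUC_CODE, GeneticCode, STANDARD_CODE
from .grantham import AMINO_ACIDS, grantham_matrix

__all__ = [
    "FrequencySet", "GtrExchangeabilities", "RateMatrix", "DiscreteGamma",
    "RateRatios", "ContextKind", "ContextScheme", "RootOrder", "RootScheme",
    "Grouping", "FreqScheme", "GammaScheme", "RateRatioScheme", "ModelSpec",
    "GY94Spec", "build_gtr_generator", "transition_matrix", "discretize_gamma",
    "context_index", "count_free_parameters", "build_gy94_generator",
    "parse_model_name", "observed_codon_frequencies", "ReversibleEigen",
    "EXCH_PAIRS", "EXCH_NAMES",
]

#: Unordered nucleotide pairs in canonical order; the last (GT) is the
#: reference exchangeability fixed at 1, leaving 5 free parameters per matrix.
EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
EXCH_NAMES = ["AC", "AG", "AT", "CG", "CT", "GT"]


# ---------------------------------------------------------------------------
# Parameter value types


@dataclass(frozen=True)
class FrequencySet:
    """Base frequencies (pi_A, pi_C, pi_G, pi_T); must sum to 1."""

    pi_A: float
    pi_C: float
    pi_G: float
    pi_T: float

    def __post_init__(self):
        arr = self.array
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies must sum to 1, got {arr.sum()!r}")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.pi_A, self.pi_C, self.pi_G, self.pi_T])

    @classmethod
    def from_array(cls, arr) -> "FrequencySet":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class GtrExchangeabilities:
    """Relative substitution rates r_AC..r_GT with r_GT = 1 as reference."""

    rAC: float
    rAG: float
    rAT: float
    rCG: float
    rCT: float
    rGT: float = 1.0

    def __post_init__(self):
        if np.any(self.array <= 0):
            raise ValueError("exchangeabilities must be positive")
        if abs(self.rGT - 1.0) > 1e-12:
            raise ValueError("the reference exchangeability rGT is fixed at 1")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.rAC, self.rAG, self.rAT, self.rCG, self.rCT, self.rGT])

    @classmethod
    def from_array(cls, arr) -> "GtrExchangeabilities":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class RateMatrix:
    """A reversible continuous-time generator with its stationary distribution.

    Rows sum to zero, off-diagonals are nonnegative, and the matrix is scaled
    so the mean substitution rate at stationarity is one:
    ``-sum_i pi_i Q_ii = 1``.
    """

    states: tuple
    Q: np.ndarray
    stationary: np.ndarray

    def __post_init__(self):
        n = len(self.states)
        if self.Q.shape != (n, n):
            raise ValueError("generator shape does not match state count")
        if np.any(self.Q[~np.eye(n, dtype=bool)] < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-10:
            raise ValueError("generator rows must sum to zero")

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class DiscreteGamma:
    """Discrete approximation of gamma rate heterogeneity (mean rate 1).

    ``category_rates`` holds K equal-probability category rates, each the mean
    of its quantile bin of the Gamma(alpha, alpha) density.
    """

    alpha: float
    K: int
    category_rates: np.ndarray

    def __post_init__(self):
        if abs(float(np.mean(self.category_rates)) - 1.0) > 1e-10:
            raise ValueError("category rates must average to 1")
        if np.any(np.diff(self.category_rates) < 0):
            raise ValueError("category rates must be nondecreasing")


@dataclass(frozen=True)
class RateRatios:
    """Per-codon-position mean rates constrained to average one
    (the random-rates treatment of among-partition rate variation)."""

    r1: float
    r2: float
    r3: float

    def __post_init__(self):
        arr = np.array([self.r1, self.r2, self.r3])
        if np.any(arr <= 0):
            raise ValueError("rate ratios must be positive")
        if abs(arr.mean() - 1.0) > 1e-10:
            raise ValueError("rate ratios must average to 1")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.r3])


# ---------------------------------------------------------------------------
# Declarative model structure


class Grouping(str, Enum):
    """How alignment columns are partitioned into substitution groups."""

    NONCODING = "noncoding"   # one process for every column
    G112 = "112"              # positions 1+2 together, position 3 separate
    G123 = "123"              # each codon position separate


class FreqScheme(str, Enum):
    SHARED = "shared"
    PER_GROUP = "per_group"


class GammaScheme(str, Enum):
    NONE = "none"
    SHARED = "shared"
    PER_GROUP = "per_group"


class RateRatioScheme(str, Enum):
    NONE = "none"
    PER_GROUP = "per_group"


class ContextKind(str, Enum):
    NONE = "none"
    GTR16C = "gtr16c"   # every column context-dependent (non-coding style)
    CD3 = "cd3"         # third positions, 3 A+T-content contexts
    CD16 = "cd16"       # third positions, 16 neighbour combinations
    FF3 = "ff3"         # CD3 restricted to four-fold degenerate sites
    FF16 = "ff16"       # CD16 restricted to four-fold degenerate sites


_N_CONTEXTS = {
    ContextKind.NONE: 0, ContextKind.GTR16C: 16, ContextKind.CD3: 3,
    ContextKind.CD16: 16, ContextKind.FF3: 3, ContextKind.FF16: 16,
}


@dataclass(frozen=True)
class ContextScheme:
    kind: ContextKind = ContextKind.NONE

    @property
    def n_contexts(self) -> int:
        return _N_CONTEXTS[self.kind]

    @property
    def fourfold_restricted(self) -> bool:
        return self.kind in (ContextKind.FF3, ContextKind.FF16)


class RootOrder(str, Enum):
    STATIONARY = "stationary"  # model frequencies as the root prior
    ORDER0 = "order0"          # separate base-frequency set at third positions
    ORDER1 = "order1"          # conditioned on the same codon's second position
    ORDER2 = "order2"          # conditioned on both flanking bases


_N_ROOT_SETS = {RootOrder.STATIONARY: 0, RootOrder.ORDER0: 1,
                RootOrder.ORDER1: 4, RootOrder.ORDER2: 16}


@dataclass(frozen=True)
class RootScheme:
    order: RootOrder = RootOrder.STATIONARY

    @property
    def n_sets(self) -> int:
        return _N_ROOT_SETS[self.order]


@dataclass(frozen=True)
class GY94Spec:
    """Parameter values of the Goldman-Yang codon model.

    Rates between codons i, j differing at exactly one position are
    ``pi_j * kappa^[transition] * exp(-d(aa_i, aa_j) / V)`` with ``d`` the
    Grantham distance (zero for synonymous changes); multi-position changes
    have rate zero.
    """

    kappa: float
    V: float
    codon_freqs: np.ndarray
    gamma: Optional[DiscreteGamma] = None

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.V <= 0:
            raise ValueError("V must be positive")
        f = np.asarray(self.codon_freqs, dtype=float)
        if f.shape != (61,):
            raise ValueError("codon_freqs must have 61 entries")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("codon frequencies must sum to 1")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model from the ladder.

    The nucleotide fields (grouping/frequency/gamma/rate-ratio/context/root
    schemes) and the codon-model flag are mutually exclusive; ``name`` renders
    the standard notation (e.g. ``GTR123+G123+CP123+F123+FF16+ROOT1``).
    """

    grouping: Grouping = Grouping.NONCODING
    freq_scheme: FreqScheme = FreqScheme.SHARED
    gamma_scheme: GammaScheme = GammaScheme.NONE
    rate_ratio_scheme: RateRatioScheme = RateRatioScheme.NONE
    context: ContextScheme = field(default_factory=ContextScheme)
    root: RootScheme = field(default_factory=RootScheme)
    gy94: bool = False
    gy94_gamma: bool = False

    def __post_init__(self):
        if self.gy94:
            if (self.grouping != Grouping.NONCODING
                    or self.freq_scheme != FreqScheme.SHARED
                    or self.gamma_scheme != GammaScheme.NONE
                    or self.rate_ratio_scheme != RateRatioScheme.NONE
                    or self.context.kind != ContextKind.NONE
                    or self.root.order != RootOrder.STATIONARY):
                raise ValueError("GY94 is exclusive with the nucleotide fields")
            return
        if self.gy94_gamma:
            raise ValueError("gy94_gamma requires gy94")
        ck = self.context.kind
        if ck == ContextKind.GTR16C and self.grouping != Grouping.NONCODING:
            raise ValueError("GTR16C requires the ungrouped (noncoding) layout")
        if ck in (ContextKind.CD3, ContextKind.CD16, ContextKind.FF3,
                  ContextKind.FF16) and self.grouping == Grouping.NONCODING:
            raise ValueError(f"{ck.value} contexts require codon-position groups")
        if self.grouping == Grouping.NONCODING:
            if self.freq_scheme != FreqScheme.SHARED:
                raise ValueError("per-group frequencies require grouping")
            if self.rate_ratio_scheme != RateRatioScheme.NONE:
                raise ValueError("rate ratios require grouping")
            if self.gamma_scheme == GammaScheme.PER_GROUP:
                raise ValueError("per-group gamma requires grouping")
            if self.root.order in (RootOrder.ORDER1, RootOrder.ORDER2):
                raise ValueError("Markov-chain root schemes require codon groups")

    # -- structural helpers -------------------------------------------------

    @property
    def groups(self) -> tuple:
        """Ordered group names ('n' | 'p12','p3' | 'p1','p2','p3')."""
        if self.gy94:
            return ("codon",)
        return {Grouping.NONCODING: ("n",),
                Grouping.G112: ("p12", "p3"),
                Grouping.G123: ("p1", "p2", "p3")}[self.grouping]

    @property
    def group_of_position(self) -> dict:
        """Codon position (1, 2, 3) -> group name (position 0 = noncoding)."""
        if self.grouping == Grouping.NONCODING:
            return {0: "n", 1: "n", 2: "n", 3: "n"}
        if self.grouping == Grouping.G112:
            return {1: "p12", 2: "p12", 3: "p3"}
        return {1: "p1", 2: "p2", 3: "p3"}

    @property
    def context_group(self) -> Optional[str]:
        if self.context.kind == ContextKind.NONE:
            return None
        return "n" if self.context.kind == ContextKind.GTR16C else "p3"

    def freq_key(self, group: str) -> str:
        return "shared" if self.freq_scheme == FreqScheme.SHARED else group

    def gamma_key(self, group: str) -> Optional[str]:
        if self.gamma_scheme == GammaScheme.NONE:
            return None
        return "shared" if self.gamma_scheme == GammaScheme.SHARED else group

    # -- naming -------------------------------------------------------------

    @property
    def name(self) -> str:
        if self.gy94:
            return "GY94+G" if self.gy94_gamma else "GY94"
        sub = {Grouping.NONCODING: "", Grouping.G112: "112",
               Grouping.G123: "123"}[self.grouping]
        if self.context.kind == ContextKind.GTR16C:
            base = "GTR16C"
        else:
            base = "GTR" + sub
        parts = [base]
        if self.gamma_scheme == GammaScheme.SHARED:
            parts.append("G")
        elif self.gamma_scheme == GammaScheme.PER_GROUP:
            parts.append("G" + sub)
        if self.rate_ratio_scheme == RateRatioScheme.PER_GROUP:
            parts.append("CP" + sub)
        if self.freq_scheme == FreqScheme.PER_GROUP:
            parts.append("F" + sub)
        ctx = {ContextKind.CD3: "CD3", ContextKind.CD16: "CD16",
               ContextKind.FF3: "FF3", ContextKind.FF16: "FF16"}.get(self.context.kind)
        if ctx:
            parts.append(ctx)
        root = {RootOrder.ORDER0: "ROOT0", RootOrder.ORDER1: "ROOT1",
                RootOrder.ORDER2: "ROOT2"}.get(self.root.order)
        if root:
            parts.append(root)
        return "+".join(parts)


def parse_model_name(name: str) -> ModelSpec:
    """Parse the standard model notation into a :class:`ModelSpec`.

    Grammar (tokens joined by ``+``)::

        base   := GTR | GTR112 | GTR123 | GTR16C | GY94
        suffix := G | G112 | G123          (gamma rate heterogeneity)
                | CP112 | CP123            (per-partition rate ratios)
                | F112 | F123              (per-partition frequencies)
                | CD3 | CD16 | FF3 | FF16  (third-position contexts)
                | ROOT0 | ROOT1 | ROOT2    (root Markov chain; `3F` = ROOT1)

    Subscripts of suffixes must match the base grouping.
    """
    tokens = name.strip().split("+")
    base = tokens[0].upper()
    rest = [t.upper() for t in tokens[1:]]
    if base == "GY94":
        if rest == []:
            return ModelSpec(gy94=True)
        if rest == ["G"]:
            return ModelSpec(gy94=True, gy94_gamma=True)
        raise ValueError(f"unrecognized GY94 variant {name!r}")
    grouping = {"GTR": Grouping.NONCODING, "GTR16C": Grouping.NONCODING,
                "GTR112": Grouping.G112, "GTR123": Grouping.G123}.get(base)
    if grouping is None:
        raise ValueError(f"unknown base model {base!r} in {name!r}")
    sub = {Grouping.NONCODING: "", Grouping.G112: "112", Grouping.G123: "123"}[grouping]
    kw = dict(grouping=grouping)
    if base == "GTR16C":
        kw["context"] = ContextScheme(ContextKind.GTR16C)
    for tok in rest:
        if tok == "G":
            kw["gamma_scheme"] = GammaScheme.SHARED
        elif re.fullmatch(r"G(112|123)", tok):
            if tok[1:] != sub:
                raise ValueError(f"gamma subscript {tok} does not match base {base}")
            kw["gamma_scheme"] = GammaScheme.PER_GROUP
        elif re.fullmatch(r"CP(112|123)", tok):
            if tok[2:] != sub:
                raise ValueError(f"rate-ratio subscript {tok} does not match base {base}")
            kw["rate_ratio_scheme"] = RateRatioScheme.PER_GROUP
        elif re.fullmatch(r"F(112|123)", tok):
            if tok[1:] != sub:
                raise ValueError(f"frequency subscript {tok} does not match base {base}")
            kw["freq_scheme"] = FreqScheme.PER_GROUP
        elif tok in ("CD3", "CD16", "FF3", "FF16"):
            kw["context"] = ContextScheme(ContextKind(tok.lower()))
        elif tok in ("ROOT0", "ROOT1", "ROOT2"):
            kw["root"] = RootScheme(RootOrder("order" + tok[-1]))
        elif tok == "3F":  # historical alias for the first-order root chain
            kw["root"] = RootScheme(RootOrder.ORDER1)
        elif tok == "0F":
            kw["root"] = RootScheme(RootOrder.ORDER0)
        else:
            raise ValueError(f"unknown model token {tok!r} in {name!r}")
    return ModelSpec(**kw)


# ---------------------------------------------------------------------------
# Generators and rates


def build_gtr_generator(exch, freqs) -> RateMatrix:
    """Build the reversible GTR generator ``Q_ij = r_ij * pi_j`` (i != j),
    rescaled to mean rate one at stationarity."""
    r = exch.array if isinstance(exch, GtrExchangeabilities) else np.asarray(exch, float)
    pi = freqs.array if isinstance(freqs, FrequencySet) else np.asarray(freqs, float)
    if r.shape != (6,) or np.any(r <= 0):
        raise ValueError("need 6 positive exchangeabilities")
    if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("need 4 positive frequencies summing to 1")
    Q = np.zeros((4, 4))
    for k, (i, j) in enumerate(EXCH_PAIRS):
        Q[i, j] = r[k] * pi[j]
        Q[j, i] = r[k] * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    return RateMatrix(tuple(NUCLEOTIDES), Q / scale, pi)


def transition_matrix(Q: RateMatrix, t: float, rate_multiplier: float = 1.0) -> np.ndarray:
    """Transition probabilities ``P = exp(rate * t * Q)`` (scaling-and-squaring)."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if rate_multiplier <= 0:
        raise ValueError("rate multiplier must be positive")
    P = expm(Q.Q * (t * rate_multiplier))
    return np.clip(P, 0.0, None)


def discretize_gamma(alpha: float, K: int = 4) -> DiscreteGamma:
    """K equal-probability categories of Gamma(alpha, alpha), each represented
    by its bin mean, normalised to average exactly one."""
    return _discretize_gamma_cached(float(alpha), int(K))


@lru_cache(maxsize=8192)
def _discretize_gamma_cached(alpha: float, K: int) -> DiscreteGamma:
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if K < 1:
        raise ValueError("need at least one category")
    if K == 1:
        return DiscreteGamma(alpha, 1, np.ones(1))
    edges = gamma_dist.ppf(np.arange(1, K) / K, alpha, scale=1.0 / alpha)
    # mean within each bin via the shape alpha+1 incomplete-gamma identity
    cdf_up = gamma_dist.cdf(edges, alpha + 1, scale=1.0 / alpha)
    upper = np.concatenate([cdf_up, [1.0]])
    lower = np.concatenate([[0.0], cdf_up])
    rates = (upper - lower) * K
    rates = rates / rates.mean()
    return DiscreteGamma(alpha, K, rates)


def context_index(left, right, scheme: ContextScheme) -> int:
    """Map a flanking-base pair onto a context id.

    16-context schemes use the bijection ``4*code(left) + code(right)``
    (A, C, G, T order); 3-context schemes count how many flanking bases are
    A or T (0, 1, or 2).
    """
    if scheme.kind == ContextKind.NONE:
        raise ValueError("scheme has no contexts")

    def _code(b):
        if isinstance(b, str):
            b = b.upper().replace("U", "T")
            if b not in NUC_CODE:
                raise ValueError(f"context unavailable for symbol {b!r}")
            return NUC_CODE[b]
        b = int(b)
        if not 0 <= b <= 3:
            raise ValueError(f"context unavailable for code {b}")
        return b

    lc, rc = _code(left), _code(right)
    if scheme.n_contexts == 16:
        return 4 * lc + rc
    return int(lc in (0, 3)) + int(rc in (0, 3))


# ---------------------------------------------------------------------------
# Free-parameter accounting


class Component(str, Enum):
    EXCHANGEABILITIES = "exchangeabilities"
    FREQUENCIES = "frequencies"
    ROOT = "root"
    ALL = "all"


def count_free_parameters(spec: ModelSpec, component="all",
                          positions: Optional[Sequence[int]] = None) -> int:
    """Exact free-parameter count per the conventional accounting: 5 free
    exchangeabilities per GTR matrix, 3 per frequency set, one gamma shape per
    distribution, n_groups - 1 rate ratios.

    ``positions`` restricts the count to the groups covering those codon
    positions (e.g. ``positions=(3,)`` for the third codon position).  For
    context schemes the exchangeability count covers the context matrices
    (16 matrices = 80 free parameters, 3 matrices = 15); the FF schemes add
    the separate independent model used at non-four-fold-degenerate sites.
    """
    component = Component(component)
    if spec.gy94:
        if component == Component.ALL:
            return 2 + (1 if spec.gy94_gamma else 0)  # kappa, V (+ gamma shape)
        return 0

    if positions is None:
        sel_groups = list(spec.groups)
    else:
        gop = spec.group_of_position
        sel_groups = sorted({gop[p] for p in positions},
                            key=lambda g: spec.groups.index(g))

    def exch_count():
        total = 0
        for g in sel_groups:
            if g == spec.context_group:
                total += 5 * spec.context.n_contexts
                if spec.context.fourfold_restricted:
                    total += 5  # independent model at non-FFD sites
            else:
                total += 5
        return total

    def freq_count():
        if spec.freq_scheme == FreqScheme.SHARED:
            return 3
        return 3 * len(sel_groups)

    def root_count():
        return 3 * spec.root.n_sets

    if component == Component.EXCHANGEABILITIES:
        return exch_count()
    if component == Component.FREQUENCIES:
        return freq_count()
    if component == Component.ROOT:
        return root_count()

    total = exch_count() + freq_count() + root_count()
    if spec.gamma_scheme == GammaScheme.SHARED:
        total += 1
    elif spec.gamma_scheme == GammaScheme.PER_GROUP:
        total += len(sel_groups)
    if spec.rate_ratio_scheme == RateRatioScheme.PER_GROUP:
        total += len(spec.groups) - 1
    return total


# ---------------------------------------------------------------------------
# Goldman-Yang codon model


def observed_codon_frequencies(alignment, pseudo_count: float = 0.5,
                               code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Average observed codon frequencies (F61) over an in-frame alignment.

    Codons containing missing data are skipped; sense codons never observed
    receive ``pseudo_count`` so the generator stays ergodic.
    """
    codons = code.sense_codons
    index = {c: i for i, c in enumerate(codons)}
    counts = np.zeros(61)
    codes = alignment.codes if hasattr(alignment, "codes") else np.asarray(alignment)
    n_codons = codes.shape[1] // 3
    for row in codes:
        tri = row[: 3 * n_codons].reshape(n_codons, 3)
        ok = np.all(tri >= 0, axis=1)
        for a, b, c in tri[ok]:
            codon = NUCLEOTIDES[a] + NUCLEOTIDES[b] + NUCLEOTIDES[c]
            if codon in index:
                counts[index[codon]] += 1
    counts[counts == 0] = pseudo_count
    return counts / counts.sum()


def build_gy94_generator(spec: GY94Spec, code: GeneticCode = STANDARD_CODE) -> RateMatrix:
    """Build the 61x61 Goldman-Yang generator (single-nucleotide changes only,
    transition factor kappa, Grantham penalty exp(-d/V)), mean rate one."""
    codons = code.sense_codons
    n = len(codons)
    pi = np.asarray(spec.codon_freqs, dtype=float)
    d = grantham_matrix()
    aa_idx = [AMINO_ACIDS.index(code.table[c]) for c in codons]
    transitions = {frozenset("AG"), frozenset("CT")}
    Q = np.zeros((n, n))
    for i in range(n):
        ci = codons[i]
        for j in range(n):
            if i == j:
                continue
            cj = codons[j]
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rate = pi[j]
            if frozenset((ci[k], cj[k])) in transitions:
                rate *= spec.kappa
            if aa_idx[i] != aa_idx[j]:
                rate *= np.exp(-d[aa_idx[i], aa_idx[j]] / spec.V)
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    return RateMatrix(tuple(codons), Q / scale, pi)


# ---------------------------------------------------------------------------
# Fast transition probabilities for reversible generators


class ReversibleEigen:
    """Eigendecomposition of a reversible generator via the symmetric similarity
    transform, giving cheap ``P(t) = U exp(lambda t) U^-1`` evaluations."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        sqrt_pi = np.sqrt(pi)
        S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)
        lam, V = np.linalg.eigh(S)
        self.lam = lam
        self.U = V / sqrt_pi[:, None]
        self.Uinv = V.T * sqrt_pi[None, :]

    def probs(self, t: float) -> np.ndarray:
        P = (self.U * np.exp(self.lam * t)) @ self.Uinv
        return np.clip(P, 0.0, None)

    def probs_many(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for an array of scaled times; returns shape ts.shape + (n, n)."""
        ts = np.asarray(ts, dtype=float)
        e = np.exp(np.multiply.outer(ts, self.lam))      # (..., n)
        P = np.einsum("il,...l,lj->...ij", self.U, e, self.Uinv)
        return np.clip(P, 0.0, None)
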