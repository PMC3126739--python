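"""Concrete parameter values for a declared model.

A :class:`ModelParams` instance pairs a :class:`~codonctx.model_core.ModelSpec`
with numeric values for every block the spec declares: one exchangeability
vector per substitution matrix "slot", frequency sets, gamma shapes, rate
ratios, root-chain frequency sets, the codon-model parameters and the
branch-length hyperparameter mu.

Matrix slots are ordered: one independent GTR per group (in group order),
followed by the context matrices of the context-bearing group.  The
independent matrix of the context group serves the sites the context cannot
cover (the final codon's third position, boundary columns, and — for the
FF schemes — every non-four-fold-degenerate third position).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .model_core import (FreqScheme, GammaScheme, GY94Spec, ModelSpec,
                         RateRatioScheme, RootOrder, discretize_gamma)

__all__ = ["ModelParams", "slot_names", "context_slot_labels", "GAMMA_CATEGORIES"]

#: Conventional number of discrete gamma categories.
GAMMA_CATEGORIES = 4

_FREE_EXCH = ["AC", "AG", "AT", "CG", "CT"]
_CTX16 = [a + b for a in "ACGT" for b in "ACGT"]
_CTX3 = ["at0", "at1", "at2"]


def context_slot_labels(spec: ModelSpec) -> List[str]:
    n = spec.context.n_contexts
    return {0: [], 3: list(_CTX3), 16: list(_CTX16)}[n]


def slot_names(spec: ModelSpec) -> List[str]:
    """Ordered matrix-slot names: independent groups, then context matrices."""
    names = list(spec.groups)
    cg = spec.context_group
    names.extend(f"{cg}|{lab}" for lab in context_slot_labels(spec))
    return names


@dataclass
class ModelParams:
    """Numeric parameter values for one :class:`ModelSpec`.

    Attributes
    ----------
    exch : dict
        Slot name -> 6 exchangeabilities (AC, AG, AT, CG, CT, GT); GT = 1.
    freqs : dict
        Frequency-set key ("shared" or group name) -> 4 base frequencies.
    alphas : dict
        Gamma key ("shared" or group name) -> shape; empty when no gamma.
    rate_ratios : dict
        Group name -> mean rate; position-weighted mean is 1; empty when the
        rate-ratio scheme is off.
    root_freqs : ndarray or None
        (1, 4), (4, 4) or (16, 4) conditional frequency sets for the zero/
        first/second-order root chain at third positions.
    gy : GY94Spec or None
        Codon-model values when the spec is GY94.
    mu : float
        Branch-length prior mean (hyperparameter).
    """

    spec: ModelSpec
    exch: Dict[str, np.ndarray] = field(default_factory=dict)
    freqs: Dict[str, np.ndarray] = field(default_factory=dict)
    alphas: Dict[str, float] = field(default_factory=dict)
    rate_ratios: Dict[str, float] = field(default_factory=dict)
    root_freqs: Optional[np.ndarray] = None
    gy: Optional[GY94Spec] = None
    mu: float = 0.1

    # -- construction -------------------------------------------------------

    @classmethod
    def default(cls, spec: ModelSpec, codon_freqs=None) -> "ModelParams":
        """Neutral starting values: unit exchangeabilities, uniform
        frequencies, alpha = 1, unit rate ratios."""
        p = cls(spec)
        if spec.gy94:
            if codon_freqs is None:
                codon_freqs = np.full(61, 1 / 61)
            gamma = discretize_gamma(1.0, GAMMA_CATEGORIES) if spec.gy94_gamma else None
            p.gy = GY94Spec(kappa=2.0, V=100.0, codon_freqs=np.asarray(codon_freqs),
                            gamma=gamma)
            return p
        for s in slot_names(spec):
            p.exch[s] = np.ones(6)
        for key in p.freq_keys():
            p.freqs[key] = np.full(4, 0.25)
        for key in p.gamma_keys():
            p.alphas[key] = 1.0
        if spec.rate_ratio_scheme == RateRatioScheme.PER_GROUP:
            for g in spec.groups:
                p.rate_ratios[g] = 1.0
        if spec.root.n_sets:
            p.root_freqs = np.full((spec.root.n_sets, 4), 0.25)
        return p

    # -- structural keys ----------------------------------------------------

    def freq_keys(self) -> List[str]:
        if self.spec.freq_scheme == FreqScheme.SHARED:
            return ["shared"]
        return list(self.spec.groups)

    def gamma_keys(self) -> List[str]:
        if self.spec.gamma_scheme == GammaScheme.NONE:
            return []
        if self.spec.gamma_scheme == GammaScheme.SHARED:
            return ["shared"]
        return list(self.spec.groups)

    def group_weights(self) -> Dict[str, float]:
        """Fraction of alignment columns each group covers."""
        gop = self.spec.group_of_position
        w: Dict[str, float] = {}
        for pos in (1, 2, 3):
            w[gop[pos]] = w.get(gop[pos], 0.0) + 1 / 3
        return w

    def group_rate(self, group: str) -> float:
        return self.rate_ratios.get(group, 1.0)

    def gamma_rates(self, group: str, K: int = GAMMA_CATEGORIES) -> np.ndarray:
        key = self.spec.gamma_key(group)
        if key is None:
            return np.ones(1)
        return discretize_gamma(self.alphas[key], K).category_rates

    def group_freqs(self, group: str) -> np.ndarray:
        return self.freqs[self.spec.freq_key(group)]

    # -- bookkeeping --------------------------------------------------------

    def copy(self) -> "ModelParams":
        return ModelParams(
            spec=self.spec,
            exch={k: v.copy() for k, v in self.exch.items()},
            freqs={k: v.copy() for k, v in self.freqs.items()},
            alphas=dict(self.alphas),
            rate_ratios=dict(self.rate_ratios),
            root_freqs=None if self.root_freqs is None else self.root_freqs.copy(),
            gy=self.gy if self.gy is None else replace(self.gy),
            mu=self.mu,
        )

    def flatten(self) -> Dict[str, float]:
        """Flat scalar view for traces and summaries (free parameters only)."""
        out: Dict[str, float] = {}
        if self.spec.gy94:
            out["kappa"] = self.gy.kappa
            out["V"] = self.gy.V
            if self.gy.gamma is not None:
                out["alpha[codon]"] = self.gy.gamma.alpha
            return out
        for slot, r in self.exch.items():
            for i, nm in enumerate(_FREE_EXCH):
                out[f"r{nm}[{slot}]"] = float(r[i])
        for key, pi in self.freqs.items():
            for b, v in zip("ACGT", pi):
                out[f"pi{b}[{key}]"] = float(v)
        for key, a in self.alphas.items():
            out[f"alpha[{key}]"] = float(a)
        for g, r in self.rate_ratios.items():
            out[f"rate[{g}]"] = float(r)
        if self.root_freqs is not None:
            order = self.spec.root.order
            for si in range(self.root_freqs.shape[0]):
                if order == RootOrder.ORDER0:
                    cond = ""
                elif order == RootOrder.ORDER1:
                    cond = "|" + "ACGT"[si]
                else:
                    cond = "|" + "ACGT"[si // 4] + "ACGT"[si % 4]
                for b, v in zip("ACGT", self.root_freqs[si]):
                    out[f"root.pi{b}{cond}"] = float(v)
        return out
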