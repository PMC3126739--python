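"""Model/Results front end.

:class:`SubstitutionModel` binds one declared model to an alignment and a
fixed rooted tree; :meth:`SubstitutionModel.fit` runs the data-augmented
MCMC and returns a :class:`FitResult` carrying posterior samples, credibility
intervals, diagnostics and a summary table.  Simulation and model comparison
hang off the model object.
"""

from __future__ import annotations

from typing import Optional, Union

import pandas as pd

from .degeneracy import get_genetic_code
from .likelihood import AugmentedTree, augmented_loglik, prune_loglik
from .mcmc import (ChainResult, PriorConfig, format_estimate, run_chain,
                   summarize_posterior)
from .model_core import (ContextKind, ModelSpec, observed_codon_frequencies,
                         parse_model_name)
from .parameters import ModelParams
from .phylo_io import (CodingAlignment, PhyloTree, read_alignment, read_tree,
                       validate_coding)
from .simulate import SimulatedDataset, SimulationConfig, simulate_alignment

__all__ = ["SubstitutionModel", "FitResult"]


class SubstitutionModel:
    """A substitution model bound to data.

    Parameters
    ----------
    spec : ModelSpec or str
        Declarative model (or its name, e.g. ``"GTR123+G123+CP123+F123+FF3"``).
    alignment : CodingAlignment
        In-frame protein-coding nucleotide alignment.
    tree : PhyloTree
        Fixed rooted tree with branch lengths; taxa must match the alignment.
    prior : PriorConfig, optional
    genetic_code : int
        NCBI translation-table id (1 = standard).
    """

    def __init__(self, spec: Union[ModelSpec, str], alignment: CodingAlignment,
                 tree: PhyloTree, prior: Optional[PriorConfig] = None,
                 genetic_code: int = 1):
        self.spec = parse_model_name(spec) if isinstance(spec, str) else spec
        self.alignment = alignment
        self.tree = tree
        self.prior = prior or PriorConfig()
        self.code = get_genetic_code(genetic_code)
        tree.check_taxa(alignment)
        report = validate_coding(alignment, self.code,
                                 forbid_stops=self.spec.gy94)
        if not report.ok:
            raise ValueError("alignment failed coding validation: "
                             + "; ".join(report.failures))

    @classmethod
    def from_files(cls, spec: Union[ModelSpec, str], alignment_path,
                   tree_path, **kwargs) -> "SubstitutionModel":
        return cls(spec, read_alignment(alignment_path), read_tree(tree_path),
                   **kwargs)

    # -- likelihood ----------------------------------------------------------

    def loglik(self, params: Optional[ModelParams] = None,
               augmentation: Optional[AugmentedTree] = None) -> float:
        """Log-likelihood at given (or default) parameter values.

        Site-independent models are scored exactly by pruning; context models
        need an augmentation with complete states.
        """
        params = params or self.default_params()
        if self.spec.gy94 or self.spec.context.kind == ContextKind.NONE:
            return prune_loglik(self.spec, params, self.tree, self.alignment,
                                self.code)
        if augmentation is None:
            raise ValueError("context-dependent models are scored conditional "
                             "on an augmentation; pass one (e.g. the "
                             "true_states of a simulation, or sample via fit)")
        return augmented_loglik(self.spec, params, augmentation, self.code)

    def default_params(self) -> ModelParams:
        codon_freqs = None
        if self.spec.gy94:
            codon_freqs = observed_codon_frequencies(self.alignment,
                                                     code=self.code)
        return ModelParams.default(self.spec, codon_freqs=codon_freqs)

    # -- inference -----------------------------------------------------------

    def fit(self, iterations: int = 2000, burn_in: int = 500, thin: int = 2,
            seed: int = 0, fix_branch_lengths: bool = True,
            max_segment_length: Optional[float] = None) -> "FitResult":
        """Run the data-augmented MCMC and summarise the posterior."""
        chain = run_chain(self.spec, self.prior, self.alignment, self.tree,
                          n_iter=iterations, thin=thin, burn_in=burn_in,
                          seed=seed, fix_branch_lengths=fix_branch_lengths,
                          max_segment_length=max_segment_length,
                          code=self.code)
        return FitResult(self, chain)

    # -- simulation ----------------------------------------------------------

    def simulate(self, params: ModelParams, n_codons: int, seed: int,
                 max_segment_length: Optional[float] = None) -> SimulatedDataset:
        """Forward-simulate an alignment of ``n_codons`` under this model
        down this model's tree."""
        cfg = SimulationConfig(self.spec, params, self.tree, n_codons, seed,
                               max_segment_length)
        return simulate_alignment(cfg, self.code)

    def compare_to(self, other: Union[ModelSpec, str], **kwargs):
        """Thermodynamic-integration log Bayes factor of ``other`` over this
        model (see :func:`codonctx.ti.compare_models` for options)."""
        from .ti import compare_models
        other = parse_model_name(other) if isinstance(other, str) else other
        return compare_models(self.spec, other, self.alignment, self.tree,
                              prior=self.prior, **kwargs)


class FitResult:
    """Posterior samples and summaries from one MCMC fit."""

    def __init__(self, model: SubstitutionModel, chain: ChainResult):
        self.model = model
        self.chain = chain
        self.samples: pd.DataFrame = chain.samples
        self.acceptance = chain.acceptance
        self.seed = chain.seed

    @property
    def param_names(self):
        return [c for c in self.samples.columns
                if c not in ("loglik", "log_posterior")]

    def summary(self) -> pd.DataFrame:
        """Posterior mean, central 95% interval and the conventional
        ``mean[lo; hi]`` rendering per parameter."""
        tab = summarize_posterior(self.samples[self.param_names])
        tab["estimate"] = [format_estimate(m, lo, hi) for m, lo, hi in
                           zip(tab["mean"], tab["lower"], tab["upper"])]
        return tab

    def summary_text(self) -> str:
        tab = self.summary()
        name = self.model.spec.name
        lines = [f"Model: {name}", f"Retained samples: {len(self.samples)}",
                 f"Mean log-likelihood: {self.samples['loglik'].mean():.2f}", ""]
        width = max(len(i) for i in tab.index) + 2
        for pname, row in tab.iterrows():
            lines.append(f"{pname:<{width}}{row['estimate']}")
        return "\n".join(lines)

    def credibility_interval(self, name: str, level: float = 0.95):
        lo = (1 - level) / 2
        s = self.samples[name]
        return float(s.quantile(lo)), float(s.quantile(1 - lo))

    def plot_trace(self, names=None, path=None):
        """Trace plots of selected parameters (default: log-likelihood plus
        the first few parameters)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        names = names or (["loglik"] + self.param_names[:5])
        fig, axes = plt.subplots(len(names), 1, figsize=(7, 1.8 * len(names)),
                                 sharex=True, squeeze=False)
        for ax, nm in zip(axes[:, 0], names):
            ax.plot(self.samples[nm].to_numpy(), lw=0.6)
            ax.set_ylabel(nm, fontsize=8)
        axes[-1, 0].set_xlabel("retained sample")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig
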