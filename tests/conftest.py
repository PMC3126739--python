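import numpy as np
import pytest

from codonctx.model_core import parse_model_name
from codonctx.parameters import ModelParams
from codonctx.phylo_io import PhyloTree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def quartet_tree():
    return PhyloTree.from_newick(
        "((A:0.3,B:0.7):0.2,(C:0.4,D:0.15):0.12);")


@pytest.fixture
def octet_tree():
    return PhyloTree.from_newick(
        "(((A:0.12,B:0.2):0.1,(C:0.15,D:0.25):0.08):0.05,"
        "((E:0.1,F:0.3):0.12,(G:0.2,H:0.1):0.09):0.06);")


def random_params(spec_name, rng, exch_range=(0.3, 3.0), freq_conc=5.0):
    """Random but well-conditioned parameter values for a named model."""
    spec = parse_model_name(spec_name)
    params = ModelParams.default(spec)
    for key in params.exch:
        params.exch[key] = np.concatenate(
            [rng.uniform(*exch_range, 5), [1.0]])
    for key in params.freqs:
        params.freqs[key] = rng.dirichlet(np.full(4, freq_conc))
    for key in params.alphas:
        params.alphas[key] = rng.uniform(0.3, 2.0)
    if params.rate_ratios:
        gw = params.group_weights()
        p = rng.dirichlet(np.full(len(spec.groups), 10.0))
        params.rate_ratios = {g: float(p[i] / gw[g])
                              for i, g in enumerate(spec.groups)}
    if spec.root.n_sets:
        params.root_freqs = rng.dirichlet(np.full(4, freq_conc),
                                          size=spec.root.n_sets)
    return spec, params
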