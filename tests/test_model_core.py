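"""Generators, gamma discretisation, contexts, parameter accounting, naming."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from codonctx.degeneracy import STANDARD_CODE
from codonctx.grantham import AMINO_ACIDS, grantham_distance, grantham_matrix
from codonctx.model_core import (ContextScheme, ContextKind, FrequencySet,
                                 GtrExchangeabilities, GY94Spec,
                                 build_gtr_generator, build_gy94_generator,
                                 context_index, count_free_parameters,
                                 discretize_gamma, parse_model_name,
                                 transition_matrix)

simplex4 = st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4).map(
    lambda v: np.array(v) / np.sum(v))
exch6 = st.lists(st.floats(0.05, 20.0), min_size=5, max_size=5).map(
    lambda v: np.array(list(v) + [1.0]))


class TestGtrGenerator:
    def test_uniform_inputs_give_jukes_cantor(self):
        rm = build_gtr_generator(np.ones(6), np.full(4, 0.25))
        off = rm.Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1 / 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(exch6, simplex4)
    def test_reversibility_and_normalization(self, r, pi):
        rm = build_gtr_generator(r, pi)
        assert np.allclose(rm.Q.sum(axis=1), 0, atol=1e-10)
        assert np.allclose(pi @ rm.Q, 0, atol=1e-10)
        # detailed balance
        F = pi[:, None] * rm.Q
        assert np.allclose(F, F.T, atol=1e-8)
        assert np.isclose(-(pi * np.diag(rm.Q)).sum(), 1.0, atol=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_gtr_generator(np.array([1, 1, -1, 1, 1, 1.0]), np.full(4, 0.25))
        with pytest.raises(ValueError):
            build_gtr_generator(np.ones(6), np.array([0.5, 0.5, 0.2, -0.2]))


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        rm = build_gtr_generator(np.ones(6), np.full(4, 0.25))
        assert np.allclose(transition_matrix(rm, 0.0), np.eye(4))

    def test_jukes_cantor_closed_form(self):
        rm = build_gtr_generator(np.ones(6), np.full(4, 0.25))
        P = transition_matrix(rm, 0.1)
        expected = 0.25 * (1 - np.exp(-4 * 0.1 / 3))
        assert np.allclose(P[~np.eye(4, dtype=bool)], expected, atol=1e-12)
        assert np.allclose(P.sum(axis=1), 1, atol=1e-10)

    def test_long_time_reaches_stationarity(self, rng):
        pi = rng.dirichlet(np.ones(4) * 3)
        rm = build_gtr_generator(rng.uniform(0.2, 3, 6), pi)
        P = transition_matrix(rm, 1e3)
        assert np.allclose(P, np.tile(pi, (4, 1)), atol=1e-6)

    def test_negative_time_rejected(self):
        rm = build_gtr_generator(np.ones(6), np.full(4, 0.25))
        with pytest.raises(ValueError):
            transition_matrix(rm, -0.1)


class TestDiscreteGamma:
    def test_large_shape_collapses_to_unit_rate(self):
        dg = discretize_gamma(1000.0, 4)
        assert np.all(np.abs(dg.category_rates - 1) < 0.05)

    @pytest.mark.parametrize("alpha", [0.05, 0.3, 0.5, 1.0, 7.0, 49.0])
    def test_mean_one_and_monotone(self, alpha):
        dg = discretize_gamma(alpha, 4)
        assert abs(dg.category_rates.mean() - 1) < 1e-10
        assert np.all(np.diff(dg.category_rates) >= 0)

    def test_bin_means_match_quadrature(self):
        alpha, K = 0.5, 4
        edges = np.concatenate([[0.0],
                                gamma_dist.ppf(np.arange(1, K) / K, alpha,
                                               scale=1 / alpha), [np.inf]])
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mass, _ = quad(lambda x: x * gamma_dist.pdf(x, alpha, scale=1 / alpha),
                           lo, min(hi, 400.0))
            expected.append(mass * K)
        dg = discretize_gamma(alpha, K)
        assert np.allclose(dg.category_rates, expected, atol=1e-6)

    @pytest.mark.parametrize("K", [4, 32, 256])
    def test_converges_to_continuous_moments(self, K):
        alpha = 0.8
        dg = discretize_gamma(alpha, K)
        # discrete variance approaches 1/alpha from below as K grows
        var = dg.category_rates.var()
        assert var < 1 / alpha + 1e-9
        if K == 256:
            assert var > 0.95 / alpha

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            discretize_gamma(0.0, 4)


class TestContextIndex:
    def test_at_content_pooling(self):
        cd3 = ContextScheme(ContextKind.CD3)
        assert context_index("G", "C", cd3) == 0
        assert context_index("A", "T", cd3) == 2
        assert context_index("G", "A", cd3) == 1

    def test_sixteen_contexts_are_a_bijection(self):
        cd16 = ContextScheme(ContextKind.CD16)
        seen = {context_index(l, r, cd16) for l in "ACGT" for r in "ACGT"}
        assert seen == set(range(16))
        assert context_index("C", "A", cd16) == 4 * 1 + 0

    def test_ambiguity_signals_unavailable(self):
        with pytest.raises(ValueError):
            context_index("N", "A", ContextScheme(ContextKind.CD16))


class TestParameterCounts:
    @pytest.mark.parametrize("model,component,positions,expected", [
        ("GTR123+CD16", "exchangeabilities", (3,), 80),
        ("GTR123+CD3", "exchangeabilities", (3,), 15),
        ("GTR112", "exchangeabilities", None, 10),
        ("GTR123", "exchangeabilities", None, 15),
        ("GTR16C", "exchangeabilities", None, 80),
        ("GTR", "frequencies", None, 3),
        ("GTR112+F112", "frequencies", None, 6),
        ("GTR123+F123", "frequencies", None, 9),
        ("GTR123+FF3+ROOT0", "root", None, 3),
        ("GTR123+FF3+ROOT1", "root", None, 12),
        ("GTR123+FF3+ROOT2", "root", None, 48),
        ("GTR123+CD16", "exchangeabilities", None, 90),  # 5+5+80
        ("GTR123+FF16", "exchangeabilities", (3,), 85),  # contexts + non-FFD model
    ])
    def test_printed_counts(self, model, component, positions, expected):
        spec = parse_model_name(model)
        assert count_free_parameters(spec, component, positions) == expected

    def test_order2_has_sixteen_sets(self):
        spec = parse_model_name("GTR123+FF16+ROOT2")
        assert spec.root.n_sets == 16

    def test_all_component_sums_everything(self):
        spec = parse_model_name("GTR123+G123+CP123+F123+FF3+ROOT1")
        # exch 5+5+(15+5), freqs 9, gammas 3, ratios 2, root 12
        assert count_free_parameters(spec, "all") == 30 + 9 + 3 + 2 + 12

    def test_gy94_counts(self):
        assert count_free_parameters(parse_model_name("GY94"), "all") == 2
        assert count_free_parameters(parse_model_name("GY94+G"), "all") == 3


@pytest.fixture(scope="module")
def generator():
    spec = GY94Spec(kappa=2.5, V=80.0, codon_freqs=np.full(61, 1 / 61))
    return build_gy94_generator(spec)


class TestGY94:

    def test_has_61_states(self, generator):
        assert generator.n_states == 61
        assert len(set(generator.states)) == 61
        assert not set(STANDARD_CODE.stop_codons) & set(generator.states)

    def test_multi_position_changes_forbidden(self, generator):
        states = generator.states
        for i in range(61):
            for j in range(61):
                ndiff = sum(a != b for a, b in zip(states[i], states[j]))
                if ndiff > 1:
                    assert generator.Q[i, j] == 0.0

    def test_transition_transversion_ratio_is_kappa(self, generator):
        states = list(generator.states)
        # GGA -> GGG is a synonymous transition; GGA -> GGC a synonymous
        # transversion; equal target frequencies, so the rate ratio is kappa.
        i, jt, jv = (states.index(c) for c in ("GGA", "GGG", "GGC"))
        assert np.isclose(generator.Q[i, jt] / generator.Q[i, jv], 2.5)

    def test_detailed_balance(self):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(61) * 5)
        rm = build_gy94_generator(GY94Spec(kappa=3.0, V=50.0, codon_freqs=pi))
        F = pi[:, None] * rm.Q
        assert np.allclose(F, F.T, atol=1e-8)
        assert np.isclose(-(pi * np.diag(rm.Q)).sum(), 1.0, atol=1e-10)

    def test_invalid_scalars_rejected(self):
        with pytest.raises(ValueError):
            GY94Spec(kappa=-1.0, V=80.0, codon_freqs=np.full(61, 1 / 61))
        with pytest.raises(ValueError):
            GY94Spec(kappa=2.0, V=0.0, codon_freqs=np.full(61, 1 / 61))


class TestGrantham:
    def test_symmetric_zero_diagonal(self):
        d = grantham_matrix()
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_published_extremes(self):
        off = grantham_matrix()[~np.eye(20, dtype=bool)]
        assert off.min() == 5.0      # Leu-Ile
        assert off.max() == 215.0    # Cys-Trp
        assert grantham_distance("L", "I") == 5.0
        assert grantham_distance("C", "W") == 215.0
        assert len(AMINO_ACIDS) == 20


class TestModelGrammar:
    @pytest.mark.parametrize("name", [
        "GTR", "GTR+G", "GTR16C", "GTR16C+G", "GY94", "GY94+G",
        "GTR112", "GTR112+G112+CP112+F112+CD3",
        "GTR123+G123+CP123+F123+FF16+ROOT1",
        "GTR123+G123+CP123+F123+FF3+ROOT2",
    ])
    def test_round_trip(self, name):
        assert parse_model_name(name).name == name

    def test_historic_root_alias(self):
        spec = parse_model_name("GTR123+FF3+3F")
        assert spec.root.order.value == "order1"
        assert spec.name == "GTR123+FF3+ROOT1"

    @pytest.mark.parametrize("bad", [
        "GTR16C+CD3", "GTR+CD16", "GTR123+G112", "HKY", "GTR123+XYZ",
        "GY94+CD3", "GTR+F123",
    ])
    def test_invalid_names_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_model_name(bad)


class TestValueTypes:
    def test_frequency_set_invariants(self):
        with pytest.raises(ValueError):
            FrequencySet(0.5, 0.5, 0.5, -0.5)
        with pytest.raises(ValueError):
            FrequencySet(0.3, 0.3, 0.3, 0.3)
        assert np.allclose(FrequencySet(0.1, 0.2, 0.3, 0.4).array.sum(), 1)

    def test_exchangeability_reference_fixed(self):
        with pytest.raises(ValueError):
            GtrExchangeabilities(1, 1, 1, 1, 1, rGT=2.0)
        with pytest.raises(ValueError):
            GtrExchangeabilities(0.0, 1, 1, 1, 1)
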