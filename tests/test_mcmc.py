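"""Prior sampling, Metropolis-within-Gibbs correctness, augmentation Gibbs,
chain mechanics and posterior summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from codonctx.likelihood import AugmentedLikelihood, AugmentedTree
from codonctx.mcmc import (PriorConfig, Sampler, format_estimate,
                           gibbs_update_node, run_chain, sample_prior,
                           summarize_posterior)
from codonctx.model_core import build_gtr_generator, parse_model_name, transition_matrix
from codonctx.phylo_io import CodingAlignment, PhyloTree
from codonctx.simulate import SimulationConfig, simulate_alignment

from conftest import random_params


class TestSamplePrior:
    def test_simplex_blocks_sum_to_one(self, rng):
        spec = parse_model_name("GTR123+G123+CP123+F123+FF16+ROOT2")
        st = sample_prior(spec, PriorConfig(), rng)
        for pi in st.params.freqs.values():
            assert np.isclose(pi.sum(), 1.0)
        assert np.allclose(st.params.root_freqs.sum(axis=1), 1.0)

    def test_alpha_inside_uniform_support(self, rng):
        spec = parse_model_name("GTR+G")
        for _ in range(50):
            st = sample_prior(spec, PriorConfig(), rng)
            assert 0 < st.params.alphas["shared"] < 50

    def test_rate_ratios_average_one(self, rng):
        spec = parse_model_name("GTR123+CP123")
        st = sample_prior(spec, PriorConfig(), rng)
        rr = st.params.rate_ratios
        assert np.isclose((rr["p1"] + rr["p2"] + rr["p3"]) / 3, 1.0, atol=1e-12)


class TestPriorOnlyChains:
    def test_uniform_alpha_prior_recovered(self):
        spec = parse_model_name("GTR+G")
        res = run_chain(spec, None, None, None, n_iter=4000, burn_in=500,
                        thin=1, seed=1)
        assert abs(res.samples["alpha[shared]"].mean() - 25.0) < 2.5
        assert abs(res.samples["piA[shared]"].mean() - 0.25) < 0.02
        assert abs(res.samples["rAC[n]"].mean() - 1.0) < 0.15


class TestConjugateToy:
    def test_dirichlet_multinomial_posterior_mean(self):
        # two identical taxa on zero-length branches: the likelihood is a
        # multinomial in the base frequencies, conjugate to the Dirichlet prior
        spec = parse_model_name("GTR")
        seq = "A" * 30 + "C" * 9 + "G" * 15 + "T" * 6
        aln = CodingAlignment.from_sequences(["A", "B"], [seq, seq])
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
        res = run_chain(spec, None, aln, tree, n_iter=5000, burn_in=1000,
                        thin=1, seed=2)
        counts = np.array([30, 9, 15, 6])
        analytic = (counts + 1) / (counts.sum() + 4)
        for i, b in enumerate("ACGT"):
            s = res.samples[f"pi{b}[shared]"]
            se = s.std() / np.sqrt(len(s) / 20)  # generous autocorrelation
            assert abs(s.mean() - analytic[i]) < max(3 * se, 0.01)


class TestAugmentationGibbs:
    def test_star_tree_conditional_matches_enumeration(self, rng):
        # 3-taxon star, GTR: the central node's per-site conditional is
        # proportional to pi(x) * prod_leaves P[x, leaf]
        spec, params = random_params("GTR", rng)
        tree = PhyloTree.from_newick("(A:0.3,B:0.5,C:0.2);")
        aln = CodingAlignment.from_sequences(["A", "B", "C"],
                                             ["ACG", "CCT", "ACT"])
        aug = AugmentedTree(tree)
        aug.attach_alignment(aln)
        aug.initialize_states(rng)
        eng = AugmentedLikelihood(spec, params, aug)
        rm = build_gtr_generator(params.exch["n"], params.freqs["shared"])
        counts = np.zeros((3, 4))
        n_draws = 8000
        for _ in range(n_draws):
            gibbs_update_node([(eng, 1.0)], 0, rng)
            for s in range(3):
                counts[s, aug.states[0, s]] += 1
        for s in range(3):
            probs = rm.stationary.copy()
            for leaf in (1, 2, 3):
                P = transition_matrix(rm, float(tree.lengths[leaf]))
                probs = probs * P[:, aln.codes[leaf - 1, s]]
            probs /= probs.sum()
            tv = 0.5 * np.abs(counts[s] / n_draws - probs).sum()
            assert tv < 0.03

    def test_context_conditional_matches_enumeration(self, rng):
        # 2-taxon tree under CD16: enumerate the root-sequence posterior
        # exactly and compare with the Gibbs sampler's empirical distribution
        # of one third-position site.
        spec, params = random_params("GTR112+CD16", rng)
        tree = PhyloTree.from_newick("(A:0.4,B:0.6);")
        aln = CodingAlignment.from_sequences(["A", "B"], ["GCAATG", "GTGATG"])
        aug = AugmentedTree(tree)
        aug.attach_alignment(aln)
        aug.initialize_states(rng)
        eng = AugmentedLikelihood(spec, params, aug)
        # exact marginal of site 2 (third position of codon 1) at the root
        weights = np.zeros(4)
        lls = {}
        for seq in itertools.product(range(4), repeat=6):
            aug.states[0] = np.array(seq, dtype=np.int8)
            eng.refresh_edges(range(eng.n_edges))
            lls[seq] = eng.loglik()
        mx = max(lls.values())
        for seq, ll in lls.items():
            weights[seq[2]] += np.exp(ll - mx)
        exact = weights / weights.sum()
        counts = np.zeros(4)
        n_draws = 6000
        for _ in range(n_draws):
            gibbs_update_node([(eng, 1.0)], 0, rng)
            counts[aug.states[0, 2]] += 1
        tv = 0.5 * np.abs(counts / n_draws - exact).sum()
        assert tv < 0.03

    def test_zero_length_pendants_force_parent_states(self, rng):
        spec, params = random_params("GTR", rng)
        tree = PhyloTree.from_newick("(A:0.0,B:0.0,C:0.5);")
        aln = CodingAlignment.from_sequences(["A", "B", "C"],
                                             ["ACG", "ACG", "TTT"])
        aug = AugmentedTree(tree)
        aug.attach_alignment(aln)
        aug.initialize_states(rng)
        eng = AugmentedLikelihood(spec, params, aug)
        for _ in range(20):
            gibbs_update_node([(eng, 1.0)], 0, rng)
            assert aug.states[0].tolist() == aln.codes[0].tolist()

    def test_ambiguous_leaf_sites_are_augmented_without_gaps(self, rng, quartet_tree):
        spec, params = random_params("GTR123+FF3", rng)
        aln = CodingAlignment.from_sequences(
            ["A", "B", "C", "D"],
            ["GCANTG", "GC-ATG", "GCAATG", "GCGATG"])
        res_sampler = Sampler(spec, aln, quartet_tree, PriorConfig())
        res_sampler.init_state(rng)
        for _ in range(5):
            res_sampler.update_parameters(rng)
            res_sampler.resample_augmentation(rng)
        assert np.all(res_sampler.aug.states >= 0)
        # observed leaf entries stay fixed
        assert res_sampler.aug.states[res_sampler.aug.is_leaf.nonzero()[0][0], 0] == aln.codes[0, 0]


class TestChainMechanics:
    def test_identical_seeds_identical_samples(self, rng, quartet_tree):
        spec, params = random_params("GTR123+CD3", rng)
        ds = simulate_alignment(SimulationConfig(spec, params, quartet_tree,
                                                 10, seed=3))
        a = run_chain(spec, None, ds.alignment, quartet_tree, n_iter=40,
                      burn_in=10, thin=1, seed=11)
        b = run_chain(spec, None, ds.alignment, quartet_tree, n_iter=40,
                      burn_in=10, thin=1, seed=11)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_doubled_thinning_halves_retained_samples(self, quartet_tree, rng):
        spec, params = random_params("GTR", rng)
        ds = simulate_alignment(SimulationConfig(spec, params, quartet_tree,
                                                 5, seed=4))
        one = run_chain(spec, None, ds.alignment, quartet_tree, n_iter=120,
                        burn_in=20, thin=1, seed=5)
        two = run_chain(spec, None, ds.alignment, quartet_tree, n_iter=120,
                        burn_in=20, thin=2, seed=5)
        assert len(one.samples) == 2 * len(two.samples)

    def test_taxa_mismatch_rejected_before_sampling(self, quartet_tree):
        spec = parse_model_name("GTR")
        aln = CodingAlignment.from_sequences(["X", "Y"], ["ATG", "ATG"])
        with pytest.raises(ValueError, match="mismatch"):
            run_chain(spec, None, aln, quartet_tree, n_iter=10, burn_in=2,
                      seed=0)

    def test_posterior_joint_calibration_geweke(self):
        # successive-conditional simulator: alternating (simulate data |
        # params) and (MCMC sweep | data) must keep the prior invariant
        spec = parse_model_name("GTR112+G112+CD3")
        prior = PriorConfig()
        tree = PhyloTree.from_newick("((A:0.15,B:0.3):0.1,C:0.2);")
        rng = np.random.default_rng(7)
        params = sample_prior(spec, prior, rng).params
        kept = {"rAC[p12]": [], "piA[shared]": [], "alpha[p12]": []}
        scales = None
        for cycle in range(600):
            ds = simulate_alignment(SimulationConfig(
                spec, params, tree, 6, seed=int(rng.integers(2 ** 31))))
            s = Sampler(spec, ds.alignment, tree, prior)
            if scales is not None:  # carry tuned proposal scales across cycles
                s._scales = scales
            s.aug.states[:] = ds.true_states.states
            s.init_state(rng, params=params)
            for _ in range(3):
                s.update_parameters(rng)
                s.resample_augmentation(rng)
            scales = s._scales
            params = s.params
            f = params.flatten()
            for k in kept:
                kept[k].append(f[k])
        # tolerances sized to the feedback chain's autocorrelation at this
        # cycle count (gross kernel bias shows up far outside these)
        assert abs(np.mean(kept["rAC[p12]"]) - 1.0) < 0.45
        assert abs(np.mean(kept["piA[shared]"]) - 0.25) < 0.11
        assert abs(np.mean(kept["alpha[p12]"]) - 25.0) < 6.0
        # the stationary spread must match the prior's, not collapse
        assert 0.10 < np.std(kept["piA[shared]"]) < 0.30
        assert 9.0 < np.std(kept["alpha[p12]"]) < 20.0


class TestSummaries:
    def test_constant_samples_zero_width(self):
        df = pd.DataFrame({"x": np.full(100, 2.5)})
        tab = summarize_posterior(df)
        assert tab.loc["x", "lower"] == tab.loc["x", "upper"] == 2.5

    def test_uniform_draws_recover_order_statistics(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"u": rng.random(1_000_000)})
        tab = summarize_posterior(df)
        assert abs(tab.loc["u", "lower"] - 0.025) < 0.005
        assert abs(tab.loc["u", "upper"] - 0.975) < 0.005

    def test_bracketed_rendering(self):
        assert format_estimate(0.2396, 0.213, 0.284) == "0.2396[0.21; 0.28]"

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(pd.DataFrame())
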