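"""Pruning vs oracles, augmentation-conditional likelihoods, segmentation,
root distributions."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import logsumexp

from codonctx.likelihood import (AugmentedLikelihood, AugmentedTree,
                                 augmented_loglik, prune_loglik,
                                 root_log_probability, sample_augmentation,
                                 segment_branches)
from codonctx.model_core import build_gtr_generator, parse_model_name
from codonctx.parameters import ModelParams
from codonctx.phylo_io import CodingAlignment, PhyloTree
from codonctx.simulate import SimulationConfig, simulate_alignment

from conftest import random_params


def enumeration_loglik(spec, params, tree, aln, K=4):
    """Independent oracle: per-site exhaustive sum over internal-node states
    using scipy expm directly (no pruning, no eigen caching)."""
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    leaves = [i for i in range(tree.n_nodes) if not tree.children[i]]
    gop = spec.group_of_position
    total = 0.0
    for s in range(aln.n_columns):
        g = gop[s % 3 + 1] if spec.grouping.value != "noncoding" else gop[0]
        rm = build_gtr_generator(params.exch[g], params.group_freqs(g))
        rates = params.group_rate(g) * params.gamma_rates(g, K)
        per_k = []
        for k in range(len(rates)):
            P = {i: expm(rm.Q * rates[k] * tree.lengths[i])
                 for i in range(1, tree.n_nodes)}
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = dict(zip(internal, assign))
                for nd in leaves:
                    st[nd] = aln.row(tree.names[nd])[s]
                if st[0] < 0:
                    continue
                pr = rm.stationary[st[0]]
                for i in range(1, tree.n_nodes):
                    if st[i] < 0:  # missing leaf: marginalise
                        continue
                    pr *= P[i][st[tree.parent[i]], st[i]]
                acc += pr
            per_k.append(acc)
        total += math.log(sum(per_k) / len(per_k))
    return total


class TestPruning:
    def test_matches_exhaustive_enumeration(self, rng, quartet_tree):
        spec, params = random_params("GTR123+G123+CP123+F123", rng)
        ds = simulate_alignment(SimulationConfig(spec, params, quartet_tree,
                                                 2, seed=5))
        got = prune_loglik(spec, params, quartet_tree, ds.alignment)
        want = enumeration_loglik(spec, params, quartet_tree, ds.alignment)
        assert abs(got - want) < 1e-8

    def test_missing_data_marginalised(self, rng, quartet_tree):
        spec, params = random_params("GTR123+F123", rng)
        aln = CodingAlignment.from_sequences(
            ["A", "B", "C", "D"], ["ATGNCA", "AT-GCA", "ATGGCA", "CTGGCA"])
        got = prune_loglik(spec, params, quartet_tree, aln)
        want = enumeration_loglik(spec, params, quartet_tree, aln, K=1)
        assert abs(got - want) < 1e-8

    def test_two_taxa_jukes_cantor_closed_form(self):
        spec = parse_model_name("GTR")
        params = ModelParams.default(spec)
        tree = PhyloTree.from_newick("(A:0.1,B:0.15);")
        aln = CodingAlignment.from_sequences(["A", "B"], ["AAA", "AAC"])
        t = 0.25
        same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        expected = 2 * np.log(0.25 * same) + np.log(0.25 * diff)
        assert abs(prune_loglik(spec, params, tree, aln) - expected) < 1e-10

    def test_identical_taxa_zero_lengths_reduce_to_root_probability(self):
        spec = parse_model_name("GTR")
        params = ModelParams.default(spec)
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
        aln = CodingAlignment.from_sequences(["A", "B"], ["ACG", "ACG"])
        assert np.isclose(prune_loglik(spec, params, tree, aln),
                          3 * np.log(0.25))

    def test_context_models_are_refused(self, quartet_tree):
        spec = parse_model_name("GTR123+CD16")
        params = ModelParams.default(spec)
        aln = CodingAlignment.from_sequences(
            ["A", "B", "C", "D"], ["ATGGCA"] * 4)
        with pytest.raises(ValueError, match="augmented"):
            prune_loglik(spec, params, quartet_tree, aln)

    @pytest.mark.parametrize("root", ["ROOT0", "ROOT1", "ROOT2"])
    def test_root_chain_pruning_matches_augmentation_enumeration(self, rng, root):
        # 2 taxa + root only: sum over all root sequences of the augmented
        # likelihood must equal the pruned likelihood, for every root chain.
        spec, params = random_params(f"GTR123+F123+{root}", rng)
        tree = PhyloTree.from_newick("(A:0.2,B:0.35);")
        ds = simulate_alignment(SimulationConfig(spec, params, tree, 2, seed=8))
        aln = ds.alignment
        aug = AugmentedTree(tree)
        aug.attach_alignment(aln)
        aug.initialize_states(np.random.default_rng(0))
        eng = AugmentedLikelihood(spec, params, aug)
        lls = []
        for seq in itertools.product(range(4), repeat=6):
            aug.states[0] = np.array(seq, dtype=np.int8)
            eng.refresh_edges(range(eng.n_edges))
            lls.append(eng.loglik())
        brute = logsumexp(lls)
        assert abs(brute - prune_loglik(spec, params, tree, aln)) < 1e-8


class TestSegmentation:
    def test_single_segment_at_threshold(self):
        tree = PhyloTree.from_newick("(A:0.005,B:0.004);")
        aug = segment_branches(tree, 0.005)
        assert aug.n_nodes == tree.n_nodes

    def test_ceil_split_into_equal_parts(self):
        tree = PhyloTree.from_newick("(A:0.012,B:0.004);")
        aug = segment_branches(tree, 0.005)
        segs = aug.segment_lengths(1)
        assert len(segs) == 3
        assert np.allclose(segs, 0.004)

    def test_segment_sums_preserved(self, rng, octet_tree):
        aug = segment_branches(octet_tree, 0.005)
        for b in range(1, octet_tree.n_nodes):
            assert abs(aug.segment_lengths(b).sum()
                       - octet_tree.lengths[b]) < 1e-12

    def test_zero_length_branches_kept_whole(self):
        tree = PhyloTree.from_newick("(A:0.0,B:0.01);")
        aug = segment_branches(tree, 0.005)
        assert aug.segments_of_branch[1] == [1]

    def test_chapman_kolmogorov_invariance_context_free(self, rng):
        # with a context-free model, summing the augmented likelihood over
        # the segment-node states must reproduce the unsegmented value
        spec, params = random_params("GTR123+G123+F123", rng)
        tree = PhyloTree.from_newick("(A:0.012,B:0.001);")
        ds = simulate_alignment(SimulationConfig(spec, params, tree, 2, seed=2))
        aln = ds.alignment
        root = np.array([0, 1, 2, 3, 0, 2], dtype=np.int8)

        plain = AugmentedTree(tree)
        plain.attach_alignment(aln)
        plain.initialize_states(rng)
        plain.states[0] = root
        ll_whole = augmented_loglik(spec, params, plain)

        seg = segment_branches(tree, 0.006)  # one extra node on branch A
        seg.attach_alignment(aln)
        seg.initialize_states(rng)
        seg.states[0] = root
        eng = AugmentedLikelihood(spec, params, seg)
        seg_node = tree.n_nodes  # the appended segment node
        lls = []
        for states in itertools.product(range(4), repeat=6):
            seg.states[seg_node] = np.array(states, dtype=np.int8)
            eng.refresh_edges(range(eng.n_edges))
            lls.append(eng.loglik())
        assert abs(logsumexp(lls) - ll_whole) < 1e-8


class TestAugmentedLikelihood:
    def test_conditional_draw_identity_with_pruning(self, rng, quartet_tree):
        # p(a, y) / p(a | y) = p(y) exactly, for every conditional draw
        spec, params = random_params("GTR123+G123+CP123+F123", rng)
        ds = simulate_alignment(SimulationConfig(spec, params, quartet_tree,
                                                 5, seed=4))
        llp = prune_loglik(spec, params, quartet_tree, ds.alignment)
        aug = AugmentedTree(quartet_tree)
        aug.attach_alignment(ds.alignment)
        aug.initialize_states(rng)
        for _ in range(10):
            logq = sample_augmentation(spec, params, aug, rng)
            lla = augmented_loglik(spec, params, aug)
            assert abs(lla - logq - llp) < 1e-8

    def test_prior_draw_importance_average_matches_pruning(self, rng):
        # Monte-Carlo: augmentations from the prior process, weighted by the
        # leaf likelihood, average to the pruned likelihood within 3 SE.
        spec, params = random_params("GTR123+F123", rng, exch_range=(0.5, 2))
        tree = PhyloTree.from_newick("(A:0.08,B:0.12);")
        obs = simulate_alignment(SimulationConfig(spec, params, tree, 2,
                                                  seed=31)).alignment
        llp = prune_loglik(spec, params, tree, obs)
        aug = AugmentedTree(tree)
        aug.attach_alignment(obs)
        aug.initialize_states(rng)
        eng = AugmentedLikelihood(spec, params, aug)
        ratios = []
        for rep in range(1500):
            d = simulate_alignment(SimulationConfig(spec, params, tree, 2,
                                                    seed=50_000 + rep))
            aug.states[0] = d.true_states.states[0]
            eng.refresh_edges(range(eng.n_edges))
            logw = eng.loglik(True) - eng.loglik(False)
            ratios.append(np.exp(logw - llp))
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) < 3 * se

    def test_context_matrix_selected_by_parent_flanking_bases(self, rng):
        # CD16 with one context pinned to near-zero rates: the third position
        # inside that context cannot change; others can.
        spec, params = random_params("GTR123+CD16", rng)
        dead = 4 * 1 + 0  # context (C, A)
        from codonctx.parameters import context_slot_labels
        label = context_slot_labels(spec)[dead]
        assert label == "CA"
        params.exch[f"p3|{label}"] = np.array([1e-9] * 5 + [1.0])
        tree = PhyloTree.from_newick("(A:0.4,B:0.4);")
        # root GC A | A ...: codon1 = GCA, codon2 = ATG -> third of codon 1
        # has left neighbour C and right neighbour A: the dead context
        root = np.array([2, 1, 0, 0, 3, 2], dtype=np.int8)
        aln = CodingAlignment.from_sequences(["A", "B"], ["GCGATG", "GCAATG"])
        aug = AugmentedTree(tree)
        aug.attach_alignment(aln)
        aug.initialize_states(rng)
        aug.states[0] = root
        eng = AugmentedLikelihood(spec, params, aug)
        # taxon A differs at the dead-context site -> vanishing probability
        assert eng.loglik() < -15
        ids = eng.layout.site_ids(root)
        assert ids[2] == eng.layout.ctx_base + dead
        assert ids[5] == eng.layout.group_slot["p3"]  # final codon fallback

    def test_fourfold_gating_uses_parent_prefix(self, rng):
        spec, params = random_params("GTR123+FF16", rng)
        layout_probe = np.array([2, 1, 0, 0, 3, 2, 0, 0, 0], dtype=np.int8)
        # codon1 GCA (prefix GC: four-fold) -> context matrix
        # codon2 ATG (prefix AT: not four-fold) -> independent third-position
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        aln = CodingAlignment.from_sequences(["A", "B"],
                                             ["GCAATGAAA", "GCAATGAAA"])
        aug = AugmentedTree(tree)
        aug.attach_alignment(aln)
        aug.initialize_states(rng)
        aug.states[0] = layout_probe
        eng = AugmentedLikelihood(spec, params, aug)
        ids = eng.layout.site_ids(layout_probe)
        assert ids[2] >= eng.layout.ctx_base
        assert ids[5] == eng.layout.group_slot["p3"]

    def test_zero_lengths_and_leaf_states_reduce_to_root_term(self, rng):
        spec, params = random_params("GTR123+CD3+ROOT0", rng)
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
        aln = CodingAlignment.from_sequences(["A", "B"], ["GCAATG", "GCAATG"])
        aug = AugmentedTree(tree)
        aug.attach_alignment(aln)
        aug.initialize_states(rng)
        aug.states[0] = aln.codes[0]
        ll = augmented_loglik(spec, params, aug)
        assert np.isclose(ll, root_log_probability(spec, params, aln.codes[0]))

    def test_incomplete_states_rejected(self, rng, quartet_tree):
        spec, params = random_params("GTR123+CD3", rng)
        aln = CodingAlignment.from_sequences(["A", "B", "C", "D"],
                                             ["GCAATG"] * 4)
        aug = AugmentedTree(quartet_tree)
        aug.attach_alignment(aln)
        with pytest.raises(ValueError, match="incomplete"):
            augmented_loglik(spec, params, aug)


class TestRootLogProbability:
    def test_order0_uniform_adds_log_quarter_per_third_position(self, rng):
        spec, params = random_params("GTR123+F123+ROOT0", rng)
        params.root_freqs = np.full((1, 4), 0.25)
        seq = rng.integers(0, 4, 12).astype(np.int8)
        base = root_log_probability(spec, params, seq)
        # replace the third-position sets by the stationary model: difference
        # must be exactly n_codons * log(1/4) minus the stationary terms
        gop = spec.group_of_position
        pi3 = params.group_freqs(gop[3])
        manual = sum(np.log(params.group_freqs(gop[p]))[seq[p - 1::3]].sum()
                     for p in (1, 2)) + 4 * np.log(0.25)
        assert np.isclose(base, manual)

    def test_order1_degenerate_set_forbids_other_states(self, rng):
        spec, params = random_params("GTR123+F123+ROOT1", rng)
        params.root_freqs = np.tile(np.array([0.0, 1.0, 0.0, 0.0]), (4, 1))
        ok = np.array([2, 0, 1, 2, 0, 1], dtype=np.int8)   # third = C after A
        bad = np.array([2, 0, 3, 2, 0, 1], dtype=np.int8)  # third = T after A
        assert np.isfinite(root_log_probability(spec, params, ok))
        assert root_log_probability(spec, params, bad) < -600

    def test_order2_matches_direct_lookup_product(self, rng):
        spec, params = random_params("GTR123+F123+ROOT2", rng)
        seq = rng.integers(0, 4, 15).astype(np.int8)  # 5 codons
        got = root_log_probability(spec, params, seq)
        gop = spec.group_of_position
        manual = 0.0
        for c in range(5):
            s1, s2, s3 = 3 * c, 3 * c + 1, 3 * c + 2
            manual += np.log(params.group_freqs(gop[1])[seq[s1]])
            manual += np.log(params.group_freqs(gop[2])[seq[s2]])
            if c < 4:
                row = 4 * seq[s2] + seq[s3 + 1]
                manual += np.log(params.root_freqs[row, seq[s3]])
            else:
                manual += np.log(params.group_freqs(gop[3])[seq[s3]])
        assert np.isclose(got, manual)
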