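"""Reversible models, pruning likelihoods, column rates, indel coding."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from idr_evosig import (
    PhyloTree,
    ReversibleModel,
    ScoredAlignment,
    encode_indel_characters,
    fit_branch_scale_and_site_rates,
    fit_indel_rates,
    fit_reversible_model,
    log10_ratio_matrices,
    rate_matrix,
    region_average_aa_rate,
    sample_meta_alignment,
    sample_tree,
    simulate_msa,
)
from idr_evosig.region_calling import Region
from idr_evosig.subst_models import _encode_patterns, discrete_gamma_rates, pruning_loglik
from idr_evosig.synthetic_data import SimSpec


def toy_model(k=3, seed=0):
    rng = np.random.default_rng(seed)
    S = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    S[iu] = rng.uniform(0.3, 2.0, size=len(iu[0]))
    S = S + S.T
    pi = rng.dirichlet(np.ones(k) * 5)
    return ReversibleModel("ABCD"[:k], pi, S)


class TestRateMatrix:
    def test_uniform_model_symmetric_rates(self):
        k = 4
        S = np.ones((k, k)) - np.eye(k)
        model = ReversibleModel("ABCD", np.full(k, 0.25), S)
        Q = rate_matrix(model)
        off = Q[~np.eye(k, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_detailed_balance_and_normalization(self):
        model = toy_model(4, 1)
        Q = rate_matrix(model)
        pi = model.freqs
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)
        assert -pi @ np.diag(Q) == pytest.approx(1.0, abs=1e-10)

    def test_doubling_one_exchangeability(self):
        model = toy_model(3, 2)
        S2 = model.exchangeabilities.copy()
        S2[0, 1] *= 2
        S2[1, 0] *= 2
        doubled = ReversibleModel(model.states, model.freqs, S2)
        Q1 = rate_matrix(model, normalize=False)
        Q2 = rate_matrix(doubled, normalize=False)
        assert Q2[0, 1] == pytest.approx(2 * Q1[0, 1])
        assert Q2[1, 0] == pytest.approx(2 * Q1[1, 0])


class TestLog10Ratios:
    def test_identical_matrices_zero(self):
        m = np.ones((3, 3))
        assert np.allclose(log10_ratio_matrices(m, m), 0.0)

    def test_factor_ten(self):
        m = np.full((2, 2), 0.3)
        assert np.allclose(log10_ratio_matrices(10 * m, m), 1.0)

    def test_zeros_masked_and_shape_checked(self):
        m = np.array([[1.0, 0.0], [2.0, 3.0]])
        out = log10_ratio_matrices(m, np.ones((2, 2)))
        assert np.isnan(out[0, 1]) and np.isfinite(out[1, 1])
        with pytest.raises(ValueError):
            log10_ratio_matrices(np.ones((2, 2)), np.ones((3, 3)))


class TestPruningOracle:
    @pytest.mark.parametrize("seed", range(4))
    def test_equals_exhaustive_sum(self, seed):
        """Pruning likelihood equals brute-force summation over all internal
        state assignments on 4-tip toys, including under a rate mixture."""
        rng = np.random.default_rng(seed)
        model = toy_model(3, seed)
        model.rate_categories = [(0.5, 0.5), (1.5, 0.5)]
        tree = sample_tree(4, seed + 5)
        species = tree.tip_labels
        rows = ["".join(rng.choice(list(model.states), size=6)) for _ in species]
        patterns, counts, _ = _encode_patterns(rows, model.states)
        ll, _ = pruning_loglik(tree, species, patterns, counts, model, scale=0.8)

        Q = rate_matrix(model)
        internal = [n for n in tree.postorder() if not n.is_tip and n is not tree.root]
        nodes = internal + [tree.root]
        total_ll = 0.0
        for j in range(len(rows[0])):
            obs = {sp: model.states.index(rows[i][j]) for i, sp in enumerate(species)}
            site = 0.0
            for rate, w in model.rate_categories:
                cat = 0.0
                for assignment in itertools.product(range(model.k), repeat=len(nodes)):
                    states = dict(zip(map(id, nodes), assignment))
                    prob = model.freqs[states[id(tree.root)]]
                    for node in tree.postorder():
                        if node is tree.root:
                            continue
                        parent = next(p for p in tree.postorder() if node in p.children)
                        ps = states[id(parent)]
                        cs = obs[node.label] if node.is_tip else states[id(node)]
                        P = expm(Q * node.length * 0.8 * rate) if node.length * rate > 0 else np.eye(model.k)
                        prob *= P[ps, cs]
                    cat += prob
                site += w * cat
            total_ll += np.log(site)
        assert ll == pytest.approx(total_ll, abs=1e-8)


class TestMetaAlignment:
    def _fixture(self):
        aln = ScoredAlignment(
            "a1",
            [f"s{i}" for i in range(1, 7)],
            ["ACDEFG", "ACDEF-", "ACD---", "AC--//"[:4] + "FG", "ACDEFG", "---EFG"],
        )
        region = Region("a1", 0, 6, True)
        return {"a1": aln}, [region]

    def test_half_gap_column_excluded_at_strict_boundary(self):
        alns, regions = self._fixture()
        gap = alns["a1"].gap_matrix()
        fracs = gap.mean(axis=0)
        eligible = int((fracs < 0.5).sum())
        meta = sample_meta_alignment(regions, alns, eligible, 0.5, seed=0)
        assert meta.n_columns == eligible
        with pytest.raises(ValueError, match="eligible"):
            sample_meta_alignment(regions, alns, eligible + 1, 0.5, seed=0)

    def test_gap_fraction_one_accepts_all(self):
        alns, regions = self._fixture()
        meta = sample_meta_alignment(regions, alns, 6, 1.0, seed=1)
        assert meta.n_columns == 6

    def test_deterministic_given_seed(self):
        alns, regions = self._fixture()
        a = sample_meta_alignment(regions, alns, 4, 1.0, seed=3)
        b = sample_meta_alignment(regions, alns, 4, 1.0, seed=3)
        assert a.rows == b.rows


class TestModelFitting:
    def test_identical_sequences_drive_scale_to_zero(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        aln = ScoredAlignment("x", ["A", "B"], ["ABAB" * 10, "ABAB" * 10])
        model, scale, ll = fit_reversible_model(
            aln, tree, n_categories=1, states="AB", n_restarts=1
        )
        assert scale < 1e-4

    def test_binary_divergence_recovery(self):
        """Simulated two-state divergence is recovered within 20%."""
        tree = PhyloTree.from_newick("(A:0.25,B:0.25);")
        spec = SimSpec(
            n_tips=2, msa_length=10000, indel_rate=0.0,
            site_rate_categories=[(1.0, 1.0)], seed=4,
            freqs={"A": 0.6, "B": 0.4},
        )
        aln = simulate_msa(tree, spec)
        model, scale, _ = fit_reversible_model(
            aln, tree, n_categories=1, states="AB", n_restarts=1
        )
        # expected substitutions per column = tree length (mean rate 1)
        assert scale * 0.5 == pytest.approx(0.5, rel=0.2)
        assert model.freqs[0] == pytest.approx(0.6, abs=0.05)

    def test_row_order_invariance(self):
        tree = sample_tree(4, 8)
        spec = SimSpec(n_tips=4, msa_length=400, indel_rate=0.0, seed=8,
                       site_rate_categories=[(1.0, 1.0)], freqs={"A": 0.4, "B": 0.35, "C": 0.25})
        aln = simulate_msa(tree, spec)
        rev = ScoredAlignment("r", aln.species[::-1], aln.rows[::-1])
        m1, s1, ll1 = fit_reversible_model(aln, tree, 1, states="ABC", n_restarts=1)
        m2, s2, ll2 = fit_reversible_model(rev, tree, 1, states="ABC", n_restarts=1)
        assert ll1 == pytest.approx(ll2, abs=1e-3)
        assert s1 == pytest.approx(s2, rel=1e-2)


class TestBranchScaleAndRates:
    def test_identical_sequences(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        aln = ScoredAlignment("x", ["A", "B"], ["ACDEF" * 6, "ACDEF" * 6])
        model = ReversibleModel("ACDEF", np.full(5, 0.2), np.ones((5, 5)) - np.eye(5))
        scale, rates, ll = fit_branch_scale_and_site_rates(aln, model, tree, n_gamma=2)
        assert scale < 1e-4

    def test_fast_column_gets_higher_posterior_rate(self):
        tree = sample_tree(10, 12).scaled_to_depth(0.5)
        spec = SimSpec(
            n_tips=10, msa_length=300, indel_rate=0.0, seed=12,
            site_rate_categories=[(1.0, 1.0)],
        )
        slow = simulate_msa(tree, spec)
        fast_spec = SimSpec(
            n_tips=10, msa_length=30, indel_rate=0.0, seed=13,
            site_rate_categories=[(6.0, 1.0)],
        )
        fast = simulate_msa(tree.scaled_to_depth(0.5), fast_spec)
        rows = [a + b for a, b in zip(slow.rows, fast.rows)]
        aln = ScoredAlignment("x", slow.species, rows)
        freqs = np.full(20, 0.05)
        model = ReversibleModel("ACDEFGHIKLMNPQRSTVWY", freqs, np.ones((20, 20)) - np.eye(20))
        scale, rates, _ = fit_branch_scale_and_site_rates(aln, model, tree, n_gamma=4)
        assert np.nanmean(rates[300:]) > np.nanmean(rates)

    def test_optimum_beats_unit_scale(self):
        tree = sample_tree(6, 14)
        aln = simulate_msa(tree, SimSpec(n_tips=6, msa_length=150, indel_rate=0.0, seed=14))
        freqs = np.full(20, 0.05)
        model = ReversibleModel("ACDEFGHIKLMNPQRSTVWY", freqs, np.ones((20, 20)) - np.eye(20))
        scale, rates, ll = fit_branch_scale_and_site_rates(aln, model, tree, n_gamma=2, use_invariant=False)
        patterns, counts, _ = _encode_patterns(aln.rows, model.states)
        from idr_evosig.subst_models import mixture_categories

        mdl = ReversibleModel(model.states, model.freqs, model.exchangeabilities, mixture_categories(1.0, 2))
        ll_unit, _ = pruning_loglik(tree, aln.species, patterns, counts, mdl, scale=1.0)
        assert ll >= ll_unit - 1e-6


class TestRegionAverage:
    def test_factor_one_is_plain_mean(self):
        rates = np.array([0.5, 1.5, 1.0, 2.0])
        region = Region("a", 0, 4, True)
        assert region_average_aa_rate(rates, 1.0, 3.0, 3.0, region) == pytest.approx(1.25)

    def test_linear_in_factor(self):
        rates = np.ones(10)
        region = Region("a", 0, 10, True)
        assert region_average_aa_rate(rates, 0.5, 1.5, 3.0, region) == pytest.approx(0.5)

    def test_mean_then_scale_equals_scale_then_mean(self):
        rng = np.random.default_rng(0)
        rates = rng.random(50)
        region = Region("a", 10, 40, True)
        a = region_average_aa_rate(rates, 1.0, 2.7, 1.3, region)
        b = (2.7 / 1.3) * np.mean(rates[10:40])
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_reference_length(self):
        with pytest.raises(ValueError):
            region_average_aa_rate(np.ones(5), 1.0, 1.0, 0.0, Region("a", 0, 5, True))


class TestIndelCoding:
    def test_hand_traced_toy(self, toy_gap_alignment):
        chars = encode_indel_characters(toy_gap_alignment)
        assert chars.characters == [(1, 4), (2, 4)]
        coding = {c: chars.coding[:, i].tolist() for i, c in enumerate(chars.characters)}
        assert coding[(2, 4)] == [1, 0, 1]  # row 3's run (1,4) nests (2,4)
        assert coding[(1, 4)] == [0, 0, 1]

    def test_gap_free_alignment(self):
        aln = ScoredAlignment("x", ["a", "b"], ["ACDE", "ACDE"])
        assert encode_indel_characters(aln).characters == []

    def test_shared_gap_structure(self):
        aln = ScoredAlignment("x", ["a", "b", "c"], ["AC--GT"] * 3)
        chars = encode_indel_characters(aln)
        assert chars.characters == [(2, 4)]
        assert chars.coding.tolist() == [[1], [1], [1]]


class TestIndelRates:
    def test_gamma_category_count_rule(self):
        assert len(discrete_gamma_rates(1.0, min(4, max(1, 12 // 5)))) == 2
        assert len(discrete_gamma_rates(1.0, min(4, max(1, 25 // 5)))) == 4
        assert len(discrete_gamma_rates(1.0, min(4, max(1, 4 // 5)))) == 1

    def test_fewer_than_five_characters_rate_zero(self):
        rows = ["AC--GTAC", "ACTTGTAC", "A---GTAC"]
        aln = ScoredAlignment("x", ["s1", "s2", "s3"], rows)
        tree = PhyloTree.from_newick("((s1:1,s2:1):1,s3:2);")
        col_rates, scale, char_rates = fit_indel_rates(encode_indel_characters(aln), tree)
        assert np.all(char_rates == 0.0)
        assert all(v == 0.0 for v in col_rates.values())

    def test_conditional_likelihood_matches_enumeration(self):
        """2-tip toy, one character present in one tip: the ascertainment-
        corrected likelihood equals joint / (1 - P(all-absent))."""
        tree = PhyloTree.from_newick("(A:0.4,B:0.4);")
        pi = np.array([0.7, 0.3])
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        model = ReversibleModel("01", pi, S)
        patterns, counts, _ = _encode_patterns(["1", "0"], "01")
        ll, _ = pruning_loglik(tree, ["A", "B"], patterns, counts, model, scale=1.0, ascertainment="variable")
        Q = rate_matrix(model)
        P = expm(Q * 0.4)
        joint = lambda a, b: sum(pi[z] * P[z, a] * P[z, b] for z in range(2))
        expected = np.log(joint(1, 0) / (1.0 - joint(0, 0)))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_rates_split_onto_start_and_stop_columns(self):
        rng = np.random.default_rng(5)
        tree = sample_tree(8, 15)
        aln = simulate_msa(tree, SimSpec(n_tips=8, msa_length=300, indel_rate=0.3, mean_gap_length=6.0, seed=15))
        chars = encode_indel_characters(aln)
        if len(chars.characters) >= 5:
            col_rates, scale, char_rates = fit_indel_rates(chars, tree)
            total_cols = sum(col_rates.values())
            assert total_cols == pytest.approx(char_rates.sum(), rel=1e-9)
            assert (char_rates >= 0).all()


class TestDivergenceOrdering:
    def test_disorder_partition_faster_than_order(self):
        """Columns simulated at a higher rate must receive higher region
        rates than columns simulated at a lower rate."""
        tree = sample_tree(12, 21).scaled_to_depth(0.4)
        slow = simulate_msa(tree, SimSpec(n_tips=12, msa_length=200, indel_rate=0.0,
                                          site_rate_categories=[(1.0, 1.0)], seed=21))
        fast = simulate_msa(tree.scaled_to_depth(1.6), SimSpec(n_tips=12, msa_length=200, indel_rate=0.0,
                                          site_rate_categories=[(1.0, 1.0)], seed=22))
        rows = [a + b for a, b in zip(slow.rows, fast.rows)]
        aln = ScoredAlignment("x", slow.species, rows)
        freqs = np.full(20, 0.05)
        model = ReversibleModel("ACDEFGHIKLMNPQRSTVWY", freqs, np.ones((20, 20)) - np.eye(20))
        scale, rates, _ = fit_branch_scale_and_site_rates(aln, model, tree, n_gamma=4)
        order_region = Region("x", 0, 200, False)
        disorder_region = Region("x", 200, 400, True)
        ref_len = tree.total_length()
        fitted_len = scale * ref_len
        r_order = region_average_aa_rate(rates, scale, fitted_len, ref_len, order_region)
        r_disorder = region_average_aa_rate(rates, scale, fitted_len, ref_len, disorder_region)
        assert r_disorder > r_order
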