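"""Correlation statistic, bootstrap null, empirical P-values, BH FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import coevonet as cn
from coevonet.coevolution import CandidatePairs, bh_critical_value
from coevonet.errors import CoevonetError, ValidationError


class TestPearson:
    def test_self_correlation(self):
        v = np.array([1.0, 0.0, 2.0, 0.5])
        assert cn.pearson(v, v) == pytest.approx(1.0)
        assert cn.pearson(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_deviations(self):
        assert cn.pearson(np.array([1, 0, 0, 1.0]), np.array([1, 1, 0, 0.0])) == pytest.approx(0.0)

    def test_constant_vector_is_nan_not_zero(self):
        r = cn.pearson(np.ones(4), np.array([1, 0, 1, 0.0]))
        assert math.isnan(r)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        u, v = rng.random(10), rng.random(10)
        assert cn.pearson(u, v) == cn.pearson(v, u)


class TestCandidatePairs:
    def test_strict_threshold(self):
        exch = {"a": 5.0, "b": 5.1, "c": 7.0, "d": 2.0}
        pairs = cn.candidate_pairs(exch, 5.0)
        assert pairs.genes == ["b", "c"]
        assert len(pairs) == 1

    def test_pair_count_is_choose_two(self):
        exch = {f"g{i}": 10.0 for i in range(4)}
        assert len(cn.candidate_pairs(exch, 5.0)) == 6

    def test_count_without_materialization(self):
        # counting is closed-form, so very large gene sets are instant
        pairs = CandidatePairs([f"g{i}" for i in range(100_000)])
        assert len(pairs) == 100_000 * 99_999 // 2

    def test_iteration_yields_canonical_pairs(self):
        pairs = cn.candidate_pairs({"z": 9.0, "a": 9.0, "m": 9.0}, 5.0)
        listed = list(pairs)
        assert listed == [("a", "m"), ("a", "z"), ("m", "z")]


class TestEmpiricalPvalue:
    def test_add_one_rule(self):
        null = np.linspace(-0.9, 0.9, 999)
        assert cn.empirical_pvalue(1.0, null) == pytest.approx(1 / 1000)

    def test_minus_one_gives_one(self):
        null = np.linspace(-0.9, 0.9, 50)
        assert cn.empirical_pvalue(-1.0, null) == pytest.approx(1.0)

    def test_never_zero(self):
        null = np.array([0.0])
        assert cn.empirical_pvalue(0.5, null) > 0

    def test_empty_bin_raises(self):
        with pytest.raises(CoevonetError, match="null"):
            cn.empirical_pvalue(0.5, np.empty(0))


class TestBH:
    def test_step_up_enumeration_example(self):
        res = cn.bh_fdr([0.001, 0.02, 0.03, 0.5], 0.05)
        assert res.reject.tolist() == [True, True, True, False]
        assert res.critical_value == pytest.approx(3 * 0.05 / 4)

    def test_all_ones_rejects_nothing(self):
        res = cn.bh_fdr([1.0, 1.0, 1.0], 0.05)
        assert res.n_rejected == 0
        assert res.critical_value == 0.0

    def test_empty_input(self):
        res = cn.bh_fdr([], 0.05)
        assert res.reject.size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            cn.bh_fdr([0.0, 0.5], 0.05)

    def test_critical_value_arithmetic(self):
        assert bh_critical_value(10, 100, 0.05) == pytest.approx(0.005)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_statsmodels(self, ps, q):
        res = cn.bh_fdr(ps, q)
        reject, qvals, *_ = multipletests(ps, alpha=q, method="fdr_bh")
        assert res.reject.tolist() == reject.tolist()
        assert np.allclose(res.qvalues, qvals)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(1)
        ps = rng.random(200) ** 2
        n_prev = -1
        for q in (0.01, 0.05, 0.1, 0.3):
            n = cn.bh_fdr(ps, q).n_rejected
            assert n >= n_prev
            n_prev = n


@pytest.fixture(scope="module")
def null32(tree32, model_k1):
    return cn.build_null(tree32, model_k1, per_bin=1500, seed=4, max_pairs=25_000)


class TestNullTable:
    def test_reproducible_given_seed(self, tree32, model_k1):
        a = cn.build_null(tree32, model_k1, per_bin=200, seed=4, max_pairs=3_000)
        b = cn.build_null(tree32, model_k1, per_bin=200, seed=4, max_pairs=3_000)
        assert all((x == y).all() for x, y in zip(a.samples, b.samples))

    def test_samples_in_range_and_binned(self, null32):
        for s in null32.samples:
            if s.size:
                assert s.min() >= -1 and s.max() <= 1

    def test_bin_assignment_ties_go_down(self, null32):
        assert null32.bin_of(5.0001) == 0
        assert null32.bin_of(7.5) == 0  # tie at the edge -> lower bin
        assert null32.bin_of(7.5001) == 1
        with pytest.raises(ValidationError):
            null32.bin_of(5.0)

    def test_null_spread_narrows_with_exchangeability(self, null32):
        """Low-exchangeability pairs reach higher correlations by chance."""
        q99 = [
            np.quantile(s, 0.99)
            for s in null32.samples
            if s.size >= 500
        ]
        assert len(q99) >= 2
        assert all(a > b for a, b in zip(q99, q99[1:]))

    def test_shortfall_flagged(self, tree32, model_k1):
        null = cn.build_null(tree32, model_k1, per_bin=500, seed=1, max_pairs=600)
        assert null.shortfall  # tiny budget cannot fill all bins

    def test_save_load_roundtrip(self, null32, tmp_path):
        null32.save(tmp_path / "n.json", tmp_path / "n.tsv")
        again = cn.NullTable.load(tmp_path / "n.json", tmp_path / "n.tsv")
        assert (again.bin_edges == null32.bin_edges).all()
        assert all((a == b).all() for a, b in zip(again.samples, null32.samples))


class TestCoevolutionTest:
    def test_results_schema_and_flags(self, tree32, model_k1, null32):
        sim = cn.simulate_genes(tree32, model_k1, 40, np.random.default_rng(2))
        tab = cn.expected_events(sim.leaf_states, tree32, model_k1)
        res = cn.coevolution_test(tab, null32, fdr=0.05)
        assert set(res.columns) >= {
            "gene_a", "gene_b", "r", "min_exch", "bin", "pvalue", "qvalue", "significant"
        }
        assert ((res["pvalue"] > 0) & (res["pvalue"] <= 1)).all()
        assert ((res["r"] >= -1) & (res["r"] <= 1)).all()
        # significance flag consistent with the BH critical value
        bh = cn.bh_fdr(res["pvalue"].to_numpy(), 0.05)
        assert (res["significant"] == (res["pvalue"] <= max(bh.critical_value, 0))).all()

    def test_min_exchangeability_binning(self, tree32, model_k1, null32):
        sim = cn.simulate_genes(tree32, model_k1, 20, np.random.default_rng(6))
        tab = cn.expected_events(sim.leaf_states, tree32, model_k1)
        res = cn.coevolution_test(tab, null32, fdr=0.05)
        exch = dict(zip(tab.gene_ids, tab.exchangeability))
        for row in res.itertuples():
            assert row.min_exch == pytest.approx(min(exch[row.gene_a], exch[row.gene_b]))
            assert row.bin == null32.bin_of(row.min_exch)

    def test_detects_strongly_coupled_pair(self, tree32, model_k1, null32):
        rng = np.random.default_rng(10)
        rows, names = [], []
        for j in range(3):
            a, b = cn.simulate_coupled_pair(tree32, model_k1, 0.95, rng)
            rows += [a.leaf_states[0], b.leaf_states[0]]
            names += [f"p{j}a", f"p{j}b"]
        sim = cn.simulate_genes(tree32, model_k1, 30, rng)
        X = np.vstack([np.array(rows), sim.leaf_states])
        ids = names + [f"bg{i}" for i in range(30)]
        tab = cn.expected_events(X, tree32, model_k1, gene_ids=ids)
        res = cn.coevolution_test(tab, null32, fdr=0.05)
        top = res.nsmallest(3, "pvalue")
        for row in top.itertuples():
            assert row.gene_a[0] == "p" and row.gene_a[:2] == row.gene_b[:2]
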