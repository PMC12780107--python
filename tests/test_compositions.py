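import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lowbiome as lb


def make_clr(values, taxa=None, samples=None):
    arr = np.asarray(values, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return lb.ClrMatrix(pd.DataFrame(arr, index=taxa, columns=samples))


class TestClr:
    def test_equal_counts_all_zero(self):
        table = lb.CountTable(pd.DataFrame({"s": [7.0, 7.0, 7.0]}, index=list("abc")))
        assert np.allclose(lb.clr_transform(table).data["s"], 0.0)

    def test_two_taxa_hand_value(self):
        table = lb.CountTable(pd.DataFrame({"s": [1.0, 4.0]}, index=["a", "b"]))
        clr = lb.clr_transform(table, 0.05)
        half_gap = (np.log(4.05) - np.log(1.05)) / 2
        assert clr.data["s"].to_numpy() == pytest.approx([-half_gap, half_gap])
        assert half_gap == pytest.approx(0.675, abs=5e-4)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 10_000), min_size=3, max_size=3),
            min_size=2,
            max_size=5,
        )
    )
    def test_columns_sum_to_zero(self, rows):
        table = lb.CountTable(
            pd.DataFrame(
                np.array(rows, dtype=float).T,
                index=["a", "b", "c"],
                columns=[f"s{i}" for i in range(len(rows))],
            )
        )
        clr = lb.clr_transform(table)
        assert np.allclose(clr.data.sum(axis=0), 0.0, atol=1e-9)

    def test_nonpositive_pseudo_count_rejected(self, small_table):
        with pytest.raises(ValueError):
            lb.clr_transform(small_table, 0.0)


class TestPairedDaTest:
    @pytest.fixture
    def paired_clr(self):
        rng = np.random.default_rng(42)
        n = 30
        tumor = rng.normal(0.0, 1.0, size=(4, n))
        tumor[0] += 1.2  # one shifted taxon
        normal = rng.normal(0.0, 1.0, size=(4, n))
        data = np.hstack([tumor, normal])
        samples = [f"P{i}_T" for i in range(n)] + [f"P{i}_N" for i in range(n)]
        clr = make_clr(data, samples=samples)
        pairs = [(f"P{i}_T", f"P{i}_N") for i in range(n)]
        return clr, pairs

    def test_identical_pairs_degenerate_p_one(self):
        vals = np.tile(np.array([[1.0], [2.0]]), (1, 6))
        clr = make_clr(vals, samples=[f"P{i}_{s}" for i in range(3) for s in "TN"])
        pairs = [(f"P{i}_T", f"P{i}_N") for i in range(3)]
        res = lb.paired_da_test(clr, pairs)
        assert (res.table["p"] == 1.0).all()
        assert res.table["degenerate"].all()

    def test_label_swap_flips_t_not_p(self, paired_clr):
        clr, pairs = paired_clr
        forward = lb.paired_da_test(clr, pairs)
        swapped = lb.paired_da_test(clr, [(n, t) for t, n in pairs])
        np.testing.assert_allclose(forward.table["t"], -swapped.table["t"])
        np.testing.assert_allclose(forward.table["p"], swapped.table["p"])

    def test_shifted_taxon_detected(self, paired_clr):
        clr, pairs = paired_clr
        res = lb.paired_da_test(clr, pairs)
        assert res.table["p"].idxmin() == "t0"
        assert res.table.loc["t0", "p_adj"] < 0.01

    def test_too_few_pairs_rejected(self, paired_clr):
        clr, _ = paired_clr
        with pytest.raises(ValueError):
            lb.paired_da_test(clr, [("P0_T", "P0_N"), ("P1_T", "P1_N")])


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        out = lb.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_holm_step_down_hand_example(self):
        out = lb.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "holm")
        assert out == pytest.approx([0.04, 0.06, 0.06, 0.06])

    def test_single_p_unchanged(self):
        for method in ("bh", "holm"):
            assert lb.adjust_pvalues([0.3], method) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lb.adjust_pvalues([0.5, 1.5], "bh")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_holm_dominates_bh_and_both_dominate_raw(self, p):
        bh = lb.adjust_pvalues(p, "bh")
        holm = lb.adjust_pvalues(p, "holm")
        assert (holm >= bh - 1e-12).all()
        assert (bh >= np.asarray(p) - 1e-12).all()
        assert (holm <= 1.0).all() and (bh <= 1.0).all()


class TestMeta:
    def test_equal_weight_pooling(self):
        res = lb.fixed_effect_meta([(1.0, 1.0), (3.0, 1.0)])
        assert res.estimate == pytest.approx(2.0)
        assert res.se == pytest.approx(1 / np.sqrt(2))

    def test_single_input_identity(self):
        res = lb.fixed_effect_meta([(0.7, 0.2)])
        assert res.estimate == 0.7 and res.se == 0.2

    def test_scaling_all_ses_leaves_estimate_unchanged(self):
        a = lb.fixed_effect_meta([(1.0, 0.5), (2.0, 1.0)])
        b = lb.fixed_effect_meta([(1.0, 1.0), (2.0, 2.0)])
        assert a.estimate == pytest.approx(b.estimate)

    def test_pooled_estimate_within_input_range_and_se_shrinks(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            inputs = [(rng.normal(), rng.uniform(0.1, 2)) for _ in range(4)]
            res = lb.fixed_effect_meta(inputs)
            bs = [b for b, _ in inputs]
            assert min(bs) - 1e-12 <= res.estimate <= max(bs) + 1e-12
            assert res.se <= min(s for _, s in inputs)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            lb.fixed_effect_meta([(1.0, 0.0)])


class TestFisher:
    def test_two_half_pvalues(self):
        x2, df, p = lb.fisher_combine([0.5, 0.5])
        assert x2 == pytest.approx(2.7726, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.5966, abs=1e-4)

    def test_single_p_round_trips(self):
        _, _, p = lb.fisher_combine([0.123])
        assert p == pytest.approx(0.123)

    def test_p_equal_one_contributes_nothing(self):
        x2_with, _, _ = lb.fisher_combine([0.2, 1.0])
        x2_without, _, _ = lb.fisher_combine([0.2])
        assert x2_with == pytest.approx(x2_without)

    def test_zero_p_clipped_not_fatal(self):
        x2, df, p = lb.fisher_combine([0.0, 0.5])
        assert np.isfinite(x2) and 0 <= p <= 1

    def test_meta_beta_r2_averages_and_combines(self):
        r2, p = lb.meta_beta_r2([0.2, 0.4], [0.5, 0.5])
        assert r2 == pytest.approx(0.3)
        assert p == pytest.approx(0.5966, abs=1e-4)
        with pytest.raises(ValueError):
            lb.meta_beta_r2([0.2], [0.5, 0.5])


class TestConcordance:
    def test_identical_and_negated_matrices(self):
        rng = np.random.default_rng(0)
        clr_a = make_clr(rng.normal(size=(5, 8)))
        per_taxon, per_sample = lb.platform_concordance(clr_a, clr_a)
        assert np.allclose(per_taxon, 1.0) and np.allclose(per_sample, 1.0)
        clr_b = lb.ClrMatrix(-clr_a.data)
        per_taxon, _ = lb.platform_concordance(clr_a, clr_b)
        assert np.allclose(per_taxon, -1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(1)
        n = 1000
        a = make_clr(rng.normal(size=(3, n)))
        b = lb.ClrMatrix(pd.DataFrame(rng.normal(size=(3, n)),
                                      index=a.taxa, columns=a.samples))
        per_taxon, _ = lb.platform_concordance(a, b)
        assert np.all(np.abs(per_taxon) < 3 / np.sqrt(n) * 3)

    def test_zero_variance_vector_reported_missing(self):
        a = make_clr([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        b = make_clr([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]])
        per_taxon, _ = lb.platform_concordance(a, b)
        assert np.isnan(per_taxon["t0"]) and per_taxon["t1"] == pytest.approx(1.0)

    def test_fewer_than_three_shared_samples_rejected(self):
        a = make_clr([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            lb.platform_concordance(a, a)


class TestCelltypeScores:
    @pytest.fixture
    def expression(self):
        return pd.DataFrame(
            {"s1": [10.0, 30.0, 60.0], "s2": [20.0, 60.0, 120.0]},
            index=["gA", "gB", "gC"],
        )

    def test_single_gene_marker_is_its_logcpm(self, expression):
        scores = lb.celltype_scores(expression, {"T": ["gA"]})
        cpm = 10 / 100 * 1e6
        assert scores.loc["T", "s1"] == pytest.approx(np.log2(cpm + 1))

    def test_median_of_two_markers(self, expression):
        scores = lb.celltype_scores(expression, {"T": ["gA", "gC"]})
        log_cpm = np.log2(expression["s1"] / 100 * 1e6 + 1)
        assert scores.loc["T", "s1"] == pytest.approx(
            np.median([log_cpm["gA"], log_cpm["gC"]])
        )

    def test_library_size_invariance(self, expression):
        scores = lb.celltype_scores(expression, {"T": ["gA", "gB"]})
        assert scores.loc["T", "s1"] == pytest.approx(scores.loc["T", "s2"])

    def test_missing_markers_skipped_empty_set_nan(self, expression):
        scores = lb.celltype_scores(expression, {"T": ["gA", "nope"], "U": ["zzz"]})
        assert np.isfinite(scores.loc["T", "s1"])
        assert scores.loc["U"].isna().all()


class TestDiversityGlm:
    def test_recovers_linear_effect_adjusted_for_site(self):
        rng = np.random.default_rng(6)
        n = 120
        site = rng.choice(["a", "b", "c"], n)
        age = rng.normal(65, 8, n)
        site_effect = pd.Series({"a": 0.0, "b": 0.5, "c": -0.4})
        y = 0.05 * age + site_effect[site].to_numpy() + rng.normal(0, 0.1, n)
        meta = pd.DataFrame({"study_site": site, "age_years": age},
                            index=[f"s{i}" for i in range(n)])
        div = pd.Series(y, index=meta.index)
        out = lb.compositions.diversity_glm(div, meta, "age_years")
        assert out.loc["age_years", "estimate"] == pytest.approx(0.05, abs=0.01)
        assert out.loc["age_years", "p"] < 1e-6
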