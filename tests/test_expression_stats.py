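import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twohit import expression_stats as es


def frame(values, columns, index=None):
    return pd.DataFrame(values, columns=columns,
                        index=index or [f"g{i}" for i in range(len(values))])


class TestTpm:
    def test_equal_counts_equal_lengths(self):
        counts = frame([[10], [10]], ["s.1"])
        lengths = pd.Series({"g0": 1000.0, "g1": 1000.0})
        tpm = es.compute_tpm(counts, lengths)
        assert tpm["s.1"].tolist() == [5e5, 5e5]

    def test_rate_equality(self):
        counts = frame([[100], [300]], ["s.1"])
        lengths = pd.Series({"g0": 1000.0, "g1": 3000.0})
        tpm = es.compute_tpm(counts, lengths)
        assert tpm["s.1"].tolist() == [5e5, 5e5]

    def test_single_gene_is_1e6(self):
        tpm = es.compute_tpm(frame([[7]], ["s.1"]), pd.Series({"g0": 500.0}))
        assert tpm.iloc[0, 0] == 1e6

    def test_columns_sum_to_1e6(self, cohort):
        sums = cohort.tpm.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            es.compute_tpm(frame([[0]], ["s.1"]), pd.Series({"g0": 100.0}))


class TestExpressedFilter:
    cols = ["a.1", "a.2", "a.3", "b.1", "b.2", "b.3"]

    def test_one_sample_with_all_replicates_above(self):
        tpm = frame([[0.3, 0.3, 0.3, 0.0, 0.0, 0.0]], self.cols)
        assert es.filter_expressed(tpm) == ["g0"]

    def test_failing_replicate_in_every_sample(self):
        tpm = frame([[0.3, 0.1, 0.3, 0.3, 0.1, 0.3]], self.cols)
        assert es.filter_expressed(tpm) == []

    def test_boundary_is_strict(self):
        tpm = frame([[0.2, 0.2, 0.2, 0.2, 0.2, 0.2]], self.cols)
        assert es.filter_expressed(tpm) == []


class TestBhFdr:
    def test_step_up_example(self):
        assert es.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert es.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert es.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            es.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_q_at_least_p_and_monotone(self, ps):
        q = es.bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDeTest:
    def test_constant_counts_null(self):
        cols = [f"s{i}.1" for i in range(8)]
        counts = frame([[100] * 8, [40] * 8], cols)
        res = es.de_test(counts, cols[:4], cols[4:])
        assert res["log2fc"].abs().max() < 1e-6
        assert (res["pvalue"] > 0.99).all()

    def test_planted_fourfold_change_detected(self):
        rng = np.random.default_rng(0)
        G, half = 200, 6
        mean = np.full(G, 100.0)
        lfc = np.zeros(G)
        lfc[:20] = 2.0  # 4-fold in the first 20 genes
        npar = 1 / 0.1
        muA = mean * 2.0**lfc
        yA = rng.negative_binomial(npar, npar / (npar + muA[:, None]),
                                   size=(G, half))
        yB = rng.negative_binomial(npar, npar / (npar + mean[:, None]),
                                   size=(G, half))
        cols = [f"s{i}.1" for i in range(2 * half)]
        counts = frame(np.hstack([yA, yB]), cols)
        res = es.de_test(counts, cols[:half], cols[half:])
        hits = res.iloc[:20]
        power = ((hits["fdr"] < 0.05) & (hits["log2fc"] > 0.5)).mean()
        assert power >= 0.9

    def test_non_integer_counts_rejected(self):
        cols = [f"s{i}.1" for i in range(4)]
        counts = frame([[1.5, 2, 3, 4]], cols)
        with pytest.raises(ValueError, match="integers"):
            es.de_test(counts, cols[:2], cols[2:])

    def test_group_size_guard(self):
        cols = [f"s{i}.1" for i in range(3)]
        counts = frame([[1, 2, 3]], cols)
        with pytest.raises(ValueError, match="two columns"):
            es.de_test(counts, cols[:1], cols[1:])


class TestTrioDe:
    def make_counts(self, ratio, n=3, mean=20000):
        # near-deterministic large counts so thresholds, not noise, decide
        rng = np.random.default_rng(1)
        base = rng.poisson(mean, size=(50, 2 * n))
        target = base.copy()
        target[0, :n] = np.round(base[0, :n] * ratio)
        cols = [f"off.{i+1}" for i in range(n)] + [f"par.{i+1}" for i in range(n)]
        return frame(target, cols), cols[:n], cols[n:]

    def test_large_but_subthreshold_fold_change_not_called(self):
        counts, off, par = self.make_counts(2**0.4)
        res = es.trio_de(counts, off, par)
        assert "g0" not in res["de_set"]
        assert res["table"].loc["g0", "fdr"] < 0.05  # significant yet filtered

    def test_suprathreshold_fold_change_called(self):
        counts, off, par = self.make_counts(2**-0.8)
        res = es.trio_de(counts, off, par)
        assert "g0" in res["de_set"]
        assert res["table"].loc["g0", "log2fc"] == pytest.approx(-0.8, abs=0.1)

    def test_low_expression_genes_removed_before_testing(self):
        counts, off, par = self.make_counts(1.0)
        counts.iloc[1] = 0
        counts.iloc[1, 0] = 5  # expressed in 1/6 < 25% of replicates
        res = es.trio_de(counts, off, par)
        assert "g1" not in res["table"].index


class TestGlobalLoo:
    def test_intersection_contained_in_every_iteration(self, pipeline_results):
        loo = pipeline_results["global_de"]
        for de_set in loo["per_iteration"].values():
            assert loo["intersection"] <= de_set

    def test_deletion_genes_recovered_downregulated(self, cohort,
                                                    pipeline_results):
        loo = pipeline_results["global_de"]
        tab = loo["full_table"]
        for g in cohort.deletion_genes:
            assert g in loo["intersection"]
            assert tab.loc[g, "log2fc"] < 0

    def test_too_few_samples_per_group_rejected(self):
        cols = [f"s{i}.1" for i in range(5)]
        counts = frame([[10] * 5], cols)
        meta = pd.DataFrame(
            {"carrier": [True] * 2 + [False] * 3, "family": ["f"] * 5},
            index=[f"s{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="at least three"):
            es.global_de_loo(counts, meta)


class TestOutlierZ:
    def test_boundary_z_exactly_two_not_flagged(self):
        cols = {f"s{i}.{r}": [float(2**v - 1)]
                for i, v in enumerate([1, 1, 1, 1, 9]) for r in (1, 2, 3)}
        tpm = pd.DataFrame(cols, index=["g"])
        zm = es.outlier_zscores(tpm, n_latent=0)
        assert zm.z.loc["g", "s4"] == pytest.approx(2.0)
        assert all(len(s) == 0 for s in zm.outlier_sets().values())

    def test_constant_gene_dropped(self):
        cols = {f"s{i}.1": [5.0, 1.0 * i] for i in range(4)}
        tpm = pd.DataFrame(cols, index=["flat", "varies"])
        zm = es.outlier_zscores(tpm, n_latent=0)
        assert "flat" in zm.dropped_genes
        assert list(zm.z.index) == ["varies"]

    def test_rows_standardised_after_correction(self, pipeline_results):
        z = pipeline_results["zscores"].z
        assert z.mean(axis=1).abs().max() < 1e-6
        assert (z.std(axis=1, ddof=0) - 1).abs().max() < 1e-6

    def test_latent_factor_removes_family_batch(self, cohort):
        # add a rank-1 family batch (one family shifted on every gene) and
        # check the correction equalises per-family outlier counts
        expressed = es.filter_expressed(cohort.tpm)
        tpm = cohort.tpm.loc[expressed].copy()
        fams = {i.sample_id: i.family_id for i in cohort.pedigree}
        batch_cols = [c for c in tpm.columns
                      if fams[c.rsplit(".", 1)[0]] == "F1"]
        tpm[batch_cols] *= 2.0  # +1 on the log2 scale for family F1
        raw = es.outlier_zscores(tpm, n_latent=0)
        corr = es.outlier_zscores(tpm, n_latent=1)

        def f1_excess(zm):
            counts = pd.Series({s: len(g) for s, g in zm.outlier_sets().items()})
            per_fam = counts.groupby(fams).mean()
            return per_fam["F1"] - per_fam.drop("F1").mean()

        assert abs(f1_excess(corr)) < abs(f1_excess(raw))

    def test_planted_outlier_has_extreme_rank(self, cohort):
        t = cohort.truth
        rec = t[(t["kind"] == "outlier") & (t["magnitude"] > 0)].iloc[0]
        cols = [c for c in cohort.tpm.columns]
        med = pd.DataFrame(
            {s: cohort.tpm[[c for c in cols if c.rsplit(".", 1)[0] == s]]
             .median(axis=1) for s in cohort.pedigree.sample_ids}
        )
        assert med.loc[rec["gene"]].idxmax() == rec["sample"]


class TestPage:
    def test_set_mean_equals_global_mean(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.normal(size=2000),
                         index=[f"g{i}" for i in range(2000)])
        # symmetric set: every gene and its negation
        members = set(vals.index)
        tab = es.page_enrichment(vals, {"all": members})
        assert tab.loc["all", "z"] == pytest.approx(0.0, abs=1e-9)
        assert tab.loc["all", "pvalue"] == pytest.approx(1.0)

    def test_z_formula_arithmetic(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.normal(size=500),
                         index=[f"g{i}" for i in range(500)])
        members = set(vals.index[:16])
        tab = es.page_enrichment(vals, {"s": members})
        mu, delta = vals.mean(), vals.std(ddof=1)
        s_m = vals.iloc[:16].mean()
        assert tab.loc["s", "z"] == pytest.approx(
            (s_m - mu) * np.sqrt(16) / delta
        )

    def test_null_sets_uniform_p(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        vals = pd.Series(rng.normal(size=3000),
                         index=[f"g{i}" for i in range(3000)])
        sets = {
            f"s{k}": set(rng.choice(vals.index, 40, replace=False))
            for k in range(200)
        }
        tab = es.page_enrichment(vals, sets)
        assert stats.kstest(tab["pvalue"], "uniform").pvalue > 0.01

    def test_small_sets_skipped_and_zero_variance_rejected(self):
        vals = pd.Series([0.0, 0.0], index=["a", "b"])
        with pytest.raises(ValueError):
            es.page_enrichment(vals, {"s": {"a"}})


class TestPreferentialExpression:
    def test_flat_profile_no_flags(self):
        tab = pd.DataFrame({"t1": [1.0], "t2": [1.0], "t3": [1.0]}, index=["g"])
        assert not es.preferential_expression(tab).any().any()

    def test_strongly_elevated_tissue_flagged(self):
        base = pd.DataFrame(
            {"t1": [0.0], "t2": [0.0], "t3": [0.0], "t4": [0.0], "t5": [10.0]},
            index=["hi"],
        )
        med = base.median(axis=1)
        sd = base.std(axis=1, ddof=1)
        assert base.loc["hi", "t5"] > med["hi"] + 2 * sd["hi"]
        flags = es.preferential_expression(base)
        assert flags.loc["hi"].tolist() == [False, False, False, False, True]

    def test_requires_three_tissues(self):
        with pytest.raises(ValueError):
            es.preferential_expression(pd.DataFrame({"t1": [1], "t2": [2]}))
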