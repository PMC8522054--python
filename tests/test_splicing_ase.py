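from math import comb

import numpy as np
import pandas as pd
import pytest

from twohit import splicing_ase as sa
from twohit.variants import ClassifiedVariant


def exact_two_sided_binomial(a, n):
    """Independent oracle: sum of outcome probabilities <= P(observed)."""
    pmf = [comb(n, k) * 0.5**n for k in range(n + 1)]
    p_obs = pmf[a]
    return sum(p for p in pmf if p <= p_obs * (1 + 1e-12))


class TestBinomialKernel:
    def test_nine_one_split(self):
        assert sa.binomial_ase_pvalue(9, 1) == pytest.approx(22 / 1024)

    def test_balanced_is_one(self):
        assert sa.binomial_ase_pvalue(50, 50) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", range(2, 21))
    def test_matches_exact_enumeration(self, n):
        for a in range(n + 1):
            assert sa.binomial_ase_pvalue(a, n - a) == pytest.approx(
                exact_two_sided_binomial(a, n), rel=1e-9
            )


def hap_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "sample", "hap_a", "hap_b"])


class TestAseTest:
    def test_low_coverage_untested(self):
        counts = hap_frame([("g", "s", 9, 1)])  # total 10, not > 10
        assert sa.ase_test(counts, "s") == []

    def test_balanced_gene_not_called(self):
        counts = hap_frame([("g", "s", 50, 50)])
        assert sa.ase_test(counts, "s") == []

    def test_strong_imbalance_called_with_major_hap(self):
        counts = hap_frame([("g", "s", 170, 30)])
        calls = sa.ase_test(counts, "s")
        assert len(calls) == 1
        assert calls[0].overexpressed_hap == "A"
        assert calls[0].log2_allelic_fc == pytest.approx(np.log2(170 / 30))

    def test_label_swap_flips_sign_only(self):
        fwd = sa.ase_test(hap_frame([("g", "s", 170, 30)]), "s")[0]
        rev = sa.ase_test(hap_frame([("g", "s", 30, 170)]), "s")[0]
        assert fwd.pvalue == rev.pvalue and fwd.fdr == rev.fdr
        assert fwd.log2_allelic_fc == pytest.approx(-rev.log2_allelic_fc)
        assert (fwd.overexpressed_hap, rev.overexpressed_hap) == ("A", "B")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sa.ase_test(hap_frame([("g", "s", -1, 30)]), "s")

    def test_planted_ase_recalled_on_cohort(self, cohort, pipeline_results):
        called = {(c.gene_id, c.sample) for c in pipeline_results["ase"]}
        planted = cohort.truth[cohort.truth["kind"] == "ase"]
        recall = np.mean([
            (t["gene"], t["sample"]) in called for _, t in planted.iterrows()
        ])
        assert recall >= 0.9


class TestCodingHitFlag:
    def make_call(self):
        return sa.ASECall("g", "s", 170, 30, 2.5, 1e-6, 1e-5, "A")

    def test_variant_on_major_haplotype_flagged(self):
        v = ClassifiedVariant("v1", "g", "missense", "s")
        phase = pd.DataFrame([("g", "s", "v1", "A")],
                             columns=["gene_id", "sample", "variant_id",
                                      "haplotype"])
        out = sa.flag_ase_with_coding_hit([self.make_call()], [v], phase)
        assert out[0].deleterious_variant == "v1"

    def test_variant_on_minor_haplotype_not_flagged(self):
        v = ClassifiedVariant("v1", "g", "missense", "s")
        phase = pd.DataFrame([("g", "s", "v1", "B")],
                             columns=["gene_id", "sample", "variant_id",
                                      "haplotype"])
        out = sa.flag_ase_with_coding_hit([self.make_call()], [v], phase)
        assert out[0].deleterious_variant is None

    def test_unphased_variant_warns_and_skips(self):
        v = ClassifiedVariant("v1", "g", "missense", "s")
        phase = pd.DataFrame(columns=["gene_id", "sample", "variant_id",
                                      "haplotype"])
        with pytest.warns(UserWarning, match="unphased"):
            out = sa.flag_ase_with_coding_hit([self.make_call()], [v], phase)
        assert out[0].deleterious_variant is None

    def test_noncoding_class_never_flags(self):
        v = ClassifiedVariant("v1", "g", "intronic_snv", "s")
        phase = pd.DataFrame([("g", "s", "v1", "A")],
                             columns=["gene_id", "sample", "variant_id",
                                      "haplotype"])
        out = sa.flag_ase_with_coding_hit([self.make_call()], [v], phase)
        assert out[0].deleterious_variant is None

    def test_planted_variant_on_major_cases_all_flagged(self, cohort,
                                                        pipeline_results):
        flagged = {(c.gene_id, c.sample)
                   for c in pipeline_results["ase"] if c.deleterious_variant}
        planted = cohort.truth[cohort.truth["kind"] == "ase_with_coding_hit"]
        assert len(planted) > 0
        for _, t in planted.iterrows():
            assert (t["gene"], t["sample"]) in flagged


class TestAltSplicing:
    @staticmethod
    def usage_flip_fixture(flip=True, gene_fold=1.0, seed=0):
        """Gene with conserved totals; isoform usage flips in offspring."""
        rng = np.random.default_rng(seed)
        cols = [f"off.{i}" for i in (1, 2, 3)] + [f"par.{i}" for i in (1, 2, 3)]
        genes, iso_rows = {}, {}
        for g in range(30):
            total = rng.poisson(4000, 6)
            if gene_fold != 1.0 and g == 0:
                total[:3] = np.round(total[:3] * gene_fold).astype(int)
            usage = np.full(6, 0.8)
            if flip and g == 0:
                usage[:3] = 0.2
            iso2 = rng.binomial(total, 1 - usage)
            genes[f"g{g}"] = total
            iso_rows[f"g{g}.iso1"] = total - iso2
            iso_rows[f"g{g}.iso2"] = iso2
        gene_counts = pd.DataFrame.from_dict(genes, orient="index")
        gene_counts.columns = cols
        iso_counts = pd.DataFrame.from_dict(iso_rows, orient="index")
        iso_counts.columns = cols
        gene_map = pd.Series({i: i.rsplit(".", 1)[0] for i in iso_counts.index})
        return gene_counts, iso_counts, gene_map, cols

    def test_usage_flip_called_without_gene_de(self):
        gene_counts, iso, gmap, cols = self.usage_flip_fixture(flip=True)
        calls = sa.alt_splicing(iso, gene_counts, gmap, "off",
                                cols[3:], cols[3:], cols[:3])
        assert {c.gene_id for c in calls} == {"g0"}

    def test_proportional_gene_change_excluded(self):
        gene_counts, iso, gmap, cols = self.usage_flip_fixture(
            flip=False, gene_fold=4.0
        )
        calls = sa.alt_splicing(iso, gene_counts, gmap, "off",
                                cols[3:], cols[3:], cols[:3])
        assert all(c.gene_id != "g0" for c in calls)

    def test_single_isoform_gene_never_callable(self):
        cols = [f"off.{i}" for i in (1, 2, 3)] + [f"par.{i}" for i in (1, 2, 3)]
        counts = pd.DataFrame({c: [1000, 1000] for c in cols},
                              index=["solo", "other"])
        counts.loc["solo", cols[:3]] = 4000
        iso = pd.DataFrame({c: [counts.loc["solo", c], 800, 200] for c in cols},
                           index=["solo.iso1", "other.iso1", "other.iso2"])
        gmap = pd.Series({"solo.iso1": "solo", "other.iso1": "other",
                          "other.iso2": "other"})
        calls = sa.alt_splicing(iso, counts, gmap, "off",
                                cols[3:], cols[3:], cols[:3])
        assert all(c.gene_id != "solo" for c in calls)

    def test_planted_usage_shifts_recalled_on_cohort(self, cohort,
                                                     pipeline_results):
        called = {(c.gene_id, c.offspring_id)
                  for c in pipeline_results["splicing"]}
        planted = cohort.truth[cohort.truth["kind"] == "splice_shift"]
        recall = np.mean([
            (t["gene"], t["sample"]) in called for _, t in planted.iterrows()
        ])
        assert recall >= 0.9
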