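import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twohit.genes import GeneModel
from twohit.pedigree import Individual, Pedigree
from twohit.variant_taxonomy import (
    assign_inheritance,
    call_str_expansions,
    classify_small_variant,
    classify_str,
    classify_sv,
    filter_small_variants,
    merge_cnv_calls,
    reciprocal_overlap,
)
from twohit.variants import (
    ALL_CLASSES,
    ChromatinSegment,
    ClassifiedVariant,
    SmallVariant,
    StrCall,
    SvCall,
)


def make_variant(**kw):
    base = dict(
        contig="chr1", pos=1000, ref="A", alt="T", qual=200.0, depth=30,
        allele_balance=0.5, quality_depth=5.0, gnomad_af=1e-4, cohort_count=1,
        cadd=25.0, consequence="missense", genotypes={"kid": "0/1"},
    )
    base.update(kw)
    return SmallVariant(**base)


PLUS_GENE = GeneModel(
    gene_id="G1", contig="chr1", strand="+", start=10_000, end=19_000,
    exons=[(10_000, 11_000), (14_000, 15_000), (18_000, 19_000)],
    cds=[(10_500, 11_000), (14_000, 15_000), (18_000, 18_500)],
    utr5=[(10_000, 10_500)], utr3=[(18_500, 19_000)],
)


class TestFilters:
    def test_clean_rare_deleterious_variant_kept(self):
        v = make_variant(qual=60.0, depth=10, allele_balance=0.5,
                         gnomad_af=1e-4, cadd=15.0)
        assert filter_small_variants([v]) == [v]

    def test_low_cadd_missense_removed(self):
        v = make_variant(cadd=9.0)
        assert filter_small_variants([v]) == []

    def test_lof_and_splice_exempt_from_cadd(self):
        lof = make_variant(cadd=5.0, consequence="stopgain")
        spl = make_variant(cadd=5.0, consequence="other", splice_flag=True)
        assert filter_small_variants([lof, spl]) == [lof, spl]

    @pytest.mark.parametrize(
        "override",
        [dict(qual=40.0), dict(depth=5), dict(allele_balance=0.1),
         dict(quality_depth=1.0), dict(gnomad_af=0.01), dict(cohort_count=15)],
    )
    def test_quality_and_rarity_failures_removed(self, override):
        assert filter_small_variants([make_variant(**override)]) == []

    def test_homozygous_allele_balance_exception(self):
        v = make_variant(allele_balance=0.95, genotypes={"kid": "1/1"})
        assert filter_small_variants([v]) == [v]

    def test_negative_depth_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_variant(depth=-1)


class TestSnvClassification:
    def test_stopgain_in_cds_is_lof(self):
        v = make_variant(pos=14_100, consequence="stopgain")
        labels = {r.class_label for r in classify_small_variant(v, [PLUS_GENE])}
        assert labels == {"LOF"}

    def test_upstream_variant_in_enhancer_segment(self):
        # 500 bp 5' of the TSS on the + strand inside a state-5 segment
        v = make_variant(pos=9_500, consequence="other")
        seg = ChromatinSegment("chr1", 9_400, 9_600, state=5)
        labels = {r.class_label
                  for r in classify_small_variant(v, [PLUS_GENE], [seg])}
        assert labels == {"upstream_snv", "enhancer_snv"}

    def test_silencer_beyond_50kb_not_labelled(self):
        v = make_variant(pos=10_000 + 60_000 + 1, consequence="other")
        seg = ChromatinSegment("chr1", 69_900, 70_200, state=12)
        gene = GeneModel(gene_id="G2", contig="chr1", strand="-",
                         start=10_000, end=19_000,
                         exons=[(10_000, 19_000)])
        # TSS of the minus-strand gene is at 18_999; 70_001 is > 50 kbp away
        assert classify_small_variant(v, [gene], [seg]) == []

    @pytest.mark.parametrize(
        "pos,expected",
        [(10_100, "UTR5_snv"), (18_700, "UTR3_snv"), (12_000, "intronic_snv"),
         (9_500, "upstream_snv"), (19_400, "downstream_snv")],
    )
    def test_positional_labels_plus_strand(self, pos, expected):
        v = make_variant(pos=pos, consequence="other")
        labels = {r.class_label for r in classify_small_variant(v, [PLUS_GENE])}
        assert labels == {expected}

    def test_variant_outside_contigs_warns_and_empty(self):
        v = make_variant(contig="chrZ")
        with pytest.warns(UserWarning, match="outside all contigs"):
            assert classify_small_variant(v, [PLUS_GENE]) == []


class TestCnvMerging:
    def test_small_gap_merged(self):
        calls = [SvCall("chr1", 0, 100_000, "DEL", "s"),
                 SvCall("chr1", 110_000, 200_000, "DEL", "s")]
        merged = merge_cnv_calls(calls)
        assert [(c.start, c.end) for c in merged] == [(0, 200_000)]

    def test_gap_over_50kb_not_merged(self):
        calls = [SvCall("chr1", 0, 100_000, "DEL", "s"),
                 SvCall("chr1", 160_000, 260_000, "DEL", "s")]
        assert len(merge_cnv_calls(calls)) == 2

    def test_overlapping_always_merged(self):
        calls = [SvCall("chr1", 0, 100_000, "DEL", "s"),
                 SvCall("chr1", 50_000, 150_000, "DEL", "s")]
        merged = merge_cnv_calls(calls)
        assert [(c.start, c.end) for c in merged] == [(0, 150_000)]

    def test_types_never_merge(self):
        calls = [SvCall("chr1", 0, 100_000, "DEL", "s"),
                 SvCall("chr1", 50_000, 150_000, "DUP", "s")]
        assert len(merge_cnv_calls(calls)) == 2


class TestSvClassification:
    @pytest.mark.parametrize(
        "start,end,svtype,expected",
        [(9_000, 21_000, "DUP", "DUP_encapsulating"),
         (8_000, 14_500, "DEL", "DEL_UTR5_overhang"),
         (11_100, 11_200, "DEL", "DEL_interstitial"),
         (14_500, 21_000, "DEL", "DEL_UTR3_overhang")],
    )
    def test_geometry_labels(self, start, end, svtype, expected):
        sv = SvCall("chr1", start, end, svtype, "s")
        recs = classify_sv(sv, [PLUS_GENE])
        assert [r.class_label for r in recs] == [expected]

    def test_minus_strand_overhang_is_strand_aware(self):
        gene = GeneModel(gene_id="G3", contig="chr1", strand="-",
                         start=10_000, end=19_000, exons=[(10_000, 19_000)])
        sv = SvCall("chr1", 14_500, 21_000, "DEL", "s")  # covers the 5' end
        assert [r.class_label for r in classify_sv(sv, [gene])] == [
            "DEL_UTR5_overhang"
        ]


class TestStrExpansions:
    def test_mean_plus_three_sd_threshold(self):
        calls = [StrCall("chr1", 0, 30, "CAG", f"s{i}", 10.0) for i in range(20)]
        calls.append(StrCall("chr1", 0, 30, "CAG", "s20", 30.0))
        flagged = call_str_expansions(calls, n_samples=21)
        assert [f.call.sample for f in flagged] == ["s20"]
        assert flagged[0].threshold == pytest.approx(24.0, abs=0.1)

    def test_zero_variance_locus_dropped(self):
        calls = [StrCall("chr1", 0, 30, "CAG", f"s{i}", 10.0) for i in range(21)]
        assert call_str_expansions(calls, n_samples=21) == []

    def test_low_call_rate_locus_dropped(self):
        calls = [StrCall("chr1", 0, 30, "CAG", f"s{i}", 10.0 + i)
                 for i in range(18)]  # 18/20 = 90% < 95%
        assert call_str_expansions(calls, n_samples=20) == []

    @pytest.mark.parametrize(
        "interval,expected",
        [((14_010, 14_040), "STR_exonic"), ((12_000, 12_030), "STR_intronic"),
         ((10_010, 10_040), "STR_UTR5"), ((18_710, 18_740), "STR_UTR3"),
         ((9_480, 9_510), "STR_upstream"), ((19_480, 19_510), "STR_downstream")],
    )
    def test_str_location_labels(self, interval, expected):
        calls = [StrCall("chr1", interval[0], interval[1], "CAG", f"s{i}", 10.0)
                 for i in range(20)]
        calls.append(StrCall("chr1", interval[0], interval[1], "CAG", "sX", 40.0))
        flagged = call_str_expansions(calls, n_samples=21)
        recs = classify_str(flagged[0], [PLUS_GENE])
        assert [r.class_label for r in recs] == [expected]


class TestInheritance:
    @staticmethod
    def trio():
        ped = Pedigree()
        ped.add(Individual("dad", "f", "0", "0", 1, carrier=True))
        ped.add(Individual("mom", "f", "0", "0", 2, carrier=False))
        ped.add(Individual("kid", "f", "dad", "mom", 1, carrier=True))
        return ped

    def run_snv(self, genotypes):
        v = make_variant(pos=14_100, genotypes=genotypes)
        rec = ClassifiedVariant(v.variant_id, "G1", "missense", "kid")
        out = assign_inheritance([rec], [v], [], [], self.trio())
        return out[0].inheritance

    def test_snv_from_carrier_parent(self):
        assert self.run_snv({"kid": "0/1", "dad": "0/1", "mom": "0/0"}) == (
            "carrier_parent"
        )

    def test_snv_from_noncarrier_parent(self):
        assert self.run_snv({"kid": "0/1", "dad": "0/0", "mom": "0/1"}) == (
            "noncarrier_parent"
        )

    def test_snv_de_novo_and_unresolved(self):
        assert self.run_snv({"kid": "0/1", "dad": "0/0", "mom": "0/0"}) == "de_novo"
        assert self.run_snv({"kid": "0/1", "dad": "0/1", "mom": "0/1"}) == (
            "unresolved"
        )

    def test_sv_exactly_half_overlap_not_inherited(self):
        # child [100,200) vs parent [150,250): reciprocal overlap exactly 0.5
        child = SvCall("chr1", 100, 200, "DEL", "kid")
        parent = SvCall("chr1", 150, 250, "DEL", "dad")
        rec = ClassifiedVariant(child.variant_id, "G1", "DEL_interstitial", "kid",
                                kind="sv")
        out = assign_inheritance([rec], [], [child, parent], [], self.trio())
        assert out[0].inheritance == "de_novo"

    def test_sv_majority_overlap_inherited(self):
        child = SvCall("chr1", 100, 200, "DEL", "kid")
        parent = SvCall("chr1", 120, 210, "DEL", "dad")
        rec = ClassifiedVariant(child.variant_id, "G1", "DEL_interstitial", "kid",
                                kind="sv")
        out = assign_inheritance([rec], [], [child, parent], [], self.trio())
        assert out[0].inheritance == "carrier_parent"

    def test_str_repeat_match(self):
        kid = StrCall("chr1", 0, 30, "CAG", "kid", 30.0)
        mom = StrCall("chr1", 0, 30, "CAG", "mom", 30.0)
        dad = StrCall("chr1", 0, 30, "CAG", "dad", 10.0)
        rec = ClassifiedVariant(kid.variant_id, "G1", "STR_exonic", "kid",
                                kind="str")
        out = assign_inheritance([rec], [], [], [kid, mom, dad], self.trio())
        assert out[0].inheritance == "noncarrier_parent"

    def test_unknown_sample_raises(self):
        rec = ClassifiedVariant("x", "G1", "missense", "ghost")
        with pytest.raises(KeyError):
            assign_inheritance([rec], [], [], [], self.trio())

    @given(
        a=st.tuples(st.integers(0, 500), st.integers(1, 500)),
        b=st.tuples(st.integers(0, 500), st.integers(1, 500)),
    )
    @settings(max_examples=200, deadline=None)
    def test_reciprocal_overlap_symmetric(self, a, b):
        ia = (a[0], a[0] + a[1])
        ib = (b[0], b[0] + b[1])
        assert reciprocal_overlap(ia, ib) == pytest.approx(
            reciprocal_overlap(ib, ia)
        )


class TestTaxonomyInvariants:
    def test_labels_are_the_25_class_enumeration(self, classified):
        assert len(ALL_CLASSES) == 25
        assert {r.class_label for r in classified} <= set(ALL_CLASSES)

    def test_every_planted_triple_recovered(self, cohort, classified):
        emitted = {
            (r.variant_id, r.gene_id, r.class_label, r.sample, r.inheritance)
            for r in classified
        }
        truth = cohort.truth[cohort.truth["kind"] == "variant"]
        for _, t in truth.iterrows():
            assert (
                t["variant_id"], t["gene"], t["class_label"], t["sample"],
                t["inheritance"],
            ) in emitted

    def test_every_decoy_excluded(self, cohort, classified):
        decoys = set(cohort.truth[cohort.truth["kind"] == "decoy"]["variant_id"])
        assert not [r for r in classified if r.variant_id in decoys]

    def test_classification_order_independent(self, cohort):
        from twohit.variant_taxonomy import filter_small_variants

        rev = list(reversed(cohort.small_variants))
        kept_fwd = filter_small_variants(cohort.small_variants)
        kept_rev = filter_small_variants(rev)
        assert {v.variant_id for v in kept_fwd} == {v.variant_id for v in kept_rev}
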