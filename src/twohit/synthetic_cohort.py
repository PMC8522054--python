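"""Fully labelled synthetic CNV-deletion family cohort.

Emulates the study design every downstream stage expects: five
multi-generation families (32 individuals, 19 deletion carriers and 13
noncarriers, three LCL replicates each), a hemizygous seven-gene
deletion region, planted second-hit variants of all 25 taxonomy classes
with Mendelian transmission plus filter-failing decoys,
negative-binomial expression with family / deletion-dosage / cis /
outlier effects, isoform-usage shifts, allelic imbalance, and a gene
interaction network with optional planted proximity between second-hit
genes and dysregulated genes. Every planted effect is recorded in a
truth table for parameter-recovery tests.

The pedigree itself is a fixed template reproducing the cohort's
structural counts (10 carrier children, six discordant parent pairs,
three grandparent couples, four noncarrier siblings; 13 trios with
carrier offspring); the seed drives all downstream randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_stats import compute_tpm
from .genes import GeneModel
from .pedigree import FEMALE, MALE, Individual, Pedigree, replicate_columns
from .variants import (
    ALL_CLASSES,
    CODING_CLASSES,
    ChromatinSegment,
    SmallVariant,
    StrCall,
    SvCall,
)

DELETION_GENES = ["UQCRC2", "PDZD9", "MOSMO", "VWA3A", "EEF2K", "POLR3E", "CDR2"]
DELETION_REGION = ("chr16", 21_950_000, 22_470_000)  # ~520 kbp

DEFAULT_CIS_EFFECTS = {
    # log2 fold change applied in cis to carriers of each planted class;
    # unanchored placeholder effect sizes for power studies
    "LOF": -1.0,
    "missense": -0.7,
    "splice_site": 0.0,  # acts on isoform usage, not gene dosage
    "UTR5_snv": -0.6,
    "UTR3_snv": -0.5,
    "upstream_snv": -0.6,
    "downstream_snv": -0.5,
    "intronic_snv": -0.5,
    "promoter_snv": 0.6,
    "enhancer_snv": 0.6,
    "silencer_snv": -0.6,
    "DEL_encapsulating": -1.0,
    "DEL_interstitial": -0.7,
    "DEL_UTR5_overhang": -0.7,
    "DEL_UTR3_overhang": -0.5,
    "DUP_encapsulating": 0.58,
    "DUP_interstitial": 0.5,
    "DUP_UTR5_overhang": 0.5,
    "DUP_UTR3_overhang": 0.4,
    "STR_exonic": -0.6,
    "STR_intronic": -0.5,
    "STR_UTR5": -0.5,
    "STR_UTR3": -0.4,
    "STR_upstream": -0.5,
    "STR_downstream": -0.4,
}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    replicates_per_sample: int = 3
    n_flanking_genes: int = 13  # non-deleted genes on the deletion contig
    n_variant_genes: int = 100  # pool receiving planted variants (chr1)
    n_effect_genes: int = 100  # pool for outlier/splice/ASE planting (chr2)
    variants_per_class: int = 3
    cis_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CIS_EFFECTS)
    )
    include_decoys: bool = True
    # negative-binomial expression model
    baseline_mean_range: tuple[float, float] = (50.0, 1000.0)
    dispersion_range: tuple[float, float] = (0.02, 0.1)
    family_effect_sd: float = 0.2  # log2-scale SD of shared family shift
    deletion_log2_dosage: float = -1.0  # hemizygous = half dosage
    # downstream deletion-responsive genes: globally DE in carriers so the
    # synergy triple (global DE + outlier + inherited second hit) can occur;
    # the offset skips the coding-class variant genes so their outlier
    # signal stays clean (synergy hits are then mostly non-coding, as in
    # the study cohort)
    n_downstream_genes: int = 24
    downstream_gene_offset: int = 9
    downstream_log2fc: float = 0.6
    outliers_per_individual: int = 1
    outlier_z_shift: float = 4.0
    splice_shifts_per_offspring: int = 1
    splice_shift_usage: float = 0.9  # target-isoform usage in shifted samples
    isoform_baseline_usage: tuple[float, float] = (0.7, 0.3)
    ase_per_individual: int = 1
    ase_shift: float = 0.85
    ase_depth: float = 200.0
    # network
    network_mode: str = "planted"  # planted | null
    n_background_edges: int = 1500
    n_subthreshold_edges: int = 300
    proximity_strength: float = 0.8  # fraction of A x B pairs wired directly
    edge_threshold: float = 2.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.replicates_per_sample < 2:
            raise ValueError("need at least two replicates per sample")
        if self.network_mode not in ("planted", "null"):
            raise ValueError("network_mode must be 'planted' or 'null'")
        if not 0 < self.ase_shift < 1:
            raise ValueError("ase_shift must be in (0, 1)")
        if self.dispersion_range[0] <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class Cohort:
    spec: CohortSpec
    pedigree: Pedigree
    genes: list[GeneModel]
    chromatin_segments: list[ChromatinSegment]
    small_variants: list[SmallVariant]
    sv_calls: list[SvCall]
    str_calls: list[StrCall]
    counts: pd.DataFrame
    tpm: pd.DataFrame
    gene_lengths: pd.Series
    isoform_counts: pd.DataFrame
    isoform_gene_map: pd.Series
    haplotype_counts: pd.DataFrame
    phase: pd.DataFrame
    network_edges: list[tuple[str, str, float]]
    truth: pd.DataFrame

    @property
    def deletion_genes(self) -> list[str]:
        return list(DELETION_GENES)


# --------------------------------------------------------------------------
# pedigree template


def simulate_pedigree(spec: CohortSpec | None = None) -> Pedigree:
    """The default five-family pedigree (deterministic template)."""
    ped = Pedigree()

    def add(sid, fam, father, mother, sex, carrier, role):
        ped.add(Individual(sid, fam, father, mother, sex, carrier, role))

    # family F1: grandparents, two carrier-parent couples, four children
    add("F1_GF", "F1", "0", "0", MALE, True, "grandparent")
    add("F1_GM", "F1", "0", "0", FEMALE, False, "grandparent")
    add("F1_P1", "F1", "F1_GF", "F1_GM", MALE, True, "parent")
    add("F1_S1", "F1", "0", "0", FEMALE, False, "parent")
    add("F1_P2", "F1", "F1_GF", "F1_GM", FEMALE, True, "parent")
    add("F1_S2", "F1", "0", "0", MALE, False, "parent")
    add("F1_C1", "F1", "F1_P1", "F1_S1", MALE, True, "child")
    add("F1_C2", "F1", "F1_P1", "F1_S1", FEMALE, True, "child")
    add("F1_C3", "F1", "F1_S2", "F1_P2", MALE, True, "child")
    add("F1_C4", "F1", "F1_S2", "F1_P2", FEMALE, False, "sibling")
    # family F2: grandparents, one couple, three children
    add("F2_GF", "F2", "0", "0", MALE, True, "grandparent")
    add("F2_GM", "F2", "0", "0", FEMALE, False, "grandparent")
    add("F2_P", "F2", "F2_GF", "F2_GM", FEMALE, True, "parent")
    add("F2_S", "F2", "0", "0", MALE, False, "parent")
    add("F2_C1", "F2", "F2_S", "F2_P", MALE, True, "child")
    add("F2_C2", "F2", "F2_S", "F2_P", FEMALE, True, "child")
    add("F2_C3", "F2", "F2_S", "F2_P", MALE, False, "sibling")
    # family F3: grandparents, one couple, two children
    add("F3_GF", "F3", "0", "0", MALE, True, "grandparent")
    add("F3_GM", "F3", "0", "0", FEMALE, False, "grandparent")
    add("F3_P", "F3", "F3_GF", "F3_GM", MALE, True, "parent")
    add("F3_S", "F3", "0", "0", FEMALE, False, "parent")
    add("F3_C1", "F3", "F3_P", "F3_S", FEMALE, True, "child")
    add("F3_C2", "F3", "F3_P", "F3_S", MALE, False, "sibling")
    # family F4: one couple, two carrier children
    add("F4_P", "F4", "0", "0", MALE, True, "parent")
    add("F4_S", "F4", "0", "0", FEMALE, False, "parent")
    add("F4_C1", "F4", "F4_P", "F4_S", MALE, True, "child")
    add("F4_C2", "F4", "F4_P", "F4_S", FEMALE, True, "child")
    # family F5: one couple, one carrier child with an ungenotyped father
    add("F5_P", "F5", "0", "0", FEMALE, True, "parent")
    add("F5_S", "F5", "0", "0", MALE, False, "parent")
    add("F5_C1", "F5", "F5_S", "F5_P", MALE, True, "child")
    add("F5_C2", "F5", "0", "F5_P", FEMALE, True, "child")
    add("F5_C3", "F5", "F5_S", "F5_P", FEMALE, False, "sibling")

    ped.validate()
    return ped


# --------------------------------------------------------------------------
# gene models


def _make_gene(
    gene_id: str, contig: str, start: int, strand: str,
    pli: float, rvis: float,
) -> GeneModel:
    """Three-exon gene of 9 kbp span with UTRs at the strand-aware ends."""
    span = 9000
    end = start + span
    e1 = (start, start + 1000)
    e2 = (start + 4000, start + 5000)
    e3 = (start + 8000, end)
    if strand == "+":
        utr5 = [(start, start + 500)]
        utr3 = [(end - 500, end)]
        cds = [(start + 500, start + 1000), e2, (start + 8000, end - 500)]
    else:
        utr5 = [(end - 500, end)]
        utr3 = [(start, start + 500)]
        cds = [(start + 500, start + 1000), e2, (start + 8000, end - 500)]
    return GeneModel(
        gene_id=gene_id, contig=contig, strand=strand, start=start, end=end,
        exons=[e1, e2, e3], cds=cds, utr5=utr5, utr3=utr3,
        biotype="protein_coding", pli=pli, rvis_percentile=rvis,
    )


def simulate_genes(spec: CohortSpec, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    # deletion-region genes on chr16
    contig, region_start, _ = DELETION_REGION
    for i, name in enumerate(DELETION_GENES):
        genes.append(
            _make_gene(name, contig, region_start + 10_000 + i * 70_000,
                       "+" if i % 2 == 0 else "-",
                       pli=float(rng.uniform(0, 1)), rvis=float(rng.uniform(0, 100)))
        )
    for i in range(spec.n_flanking_genes):
        genes.append(
            _make_gene(f"FLANK{i + 1:02d}", contig, 20_000_000 + i * 200_000,
                       "+" if i % 2 == 0 else "-",
                       pli=float(rng.uniform(0, 1)), rvis=float(rng.uniform(0, 100)))
        )
    for i in range(spec.n_variant_genes):
        genes.append(
            _make_gene(f"VG{i + 1:03d}", "chr1", 1_000_000 + i * 200_000,
                       "+" if i % 2 == 0 else "-",
                       pli=float(rng.uniform(0, 1)), rvis=float(rng.uniform(0, 100)))
        )
    for i in range(spec.n_effect_genes):
        genes.append(
            _make_gene(f"EG{i + 1:03d}", "chr2", 1_000_000 + i * 200_000,
                       "+" if i % 2 == 0 else "-",
                       pli=float(rng.uniform(0, 1)), rvis=float(rng.uniform(0, 100)))
        )
    return genes


# --------------------------------------------------------------------------
# variant planting


def _snv_position(gene: GeneModel, cls: str) -> tuple[int, str, bool]:
    """(position, consequence annotation, splice flag) for a planted class."""
    mid_cds = gene.cds[1][0] + 50
    intron = gene.start + 2000  # between exon 1 and exon 2
    if cls == "LOF":
        return mid_cds, "stopgain", False
    if cls == "missense":
        return mid_cds, "missense", False
    if cls == "splice_site":
        return intron, "other", True
    if cls == "UTR5_snv":
        return gene.utr5[0][0] + 100, "other", False
    if cls == "UTR3_snv":
        return gene.utr3[0][0] + 100, "other", False
    if cls == "intronic_snv":
        return intron, "other", False
    if cls == "upstream_snv":
        pos = gene.start - 500 if gene.strand == "+" else gene.end + 499
        return pos, "other", False
    if cls == "downstream_snv":
        pos = gene.end + 499 if gene.strand == "+" else gene.start - 500
        return pos, "other", False
    # regulatory classes sit 10 kbp 5' of the TSS, outside the 1-kbp flank
    pos = gene.tss - 10_000 if gene.strand == "+" else gene.tss + 10_000
    return pos, "other", False


_REGULATORY_STATE = {"promoter_snv": 2, "enhancer_snv": 5, "silencer_snv": 12}

SNV_CLASS_LIST = [
    "LOF", "missense", "splice_site", "UTR5_snv", "UTR3_snv",
    "upstream_snv", "downstream_snv", "intronic_snv",
    "promoter_snv", "enhancer_snv", "silencer_snv",
]


def _sv_interval(gene: GeneModel, geom: str) -> tuple[int, int]:
    if geom == "encapsulating":
        return gene.start - 1000, gene.end + 1000
    if geom == "interstitial":
        return gene.start + 1500, gene.start + 3500  # inside intron 1
    five_prime_low = (gene.strand == "+")  # 5' end at low coordinate?
    if geom == "UTR5_overhang":
        if five_prime_low:
            return gene.start - 2000, gene.start + 3000
        return gene.end - 3000, gene.end + 2000
    # UTR3_overhang
    if five_prime_low:
        return gene.end - 3000, gene.end + 2000
    return gene.start - 2000, gene.start + 3000


def _str_interval(gene: GeneModel, loc: str) -> tuple[int, int]:
    if loc == "exonic":
        return gene.cds[1][0] + 10, gene.cds[1][0] + 40
    if loc == "intronic":
        return gene.start + 2000, gene.start + 2030
    if loc == "UTR5":
        return gene.utr5[0][0] + 10, gene.utr5[0][0] + 40
    if loc == "UTR3":
        return gene.utr3[0][0] + 10, gene.utr3[0][0] + 40
    if loc == "upstream":
        s = gene.start - 520 if gene.strand == "+" else gene.end + 480
        return s, s + 30
    s = gene.end + 480 if gene.strand == "+" else gene.start - 520
    return s, s + 30


def simulate_variants(
    pedigree: Pedigree,
    genes: list[GeneModel],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[
    list[SmallVariant], list[SvCall], list[StrCall],
    list[ChromatinSegment], list[dict],
]:
    """Plant one batch of second-hit variants of every class, plus decoys.

    Each planted variant lives in its own gene on the variant-gene
    contig, is carried heterozygously by one carrier child and the
    transmitting parent (alternating noncarrier/carrier parent), and is
    recorded in the truth table with its class and inheritance label.
    """
    children = [
        i.sample_id for i in pedigree
        if i.role == "child" and i.carrier and i.has_both_parents
    ]
    gene_pool = iter([g for g in genes if g.gene_id.startswith("VG")])
    all_samples = pedigree.sample_ids

    small: list[SmallVariant] = []
    svs: list[SvCall] = []
    strs: list[StrCall] = []
    segments: list[ChromatinSegment] = []
    truth: list[dict] = []

    def base_gt(carrier_samples: list[str]) -> dict[str, str]:
        gts = {s: "0/0" for s in all_samples}
        for s in carrier_samples:
            gts[s] = "0/1"
        return gts

    def pick_transmission(i: int, child_id: str) -> tuple[str, str]:
        father, mother = pedigree.parents_of(child_id)
        assert father is not None and mother is not None
        carrier_p = father if father.carrier else mother
        noncarrier_p = mother if father.carrier else father
        if i % 2 == 0:
            return noncarrier_p.sample_id, "noncarrier_parent"
        return carrier_p.sample_id, "carrier_parent"

    def carrier_chain(child_id: str, parent_id: str) -> list[str]:
        """Variant carriers up the pedigree so no planted allele is de novo."""
        chain = [child_id, parent_id]
        cur = parent_id
        while True:
            father, mother = pedigree.parents_of(cur)
            nxt = father or mother
            if nxt is None:
                return chain
            chain.append(nxt.sample_id)
            cur = nxt.sample_id

    planted = 0
    for cls in ALL_CLASSES:
        for i in range(spec.variants_per_class):
            child = children[planted % len(children)]
            parent, inheritance = pick_transmission(i, child)
            carriers = carrier_chain(child, parent)
            gene = next(gene_pool)
            planted += 1
            if cls in SNV_CLASS_LIST:
                pos, csq, spl = _snv_position(gene, cls)
                v = SmallVariant(
                    contig=gene.contig, pos=pos, ref="A", alt="T",
                    qual=float(rng.uniform(100, 500)), depth=int(rng.integers(20, 60)),
                    allele_balance=float(rng.uniform(0.4, 0.6)),
                    quality_depth=float(rng.uniform(2.0, 10.0)),
                    gnomad_af=float(rng.uniform(0, 5e-4)), cohort_count=1,
                    cadd=(5.0 if cls in ("LOF", "splice_site")
                          else float(rng.uniform(15, 35))),
                    consequence=csq, splice_flag=spl,
                    genotypes=base_gt(carriers),
                )
                small.append(v)
                vid = v.variant_id
                if cls in _REGULATORY_STATE:
                    segments.append(
                        ChromatinSegment(gene.contig, pos - 100, pos + 100,
                                         _REGULATORY_STATE[cls])
                    )
            elif cls.startswith(("DEL", "DUP")):
                svtype, geom = cls.split("_", 1)
                s, e = _sv_interval(gene, geom)
                for sample in carriers:
                    svs.append(SvCall(gene.contig, s, e, svtype, sample))
                vid = svs[-1].variant_id
            else:  # STR classes
                loc = cls.split("_", 1)[1]
                s, e = _str_interval(gene, loc)
                expanded = set(carriers)
                for sample in all_samples:
                    strs.append(
                        StrCall(gene.contig, s, e, "CAG", sample,
                                repeat_length=30.0 if sample in expanded else 10.0)
                    )
                vid = f"STR:{gene.contig}:{s}-{e}"
            truth.append(
                dict(kind="variant", effect="classified", gene=gene.gene_id,
                     sample=child, class_label=cls, inheritance=inheritance,
                     transmitting_parent=parent, variant_id=vid,
                     carrier_samples=";".join(carriers),
                     magnitude=spec.cis_effects.get(cls, 0.0))
            )

    if spec.include_decoys:
        decoys = [
            ("low_cadd", dict(cadd=9.0)),
            ("common_af", dict(gnomad_af=0.01)),
            ("low_qual", dict(qual=40.0)),
            ("low_depth", dict(depth=5)),
            ("bad_allele_balance", dict(allele_balance=0.1)),
            ("high_cohort_count", dict(cohort_count=15)),
            ("low_quality_depth", dict(quality_depth=1.0)),
        ]
        for reason, override in decoys:
            child = children[planted % len(children)]
            parent, _ = pick_transmission(0, child)
            gene = next(gene_pool)
            planted += 1
            fields = dict(
                contig=gene.contig, pos=gene.cds[1][0] + 60, ref="G", alt="C",
                qual=200.0, depth=30, allele_balance=0.5, quality_depth=5.0,
                gnomad_af=1e-4, cohort_count=1, cadd=25.0,
                consequence="missense", splice_flag=False,
                genotypes=base_gt([child, parent]),
            )
            fields.update(override)
            v = SmallVariant(**fields)
            small.append(v)
            truth.append(
                dict(kind="decoy", effect=reason, gene=gene.gene_id,
                     sample=child, class_label="missense", inheritance="",
                     transmitting_parent=parent, variant_id=v.variant_id,
                     magnitude=0.0)
            )
        # STR decoy loci: zero variance, and low call rate
        gene = next(gene_pool)
        s, e = gene.start + 2200, gene.start + 2230
        for sample in all_samples:
            strs.append(StrCall(gene.contig, s, e, "CTG", sample, 10.0))
        truth.append(dict(kind="decoy", effect="str_zero_variance",
                          gene=gene.gene_id, sample="", class_label="STR_intronic",
                          inheritance="", transmitting_parent="",
                          variant_id=f"STR:{gene.contig}:{s}-{e}", magnitude=0.0))
        gene = next(gene_pool)
        s, e = gene.start + 2200, gene.start + 2230
        called = all_samples[: int(0.9 * len(all_samples))]
        for j, sample in enumerate(called):
            strs.append(StrCall(gene.contig, s, e, "CTG", sample,
                                40.0 if j == 0 else 10.0))
        truth.append(dict(kind="decoy", effect="str_low_call_rate",
                          gene=gene.gene_id, sample="", class_label="STR_intronic",
                          inheritance="", transmitting_parent="",
                          variant_id=f"STR:{gene.contig}:{s}-{e}", magnitude=0.0))
    return small, svs, strs, segments, truth


# --------------------------------------------------------------------------
# expression


def simulate_expression(
    pedigree: Pedigree,
    genes: list[GeneModel],
    truth: list[dict],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, list[dict]]:
    """Replicate-level NB counts and TPM with all planted effects.

    Log2 mean = baseline + family shift + deletion dosage (carriers,
    deletion genes) + cis shifts of planted variants; outliers are
    injected afterwards as a multiplicative shift of ``z_shift`` times
    the realised cross-individual SD of log2 median TPM.
    """
    samples = pedigree.sample_ids
    cols = replicate_columns(samples, spec.replicates_per_sample)
    gene_ids = [g.gene_id for g in genes]
    lo, hi = spec.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(gene_ids)))
    disp = rng.uniform(*spec.dispersion_range, size=len(gene_ids))
    fam_shift = {
        (f, g): rng.normal(0.0, spec.family_effect_sd)
        for f in pedigree.families
        for g in gene_ids
    }
    cis: dict[tuple[str, str], float] = {}
    for rec in truth:
        if rec["kind"] != "variant" or rec["magnitude"] == 0.0:
            continue
        holders = rec.get("carrier_samples") or ";".join(
            [rec["sample"], rec["transmitting_parent"]]
        )
        for carrier in holders.split(";"):
            key = (rec["gene"], carrier)
            cis[key] = cis.get(key, 0.0) + rec["magnitude"]

    off = spec.downstream_gene_offset
    downstream = {
        f"VG{off + i + 1:03d}": (1.0 if i % 2 == 0 else -1.0)
        * spec.downstream_log2fc
        for i in range(spec.n_downstream_genes)
    }
    downstream = {g: s for g, s in downstream.items() if g in set(gene_ids)}

    gidx = {g: i for i, g in enumerate(gene_ids)}
    log2mu = np.zeros((len(gene_ids), len(cols)))
    for j, col in enumerate(cols):
        sample = col.rsplit(".", 1)[0]
        ind = pedigree[sample]
        for g in gene_ids:
            i = gidx[g]
            shift = fam_shift[(ind.family_id, g)]
            if ind.carrier and g in DELETION_GENES:
                shift += spec.deletion_log2_dosage
            if ind.carrier and g in downstream:
                shift += downstream[g]
            shift += cis.get((g, sample), 0.0)
            log2mu[i, j] = np.log2(baseline[i]) + shift
    depth_factor = rng.uniform(0.9, 1.1, size=len(cols))
    mu = np.power(2.0, log2mu) * depth_factor
    n_param = 1.0 / disp
    counts = rng.negative_binomial(
        n_param[:, None], n_param[:, None] / (n_param[:, None] + mu)
    )
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=cols)

    lengths = pd.Series({g.gene_id: float(g.length) for g in genes})

    # outlier injection relative to realised cross-individual variability
    pre_tpm = compute_tpm(counts_df, lengths)
    med = pd.DataFrame(
        {s: pre_tpm[[c for c in cols if c.rsplit(".", 1)[0] == s]].median(axis=1)
         for s in samples}
    )
    log_med = np.log2(med + 1.0)
    sd = log_med.std(axis=1, ddof=1)
    effect_pool = [g for g in gene_ids if g.startswith("EG")]
    pool_iter = iter(effect_pool)
    new_truth = []
    for k, sample in enumerate(samples):
        for _ in range(spec.outliers_per_individual):
            g = next(pool_iter)
            sign = 1.0 if k % 2 == 0 else -1.0
            shift = sign * spec.outlier_z_shift * max(float(sd[g]), 0.05)
            sel = [c for c in cols if c.rsplit(".", 1)[0] == sample]
            vals = counts_df.loc[g, sel].to_numpy(float) * np.power(2.0, shift)
            counts_df.loc[g, sel] = np.round(vals).astype(int)
            new_truth.append(
                dict(kind="outlier", effect="z_shift", gene=g, sample=sample,
                     class_label="", inheritance="", transmitting_parent="",
                     variant_id="", magnitude=sign * spec.outlier_z_shift)
            )
    for g, s in downstream.items():
        new_truth.append(
            dict(kind="global_de", effect="downstream_of_deletion", gene=g,
                 sample="", class_label="", inheritance="",
                 transmitting_parent="", variant_id="", magnitude=s)
        )
    tpm = compute_tpm(counts_df, lengths)
    return counts_df, tpm, lengths, new_truth


def simulate_isoforms(
    counts: pd.DataFrame,
    pedigree: Pedigree,
    spec: CohortSpec,
    rng: np.random.Generator,
    skip_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, list[dict]]:
    """Two isoforms per gene as a binomial split of the gene counts.

    Planted splice shifts move the usage of isoform 2 to
    ``splice_shift_usage`` for one offspring's replicates (gene totals
    preserved); per-gene totals always sum to the gene counts.
    """
    if abs(sum(spec.isoform_baseline_usage) - 1.0) > 1e-9:
        raise ValueError("isoform usage proportions must sum to 1")
    skip = skip_genes or set()
    offspring = [
        i.sample_id for i in pedigree
        if i.role == "child" and i.carrier and i.has_both_parents
    ]
    pool = [g for g in counts.index if g.startswith("EG") and g not in skip]
    pool_iter = iter(pool)
    shift_plan: dict[tuple[str, str], float] = {}
    truth = []
    for off in offspring:
        for _ in range(spec.splice_shifts_per_offspring):
            g = next(pool_iter)
            shift_plan[(g, off)] = spec.splice_shift_usage
            truth.append(
                dict(kind="splice_shift", effect="usage", gene=g, sample=off,
                     class_label="", inheritance="", transmitting_parent="",
                     variant_id="", magnitude=spec.splice_shift_usage)
            )
    iso_rows = {}
    p2_base = spec.isoform_baseline_usage[1]
    for g in counts.index:
        row = counts.loc[g].to_numpy(int)
        p2 = np.full(len(row), p2_base)
        for j, col in enumerate(counts.columns):
            sample = col.rsplit(".", 1)[0]
            if (g, sample) in shift_plan:
                p2[j] = shift_plan[(g, sample)]
        iso2 = rng.binomial(row, p2)
        iso_rows[f"{g}.iso1"] = row - iso2
        iso_rows[f"{g}.iso2"] = iso2
    iso_counts = pd.DataFrame.from_dict(iso_rows, orient="index")
    iso_counts.columns = counts.columns
    gene_map = pd.Series(
        {iso: iso.rsplit(".", 1)[0] for iso in iso_counts.index}
    )
    return iso_counts, gene_map, truth


def simulate_haplotype_counts(
    pedigree: Pedigree,
    genes: list[GeneModel],
    truth: list[dict],
    spec: CohortSpec,
    rng: np.random.Generator,
    skip_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Per-(gene, individual) haplotype read counts plus variant phase.

    Null genes split reads binomial(n, 0.5); planted ASE genes use
    ``ase_shift`` on haplotype A. Planted coding variants of the
    missense class additionally get an ASE gene with the variant phased
    onto the overexpressed haplotype.
    """
    skip = skip_genes or set()
    samples = pedigree.sample_ids
    pool = [g.gene_id for g in genes if g.gene_id.startswith("EG")
            and g.gene_id not in skip]
    pool_iter = iter(pool)
    plan: dict[tuple[str, str], float] = {}  # (gene, sample) -> P(hap A)
    phase_rows = []
    new_truth = []
    for k, sample in enumerate(samples):
        for _ in range(spec.ase_per_individual):
            g = next(pool_iter)
            plan[(g, sample)] = spec.ase_shift
            new_truth.append(
                dict(kind="ase", effect="allelic_fraction", gene=g, sample=sample,
                     class_label="", inheritance="", transmitting_parent="",
                     variant_id="", magnitude=spec.ase_shift)
            )
    # deleterious coding variant on the overexpressed haplotype
    for rec in truth:
        if rec["kind"] == "variant" and rec["class_label"] == "missense":
            key = (rec["gene"], rec["sample"])
            plan[key] = spec.ase_shift
            phase_rows.append(
                dict(gene_id=rec["gene"], sample=rec["sample"],
                     variant_id=rec["variant_id"], haplotype="A")
            )
            new_truth.append(
                dict(kind="ase_with_coding_hit", effect="variant_on_major",
                     gene=rec["gene"], sample=rec["sample"],
                     class_label=rec["class_label"],
                     inheritance=rec["inheritance"],
                     transmitting_parent=rec["transmitting_parent"],
                     variant_id=rec["variant_id"], magnitude=spec.ase_shift)
            )
    tested_genes = sorted(
        {g for g, _ in plan} | set(pool[: 2 * len(samples)])
    )
    rows = []
    for g in tested_genes:
        for sample in samples:
            n = int(rng.poisson(spec.ase_depth))
            p = plan.get((g, sample), 0.5)
            a = int(rng.binomial(n, p)) if n > 0 else 0
            rows.append(dict(gene_id=g, sample=sample, hap_a=a, hap_b=n - a))
    hap = pd.DataFrame(rows)
    phase = pd.DataFrame(
        phase_rows, columns=["gene_id", "sample", "variant_id", "haplotype"]
    )
    return hap, phase, new_truth


# --------------------------------------------------------------------------
# network


def second_hit_gene_sets(truth: pd.DataFrame) -> dict[str, set[str]]:
    """Per-child sets of genes with planted coding second hits."""
    sub = truth[(truth["kind"] == "variant")
                & truth["class_label"].isin(CODING_CLASSES)]
    return {
        s: set(sub[sub["sample"] == s]["gene"]) for s in sub["sample"].unique()
    }


def expression_change_gene_sets(truth: pd.DataFrame) -> dict[str, set[str]]:
    """Per-individual genes with any planted expression change + deletion genes."""
    out: dict[str, set[str]] = {}
    for _, r in truth.iterrows():
        if r["kind"] in ("variant", "outlier", "ase", "splice_shift") and r["sample"]:
            if r["kind"] == "variant" and r["magnitude"] == 0.0:
                continue
            out.setdefault(r["sample"], set()).add(r["gene"])
    return out


def simulate_network(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> list[tuple[str, str, float]]:
    """Weighted edge list; in planted mode second-hit genes are wired
    close to expression-changed genes, in null mode wiring ignores labels."""
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    edges: dict[tuple[str, str], float] = {}

    def add_edge(u: str, v: str, prob: float) -> None:
        if u == v:
            return
        key = (u, v) if u < v else (v, u)
        edges[key] = max(edges.get(key, 0.0), prob)

    for _ in range(spec.n_background_edges):
        i, j = rng.integers(0, n, size=2)
        add_edge(gene_ids[i], gene_ids[j],
                 float(rng.uniform(spec.edge_threshold + 0.05, 4.0)))
    for _ in range(spec.n_subthreshold_edges):
        i, j = rng.integers(0, n, size=2)
        add_edge(gene_ids[i], gene_ids[j], float(rng.uniform(0.5, spec.edge_threshold)))
    if spec.network_mode == "planted":
        hits = second_hit_gene_sets(truth)
        changes = expression_change_gene_sets(truth)
        for sample, a_genes in hits.items():
            b_genes = changes.get(sample, set())
            for a in sorted(a_genes):
                for b in sorted(b_genes):
                    if a != b and rng.random() < spec.proximity_strength:
                        add_edge(a, b, float(rng.uniform(3.2, 4.0)))
    return [(u, v, p) for (u, v), p in sorted(edges.items())]


# --------------------------------------------------------------------------
# orchestration


def simulate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Generate the complete labelled cohort for one seed."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    pedigree = simulate_pedigree(spec)
    genes = simulate_genes(spec, rng)
    small, svs, strs, segments, truth = simulate_variants(pedigree, genes, spec, rng)
    counts, tpm, lengths, t_out = simulate_expression(
        pedigree, genes, truth, spec, rng
    )
    truth += t_out
    outlier_genes = {r["gene"] for r in t_out}
    iso_counts, iso_map, t_spl = simulate_isoforms(
        counts, pedigree, spec, rng, skip_genes=outlier_genes
    )
    truth += t_spl
    used = outlier_genes | {r["gene"] for r in t_spl}
    hap, phase, t_ase = simulate_haplotype_counts(
        pedigree, genes, truth, spec, rng, skip_genes=used
    )
    truth += t_ase
    truth_df = pd.DataFrame(truth)
    network = simulate_network(genes, truth_df, spec, rng)
    return Cohort(
        spec=spec, pedigree=pedigree, genes=genes, chromatin_segments=segments,
        small_variants=small, sv_calls=svs, str_calls=strs,
        counts=counts, tpm=tpm, gene_lengths=lengths,
        isoform_counts=iso_counts, isoform_gene_map=iso_map,
        haplotype_counts=hap, phase=phase, network_edges=network,
        truth=truth_df,
    )
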