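"""Rare-variant filtering, 25-class classification, and inheritance.

Small variants pass quality (QUAL > 50, depth > 8, allele balance in
[0.25, 0.75] or > 0.9 for homozygotes, quality-depth >= 1.5) and rarity
(gnomAD AF <= 0.001, in-house panel < 10 carriers) filters, plus a CADD
Phred >= 10 cutoff from which loss-of-function and splice-site variants
are exempt. Each surviving variant is classified per overlapped gene
into genic labels (LOF / missense / splice_site / UTR / intronic /
1-kbp upstream / 1-kbp downstream) and, within 50 kbp of a TSS, into
regulatory labels from ChromHMM segments (states 1-3 promoter, 4-7
enhancer, 12 silencer). SVs get gene-geometry labels (encapsulating /
interstitial / UTR-overhang, crossed with DEL/DUP), and STR expansions
(repeat length > cohort mean + 3 SD at a well-called locus) get
location labels. Inheritance is resolved against parental genotypes,
>50% reciprocal SV overlap, or exact STR repeat-length matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import mean, stdev

from .genes import GeneModel, genes_by_contig
from .pedigree import Pedigree
from .variants import (
    ChromatinSegment,
    ClassifiedVariant,
    SmallVariant,
    StrCall,
    SvCall,
)

PROMOTER_STATES = frozenset({1, 2, 3})
ENHANCER_STATES = frozenset({4, 5, 6, 7})
SILENCER_STATES = frozenset({12})


@dataclass
class FilterConfig:
    min_qual: float = 50.0
    min_depth: int = 8
    ab_lo: float = 0.25
    ab_hi: float = 0.75
    ab_hom: float = 0.9
    min_quality_depth: float = 1.5  # variants with QD below this are removed
    max_gnomad_af: float = 0.001
    max_cohort_count: int = 10  # keep if present in < this many panel samples
    min_cadd: float = 10.0
    drop_missing: bool = True  # variants with missing quality fields are dropped
    flank_bp: int = 1000  # upstream/downstream window around TSS/TES
    regulatory_window_bp: int = 50_000  # chromatin-state labels within this of a TSS
    str_call_rate: float = 0.95
    str_sd_multiplier: float = 3.0
    str_inheritance_tolerance: float = 0.0
    sv_reciprocal_overlap: float = 0.5


def _cadd_exempt(v: SmallVariant) -> bool:
    return v.consequence in ("stopgain", "frameshift") or v.splice_flag


def filter_small_variants(
    variants: list[SmallVariant], config: FilterConfig | None = None
) -> list[SmallVariant]:
    """Quality + rarity + deleteriousness filter for SNVs and indels."""
    cfg = config or FilterConfig()
    kept = []
    for v in variants:
        if v.qual is None or v.depth is None:
            if cfg.drop_missing:
                continue
        if not v.qual > cfg.min_qual:
            continue
        if not v.depth > cfg.min_depth:
            continue
        hom = any(g in ("1/1", "1|1") for g in v.genotypes.values())
        ab_ok = cfg.ab_lo <= v.allele_balance <= cfg.ab_hi or (
            hom and v.allele_balance > cfg.ab_hom
        )
        if not ab_ok:
            continue
        if v.quality_depth < cfg.min_quality_depth:
            continue
        if not v.gnomad_af <= cfg.max_gnomad_af:
            continue
        if not v.cohort_count < cfg.max_cohort_count:
            continue
        if not _cadd_exempt(v) and not v.cadd >= cfg.min_cadd:
            continue
        kept.append(v)
    return kept


def classify_small_variant(
    variant: SmallVariant,
    gene_models: list[GeneModel],
    chromatin_segments: list[ChromatinSegment] | None = None,
    config: FilterConfig | None = None,
) -> list[ClassifiedVariant]:
    """Class labels for one filtered variant; may span genes and labels."""
    cfg = config or FilterConfig()
    by_contig = genes_by_contig(gene_models)
    if variant.contig not in by_contig:
        warnings.warn(
            f"variant {variant.variant_id} outside all contigs in gene models"
        )
        return []
    pos = variant.pos
    out: list[tuple[str, str]] = []  # (gene_id, label)
    for g in by_contig[variant.contig]:
        label = _genic_label(variant, g, pos, cfg)
        if label is not None:
            out.append((g.gene_id, label))
        # regulatory labels: chromatin segment within 50 kbp of this TSS
        if chromatin_segments and abs(pos - g.tss) <= cfg.regulatory_window_bp:
            for seg in chromatin_segments:
                if not seg.contains(variant.contig, pos):
                    continue
                if seg.state in PROMOTER_STATES:
                    out.append((g.gene_id, "promoter_snv"))
                elif seg.state in ENHANCER_STATES:
                    out.append((g.gene_id, "enhancer_snv"))
                elif seg.state in SILENCER_STATES:
                    out.append((g.gene_id, "silencer_snv"))
    records = []
    seen = set()
    for gene_id, label in out:
        key = (gene_id, label)
        if key in seen:
            continue
        seen.add(key)
        for sample in variant.genotypes:
            if variant.carries_alt(sample):
                records.append(
                    ClassifiedVariant(
                        variant_id=variant.variant_id,
                        gene_id=gene_id,
                        class_label=label,
                        sample=sample,
                        kind="snv",
                    )
                )
    return records


def _genic_label(
    variant: SmallVariant, g: GeneModel, pos: int, cfg: FilterConfig
) -> str | None:
    if g.contains(pos):
        if variant.splice_flag:
            return "splice_site"
        if variant.consequence in ("stopgain", "frameshift") and g.in_intervals(
            pos, g.cds
        ):
            return "LOF"
        if variant.consequence == "missense" and g.in_intervals(pos, g.cds):
            return "missense"
        if g.in_intervals(pos, g.utr5):
            return "UTR5_snv"
        if g.in_intervals(pos, g.utr3):
            return "UTR3_snv"
        if not g.in_intervals(pos, g.exons):
            return "intronic_snv"
        return None
    # flanking windows are strand-aware and inclusive of the boundary base
    if g.strand == "+":
        if g.tss - cfg.flank_bp <= pos < g.start:
            return "upstream_snv"
        if g.end <= pos <= g.tes + cfg.flank_bp:
            return "downstream_snv"
    else:
        if g.end <= pos <= g.tss + cfg.flank_bp:
            return "upstream_snv"
        if g.tes - cfg.flank_bp <= pos < g.start:
            return "downstream_snv"
    return None


def merge_cnv_calls(
    calls: list[SvCall],
    max_gap_fraction: float = 0.2,
    max_gap_bp: int = 50_000,
) -> list[SvCall]:
    """Merge adjacent same-type calls per sample.

    Two calls merge when they overlap, or when the gap between them is
    both < ``max_gap_fraction`` of the (larger) CNV length and
    < ``max_gap_bp``. Merging is transitive; the merged interval is the
    union span.
    """
    groups: dict[tuple[str, str, str], list[SvCall]] = {}
    for c in calls:
        groups.setdefault((c.contig, c.svtype, c.sample), []).append(c)
    merged: list[SvCall] = []
    for (contig, svtype, sample), group in groups.items():
        group = sorted(group, key=lambda c: (c.start, c.end))
        cur_start, cur_end = group[0].start, group[0].end
        for c in group[1:]:
            gap = c.start - cur_end
            ref_len = max(cur_end - cur_start, c.length)
            if gap <= 0 or (gap < max_gap_fraction * ref_len and gap < max_gap_bp):
                cur_end = max(cur_end, c.end)
            else:
                merged.append(SvCall(contig, cur_start, cur_end, svtype, sample))
                cur_start, cur_end = c.start, c.end
        merged.append(SvCall(contig, cur_start, cur_end, svtype, sample))
    return merged


def classify_sv(sv: SvCall, gene_models: list[GeneModel]) -> list[ClassifiedVariant]:
    """Gene-geometry labels for one SV call."""
    out = []
    for g in gene_models:
        if g.contig != sv.contig or sv.end <= g.start or sv.start >= g.end:
            continue
        if sv.start <= g.start and sv.end >= g.end:
            geom = "encapsulating"
        elif sv.start >= g.start and sv.end <= g.end:
            geom = "interstitial"
        else:
            covers_5p = sv.start <= g.tss < sv.end
            geom = "UTR5_overhang" if covers_5p else "UTR3_overhang"
        out.append(
            ClassifiedVariant(
                variant_id=sv.variant_id,
                gene_id=g.gene_id,
                class_label=f"{sv.svtype}_{geom}",
                sample=sv.sample,
                kind="sv",
            )
        )
    return out


@dataclass
class StrExpansion:
    call: StrCall
    locus_mean: float
    locus_sd: float

    @property
    def threshold(self) -> float:
        return self.locus_mean + 3.0 * self.locus_sd


def call_str_expansions(
    calls: list[StrCall],
    n_samples: int,
    config: FilterConfig | None = None,
) -> list[StrExpansion]:
    """Flag repeat-length expansions per locus across the cohort.

    A locus is usable when called in > 95% of samples with nonzero
    length variance; an expansion is any call whose repeat length
    exceeds the locus mean + 3 sample SDs (one call per individual).
    """
    cfg = config or FilterConfig()
    loci: dict[tuple[str, int, int], list[StrCall]] = {}
    for c in calls:
        loci.setdefault(c.locus, []).append(c)
    out = []
    for locus_calls in loci.values():
        # one call per individual at a locus
        per_sample: dict[str, StrCall] = {}
        for c in locus_calls:
            per_sample.setdefault(c.sample, c)
        if len(per_sample) <= cfg.str_call_rate * n_samples:
            continue
        lengths = [c.repeat_length for c in per_sample.values()]
        if len(lengths) < 2:
            continue
        sd = stdev(lengths)
        if sd == 0.0:
            continue  # zero variance locus
        mu = mean(lengths)
        thr = mu + cfg.str_sd_multiplier * sd
        for c in per_sample.values():
            if c.repeat_length > thr:
                out.append(StrExpansion(call=c, locus_mean=mu, locus_sd=sd))
    return out


def classify_str(
    expansion: StrExpansion,
    gene_models: list[GeneModel],
    config: FilterConfig | None = None,
) -> list[ClassifiedVariant]:
    """Location label for a flagged STR expansion, per overlapped gene."""
    cfg = config or FilterConfig()
    c = expansion.call
    out = []
    for g in gene_models:
        if g.contig != c.contig or g.biotype != "protein_coding":
            continue
        label = None
        overlaps = c.end > g.start and c.start < g.end
        if overlaps:
            if _intervals_overlap(c.start, c.end, g.utr5):
                label = "STR_UTR5"
            elif _intervals_overlap(c.start, c.end, g.utr3):
                label = "STR_UTR3"
            elif _intervals_overlap(c.start, c.end, g.exons):
                label = "STR_exonic"
            else:
                label = "STR_intronic"
        else:
            mid = (c.start + c.end) // 2
            if g.strand == "+":
                if g.tss - cfg.flank_bp <= mid < g.start:
                    label = "STR_upstream"
                elif g.end <= mid <= g.tes + cfg.flank_bp:
                    label = "STR_downstream"
            else:
                if g.end <= mid <= g.tss + cfg.flank_bp:
                    label = "STR_upstream"
                elif g.tes - cfg.flank_bp <= mid < g.start:
                    label = "STR_downstream"
        if label is not None:
            out.append(
                ClassifiedVariant(
                    variant_id=c.variant_id,
                    gene_id=g.gene_id,
                    class_label=label,
                    sample=c.sample,
                    kind="str",
                )
            )
    return out


def _intervals_overlap(s: int, e: int, intervals: list[tuple[int, int]]) -> bool:
    return any(e > a and s < b for a, b in intervals)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len_a, overlap/len_b); symmetric in a and b."""
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if ov == 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _parent_label(parent_carrier: bool) -> str:
    return "carrier_parent" if parent_carrier else "noncarrier_parent"


def assign_inheritance(
    records: list[ClassifiedVariant],
    small_variants: list[SmallVariant],
    sv_calls: list[SvCall],
    str_calls: list[StrCall],
    pedigree: Pedigree,
    config: FilterConfig | None = None,
) -> list[ClassifiedVariant]:
    """Resolve inheritance of each child record against the parents.

    SNVs: inherited from whichever parent carries the alternate allele
    (both parents -> unresolved, neither -> de novo). SVs: inherited when
    a same-type parental call has > 50% reciprocal overlap. STRs:
    inherited when the child's repeat length matches a parental call at
    the same locus (within a configurable tolerance). Records of samples
    without two genotyped parents stay unresolved.
    """
    cfg = config or FilterConfig()
    snv_by_id = {v.variant_id: v for v in small_variants}
    sv_by_sample: dict[str, list[SvCall]] = {}
    for c in sv_calls:
        sv_by_sample.setdefault(c.sample, []).append(c)
    # ids repeat across samples at a shared locus, so key by (id, sample)
    sv_by_id = {(c.variant_id, c.sample): c for c in sv_calls}
    str_by_sample: dict[str, dict[tuple[str, int, int], StrCall]] = {}
    for c in str_calls:
        str_by_sample.setdefault(c.sample, {})[c.locus] = c
    str_by_id = {(c.variant_id, c.sample): c for c in str_calls}

    out = []
    for rec in records:
        if rec.sample not in pedigree:
            raise KeyError(f"sample {rec.sample} absent from pedigree")
        father, mother = pedigree.parents_of(rec.sample)
        if father is None or mother is None:
            out.append(_with_inheritance(rec, "unresolved"))
            continue
        if rec.kind == "snv":
            v = snv_by_id.get(rec.variant_id)
            if v is None:
                out.append(_with_inheritance(rec, "unresolved"))
                continue
            in_f = v.carries_alt(father.sample_id)
            in_m = v.carries_alt(mother.sample_id)
            if in_f and in_m:
                label = "unresolved"
            elif in_f:
                label = _parent_label(father.carrier)
            elif in_m:
                label = _parent_label(mother.carrier)
            else:
                label = "de_novo"
        elif rec.kind == "sv":
            child_sv = sv_by_id.get((rec.variant_id, rec.sample))
            label = "de_novo"
            if child_sv is None:
                label = "unresolved"
            else:
                matches = []
                for parent in (father, mother):
                    for pc in sv_by_sample.get(parent.sample_id, []):
                        if (
                            pc.contig == child_sv.contig
                            and pc.svtype == child_sv.svtype
                            and reciprocal_overlap(
                                (child_sv.start, child_sv.end), (pc.start, pc.end)
                            )
                            > cfg.sv_reciprocal_overlap
                        ):
                            matches.append(parent)
                            break
                if len(matches) == 2:
                    label = "unresolved"
                elif len(matches) == 1:
                    label = _parent_label(matches[0].carrier)
        else:  # str
            child_str = str_by_id.get((rec.variant_id, rec.sample))
            label = "de_novo"
            if child_str is None:
                label = "unresolved"
            else:
                matches = []
                for parent in (father, mother):
                    pc = str_by_sample.get(parent.sample_id, {}).get(child_str.locus)
                    if pc is not None and abs(
                        pc.repeat_length - child_str.repeat_length
                    ) <= cfg.str_inheritance_tolerance:
                        matches.append(parent)
                if len(matches) == 2:
                    label = "unresolved"
                elif len(matches) == 1:
                    label = _parent_label(matches[0].carrier)
        out.append(_with_inheritance(rec, label))
    return out


def _with_inheritance(rec: ClassifiedVariant, label: str) -> ClassifiedVariant:
    return ClassifiedVariant(
        variant_id=rec.variant_id,
        gene_id=rec.gene_id,
        class_label=rec.class_label,
        sample=rec.sample,
        inheritance=label,
        kind=rec.kind,
    )
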