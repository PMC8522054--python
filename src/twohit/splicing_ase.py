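"""Alternative splicing and allele-specific expression calls.

A splicing call is a differentially expressed isoform inside a gene
that shows no gene-level differential expression for the same
offspring-parent comparison, so that pure usage shifts are separated
from dosage changes. ASE is a two-sided exact binomial test of the two
haplotype read counts per gene and individual (total > 10 reads),
BH-corrected within the individual; ASE events whose overexpressed
haplotype carries a rare deleterious coding variant are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_stats import DEFAULT_FDR, bh_fdr, trio_de
from .family_patterns import PatternCall, classify_pattern
from .variants import CODING_CLASSES, ClassifiedVariant


@dataclass
class SplicingCall:
    isoform_id: str
    gene_id: str
    offspring_id: str
    pattern: str
    novel_isoform: bool = False


@dataclass
class ASECall:
    gene_id: str
    sample: str
    hap_a: int
    hap_b: int
    log2_allelic_fc: float
    pvalue: float
    fdr: float
    overexpressed_hap: str  # "A" or "B"
    deleterious_variant: str | None = None


def _splicing_sets(
    isoform_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
    isoform_gene_map: pd.Series,
    offspring_cols: list[str],
    parent_cols: list[str],
    fdr_threshold: float,
    min_total_count: int,
) -> set[str]:
    """Isoforms DE against one parent whose gene shows no gene-level DE."""
    iso = isoform_counts[isoform_counts.sum(axis=1) > min_total_count]
    genes = isoform_gene_map.reindex(iso.index)
    multi = genes.map(genes.value_counts()) > 1
    iso = iso[multi.values]  # single-isoform genes are never callable
    iso_de = trio_de(iso, offspring_cols, parent_cols, lfc_threshold=0.0,
                     fdr_threshold=fdr_threshold)
    gene_de = trio_de(gene_counts, offspring_cols, parent_cols, lfc_threshold=0.0,
                      fdr_threshold=fdr_threshold)
    out = set()
    for isoform in iso_de["de_set"]:
        gene = isoform_gene_map.get(isoform)
        if gene is not None and gene not in gene_de["de_set"]:
            out.add(isoform)
    return out


def alt_splicing(
    isoform_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
    isoform_gene_map: pd.Series,
    offspring_id: str,
    carrier_parent_cols: list[str],
    noncarrier_parent_cols: list[str],
    offspring_cols: list[str],
    fdr_threshold: float = DEFAULT_FDR,
    min_total_count: int = 2,
    reference_isoforms: set[str] | None = None,
) -> list[SplicingCall]:
    """Splicing calls for one offspring with family-specific patterns."""
    vs_carrier = _splicing_sets(
        isoform_counts, gene_counts, isoform_gene_map, offspring_cols,
        carrier_parent_cols, fdr_threshold, min_total_count,
    )
    vs_noncarrier = _splicing_sets(
        isoform_counts, gene_counts, isoform_gene_map, offspring_cols,
        noncarrier_parent_cols, fdr_threshold, min_total_count,
    )
    patterns = classify_pattern(vs_carrier, vs_noncarrier, offspring_id, "splicing")
    calls = []
    for p in patterns:
        calls.append(
            SplicingCall(
                isoform_id=p.gene_id,  # pattern keys are isoform ids here
                gene_id=str(isoform_gene_map.get(p.gene_id, "")),
                offspring_id=offspring_id,
                pattern=p.pattern,
                novel_isoform=(
                    reference_isoforms is not None
                    and p.gene_id not in reference_isoforms
                ),
            )
        )
    return calls


def splicing_pattern_calls(calls: list[SplicingCall]) -> list[PatternCall]:
    """Collapse isoform-level calls to gene-level pattern records."""
    seen = set()
    out = []
    for c in calls:
        key = (c.gene_id, c.offspring_id, c.pattern)
        if key in seen:
            continue
        seen.add(key)
        out.append(PatternCall(c.gene_id, c.offspring_id, "splicing", c.pattern))
    return out


def binomial_ase_pvalue(hap_a: int, hap_b: int) -> float:
    """Two-sided exact binomial p at rate 0.5 (minimum-likelihood method)."""
    return float(stats.binomtest(hap_a, hap_a + hap_b, 0.5).pvalue)


def ase_test(
    haplotype_counts: pd.DataFrame,
    sample: str,
    min_total: int = 10,
    fdr_threshold: float = DEFAULT_FDR,
) -> list[ASECall]:
    """ASE calls for one individual.

    ``haplotype_counts`` has columns gene_id, sample, hap_a, hap_b.
    Genes with total reads > ``min_total`` are tested; BH correction is
    applied across the individual's tested genes and ASE is called at
    FDR < 0.05.
    """
    sub = haplotype_counts[haplotype_counts["sample"] == sample]
    rows = []
    for _, r in sub.iterrows():
        a, b = int(r["hap_a"]), int(r["hap_b"])
        if a < 0 or b < 0:
            raise ValueError("negative haplotype count")
        if a + b <= min_total:
            continue
        p = binomial_ase_pvalue(a, b)
        lfc = np.log2((a + 0.5) / (b + 0.5)) if (a == 0 or b == 0) else np.log2(a / b)
        rows.append((str(r["gene_id"]), a, b, lfc, p))
    if not rows:
        return []
    fdrs = bh_fdr([r[4] for r in rows])
    calls = []
    for (gene, a, b, lfc, p), q in zip(rows, fdrs):
        if q < fdr_threshold:
            calls.append(
                ASECall(
                    gene_id=gene,
                    sample=sample,
                    hap_a=a,
                    hap_b=b,
                    log2_allelic_fc=lfc,
                    pvalue=p,
                    fdr=float(q),
                    overexpressed_hap="A" if a >= b else "B",
                )
            )
    return calls


def flag_ase_with_coding_hit(
    ase_calls: list[ASECall],
    classified_variants: list[ClassifiedVariant],
    phase: pd.DataFrame,
    coding_classes: tuple[str, ...] = ("LOF", "missense", "splice_site"),
) -> list[ASECall]:
    """Flag ASE events with a deleterious coding variant on the major haplotype.

    ``phase`` has columns gene_id, sample, variant_id, haplotype ("A"/"B").
    Unphased variants never flag (with a warning).
    """
    by_unit: dict[tuple[str, str], list[ClassifiedVariant]] = {}
    for v in classified_variants:
        if v.class_label in coding_classes:
            by_unit.setdefault((v.gene_id, v.sample), []).append(v)
    phase_map: dict[tuple[str, str, str], str] = {}
    for _, r in phase.iterrows():
        phase_map[(str(r["gene_id"]), str(r["sample"]), str(r["variant_id"]))] = str(
            r["haplotype"]
        )
    out = []
    for call in ase_calls:
        flagged = None
        for v in by_unit.get((call.gene_id, call.sample), []):
            hap = phase_map.get((call.gene_id, call.sample, v.variant_id))
            if hap is None:
                warnings.warn(
                    f"variant {v.variant_id} unphased in {call.sample}; not flagged"
                )
                continue
            if hap == call.overexpressed_hap:
                flagged = v.variant_id
                break
        out.append(
            ASECall(
                gene_id=call.gene_id,
                sample=call.sample,
                hap_a=call.hap_a,
                hap_b=call.hap_b,
                log2_allelic_fc=call.log2_allelic_fc,
                pvalue=call.pvalue,
                fdr=call.fdr,
                overexpressed_hap=call.overexpressed_hap,
                deleterious_variant=flagged,
            )
        )
    return out


__all__ = [
    "SplicingCall",
    "ASECall",
    "alt_splicing",
    "splicing_pattern_calls",
    "binomial_ase_pvalue",
    "ase_test",
    "flag_ase_with_coding_hit",
    "CODING_CLASSES",
]
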