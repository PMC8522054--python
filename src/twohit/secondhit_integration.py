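"""Variant-class x expression-change enrichment and synergy detection.

The unit of analysis is the (gene, individual) pair pooled within a
stratum: a 2x2 table counts units with/without a variant of one class
against units with/without an expression change, over a background of
expressed genes crossed with the stratum's individuals. Odds ratios use
a Haldane-Anscombe 0.5 correction for zero cells (CI only; the Fisher p
is always exact), and BH correction runs across the 25 classes within
each (change type, stratum). Synergy genes are the triple intersection:
globally differentially expressed, outlier-expressed in a specific
deletion carrier, and hit by a second-hit variant inherited from the
noncarrier parent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .expression_stats import bh_fdr
from .variants import ALL_CLASSES, ClassifiedVariant

Unit = tuple[str, str]  # (gene_id, individual)


@dataclass
class StratumSpec:
    name: str
    individuals: list[str]
    inheritance: str | None = None  # restrict variants to this inheritance


def variant_units_by_class(
    variants: list[ClassifiedVariant],
    individuals: list[str] | None = None,
    inheritance: str | None = None,
) -> dict[str, set[Unit]]:
    """(gene, individual) units per variant class, optionally restricted."""
    keep = set(individuals) if individuals is not None else None
    out: dict[str, set[Unit]] = {c: set() for c in ALL_CLASSES}
    for v in variants:
        if keep is not None and v.sample not in keep:
            continue
        if inheritance is not None and v.inheritance != inheritance:
            continue
        out[v.class_label].add((v.gene_id, v.sample))
    return out


def _wald_ci(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """OR with 95% Wald CI on log OR; 0.5 correction when any cell is zero."""
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = np.exp(np.log(or_) - 1.96 * se)
    hi = np.exp(np.log(or_) + 1.96 * se)
    return or_, lo, hi


def enrichment_matrix(
    change_units: dict[str, set[Unit]],
    variants: list[ClassifiedVariant],
    expressed_genes: list[str],
    strata: list[StratumSpec],
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher-exact enrichment per (variant class, change type, stratum).

    ``change_units`` maps change types (DE, outlier, ...) to their
    (gene, individual) unit sets. The background for a stratum is the
    expressed genes crossed with its individuals. Rows with empty
    strata are skipped.
    """
    classes = classes or ALL_CLASSES
    genes = list(expressed_genes)
    rows = []
    for stratum in strata:
        if not stratum.individuals:
            warnings.warn(f"empty stratum {stratum.name}; skipped")
            continue
        background = {(g, i) for g in genes for i in stratum.individuals}
        vunits = variant_units_by_class(
            variants, stratum.individuals, stratum.inheritance
        )
        for change_type, cunits in change_units.items():
            changed = cunits & background
            for cls in classes:
                withv = vunits[cls] & background
                a = len(withv & changed)
                b = len(withv) - a
                c = len(changed) - a
                d = len(background) - a - b - c
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
                or_, lo, hi = _wald_ci(a, b, c, d)
                rows.append(
                    (cls, change_type, stratum.name, a, b, c, d, or_, lo, hi, p)
                )
    tab = pd.DataFrame(
        rows,
        columns=[
            "class", "change_type", "stratum", "a", "b", "c", "d",
            "odds_ratio", "ci_lo", "ci_hi", "pvalue",
        ],
    )
    tab["fdr"] = np.nan
    for (_, _), idx in tab.groupby(["change_type", "stratum"]).groups.items():
        tab.loc[idx, "fdr"] = bh_fdr(tab.loc[idx, "pvalue"].to_numpy())
    return tab


def variant_burden_test(
    outlier_units: set[Unit],
    variants: list[ClassifiedVariant],
    background_units: set[Unit],
    gene_sets: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """One-tailed t-tests of per-unit variant burden, outlier vs non-outlier.

    Burden is the number of distinct (variant, class) hits on each
    (gene, individual) unit, aggregated and per class; ``gene_sets``
    (e.g. intolerant or brain-preferential genes) add restricted
    aggregate contrasts. BH correction runs across the per-class rows.
    """
    per_class: dict[str, dict[Unit, int]] = {c: {} for c in ALL_CLASSES}
    total: dict[Unit, int] = {}
    seen = set()
    for v in variants:
        key = (v.gene_id, v.sample, v.class_label, v.variant_id)
        if key in seen:
            continue
        seen.add(key)
        unit = (v.gene_id, v.sample)
        if unit not in background_units:
            continue
        per_class[v.class_label][unit] = per_class[v.class_label].get(unit, 0) + 1
        total[unit] = total.get(unit, 0) + 1

    def _test(counts: dict[Unit, int], units: set[Unit]) -> tuple[float, float]:
        x = np.array([counts.get(u, 0) for u in units if u in outlier_units], float)
        y = np.array(
            [counts.get(u, 0) for u in units if u not in outlier_units], float
        )
        if len(x) < 2 or len(y) < 2:
            return np.nan, np.nan
        t, p = stats.ttest_ind(x, y, alternative="greater", equal_var=False)
        return float(t), float(p)

    rows = [("aggregate", *_test(total, background_units))]
    class_rows = []
    for cls in ALL_CLASSES:
        class_rows.append((cls, *_test(per_class[cls], background_units)))
    for name, genes in (gene_sets or {}).items():
        units = {u for u in background_units if u[0] in genes}
        rows.append((f"aggregate_{name}", *_test(total, units)))
    tab = pd.DataFrame(rows + class_rows, columns=["group", "t", "pvalue"])
    cls_mask = tab["group"].isin(ALL_CLASSES) & tab["pvalue"].notna()
    tab["fdr"] = np.nan
    if cls_mask.any():
        tab.loc[cls_mask, "fdr"] = bh_fdr(tab.loc[cls_mask, "pvalue"].to_numpy())
    return tab


@dataclass
class SynergyGene:
    gene_id: str
    sample: str  # the deletion-carrier individual
    variant_id: str
    global_log2fc: float
    outlier_z: float


def synergy_detect(
    global_de: set[str],
    outlier_sets: dict[str, set[str]],
    variants: list[ClassifiedVariant],
    carriers: list[str],
    global_log2fc: pd.Series | None = None,
    zscores: pd.DataFrame | None = None,
) -> list[SynergyGene]:
    """Genes where the deletion and an inherited second-hit act together.

    Emits every (gene, carrier) pair where the gene is in the global
    carrier-vs-noncarrier DE set, is an expression outlier in that
    carrier, and carries a second-hit variant in that carrier inherited
    from the noncarrier parent.
    """
    carrier_set = set(carriers)
    by_unit: dict[Unit, str] = {}
    for v in variants:
        if v.inheritance == "noncarrier_parent" and v.sample in carrier_set:
            by_unit.setdefault((v.gene_id, v.sample), v.variant_id)
    out = []
    for sample in carriers:
        for gene in sorted(outlier_sets.get(sample, set()) & global_de):
            vid = by_unit.get((gene, sample))
            if vid is None:
                continue
            lfc = (
                float(global_log2fc.get(gene, np.nan))
                if global_log2fc is not None
                else np.nan
            )
            z = (
                float(zscores.loc[gene, sample])
                if zscores is not None and gene in zscores.index
                else np.nan
            )
            out.append(SynergyGene(gene, sample, vid, lfc, z))
    return out


def change_count_correlations(change_counts: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between per-offspring change-count columns.

    Zero-variance columns are skipped; BH correction runs across the
    tested pairs.
    """
    if change_counts.shape[0] < 5:
        raise ValueError("need at least five offspring")
    cols = [c for c in change_counts.columns if change_counts[c].std(ddof=1) > 0]
    rows = []
    for x, y in combinations(cols, 2):
        r, p = stats.pearsonr(change_counts[x], change_counts[y])
        rows.append((x, y, float(r), float(p)))
    tab = pd.DataFrame(rows, columns=["var_a", "var_b", "r", "pvalue"])
    tab["fdr"] = bh_fdr(tab["pvalue"].to_numpy()) if len(tab) else np.nan
    return tab
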