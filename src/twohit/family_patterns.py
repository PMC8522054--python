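"""Family-specific patterns of offspring expression changes.

An offspring's change for a gene is "unique" when it appears against
both parents, "shared with the carrier parent" when it appears only
against the noncarrier parent, and "shared with the noncarrier parent"
when it appears only against the carrier parent. The cohort-level
contrast of shared-with-carrier vs shared-with-noncarrier counts uses a
paired two-sided Wilcoxon signed-rank test (exact for small n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .pedigree import Trio, extract_trios  # re-exported

__all__ = [
    "Trio",
    "extract_trios",
    "PatternCall",
    "classify_pattern",
    "classify_presence_pattern",
    "pattern_counts",
    "compare_pattern_counts",
]

PATTERNS = ["unique", "shared_carrier", "shared_noncarrier"]


@dataclass
class PatternCall:
    gene_id: str
    offspring_id: str
    change_type: str  # DE | splicing | ASE
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


def classify_pattern(
    set_vs_carrier: set[str],
    set_vs_noncarrier: set[str],
    offspring_id: str = "",
    change_type: str = "DE",
) -> list[PatternCall]:
    """Partition the union of the two per-parent change sets.

    ``set_vs_carrier`` holds genes changed against the carrier parent,
    ``set_vs_noncarrier`` against the noncarrier parent. Genes in both
    are unique to the offspring; genes in exactly one are shared with
    the *other* parent.
    """
    calls = []
    for gene in set_vs_carrier & set_vs_noncarrier:
        calls.append(PatternCall(gene, offspring_id, change_type, "unique"))
    for gene in set_vs_noncarrier - set_vs_carrier:
        calls.append(PatternCall(gene, offspring_id, change_type, "shared_carrier"))
    for gene in set_vs_carrier - set_vs_noncarrier:
        calls.append(PatternCall(gene, offspring_id, change_type, "shared_noncarrier"))
    return sorted(calls, key=lambda c: (c.pattern, c.gene_id))


def classify_presence_pattern(
    offspring_set: set[str],
    carrier_parent_set: set[str],
    noncarrier_parent_set: set[str],
    offspring_id: str = "",
    change_type: str = "ASE",
) -> list[PatternCall]:
    """Patterns for presence-type changes (e.g. ASE).

    Unlike DE patterns (built from two offspring-vs-parent comparisons),
    presence patterns ask whether the *parent also shows* the change:
    shared with whichever parent has it, unique when neither does. A
    change present in both parents yields one call per parent.
    """
    calls = []
    for gene in offspring_set:
        shared = False
        if gene in carrier_parent_set:
            calls.append(PatternCall(gene, offspring_id, change_type,
                                     "shared_carrier"))
            shared = True
        if gene in noncarrier_parent_set:
            calls.append(PatternCall(gene, offspring_id, change_type,
                                     "shared_noncarrier"))
            shared = True
        if not shared:
            calls.append(PatternCall(gene, offspring_id, change_type, "unique"))
    return sorted(calls, key=lambda c: (c.pattern, c.gene_id))


def pattern_counts(calls: list[PatternCall]) -> pd.DataFrame:
    """Per-offspring counts of calls by pattern (offspring x pattern)."""
    rows: dict[str, dict[str, int]] = {}
    for c in calls:
        rows.setdefault(c.offspring_id, {p: 0 for p in PATTERNS})
        rows[c.offspring_id][c.pattern] += 1
    tab = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    for p in PATTERNS:
        if p not in tab.columns:
            tab[p] = 0
    return tab[PATTERNS].sort_index()


def compare_pattern_counts(
    shared_carrier: list[float],
    shared_noncarrier: list[float],
    use_proportions: bool = True,
    totals: list[float] | None = None,
) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank on per-offspring counts.

    With ``use_proportions`` the two counts are first divided by each
    offspring's total number of changes (``totals``, defaulting to the
    pairwise sum). Returns (statistic, p).
    """
    if len(shared_carrier) != len(shared_noncarrier):
        raise ValueError("paired vectors must have equal length")
    if len(shared_carrier) < 5:
        raise ValueError("need at least five offspring")
    a = pd.Series(shared_carrier, dtype=float)
    b = pd.Series(shared_noncarrier, dtype=float)
    if use_proportions:
        tot = pd.Series(totals, dtype=float) if totals is not None else a + b
        ok = tot > 0
        a, b = a[ok] / tot[ok], b[ok] / tot[ok]
    diffs = a - b
    if (diffs == 0).all():
        warnings.warn("all paired differences are zero")
        return 0.0, 1.0
    method = "exact" if len(diffs) <= 25 and (diffs != 0).all() else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
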