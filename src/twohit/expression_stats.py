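"""Expression statistics for replicate-level family RNA-seq matrices.

Count and TPM matrices are pandas DataFrames indexed by gene with
``sample.replicate`` columns. Differential expression uses the in-house
negative-binomial GLM (see :mod:`twohit.nbglm`) in two modes: a global
carrier-vs-noncarrier comparison with family covariate run
leave-one-sample-out and intersected across iterations, and pairwise
trio comparisons thresholded at |log2FC| > 0.5 and FDR < 0.05. Outlier
expression is a per-individual z-score of log2(median TPM + 1) after
removing one latent factor (rank-1 SVD component) and re-standardising,
flagged at |z| > 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nbglm

DEFAULT_TPM_THRESHOLD = 0.2
DEFAULT_Z_THRESHOLD = 2.0
DEFAULT_LFC_THRESHOLD = 0.5
DEFAULT_FDR = 0.05


def sample_of_column(col: str) -> str:
    """``sample.replicate`` column label -> sample id."""
    return col.rsplit(".", 1)[0]


def columns_of_sample(columns: list[str], sample: str) -> list[str]:
    return [c for c in columns if sample_of_column(c) == sample]


def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Counts -> transcripts-per-million using per-gene transcript lengths."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("all-zero column in count matrix")
    return rate.div(denom, axis=1) * 1e6


def filter_expressed(
    tpm: pd.DataFrame, threshold: float = DEFAULT_TPM_THRESHOLD
) -> list[str]:
    """Genes where all replicates of at least one sample exceed ``threshold`` TPM."""
    samples = sorted({sample_of_column(c) for c in tpm.columns})
    keep = pd.Series(False, index=tpm.index)
    for s in samples:
        cols = columns_of_sample(list(tpm.columns), s)
        keep |= (tpm[cols] > threshold).all(axis=1)
    return list(tpm.index[keep])


def _design(
    columns: list[str],
    group_a: list[str],
    group_b: list[str],
    covariates: pd.Series | None,
) -> np.ndarray:
    n = len(columns)
    parts = [np.ones((n, 1))]
    if covariates is not None:
        cov = covariates.reindex(columns)
        if cov.isna().any():
            raise ValueError("covariate missing for some columns")
        levels = sorted(cov.unique())
        for lev in levels[1:]:  # first level absorbed by intercept
            parts.append((cov.values == lev).astype(float)[:, None])
    group = np.array([1.0 if c in set(group_a) else 0.0 for c in columns])[:, None]
    parts.append(group)
    return np.hstack(parts)


def de_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    covariates: pd.Series | None = None,
    min_count: int = 10,
    min_prop: float = 0.7,
) -> pd.DataFrame:
    """NB-GLM differential expression of group A vs group B.

    Positive log2FC means higher expression in group A. Genes failing a
    low-expression rule (fewer than ``min_prop`` of the smaller group's
    columns with >= ``min_count`` reads) are excluded before testing.
    BH FDR is computed across the tested genes.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two columns")
    cols = group_a + group_b
    sub = counts[cols]
    if not np.allclose(sub.to_numpy(float), np.round(sub.to_numpy(float))):
        raise ValueError("counts must be integers")
    smallest = min(len(group_a), len(group_b))
    ok = (sub >= min_count).sum(axis=1) >= min_prop * smallest
    ok &= sub.sum(axis=1) > 0
    tested_genes = sub.index[ok]
    result = pd.DataFrame(
        index=counts.index,
        data={
            "log2fc": np.nan,
            "pvalue": np.nan,
            "fdr": np.nan,
            "mean": sub.mean(axis=1),
            "tested": False,
        },
    )
    if len(tested_genes) == 0:
        return result
    y = sub.loc[tested_genes].to_numpy()
    X_full = _design(cols, group_a, group_b, covariates)
    X_red = X_full[:, :-1]
    offset = np.log(np.clip(counts[cols].sum(axis=0).to_numpy(float), 1.0, None))
    # dispersion cells: one label per distinct design row
    cells = [tuple(row) for row in X_full]
    cell_ids = np.array([sorted(set(cells)).index(c) for c in cells])
    res = nbglm.nb_lrt(y, X_full, X_red, offset=offset, groups=cell_ids)
    result.loc[tested_genes, "log2fc"] = res["log2fc"]
    result.loc[tested_genes, "pvalue"] = res["pvalue"]
    result.loc[tested_genes, "tested"] = res["tested"]
    mask = result.loc[tested_genes, "tested"].to_numpy(bool)
    idx = tested_genes[mask]
    result.loc[idx, "fdr"] = bh_fdr(result.loc[idx, "pvalue"].to_numpy())
    return result


def global_de_loo(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
    exclude_genes: set[str] | None = None,
) -> dict:
    """Leave-one-sample-out intersection DE between carriers and noncarriers.

    ``meta`` is indexed by sample with ``carrier`` (bool) and ``family``
    columns. Each iteration drops all replicates of one sample, runs the
    carrier-vs-noncarrier NB-GLM with family covariate, and the final
    set is the intersection of the per-iteration FDR < 0.05 sets.
    """
    if exclude_genes:
        counts = counts.drop(index=[g for g in exclude_genes if g in counts.index])
    samples = list(meta.index)
    carriers = [s for s in samples if meta.loc[s, "carrier"]]
    noncarriers = [s for s in samples if not meta.loc[s, "carrier"]]
    if len(carriers) < 3 or len(noncarriers) < 3:
        raise ValueError("need at least three carriers and three noncarriers")
    all_cols = list(counts.columns)

    def _run(excluded: str | None) -> pd.DataFrame:
        keep = [s for s in samples if s != excluded]
        kc = [s for s in keep if meta.loc[s, "carrier"]]
        nc = [s for s in keep if not meta.loc[s, "carrier"]]
        if not kc or not nc:
            raise ValueError("leave-one-out subset lost an entire group")
        ga = [c for s in kc for c in columns_of_sample(all_cols, s)]
        gb = [c for s in nc for c in columns_of_sample(all_cols, s)]
        fam = pd.Series(
            {c: meta.loc[sample_of_column(c), "family"] for c in ga + gb}
        )
        return de_test(counts, ga, gb, covariates=fam)

    per_iteration: dict[str, set[str]] = {}
    for s in samples:
        tab = _run(s)
        per_iteration[s] = set(tab.index[(tab["fdr"] < fdr_threshold).fillna(False)])
    intersection = set.intersection(*per_iteration.values())
    full = _run(None)
    return {
        "intersection": intersection,
        "per_iteration": per_iteration,
        "full_table": full,
    }


def trio_de(
    counts: pd.DataFrame,
    offspring_cols: list[str],
    parent_cols: list[str],
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR,
    min_expressed_prop: float = 0.25,
    exclude_genes: set[str] | None = None,
) -> dict:
    """Offspring-vs-parent DE set at |log2FC| > 0.5 and FDR < 0.05.

    Genes expressed (nonzero count) in fewer than 25% of all replicates
    in the matrix are removed before testing. Returns the thresholded
    gene set plus the full per-gene table.
    """
    if not offspring_cols or not parent_cols:
        raise ValueError("missing replicate columns for trio comparison")
    if exclude_genes:
        counts = counts.drop(index=[g for g in exclude_genes if g in counts.index])
    expressed = (counts > 0).mean(axis=1) >= min_expressed_prop
    sub = counts[expressed.values]
    tab = de_test(sub, offspring_cols, parent_cols, covariates=None,
                  min_count=1, min_prop=0.0)
    sig = tab["tested"] & (tab["fdr"] < fdr_threshold) & (
        tab["log2fc"].abs() > lfc_threshold
    )
    return {"de_set": set(tab.index[sig.fillna(False)]), "table": tab}


@dataclass
class ZScoreMatrix:
    """Corrected per-individual expression z-scores with outlier flags."""

    z: pd.DataFrame  # genes x individuals
    n_latent: int
    z_threshold: float = DEFAULT_Z_THRESHOLD
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def outliers(self) -> pd.DataFrame:
        return self.z.abs() > self.z_threshold

    def outlier_sets(self) -> dict[str, set[str]]:
        flags = self.outliers
        return {s: set(flags.index[flags[s]]) for s in flags.columns}


def outlier_zscores(
    tpm: pd.DataFrame,
    n_latent: int = 1,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    genes: list[str] | None = None,
) -> ZScoreMatrix:
    """Per-individual outlier z-scores from replicate-level TPM.

    Median TPM over replicates -> log2(x+1) -> per-gene z across
    individuals -> subtract the top ``n_latent`` SVD components (latent
    batch/family factors) -> re-standardise each gene.
    """
    if genes is not None:
        tpm = tpm.loc[[g for g in genes if g in tpm.index]]
    samples = sorted({sample_of_column(c) for c in tpm.columns})
    if len(samples) < 3:
        raise ValueError("need at least three individuals")
    med = pd.DataFrame(
        {s: tpm[columns_of_sample(list(tpm.columns), s)].median(axis=1)
         for s in samples}
    )
    logtpm = np.log2(med + 1.0)
    mu = logtpm.mean(axis=1)
    sd = logtpm.std(axis=1, ddof=0)  # population SD: z of the max of
    # (1,1,1,1,9) is exactly 2, so the strict |z| > 2 rule excludes it
    dropped = list(logtpm.index[sd == 0])
    keep = sd > 0
    z = logtpm[keep.values].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    if n_latent > 0 and z.shape[0] > n_latent:
        mat = z.to_numpy()
        u, s, vt = np.linalg.svd(mat, full_matrices=False)
        k = min(n_latent, len(s))
        mat = mat - (u[:, :k] * s[:k]) @ vt[:k]
        # re-standardise each gene so the |z| > 2 rule stays calibrated
        msd = mat.std(axis=1, ddof=0)
        ok = msd > 0
        dropped += list(z.index[~ok])
        mat = (mat - mat.mean(axis=1, keepdims=True))[ok] / msd[ok][:, None]
        z = pd.DataFrame(mat, index=z.index[ok], columns=z.columns)
    return ZScoreMatrix(z=z, n_latent=n_latent, z_threshold=z_threshold,
                        dropped_genes=dropped)


def page_enrichment(
    log2fc: pd.Series,
    gene_sets: dict[str, set[str]],
    min_size: int = 10,
) -> pd.DataFrame:
    """Parametric gene-set enrichment on signed log fold changes.

    Z = (S_m - mu) * sqrt(m) / delta with mu, delta the mean/SD of all
    fold changes, S_m the set mean over its m members; two-tailed normal
    p with BH correction across sets.
    """
    from scipy import stats

    vals = log2fc.dropna()
    mu = vals.mean()
    delta = vals.std(ddof=1)
    if delta == 0 or not np.isfinite(delta):
        raise ValueError("zero variance in fold changes")
    rows = []
    for name, members in gene_sets.items():
        hit = vals.index.intersection(list(members))
        m = len(hit)
        if m < min_size:
            continue
        s_m = vals.loc[hit].mean()
        zstat = (s_m - mu) * np.sqrt(m) / delta
        rows.append((name, m, s_m, zstat, 2.0 * stats.norm.sf(abs(zstat))))
    tab = pd.DataFrame(rows, columns=["set", "size", "set_mean", "z", "pvalue"])
    if len(tab):
        tab["fdr"] = bh_fdr(tab["pvalue"].to_numpy())
    else:
        tab["fdr"] = []
    return tab.set_index("set")


def preferential_expression(tissue_expr: pd.DataFrame) -> pd.DataFrame:
    """Flag (gene, tissue) where expression > median + 2 SD across tissues."""
    if tissue_expr.shape[1] < 3:
        raise ValueError("need at least three tissues")
    med = tissue_expr.median(axis=1)
    sd = tissue_expr.std(axis=1, ddof=1)
    return tissue_expr.gt(med + 2.0 * sd, axis=0)
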