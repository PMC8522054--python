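"""End-to-end pipeline over an in-memory or on-disk cohort.

Stage order: variant classification -> global leave-one-out DE ->
outlier z-scores -> trio DE with family patterns -> splicing -> ASE ->
variant-class enrichment + synergy -> network proximity. Every stage
writes a TSV and the run closes with a JSON manifest of row counts and
seeds so reruns are auditable and byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import brain_network, expression_stats, secondhit_integration
from . import splicing_ase, variant_taxonomy
from .family_patterns import (
    PatternCall,
    classify_pattern,
    classify_presence_pattern,
    extract_trios,
)
from .pedigree import Pedigree
from .synthetic_cohort import Cohort
from .variants import CODING_CLASSES, ClassifiedVariant


@dataclass
class PipelineConfig:
    tpm_threshold: float = 0.2
    z_threshold: float = 2.0
    lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    edge_threshold: float = 2.0
    n_permutations: int = 100
    seed: int = 0


def classify_cohort_variants(cohort: Cohort,
                             config: variant_taxonomy.FilterConfig | None = None
                             ) -> list[ClassifiedVariant]:
    """Filter, classify and inheritance-resolve all cohort variants."""
    cfg = config or variant_taxonomy.FilterConfig()
    kept = variant_taxonomy.filter_small_variants(cohort.small_variants, cfg)
    records: list[ClassifiedVariant] = []
    for v in kept:
        records += variant_taxonomy.classify_small_variant(
            v, cohort.genes, cohort.chromatin_segments, cfg
        )
    merged = variant_taxonomy.merge_cnv_calls(cohort.sv_calls)
    for sv in merged:
        records += variant_taxonomy.classify_sv(sv, cohort.genes)
    expansions = variant_taxonomy.call_str_expansions(
        cohort.str_calls, n_samples=len(cohort.pedigree), config=cfg
    )
    for exp in expansions:
        records += variant_taxonomy.classify_str(exp, cohort.genes, cfg)
    return variant_taxonomy.assign_inheritance(
        records, kept, merged, cohort.str_calls, cohort.pedigree, cfg
    )


def _variants_table(records: list[ClassifiedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(variant_id=r.variant_id, gene_id=r.gene_id, sample=r.sample,
                 class_label=r.class_label, inheritance=r.inheritance, kind=r.kind)
            for r in records
        ],
        columns=["variant_id", "gene_id", "sample", "class_label",
                 "inheritance", "kind"],
    ).sort_values(["sample", "gene_id", "class_label", "variant_id"],
                  kind="mergesort").reset_index(drop=True)


def _offspring_cols(counts: pd.DataFrame, sample: str) -> list[str]:
    return expression_stats.columns_of_sample(list(counts.columns), sample)


def _strata(pedigree: Pedigree) -> list[secondhit_integration.StratumSpec]:
    carrier_children = [
        i.sample_id for i in pedigree if i.carrier and i.role == "child"
    ]
    carrier_parents = [
        i.sample_id for i in pedigree if i.carrier and i.role in ("parent",)
    ]
    noncarrier_parents = [
        i.sample_id for i in pedigree if not i.carrier and i.role == "parent"
    ]
    S = secondhit_integration.StratumSpec
    return [
        S("all", pedigree.sample_ids),
        S("carrier_child", carrier_children),
        S("carrier_parent", carrier_parents),
        S("noncarrier_parent", noncarrier_parents),
        S("inherited_from_carrier", carrier_children, "carrier_parent"),
        S("inherited_from_noncarrier", carrier_children, "noncarrier_parent"),
    ]


def run_pipeline(
    cohort: Cohort,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run all stages on ``cohort`` and write outputs under ``outdir``.

    Returns the in-memory results dict (same content as the files).
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}
    results: dict = {}

    # ---- variants ----------------------------------------------------
    records = classify_cohort_variants(cohort)
    vtab = _variants_table(records)
    vtab.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    manifest["stages"]["variants"] = len(vtab)
    results["variants"] = records

    # ---- expression basics ------------------------------------------
    expressed = expression_stats.filter_expressed(cohort.tpm, cfg.tpm_threshold)
    meta = pd.DataFrame(
        {
            "carrier": {i.sample_id: i.carrier for i in cohort.pedigree},
            "family": {i.sample_id: i.family_id for i in cohort.pedigree},
        }
    )
    loo = expression_stats.global_de_loo(
        cohort.counts.loc[expressed], meta, fdr_threshold=cfg.fdr_threshold
    )
    detab = loo["full_table"].loc[sorted(loo["intersection"])]
    detab.to_csv(outdir / "de_global.tsv", sep="\t", index_label="gene_id")
    manifest["stages"]["de_global"] = len(detab)
    results["global_de"] = loo

    zmat = expression_stats.outlier_zscores(
        cohort.tpm.loc[expressed], n_latent=1, z_threshold=cfg.z_threshold
    )
    outlier_sets = zmat.outlier_sets()
    orows = [
        dict(gene_id=g, sample=s, z=float(zmat.z.loc[g, s]))
        for s in zmat.z.columns
        for g in sorted(outlier_sets[s])
    ]
    pd.DataFrame(orows, columns=["gene_id", "sample", "z"]).to_csv(
        outdir / "outliers.tsv", sep="\t", index=False
    )
    manifest["stages"]["outliers"] = len(orows)
    results["zscores"] = zmat

    # ---- trio DE + patterns -----------------------------------------
    trios = extract_trios(cohort.pedigree)
    pattern_calls: list[PatternCall] = []
    for trio in trios:
        oc = _offspring_cols(cohort.counts, trio.offspring_id)
        cc = _offspring_cols(cohort.counts, trio.carrier_parent_id)
        nc = _offspring_cols(cohort.counts, trio.noncarrier_parent_id)
        vs_carrier = expression_stats.trio_de(
            cohort.counts.loc[expressed], oc, cc,
            lfc_threshold=cfg.lfc_threshold, fdr_threshold=cfg.fdr_threshold,
        )["de_set"]
        vs_noncarrier = expression_stats.trio_de(
            cohort.counts.loc[expressed], oc, nc,
            lfc_threshold=cfg.lfc_threshold, fdr_threshold=cfg.fdr_threshold,
        )["de_set"]
        pattern_calls += classify_pattern(
            vs_carrier, vs_noncarrier, trio.offspring_id, "DE"
        )
    ptab = pd.DataFrame(
        [
            dict(offspring=c.offspring_id, gene_id=c.gene_id,
                 change_type=c.change_type, pattern=c.pattern)
            for c in pattern_calls
        ],
        columns=["offspring", "gene_id", "change_type", "pattern"],
    )
    ptab.to_csv(outdir / "patterns.tsv", sep="\t", index=False)
    manifest["stages"]["patterns"] = len(ptab)
    results["trios"] = trios
    results["de_patterns"] = pattern_calls

    # ---- splicing ----------------------------------------------------
    splicing_calls = []
    for trio in trios:
        oc = _offspring_cols(cohort.isoform_counts, trio.offspring_id)
        cc = _offspring_cols(cohort.isoform_counts, trio.carrier_parent_id)
        nc = _offspring_cols(cohort.isoform_counts, trio.noncarrier_parent_id)
        splicing_calls += splicing_ase.alt_splicing(
            cohort.isoform_counts, cohort.counts, cohort.isoform_gene_map,
            trio.offspring_id, cc, nc, oc, fdr_threshold=cfg.fdr_threshold,
        )
    stab = pd.DataFrame(
        [
            dict(isoform_id=c.isoform_id, gene_id=c.gene_id,
                 offspring=c.offspring_id, pattern=c.pattern)
            for c in splicing_calls
        ],
        columns=["isoform_id", "gene_id", "offspring", "pattern"],
    )
    stab.to_csv(outdir / "splicing.tsv", sep="\t", index=False)
    manifest["stages"]["splicing"] = len(stab)
    results["splicing"] = splicing_calls

    # ---- ASE ---------------------------------------------------------
    ase_calls = []
    for sample in cohort.pedigree.sample_ids:
        calls = splicing_ase.ase_test(
            cohort.haplotype_counts, sample, fdr_threshold=cfg.fdr_threshold
        )
        ase_calls += splicing_ase.flag_ase_with_coding_hit(
            calls, records, cohort.phase
        )
    atab = pd.DataFrame(
        [
            dict(gene_id=c.gene_id, sample=c.sample, hap_a=c.hap_a, hap_b=c.hap_b,
                 log2_allelic_fc=c.log2_allelic_fc, pvalue=c.pvalue, fdr=c.fdr,
                 overexpressed_hap=c.overexpressed_hap,
                 deleterious_variant=c.deleterious_variant or "")
            for c in ase_calls
        ],
        columns=["gene_id", "sample", "hap_a", "hap_b", "log2_allelic_fc",
                 "pvalue", "fdr", "overexpressed_hap", "deleterious_variant"],
    )
    atab.to_csv(outdir / "ase.tsv", sep="\t", index=False)
    manifest["stages"]["ase"] = len(atab)
    results["ase"] = ase_calls

    # ASE family patterns: presence of the same ASE gene in a parent
    ase_sets: dict[str, set[str]] = {}
    for c in ase_calls:
        ase_sets.setdefault(c.sample, set()).add(c.gene_id)
    ase_patterns: list[PatternCall] = []
    for trio in trios:
        ase_patterns += classify_presence_pattern(
            ase_sets.get(trio.offspring_id, set()),
            ase_sets.get(trio.carrier_parent_id, set()),
            ase_sets.get(trio.noncarrier_parent_id, set()),
            trio.offspring_id,
        )
    results["ase_patterns"] = ase_patterns

    # ---- enrichment + synergy ---------------------------------------
    de_units = {(c.gene_id, c.offspring_id) for c in pattern_calls}
    outlier_units = {
        (g, s) for s, genes in outlier_sets.items() for g in genes
    }
    splice_units = {(c.gene_id, c.offspring_id) for c in splicing_calls}
    change_units = {"DE": de_units, "outlier": outlier_units,
                    "splicing": splice_units}
    enr = secondhit_integration.enrichment_matrix(
        change_units, records, expressed, _strata(cohort.pedigree)
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    manifest["stages"]["enrichment"] = len(enr)
    results["enrichment"] = enr

    background = {(g, s) for g in expressed
                  for s in cohort.pedigree.sample_ids}
    burden = secondhit_integration.variant_burden_test(
        outlier_units, records, background,
        gene_sets={"intolerant": {g.gene_id for g in cohort.genes if g.intolerant}},
    )
    burden.to_csv(outdir / "burden.tsv", sep="\t", index=False)
    results["burden"] = burden

    synergy = secondhit_integration.synergy_detect(
        loo["intersection"], outlier_sets, records,
        carriers=cohort.pedigree.carriers(),
        global_log2fc=loo["full_table"]["log2fc"], zscores=zmat.z,
    )
    syn_tab = pd.DataFrame(
        [
            dict(gene_id=s.gene_id, sample=s.sample, variant_id=s.variant_id,
                 global_log2fc=s.global_log2fc, outlier_z=s.outlier_z)
            for s in synergy
        ],
        columns=["gene_id", "sample", "variant_id", "global_log2fc", "outlier_z"],
    )
    syn_tab.to_csv(outdir / "synergy.tsv", sep="\t", index=False)
    manifest["stages"]["synergy"] = len(syn_tab)
    results["synergy"] = synergy

    # ---- change-count correlations ----------------------------------
    splice_patterns = splicing_ase.splicing_pattern_calls(splicing_calls)
    count_rows: dict[str, dict[str, int]] = {
        t.offspring_id: {} for t in trios
    }
    for call in pattern_calls + splice_patterns + ase_patterns:
        row = count_rows.setdefault(call.offspring_id, {})
        key = f"{call.change_type}_{call.pattern}"
        row[key] = row.get(key, 0) + 1
    count_tab = pd.DataFrame.from_dict(count_rows, orient="index").fillna(0)
    count_tab = count_tab[sorted(count_tab.columns)].astype(int).sort_index()
    if len(count_tab) >= 5 and count_tab.shape[1] >= 2:
        corr = secondhit_integration.change_count_correlations(count_tab)
    else:
        corr = pd.DataFrame(columns=["var_a", "var_b", "r", "pvalue", "fdr"])
    corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    manifest["stages"]["correlations"] = len(corr)
    results["change_counts"] = count_tab
    results["correlations"] = corr

    # ---- network proximity ------------------------------------------
    net = brain_network.build_network(cohort.network_edges, cfg.edge_threshold)
    by_sample_coding: dict[str, set[str]] = {}
    for r in records:
        if r.class_label in CODING_CLASSES:
            by_sample_coding.setdefault(r.sample, set()).add(r.gene_id)
    change_by_sample: dict[str, set[str]] = {}
    for g, s in de_units | outlier_units | splice_units:
        change_by_sample.setdefault(s, set()).add(g)
    for c in ase_calls:
        change_by_sample.setdefault(c.sample, set()).add(c.gene_id)
    prox = []
    rng = np.random.default_rng(cfg.seed)
    for trio in trios:
        a = by_sample_coding.get(trio.offspring_id, set())
        b = change_by_sample.get(trio.offspring_id, set()) - a
        if not a or not b:
            continue
        prox.append(
            brain_network.permutation_test(
                net, a, b, n_permutations=cfg.n_permutations, seed=rng,
                offspring_id=trio.offspring_id,
            )
        )
    prox = brain_network.fdr_across_offspring(prox)
    ntab = pd.DataFrame(
        [
            dict(offspring=r.offspring_id, observed=r.observed,
                 permuted_mean=r.permuted_mean, permuted_sd=r.permuted_sd,
                 z=r.z, pvalue=r.pvalue, empirical_p=r.empirical_p,
                 fdr=r.fdr, n_pairs=r.n_pairs)
            for r in prox
        ],
        columns=["offspring", "observed", "permuted_mean", "permuted_sd", "z",
                 "pvalue", "empirical_p", "fdr", "n_pairs"],
    )
    ntab.to_csv(outdir / "network_proximity.tsv", sep="\t", index=False)
    manifest["stages"]["network_proximity"] = len(ntab)
    results["proximity"] = prox
    if len(prox) >= 5:
        stat, p = brain_network.cohort_proximity_test(prox)
        manifest["cohort_proximity"] = {"statistic": stat, "pvalue": p}
        results["cohort_proximity"] = (stat, p)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    results["manifest"] = manifest
    return results
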