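"""Readers and writers for the cohort's standard file formats.

VCF 4.2 for small variants (INFO keys CADD, GNOMAD_AF, CSQ, SPLICE,
plus the quality metrics), GTF (1-based inclusive, converted at this
boundary) for gene models, BED (0-based half-open) for chromatin-state
segments, PED + status TSV for the pedigree, and TSV for SV/STR calls,
expression matrices, haplotype counts, edge lists, and the truth table.
Every writer round-trips through its paired reader.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .genes import GeneModel
from .pedigree import Individual, Pedigree
from .synthetic_cohort import Cohort, CohortSpec
from .variants import ChromatinSegment, SmallVariant, StrCall, SvCall

# --------------------------------------------------------------------------
# VCF


def write_vcf(
    variants: list[SmallVariant], samples: list[str], path: str | Path
) -> None:
    path = Path(path)
    contigs = sorted({v.contig for v in variants})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD Phred score">',
        '##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="gnomAD allele frequency">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence annotation">',
        '##INFO=<ID=SPLICE,Number=1,Type=Integer,Description="Splice-disrupting flag">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AB,Number=1,Type=Float,Description="Allele balance">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality depth">',
        '##INFO=<ID=COHORT_N,Number=1,Type=Integer,Description="In-house cohort carrier count">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
        info = (
            f"CADD={v.cadd:g};GNOMAD_AF={v.gnomad_af:g};CSQ={v.consequence};"
            f"SPLICE={1 if v.splice_flag else 0};DP={v.depth};"
            f"AB={v.allele_balance:g};QD={v.quality_depth:g};"
            f"COHORT_N={v.cohort_count}"
        )
        gts = "\t".join(v.genotypes.get(s, "./.") for s in samples)
        lines.append(
            f"{v.contig}\t{v.pos + 1}\t{v.variant_id}\t{v.ref}\t{v.alt}\t"
            f"{v.qual:g}\tPASS\t{info}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[SmallVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for rec in vcf:
        gts = {}
        for s, g in zip(samples, rec.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                gts[s] = "./."
            else:
                gts[s] = f"{a}/{b}"
        out.append(
            SmallVariant(
                contig=rec.CHROM,
                pos=rec.POS - 1,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else ".",
                qual=float(rec.QUAL if rec.QUAL is not None else 0.0),
                depth=int(rec.INFO.get("DP", 0)),
                allele_balance=float(rec.INFO.get("AB", 0.5)),
                quality_depth=float(rec.INFO.get("QD", 10.0)),
                gnomad_af=float(rec.INFO.get("GNOMAD_AF", 0.0)),
                cohort_count=int(rec.INFO.get("COHORT_N", 0)),
                cadd=float(rec.INFO.get("CADD", 0.0)),
                consequence=str(rec.INFO.get("CSQ", "other")),
                splice_flag=bool(int(rec.INFO.get("SPLICE", 0))),
                genotypes=gts,
                variant_id=rec.ID or "",
            )
        )
    return out


# --------------------------------------------------------------------------
# GTF gene models (1-based inclusive on disk; 0-based half-open in memory)

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        attrs = (
            f'gene_id "{g.gene_id}"; biotype "{g.biotype}"; '
            f'pli "{g.pli!r}"; rvis "{g.rvis_percentile!r}";'
        )

        def feat(kind: str, s: int, e: int) -> str:
            return (
                f"{g.contig}\tsynthetic\t{kind}\t{s + 1}\t{e}\t.\t"
                f"{g.strand}\t.\t{attrs}"
            )

        rows.append(feat("transcript", g.start, g.end))
        for s, e in g.exons:
            rows.append(feat("exon", s, e))
        for s, e in g.cds:
            rows.append(feat("CDS", s, e))
        for s, e in g.utr5:
            rows.append(feat("five_prime_utr", s, e))
        for s, e in g.utr3:
            rows.append(feat("three_prime_utr", s, e))
    Path(path).write_text("\n".join(rows) + "\n")


def read_gtf(path: str | Path) -> list[GeneModel]:
    records: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        contig, _, kind, start1, end1, _, strand, _, attr_str = f
        attrs = dict(_ATTR_RE.findall(attr_str))
        gid = attrs["gene_id"]
        rec = records.setdefault(
            gid,
            dict(contig=contig, strand=strand, start=None, end=None,
                 exons=[], cds=[], utr5=[], utr3=[],
                 biotype=attrs.get("biotype", "protein_coding"),
                 pli=float(attrs.get("pli", 0.0)),
                 rvis=float(attrs.get("rvis", 50.0))),
        )
        s, e = int(start1) - 1, int(end1)
        if kind == "transcript":
            rec["start"], rec["end"] = s, e
        elif kind == "exon":
            rec["exons"].append((s, e))
        elif kind == "CDS":
            rec["cds"].append((s, e))
        elif kind == "five_prime_utr":
            rec["utr5"].append((s, e))
        elif kind == "three_prime_utr":
            rec["utr3"].append((s, e))
    out = []
    for gid, r in records.items():
        out.append(
            GeneModel(
                gene_id=gid, contig=r["contig"], strand=r["strand"],
                start=r["start"], end=r["end"], exons=sorted(r["exons"]),
                cds=sorted(r["cds"]), utr5=sorted(r["utr5"]),
                utr3=sorted(r["utr3"]), biotype=r["biotype"],
                pli=r["pli"], rvis_percentile=r["rvis"],
            )
        )
    return out


# --------------------------------------------------------------------------
# BED / TSV tables


def write_bed_segments(segments: list[ChromatinSegment], path: str | Path) -> None:
    lines = [f"{s.contig}\t{s.start}\t{s.end}\t{s.state}" for s in segments]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed_segments(path: str | Path) -> list[ChromatinSegment]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        c, s, e, st = line.split("\t")
        out.append(ChromatinSegment(c, int(s), int(e), int(st)))
    return out


def write_sv_tsv(calls: list[SvCall], path: str | Path) -> None:
    rows = [
        dict(chrom=c.contig, start=c.start, end=c.end, type=c.svtype,
             sample=c.sample, genotype="0/1")
        for c in calls
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "sample",
                                "genotype"]).to_csv(path, sep="\t", index=False)


def read_sv_tsv(path: str | Path) -> list[SvCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        SvCall(r["chrom"], int(r["start"]), int(r["end"]), r["type"], r["sample"])
        for _, r in df.iterrows()
    ]


def write_str_tsv(calls: list[StrCall], path: str | Path) -> None:
    rows = [
        dict(chrom=c.contig, start=c.start, end=c.end, motif=c.motif,
             sample=c.sample, repeat_length=c.repeat_length)
        for c in calls
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "motif", "sample",
                                "repeat_length"]).to_csv(path, sep="\t", index=False)


def read_str_tsv(path: str | Path) -> list[StrCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        StrCall(r["chrom"], int(r["start"]), int(r["end"]), r["motif"],
                r["sample"], float(r["repeat_length"]))
        for _, r in df.iterrows()
    ]


# --------------------------------------------------------------------------
# pedigree


def write_pedigree(pedigree: Pedigree, ped_path: str | Path,
                   status_path: str | Path) -> None:
    lines = [
        f"{i.family_id}\t{i.sample_id}\t{i.father_id}\t{i.mother_id}\t{i.sex}\t-9"
        for i in pedigree
    ]
    Path(ped_path).write_text("\n".join(lines) + "\n")
    rows = [
        dict(sample_id=i.sample_id, deletion_carrier=int(i.carrier), role=i.role)
        for i in pedigree
    ]
    pd.DataFrame(rows).to_csv(status_path, sep="\t", index=False)


def parse_pedigree(ped_path: str | Path, status_path: str | Path) -> Pedigree:
    """PED + carrier-status TSV -> validated Pedigree."""
    status = pd.read_csv(status_path, sep="\t").set_index("sample_id")
    ped = Pedigree()
    for line in Path(ped_path).read_text().splitlines():
        if not line:
            continue
        fam, sid, father, mother, sex, _ = line.split("\t")
        if sid not in status.index:
            raise ValueError(f"carrier status missing for sample {sid}")
        ped.add(
            Individual(
                sample_id=sid, family_id=fam, father_id=father, mother_id=mother,
                sex=int(sex), carrier=bool(int(status.loc[sid, "deletion_carrier"])),
                role=str(status.loc[sid].get("role", "")),
            )
        )
    ped.validate()
    return ped


# --------------------------------------------------------------------------
# matrices and edge lists


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id"
                 ) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_isoform_matrix(iso: pd.DataFrame, gene_map: pd.Series,
                         path: str | Path) -> None:
    out = iso.copy()
    out.insert(0, "gene_id", gene_map.reindex(iso.index).values)
    out.to_csv(path, sep="\t", index_label="isoform_id")


def read_isoform_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_map = df["gene_id"]
    return df.drop(columns=["gene_id"]), gene_map


def parse_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Tolerant TSV edge-list parse with header detection."""
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed edge row at line {lineno}")
        u, v, w = parts
        try:
            weight = float(w)
        except ValueError:
            if lineno == 1:
                continue  # header row
            raise ValueError(
                f"non-numeric edge weight {w!r} at line {lineno}"
            ) from None
        edges.append((u, v, weight))
    return edges


def write_edge_list(edges: list[tuple[str, str, float]], path: str | Path) -> None:
    lines = ["geneA\tgeneB\tprobability"]
    lines += [f"{u}\t{v}\t{p!r}" for u, v, p in edges]
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# whole-cohort round trip


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every cohort artefact under ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = cohort.pedigree.sample_ids
    paths = {
        "vcf": outdir / "variants.vcf",
        "sv": outdir / "sv_calls.tsv",
        "str": outdir / "str_calls.tsv",
        "chromhmm": outdir / "chromatin_states.bed",
        "gtf": outdir / "genes.gtf",
        "ped": outdir / "cohort.ped",
        "status": outdir / "status.tsv",
        "counts": outdir / "counts.tsv",
        "tpm": outdir / "tpm.tsv",
        "isoforms": outdir / "isoform_counts.tsv",
        "haplotypes": outdir / "haplotype_counts.tsv",
        "phase": outdir / "phase.tsv",
        "edges": outdir / "network_edges.tsv",
        "truth": outdir / "truth.tsv",
        "spec": outdir / "cohort_spec.json",
    }
    write_vcf(cohort.small_variants, samples, paths["vcf"])
    write_sv_tsv(cohort.sv_calls, paths["sv"])
    write_str_tsv(cohort.str_calls, paths["str"])
    write_bed_segments(cohort.chromatin_segments, paths["chromhmm"])
    write_gtf(cohort.genes, paths["gtf"])
    write_pedigree(cohort.pedigree, paths["ped"], paths["status"])
    write_matrix(cohort.counts, paths["counts"])
    write_matrix(cohort.tpm, paths["tpm"])
    write_isoform_matrix(cohort.isoform_counts, cohort.isoform_gene_map,
                         paths["isoforms"])
    cohort.haplotype_counts.to_csv(paths["haplotypes"], sep="\t", index=False)
    cohort.phase.to_csv(paths["phase"], sep="\t", index=False)
    write_edge_list(cohort.network_edges, paths["edges"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["spec"].write_text(json.dumps(vars(cohort.spec), default=list, indent=1))
    return paths


def read_cohort(outdir: str | Path) -> Cohort:
    """Re-read a written cohort directory into memory."""
    outdir = Path(outdir)
    spec_dict = json.loads((outdir / "cohort_spec.json").read_text())
    for key in ("baseline_mean_range", "dispersion_range", "isoform_baseline_usage"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = CohortSpec(**spec_dict)
    pedigree = parse_pedigree(outdir / "cohort.ped", outdir / "status.tsv")
    genes = read_gtf(outdir / "genes.gtf")
    counts = read_matrix(outdir / "counts.tsv")
    tpm = read_matrix(outdir / "tpm.tsv")
    iso, gene_map = read_isoform_matrix(outdir / "isoform_counts.tsv")
    lengths = pd.Series({g.gene_id: float(g.length) for g in genes})
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t").fillna("")
    phase_path = outdir / "phase.tsv"
    try:
        phase = pd.read_csv(phase_path, sep="\t")
    except pd.errors.EmptyDataError:
        phase = pd.DataFrame(columns=["gene_id", "sample", "variant_id", "haplotype"])
    return Cohort(
        spec=spec,
        pedigree=pedigree,
        genes=genes,
        chromatin_segments=read_bed_segments(outdir / "chromatin_states.bed"),
        small_variants=read_vcf(outdir / "variants.vcf"),
        sv_calls=read_sv_tsv(outdir / "sv_calls.tsv"),
        str_calls=read_str_tsv(outdir / "str_calls.tsv"),
        counts=counts,
        tpm=tpm,
        gene_lengths=lengths,
        isoform_counts=iso,
        isoform_gene_map=gene_map,
        haplotype_counts=pd.read_csv(outdir / "haplotype_counts.tsv", sep="\t"),
        phase=phase,
        network_edges=parse_edge_list(outdir / "network_edges.tsv"),
        truth=truth,
    )
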