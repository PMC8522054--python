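"""Gene models with exon/CDS/UTR structure and intolerance scores.

Coordinates are internally 0-based half-open on the transcript span;
GTF conversion (1-based inclusive) happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    start: int  # transcript interval, 0-based half-open
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"
    pli: float = 0.0
    rvis_percentile: float = 50.0
    length: int = 0  # mature transcript length in bp (for TPM)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"empty gene interval for {self.gene_id}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon outside transcript in {self.gene_id}")
        if self.length <= 0:
            self.length = sum(e - s for s, e in self.exons) or (self.end - self.start)

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware, 0-based position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site."""
        return self.end - 1 if self.strand == "+" else self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def in_intervals(self, pos: int, intervals: list[tuple[int, int]]) -> bool:
        return any(s <= pos < e for s, e in intervals)

    @property
    def intolerant(self) -> bool:
        """Intolerant to variation: pLI > 0.9 or RVIS below 20th percentile."""
        return self.pli > 0.9 or self.rvis_percentile < 20.0


def genes_by_contig(genes: list[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.contig, []).append(g)
    for glist in out.values():
        glist.sort(key=lambda g: g.start)
    return out
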