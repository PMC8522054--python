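"""Variant records and the 25-class rare-variant taxonomy labels.

The class set is 11 SNV/indel labels, 8 SV labels (DEL/DUP crossed with
four gene-overlap geometries), and 6 STR location labels. Inheritance is
assigned relative to the deletion-carrier status of the transmitting
parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SNV_CLASSES = [
    "LOF",
    "missense",
    "splice_site",
    "UTR5_snv",
    "UTR3_snv",
    "upstream_snv",
    "downstream_snv",
    "intronic_snv",
    "promoter_snv",
    "enhancer_snv",
    "silencer_snv",
]
SV_CLASSES = [
    f"{t}_{g}"
    for t in ("DEL", "DUP")
    for g in ("encapsulating", "interstitial", "UTR5_overhang", "UTR3_overhang")
]
STR_CLASSES = [
    f"STR_{loc}"
    for loc in ("exonic", "intronic", "UTR5", "UTR3", "upstream", "downstream")
]
ALL_CLASSES = SNV_CLASSES + SV_CLASSES + STR_CLASSES  # the 25-class taxonomy

# coding classes used for network set A and ASE haplotype flags
CODING_CLASSES = ["LOF", "missense", "splice_site", "STR_exonic",
                  "DEL_encapsulating", "DUP_encapsulating"]

INHERITANCE = ["carrier_parent", "noncarrier_parent", "de_novo", "unresolved"]


@dataclass
class SmallVariant:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    qual: float
    depth: int
    allele_balance: float
    quality_depth: float  # QUAL / reads supporting the alternate allele
    gnomad_af: float
    cohort_count: int  # carriers in the in-house panel
    cadd: float
    consequence: str  # stopgain | frameshift | missense | other
    splice_flag: bool = False
    genotypes: dict[str, str] = field(default_factory=dict)  # sample -> "0/1"
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("negative read depth")
        if not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError("allele frequency outside [0,1]")
        if not 0.0 <= self.allele_balance <= 1.0:
            raise ValueError("allele balance outside [0,1]")
        if not self.variant_id:
            self.variant_id = f"{self.contig}:{self.pos + 1}:{self.ref}>{self.alt}"

    def carries_alt(self, sample: str) -> bool:
        gt = self.genotypes.get(sample, "./.")
        return "1" in gt

    def is_hom_alt(self, sample: str) -> bool:
        return self.genotypes.get(sample, "./.") in ("1/1", "1|1")


@dataclass
class SvCall:
    contig: str
    start: int  # 0-based half-open
    end: int
    svtype: str  # DEL | DUP
    sample: str
    source: str = "wgs"
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("SV start must be < end")
        if self.svtype not in ("DEL", "DUP"):
            raise ValueError(f"bad SV type {self.svtype}")
        if not self.variant_id:
            self.variant_id = f"{self.svtype}:{self.contig}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StrCall:
    contig: str
    start: int
    end: int
    motif: str
    sample: str
    repeat_length: float  # motif copies
    depth: int = 50
    qual: float = 1.0
    spanning: bool = True
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.repeat_length < 0:
            raise ValueError("negative repeat length")
        if not self.variant_id:
            self.variant_id = f"STR:{self.contig}:{self.start}-{self.end}"

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


@dataclass
class ChromatinSegment:
    contig: str
    start: int  # 0-based half-open
    end: int
    state: int  # ChromHMM state index 1-15

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError("bad chromatin segment interval")
        if not 1 <= self.state <= 15:
            raise ValueError("chromatin state must be in 1..15")

    def contains(self, contig: str, pos: int) -> bool:
        return self.contig == contig and self.start <= pos < self.end


@dataclass
class ClassifiedVariant:
    """One (variant, gene, class label) record; unit of all second-hit analyses."""

    variant_id: str
    gene_id: str
    class_label: str
    sample: str
    inheritance: str = "unresolved"
    kind: str = "snv"  # snv | sv | str

    def __post_init__(self) -> None:
        if self.class_label not in ALL_CLASSES:
            raise ValueError(f"unknown variant class {self.class_label!r}")
        if self.inheritance not in INHERITANCE:
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
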