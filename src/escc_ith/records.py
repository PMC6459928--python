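"""Core record types shared across the pipeline.

Coordinates are 1-based with closed intervals throughout (MAF/SEG
convention).  Optional annotations (SIFT, PolyPhen, trinucleotide
context) are represented as ``None`` when absent, never as a sentinel
numeric value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class VariantType(str, enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    SILENT = "silent"
    OTHER = "other"


#: consequences treated as protein-truncating / deleterious
TRUNCATING = {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE}


class SampleType(str, enum.Enum):
    PRIMARY_REGION = "primary_region"
    LYMPH_NODE_MET = "lymph_node_met"
    NORMAL_TISSUE = "normal_tissue"
    BLOOD = "blood"


class Chain(str, enum.Enum):
    TRA = "TRA"
    TRB = "TRB"


@dataclass
class ReadCounts:
    alt: int
    ref: int

    @property
    def depth(self) -> int:
        return self.alt + self.ref

    @property
    def vaf(self) -> float:
        d = self.depth
        return self.alt / d if d > 0 else 0.0


@dataclass
class MutationRecord:
    """One somatic variant of a patient with per-sample read support."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: VariantType
    gene: str | None = None
    consequence: Consequence = Consequence.OTHER
    sift: float | None = None
    polyphen: float | None = None
    tri_context: str | None = None
    per_sample_counts: dict[str, ReadCounts] = field(default_factory=dict)
    is_driver: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.variant_type == VariantType.SNV and not (
            len(self.ref) == 1 == len(self.alt)
        ):
            raise ValueError("SNV requires single-base ref and alt")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def mutation_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def vaf(self, sample_id: str) -> float:
        return self.per_sample_counts[sample_id].vaf


@dataclass
class SampleMeta:
    patient_id: str
    sample_id: str
    sample_type: SampleType
    purity: float | None = None
    ploidy: float | None = None
    mean_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.purity is not None and not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")

    @property
    def is_tumor(self) -> bool:
        return self.sample_type in (
            SampleType.PRIMARY_REGION,
            SampleType.LYMPH_NODE_MET,
        )


@dataclass
class SegmentRecord:
    """Allele-specific copy-number segment (1-based closed interval)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log_r: float
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.n_major < self.n_minor:
            raise ValueError("n_major must be >= n_minor")

    def overlaps(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class SnpBafRecord:
    sample_id: str
    chrom: str
    pos: int
    a_reads: int
    b_reads: int
    phase_id: str | None = None

    def __post_init__(self) -> None:
        if self.a_reads + self.b_reads <= 0:
            raise ValueError("SNP must have at least one read")

    @property
    def baf(self) -> float:
        return self.b_reads / (self.a_reads + self.b_reads)


@dataclass
class TcrCloneRecord:
    sample_id: str
    chain: Chain
    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    productive: bool = True

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("clone count must be positive")

    @property
    def clone_id(self) -> tuple[str, str, str]:
        """Clone identity: CDR3 amino-acid sequence plus V and J gene."""
        return (self.cdr3_aa, self.v_gene, self.j_gene)


@dataclass
class GermlineVariant:
    """Germline variant in a homologous-recombination pathway gene."""

    gene: str
    consequence: Consequence
    clinvar_pathogenic: bool
    coverage: int
    vaf: float
    population_maf: float | None = None
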