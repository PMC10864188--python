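"""Core domain types for pediatric-AML (pAML) molecular evidence.

Each case carries the full evidence bundle a molecular diagnostic workflow
consumes: fusion/SV calls, somatic SNV/indel calls, tandem-duplication
candidates, a karyotype summary and a clinical record.  Categories and HOX
superfamily labels are attached after classification.

Conventions
-----------
* Genomic coordinates are 1-based inclusive; the default build tag is
  GRCh37.
* Variant allele fraction (VAF) is ``alt_reads / total_reads``.
* Pathogenicity is consumed as an annotation, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .expression import ExpressionMatrix

PATHOGENICITY_LEVELS = ("pathogenic", "likely_pathogenic", "uncertain", "benign")
VARIANT_CLASSES = ("snv", "indel")
FUSION_SOURCES = ("rna_fusion", "dna_sv")
TD_KINDS = ("itd", "ptd")
TIMEPOINTS = ("diagnosis", "relapse")
HOX_GROUPS = ("HOXA", "HOXB", "other")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    build: str = "GRCh37"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} exceeds end {self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def padded(self, pad: int) -> "GenomicInterval":
        """Interval widened by ``pad`` bases on both sides (floored at 1)."""
        return GenomicInterval(
            self.chrom, max(1, self.start - pad), self.end + pad, self.build
        )


@dataclass(frozen=True)
class FusionCall:
    """An in-frame fusion or structural-variant call joining two genes.

    ``source`` distinguishes RNA fusion callers from DNA SV callers; SV
    records are used, e.g., for enhancer-hijacking events driving MECOM,
    BCL11B or MNX1 where no in-frame chimeric transcript exists.
    """

    gene_a: str
    gene_b: str
    in_frame: bool = True
    supporting_reads: int = 0
    caller_score: float = 0.0
    source: str = "rna_fusion"

    def __post_init__(self) -> None:
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")
        if self.source not in FUSION_SOURCES:
            raise ValueError(f"unknown fusion source token: {self.source!r}")

    @property
    def genes(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic SNV or indel with read support and annotations."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    alt_reads: int
    total_reads: int
    population_af: float = 0.0
    pathogenicity: str = "uncertain"
    variant_class: str = "snv"

    def __post_init__(self) -> None:
        if not 0 <= self.vaf <= 1:
            raise ValueError("vaf must be in [0, 1]")
        if not 0 <= self.population_af <= 1:
            raise ValueError("population_af must be in [0, 1]")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.alt_reads < 0 or self.alt_reads > self.total_reads:
            raise ValueError("alt_reads must be in [0, total_reads]")
        if self.pathogenicity not in PATHOGENICITY_LEVELS:
            raise ValueError(
                f"unknown pathogenicity token: {self.pathogenicity!r}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"unknown variant_class token: {self.variant_class!r}"
            )
        # VAF must agree with the read counts up to rounding of the input.
        if abs(self.vaf - self.alt_reads / self.total_reads) > 0.01:
            raise ValueError(
                "vaf inconsistent with alt_reads/total_reads "
                f"({self.vaf} vs {self.alt_reads}/{self.total_reads})"
            )

    @property
    def allele_key(self) -> tuple:
        """Exact-allele identity used for cohort-recurrence counting."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_pathogenic(self) -> bool:
        return self.pathogenicity in ("pathogenic", "likely_pathogenic")


@dataclass(frozen=True)
class TandemDupCandidate:
    """Candidate internal/partial tandem duplication (e.g. FLT3-ITD, UBTF-TD)."""

    gene: str
    interval: GenomicInterval
    supporting_reads: int
    caller_score: float
    kind: str = "itd"

    def __post_init__(self) -> None:
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")
        if self.kind not in TD_KINDS:
            raise ValueError(f"unknown tandem-dup kind token: {self.kind!r}")


@dataclass(frozen=True)
class SoftClipRead:
    """A read summarized by its soft-clip position and clipped length."""

    clip_pos: int
    clip_len: int
    chrom: str

    def __post_init__(self) -> None:
        if self.clip_len < 0:
            raise ValueError("clip_len must be >= 0")


@dataclass(frozen=True)
class KaryotypeRecord:
    complex_karyotype: bool = False
    monosomy7: bool = False
    other_events: tuple = ()


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical covariates and censored outcomes for one patient.

    Optional fields may be ``None``; analyses exclude missing values
    pairwise.  ``nonresponse`` marks induction failure, which event-free
    survival encodes as an event at time zero.
    """

    age_years: float
    timepoint: str = "diagnosis"
    mrd_positive: Optional[bool] = None
    os_time: float = 0.0
    os_event: bool = False
    efs_time: Optional[float] = None
    efs_event: Optional[bool] = None
    nonresponse: Optional[bool] = None
    relapse_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint token: {self.timepoint!r}")
        if self.os_time < 0:
            raise ValueError("os_time must be >= 0")
        if self.efs_time is not None and self.efs_time < 0:
            raise ValueError("efs_time must be >= 0")


@dataclass
class Case:
    """One patient's complete evidence bundle plus assigned labels."""

    case_id: str
    fusions: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    tandem_dups: list = field(default_factory=list)
    karyotype: KaryotypeRecord = field(default_factory=KaryotypeRecord)
    clinical: Optional[ClinicalRecord] = None
    category: Optional[str] = None
    hox_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.hox_group is not None and self.hox_group not in HOX_GROUPS:
            raise ValueError(f"unknown hox_group token: {self.hox_group!r}")


@dataclass
class Cohort:
    """A collection of cases with unique identifiers.

    ``expression`` optionally references a gene-by-sample expression
    matrix keyed by ``case_id``.
    """

    cases: list
    expression: Optional["ExpressionMatrix"] = None

    def __post_init__(self) -> None:
        seen = set()
        for case in self.cases:
            if case.case_id in seen:
                raise ValueError(f"duplicate case_id: {case.case_id!r}")
            seen.add(case.case_id)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def case_ids(self) -> list:
        return [c.case_id for c in self.cases]

    def get(self, case_id: str) -> Case:
        for case in self.cases:
            if case.case_id == case_id:
                return case
        raise KeyError(case_id)
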