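"""Tumor-only variant screening rules.

These are the bespoke screens a tumor-only RNA-seq pipeline needs when no
matched germline sample is available:

* a somatic SNV/indel filter combining a gene panel, pathogenicity
  annotation, population allele frequency, cohort recurrence, read support
  and VAF cuts;
* a UBTF exon-13 tandem-duplication detector combining caller candidates
  with a soft-clipped-read count over the ITD/PTD hotspot;
* germline candidate criteria (coverage and VAF windows differing for SNVs
  and indels);
* genotype-fingerprint concordance for detecting duplicate individuals.

Boundary semantics follow the screening rules verbatim: read support <= 5
and VAF <= 5% are filtered (inclusive), while >= 3 supporting reads,
>= 10 clipped bases, coverage >= 20/15 and VAF within [0.2, 0.8] are kept
(inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .types import GenomicInterval, SoftClipRead, SomaticVariant, TandemDupCandidate

#: Somatic screening panel. The production screen used an 87-gene panel of
#: recurrently mutated pAML/MDS genes; this default ships the well-known
#: core and is intended to be replaced by a site-specific list.
DEFAULT_SOMATIC_PANEL = frozenset({
    "ASXL1", "ASXL2", "BCOR", "BCORL1", "BRAF", "CBL", "CEBPA", "CBFB",
    "CSF3R", "CTCF", "DNMT3A", "ETV6", "EZH2", "FLT3", "GATA1", "GATA2",
    "IDH1", "IDH2", "IKZF1", "JAK1", "JAK2", "JAK3", "KDM6A", "KIT",
    "KMT2A", "KMT2C", "KMT2D", "KRAS", "MPL", "MYC", "NF1", "NPM1",
    "NRAS", "PHF6", "PTPN11", "RAD21", "RB1", "RIT1", "RUNX1", "SETD2",
    "SF3B1", "SMC1A", "SMC3", "SOS1", "SRSF2", "STAG2", "TET2", "TP53",
    "U2AF1", "UBTF", "WT1", "ZBTB7A",
})

#: Germline curation panel. The curated screen used 15 category-defining
#: AML predisposition genes; replace with a site-specific list as needed.
DEFAULT_GERMLINE_PANEL = frozenset({
    "ANKRD26", "CEBPA", "DDX41", "ETV6", "GATA2", "RUNX1", "SAMD9",
    "SAMD9L", "TP53", "FANCA", "BRCA2", "NF1", "PTPN11", "CBL", "MBD4",
})

#: GRCh37 UBTF exon-13 ITD/PTD hotspot.
UBTF_HOTSPOT = GenomicInterval("chr17", 42288162, 42288192, "GRCh37")

RULE_GENE_PANEL = "gene-panel"
RULE_PATHOGENICITY = "pathogenicity"
RULE_POPULATION_AF = "population-af"
RULE_RECURRENCE = "recurrence"
RULE_READ_SUPPORT = "read-support"
RULE_VAF = "vaf"
RULE_COVERAGE = "coverage"
RULE_ALT_READS = "alt-reads"

SOMATIC_RULES = (
    RULE_GENE_PANEL,
    RULE_PATHOGENICITY,
    RULE_POPULATION_AF,
    RULE_RECURRENCE,
    RULE_READ_SUPPORT,
    RULE_VAF,
)
GERMLINE_RULES = (RULE_POPULATION_AF, RULE_COVERAGE, RULE_VAF, RULE_ALT_READS)


@dataclass(frozen=True)
class SomaticFilterConfig:
    max_population_af: float = 0.001
    max_cohort_recurrence: float = 0.05
    min_supporting_reads_exclusive: int = 5  # filtered if alt_reads <= this
    min_vaf_exclusive: float = 0.05          # filtered if vaf <= this
    gene_panel: frozenset = DEFAULT_SOMATIC_PANEL


@dataclass(frozen=True)
class UbtfTdConfig:
    hotspot: GenomicInterval = UBTF_HOTSPOT
    min_supporting_reads: int = 3
    max_caller_score_exclusive: float = 10.0  # retained if score < this
    min_softclip_len: int = 10
    min_softclip_evidence: int = 3
    exon_window: int = 500  # pad around the hotspot approximating exon 13


@dataclass(frozen=True)
class GermlineFilterConfig:
    max_population_af: float = 0.001
    min_cov_snv: int = 20
    min_cov_indel: int = 15
    snv_vaf_range: tuple = (0.2, 0.8)
    min_indel_alt_reads: int = 3
    gene_panel: frozenset = DEFAULT_GERMLINE_PANEL


@dataclass(frozen=True)
class FilterDecision:
    variant: SomaticVariant
    kept: bool
    reasons: tuple = ()

    def __post_init__(self):
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must be true iff no reasons fired")


def _decision(variant: SomaticVariant, reasons: list) -> FilterDecision:
    return FilterDecision(variant=variant, kept=not reasons, reasons=tuple(reasons))


def filter_rna_somatic(
    variants: Sequence[tuple],
    cfg: SomaticFilterConfig = SomaticFilterConfig(),
    n_cases: Optional[int] = None,
) -> list:
    """Screen tumor-only RNA-seq variant calls.

    Parameters
    ----------
    variants
        ``(case_id, SomaticVariant)`` pairs across the cohort; the exact
        allele (chrom, pos, ref, alt) is used for recurrence counting.
    cfg
        Thresholds; defaults mirror the tumor-only screen (panel gene,
        pathogenic/likely-pathogenic, population AF <= 0.1%, allele in
        <= 5% of cases, > 5 supporting reads, VAF > 5%).
    n_cases
        Cohort-recurrence denominator.  Defaults to the number of distinct
        case identifiers in ``variants``; pass explicitly when re-screening
        a subset so that recurrence keeps its original meaning.

    Returns one `FilterDecision` per input record, in input order, with
    every failed rule identifier listed.
    """
    if not variants:
        return []
    case_ids = {cid for cid, _ in variants}
    denom = n_cases if n_cases is not None else len(case_ids)
    carriers: dict = {}
    for cid, var in variants:
        carriers.setdefault(var.allele_key, set()).add(cid)

    decisions = []
    for cid, var in variants:
        reasons = []
        if var.gene not in cfg.gene_panel:
            reasons.append(RULE_GENE_PANEL)
        if not var.is_pathogenic:
            reasons.append(RULE_PATHOGENICITY)
        if var.population_af > cfg.max_population_af:
            reasons.append(RULE_POPULATION_AF)
        if len(carriers[var.allele_key]) / denom > cfg.max_cohort_recurrence:
            reasons.append(RULE_RECURRENCE)
        if var.alt_reads <= cfg.min_supporting_reads_exclusive:
            reasons.append(RULE_READ_SUPPORT)
        if var.vaf <= cfg.min_vaf_exclusive:
            reasons.append(RULE_VAF)
        decisions.append(_decision(var, reasons))
    return decisions


@dataclass(frozen=True)
class UbtfTdDecision:
    """Evidence summary for a UBTF tandem-duplication call.

    Both evidence channels are reported: caller candidates surviving the
    read-support/score screen, and the count of reads soft-clipped by at
    least ``min_softclip_len`` bases inside the hotspot.  The overall call
    is positive if either channel fires.
    """

    retained_candidates: tuple
    softclip_count: int
    total_reads_at_hotspot: int
    positive: bool
    candidate_positive: bool
    softclip_positive: bool


def detect_ubtf_td(
    candidates: Sequence[TandemDupCandidate],
    reads: Sequence[SoftClipRead],
    cfg: UbtfTdConfig = UbtfTdConfig(),
) -> UbtfTdDecision:
    """Detect a UBTF exon-13 tandem duplication for one case."""
    exon_region = cfg.hotspot.padded(cfg.exon_window)
    retained = tuple(
        c
        for c in candidates
        if c.gene == "UBTF"
        and c.interval.overlaps(exon_region)
        and c.supporting_reads >= cfg.min_supporting_reads
        and c.caller_score < cfg.max_caller_score_exclusive
    )
    softclip_count = sum(
        1
        for r in reads
        if r.clip_len >= cfg.min_softclip_len
        and cfg.hotspot.contains(r.chrom, r.clip_pos)
    )
    total_at_hotspot = sum(
        1 for r in reads if cfg.hotspot.contains(r.chrom, r.clip_pos)
    )
    candidate_positive = bool(retained)
    softclip_positive = softclip_count >= cfg.min_softclip_evidence
    return UbtfTdDecision(
        retained_candidates=retained,
        softclip_count=softclip_count,
        total_reads_at_hotspot=total_at_hotspot,
        positive=candidate_positive or softclip_positive,
        candidate_positive=candidate_positive,
        softclip_positive=softclip_positive,
    )


def germline_candidate_filter(
    variants: Sequence[SomaticVariant],
    cfg: GermlineFilterConfig = GermlineFilterConfig(),
) -> list:
    """Apply germline candidate criteria to variants with germline provenance.

    SNVs require coverage >= 20 and VAF in [0.2, 0.8]; indels require
    coverage >= 15 and >= 3 alternative-allele reads; both require
    population allele frequency <= 0.001.  All boundaries inclusive.
    """
    lo, hi = cfg.snv_vaf_range
    decisions = []
    for var in variants:
        reasons = []
        if var.population_af > cfg.max_population_af:
            reasons.append(RULE_POPULATION_AF)
        if var.variant_class == "snv":
            if var.total_reads < cfg.min_cov_snv:
                reasons.append(RULE_COVERAGE)
            if not lo <= var.vaf <= hi:
                reasons.append(RULE_VAF)
        else:
            if var.total_reads < cfg.min_cov_indel:
                reasons.append(RULE_COVERAGE)
            if var.alt_reads < cfg.min_indel_alt_reads:
                reasons.append(RULE_ALT_READS)
        decisions.append(_decision(var, reasons))
    return decisions


def genotype_concordance(
    genotypes_a: dict,
    genotypes_b: dict,
    coverage_a: Optional[dict] = None,
    coverage_b: Optional[dict] = None,
    min_cov: int = 20,
    duplicate_cutoff: float = 0.90,
) -> tuple:
    """Pairwise genotype-fingerprint concordance between two samples.

    Genotype maps are ``{snp_id: genotype call}``; when coverage maps are
    given, SNPs under ``min_cov`` in either sample are excluded.  Returns
    ``(concordance, is_duplicate)`` where the duplicate flag fires at a
    concordance of at least ``duplicate_cutoff`` (default 90%).
    """
    shared = set(genotypes_a) & set(genotypes_b)
    if coverage_a is not None:
        shared = {s for s in shared if coverage_a.get(s, 0) >= min_cov}
    if coverage_b is not None:
        shared = {s for s in shared if coverage_b.get(s, 0) >= min_cov}
    if not shared:
        raise ValueError("no shared SNPs with sufficient coverage")
    concordant = sum(1 for s in shared if genotypes_a[s] == genotypes_b[s])
    fraction = concordant / len(shared)
    return fraction, fraction >= duplicate_cutoff
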