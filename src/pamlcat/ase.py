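"""Allele-specific expression (ASE) assessment from SNP marker read counts.

Structural variants that hijack enhancers (MECOM, BCL11B, MNX1) typically
express only the rearranged allele.  With paired WGS, heterozygous SNP
markers in the gene locus are tested for allelic imbalance in RNA with an
exact two-sided binomial test at success probability 0.5; the median of
the per-marker p-values summarizes the locus.  Without WGS, markers with
adequate RNA coverage support ASE when their RNA allele fractions are
strongly imbalanced (VAF <= 0.2 or >= 0.8).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import binomtest

MIN_RNA_COVERAGE = 10


@dataclass(frozen=True)
class ASEMarker:
    """One SNP marker with RNA allele counts and optional WGS genotyping."""

    snp_id: str
    ref_reads_rna: int
    alt_reads_rna: int
    vaf_wgs: Optional[float] = None
    cov_wgs: Optional[int] = None

    def __post_init__(self):
        if self.ref_reads_rna < 0 or self.alt_reads_rna < 0:
            raise ValueError("read counts must be >= 0")
        if self.vaf_wgs is not None and not 0 <= self.vaf_wgs <= 1:
            raise ValueError("vaf_wgs must be in [0, 1]")

    @property
    def cov_rna(self) -> int:
        return self.ref_reads_rna + self.alt_reads_rna

    @property
    def vaf_rna(self) -> float:
        if self.cov_rna == 0:
            raise ValueError("marker has zero RNA coverage")
        return self.alt_reads_rna / self.cov_rna


@dataclass(frozen=True)
class ASEVerdict:
    """Outcome of an ASE assessment over a marker set.

    ``status`` is ``positive``/``negative``/``supported``/``unsupported``
    (RNA-only mode) or ``indeterminate`` when no marker is eligible.
    """

    status: str
    n_markers: int
    median_p: Optional[float] = None
    imbalanced_fraction: Optional[float] = None

    @property
    def is_positive(self) -> bool:
        return self.status in ("positive", "supported")


def select_het_markers(markers: Sequence[ASEMarker],
                       min_cov_rna: int = MIN_RNA_COVERAGE) -> list:
    """Keep markers heterozygous in WGS (0.2 <= VAF <= 0.8, inclusive)
    with RNA coverage of at least 10x."""
    return [
        m
        for m in markers
        if m.vaf_wgs is not None
        and 0.2 <= m.vaf_wgs <= 0.8
        and m.cov_rna >= min_cov_rna
    ]


def ase_binomial(marker: ASEMarker) -> float:
    """Exact two-sided binomial p-value for allelic imbalance at p = 0.5.

    Two-sided by the minimum-likelihood rule: the p-value sums the
    probabilities of all outcomes no more probable than the observed
    count.  At p = 0.5 this is symmetric in ref/alt.
    """
    if marker.cov_rna == 0:
        raise ValueError("marker has zero RNA coverage")
    return binomtest(marker.alt_reads_rna, marker.cov_rna, 0.5).pvalue


def assess_ase(
    markers: Sequence[ASEMarker],
    mode: str = "wgs_paired",
    alpha: float = 0.05,
    min_imbalanced_fraction: float = 1.0,
) -> ASEVerdict:
    """Assess allele-specific expression over a case's marker set.

    Parameters
    ----------
    markers
        SNP markers in the gene locus.
    mode
        ``wgs_paired``: restrict to WGS-heterozygous markers and call ASE
        when the median binomial p-value falls below ``alpha``.
        ``rna_only``: markers with >= 10x RNA coverage support ASE when
        their RNA VAF is <= 0.2 or >= 0.8; by default every eligible
        marker must be imbalanced (relax with
        ``min_imbalanced_fraction``).

    Returns an `ASEVerdict`; with no eligible markers the status is
    ``indeterminate``, which is distinct from a negative call.
    """
    if mode == "wgs_paired":
        selected = select_het_markers(markers)
        if not selected:
            return ASEVerdict(status="indeterminate", n_markers=0)
        pvals = [ase_binomial(m) for m in selected]
        med = statistics.median(pvals)
        status = "positive" if med < alpha else "negative"
        return ASEVerdict(status=status, n_markers=len(selected), median_p=med)
    if mode == "rna_only":
        eligible = [m for m in markers if m.cov_rna >= MIN_RNA_COVERAGE]
        if not eligible:
            return ASEVerdict(status="indeterminate", n_markers=0)
        imbalanced = [m for m in eligible if m.vaf_rna <= 0.2 or m.vaf_rna >= 0.8]
        frac = len(imbalanced) / len(eligible)
        status = "supported" if frac >= min_imbalanced_fraction else "unsupported"
        return ASEVerdict(
            status=status, n_markers=len(eligible), imbalanced_fraction=frac
        )
    raise ValueError(f"unknown ASE mode: {mode!r}")
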