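"""Cohort-level descriptive statistics.

Percentages are rounded half-up to one decimal, matching the convention
used when such counts are reported in print (e.g. 333 of 887 = 37.5%).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .types import Cohort

#: Genes counted as RAS-pathway (Noonan-syndrome spectrum); configurable.
DEFAULT_RAS_PATHWAY_GENES = frozenset(
    {"NRAS", "KRAS", "PTPN11", "NF1", "CBL", "BRAF", "RIT1", "SOS1"}
)


def percent(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-up to one decimal."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def validation_rate(
    total_rna_calls: int, cross_called: int, additional_read_supported: int
) -> float:
    """Share of RNA-seq variant calls validated by orthogonal DNA data.

    A call validates if it was independently called from WGS/WES
    (``cross_called``) or has supporting reads in the DNA data
    (``additional_read_supported``).
    """
    if total_rna_calls == 0:
        raise ValueError("total_rna_calls must be positive")
    validated = cross_called + additional_read_supported
    if validated > total_rna_calls:
        raise ValueError("validated calls exceed total RNA-seq calls")
    return percent(validated, total_rna_calls)


def _has_pathogenic_fusion(case) -> bool:
    return len(case.fusions) > 0


def _ras_genes_mutated(case, ras_genes) -> set:
    return {
        v.gene
        for v in case.variants
        if v.gene in ras_genes and v.is_pathogenic
    }


def cohort_summary(cohort: Cohort, ras_genes=DEFAULT_RAS_PATHWAY_GENES) -> pd.DataFrame:
    """Summarize a cohort as (metric, numerator, denominator, percent) rows.

    Reported metrics: share at diagnosis vs relapse, share with at least
    one pathogenic fusion/SV, share with at least one RAS-pathway mutation,
    share of RAS-mutant cases with multiple RAS-pathway genes mutated,
    per-category counts and classification coverage (fraction of cases not
    Unclassified, when categories are assigned).
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")

    n_dx = sum(1 for c in cohort if c.clinical and c.clinical.timepoint == "diagnosis")
    n_rel = sum(1 for c in cohort if c.clinical and c.clinical.timepoint == "relapse")
    n_fusion = sum(1 for c in cohort if _has_pathogenic_fusion(c))
    ras_counts = [len(_ras_genes_mutated(c, ras_genes)) for c in cohort]
    n_ras = sum(1 for k in ras_counts if k >= 1)
    n_multi_ras = sum(1 for k in ras_counts if k >= 2)

    rows = [
        ("diagnosis", n_dx, n),
        ("relapse", n_rel, n),
        ("pathogenic_fusion_or_sv", n_fusion, n),
        ("ras_pathway_mutated", n_ras, n),
        ("multi_ras_pathway_mutated", n_multi_ras, max(n_ras, 1) if n_ras else n_ras),
    ]
    # Multi-RAS share is reported among RAS-mutant cases; define 0/0 as 0.
    if n_ras == 0:
        rows[-1] = ("multi_ras_pathway_mutated", 0, n)

    labelled = [c for c in cohort if c.category is not None]
    if labelled:
        n_classified = sum(1 for c in labelled if c.category != "Unclassified")
        rows.append(("classified_coverage", n_classified, len(labelled)))
        counts: dict = {}
        for c in labelled:
            counts[c.category] = counts.get(c.category, 0) + 1
        for label in sorted(counts):
            rows.append((f"category:{label}", counts[label], len(labelled)))

    return pd.DataFrame(
        [
            dict(
                metric=m,
                numerator=num,
                denominator=den,
                percent=percent(num, den) if den else 0.0,
            )
            for m, num, den in rows
        ]
    )
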