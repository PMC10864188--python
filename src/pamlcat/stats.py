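"""Exact co-occurrence and enrichment statistics.

Category-versus-alteration enrichment is assessed with the two-sided
Fisher's exact test (minimum-likelihood rule) and Benjamini-Hochberg
adjustment across the category-by-alteration grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .types import Cohort


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: (category & altered, category & not, rest & altered, rest & not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


def fisher_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Sums the hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed that of the observed table.
    Degenerate margins give p = 1.
    """
    return float(fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


def bh_adjust(pvals: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    pvals = list(pvals)
    if not pvals:
        return []
    if any(not 0 <= p <= 1 for p in pvals):
        raise ValueError("p-values must be in [0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


# Built-in alteration predicates ------------------------------------------


def has_pathogenic_mutation(gene: str) -> Callable:
    def predicate(case) -> bool:
        return any(v.gene == gene and v.is_pathogenic for v in case.variants)

    predicate.__name__ = f"{gene}_mutation"
    return predicate


def has_tandem_dup(gene: str, kind: str | None = None) -> Callable:
    def predicate(case) -> bool:
        return any(
            t.gene == gene and (kind is None or t.kind == kind)
            for t in case.tandem_dups
        )

    predicate.__name__ = f"{gene}_{kind or 'td'}".replace("itd", "ITD")
    return predicate


def enrichment_matrix(
    cohort: Cohort,
    alterations: Mapping[str, Callable],
    labels: Mapping[str, str] | None = None,
    family: str = "global",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Category-by-alteration frequency and enrichment table.

    Parameters
    ----------
    cohort
        A classified cohort; category labels are taken from
        ``case.category`` unless ``labels`` overrides them.
    alterations
        ``{name: predicate(case) -> bool}`` alteration definitions.
    family
        Multiple-testing family: ``global`` adjusts across the whole grid,
        ``per_alteration`` adjusts each alteration's column separately.

    Returns one row per (category, alteration) cell with the within-
    category frequency, Fisher p versus the rest of the cohort, BH q and
    significance flags.  Categories with zero cases are excluded.
    """
    if labels is None:
        labels = {c.case_id: c.category for c in cohort}
    missing = [cid for cid, lab in labels.items() if lab is None]
    if missing:
        raise ValueError(f"unclassified cases in enrichment input: {missing[:3]}")
    cases = {c.case_id: c for c in cohort}
    categories = sorted(set(labels.values()))

    altered = {
        name: {cid for cid, case in cases.items() if pred(case)}
        for name, pred in alterations.items()
    }
    members = {
        cat: {cid for cid, lab in labels.items() if lab == cat}
        for cat in categories
    }

    rows = []
    for cat in categories:
        inside = members[cat]
        outside = set(labels) - inside
        if not inside:
            continue
        for name in alterations:
            a = len(inside & altered[name])
            b = len(inside) - a
            c = len(outside & altered[name])
            d = len(outside) - c
            table = ContingencyTable2x2(a, b, c, d)
            rows.append(
                dict(
                    category=cat,
                    alteration=name,
                    n_category=len(inside),
                    n_altered=a,
                    frequency=a / len(inside),
                    p=fisher_two_sided(table),
                )
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if family == "global":
        df["q"] = bh_adjust(df["p"].tolist())
    elif family == "per_alteration":
        df["q"] = np.nan
        for name in alterations:
            mask = df["alteration"] == name
            df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].tolist())
    else:
        raise ValueError(f"unknown multiple-testing family: {family!r}")
    df["sig_p"] = df["p"] < alpha
    df["sig_q"] = df["q"] < alpha
    return df
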