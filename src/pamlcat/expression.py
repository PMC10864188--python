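"""Expression preprocessing, signature scoring and two-group DE.

The pipeline works on bulk RNA-seq gene counts: genes are filtered for
expression (cpm >= 10 in at least five samples), transformed to
log2(cpm) with negative values floored at zero, and summarized either by
variance (variable-gene selection) or by z-scored signature means.  HOX
superfamily assignment replaces cluster-based grouping with transparent
signature thresholds: the HOXA group shows high HOXA and low HOXB
signature expression, while the HOXB group expresses both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

UNITS = ("raw_counts", "log2cpm")

#: Transparent stand-ins for the HOXA/HOXB expression-cluster memberships.
HOXA_SIGNATURE_GENES = frozenset({"HOXA9", "HOXA10", "MEIS1"})
HOXB_SIGNATURE_GENES = frozenset({"HOXB2", "HOXB3", "HOXB4", "HOXB5"})
#: Megakaryocytic marker genes used as the expression-consistency check
#: for the GATA1 category.
AMKL_SIGNATURE_GENES = frozenset({"PF4", "ITGA2B", "GP9"})


@dataclass
class ExpressionMatrix:
    """Genes-by-samples matrix with a units tag.

    ``data`` is a pandas DataFrame indexed by gene symbol with case_id
    columns; ``units`` is ``raw_counts`` or ``log2cpm``.
    """

    data: pd.DataFrame
    units: str = "raw_counts"

    def __post_init__(self):
        if self.units not in UNITS:
            raise ValueError(f"unknown units tag: {self.units!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")

    @property
    def genes(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)


@dataclass(frozen=True)
class SignatureSet:
    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError("signature gene set must be non-empty")


HOXA_SIGNATURE = SignatureSet("HOXA", HOXA_SIGNATURE_GENES)
HOXB_SIGNATURE = SignatureSet("HOXB", HOXB_SIGNATURE_GENES)
AMKL_SIGNATURE = SignatureSet("AMKL", AMKL_SIGNATURE_GENES)


@dataclass(frozen=True)
class HoxThresholds:
    """Signature-score cuts for HOX superfamily assignment."""

    t_high: float = 0.5
    t_low: float = 0.0


def filter_expressed(
    m: ExpressionMatrix, min_cpm: float = 10.0, min_samples: int = 5
) -> ExpressionMatrix:
    """Keep genes with cpm >= ``min_cpm`` in at least ``min_samples`` samples."""
    if m.units != "raw_counts":
        raise ValueError("filter_expressed requires raw counts")
    counts = m.data.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if np.any(libsize == 0):
        bad = [m.samples[i] for i in np.where(libsize == 0)[0]]
        raise ValueError(f"zero library size for samples: {bad}")
    cpm = counts / libsize * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return ExpressionMatrix(data=m.data.loc[keep], units="raw_counts")


def log2cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Transform counts to log2(cpm), flooring values below zero at zero.

    Zero counts map to 0 exactly (their cpm is zero, and the floor
    applies), so the output is non-negative everywhere.
    """
    if m.units != "raw_counts":
        raise ValueError("log2cpm requires raw counts")
    counts = m.data.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if np.any(libsize == 0):
        bad = [m.samples[i] for i in np.where(libsize == 0)[0]]
        raise ValueError(f"zero library size for samples: {bad}")
    cpm = counts / libsize * 1e6
    with np.errstate(divide="ignore"):
        values = np.log2(cpm)
    values = np.maximum(values, 0.0)
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=m.data.index, columns=m.data.columns),
        units="log2cpm",
    )


def select_variable_genes(m: ExpressionMatrix, n: int = 315) -> SignatureSet:
    """Top-``n`` genes by log2-cpm variance, ties broken by gene symbol."""
    if m.units != "log2cpm":
        raise ValueError("select_variable_genes requires log2cpm units")
    if n > len(m.genes):
        raise ValueError("n exceeds gene count")
    variances = m.data.var(axis=1, ddof=1)
    order = sorted(m.genes, key=lambda g: (-variances[g], g))
    return SignatureSet(name=f"top{n}_variable", genes=frozenset(order[:n]))


def _zscore_matrix(m: ExpressionMatrix, genes) -> pd.DataFrame:
    """Per-gene z-scores across samples (population SD); zero-variance
    genes give all-zero rows."""
    present = [g for g in m.genes if g in genes]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    sub = m.data.loc[present]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z


def signature_score(m: ExpressionMatrix, sig: SignatureSet, case: str) -> float:
    """Mean per-gene z-score of the signature genes for one case."""
    z = _zscore_matrix(m, sig.genes)
    if case not in z.columns:
        raise KeyError(case)
    return float(z[case].mean())


def signature_scores(m: ExpressionMatrix, sig: SignatureSet) -> pd.Series:
    """Vectorized `signature_score` over every sample."""
    return _zscore_matrix(m, sig.genes).mean(axis=0)


def hox_group_assign(
    m: ExpressionMatrix,
    hoxa_sig: SignatureSet = HOXA_SIGNATURE,
    hoxb_sig: SignatureSet = HOXB_SIGNATURE,
    thresholds: HoxThresholds = HoxThresholds(),
) -> pd.Series:
    """Assign each sample to the HOXA group, HOXB group or ``other``.

    HOXA: HOXA score >= t_high and HOXB score <= t_low (high HOXA, low
    HOXB).  HOXB: both scores >= t_high (high HOXA and HOXB).  Everything
    else is ``other``.
    """
    a = signature_scores(m, hoxa_sig)
    b = signature_scores(m, hoxb_sig)
    labels = []
    for s in m.samples:
        if a[s] >= thresholds.t_high and b[s] >= thresholds.t_high:
            labels.append("HOXB")
        elif a[s] >= thresholds.t_high and b[s] <= thresholds.t_low:
            labels.append("HOXA")
        else:
            labels.append("other")
    return pd.Series(labels, index=m.samples, name="hox_group")


def outlier_expression_flag(
    m: ExpressionMatrix, gene: str, case: str, z_cut: float = 3.0
) -> bool:
    """True when a case's expression of ``gene`` is >= ``z_cut`` SDs above
    the cohort mean.  A zero-variance gene can never flag (warns)."""
    if gene not in m.data.index:
        raise KeyError(gene)
    row = m.data.loc[gene]
    sd = float(row.std(ddof=0))
    if sd == 0:
        warnings.warn(f"gene {gene} has zero variance; outlier flag is False")
        return False
    z = (float(row[case]) - float(row.mean())) / sd
    return z >= z_cut


def differential_expression(
    m: ExpressionMatrix,
    group_a,
    group_b,
    fc_cut: float = 2.0,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression on log2-cpm values.

    Per-gene Welch two-sample t-test, Benjamini-Hochberg adjusted.  Fold
    change is computed on the cpm scale from the difference of group
    means of log2-cpm; a gene is significant when |fold change| exceeds
    ``fc_cut`` and FDR is below ``fdr_cut``.  Genes with no variance in
    either group get p = 1.
    """
    if m.units != "log2cpm":
        raise ValueError("differential_expression requires log2cpm units")
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least two samples")
    xa = m.data[group_a].to_numpy(dtype=float)
    xb = m.data[group_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = _sps.ttest_ind(xa, xb, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    fold = np.power(2.0, log2fc)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    # |fold change| > fc_cut means fc_cut-fold in either direction.
    sig = ((fold > fc_cut) | (fold < 1.0 / fc_cut)) & (fdr < fdr_cut)
    return pd.DataFrame(
        dict(
            gene=m.genes,
            log2_fold_change=log2fc,
            fold_change=fold,
            p_value=pvals,
            fdr=fdr,
            significant=sig,
        )
    ).set_index("gene")
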