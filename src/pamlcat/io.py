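"""Readers and writers for the plain-text evidence dialects.

A cohort on disk is a directory of TSV tables sharing a ``case_id`` key:

``fusions.tsv``
    case_id, gene_a, gene_b, in_frame, supporting_reads, caller_score, source
``variants.tsv``
    case_id, gene, chrom, pos, ref, alt, vaf, alt_reads, total_reads,
    population_af, pathogenicity, variant_class
``tandem_dups.tsv``
    case_id, gene, chrom, start, end, build, supporting_reads,
    caller_score, kind
``karyotype.tsv``
    case_id, complex_karyotype, monosomy7, other_events (``;``-joined)
``clinical.tsv``
    case_id, age_years, timepoint, mrd_positive, os_time, os_event,
    efs_time, efs_event, nonresponse, relapse_flag

Booleans are written ``true``/``false``; missing optionals are empty
fields.  Variants may alternatively be supplied as VCF 4.x, with the
gene/VAF/annotation fields mapped from INFO keys via `VcfFieldMap`.
Expression matrices are read from a genes-by-samples TSV or a
MatrixMarket triplet plus row/column name files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io

from .types import (
    Case,
    ClinicalRecord,
    Cohort,
    FusionCall,
    GenomicInterval,
    KaryotypeRecord,
    SomaticVariant,
)

TABLE_FILES = {
    "fusions": "fusions.tsv",
    "variants": "variants.tsv",
    "tandem_dups": "tandem_dups.tsv",
    "karyotype": "karyotype.tsv",
    "clinical": "clinical.tsv",
}


class CohortFormatError(ValueError):
    """Raised for malformed evidence tables; includes the offending line."""


def _fmt_bool(value) -> str:
    if value is None:
        return ""
    return "true" if value else "false"


def _parse_bool(token, *, line: int, path: str, optional: bool = False):
    if token is None or (isinstance(token, float) and math.isnan(token)) or token == "":
        if optional:
            return None
        raise CohortFormatError(f"{path}:{line}: missing boolean value")
    token = str(token).strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no"):
        return False
    raise CohortFormatError(f"{path}:{line}: unknown boolean token: {token!r}")


def _opt_float(token):
    if token is None or token == "" or (isinstance(token, float) and math.isnan(token)):
        return None
    return float(token)


def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _rows(df: pd.DataFrame):
    """Yield (1-based data line number incl. header, row) pairs."""
    for i, row in enumerate(df.itertuples(index=False), start=2):
        yield i, row._asdict()


# ---------------------------------------------------------------------------
# per-table parsers


def read_fusion_table(path: str) -> dict:
    out: dict = {}
    for line, r in _rows(_read_tsv(path)):
        try:
            call = FusionCall(
                gene_a=r["gene_a"],
                gene_b=r["gene_b"],
                in_frame=_parse_bool(r["in_frame"], line=line, path=path),
                supporting_reads=int(r["supporting_reads"]),
                caller_score=float(r["caller_score"]),
                source=r["source"],
            )
        except (ValueError, KeyError) as exc:
            raise CohortFormatError(f"{path}:{line}: {exc}") from exc
        out.setdefault(r["case_id"], []).append(call)
    return out


def read_variant_table(path: str) -> dict:
    out: dict = {}
    for line, r in _rows(_read_tsv(path)):
        try:
            var = SomaticVariant(
                gene=r["gene"],
                chrom=r["chrom"],
                pos=int(r["pos"]),
                ref=r["ref"],
                alt=r["alt"],
                vaf=float(r["vaf"]),
                alt_reads=int(r["alt_reads"]),
                total_reads=int(r["total_reads"]),
                population_af=float(r["population_af"]),
                pathogenicity=r["pathogenicity"],
                variant_class=r["variant_class"],
            )
        except (ValueError, KeyError) as exc:
            raise CohortFormatError(f"{path}:{line}: {exc}") from exc
        out.setdefault(r["case_id"], []).append(var)
    return out


def read_tandem_dup_table(path: str) -> dict:
    from .types import TandemDupCandidate

    out: dict = {}
    for line, r in _rows(_read_tsv(path)):
        try:
            td = TandemDupCandidate(
                gene=r["gene"],
                interval=GenomicInterval(
                    r["chrom"], int(r["start"]), int(r["end"]), r["build"]
                ),
                supporting_reads=int(r["supporting_reads"]),
                caller_score=float(r["caller_score"]),
                kind=r["kind"],
            )
        except (ValueError, KeyError) as exc:
            raise CohortFormatError(f"{path}:{line}: {exc}") from exc
        out.setdefault(r["case_id"], []).append(td)
    return out


def read_karyotype_table(path: str) -> dict:
    out: dict = {}
    for line, r in _rows(_read_tsv(path)):
        events = tuple(t for t in r["other_events"].split(";") if t)
        out[r["case_id"]] = KaryotypeRecord(
            complex_karyotype=_parse_bool(
                r["complex_karyotype"], line=line, path=path
            ),
            monosomy7=_parse_bool(r["monosomy7"], line=line, path=path),
            other_events=events,
        )
    return out


def read_clinical_table(path: str) -> dict:
    out: dict = {}
    for line, r in _rows(_read_tsv(path)):
        try:
            rec = ClinicalRecord(
                age_years=float(r["age_years"]),
                timepoint=r["timepoint"],
                mrd_positive=_parse_bool(
                    r["mrd_positive"], line=line, path=path, optional=True
                ),
                os_time=float(r["os_time"]),
                os_event=_parse_bool(r["os_event"], line=line, path=path),
                efs_time=_opt_float(r["efs_time"]),
                efs_event=_parse_bool(
                    r["efs_event"], line=line, path=path, optional=True
                ),
                nonresponse=_parse_bool(
                    r["nonresponse"], line=line, path=path, optional=True
                ),
                relapse_flag=_parse_bool(
                    r["relapse_flag"], line=line, path=path, optional=True
                ),
            )
        except (ValueError, KeyError) as exc:
            raise CohortFormatError(f"{path}:{line}: {exc}") from exc
        if r["case_id"] in out:
            raise CohortFormatError(
                f"{path}:{line}: duplicate case_id: {r['case_id']!r}"
            )
        out[r["case_id"]] = rec
    return out


# ---------------------------------------------------------------------------
# VCF ingestion


@dataclass(frozen=True)
class VcfFieldMap:
    """INFO-key mapping used when ingesting variants from VCF."""

    gene: str = "GENE"
    vaf: str = "VAF"
    population_af: str = "POP_AF"
    pathogenicity: str = "PATH"
    variant_class: str = "VCLASS"
    alt_reads: str = "ALT_READS"
    total_reads: str = "DP"


def _info_scalar(value):
    if isinstance(value, tuple):
        value = value[0]
    return value


def read_variants_vcf(path: str, case_id: str, field_map: VcfFieldMap | None = None) -> list:
    """Read one case's variants from a VCF 4.x file.

    Annotation fields live in INFO under the keys named by ``field_map``;
    missing VAF is recomputed from the read counts.
    """
    import pysam

    fm = field_map or VcfFieldMap()
    variants = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = rec.info
            alt_reads = int(_info_scalar(info[fm.alt_reads]))
            total_reads = int(_info_scalar(info[fm.total_reads]))
            vaf = (
                float(_info_scalar(info[fm.vaf]))
                if fm.vaf in info
                else alt_reads / total_reads
            )
            variants.append(
                SomaticVariant(
                    gene=str(_info_scalar(info[fm.gene])),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    vaf=vaf,
                    alt_reads=alt_reads,
                    total_reads=total_reads,
                    population_af=float(_info_scalar(info.get(fm.population_af, 0.0))),
                    pathogenicity=str(_info_scalar(info[fm.pathogenicity])),
                    variant_class=str(_info_scalar(info[fm.variant_class])),
                )
            )
    return variants


# ---------------------------------------------------------------------------
# cohort-level read/write


def read_cohort(directory: str) -> Cohort:
    """Assemble a validated `Cohort` from a directory of TSV tables.

    The clinical table is the case roster: every case listed there becomes
    a `Case`, with evidence attached from the other tables.  Duplicate
    identifiers or unknown enum tokens raise `CohortFormatError` naming
    the offending value and line.
    """
    paths = {k: os.path.join(directory, v) for k, v in TABLE_FILES.items()}
    clinical = read_clinical_table(paths["clinical"])
    fusions = (
        read_fusion_table(paths["fusions"]) if os.path.exists(paths["fusions"]) else {}
    )
    variants = (
        read_variant_table(paths["variants"])
        if os.path.exists(paths["variants"])
        else {}
    )
    tds = (
        read_tandem_dup_table(paths["tandem_dups"])
        if os.path.exists(paths["tandem_dups"])
        else {}
    )
    karyo = (
        read_karyotype_table(paths["karyotype"])
        if os.path.exists(paths["karyotype"])
        else {}
    )
    cases = [
        Case(
            case_id=cid,
            fusions=fusions.get(cid, []),
            variants=variants.get(cid, []),
            tandem_dups=tds.get(cid, []),
            karyotype=karyo.get(cid, KaryotypeRecord()),
            clinical=rec,
        )
        for cid, rec in clinical.items()
    ]
    return Cohort(cases=cases)


def write_cohort(cohort: Cohort, directory: str) -> None:
    """Write a cohort back to the TSV dialects (inverse of `read_cohort`)."""
    os.makedirs(directory, exist_ok=True)
    fus_rows, var_rows, td_rows, karyo_rows, clin_rows = [], [], [], [], []
    for case in cohort:
        cid = case.case_id
        for f in case.fusions:
            fus_rows.append(
                dict(
                    case_id=cid,
                    gene_a=f.gene_a,
                    gene_b=f.gene_b,
                    in_frame=_fmt_bool(f.in_frame),
                    supporting_reads=f.supporting_reads,
                    caller_score=f.caller_score,
                    source=f.source,
                )
            )
        for v in case.variants:
            var_rows.append(
                dict(
                    case_id=cid,
                    gene=v.gene,
                    chrom=v.chrom,
                    pos=v.pos,
                    ref=v.ref,
                    alt=v.alt,
                    vaf=v.vaf,
                    alt_reads=v.alt_reads,
                    total_reads=v.total_reads,
                    population_af=v.population_af,
                    pathogenicity=v.pathogenicity,
                    variant_class=v.variant_class,
                )
            )
        for t in case.tandem_dups:
            td_rows.append(
                dict(
                    case_id=cid,
                    gene=t.gene,
                    chrom=t.interval.chrom,
                    start=t.interval.start,
                    end=t.interval.end,
                    build=t.interval.build,
                    supporting_reads=t.supporting_reads,
                    caller_score=t.caller_score,
                    kind=t.kind,
                )
            )
        karyo_rows.append(
            dict(
                case_id=cid,
                complex_karyotype=_fmt_bool(case.karyotype.complex_karyotype),
                monosomy7=_fmt_bool(case.karyotype.monosomy7),
                other_events=";".join(case.karyotype.other_events),
            )
        )
        c = case.clinical
        if c is None:
            raise ValueError(f"case {cid!r} lacks a clinical record")
        clin_rows.append(
            dict(
                case_id=cid,
                age_years=c.age_years,
                timepoint=c.timepoint,
                mrd_positive=_fmt_bool(c.mrd_positive),
                os_time=c.os_time,
                os_event=_fmt_bool(c.os_event),
                efs_time="" if c.efs_time is None else c.efs_time,
                efs_event=_fmt_bool(c.efs_event),
                nonresponse=_fmt_bool(c.nonresponse),
                relapse_flag=_fmt_bool(c.relapse_flag),
            )
        )
    specs = [
        ("fusions", fus_rows, ["case_id", "gene_a", "gene_b", "in_frame",
                               "supporting_reads", "caller_score", "source"]),
        ("variants", var_rows, ["case_id", "gene", "chrom", "pos", "ref", "alt",
                                "vaf", "alt_reads", "total_reads", "population_af",
                                "pathogenicity", "variant_class"]),
        ("tandem_dups", td_rows, ["case_id", "gene", "chrom", "start", "end",
                                  "build", "supporting_reads", "caller_score",
                                  "kind"]),
        ("karyotype", karyo_rows, ["case_id", "complex_karyotype", "monosomy7",
                                   "other_events"]),
        ("clinical", clin_rows, ["case_id", "age_years", "timepoint",
                                 "mrd_positive", "os_time", "os_event",
                                 "efs_time", "efs_event", "nonresponse",
                                 "relapse_flag"]),
    ]
    for name, rows, columns in specs:
        pd.DataFrame(rows, columns=columns).to_csv(
            os.path.join(directory, TABLE_FILES[name]), sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_tsv(path: str, units: str = "raw_counts"):
    from .expression import ExpressionMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(data=df, units=units)


def write_expression_tsv(matrix, path: str) -> None:
    matrix.data.to_csv(path, sep="\t")


def read_expression_mtx(mtx_path: str, genes_path: str, samples_path: str,
                        units: str = "raw_counts"):
    """Read a MatrixMarket genes-by-samples matrix with sidecar name files."""
    from .expression import ExpressionMatrix

    mat = scipy.io.mmread(mtx_path)
    genes = [line.strip() for line in open(genes_path) if line.strip()]
    samples = [line.strip() for line in open(samples_path) if line.strip()]
    df = pd.DataFrame(np.asarray(mat.todense() if hasattr(mat, "todense") else mat),
                      index=genes, columns=samples)
    return ExpressionMatrix(data=df, units=units)


# ---------------------------------------------------------------------------
# ASE marker tables


def read_ase_table(path: str) -> dict:
    """Read ASE markers into ``{case_id: {gene: [ASEMarker, ...]}}``."""
    from .ase import ASEMarker

    out: dict = {}
    for line, r in _rows(_read_tsv(path)):
        try:
            marker = ASEMarker(
                snp_id=r["snp_id"],
                ref_reads_rna=int(r["ref_reads_rna"]),
                alt_reads_rna=int(r["alt_reads_rna"]),
                vaf_wgs=_opt_float(r["vaf_wgs"]),
                cov_wgs=None if r["cov_wgs"] == "" else int(r["cov_wgs"]),
            )
        except (ValueError, KeyError) as exc:
            raise CohortFormatError(f"{path}:{line}: {exc}") from exc
        out.setdefault(r["case_id"], {}).setdefault(r["gene"], []).append(marker)
    return out


def write_ase_table(markers: dict, path: str) -> None:
    rows = []
    for cid, by_gene in markers.items():
        for gene, ms in by_gene.items():
            for m in ms:
                rows.append(
                    dict(
                        case_id=cid,
                        gene=gene,
                        snp_id=m.snp_id,
                        ref_reads_rna=m.ref_reads_rna,
                        alt_reads_rna=m.alt_reads_rna,
                        vaf_wgs="" if m.vaf_wgs is None else m.vaf_wgs,
                        cov_wgs="" if m.cov_wgs is None else m.cov_wgs,
                    )
                )
    pd.DataFrame(
        rows,
        columns=["case_id", "gene", "snp_id", "ref_reads_rna",
                 "alt_reads_rna", "vaf_wgs", "cov_wgs"],
    ).to_csv(path, sep="\t", index=False)
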