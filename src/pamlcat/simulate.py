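"""Seeded synthetic pAML cohort generator with full ground truth.

The generator emits cohorts with the statistical structure the analysis
pipeline assumes: each case draws a molecular category, receives that
category's defining evidence (fusion, mutation, tandem duplication, or SV
with skewed allele-specific expression and outlier expression),
category-conditional cooperating mutations (FLT3-ITD and WT1 enriched in
HOXB-signature categories, KRAS in HOXA-signature categories, NRAS
broadly), negative-binomial expression counts with category-shifted
signature blocks, MRD status, and exponential survival with uniform
censoring whose hazard depends on the risk stratum.

Defining evidence is always generated above the corresponding screening
thresholds, so detection modules see no accidental sub-threshold truth.
Every draw comes from one seeded generator: a fixed seed reproduces the
outputs exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ase import ASEMarker
from .expression import ExpressionMatrix
from .screen import UBTF_HOTSPOT
from .types import (
    Case,
    ClinicalRecord,
    Cohort,
    FusionCall,
    GenomicInterval,
    KaryotypeRecord,
    SomaticVariant,
    TandemDupCandidate,
)

# ---------------------------------------------------------------------------
# default study conditions

DEFAULT_CATEGORY_FREQS = {
    "KMT2Ar": 0.203,
    "RUNX1::RUNX1T1": 0.124,
    "NUP98r": 0.090,
    "NPM1": 0.076,
    "CBFB::MYH11": 0.065,
    "CEBPA": 0.055,
    "UBTF": 0.045,
    "GATA1": 0.025,
    "APL": 0.020,
    "MECOM": 0.020,
    "GLISr": 0.020,
    "BCL11B": 0.020,
    "KMT2A-PTD": 0.020,
    "FET::ETS": 0.015,
    "PICALM::MLLT10": 0.015,
    "KAT6Ar": 0.015,
    "DEK::NUP214": 0.015,
    "HOXr": 0.015,
    "RBM15::MRTFA": 0.010,
    "BCR::ABL1": 0.010,
    "MNX1": 0.010,
    "RUNX1::RUNX1T1-like": 0.010,
    "CBFB-GDXY": 0.010,
    "Unclassified": 0.092,
}

#: HOX superfamily membership planted into expression.
HOX_GROUP_OF_CATEGORY = {
    "KMT2Ar": "HOXA",
    "KAT6Ar": "HOXA",
    "HOXr": "HOXA",
    "NPM1": "HOXB",
    "NUP98r": "HOXB",
    "UBTF": "HOXB",
    "KMT2A-PTD": "HOXB",
    "DEK::NUP214": "HOXB",
}

#: Cooperating-mutation probabilities: enriched categories vs. baseline.
DEFAULT_COOP_MUTATIONS = {
    "FLT3-ITD": {
        "default": 0.05,
        "by_category": {
            "NUP98r": 0.60, "NPM1": 0.60, "UBTF": 0.60,
            "KMT2A-PTD": 0.60, "BCL11B": 0.60,
        },
    },
    "WT1": {
        "default": 0.03,
        "by_category": {"NUP98r": 0.40, "UBTF": 0.40, "BCL11B": 0.40},
    },
    "KRAS": {
        "default": 0.04,
        "by_category": {"KMT2Ar": 0.30, "KAT6Ar": 0.30, "HOXr": 0.30},
    },
    "NRAS": {"default": 0.18, "by_category": {}},
}

#: Stratum hazards (events per year) for exponential survival times,
#: monotone in risk group and MRD positivity.
DEFAULT_STRATUM_HAZARDS = {
    ("low", False): 0.03,
    ("low", True): 0.08,
    ("intermediate", False): 0.15,
    ("intermediate", True): 0.28,
    ("high", False): 0.50,
    ("high", True): 0.90,
}

DEFAULT_MRD_PROBS = {"low": 0.15, "intermediate": 0.30, "high": 0.45}

FUSION_PARTNERS = {
    "APL": [("PML", "RARA"), ("TBL1XR1", "RARB")],
    "RUNX1::RUNX1T1": [("RUNX1", "RUNX1T1")],
    "CBFB::MYH11": [("CBFB", "MYH11")],
    "RBM15::MRTFA": [("RBM15", "MRTFA")],
    "DEK::NUP214": [("DEK", "NUP214")],
    "BCR::ABL1": [("BCR", "ABL1")],
    "PICALM::MLLT10": [("PICALM", "MLLT10")],
    "RUNX1::RUNX1T1-like": [("RUNX1", "CBFA2T2"), ("RUNX1", "CBFA2T3")],
    "NUP98r": [("NUP98", "NSD1"), ("NUP98", "KDM5A"), ("NUP98", "BPTF")],
    "KMT2Ar": [("KMT2A", "MLLT3"), ("KMT2A", "MLLT10"), ("KMT2A", "AFDN"),
               ("KMT2A", "ELL"), ("KMT2A", "MLLT1")],
    "KAT6Ar": [("KAT6A", "CREBBP"), ("KAT6A", "EP300")],
    "GLISr": [("CBFA2T3", "GLIS2"), ("GLIS3", "PAX5")],
    "FET::ETS": [("FUS", "ERG"), ("EWSR1", "FLI1")],
    "HOXr": [("HOXA9", "ETV6"), ("HOXB8", "MYB")],
}

SV_PARTNERS = {"MECOM": "RPN1", "BCL11B": "CDK6", "MNX1": "ETV6"}

#: Infant-enriched (megakaryoblastic/erythroid phenotype) categories.
INFANT_CATEGORIES = frozenset({"GATA1", "RBM15::MRTFA", "GLISr", "MNX1"})

MUTATION_LOCI = {
    "NPM1": ("chr5", 170837543, "C", "CTCTG", "indel"),
    "CEBPA": ("chr19", 33792244, "C", "CAG", "indel"),
    "CBFB": ("chr16", 67116211, "G", "GGACTACTAT", "indel"),
    "GATA1": ("chrX", 48650264, "G", "GA", "indel"),
    "WT1": ("chr11", 32417945, "C", "T", "snv"),
    "KRAS": ("chr12", 25398284, "C", "T", "snv"),
    "NRAS": ("chr1", 115258747, "C", "T", "snv"),
    "TP53": ("chr17", 7577538, "C", "T", "snv"),
    "ETV6": ("chr12", 12022903, "C", "T", "snv"),
}

SIGNATURE_BLOCKS = {
    "HOXA": ("HOXA9", "HOXA10", "MEIS1"),
    "HOXB": ("HOXB2", "HOXB3", "HOXB4", "HOXB5"),
    "AMKL": ("PF4", "ITGA2B", "GP9"),
    "MECOM": ("MECOM",),
    "BCL11B": ("BCL11B",),
    "MNX1": ("MNX1",),
}


@dataclass
class GeneratorConfig:
    """All frequencies, effect sizes, hazards and the seed.

    Defaults are chosen for clear separation between the planted
    structures (strong defining evidence, 32-fold signature shifts, 0.9
    ASE allele fraction, well-spaced stratum hazards) so that recovery by
    the analysis modules is determined by correctness, not luck.
    """

    n_cases: int = 500
    seed: int = 0
    category_freqs: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FREQS)
    )
    coop_mutation_probs: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_COOP_MUTATIONS)
    )
    signature_log2_effect: float = 5.0
    nb_dispersion: float = 10.0
    n_filler_genes: int = 150
    ase_skew: float = 0.9
    ase_markers_per_case: int = 5
    survival_hazards: dict = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_HAZARDS)
    )
    censor_horizon_years: float = 10.0
    mrd_probs: dict = field(default_factory=lambda: dict(DEFAULT_MRD_PROBS))
    mrd_missing_prob: float = 0.05
    diagnosis_prob: float = 0.883
    nonresponse_prob: float = 0.02

    def validate(self) -> None:
        total = sum(self.category_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category frequencies sum to {total}, not 1")
        for entry in self.coop_mutation_probs.values():
            probs = [entry["default"], *entry["by_category"].values()]
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError("cooperating-mutation probabilities must be in [0,1]")
        if any(h <= 0 for h in self.survival_hazards.values()):
            raise ValueError("hazards must be > 0")
        if not 0 <= self.ase_skew <= 1:
            raise ValueError("ase_skew must be in [0,1]")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")


def planted_enrichments(config: GeneratorConfig) -> list:
    """(category, mutation) pairs planted above baseline by the config."""
    pairs = []
    for mutation, entry in config.coop_mutation_probs.items():
        for category, p in entry["by_category"].items():
            if p > entry["default"]:
                pairs.append((category, mutation))
    return pairs


def planted_group_enrichments(config: GeneratorConfig) -> dict:
    """Mutation -> HOX superfamily carrying its planted enrichment.

    The cooperating-mutation structure is planted along the HOX
    superfamilies (FLT3-ITD and WT1 in HOXB-signature categories, KRAS
    in HOXA-signature categories); the mapping is the majority HOX group
    among each mutation's enriched categories.
    """
    out = {}
    for mutation, entry in config.coop_mutation_probs.items():
        groups = [
            HOX_GROUP_OF_CATEGORY.get(c, "other")
            for c, p in entry["by_category"].items()
            if p > entry["default"]
        ]
        hox = [g for g in groups if g != "other"]
        if hox:
            out[mutation] = max(set(hox), key=hox.count)
    return out


def powered_planted_pairs(
    config: GeneratorConfig, min_expected_carriers: float = 12.0
) -> list:
    """Planted (category, mutation) pairs with adequate expected support.

    A per-category enrichment cell is considered powered when the
    expected number of mutation carriers inside the category
    (``n_cases * category frequency * planted probability``) reaches
    ``min_expected_carriers``; smaller planted cells exist in the
    configuration but cannot be individually resolved against the
    cohort-wide baseline at the configured cohort size.
    """
    pairs = []
    for mutation, entry in config.coop_mutation_probs.items():
        for category, p in entry["by_category"].items():
            expected = config.n_cases * config.category_freqs.get(category, 0) * p
            if p > entry["default"] and expected >= min_expected_carriers:
                pairs.append((category, mutation))
    return pairs


def risk_group_of(category: str) -> str:
    from .survival import DEFAULT_RISK_GROUPS

    return DEFAULT_RISK_GROUPS.get(category, "intermediate")


def _defining_variant(rng, gene: str) -> SomaticVariant:
    chrom, pos, ref, alt, vclass = MUTATION_LOCI[gene]
    # spread hotspot alleles over nearby positions so no exact allele
    # recurs in >5% of a cohort (mirrors real hotspot allele diversity)
    pos = pos + int(rng.integers(0, 20))
    total = int(rng.integers(30, 101))
    vaf = float(rng.uniform(0.25, 0.6))
    alt_reads = max(6, int(round(vaf * total)))
    return SomaticVariant(
        gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
        vaf=alt_reads / total, alt_reads=alt_reads, total_reads=total,
        population_af=0.0, pathogenicity="pathogenic", variant_class=vclass,
    )


def _coop_alteration(rng, case: Case, mutation: str) -> None:
    if mutation == "FLT3-ITD":
        case.tandem_dups.append(
            TandemDupCandidate(
                gene="FLT3",
                interval=GenomicInterval("chr13", 28608219, 28608300),
                supporting_reads=int(rng.integers(10, 51)),
                caller_score=float(rng.uniform(0, 9)),
                kind="itd",
            )
        )
    else:
        case.variants.append(_defining_variant(rng, mutation))


def _defining_evidence(rng, case: Case, category: str) -> None:
    if category in FUSION_PARTNERS:
        pair = FUSION_PARTNERS[category][
            int(rng.integers(len(FUSION_PARTNERS[category])))
        ]
        case.fusions.append(
            FusionCall(
                gene_a=pair[0], gene_b=pair[1], in_frame=True,
                supporting_reads=int(rng.integers(10, 80)),
                caller_score=float(rng.uniform(20, 80)),
                source="rna_fusion",
            )
        )
    elif category in SV_PARTNERS:
        case.fusions.append(
            FusionCall(
                gene_a=category, gene_b=SV_PARTNERS[category], in_frame=False,
                supporting_reads=int(rng.integers(8, 40)),
                caller_score=float(rng.uniform(20, 80)),
                source="dna_sv",
            )
        )
    elif category in ("NPM1", "CEBPA", "GATA1"):
        case.variants.append(_defining_variant(rng, category))
    elif category == "CBFB-GDXY":
        case.variants.append(_defining_variant(rng, "CBFB"))
    elif category == "UBTF":
        case.tandem_dups.append(
            TandemDupCandidate(
                gene="UBTF",
                interval=GenomicInterval(
                    UBTF_HOTSPOT.chrom, UBTF_HOTSPOT.start - 10,
                    UBTF_HOTSPOT.end + 10,
                ),
                supporting_reads=int(rng.integers(3, 31)),
                caller_score=float(rng.uniform(0, 9)),
                kind="itd" if rng.random() < 0.7 else "ptd",
            )
        )
    elif category == "KMT2A-PTD":
        case.tandem_dups.append(
            TandemDupCandidate(
                gene="KMT2A",
                interval=GenomicInterval("chr11", 118342377, 118345030),
                supporting_reads=int(rng.integers(3, 31)),
                caller_score=float(rng.uniform(0, 9)),
                kind="ptd",
            )
        )
    elif category == "Unclassified":
        # non-defining pathogenic alterations only
        if rng.random() < 0.5:
            case.variants.append(
                _defining_variant(rng, "TP53" if rng.random() < 0.5 else "ETV6")
            )
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"no evidence emitter for category {category!r}")


def _expression_matrix(rng, config, case_ids, categories) -> ExpressionMatrix:
    hox_of = [HOX_GROUP_OF_CATEGORY.get(c, "other") for c in categories]
    sig_genes = [g for block in SIGNATURE_BLOCKS.values() for g in block]
    filler = [f"GENE{i:04d}" for i in range(1, config.n_filler_genes + 1)]
    low = [f"LOWEXP{i}" for i in range(1, 6)]
    genes = sig_genes + filler + low

    # signature/marker baseline high enough that zero counts are rare;
    # otherwise the log2cpm floor at zero makes the baseline bimodal and
    # planted outlier shifts stop being outliers
    base = np.empty(len(genes))
    base[: len(sig_genes)] = 20.0
    base[len(sig_genes): len(sig_genes) + len(filler)] = rng.lognormal(
        3.0, 1.0, len(filler)
    )
    base[len(sig_genes) + len(filler):] = 0.05

    effect = 2.0 ** config.signature_log2_effect
    mu = np.tile(base[:, None], (1, len(case_ids)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for j, (cat, hox) in enumerate(zip(categories, hox_of)):
        boosted = []
        if hox in ("HOXA", "HOXB"):
            boosted += SIGNATURE_BLOCKS["HOXA"]
        if hox == "HOXB":
            boosted += SIGNATURE_BLOCKS["HOXB"]
        if cat in ("MECOM", "BCL11B", "MNX1"):
            boosted += SIGNATURE_BLOCKS[cat]
        if cat == "GATA1":
            boosted += SIGNATURE_BLOCKS["AMKL"]
        for g in boosted:
            mu[gene_idx[g], j] *= effect
    libsize_factor = rng.lognormal(0.0, 0.2, len(case_ids))
    mu = mu * libsize_factor[None, :]

    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=genes, columns=case_ids)
    return ExpressionMatrix(data=df, units="raw_counts")


def _ase_markers(rng, config, case_id, category, skewed: bool) -> list:
    markers = []
    p = config.ase_skew if skewed else 0.5
    for k in range(config.ase_markers_per_case):
        cov = 10 + int(rng.poisson(20))
        alt = int(rng.binomial(cov, p))
        markers.append(
            ASEMarker(
                snp_id=f"{case_id}_{category}_snp{k+1}",
                ref_reads_rna=cov - alt,
                alt_reads_rna=alt,
                vaf_wgs=float(rng.uniform(0.35, 0.65)),
                cov_wgs=40,
            )
        )
    return markers


def generate(config: GeneratorConfig | None = None):
    """Generate a synthetic cohort with ground truth.

    Returns ``(cohort, expression, ase_markers, truth)`` where
    ``expression`` is a raw-count `ExpressionMatrix`, ``ase_markers``
    maps case_id -> gene -> markers, and ``truth`` is a DataFrame with
    one row per case recording the planted category, HOX group, risk
    stratum, cooperating mutations and survival parameters.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    labels = list(config.category_freqs)
    freqs = np.array([config.category_freqs[c] for c in labels])
    categories = [
        labels[i] for i in rng.choice(len(labels), config.n_cases, p=freqs)
    ]
    case_ids = [f"PAML{i+1:04d}" for i in range(config.n_cases)]

    cases, truth_rows = [], []
    ase_markers: dict = {}
    mutation_names = list(config.coop_mutation_probs)

    for case_id, category in zip(case_ids, categories):
        risk = risk_group_of(category)
        mrd = bool(rng.random() < config.mrd_probs[risk])
        mrd_missing = rng.random() < config.mrd_missing_prob
        hazard = config.survival_hazards[(risk, mrd)]

        event_time = float(rng.exponential(1.0 / hazard))
        censor_time = float(rng.uniform(0, config.censor_horizon_years))
        os_time = min(event_time, censor_time)
        os_event = event_time <= censor_time

        nonresponse = bool(rng.random() < config.nonresponse_prob)
        relapse_time = float(rng.exponential(1.0 / (1.5 * hazard)))
        if nonresponse:
            efs_time, efs_event, relapse_flag = 0.0, True, False
        elif relapse_time <= min(event_time, censor_time):
            efs_time, efs_event, relapse_flag = relapse_time, True, True
        elif os_event:
            efs_time, efs_event, relapse_flag = os_time, True, False
        else:
            efs_time, efs_event, relapse_flag = os_time, False, False

        if category in INFANT_CATEGORIES:
            age = float(rng.uniform(0.1, 3.0))
        else:
            age = float(rng.uniform(0.1, 23.5))

        clinical = ClinicalRecord(
            age_years=round(age, 2),
            timepoint="diagnosis" if rng.random() < config.diagnosis_prob
            else "relapse",
            mrd_positive=None if mrd_missing else mrd,
            os_time=os_time,
            os_event=os_event,
            efs_time=efs_time,
            efs_event=efs_event,
            nonresponse=nonresponse,
            relapse_flag=relapse_flag,
        )
        karyotype = KaryotypeRecord(
            complex_karyotype=bool(
                rng.random() < (0.3 if category == "Unclassified" else 0.08)
            ),
            monosomy7=bool(rng.random() < 0.05),
        )
        case = Case(
            case_id=case_id, clinical=clinical, karyotype=karyotype
        )
        _defining_evidence(rng, case, category)

        coop_flags = {}
        for mutation in mutation_names:
            entry = config.coop_mutation_probs[mutation]
            p = entry["by_category"].get(category, entry["default"])
            hit = bool(rng.random() < p)
            coop_flags[mutation] = hit
            if hit:
                _coop_alteration(rng, case, mutation)

        if category in SV_PARTNERS:
            ase_markers[case_id] = {
                category: _ase_markers(rng, config, case_id, category, True)
            }
        elif rng.random() < 0.05:
            # balanced negative-control marker set at the MECOM locus
            ase_markers[case_id] = {
                "MECOM": _ase_markers(rng, config, case_id, "MECOM", False)
            }

        cases.append(case)
        truth_rows.append(
            dict(
                case_id=case_id,
                category=category,
                hox_group=HOX_GROUP_OF_CATEGORY.get(category, "other"),
                risk_group=risk,
                mrd_positive=mrd,
                mrd_missing=mrd_missing,
                stratum=f"{risk}/MRD{'+' if mrd else '-'}",
                hazard=hazard,
                **{m: coop_flags[m] for m in mutation_names},
            )
        )

    expression = _expression_matrix(rng, config, case_ids, categories)
    cohort = Cohort(cases=cases, expression=expression)
    truth = pd.DataFrame(truth_rows).set_index("case_id")
    return cohort, expression, ase_markers, truth


#: Evidence kinds the ambiguity injector can add; each is strictly
#: lower-priority than any tier-1 defining fusion.
INJECTABLE = ("NPM1", "CEBPA", "KMT2A-PTD")

#: Categories defined by tier-1 fusions, safe targets for injection.
#: HOXr emits a fusion but its rule is conditional (tier 4), so a
#: tier-2 injection would legitimately outrank it; it is excluded.
_TIER1_CATEGORIES = frozenset(FUSION_PARTNERS) - {"HOXr"}


def ambiguity_injector(
    cohort: Cohort,
    truth: pd.DataFrame,
    rate: float,
    seed: int = 0,
    kinds=INJECTABLE,
):
    """Add a second, lower-tier alteration to a random subset of cases.

    Only cases whose true category is defined by a tier-1 fusion are
    eligible, so the expected resolution is always the original defining
    alteration.  Returns the modified cohort and a truth copy with an
    ``injected`` column recording what was added.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    truth = truth.copy()
    truth["injected"] = ""
    if rate == 0:
        return cohort, truth
    for case in cohort:
        category = truth.loc[case.case_id, "category"]
        if category not in _TIER1_CATEGORIES:
            continue
        if rng.random() >= rate:
            continue
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "KMT2A-PTD":
            case.tandem_dups.append(
                TandemDupCandidate(
                    gene="KMT2A",
                    interval=GenomicInterval("chr11", 118342377, 118345030),
                    supporting_reads=int(rng.integers(3, 31)),
                    caller_score=float(rng.uniform(0, 9)),
                    kind="ptd",
                )
            )
        else:
            case.variants.append(_defining_variant(rng, kind))
        truth.loc[case.case_id, "injected"] = kind
    return cohort, truth
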