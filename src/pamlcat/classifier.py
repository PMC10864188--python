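"""Mutually exclusive molecular categorization of pAML cases.

The diagnostic workflow evaluates an ordered registry of category rules
over each case's evidence bundle:

* tier 1 - category-defining fusions and SVs (gene-pair patterns with
  family wildcards; NPM1 fusions map to the NPM1 category and
  TBL1XR1::RARB to APL);
* tier 2 - defining mutations and tandem duplications (NPM1 indels,
  CEBPA mutations, UBTF-TD, CBFB-GDXY insertions);
* tier 3 - SV-driven categories requiring expression corroboration
  (MECOM, BCL11B, MNX1: an SV at the locus plus allele-specific or
  outlier expression);
* tier 4 - conditional categories (GATA1, HOXr, KMT2A-PTD) assigned only
  when no earlier rule fired and the case's expression is consistent with
  the category's expected signature.

The first matching rule, in (tier, registry order), assigns the single
category label; every later match is retained as a conflict note, so
mutual exclusivity holds by construction.  Cases matching no rule fall
back to ``Unclassified``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

from .types import Case, Cohort

UNCLASSIFIED = "Unclassified"

#: Gene families referenced by fusion patterns.  ``*`` matches any
#: partner; ``HOX_CLUSTER`` matches by gene-symbol prefix.
GENE_FAMILIES = {
    "GLIS": frozenset({"GLIS2", "GLIS3"}),
    "FET": frozenset({"FUS", "EWSR1"}),
    "ETS": frozenset({"ERG", "FEV", "FLI1"}),
    "CBFA2T": frozenset({"CBFA2T2", "CBFA2T3"}),
}
HOX_PREFIXES = ("HOXA", "HOXB", "HOXC", "HOXD")

#: Mutations/karyotypes defining "AML, myelodysplasia-related" in WHO 5th.
#: They never classify here (they do not drive consistent expression
#: patterns) but are annotated onto results for reporting.
AML_MR_GENES = frozenset(
    {"ASXL1", "BCOR", "EZH2", "SF3B1", "SRSF2", "STAG2", "U2AF1", "ZRSR2"}
)


def _match_token(token: str, gene: str) -> bool:
    if token == "*":
        return True
    if token == "HOX_CLUSTER":
        return gene.startswith(HOX_PREFIXES)
    if token in GENE_FAMILIES:
        return gene in GENE_FAMILIES[token]
    return gene == token


def _match_pair(pattern: tuple, fusion) -> bool:
    ta, tb = pattern
    return (_match_token(ta, fusion.gene_a) and _match_token(tb, fusion.gene_b)) or (
        _match_token(ta, fusion.gene_b) and _match_token(tb, fusion.gene_a)
    )


@dataclass(frozen=True)
class CategoryRule:
    """Declarative evidence clause for one molecular category.

    Any populated evidence channel can fire the rule: a fusion matching
    one of ``fusion_patterns``, a pathogenic mutation in
    ``mutation_genes`` (optionally restricted to ``mutation_classes``),
    or a tandem duplication matching ``tandem_dup`` (gene, kind-or-None).
    ``require_ase_or_outlier`` additionally demands ASE or outlier
    expression of the named gene (tier 3).  ``expression_consistency``
    lists (signature, minimum score) alternatives; when present the case
    must reach at least one of them (tier 4).
    """

    label: str
    tier: int
    fusion_patterns: tuple = ()
    mutation_genes: frozenset = frozenset()
    mutation_classes: Optional[frozenset] = None
    tandem_dup: Optional[tuple] = None
    require_ase_or_outlier: Optional[str] = None
    expression_consistency: tuple = ()

    def __post_init__(self):
        if self.tier < 1:
            raise ValueError("tier must be >= 1")


@dataclass
class ExpressionContext:
    """Per-case expression evidence consumed by tiers 3 and 4.

    ``signature_scores``: case_id -> {signature name -> score};
    ``ase_positive`` and ``outlier``: case_id -> {gene -> bool}.
    """

    signature_scores: dict = field(default_factory=dict)
    ase_positive: dict = field(default_factory=dict)
    outlier: dict = field(default_factory=dict)

    def score(self, case_id: str, signature: str) -> Optional[float]:
        return self.signature_scores.get(case_id, {}).get(signature)

    def has_ase(self, case_id: str, gene: str) -> bool:
        return bool(self.ase_positive.get(case_id, {}).get(gene))

    def has_outlier(self, case_id: str, gene: str) -> bool:
        return bool(self.outlier.get(case_id, {}).get(gene))


@dataclass
class CategoryRegistry:
    """Ordered rule set covering the 23 molecular categories.

    ``Unclassified`` is the fallback, not a rule.  Rules are evaluated in
    (tier, registry order); within-tier conflicts resolve by registry
    order and are logged on the result.
    """

    rules: list

    def __post_init__(self):
        labels = [r.label for r in self.rules]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate labels in registry")

    def ordered(self) -> list:
        return sorted(
            enumerate(self.rules), key=lambda ir: (ir[1].tier, ir[0])
        )

    @property
    def labels(self) -> list:
        return [r.label for r in self.rules]


@dataclass
class ClassificationResult:
    case_id: str
    label: str
    tier_used: Optional[int]
    evidence: list = field(default_factory=list)
    notes: list = field(default_factory=list)


def default_registry() -> CategoryRegistry:
    """The shipped 23-category registry (11 WHO-defined + 12 new)."""
    r = CategoryRule
    rules = [
        # --- tier 1: defining fusions / SVs ------------------------------
        r("APL", 1, fusion_patterns=(("PML", "RARA"), ("TBL1XR1", "RARB"))),
        r("RUNX1::RUNX1T1", 1, fusion_patterns=(("RUNX1", "RUNX1T1"),)),
        r("CBFB::MYH11", 1, fusion_patterns=(("CBFB", "MYH11"),)),
        r("RBM15::MRTFA", 1, fusion_patterns=(("RBM15", "MRTFA"),)),
        r("DEK::NUP214", 1, fusion_patterns=(("DEK", "NUP214"),)),
        r("BCR::ABL1", 1, fusion_patterns=(("BCR", "ABL1"),)),
        r("PICALM::MLLT10", 1, fusion_patterns=(("PICALM", "MLLT10"),)),
        r("RUNX1::RUNX1T1-like", 1, fusion_patterns=(("RUNX1", "CBFA2T"),)),
        r("NUP98r", 1, fusion_patterns=(("NUP98", "*"),)),
        r("KMT2Ar", 1, fusion_patterns=(("KMT2A", "*"),)),
        r("KAT6Ar", 1, fusion_patterns=(("KAT6A", "*"),)),
        r("GLISr", 1, fusion_patterns=(("GLIS", "*"),)),
        r("FET::ETS", 1, fusion_patterns=(("FET", "ETS"),)),
        # --- tier 2: defining mutations / tandem duplications ------------
        # NPM1 fusions and indels (C-terminal or not) both map to NPM1.
        r("NPM1", 2,
          fusion_patterns=(("NPM1", "*"),),
          mutation_genes=frozenset({"NPM1"}),
          mutation_classes=frozenset({"indel"})),
        r("CEBPA", 2, mutation_genes=frozenset({"CEBPA"})),
        r("UBTF", 2, tandem_dup=("UBTF", None)),
        r("CBFB-GDXY", 2,
          mutation_genes=frozenset({"CBFB"}),
          mutation_classes=frozenset({"indel"})),
        # --- tier 3: SV-driven, expression-corroborated ------------------
        r("MECOM", 3, require_ase_or_outlier="MECOM"),
        r("BCL11B", 3, require_ase_or_outlier="BCL11B"),
        r("MNX1", 3, require_ase_or_outlier="MNX1"),
        # --- tier 4: conditional, expression-consistent ------------------
        r("GATA1", 4,
          fusion_patterns=(("GATA1", "*"),),
          mutation_genes=frozenset({"GATA1"}),
          expression_consistency=(("AMKL", 0.5),)),
        r("HOXr", 4,
          fusion_patterns=(("HOX_CLUSTER", "*"),),
          expression_consistency=(("HOXA", 0.5), ("HOXB", 0.5))),
        r("KMT2A-PTD", 4,
          tandem_dup=("KMT2A", "ptd"),
          expression_consistency=(("HOXB", 0.5),)),
    ]
    return CategoryRegistry(rules=rules)


def _rule_evidence(rule: CategoryRule, case: Case,
                   ctx: Optional[ExpressionContext]) -> list:
    """Matched evidence records for ``rule`` on ``case`` (empty = no match)."""
    evidence = []
    for pattern in rule.fusion_patterns:
        for fusion in case.fusions:
            if _match_pair(pattern, fusion):
                evidence.append(("fusion", fusion))
    if rule.mutation_genes:
        for var in case.variants:
            if (
                var.gene in rule.mutation_genes
                and var.is_pathogenic
                and (
                    rule.mutation_classes is None
                    or var.variant_class in rule.mutation_classes
                )
            ):
                evidence.append(("mutation", var))
    if rule.tandem_dup is not None:
        gene, kind = rule.tandem_dup
        for td in case.tandem_dups:
            if td.gene == gene and (kind is None or td.kind == kind):
                evidence.append(("tandem_dup", td))
    if rule.require_ase_or_outlier is not None:
        gene = rule.require_ase_or_outlier
        sv_hit = [
            ("sv", f) for f in case.fusions if gene in (f.gene_a, f.gene_b)
        ]
        expr_hit = ctx is not None and (
            ctx.has_ase(case.case_id, gene) or ctx.has_outlier(case.case_id, gene)
        )
        if sv_hit and expr_hit:
            evidence.extend(sv_hit)
            evidence.append(("expression", f"{gene} ASE/outlier"))
        else:
            return []  # both channels required
    if not evidence:
        return []
    if rule.expression_consistency:
        if ctx is None:
            return []
        ok = any(
            (ctx.score(case.case_id, sig) or float("-inf")) >= cut
            for sig, cut in rule.expression_consistency
        )
        if not ok:
            return []
        evidence.append(
            ("expression", f"consistent with {rule.expression_consistency}")
        )
    return evidence


def classify_case(
    case: Case,
    registry: Optional[CategoryRegistry] = None,
    expression_context: Optional[ExpressionContext] = None,
) -> ClassificationResult:
    """Assign exactly one category label (possibly Unclassified) to a case."""
    registry = registry or default_registry()
    winner = None
    notes = []
    for _, rule in registry.ordered():
        evidence = _rule_evidence(rule, case, expression_context)
        if not evidence:
            continue
        if winner is None:
            winner = ClassificationResult(
                case_id=case.case_id,
                label=rule.label,
                tier_used=rule.tier,
                evidence=evidence,
            )
        else:
            kind = "conflict" if rule.tier == winner.tier_used else "secondary"
            notes.append(
                f"{kind}: evidence for {rule.label} (tier {rule.tier}) "
                f"superseded by {winner.label}"
            )
    if winner is None:
        winner = ClassificationResult(
            case_id=case.case_id, label=UNCLASSIFIED, tier_used=None
        )
    mr_hits = sorted(
        {v.gene for v in case.variants if v.gene in AML_MR_GENES and v.is_pathogenic}
    )
    if case.karyotype.complex_karyotype:
        mr_hits.append("complex karyotype")
    if case.karyotype.monosomy7:
        mr_hits.append("monosomy 7")
    if mr_hits:
        notes.append("AML-MR-defining features present: " + ", ".join(mr_hits))
    winner.notes = notes
    return winner


def classify_cohort(
    cohort: Cohort,
    registry: Optional[CategoryRegistry] = None,
    expression_context: Optional[ExpressionContext] = None,
) -> tuple:
    """Classify every case; returns (results, coverage).

    Coverage is the fraction of cases not assigned to Unclassified.
    Case ``category`` fields are updated in place.
    """
    registry = registry or default_registry()
    results = [
        classify_case(c, registry, expression_context) for c in cohort
    ]
    for case, res in zip(cohort, results):
        case.category = res.label
    n = len(results)
    coverage = (
        sum(1 for r in results if r.label != UNCLASSIFIED) / n if n else 0.0
    )
    return results, coverage


def registry_lint(registry: CategoryRegistry, expected_labels: int = 23) -> dict:
    """Sanity-check a registry; the shipped default must carry 23 labels."""
    problems = []
    labels = registry.labels
    if len(labels) != len(set(labels)):
        problems.append("duplicate category labels")
    if not labels:
        problems.append("registry is empty")
    if UNCLASSIFIED in labels:
        problems.append("Unclassified must be the fallback, not a rule")
    for rule in registry.rules:
        if rule.tier < 1:
            problems.append(f"{rule.label}: tier must be >= 1")
        for pattern in rule.fusion_patterns:
            if len(pattern) != 2:
                problems.append(f"{rule.label}: malformed fusion pattern {pattern}")
        has_evidence = (
            rule.fusion_patterns
            or rule.mutation_genes
            or rule.tandem_dup
            or rule.require_ase_or_outlier
        )
        if not has_evidence:
            problems.append(f"{rule.label}: rule has no evidence clause")
    if expected_labels is not None and len(labels) != expected_labels:
        problems.append(
            f"registry has {len(labels)} labels, expected {expected_labels}"
        )
    return {"ok": not problems, "n_labels": len(labels), "problems": problems}


# ---------------------------------------------------------------------------
# YAML round-trip for the registry


def registry_to_yaml(registry: CategoryRegistry) -> str:
    docs = []
    for rule in registry.rules:
        doc = {"label": rule.label, "tier": rule.tier}
        if rule.fusion_patterns:
            doc["fusion_patterns"] = [list(p) for p in rule.fusion_patterns]
        if rule.mutation_genes:
            doc["mutation_genes"] = sorted(rule.mutation_genes)
        if rule.mutation_classes is not None:
            doc["mutation_classes"] = sorted(rule.mutation_classes)
        if rule.tandem_dup is not None:
            doc["tandem_dup"] = list(rule.tandem_dup)
        if rule.require_ase_or_outlier is not None:
            doc["require_ase_or_outlier"] = rule.require_ase_or_outlier
        if rule.expression_consistency:
            doc["expression_consistency"] = [
                list(p) for p in rule.expression_consistency
            ]
        docs.append(doc)
    return yaml.safe_dump({"rules": docs}, sort_keys=False)


def registry_from_yaml(text: str) -> CategoryRegistry:
    raw = yaml.safe_load(text)
    rules = []
    for doc in raw["rules"]:
        rules.append(
            CategoryRule(
                label=doc["label"],
                tier=doc["tier"],
                fusion_patterns=tuple(
                    tuple(p) for p in doc.get("fusion_patterns", [])
                ),
                mutation_genes=frozenset(doc.get("mutation_genes", [])),
                mutation_classes=(
                    frozenset(doc["mutation_classes"])
                    if "mutation_classes" in doc
                    else None
                ),
                tandem_dup=(
                    tuple(doc["tandem_dup"]) if "tandem_dup" in doc else None
                ),
                require_ase_or_outlier=doc.get("require_ase_or_outlier"),
                expression_consistency=tuple(
                    (sig, float(cut))
                    for sig, cut in doc.get("expression_consistency", [])
                ),
            )
        )
    return CategoryRegistry(rules=rules)


# ---------------------------------------------------------------------------
# Building the expression context from cohort-level data


def build_expression_context(
    log_expr,
    ase_markers: Optional[Mapping] = None,
    signatures: Optional[Sequence] = None,
    ase_genes: Sequence[str] = ("MECOM", "BCL11B", "MNX1"),
    outlier_z: float = 3.0,
    ase_alpha: float = 0.05,
) -> ExpressionContext:
    """Precompute signature scores, ASE verdicts and outlier flags.

    ``log_expr`` is a log2-cpm `ExpressionMatrix`; ``ase_markers`` maps
    case_id -> gene -> marker list.  Signature scores default to the
    HOXA/HOXB/AMKL signatures used by the shipped registry.
    """
    from .ase import assess_ase
    from .expression import (
        AMKL_SIGNATURE,
        HOXA_SIGNATURE,
        HOXB_SIGNATURE,
        outlier_expression_flag,
        signature_scores,
    )

    sigs = signatures or (HOXA_SIGNATURE, HOXB_SIGNATURE, AMKL_SIGNATURE)
    ctx = ExpressionContext()
    per_sig = {}
    for sig in sigs:
        try:
            per_sig[sig.name] = signature_scores(log_expr, sig)
        except ValueError:
            continue
    for case_id in log_expr.samples:
        ctx.signature_scores[case_id] = {
            name: float(scores[case_id]) for name, scores in per_sig.items()
        }
        for gene in ase_genes:
            if gene in log_expr.data.index:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    flag = outlier_expression_flag(
                        log_expr, gene, case_id, z_cut=outlier_z
                    )
                if flag:
                    ctx.outlier.setdefault(case_id, {})[gene] = True
    if ase_markers:
        for case_id, by_gene in ase_markers.items():
            for gene, markers in by_gene.items():
                verdict = assess_ase(markers, mode="wgs_paired", alpha=ase_alpha)
                if verdict.is_positive:
                    ctx.ase_positive.setdefault(case_id, {})[gene] = True
    return ctx
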