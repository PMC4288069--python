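"""Risk assessment under the three association regimes.

*Independent* associations are graded on a 3x3 impact x evidence grid
(1=Weak, 2=Moderate, 3=Strong).  The impact category derives from the odds
ratio: most clinically relevant SNPs have minor effects (OR below about
1.5-2.0), so the default cut-offs are Weak below 1.50, Moderate from 1.50 up
to (but excluding) 2.00, Strong from 2.00 — a boundary value belongs to the
higher category.  Both cut-offs are configurable; a record carrying
pre-assigned categories keeps them.

*Cumulative* models sum per-association impact values into a total personal
risk value, optionally augmented by a family-history increment defined in the
model table, and interpret the total against the model's reference bands
(largest reference level not exceeding the total).

*Probabilistic* models group associations into branches (genotype profiles).
A branch is complete — and the patient flagged at risk with the model's
accuracy/precision/recall narrative — exactly when the number of matched
associations equals the branch's total SNP count.  Because KB validation
guarantees that count equals the branch's number of rules, count equality is
equivalent to a full genotype-profile match.  No-calls never count toward a
branch; an incomplete branch containing an untyped rsID is reported as
indeterminate rather than absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import KBIntegrityError, ModelNotFoundError
from .inference import PersonalAssociation, PersonalAssociationSet
from .kb import KnowledgeBase, ModelDefinition, ModelType

__all__ = [
    "ORThresholds",
    "IndependentAssessment",
    "CumulativeResult",
    "BranchResult",
    "ProbabilisticResult",
    "ExternalRiskFactors",
    "categorize_independent",
    "evaluate_cumulative",
    "evaluate_probabilistic",
    "CATEGORY_LABELS",
]

CATEGORY_LABELS = {1: "Weak", 2: "Moderate", 3: "Strong"}


@dataclass(frozen=True)
class ORThresholds:
    """Odds-ratio cut-offs between impact categories.

    ``moderate`` and ``strong`` are the lower bounds of categories 2 and 3;
    values exactly at a cut-off take the higher category.
    """

    moderate: float = 1.50
    strong: float = 2.00

    def category(self, odds_ratio: float) -> int:
        if odds_ratio >= self.strong:
            return 3
        if odds_ratio >= self.moderate:
            return 2
        return 1


@dataclass(frozen=True)
class IndependentAssessment:
    """One independent association placed on the impact x evidence grid."""

    assoc_id: int
    rs_id: str
    genotype: str
    disease_code: str
    disease_name: str
    magnitude_of_impact: float
    evidence_quality: int
    impact_category: int
    evidence_category: int

    @property
    def grid(self) -> tuple[int, int]:
        """(x, y) = (impact_category, evidence_category)."""
        return (self.impact_category, self.evidence_category)

    @property
    def labels(self) -> tuple[str, str]:
        return (CATEGORY_LABELS[self.impact_category],
                CATEGORY_LABELS[self.evidence_category])


@dataclass(frozen=True)
class ExternalRiskFactors:
    """Non-genomic risk data captured at the end-user side.

    ``family_history`` is tri-state ("yes"/"no"/"unknown") because absence of
    a report is not a negative report.  Other factors (BMI, smoking, alcohol,
    ...) are a name -> (value, unit) map with unique names.
    """

    family_history: str = "unknown"  # yes | no | unknown
    family_history_detail: str = ""
    factors: dict[str, tuple[object, str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.family_history not in ("yes", "no", "unknown"):
            raise ValueError(
                f"family_history must be yes/no/unknown, got {self.family_history!r}")


def categorize_independent(assoc: PersonalAssociation,
                           thresholds: ORThresholds = ORThresholds()
                           ) -> IndependentAssessment:
    """Grade one independent association onto the 3x3 grid.

    Pre-assigned categories on the record win over threshold derivation;
    the evidence category defaults to the 1-3 evidence-quality grade.
    """
    r = assoc.record
    if r.model_type is not ModelType.INDEPENDENT:
        raise ValueError(f"association {r.assoc_id} is not independent")
    if r.magnitude_of_impact is None or r.magnitude_of_impact <= 0:
        raise ValueError(
            f"association {r.assoc_id}: odds ratio must be positive, "
            f"got {r.magnitude_of_impact!r}")
    impact = (r.impact_category if r.impact_category is not None
              else thresholds.category(r.magnitude_of_impact))
    evidence = (r.evidence_category if r.evidence_category is not None
                else r.evidence_quality)
    return IndependentAssessment(
        assoc_id=r.assoc_id, rs_id=r.rs_id, genotype=assoc.genotype,
        disease_code=r.disease_code, disease_name=r.disease_name,
        magnitude_of_impact=r.magnitude_of_impact,
        evidence_quality=r.evidence_quality,
        impact_category=impact, evidence_category=evidence)


@dataclass
class CumulativeResult:
    """Outcome of one cumulative (polygenic total-impact) model."""

    model_name: str
    matched_assoc_ids: list[int]
    total_impact: float
    family_history_increment: float
    matched_definition: ModelDefinition | None
    explanation: str


def evaluate_cumulative(assocs: PersonalAssociationSet, model_name: str,
                        kb: KnowledgeBase,
                        external: ExternalRiskFactors | None = None
                        ) -> CumulativeResult:
    """Sum the patient's impact values for one cumulative model.

    total = sum of ``impact_value`` over the patient's associations with this
    model name, plus the model's family-history increment (a factor row in
    the definition table) when the patient reports a positive family history.
    The explanation comes from the reference row with the largest
    ``total_value`` not exceeding the total.
    """
    defs = kb.definitions_for(model_name, ModelType.CUMULATIVE)
    if not defs:
        raise ModelNotFoundError(f"no cumulative model named {model_name!r}")
    reference_rows = sorted((d for d in defs if not d.is_factor),
                            key=lambda d: d.total_value)
    factor_rows = [d for d in defs if d.is_factor]

    matched = sorted((a for a in assocs.associations
                      if a.model_type is ModelType.CUMULATIVE
                      and a.model_name == model_name),
                     key=lambda a: a.assoc_id)

    increment = 0.0
    if external is not None and external.family_history == "yes" and factor_rows:
        increment = math.fsum(d.total_value for d in factor_rows)
    # fsum: the total is the correctly rounded sum of the exact addends, so
    # it is independent of association order and grouping
    total = math.fsum([a.record.impact_value for a in matched] + [increment])

    matched_def = None
    for d in reference_rows:
        if d.total_value <= total:
            matched_def = d
        else:
            break

    if not matched and increment == 0.0:
        explanation = "no risk alleles matched"
    elif matched_def is not None:
        explanation = matched_def.explanation_1
    else:
        explanation = "total below the lowest reference level"
    return CumulativeResult(
        model_name=model_name,
        matched_assoc_ids=[a.assoc_id for a in matched],
        total_impact=total, family_history_increment=increment,
        matched_definition=matched_def, explanation=explanation)


@dataclass
class BranchResult:
    """One branch (genotype profile) of a probabilistic model."""

    branch_id: int
    required_count: int
    matched_count: int
    complete: bool
    indeterminate: bool  # incomplete, but an untyped rsID leaves it undecidable


@dataclass
class ProbabilisticResult:
    """Outcome of one probabilistic (branch-matching) model.

    ``flagged`` is true when any branch is complete; only branches the patient
    touches (matched or indeterminate) are listed.
    """

    model_name: str
    branches: list[BranchResult]
    flagged: bool
    interpretation: str


def evaluate_probabilistic(assocs: PersonalAssociationSet, model_name: str,
                           kb: KnowledgeBase) -> ProbabilisticResult:
    """Check each branch of a probabilistic model for completeness.

    matched_count counts the patient's associations within a
    (model_name, branch_id) group; a branch is complete exactly when that
    count equals the branch's required total SNP count.
    """
    branch_defs = {d.branch_id: d for d in
                   kb.definitions_for(model_name, ModelType.PROBABILISTIC)}
    if not branch_defs:
        raise ModelNotFoundError(f"no probabilistic model named {model_name!r}")

    mine = [a for a in assocs.associations
            if a.model_type is ModelType.PROBABILISTIC
            and a.model_name == model_name]
    by_branch: dict[int, list[PersonalAssociation]] = {}
    for a in mine:
        if a.record.branch_id not in branch_defs:
            raise KBIntegrityError(
                f"association {a.assoc_id} references undefined branch "
                f"{a.record.branch_id} of model {model_name!r}")
        by_branch.setdefault(a.record.branch_id, []).append(a)

    # rsIDs per branch over the whole KB, to spot branches touched only by
    # no-calls and to flag indeterminate ones
    branch_rsids: dict[int, set[str]] = {}
    for r in kb.active_associations():
        if r.model_type is ModelType.PROBABILISTIC and r.model_name == model_name:
            branch_rsids.setdefault(r.branch_id, set()).add(r.rs_id)
    no_call_set = set(assocs.no_calls)

    results: list[BranchResult] = []
    for branch_id in sorted(branch_defs):
        required = int(branch_defs[branch_id].total_value)
        matched = len(by_branch.get(branch_id, []))
        touched_by_no_call = bool(branch_rsids.get(branch_id, set()) & no_call_set)
        if matched == 0 and not touched_by_no_call:
            continue
        complete = matched == required
        results.append(BranchResult(
            branch_id=branch_id, required_count=required, matched_count=matched,
            complete=complete,
            indeterminate=not complete and touched_by_no_call))

    flagged = any(b.complete for b in results)
    if flagged:
        parts = []
        for b in results:
            if b.complete:
                d = branch_defs[b.branch_id]
                text = d.explanation_1
                if d.explanation_2:
                    text += f" [{d.explanation_2}]"
                parts.append(text)
        interpretation = " | ".join(parts)
    else:
        interpretation = "no complete risk profile matched"
    return ProbabilisticResult(model_name=model_name, branches=results,
                               flagged=flagged, interpretation=interpretation)
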