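"""Personal risk report: assembly, rendering, and external risk-factor store.

The report has three sections, mirroring how clinicogenomic decision support
is presented to end users: (1) independent associations placed on the 3x3
impact x evidence grid, (2) counts of clinically relevant SNPs (matched /
unmatched / untyped), and (3) model-based interpretations (cumulative totals
and probabilistic branch verdicts), followed by an echo of the external risk
factors (family history, BMI, smoking, ...) supplied by the user.

Renderings: plain text, HTML (with the grid as a table, one marker per
independent association), and a structured JSON form that round-trips to an
equal ``RiskReport``.
"""

from __future__ import annotations

import html as html_mod
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable

from .errors import StaleInterpretationError
from .inference import PersonalAssociationSet
from .kb import KnowledgeBase, ModelDefinition, ModelType
from .risk import (CATEGORY_LABELS, BranchResult, CumulativeResult,
                   ExternalRiskFactors, IndependentAssessment, ORThresholds,
                   ProbabilisticResult, categorize_independent,
                   evaluate_cumulative, evaluate_probabilistic)

__all__ = [
    "RiskReport",
    "build_report",
    "render_report",
    "report_from_structured",
    "ExternalFactorStore",
    "record_external_data",
    "KNOWN_FACTORS",
]


def _utc_now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class RiskReport:
    """Three-part personal risk report, versioned against the KB."""

    patient_id: str
    kb_version: int
    independent: list[IndependentAssessment]
    counts: dict[str, int]
    models: list[CumulativeResult | ProbabilisticResult]
    external: ExternalRiskFactors | None
    generated_at: str
    #: every matched association row: (assoc_id, rs_id, genotype, model_type,
    #: model_name) — the detailed listing backing all three sections
    variants: list[tuple[int, str, str, str, str]] = field(default_factory=list)


def _relevant_model_names(assocs: PersonalAssociationSet,
                          kb: KnowledgeBase) -> list[tuple[ModelType, str]]:
    """Model definitions relevant to the patient's matched disease codes.

    A model is relevant when any of its association records targets a disease
    code the patient matched (under any model).  Each model appears once,
    ordered by (model_type, model_name) for determinism.
    """
    patient_codes = {a.record.disease_code for a in assocs.associations}
    model_codes: dict[tuple[ModelType, str], set[str]] = {}
    for r in kb.active_associations():
        if r.model_type in (ModelType.CUMULATIVE, ModelType.PROBABILISTIC):
            model_codes.setdefault((r.model_type, r.model_name),
                                   set()).add(r.disease_code)
    relevant = [(t, n) for (t, n), codes in model_codes.items()
                if codes & patient_codes]
    return sorted(relevant, key=lambda tn: (tn[0].value, tn[1]))


def build_report(assocs: PersonalAssociationSet, kb: KnowledgeBase,
                 external: ExternalRiskFactors | None = None,
                 thresholds: ORThresholds = ORThresholds(),
                 clock: Callable[[], str] = _utc_now) -> RiskReport:
    """Assemble the three-part report for one patient.

    The association set must have been inferred against this exact KB version
    (otherwise the interpretation is stale and must be recomputed first).
    """
    if assocs.kb_version != kb.version:
        raise StaleInterpretationError(
            f"association set at KB v{assocs.kb_version}, KB is v{kb.version}; "
            "reinterpret before reporting")

    independent = [categorize_independent(a, thresholds)
                   for a in assocs.associations
                   if a.model_type is ModelType.INDEPENDENT]

    counts = {
        "matched_associations": len(assocs.associations),
        "matched_rs_ids": len({a.rs_id for a in assocs.associations}),
        "unmatched": len(assocs.unmatched),
        "no_calls": len(assocs.no_calls),
    }

    models: list[CumulativeResult | ProbabilisticResult] = []
    for model_type, name in _relevant_model_names(assocs, kb):
        if model_type is ModelType.CUMULATIVE:
            models.append(evaluate_cumulative(assocs, name, kb, external))
        else:
            models.append(evaluate_probabilistic(assocs, name, kb))

    variants = [(a.assoc_id, a.rs_id, a.genotype, a.model_type.value,
                 a.model_name)
                for a in sorted(assocs.associations, key=lambda a: a.assoc_id)]
    return RiskReport(patient_id=assocs.patient_id, kb_version=kb.version,
                      independent=independent, counts=counts, models=models,
                      external=external, generated_at=clock(),
                      variants=variants)


# ---------------------------------------------------------------------------
# rendering

def _grid_counts(report: RiskReport) -> dict[tuple[int, int], list[str]]:
    grid: dict[tuple[int, int], list[str]] = {}
    for a in report.independent:
        grid.setdefault(a.grid, []).append(f"{a.rs_id}-{a.genotype}")
    return grid


def _render_text(report: RiskReport) -> str:
    lines = [f"Personal risk report — patient {report.patient_id} "
             f"(KB v{report.kb_version}, generated {report.generated_at})",
             "",
             "1. Independent associations (impact x evidence grid)"]
    if report.independent:
        for a in sorted(report.independent, key=lambda a: a.assoc_id):
            li, le = a.labels
            lines.append(f"   {a.rs_id}-{a.genotype}  {a.disease_code} "
                         f"{a.disease_name}  OR={a.magnitude_of_impact:g}  "
                         f"impact={li}({a.impact_category}) "
                         f"evidence={le}({a.evidence_category})")
    else:
        lines.append("   (none)")
    c = report.counts
    lines += ["", "2. Clinically relevant SNP counts",
              f"   matched associations: {c['matched_associations']} "
              f"(distinct rsIDs: {c['matched_rs_ids']}), "
              f"unmatched: {c['unmatched']}, untyped/no-call: {c['no_calls']}"]
    for assoc_id, rs_id, genotype, model_type, model_name in report.variants:
        lines.append(f"   #{assoc_id} {rs_id}-{genotype} "
                     f"[{model_type}/{model_name}]")
    lines += ["", "3. Model-based interpretations"]
    if report.models:
        for m in report.models:
            if isinstance(m, CumulativeResult):
                lines.append(f"   [cumulative] {m.model_name}: total impact "
                             f"{m.total_impact:g} "
                             f"(family history +{m.family_history_increment:g}) "
                             f"— {m.explanation}")
            else:
                verdict = "AT RISK" if m.flagged else "no complete profile"
                lines.append(f"   [probabilistic] {m.model_name}: {verdict} "
                             f"— {m.interpretation}")
                for b in m.branches:
                    status = ("complete" if b.complete else
                              "indeterminate (untyped SNP)" if b.indeterminate
                              else "incomplete")
                    lines.append(f"      branch {b.branch_id}: "
                                 f"{b.matched_count}/{b.required_count} {status}")
    else:
        lines.append("   (none)")
    lines.append("")
    lines.append("External risk factors")
    ext = report.external
    if ext is None:
        lines.append("   (not recorded)")
    else:
        lines.append(f"   family history: {ext.family_history}"
                     + (f" ({ext.family_history_detail})"
                        if ext.family_history_detail else ""))
        for name in sorted(ext.factors):
            value, unit = ext.factors[name]
            lines.append(f"   {name}: {value} {unit}".rstrip())
    return "\n".join(lines) + "\n"


def _render_html(report: RiskReport) -> str:
    esc = html_mod.escape
    grid = _grid_counts(report)
    rows = []
    # y axis (evidence) from Strong (3) at the top to Weak (1)
    for evidence in (3, 2, 1):
        cells = []
        for impact in (1, 2, 3):
            markers = grid.get((impact, evidence), [])
            content = " ".join(f'<span class="marker">{esc(m)}</span>'
                               for m in markers)
            cells.append(f'<td data-impact="{impact}" data-evidence="{evidence}">'
                         f"{content}</td>")
        rows.append(f"<tr><th>{CATEGORY_LABELS[evidence]}</th>"
                    + "".join(cells) + "</tr>")
    grid_html = (
        '<table class="grid"><caption>Impact (x) vs evidence (y)</caption>'
        "<thead><tr><th></th><th>Weak</th><th>Moderate</th><th>Strong</th>"
        "</tr></thead><tbody>" + "".join(rows) + "</tbody></table>")

    assoc_rows = "".join(
        f"<tr><td>{esc(a.rs_id)}</td><td>{esc(a.genotype)}</td>"
        f"<td>{esc(a.disease_code)}</td><td>{esc(a.disease_name)}</td>"
        f"<td>{a.magnitude_of_impact:g}</td>"
        f"<td>{esc(a.labels[0])}</td><td>{esc(a.labels[1])}</td></tr>"
        for a in sorted(report.independent, key=lambda a: a.assoc_id))

    model_items = []
    for m in report.models:
        if isinstance(m, CumulativeResult):
            model_items.append(
                f"<li><b>{esc(m.model_name)}</b> (cumulative): total "
                f"{m.total_impact:g} — {esc(m.explanation)}</li>")
        else:
            verdict = "AT RISK" if m.flagged else "no complete profile"
            branches = "; ".join(
                f"branch {b.branch_id}: {b.matched_count}/{b.required_count}"
                for b in m.branches)
            model_items.append(
                f"<li><b>{esc(m.model_name)}</b> (probabilistic): {verdict} — "
                f"{esc(m.interpretation)}<br><small>{esc(branches)}</small></li>")

    ext = report.external
    if ext is None:
        ext_html = "<p>(not recorded)</p>"
    else:
        items = [f"<li>family history: {esc(ext.family_history)}</li>"]
        items += [f"<li>{esc(n)}: {esc(str(v))} {esc(u)}</li>"
                  for n, (v, u) in sorted(ext.factors.items())]
        ext_html = "<ul>" + "".join(items) + "</ul>"

    c = report.counts
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8">
<title>Risk report {esc(report.patient_id)}</title></head>
<body>
<h1>Personal risk report — patient {esc(report.patient_id)}</h1>
<p>KB version {report.kb_version}, generated {esc(report.generated_at)}</p>
<h2>1. Independent associations</h2>
<table class="assoc"><thead><tr><th>rsID</th><th>genotype</th><th>ICD-10</th>
<th>disease</th><th>OR</th><th>impact</th><th>evidence</th></tr></thead>
<tbody>{assoc_rows}</tbody></table>
{grid_html}
<h2>2. Clinically relevant SNP counts</h2>
<p>matched associations: {c['matched_associations']}
(distinct rsIDs: {c['matched_rs_ids']}), unmatched: {c['unmatched']},
untyped/no-call: {c['no_calls']}</p>
<ul class="variants">{''.join(
    f"<li>#{aid} {esc(rs)}-{esc(gt)} [{esc(mt)}/{esc(mn)}]</li>"
    for aid, rs, gt, mt, mn in report.variants)}</ul>
<h2>3. Model-based interpretations</h2>
<ul>{''.join(model_items)}</ul>
<h2>External risk factors</h2>
{ext_html}
</body></html>
"""


def _definition_to_dict(d: ModelDefinition | None):
    if d is None:
        return None
    return {"model_type": d.model_type.value, "model_name": d.model_name,
            "total_value": d.total_value, "explanation_1": d.explanation_1,
            "explanation_2": d.explanation_2, "branch_id": d.branch_id}


def _definition_from_dict(d):
    if d is None:
        return None
    return ModelDefinition(model_type=ModelType(d["model_type"]),
                           model_name=d["model_name"],
                           total_value=d["total_value"],
                           explanation_1=d["explanation_1"],
                           explanation_2=d["explanation_2"],
                           branch_id=d["branch_id"])


def _render_structured(report: RiskReport) -> str:
    models = []
    for m in report.models:
        if isinstance(m, CumulativeResult):
            models.append({
                "kind": "cumulative", "model_name": m.model_name,
                "matched_assoc_ids": m.matched_assoc_ids,
                "total_impact": m.total_impact,
                "family_history_increment": m.family_history_increment,
                "matched_definition": _definition_to_dict(m.matched_definition),
                "explanation": m.explanation})
        else:
            models.append({
                "kind": "probabilistic", "model_name": m.model_name,
                "flagged": m.flagged, "interpretation": m.interpretation,
                "branches": [b.__dict__ for b in m.branches]})
    ext = report.external
    doc = {
        "format": "clingenkit-report-1",
        "patient_id": report.patient_id,
        "kb_version": report.kb_version,
        "generated_at": report.generated_at,
        "independent": [a.__dict__ for a in report.independent],
        "counts": report.counts,
        "variants": [list(v) for v in report.variants],
        "models": models,
        "external": None if ext is None else {
            "family_history": ext.family_history,
            "family_history_detail": ext.family_history_detail,
            "factors": {n: list(vu) for n, vu in ext.factors.items()},
        },
    }
    return json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False)


def report_from_structured(text: str) -> RiskReport:
    """Parse the structured rendering back into an equal ``RiskReport``."""
    doc = json.loads(text)
    models: list[CumulativeResult | ProbabilisticResult] = []
    for m in doc["models"]:
        if m["kind"] == "cumulative":
            models.append(CumulativeResult(
                model_name=m["model_name"],
                matched_assoc_ids=list(m["matched_assoc_ids"]),
                total_impact=m["total_impact"],
                family_history_increment=m["family_history_increment"],
                matched_definition=_definition_from_dict(m["matched_definition"]),
                explanation=m["explanation"]))
        else:
            models.append(ProbabilisticResult(
                model_name=m["model_name"],
                branches=[BranchResult(**b) for b in m["branches"]],
                flagged=m["flagged"], interpretation=m["interpretation"]))
    ext = doc["external"]
    external = None if ext is None else ExternalRiskFactors(
        family_history=ext["family_history"],
        family_history_detail=ext["family_history_detail"],
        factors={n: tuple(vu) for n, vu in ext["factors"].items()})
    return RiskReport(
        patient_id=doc["patient_id"], kb_version=doc["kb_version"],
        independent=[IndependentAssessment(**a) for a in doc["independent"]],
        counts=dict(doc["counts"]), models=models, external=external,
        generated_at=doc["generated_at"],
        variants=[tuple(v) for v in doc["variants"]])


def render_report(report: RiskReport, format: str = "text") -> str:
    """Render to ``text``, ``html``, or ``structured`` (JSON round-trip)."""
    if format == "text":
        return _render_text(report)
    if format == "html":
        return _render_html(report)
    if format == "structured":
        return _render_structured(report)
    raise ValueError(f"unknown report format {format!r}")


# ---------------------------------------------------------------------------
# external risk-factor store

#: Declared factor schema: name -> (python type, unit).  Unknown names are
#: accepted under the free-form "x:" namespace with a warning.
KNOWN_FACTORS: dict[str, tuple[type, str]] = {
    "family_history": (str, ""),       # yes/no/unknown
    "bmi": (float, "kg/m2"),
    "smoking": (str, ""),              # never/former/current
    "alcohol": (float, "units/week"),
    "age": (float, "years"),
}


@dataclass
class ExternalFactorStore:
    """Per-patient external risk-factor history (latest-write-wins view).

    Family history and the other envirobehavioral factors change over time,
    so every write is timestamped and kept; ``current`` exposes the latest
    value per factor name.
    """

    history: dict[str, dict[str, list[tuple[str, object, str]]]] = field(
        default_factory=dict)
    clock: Callable[[], str] = _utc_now

    def record(self, patient_id: str, name: str, value, unit: str = "") -> str:
        """Store one factor write; returns the (possibly namespaced) name."""
        if name in KNOWN_FACTORS:
            expected_type, expected_unit = KNOWN_FACTORS[name]
            try:
                value = expected_type(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"factor {name!r} expects {expected_type.__name__}, "
                    f"got {value!r}")
            if name == "family_history" and value not in ("yes", "no", "unknown"):
                raise ValueError("family_history must be yes/no/unknown")
            if not unit:
                unit = expected_unit
        else:
            warnings.warn(f"unknown factor {name!r}: storing under free-form "
                          "namespace 'x:'", stacklevel=2)
            name = f"x:{name}"
        entry = (self.clock(), value, unit)
        self.history.setdefault(patient_id, {}).setdefault(name, []).append(entry)
        return name

    def current(self, patient_id: str) -> ExternalRiskFactors:
        """Latest-write-wins snapshot as an ``ExternalRiskFactors``."""
        per_patient = self.history.get(patient_id, {})
        family_history = "unknown"
        factors: dict[str, tuple[object, str]] = {}
        for name, writes in per_patient.items():
            _, value, unit = writes[-1]
            if name == "family_history":
                family_history = value
            else:
                factors[name] = (value, unit)
        return ExternalRiskFactors(family_history=family_history, factors=factors)

    def factor_history(self, patient_id: str, name: str):
        return list(self.history.get(patient_id, {}).get(name, []))


def record_external_data(store: ExternalFactorStore, patient_id: str,
                         factors: dict[str, tuple[object, str]] | ExternalRiskFactors
                         ) -> ExternalFactorStore:
    """Record a batch of factor writes for one patient (latest-write-wins)."""
    if isinstance(factors, ExternalRiskFactors):
        store.record(patient_id, "family_history", factors.family_history)
        for name, (value, unit) in factors.factors.items():
            store.record(patient_id, name, value, unit)
    else:
        for name, (value, unit) in factors.items():
            store.record(patient_id, name, value, unit)
    return store
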