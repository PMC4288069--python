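"""Clinicogenomic knowledge base: association rules, model definitions,
versioning and queries.

The knowledge base holds two kinds of content:

* **Association records** — one rule per (SNP genotype, disease, model)
  linking an rsID + forward-strand genotype to a disease under one of three
  representation regimes: *independent* (odds ratio + evidence quality),
  *cumulative* (an additive impact value feeding a polygenic total), or
  *probabilistic* (membership of a branch — a genotype profile that flags
  risk only when complete).
* **Model definitions** — reference rows interpreting a model's total value:
  for cumulative models a banded total-impact → explanation lookup, for
  probabilistic models the required SNP count and interpretation per branch.

Persistence is two UTF-8 tab-separated tables (``associations.tsv``,
``models.tsv``) plus a JSON sidecar carrying version and changelog, keeping
the content diffable and curator-editable.  Mutations are functional: every
upsert returns a new, validated ``KnowledgeBase``; cancelled records are
tombstoned in the changelog, never silently deleted.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import KBSchemaError, KBValidationError, UpsertError

__all__ = [
    "ModelType",
    "AssociationRecord",
    "ModelDefinition",
    "ChangelogEntry",
    "KnowledgeBase",
    "Violation",
    "FAMILY_HISTORY_FACTOR",
    "load_knowledge_base",
    "write_knowledge_base",
    "validate_knowledge_base",
    "upsert_associations",
    "cr_snp_list",
    "query_by_variant",
    "canonical_allele",
]

# Cumulative definition rows whose explanation_2 equals this token carry a
# family-history risk increment (total_value) instead of a reference band.
FAMILY_HISTORY_FACTOR = "family_history"

_RSID_RE = re.compile(r"^rs\d+$")
_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")

ASSOCIATION_COLUMNS = [
    "assoc_id", "rs_id", "allele", "disease_code", "disease_name",
    "model_type", "model_name", "magnitude_of_impact", "evidence_quality",
    "impact_category", "evidence_category", "impact_value", "branch_id",
]
MODEL_COLUMNS = [
    "model_type", "model_name", "branch_id", "total_value",
    "explanation_1", "explanation_2",
]


class ModelType(str, Enum):
    INDEPENDENT = "independent"
    CUMULATIVE = "cumulative"
    PROBABILISTIC = "probabilistic"


def canonical_allele(allele: str) -> str:
    """Return the two-letter genotype in canonical (lexicographic) order."""
    return "".join(sorted(allele))


def _utc_now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass(frozen=True)
class AssociationRecord:
    """One clinicogenomic rule: (rsID, genotype) -> disease under a model.

    Value parameters are model-specific: independent records carry an odds
    ratio (``magnitude_of_impact``) and an evidence-quality grade 1-3 (with
    optional pre-assigned Weak/Moderate/Strong categories); cumulative records
    carry an additive ``impact_value``; probabilistic records carry the
    ``branch_id`` of the genotype profile they belong to.
    """

    assoc_id: int | None
    rs_id: str
    allele: str
    disease_code: str
    disease_name: str
    model_type: ModelType
    model_name: str
    magnitude_of_impact: float | None = None
    evidence_quality: int | None = None
    impact_category: int | None = None
    evidence_category: int | None = None
    impact_value: float | None = None
    branch_id: int | None = None


@dataclass(frozen=True)
class ModelDefinition:
    """One reference row of the model definition table.

    Cumulative rows map a total-impact level (``total_value``) to an OR-style
    explanation; a cumulative model usually has several rows forming bands.
    Probabilistic rows give, per branch, the total count of SNPs in the
    branch and the risk interpretation (accuracy/precision/recall narrative
    in ``explanation_1``, branch reference in ``explanation_2``).

    A cumulative row with ``explanation_2 == "family_history"`` is a *factor
    row*: its ``total_value`` is the increment added to the model total when
    the patient reports a positive family history.
    """

    model_type: ModelType
    model_name: str
    total_value: float
    explanation_1: str = ""
    explanation_2: str | None = None
    branch_id: int | None = None

    @property
    def is_factor(self) -> bool:
        return (self.model_type is ModelType.CUMULATIVE
                and self.explanation_2 == FAMILY_HISTORY_FACTOR)


@dataclass(frozen=True)
class ChangelogEntry:
    version: int
    operation: str  # "add" | "update" | "cancel"
    assoc_id: int
    record: dict | None  # payload after the operation (None for cancel)
    timestamp: str


@dataclass
class Violation:
    """One invariant violation: which record, which rule, and why."""

    record_id: object
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] record {self.record_id}: {self.message}"


@dataclass
class KnowledgeBase:
    """Versioned collection of association records and model definitions."""

    associations: list[AssociationRecord] = field(default_factory=list)
    model_definitions: list[ModelDefinition] = field(default_factory=list)
    version: int = 1
    timestamp: str = field(default_factory=_utc_now)
    changelog: list[ChangelogEntry] = field(default_factory=list)
    cancelled: set[int] = field(default_factory=set)

    def active_associations(self) -> list[AssociationRecord]:
        """Non-cancelled records, assoc_id ascending."""
        return sorted(
            (r for r in self.associations if r.assoc_id not in self.cancelled),
            key=lambda r: r.assoc_id,
        )

    def get(self, assoc_id: int) -> AssociationRecord | None:
        for r in self.associations:
            if r.assoc_id == assoc_id and assoc_id not in self.cancelled:
                return r
        return None

    def definitions_for(self, model_name: str,
                        model_type: ModelType | None = None) -> list[ModelDefinition]:
        return [d for d in self.model_definitions
                if d.model_name == model_name
                and (model_type is None or d.model_type is model_type)]


# ---------------------------------------------------------------------------
# table parsing

def _parse_int(value, row: int, fld: str) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return int(float(value))
    except (TypeError, ValueError):
        raise KBSchemaError(f"not an integer: {value!r}", row=row, field=fld)


def _parse_float(value, row: int, fld: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise KBSchemaError(f"not a number: {value!r}", row=row, field=fld)


def _parse_str(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value)


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise KBSchemaError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""], comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KBSchemaError(f"missing column(s) {missing} in {path.name}")
    return df


def _record_from_row(row: pd.Series, rownum: int) -> AssociationRecord:
    model_type_raw = _parse_str(row["model_type"]).strip().lower()
    try:
        model_type = ModelType(model_type_raw)
    except ValueError:
        raise KBSchemaError(f"unknown model_type {model_type_raw!r}",
                            row=rownum, field="model_type")
    return AssociationRecord(
        assoc_id=_parse_int(row["assoc_id"], rownum, "assoc_id"),
        rs_id=_parse_str(row["rs_id"]).strip(),
        allele=_parse_str(row["allele"]).strip().upper(),
        disease_code=_parse_str(row["disease_code"]).strip(),
        disease_name=_parse_str(row["disease_name"]),
        model_type=model_type,
        model_name=_parse_str(row["model_name"]).strip(),
        magnitude_of_impact=_parse_float(row["magnitude_of_impact"], rownum,
                                         "magnitude_of_impact"),
        evidence_quality=_parse_int(row["evidence_quality"], rownum,
                                    "evidence_quality"),
        impact_category=_parse_int(row["impact_category"], rownum, "impact_category"),
        evidence_category=_parse_int(row["evidence_category"], rownum,
                                     "evidence_category"),
        impact_value=_parse_float(row["impact_value"], rownum, "impact_value"),
        branch_id=_parse_int(row["branch_id"], rownum, "branch_id"),
    )


def _definition_from_row(row: pd.Series, rownum: int) -> ModelDefinition:
    model_type_raw = _parse_str(row["model_type"]).strip().lower()
    try:
        model_type = ModelType(model_type_raw)
    except ValueError:
        raise KBSchemaError(f"unknown model_type {model_type_raw!r}",
                            row=rownum, field="model_type")
    if model_type is ModelType.INDEPENDENT:
        raise KBSchemaError("independent associations have no model definition rows",
                            row=rownum, field="model_type")
    total = _parse_float(row["total_value"], rownum, "total_value")
    if total is None:
        raise KBSchemaError("total_value is required", row=rownum, field="total_value")
    expl2 = _parse_str(row["explanation_2"])
    return ModelDefinition(
        model_type=model_type,
        model_name=_parse_str(row["model_name"]).strip(),
        branch_id=_parse_int(row["branch_id"], rownum, "branch_id"),
        total_value=total,
        explanation_1=_parse_str(row["explanation_1"]),
        explanation_2=expl2 if expl2 != "" else None,
    )


# ---------------------------------------------------------------------------
# validation

def _record_violations(r: AssociationRecord) -> list[Violation]:
    v: list[Violation] = []
    rid = r.assoc_id

    if not _RSID_RE.match(r.rs_id):
        v.append(Violation(rid, "rs_id format", f"{r.rs_id!r} is not 'rs'+digits"))
    if len(r.allele) != 2 or any(c not in "ACGT" for c in r.allele):
        v.append(Violation(rid, "allele alphabet",
                           f"{r.allele!r} is not a two-letter genotype over ACGT"))
    elif r.allele != canonical_allele(r.allele):
        v.append(Violation(rid, "allele canonical order",
                           f"{r.allele!r} is not in lexicographic order"))
    if not _ICD10_RE.match(r.disease_code):
        v.append(Violation(rid, "disease_code format",
                           f"{r.disease_code!r} is not a syntactic ICD-10 code"))
    if not r.model_name:
        v.append(Violation(rid, "model_name required", "model_name is empty"))

    def require(name, ok):
        if not ok:
            v.append(Violation(rid, "field required for model_type",
                               f"{name} required for {r.model_type.value}"))

    def forbid(name, value):
        if value is not None:
            v.append(Violation(rid, "field forbidden for model_type",
                               f"{name} forbidden for {r.model_type.value}"))

    if r.model_type is ModelType.INDEPENDENT:
        require("magnitude_of_impact", r.magnitude_of_impact is not None)
        require("evidence_quality", r.evidence_quality is not None)
        forbid("impact_value", r.impact_value)
        forbid("branch_id", r.branch_id)
        if r.magnitude_of_impact is not None and r.magnitude_of_impact <= 0:
            v.append(Violation(rid, "odds ratio positive",
                               f"magnitude_of_impact={r.magnitude_of_impact}"))
    elif r.model_type is ModelType.CUMULATIVE:
        require("impact_value", r.impact_value is not None)
        forbid("magnitude_of_impact", r.magnitude_of_impact)
        forbid("evidence_quality", r.evidence_quality)
        forbid("impact_category", r.impact_category)
        forbid("evidence_category", r.evidence_category)
        forbid("branch_id", r.branch_id)
    elif r.model_type is ModelType.PROBABILISTIC:
        require("branch_id", r.branch_id is not None)
        forbid("magnitude_of_impact", r.magnitude_of_impact)
        forbid("evidence_quality", r.evidence_quality)
        forbid("impact_category", r.impact_category)
        forbid("evidence_category", r.evidence_category)
        forbid("impact_value", r.impact_value)
        if r.branch_id is not None and r.branch_id <= 0:
            v.append(Violation(rid, "branch_id positive", f"branch_id={r.branch_id}"))

    for name in ("evidence_quality", "impact_category", "evidence_category"):
        val = getattr(r, name)
        if val is not None and val not in (1, 2, 3):
            v.append(Violation(rid, "category range", f"{name}={val} not in 1..3"))
    return v


def validate_knowledge_base(kb: KnowledgeBase) -> list[Violation]:
    """Return every invariant violation in the KB (empty list == valid).

    Violations are data, not exceptions: callers decide whether to abort.
    Checks per-record field rules, cross-record uniqueness, the definition
    table, and branch-count consistency (each probabilistic branch's
    ``total_value`` must equal the number of association rows in the branch).
    """
    violations: list[Violation] = []
    active = kb.active_associations()

    seen_ids: set[int] = set()
    for r in kb.associations:
        if r.assoc_id is None:
            violations.append(Violation(None, "assoc_id required",
                                        "record has no assoc_id"))
            continue
        if r.assoc_id in seen_ids:
            violations.append(Violation(r.assoc_id, "assoc_id unique",
                                        "duplicate assoc_id"))
        seen_ids.add(r.assoc_id)

    for r in active:
        violations.extend(_record_violations(r))

    # one record per (rs_id, allele, disease_code, model_type, model_name)
    combo_seen: set[tuple] = set()
    for r in active:
        key = (r.rs_id, r.allele, r.disease_code, r.model_type, r.model_name,
               r.branch_id)
        if key in combo_seen:
            violations.append(Violation(
                r.assoc_id, "variant/condition/model unique",
                f"(rs_id, allele)=({r.rs_id}, {r.allele}) repeats with the same "
                "(disease_code, model_type, model_name, branch_id)"))
        combo_seen.add(key)

    # model definition table
    def_seen: set[tuple] = set()
    for d in kb.model_definitions:
        did = f"{d.model_name}/branch={d.branch_id}"
        if d.model_type is ModelType.PROBABILISTIC and d.branch_id is None:
            violations.append(Violation(did, "branch_id required",
                                        "probabilistic definition lacks branch_id"))
        if d.model_type is ModelType.CUMULATIVE and d.branch_id is not None:
            violations.append(Violation(did, "branch_id forbidden",
                                        "cumulative definition carries branch_id"))
        key = (d.model_type, d.model_name, d.branch_id, d.total_value, d.is_factor)
        if key in def_seen:
            violations.append(Violation(did, "definition unique",
                                        "duplicate model definition row"))
        def_seen.add(key)

    # branch-count consistency + every probabilistic association has a definition
    branch_counts: dict[tuple[str, int], int] = {}
    for r in active:
        if r.model_type is ModelType.PROBABILISTIC and r.branch_id is not None:
            branch_counts[(r.model_name, r.branch_id)] = (
                branch_counts.get((r.model_name, r.branch_id), 0) + 1)
    defined_branches = {(d.model_name, d.branch_id): d
                        for d in kb.model_definitions
                        if d.model_type is ModelType.PROBABILISTIC}
    for (name, branch), d in defined_branches.items():
        n = branch_counts.get((name, branch), 0)
        if n != int(d.total_value):
            violations.append(Violation(
                f"{name}/branch={branch}", "branch count mismatch",
                f"total_value={int(d.total_value)} but {n} association row(s)"))
    for (name, branch) in branch_counts:
        if (name, branch) not in defined_branches:
            violations.append(Violation(
                f"{name}/branch={branch}", "missing branch definition",
                "probabilistic associations reference an undefined branch"))

    # cumulative/probabilistic associations must name a defined model
    defined_models = {(d.model_type, d.model_name) for d in kb.model_definitions}
    for r in active:
        if r.model_type in (ModelType.CUMULATIVE, ModelType.PROBABILISTIC):
            if (r.model_type, r.model_name) not in defined_models:
                violations.append(Violation(
                    r.assoc_id, "missing model definition",
                    f"no definition rows for {r.model_type.value} model "
                    f"{r.model_name!r}"))
    return violations


# ---------------------------------------------------------------------------
# load / write

def load_knowledge_base(assoc_table: str | Path, model_table: str | Path,
                        meta_path: str | Path | None = None,
                        strict: bool = True) -> KnowledgeBase:
    """Load a knowledge base from its two TSV tables (plus optional sidecar).

    assoc_ids absent from the file are auto-assigned (max+1 order of
    appearance).  With ``strict`` (default) the loaded KB must pass
    :func:`validate_knowledge_base`; violations raise ``KBValidationError``.
    Duplicate assoc_ids in the file are always a hard error.
    """
    adf = _read_table(assoc_table, ASSOCIATION_COLUMNS)
    records: list[AssociationRecord] = []
    seen: set[int] = set()
    pending: list[int] = []  # indices needing auto ids
    for i, (_, row) in enumerate(adf.iterrows()):
        rec = _record_from_row(row, rownum=i + 2)  # +2: header + 1-based
        if rec.assoc_id is not None:
            if rec.assoc_id in seen:
                raise KBSchemaError(f"duplicate assoc_id {rec.assoc_id}",
                                    row=i + 2, field="assoc_id")
            seen.add(rec.assoc_id)
        else:
            pending.append(len(records))
        records.append(rec)
    next_id = max(seen, default=0) + 1
    for idx in pending:
        records[idx] = replace(records[idx], assoc_id=next_id)
        seen.add(next_id)
        next_id += 1

    mdf = _read_table(model_table, MODEL_COLUMNS)
    definitions = [_definition_from_row(row, rownum=i + 2)
                   for i, (_, row) in enumerate(mdf.iterrows())]

    kb = KnowledgeBase(associations=records, model_definitions=definitions)
    if meta_path is not None and Path(meta_path).exists():
        meta = json.loads(Path(meta_path).read_text(encoding="utf-8"))
        kb.version = int(meta["version"])
        kb.timestamp = meta["timestamp"]
        kb.cancelled = set(meta.get("cancelled", []))
        kb.changelog = [ChangelogEntry(**e) for e in meta.get("changelog", [])]

    if strict:
        violations = validate_knowledge_base(kb)
        if violations:
            raise KBValidationError(violations)
    return kb


def _record_to_cells(r: AssociationRecord) -> dict:
    def num(x):
        if x is None:
            return ""
        if isinstance(x, float) and x == int(x):
            return repr(x)
        return repr(x) if isinstance(x, float) else str(x)

    return {
        "assoc_id": str(r.assoc_id),
        "rs_id": r.rs_id,
        "allele": r.allele,
        "disease_code": r.disease_code,
        "disease_name": r.disease_name,
        "model_type": r.model_type.value,
        "model_name": r.model_name,
        "magnitude_of_impact": num(r.magnitude_of_impact),
        "evidence_quality": "" if r.evidence_quality is None else str(r.evidence_quality),
        "impact_category": "" if r.impact_category is None else str(r.impact_category),
        "evidence_category": "" if r.evidence_category is None else str(r.evidence_category),
        "impact_value": num(r.impact_value),
        "branch_id": "" if r.branch_id is None else str(r.branch_id),
    }


def write_knowledge_base(kb: KnowledgeBase, assoc_table: str | Path,
                         model_table: str | Path,
                         meta_path: str | Path | None = None) -> None:
    """Write the KB back to its TSV tables (active records, assoc_id order)."""
    rows = [_record_to_cells(r) for r in kb.active_associations()]
    adf = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    adf.to_csv(assoc_table, sep="\t", index=False)

    mrows = [{
        "model_type": d.model_type.value,
        "model_name": d.model_name,
        "branch_id": "" if d.branch_id is None else str(d.branch_id),
        "total_value": repr(d.total_value) if d.total_value != int(d.total_value)
        else str(int(d.total_value)),
        "explanation_1": d.explanation_1,
        "explanation_2": "" if d.explanation_2 is None else d.explanation_2,
    } for d in kb.model_definitions]
    mdf = pd.DataFrame(mrows, columns=MODEL_COLUMNS)
    mdf.to_csv(model_table, sep="\t", index=False)

    if meta_path is not None:
        meta = {
            "version": kb.version,
            "timestamp": kb.timestamp,
            "cancelled": sorted(kb.cancelled),
            "changelog": [e.__dict__ for e in kb.changelog],
        }
        Path(meta_path).write_text(json.dumps(meta, indent=1, ensure_ascii=False),
                                   encoding="utf-8")


# ---------------------------------------------------------------------------
# mutation + queries

def record_to_payload(r: AssociationRecord) -> dict:
    d = dict(r.__dict__)
    d["model_type"] = r.model_type.value
    return d


def record_from_payload(d: dict) -> AssociationRecord:
    d = dict(d)
    d["model_type"] = ModelType(d["model_type"])
    return AssociationRecord(**d)


def upsert_associations(kb: KnowledgeBase, records: Iterable,
                        mode: str,
                        clock: Callable[[], str] = _utc_now) -> KnowledgeBase:
    """Apply add/update/cancel of association records; returns a new KB.

    The input KB is never modified.  The new KB's version is one higher and
    carries one changelog entry per affected record.  If the mutated KB would
    fail validation, the mutation is rolled back (error raised, input KB
    untouched).  ``cancel`` accepts either records or bare assoc_ids;
    cancelled records stay recoverable from the changelog.
    """
    if mode not in ("add", "update", "cancel"):
        raise ValueError(f"unknown mode {mode!r}")
    new = copy.deepcopy(kb)
    new.version = kb.version + 1
    new.timestamp = clock()
    index = {r.assoc_id: i for i, r in enumerate(new.associations)}
    active_ids = {r.assoc_id for r in new.active_associations()}

    entries: list[ChangelogEntry] = []
    if mode == "cancel":
        ids = [r if isinstance(r, int) else r.assoc_id for r in records]
        for assoc_id in ids:
            if assoc_id not in active_ids:
                raise UpsertError(f"cancel: assoc_id {assoc_id} not present")
            new.cancelled.add(assoc_id)
            entries.append(ChangelogEntry(new.version, "cancel", assoc_id,
                                          None, new.timestamp))
    else:
        next_id = max((r.assoc_id for r in new.associations
                       if r.assoc_id is not None), default=0) + 1
        for rec in records:
            if mode == "add":
                if rec.assoc_id is None:
                    rec = replace(rec, assoc_id=next_id)
                    next_id += 1
                elif rec.assoc_id in index:
                    raise UpsertError(f"add: assoc_id {rec.assoc_id} already present")
                new.associations.append(rec)
                index[rec.assoc_id] = len(new.associations) - 1
                entries.append(ChangelogEntry(new.version, "add", rec.assoc_id,
                                              record_to_payload(rec), new.timestamp))
            else:  # update
                if rec.assoc_id not in active_ids:
                    raise UpsertError(f"update: assoc_id {rec.assoc_id} not present")
                new.associations[index[rec.assoc_id]] = rec
                entries.append(ChangelogEntry(new.version, "update", rec.assoc_id,
                                              record_to_payload(rec), new.timestamp))
    new.changelog.extend(entries)

    # Branch-count mismatches are advisory here: cancelling one rule of a
    # probabilistic branch (or adding a branch's rules incrementally) leaves
    # the branch temporarily short of its definition total — the branch just
    # cannot complete, which is the intended interpretation outcome.  All
    # other violations roll the mutation back (caller's KB is untouched).
    violations = [v for v in validate_knowledge_base(new)
                  if v.rule != "branch count mismatch"]
    if violations:
        raise KBValidationError(violations)
    return new


def replay_changelog(base: KnowledgeBase, entries: Sequence[ChangelogEntry]) -> KnowledgeBase:
    """Reconstruct a KB state by replaying changelog entries onto ``base``."""
    kb = copy.deepcopy(base)
    for e in entries:
        if e.operation == "add":
            kb.associations.append(record_from_payload(e.record))
        elif e.operation == "update":
            for i, r in enumerate(kb.associations):
                if r.assoc_id == e.assoc_id:
                    kb.associations[i] = record_from_payload(e.record)
                    break
        elif e.operation == "cancel":
            kb.cancelled.add(e.assoc_id)
        kb.version = e.version
        kb.timestamp = e.timestamp
    return kb


def cr_snp_list(kb: KnowledgeBase) -> set[str]:
    """Distinct rsIDs over non-cancelled associations (the CR-SNP data list)."""
    return {r.rs_id for r in kb.active_associations()}


def query_by_variant(kb: KnowledgeBase, rs_id: str, allele: str) -> list[AssociationRecord]:
    """All non-cancelled records matching (rs_id, allele) exactly, assoc_id order.

    ``allele`` must be canonical (use :func:`canonical_allele`).
    """
    return [r for r in kb.active_associations()
            if r.rs_id == rs_id and r.allele == allele]
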