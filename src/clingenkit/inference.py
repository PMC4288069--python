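"""Inference of personal clinicogenomic associations from CR-SNP data.

The join key is (rsID, canonical genotype): a patient's call matches an
association record only when the genotypes are exactly equal — a heterozygote
rule like rs2999081-CT matches a patient's TC call only through
canonicalization, never through allele-subset logic.  One genotype matching
several records (different diseases or models) yields several personal
associations, since the knowledge base defines one record per instance.

Reinterpretation re-runs inference for stored patients whenever the knowledge
base changes, producing a per-patient diff of added/removed associations —
the update semantics that keep interpretations current as curation evolves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import GenotypeParseError, StaleInterpretationError
from .genotypes import NO_CALL, CRSNPSet, PersonalGenotypeSet, extract_cr_snps
from .kb import AssociationRecord, KnowledgeBase, ModelType, cr_snp_list

__all__ = [
    "PersonalAssociation",
    "PersonalAssociationSet",
    "infer_associations",
    "reinterpret",
    "ReinterpretationDiff",
    "write_association_file",
    "read_association_file",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PersonalAssociation:
    """One matched rule: the patient's genotype plus the full KB record."""

    genotype: str
    record: AssociationRecord

    # passthrough conveniences
    @property
    def assoc_id(self) -> int:
        return self.record.assoc_id

    @property
    def rs_id(self) -> str:
        return self.record.rs_id

    @property
    def model_type(self) -> ModelType:
        return self.record.model_type

    @property
    def model_name(self) -> str:
        return self.record.model_name


@dataclass
class PersonalAssociationSet:
    """A patient's matched associations, versioned against the KB.

    ``associations``, ``unmatched`` and ``no_calls`` partition the CR-SNP set
    by rsID coverage: an rsID with at least one match never also appears in
    ``unmatched``; untyped (no-call) rsIDs are listed separately and never
    match anything.
    """

    patient_id: str
    kb_version: int
    associations: list[PersonalAssociation] = field(default_factory=list)
    unmatched: list[tuple[str, str]] = field(default_factory=list)
    no_calls: list[str] = field(default_factory=list)


def infer_associations(crsnps: CRSNPSet, kb: KnowledgeBase) -> PersonalAssociationSet:
    """Materialize every (rsID, genotype) match against the knowledge base.

    Output is deterministic: associations sorted by assoc_id, unmatched and
    no-call lists sorted by rsID.  The result is stamped with ``kb.version``
    (a CR-SNP set extracted under a newer KB than the one queried is an
    error).
    """
    if crsnps.kb_version > kb.version:
        raise StaleInterpretationError(
            f"CR-SNP set extracted at KB v{crsnps.kb_version} but inference KB "
            f"is v{kb.version}")
    # one-pass index over active records; semantically identical to calling
    # query_by_variant per rsID, but linear instead of quadratic
    index: dict[tuple[str, str], list[AssociationRecord]] = {}
    for r in kb.active_associations():
        index.setdefault((r.rs_id, r.allele), []).append(r)

    matched: list[PersonalAssociation] = []
    unmatched: list[tuple[str, str]] = []
    no_calls: list[str] = []
    for rs_id in sorted(crsnps.calls):
        call = crsnps.calls[rs_id]
        if call.genotype == NO_CALL:
            no_calls.append(rs_id)
            continue
        hits = index.get((rs_id, call.genotype), [])
        if hits:
            matched.extend(PersonalAssociation(call.genotype, r) for r in hits)
        else:
            unmatched.append((rs_id, call.genotype))
    matched.sort(key=lambda a: a.assoc_id)
    log.info("inference: patient=%s kb_version=%d matched=%d unmatched=%d no_call=%d",
             crsnps.patient_id, kb.version, len(matched), len(unmatched),
             len(no_calls))
    return PersonalAssociationSet(
        patient_id=crsnps.patient_id, kb_version=kb.version,
        associations=matched, unmatched=unmatched, no_calls=no_calls)


@dataclass
class ReinterpretationDiff:
    """Per-patient change report produced by :func:`reinterpret`."""

    patient_id: str
    added: list[int]
    removed: list[int]
    extraction_stale: bool = False


def reinterpret(patient_store, new_kb: KnowledgeBase):
    """Re-run inference for stored patients against an updated KB.

    ``patient_store`` is a sequence of ``(CRSNPSet, PersonalAssociationSet)``
    tuples, optionally extended with the patient's raw ``PersonalGenotypeSet``
    as a third element.  When the raw file is available, CR-SNP extraction is
    re-run against the new KB (new KB rsIDs are picked up); otherwise, if the
    new KB covers rsIDs absent from the stored CR-SNP set, the patient is
    flagged ``extraction_stale``.

    Returns ``(updated, diffs)`` where ``updated`` is a list of
    ``(CRSNPSet, PersonalAssociationSet)`` recomputed under ``new_kb`` and
    ``diffs`` lists added/removed assoc_ids per patient.
    """
    relevant = cr_snp_list(new_kb)
    updated = []
    diffs: list[ReinterpretationDiff] = []
    n_stale = 0
    for entry in patient_store:
        crsnps, old_set = entry[0], entry[1]
        raw: PersonalGenotypeSet | None = entry[2] if len(entry) > 2 else None
        if old_set.kb_version > new_kb.version:
            raise StaleInterpretationError(
                f"stored association set at KB v{old_set.kb_version} is newer "
                f"than KB v{new_kb.version}")
        stale = False
        if raw is not None:
            crsnps = extract_cr_snps(raw, new_kb)
        elif not relevant <= set(crsnps.calls):
            # KB gained rsIDs the stored extraction never saw; the stored raw
            # file would be needed to recover them.
            stale = True
            n_stale += 1
            crsnps = CRSNPSet(crsnps.patient_id,
                              {rs: c for rs, c in crsnps.calls.items()
                               if rs in relevant},
                              new_kb.version)
        else:
            crsnps = extract_cr_snps(
                PersonalGenotypeSet(crsnps.patient_id, crsnps.calls, "raw_tsv"),
                new_kb)
        new_set = infer_associations(crsnps, new_kb)
        old_ids = {a.assoc_id for a in old_set.associations}
        new_ids = {a.assoc_id for a in new_set.associations}
        diffs.append(ReinterpretationDiff(
            patient_id=crsnps.patient_id,
            added=sorted(new_ids - old_ids),
            removed=sorted(old_ids - new_ids),
            extraction_stale=stale))
        updated.append((crsnps, new_set))
    log.info("reinterpretation: kb_version=%d patients=%d stale_extractions=%d",
             new_kb.version, len(updated), n_stale)
    return updated, diffs


# ---------------------------------------------------------------------------
# personal association file (TSV with header comments)

_ASSOC_FILE_COLUMNS = [
    "assoc_id", "rs_id", "genotype", "disease_code", "disease_name",
    "model_type", "model_name", "magnitude_of_impact", "evidence_quality",
    "impact_category", "evidence_category", "impact_value", "branch_id",
]


def association_set_to_text(pas: PersonalAssociationSet) -> str:
    """Serialize to the personal-association TSV (also the exchange body)."""
    def cell(x):
        return "" if x is None else (repr(x) if isinstance(x, float) else str(x))

    lines = [f"# patient_id={pas.patient_id}",
             f"# kb_version={pas.kb_version}",
             "# unmatched=" + ",".join(f"{rs}:{gt}" for rs, gt in sorted(pas.unmatched)),
             "# no_calls=" + ",".join(sorted(pas.no_calls)),
             "\t".join(_ASSOC_FILE_COLUMNS)]
    for a in sorted(pas.associations, key=lambda a: a.assoc_id):
        r = a.record
        lines.append("\t".join([
            str(r.assoc_id), r.rs_id, a.genotype, r.disease_code, r.disease_name,
            r.model_type.value, r.model_name, cell(r.magnitude_of_impact),
            cell(r.evidence_quality), cell(r.impact_category),
            cell(r.evidence_category), cell(r.impact_value), cell(r.branch_id),
        ]))
    return "\n".join(lines) + "\n"


def association_set_from_text(text: str) -> PersonalAssociationSet:
    patient_id = None
    kb_version = None
    unmatched: list[tuple[str, str]] = []
    no_calls: list[str] = []
    associations: list[PersonalAssociation] = []
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("patient_id="):
                patient_id = body.split("=", 1)[1]
            elif body.startswith("kb_version="):
                kb_version = int(body.split("=", 1)[1])
            elif body.startswith("unmatched="):
                payload = body.split("=", 1)[1]
                unmatched = [tuple(tok.split(":", 1)) for tok in payload.split(",")
                             if tok]
            elif body.startswith("no_calls="):
                payload = body.split("=", 1)[1]
                no_calls = [tok for tok in payload.split(",") if tok]
            continue
        if not line.strip() or line.startswith("assoc_id\t"):
            continue
        cells = line.split("\t")
        if len(cells) != len(_ASSOC_FILE_COLUMNS):
            raise GenotypeParseError(
                f"expected {len(_ASSOC_FILE_COLUMNS)} columns, got {len(cells)}")
        d = dict(zip(_ASSOC_FILE_COLUMNS, cells))

        def num(key, conv):
            return None if d[key] == "" else conv(d[key])

        record = AssociationRecord(
            assoc_id=int(d["assoc_id"]), rs_id=d["rs_id"], allele=d["genotype"],
            disease_code=d["disease_code"], disease_name=d["disease_name"],
            model_type=ModelType(d["model_type"]), model_name=d["model_name"],
            magnitude_of_impact=num("magnitude_of_impact", float),
            evidence_quality=num("evidence_quality", lambda s: int(float(s))),
            impact_category=num("impact_category", lambda s: int(float(s))),
            evidence_category=num("evidence_category", lambda s: int(float(s))),
            impact_value=num("impact_value", float),
            branch_id=num("branch_id", lambda s: int(float(s))),
        )
        associations.append(PersonalAssociation(d["genotype"], record))
    if patient_id is None or kb_version is None:
        raise GenotypeParseError("missing patient_id/kb_version header comments")
    return PersonalAssociationSet(patient_id=patient_id, kb_version=kb_version,
                                  associations=associations, unmatched=unmatched,
                                  no_calls=no_calls)


def write_association_file(pas: PersonalAssociationSet, path: str | Path) -> None:
    Path(path).write_text(association_set_to_text(pas), encoding="utf-8")


def read_association_file(path: str | Path) -> PersonalAssociationSet:
    return association_set_from_text(Path(path).read_text(encoding="utf-8"))
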