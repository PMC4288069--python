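"""Exchange payloads (cgx-1.0 XML envelope) and replica synchronization.

CR-SNP and personal-association files travel between a genomic laboratory,
central EHR repositories and end-user applications as encapsulated text
inside a clinical-document-style XML envelope.  The cgx-1.0 envelope is a
deliberately simplified stand-in for a full HL7 CDA R2 document: a single
root element carrying payload type, patient, KB version, creation time and a
SHA-256 checksum, wrapping the TSV body as CDATA.  Serialization is
deterministic (stable attribute order, injectable clock), so identical
content yields byte-identical documents.

Replica synchronization copies the central KB state wholesale onto a replica
(replicas are read-only; a replica ahead of the central KB is a divergence
error), so client-side inference equals central inference after a sync.
"""

from __future__ import annotations

import copy
import hashlib
from datetime import datetime, timezone
from typing import Callable

from lxml import etree

from .errors import PayloadError, ReplicaDivergenceError
from .genotypes import NO_CALL, CRSNPSet, GenotypeCall, normalize_genotype
from .inference import (PersonalAssociationSet, association_set_from_text,
                        association_set_to_text)
from .kb import KnowledgeBase

__all__ = ["CGX_VERSION", "serialize_payload", "parse_payload", "sync_replica"]

CGX_VERSION = "1.0"


def _default_clock() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def _crsnp_body(crsnps: CRSNPSet) -> str:
    lines = ["rs_id\tchromosome\tposition\tgenotype"]
    for rs in sorted(crsnps.calls):
        c = crsnps.calls[rs]
        lines.append(f"{c.rs_id}\t{c.chromosome}\t{c.position}\t{c.genotype}")
    return "\n".join(lines) + "\n"


def _crsnp_from_body(body: str, patient_id: str, kb_version: int) -> CRSNPSet:
    calls: dict[str, GenotypeCall] = {}
    for line in body.splitlines():
        if not line.strip() or line.startswith("rs_id\t"):
            continue
        cells = line.split("\t")
        if len(cells) != 4:
            raise PayloadError("schema-mismatch",
                               f"cr_snp body row has {len(cells)} columns")
        rs_id, chrom, pos, gt = cells
        genotype = gt if gt == NO_CALL else normalize_genotype(gt)
        calls[rs_id] = GenotypeCall(rs_id, chrom, int(pos), genotype)
    return CRSNPSet(patient_id=patient_id, calls=calls, kb_version=kb_version)


def serialize_payload(content: CRSNPSet | PersonalAssociationSet,
                      clock: Callable[[], str] = _default_clock) -> bytes:
    """Wrap a CR-SNP or association set into a cgx-1.0 XML document.

    The checksum is SHA-256 over the exact UTF-8 body bytes; ``clock`` is
    injectable so tests can fix the creation timestamp.
    """
    if isinstance(content, CRSNPSet):
        payload_type = "cr_snp"
        body = _crsnp_body(content)
    elif isinstance(content, PersonalAssociationSet):
        payload_type = "cg_assoc"
        body = association_set_to_text(content)
    else:
        raise TypeError(f"cannot serialize {type(content).__name__}")

    body_bytes = body.encode("utf-8")
    root = etree.Element("cgx")
    root.set("version", CGX_VERSION)
    root.set("payload_type", payload_type)
    root.set("patient_id", content.patient_id)
    root.set("kb_version", str(content.kb_version))
    root.set("created_at", clock())
    root.set("checksum", hashlib.sha256(body_bytes).hexdigest())
    body_el = etree.SubElement(root, "body")
    body_el.text = etree.CDATA(body)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=False)


def parse_payload(xml: bytes | str) -> CRSNPSet | PersonalAssociationSet:
    """Parse and verify a cgx-1.0 document (inverse of serialize).

    Raises ``PayloadError`` with a distinct code per failure mode:
    malformed XML, missing attribute, checksum mismatch, body/type mismatch.
    """
    if isinstance(xml, str):
        xml = xml.encode("utf-8")
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise PayloadError("malformed-xml", str(exc)) from None
    if root.tag != "cgx":
        raise PayloadError("malformed-xml", f"unexpected root element {root.tag!r}")

    attrs = {}
    for name in ("version", "payload_type", "patient_id", "kb_version",
                 "created_at", "checksum"):
        value = root.get(name)
        if value is None:
            raise PayloadError("missing-attribute", f"attribute {name!r} missing")
        attrs[name] = value

    body_el = root.find("body")
    body = body_el.text if body_el is not None and body_el.text is not None else ""
    digest = hashlib.sha256(body.encode("utf-8")).hexdigest()
    if digest != attrs["checksum"]:
        raise PayloadError("checksum-mismatch",
                           f"body digest {digest[:12]}... != declared "
                           f"{attrs['checksum'][:12]}...")

    kb_version = int(attrs["kb_version"])
    if attrs["payload_type"] == "cr_snp":
        try:
            return _crsnp_from_body(body, attrs["patient_id"], kb_version)
        except PayloadError:
            raise
        except Exception as exc:
            raise PayloadError("schema-mismatch", str(exc)) from None
    if attrs["payload_type"] == "cg_assoc":
        try:
            parsed = association_set_from_text(body)
        except Exception as exc:
            raise PayloadError("schema-mismatch", str(exc)) from None
        if parsed.patient_id != attrs["patient_id"] or parsed.kb_version != kb_version:
            raise PayloadError("schema-mismatch",
                               "envelope attributes disagree with body headers")
        return parsed
    raise PayloadError("unknown-payload-type", attrs["payload_type"])


def sync_replica(central: KnowledgeBase, replica: KnowledgeBase) -> KnowledgeBase:
    """Bring a read-only replica up to the central KB state.

    Returns a deep copy of the central KB (records, version, changelog);
    a no-op when versions are already equal.  A replica *ahead* of the
    central KB has been written to locally — that is a divergence error.
    """
    if replica.version > central.version:
        raise ReplicaDivergenceError(
            f"replica v{replica.version} is ahead of central v{central.version}")
    return copy.deepcopy(central)
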