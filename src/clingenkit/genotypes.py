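"""Personal genotype parsing and clinically-relevant SNP (CR-SNP) extraction.

Reads two input dialects:

* ``raw_tsv`` — the de-facto direct-to-consumer raw download: 4 tab-separated
  columns (rsid, chromosome, position, genotype), ``#``-prefixed comments.
* ``vcf`` — a minimal VCF subset via pysam: biallelic SNP records with a GT
  field; multi-allelic and indel records are skipped with a logged reason.

All genotypes are normalized to a canonical two-letter form (characters in
ACGT, lexicographic order; haploid calls doubled to homozygous).  Inputs are
assumed to already be on the forward strand — no complementing or strand
flipping is ever attempted, so a reverse-strand genotype simply fails to
match the knowledge base.  No-calls are kept explicit (``--``) and never
match any association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import GenotypeParseError
from .kb import KnowledgeBase, canonical_allele, cr_snp_list

__all__ = [
    "NO_CALL",
    "GenotypeCall",
    "PersonalGenotypeSet",
    "CRSNPSet",
    "normalize_genotype",
    "read_raw_genotypes",
    "extract_cr_snps",
    "write_cr_snp_file",
    "read_cr_snp_file",
]

#: Explicit no-call token (never the empty string).
NO_CALL = "--"

_NO_CALL_TOKENS = {"--", "NN", ".", "..", "00", "0"}
_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}


def normalize_genotype(raw: str) -> str:
    """Normalize a genotype token to canonical form, or :data:`NO_CALL`.

    Single-character tokens (haploid calls, e.g. chrX/chrY/MT) are doubled to
    the homozygous form.  Recognized no-call tokens map to :data:`NO_CALL`.
    Anything else outside the ACGT alphabet raises ``GenotypeParseError``.
    """
    token = raw.strip().upper()
    if token in _NO_CALL_TOKENS:
        return NO_CALL
    if len(token) == 1 and token in "ACGT":
        return token + token
    if len(token) == 2 and all(c in "ACGT" for c in token):
        return canonical_allele(token)
    raise GenotypeParseError(f"unrecognized genotype token {raw!r}")


@dataclass(frozen=True)
class GenotypeCall:
    rs_id: str
    chromosome: str
    position: int
    genotype: str  # canonical two-letter, or NO_CALL


@dataclass
class PersonalGenotypeSet:
    """A patient's full genotype file: one call per rsID."""

    patient_id: str
    calls: dict[str, GenotypeCall]
    source_format: str  # "raw_tsv" | "vcf"
    skipped: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class CRSNPSet:
    """The clinically relevant subset of a patient's calls.

    Restricted to the knowledge base's CR-SNP list and stamped with the KB
    version used for extraction, so downstream interpretation can detect
    staleness.  No-call entries at relevant rsIDs are retained (flagged in
    reports as untyped) rather than dropped.
    """

    patient_id: str
    calls: dict[str, GenotypeCall]
    kb_version: int


def _read_raw_tsv(path: Path, patient_id: str) -> PersonalGenotypeSet:
    calls: dict[str, GenotypeCall] = {}
    skipped: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise GenotypeParseError(
                    f"expected 4 tab-separated columns, got {len(parts)}",
                    line=lineno)
            rs_id, chrom, pos, gt = (p.strip() for p in parts)
            chrom = chrom.upper().removeprefix("CHR")
            token = gt.strip().upper()
            if token and all(c in "DI" for c in token):
                skipped.append((lineno, f"indel genotype {gt!r} ({rs_id})"))
                continue
            try:
                genotype = normalize_genotype(gt)
            except GenotypeParseError as exc:
                raise GenotypeParseError(str(exc), line=lineno) from None
            try:
                position = int(pos)
            except ValueError:
                raise GenotypeParseError(f"position not an integer: {pos!r}",
                                         line=lineno)
            if rs_id in calls:
                raise GenotypeParseError(f"duplicate rs_id {rs_id}", line=lineno)
            calls[rs_id] = GenotypeCall(rs_id, chrom, position, genotype)
    return PersonalGenotypeSet(patient_id, calls, "raw_tsv", skipped)


def _read_vcf(path: Path, patient_id: str | None) -> PersonalGenotypeSet:
    import pysam

    calls: dict[str, GenotypeCall] = {}
    skipped: list[tuple[int, str]] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise GenotypeParseError("VCF has no sample columns")
        sample = samples[0]
        if patient_id is None:
            patient_id = sample
        for i, rec in enumerate(vf.fetch() if vf.index else vf):
            rsid = rec.id
            if not rsid or not rsid.startswith("rs"):
                skipped.append((i, f"no rsID at {rec.chrom}:{rec.pos}"))
                continue
            alts = rec.alts or ()
            alleles = (rec.ref,) + tuple(alts)
            if len(alts) != 1:
                skipped.append((i, f"multi-allelic record {rsid}"))
                continue
            if any(a is None or len(a) != 1 or a not in "ACGT" for a in alleles):
                skipped.append((i, f"non-SNP record {rsid}"))
                continue
            gt_idx = rec.samples[sample].get("GT")
            if gt_idx is None or all(g is None for g in gt_idx):
                genotype = NO_CALL
            else:
                bases = "".join(alleles[g] for g in gt_idx if g is not None)
                genotype = normalize_genotype(bases)
            if rsid in calls:
                raise GenotypeParseError(f"duplicate rs_id {rsid}")
            chrom = rec.chrom.upper().removeprefix("CHR")
            calls[rsid] = GenotypeCall(rsid, chrom, rec.pos, genotype)
    return PersonalGenotypeSet(patient_id, calls, "vcf", skipped)


def read_raw_genotypes(path: str | Path, format: str = "raw_tsv",
                       patient_id: str | None = None) -> PersonalGenotypeSet:
    """Parse a personal genotype file.

    ``patient_id`` defaults to the file stem (raw_tsv) or the VCF sample name.
    Every data line yields exactly one call or an entry in ``.skipped`` with a
    reason; duplicate rsIDs and malformed genotypes are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeParseError(f"file not found: {path}")
    if format == "raw_tsv":
        return _read_raw_tsv(path, patient_id or path.stem)
    if format == "vcf":
        return _read_vcf(path, patient_id)
    raise ValueError(f"unknown format {format!r}")


def extract_cr_snps(genotypes: PersonalGenotypeSet | CRSNPSet,
                    kb: KnowledgeBase) -> CRSNPSet:
    """Restrict a patient's calls to the KB's CR-SNP list.

    A projection: applying it twice equals applying it once.  No-calls at
    relevant rsIDs are retained.  The result is stamped with ``kb.version``.
    """
    relevant = cr_snp_list(kb)
    calls = {rs: call for rs, call in genotypes.calls.items() if rs in relevant}
    return CRSNPSet(patient_id=genotypes.patient_id, calls=calls,
                    kb_version=kb.version)


def write_cr_snp_file(crsnps: CRSNPSet, path: str | Path) -> None:
    """Write a CR-SNP set as TSV with patient/KB-version header comments."""
    lines = [f"# patient_id={crsnps.patient_id}",
             f"# kb_version={crsnps.kb_version}",
             "rs_id\tchromosome\tposition\tgenotype"]
    for rs in sorted(crsnps.calls):
        c = crsnps.calls[rs]
        lines.append(f"{c.rs_id}\t{c.chromosome}\t{c.position}\t{c.genotype}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cr_snp_file(path: str | Path) -> CRSNPSet:
    patient_id = None
    kb_version = None
    calls: dict[str, GenotypeCall] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("patient_id="):
                    patient_id = body.split("=", 1)[1]
                elif body.startswith("kb_version="):
                    kb_version = int(body.split("=", 1)[1])
                continue
            if not line.strip() or line.startswith("rs_id\t"):
                continue
            rs_id, chrom, pos, gt = line.split("\t")
            genotype = gt if gt == NO_CALL else normalize_genotype(gt)
            if rs_id in calls:
                raise GenotypeParseError(f"duplicate rs_id {rs_id}", line=lineno)
            calls[rs_id] = GenotypeCall(rs_id, chrom, int(pos), genotype)
    if patient_id is None or kb_version is None:
        raise GenotypeParseError("missing patient_id/kb_version header comments")
    return CRSNPSet(patient_id=patient_id, calls=calls, kb_version=kb_version)
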