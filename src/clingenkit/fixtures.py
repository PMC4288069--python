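"""Synthetic knowledge bases and patient genotype files.

Every other module is testable without downloads: this module generates a
valid knowledge base (independent, cumulative and probabilistic content), a
cohort of raw genotype files with controlled overlap, and a ground-truth
manifest per patient (which associations match, which branches complete,
which cumulative totals result) computed by direct construction — an oracle
independent of the extraction/inference/assessment pipeline it is used to
check.

The default content emulates the prostate-cancer study conditions: an
"SNP-only" probabilistic model defining 154 branch possibilities whose first
branch is the worked example (rs11720239-AA, rs2999081-CT, rs2811518-CT,
rs4793790-TT, required count 4), two cumulative models with banded reference
tables and a family-history increment, and a few dozen independent
odds-ratio associations.  All quantitative model metrics in generated
explanation texts are synthetic placeholders, not literature values.
Genotypes are drawn from configured carrier probabilities, not population
genetics — the fixtures test rule mechanics, not allele-frequency realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotypes import NO_CALL
from .kb import (AssociationRecord, KnowledgeBase, ModelDefinition, ModelType,
                 canonical_allele, write_knowledge_base)

__all__ = [
    "FixtureSpec",
    "WORKED_EXAMPLE_BRANCH",
    "WORKED_EXAMPLE_MODEL",
    "PatientFixture",
    "generate_kb",
    "generate_kb_files",
    "generate_patient",
    "generate_cohort",
    "write_patient_file",
    "write_manifest",
]

#: The branch-1 genotype profile of the SNP-only probabilistic model.
WORKED_EXAMPLE_BRANCH: list[tuple[str, str]] = [
    ("rs11720239", "AA"),
    ("rs2999081", "CT"),
    ("rs2811518", "CT"),
    ("rs4793790", "TT"),
]
WORKED_EXAMPLE_MODEL = "SNP-only"

_DISEASES = [
    ("C61", "Malignant neoplasm of prostate"),
    ("E11", "Type 2 diabetes mellitus"),
    ("I25.1", "Atherosclerotic heart disease"),
]
_PROSTATE = _DISEASES[0]

# rsID numeric ranges: clinically relevant vs background padding are disjoint
# by construction, so a background SNP can never collide with a KB rsID.
_CR_BASE = 1_000_000
_BACKGROUND_BASE = 9_000_000


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study content.

    Defaults mirror the modelled content: one SNP-only probabilistic model
    with 154 branches (branch 1 being the worked example), cumulative models
    with ~10 SNPs each, and a raw file padded with background SNPs.
    """

    seed: int = 0
    n_independent: int = 30
    n_cumulative_models: int = 2
    cumulative_assocs_per_model: int = 10
    n_probabilistic_models: int = 1
    branches_per_model: int = 154
    snps_per_branch: tuple[int, int] = (2, 6)
    n_patients: int = 20
    match_probability: float = 0.3
    no_call_fraction: float = 0.02
    n_background_snps: int = 1000
    include_worked_example: bool = True

    def __post_init__(self):
        for name in ("n_independent", "n_cumulative_models",
                     "cumulative_assocs_per_model", "n_probabilistic_models",
                     "branches_per_model", "n_patients", "n_background_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("match_probability", "no_call_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.snps_per_branch
        if not (1 <= lo <= hi):
            raise ValueError("snps_per_branch must be (lo, hi) with 1 <= lo <= hi")

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        d = dict(d)
        if "snps_per_branch" in d:
            d["snps_per_branch"] = tuple(d["snps_per_branch"])
        return cls(**d)


def _random_genotype(rng: np.random.Generator) -> str:
    bases = rng.choice(list("ACGT"), size=2)
    return canonical_allele("".join(bases))


def generate_kb(spec: FixtureSpec) -> KnowledgeBase:
    """Build a valid knowledge base from the spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    records: list[AssociationRecord] = []
    definitions: list[ModelDefinition] = []
    next_rs = _CR_BASE + 1
    next_id = 1

    def fresh_rs() -> str:
        nonlocal next_rs
        rs = f"rs{next_rs}"
        next_rs += 1
        return rs

    def add(rec: AssociationRecord) -> None:
        nonlocal next_id
        records.append(rec)
        next_id += 1

    # independent associations (odds ratio + evidence quality)
    for _ in range(spec.n_independent):
        code, name = _DISEASES[int(rng.integers(0, len(_DISEASES)))]
        add(AssociationRecord(
            assoc_id=next_id, rs_id=fresh_rs(), allele=_random_genotype(rng),
            disease_code=code, disease_name=name,
            model_type=ModelType.INDEPENDENT, model_name="Increased",
            magnitude_of_impact=round(float(rng.uniform(1.05, 3.0)), 2),
            evidence_quality=int(rng.integers(1, 4))))

    # cumulative models: additive impact values + banded reference table
    for m in range(spec.n_cumulative_models):
        model_name = f"{spec.cumulative_assocs_per_model}SNP-Cum{m + 1}"
        impact_values = []
        for _ in range(spec.cumulative_assocs_per_model):
            iv = round(float(rng.uniform(0.5, 2.0)), 2)
            impact_values.append(iv)
            add(AssociationRecord(
                assoc_id=next_id, rs_id=fresh_rs(),
                allele=_random_genotype(rng),
                disease_code=_PROSTATE[0], disease_name=_PROSTATE[1],
                model_type=ModelType.CUMULATIVE, model_name=model_name,
                impact_value=iv))
        max_total = sum(impact_values)
        levels = sorted({round(max_total * f, 2) for f in (0.0, 0.25, 0.5, 0.75)})
        for j, level in enumerate(levels):
            definitions.append(ModelDefinition(
                model_type=ModelType.CUMULATIVE, model_name=model_name,
                total_value=level,
                explanation_1=(f"Total impact >= {level:g}: risk band {j + 1} "
                               f"of {len(levels)} (synthetic OR narrative)")))
        # family-history factor row: positive family history augments the total
        definitions.append(ModelDefinition(
            model_type=ModelType.CUMULATIVE, model_name=model_name,
            total_value=1.0,
            explanation_1="Positive family history increment",
            explanation_2="family_history"))

    # probabilistic models: branches of genotype profiles
    lo, hi = spec.snps_per_branch
    for m in range(spec.n_probabilistic_models):
        model_name = (WORKED_EXAMPLE_MODEL if m == 0
                      else f"Prob{m + 1}-SVMID3-synthetic")
        for branch in range(1, spec.branches_per_model + 1):
            if m == 0 and branch == 1 and spec.include_worked_example:
                profile = list(WORKED_EXAMPLE_BRANCH)
            else:
                k = int(rng.integers(lo, hi + 1))
                profile = [(fresh_rs(), _random_genotype(rng)) for _ in range(k)]
            for rs_id, allele in profile:
                add(AssociationRecord(
                    assoc_id=next_id, rs_id=rs_id, allele=allele,
                    disease_code=_PROSTATE[0], disease_name=_PROSTATE[1],
                    model_type=ModelType.PROBABILISTIC, model_name=model_name,
                    branch_id=branch))
            definitions.append(ModelDefinition(
                model_type=ModelType.PROBABILISTIC, model_name=model_name,
                branch_id=branch, total_value=float(len(profile)),
                explanation_1=("At risk of prostate cancer (synthetic model "
                               "metrics: accuracy 0.85, precision 0.80, "
                               "recall 0.78)"),
                explanation_2=f"branch_id={branch}"))

    return KnowledgeBase(associations=records, model_definitions=definitions,
                         version=1, timestamp="1970-01-01T00:00:00+00:00")


def generate_kb_files(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Generate the KB and write associations.tsv / models.tsv under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kb = generate_kb(spec)
    assoc_path = out_dir / "associations.tsv"
    model_path = out_dir / "models.tsv"
    write_knowledge_base(kb, assoc_path, model_path,
                         meta_path=out_dir / "kb_meta.json")
    return assoc_path, model_path


@dataclass
class PatientFixture:
    """One synthetic patient: raw genotype rows plus a ground-truth manifest."""

    patient_id: str
    rows: list[tuple[str, str, int, str]]  # (rs_id, chromosome, position, genotype)
    manifest: dict = field(default_factory=dict)

    def raw_text(self) -> str:
        lines = ["# synthetic raw genotype file",
                 f"# patient_id={self.patient_id}",
                 "# rsid\tchromosome\tposition\tgenotype"]
        lines += [f"{rs}\t{chrom}\t{pos}\t{gt}"
                  for rs, chrom, pos, gt in self.rows]
        return "\n".join(lines) + "\n"


def generate_patient(spec: FixtureSpec, kb: KnowledgeBase,
                     carrier_profile: dict | None = None,
                     patient_id: str = "P1",
                     patient_index: int = 0) -> PatientFixture:
    """Generate one raw genotype file plus its ground-truth manifest.

    ``carrier_profile`` keys (all optional):

    * ``match_probability`` — per-rsID chance of carrying a KB risk genotype
      (default from the spec);
    * ``no_call_fraction`` — per-row chance of an untyped call;
    * ``force_complete_branches`` — list of ``(model_name, branch_id)`` whose
      genotype profiles are set exactly (completing those branches);
    * ``exclude_assoc_ids`` — assoc_ids whose genotype is forced to a
      non-matching value (for ablation fixtures).

    The manifest (matched assoc_ids, complete branches, cumulative totals,
    no-call rsIDs) is computed by a direct scan of the designed genotypes
    against the KB records — bookkeeping at construction time, independent of
    the parsing/extraction/inference pipeline.
    """
    profile = dict(carrier_profile or {})
    p_match = profile.get("match_probability", spec.match_probability)
    p_nocall = profile.get("no_call_fraction", spec.no_call_fraction)
    forced_branches = set(map(tuple, profile.get("force_complete_branches", [])))
    excluded_ids = set(profile.get("exclude_assoc_ids", []))

    rng = np.random.default_rng([spec.seed, 7919, patient_index])
    active = kb.active_associations()
    by_rs: dict[str, list[AssociationRecord]] = {}
    for r in active:
        by_rs.setdefault(r.rs_id, []).append(r)

    forced_genotypes: dict[str, str] = {}
    for r in active:
        if (r.model_type is ModelType.PROBABILISTIC
                and (r.model_name, r.branch_id) in forced_branches):
            forced_genotypes[r.rs_id] = r.allele

    def non_matching(records: list[AssociationRecord]) -> str:
        alleles = {r.allele for r in records}
        while True:
            g = _random_genotype(rng)
            if g not in alleles:
                return g

    genotypes: dict[str, str] = {}
    for rs_id in sorted(by_rs, key=lambda rs: int(rs[2:])):
        records = by_rs[rs_id]
        if any(r.assoc_id in excluded_ids for r in records):
            genotypes[rs_id] = non_matching(records)
            continue
        if rs_id in forced_genotypes:
            genotypes[rs_id] = forced_genotypes[rs_id]
            continue
        if rng.random() < p_nocall:
            genotypes[rs_id] = NO_CALL
        elif rng.random() < p_match:
            pick = records[int(rng.integers(0, len(records)))]
            genotypes[rs_id] = pick.allele
        else:
            genotypes[rs_id] = non_matching(records)

    # ground truth by direct scan of the designed genotypes
    matched_ids = sorted(r.assoc_id for r in active
                         if genotypes.get(r.rs_id) == r.allele)
    matched_set = set(matched_ids)
    branch_matched: dict[tuple[str, int], int] = {}
    for r in active:
        if r.model_type is ModelType.PROBABILISTIC and r.assoc_id in matched_set:
            key = (r.model_name, r.branch_id)
            branch_matched[key] = branch_matched.get(key, 0) + 1
    complete_branches = sorted(
        key for d in kb.model_definitions
        if d.model_type is ModelType.PROBABILISTIC
        for key in [(d.model_name, d.branch_id)]
        if branch_matched.get(key, 0) == int(d.total_value))
    cumulative_totals: dict[str, float] = {}
    for r in active:
        if r.model_type is ModelType.CUMULATIVE:
            cumulative_totals.setdefault(r.model_name, 0.0)
            if r.assoc_id in matched_set:
                cumulative_totals[r.model_name] += r.impact_value
    no_call_rs = sorted(rs for rs, g in genotypes.items() if g == NO_CALL)

    rows: list[tuple[str, str, int, str]] = []
    for rs_id in sorted(genotypes, key=lambda rs: int(rs[2:])):
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(1, 250_000_000))
        rows.append((rs_id, chrom, pos, genotypes[rs_id]))
    n_bg_nocall = 0
    for i in range(spec.n_background_snps):
        rs_id = f"rs{_BACKGROUND_BASE + 1 + i}"
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(1, 250_000_000))
        if rng.random() < p_nocall:
            gt = NO_CALL
            n_bg_nocall += 1
        else:
            gt = _random_genotype(rng)
        rows.append((rs_id, chrom, pos, gt))

    manifest = {
        "patient_id": patient_id,
        "matched_assoc_ids": matched_ids,
        "complete_branches": [list(b) for b in complete_branches],
        "cumulative_totals": {k: round(v, 10)
                              for k, v in sorted(cumulative_totals.items())},
        "no_call_rs_ids": no_call_rs,
        "n_cr_snps": len(genotypes),
        "n_background_snps": spec.n_background_snps,
        "n_background_no_calls": n_bg_nocall,
    }
    return PatientFixture(patient_id=patient_id, rows=rows, manifest=manifest)


def generate_cohort(spec: FixtureSpec, kb: KnowledgeBase,
                    carrier_profile: dict | None = None) -> list[PatientFixture]:
    """Generate ``spec.n_patients`` patients (deterministic per seed)."""
    return [generate_patient(spec, kb, carrier_profile,
                             patient_id=f"P{i + 1:04d}", patient_index=i)
            for i in range(spec.n_patients)]


def write_patient_file(fixture: PatientFixture, path: str | Path) -> None:
    Path(path).write_text(fixture.raw_text(), encoding="utf-8")


def write_manifest(fixture: PatientFixture, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fixture.manifest, indent=1, sort_keys=True),
                          encoding="utf-8")
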