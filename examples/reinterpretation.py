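"""Reinterpretation after a knowledge-base update.

Stores a cohort's inferred associations, mutates the KB (add a rule, cancel
a rule), and re-runs interpretation: each patient's association set is
recomputed against the new version, and the printed diff lists exactly which
associations appeared or disappeared per patient.
"""

from clingenkit import infer_associations, reinterpret
from clingenkit.fixtures import FixtureSpec, generate_cohort, generate_kb
from clingenkit.genotypes import GenotypeCall, PersonalGenotypeSet, extract_cr_snps
from clingenkit.kb import AssociationRecord, ModelType, upsert_associations

spec = FixtureSpec(seed=5, n_patients=5, branches_per_model=8,
                   n_background_snps=50, match_probability=0.5)
kb = generate_kb(spec)

store = []
for fixture in generate_cohort(spec, kb):
    calls = {rs: GenotypeCall(rs, c, p, g) for rs, c, p, g in fixture.rows}
    raw = PersonalGenotypeSet(fixture.patient_id, calls, "raw_tsv")
    crsnps = extract_cr_snps(raw, kb)
    store.append((crsnps, infer_associations(crsnps, kb), raw))
print(f"stored {len(store)} patients at KB v{kb.version}")

# curation: cancel the first independent rule, add a new one
victim = next(r.assoc_id for r in kb.active_associations()
              if r.model_type is ModelType.INDEPENDENT)
kb = upsert_associations(kb, [victim], mode="cancel")
kb = upsert_associations(kb, [AssociationRecord(
    assoc_id=None, rs_id="rs1000002", allele="AA", disease_code="C61",
    disease_name="Malignant neoplasm of prostate",
    model_type=ModelType.INDEPENDENT, model_name="Increased",
    magnitude_of_impact=2.1, evidence_quality=3)], mode="add")
print(f"KB mutated to v{kb.version} (cancelled assoc {victim}, added one rule)")

updated, diffs = reinterpret(store, kb)
for diff in diffs:
    print(f"  {diff.patient_id}: +{diff.added} -{diff.removed}"
          f"{' (extraction stale)' if diff.extraction_stale else ''}")
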