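"""Knowledge-base curation: validate, upsert, cancel, audit.

Shows the KB lifecycle: load content, validate it, add and cancel rules
(each mutation bumps the version and appends changelog entries), and replay
the changelog to reconstruct the final state — the audit trail that backs
reinterpretation of stored patients.
"""

from clingenkit import validate_knowledge_base
from clingenkit.fixtures import FixtureSpec, generate_kb
from clingenkit.kb import (AssociationRecord, ModelType, cr_snp_list,
                           query_by_variant, replay_changelog,
                           upsert_associations)

kb = generate_kb(FixtureSpec(seed=7, n_independent=5, n_cumulative_models=1,
                             branches_per_model=3, n_patients=0))
print(f"v{kb.version}: {len(kb.active_associations())} associations, "
      f"violations={len(validate_knowledge_base(kb))}")

new_rule = AssociationRecord(
    assoc_id=None,  # auto-assigned
    rs_id="rs1447295", allele="AA", disease_code="C61",
    disease_name="Malignant neoplasm of prostate",
    model_type=ModelType.INDEPENDENT, model_name="Increased",
    magnitude_of_impact=1.62, evidence_quality=2)
kb2 = upsert_associations(kb, [new_rule], mode="add")
added_id = kb2.changelog[-1].assoc_id
print(f"v{kb2.version}: added assoc {added_id} "
      f"(rs1447295-AA, OR 1.62)")
print(f"  query rs1447295/AA -> {len(query_by_variant(kb2, 'rs1447295', 'AA'))} hit(s)")

kb3 = upsert_associations(kb2, [added_id], mode="cancel")
print(f"v{kb3.version}: cancelled assoc {added_id}")
print(f"  query rs1447295/AA -> {len(query_by_variant(kb3, 'rs1447295', 'AA'))} hit(s)")
print(f"  rs1447295 in CR-SNP list: {'rs1447295' in cr_snp_list(kb3)}")

replayed = replay_changelog(kb, kb3.changelog[len(kb.changelog):])
print(f"changelog replay reconstructs v{replayed.version} exactly: "
      f"{replayed.active_associations() == kb3.active_associations()}")
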