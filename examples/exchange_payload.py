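"""cgx-1.0 exchange payloads and replica synchronization.

Wraps a CR-SNP set into the XML envelope (checksummed encapsulated TSV),
parses it back, shows that tampering is detected, and synchronizes a stale
replica knowledge base so client-side inference equals central inference.
"""

from clingenkit import (infer_associations, parse_payload, serialize_payload,
                        sync_replica)
from clingenkit.errors import PayloadError
from clingenkit.fixtures import FixtureSpec, generate_kb, generate_patient
from clingenkit.genotypes import GenotypeCall, PersonalGenotypeSet, extract_cr_snps
from clingenkit.kb import AssociationRecord, ModelType, upsert_associations

spec = FixtureSpec(seed=9, branches_per_model=5, n_background_snps=50)
kb = generate_kb(spec)
fixture = generate_patient(spec, kb, patient_id="P1")
calls = {rs: GenotypeCall(rs, c, p, g) for rs, c, p, g in fixture.rows}
crsnps = extract_cr_snps(PersonalGenotypeSet("P1", calls, "raw_tsv"), kb)

xml = serialize_payload(crsnps, clock=lambda: "2014-08-11T00:00:00+00:00")
print(f"payload: {len(xml)} bytes, {len(crsnps.calls)} CR-SNP rows")
assert parse_payload(xml) == crsnps
print("round trip: parsed payload equals the original")

tampered = xml.replace(b"rs1000001", b"rs1000002", 1)
try:
    parse_payload(tampered)
except PayloadError as exc:
    print(f"tampered payload rejected: {exc.code}")

# replica sync: central KB moves ahead, replica catches up
central = upsert_associations(kb, [AssociationRecord(
    assoc_id=None, rs_id="rs7777777", allele="GG", disease_code="C61",
    disease_name="Malignant neoplasm of prostate",
    model_type=ModelType.INDEPENDENT, model_name="Increased",
    magnitude_of_impact=1.9, evidence_quality=2)], mode="add")
replica = sync_replica(central, kb)
print(f"replica synced to v{replica.version} "
      f"({len(replica.active_associations())} associations)")
same = (infer_associations(extract_cr_snps(
            PersonalGenotypeSet('P1', calls, 'raw_tsv'), replica), replica)
        == infer_associations(extract_cr_snps(
            PersonalGenotypeSet('P1', calls, 'raw_tsv'), central), central))
print(f"client-side inference equals central inference: {same}")
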