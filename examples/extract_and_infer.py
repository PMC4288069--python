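"""Raw genotype file -> CR-SNP extraction -> personal associations.

Generates a synthetic knowledge base and one patient raw file (direct-to-
consumer 4-column TSV with 1,000 background SNPs), then runs the laboratory
side of the pipeline: parse the raw file, restrict it to the KB's clinically
relevant rsID list, and join on (rsID, genotype).  The printed counts show
how a large raw file collapses to a small clinically relevant subset, and
how that subset partitions into matched / unmatched / untyped calls.
"""

import tempfile
from pathlib import Path

from clingenkit import extract_cr_snps, infer_associations, read_raw_genotypes
from clingenkit.fixtures import FixtureSpec, generate_kb, generate_patient

spec = FixtureSpec(seed=42)
kb = generate_kb(spec)
fixture = generate_patient(spec, kb, patient_id="P1")

with tempfile.TemporaryDirectory() as d:
    raw_path = Path(d) / "P1.tsv"
    raw_path.write_text(fixture.raw_text())
    genotypes = read_raw_genotypes(raw_path, format="raw_tsv", patient_id="P1")

print(f"raw file calls:        {len(genotypes.calls)}")

crsnps = extract_cr_snps(genotypes, kb)
print(f"clinically relevant:   {len(crsnps.calls)} (KB v{crsnps.kb_version})")

pas = infer_associations(crsnps, kb)
print(f"matched associations:  {len(pas.associations)}")
print(f"unmatched genotypes:   {len(pas.unmatched)}")
print(f"untyped (no-call):     {len(pas.no_calls)}")

# the generator's ground-truth manifest agrees with the pipeline
assert [a.assoc_id for a in pas.associations] == \
    fixture.manifest["matched_assoc_ids"]
print("pipeline output matches the generator's ground-truth manifest")
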