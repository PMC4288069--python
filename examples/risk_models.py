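"""The three risk regimes on one synthetic patient.

Evaluates a patient against independent associations (odds-ratio grid),
a cumulative model (total impact with and without a positive family
history), and the SNP-only probabilistic model (branch completeness).
"""

from clingenkit import infer_associations
from clingenkit.fixtures import FixtureSpec, generate_kb, generate_patient
from clingenkit.genotypes import GenotypeCall, PersonalGenotypeSet, extract_cr_snps
from clingenkit.kb import ModelType
from clingenkit.risk import (ExternalRiskFactors, categorize_independent,
                             evaluate_cumulative, evaluate_probabilistic)

spec = FixtureSpec(seed=3)
kb = generate_kb(spec)
fixture = generate_patient(spec, kb, {"match_probability": 0.6,
                                      "force_complete_branches": [("SNP-only", 1)]},
                           patient_id="P1")
calls = {rs: GenotypeCall(rs, c, p, g) for rs, c, p, g in fixture.rows}
pas = infer_associations(
    extract_cr_snps(PersonalGenotypeSet("P1", calls, "raw_tsv"), kb), kb)

print("independent associations (impact x evidence, 1=Weak..3=Strong):")
for a in pas.associations:
    if a.model_type is ModelType.INDEPENDENT:
        g = categorize_independent(a)
        print(f"  {g.rs_id}-{g.genotype} OR={g.magnitude_of_impact:g} "
              f"grid={g.grid} ({g.labels[0]}/{g.labels[1]})")

model = next(d.model_name for d in kb.model_definitions
             if d.model_type is ModelType.CUMULATIVE)
plain = evaluate_cumulative(pas, model, kb)
fam = evaluate_cumulative(pas, model, kb,
                          ExternalRiskFactors(family_history="yes"))
print(f"\ncumulative {model}:")
print(f"  total impact {plain.total_impact:g} -> {plain.explanation}")
print(f"  with family history {fam.total_impact:g} "
      f"(+{fam.family_history_increment:g})")

prob = evaluate_probabilistic(pas, "SNP-only", kb)
print(f"\nprobabilistic SNP-only: flagged={prob.flagged}")
for b in prob.branches[:5]:
    print(f"  branch {b.branch_id}: {b.matched_count}/{b.required_count}"
          f"{' COMPLETE' if b.complete else ''}")
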