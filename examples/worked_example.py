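"""The branch-1 worked example, end to end.

Builds a minimal knowledge base holding one probabilistic branch (four
genotype rules for prostate cancer), runs inference for a patient carrying
exactly that profile, and prints the risk assessment: the patient matches
4/4 rules, so the branch is complete and the patient is flagged at risk.
Removing any single genotype drops the flag — branch matching is strict.
"""

import tempfile
from pathlib import Path

from clingenkit import (build_report, infer_associations, load_knowledge_base,
                        render_report)
from clingenkit.genotypes import CRSNPSet, GenotypeCall
from clingenkit.risk import evaluate_probabilistic

ASSOCIATIONS = """\
assoc_id\trs_id\tallele\tdisease_code\tdisease_name\tmodel_type\tmodel_name\tmagnitude_of_impact\tevidence_quality\timpact_category\tevidence_category\timpact_value\tbranch_id
1\trs11720239\tAA\tC61\tMalignant neoplasm of prostate\tprobabilistic\tSNP-only\t\t\t\t\t\t1
2\trs2999081\tCT\tC61\tMalignant neoplasm of prostate\tprobabilistic\tSNP-only\t\t\t\t\t\t1
3\trs2811518\tCT\tC61\tMalignant neoplasm of prostate\tprobabilistic\tSNP-only\t\t\t\t\t\t1
4\trs4793790\tTT\tC61\tMalignant neoplasm of prostate\tprobabilistic\tSNP-only\t\t\t\t\t\t1
"""
MODELS = """\
model_type\tmodel_name\tbranch_id\ttotal_value\texplanation_1\texplanation_2
probabilistic\tSNP-only\t1\t4\tAt risk of prostate cancer (model accuracy/precision/recall)\tbranch_id=1
"""

with tempfile.TemporaryDirectory() as d:
    (Path(d) / "associations.tsv").write_text(ASSOCIATIONS)
    (Path(d) / "models.tsv").write_text(MODELS)
    kb = load_knowledge_base(Path(d) / "associations.tsv", Path(d) / "models.tsv")

genotypes = {"rs11720239": "AA", "rs2999081": "CT",
             "rs2811518": "CT", "rs4793790": "TT"}
calls = {rs: GenotypeCall(rs, "1", i + 1, gt)
         for i, (rs, gt) in enumerate(genotypes.items())}
patient = CRSNPSet(patient_id="P1", calls=calls, kb_version=kb.version)

pas = infer_associations(patient, kb)
print(f"matched associations: {len(pas.associations)}")

result = evaluate_probabilistic(pas, "SNP-only", kb)
branch = result.branches[0]
print(f"branch {branch.branch_id}: {branch.matched_count}/"
      f"{branch.required_count} -> flagged={result.flagged}")

# ablation: drop one genotype, the profile is incomplete, no flag
ablated = CRSNPSet("P1", {rs: c for rs, c in calls.items()
                          if rs != "rs4793790"}, kb.version)
result_a = evaluate_probabilistic(infer_associations(ablated, kb), "SNP-only", kb)
print(f"without rs4793790: flagged={result_a.flagged}")

print()
print(render_report(build_report(pas, kb), "text"))
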