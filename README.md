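# clingenkit

A toolkit for turning personal SNP genotype data into clinical risk reports
through a versioned clinicogenomic knowledge base. It is aimed at
informaticians building genomic decision-support around EHR systems and at
anyone who needs a self-contained, testable implementation of
rule-based SNP interpretation: knowledge-base curation with full audit
history, CR-SNP extraction from raw genotype files, rsID+genotype rule
matching, risk scoring under three model regimes, an XML exchange envelope
for payloads, and reinterpretation of stored patients when the knowledge
base changes.

## The model

A knowledge base holds association rules, each linking a forward-strand
genotype at one SNP to a disease (ICD-10 coded) under one of three regimes:

- **Independent** — a stand-alone rule with odds ratio OR and evidence
  grade *e* ∈ {1,2,3}. Reported on a 3×3 grid, x = impact category from OR
  (Weak < 1.50 ≤ Moderate < 2.00 ≤ Strong by default, configurable),
  y = evidence category (defaults to *e*).
- **Cumulative** — each rule carries an impact value `v_i`; the personal
  total `T = Σ v_i` over matched rules (plus an optional family-history
  increment defined by the model) is interpreted against banded reference
  rows: the largest reference level not exceeding `T` supplies the
  explanation.
- **Probabilistic** — rules grouped into branches (genotype profiles); a
  branch of required size `k` is complete iff the patient matches all `k`
  of its genotypes, and any complete branch flags the patient at risk with
  the model's accuracy/precision/recall narrative.

Matching is exact on canonical genotypes (two letters over ACGT,
lexicographic order, so TC ≡ CT); no-calls are explicit and never match.
The pipeline is: raw genotype file → `extract` (restrict to the KB's rsID
list) → `infer` (materialize every (rsID, genotype) match) → `assess` /
`report`.

## Worked example

A patient carrying the branch-1 genotype profile of the SNP-only
probabilistic model — rs11720239-AA, rs2999081-CT, rs2811518-CT,
rs4793790-TT — against a knowledge base holding that branch
(`python examples/worked_example.py`):

```
matched associations: 4
branch 1: 4/4 -> flagged=True
without rs4793790: flagged=False
```

The patient matches all four rules of the branch (required count 4), so the
branch is complete and the patient is flagged at risk; with any one of the
four genotypes removed the profile is incomplete and no risk is flagged —
branch matching is strict, not fractional. The rendered report shows the
same result in its three sections (independent grid, CR-SNP counts,
model-based interpretations):

```
2. Clinically relevant SNP counts
   matched associations: 4 (distinct rsIDs: 4), unmatched: 0, untyped/no-call: 0
   #1 rs11720239-AA [probabilistic/SNP-only]
   ...
3. Model-based interpretations
   [probabilistic] SNP-only: AT RISK — At risk of prostate cancer (...) [branch_id=1]
      branch 1: 4/4 complete
```

The other scripts in `examples/` each demonstrate one capability:
`extract_and_infer.py` (raw file → associations), `kb_curation.py`
(versioned upserts and changelog replay), `risk_models.py` (all three
regimes), `exchange_payload.py` (cgx-1.0 envelope + replica sync),
`reinterpretation.py` (KB update diffs).

## Command line

The same pipeline is exposed as a thin CLI:

```bash
clingenkit fixtures generate --seed 1 --out demo/
clingenkit kb validate demo/kb
clingenkit extract demo/patients/P0001.tsv demo/kb --out cr.tsv
clingenkit infer cr.tsv demo/kb --out assoc.tsv
clingenkit assess assoc.tsv demo/kb SNP-only
clingenkit report assoc.tsv demo/kb --format html --family-history yes --out report.html
clingenkit payload pack cr.tsv --type cr_snp --out payload.xml
clingenkit sync demo/kb replica/
```

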