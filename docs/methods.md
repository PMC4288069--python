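# Methods

## Problem and model

`clingenkit` implements a clinicogenomic interpretation pipeline of the kind
used to plug consumer/clinical SNP genotyping into an EHR-centred decision
support workflow. A curated **knowledge base (KB)** holds association rules
`(rsID, genotype) → disease` under three representation regimes, plus a
**model definition table** that maps each model's total value to a clinical
explanation. A patient's raw genotype file is reduced to its **clinically
relevant SNPs (CR-SNPs)** — the rsIDs the KB covers — then joined against the
rules to produce **personal clinicogenomic associations**, which are assessed
and rendered as a three-part risk report.

The three regimes:

1. **Independent associations.** Each rule carries an odds ratio OR and an
   evidence-quality grade *e* ∈ {1,2,3}. For reporting, every matched rule is
   placed on a 3×3 grid with x = impact category and y = evidence category
   (1 = Weak, 2 = Moderate, 3 = Strong). The impact category is derived from
   OR by thresholds; the evidence category defaults to *e*. Records may carry
   pre-assigned categories (the "complete assessment" representation), which
   take precedence.
2. **Cumulative models.** Each rule carries an additive impact value `v_i`.
   The personal total is `T = Σ v_i` over matched rules, plus a per-model
   family-history increment when the patient reports positive family
   history. `T` is interpreted against the model's banded reference rows:
   the row with the largest `total_value ≤ T` supplies the explanation.
3. **Probabilistic models.** Rules are grouped into *branches* (genotype
   profiles) by `branch_id`. A branch with required count `k` (its
   definition row's total value, equal by KB invariant to its number of
   rules) is *complete* iff the patient matches exactly `k` of its rules;
   the patient is flagged at risk iff any branch is complete. Because the KB
   guarantees `k` equals the branch's rule count, count equality is
   equivalent to a full genotype-subset match; the test suite checks both
   routes against each other.

Matching is **exact on canonical genotype**: two-letter genotypes over
{A,C,G,T} in lexicographic order, haploid calls doubled to homozygous.
Heterozygote order is erased by canonicalization (TC ≡ CT), but there is no
allele-subset logic — a rule for CT does not match a CC call. All content is
assumed forward-strand; no complementing or strand flipping is attempted,
because silently complementing ambiguous A/T and C/G genotypes is unsafe. A
mismatched strand therefore simply fails to match.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| OR threshold, Moderate | 1.50 | lower bound of impact category 2 |
| OR threshold, Strong | 2.00 | lower bound of impact category 3 |
| boundary rule | higher category | OR exactly at a cut-off takes the higher category |
| family-history increment | per-model content | cumulative factor row in `models.tsv` |
| no-call tokens | `--`, `NN`, `.` | parsed to an explicit NO_CALL, never empty string |

The OR cut-offs are anchored to the observation that most clinically
relevant SNPs have minor effects (OR below roughly 1.5–2.0), so 1.5/2.0
separates the bulk of minor-effect variants from moderate and strong ones.
They are configuration, not code: `ORThresholds` is a parameter of
`categorize_independent`/`build_report`, and the CLI reads them from a JSON
config. The family-history increment is deliberately *content*: it is
declared per cumulative model as a factor row in the model table
(`explanation_2 == "family_history"`, increment in `total_value`), because
how much a positive family history augments a model's total is a property
of the model, not of the toolkit.

## Knowledge-base semantics

* **Validation is data, not exceptions.** `validate_knowledge_base` returns
  a list of violations (record id + rule + message); loading is strict by
  default but invalid KBs can be constructed and inspected in memory.
* **Versioning.** Every successful upsert returns a new KB with version + 1
  and one changelog entry per affected record. Cancel tombstones: cancelled
  records leave all queries but remain recoverable from the changelog, and
  `replay_changelog` reconstructs any state from version 1 — the audit trail
  required for reinterpretation.
* **Rollback.** A mutation whose result fails validation raises and leaves
  the caller's KB untouched. One rule is advisory during upserts:
  *branch count mismatch*. Cancelling a single rule of a probabilistic
  branch (or adding a branch's rules over several upserts) necessarily makes
  the branch's definition total disagree with its rule count; blocking that
  would make curation of probabilistic content impossible. The shortened
  branch simply can never complete, and full validation still reports the
  mismatch.
* **Uniqueness.** A given `(rs_id, allele)` may repeat only with a distinct
  `(disease_code, model_type, model_name, branch_id)`. Including
  `branch_id` in the key is deliberate: probabilistic models with many
  branches reuse the same genotype across branches of one model, which a
  key without `branch_id` would forbid.
* **Cumulative reference rows** are intentionally non-unique per model name:
  a banded lookup needs several `(model_name, total_value)` rows. Uniqueness
  is enforced on `(model_type, model_name, branch_id, total_value,
  is_factor)`.
* ICD-10 codes are validated syntactically (letter + 2 digits + optional
  `.d`); the toolkit does not bundle a terminology service. Disease names
  are carried verbatim and never used as join keys.

## Inference and reinterpretation

`infer_associations` materializes every `(rsID, genotype)` match (one
genotype hitting several records yields several personal associations) and
partitions the CR-SNP set into matched / unmatched / no-call, stamped with
the KB version. Internally it builds a one-pass `(rs_id, allele)` index;
tests assert exact agreement with a nested-loop brute-force join.

`reinterpret` re-runs inference for stored patients against an updated KB
and reports per-patient added/removed assoc_ids. When the stored raw
genotype file is available, CR-SNP extraction is re-run (new KB rsIDs are
recovered); when only the CR-SNP file is stored and the new KB covers rsIDs
the old extraction never saw, the patient is flagged `extraction_stale`
rather than silently under-interpreted.

Replicated deployment is supported by `sync_replica`: a replica is a
read-only deep copy of the central KB; a replica whose version is ahead has
diverged and is rejected. After a sync, client-side inference provably
equals central inference (tested).

## Exchange envelope (cgx-1.0)

Payloads travel as a deliberately simplified clinical-document-style XML
envelope, not a conformant HL7 CDA R2 instance: one root element with
`payload_type` (`cr_snp` | `cg_assoc`), `patient_id`, `kb_version`,
`created_at` and a SHA-256 checksum, wrapping the TSV body as CDATA. The
checksum is over the exact UTF-8 body bytes; parse failures carry distinct
error codes (malformed XML, missing attribute, checksum mismatch, schema
mismatch). Serialization is byte-deterministic given an injected clock.

## Numerical choices

* Cumulative totals use `math.fsum`, so the total is the correctly rounded
  sum of the addends and is independent of association order and grouping.
  Exactness claims in tests are made against rational (`Fraction`)
  arithmetic, not float-association accidents.
* OR threshold boundaries belong to the higher category (tested at 1.50 and
  2.00 exactly).
* Reference-band lookup is "largest `total_value ≤ T`"; a total below the
  lowest band yields an explicit "below the lowest reference level" result,
  and zero matches yield total 0 with a "no risk alleles matched"
  explanation rather than an error.
* NO_CALL never matches and never counts toward a branch; an incomplete
  branch containing an untyped rsID is reported *indeterminate* (the risk
  booleans are unchanged — the flag stays false).

## Synthetic data generator

`clingenkit.fixtures` generates the entire test universe. Defaults model
the study conditions: one SNP-only probabilistic model with **154 branches**
whose branch 1 is the worked example (rs11720239-AA, rs2999081-CT,
rs2811518-CT, rs4793790-TT; required count 4), two cumulative models of 10
SNPs each with banded reference tables and a family-history increment of
1.0, 30 independent associations, and raw files padded with 1,000
background SNPs drawn from a reserved rsID range disjoint from KB content.
All narrative metrics in generated explanation texts (accuracy/precision/
recall figures) are synthetic placeholders, and the generated tables are a
synthetic stand-in for curated content — the generator exists to exercise
rule mechanics, not to reproduce literature allele frequencies.

What it does **not** emulate: population genetics (no Hardy–Weinberg or LD
structure; genotypes are drawn per-SNP from a configured carrier
probability), sequencing error, strand ambiguity, indels/multi-allelic
variation in raw files, or realistic effect-size distributions. Passing
tests therefore demonstrate correctness of the rule machinery, versioning,
and serialization — not calibration of any risk model on real cohorts.

Each generated patient comes with a ground-truth manifest (matched
assoc_ids, complete branches, cumulative totals, no-calls) computed by a
direct scan of the designed genotypes at construction time — an oracle
independent of the parse→extract→infer→assess pipeline it checks. Per-module
tests run a scaled-down universe (≈12 branches, 300 background SNPs);
the acceptance checks run the full 154-branch/1,000-background
configuration with 200-patient cohorts, sizes chosen so the whole suite
stays interactive.

## Known limitations

* No imputation, phasing, liftover, dbSNP lookup, or strand inference;
  positions are carried but never used as join keys.
* VCF support is a minimal biallelic-SNP subset (first sample, GT field);
  multi-allelic and indel records are skipped with logged reasons.
* No decreased-risk/protective scoring in generated content (the schema
  permits it); no cross-disease risk combination; no family-member risk
  propagation.
* The cgx envelope is not HL7 CDA conformant by design; no transport,
  authentication, or identity validation is included (patient ids are
  opaque).
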