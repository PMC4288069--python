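"""Independent categorization, cumulative totals, probabilistic branches."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clingenkit.errors import KBIntegrityError, ModelNotFoundError
from clingenkit.fixtures import generate_cohort, generate_patient
from clingenkit.genotypes import NO_CALL, PersonalGenotypeSet, extract_cr_snps
from clingenkit.inference import PersonalAssociation, infer_associations
from clingenkit.kb import ModelType
from clingenkit.risk import (ExternalRiskFactors, ORThresholds,
                             categorize_independent, evaluate_cumulative,
                             evaluate_probabilistic)
from tests.conftest import crsnp_set, make_independent
from tests.test_inference import BRANCH1_GENOTYPES


def passoc(record):
    return PersonalAssociation(record.allele, record)


def infer_fixture(fx, kb):
    from clingenkit.genotypes import GenotypeCall

    calls = {rs: GenotypeCall(rs, chrom, pos, gt)
             for rs, chrom, pos, gt in fx.rows}
    gs = PersonalGenotypeSet(fx.patient_id, calls, "raw_tsv")
    return infer_associations(extract_cr_snps(gs, kb), kb)


class TestIndependent:
    def test_weak_weak_under_default_thresholds(self):
        a = categorize_independent(passoc(make_independent(1, odds_ratio=1.2,
                                                           evidence_quality=1)))
        assert a.grid == (1, 1)
        assert a.labels == ("Weak", "Weak")

    def test_preassigned_categories_override_thresholds(self):
        rec = make_independent(1, odds_ratio=1.2, evidence_quality=1,
                               impact_category=3, evidence_category=3)
        a = categorize_independent(passoc(rec))
        assert a.grid == (3, 3)
        assert a.labels == ("Strong", "Strong")

    @pytest.mark.parametrize("odds_ratio,category", [
        (1.49, 1), (1.50, 2), (1.99, 2), (2.00, 3), (5.0, 3), (0.1, 1),
    ])
    def test_boundary_values_take_higher_category(self, odds_ratio, category):
        a = categorize_independent(passoc(make_independent(1, odds_ratio=odds_ratio)))
        assert a.impact_category == category

    def test_nonpositive_odds_ratio_rejected(self):
        rec = make_independent(1)
        rec = type(rec)(**{**rec.__dict__, "magnitude_of_impact": 0.0})
        with pytest.raises(ValueError, match="positive"):
            categorize_independent(passoc(rec))

    @given(odds_ratio=st.floats(min_value=1e-6, max_value=1e6,
                                allow_nan=False, allow_infinity=False),
           moderate=st.floats(min_value=0.5, max_value=3.0),
           gap=st.floats(min_value=0.01, max_value=3.0))
    @settings(deadline=None, max_examples=200)
    def test_every_positive_or_maps_to_exactly_one_category(
            self, odds_ratio, moderate, gap):
        t = ORThresholds(moderate=moderate, strong=moderate + gap)
        assert t.category(odds_ratio) in (1, 2, 3)
        # strictly increasing thresholds partition the positive axis
        assert (t.category(odds_ratio) == 1) == (odds_ratio < moderate)
        assert (t.category(odds_ratio) == 3) == (odds_ratio >= moderate + gap)


class TestCumulative:
    def test_singleton_sum(self, small_kb):
        model = next(d.model_name for d in small_kb.model_definitions
                     if d.model_type is ModelType.CUMULATIVE)
        rec = next(r for r in small_kb.active_associations()
                   if r.model_type is ModelType.CUMULATIVE
                   and r.model_name == model)
        pas = infer_associations(crsnp_set({rec.rs_id: rec.allele}), small_kb)
        res = evaluate_cumulative(pas, model, small_kb)
        assert res.total_impact == rec.impact_value
        assert res.matched_assoc_ids == [rec.assoc_id]

    def test_zero_matches_gives_zero_total(self, small_kb):
        model = next(d.model_name for d in small_kb.model_definitions
                     if d.model_type is ModelType.CUMULATIVE)
        pas = infer_associations(crsnp_set({}), small_kb)
        res = evaluate_cumulative(pas, model, small_kb)
        assert res.total_impact == 0.0
        assert res.explanation == "no risk alleles matched"

    def test_unknown_model_rejected(self, small_kb):
        pas = infer_associations(crsnp_set({}), small_kb)
        with pytest.raises(ModelNotFoundError):
            evaluate_cumulative(pas, "no-such-model", small_kb)

    def test_random_patients_match_summation_oracle(self, small_kb, small_spec):
        models = sorted({d.model_name for d in small_kb.model_definitions
                         if d.model_type is ModelType.CUMULATIVE})
        fam = ExternalRiskFactors(family_history="yes")
        increments = {
            m: sum(d.total_value for d in small_kb.definitions_for(m)
                   if d.is_factor)
            for m in models}
        from fractions import Fraction

        for fx in generate_cohort(small_spec, small_kb):
            pas = infer_fixture(fx, small_kb)
            for m in models:
                # independently coded oracle: exact rational sum over the KB
                # records the manifest says matched
                matched = set(fx.manifest["matched_assoc_ids"])
                oracle = sum((Fraction(r.impact_value)
                              for r in small_kb.active_associations()
                              if r.assoc_id in matched
                              and r.model_type is ModelType.CUMULATIVE
                              and r.model_name == m), Fraction(0))
                res = evaluate_cumulative(pas, m, small_kb)
                assert res.total_impact == float(oracle)
                res_fam = evaluate_cumulative(pas, m, small_kb, fam)
                assert res_fam.total_impact == float(
                    oracle + Fraction(increments[m]))

    def test_additivity_over_disjoint_subsets(self, small_kb, small_spec):
        fx = generate_patient(small_spec, small_kb,
                              {"match_probability": 0.8}, "P1")
        pas = infer_fixture(fx, small_kb)
        model = next(d.model_name for d in small_kb.model_definitions
                     if d.model_type is ModelType.CUMULATIVE)
        full = evaluate_cumulative(pas, model, small_kb)
        # split the patient's associations into two disjoint halves
        import copy

        half1, half2 = copy.copy(pas), copy.copy(pas)
        half1.associations = pas.associations[::2]
        half2.associations = pas.associations[1::2]
        t1 = evaluate_cumulative(half1, model, small_kb).total_impact
        t2 = evaluate_cumulative(half2, model, small_kb).total_impact
        assert t1 + t2 == pytest.approx(full.total_impact, rel=1e-12)

    def test_reference_band_is_largest_not_exceeding_total(self, small_kb,
                                                           small_spec):
        model = next(d.model_name for d in small_kb.model_definitions
                     if d.model_type is ModelType.CUMULATIVE)
        fx = generate_patient(small_spec, small_kb,
                              {"match_probability": 0.9}, "P1")
        pas = infer_fixture(fx, small_kb)
        res = evaluate_cumulative(pas, model, small_kb)
        bands = sorted(d.total_value for d in small_kb.definitions_for(model)
                       if not d.is_factor)
        expected = max((b for b in bands if b <= res.total_impact), default=None)
        assert res.matched_definition.total_value == expected


class TestProbabilistic:
    def test_complete_branch1_flags_risk(self, kb_branch1):
        pas = infer_associations(crsnp_set(BRANCH1_GENOTYPES), kb_branch1)
        res = evaluate_probabilistic(pas, "SNP-only", kb_branch1)
        assert res.flagged
        b = res.branches[0]
        assert (b.branch_id, b.matched_count, b.required_count,
                b.complete) == (1, 4, 4, True)
        assert "branch_id=1" in res.interpretation

    def test_missing_one_genotype_not_flagged(self, kb_branch1):
        genotypes = dict(BRANCH1_GENOTYPES)
        del genotypes["rs4793790"]
        pas = infer_associations(crsnp_set(genotypes), kb_branch1)
        res = evaluate_probabilistic(pas, "SNP-only", kb_branch1)
        assert not res.flagged
        assert res.branches[0].matched_count == 3
        assert res.interpretation == "no complete risk profile matched"

    def test_no_call_makes_branch_indeterminate(self, kb_branch1):
        genotypes = dict(BRANCH1_GENOTYPES, rs4793790=NO_CALL)
        pas = infer_associations(crsnp_set(genotypes), kb_branch1)
        res = evaluate_probabilistic(pas, "SNP-only", kb_branch1)
        assert not res.flagged
        assert res.branches[0].indeterminate

    def test_exhaustive_ablation_breaks_completeness(self, kb_branch1):
        for rs in BRANCH1_GENOTYPES:
            genotypes = dict(BRANCH1_GENOTYPES)
            genotypes[rs] = "GG" if genotypes[rs] != "GG" else "AA"
            pas = infer_associations(crsnp_set(genotypes), kb_branch1)
            assert not evaluate_probabilistic(pas, "SNP-only", kb_branch1).flagged

    def test_count_equality_equals_subset_match_oracle(self, small_kb,
                                                       small_spec):
        """Dual-route check: the count-equality rule must agree with a direct
        per-branch genotype-subset verification."""
        by_branch: dict[int, list] = {}
        for r in small_kb.active_associations():
            if (r.model_type is ModelType.PROBABILISTIC
                    and r.model_name == "SNP-only"):
                by_branch.setdefault(r.branch_id, []).append(r)
        for fx in generate_cohort(small_spec, small_kb):
            pas = infer_fixture(fx, small_kb)
            res = evaluate_probabilistic(pas, "SNP-only", small_kb)
            genotype_of = {rs: gt for rs, _, _, gt in fx.rows}
            flags = {b.branch_id: b.complete for b in res.branches}
            for branch_id, records in by_branch.items():
                subset_match = all(genotype_of.get(r.rs_id) == r.allele
                                   for r in records)
                assert flags.get(branch_id, False) == subset_match
            assert res.flagged == any(
                all(genotype_of.get(r.rs_id) == r.allele for r in records)
                for records in by_branch.values())

    def test_undefined_branch_is_integrity_error(self, kb_branch1):
        pas = infer_associations(crsnp_set(BRANCH1_GENOTYPES), kb_branch1)
        kb_branch1.model_definitions[0] = type(
            kb_branch1.model_definitions[0])(
                model_type=ModelType.PROBABILISTIC, model_name="SNP-only",
                branch_id=2, total_value=4.0, explanation_1="x")
        with pytest.raises(KBIntegrityError):
            evaluate_probabilistic(pas, "SNP-only", kb_branch1)

    def test_unknown_model_rejected(self, kb_branch1):
        pas = infer_associations(crsnp_set({}), kb_branch1)
        with pytest.raises(ModelNotFoundError):
            evaluate_probabilistic(pas, "nope", kb_branch1)
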