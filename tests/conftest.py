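import pytest
from hypothesis import settings

from clingenkit.fixtures import (WORKED_EXAMPLE_BRANCH, WORKED_EXAMPLE_MODEL,
                                 FixtureSpec, generate_kb)
from clingenkit.genotypes import CRSNPSet, GenotypeCall
from clingenkit.kb import (AssociationRecord, KnowledgeBase, ModelDefinition,
                           ModelType)

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")


def make_independent(assoc_id, rs_id="rs100", allele="AA", odds_ratio=1.2,
                     evidence_quality=1, **kw):
    fields = dict(
        assoc_id=assoc_id, rs_id=rs_id, allele=allele, disease_code="C61",
        disease_name="Malignant neoplasm of prostate",
        model_type=ModelType.INDEPENDENT, model_name="Increased",
        magnitude_of_impact=odds_ratio, evidence_quality=evidence_quality)
    fields.update(kw)
    return AssociationRecord(**fields)


def branch1_kb() -> KnowledgeBase:
    """Minimal KB holding only the branch-1 genotype profile (4 rules)."""
    records = [
        AssociationRecord(
            assoc_id=i + 1, rs_id=rs, allele=allele, disease_code="C61",
            disease_name="Malignant neoplasm of prostate",
            model_type=ModelType.PROBABILISTIC,
            model_name=WORKED_EXAMPLE_MODEL, branch_id=1)
        for i, (rs, allele) in enumerate(WORKED_EXAMPLE_BRANCH)
    ]
    definitions = [ModelDefinition(
        model_type=ModelType.PROBABILISTIC, model_name=WORKED_EXAMPLE_MODEL,
        branch_id=1, total_value=4.0,
        explanation_1="At risk of prostate cancer "
                      "(synthetic accuracy/precision/recall)",
        explanation_2="branch_id=1")]
    return KnowledgeBase(associations=records, model_definitions=definitions)


def crsnp_set(genotypes: dict[str, str], patient_id="P1", kb_version=1) -> CRSNPSet:
    calls = {rs: GenotypeCall(rs, "1", i + 1, gt)
             for i, (rs, gt) in enumerate(sorted(genotypes.items()))}
    return CRSNPSet(patient_id=patient_id, calls=calls, kb_version=kb_version)


@pytest.fixture
def kb_branch1():
    return branch1_kb()


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down study content for fast per-module tests."""
    return FixtureSpec(seed=11, n_independent=10, n_cumulative_models=2,
                       cumulative_assocs_per_model=5, n_probabilistic_models=1,
                       branches_per_model=12, snps_per_branch=(2, 5),
                       n_patients=6, match_probability=0.35,
                       no_call_fraction=0.03, n_background_snps=300)


@pytest.fixture(scope="session")
def small_kb(small_spec):
    return generate_kb(small_spec)
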