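"""Knowledge-base loading, validation, mutation and query semantics."""

import copy
import random

import pytest

from clingenkit.errors import KBSchemaError, KBValidationError, UpsertError
from clingenkit.fixtures import FixtureSpec, generate_kb, generate_kb_files
from clingenkit.kb import (AssociationRecord, KnowledgeBase, ModelDefinition,
                           ModelType, cr_snp_list, load_knowledge_base,
                           query_by_variant, replay_changelog,
                           upsert_associations, validate_knowledge_base,
                           write_knowledge_base)
from tests.conftest import branch1_kb, make_independent

ASSOC_HEADER = ("assoc_id\trs_id\tallele\tdisease_code\tdisease_name\t"
                "model_type\tmodel_name\tmagnitude_of_impact\t"
                "evidence_quality\timpact_category\tevidence_category\t"
                "impact_value\tbranch_id\n")
MODEL_HEADER = ("model_type\tmodel_name\tbranch_id\ttotal_value\t"
                "explanation_1\texplanation_2\n")


def write_tables(tmp_path, assoc_rows, model_rows):
    apath = tmp_path / "associations.tsv"
    mpath = tmp_path / "models.tsv"
    apath.write_text(ASSOC_HEADER + "".join(assoc_rows))
    mpath.write_text(MODEL_HEADER + "".join(model_rows))
    return apath, mpath


class TestLoad:
    def test_single_branch_rule(self, tmp_path):
        apath, mpath = write_tables(
            tmp_path,
            ["1\trs11720239\tAA\tC61\tProstate ca.\tprobabilistic\t"
             "SNP-only\t\t\t\t\t\t1\n"],
            ["probabilistic\tSNP-only\t1\t1\tat risk\tbranch_id=1\n"])
        kb = load_knowledge_base(apath, mpath)
        assert len(kb.active_associations()) == 1
        rec = kb.active_associations()[0]
        assert (rec.rs_id, rec.allele, rec.branch_id) == ("rs11720239", "AA", 1)
        assert kb.version == 1

    def test_empty_tables(self, tmp_path):
        apath, mpath = write_tables(tmp_path, [], [])
        kb = load_knowledge_base(apath, mpath)
        assert kb.active_associations() == []
        assert kb.model_definitions == []
        assert kb.version == 1

    def test_500_row_counts_match_file_scan(self, tmp_path):
        spec = FixtureSpec(seed=3, n_independent=200, n_cumulative_models=10,
                           cumulative_assocs_per_model=20,
                           n_probabilistic_models=1, branches_per_model=30,
                           snps_per_branch=(2, 5))
        apath, mpath = generate_kb_files(spec, tmp_path)
        kb = load_knowledge_base(apath, mpath)
        assert len(kb.active_associations()) >= 500

        # independent oracle: line-by-line scan of the raw file
        expected = {}
        with open(apath) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            col = header.index("model_type")
            for line in fh:
                mt = line.rstrip("\n").split("\t")[col]
                expected[mt] = expected.get(mt, 0) + 1
        got = {}
        for r in kb.active_associations():
            got[r.model_type.value] = got.get(r.model_type.value, 0) + 1
        assert got == expected

    def test_duplicate_assoc_id_is_hard_error(self, tmp_path):
        row = ("{}\trs1\tAA\tC61\tx\tindependent\tIncreased\t1.5\t2\t\t\t\t\n")
        apath, mpath = write_tables(tmp_path, [row.format(1), row.format(1)], [])
        with pytest.raises(KBSchemaError, match="duplicate assoc_id"):
            load_knowledge_base(apath, mpath)

    def test_schema_violation_names_row_and_field(self, tmp_path):
        apath, mpath = write_tables(
            tmp_path,
            ["1\trs1\tAA\tC61\tx\tindependent\tIncreased\tnot_a_number\t2"
             "\t\t\t\t\n"], [])
        with pytest.raises(KBSchemaError) as exc:
            load_knowledge_base(apath, mpath)
        assert exc.value.row == 2
        assert exc.value.field == "magnitude_of_impact"

    def test_auto_assigned_ids_fill_from_max(self, tmp_path):
        rows = ["5\trs1\tAA\tC61\tx\tindependent\tIncreased\t1.5\t2\t\t\t\t\n",
                "\trs2\tCC\tC61\tx\tindependent\tIncreased\t1.5\t2\t\t\t\t\n"]
        apath, mpath = write_tables(tmp_path, rows, [])
        kb = load_knowledge_base(apath, mpath)
        assert sorted(r.assoc_id for r in kb.active_associations()) == [5, 6]


class TestRoundTrip:
    def test_write_then_load_reproduces_records(self, tmp_path, small_kb):
        a1 = tmp_path / "a.tsv"
        m1 = tmp_path / "m.tsv"
        write_knowledge_base(small_kb, a1, m1)
        kb2 = load_knowledge_base(a1, m1)
        assert kb2.active_associations() == small_kb.active_associations()
        assert kb2.model_definitions == small_kb.model_definitions
        # a second round trip is byte-identical
        a2 = tmp_path / "a2.tsv"
        m2 = tmp_path / "m2.tsv"
        write_knowledge_base(kb2, a2, m2)
        assert a1.read_text() == a2.read_text()
        assert m1.read_text() == m2.read_text()


class TestValidate:
    def test_valid_fixture_has_no_violations(self, small_kb):
        assert validate_knowledge_base(small_kb) == []

    def test_branch_count_mismatch(self):
        kb = branch1_kb()
        kb.model_definitions[0] = ModelDefinition(
            model_type=ModelType.PROBABILISTIC, model_name="SNP-only",
            branch_id=1, total_value=5.0, explanation_1="x",
            explanation_2="branch_id=1")
        rules = {v.rule for v in validate_knowledge_base(kb)}
        assert rules == {"branch count mismatch"}

    def test_independent_with_branch_id_forbidden(self):
        kb = KnowledgeBase(associations=[
            make_independent(1, branch_id=7)])
        rules = [v.rule for v in validate_knowledge_base(kb)]
        assert "field forbidden for model_type" in rules

    @pytest.mark.parametrize("field,value,rule", [
        ("allele", "TA", "allele canonical order"),
        ("allele", "AXT", "allele alphabet"),
        ("disease_code", "61C", "disease_code format"),
        ("rs_id", "snp42", "rs_id format"),
        ("evidence_quality", 4, "category range"),
        ("magnitude_of_impact", -1.0, "odds ratio positive"),
    ])
    def test_field_rules(self, field, value, rule):
        rec = make_independent(1)
        rec = AssociationRecord(**{**rec.__dict__, field: value})
        kb = KnowledgeBase(associations=[rec])
        assert rule in [v.rule for v in validate_knowledge_base(kb)]

    def test_duplicate_variant_condition_model_combo(self):
        kb = KnowledgeBase(associations=[make_independent(1),
                                         make_independent(2)])
        rules = [v.rule for v in validate_knowledge_base(kb)]
        assert "variant/condition/model unique" in rules


class TestUpsert:
    def test_add_bumps_version_and_logs_each_record(self, kb_branch1):
        kb = kb_branch1
        kb.version = 5
        new_records = [make_independent(10 + i, rs_id=f"rs9{i}") for i in range(3)]
        kb2 = upsert_associations(kb, new_records, mode="add")
        assert kb2.version == 6
        assert len([e for e in kb2.changelog if e.version == 6]) == 3
        assert kb.version == 5  # input untouched

    def test_cancel_excludes_from_queries_but_not_changelog(self, kb_branch1):
        kb2 = upsert_associations(kb_branch1, [2], mode="cancel")
        assert query_by_variant(kb2, "rs2999081", "CT") == []
        assert "rs2999081" not in cr_snp_list(kb2)
        assert any(e.operation == "cancel" and e.assoc_id == 2
                   for e in kb2.changelog)
        assert 2 in kb2.cancelled
        # the shortened branch is now flagged by full validation (advisory
        # during upsert: the branch simply cannot complete any more)
        assert [v.rule for v in validate_knowledge_base(kb2)] == [
            "branch count mismatch"]

    def test_add_existing_id_rejected(self, kb_branch1):
        with pytest.raises(UpsertError, match="already present"):
            upsert_associations(kb_branch1, [make_independent(1, rs_id="rs77")],
                                mode="add")

    def test_update_missing_id_rejected(self, kb_branch1):
        with pytest.raises(UpsertError, match="not present"):
            upsert_associations(kb_branch1, [make_independent(99, rs_id="rs77")],
                                mode="update")

    def test_failed_validation_rolls_back(self, kb_branch1):
        before = copy.deepcopy(kb_branch1)
        bad = make_independent(50, allele="ZZ")
        with pytest.raises(KBValidationError):
            upsert_associations(kb_branch1, [bad], mode="add")
        assert kb_branch1.version == before.version
        assert kb_branch1.associations == before.associations

    def test_random_script_matches_replay_oracle(self, small_kb):
        rng = random.Random(42)
        kb = small_kb
        base = copy.deepcopy(kb)
        # naive oracle state: dict of active records
        oracle = {r.assoc_id: r for r in kb.active_associations()}
        next_rs = 5_000_000
        for step in range(100):
            op = rng.choice(["add", "update", "cancel"])
            if op == "add":
                next_rs += 1
                rec = make_independent(None, rs_id=f"rs{next_rs}",
                                       odds_ratio=round(rng.uniform(1.1, 3), 2),
                                       evidence_quality=rng.randint(1, 3))
                kb = upsert_associations(kb, [rec], mode="add")
                new_id = kb.changelog[-1].assoc_id
                oracle[new_id] = kb.get(new_id)
            elif op == "update":
                candidates = [i for i, r in oracle.items()
                              if r.model_type is ModelType.INDEPENDENT]
                if not candidates:
                    continue
                target = rng.choice(candidates)
                rec = AssociationRecord(**{**oracle[target].__dict__,
                                           "magnitude_of_impact": 2.22})
                kb = upsert_associations(kb, [rec], mode="update")
                oracle[target] = rec
            else:
                candidates = [i for i, r in oracle.items()
                              if r.model_type is ModelType.INDEPENDENT]
                if not candidates:
                    continue
                target = rng.choice(candidates)
                kb = upsert_associations(kb, [target], mode="cancel")
                del oracle[target]
        assert {r.assoc_id: r for r in kb.active_associations()} == oracle
        # versions strictly increase and replay reconstructs the final state
        versions = [e.version for e in kb.changelog]
        assert versions == sorted(versions)
        replayed = replay_changelog(base, kb.changelog)
        assert replayed.active_associations() == kb.active_associations()
        assert replayed.version == kb.version


class TestQueries:
    def test_cr_snp_list_dedups_alleles(self):
        kb = KnowledgeBase(associations=[
            make_independent(1, rs_id="rs11720239", allele="AA"),
            make_independent(2, rs_id="rs11720239", allele="AC",
                             odds_ratio=1.4),
            make_independent(3, rs_id="rs2999081", allele="CT"),
        ])
        assert cr_snp_list(kb) == {"rs11720239", "rs2999081"}

    def test_empty_kb_empty_list(self):
        assert cr_snp_list(KnowledgeBase()) == set()

    def test_cr_snp_list_matches_scan_oracle(self, small_kb, tmp_path):
        apath = tmp_path / "a.tsv"
        write_knowledge_base(small_kb, apath, tmp_path / "m.tsv")
        with open(apath) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            col = header.index("rs_id")
            expected = {line.rstrip("\n").split("\t")[col] for line in fh}
        assert cr_snp_list(small_kb) == expected

    def test_query_branch1_exact_match(self, kb_branch1):
        hits = query_by_variant(kb_branch1, "rs11720239", "AA")
        assert [r.assoc_id for r in hits] == [1]

    def test_query_allele_mismatch_empty(self, kb_branch1):
        assert query_by_variant(kb_branch1, "rs11720239", "AC") == []

    def test_1000_random_queries_match_linear_scan(self, small_kb):
        rng = random.Random(7)
        records = small_kb.active_associations()
        rs_pool = [r.rs_id for r in records] + ["rs424242"]
        alleles = ["AA", "AC", "AG", "AT", "CC", "CG", "CT", "GG", "GT", "TT"]
        for _ in range(1000):
            rs = rng.choice(rs_pool)
            al = rng.choice(alleles)
            oracle = [r for r in records if r.rs_id == rs and r.allele == al]
            assert query_by_variant(small_kb, rs, al) == oracle

    def test_every_cr_snp_has_a_record(self, small_kb):
        by_rs = {}
        for r in small_kb.active_associations():
            by_rs.setdefault(r.rs_id, []).append(r)
        for rs in cr_snp_list(small_kb):
            assert any(query_by_variant(small_kb, rs, r.allele)
                       for r in by_rs[rs])
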