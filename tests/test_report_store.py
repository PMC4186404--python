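"""Report-store model, I/O round-trips, dedup and term/challenge matching."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from atrophysignal.report_store import (
    DEFAULT_ATROPHY_TERMS,
    ChallengeCode,
    ChallengeKind,
    Dialect,
    DrugEntry,
    DrugRole,
    FormatError,
    ReportRecord,
    ReportStore,
    deduplicate,
    find_challenge_reports,
    match_atrophy_terms,
    read_reports,
    write_reports,
)
from atrophysignal.synthetic import ReportSimConfig, gen_reports

from conftest import make_record


def records_equal(a: ReportRecord, b: ReportRecord) -> bool:
    return dataclasses.asdict(a) == dataclasses.asdict(b)


def stores_equal(a: ReportStore, b: ReportStore) -> bool:
    if len(a) != len(b):
        return False
    by_id = {rec.report_id: rec for rec in b}
    return all(rec.report_id in by_id and records_equal(rec, by_id[rec.report_id]) for rec in a)


class TestModel:
    def test_report_requires_reactions_and_id(self):
        with pytest.raises(ValueError):
            make_record("R1", reactions=())
        with pytest.raises(ValueError):
            make_record("", reactions=("NAUSEA",))

    def test_reactions_are_uppercase_normalized(self):
        rec = make_record("R1", reactions=("muscle  atrophy",))
        assert rec.reactions == {"MUSCLE ATROPHY"}

    def test_drug_entry_rejects_empty_name(self):
        with pytest.raises(ValueError):
            DrugEntry("")

    def test_store_rejects_duplicate_ids(self):
        with pytest.raises(ValueError):
            ReportStore(records=[make_record("R1"), make_record("R1")])

    def test_synonym_map_is_idempotent(self):
        store = ReportStore()
        assert store.canonical("glyburide") == "GLIBENCLAMIDE"
        assert store.canonical("GLIBENCLAMIDE") == "GLIBENCLAMIDE"
        # canonical names map to themselves
        for canon in store.synonym_map.values():
            assert store.synonym_map[canon] == canon


class TestIO:
    @pytest.mark.parametrize("dialect", [Dialect.AERS_DOLLAR, Dialect.CSV])
    def test_empty_store_round_trips(self, tmp_path, dialect):
        sink = tmp_path / ("dump" if dialect is Dialect.AERS_DOLLAR else "dump.csv")
        write_reports(ReportStore(), sink, dialect)
        back = read_reports(sink, dialect)
        assert len(back) == 0

    def test_three_table_dump_structure(self, tmp_path):
        store = ReportStore(
            records=[
                make_record("R1", ("GLIBENCLAMIDE", "SIMVASTATIN"), ("MUSCLE ATROPHY",)),
                make_record("R2", ("METFORMIN",), ("NAUSEA", "RASH")),
            ]
        )
        write_reports(store, tmp_path / "dump", Dialect.AERS_DOLLAR)
        lines = (tmp_path / "dump" / "DRUG.txt").read_text().strip().splitlines()
        assert len(lines) == 1 + 3  # header + 3 drug rows
        back = read_reports(tmp_path / "dump", Dialect.AERS_DOLLAR)
        assert len(back) == 2
        first = next(rec for rec in back if rec.report_id == "R1")
        assert len(first.drugs) == 2 and first.reactions == {"MUSCLE ATROPHY"}

    @pytest.mark.parametrize("dialect", [Dialect.AERS_DOLLAR, Dialect.CSV])
    def test_synthetic_500_record_round_trip(self, tmp_path, dialect):
        store, _ = gen_reports(
            ReportSimConfig(n_reports=500, duplicate_fraction=0.05, pos_rechallenge_fraction=0.05, seed=11)
        )
        sink = tmp_path / ("dump" if dialect is Dialect.AERS_DOLLAR else "dump.csv")
        write_reports(store, sink, dialect)
        back = read_reports(sink, dialect)
        assert stores_equal(store, back)

    def test_demo_row_without_reactions_is_dropped_and_counted(self, tmp_path):
        store = ReportStore(records=[make_record("R1"), make_record("R2")])
        write_reports(store, tmp_path / "dump", Dialect.AERS_DOLLAR)
        reac = tmp_path / "dump" / "REAC.txt"
        lines = [l for l in reac.read_text().splitlines() if not l.startswith("R2")]
        reac.write_text("\n".join(lines) + "\n")
        back = read_reports(tmp_path / "dump", Dialect.AERS_DOLLAR)
        assert len(back) == 1
        assert back.load_report.n_dropped_no_reaction == 1

    def test_dangling_rows_collected_as_warnings(self, tmp_path):
        store = ReportStore(records=[make_record("R1")])
        write_reports(store, tmp_path / "dump", Dialect.AERS_DOLLAR)
        with open(tmp_path / "dump" / "REAC.txt", "a") as fh:
            fh.write("R999$NAUSEA\n")
        back = read_reports(tmp_path / "dump", Dialect.AERS_DOLLAR)
        assert len(back) == 1
        assert any("R999" in w for w in back.load_report.warnings)

    def test_missing_key_column_names_the_table(self, tmp_path):
        store = ReportStore(records=[make_record("R1")])
        write_reports(store, tmp_path / "dump", Dialect.AERS_DOLLAR)
        drug = tmp_path / "dump" / "DRUG.txt"
        drug.write_text(drug.read_text().replace("ISR", "BADCOL"))
        with pytest.raises(FormatError, match="DRUG"):
            read_reports(tmp_path / "dump", Dialect.AERS_DOLLAR)

    def test_duplicate_roles_keep_most_suspect(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text(
            "ISR$RECEIVE_DATE$SERIOUS$OUTCOME_CODES$RECHALLENGE$DECHALLENGE$NARRATIVE\n"
            "R1$2012-01-01$0$$ABSENT$ABSENT$\n"
        )
        (tmp_path / "DRUG.txt").write_text(
            "ISR$DRUGNAME$ROLE_COD\nR1$ASPIRIN$C\nR1$ASPIRIN$PS\n"
        )
        (tmp_path / "REAC.txt").write_text("ISR$PT\nR1$NAUSEA\n")
        back = read_reports(tmp_path, Dialect.AERS_DOLLAR)
        assert back.records[0].drugs == [DrugEntry("ASPIRIN", DrugRole.PRIMARY_SUSPECT)]


class TestDeduplicate:
    def test_identical_key_keeps_one(self):
        store = ReportStore(records=[make_record("R1"), make_record("R2")])
        out, removed = deduplicate(store)
        assert removed == 1 and [r.report_id for r in out] == ["R1"]

    def test_key_ignores_challenge_codes(self):
        store = ReportStore(
            records=[
                make_record("R1", dechallenge=ChallengeCode.POS),
                make_record("R2", dechallenge=ChallengeCode.NEG),
            ]
        )
        _, removed = deduplicate(store)
        assert removed == 1

    def test_synonyms_collapse_into_one_key(self):
        store = ReportStore(records=[make_record("R1", ("GLYBURIDE",)), make_record("R2", ("GLIBENCLAMIDE",))])
        _, removed = deduplicate(store)
        assert removed == 1

    def test_planted_clusters_removed_count(self):
        # 3 clusters of sizes 3, 2, 1 -> 2 + 1 + 0 removed
        records = (
            [make_record(f"A{i}", date="2012-02-01") for i in range(3)]
            + [make_record(f"B{i}", ("METFORMIN",), date="2012-03-01") for i in range(2)]
            + [make_record("C0", ("ASPIRIN",), date="2012-04-01")]
        )
        _, removed = deduplicate(ReportStore(records=records))
        assert removed == 3

    def test_idempotent(self):
        store, _ = gen_reports(ReportSimConfig(n_reports=300, duplicate_fraction=0.2, seed=5))
        once, removed1 = deduplicate(store)
        twice, removed2 = deduplicate(once)
        assert removed1 > 0 and removed2 == 0
        assert [r.report_id for r in once] == [r.report_id for r in twice]


class TestTermMatching:
    def test_atrophy_term_matches_and_weakness_does_not(self, small_store):
        matched = match_atrophy_terms(small_store)
        assert "R1" in matched and "R6" not in matched
        assert matched == {"R1", "R2", "R4"}

    def test_match_is_case_insensitive_exact(self, small_store):
        assert match_atrophy_terms(small_store, {"muscle atrophy"}) == {"R1", "R2", "R4"}
        # substring of a coded term does not match in exact mode
        assert match_atrophy_terms(small_store, {"ATROPHY"}) == set()
        assert match_atrophy_terms(small_store, {"ATROPHY"}, substring=True) == {"R1", "R2", "R4"}

    def test_empty_term_set_rejected(self, small_store):
        with pytest.raises(ValueError):
            match_atrophy_terms(small_store, set())

    @given(st.data())
    def test_union_distributes_over_term_sets(self, data):
        store, _ = gen_reports(ReportSimConfig(n_reports=80, seed=3))
        terms = sorted({t for rec in store for t in rec.reactions})
        t1 = set(data.draw(st.lists(st.sampled_from(terms), min_size=1, max_size=3)))
        t2 = set(data.draw(st.lists(st.sampled_from(terms), min_size=1, max_size=3)))
        assert match_atrophy_terms(store, t1 | t2) == (
            match_atrophy_terms(store, t1) | match_atrophy_terms(store, t2)
        )

    def test_linear_scan_oracle_on_synthetic_store(self):
        store, _ = gen_reports(
            ReportSimConfig(n_reports=400, planted_signals=(("GLIBENCLAMIDE", "MUSCLE ATROPHY", 50.0),), seed=9)
        )
        expected = {rec.report_id for rec in store if rec.reactions & DEFAULT_ATROPHY_TERMS}
        assert match_atrophy_terms(store) == expected

    def test_dedup_does_not_change_matching_of_retained_reports(self):
        store, _ = gen_reports(ReportSimConfig(n_reports=300, duplicate_fraction=0.15, seed=2))
        deduped, _ = deduplicate(store)
        retained = {rec.report_id for rec in deduped}
        assert match_atrophy_terms(deduped) == match_atrophy_terms(store) & retained


class TestChallengeReports:
    def test_structured_pos_code_included(self):
        store = ReportStore(records=[make_record("R1", rechallenge=ChallengeCode.POS)])
        assert find_challenge_reports(store, ChallengeKind.RECHALLENGE) == {"R1"}

    def test_narrative_phrase_included(self):
        store = ReportStore(
            records=[make_record("R1", narrative="Symptoms RECURRED after rechallenge with the drug.")]
        )
        assert find_challenge_reports(store, ChallengeKind.RECHALLENGE) == {"R1"}
        assert find_challenge_reports(store, ChallengeKind.DECHALLENGE) == set()

    def test_dechallenge_phrase_and_code(self):
        store = ReportStore(
            records=[
                make_record("R1", narrative="rash resolved after discontinuation"),
                make_record("R2", dechallenge=ChallengeCode.POS),
                make_record("R3", narrative="no relevant course"),
            ]
        )
        assert find_challenge_reports(store, ChallengeKind.DECHALLENGE) == {"R1", "R2"}

    def test_no_codes_no_phrases_empty(self, small_store):
        assert find_challenge_reports(small_store, ChallengeKind.RECHALLENGE) == set()
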