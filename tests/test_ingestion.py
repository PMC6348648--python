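"""Ingestion engine: assignment rules, parsing/merging, validation,
counts import, plan replay."""

import io
import random

import pytest

from compendia import ingestion
from compendia.formats import parse_fasta
from compendia.model import LogLevel, PlatformKind, ValidationError
from compendia.store import create_compendium


def build_assignments(d):
    """Standard assignment set for the generated SOFT dataset: metadata from
    the SOFT file, probes from the probe table, values from per-sample files."""
    entities = ingestion.discover_entities(d / "exp.soft")
    plats = [e for e in entities if e[0] == "platform"]
    samps = [e for e in entities if e[0] == "sample"]
    assignments = []
    for ents, parser, params in [
        ([("experiment", None)], "soft_experiment", None),
        (plats, "soft_platform", None),
        (samps, "soft_sample", {"include_table": "false"}),
    ]:
        a, _ = ingestion.assign_files([d / "exp.soft"], ents, "assign_all", parser, params)
        assignments += a
    a, _ = ingestion.assign_files([d / "probes.tsv"], plats, "assign_all", "probe_table")
    assignments += a
    value_files = sorted(str(p) for p in d.glob("s*.tsv"))
    a, warnings = ingestion.assign_files(value_files, samps, "match_entity_name", "value_table")
    assignments += a
    assert warnings == []
    return assignments


def parsed_equal(a, b):
    assert a.experiment_id == b.experiment_id
    assert a.metadata == b.metadata
    assert a.platform.id == b.platform.id and a.platform.kind is b.platform.kind
    assert [(r.id, r.sequence) for r in a.platform.reporters] == [
        (r.id, r.sequence) for r in b.platform.reporters
    ]
    assert [
        (s.name, s.metadata, [(m.key, m.value) for m in s.measurements])
        for s in a.samples
    ] == [
        (s.name, s.metadata, [(m.key, m.value) for m in s.measurements])
        for s in b.samples
    ]


# --- assignment rules -----------------------------------------------------

def test_match_entity_name_couples_files_to_samples(tmp_path):
    for n in ("s1.txt", "s2.txt"):
        (tmp_path / n).write_text("ID_REF\tVALUE\n")
    a, issues = ingestion.assign_files(
        [tmp_path / "s1.txt", tmp_path / "s2.txt"],
        [("sample", "s1"), ("sample", "s2")],
        "match_entity_name",
        "value_table",
    )
    assert [(x.file.name, x.entity) for x in a] == [
        ("s1.txt", ("sample", "s1")),
        ("s2.txt", ("sample", "s2")),
    ]
    assert issues == []


def test_match_entity_name_is_case_insensitive_on_stems(tmp_path):
    (tmp_path / "S1.CEL.txt").write_text("")
    a, _ = ingestion.assign_files(
        [tmp_path / "S1.CEL.txt"], [("sample", "s1.cel")], "match_entity_name", "value_table"
    )
    assert a[0].entity == ("sample", "s1.cel")


def test_assign_all_counts(tmp_path):
    f = tmp_path / "exp.soft"
    f.write_text("")
    ents = [("experiment", None), ("platform", "p1")] + [
        ("sample", f"s{i}") for i in (1, 2, 3)
    ]
    a, _ = ingestion.assign_files([f], ents, "assign_all", "soft_sample")
    assert len(a) == 5


def test_unmatched_file_is_warning(tmp_path):
    (tmp_path / "s3.txt").write_text("")
    a, issues = ingestion.assign_files(
        [tmp_path / "s3.txt"], [("sample", "s1")], "match_entity_name", "value_table"
    )
    assert a == []
    assert len(issues) == 1 and issues[0].level is LogLevel.warning
    assert "s3.txt" in issues[0].message


def test_two_samples_same_name_is_ambiguous(tmp_path):
    (tmp_path / "s1.txt").write_text("")
    with pytest.raises(ValidationError, match="ambiguous"):
        ingestion.assign_files(
            [tmp_path / "s1.txt"],
            [("sample", "s1"), ("sample", "S1")],
            "match_entity_name",
            "value_table",
        )


# --- parsing engine -------------------------------------------------------

def test_end_to_end_parsing_matches_generator_expectation(soft_dataset):
    d, expected = soft_dataset
    parsed = ingestion.run_parsing(build_assignments(d))
    assert parsed.error_issues() == []
    parsed_equal(parsed, expected)


def test_parsing_is_order_independent(soft_dataset):
    d, _ = soft_dataset
    assignments = build_assignments(d)
    reference = ingestion.run_parsing(assignments)
    rng = random.Random(0)
    for _ in range(3):
        shuffled = assignments[:]
        rng.shuffle(shuffled)
        parsed_equal(ingestion.run_parsing(shuffled), reference)


def test_soft_tables_and_value_tables_are_interchangeable(soft_dataset):
    d, expected = soft_dataset
    entities = ingestion.discover_entities(d / "exp.soft")
    samps = [e for e in entities if e[0] == "sample"]
    plats = [e for e in entities if e[0] == "platform"]
    assignments = []
    for ents, parser in [
        ([("experiment", None)], "soft_experiment"),
        (plats, "soft_platform"),
        (samps, "soft_sample"),  # include_table defaults to true
    ]:
        a, _ = ingestion.assign_files([d / "exp.soft"], ents, "assign_all", parser)
        assignments += a
    a, _ = ingestion.assign_files([d / "probes.tsv"], plats, "assign_all", "probe_table")
    assignments += a
    parsed = ingestion.run_parsing(assignments)
    assert parsed.error_issues() == []
    parsed_equal(parsed, expected)


def test_failing_file_is_isolated(soft_dataset):
    d, _ = soft_dataset
    (d / "s2.tsv").write_text("ID_REF\tVALUE\nr1\tnot_a_number\n")
    parsed = ingestion.run_parsing(build_assignments(d))
    errors = parsed.error_issues()
    assert len(errors) == 1 and "s2.tsv" in errors[0].context
    s1 = next(s for s in parsed.samples if s.name == "s1")
    assert len(s1.measurements) == 4  # sibling sample unharmed


def test_conflicting_metadata_is_error_not_last_writer_wins(tmp_path):
    a_file = tmp_path / "a.soft"
    b_file = tmp_path / "b.soft"
    a_file.write_text("^SERIES = e1\n!Series_title = one\n")
    b_file.write_text("^SERIES = e1\n!Series_title = two\n")
    a1, _ = ingestion.assign_files([a_file], [("experiment", None)], "assign_all", "soft_experiment")
    a2, _ = ingestion.assign_files([b_file], [("experiment", None)], "assign_all", "soft_experiment")
    parsed = ingestion.run_parsing(a1 + a2)
    (err,) = parsed.error_issues()
    assert "Series_title" in err.message
    assert "a.soft" in err.message and "b.soft" in err.message


def test_two_measurement_sources_for_one_sample_is_error(soft_dataset):
    d, _ = soft_dataset
    entities = ingestion.discover_entities(d / "exp.soft")
    samps = [e for e in entities if e[0] == "sample"]
    assignments = []
    a, _ = ingestion.assign_files([d / "exp.soft"], samps, "assign_all", "soft_sample")
    assignments += a  # soft tables carry values...
    value_files = sorted(str(p) for p in d.glob("s*.tsv"))
    a, _ = ingestion.assign_files(value_files, samps, "match_entity_name", "value_table")
    assignments += a  # ...and so do the per-sample files
    parsed = ingestion.run_parsing(assignments)
    assert any("two" in e.message and "files" in e.message for e in parsed.error_issues())


def test_empty_assignment_list_yields_empty_staged_with_warning():
    parsed = ingestion.run_parsing([])
    assert parsed.samples == []
    assert any(i.level is LogLevel.warning for i in parsed.issues)


# --- validation -----------------------------------------------------------

def test_validate_clean_experiment_is_empty(compendium, toy_parsed):
    assert ingestion.validate_parsed(toy_parsed, compendium) == []


def test_validate_reports_unknown_reporter(compendium, toy_parsed):
    from compendia.model import Measurement

    toy_parsed.samples[0].measurements.append(Measurement("rX", 1.0))
    errors = ingestion.validate_parsed(toy_parsed, compendium)
    assert len(errors) == 1 and "rX" in errors[0].message


def test_validate_rnaseq_keys_against_background(compendium):
    from compendia.model import BioFeature

    compendium.set_genomic_background([BioFeature("g1", "ACGT" * 10)])
    matrix = "gene\ts1\ns1_unknown_gene\t4\n"
    parsed = ingestion.import_counts_matrix(io.StringIO(matrix), "e1", compendium)
    assert any("absent from background" in e.message for e in parsed.error_issues())


def test_commit_succeeds_iff_validation_clean(compendium, toy_parsed):
    assert ingestion.validate_parsed(toy_parsed, compendium) == []
    compendium.commit_experiment(toy_parsed)
    # now the id is taken: validation finds it, and commit refuses it
    from conftest import make_toy_parsed

    again = make_toy_parsed()
    assert ingestion.validate_parsed(again, compendium) != []
    with pytest.raises(ValidationError):
        compendium.commit_experiment(again)


# --- counts path ----------------------------------------------------------

@pytest.fixture
def bg_compendium(compendium):
    from compendia.model import BioFeature

    compendium.set_genomic_background(
        [BioFeature(f"g{i}", "ACGTACGTAC" * 4) for i in (1, 2, 3)]
    )
    return compendium


def test_counts_matrix_import(bg_compendium):
    matrix = "gene\tsA\tsB\ng1\t5\t0\ng2\t7\t2\ng3\t0\t9\n"
    parsed = ingestion.import_counts_matrix(io.StringIO(matrix), "rna1", bg_compendium)
    assert parsed.error_issues() == []
    assert parsed.platform.kind is PlatformKind.rnaseq
    assert parsed.measurement_count() == 6
    exp = bg_compendium.commit_experiment(parsed)
    assert bg_compendium.measurement_count(exp.id) == 6


def test_counts_negative_is_error(bg_compendium):
    parsed = ingestion.import_counts_matrix(
        io.StringIO("gene\tsA\ng1\t-1\n"), "rna1", bg_compendium
    )
    assert any("non-negative" in e.message for e in parsed.error_issues())


def test_counts_non_numeric_reports_coordinates(bg_compendium):
    parsed = ingestion.import_counts_matrix(
        io.StringIO("gene\tsA\ng1\tmany\n"), "rna1", bg_compendium
    )
    (err,) = parsed.error_issues()
    assert "g1" in err.message and "sA" in err.message


def test_counts_sample_name_collision(bg_compendium, toy_parsed):
    bg_compendium.commit_experiment(toy_parsed)  # owns samples s1, s2
    parsed = ingestion.import_counts_matrix(
        io.StringIO("gene\ts1\ng1\t3\n"), "rna1", bg_compendium
    )
    assert any("already present" in e.message for e in parsed.error_issues())


# --- plan replay ----------------------------------------------------------

def rebuild_store(path, d, plan_file):
    from compendia.model import BioFeature

    c = create_compendium("replay", path)
    c.set_genomic_background([BioFeature("g1", "ACGT" * 10)], source_name="bg")
    assignments, exp_id = ingestion.load_plan(plan_file)
    parsed = ingestion.run_parsing(assignments, experiment_id=exp_id)
    c.commit_experiment(parsed)
    digest = c.content_digest()
    c.close()
    return digest


def test_plan_round_trip_and_replay_identical_store(tmp_path, soft_dataset):
    d, _ = soft_dataset
    assignments = build_assignments(d)
    plan_file = tmp_path / "plan.yaml"
    ingestion.save_plan(assignments, plan_file, experiment_id=None)
    loaded, exp_id = ingestion.load_plan(plan_file)
    assert loaded == sorted(
        assignments, key=lambda a: (str(a.file), a.entity, a.parser, a.params)
    ) or set(loaded) == set(assignments)
    d1 = rebuild_store(tmp_path / "store1", d, plan_file)
    d2 = rebuild_store(tmp_path / "store2", d, plan_file)
    assert d1 == d2
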