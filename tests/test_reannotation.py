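"""Aligner and two-step filter: worked example, oracle equivalence,
filter laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compendia.model import (
    AlignmentHit,
    BioFeature,
    FilterThreshold,
    Reporter,
    TwoStepConfig,
    ValidationError,
)
from compendia.reannotation import (
    align_probes,
    hit_passes,
    manual_map,
    probe_lengths_of,
    read_mapping,
    single_step_filter,
    two_step_filter,
    write_mapping,
)
from compendia.synthetic import five_probe_fixture, score_threshold

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s):
    return s.translate(COMP)[::-1]


def hamming_scan_oracle(probes, features, max_mm):
    """Independent position-by-position Hamming scan over both strands.

    Returns {(probe_id, feature_id, strand, start_0based): mismatches}."""
    out = {}
    for r in probes:
        if not r.sequence:
            continue
        L = len(r.sequence)
        for f in features:
            n = len(f.sequence)
            for strand, seq in (("+", f.sequence), ("-", revcomp(f.sequence))):
                for pos in range(n - L + 1):
                    mm = sum(
                        1
                        for a, b in zip(r.sequence, seq[pos : pos + L])
                        if a != b or a == "N"
                    )
                    if mm <= max_mm:
                        out[(r.id, f.id, strand, pos)] = mm
    return out


def hit_key(h):
    """Map a reported hit back to the oracle's key space."""
    if h.strand == "+":
        pos = h.feature_start - 1
    else:
        # minus-strand hits are reported in forward coordinates; recover the
        # 0-based offset on the reverse-complemented sequence
        pos = None  # filled by caller, needs feature length
    return (h.probe_id, h.feature_id, h.strand, pos)


# --- aligner --------------------------------------------------------------

def test_exact_substring_gives_perfect_hit():
    g = BioFeature("g1", "ACGTACGTACGTACGTACGTACGTACGTACGT")
    probe = Reporter("p1", g.sequence[3:28])
    hits = align_probes([probe], [g], max_mismatches=0)
    plus = [h for h in hits if h.strand == "+"]
    assert any(
        h.identity_pct == 100.0 and h.mismatches == 0 and h.feature_start == 4
        and h.feature_end == 28 and h.alignment_length == 25
        for h in plus
    )


def test_reverse_complement_probe_hits_minus_strand():
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
    g = BioFeature("g1", seq)
    probe = Reporter("p1", revcomp(seq[10:35]))
    hits = align_probes([probe], [g], max_mismatches=0)
    assert len(hits) == 1
    h = hits[0]
    assert h.strand == "-" and h.identity_pct == 100.0
    # forward coordinates of the aligned window, 1-based inclusive
    assert (h.feature_end, h.feature_start) == (11, 35)


def test_empty_background_is_error():
    with pytest.raises(ValidationError, match="background"):
        align_probes([Reporter("p1", "ACGT")], [])


def test_probe_without_sequence_is_skipped_then_unaligned():
    g = BioFeature("g1", "ACGTACGTACGTACGTACGTACGTACGT")
    probes = [Reporter("p1", g.sequence[:25]), Reporter("p2", None)]
    hits = align_probes(probes, [g], max_mismatches=0)
    assert {h.probe_id for h in hits} == {"p1"}
    report = single_step_filter(hits, probe_lengths_of(probes), score_threshold(0.0))
    assert report.unaligned == ["p2"]


@pytest.mark.parametrize("ceiling", [0, 1, 2, 3])
def test_aligner_equals_hamming_oracle(ceiling):
    """The one-hot-matmul scanner reports exactly the placements an
    independent per-position Hamming scan finds, with identical mismatch
    counts, at every ceiling."""
    rng = np.random.default_rng(123 + ceiling)
    features = [
        BioFeature(f"g{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, 150)))
        for i in range(8)
    ]
    probes = []
    for j in range(15):
        if j % 3 == 0:  # planted: substring with j%4 mutations
            src = features[int(rng.integers(0, len(features)))].sequence
            pos = int(rng.integers(0, len(src) - 25))
            s = list(src[pos : pos + 25])
            for site in rng.choice(25, size=j % 4, replace=False):
                s[site] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(s)
        else:
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 25))
        probes.append(Reporter(f"p{j:02d}", seq))

    oracle = hamming_scan_oracle(probes, features, ceiling)
    hits = align_probes(probes, features, max_mismatches=ceiling)
    got = {}
    flen = {f.id: len(f.sequence) for f in features}
    for h in hits:
        if h.strand == "+":
            pos = h.feature_start - 1
        else:
            pos = flen[h.feature_id] - h.feature_start
        key = (h.probe_id, h.feature_id, h.strand, pos)
        assert key not in got, "duplicate hit reported"
        got[key] = h.mismatches
    assert got == oracle


def test_hits_sorted_by_probe_then_identity():
    rng = np.random.default_rng(9)
    features = [
        BioFeature(f"g{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, 200)))
        for i in range(5)
    ]
    probes = [Reporter(f"p{j}", features[j].sequence[10:35]) for j in range(5)]
    hits = align_probes(probes, features, max_mismatches=3)
    keys = [(h.probe_id, -h.identity_pct) for h in hits]
    assert keys == sorted(keys)


# --- hit_passes -----------------------------------------------------------

def make_hit(length=24, mm=2, gaps=0, probe_len=25, identity=None):
    identity = identity if identity is not None else 100.0 * (length - mm) / length
    return AlignmentHit(
        probe_id="p",
        feature_id="g",
        identity_pct=identity,
        alignment_length=length,
        mismatches=mm,
        gap_opens=gaps,
        probe_start=1,
        probe_end=min(length, probe_len),
        feature_start=1,
        feature_end=length,
        evalue=0.0,
        bit_score=1.0,
    )


def test_hit_passes_boundary_arithmetic():
    # 24 of 25 aligned = 0.96: passes a 0.95 length bar, fails a 0.98 bar
    h = make_hit(length=24, mm=2, gaps=0)
    assert hit_passes(h, 25, FilterThreshold(0.95, 0, 3))
    assert not hit_passes(h, 25, FilterThreshold(0.98, 0, 1))


def test_hit_passes_vacuous_threshold():
    h = make_hit(length=10, mm=9, gaps=5, identity=10.0)
    assert hit_passes(h, 25, FilterThreshold(0.0, 10**9, 10**9, 0.0))


def test_hit_passes_each_criterion_is_binding():
    h = make_hit(length=25, mm=1, gaps=0, probe_len=25)
    base = dict(min_len_frac=0.9, max_gap_opens=0, max_mismatches=1, min_identity_pct=90.0)
    assert hit_passes(h, 25, FilterThreshold(**base))
    for field, bad in [
        ("min_len_frac", 1.01),
        ("max_gap_opens", -1),
        ("max_mismatches", 0),
        ("min_identity_pct", 99.0),
    ]:
        if field == "min_len_frac":
            with pytest.raises(ValidationError):
                FilterThreshold(**{**base, field: bad})
            continue
        if bad < 0:
            with pytest.raises(ValidationError):
                FilterThreshold(**{**base, field: bad})
            continue
        assert not hit_passes(h, 25, FilterThreshold(**{**base, field: bad}))


# --- five-probe worked example -------------------------------------------

def run_scenarios():
    lengths, hits, expected = five_probe_fixture()
    single95 = single_step_filter(hits, lengths, score_threshold(95.0))
    single96 = single_step_filter(hits, lengths, score_threshold(96.0))
    cfg = TwoStepConfig(score_threshold(94.0), score_threshold(95.0))
    _, twostep = two_step_filter(hits, lengths, cfg)
    return expected, {"single_95": single95, "single_96": single96,
                      "two_step_94_95": twostep}


@pytest.mark.parametrize("scenario", ["single_95", "single_96", "two_step_94_95"])
def test_five_probe_example_scenarios(scenario):
    """Single-step at 95% wrongly keeps the 95/94 cross-hybridizer; raising
    to 96% loses the good 95% probe; two-step (94% then 95%) keeps exactly
    the right two probes."""
    expected, reports = run_scenarios()
    r = reports[scenario]
    assert r.retained_ids() == expected[scenario]["retained"]
    assert set(r.discarded_ambiguous) == expected[scenario]["ambiguous"]
    assert set(r.discarded_low_quality) == expected[scenario]["low_quality"]


# --- filter laws ----------------------------------------------------------

def brute_force_two_step(hits, lengths, cfg, unique_per_gene=False):
    """Independent reference: filter, group, count, filter — dict based."""
    per_probe = {p: [] for p in lengths}
    for h in hits:
        per_probe[h.probe_id].append(h)
    retained = {}
    for p, hs in per_probe.items():
        if lengths[p] is None or not hs:
            continue
        locs = {}
        for h in hs:
            if hit_passes(h, lengths[p], cfg.sensitivity):
                key = h.feature_id if unique_per_gene else h.location()
                if key not in locs or (h.identity_pct, h.bit_score) > (
                    locs[key].identity_pct, locs[key].bit_score
                ):
                    locs[key] = h
        if len(locs) == 1:
            (h,) = locs.values()
            if hit_passes(h, lengths[p], cfg.specificity):
                retained[p] = h.feature_id
    return retained


hit_strategy = st.builds(
    make_hit,
    length=st.integers(18, 25),
    mm=st.integers(0, 4),
    gaps=st.integers(0, 1),
)


@st.composite
def hit_sets(draw):
    n_probes = draw(st.integers(1, 8))
    lengths = {f"p{i}": 25 for i in range(n_probes)}
    hits = []
    for i in range(n_probes):
        for j in range(draw(st.integers(0, 4))):
            h = draw(hit_strategy)
            hits.append(
                AlignmentHit(
                    probe_id=f"p{i}",
                    feature_id=f"g{draw(st.integers(0, 3))}",
                    identity_pct=h.identity_pct,
                    alignment_length=h.alignment_length,
                    mismatches=h.mismatches,
                    gap_opens=h.gap_opens,
                    probe_start=1,
                    probe_end=h.alignment_length,
                    feature_start=1 + 30 * draw(st.integers(0, 3)),
                    feature_end=30 * draw(st.integers(0, 3)) + h.alignment_length,
                    evalue=0.0,
                    bit_score=float(draw(st.integers(0, 50))),
                )
            )
    return lengths, hits


@given(hit_sets())
@settings(max_examples=60, deadline=None)
def test_report_partitions_probe_set(data):
    lengths, hits = data
    report = single_step_filter(hits, lengths, FilterThreshold(0.9, 0, 2))
    parts = [
        report.retained_ids(),
        set(report.discarded_ambiguous),
        set(report.discarded_low_quality),
        set(report.unaligned),
    ]
    assert report.all_probes() == set(lengths)
    assert sum(len(p) for p in parts) == len(lengths)  # pairwise disjoint


@given(hit_sets())
@settings(max_examples=60, deadline=None)
def test_two_step_equals_brute_force(data):
    lengths, hits = data
    cfg = TwoStepConfig(FilterThreshold(0.8, 1, 3), FilterThreshold(0.95, 0, 1))
    _, report = two_step_filter(hits, lengths, cfg)
    assert dict(report.retained) == brute_force_two_step(hits, lengths, cfg)


@given(hit_sets())
@settings(max_examples=60, deadline=None)
def test_degenerate_config_equals_single_step(data):
    lengths, hits = data
    t = FilterThreshold(0.9, 0, 2)
    _, two = two_step_filter(hits, lengths, TwoStepConfig(t, t))
    one = single_step_filter(hits, lengths, t)
    assert two.retained == one.retained
    assert two.discarded_ambiguous == one.discarded_ambiguous
    assert two.discarded_low_quality == one.discarded_low_quality
    assert two.unaligned == one.unaligned


@given(hit_sets(), st.integers(0, 3))
@settings(max_examples=60, deadline=None)
def test_tightening_specificity_never_enlarges_retained(data, which):
    lengths, hits = data
    sens = FilterThreshold(0.8, 1, 3)
    spec = FilterThreshold(0.9, 1, 3)
    tighter = {
        0: FilterThreshold(0.96, 1, 3),
        1: FilterThreshold(0.9, 0, 3),
        2: FilterThreshold(0.9, 1, 1),
        3: FilterThreshold(0.9, 1, 3, 96.0),
    }[which]
    _, before = two_step_filter(hits, lengths, TwoStepConfig(sens, spec))
    _, after = two_step_filter(hits, lengths, TwoStepConfig(sens, tighter))
    assert after.retained_ids() <= before.retained_ids()


@given(hit_sets())
@settings(max_examples=60, deadline=None)
def test_filtering_is_pure(data):
    lengths, hits = data
    cfg = TwoStepConfig(FilterThreshold(0.8, 0, 3), FilterThreshold(0.95, 0, 1))
    _, r1 = two_step_filter(hits, lengths, cfg)
    _, r2 = two_step_filter(hits, lengths, cfg)
    assert r1 == r2


def test_retained_subset_of_sensitivity_unique_and_passes_specificity():
    lengths, hits, _ = five_probe_fixture()
    cfg = TwoStepConfig(score_threshold(94.0), score_threshold(95.0))
    _, report = two_step_filter(hits, lengths, cfg)
    sens_report = single_step_filter(hits, lengths, cfg.sensitivity)
    assert report.retained_ids() <= sens_report.retained_ids()


def test_duplicate_location_hits_do_not_create_ambiguity():
    h = make_hit(length=25, mm=0, probe_len=25)
    dup = AlignmentHit(**{**h.__dict__})
    report = single_step_filter([h, dup], {"p": 25}, FilterThreshold(0.9, 0, 1))
    assert report.retained == [("p", "g")]


def test_same_gene_two_positions_is_ambiguous_unless_per_gene():
    base = make_hit(length=25, mm=0, probe_len=25).__dict__
    h1 = AlignmentHit(**{**base, "feature_start": 1, "feature_end": 25})
    h2 = AlignmentHit(**{**base, "feature_start": 101, "feature_end": 125})
    t = FilterThreshold(0.9, 0, 1)
    strict = single_step_filter([h1, h2], {"p": 25}, t)
    assert strict.discarded_ambiguous == ["p"]
    relaxed = single_step_filter([h1, h2], {"p": 25}, t, unique_per_gene=True)
    assert relaxed.retained == [("p", "g")]


# --- manual mapping -------------------------------------------------------

def test_manual_map_many_probes_per_gene():
    m = manual_map([("r1", "g1"), ("r2", "g1")])
    assert len(m.entries) == 2
    assert m.provenance.method.value == "manual"


def test_manual_map_rejects_probe_twice():
    with pytest.raises(ValidationError, match="r1"):
        manual_map([("r1", "g1"), ("r1", "g2")])


def test_manual_map_unknown_ids():
    with pytest.raises(ValidationError, match="rX"):
        manual_map([("rX", "g1")], reporter_ids={"r1"}, feature_ids={"g1"})
    assert manual_map([], reporter_ids=set(), feature_ids=set()).entries == []


def test_mapping_tsv_sidecar_round_trip(tmp_path):
    lengths, hits, _ = five_probe_fixture()
    cfg = TwoStepConfig(score_threshold(94.0), score_threshold(95.0))
    mapping, _ = two_step_filter(hits, lengths, cfg, platform_id="plat9")
    out = tmp_path / "map.tsv"
    write_mapping(mapping, out)
    back = read_mapping(out)
    assert back.entries == mapping.entries
    assert back.platform_id == "plat9"
    assert back.provenance.sensitivity == cfg.sensitivity
    assert back.provenance.specificity == cfg.specificity
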