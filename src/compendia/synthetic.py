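"""Synthetic data generators.

Everything the pipeline ingests can be generated locally and
deterministically from a seed: random genomic backgrounds, microarray
platforms with a *planted truth* (each probe constructed to be uniquely
mappable, cross-hybridizing, low-identity or unmappable, and verified to be
so by exhaustive scan), GEO SOFT family files with probe and value tables,
and the five-probe worked example used to illustrate why two filtering steps
beat one.

The generators emulate the *structure* of real data — formats, entity
relationships, alignment geometry — not its biology: sequences are i.i.d.
uniform A/C/G/T and intensity values are arbitrary positive reals.  That is
what the pipeline operates on; it never models expression itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    BioFeature,
    FilterThreshold,
    Measurement,
    ParsedExperiment,
    Platform,
    PlatformKind,
    Reporter,
    Sample,
    ValidationError,
)

__all__ = [
    "PlantedTruth",
    "generate_background",
    "generate_platform_with_truth",
    "five_probe_fixture",
    "score_threshold",
    "generate_soft_experiment",
    "write_dataset_dir",
]

_BASES = np.array(list("ACGT"))
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PlantedTruth:
    """Generator-recorded classification of synthetic probes.

    The four sets are disjoint and cover every probe on the generated
    platform; they are the recovery oracle for the alignment + two-step
    filtering pipeline."""

    unique_probes: dict[str, str] = field(default_factory=dict)  # reporter -> feature
    ambiguous_probes: set[str] = field(default_factory=set)
    low_identity_probes: set[str] = field(default_factory=set)
    unmappable_probes: set[str] = field(default_factory=set)
    seed: int = 0

    def all_probes(self) -> set[str]:
        return (
            set(self.unique_probes)
            | self.ambiguous_probes
            | self.low_identity_probes
            | self.unmappable_probes
        )


def generate_background(
    n_genes: int, gene_length: int, seed: int
) -> list[BioFeature]:
    """Random gene set: i.i.d. uniform A/C/G/T sequences, deterministic in
    the seed."""
    if n_genes < 1 or gene_length < 1:
        raise ValidationError("n_genes and gene_length must be >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    return [
        BioFeature(
            id=f"g{i + 1:0{width}d}",
            sequence="".join(_BASES[rng.integers(0, 4, size=gene_length)]),
            description=f"synthetic gene {i + 1}",
        )
        for i in range(n_genes)
    ]


class _Scanner:
    """Exhaustive Hamming scan over both strands of a background, used for
    post-hoc verification of planted probe classes."""

    def __init__(self, features: Sequence[BioFeature], probe_length: int):
        self.L = probe_length
        blocks = []
        for f in features:
            if len(f.sequence) < probe_length:
                continue
            for s in (f.sequence, _revcomp(f.sequence)):
                codes = _ENC[np.frombuffer(s.encode(), dtype=np.uint8)]
                blocks.append(
                    np.lib.stride_tricks.sliding_window_view(codes, probe_length)
                )
        self.windows = (
            np.concatenate(blocks, axis=0)
            if blocks
            else np.zeros((0, probe_length), dtype=np.uint8)
        )

    def placement_counts(self, probe: str, max_mm: int) -> np.ndarray:
        """counts[k] = number of placements with exactly k mismatches,
        k = 0..max_mm.  An 'N' never matches anything."""
        codes = _ENC[np.frombuffer(probe.encode(), dtype=np.uint8)]
        mm = (self.windows != codes).sum(axis=1)
        return np.bincount(mm[mm <= max_mm], minlength=max_mm + 1)


def _class_counts(n: int, mix: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n probes over the class mix."""
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValidationError(f"class_mix must sum to 1, got {sum(mix)}")
    exact = [n * m for m in mix]
    counts = [int(x) for x in exact]
    remainders = sorted(
        range(len(mix)), key=lambda i: (exact[i] - counts[i]), reverse=True
    )
    for i in range(n - sum(counts)):
        counts[remainders[i % len(mix)]] += 1
    return counts


def generate_platform_with_truth(
    background: list[BioFeature],
    n_probes: int,
    probe_length: int = 25,
    class_mix: Sequence[float] = (0.7, 0.1, 0.1, 0.1),
    seed: int = 0,
    sensitivity_max_mm: int = 3,
    specificity_max_mm: int = 1,
    unmappable_ceiling: int = 5,
    platform_id: Optional[str] = None,
    max_attempts: int = 200,
) -> tuple[Platform, PlantedTruth]:
    """Build a microarray platform whose probes have a known ground truth.

    ``class_mix`` gives the proportions of (unique, ambiguous, low-identity,
    unmappable) probes.  Unique probes are exact substrings of one gene;
    ambiguous probes are substrings *copied into a second gene* — this
    mutates ``background`` in place, so set the compendium background from
    the list only after calling this; low-identity probes carry between
    ``specificity_max_mm + 1`` and ``sensitivity_max_mm`` planted mismatches;
    unmappable probes are random sequences.  Every class membership is
    verified post hoc by exhaustive Hamming scan over the final background
    (unique: exactly one placement within ``sensitivity_max_mm``; ambiguous:
    at least two perfect placements; low-identity: a single placement within
    ``sensitivity_max_mm`` whose mismatch count exceeds ``specificity_max_mm``;
    unmappable: no placement within ``unmappable_ceiling``), so recovery by
    the two-step filter is exact by construction, not by probability.
    """
    if not background:
        raise ValidationError("background must be non-empty")
    if any(len(f.sequence) < probe_length for f in background):
        raise ValidationError("every gene must be at least probe_length long")
    if len(class_mix) != 4:
        raise ValidationError("class_mix must have 4 proportions")
    rng = np.random.default_rng(seed)
    L = probe_length
    n_unique, n_ambig, n_low, n_unmap = _class_counts(n_probes, class_mix)

    # --- phase 1: reserve non-overlapping windows and plant duplications ---
    used: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(background))}

    def reserve(gene_idx: int) -> int:
        span = len(background[gene_idx].sequence) - L
        for _ in range(max_attempts):
            pos = int(rng.integers(0, span + 1))
            if all(pos + L <= a or pos >= b for a, b in used[gene_idx]):
                used[gene_idx].append((pos, pos + L))
                return pos
        raise ValidationError(
            "could not reserve a probe window; use a larger background "
            "(more genes or longer genes) for this many probes"
        )

    seqs = [list(f.sequence) for f in background]
    ambig_sources: list[tuple[int, int]] = []
    for _ in range(n_ambig):
        a = int(rng.integers(0, len(background)))
        b = int(rng.integers(0, len(background)))
        while len(background) > 1 and b == a:
            b = int(rng.integers(0, len(background)))
        pa, pb = reserve(a), reserve(b)
        seqs[b][pb : pb + L] = seqs[a][pa : pa + L]
        ambig_sources.append((a, pa))
    for i, f in enumerate(background):
        background[i] = BioFeature(
            id=f.id, sequence="".join(seqs[i]), description=f.description
        )

    scanner = _Scanner(background, L)
    truth = PlantedTruth(seed=seed)
    reporters: list[Reporter] = []
    width = len(str(n_probes))
    probe_no = 0

    def next_id() -> str:
        nonlocal probe_no
        probe_no += 1
        return f"p{probe_no:0{width}d}"

    # --- ambiguous: already planted, just verify ---
    for a, pa in ambig_sources:
        probe = background[a].sequence[pa : pa + L]
        counts = scanner.placement_counts(probe, sensitivity_max_mm)
        if counts[0] < 2:
            raise ValidationError(
                "planted duplication not found twice; background too small"
            )
        rid = next_id()
        reporters.append(Reporter(id=rid, sequence=probe))
        truth.ambiguous_probes.add(rid)

    # --- unique: exact substrings with exactly one near-placement ---
    for _ in range(n_unique):
        for _ in range(max_attempts):
            g = int(rng.integers(0, len(background)))
            pos = int(rng.integers(0, len(background[g].sequence) - L + 1))
            probe = background[g].sequence[pos : pos + L]
            counts = scanner.placement_counts(probe, sensitivity_max_mm)
            if counts.sum() == 1 and counts[0] == 1:
                rid = next_id()
                reporters.append(Reporter(id=rid, sequence=probe))
                truth.unique_probes[rid] = background[g].id
                break
        else:
            raise ValidationError(
                "could not draw a uniquely-placing probe; use a larger background"
            )

    # --- low identity: unique placement, planted mismatches beyond the
    #     specificity limit but within the sensitivity limit ---
    for _ in range(n_low):
        for _ in range(max_attempts):
            g = int(rng.integers(0, len(background)))
            pos = int(rng.integers(0, len(background[g].sequence) - L + 1))
            template = background[g].sequence[pos : pos + L]
            k = int(rng.integers(specificity_max_mm + 1, sensitivity_max_mm + 1))
            sites = rng.choice(L, size=k, replace=False)
            probe = list(template)
            for s in sites:
                alternatives = [b for b in "ACGT" if b != probe[s]]
                probe[s] = alternatives[int(rng.integers(0, 3))]
            probe_s = "".join(probe)
            counts = scanner.placement_counts(probe_s, sensitivity_max_mm)
            if counts.sum() == 1 and counts[:k].sum() == 0 and counts[k] == 1:
                rid = next_id()
                reporters.append(Reporter(id=rid, sequence=probe_s))
                truth.low_identity_probes.add(rid)
                break
        else:
            raise ValidationError(
                "could not plant a low-identity probe; use a larger background"
            )

    # --- unmappable: random sequences with no placement at all ---
    for _ in range(n_unmap):
        for _ in range(max_attempts):
            probe = "".join(_BASES[rng.integers(0, 4, size=L)])
            counts = scanner.placement_counts(probe, unmappable_ceiling)
            if counts.sum() == 0:
                rid = next_id()
                reporters.append(Reporter(id=rid, sequence=probe))
                truth.unmappable_probes.add(rid)
                break
        else:
            raise ValidationError(
                "could not draw an unmappable probe; probes too short for this "
                "background size"
            )

    reporters.sort(key=lambda r: r.id)
    plat = Platform(
        id=platform_id or f"synthetic-array-{seed}",
        kind=PlatformKind.microarray,
        reporters=reporters,
    )
    return plat, truth


# ---------------------------------------------------------------------------
# the five-probe worked example


def score_threshold(pct: float) -> FilterThreshold:
    """A pure score (percent-identity) threshold, all other criteria vacuous —
    the regime of the five-probe illustration, where hits are full-length and
    ungapped so identity is the only discriminating axis."""
    return FilterThreshold(
        min_len_frac=0.0,
        max_gap_opens=10**9,
        max_mismatches=10**9,
        min_identity_pct=pct,
    )


def five_probe_fixture() -> tuple[dict[str, int], list, dict[str, dict[str, set[str]]]]:
    """The five-probe, two-hits-each worked example.

    Five 100-mer probes (yellow, orange, green, purple, blue) each align
    twice, ungapped and full-length, so the score of a hit is its percent
    identity.  The purple probe scores 95 and 94 — a textbook
    cross-hybridizer whose second placement sits just under a 95% bar.  The
    other scores are chosen so that:

    * single-step at 95% retains {orange, green, purple} — purple wrongly
      kept, its 94% second hit invisible;
    * raising the bar to 96% drops purple but also loses green (best hit
      95%) — retained {orange};
    * two-step, sensitivity 94% then specificity 95%, sees both purple
      placements (ambiguous -> discarded), keeps green, and removes blue
      (best 94%) at the specificity step — retained {orange, green}.

    Returns (probe_lengths, hits, expected), where expected maps scenario
    name -> {retained, ambiguous, low_quality} reporter-id sets.
    """
    from .model import AlignmentHit

    L = 100
    scores = {
        "yellow": (98.0, 97.0),
        "orange": (99.0, 90.0),
        "green": (95.0, 91.0),
        "purple": (95.0, 94.0),
        "blue": (94.0, 90.0),
    }
    hits = []
    for i, (probe, (s1, s2)) in enumerate(sorted(scores.items())):
        for j, s in enumerate((s1, s2)):
            mm = int(round(L - s))
            start = 1 + 200 * i + 100 * j
            hits.append(
                AlignmentHit(
                    probe_id=probe,
                    feature_id=f"gene_{probe}_{j + 1}",
                    identity_pct=s,
                    alignment_length=L,
                    mismatches=mm,
                    gap_opens=0,
                    probe_start=1,
                    probe_end=L,
                    feature_start=start,
                    feature_end=start + L - 1,
                    evalue=0.0,
                    bit_score=2.0 * (L - mm),
                )
            )
    probe_lengths = {p: L for p in scores}
    expected = {
        "single_95": {
            "retained": {"orange", "green", "purple"},
            "ambiguous": {"yellow"},
            "low_quality": {"blue"},
        },
        "single_96": {
            "retained": {"orange"},
            "ambiguous": {"yellow"},
            "low_quality": {"green", "purple", "blue"},
        },
        "two_step_94_95": {
            "retained": {"orange", "green"},
            "ambiguous": {"yellow", "purple"},
            "low_quality": {"blue"},
        },
    }
    return probe_lengths, hits, expected


# ---------------------------------------------------------------------------
# SOFT experiment generator


def generate_soft_experiment(
    n_samples: int,
    n_reporters: int,
    seed: int,
    reporters: Optional[list[Reporter]] = None,
    series_id: str = "series1",
    platform_id: str = "plat1",
) -> tuple[str, str, dict[str, str], ParsedExperiment]:
    """A complete synthetic GEO-style experiment.

    Returns ``(soft_text, probe_table_text, value_tables, expected)``:

    * a SOFT family file with one series, one platform and ``n_samples``
      samples (each with an ID_REF/VALUE data table, as GEO emits);
    * a tab-delimited platform probe table (Probe ID / Sequence columns);
    * one value-table text per sample, carrying the same values as the SOFT
      sample tables (the two ingestion routes are interchangeable);
    * the expected staged experiment, for round-trip assertions.

    All output is a pure function of the arguments: the same seed gives
    byte-identical files.  Pass ``reporters`` to build the platform from
    existing probes (e.g. from a planted-truth platform) instead of random
    25-mers.
    """
    if n_samples < 1 or n_reporters < 1:
        raise ValidationError("n_samples and n_reporters must be >= 1")
    rng = np.random.default_rng(seed)
    if reporters is None:
        width = len(str(n_reporters))
        reporters = [
            Reporter(
                id=f"r{i + 1:0{width}d}",
                sequence="".join(_BASES[rng.integers(0, 4, size=25)]),
            )
            for i in range(n_reporters)
        ]
    else:
        if len(reporters) != n_reporters:
            raise ValidationError("len(reporters) must equal n_reporters")
    sample_names = [f"s{i + 1}" for i in range(n_samples)]
    values = {
        s: [round(float(v), 2) for v in rng.uniform(1.0, 10000.0, size=n_reporters)]
        for s in sample_names
    }

    lines = [
        f"^SERIES = {series_id}",
        "!Series_title = Synthetic expression series",
        f"!Series_geo_accession = {series_id}",
        f"^PLATFORM = {platform_id}",
        "!Platform_title = Synthetic 25-mer array",
        "!Platform_technology = in situ oligonucleotide",
    ]
    for i, s in enumerate(sample_names):
        lines += [
            f"^SAMPLE = {s}",
            f"!Sample_title = synthetic sample {i + 1}",
            f"!Sample_platform_id = {platform_id}",
            "!Sample_characteristics_ch1 = condition: synthetic",
            f"!Sample_characteristics_ch1 = replicate: {i + 1}",
            "#ID_REF = probe identifier",
            "#VALUE = raw intensity",
            "!sample_table_begin",
            "ID_REF\tVALUE",
        ]
        lines += [f"{r.id}\t{v!r}" for r, v in zip(reporters, values[s])]
        lines += ["!sample_table_end"]
    soft_text = "\n".join(lines) + "\n"

    probe_lines = ["Probe ID\tSequence"]
    probe_lines += [f"{r.id}\t{r.sequence}" for r in reporters]
    probe_table_text = "\n".join(probe_lines) + "\n"

    value_tables = {}
    for s in sample_names:
        vlines = ["ID_REF\tVALUE"]
        vlines += [f"{r.id}\t{v!r}" for r, v in zip(reporters, values[s])]
        value_tables[s] = "\n".join(vlines) + "\n"

    expected = ParsedExperiment(
        experiment_id=series_id,
        metadata={
            "Series_title": "Synthetic expression series",
            "Series_geo_accession": series_id,
        },
        platform=Platform(
            id=platform_id,
            kind=PlatformKind.microarray,
            reporters=list(reporters),
            metadata={
                "Platform_title": "Synthetic 25-mer array",
                "Platform_technology": "in situ oligonucleotide",
            },
        ),
        samples=[
            Sample(
                name=s,
                experiment_id=series_id,
                platform_id=platform_id,
                metadata={
                    "Sample_title": f"synthetic sample {i + 1}",
                    "Sample_platform_id": platform_id,
                    "Sample_characteristics_ch1": "condition: synthetic; "
                    f"replicate: {i + 1}",
                },
                measurements=[
                    Measurement(key=r.id, value=v)
                    for r, v in zip(reporters, values[s])
                ],
            )
            for i, s in enumerate(sample_names)
        ],
    )
    return soft_text, probe_table_text, value_tables, expected


def write_dataset_dir(
    directory: str | Path,
    n_samples: int = 2,
    n_reporters: int = 8,
    n_genes: int = 10,
    gene_length: int = 300,
    seed: int = 0,
) -> dict[str, Path]:
    """Emit a complete on-disk dataset for end-to-end (CLI) runs.

    Writes ``background.fasta``, ``experiment.soft``, ``probe_table.tsv`` and
    one ``<sample>.tsv`` value table per sample into ``directory``.  The
    platform probes are drawn from the background with a planted truth, so
    the alignment + filtering pipeline has genuinely mappable probes.
    Returns a name -> path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    background = generate_background(n_genes, gene_length, seed)
    plat, truth = generate_platform_with_truth(
        background, n_probes=n_reporters, seed=seed
    )
    soft_text, probe_text, value_tables, _ = generate_soft_experiment(
        n_samples, n_reporters, seed, reporters=plat.reporters
    )
    paths: dict[str, Path] = {}
    fasta = directory / "background.fasta"
    with open(fasta, "w") as fh:
        for f in background:
            fh.write(f">{f.id} {f.description}\n{f.sequence}\n")
    paths["background"] = fasta
    soft = directory / "experiment.soft"
    soft.write_text(soft_text)
    paths["soft"] = soft
    probes = directory / "probe_table.tsv"
    probes.write_text(probe_text)
    paths["probe_table"] = probes
    for s, text in value_tables.items():
        p = directory / f"{s}.tsv"
        p.write_text(text)
        paths[f"values:{s}"] = p
    return paths
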