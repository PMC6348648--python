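"""Domain types for a gene-expression compendium.

A compendium collects expression experiments measured on heterogeneous
platforms against one fixed *genomic background*: the set of gene (feature)
sequences every platform is re-annotated against and every RNA-seq count is
keyed to.  Microarray platforms carry *reporters* (probes) whose signal is an
indirect measurement of a gene; RNA-seq platforms carry no reporters and
their samples key measurements directly by feature id.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from typing import Optional

__all__ = [
    "ValidationError",
    "normalize_sequence",
    "BioFeature",
    "GenomicBackground",
    "Reporter",
    "PlatformKind",
    "Platform",
    "Measurement",
    "Sample",
    "Experiment",
    "ExperimentStatus",
    "ParsedExperiment",
    "MappingMethod",
    "AlignmentHit",
    "FilterThreshold",
    "TwoStepConfig",
    "FilterReport",
    "MappingProvenance",
    "ReporterMapping",
    "LogLevel",
    "LogEntry",
]

SEQUENCE_ALPHABET = frozenset("ACGTN")


class ValidationError(ValueError):
    """A domain invariant was violated."""


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Upper-case, map U->T, strip whitespace; reject characters outside ACGTN."""
    seq = "".join(raw.split()).upper().replace("U", "T")
    bad = set(seq) - SEQUENCE_ALPHABET
    if bad:
        raise ValidationError(
            f"{context}: illegal characters {sorted(bad)} (allowed: A,C,G,T,N)"
        )
    return seq


@dataclass(frozen=True)
class BioFeature:
    """A gene (or other biological feature) defined by the genomic background."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("feature id must be non-empty")
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, context=f"feature {self.id}")
        )
        if not self.sequence:
            raise ValidationError(f"feature {self.id}: empty sequence")


@dataclass(frozen=True)
class GenomicBackground:
    """The fixed gene set of a compendium, with a content digest for provenance."""

    features: tuple[BioFeature, ...]
    source_name: str = ""
    checksum: str = ""

    @staticmethod
    def from_features(
        features: list[BioFeature], source_name: str = ""
    ) -> "GenomicBackground":
        seen: set[str] = set()
        for f in features:
            if f.id in seen:
                raise ValidationError(f"duplicate feature id {f.id!r} in background")
            seen.add(f.id)
        digest = hashlib.sha256()
        for f in features:
            digest.update(f.id.encode())
            digest.update(b"\0")
            digest.update(f.sequence.encode())
            digest.update(b"\0")
        return GenomicBackground(
            features=tuple(features), source_name=source_name, checksum=digest.hexdigest()
        )

    def feature_ids(self) -> set[str]:
        return {f.id for f in self.features}


@dataclass(frozen=True)
class Reporter:
    """A platform-level measuring element (microarray probe)."""

    id: str
    sequence: Optional[str] = None
    metadata: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reporter id must be non-empty")
        if self.sequence is not None:
            object.__setattr__(
                self,
                "sequence",
                normalize_sequence(self.sequence, context=f"reporter {self.id}"),
            )


class PlatformKind(str, Enum):
    microarray = "microarray"
    rnaseq = "rnaseq"


@dataclass
class Platform:
    id: str
    kind: PlatformKind
    reporters: list[Reporter] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = PlatformKind(self.kind)
        if self.kind is PlatformKind.rnaseq and self.reporters:
            raise ValidationError(f"platform {self.id}: rnaseq platforms carry no reporters")
        ids = [r.id for r in self.reporters]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"platform {self.id}: duplicate reporter ids {dup}")

    def reporter_ids(self) -> set[str]:
        return {r.id for r in self.reporters}


@dataclass(frozen=True)
class Measurement:
    """One raw value keyed by reporter id (microarray) or feature id (RNA-seq)."""

    key: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError(f"measurement {self.key}: value must be finite")


@dataclass
class Sample:
    name: str
    experiment_id: str
    platform_id: str
    metadata: dict[str, str] = field(default_factory=dict)
    measurements: list[Measurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [m.key for m in self.measurements]
        if len(keys) != len(set(keys)):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"sample {self.name}: duplicate measurement keys {dup}")


class ExperimentStatus(str, Enum):
    staged = "staged"
    imported = "imported"


@dataclass
class Experiment:
    id: str
    metadata: dict[str, str] = field(default_factory=dict)
    samples: list[Sample] = field(default_factory=list)
    status: ExperimentStatus = ExperimentStatus.staged

    def __post_init__(self) -> None:
        self.status = ExperimentStatus(self.status)
        names = [s.name for s in self.samples]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"experiment {self.id}: duplicate sample names {dup}")


@dataclass(frozen=True)
class AlignmentHit:
    """One probe-vs-gene alignment record, 12-column tabular semantics.

    Coordinates are 1-based inclusive; ``feature_start > feature_end`` means
    the probe aligns to the minus strand of the feature.
    """

    probe_id: str
    feature_id: str
    identity_pct: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    probe_start: int
    probe_end: int
    feature_start: int
    feature_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (1 <= self.probe_start <= self.probe_end):
            raise ValidationError(
                f"hit {self.probe_id}->{self.feature_id}: bad probe coordinates "
                f"{self.probe_start}..{self.probe_end}"
            )
        if self.alignment_length < 1:
            raise ValidationError(
                f"hit {self.probe_id}->{self.feature_id}: alignment_length < 1"
            )
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValidationError(
                f"hit {self.probe_id}->{self.feature_id}: identity out of [0, 100]"
            )

    @property
    def strand(self) -> str:
        return "-" if self.feature_start > self.feature_end else "+"

    def location(self) -> tuple[str, str, int, int]:
        """Strand-aware placement key: (feature, strand, lo, hi), 1-based inclusive."""
        lo, hi = sorted((self.feature_start, self.feature_end))
        return (self.feature_id, self.strand, lo, hi)


@dataclass(frozen=True)
class FilterThreshold:
    """One hit-acceptance criterion of the alignment filter.

    A hit passes iff aligned_length/probe_length >= min_len_frac, gap opens
    <= max_gap_opens, mismatches <= max_mismatches and identity >=
    min_identity_pct.
    """

    min_len_frac: float
    max_gap_opens: int
    max_mismatches: int
    min_identity_pct: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_len_frac <= 1.0):
            raise ValidationError("min_len_frac must be in [0, 1]")
        if self.max_gap_opens < 0 or self.max_mismatches < 0:
            raise ValidationError("gap/mismatch bounds must be non-negative")
        if not (0.0 <= self.min_identity_pct <= 100.0):
            raise ValidationError("min_identity_pct must be in [0, 100]")

    def to_dict(self) -> dict:
        return {
            "min_len_frac": self.min_len_frac,
            "max_gap_opens": self.max_gap_opens,
            "max_mismatches": self.max_mismatches,
            "min_identity_pct": self.min_identity_pct,
        }

    @staticmethod
    def from_dict(d: dict) -> "FilterThreshold":
        return FilterThreshold(
            min_len_frac=float(d["min_len_frac"]),
            max_gap_opens=int(d["max_gap_opens"]),
            max_mismatches=int(d["max_mismatches"]),
            min_identity_pct=float(d.get("min_identity_pct", 0.0)),
        )


@dataclass(frozen=True)
class TwoStepConfig:
    """Sensitivity (lenient) then specificity (strict) thresholds.

    The sensitivity step must accept every hit the specificity step accepts;
    the constructor rejects configurations where any sensitivity field is
    stricter than the corresponding specificity field.
    """

    sensitivity: FilterThreshold
    specificity: FilterThreshold

    def __post_init__(self) -> None:
        s, p = self.sensitivity, self.specificity
        problems = []
        if s.min_len_frac > p.min_len_frac:
            problems.append("min_len_frac")
        if s.max_gap_opens < p.max_gap_opens:
            problems.append("max_gap_opens")
        if s.max_mismatches < p.max_mismatches:
            problems.append("max_mismatches")
        if s.min_identity_pct > p.min_identity_pct:
            problems.append("min_identity_pct")
        if problems:
            raise ValidationError(
                "sensitivity threshold is stricter than specificity for: "
                + ", ".join(problems)
            )

    @staticmethod
    def default() -> "TwoStepConfig":
        """The stock short-oligo configuration: 95% length / 0 gaps / 3
        mismatches (sensitivity), 98% length / 0 gaps / 1 mismatch
        (specificity)."""
        return TwoStepConfig(
            sensitivity=FilterThreshold(0.95, 0, 3),
            specificity=FilterThreshold(0.98, 0, 1),
        )


@dataclass
class FilterReport:
    """Partition of the filtered probe set into the four mapping outcomes."""

    retained: list[tuple[str, str]] = field(default_factory=list)
    discarded_ambiguous: list[str] = field(default_factory=list)
    discarded_low_quality: list[str] = field(default_factory=list)
    unaligned: list[str] = field(default_factory=list)

    def retained_ids(self) -> set[str]:
        return {r for r, _ in self.retained}

    def all_probes(self) -> set[str]:
        return (
            self.retained_ids()
            | set(self.discarded_ambiguous)
            | set(self.discarded_low_quality)
            | set(self.unaligned)
        )


class MappingMethod(str, Enum):
    two_step_filter = "two_step_filter"
    manual = "manual"


@dataclass(frozen=True)
class MappingProvenance:
    method: MappingMethod
    aligner: str = ""
    sensitivity: Optional[FilterThreshold] = None
    specificity: Optional[FilterThreshold] = None
    timestamp: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", MappingMethod(self.method))
        if self.method is MappingMethod.two_step_filter and (
            self.sensitivity is None or self.specificity is None
        ):
            raise ValidationError("two_step_filter provenance requires both thresholds")
        if not self.timestamp:
            object.__setattr__(
                self, "timestamp", datetime.now(timezone.utc).isoformat(timespec="seconds")
            )


@dataclass
class ReporterMapping:
    """Probe-to-gene assignments for one platform: each reporter maps to at
    most one feature; many reporters may map to the same feature."""

    platform_id: str
    entries: list[tuple[str, str]]
    provenance: MappingProvenance

    def __post_init__(self) -> None:
        rids = [r for r, _ in self.entries]
        if len(rids) != len(set(rids)):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise ValidationError(f"mapping: reporter(s) mapped more than once: {dup}")


@dataclass
class ParsedExperiment:
    """The staged, pre-import form of an experiment.

    Produced by the ingestion engine, inspected/validated, then committed
    atomically to the store.  ``issues`` accumulates warnings and errors from
    parsing; an experiment with error-level issues is not committable.
    """

    experiment_id: str
    metadata: dict[str, str] = field(default_factory=dict)
    platform: Optional[Platform] = None
    samples: list[Sample] = field(default_factory=list)
    issues: list["LogEntry"] = field(default_factory=list)

    def measurement_count(self) -> int:
        return sum(len(s.measurements) for s in self.samples)

    def error_issues(self) -> list["LogEntry"]:
        return [e for e in self.issues if e.level is LogLevel.error]


class LogLevel(str, Enum):
    info = "info"
    warning = "warning"
    error = "error"


@dataclass(frozen=True)
class LogEntry:
    level: LogLevel
    context: str
    message: str
    timestamp: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", LogLevel(self.level))
        if not self.timestamp:
            object.__setattr__(
                self, "timestamp", datetime.now(timezone.utc).isoformat(timespec="seconds")
            )
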