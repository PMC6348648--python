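"""The ingestion workflow engine.

Mirrors the three-step flow of building a compendium from files on disk:
files are *assigned* to entities (experiment, platform, sample) together
with a named parser; the parsing step runs every assignment and merges the
results into one staged :class:`~compendia.model.ParsedExperiment`; the
staged experiment is validated and then committed atomically to the store.

Parsers form a registry of named, parameterised readers rather than
user-editable scripts: extending the system means registering a new
callable with the same contract (text stream + params + assignment ->
fragments).  The engine guarantees two contracts that make ingestion
auditable:

* **order independence** — the merged result is identical under any
  assignment ordering; conflicting metadata from two files is an error, not
  a last-writer-wins race;
* **isolation** — a failing file is recorded as an issue on the staged
  experiment and never corrupts the results of sibling assignments.

RNA-seq experiments bypass file assignment: a gene-level counts matrix is
imported directly, with counts keyed to the genomic background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Callable, Optional

import pandas as pd
import yaml

from .formats import parse_probe_table, parse_soft, parse_value_table
from .model import (
    LogEntry,
    LogLevel,
    Measurement,
    ParsedExperiment,
    Platform,
    PlatformKind,
    Reporter,
    Sample,
    ValidationError,
)

__all__ = [
    "EntityRef",
    "FileAssignment",
    "Fragment",
    "PARSER_REGISTRY",
    "register_parser",
    "assign_files",
    "run_parsing",
    "validate_parsed",
    "import_counts_matrix",
    "save_plan",
    "load_plan",
    "discover_entities",
]

# ("experiment", None) | ("platform", id-or-None) | ("sample", name)
EntityRef = tuple[str, Optional[str]]

_ENTITY_KINDS = {"experiment", "platform", "sample"}


@dataclass(frozen=True)
class FileAssignment:
    """One (file, entity, parser) coupling, the unit of parsing work."""

    file: Path
    entity: EntityRef
    parser: str
    params: tuple[tuple[str, str], ...] = ()

    def params_dict(self) -> dict[str, str]:
        return dict(self.params)


@dataclass
class Fragment:
    """A parser's partial contribution to the staged experiment."""

    source: str  # file path, for conflict diagnostics
    experiment_id: Optional[str] = None
    experiment_meta: dict[str, str] = field(default_factory=dict)
    platform_id: Optional[str] = None
    platform_meta: dict[str, str] = field(default_factory=dict)
    reporters: Optional[list[Reporter]] = None
    sample_name: Optional[str] = None
    sample_meta: dict[str, str] = field(default_factory=dict)
    measurements: Optional[list[Measurement]] = None


def _flatten(value) -> str:
    """SOFT attribute values may be lists (repeated keys accumulate); entity
    metadata is plain strings, so lists are joined."""
    if isinstance(value, list):
        return "; ".join(value)
    return value


# ---------------------------------------------------------------------------
# parser registry


def _parse_soft_experiment(stream: IO[str], params: dict, a: FileAssignment) -> list[Fragment]:
    doc = parse_soft(stream)
    if doc.series is None:
        raise ValidationError("SOFT file has no ^SERIES entity")
    meta = {k: _flatten(v) for k, v in doc.series.metadata.items()}
    return [Fragment(source=str(a.file), experiment_id=doc.series.id, experiment_meta=meta)]


def _parse_soft_platform(stream: IO[str], params: dict, a: FileAssignment) -> list[Fragment]:
    doc = parse_soft(stream)
    if not doc.platforms:
        raise ValidationError("SOFT file has no ^PLATFORM entity")
    wanted = a.entity[1]
    for ent in doc.platforms:
        if wanted is None or ent.id == wanted:
            meta = {k: _flatten(v) for k, v in ent.metadata.items()}
            return [Fragment(source=str(a.file), platform_id=ent.id, platform_meta=meta)]
    raise ValidationError(f"SOFT file has no ^PLATFORM entity {wanted!r}")


def _parse_soft_sample(stream: IO[str], params: dict, a: FileAssignment) -> list[Fragment]:
    doc = parse_soft(stream)
    wanted = a.entity[1]
    for ent in doc.samples:
        if ent.id != wanted:
            continue
        meta = {k: _flatten(v) for k, v in ent.metadata.items()}
        frag = Fragment(source=str(a.file), sample_name=ent.id, sample_meta=meta)
        include_table = params.get("include_table", "true").lower() != "false"
        if include_table and ent.table is not None:
            id_field = params.get("id_field", "ID_REF")
            value_field = params.get("value_field", "VALUE")
            header, rows = ent.table
            if id_field not in header or value_field not in header:
                raise ValidationError(
                    f"sample {ent.id}: table lacks {id_field!r}/{value_field!r} "
                    f"columns; available: {header}"
                )
            ki, vi = header.index(id_field), header.index(value_field)
            seen: set[str] = set()
            ms: list[Measurement] = []
            for rownum, row in enumerate(rows, start=1):
                key, raw = row[ki].strip(), row[vi].strip()
                if key in seen:
                    raise ValidationError(
                        f"sample {ent.id} table row {rownum}: duplicate key {key!r}"
                    )
                seen.add(key)
                try:
                    val = float(raw)
                except ValueError:
                    raise ValidationError(
                        f"sample {ent.id} table row {rownum}: non-numeric value {raw!r}"
                    )
                ms.append(Measurement(key=key, value=val))
            frag.measurements = ms
        return [frag]
    raise ValidationError(f"SOFT file has no ^SAMPLE entity {wanted!r}")


def _parse_probe_table_file(stream: IO[str], params: dict, a: FileAssignment) -> list[Fragment]:
    id_field = params.get("id_field", "Probe ID")
    seq_field = params.get("seq_field", "Sequence")
    reporters = parse_probe_table(stream, id_field=id_field, seq_field=seq_field)
    return [Fragment(source=str(a.file), platform_id=a.entity[1], reporters=reporters)]


def _parse_value_table_file(stream: IO[str], params: dict, a: FileAssignment) -> list[Fragment]:
    if a.entity[0] != "sample" or not a.entity[1]:
        raise ValidationError("value_table parser requires a sample entity")
    id_field = params.get("id_field", "ID_REF")
    value_field = params.get("value_field", "VALUE")
    ms = parse_value_table(stream, id_field=id_field, value_field=value_field)
    return [Fragment(source=str(a.file), sample_name=a.entity[1], measurements=ms)]


ParserFn = Callable[[IO[str], dict, FileAssignment], list[Fragment]]

PARSER_REGISTRY: dict[str, ParserFn] = {
    "soft_experiment": _parse_soft_experiment,
    "soft_platform": _parse_soft_platform,
    "soft_sample": _parse_soft_sample,
    "probe_table": _parse_probe_table_file,
    "value_table": _parse_value_table_file,
}


def register_parser(name: str, fn: ParserFn) -> None:
    """Extend the ingestion engine with a new named parser."""
    PARSER_REGISTRY[name] = fn


# ---------------------------------------------------------------------------
# assignment


def discover_entities(soft_path: str | Path) -> list[EntityRef]:
    """Enumerate the entity references present in a SOFT family file, so a
    single assign_all call can cover experiment + platform + samples."""
    with open(soft_path) as fh:
        doc = parse_soft(fh)
    refs: list[EntityRef] = []
    if doc.series is not None:
        refs.append(("experiment", None))
    refs.extend(("platform", p.id) for p in doc.platforms)
    refs.extend(("sample", s.id) for s in doc.samples)
    return refs


def assign_files(
    files: list[str | Path],
    entities: list[EntityRef],
    rule: str,
    parser: str,
    params: Optional[dict[str, str]] = None,
) -> tuple[list[FileAssignment], list[LogEntry]]:
    """Couple files with entities under an assignment rule.

    ``assign_all`` pairs every file with every entity (the SOFT file feeding
    experiment, platform and samples at once); ``match_entity_name`` pairs a
    file with the sample whose name equals the file's base name (extension
    stripped, case-insensitive) — the rule that automatically couples
    per-sample data files with their samples.  Unmatched files produce
    warning issues; two samples with the same (case-folded) name make the
    match ambiguous, which is an error.
    """
    if parser not in PARSER_REGISTRY:
        raise ValidationError(
            f"unknown parser {parser!r}; registered: {sorted(PARSER_REGISTRY)}"
        )
    for kind, _ in entities:
        if kind not in _ENTITY_KINDS:
            raise ValidationError(f"unknown entity kind {kind!r}")
    p = tuple(sorted((params or {}).items()))
    assignments: list[FileAssignment] = []
    issues: list[LogEntry] = []
    if rule == "assign_all":
        for f in files:
            for ent in entities:
                assignments.append(
                    FileAssignment(file=Path(f), entity=ent, parser=parser, params=p)
                )
    elif rule == "match_entity_name":
        samples = [e for e in entities if e[0] == "sample"]
        if any(not e[1] for e in samples):
            raise ValidationError("match_entity_name requires non-empty sample names")
        by_name: dict[str, EntityRef] = {}
        for e in samples:
            key = e[1].lower()
            if key in by_name:
                raise ValidationError(
                    f"ambiguous match: two samples share the name {e[1]!r}"
                )
            by_name[key] = e
        for f in files:
            stem = Path(f).stem.lower()
            ent = by_name.get(stem)
            if ent is None:
                issues.append(
                    LogEntry(
                        level=LogLevel.warning,
                        context=str(f),
                        message=f"file {Path(f).name!r} matches no sample name",
                    )
                )
                continue
            assignments.append(
                FileAssignment(file=Path(f), entity=ent, parser=parser, params=p)
            )
    else:
        raise ValidationError(f"unknown assignment rule {rule!r}")
    return assignments, issues


# ---------------------------------------------------------------------------
# parsing engine


def _merge_meta(
    target: dict[str, str],
    sources: dict[str, str],
    incoming: dict[str, str],
    source: str,
    scope: str,
    issues: list[LogEntry],
) -> None:
    """Merge metadata; the same key from two files with different values is an
    error-level issue naming the key and both files (never last-writer-wins)."""
    for k, v in incoming.items():
        if k in target and target[k] != v:
            issues.append(
                LogEntry(
                    level=LogLevel.error,
                    context=scope,
                    message=(
                        f"conflicting metadata for key {k!r}: "
                        f"{target[k]!r} (from {sources[k]}) vs {v!r} (from {source})"
                    ),
                )
            )
            continue
        target[k] = v
        sources.setdefault(k, source)


def run_parsing(
    assignments: list[FileAssignment],
    experiment_id: Optional[str] = None,
    extra_issues: Optional[list[LogEntry]] = None,
) -> ParsedExperiment:
    """Execute every assignment and merge the fragments into one staged
    experiment.

    Assignments are processed in a canonical order (sorted by file, entity,
    parser) so the result is independent of the order the caller built the
    list in.  A failing assignment is captured as an error issue; the other
    assignments still run.
    """
    issues: list[LogEntry] = list(extra_issues or [])
    fragments: list[Fragment] = []
    for a in sorted(
        assignments, key=lambda a: (str(a.file), a.entity, a.parser, a.params)
    ):
        fn = PARSER_REGISTRY.get(a.parser)
        if fn is None:
            issues.append(
                LogEntry(
                    level=LogLevel.error,
                    context=str(a.file),
                    message=f"unknown parser {a.parser!r}",
                )
            )
            continue
        try:
            with open(a.file) as fh:
                fragments.extend(fn(fh, a.params_dict(), a))
        except Exception as exc:  # noqa: BLE001 - isolation contract
            issues.append(
                LogEntry(
                    level=LogLevel.error,
                    context=str(a.file),
                    message=f"parser {a.parser!r} failed: {exc}",
                )
            )

    if not assignments:
        issues.append(
            LogEntry(
                level=LogLevel.warning,
                context="ingestion",
                message="no file assignments: staged experiment is empty",
            )
        )

    exp_meta: dict[str, str] = {}
    exp_meta_src: dict[str, str] = {}
    plat_meta: dict[str, str] = {}
    plat_meta_src: dict[str, str] = {}
    plat_id: Optional[str] = None
    reporters: Optional[list[Reporter]] = None
    reporters_src = ""
    exp_id = experiment_id
    sample_meta: dict[str, dict[str, str]] = {}
    sample_meta_src: dict[str, dict[str, str]] = {}
    sample_measurements: dict[str, list[Measurement]] = {}
    sample_meas_src: dict[str, str] = {}

    for frag in fragments:
        if frag.experiment_id is not None:
            if exp_id is None:
                exp_id = frag.experiment_id
            elif exp_id != frag.experiment_id:
                issues.append(
                    LogEntry(
                        level=LogLevel.error,
                        context=frag.source,
                        message=(
                            f"conflicting experiment ids: {exp_id!r} vs "
                            f"{frag.experiment_id!r}"
                        ),
                    )
                )
        _merge_meta(exp_meta, exp_meta_src, frag.experiment_meta, frag.source,
                    "experiment", issues)
        if frag.platform_id is not None:
            if plat_id is None:
                plat_id = frag.platform_id
            elif plat_id != frag.platform_id:
                issues.append(
                    LogEntry(
                        level=LogLevel.error,
                        context=frag.source,
                        message=f"conflicting platform ids: {plat_id!r} vs "
                        f"{frag.platform_id!r}",
                    )
                )
        _merge_meta(plat_meta, plat_meta_src, frag.platform_meta, frag.source,
                    "platform", issues)
        if frag.reporters is not None:
            if reporters is None:
                reporters = frag.reporters
                reporters_src = frag.source
            elif [(r.id, r.sequence) for r in reporters] != [
                (r.id, r.sequence) for r in frag.reporters
            ]:
                issues.append(
                    LogEntry(
                        level=LogLevel.error,
                        context=frag.source,
                        message=(
                            f"conflicting platform probe tables: {reporters_src} "
                            f"vs {frag.source}"
                        ),
                    )
                )
        if frag.sample_name is not None:
            name = frag.sample_name
            sample_meta.setdefault(name, {})
            sample_meta_src.setdefault(name, {})
            _merge_meta(sample_meta[name], sample_meta_src[name], frag.sample_meta,
                        frag.source, f"sample:{name}", issues)
            if frag.measurements is not None:
                if name in sample_measurements:
                    issues.append(
                        LogEntry(
                            level=LogLevel.error,
                            context=frag.source,
                            message=(
                                f"sample {name!r} has measurements from two "
                                f"files: {sample_meas_src[name]} and {frag.source}"
                            ),
                        )
                    )
                else:
                    sample_measurements[name] = frag.measurements
                    sample_meas_src[name] = frag.source

    exp_id = exp_id or "experiment"
    plat_id = plat_id or "platform"
    platform = None
    if reporters is not None or plat_meta or fragments:
        try:
            platform = Platform(
                id=plat_id,
                kind=PlatformKind.microarray,
                reporters=reporters or [],
                metadata=plat_meta,
            )
        except ValidationError as exc:
            issues.append(
                LogEntry(level=LogLevel.error, context="platform", message=str(exc))
            )
    samples = []
    for name in sorted(sample_meta.keys() | sample_measurements.keys()):
        try:
            samples.append(
                Sample(
                    name=name,
                    experiment_id=exp_id,
                    platform_id=plat_id,
                    metadata=sample_meta.get(name, {}),
                    measurements=sample_measurements.get(name, []),
                )
            )
        except ValidationError as exc:
            issues.append(
                LogEntry(level=LogLevel.error, context=f"sample:{name}", message=str(exc))
            )
    return ParsedExperiment(
        experiment_id=exp_id,
        metadata=exp_meta,
        platform=platform,
        samples=samples,
        issues=issues,
    )


# ---------------------------------------------------------------------------
# validation


def validate_parsed(parsed: ParsedExperiment, compendium) -> list[LogEntry]:
    """Pre-commit validation; returns error-level entries (empty list means
    the experiment is committable).  Never raises."""
    errors: list[LogEntry] = list(parsed.error_issues())

    def err(context: str, message: str) -> None:
        errors.append(LogEntry(level=LogLevel.error, context=context, message=message))

    if parsed.experiment_id in set(compendium.experiment_ids()):
        err(
            f"experiment:{parsed.experiment_id}",
            f"experiment {parsed.experiment_id!r} already imported",
        )
    plat = parsed.platform
    if plat is None:
        err("platform", "staged experiment has no platform")
        return errors
    stored_platforms = set(compendium.platform_ids())
    if plat.id in stored_platforms:
        stored = compendium.get_platform(plat.id)
        if stored.kind is not plat.kind:
            err(
                f"platform:{plat.id}",
                f"platform kind mismatch: staged {plat.kind.value}, "
                f"stored {stored.kind.value}",
            )
    if plat.kind is PlatformKind.microarray:
        valid_keys = plat.reporter_ids()
        key_space = "platform"
    else:
        bg = compendium.background()
        valid_keys = bg.feature_ids() if bg else set()
        key_space = "genomic background"
    names_seen: set[str] = set()
    for s in parsed.samples:
        if s.name in names_seen:
            err(f"sample:{s.name}", f"duplicate sample name {s.name!r}")
        names_seen.add(s.name)
        if not s.measurements:
            err(f"sample:{s.name}", f"sample {s.name!r} has no measurements")
            continue
        unknown = sorted({m.key for m in s.measurements} - valid_keys)
        if unknown:
            shown = ", ".join(unknown[:5]) + ("..." if len(unknown) > 5 else "")
            err(
                f"sample:{s.name}",
                f"{len(unknown)} measurement key(s) absent from {key_space}: {shown}",
            )
        if plat.kind is PlatformKind.rnaseq:
            negative = sorted(m.key for m in s.measurements if m.value < 0)
            if negative:
                err(
                    f"sample:{s.name}",
                    f"negative count(s) for: {', '.join(negative[:5])}",
                )
    if not parsed.samples:
        err(f"experiment:{parsed.experiment_id}", "staged experiment has no samples")
    return errors


# ---------------------------------------------------------------------------
# RNA-seq counts path


def import_counts_matrix(
    stream: IO[str],
    experiment_id: str,
    compendium,
    platform_id: str = "rnaseq",
) -> ParsedExperiment:
    """Stage a gene-level counts matrix as an RNA-seq experiment.

    The matrix is tab-delimited: first column gene ids, one further column
    per sample, header row of sample names.  Counts are validated
    non-negative, unknown gene ids are collected into a single error issue,
    and a non-numeric cell is an error with its coordinates.  Counts attach
    directly to genes of the genomic background — there is no reporter layer.
    """
    issues: list[LogEntry] = []
    try:
        df = pd.read_csv(stream, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError("empty counts matrix")
    bg = compendium.background()
    known = bg.feature_ids() if bg else set()
    if bg is None:
        issues.append(
            LogEntry(
                level=LogLevel.error,
                context="background",
                message="no genomic background set; counts cannot be keyed to genes",
            )
        )
    existing_samples = {
        s.name for eid in compendium.experiment_ids()
        for s in compendium.get_experiment(eid).samples
    }
    clash = sorted(set(df.columns) & existing_samples)
    if clash:
        issues.append(
            LogEntry(
                level=LogLevel.error,
                context=f"experiment:{experiment_id}",
                message=f"sample name(s) already present in the store: {clash}",
            )
        )
    unknown = sorted(set(df.index) - known) if bg is not None else []
    if unknown:
        shown = ", ".join(unknown[:5]) + ("..." if len(unknown) > 5 else "")
        issues.append(
            LogEntry(
                level=LogLevel.error,
                context=f"experiment:{experiment_id}",
                message=f"{len(unknown)} gene id(s) absent from background: {shown}",
            )
        )
    samples: list[Sample] = []
    for col in df.columns:
        ms: list[Measurement] = []
        for gene, raw in df[col].items():
            raw = raw.strip()
            try:
                value = float(raw)
            except ValueError:
                issues.append(
                    LogEntry(
                        level=LogLevel.error,
                        context=f"sample:{col}",
                        message=f"non-numeric count {raw!r} at gene {gene!r}, "
                        f"sample {col!r}",
                    )
                )
                continue
            if not math.isfinite(value) or value < 0:
                issues.append(
                    LogEntry(
                        level=LogLevel.error,
                        context=f"sample:{col}",
                        message=f"invalid count {raw!r} at gene {gene!r}, "
                        f"sample {col!r} (counts are non-negative)",
                    )
                )
                continue
            ms.append(Measurement(key=str(gene), value=value))
        samples.append(
            Sample(
                name=str(col),
                experiment_id=experiment_id,
                platform_id=platform_id,
                measurements=ms,
            )
        )
    platform = Platform(id=platform_id, kind=PlatformKind.rnaseq)
    return ParsedExperiment(
        experiment_id=experiment_id,
        platform=platform,
        samples=samples,
        issues=issues,
    )


# ---------------------------------------------------------------------------
# plan serialization


def save_plan(
    assignments: list[FileAssignment],
    path: str | Path,
    experiment_id: Optional[str] = None,
) -> None:
    """Serialize an ingestion plan to YAML so a run is replayable exactly."""
    doc = {
        "experiment_id": experiment_id,
        "assignments": [
            {
                "file": str(a.file),
                "entity": {"kind": a.entity[0], "id": a.entity[1]},
                "parser": a.parser,
                "params": dict(a.params),
            }
            for a in assignments
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_plan(path: str | Path) -> tuple[list[FileAssignment], Optional[str]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    assignments = [
        FileAssignment(
            file=Path(a["file"]),
            entity=(a["entity"]["kind"], a["entity"]["id"]),
            parser=a["parser"],
            params=tuple(sorted((a.get("params") or {}).items())),
        )
        for a in doc.get("assignments", [])
    ]
    return assignments, doc.get("experiment_id")
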