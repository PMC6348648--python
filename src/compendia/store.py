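"""File-backed compendium store.

The store is an embedded relational database (sqlite3) living in a
directory together with a ``compendium.json`` manifest recording the
compendium name, schema version and the checksum of the genomic background.
It is a single-process store: concurrent writers are not supported.

Layout::

    <storage_path>/
        compendium.json     manifest (name, schema_version, background_checksum)
        compendium.sqlite   all entities and the append-only system log
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .model import (
    BioFeature,
    Experiment,
    ExperimentStatus,
    FilterThreshold,
    GenomicBackground,
    LogEntry,
    LogLevel,
    MappingMethod,
    MappingProvenance,
    Measurement,
    ParsedExperiment,
    Platform,
    PlatformKind,
    Reporter,
    ReporterMapping,
    Sample,
    ValidationError,
)

SCHEMA_VERSION = 1
MANIFEST_NAME = "compendium.json"
DB_NAME = "compendium.sqlite"

_SCHEMA = """
CREATE TABLE background_feature (
    ord INTEGER PRIMARY KEY,
    id TEXT NOT NULL UNIQUE,
    sequence TEXT NOT NULL,
    description TEXT NOT NULL DEFAULT ''
);
CREATE TABLE background_info (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE platform (
    id TEXT PRIMARY KEY,
    kind TEXT NOT NULL,
    metadata TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE reporter (
    platform_id TEXT NOT NULL REFERENCES platform(id),
    ord INTEGER NOT NULL,
    id TEXT NOT NULL,
    sequence TEXT,
    metadata TEXT NOT NULL DEFAULT '{}',
    PRIMARY KEY (platform_id, id)
);
CREATE TABLE experiment (
    id TEXT PRIMARY KEY,
    metadata TEXT NOT NULL DEFAULT '{}',
    status TEXT NOT NULL
);
CREATE TABLE sample (
    experiment_id TEXT NOT NULL REFERENCES experiment(id),
    name TEXT NOT NULL,
    platform_id TEXT NOT NULL REFERENCES platform(id),
    metadata TEXT NOT NULL DEFAULT '{}',
    PRIMARY KEY (experiment_id, name)
);
CREATE TABLE measurement (
    experiment_id TEXT NOT NULL,
    sample_name TEXT NOT NULL,
    key TEXT NOT NULL,
    value REAL NOT NULL,
    PRIMARY KEY (experiment_id, sample_name, key),
    FOREIGN KEY (experiment_id, sample_name) REFERENCES sample(experiment_id, name)
);
CREATE TABLE mapping (
    id INTEGER PRIMARY KEY,
    platform_id TEXT NOT NULL REFERENCES platform(id),
    method TEXT NOT NULL,
    aligner TEXT NOT NULL DEFAULT '',
    sensitivity TEXT,
    specificity TEXT,
    timestamp TEXT NOT NULL
);
CREATE TABLE mapping_entry (
    mapping_id INTEGER NOT NULL REFERENCES mapping(id),
    reporter_id TEXT NOT NULL,
    feature_id TEXT NOT NULL,
    PRIMARY KEY (mapping_id, reporter_id)
);
CREATE TABLE log (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    timestamp TEXT NOT NULL,
    level TEXT NOT NULL,
    context TEXT NOT NULL DEFAULT '',
    message TEXT NOT NULL
);
"""


class StoreError(RuntimeError):
    """Raised for store-level failures (path collisions, lookups, conflicts)."""


def _meta_dumps(d: dict[str, str]) -> str:
    return json.dumps(d, sort_keys=True, ensure_ascii=False)


class Compendium:
    """A local collection of expression experiments sharing one genomic
    background, persisted under ``storage_path``.

    Use :func:`create_compendium` / :func:`open_compendium` rather than the
    constructor.
    """

    def __init__(self, storage_path: Path, name: str):
        self.storage_path = Path(storage_path)
        self.name = name
        self._conn = sqlite3.connect(self.storage_path / DB_NAME)
        self._conn.execute("PRAGMA foreign_keys = ON")

    # -- lifecycle -----------------------------------------------------

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Compendium":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _write_manifest(self) -> None:
        bg = self._background_info()
        manifest = {
            "name": self.name,
            "schema_version": SCHEMA_VERSION,
            "background_checksum": bg.get("checksum"),
        }
        (self.storage_path / MANIFEST_NAME).write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    # -- system log ----------------------------------------------------

    def log(self, level: LogLevel | str, context: str, message: str) -> None:
        entry = LogEntry(level=LogLevel(level), context=context, message=message)
        self._conn.execute(
            "INSERT INTO log (timestamp, level, context, message) VALUES (?,?,?,?)",
            (entry.timestamp, entry.level.value, entry.context, entry.message),
        )
        self._conn.commit()

    def log_entries(self) -> list[LogEntry]:
        rows = self._conn.execute(
            "SELECT timestamp, level, context, message FROM log ORDER BY id"
        ).fetchall()
        return [LogEntry(level=lv, context=c, message=m, timestamp=t) for t, lv, c, m in rows]

    # -- genomic background --------------------------------------------

    def _background_info(self) -> dict[str, str]:
        return dict(self._conn.execute("SELECT key, value FROM background_info"))

    def background(self) -> Optional[GenomicBackground]:
        info = self._background_info()
        if "checksum" not in info:
            return None
        rows = self._conn.execute(
            "SELECT id, sequence, description FROM background_feature ORDER BY ord"
        ).fetchall()
        feats = tuple(BioFeature(id=i, sequence=s, description=d) for i, s, d in rows)
        return GenomicBackground(
            features=feats, source_name=info.get("source_name", ""), checksum=info["checksum"]
        )

    def set_genomic_background(
        self, features: list[BioFeature], source_name: str = ""
    ) -> GenomicBackground:
        """Install the gene set.  Allowed only while no experiment has been
        imported; afterwards the background is frozen."""
        n_imported = self._conn.execute(
            "SELECT COUNT(*) FROM experiment WHERE status = ?",
            (ExperimentStatus.imported.value,),
        ).fetchone()[0]
        if n_imported:
            raise StoreError(
                "background frozen: experiments have already been imported; "
                "the genomic background must not change during data collection"
            )
        bg = GenomicBackground.from_features(features, source_name=source_name)
        cur = self._conn.cursor()
        try:
            cur.execute("DELETE FROM background_feature")
            cur.execute("DELETE FROM background_info")
            cur.executemany(
                "INSERT INTO background_feature (ord, id, sequence, description) VALUES (?,?,?,?)",
                [(i, f.id, f.sequence, f.description) for i, f in enumerate(bg.features)],
            )
            cur.executemany(
                "INSERT INTO background_info (key, value) VALUES (?,?)",
                [("checksum", bg.checksum), ("source_name", bg.source_name)],
            )
            self._conn.commit()
        except Exception:
            self._conn.rollback()
            raise
        self._write_manifest()
        self.log("info", "background", f"background set: {len(bg.features)} features")
        return bg

    # -- platforms -----------------------------------------------------

    def platform_ids(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT id FROM platform ORDER BY id")]

    def get_platform(self, platform_id: str) -> Platform:
        row = self._conn.execute(
            "SELECT kind, metadata FROM platform WHERE id = ?", (platform_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown platform {platform_id!r}")
        kind, meta = row
        reps = [
            Reporter(id=i, sequence=s, metadata=tuple(sorted(json.loads(m).items())))
            for i, s, m in self._conn.execute(
                "SELECT id, sequence, metadata FROM reporter WHERE platform_id = ? ORDER BY ord",
                (platform_id,),
            )
        ]
        return Platform(id=platform_id, kind=kind, reporters=reps, metadata=json.loads(meta))

    # -- experiments ---------------------------------------------------

    def experiment_ids(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT id FROM experiment ORDER BY id")]

    def get_experiment(self, experiment_id: str) -> Experiment:
        row = self._conn.execute(
            "SELECT metadata, status FROM experiment WHERE id = ?", (experiment_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown experiment {experiment_id!r}")
        meta, status = row
        samples = []
        for name, pid, smeta in self._conn.execute(
            "SELECT name, platform_id, metadata FROM sample WHERE experiment_id = ? ORDER BY name",
            (experiment_id,),
        ):
            ms = [
                Measurement(key=k, value=v)
                for k, v in self._conn.execute(
                    "SELECT key, value FROM measurement "
                    "WHERE experiment_id = ? AND sample_name = ? ORDER BY key",
                    (experiment_id, name),
                )
            ]
            samples.append(
                Sample(
                    name=name,
                    experiment_id=experiment_id,
                    platform_id=pid,
                    metadata=json.loads(smeta),
                    measurements=ms,
                )
            )
        return Experiment(
            id=experiment_id, metadata=json.loads(meta), samples=samples, status=status
        )

    def measurement_count(self, experiment_id: str) -> int:
        return self._conn.execute(
            "SELECT COUNT(*) FROM measurement WHERE experiment_id = ?", (experiment_id,)
        ).fetchone()[0]

    def commit_experiment(self, parsed: ParsedExperiment) -> Experiment:
        """Atomically import a validated staged experiment.

        The commit is all-or-nothing: any failure leaves the store exactly as
        it was.  Validation failures are rejected and logged.
        """
        from .ingestion import validate_parsed  # local import: layering, not cycle-safe at top

        errors = validate_parsed(parsed, self)
        if errors:
            for e in errors:
                self.log(e.level, e.context, e.message)
            raise ValidationError(
                f"experiment {parsed.experiment_id!r} failed validation: "
                + "; ".join(e.message for e in errors)
            )
        cur = self._conn.cursor()
        try:
            cur.execute("BEGIN")
            plat = parsed.platform
            assert plat is not None  # guaranteed by validate_parsed
            existing = cur.execute(
                "SELECT kind FROM platform WHERE id = ?", (plat.id,)
            ).fetchone()
            if existing is None:
                cur.execute(
                    "INSERT INTO platform (id, kind, metadata) VALUES (?,?,?)",
                    (plat.id, plat.kind.value, _meta_dumps(plat.metadata)),
                )
                cur.executemany(
                    "INSERT INTO reporter (platform_id, ord, id, sequence, metadata) "
                    "VALUES (?,?,?,?,?)",
                    [
                        (plat.id, i, r.id, r.sequence, _meta_dumps(dict(r.metadata)))
                        for i, r in enumerate(plat.reporters)
                    ],
                )
            cur.execute(
                "INSERT INTO experiment (id, metadata, status) VALUES (?,?,?)",
                (
                    parsed.experiment_id,
                    _meta_dumps(parsed.metadata),
                    ExperimentStatus.imported.value,
                ),
            )
            for s in parsed.samples:
                cur.execute(
                    "INSERT INTO sample (experiment_id, name, platform_id, metadata) "
                    "VALUES (?,?,?,?)",
                    (parsed.experiment_id, s.name, plat.id, _meta_dumps(s.metadata)),
                )
                cur.executemany(
                    "INSERT INTO measurement (experiment_id, sample_name, key, value) "
                    "VALUES (?,?,?,?)",
                    [(parsed.experiment_id, s.name, m.key, m.value) for m in s.measurements],
                )
            self._conn.commit()
        except sqlite3.IntegrityError as exc:
            self._conn.rollback()
            self.log(
                "error",
                f"experiment:{parsed.experiment_id}",
                f"import conflict: {exc}",
            )
            raise StoreError(
                f"experiment {parsed.experiment_id!r} conflicts with existing data: {exc}"
            ) from exc
        except Exception:
            self._conn.rollback()
            raise
        self.log(
            "info",
            f"experiment:{parsed.experiment_id}",
            f"imported {len(parsed.samples)} samples, "
            f"{parsed.measurement_count()} measurements",
        )
        return self.get_experiment(parsed.experiment_id)

    # -- mappings ------------------------------------------------------

    def add_mapping(self, mapping: ReporterMapping) -> int:
        plat = self.get_platform(mapping.platform_id)
        bg = self.background()
        if bg is None:
            raise StoreError("no genomic background set")
        rep_ids = plat.reporter_ids()
        feat_ids = bg.feature_ids()
        for rid, fid in mapping.entries:
            if rid not in rep_ids:
                raise StoreError(f"mapping references unknown reporter {rid!r}")
            if fid not in feat_ids:
                raise StoreError(f"mapping references unknown feature {fid!r}")
        prov = mapping.provenance
        cur = self._conn.cursor()
        try:
            cur.execute("BEGIN")
            cur.execute(
                "INSERT INTO mapping (platform_id, method, aligner, sensitivity, "
                "specificity, timestamp) VALUES (?,?,?,?,?,?)",
                (
                    mapping.platform_id,
                    prov.method.value,
                    prov.aligner,
                    json.dumps(prov.sensitivity.to_dict()) if prov.sensitivity else None,
                    json.dumps(prov.specificity.to_dict()) if prov.specificity else None,
                    prov.timestamp,
                ),
            )
            mapping_id = cur.lastrowid
            cur.executemany(
                "INSERT INTO mapping_entry (mapping_id, reporter_id, feature_id) VALUES (?,?,?)",
                [(mapping_id, r, f) for r, f in mapping.entries],
            )
            self._conn.commit()
        except Exception:
            self._conn.rollback()
            raise
        self.log(
            "info",
            f"platform:{mapping.platform_id}",
            f"mapping imported: {len(mapping.entries)} probe-to-gene pairs "
            f"({prov.method.value})",
        )
        return int(mapping_id)

    def get_mapping(self, mapping_id: int) -> ReporterMapping:
        row = self._conn.execute(
            "SELECT platform_id, method, aligner, sensitivity, specificity, timestamp "
            "FROM mapping WHERE id = ?",
            (mapping_id,),
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown mapping {mapping_id}")
        pid, method, aligner, sens, spec, ts = row
        entries = [
            (r, f)
            for r, f in self._conn.execute(
                "SELECT reporter_id, feature_id FROM mapping_entry "
                "WHERE mapping_id = ? ORDER BY reporter_id",
                (mapping_id,),
            )
        ]
        prov = MappingProvenance(
            method=MappingMethod(method),
            aligner=aligner,
            sensitivity=FilterThreshold.from_dict(json.loads(sens)) if sens else None,
            specificity=FilterThreshold.from_dict(json.loads(spec)) if spec else None,
            timestamp=ts,
        )
        return ReporterMapping(platform_id=pid, entries=entries, provenance=prov)

    def mapping_ids(self) -> list[int]:
        return [r[0] for r in self._conn.execute("SELECT id FROM mapping ORDER BY id")]

    def latest_mapping(self, platform_id: str) -> Optional[ReporterMapping]:
        row = self._conn.execute(
            "SELECT id FROM mapping WHERE platform_id = ? ORDER BY id DESC LIMIT 1",
            (platform_id,),
        ).fetchone()
        return self.get_mapping(row[0]) if row else None

    # -- raw matrix ----------------------------------------------------

    def get_raw_matrix(self, experiment_ids: Iterable[str]) -> pd.DataFrame:
        """Raw-value matrix for the selected imported experiments.

        Rows are reporter/feature keys, columns sample names, both in
        lexicographic order; a cell is NaN iff the sample has no measurement
        for that key.  Raw values are passed through untouched — the store
        never normalizes.
        """
        ids = list(experiment_ids)
        known = set(self.experiment_ids())
        for eid in ids:
            if eid not in known:
                raise StoreError(f"unknown experiment {eid!r}")
        columns: list[str] = []
        for eid in sorted(ids):
            names = [
                r[0]
                for r in self._conn.execute(
                    "SELECT name FROM sample WHERE experiment_id = ? ORDER BY name", (eid,)
                )
            ]
            clash = set(names) & set(columns)
            if clash:
                raise StoreError(
                    f"sample name collision across selected experiments: {sorted(clash)}"
                )
            columns.extend(names)
        if not ids:
            return pd.DataFrame(dtype=float)
        qmarks = ",".join("?" for _ in ids)
        rows = self._conn.execute(
            f"SELECT key, sample_name, value FROM measurement "
            f"WHERE experiment_id IN ({qmarks})",
            ids,
        ).fetchall()
        keys = sorted({r[0] for r in rows})
        mat = pd.DataFrame(float("nan"), index=keys, columns=sorted(columns), dtype=float)
        for k, s, v in rows:
            mat.at[k, s] = v
        return mat

    # -- integrity & identity ------------------------------------------

    def check_referential_integrity(self) -> list[str]:
        """Return a list of integrity violations (empty means consistent)."""
        problems = []
        for (eid, sname, key) in self._conn.execute(
            "SELECT m.experiment_id, m.sample_name, m.key FROM measurement m "
            "LEFT JOIN sample s ON m.experiment_id = s.experiment_id "
            "AND m.sample_name = s.name WHERE s.name IS NULL"
        ):
            problems.append(f"measurement {eid}/{sname}/{key} has no sample")
        for (eid, sname) in self._conn.execute(
            "SELECT s.experiment_id, s.name FROM sample s "
            "LEFT JOIN experiment e ON s.experiment_id = e.id WHERE e.id IS NULL"
        ):
            problems.append(f"sample {eid}/{sname} has no experiment")
        for (eid, sname) in self._conn.execute(
            "SELECT s.experiment_id, s.name FROM sample s "
            "LEFT JOIN platform p ON s.platform_id = p.id WHERE p.id IS NULL"
        ):
            problems.append(f"sample {eid}/{sname} references missing platform")
        for (mid, rid) in self._conn.execute(
            "SELECT me.mapping_id, me.reporter_id FROM mapping_entry me "
            "JOIN mapping mp ON me.mapping_id = mp.id "
            "LEFT JOIN reporter r ON r.platform_id = mp.platform_id "
            "AND r.id = me.reporter_id WHERE r.id IS NULL"
        ):
            problems.append(f"mapping {mid} references missing reporter {rid}")
        for (mid, fid) in self._conn.execute(
            "SELECT me.mapping_id, me.feature_id FROM mapping_entry me "
            "LEFT JOIN background_feature f ON f.id = me.feature_id WHERE f.id IS NULL"
        ):
            problems.append(f"mapping {mid} references missing feature {fid}")
        return problems

    def snapshot(self) -> dict:
        """Canonical dict of all stored data (timestamps and log excluded),
        used for equality and replay-identity checks."""
        snap: dict = {"name": self.name, "schema_version": SCHEMA_VERSION}
        snap["background"] = {
            "info": sorted(self._background_info().items()),
            "features": self._conn.execute(
                "SELECT ord, id, sequence, description FROM background_feature ORDER BY ord"
            ).fetchall(),
        }
        snap["platforms"] = self._conn.execute(
            "SELECT id, kind, metadata FROM platform ORDER BY id"
        ).fetchall()
        snap["reporters"] = self._conn.execute(
            "SELECT platform_id, ord, id, sequence, metadata FROM reporter "
            "ORDER BY platform_id, ord"
        ).fetchall()
        snap["experiments"] = self._conn.execute(
            "SELECT id, metadata, status FROM experiment ORDER BY id"
        ).fetchall()
        snap["samples"] = self._conn.execute(
            "SELECT experiment_id, name, platform_id, metadata FROM sample "
            "ORDER BY experiment_id, name"
        ).fetchall()
        snap["measurements"] = self._conn.execute(
            "SELECT experiment_id, sample_name, key, value FROM measurement "
            "ORDER BY experiment_id, sample_name, key"
        ).fetchall()
        snap["mappings"] = self._conn.execute(
            "SELECT platform_id, method, aligner, sensitivity, specificity FROM mapping "
            "ORDER BY id"
        ).fetchall()
        snap["mapping_entries"] = self._conn.execute(
            "SELECT mapping_id, reporter_id, feature_id FROM mapping_entry "
            "ORDER BY mapping_id, reporter_id"
        ).fetchall()
        return snap

    def content_digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True, default=str).encode()
        ).hexdigest()


def create_compendium(name: str, storage_path: str | Path) -> Compendium:
    """Create a new, empty compendium at ``storage_path``.

    The path must not already hold a compendium.  Raises OSError if the
    location is not writable.
    """
    path = Path(storage_path)
    if (path / MANIFEST_NAME).exists():
        raise StoreError(f"a compendium already exists at {path}")
    path.mkdir(parents=True, exist_ok=True)
    c = Compendium(path, name)
    c._conn.executescript(_SCHEMA)
    c._conn.commit()
    c._write_manifest()
    c.log("info", "compendium", f"created compendium {name!r}")
    return c


def open_compendium(storage_path: str | Path) -> Compendium:
    path = Path(storage_path)
    manifest_file = path / MANIFEST_NAME
    if not manifest_file.exists():
        raise StoreError(f"no compendium at {path}")
    manifest = json.loads(manifest_file.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise StoreError(
            f"schema version mismatch: store has {manifest.get('schema_version')}, "
            f"this library expects {SCHEMA_VERSION}"
        )
    return Compendium(path, manifest["name"])
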