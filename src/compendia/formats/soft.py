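"""GEO SOFT family-file parsing.

SOFT is GEO's line-oriented format: ``^ENTITY = id`` opens an entity
(SERIES, PLATFORM or SAMPLE), ``!Key = value`` lines attach attributes,
``#Column = description`` lines describe data-table columns, and a
tab-delimited table may follow between ``!<entity>_table_begin`` and
``!<entity>_table_end`` with a header row.

The reader is tolerant by default: unknown line prefixes and unknown entity
kinds are skipped with a warning (GEO files in the wild vary); ``strict=True``
turns those into errors.  Repeated attribute keys accumulate into a list,
as GEO does with e.g. ``!Sample_characteristics_ch1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Optional, Union

MetaValue = Union[str, list[str]]


class SoftParseError(ValueError):
    """Malformed SOFT input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class SoftEntity:
    """One ^SERIES / ^PLATFORM / ^SAMPLE block."""

    kind: str
    id: str
    metadata: dict[str, MetaValue] = field(default_factory=dict)
    columns: dict[str, str] = field(default_factory=dict)
    table: Optional[tuple[list[str], list[list[str]]]] = None

    def add_attribute(self, key: str, value: str) -> None:
        if key in self.metadata:
            existing = self.metadata[key]
            if isinstance(existing, list):
                existing.append(value)
            else:
                self.metadata[key] = [existing, value]
        else:
            self.metadata[key] = value


@dataclass
class SoftDocument:
    series: Optional[SoftEntity] = None
    platforms: list[SoftEntity] = field(default_factory=list)
    samples: list[SoftEntity] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def entities(self) -> list[SoftEntity]:
        out = [self.series] if self.series else []
        return out + self.platforms + self.samples


_KNOWN_KINDS = {"SERIES", "PLATFORM", "SAMPLE"}


def parse_soft(stream: IO[str], strict: bool = False) -> SoftDocument:
    """Parse a SOFT family file into its series/platform/sample entities.

    Tables are returned as ``(header, rows)`` with all cells as strings;
    entity order follows file order.  A ``table_begin`` without a matching
    ``table_end`` is an error carrying the line number.
    """
    doc = SoftDocument()
    entity: Optional[SoftEntity] = None
    table_rows: Optional[list[list[str]]] = None
    table_start_line = 0

    def warn(msg: str, lineno: int) -> None:
        if strict:
            raise SoftParseError(msg, lineno)
        doc.warnings.append(f"line {lineno}: {msg}")

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if table_rows is not None:
            assert entity is not None
            if line.startswith("!") and line.lower().endswith("_table_end"):
                if line.lower() != f"!{entity.kind.lower()}_table_end":
                    # mismatched entity name on the end marker; accept tolerantly
                    warn(f"table_end marker {line!r} does not match entity kind", lineno)
                if table_rows:
                    header, *rows = table_rows
                    entity.table = (header, rows)
                else:
                    warn("empty data table", lineno)
                    entity.table = ([], [])
                table_rows = None
                continue
            table_rows.append(line.split("\t"))
            continue

        if not line.strip():
            continue
        if line.startswith("^"):
            if "=" not in line:
                warn(f"malformed entity line {line!r}", lineno)
                continue
            kind, _, eid = line[1:].partition("=")
            kind = kind.strip().upper()
            eid = eid.strip()
            if kind not in _KNOWN_KINDS:
                warn(f"unknown entity kind {kind!r}", lineno)
                entity = None
                continue
            entity = SoftEntity(kind=kind, id=eid)
            if kind == "SERIES":
                if doc.series is not None:
                    warn("multiple ^SERIES entities; keeping the first", lineno)
                else:
                    doc.series = entity
            elif kind == "PLATFORM":
                doc.platforms.append(entity)
            else:
                doc.samples.append(entity)
        elif line.startswith("!"):
            if entity is None:
                warn(f"attribute line outside any entity: {line!r}", lineno)
                continue
            if line.lower() == f"!{entity.kind.lower()}_table_begin":
                table_rows = []
                table_start_line = lineno
                continue
            if "=" not in line:
                warn(f"malformed attribute line {line!r}", lineno)
                continue
            key, _, value = line[1:].partition("=")
            entity.add_attribute(key.strip(), value.strip())
        elif line.startswith("#"):
            if entity is None:
                warn(f"column descriptor outside any entity: {line!r}", lineno)
                continue
            if "=" not in line:
                warn(f"malformed column descriptor {line!r}", lineno)
                continue
            col, _, desc = line[1:].partition("=")
            entity.columns[col.strip()] = desc.strip()
        else:
            warn(f"unknown line prefix: {line[:20]!r}", lineno)

    if table_rows is not None:
        raise SoftParseError(
            "table_begin without matching table_end", table_start_line
        )
    return doc
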