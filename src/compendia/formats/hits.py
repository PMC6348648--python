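"""12-column BLAST tabular ("outfmt 6") alignment-hit I/O.

Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
send evalue bitscore.  Coordinates are 1-based inclusive; a subject start
greater than the subject end marks a minus-strand hit.  ``#``-prefixed
comment lines are allowed and skipped.
"""

from __future__ import annotations

from typing import IO, Iterable

from ..model import AlignmentHit, ValidationError


class HitFormatError(ValueError):
    pass


N_COLUMNS = 12


def read_alignment_hits(stream: IO[str]) -> list[AlignmentHit]:
    """Read tabular hits in file order; wrong column counts are errors with
    the offending line number."""
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != N_COLUMNS:
            raise HitFormatError(
                f"line {lineno}: expected {N_COLUMNS} tab-separated columns, "
                f"got {len(cols)}"
            )
        try:
            hit = AlignmentHit(
                probe_id=cols[0],
                feature_id=cols[1],
                identity_pct=float(cols[2]),
                alignment_length=int(cols[3]),
                mismatches=int(cols[4]),
                gap_opens=int(cols[5]),
                probe_start=int(cols[6]),
                probe_end=int(cols[7]),
                feature_start=int(cols[8]),
                feature_end=int(cols[9]),
                evalue=float(cols[10]),
                bit_score=float(cols[11]),
            )
        except (ValueError, ValidationError) as exc:
            raise HitFormatError(f"line {lineno}: {exc}")
        hits.append(hit)
    return hits


def write_alignment_hits(hits: Iterable[AlignmentHit], stream: IO[str]) -> None:
    """Serialize hits in the same 12-column dialect (identity to 2 decimals,
    e-value in scientific notation, bit score to 1 decimal)."""
    for h in hits:
        stream.write(
            "\t".join(
                (
                    h.probe_id,
                    h.feature_id,
                    f"{h.identity_pct:.2f}",
                    str(h.alignment_length),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.probe_start),
                    str(h.probe_end),
                    str(h.feature_start),
                    str(h.feature_end),
                    f"{h.evalue:.2g}",
                    f"{h.bit_score:.1f}",
                )
            )
            + "\n"
        )
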