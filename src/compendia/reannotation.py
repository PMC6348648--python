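"""Probe-to-gene mapping: alignment and two-step hit filtering.

Microarray probes are re-annotated against the compendium's genomic
background rather than trusted to the manufacturer annotation.  The process
has two parts:

1. **Alignment** — every probe is aligned against every gene sequence.
   :func:`align_probes` is an exhaustive ungapped scanner: it reports every
   full-probe-length placement on either strand of any gene with at most a
   caller-set number of mismatches.  This is the short-oligo regime
   (25-60 nt probes), where gapped alignment adds nothing; hit files produced
   by an external aligner such as BLAST+ can be fed to the same filters via
   the tabular-hit reader, which also covers the gapped case.

2. **Two-step filtering** — a lenient *sensitivity* threshold first exposes
   cross-hybridization: any probe with more than one surviving placement is
   discarded as ambiguous.  The strict *specificity* threshold then requires
   the single surviving placement of each remaining probe to be of high
   quality.  A single-threshold filter cannot achieve both goals at once:
   set it low and multi-site probes slip through as "unique"; set it high
   and genuinely good probes just under the bar are lost.

Filtering is pure: re-running on the same hit list gives an identical
report, so thresholds can be explored cheaply without re-aligning.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import (
    AlignmentHit,
    BioFeature,
    FilterReport,
    FilterThreshold,
    MappingMethod,
    MappingProvenance,
    Reporter,
    ReporterMapping,
    TwoStepConfig,
    ValidationError,
)

__all__ = [
    "align_probes",
    "hit_passes",
    "single_step_filter",
    "two_step_filter",
    "manual_map",
    "probe_lengths_of",
    "write_mapping",
    "read_mapping",
    "BUILTIN_ALIGNER",
]

BUILTIN_ALIGNER = "compendia-ungapped-scan"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# 'N' encodes to 4, which one-hot encodes to the zero vector on both sides,
# so an N in probe or gene never matches anything (counts as a mismatch).
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def _one_hot(encoded: np.ndarray) -> np.ndarray:
    """(n, L) codes in {0..4} -> (n, 4L) float32 one-hot (N rows all-zero)."""
    n, L = encoded.shape
    out = np.zeros((n, L, 5), dtype=np.float32)
    idx = np.arange(n)[:, None], np.arange(L)[None, :], encoded
    out[idx] = 1.0
    return out[:, :, :4].reshape(n, 4 * L)


def probe_lengths_of(reporters: Iterable[Reporter]) -> dict[str, Optional[int]]:
    """Probe-length map for the filters; None marks a probe with no sequence
    (it can never align and is reported as unaligned)."""
    return {r.id: (len(r.sequence) if r.sequence else None) for r in reporters}


def align_probes(
    reporters: Sequence[Reporter],
    features: Sequence[BioFeature],
    max_mismatches: int = 5,
    batch_size: int = 256,
) -> list[AlignmentHit]:
    """Exhaustively align probes against both strands of every feature.

    Every ungapped, full-probe-length placement with at most
    ``max_mismatches`` mismatches is reported, so the hit list is complete up
    to that ceiling — there is no heuristic seeding step to miss a hit.  The
    default ceiling (5) leaves headroom above the stock sensitivity threshold
    (3 mismatches) so filter thresholds can be explored without re-aligning.

    Hits carry identity = 100*(L - mismatches)/L, alignment_length = probe
    length, and 1-based inclusive coordinates with feature_start >
    feature_end on the minus strand.  Output is sorted by (probe id,
    descending identity), ties broken by feature id and position.  Probes
    without a sequence are skipped (they surface as unaligned downstream).
    """
    if not features:
        raise ValidationError("empty genomic background: nothing to align against")
    aligned = [r for r in reporters if r.sequence]

    # windows of each probe length over both strands of every feature,
    # built once per distinct length
    feat_seqs = [(f.id, f.sequence) for f in features]
    hits: list[AlignmentHit] = []

    by_len: dict[int, list[Reporter]] = {}
    for r in aligned:
        by_len.setdefault(len(r.sequence), []).append(r)

    for L, group in sorted(by_len.items()):
        window_onehot, window_info = _build_windows(feat_seqs, L)
        if window_onehot.shape[0] == 0:
            continue
        for start in range(0, len(group), batch_size):
            batch = group[start : start + batch_size]
            codes = np.stack(
                [_ENCODE[np.frombuffer(r.sequence.encode(), dtype=np.uint8)] for r in batch]
            )
            probe_onehot = _one_hot(codes)
            # matches[w, p] = number of identical bases of window w vs probe p
            matches = window_onehot @ probe_onehot.T
            ok_w, ok_p = np.nonzero(matches >= L - max_mismatches)
            for w, p in zip(ok_w.tolist(), ok_p.tolist()):
                fid, flen, strand, pos = window_info[w]
                mm = L - int(round(matches[w, p]))
                if strand == "+":
                    fstart, fend = pos + 1, pos + L
                else:
                    fstart, fend = flen - pos, flen - pos - L + 1
                hits.append(
                    AlignmentHit(
                        probe_id=batch[p].id,
                        feature_id=fid,
                        identity_pct=100.0 * (L - mm) / L,
                        alignment_length=L,
                        mismatches=mm,
                        gap_opens=0,
                        probe_start=1,
                        probe_end=L,
                        feature_start=fstart,
                        feature_end=fend,
                        evalue=0.0,
                        bit_score=2.0 * (L - mm),
                    )
                )
    hits.sort(
        key=lambda h: (
            h.probe_id,
            -h.identity_pct,
            h.feature_id,
            min(h.feature_start, h.feature_end),
            h.strand,
        )
    )
    return hits


def _build_windows(
    feat_seqs: list[tuple[str, str]], L: int
) -> tuple[np.ndarray, list[tuple[str, int, str, int]]]:
    """One-hot matrix of all length-L windows over both strands, plus
    (feature_id, feature_len, strand, 0-based window start on that strand)
    bookkeeping per row."""
    blocks: list[np.ndarray] = []
    info: list[tuple[str, int, str, int]] = []
    for fid, seq in feat_seqs:
        n = len(seq)
        if n < L:
            continue
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            codes = _ENCODE[np.frombuffer(s.encode(), dtype=np.uint8)]
            win = np.lib.stride_tricks.sliding_window_view(codes, L)
            blocks.append(_one_hot(np.ascontiguousarray(win)))
            info.extend((fid, n, strand, q) for q in range(n - L + 1))
    if not blocks:
        return np.zeros((0, 4 * L), dtype=np.float32), info
    return np.concatenate(blocks, axis=0), info


# ---------------------------------------------------------------------------
# filtering


def hit_passes(hit: AlignmentHit, probe_length: int, threshold: FilterThreshold) -> bool:
    """One hit against one acceptance criterion."""
    if probe_length < 1:
        raise ValidationError("probe_length must be >= 1")
    return (
        hit.alignment_length / probe_length >= threshold.min_len_frac
        and hit.gap_opens <= threshold.max_gap_opens
        and hit.mismatches <= threshold.max_mismatches
        and hit.identity_pct >= threshold.min_identity_pct
    )


def _group_hits(
    hits: Iterable[AlignmentHit], probe_lengths: Mapping[str, Optional[int]]
) -> dict[str, list[AlignmentHit]]:
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.probe_id not in probe_lengths:
            raise ValidationError(
                f"hit for unknown probe {h.probe_id!r}: not in probe_lengths"
            )
        grouped.setdefault(h.probe_id, []).append(h)
    return grouped


def _surviving_locations(
    probe_hits: list[AlignmentHit],
    probe_length: int,
    threshold: FilterThreshold,
    unique_per_gene: bool,
) -> dict:
    """Deduplicated passing hits keyed by location (best hit per location)."""
    best: dict = {}
    for h in probe_hits:
        if not hit_passes(h, probe_length, threshold):
            continue
        key = h.feature_id if unique_per_gene else h.location()
        prev = best.get(key)
        if prev is None or (h.identity_pct, h.bit_score) > (prev.identity_pct, prev.bit_score):
            best[key] = h
    return best


def single_step_filter(
    hits: Iterable[AlignmentHit],
    probe_lengths: Mapping[str, Optional[int]],
    threshold: FilterThreshold,
    unique_per_gene: bool = False,
) -> FilterReport:
    """Classic one-threshold filtering.

    Per probe: hits passing the threshold are deduplicated by location;
    exactly one surviving location retains the probe, several discard it as
    ambiguous, none (with at least one input hit) discards it as low
    quality; probes with no hits at all are unaligned.

    ``unique_per_gene=True`` counts distinct *genes* instead of distinct
    placements, so a probe hitting one gene twice still counts as unique.
    """
    grouped = _group_hits(hits, probe_lengths)
    report = FilterReport()
    for probe_id in sorted(probe_lengths):
        length = probe_lengths[probe_id]
        probe_hits = grouped.get(probe_id, [])
        if length is None or not probe_hits:
            report.unaligned.append(probe_id)
            continue
        surviving = _surviving_locations(probe_hits, length, threshold, unique_per_gene)
        if len(surviving) == 1:
            (best,) = surviving.values()
            report.retained.append((probe_id, best.feature_id))
        elif len(surviving) > 1:
            report.discarded_ambiguous.append(probe_id)
        else:
            report.discarded_low_quality.append(probe_id)
    return report


def two_step_filter(
    hits: Iterable[AlignmentHit],
    probe_lengths: Mapping[str, Optional[int]],
    config: TwoStepConfig,
    platform_id: str = "",
    aligner: str = BUILTIN_ALIGNER,
    unique_per_gene: bool = False,
) -> tuple[ReporterMapping, FilterReport]:
    """Sensitivity-then-specificity filtering.

    Step 1 applies the lenient sensitivity threshold per probe and discards
    as ambiguous every probe with more than one surviving distinct location —
    this is where cross-hybridizing probes are caught, because the lenient
    threshold keeps their secondary placements visible.  Step 2 retains a
    step-1-unique probe only if its single surviving hit also passes the
    strict specificity threshold; otherwise the probe is discarded as low
    quality.  The returned mapping records both thresholds in its
    provenance, making the re-annotation reproducible.
    """
    # TwoStepConfig construction already validated sensitivity <= specificity
    grouped = _group_hits(hits, probe_lengths)
    report = FilterReport()
    for probe_id in sorted(probe_lengths):
        length = probe_lengths[probe_id]
        probe_hits = grouped.get(probe_id, [])
        if length is None or not probe_hits:
            report.unaligned.append(probe_id)
            continue
        surviving = _surviving_locations(
            probe_hits, length, config.sensitivity, unique_per_gene
        )
        if len(surviving) > 1:
            report.discarded_ambiguous.append(probe_id)
            continue
        if len(surviving) == 0:
            report.discarded_low_quality.append(probe_id)
            continue
        (best,) = surviving.values()
        if hit_passes(best, length, config.specificity):
            report.retained.append((probe_id, best.feature_id))
        else:
            report.discarded_low_quality.append(probe_id)
    mapping = ReporterMapping(
        platform_id=platform_id,
        entries=list(report.retained),
        provenance=MappingProvenance(
            method=MappingMethod.two_step_filter,
            aligner=aligner,
            sensitivity=config.sensitivity,
            specificity=config.specificity,
        ),
    )
    return mapping, report


def manual_map(
    pairs: Sequence[tuple[str, str]],
    reporter_ids: Optional[set[str]] = None,
    feature_ids: Optional[set[str]] = None,
    platform_id: str = "",
) -> ReporterMapping:
    """Manual probe-to-gene association (e.g. from manufacturer annotation).

    Many probes may map to one gene, but a probe may appear only once.  When
    id universes are given, unknown ids are lookup errors.
    """
    seen: set[str] = set()
    for rid, fid in pairs:
        if rid in seen:
            raise ValidationError(f"reporter {rid!r} mapped to more than one feature")
        seen.add(rid)
        if reporter_ids is not None and rid not in reporter_ids:
            raise ValidationError(f"unknown reporter id {rid!r}")
        if feature_ids is not None and fid not in feature_ids:
            raise ValidationError(f"unknown feature id {fid!r}")
    return ReporterMapping(
        platform_id=platform_id,
        entries=sorted(pairs),
        provenance=MappingProvenance(method=MappingMethod.manual),
    )


def write_mapping(mapping: ReporterMapping, tsv_path, sidecar_path=None) -> None:
    """Export a mapping as 2-column TSV (reporter_id, feature_id) plus a JSON
    provenance sidecar (defaults to ``<tsv>.provenance.json``)."""
    import json
    from pathlib import Path

    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        fh.write("reporter_id\tfeature_id\n")
        for rid, fid in mapping.entries:
            fh.write(f"{rid}\t{fid}\n")
    prov = mapping.provenance
    sidecar = {
        "platform_id": mapping.platform_id,
        "method": prov.method.value,
        "aligner": prov.aligner,
        "sensitivity": prov.sensitivity.to_dict() if prov.sensitivity else None,
        "specificity": prov.specificity.to_dict() if prov.specificity else None,
        "timestamp": prov.timestamp,
        "n_entries": len(mapping.entries),
    }
    sidecar_path = (
        Path(sidecar_path)
        if sidecar_path is not None
        else tsv_path.with_suffix(tsv_path.suffix + ".provenance.json")
    )
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")


def read_mapping(tsv_path, sidecar_path=None) -> ReporterMapping:
    """Load a mapping exported by :func:`write_mapping`."""
    import json
    from pathlib import Path

    tsv_path = Path(tsv_path)
    entries: list[tuple[str, str]] = []
    with open(tsv_path) as fh:
        header = fh.readline()
        if header.strip() != "reporter_id\tfeature_id":
            raise ValidationError(f"unexpected mapping header: {header!r}")
        for line in fh:
            rid, _, fid = line.rstrip("\n").partition("\t")
            entries.append((rid, fid))
    sidecar_path = (
        Path(sidecar_path)
        if sidecar_path is not None
        else tsv_path.with_suffix(tsv_path.suffix + ".provenance.json")
    )
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        prov = MappingProvenance(
            method=MappingMethod(side["method"]),
            aligner=side.get("aligner", ""),
            sensitivity=FilterThreshold.from_dict(side["sensitivity"])
            if side.get("sensitivity")
            else None,
            specificity=FilterThreshold.from_dict(side["specificity"])
            if side.get("specificity")
            else None,
            timestamp=side.get("timestamp", ""),
        )
        platform_id = side.get("platform_id", "")
    else:
        prov = MappingProvenance(method=MappingMethod.manual)
        platform_id = ""
    return ReporterMapping(platform_id=platform_id, entries=entries, provenance=prov)
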