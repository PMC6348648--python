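"""FASTA reading for the genomic background."""

from __future__ import annotations

from typing import IO

from Bio.SeqIO.FastaIO import SimpleFastaParser

from ..model import BioFeature, ValidationError


def parse_fasta(stream: IO[str]) -> list[BioFeature]:
    """Read gene sequences into BioFeatures.

    The record id is the header token up to the first whitespace; the rest of
    the header becomes the description.  Sequences are normalized (upper-case,
    U->T, line joins removed); characters outside A/C/G/T/N raise an error
    naming the record.  An empty file yields an empty list.
    """
    text = stream.read()
    head = text.lstrip()
    if head and not head.startswith(">"):
        raise ValidationError("FASTA: content before first '>' header")
    features: list[BioFeature] = []
    import io

    for header, seq in SimpleFastaParser(io.StringIO(text)):
        parts = header.split(None, 1)
        if not parts:
            raise ValidationError(f"FASTA record {len(features) + 1}: empty header")
        fid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        features.append(BioFeature(id=fid, sequence=seq, description=desc))
    return features
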