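"""Transcript sequence construction and haplotype editing."""

from __future__ import annotations

from typing import List, Sequence, Tuple

from Bio.Seq import Seq

from .models import (
    CoordinateError,
    FusedTranscript,
    FusionJoin,
    GenomeSequence,
    RefMismatchError,
    TranscriptModel,
)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_transcript_sequence(genome: GenomeSequence, tx: TranscriptModel) -> str:
    """Spliced transcript sequence in 5'->3' transcript orientation."""
    if tx.contig_id != genome.contig_id:
        raise CoordinateError(
            f"transcript {tx.transcript_id} on {tx.contig_id}, genome is {genome.contig_id}"
        )
    parts = [genome.fetch(s, e) for s, e in tx.exons]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return seq


def inject_haplotype(
    tx_sequence: str, edits: Sequence[Tuple[int, str, str]]
) -> str:
    """Apply transcript-relative (position, ref, alt) edits to a sequence.

    Edits must be sorted by position and non-overlapping; they are applied
    right-to-left so that indels do not invalidate downstream coordinates.
    """
    prev_end = None
    for pos, ref, alt in edits:
        if not ref or not alt:
            raise ValueError("edit alleles must be non-empty")
        if prev_end is not None and pos < prev_end:
            raise ValueError(f"overlapping or unsorted edits at position {pos}")
        prev_end = pos + len(ref)
        if pos < 0 or pos + len(ref) > len(tx_sequence):
            raise CoordinateError(f"edit at {pos} outside sequence of length {len(tx_sequence)}")
        if tx_sequence[pos : pos + len(ref)] != ref:
            raise RefMismatchError(
                f"ref allele {ref!r} does not match sequence "
                f"{tx_sequence[pos:pos + len(ref)]!r} at position {pos}"
            )
    out = tx_sequence
    for pos, ref, alt in reversed(list(edits)):
        out = out[:pos] + alt + out[pos + len(ref):]
    return out


def build_readthrough_transcript(
    donor: TranscriptModel,
    donor_sequence: str,
    acceptor: TranscriptModel,
    acceptor_sequence: str,
    join: FusionJoin,
    fused_id: str | None = None,
) -> FusedTranscript:
    """Assemble a readthrough fusion: donor 5' segment spliced onto acceptor 3' segment.

    The fused sequence is ``donor[0:donor_break] + acceptor[acceptor_start:]``.
    The exon-junction list (needed for decay classification) keeps donor
    junctions upstream of the break, adds the fusion junction itself, and
    shifts acceptor junctions downstream of ``acceptor_start``.
    """
    if donor.contig_id != acceptor.contig_id:
        raise ValueError("cross-contig fusion joins are unsupported")
    if donor.strand != acceptor.strand:
        raise ValueError("cross-strand fusion joins are unsupported")
    if not 0 < join.donor_break <= len(donor_sequence):
        raise CoordinateError(f"donor_break {join.donor_break} outside donor transcript")
    if not 0 <= join.acceptor_start < len(acceptor_sequence):
        raise CoordinateError(f"acceptor_start {join.acceptor_start} outside acceptor transcript")

    sequence = donor_sequence[: join.donor_break] + acceptor_sequence[join.acceptor_start:]
    junctions: List[int] = [j for j in donor.exon_junctions if j < join.donor_break]
    junctions.append(join.donor_break)
    for j in acceptor.exon_junctions:
        if j > join.acceptor_start:
            junctions.append(join.donor_break + (j - join.acceptor_start))

    cds_start = None
    if donor.cds_span is not None and donor.cds_span[0] < join.donor_break:
        cds_start = donor.cds_span[0]

    return FusedTranscript(
        transcript_id=fused_id or f"{donor.transcript_id}--{acceptor.transcript_id}",
        sequence=sequence,
        junction_offset=join.donor_break,
        exon_junctions=tuple(junctions),
        donor_transcript_id=donor.transcript_id,
        acceptor_transcript_id=acceptor.transcript_id,
        cds_start=cds_start,
    )
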