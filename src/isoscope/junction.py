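"""Fusion junction probes: extraction, uniqueness screening, read counting."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .locus_model.sequence import reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 20
DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MIN_OVERLAP = 10


@dataclass
class ProbeHit:
    sequence_id: str
    offset: int
    strand: str
    mismatches: int


@dataclass
class JunctionProbe:
    fused_transcript_id: str
    junction_offset: int
    flank: int
    probe_sequence: str
    uniqueness: str = "unknown"  # unique | non-unique | unknown
    hits: List[ProbeHit] = field(default_factory=list)


def extract_probe(
    fused_sequence: str,
    junction_offset: int,
    flank: int = DEFAULT_FLANK,
    fused_transcript_id: str = "fusion",
) -> JunctionProbe:
    """Probe of ``flank`` bases on each side of the junction."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if flank > junction_offset or flank > len(fused_sequence) - junction_offset:
        raise ValueError(
            f"flank {flank} exceeds distance from junction {junction_offset} "
            f"to a transcript end (length {len(fused_sequence)})"
        )
    probe = fused_sequence[junction_offset - flank : junction_offset + flank]
    return JunctionProbe(
        fused_transcript_id=fused_transcript_id,
        junction_offset=junction_offset,
        flank=flank,
        probe_sequence=probe,
    )


def _window_mismatches(probe: np.ndarray, seq: str) -> np.ndarray:
    """Hamming distance of the probe to every window of ``seq``."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if arr.size < probe.size:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, probe.size)
    return (windows != probe).sum(axis=1)


def screen_uniqueness(
    probe: JunctionProbe,
    background: Sequence[Tuple[str, str]],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> JunctionProbe:
    """Exhaustive Hamming scan of the probe over a background transcriptome.

    Every window of every background sequence and its reverse complement is
    compared; hits within ``max_mismatches`` are recorded.  The probe is
    unique when all hits fall on the fusion transcript itself.
    """
    if not background:
        raise ValueError("background transcript set is empty")
    parr = np.frombuffer(probe.probe_sequence.encode("ascii"), dtype=np.uint8)
    hits: List[ProbeHit] = []
    for seq_id, seq in background:
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            mism = _window_mismatches(parr, oriented)
            for off in np.nonzero(mism <= max_mismatches)[0].tolist():
                hits.append(ProbeHit(seq_id, off, strand, int(mism[off])))
    probe.hits = hits
    foreign = [h for h in hits if h.sequence_id != probe.fused_transcript_id]
    probe.uniqueness = "non-unique" if foreign else "unique"
    return probe


def count_junction_reads(
    reads: Iterable[Tuple[str, str]],
    probe: JunctionProbe,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatches: int = 0,
) -> Tuple[int, List[str]]:
    """Count reads whose match to the probe spans the junction.

    A read counts when some ungapped placement against the probe puts at
    least ``min_overlap`` read bases on each side of the junction with at
    most ``max_mismatches`` mismatches inside the overlap; each read counts
    at most once, trying both orientations.
    """
    if min_overlap > probe.flank:
        raise ValueError(
            f"min_overlap {min_overlap} exceeds probe flank {probe.flank}"
        )
    if probe.uniqueness != "unique":
        logger.warning(
            "counting junction reads with probe uniqueness %r", probe.uniqueness
        )
    plen = 2 * probe.flank
    parr = np.frombuffer(probe.probe_sequence.encode("ascii"), dtype=np.uint8)
    counted: List[str] = []
    for name, seq in reads:
        matched = False
        for oriented in (seq, reverse_complement(seq)):
            rarr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
            rlen = rarr.size
            # o = offset of probe start in read coordinates (may be negative)
            for o in range(-(plen - 1), rlen):
                lo = max(0, o)          # overlap start in read coords
                hi = min(rlen, o + plen)
                if hi <= lo:
                    continue
                junction_in_read = o + probe.flank
                left = junction_in_read - lo
                right = hi - junction_in_read
                if left < min_overlap or right < min_overlap:
                    continue
                mism = int((rarr[lo:hi] != parr[lo - o : hi - o]).sum())
                if mism <= max_mismatches:
                    matched = True
                    break
            if matched:
                break
        if matched:
            counted.append(name)
    return len(counted), counted
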