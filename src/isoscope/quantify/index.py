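"""k-mer index over a (haplotype-augmented) transcript set."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .kmers import encode_kmers

logger = logging.getLogger(__name__)

DEFAULT_K = 31


@dataclass(frozen=True)
class TranscriptSeq:
    """One indexable sequence: a transcript or a haplotype copy of one."""

    transcript_id: str
    gene_id: str
    sequence: str


@dataclass
class KmerIndex:
    k: int
    transcript_ids: List[str]
    gene_ids: List[str]
    lengths: List[int]
    effective_lengths: List[float]
    #: kmer code -> id into class_members
    kmer_to_class: Dict[int, int] = field(repr=False)
    #: class id -> sorted tuple of transcript indices
    class_members: List[Tuple[int, ...]] = field(repr=False)
    #: number of k-mer window positions per indexed transcript
    kmer_positions: List[int] = field(default_factory=list, repr=False)

    def tx_index(self, transcript_id: str) -> int:
        return self.transcript_ids.index(transcript_id)


def effective_length(length: int, mean_fragment_length: float) -> float:
    return max(length - mean_fragment_length + 1.0, 1.0)


def build_index(
    transcripts: Sequence[TranscriptSeq],
    k: int = DEFAULT_K,
    mean_fragment_length: Optional[float] = None,
) -> KmerIndex:
    """Build the complete k-mer -> transcript-set mapping.

    Sequences shorter than k are skipped with a warning.  ``mean_fragment_length``
    (default: read length, supplied at assignment time via
    :func:`set_effective_lengths`; here it defaults to k) controls effective
    lengths used for TPM.
    """
    ids: List[str] = []
    genes: List[str] = []
    lengths: List[int] = []
    positions: List[int] = []
    kept: List[TranscriptSeq] = []
    seen = set()
    for t in transcripts:
        if t.transcript_id in seen:
            raise ValueError(f"duplicate transcript id {t.transcript_id!r}")
        seen.add(t.transcript_id)
        if len(t.sequence) < k:
            logger.warning(
                "skipping %s: length %d < k=%d", t.transcript_id, len(t.sequence), k
            )
            continue
        kept.append(t)
        ids.append(t.transcript_id)
        genes.append(t.gene_id)
        lengths.append(len(t.sequence))
        positions.append(len(t.sequence) - k + 1)

    kmer_sets: Dict[int, set] = {}
    for idx, t in enumerate(kept):
        for code in set(encode_kmers(t.sequence, k).tolist()):
            kmer_sets.setdefault(code, set()).add(idx)

    class_ids: Dict[Tuple[int, ...], int] = {}
    members: List[Tuple[int, ...]] = []
    kmer_to_class: Dict[int, int] = {}
    for code, txs in kmer_sets.items():
        key = tuple(sorted(txs))
        cid = class_ids.get(key)
        if cid is None:
            cid = len(members)
            class_ids[key] = cid
            members.append(key)
        kmer_to_class[code] = cid

    mfl = mean_fragment_length if mean_fragment_length is not None else float(k)
    eff = [effective_length(ln, mfl) for ln in lengths]
    return KmerIndex(
        k=k,
        transcript_ids=ids,
        gene_ids=genes,
        lengths=lengths,
        effective_lengths=eff,
        kmer_to_class=kmer_to_class,
        class_members=members,
        kmer_positions=positions,
    )


def set_effective_lengths(index: KmerIndex, mean_fragment_length: float) -> None:
    index.effective_lengths = [
        effective_length(ln, mean_fragment_length) for ln in index.lengths
    ]
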