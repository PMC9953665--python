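"""Preproinsulin-style chain renumbering and protein motif helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Tuple

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: region -> 1-based inclusive interval on the precursor protein
DEFAULT_CHAIN_SPANS: Dict[str, Tuple[int, int]] = {
    "signal": (1, 24),
    "B": (25, 54),
    "BC_link": (55, 56),
    "C": (57, 87),
    "CA_link": (88, 89),
    "A": (90, 110),
}


@dataclass(frozen=True)
class ChainMap:
    """Mapping from precursor (preproinsulin) numbering to chain-local numbering."""

    spans: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CHAIN_SPANS)
    )

    def __post_init__(self) -> None:
        prev_end = 0
        for label, (start, end) in self.spans.items():
            if start != prev_end + 1:
                raise ValueError(
                    f"chain spans must be contiguous and ordered; gap before {label!r}"
                )
            if end < start:
                raise ValueError(f"inverted span for {label!r}")
            prev_end = end

    @property
    def total_length(self) -> int:
        return max(end for _, end in self.spans.values())

    def prepro_to_chain(self, position: int) -> Tuple[str, int]:
        """1-based precursor index -> (region label, chain-local 1-based index)."""
        if not 1 <= position <= self.total_length:
            raise ValueError(
                f"position {position} outside precursor range 1..{self.total_length}"
            )
        for label, (start, end) in self.spans.items():
            if start <= position <= end:
                return label, position - start + 1
        raise AssertionError("unreachable: spans cover the full range")

    def chain_to_prepro(self, label: str, local_index: int) -> int:
        """Inverse of :meth:`prepro_to_chain`."""
        start, end = self.spans[label]
        pos = start + local_index - 1
        if not start <= pos <= end:
            raise ValueError(f"{label}{local_index} outside span {start}-{end}")
        return pos


def prepro_to_chain(position: int, chain_map: ChainMap | None = None) -> Tuple[str, int]:
    return (chain_map or ChainMap()).prepro_to_chain(position)


def find_dibasic_sites(protein: str) -> List[int]:
    """1-based start positions of adjacent K/R pairs; overlapping pairs all reported."""
    basic = {"K", "R"}
    return [
        i + 1
        for i in range(len(protein) - 1)
        if protein[i] in basic and protein[i + 1] in basic
    ]


def longest_common_nterminal_prefix(protein_a: str, protein_b: str) -> int:
    """Length of the maximal identical leading run of two protein sequences."""
    n = 0
    for a, b in zip(protein_a, protein_b):
        if a != b:
            break
        n += 1
    return n


def canonical_preproinsulin() -> str:
    """The bundled canonical human preproinsulin sequence (110 aa).

    Loaded from a plain-text FASTA fixture shipped with the package; see the
    fixture header for provenance.
    """
    text = resources.files("isoscope.data").joinpath("preproinsulin.fasta").read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith(">")]
    return "".join(lines)
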