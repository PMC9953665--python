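"""Per-column MSA conservation relative to a reference row.

Percent identity is computed per ungapped-reference column over all rows
(including the reference itself, so the floor is 100/N, not 0); gaps and
ambiguity codes count as mismatches.  The digit bin is floor(percent/10)
capped at 9, closed at the top (90 and above bins to 9).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .locus_model.models import VariantRecord

GAP = "-"


@dataclass
class AlignmentMatrix:
    row_ids: List[str]
    rows: List[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows) or not self.rows:
            raise ValueError("row ids and rows must be non-empty and aligned")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("ragged alignment: rows differ in length")
        if self.reference_id not in self.row_ids:
            raise ValueError(f"reference row {self.reference_id!r} missing")

    @property
    def reference_row(self) -> str:
        return self.rows[self.row_ids.index(self.reference_id)]


def read_alignment_fasta(path: str | os.PathLike, reference_id: str) -> AlignmentMatrix:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return AlignmentMatrix(row_ids=ids, rows=rows, reference_id=reference_id)


def conservation_digit(percent: float) -> int:
    """floor(percent/10) with 100 -> 9 (the top bin is closed: 90..100 -> 9)."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent {percent} outside [0, 100]")
    return min(int(percent // 10), 9)


def column_conservation(
    aln: AlignmentMatrix, include_reference: bool = True
) -> pd.DataFrame:
    """Per ungapped-reference position percent identity and digit bin.

    Returns a DataFrame with columns ref_pos (0-based on the ungapped
    reference), ref_char, percent, digit.
    """
    ref = aln.reference_row
    if all(c == GAP for c in ref):
        raise ValueError("reference row has no non-gap characters")
    mat = np.array([list(r) for r in aln.rows])
    ref_idx = aln.row_ids.index(aln.reference_id)
    if not include_reference:
        keep = [i for i in range(mat.shape[0]) if i != ref_idx]
        denom_mat = mat[keep]
    else:
        denom_mat = mat
    n_rows = denom_mat.shape[0]

    records: List[Tuple[int, str, float, int]] = []
    ref_pos = 0
    for col in range(mat.shape[1]):
        c = ref[col]
        if c == GAP:
            continue
        matches = int((denom_mat[:, col] == c).sum())
        percent = 100.0 * matches / n_rows
        records.append((ref_pos, c, percent, conservation_digit(percent)))
        ref_pos += 1
    return pd.DataFrame(records, columns=["ref_pos", "ref_char", "percent", "digit"])


def variant_density(
    region: Tuple[int, int], variants: Sequence[VariantRecord]
) -> float:
    """Unique (position, ref, alt) variants inside [start, end) per base."""
    start, end = region
    if end <= start:
        raise ValueError("region length must be > 0")
    unique = {
        (v.position, v.ref_allele, v.alt_allele)
        for v in variants
        if start <= v.position < end
    }
    return len(unique) / (end - start)


def write_conservation_tsv(profile: pd.DataFrame, path: str | os.PathLike) -> None:
    profile.to_csv(path, sep="\t", index=False, lineterminator="\n")
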