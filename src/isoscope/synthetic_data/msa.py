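"""Seeded MSA generator with known per-column conservation probabilities."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from ..conservation import AlignmentMatrix
from .config import MsaSpec


def simulate_msa(spec: MsaSpec, seed: int) -> Tuple[AlignmentMatrix, List[float]]:
    """Reference row fixed; other rows match column j with probability p_j.

    Mismatching positions draw uniformly over the remaining alphabet
    characters.  Returns the alignment and the true column probabilities.
    """
    rng = np.random.default_rng([seed, 2])
    alphabet = np.array(list(spec.alphabet))
    if np.isscalar(spec.conservation):
        probs = [float(spec.conservation)] * spec.length
    else:
        probs = [float(p) for p in spec.conservation]
        if len(probs) != spec.length:
            raise ValueError("per-column probabilities must match spec.length")
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"conservation probability {p} outside [0,1]")

    ref = rng.choice(alphabet, size=spec.length)
    rows = [ref.copy()]
    ids = ["ref"]
    p_arr = np.array(probs)
    for r in range(spec.n_rows - 1):
        match = rng.random(spec.length) < p_arr
        row = ref.copy()
        for j in np.nonzero(~match)[0]:
            others = alphabet[alphabet != ref[j]]
            row[j] = others[int(rng.integers(0, len(others)))]
        rows.append(row)
        ids.append(f"row{r:03d}")
    aln = AlignmentMatrix(
        row_ids=ids, rows=["".join(r) for r in rows], reference_id="ref"
    )
    return aln, probs
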