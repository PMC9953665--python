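"""Read-to-class assignment and equivalence-class EM abundance estimation."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from ..locus_model.sequence import reverse_complement
from .index import KmerIndex
from .kmers import encode_kmers

DEFAULT_COMPAT_FRACTION = 0.8


class EmptyAbundanceError(ValueError):
    """All reads were unassigned; no abundance can be estimated."""


@dataclass
class EquivalenceClassCounts:
    counts: Dict[FrozenSet[int], int]
    unassigned: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unassigned


def _tx_match_counts(codes: List[int], index: KmerIndex) -> Dict[int, int]:
    class_hits: Counter = Counter()
    get = index.kmer_to_class.get
    for code in codes:
        cid = get(code)
        if cid is not None:
            class_hits[cid] += 1
    tx_counts: Dict[int, int] = {}
    members = index.class_members
    for cid, n in class_hits.items():
        for t in members[cid]:
            tx_counts[t] = tx_counts.get(t, 0) + n
    return tx_counts


def assign_read(
    seq: str, index: KmerIndex, compat_fraction: float = DEFAULT_COMPAT_FRACTION
) -> Optional[FrozenSet[int]]:
    """Equivalence class of one read, or None when unassigned.

    A read is compatible with transcript t when at least ``compat_fraction``
    of its k-mers occur in t; the read and its reverse complement are both
    evaluated and the better-supported orientation kept.
    """
    best: Optional[Dict[int, int]] = None
    best_n = 0
    best_max = -1
    for oriented in (seq, reverse_complement(seq)):
        codes = encode_kmers(oriented, index.k).tolist()
        if not codes:
            continue
        tx_counts = _tx_match_counts(codes, index)
        top = max(tx_counts.values(), default=0)
        if top > best_max:
            best, best_n, best_max = tx_counts, len(codes), top
    if best is None or best_n == 0:
        return None
    need = compat_fraction * best_n
    compatible = frozenset(t for t, n in best.items() if n >= need)
    return compatible or None


def assign_reads(
    reads: Iterable[str],
    index: KmerIndex,
    compat_fraction: float = DEFAULT_COMPAT_FRACTION,
) -> EquivalenceClassCounts:
    counts: Dict[FrozenSet[int], int] = {}
    unassigned = 0
    for seq in reads:
        cls = assign_read(seq, index, compat_fraction)
        if cls is None:
            unassigned += 1
        else:
            counts[cls] = counts.get(cls, 0) + 1
    return EquivalenceClassCounts(counts=counts, unassigned=unassigned)


@dataclass
class AbundanceTable:
    """Per-transcript estimates plus gene-level rollups."""

    table: pd.DataFrame  # columns: transcript_id, est_count, tpm, gene_id, pct_usage
    log_likelihoods: List[float] = field(default_factory=list)
    n_iterations: int = 0

    def tpm(self, transcript_id: str) -> float:
        return float(
            self.table.set_index("transcript_id").loc[transcript_id, "tpm"]
        )

    def gene_tpm(self, gene_id: str) -> float:
        return float(self.table.loc[self.table.gene_id == gene_id, "tpm"].sum())

    def pct_usage(self, transcript_id: str) -> float:
        return float(
            self.table.set_index("transcript_id").loc[transcript_id, "pct_usage"]
        )


def em_abundance(
    counts: EquivalenceClassCounts,
    index: KmerIndex,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> AbundanceTable:
    """EM over equivalence classes.

    Read-proportion parameters start uniform; each E step shares a class
    count among member transcripts proportionally to current proportions;
    convergence when the max absolute proportion change drops below ``tol``.
    TPM derives from count/effective_length rates normalized to 1e6.
    """
    n_tx = len(index.transcript_ids)
    items = [
        (np.fromiter(cls, dtype=np.int64), float(n)) for cls, n in counts.counts.items()
    ]
    if not items or n_tx == 0:
        raise EmptyAbundanceError("no assigned reads")
    total = sum(n for _, n in items)

    alpha = np.full(n_tx, 1.0 / n_tx)
    lls: List[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        expected = np.zeros(n_tx)
        ll = 0.0
        for members, n in items:
            probs = alpha[members]
            denom = probs.sum()
            if denom <= 0:
                continue
            expected[members] += n * probs / denom
            ll += n * np.log(denom)
        lls.append(ll)
        new_alpha = expected / total
        delta = np.max(np.abs(new_alpha - alpha))
        alpha = new_alpha
        if delta < tol:
            break

    est_count = alpha * total
    eff = np.asarray(index.effective_lengths, dtype=float)
    rates = np.where(eff > 0, est_count / eff, 0.0)
    tpm = rates / rates.sum() * 1e6 if rates.sum() > 0 else rates

    df = pd.DataFrame(
        {
            "transcript_id": index.transcript_ids,
            "est_count": est_count,
            "tpm": tpm,
            "gene_id": index.gene_ids,
        }
    )
    gene_tpm = df.groupby("gene_id")["tpm"].transform("sum")
    df["pct_usage"] = np.where(gene_tpm > 0, 100.0 * df["tpm"] / gene_tpm, 0.0)
    return AbundanceTable(table=df, log_likelihoods=lls, n_iterations=iterations)


def gene_metrics(
    abundance: AbundanceTable,
    gene_a: str,
    gene_b: str,
    primary_transcript: Optional[str] = None,
    usage_threshold: float = 90.0,
) -> Dict[str, object]:
    """Gene-level ratio and primary-isoform usage flag."""
    genes = set(abundance.table.gene_id)
    for g in (gene_a, gene_b):
        if g not in genes:
            raise KeyError(f"gene {g!r} absent from abundance table")
    tpm_a = abundance.gene_tpm(gene_a)
    tpm_b = abundance.gene_tpm(gene_b)
    ratio = tpm_a / tpm_b if tpm_b > 0 else float("nan")
    out: Dict[str, object] = {
        "gene_a": gene_a,
        "gene_b": gene_b,
        "tpm_a": tpm_a,
        "tpm_b": tpm_b,
        "ratio": ratio,
        "ratio_defined": tpm_b > 0,
    }
    if primary_transcript is not None:
        usage = abundance.pct_usage(primary_transcript)
        out["primary_transcript"] = primary_transcript
        out["primary_usage_pct"] = usage
        out["low_primary_usage"] = usage < usage_threshold
    return out


def samples_r_squared(values_a: Iterable[float], values_b: Iterable[float]) -> float:
    """R^2 of the least-squares fit between two per-sample value collections."""
    from scipy import stats

    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two collections of equal length >= 2")
    res = stats.linregress(a, b)
    return float(res.rvalue**2)
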