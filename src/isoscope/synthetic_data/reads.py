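"""Seeded stranded single-end read simulator with ground-truth labels."""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..locus_model.consequence import project_variant
from ..locus_model.sequence import inject_haplotype
from .config import GroundTruth, ReadSpec
from .locus import LocusBundle

_BASES = "ACGT"


@dataclass
class SimulatedReads:
    names: List[str]
    sequences: List[str]
    ground_truth: GroundTruth


def _default_haplotypes(
    bundle: LocusBundle, spec: ReadSpec
) -> Dict[str, List[Tuple[str, List[str], float]]]:
    """Two haplotypes per transcript carrying variants: ref and all-alt (cis)."""
    out: Dict[str, List[Tuple[str, List[str], float]]] = {}
    for tx in bundle.transcripts:
        vids = [
            v.variant_id or v.ref_allele
            for v in bundle.variants
            if project_variant(v, tx) is not None
        ]
        if vids:
            f = spec.default_alt_fraction
            out[tx.transcript_id] = [("ref", [], 1.0 - f), ("alt", vids, f)]
        else:
            out[tx.transcript_id] = [("ref", [], 1.0)]
    return out


def _haplotype_sequences(
    bundle: LocusBundle,
    haplotypes: Dict[str, List[Tuple[str, List[str], float]]],
) -> Dict[str, Dict[str, str]]:
    by_id = {v.variant_id: v for v in bundle.variants}
    out: Dict[str, Dict[str, str]] = {}
    for tx in bundle.transcripts:
        tid = tx.transcript_id
        base = bundle.sequences[tid]
        out[tid] = {}
        for name, vids, _frac in haplotypes.get(tid, [("ref", [], 1.0)]):
            edits = []
            for vid in vids:
                proj = project_variant(by_id[vid], tx)
                if proj is None:
                    raise ValueError(f"variant {vid} not on transcript {tid}")
                edits.append(proj)
            edits.sort(key=lambda e: e[0])
            out[tid][name] = inject_haplotype(base, edits)
    return out


def simulate_reads(
    bundle: LocusBundle, spec: ReadSpec, seed: int
) -> SimulatedReads:
    """Draw reads multinomially over isoforms by proportion x length weight.

    Start positions are uniform over valid offsets of the chosen haplotype;
    substitution errors are i.i.d. per base.  Ground truth records per-
    transcript/haplotype counts, expected allele fractions and the number of
    reads whose source interval spans the fusion junction by at least
    ``min_junction_overlap`` on both sides.
    """
    rng = np.random.default_rng([seed, 1])
    tx_ids = [t.transcript_id for t in bundle.transcripts]
    props = spec.isoform_proportions or {t: 1.0 / len(tx_ids) for t in tx_ids}
    unknown = set(props) - set(tx_ids)
    if unknown:
        raise ValueError(f"proportions reference unknown transcripts: {sorted(unknown)}")

    haplotypes = spec.haplotypes or _default_haplotypes(bundle, spec)
    hap_seqs = _haplotype_sequences(bundle, haplotypes)

    for tid in props:
        if len(bundle.sequences[tid]) < spec.read_length:
            raise ValueError(
                f"read length {spec.read_length} exceeds transcript {tid} length"
            )

    ids = sorted(props)
    weights = np.array(
        [
            props[t] * max(len(bundle.sequences[t]) - spec.read_length + 1, 1)
            for t in ids
        ],
        dtype=float,
    )
    weights /= weights.sum()
    choices = rng.choice(len(ids), size=spec.n_reads, p=weights)

    junction = bundle.fusion.junction_offset
    min_ov = spec.min_junction_overlap
    names: List[str] = []
    seqs: List[str] = []
    truth = GroundTruth(
        isoform_proportions={t: props.get(t, 0.0) for t in tx_ids},
        junction_offset=junction,
    )
    hap_counts: Dict[str, Dict[str, int]] = {t: {} for t in ids}
    read_counts: Dict[str, int] = {t: 0 for t in ids}
    n_span = 0

    for i, ci in enumerate(choices):
        tid = ids[ci]
        hap_list = haplotypes.get(tid, [("ref", [], 1.0)])
        fracs = np.array([h[2] for h in hap_list], dtype=float)
        hap_name, _vids, _ = hap_list[rng.choice(len(hap_list), p=fracs / fracs.sum())]
        hap = hap_seqs[tid][hap_name]
        start = int(rng.integers(0, len(hap) - spec.read_length + 1))
        seq = hap[start : start + spec.read_length]
        if spec.error_rate > 0:
            arr = list(seq)
            errs = np.nonzero(rng.random(spec.read_length) < spec.error_rate)[0]
            for j in errs:
                alternatives = [b for b in _BASES if b != arr[j]]
                arr[j] = alternatives[int(rng.integers(0, 3))]
            seq = "".join(arr)
        names.append(f"r{i}|{tid}|{hap_name}|{start}")
        seqs.append(seq)
        read_counts[tid] += 1
        hap_counts[tid][hap_name] = hap_counts[tid].get(hap_name, 0) + 1
        if tid == bundle.fusion.transcript_id:
            # haplotype edits on the fusion are SNVs in the default setup, so
            # haplotype coordinates coincide with fusion coordinates
            if start <= junction - min_ov and start + spec.read_length >= junction + min_ov:
                n_span += 1

    truth.read_counts = read_counts
    truth.haplotype_read_counts = hap_counts
    truth.junction_spanning_reads = n_span
    for tid, hap_list in haplotypes.items():
        total = sum(f for _, _, f in hap_list)
        for vid in {v for _, vids, _ in hap_list for v in vids}:
            carrying = sum(f for _, vids, f in hap_list if vid in vids)
            truth.allele_fractions.setdefault(tid, {})[vid] = carrying / total
    return SimulatedReads(names=names, sequences=seqs, ground_truth=truth)


def write_fastq(reads: SimulatedReads, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(reads.names, reads.sequences):
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> Tuple[List[str], List[str]]:
    names: List[str] = []
    seqs: List[str] = []
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return names, seqs
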