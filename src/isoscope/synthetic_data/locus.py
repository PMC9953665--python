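"""Seeded generator for the toy two-gene locus with a readthrough fusion."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..locus_model.models import (
    FusedTranscript,
    FusionJoin,
    GenomeSequence,
    TranscriptModel,
    VariantRecord,
)
from ..locus_model.orf import _STOP_CODONS, translate_codon
from ..locus_model.sequence import build_readthrough_transcript, extract_transcript_sequence
from .config import LocusSpec

_BASES = np.array(list("ACGT"))


@dataclass
class LocusBundle:
    genome: GenomeSequence
    transcripts: List[TranscriptModel]
    fusion: FusedTranscript
    variants: List[VariantRecord]
    sequences: Dict[str, str] = field(default_factory=dict)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for tx in self.transcripts:
            if tx.transcript_id == transcript_id:
                return tx
        raise KeyError(transcript_id)


def _recode_cds(
    genome: List[str],
    tx: TranscriptModel,
    cds_start: int,
    cds_end: int,
    terminal_stop: bool,
) -> None:
    """Edit genome bases so the transcript-relative CDS translates cleanly.

    Sets ATG at the start, destroys internal in-frame stops (second base ->
    C) and optionally writes a terminal TAA.
    """

    def set_tx_base(tpos: int, base: str) -> None:
        genome[tx.transcript_to_genome(tpos)] = base

    def get_tx_base(tpos: int) -> str:
        return genome[tx.transcript_to_genome(tpos)]

    for offset, base in enumerate("ATG"):
        set_tx_base(cds_start + offset, base)
    body_end = cds_end - 3 if terminal_stop else cds_end
    for p in range(cds_start + 3, body_end - 2, 3):
        codon = "".join(get_tx_base(p + i) for i in range(3))
        if codon in _STOP_CODONS:
            set_tx_base(p + 1, "C")
    if terminal_stop:
        for offset, base in enumerate("TAA"):
            set_tx_base(cds_end - 3 + offset, base)


def _pick_missense_alt(codon: str, within: int) -> Optional[str]:
    ref_aa = translate_codon(codon)
    for alt in "ACGT":
        if alt == codon[within]:
            continue
        new = codon[:within] + alt + codon[within + 1:]
        aa = translate_codon(new)
        if aa not in (ref_aa, "*"):
            return alt
    return None


def _pick_synonymous_alt(codon: str) -> Optional[str]:
    ref_aa = translate_codon(codon)
    for alt in "ACGT":
        if alt == codon[2]:
            continue
        if translate_codon(codon[:2] + alt) == ref_aa:
            return alt
    return None


def simulate_locus(
    spec: LocusSpec, seed: int, allele_frequency: float = 0.1
) -> LocusBundle:
    """Generate genome + transcript models (incl. fusion) with embedded variants.

    The layout is fixed by the spec; random sequence fills everything that
    is not engineered (start/stop codons, the fusion-frame stop).  Variants
    cover 5'UTR, missense, synonymous, 3'UTR and splice-site cases.
    """
    rng = np.random.default_rng([seed, 0])
    genome_arr: List[str] = list(rng.choice(_BASES, size=spec.genome_length))

    e0 = spec.shared_utr_exon
    a1 = TranscriptModel("A1", "GENEA", spec.contig_id, "+", [e0, *spec.a1_exons],
                         cds_span=(spec.cds_start_tx, spec.a1_cds_end_tx))
    a2 = TranscriptModel("A2", "GENEA", spec.contig_id, "+", [e0, *spec.a2_exons],
                         cds_span=(spec.cds_start_tx, spec.a2_cds_end_tx))
    a3 = TranscriptModel("A3", "GENEA", spec.contig_id, "+", [e0, *spec.a3_exons],
                         cds_span=(spec.cds_start_tx, spec.a3_cds_end_tx),
                         cds_partial=True)
    b1 = TranscriptModel("B1", "GENEB", spec.contig_id, "+", list(spec.b_exons),
                         cds_span=(spec.cds_start_tx, spec.b_cds_end_tx))

    _recode_cds(genome_arr, a1, *a1.cds_span, terminal_stop=True)
    _recode_cds(genome_arr, a2, *a2.cds_span, terminal_stop=True)
    _recode_cds(genome_arr, a3, *a3.cds_span, terminal_stop=False)
    # a stop-free CDS must also lack a stop in its final codon
    for p in range(a3.cds_span[0] + 3, a3.cds_span[1] - 2, 3):
        codon = "".join(genome_arr[a3.transcript_to_genome(p + i)] for i in range(3))
        if codon in _STOP_CODONS:
            genome_arr[a3.transcript_to_genome(p + 1)] = "C"
    _recode_cds(genome_arr, b1, *b1.cds_span, terminal_stop=True)

    # Engineer the fusion reading frame: no stop between the CDS start and
    # the designed fusion stop codon, then TAA at fusion_stop_tx.  All edits
    # land in B's 5'UTR (they cannot disturb B's protein).
    def fused_base(fpos: int) -> str:
        if fpos < spec.donor_break:
            return genome_arr[a1.transcript_to_genome(fpos)]
        bpos = spec.acceptor_start + (fpos - spec.donor_break)
        return genome_arr[b1.transcript_to_genome(bpos)]

    def set_fused_base(fpos: int, base: str) -> None:
        if fpos < spec.donor_break:
            raise AssertionError("fusion-frame edits must fall in the acceptor segment")
        bpos = spec.acceptor_start + (fpos - spec.donor_break)
        genome_arr[b1.transcript_to_genome(bpos)] = base

    for p in range(spec.cds_start_tx, spec.fusion_stop_tx - 2, 3):
        codon = "".join(fused_base(p + i) for i in range(3))
        if codon in _STOP_CODONS and p + 3 > spec.donor_break:
            set_fused_base(p + 1, "C")
    for offset, base in enumerate("TAA"):
        set_fused_base(spec.fusion_stop_tx + offset, base)

    genome = GenomeSequence(spec.contig_id, "".join(genome_arr))
    sequences = {
        tx.transcript_id: extract_transcript_sequence(genome, tx)
        for tx in (a1, a2, a3, b1)
    }
    join = FusionJoin("A1", spec.donor_break, "B1", spec.acceptor_start)
    fusion = build_readthrough_transcript(
        a1, sequences["A1"], b1, sequences["B1"], join, fused_id="F1"
    )
    fusion_model = TranscriptModel(
        "F1",
        "GENEA",
        spec.contig_id,
        "+",
        _fusion_exons(spec),
        cds_span=(spec.cds_start_tx, spec.fusion_stop_tx + 3),
    )
    sequences["F1"] = fusion.sequence

    variants = _make_variants(spec, genome, a1, sequences["A1"], allele_frequency)
    return LocusBundle(
        genome=genome,
        transcripts=[a1, a2, a3, b1, fusion_model],
        fusion=fusion,
        variants=variants,
        sequences=sequences,
    )


def _fusion_exons(spec: LocusSpec) -> List[Tuple[int, int]]:
    """Genomic exons of the fusion transcript (A1 prefix spliced to B suffix)."""
    e0 = spec.shared_utr_exon
    exons: List[Tuple[int, int]] = [e0]
    remaining = spec.donor_break - (e0[1] - e0[0])
    for s, e in spec.a1_exons:
        take = min(remaining, e - s)
        if take <= 0:
            break
        exons.append((s, s + take))
        remaining -= take
    b_first = spec.b_exons[0]
    exons.append((b_first[0] + spec.acceptor_start, b_first[1]))
    exons.extend(spec.b_exons[1:])
    return exons


def _make_variants(
    spec: LocusSpec,
    genome: GenomeSequence,
    a1: TranscriptModel,
    a1_seq: str,
    af: float,
) -> List[VariantRecord]:
    variants: List[VariantRecord] = []

    def snv(vid: str, gpos: int, alt: str) -> VariantRecord:
        return VariantRecord(
            contig_id=spec.contig_id,
            position=gpos,
            ref_allele=genome.sequence[gpos],
            alt_allele=alt,
            variant_id=vid,
            population_frequencies={"ALL": af},
        )

    def other_base(base: str) -> str:
        return {"A": "G", "C": "T", "G": "A", "T": "C"}[base]

    # 5'UTR variant in the shared first exon
    g = spec.shared_utr_exon[0] + 50
    variants.append(snv("v_5utr", g, other_base(genome.sequence[g])))

    cs = spec.cds_start_tx
    # missense: scan codons in A1's second CDS half for an editable 2nd base
    for codon_idx in range(180, 220):
        p = cs + 3 * codon_idx
        codon = a1_seq[p : p + 3]
        alt = _pick_missense_alt(codon, 1)
        if alt is not None:
            variants.append(snv("v_mis", a1.transcript_to_genome(p + 1), alt))
            break
    # synonymous: third-base wobble
    for codon_idx in range(180, 229):
        p = cs + 3 * codon_idx
        codon = a1_seq[p : p + 3]
        alt = _pick_synonymous_alt(codon)
        if alt is not None and a1.transcript_to_genome(p + 2) != variants[-1].position:
            variants.append(snv("v_syn", a1.transcript_to_genome(p + 2), alt))
            break
    # 3'UTR variant on A1
    t = spec.a1_cds_end_tx + 40
    g = a1.transcript_to_genome(t)
    variants.append(snv("v_3utr", g, other_base(genome.sequence[g])))
    # splice-site variant: +2 intronic base after the shared first exon
    g = spec.shared_utr_exon[1] + 1
    variants.append(snv("v_splice", g, other_base(genome.sequence[g])))
    return variants
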