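"""Variant-to-transcript projection and consequence classification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Set, Tuple

from .models import (
    CONSEQUENCE_PRIORITY,
    ConsequenceCall,
    GenomeSequence,
    RefMismatchError,
    TranscriptModel,
    VariantRecord,
)
from .orf import translate_codon
from .sequence import extract_transcript_sequence, reverse_complement


@dataclass(frozen=True)
class ConsequenceConfig:
    """Windows used by the classifier.

    splice_site: intronic bases flanking each exon-intron boundary.
    splice_region: exonic / intronic bases around each boundary (the intronic
    window extends beyond the splice_site bases).
    neighborhood: distance within which a non-overlapping variant is still
    reported as upstream/downstream.
    """

    splice_site_intronic: int = 2
    splice_region_exonic: int = 3
    splice_region_intronic: int = 8
    neighborhood: int = 5000


def project_variant(
    variant: VariantRecord, tx: TranscriptModel
) -> Optional[Tuple[int, str, str]]:
    """Project a genomic variant into transcript coordinates.

    Returns (transcript position, ref, alt) with alleles in transcript
    orientation, or None when the reference allele span is not fully
    contained in a single exon.
    """
    if variant.contig_id != tx.contig_id:
        return None
    span = (variant.position, variant.end)
    containing = None
    for s, e in tx.exons:
        if s <= span[0] and span[1] <= e:
            containing = (s, e)
            break
    if containing is None:
        return None
    t_first = tx.genome_to_transcript(variant.position)
    assert t_first is not None
    if tx.strand == "+":
        return t_first, variant.ref_allele, variant.alt_allele
    t_last = tx.genome_to_transcript(variant.end - 1)
    assert t_last is not None
    return (
        t_last,
        reverse_complement(variant.ref_allele),
        reverse_complement(variant.alt_allele),
    )


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _splice_candidates(
    variant: VariantRecord, tx: TranscriptModel, cfg: ConsequenceConfig
) -> Set[str]:
    """splice_site / splice_region hits around internal exon boundaries."""
    out: Set[str] = set()
    v0, v1 = variant.position, variant.end
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        # donor/acceptor intron edges of the intron [e1, s2)
        for intron_edge, direction in ((e1, +1), (s2, -1)):
            if direction > 0:
                site = (intron_edge, intron_edge + cfg.splice_site_intronic)
                region_intronic = (intron_edge, intron_edge + cfg.splice_region_intronic)
                region_exonic = (intron_edge - cfg.splice_region_exonic, intron_edge)
            else:
                site = (intron_edge - cfg.splice_site_intronic, intron_edge)
                region_intronic = (intron_edge - cfg.splice_region_intronic, intron_edge)
                region_exonic = (intron_edge, intron_edge + cfg.splice_region_exonic)
            if _overlaps(v0, v1, *site):
                out.add("splice_site")
            elif _overlaps(v0, v1, *region_intronic) or _overlaps(v0, v1, *region_exonic):
                out.add("splice_region")
    return out


def _coding_candidate(
    tpos: int,
    t_ref: str,
    t_alt: str,
    tx: TranscriptModel,
    tx_seq: str,
) -> Tuple[str, Optional[str]]:
    """Consequence of an exonic variant given its transcript projection."""
    if tx.cds_span is None:
        return "noncoding_transcript", None
    cs, ce = tx.cds_span
    v_end = tpos + len(t_ref)
    if v_end <= cs:
        return "five_prime_UTR", None
    if tpos >= ce:
        return "three_prime_UTR", None

    aa_pos = (tpos - cs) // 3 + 1
    if len(t_ref) != len(t_alt):
        ref_codon_start = cs + (aa_pos - 1) * 3
        ref_aa = translate_codon(tx_seq[ref_codon_start : ref_codon_start + 3])
        if (len(t_ref) - len(t_alt)) % 3 != 0:
            return "frameshift", f"p.{ref_aa}{aa_pos}fs"
        return "inframe_indel", f"p.{ref_aa}{aa_pos}delins"

    # substitution: retranslate the affected codons
    first_codon = (tpos - cs) // 3
    last_codon = (v_end - 1 - cs) // 3
    block0 = cs + first_codon * 3
    block1 = min(cs + (last_codon + 1) * 3, len(tx_seq))
    ref_block = tx_seq[block0:block1]
    alt_block = (
        tx_seq[block0:tpos] + t_alt + tx_seq[v_end:block1]
    )
    ref_aa = "".join(
        translate_codon(ref_block[i : i + 3]) for i in range(0, len(ref_block) - 2, 3)
    )
    alt_aa = "".join(
        translate_codon(alt_block[i : i + 3]) for i in range(0, len(alt_block) - 2, 3)
    )
    if ref_aa == alt_aa:
        return "synonymous", None
    change = f"p.{ref_aa}{aa_pos}{alt_aa}"
    if "*" in ref_aa and "*" not in alt_aa:
        return "stop_lost", change
    if "*" in alt_aa and "*" not in ref_aa:
        return "stop_gained", change
    return "missense", change


def classify_consequence(
    variant: VariantRecord,
    tx: TranscriptModel,
    genome: GenomeSequence,
    cfg: ConsequenceConfig | None = None,
    tx_sequence: Optional[str] = None,
) -> Optional[ConsequenceCall]:
    """Single highest-priority consequence of a variant on one transcript.

    Returns None when the variant lies outside the transcript and beyond the
    upstream/downstream neighborhood window.
    """
    cfg = cfg or ConsequenceConfig()
    if variant.contig_id != tx.contig_id:
        return None
    observed = genome.fetch(variant.position, variant.end)
    if observed != variant.ref_allele:
        raise RefMismatchError(
            f"ref allele {variant.ref_allele!r} != genome {observed!r} "
            f"at {variant.contig_id}:{variant.position}"
        )

    t0, t1 = tx.span
    v0, v1 = variant.position, variant.end
    if not _overlaps(v0, v1, t0, t1):
        if not _overlaps(v0, v1, t0 - cfg.neighborhood, t1 + cfg.neighborhood):
            return None
        before = v1 <= t0
        if tx.strand == "+":
            cons = "upstream_gene" if before else "downstream_gene"
        else:
            cons = "downstream_gene" if before else "upstream_gene"
        return ConsequenceCall(tx.transcript_id, cons)

    candidates: Set[Tuple[str, Optional[str]]] = set()
    for c in _splice_candidates(variant, tx, cfg):
        candidates.add((c, None))

    projection = project_variant(variant, tx)
    if projection is not None:
        tx_seq = tx_sequence or extract_transcript_sequence(genome, tx)
        tpos, t_ref, t_alt = projection
        candidates.add(_coding_candidate(tpos, t_ref, t_alt, tx, tx_seq))
    else:
        exonic = any(_overlaps(v0, v1, s, e) for s, e in tx.exons)
        if not exonic:
            candidates.add(("intronic", None))

    if not candidates:
        candidates.add(("intronic", None))

    rank = {c: i for i, c in enumerate(CONSEQUENCE_PRIORITY)}
    cons, change = min(candidates, key=lambda c: rank[c[0]])
    from .models import CODING_ALTERING

    if cons not in CODING_ALTERING:
        change = None
    return ConsequenceCall(tx.transcript_id, cons, change)
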