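"""Allele fractions, genotype classes and read-level phase checks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from ..locus_model.sequence import inject_haplotype, reverse_complement
from .kmers import kmer_set, spanning_kmer_set

DEFAULT_THRESHOLDS = {
    "hom_ref_max": 0.1,
    "het_min": 0.2,
    "het_max": 0.8,
    "hom_alt_min": 0.9,
}


@dataclass
class AlleleCall:
    variant_id: str
    transcript_id: str
    ref_reads: int
    alt_reads: int
    ambiguous_reads: int
    alt_fraction: Optional[float]
    genotype: str


@dataclass
class PhasePairCounts:
    ref_ref: int = 0
    ref_alt: int = 0
    alt_ref: int = 0
    alt_alt: int = 0
    verdict: str = "uninformative"

    @property
    def covering(self) -> int:
        return self.ref_ref + self.ref_alt + self.alt_ref + self.alt_alt


def discriminating_kmers(
    ref_hap: str,
    alt_hap: str,
    site: int,
    ref_len: int,
    alt_len: int,
    k: int,
) -> Tuple[set, set]:
    """Site-spanning k-mers occurring in exactly one of the two haplotypes."""
    ref_span = spanning_kmer_set(ref_hap, site, site + ref_len, k)
    alt_span = spanning_kmer_set(alt_hap, site, site + alt_len, k)
    all_ref = kmer_set(ref_hap, k)
    all_alt = kmer_set(alt_hap, k)
    return ref_span - all_alt, alt_span - all_ref


def classify_fraction(
    fraction: Optional[float], thresholds: Optional[Dict[str, float]] = None
) -> str:
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if fraction is None:
        return "no_data"
    if fraction <= th["hom_ref_max"]:
        return "hom_ref"
    if fraction >= th["hom_alt_min"]:
        return "hom_alt"
    if th["het_min"] <= fraction <= th["het_max"]:
        return "het"
    return "ambiguous"


def sample_genotype_class(variant_genotypes: Sequence[str]) -> str:
    """Sample-level class from per-variant genotype labels.

    WT when every variant is hom_ref; het-single for exactly one het;
    compound-het for two or more het variants; hom-alt when any variant is
    homozygous alternate; otherwise ambiguous.
    """
    calls = [g for g in variant_genotypes if g != "no_data"]
    if not calls:
        return "no_data"
    if any(g == "ambiguous" for g in calls):
        return "ambiguous"
    if any(g == "hom_alt" for g in calls):
        return "hom-alt"
    hets = sum(g == "het" for g in calls)
    if hets == 0:
        return "WT"
    if hets == 1:
        return "het-single"
    return "compound-het"


def allele_fraction(
    reads: Iterable[str],
    ref_hap: str,
    alt_hap: str,
    site: int,
    ref_allele: str,
    alt_allele: str,
    k: int = 31,
    variant_id: str = "",
    transcript_id: str = "",
    thresholds: Optional[Dict[str, float]] = None,
) -> AlleleCall:
    """Count reads supporting each allele via allele-discriminating k-mers.

    ``site`` is the variant position in ref-haplotype transcript coordinates
    (the alt haplotype carries the alt allele at the same offset).  A read
    supports an allele when it contains a site-spanning k-mer unique to one
    haplotype; reads matching both sets are ambiguous and excluded from the
    fraction.
    """
    if not 0 <= site < len(ref_hap):
        raise ValueError(f"variant site {site} not on transcript")
    ref_disc, alt_disc = discriminating_kmers(
        ref_hap, alt_hap, site, len(ref_allele), len(alt_allele), k
    )
    n_ref = n_alt = n_amb = 0
    for seq in reads:
        codes = kmer_set(seq, k) | kmer_set(reverse_complement(seq), k)
        hit_ref = not codes.isdisjoint(ref_disc)
        hit_alt = not codes.isdisjoint(alt_disc)
        if hit_ref and hit_alt:
            n_amb += 1
        elif hit_ref:
            n_ref += 1
        elif hit_alt:
            n_alt += 1
    informative = n_ref + n_alt
    fraction = n_alt / informative if informative > 0 else None
    return AlleleCall(
        variant_id=variant_id,
        transcript_id=transcript_id,
        ref_reads=n_ref,
        alt_reads=n_alt,
        ambiguous_reads=n_amb,
        alt_fraction=fraction,
        genotype=classify_fraction(fraction, thresholds),
    )


def _find_spanning(hap: str, read: str, lo: int, hi: int) -> bool:
    """True when ``read`` occurs in ``hap`` at an offset covering [lo, hi)."""
    start = 0
    while True:
        off = hap.find(read, start)
        if off < 0:
            return False
        if off <= lo and hi <= off + len(read):
            return True
        start = off + 1


def phase_pair(
    reads: Iterable[str],
    tx_sequence: str,
    variant_a: Tuple[int, str, str],
    variant_b: Tuple[int, str, str],
    read_length: Optional[int] = None,
    min_flank: int = 1,
    min_cis_reads: int = 1,
) -> PhasePairCounts:
    """Count allele combinations across reads covering both variant sites.

    Reads are matched exactly against the four two-site haplotype sequences
    (ref-ref, ref-alt, alt-ref, alt-alt); a read counts only when it matches
    exactly one candidate at an offset covering both edited sites.  The
    verdict is cis-observed when at least ``min_cis_reads`` alt-alt reads
    are seen, trans-only when alt alleles appear only separately, else
    uninformative.
    """
    (pa, ra, aa_) = variant_a
    (pb, rb, ab_) = variant_b
    if pa > pb:
        return phase_pair(
            reads, tx_sequence, variant_b, variant_a, read_length, min_flank, min_cis_reads
        )
    counts = PhasePairCounts()
    span = (pb + len(rb)) - pa
    if read_length is not None and span > read_length - 2 * min_flank + 2:
        counts.verdict = "uninformative"
        return counts

    candidates = {}
    for name, edits in {
        "ref_ref": [],
        "ref_alt": [(pb, rb, ab_)],
        "alt_ref": [(pa, ra, aa_)],
        "alt_alt": [(pa, ra, aa_), (pb, rb, ab_)],
    }.items():
        hap = inject_haplotype(tx_sequence, edits)
        # site coordinates within this candidate haplotype
        shift_a = 0
        a_span = (pa, pa + (len(aa_) if any(e[0] == pa for e in edits) else len(ra)))
        b_shift = (len(aa_) - len(ra)) if any(e[0] == pa for e in edits) else 0
        b_alt = any(e[0] == pb for e in edits)
        b_span = (
            pb + b_shift,
            pb + b_shift + (len(ab_) if b_alt else len(rb)),
        )
        candidates[name] = (hap, min(a_span[0], b_span[0]), max(a_span[1], b_span[1]))

    for seq in reads:
        for oriented in (seq, reverse_complement(seq)):
            matches = [
                name
                for name, (hap, lo, hi) in candidates.items()
                if _find_spanning(hap, oriented, lo, hi)
            ]
            if len(matches) == 1:
                setattr(counts, matches[0], getattr(counts, matches[0]) + 1)
                break

    if counts.alt_alt >= min_cis_reads:
        counts.verdict = "cis-observed"
    elif counts.ref_alt > 0 or counts.alt_ref > 0:
        counts.verdict = "trans-only"
    else:
        counts.verdict = "uninformative"
    return counts
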