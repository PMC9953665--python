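"""Core domain types for the locus model.

Coordinates are 0-based half-open everywhere inside the package; 1-based
conversions happen only at GTF/VCF I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

NUCLEOTIDES = set("ACGTN")

#: Consequence terms ordered from highest to lowest priority.
CONSEQUENCE_PRIORITY: Tuple[str, ...] = (
    "splice_site",
    "frameshift",
    "stop_gained",
    "stop_lost",
    "missense",
    "inframe_indel",
    "synonymous",
    "splice_region",
    "five_prime_UTR",
    "three_prime_UTR",
    "intronic",
    "noncoding_transcript",
    "upstream_gene",
    "downstream_gene",
)

#: Consequences that carry a protein_change annotation.
CODING_ALTERING = frozenset(
    {"missense", "stop_gained", "stop_lost", "frameshift", "inframe_indel"}
)

DECAY_NORMAL = "normal"
DECAY_NMD = "nmd_predicted"
DECAY_NONSTOP = "nonstop_predicted"


class CoordinateError(ValueError):
    """A genomic/transcript coordinate falls outside its container."""


class RefMismatchError(ValueError):
    """A declared reference allele disagrees with the genome sequence."""


@dataclass(frozen=True)
class GenomeSequence:
    """A plus-strand contig sequence."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ValueError(f"disallowed characters in genome sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        if start < 0 or end > len(self.sequence) or start > end:
            raise CoordinateError(
                f"interval [{start},{end}) outside contig {self.contig_id} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass
class TranscriptModel:
    """Exon structure of one transcript on a genome contig.

    ``exons`` are genomic intervals, 0-based half-open, sorted by genome
    coordinate regardless of strand.  ``cds_span`` is transcript-relative
    (5'->3' in transcript orientation), 0-based half-open, and includes the
    stop codon when one is annotated.
    """

    transcript_id: str
    gene_id: str
    contig_id: str
    strand: str
    exons: Sequence[Tuple[int, int]]
    cds_span: Optional[Tuple[int, int]] = None
    cds_partial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = [tuple(e) for e in self.exons]
        if not exons:
            raise ValueError("transcript must have at least one exon")
        for s, e in exons:
            if s >= e:
                raise ValueError(f"empty or inverted exon [{s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be sorted and non-overlapping")
        self.exons = exons
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (0 <= cs < ce <= self.length):
                raise ValueError(
                    f"cds_span [{cs},{ce}) outside transcript of length {self.length}"
                )
            if (ce - cs) % 3 != 0 and not self.cds_partial:
                raise ValueError("cds_span length not divisible by 3 and not flagged partial")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_junctions(self) -> Tuple[int, ...]:
        """Transcript-relative positions of exon-exon junctions (5'->3').

        A junction at position j means transcript bases j-1 and j come from
        different exons.  Single-exon transcripts have none.
        """
        lengths = [e - s for s, e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        out = []
        acc = 0
        for ln in lengths[:-1]:
            acc += ln
            out.append(acc)
        return tuple(out)

    def genome_to_transcript(self, gpos: int) -> Optional[int]:
        """Map a genomic position to a transcript coordinate, or None if intronic/outside."""
        acc = 0
        hit = None
        for s, e in self.exons:
            if s <= gpos < e:
                hit = acc + (gpos - s)
                break
            acc += e - s
        if hit is None:
            return None
        if self.strand == "+":
            return hit
        return self.length - 1 - hit

    def transcript_to_genome(self, tpos: int) -> int:
        """Map a transcript coordinate to its genomic position."""
        if not 0 <= tpos < self.length:
            raise CoordinateError(f"transcript position {tpos} outside length {self.length}")
        plus = tpos if self.strand == "+" else self.length - 1 - tpos
        acc = 0
        for s, e in self.exons:
            if plus < acc + (e - s):
                return s + (plus - acc)
            acc += e - s
        raise AssertionError("unreachable")


@dataclass
class VariantRecord:
    """Normalized genomic SNV/indel.

    ``position`` is 0-based internally (converted from 1-based at VCF I/O).
    """

    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_id: Optional[str] = None
    population_frequencies: Mapping[str, float] = field(default_factory=dict)
    annotation_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        for pop, f in self.population_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency for {pop} outside [0,1]: {f}")

    @property
    def end(self) -> int:
        """Genomic end of the reference allele span (half-open)."""
        return self.position + len(self.ref_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig_id, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class ConsequenceCall:
    transcript_id: str
    consequence: str
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_PRIORITY:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        has_change = self.protein_change is not None
        if has_change != (self.consequence in CODING_ALTERING):
            raise ValueError(
                "protein_change must be present iff the consequence is coding-altering"
            )


@dataclass(frozen=True)
class FusionJoin:
    """Transcript-relative breakpoints of a readthrough fusion."""

    donor_transcript_id: str
    donor_break: int
    acceptor_transcript_id: str
    acceptor_start: int


@dataclass
class FusedTranscript:
    """A readthrough fusion transcript assembled from donor and acceptor."""

    transcript_id: str
    sequence: str
    junction_offset: int
    exon_junctions: Tuple[int, ...]
    donor_transcript_id: str
    acceptor_transcript_id: str
    cds_start: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    sequence: str
    source_transcript_id: Optional[str]
    orf_span: Tuple[int, int]
    stop_reached: bool
    decay_class: Optional[str] = None

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise ValueError("protein sequence contains internal stop symbol")
        expect = 3 * (len(self.sequence) + 1) if self.stop_reached else 3 * len(self.sequence)
        got = self.orf_span[1] - self.orf_span[0]
        if got != expect:
            raise ValueError(f"orf_span length {got} inconsistent with protein ({expect})")
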