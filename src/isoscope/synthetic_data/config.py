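"""Simulation configuration and ground-truth containers."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple


@dataclass
class LocusSpec:
    """Layout of the toy two-gene same-strand locus.

    Gene A has three isoforms sharing a 5'UTR exon: A1 (normal), A2
    (NMD-structured: stop well upstream of the last junction) and A3
    (stop-free).  Gene B sits downstream on the same strand; the fusion
    transcript F joins A1 broken inside its CDS onto B's 5'UTR in a
    shifted frame.
    """

    contig_id: str = "chrT"
    genome_length: int = 12000
    # exon coordinates, 0-based half-open, plus strand
    shared_utr_exon: Tuple[int, int] = (1000, 1120)
    a1_exons: Tuple[Tuple[int, int], ...] = ((1500, 1900), (2500, 2900))
    a2_exons: Tuple[Tuple[int, int], ...] = ((3200, 3600), (4200, 4500))
    a3_exons: Tuple[Tuple[int, int], ...] = ((5000, 5480),)
    b_exons: Tuple[Tuple[int, int], ...] = ((8000, 8300), (9000, 9500))
    cds_start_tx: int = 150          # all CDS starts, transcript-relative
    a1_cds_end_tx: int = 840
    a2_cds_end_tx: int = 390
    a3_cds_end_tx: int = 600         # runs to transcript end, no stop
    b_cds_end_tx: int = 600
    donor_break: int = 421           # fusion break inside A1's CDS
    acceptor_start: int = 30         # inside B's 5'UTR, frame-shifting
    fusion_stop_tx: int = 528        # engineered fusion stop codon start


@dataclass
class VariantSpec:
    """One simulated SNV, positioned in transcript coordinates of a host."""

    variant_id: str
    kind: str  # five_prime_UTR | missense | synonymous | three_prime_UTR | splice_site
    allele_frequency: float = 0.1


@dataclass
class ReadSpec:
    n_reads: int = 10000
    read_length: int = 100
    error_rate: float = 0.0
    #: transcript id -> molar proportion (simplex); defaults set by the generator
    isoform_proportions: Dict[str, float] = field(default_factory=dict)
    #: transcript id -> list of (haplotype name, variant ids carried, fraction)
    haplotypes: Dict[str, List[Tuple[str, List[str], float]]] = field(default_factory=dict)
    #: fraction used for default two-haplotype (ref/alt) construction
    default_alt_fraction: float = 0.5
    min_junction_overlap: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error rate must be in [0, 0.2]")
        if self.n_reads <= 0 or self.read_length <= 0:
            raise ValueError("counts must be positive")
        if self.isoform_proportions:
            total = sum(self.isoform_proportions.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"isoform proportions sum to {total}, not 1")


@dataclass
class MsaSpec:
    n_rows: int = 200
    length: int = 60
    #: per-column conservation probability; scalar broadcast or full list
    conservation: float | Sequence[float] = 0.9
    alphabet: str = "ACGT"


@dataclass
class StructureSpec:
    #: chain id -> number of residues
    chains: Dict[str, int] = field(default_factory=lambda: {"A": 6, "B": 6, "C": 6})
    #: inter-chain contact pairs ((chain, res), (chain, res)) placed at 3.5 A
    contacts: List[Tuple[Tuple[str, int], Tuple[str, int]]] = field(
        default_factory=lambda: [(("A", 2), ("B", 3)), (("B", 5), ("C", 1))]
    )
    #: metal site: residues of the FIRST chain that coordinate one Zn at 2.1 A
    metal_residues: List[int] = field(default_factory=lambda: [4, 5, 6])
    contact_distance: float = 3.5
    metal_distance: float = 2.1
    grid_spacing: float = 10.0


@dataclass
class SimulationConfig:
    seed: int = 0
    locus: LocusSpec = field(default_factory=LocusSpec)
    reads: ReadSpec = field(default_factory=ReadSpec)
    msa: MsaSpec = field(default_factory=MsaSpec)
    structure: StructureSpec = field(default_factory=StructureSpec)


@dataclass
class GroundTruth:
    """Everything needed to score recovery tests without re-simulation."""

    isoform_proportions: Dict[str, float] = field(default_factory=dict)
    read_counts: Dict[str, int] = field(default_factory=dict)
    haplotype_read_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    allele_fractions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    junction_spanning_reads: int = 0
    junction_offset: int = 0
    msa_column_probabilities: List[float] = field(default_factory=list)
    contact_set: List[Tuple[str, int, str, int]] = field(default_factory=list)
    metal_residues: List[Tuple[str, int]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return asdict(self)
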