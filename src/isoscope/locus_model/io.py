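"""Reading and writing of FASTA / GTF / VCF at the package boundary.

Internal coordinates are 0-based half-open; GTF and VCF are 1-based at I/O.
The GTF written here annotates the CDS inclusive of the stop codon.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GenomeSequence, TranscriptModel, VariantRecord


# ---------------------------------------------------------------------------
# FASTA


def read_genome_fasta(path: str | os.PathLike) -> Dict[str, GenomeSequence]:
    genomes: Dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(records: Iterable[Tuple[str, str]], path: str | os.PathLike) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | os.PathLike) -> None:
    """Write gene/transcript/exon/CDS features (1-based inclusive)."""
    lines: List[str] = []

    def feat(tx: TranscriptModel, kind: str, start0: int, end0: int) -> str:
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        return "\t".join(
            [
                tx.contig_id,
                "isoscope",
                kind,
                str(start0 + 1),
                str(end0),
                ".",
                tx.strand,
                ".",
                attrs,
            ]
        )

    by_gene: Dict[str, List[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    for gene_id, txs in by_gene.items():
        g0 = min(tx.span[0] for tx in txs)
        g1 = max(tx.span[1] for tx in txs)
        proto = txs[0]
        attrs = f'gene_id "{gene_id}";'
        lines.append(
            "\t".join(
                [proto.contig_id, "isoscope", "gene", str(g0 + 1), str(g1), ".",
                 proto.strand, ".", attrs]
            )
        )
        for tx in txs:
            lines.append(feat(tx, "transcript", tx.span[0], tx.span[1]))
            for s, e in tx.exons:
                lines.append(feat(tx, "exon", s, e))
            if tx.cds_span is not None:
                for s, e in _cds_genomic_intervals(tx):
                    lines.append(feat(tx, "CDS", s, e))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _cds_genomic_intervals(tx: TranscriptModel) -> List[Tuple[int, int]]:
    """Genomic intervals (sorted) covered by the transcript-relative CDS span."""
    cs, ce = tx.cds_span  # type: ignore[misc]
    gpos = sorted(tx.transcript_to_genome(t) for t in range(cs, ce))
    out: List[Tuple[int, int]] = []
    for g in gpos:
        if out and g == out[-1][1]:
            out[-1] = (out[-1][0], g + 1)
        else:
            out.append((g, g + 1))
    return out


def read_gtf(path: str | os.PathLike) -> List[TranscriptModel]:
    """Read transcript models from a GTF file (exon and CDS features)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: List[TranscriptModel] = []
    for t in db.features_of_type("transcript"):
        tid = t.attributes["transcript_id"][0]
        gid = t.attributes["gene_id"][0]
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(t, featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end)
            for f in db.children(t, featuretype="CDS")
        )
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            contig_id=t.seqid,
            strand=t.strand,
            exons=exons,
            cds_span=None,
        )
        if cds:
            tpos = sorted(
                model.genome_to_transcript(g)
                for s, e in cds
                for g in range(s, e)
            )
            span = (tpos[0], tpos[-1] + 1)
            if tpos[-1] + 1 - tpos[0] != len(tpos):
                raise ValueError(f"CDS of {tid} is not contiguous in transcript space")
            partial = (span[1] - span[0]) % 3 != 0
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                contig_id=t.seqid,
                strand=t.strand,
                exons=exons,
                cds_span=span,
                cds_partial=partial,
            )
        out.append(model)
    return out


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | os.PathLike) -> List[VariantRecord]:
    """Read biallelic records; multiallelic sites are split per ALT allele.

    INFO keys named AF or AF_<population> populate population_frequencies;
    other numeric INFO keys are ingested verbatim as annotation scores.
    """
    out: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            freqs: Dict[str, float] = {}
            scores: Dict[str, float] = {}
            for key, val in rec.info.items():
                vals = val if isinstance(val, tuple) else (val,)
                try:
                    num = float(vals[0])
                except (TypeError, ValueError):
                    continue
                if key == "AF" or key.startswith("AF_"):
                    freqs[key[3:] or "ALL"] = num
                else:
                    scores[key] = num
            for alt in rec.alts or ():
                ref, alt_a, pos = _left_align_trim(rec.ref, alt, rec.start)
                out.append(
                    VariantRecord(
                        contig_id=rec.chrom,
                        position=pos,
                        ref_allele=ref,
                        alt_allele=alt_a,
                        variant_id=rec.id,
                        population_frequencies=freqs,
                        annotation_scores=scores,
                    )
                )
    return out


def _left_align_trim(ref: str, alt: str, pos: int) -> Tuple[str, str, int]:
    """Trim a shared suffix then a shared prefix, keeping one anchor base for indels."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return ref, alt, pos


def write_vcf(
    variants: Sequence[VariantRecord],
    path: str | os.PathLike,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write a minimal uncompressed VCF 4.2 file."""
    info_keys: List[str] = []
    for v in variants:
        for pop in v.population_frequencies:
            key = "AF" if pop == "ALL" else f"AF_{pop}"
            if key not in info_keys:
                info_keys.append(key)
        for name in v.annotation_scores:
            if name not in info_keys:
                info_keys.append(name)
    lines = ["##fileformat=VCFv4.2"]
    for contig, length in (contig_lengths or {}).items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    for key in info_keys:
        number = "A" if key == "AF" or key.startswith("AF_") else "1"
        lines.append(
            f'##INFO=<ID={key},Number={number},Type=Float,Description="{key}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.contig_id, v.position)):
        info_parts = []
        for pop, f in v.population_frequencies.items():
            key = "AF" if pop == "ALL" else f"AF_{pop}"
            info_parts.append(f"{key}={f:g}")
        for name, score in v.annotation_scores.items():
            info_parts.append(f"{name}={score:g}")
        lines.append(
            "\t".join(
                [
                    v.contig_id,
                    str(v.position + 1),
                    v.variant_id or ".",
                    v.ref_allele,
                    v.alt_allele,
                    ".",
                    "PASS",
                    ";".join(info_parts) or ".",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
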