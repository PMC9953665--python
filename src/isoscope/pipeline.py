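"""Stage orchestration behind the CLI: simulate -> annotate -> quantify ->
junction -> conserve -> contacts, with fixed-format reports and a manifest."""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from . import conservation as cons_mod
from . import junction as junc_mod
from . import structure as struct_mod
from .locus_model import (
    ConsequenceConfig,
    classify_consequence,
    project_variant,
    read_genome_fasta,
    read_gtf,
    read_vcf,
    write_fasta,
    write_gtf,
    write_vcf,
)
from .locus_model.sequence import inject_haplotype
from .quantify import (
    TranscriptSeq,
    allele_fraction,
    assign_reads,
    build_index,
    em_abundance,
    phase_pair,
    set_effective_lengths,
)
from .reports import REPORT_SCHEMAS, write_manifest, write_report
from .synthetic_data import (
    LocusSpec,
    MsaSpec,
    ReadSpec,
    StructureSpec,
    read_fastq,
    simulate_locus,
    simulate_msa,
    simulate_reads,
    simulate_structure,
    write_fastq,
)

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: Dict[str, object] = {
    "k": 31,
    "compat_fraction": 0.8,
    "flank": 20,
    "min_overlap": 10,
    "max_mismatches": 2,
    "nmd_threshold": 50,
    "interface_cutoff": 4.0,
    "metal_cutoff": 2.8,
    "usage_threshold": 90.0,
    "n_reads": 10000,
    "read_length": 100,
    "error_rate": 0.0,
    "neighborhood": 5000,
}

ALL_STAGES = ("simulate", "annotate", "quantify", "junction", "conserve", "contacts")

#: files produced by simulate and required by downstream stages
STAGE_INPUTS = {
    "annotate": ["genome.fasta", "annotation.gtf", "variants.vcf"],
    "quantify": ["genome.fasta", "annotation.gtf", "variants.vcf", "reads.fastq"],
    "junction": ["genome.fasta", "annotation.gtf", "locus.json", "reads.fastq"],
    "conserve": ["msa.fasta"],
    "contacts": ["structure.pdb"],
}


class ConfigurationError(ValueError):
    pass


def load_config(path: Optional[str]) -> dict:
    config: dict = {}
    if path:
        import yaml

        with open(path) as fh:
            config = yaml.safe_load(fh) or {}
    return config


def run_pipeline(config: dict) -> Dict[str, str]:
    """Execute enabled stages in dependency order; returns report paths.

    Re-running with the same config and seed produces byte-identical files.
    """
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "isoscope_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **(config.get("params") or {})}
    stages = {s: True for s in ALL_STAGES}
    stages.update(config.get("stages") or {})

    # fail fast on missing inter-stage inputs
    for stage, enabled in stages.items():
        if not enabled or stage == "simulate":
            continue
        needed = STAGE_INPUTS[stage]
        if not stages.get("simulate", False):
            missing = [f for f in needed if not (out_dir / f).exists()]
            if missing:
                raise ConfigurationError(
                    f"stage {stage!r} enabled but inputs missing and simulate "
                    f"disabled: {missing}"
                )

    outputs: Dict[str, str] = {}
    row_counts: Dict[str, int] = {}

    if stages.get("simulate"):
        _stage_simulate(seed, out_dir, params, outputs)
    if stages.get("annotate"):
        row_counts["consequences"] = _stage_annotate(out_dir, params, outputs)
    if stages.get("quantify"):
        counts = _stage_quantify(out_dir, params, outputs)
        row_counts.update(counts)
    if stages.get("junction"):
        row_counts["junction_counts"] = _stage_junction(out_dir, params, outputs)
    if stages.get("conserve"):
        row_counts["conservation"] = _stage_conserve(out_dir, outputs)
    if stages.get("contacts"):
        row_counts["contacts"] = _stage_contacts(out_dir, params, outputs)

    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: params[k] for k in sorted(params)},
        "stages": {s: bool(stages.get(s)) for s in ALL_STAGES},
        "row_counts": row_counts,
    }
    manifest_path = out_dir / "manifest.json"
    write_manifest(manifest, manifest_path)
    outputs["manifest"] = str(manifest_path)
    return outputs


def _stage_simulate(seed: int, out_dir: Path, params: dict, outputs: Dict[str, str]) -> None:
    logger.info("simulate: generating locus, reads, MSA and structure")
    bundle = simulate_locus(LocusSpec(), seed)
    write_fasta([(bundle.genome.contig_id, bundle.genome.sequence)], out_dir / "genome.fasta")
    write_gtf(bundle.transcripts, out_dir / "annotation.gtf")
    write_vcf(
        bundle.variants,
        out_dir / "variants.vcf",
        contig_lengths={bundle.genome.contig_id: len(bundle.genome)},
    )
    write_fasta(sorted(bundle.sequences.items()), out_dir / "transcripts.fasta")

    read_spec = ReadSpec(
        n_reads=int(params["n_reads"]),
        read_length=int(params["read_length"]),
        error_rate=float(params["error_rate"]),
    )
    reads = simulate_reads(bundle, read_spec, seed)
    write_fastq(reads, out_dir / "reads.fastq")

    aln, probs = simulate_msa(MsaSpec(), seed)
    write_fasta(list(zip(aln.row_ids, aln.rows)), out_dir / "msa.fasta")

    pdb_text, contact_set, metal_residues = simulate_structure(StructureSpec(), seed)
    (out_dir / "structure.pdb").write_text(pdb_text)

    locus_meta = {
        "fusion_id": bundle.fusion.transcript_id,
        "junction_offset": bundle.fusion.junction_offset,
        "donor": bundle.fusion.donor_transcript_id,
        "acceptor": bundle.fusion.acceptor_transcript_id,
    }
    (out_dir / "locus.json").write_text(json.dumps(locus_meta, indent=2) + "\n")
    truth = reads.ground_truth.to_json_dict()
    truth["msa_column_probabilities"] = probs
    truth["contact_set"] = sorted(contact_set)
    truth["metal_residues"] = metal_residues
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )
    for name in (
        "genome.fasta", "annotation.gtf", "variants.vcf", "transcripts.fasta",
        "reads.fastq", "msa.fasta", "structure.pdb", "locus.json", "ground_truth.json",
    ):
        outputs[name] = str(out_dir / name)


def _stage_annotate(out_dir: Path, params: dict, outputs: Dict[str, str]) -> int:
    logger.info("annotate: classifying variant consequences")
    genome = next(iter(read_genome_fasta(out_dir / "genome.fasta").values()))
    transcripts = read_gtf(out_dir / "annotation.gtf")
    variants = read_vcf(out_dir / "variants.vcf")
    cfg = ConsequenceConfig(neighborhood=int(params["neighborhood"]))
    rows = []
    for v in variants:
        for tx in transcripts:
            call = classify_consequence(v, tx, genome, cfg)
            if call is None:
                continue
            rows.append(
                {
                    "variant_id": v.variant_id or f"{v.position}:{v.ref_allele}>{v.alt_allele}",
                    "transcript_id": call.transcript_id,
                    "consequence": call.consequence,
                    "protein_change": call.protein_change or "",
                }
            )
    df = pd.DataFrame(rows, columns=REPORT_SCHEMAS["consequences"])
    path = out_dir / "consequences.tsv"
    write_report("consequences", df, path)
    outputs["consequences"] = str(path)
    return len(df)


def _quantify_inputs(out_dir: Path):
    genome = next(iter(read_genome_fasta(out_dir / "genome.fasta").values()))
    transcripts = read_gtf(out_dir / "annotation.gtf")
    from .locus_model.sequence import extract_transcript_sequence

    seqs = {
        tx.transcript_id: extract_transcript_sequence(genome, tx) for tx in transcripts
    }
    return genome, transcripts, seqs


def _stage_quantify(out_dir: Path, params: dict, outputs: Dict[str, str]) -> Dict[str, int]:
    logger.info("quantify: k-mer EM abundance, allele fractions, phase")
    genome, transcripts, seqs = _quantify_inputs(out_dir)
    variants = read_vcf(out_dir / "variants.vcf")
    names, read_seqs = read_fastq(out_dir / "reads.fastq")

    k = int(params["k"])
    index = build_index(
        [TranscriptSeq(t.transcript_id, t.gene_id, seqs[t.transcript_id]) for t in transcripts],
        k=k,
    )
    set_effective_lengths(index, float(params["read_length"]))
    counts = assign_reads(read_seqs, index, float(params["compat_fraction"]))
    abundance = em_abundance(counts, index)
    path = out_dir / "abundance.tsv"
    write_report("abundance", abundance.table, path)
    outputs["abundance"] = str(path)

    allele_rows = []
    exonic: Dict[str, List] = {}
    for v in variants:
        for tx in transcripts:
            proj = project_variant(v, tx)
            if proj is None:
                continue
            ref_hap = seqs[tx.transcript_id]
            alt_hap = inject_haplotype(ref_hap, [proj])
            call = allele_fraction(
                read_seqs,
                ref_hap,
                alt_hap,
                proj[0],
                proj[1],
                proj[2],
                k=k,
                variant_id=v.variant_id or "",
                transcript_id=tx.transcript_id,
            )
            exonic.setdefault(tx.transcript_id, []).append((v, proj))
            allele_rows.append(
                {
                    "variant_id": call.variant_id,
                    "transcript_id": call.transcript_id,
                    "ref_reads": call.ref_reads,
                    "alt_reads": call.alt_reads,
                    "ambiguous_reads": call.ambiguous_reads,
                    "alt_fraction": "" if call.alt_fraction is None else f"{call.alt_fraction:.6f}",
                    "genotype": call.genotype,
                }
            )
    allele_df = pd.DataFrame(allele_rows, columns=REPORT_SCHEMAS["alleles"])
    path = out_dir / "alleles.tsv"
    write_report("alleles", allele_df, path)
    outputs["alleles"] = str(path)

    phase_rows = []
    read_len = int(params["read_length"])
    for tid, items in exonic.items():
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                (va, pa), (vb, pb) = items[i], items[j]
                pair = sorted([pa, pb], key=lambda p: p[0])
                span = pair[1][0] + len(pair[1][1]) - pair[0][0]
                if span > read_len:
                    continue
                res = phase_pair(read_seqs, seqs[tid], pair[0], pair[1], read_length=read_len)
                phase_rows.append(
                    {
                        "variant_a": va.variant_id or "",
                        "variant_b": vb.variant_id or "",
                        "transcript_id": tid,
                        "ref_ref": res.ref_ref,
                        "ref_alt": res.ref_alt,
                        "alt_ref": res.alt_ref,
                        "alt_alt": res.alt_alt,
                        "verdict": res.verdict,
                    }
                )
    phase_df = pd.DataFrame(phase_rows, columns=REPORT_SCHEMAS["phase"])
    path = out_dir / "phase.tsv"
    write_report("phase", phase_df, path)
    outputs["phase"] = str(path)
    return {
        "abundance": len(abundance.table),
        "alleles": len(allele_df),
        "phase": len(phase_df),
    }


def _stage_junction(out_dir: Path, params: dict, outputs: Dict[str, str]) -> int:
    logger.info("junction: probe design, uniqueness screen, read counting")
    meta = json.loads((out_dir / "locus.json").read_text())
    genome, transcripts, seqs = _quantify_inputs(out_dir)
    fusion_id = meta["fusion_id"]
    probe = junc_mod.extract_probe(
        seqs[fusion_id],
        int(meta["junction_offset"]),
        int(params["flank"]),
        fused_transcript_id=fusion_id,
    )
    background = sorted(seqs.items())
    probe = junc_mod.screen_uniqueness(probe, background, int(params["max_mismatches"]))
    probe_df = pd.DataFrame(
        [
            {
                "fused_transcript_id": probe.fused_transcript_id,
                "junction_offset": probe.junction_offset,
                "flank": probe.flank,
                "probe_sequence": probe.probe_sequence,
                "uniqueness": probe.uniqueness,
                "n_hits": len(probe.hits),
            }
        ],
        columns=REPORT_SCHEMAS["probes"],
    )
    path = out_dir / "probes.tsv"
    write_report("probes", probe_df, path)
    outputs["probes"] = str(path)

    names, read_seqs = read_fastq(out_dir / "reads.fastq")
    n, _hits = junc_mod.count_junction_reads(
        zip(names, read_seqs), probe, int(params["min_overlap"]), 0
    )
    count_df = pd.DataFrame(
        [
            {
                "fused_transcript_id": fusion_id,
                "sample": "reads.fastq",
                "junction_reads": n,
            }
        ],
        columns=REPORT_SCHEMAS["junction_counts"],
    )
    path = out_dir / "junction_counts.tsv"
    write_report("junction_counts", count_df, path)
    outputs["junction_counts"] = str(path)
    return len(count_df)


def _stage_conserve(out_dir: Path, outputs: Dict[str, str]) -> int:
    logger.info("conserve: per-column conservation profile")
    aln = cons_mod.read_alignment_fasta(out_dir / "msa.fasta", reference_id="ref")
    profile = cons_mod.column_conservation(aln)
    path = out_dir / "conservation.tsv"
    write_report("conservation", profile, path)
    outputs["conservation"] = str(path)
    return len(profile)


def _stage_contacts(out_dir: Path, params: dict, outputs: Dict[str, str]) -> int:
    logger.info("contacts: inter-chain and metal-coordination tables")
    model = struct_mod.load_structure(out_dir / "structure.pdb", structure_id="structure.pdb")
    interface = struct_mod.inter_chain_contacts(model, float(params["interface_cutoff"]))
    metal = struct_mod.metal_coordination(model, cutoff=float(params["metal_cutoff"]))
    contacts = pd.concat([interface, metal], ignore_index=True)
    path = out_dir / "contacts.tsv"
    write_report("contacts", contacts, path)
    outputs["contacts"] = str(path)
    return len(contacts)
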