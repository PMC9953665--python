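import json

import numpy as np
import pytest

from isoscope.locus_model import (
    DECAY_NMD,
    DECAY_NONSTOP,
    DECAY_NORMAL,
    classify_decay,
    extract_transcript_sequence,
    find_orf_translate,
    read_gtf,
    write_gtf,
)
from isoscope.structure import inter_chain_contacts, load_structure, metal_coordination
from isoscope.synthetic_data import (
    GenerationError,
    LocusSpec,
    MsaSpec,
    ReadSpec,
    StructureSpec,
    simulate_locus,
    simulate_msa,
    simulate_reads,
    simulate_structure,
    write_fastq,
)
from isoscope.conservation import column_conservation


class TestSimulateLocus:
    def test_gtf_round_trip_identical_models(self, bundle, tmp_path):
        path = tmp_path / "locus.gtf"
        write_gtf(bundle.transcripts, path)
        reread = {t.transcript_id: t for t in read_gtf(path)}
        for tx in bundle.transcripts:
            back = reread[tx.transcript_id]
            assert back.exons == tx.exons
            assert back.strand == tx.strand
            assert back.cds_span == tx.cds_span

    def test_decay_classes_as_designed(self, bundle):
        expected = {"A1": DECAY_NORMAL, "A2": DECAY_NMD, "A3": DECAY_NONSTOP, "B1": DECAY_NORMAL}
        for tid, decay in expected.items():
            tx = bundle.transcript(tid)
            rec = find_orf_translate(bundle.sequences[tid], tx.cds_span, tx.cds_partial)
            assert classify_decay(tx, rec) == decay, tid

    def test_fusion_translation_diverges_after_junction(self, bundle, spec):
        a1 = bundle.transcript("A1")
        f1 = bundle.transcript("F1")
        pa = find_orf_translate(bundle.sequences["A1"], a1.cds_span)
        pf = find_orf_translate(bundle.sequences["F1"], f1.cds_span)
        n_full = (spec.donor_break - spec.cds_start_tx) // 3
        assert pf.sequence[:n_full] == pa.sequence[:n_full]
        assert pf.sequence[n_full:] != pa.sequence[n_full : len(pf.sequence)]
        assert pf.stop_reached

    def test_fusion_lands_in_acceptor_utr_with_frameshift(self, bundle, spec):
        b1 = bundle.transcript("B1")
        assert spec.acceptor_start < b1.cds_span[0]
        b_cds_in_fusion = spec.donor_break + (b1.cds_span[0] - spec.acceptor_start)
        assert (b_cds_in_fusion - spec.cds_start_tx) % 3 != 0

    def test_variants_match_genome(self, bundle):
        for v in bundle.variants:
            assert bundle.genome.sequence[v.position : v.end] == v.ref_allele
            assert v.alt_allele != v.ref_allele

    def test_variant_kinds_present(self, bundle):
        ids = {v.variant_id for v in bundle.variants}
        assert ids == {"v_5utr", "v_mis", "v_syn", "v_3utr", "v_splice"}

    def test_determinism(self, spec):
        b1 = simulate_locus(spec, seed=5)
        b2 = simulate_locus(spec, seed=5)
        assert b1.genome.sequence == b2.genome.sequence
        assert b1.sequences == b2.sequences
        b3 = simulate_locus(spec, seed=6)
        assert b3.genome.sequence != b1.genome.sequence


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, bundle):
        reads = simulate_reads(bundle, ReadSpec(n_reads=300, read_length=80), seed=3)
        haps = {}
        for name, seq in zip(reads.names, reads.sequences):
            _, tid, hap, start = name.split("|")
            source = bundle.sequences[tid]
            if hap != "ref":
                continue  # alt haplotypes checked via allele tests
            assert source[int(start) : int(start) + 80] == seq

    def test_multinomial_3sigma(self, bundle):
        props = {"A1": 0.7, "A3": 0.3}
        spec = ReadSpec(
            n_reads=10000,
            read_length=80,
            isoform_proportions=props,
            haplotypes={t: [("ref", [], 1.0)] for t in props},
        )
        reads = simulate_reads(bundle, spec, seed=4)
        lengths = {t: len(bundle.sequences[t]) - 80 + 1 for t in props}
        weights = {t: props[t] * lengths[t] for t in props}
        total_w = sum(weights.values())
        for t in props:
            p = weights[t] / total_w
            n = reads.ground_truth.read_counts[t]
            sigma = np.sqrt(10000 * p * (1 - p))
            assert abs(n - 10000 * p) <= 3 * sigma

    def test_seeded_determinism_byte_identical(self, bundle, tmp_path):
        spec = ReadSpec(n_reads=200, read_length=80, error_rate=0.01)
        r1 = simulate_reads(bundle, spec, seed=7)
        r2 = simulate_reads(bundle, spec, seed=7)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(r1, p1)
        write_fastq(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_read_longer_than_transcript_rejected(self, bundle):
        with pytest.raises(ValueError):
            simulate_reads(bundle, ReadSpec(n_reads=10, read_length=5000), seed=1)

    def test_error_rate_validation(self):
        with pytest.raises(ValueError):
            ReadSpec(error_rate=0.5)

    def test_ground_truth_allele_fractions(self, bundle):
        spec = ReadSpec(n_reads=100, read_length=80, default_alt_fraction=0.3)
        reads = simulate_reads(bundle, spec, seed=2)
        af = reads.ground_truth.allele_fractions
        assert af["A1"]["v_mis"] == pytest.approx(0.3)

    def test_junction_ground_truth_counts(self, bundle):
        spec = ReadSpec(
            n_reads=5000,
            read_length=80,
            isoform_proportions={"F1": 1.0},
            haplotypes={"F1": [("ref", [], 1.0)]},
        )
        reads = simulate_reads(bundle, spec, seed=9)
        junction = bundle.fusion.junction_offset
        expected = 0
        for name in reads.names:
            start = int(name.split("|")[3])
            if start <= junction - 10 and start + 80 >= junction + 10:
                expected += 1
        assert reads.ground_truth.junction_spanning_reads == expected
        assert expected > 0


class TestSimulateMsa:
    def test_p1_all_identical(self):
        aln, probs = simulate_msa(MsaSpec(n_rows=20, length=30, conservation=1.0), seed=1)
        assert all(r == aln.rows[0] for r in aln.rows)

    def test_p05_3sigma(self):
        aln, probs = simulate_msa(MsaSpec(n_rows=200, length=40, conservation=0.5), seed=0)
        prof = column_conservation(aln, include_reference=False)
        # 3-sigma binomial band around 50%
        sigma = 100 * np.sqrt(0.25 / 199)
        assert ((prof["percent"] - 50.0).abs() <= 3 * sigma + 1e-9).all()

    def test_determinism(self):
        a1, _ = simulate_msa(MsaSpec(), seed=11)
        a2, _ = simulate_msa(MsaSpec(), seed=11)
        assert a1.rows == a2.rows

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_msa(MsaSpec(conservation=1.5), seed=1)


class TestSimulateStructure:
    def test_contacts_recovered_exactly(self):
        spec = StructureSpec()
        pdb_text, contact_set, metal_residues = simulate_structure(spec, seed=1)
        s = load_structure(pdb_text, structure_id="sim")
        table = inter_chain_contacts(s, cutoff=4.0)
        got = {
            (r.chain_i, r.residue_i, r.chain_j, r.residue_j) for r in table.itertuples()
        }
        assert got == contact_set

    def test_metal_site_recovered(self):
        pdb_text, _, metal_residues = simulate_structure(StructureSpec(), seed=1)
        s = load_structure(pdb_text)
        table = metal_coordination(s, cutoff=2.8)
        got = {(r.chain_i, r.residue_i) for r in table.itertuples()}
        assert got == set(metal_residues)

    def test_empty_contact_spec(self):
        spec = StructureSpec(contacts=[], metal_residues=[])
        pdb_text, contact_set, metal_residues = simulate_structure(spec, seed=1)
        s = load_structure(pdb_text)
        assert inter_chain_contacts(s, cutoff=4.0).empty
        assert metal_coordination(s).empty
        assert contact_set == set()

    def test_infeasible_requests_rejected(self):
        with pytest.raises(GenerationError):
            simulate_structure(
                StructureSpec(contacts=[(("A", 1), ("A", 2))]), seed=1
            )
        with pytest.raises(GenerationError):
            simulate_structure(
                StructureSpec(contacts=[(("A", 1), ("B", 1)), (("A", 1), ("C", 1))]),
                seed=1,
            )
        with pytest.raises(GenerationError):
            simulate_structure(StructureSpec(metal_residues=[99]), seed=1)
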