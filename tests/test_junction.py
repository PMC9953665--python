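import numpy as np
import pytest

from isoscope.junction import (
    JunctionProbe,
    count_junction_reads,
    extract_probe,
    screen_uniqueness,
)
from isoscope.locus_model import reverse_complement


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_hits(probe_seq, background, max_mismatches):
    """Oracle: all-windows Hamming scan in pure python."""
    hits = []
    for seq_id, seq in background:
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            for off in range(len(oriented) - len(probe_seq) + 1):
                window = oriented[off : off + len(probe_seq)]
                mism = sum(a != b for a, b in zip(window, probe_seq))
                if mism <= max_mismatches:
                    hits.append((seq_id, off, strand, mism))
    return hits


class TestExtractProbe:
    def test_flank_one(self):
        p = extract_probe("AACCGGTT", 4, flank=1)
        assert p.probe_sequence == "CG"

    def test_default_flank_construction_identity(self, rng):
        donor = random_seq(rng, 100)
        acceptor = random_seq(rng, 100)
        fused = donor + acceptor
        p = extract_probe(fused, 100)
        assert len(p.probe_sequence) == 40
        assert p.probe_sequence == donor[-20:] + acceptor[:20]

    def test_flank_too_large(self):
        with pytest.raises(ValueError):
            extract_probe("A" * 100, 10, flank=25)


class TestScreenUniqueness:
    def test_verbatim_copy_non_unique(self, rng):
        probe_seq = random_seq(rng, 40)
        probe = JunctionProbe("F", 20, 20, probe_seq)
        decoy = random_seq(rng, 300) + probe_seq + random_seq(rng, 300)
        screened = screen_uniqueness(probe, [("decoy", decoy)], max_mismatches=2)
        assert screened.uniqueness == "non-unique"
        assert any(h.mismatches == 0 for h in screened.hits)

    def test_100_random_decoys_vs_brute_force(self, rng):
        probe_seq = random_seq(rng, 40)
        probe = JunctionProbe("F", 20, 20, probe_seq)
        background = [(f"d{i}", random_seq(rng, 1000)) for i in range(100)]
        screened = screen_uniqueness(probe, background, max_mismatches=2)
        expected = brute_force_hits(probe_seq, background, 2)
        got = [(h.sequence_id, h.offset, h.strand, h.mismatches) for h in screened.hits]
        assert sorted(got) == sorted(expected)
        assert screened.uniqueness == ("non-unique" if expected else "unique")

    def test_two_mismatch_boundary(self, rng):
        probe_seq = random_seq(rng, 40)
        window = list(probe_seq)
        for i in (5, 25):
            window[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[i]]
        decoy = random_seq(rng, 100) + "".join(window) + random_seq(rng, 100)
        p2 = screen_uniqueness(
            JunctionProbe("F", 20, 20, probe_seq), [("decoy", decoy)], max_mismatches=2
        )
        assert p2.uniqueness == "non-unique"
        p1 = screen_uniqueness(
            JunctionProbe("F", 20, 20, probe_seq), [("decoy", decoy)], max_mismatches=1
        )
        assert p1.uniqueness == "unique"

    def test_self_hit_is_unique(self, rng):
        fused = random_seq(rng, 200)
        probe = extract_probe(fused, 100, fused_transcript_id="F")
        screened = screen_uniqueness(probe, [("F", fused)], max_mismatches=2)
        assert screened.uniqueness == "unique"
        assert len(screened.hits) >= 1

    def test_empty_background_rejected(self, rng):
        probe = JunctionProbe("F", 20, 20, random_seq(rng, 40))
        with pytest.raises(ValueError):
            screen_uniqueness(probe, [])


class TestCountJunctionReads:
    @pytest.fixture()
    def fused(self, rng):
        fused = random_seq(rng, 400)
        probe = extract_probe(fused, 200, fused_transcript_id="F")
        probe.uniqueness = "unique"
        return fused, probe

    def test_no_reads(self, fused):
        _, probe = fused
        n, hits = count_junction_reads([], probe)
        assert n == 0 and hits == []

    def test_spanning_read_counted_both_orientations(self, fused):
        seq, probe = fused
        read = seq[150:250]
        assert count_junction_reads([("r1", read)], probe)[0] == 1
        assert count_junction_reads([("r1", reverse_complement(read))], probe)[0] == 1

    def test_donor_side_only_not_counted(self, fused):
        seq, probe = fused
        # ends 5 bases past the junction: right overlap 5 < min_overlap 10
        read = seq[105:205]
        assert count_junction_reads([("r1", read)], probe)[0] == 0

    def test_min_overlap_exceeds_flank(self, fused):
        _, probe = fused
        with pytest.raises(ValueError):
            count_junction_reads([], probe, min_overlap=25)

    def test_read_counted_once(self, fused):
        seq, probe = fused
        read = seq[150:250]
        n, hits = count_junction_reads([("r1", read)] * 3, probe)
        assert n == 3 and hits == ["r1", "r1", "r1"]

    def test_monotonicity(self, fused, rng):
        seq, probe = fused
        reads = [("r%d" % i, seq[s : s + 100]) for i, s in enumerate(range(90, 290, 7))]
        extra = [("x%d" % i, random_seq(rng, 100)) for i in range(5)]
        base, _ = count_junction_reads(reads, probe)
        more, _ = count_junction_reads(reads + extra, probe)
        assert more >= base
        relaxed, _ = count_junction_reads(reads, probe, max_mismatches=2)
        assert relaxed >= base
        stricter, _ = count_junction_reads(reads, probe, min_overlap=15)
        assert stricter <= base

    def test_exact_agreement_with_ground_truth_intervals(self, fused):
        """Error-free reads: counted iff the source interval spans the
        junction by >= min_overlap on both sides."""
        seq, probe = fused
        junction, min_ov = 200, 10
        reads = []
        expected = 0
        for start in range(100, 300, 3):
            reads.append((f"r{start}", seq[start : start + 100]))
            if start <= junction - min_ov and start + 100 >= junction + min_ov:
                expected += 1
        n, _ = count_junction_reads(reads, probe, min_overlap=min_ov)
        assert n == expected


class TestConcordanceWithQuantifier:
    def test_junction_counts_track_fusion_abundance(self, bundle):
        """Across samples with varying fusion abundance, junction-spanning
        read counts correlate with the EM fusion estimate (Spearman > 0.9)."""
        from scipy.stats import spearmanr

        from isoscope.quantify import (
            TranscriptSeq,
            assign_reads,
            build_index,
            em_abundance,
            set_effective_lengths,
        )
        from isoscope.synthetic_data import ReadSpec, simulate_reads

        tx_ids = ["A1", "A2", "A3", "B1", "F1"]
        index = build_index(
            [TranscriptSeq(t, "G", bundle.sequences[t]) for t in tx_ids], k=31
        )
        set_effective_lengths(index, 80.0)
        probe = extract_probe(
            bundle.sequences["F1"], bundle.fusion.junction_offset, 20,
            fused_transcript_id="F1",
        )
        probe = screen_uniqueness(probe, sorted(bundle.sequences.items()), 2)
        assert probe.uniqueness == "unique"

        fusion_props = np.linspace(0.02, 0.5, 20)
        junction_counts = []
        fusion_estimates = []
        for i, f in enumerate(fusion_props):
            rest = (1.0 - f) / 4.0
            props = {t: rest for t in tx_ids}
            props["F1"] = float(f)
            spec = ReadSpec(
                n_reads=2000,
                read_length=80,
                isoform_proportions=props,
                haplotypes={t: [("ref", [], 1.0)] for t in tx_ids},
            )
            reads = simulate_reads(bundle, spec, seed=100 + i)
            n, _ = count_junction_reads(
                zip(reads.names, reads.sequences), probe, min_overlap=10
            )
            junction_counts.append(n)
            counts = assign_reads(reads.sequences, index)
            ab = em_abundance(counts, index)
            fusion_estimates.append(ab.tpm("F1"))
        rho = spearmanr(junction_counts, fusion_estimates).statistic
        assert rho > 0.9
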