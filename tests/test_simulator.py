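import numpy as np
import pytest

from virin.candidate_extraction import passes_single_mate_unmapped_filter
from virin.io_formats import cigar_query_length, write_sam_record
from virin.simulator import (
    SimulationConfig,
    TrackLayout,
    emit_tracks,
    layout_for_truth,
    plant_integrations,
    simulate_host,
    simulate_sample,
)
from virin.viral_search import revcomp


class TestHost:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=1, host_length=5000)
        assert simulate_host(cfg).seq == simulate_host(cfg).seq

    def test_gc_concentration(self):
        cfg = SimulationConfig(seed=2, host_length=100_000, gc=0.5)
        seq = simulate_host(cfg).seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.49 <= gc <= 0.51

    def test_gc_zero_is_at_only(self):
        cfg = SimulationConfig(seed=3, host_length=2000, gc=0.0)
        assert set(simulate_host(cfg).seq) <= {"A", "T"}


class TestIntegrations:
    def test_no_insertions_identity(self, clean_sim):
        sample, _ = clean_sim
        cfg = SimulationConfig(seed=5, host_length=20_000, n_insertions=0)
        rng = np.random.default_rng(5)
        host = simulate_host(cfg, rng)
        genome, _segs, truth = plant_integrations(host, sample.virus, cfg, rng)
        assert genome == host.seq and truth == []

    def test_splice_arithmetic_and_conservation(self, clean_sim):
        sample, _ = clean_sim
        host, virus = sample.host, sample.virus
        inserted = sum(t.virus_end - t.virus_start + 1 for t in sample.truth)
        assert len(sample.augmented) == len(host.seq) + inserted
        for t in sample.truth:
            assert t.right_junction == t.left_junction + 1

    def test_partial_minus_strand_segment_is_revcomp(self):
        cfg = SimulationConfig(
            seed=17, host_length=30_000, n_insertions=3, virus_length=2000,
            fraction_partial=1.0, min_spacing=4000,
        )
        rng = np.random.default_rng(17)
        host = simulate_host(cfg, rng)
        from virin.simulator import simulate_virus

        virus = simulate_virus(cfg)
        genome, segs, truth = plant_integrations(host, virus, cfg, rng)
        for seg, t in zip([s for s in segs if s.kind == "virus"], truth):
            piece = genome[seg.aug_start : seg.aug_start + seg.length]
            ref = virus.seq[t.virus_start - 1 : t.virus_end]
            assert piece == (ref if t.strand == "+" else revcomp(ref))
            assert not t.full_length

    def test_impossible_spacing_rejected(self):
        cfg = SimulationConfig(seed=6, host_length=8000, n_insertions=10)
        rng = np.random.default_rng(6)
        host = simulate_host(cfg, rng)
        from virin.simulator import simulate_virus

        with pytest.raises(ValueError):
            plant_integrations(host, simulate_virus(cfg), cfg, rng)


class TestReads:
    def test_pair_count_tracks_coverage(self, clean_sim):
        sample, prov = clean_sim
        expected = sample.config.coverage * len(sample.augmented) / (2 * sample.config.read_len)
        assert len(prov) == int(round(expected))
        assert len(sample.reads) == len(sample.reads2) == len(prov)

    def test_error_free_reads_are_genome_substrings(self, clean_sim):
        sample, _ = clean_sim
        g = sample.augmented
        for name, seq, _q in sample.reads[:200]:
            assert seq in g or revcomp(seq) in g

    def test_byte_identical_under_seed(self):
        cfg = SimulationConfig(seed=9, host_length=12_000, n_insertions=1,
                               virus_length=2000, coverage=3)
        s1, _ = simulate_sample(cfg)
        s2, _ = simulate_sample(cfg)
        assert s1.reads == s2.reads and s1.reads2 == s2.reads2
        assert [write_sam_record(r) for r in s1.alignment] == [
            write_sam_record(r) for r in s2.alignment
        ]


class TestTruthAlignment:
    def test_flag_and_cigar_consistency(self, clean_sim):
        sample, _ = clean_sim
        by_name = {}
        for rec in sample.alignment:
            by_name.setdefault(rec.qname, []).append(rec)
            if rec.cigar:
                assert cigar_query_length(rec.cigar) == len(rec.seq)
            if rec.flag & 0x4:
                assert rec.cigar == []
        for recs in by_name.values():
            assert len(recs) == 2
            f1, f2 = recs[0].flag, recs[1].flag
            assert bool(f1 & 0x4) == bool(f2 & 0x8)
            assert bool(f2 & 0x4) == bool(f1 & 0x8)

    def test_junction_reads_softclip_at_truth(self, clean_sim):
        sample, _ = clean_sim
        truth = set(sample.truth_junctions)
        n_clip = 0
        for rec in sample.alignment:
            if not rec.cigar or len(rec.cigar) == 1:
                continue
            ops = [op for op, _n in rec.cigar]
            if ops == ["S", "M"]:
                assert rec.pos in truth
            elif ops == ["M", "S"]:
                assert rec.reference_end in truth
            n_clip += 1
        assert n_clip > 0

    def test_fully_viral_reads_form_candidate_population(self, clean_sim):
        sample, _ = clean_sim
        n_cand = sum(
            1 for rec in sample.alignment
            if passes_single_mate_unmapped_filter(rec.flag)
        )
        assert n_cand > 0
        for rec in sample.alignment:
            if passes_single_mate_unmapped_filter(rec.flag):
                assert rec.mate_rname != "*"


class TestTracks:
    def test_layout_renders_consistent_tracks(self, clean_sim):
        sample, _ = clean_sim
        layout, expected = layout_for_truth(sample.truth, len(sample.host.seq))
        dnase, repeats, gtf = emit_tracks(layout, sample.host.id)
        assert len(expected) == 2 * len(sample.truth)
        assert all(iv.attrs["repeat_class"] in ("LTR", "LINE") for iv in repeats)
        assert all(line.count("\t") == 8 for line in gtf)

    def test_overlapping_layout_conflict_rejected(self):
        layout = TrackLayout(dnase=[(100, 200), (150, 250)])
        with pytest.raises(ValueError, match="overlapping"):
            emit_tracks(layout, "chr1")

    def test_empty_layout_gives_empty_tracks(self):
        dnase, repeats, gtf = emit_tracks(TrackLayout(), "chr1")
        assert dnase == [] and repeats == [] and gtf == []
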