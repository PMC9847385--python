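import numpy as np
import pytest
from Bio import Align

from virin.config import ScreenConfig
from virin.io_formats import FastaRecord
from virin.viral_search import (
    align_to_panel,
    build_kmer_index,
    revcomp,
    screen_sample,
)

RAW = ScreenConfig(min_identity=0.0, min_aln_len=1)  # no acceptance gates


def full_sw():
    """Independent full-matrix local-alignment oracle (same scoring scheme)."""
    return Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-1,
    )


class TestKmerIndex:
    def test_forward_position_count(self):
        panel = [FastaRecord("v", "", "ACGTACGTACGTACGTACGT")]  # 20-mer
        idx = build_kmer_index(panel, k=15)
        fwd = sum(
            1 for hits in idx.index.values() for v, off, s in hits if s == "+"
        )
        assert fwd == 6  # 20 - 15 + 1

    def test_k_larger_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_index([FastaRecord("v", "", "ACGT")], k=15)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_index([], k=15)

    def test_both_strands_indexed(self):
        panel = [FastaRecord("v", "", "A" * 10 + "CGCGCGTTTTAAACG" + "T" * 10)]
        idx = build_kmer_index(panel, k=15)
        kmer = "CGCGCGTTTTAAACG"
        assert any(s == "+" for _, _, s in idx.seeds(kmer))
        assert any(s == "-" for _, _, s in idx.seeds(revcomp(kmer)))

    def test_n_containing_kmers_skipped(self):
        panel = [FastaRecord("v", "", "ACGTN" + "ACGT" * 10)]
        idx = build_kmer_index(panel, k=15)
        assert all("N" not in km for km in idx.index)


class TestAligner:
    def test_exact_substring(self, panel):
        idx = build_kmer_index(panel, k=15)
        query = panel[0].seq[50:150]
        hit = align_to_panel(query, idx, config=RAW)
        assert hit.virus_id == "virusA"
        assert hit.score == 100
        assert hit.identity == 1.0
        assert (hit.r_start, hit.r_end, hit.strand) == (51, 150, "+")

    def test_strand_symmetry(self, panel):
        idx = build_kmer_index(panel, k=15)
        query = panel[0].seq[50:150]
        fwd = align_to_panel(query, idx, config=RAW)
        rev = align_to_panel(revcomp(query), idx, config=RAW)
        assert rev.score == fwd.score
        assert rev.strand == "-"
        assert (rev.r_start, rev.r_end) == (fwd.r_start, fwd.r_end)

    def test_random_query_yields_none_at_default_gates(self, panel):
        rng = np.random.default_rng(99)
        idx = build_kmer_index(panel, k=15)
        query = "".join(rng.choice(list("ACGT"), size=100))
        assert align_to_panel(query, idx, config=ScreenConfig()) is None
        # oracle: no local alignment with >= 90% identity over >= 30 columns
        aligner = full_sw()
        best = max(aligner.score(rec.seq, query) for rec in panel)
        # score of any 90%-identity, 30+-column alignment is >= 0.8 * 30
        assert best < 0.8 * 30

    def test_agreement_with_full_matrix_oracle(self, panel):
        """Banded score equals full local DP when the optimum is in-band
        (substitution-only divergence keeps the optimum on the seed diagonal)."""
        rng = np.random.default_rng(5)
        aligner = full_sw()
        idx = build_kmer_index(panel, k=15)
        for _ in range(50):
            src = panel[int(rng.integers(0, 2))]
            start = int(rng.integers(0, len(src.seq) - 120))
            q = list(src.seq[start : start + 100])
            for pos in rng.choice(100, size=int(rng.integers(0, 10)), replace=False):
                q[pos] = rng.choice([b for b in "ACGT" if b != q[pos]])
            query = "".join(q)
            hit = align_to_panel(query, idx, config=RAW)
            full = max(aligner.score(rec.seq, query) for rec in panel)
            assert hit is not None and hit.score == int(full)

    def test_determinism(self, panel):
        idx = build_kmer_index(panel, k=15)
        query = panel[1].seq[10:90]
        hits = [align_to_panel(query, idx, config=RAW) for _ in range(3)]
        assert len({(h.virus_id, h.score, h.r_start, h.r_end, h.strand) for h in hits}) == 1

    def test_query_shorter_than_k_is_none(self, panel):
        idx = build_kmer_index(panel, k=15)
        assert align_to_panel("ACGTACGT", idx, config=RAW) is None


class _Frag:
    def __init__(self, fid, seq):
        self.fragment_id = fid
        self.clipped_seq = seq


class _Cand:
    def __init__(self, name, seq):
        self.qname = name
        self.seq = seq


class TestScreen:
    def test_read_count_cutoff_boundary(self, panel):
        idx = build_kmer_index(panel, k=15)
        cfg = ScreenConfig(min_virus_reads=3)
        frag_seq = panel[0].seq[100:160]
        # 2 hits: below the closed cutoff bound
        res = screen_sample([], [_Frag(f"f{i}", frag_seq) for i in range(2)], idx, config=cfg)
        assert res.counts == {"virusA": 2}
        assert res.retained_viruses == set()
        # 3 hits: exactly at the cutoff -> retained
        res = screen_sample([], [_Frag(f"f{i}", frag_seq) for i in range(3)], idx, config=cfg)
        assert res.retained_viruses == {"virusA"}

    def test_no_hits_gives_empty_result(self, panel):
        idx = build_kmer_index(panel, k=15)
        res = screen_sample([_Cand("q", "ACGT" * 30)], [], idx, config=ScreenConfig())
        assert res.counts == {} and res.retained_viruses == set()

    def test_best_hit_assignment_counts_each_read_once(self, panel):
        idx = build_kmer_index(panel, k=15)
        cfg = ScreenConfig(min_virus_reads=1)
        reads = [_Cand("a", panel[0].seq[:80]), _Cand("b", panel[1].seq[:80])]
        res = screen_sample(reads, [], idx, config=cfg)
        assert res.counts == {"virusA": 1, "virusB": 1}
        assert sum(res.counts.values()) == len(reads)
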