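import numpy as np
import pytest

from virin.assembly import (
    Contig,
    assemble_contigs,
    assign_contigs,
    build_dbg,
    completeness,
    count_supporting_reads,
)
from virin.config import AssemblyConfig, ScreenConfig
from virin.io_formats import FastaRecord
from virin.viral_search import build_kmer_index, revcomp

ERRORFREE = AssemblyConfig(k=33, min_kmer_count=1)


def tiling_reads(source: str, read_len: int = 150, step: int = 5, rc_every: int = 2) -> list[str]:
    reads = []
    for j, i in enumerate(range(0, len(source) - read_len + 1, step)):
        r = source[i : i + read_len]
        reads.append(revcomp(r) if j % rc_every == 0 else r)
    return reads


def unique_kmer_sequence(rng: np.random.Generator, length: int, k: int = 33) -> str:
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        kmers = {seq[i : i + k] for i in range(length - k + 1)}
        rc_kmers = {revcomp(km) for km in kmers}
        if len(kmers) == length - k + 1 and not (kmers & rc_kmers):
            return seq


class TestGraph:
    def test_single_kmer_read(self):
        g = build_dbg(["A" * 16 + "C" + "G" * 16], k=33)
        assert len(g.edge_counts) == 1
        assert list(g.edge_counts.values()) == [1]

    def test_repeated_reads_multiply_edges(self):
        # every canonical 5-mer of this read occurs once per copy
        read = "ACGGATTCAGC"
        g = build_dbg([read] * 3, k=5)
        assert set(g.edge_counts.values()) == {3}
        assert len(g.edge_counts) == len(read) - 5 + 1

    def test_short_reads_only_empty_graph(self):
        g = build_dbg(["ACGT", "GGGG"], k=33)
        assert not g.edge_counts
        assert assemble_contigs(g, ERRORFREE) == []

    def test_reads_split_at_n(self):
        left, right = "A" * 20 + "CGCA" * 4, "T" * 20 + "GCAT" * 4
        g = build_dbg([left + "N" + right], k=33)
        expected = (len(left) - 32) + (len(right) - 32)
        assert sum(g.edge_counts.values()) == expected


class TestContigs:
    def test_reconstruction_from_tiling_reads(self):
        rng = np.random.default_rng(11)
        source = unique_kmer_sequence(rng, 5000)
        g = build_dbg(tiling_reads(source), k=33)
        contigs = assemble_contigs(g, ERRORFREE)
        assert len(contigs) == 1
        c = contigs[0]
        assert c.length >= 0.99 * len(source)
        assert c.seq in source or revcomp(c.seq) in source

    def test_disjoint_sources_no_chimeras(self):
        rng = np.random.default_rng(12)
        a = unique_kmer_sequence(rng, 2000)
        b = unique_kmer_sequence(rng, 2000)
        g = build_dbg(tiling_reads(a) + tiling_reads(b), k=33)
        contigs = assemble_contigs(g, ERRORFREE)
        assert len(contigs) >= 2
        for c in contigs:
            assert (c.seq in a or revcomp(c.seq) in a) != (c.seq in b or revcomp(c.seq) in b)

    def test_no_contig_kmer_absent_from_reads(self):
        rng = np.random.default_rng(13)
        source = unique_kmer_sequence(rng, 1000)
        reads = tiling_reads(source)
        g = build_dbg(reads, k=33)
        read_kmers = set()
        for r in reads:
            for i in range(len(r) - 32):
                km = r[i : i + 33]
                read_kmers.add(min(km, revcomp(km)))
        for c in assemble_contigs(g, ERRORFREE):
            for i in range(len(c.seq) - 32):
                km = c.seq[i : i + 33]
                assert min(km, revcomp(km)) in read_kmers

    def test_pruning_drops_singleton_error_kmers(self):
        rng = np.random.default_rng(14)
        source = unique_kmer_sequence(rng, 1500)
        reads = tiling_reads(source, step=3)
        bad = list(reads[0])
        bad[70] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad[70]]
        g = build_dbg(reads + ["".join(bad)], k=33)
        contigs = assemble_contigs(g, AssemblyConfig(k=33, min_kmer_count=2))
        assert len(contigs) == 1
        assert contigs[0].seq in source or revcomp(contigs[0].seq) in source

    def test_supporting_read_counts(self):
        rng = np.random.default_rng(15)
        source = unique_kmer_sequence(rng, 500)
        reads = tiling_reads(source, step=10)
        g = build_dbg(reads, k=33)
        contigs = assemble_contigs(g, ERRORFREE)
        count_supporting_reads(contigs, reads, 33)
        assert contigs[0].n_reads_supporting == len(reads)


class TestCompleteness:
    def test_percent_and_strict_bound(self, panel):
        genome = FastaRecord("g", "", "ACGT" * 250)  # 1000 nt
        reports = completeness(
            [Contig(seq="A" * 860, virus_id="g")], [genome], config=AssemblyConfig()
        )
        assert reports[0].completeness_pct == pytest.approx(86.0)
        assert reports[0].retained

    def test_exactly_five_percent_not_retained(self):
        genome = FastaRecord("g", "", "ACGT" * 250)
        (rep,) = completeness([Contig(seq="A" * 50, virus_id="g")], [genome])
        assert rep.completeness_pct == pytest.approx(5.0)
        assert not rep.retained  # strict > 5 bound

    def test_screened_virus_without_contigs_reports_zero(self):
        genome = FastaRecord("g", "", "ACGT" * 250)
        (rep,) = completeness([], [genome], viruses={"g"})
        assert rep.completeness_pct == 0.0 and not rep.retained

    def test_unassigned_contigs_excluded(self):
        genome = FastaRecord("g", "", "ACGT" * 250)
        assert completeness([Contig(seq="A" * 700)], [genome]) == []

    def test_assignment_via_panel_alignment(self, panel):
        idx = build_kmer_index(panel, k=15)
        contigs = [Contig(seq=panel[1].seq[10:200])]
        assign_contigs(contigs, idx, ScreenConfig())
        assert contigs[0].virus_id == "virusB"
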