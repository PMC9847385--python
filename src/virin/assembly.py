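"""Minimal de Bruijn graph assembler (default k = 33) and completeness screen.

K-mers are canonicalized (each stored under min(kmer, revcomp)) so strandless
reads from either orientation collapse onto one graph.  Contigs are maximal
non-branching paths (unitigs); no bubble popping or scaffolding is attempted —
adequate for desk-scale viral genomes.  The completeness screen reports the
longest assembled contig per virus as a percentage of the viral genome length
and retains viruses strictly above 5% by default.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from virin.config import AssemblyConfig, ScreenConfig
from virin.io_formats import FastaRecord
from virin.viral_search import KmerIndex, align_to_panel, revcomp


@dataclass
class Contig:
    seq: str
    virus_id: str = "unassigned"
    n_reads_supporting: int = 0

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class CompletenessReport:
    sample_id: str
    virus_id: str
    genome_length: int
    longest_contig_length: int
    completeness_pct: float
    retained: bool


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _split_at_n(seq: str) -> list[str]:
    return [part for part in seq.upper().split("N") if part]


class DeBruijnGraph:
    """(k-1)-mer nodes with k-mer edges weighted by occurrence count.

    Edges are stored in the doubled (both-orientations) representation:
    every k-mer contributes prefix->suffix and revcomp(suffix)->revcomp(prefix).
    """

    def __init__(self, k: int):
        self.k = k
        self.edge_counts: Counter = Counter()  # canonical k-mer -> count

    def add_read(self, seq: str) -> None:
        for part in _split_at_n(seq):
            if len(part) < self.k:
                continue
            for i in range(len(part) - self.k + 1):
                self.edge_counts[_canonical(part[i : i + self.k])] += 1

    def pruned_kmers(self, min_count: int) -> list[str]:
        return [km for km, c in self.edge_counts.items() if c >= min_count]


def build_dbg(reads: list[str], k: int = 33, min_kmer_count: int | None = None) -> DeBruijnGraph:
    """Count canonical k-mers from reads; reads with N are split at the N."""
    graph = DeBruijnGraph(k)
    for read in reads:
        graph.add_read(read)
    return graph


def _prune_minority_edges(
    kmers: set[str], counts: Counter, ratio: float, min_count: int
) -> set[str]:
    """Drop branch edges far below their dominant sibling's multiplicity.

    Recurrent sequencing errors at high coverage pass an absolute count
    threshold but remain rare relative to the true edge sharing their source
    node; removing them restores non-branching paths (cheap stand-in for
    bubble popping / tip clipping).  Both orientations are scanned, so
    in-branches are handled via the reverse complement.
    """
    for _ in range(3):
        by_source: dict[str, list[str]] = defaultdict(list)
        for km in kmers:
            for edge in {km, revcomp(km)}:
                by_source[edge[:-1]].append(edge)
        drop: set[str] = set()
        for edges in by_source.values():
            if len(edges) < 2:
                continue
            cmax = max(counts[_canonical(e)] for e in edges)
            for e in edges:
                c = counts[_canonical(e)]
                if c < ratio * cmax and c <= max(min_count, ratio * cmax):
                    drop.add(_canonical(e))
        if not drop:
            break
        kmers -= drop
    return kmers


def assemble_contigs(graph: DeBruijnGraph, config: AssemblyConfig | None = None) -> list[Contig]:
    """Emit maximal non-branching paths (unitigs) as contigs.

    Edges below ``min_kmer_count`` are pruned first, then minority branch
    edges relative to their siblings.  Contigs shorter than 2k are dropped.
    Output order: length descending, ties by sequence.
    """
    config = config or AssemblyConfig(k=graph.k)
    k = graph.k
    kmers = set(graph.pruned_kmers(config.min_kmer_count))
    kmers = _prune_minority_edges(
        kmers, graph.edge_counts, config.minority_edge_ratio, config.min_kmer_count
    )
    if not kmers:
        return []
    # adjacency over oriented (k-1)-mers
    out_edges: dict[str, list[str]] = defaultdict(list)
    in_deg: Counter = Counter()
    oriented: set[str] = set()
    for km in kmers:
        for edge in {km, revcomp(km)}:
            pre, suf = edge[:-1], edge[1:]
            out_edges[pre].append(suf)
            in_deg[suf] += 1
            oriented.add(edge)
    nodes = set(out_edges) | set(in_deg)

    def is_branching(node: str) -> bool:
        return len(out_edges.get(node, [])) != 1 or in_deg.get(node, 0) != 1

    paths: list[str] = []
    used: set[str] = set()  # oriented k-mers consumed
    for node in nodes:
        if not is_branching(node):
            continue
        for nxt in out_edges.get(node, []):
            edge = node + nxt[-1]
            if edge in used:
                continue
            used.add(edge)
            used.add(revcomp(edge))
            path = [node, nxt]
            cur = nxt
            while not is_branching(cur):
                nxt2 = out_edges[cur][0]
                edge2 = cur + nxt2[-1]
                if edge2 in used:
                    break
                used.add(edge2)
                used.add(revcomp(edge2))
                path.append(nxt2)
                cur = nxt2
            paths.append(path[0] + "".join(p[-1] for p in path[1:]))
    # isolated cycles: every node 1-in-1-out
    for km in sorted(kmers):
        for edge in (km, revcomp(km)):
            if edge in used:
                continue
            node = edge[:-1]
            if is_branching(node):
                continue
            path = [node]
            cur = node
            while True:
                nxt = out_edges[cur][0]
                edge2 = cur + nxt[-1]
                if edge2 in used:
                    break
                used.add(edge2)
                used.add(revcomp(edge2))
                path.append(nxt)
                cur = nxt
            if len(path) > 1:
                paths.append(path[0] + "".join(p[-1] for p in path[1:]))
    # deduplicate reverse-complement twins; keep canonical orientation
    seen: set[str] = set()
    contigs: list[Contig] = []
    for seq in paths:
        canon = min(seq, revcomp(seq))
        if canon in seen:
            continue
        seen.add(canon)
        if len(canon) < 2 * k:
            continue
        contigs.append(Contig(seq=canon))
    contigs.sort(key=lambda c: (-c.length, c.seq))
    return contigs


def count_supporting_reads(contigs: list[Contig], reads: list[str], k: int) -> None:
    """Set n_reads_supporting = reads sharing >= 1 canonical k-mer with the contig."""
    contig_kmers: list[set[str]] = []
    for contig in contigs:
        kms = {
            _canonical(contig.seq[i : i + k])
            for i in range(len(contig.seq) - k + 1)
        }
        contig_kmers.append(kms)
    for ci, kms in enumerate(contig_kmers):
        n = 0
        for read in reads:
            hit = False
            for part in _split_at_n(read):
                for i in range(len(part) - k + 1):
                    if _canonical(part[i : i + k]) in kms:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                n += 1
        contigs[ci].n_reads_supporting = n


def assign_contigs(
    contigs: list[Contig],
    index: KmerIndex,
    screen_config: ScreenConfig | None = None,
) -> None:
    """Assign each contig to its best panel virus via the internal aligner."""
    for contig in contigs:
        hit = align_to_panel(contig.seq, index, query_id="contig", config=screen_config)
        contig.virus_id = hit.virus_id if hit is not None else "unassigned"


def completeness(
    contigs: list[Contig],
    panel: list[FastaRecord],
    sample_id: str = "sample",
    config: AssemblyConfig | None = None,
    viruses: set[str] | None = None,
) -> list[CompletenessReport]:
    """Longest assigned contig per virus as % of genome length; retained iff > 5%.

    Unassigned contigs are excluded.  ``viruses`` optionally forces a report
    row (completeness 0) for screened viruses with no contigs.
    """
    config = config or AssemblyConfig()
    genome_len = {rec.id: len(rec.seq) for rec in panel}
    longest: dict[str, int] = defaultdict(int)
    breadth: dict[str, int] = defaultdict(int)
    for contig in contigs:
        if contig.virus_id == "unassigned" or contig.virus_id not in genome_len:
            continue
        capped = min(contig.length, genome_len[contig.virus_id])
        longest[contig.virus_id] = max(longest[contig.virus_id], capped)
        breadth[contig.virus_id] = min(
            breadth[contig.virus_id] + capped, genome_len[contig.virus_id]
        )
    report_viruses = set(longest) | (viruses or set())
    reports = []
    for vid in sorted(report_viruses):
        glen = genome_len.get(vid)
        if glen is None:
            continue
        basis = breadth[vid] if config.use_summed_breadth else longest[vid]
        pct = 100.0 * basis / glen
        reports.append(
            CompletenessReport(
                sample_id=sample_id,
                virus_id=vid,
                genome_length=glen,
                longest_contig_length=longest[vid],
                completeness_pct=pct,
                retained=pct > config.min_completeness_pct,
            )
        )
    return reports
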