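"""Conversion of viral-aligned candidate evidence into host-genome breakpoints.

Junction-base convention: a breakpoint is the host base adjacent to the first
viral base.  Soft-clip evidence is exact — a left clip reports the first
aligned host base, a right clip the last.  Discordant (single-mate-unmapped)
evidence is approximate — the junction is placed just beyond the mapped
mate's aligned span, on the side where the viral sequence must lie.

Per-sample clustering is single-linkage along the coordinate among exact
breakpoints (gap <= cluster_window); approximate breakpoints attach to the
nearest exact cluster within one insert size, else form approximate-only
clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from virin.assembly import assign_contigs, assemble_contigs, build_dbg, completeness
from virin.candidate_extraction import (
    CandidateRead,
    SoftClipFragment,
    extract_candidates,
    extract_softclip_fragments,
    extract_unmapped_reads,
)
from virin.config import PipelineConfig
from virin.io_formats import FastaRecord, ReadRecord
from virin.viral_search import KmerIndex, ViralHit, align_to_panel, screen_sample

logger = logging.getLogger(__name__)


@dataclass
class Breakpoint:
    sample_id: str
    chrom: str
    pos: int  # 1-based host coordinate
    virus_id: str
    evidence: str  # {softclip, discordant}
    support: int = 1
    precision: str = "exact"  # {exact, approximate}
    virus_pos: int | None = None  # 1-based viral coordinate at the junction
    # junction orientation: host_virus (host 5' of the viral sequence) or
    # virus_host; the two junctions of one insertion are adjacent host bases
    # and are kept as separate clusters only because their orientations differ
    orientation: str = "host_virus"


@dataclass
class BreakpointCluster:
    members: list[Breakpoint] = field(default_factory=list)

    @property
    def sample_id(self) -> str:
        return self.members[0].sample_id

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def virus_id(self) -> str:
        return self.members[0].virus_id

    @property
    def exact_members(self) -> list[Breakpoint]:
        return [m for m in self.members if m.precision == "exact"]

    @property
    def representative_pos(self) -> int:
        """Median of exact members (or of all members when none are exact);
        the lower of the two middles for even counts."""
        basis = self.exact_members or self.members
        positions = sorted(m.pos for m in basis)
        return positions[(len(positions) - 1) // 2]

    @property
    def support(self) -> int:
        return sum(m.support for m in self.members)

    @property
    def evidence_summary(self) -> str:
        n_sc = sum(m.support for m in self.members if m.evidence == "softclip")
        n_dc = self.support - n_sc
        return f"softclip:{n_sc};discordant:{n_dc}"


def breakpoint_from_softclip(
    fragment: SoftClipFragment,
    hit: ViralHit | None,
    sample_id: str = "sample",
    min_mapq: int = 0,
) -> Breakpoint | None:
    """Exact breakpoint at the fragment's anchor; None when the hit is absent.

    virus_pos is the viral-reference coordinate adjacent to the junction:
    r_end for a left clip aligned forward, r_start for a right clip, mirrored
    on the minus strand.
    """
    if hit is None or fragment.anchor_mapq < min_mapq:
        return None
    if fragment.side == "left":
        virus_pos = hit.r_end if hit.strand == "+" else hit.r_start
    else:
        virus_pos = hit.r_start if hit.strand == "+" else hit.r_end
    return Breakpoint(
        sample_id=sample_id,
        chrom=fragment.anchor_chrom,
        pos=fragment.anchor_pos,
        virus_id=hit.virus_id,
        evidence="softclip",
        support=1,
        precision="exact",
        virus_pos=virus_pos,
        orientation="virus_host" if fragment.side == "left" else "host_virus",
    )


def breakpoint_from_discordant(
    candidate: CandidateRead,
    hit: ViralHit | None,
    sample_id: str = "sample",
    min_mapq: int = 0,
    allow_approximate_mate_end: bool = True,
) -> Breakpoint | None:
    """Approximate breakpoint beyond the mapped mate's span; None on no hit.

    A plus-strand mate points 3' at the virus: pos = mate_end + 1.  A
    minus-strand mate points 5': pos = mate_pos - 1.  Positions falling off
    the genome edge are skipped with a warning.
    """
    if hit is None or candidate.mate_mapq < min_mapq:
        return None
    if not candidate.mate_end_exact and not allow_approximate_mate_end:
        logger.warning("mate_end unavailable for %s; skipping", candidate.qname)
        return None
    pos = candidate.mate_end + 1 if candidate.mate_strand == "+" else candidate.mate_pos - 1
    if pos < 1:
        logger.warning("breakpoint at genome edge for %s; skipping", candidate.qname)
        return None
    return Breakpoint(
        sample_id=sample_id,
        chrom=candidate.mate_chrom,
        pos=pos,
        virus_id=hit.virus_id,
        evidence="discordant",
        support=1,
        precision="approximate",
        orientation="host_virus" if candidate.mate_strand == "+" else "virus_host",
    )


def cluster_breakpoints(
    breakpoints: list[Breakpoint],
    cluster_window: int = 10,
    max_insert: int = 1000,
) -> list[BreakpointCluster]:
    """Cluster per (sample, virus, chrom); deterministic output ordering."""
    groups: dict[tuple[str, str, str, str], list[Breakpoint]] = {}
    for bp in breakpoints:
        groups.setdefault((bp.sample_id, bp.virus_id, bp.chrom, bp.orientation), []).append(bp)
    clusters: list[BreakpointCluster] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda b: (b.pos, b.precision, b.evidence))
        exact = [b for b in members if b.precision == "exact"]
        approx = [b for b in members if b.precision != "exact"]
        group_clusters: list[BreakpointCluster] = []
        # single-linkage over exact positions
        current: list[Breakpoint] = []
        for bp in exact:
            if current and bp.pos - current[-1].pos > cluster_window:
                group_clusters.append(BreakpointCluster(members=current))
                current = []
            current.append(bp)
        if current:
            group_clusters.append(BreakpointCluster(members=current))
        # attach approximate breakpoints to the nearest exact cluster
        leftover: list[Breakpoint] = []
        reps = [c.representative_pos for c in group_clusters]
        for bp in approx:
            if reps:
                dists = [abs(bp.pos - r) for r in reps]
                best = min(range(len(reps)), key=lambda i: (dists[i], reps[i]))
                if dists[best] <= max_insert:
                    group_clusters[best].members.append(bp)
                    continue
            leftover.append(bp)
        # approximate-only clusters from the leftovers
        current = []
        for bp in leftover:
            if current and bp.pos - current[-1].pos > cluster_window:
                group_clusters.append(BreakpointCluster(members=current))
                current = []
            current.append(bp)
        if current:
            group_clusters.append(BreakpointCluster(members=current))
        clusters.extend(group_clusters)
    clusters.sort(key=lambda c: (c.sample_id, c.chrom, c.representative_pos, c.virus_id))
    return clusters


def call_sample(
    alignment: list[ReadRecord],
    panel: list[FastaRecord],
    config: PipelineConfig | None = None,
    sample_id: str = "sample",
    index: KmerIndex | None = None,
) -> list[BreakpointCluster]:
    """Full per-sample pipeline: extract -> screen -> (assembly gate) -> call -> cluster."""
    config = config or PipelineConfig()
    config.validate()
    if index is None:
        index = KmerIndex(panel, k=config.screen.seed_k)

    candidates = extract_candidates(alignment, config.flags, min_mapq=config.clip.min_mapq)
    fragments = extract_softclip_fragments(alignment, config.clip)
    logger.info(
        "%s: %d candidate reads, %d soft-clip fragments",
        sample_id, len(candidates), len(fragments),
    )

    screen = screen_sample(
        candidates, fragments, index, sample_id=sample_id, config=config.screen
    )
    retained = set(screen.retained_viruses)
    logger.info("%s: per-virus counts %s; retained %s", sample_id, screen.counts, retained)

    if config.use_assembly_gate and retained:
        # assemble from every panel-hitting unmapped read (including
        # fully-viral pairs, which never pass the candidate filter but carry
        # most of the proviral sequence) plus the long soft-clips
        viral_reads = []
        for qname, seq in extract_unmapped_reads(alignment):
            hit = screen.assignments.get(f"read:{qname}")
            if hit is None:
                hit = align_to_panel(seq, index, query_id=qname, config=config.screen)
            if hit is not None:
                viral_reads.append(seq)
        reads = viral_reads + [
            f.clipped_seq for f in fragments if len(f.clipped_seq) >= config.assembly.k
        ]
        graph = build_dbg(reads, k=config.assembly.k)
        contigs = assemble_contigs(graph, config.assembly)
        assign_contigs(contigs, index, config.screen)
        reports = completeness(
            contigs, panel, sample_id=sample_id, config=config.assembly, viruses=retained
        )
        passing = {r.virus_id for r in reports if r.retained}
        retained &= passing
        logger.info("%s: completeness gate keeps %s", sample_id, retained)

    breakpoints: list[Breakpoint] = []
    for frag in fragments:
        hit = screen.assignments.get(f"clip:{frag.fragment_id}")
        if hit is None or hit.virus_id not in retained:
            continue
        bp = breakpoint_from_softclip(frag, hit, sample_id=sample_id)
        if bp is not None:
            breakpoints.append(bp)
    for cand in candidates:
        hit = screen.assignments.get(f"read:{cand.qname}")
        if hit is None or hit.virus_id not in retained:
            continue
        bp = breakpoint_from_discordant(cand, hit, sample_id=sample_id)
        if bp is not None:
            breakpoints.append(bp)

    clusters = cluster_breakpoints(
        breakpoints,
        cluster_window=config.calling.cluster_window,
        max_insert=config.calling.max_insert,
    )
    return [c for c in clusters if c.support >= config.calling.min_support]
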