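"""Extraction of integration-candidate material from a host alignment.

Two evidence streams feed breakpoint calling:

* single-mate-unmapped reads — the ``samtools view -f 4 -F 264`` population
  (read unmapped, mate mapped, not secondary) whose fully-viral sequence is
  positioned near a junction by its mapped mate;
* soft-clipped fragments — terminal S-operation bases of mapped reads, whose
  clipped portion derives from the viral side of a junction and whose anchor
  coordinate pins the junction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from virin.config import ClipConfig, FlagConfig
from virin.io_formats import ReadRecord, normalize_chrom


class ConsistencyError(ValueError):
    """A record passed the flag filter but its mate fields are inconsistent."""


@dataclass
class SoftClipFragment:
    """A clipped subsequence with its host-anchor coordinate and side.

    ``anchor_pos`` is the 1-based host coordinate of the junction base: the
    first aligned base for a left (leading-S) clip, the last aligned base for
    a right (trailing-S) clip.
    """

    source_qname: str
    anchor_chrom: str
    anchor_pos: int
    side: str  # {left, right}
    clipped_seq: str
    anchor_mapq: int

    @property
    def fragment_id(self) -> str:
        return f"{self.source_qname}|{self.anchor_chrom}|{self.anchor_pos}|{self.side}"


@dataclass
class CandidateRead:
    """An unmapped read whose mate is mapped, with the mate's anchor geometry."""

    qname: str
    seq: str
    qual: str
    mate_chrom: str
    mate_pos: int  # 1-based leftmost aligned base of the mate
    mate_strand: str  # {+, -}
    mate_end: int  # 1-based last aligned base of the mate
    mate_mapq: int = 255
    mate_end_exact: bool = True  # False when the mate record was unavailable


def passes_single_mate_unmapped_filter(flag: int, flags: FlagConfig | None = None) -> bool:
    """True iff the flag passes the -f 4 -F 264 contract.

    Read unmapped (bit 4 set), mate mapped (bit 8 clear), not secondary
    (bit 256 clear).
    """
    flags = flags or FlagConfig()
    if not (0 <= flag < 4096):
        raise ValueError(f"SAM flag out of range: {flag}")
    return (flag & flags.include) == flags.include and (flag & flags.exclude) == 0


def extract_candidates(
    alignment: Iterable[ReadRecord],
    flags: FlagConfig | None = None,
    min_mapq: int = 0,
) -> list[CandidateRead]:
    """Collect single-mate-unmapped candidate reads from an alignment stream.

    ``mate_end`` is computed from the mate record's CIGAR reference span when
    that record is present in the stream; otherwise it falls back to
    ``mate_pos`` and is flagged approximate.
    """
    flags = flags or FlagConfig()
    records = list(alignment)
    # index mapped primary records by qname for mate-geometry lookup
    mates: dict[str, ReadRecord] = {}
    for rec in records:
        if not rec.is_unmapped and not rec.is_secondary_or_supplementary:
            mates.setdefault(rec.qname, rec)
    candidates: list[CandidateRead] = []
    for rec in records:
        if not passes_single_mate_unmapped_filter(rec.flag, flags):
            continue
        if rec.mate_rname == "*":
            raise ConsistencyError(
                f"{rec.qname}: passes mate-mapped filter but RNEXT is '*'"
            )
        mate = mates.get(rec.qname)
        if mate is not None and mate.cigar:
            mate_end = mate.reference_end
            mate_strand = "-" if mate.is_reverse else "+"
            mate_mapq = mate.mapq
            exact = True
        else:
            mate_end = rec.mate_pos
            mate_strand = "-" if rec.flag & 0x20 else "+"
            mate_mapq = 255
            exact = False
        if mate_mapq < min_mapq:
            continue
        candidates.append(
            CandidateRead(
                qname=rec.qname,
                seq=rec.seq,
                qual=rec.qual,
                mate_chrom=normalize_chrom(
                    rec.rname if rec.mate_rname == "=" else rec.mate_rname
                ),
                mate_pos=rec.mate_pos,
                mate_strand=mate_strand,
                mate_end=mate_end,
                mate_mapq=mate_mapq,
                mate_end_exact=exact,
            )
        )
    return candidates


def extract_unmapped_reads(alignment: Iterable[ReadRecord]) -> list[tuple[str, str]]:
    """All primary unmapped reads as (qname, seq), regardless of mate state.

    This is the assembly substrate: fully-viral fragments have both mates
    unmapped and are excluded from the breakpoint-candidate filter, but they
    carry most of the proviral sequence.
    """
    out = []
    for rec in alignment:
        if rec.is_unmapped and not rec.is_secondary_or_supplementary and rec.seq != "*":
            out.append((rec.qname, rec.seq))
    return out


def extract_softclip_fragments(
    alignment: Iterable[ReadRecord],
    clip: ClipConfig | None = None,
) -> list[SoftClipFragment]:
    """Extract terminal soft-clipped fragments of length >= min_clip_len.

    A read may yield two fragments (leading and trailing S).  Secondary and
    supplementary records are skipped; hard clips carry no sequence and are
    ignored.  Anchors below ``min_mapq`` are dropped.
    """
    clip = clip or ClipConfig()
    fragments: list[SoftClipFragment] = []
    for rec in alignment:
        if rec.is_unmapped or not rec.cigar or rec.is_secondary_or_supplementary:
            continue
        if rec.mapq < clip.min_mapq:
            continue
        chrom = normalize_chrom(rec.rname)
        op0, n0 = rec.cigar[0]
        if op0 == "S" and n0 >= clip.min_clip_len:
            fragments.append(
                SoftClipFragment(
                    source_qname=rec.qname,
                    anchor_chrom=chrom,
                    anchor_pos=rec.pos,
                    side="left",
                    clipped_seq=rec.seq[:n0],
                    anchor_mapq=rec.mapq,
                )
            )
        opn, nn = rec.cigar[-1]
        if opn == "S" and nn >= clip.min_clip_len and len(rec.cigar) > 1:
            fragments.append(
                SoftClipFragment(
                    source_qname=rec.qname,
                    anchor_chrom=chrom,
                    anchor_pos=rec.pos + rec.reference_span - 1,
                    side="right",
                    clipped_seq=rec.seq[-nn:],
                    anchor_mapq=rec.mapq,
                )
            )
    return fragments
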