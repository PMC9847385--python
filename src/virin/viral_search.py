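"""Seed-and-extend alignment of candidate fragments to a viral panel.

A k-mer hash index over both strands of the panel seeds candidate alignments;
the best-seeded diagonal per (virus, strand) is refined by banded local
dynamic programming with affine gaps (match +1, mismatch -1, gap open -2,
gap extend -1).  Hits are accepted at identity >= 0.90 over >= 30 aligned
columns by default.  Per-virus read counts feed the sample-level screen:
viruses supported by at least ``min_virus_reads`` candidate reads/fragments
(1,000 at full scale) are retained for assembly and breakpoint calling.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from virin.config import ScreenConfig
from virin.io_formats import FastaRecord

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -2, -1

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ViralHit:
    """A candidate fragment's best local alignment to a panel virus."""

    query_id: str
    virus_id: str
    score: int
    identity: float  # matched columns / aligned columns
    q_start: int  # 1-based on the original query orientation
    q_end: int
    r_start: int  # 1-based on the viral reference
    r_end: int
    strand: str  # {+, -}
    aligned_columns: int = 0


@dataclass
class ViralScreenResult:
    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    retained_viruses: set[str] = field(default_factory=set)
    assignments: dict[str, ViralHit] = field(default_factory=dict)


class KmerIndex:
    """Exact k-mer seed index over both strands of a viral panel."""

    def __init__(self, panel: list[FastaRecord], k: int = 15):
        if not panel:
            raise ValueError("empty viral panel")
        shortest = min(len(rec.seq) for rec in panel)
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest panel sequence ({shortest})")
        self.k = k
        self.panel = {rec.id: rec.seq.upper() for rec in panel}
        self.encoded = {vid: _encode(seq) for vid, seq in self.panel.items()}
        index: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        for rec in panel:
            seq = rec.seq.upper()
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                index[kmer].append((rec.id, off, "+"))
                index[revcomp(kmer)].append((rec.id, off, "-"))
        self.index = dict(index)

    def seeds(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.index.get(kmer, [])


def build_kmer_index(panel: list[FastaRecord], k: int = 15) -> KmerIndex:
    return KmerIndex(panel, k=k)


@njit(cache=True)
def _banded_local_dp(q, r, d0, band, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    """Banded affine local DP around diagonal d0 (= j - i for 0-based offsets).

    Returns (score, q_start, q_end, r_start, r_end, matches, columns), spans
    1-based inclusive; score 0 means no positive-scoring alignment in band.
    """
    m, n = len(q), len(r)
    W = 2 * band + 1
    NEG = -(10 ** 9)
    H = np.full((m + 1, W), 0, dtype=np.int32)
    E = np.full((m + 1, W), NEG, dtype=np.int32)
    F = np.full((m + 1, W), NEG, dtype=np.int32)
    # cell (i, w) is query i (1-based), reference j = i + d0 - band + w (1-based)
    best, bi, bw = 0, 0, 0
    for i in range(1, m + 1):
        jlo = i + d0 - band
        for w in range(W):
            j = jlo + w
            if j < 1 or j > n:
                H[i, w] = NEG // 2
                continue
            # diagonal predecessor shares w; vertical is w+1 in row i-1;
            # horizontal is w-1 in row i
            sub = match if (q[i - 1] == r[j - 1] and q[i - 1] != 4) else mismatch
            e = NEG
            if w >= 1:
                a = H[i, w - 1] + gap_open
                b = E[i, w - 1] + gap_ext
                e = a if a > b else b
            f = NEG
            if w + 1 < W:
                a = H[i - 1, w + 1] + gap_open
                b = F[i - 1, w + 1] + gap_ext
                f = a if a > b else b
            h = H[i - 1, w] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, w] = h
            E[i, w] = e
            F[i, w] = f
            if h > best:
                best, bi, bw = h, i, w
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback from (bi, bw)
    i, w = bi, bw
    matches = 0
    columns = 0
    state = 0  # 0=H, 1=E (horizontal), 2=F (vertical)
    while i > 0:
        j = i + d0 - band + w
        if state == 0:
            if H[i, w] == 0:
                break
            if E[i, w] == H[i, w]:
                state = 1
                continue
            if F[i, w] == H[i, w]:
                state = 2
                continue
            # diagonal move
            columns += 1
            if q[i - 1] == r[j - 1] and q[i - 1] != 4:
                matches += 1
            i -= 1
        elif state == 1:
            # horizontal: consume reference base j
            columns += 1
            prev_h = H[i, w - 1] + gap_open if w >= 1 else NEG
            if E[i, w] == prev_h:
                state = 0
            w -= 1
        else:
            # vertical: consume query base i
            columns += 1
            prev_h = H[i - 1, w + 1] + gap_open if w + 1 < W else NEG
            if F[i, w] == prev_h:
                state = 0
            i -= 1
            w += 1
    q_start = i + 1
    r_start = (i + d0 - band + w) + 1
    q_end = bi
    r_end = bi + d0 - band + bw
    return best, q_start, q_end, r_start, r_end, matches, columns


def _align_one_strand(
    query: str, ref_id: str, index: KmerIndex, d0: int, band: int
) -> tuple[int, int, int, int, int, int, int]:
    q = _encode(query)
    r = index.encoded[ref_id]
    return _banded_local_dp(
        q, r, d0, band, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
    )


def align_to_panel(
    query: str,
    index: KmerIndex,
    query_id: str = "query",
    config: ScreenConfig | None = None,
    max_groups: int = 5,
) -> ViralHit | None:
    """Best local alignment of a query against the panel, or None.

    Seeds are grouped per (virus, strand, diagonal); the most-seeded diagonal
    per (virus, strand) is refined by banded DP.  A hit is reported only if
    identity >= min_identity and aligned columns >= min_aln_len.
    """
    config = config or ScreenConfig()
    k = index.k
    if len(query) < k:
        return None
    query = query.upper()
    qrc = revcomp(query)
    m = len(query)
    # seed diagonals per (virus, strand)
    diag_counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for i in range(m - k + 1):
        for vid, off, strand in index.seeds(query[i : i + k]):
            if strand == "+":
                diag_counts[(vid, "+")][off - i] += 1
            else:
                # query matches reverse strand: rc(query) matches forward at off
                i_rc = m - k - i
                diag_counts[(vid, "-")][off - i_rc] += 1
    if not diag_counts:
        return None
    band = config.band
    # rank (virus, strand) groups by seeds summed within +/- band of mode diagonal
    groups = []
    for (vid, strand), counts in diag_counts.items():
        mode_d, _ = max(counts.items(), key=lambda kv: (kv[1], -abs(kv[0])))
        support = sum(c for d, c in counts.items() if abs(d - mode_d) <= band)
        groups.append((support, vid, strand, mode_d))
    groups.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_hit: ViralHit | None = None
    for support, vid, strand, d0 in groups[:max_groups]:
        qseq = query if strand == "+" else qrc
        score, qs, qe, rs, re_, matches, cols = _align_one_strand(
            qseq, vid, index, d0, band
        )
        if score <= 0 or cols < config.min_aln_len:
            continue
        identity = matches / cols
        if identity < config.min_identity:
            continue
        if strand == "-":
            qs, qe = m - qe + 1, m - qs + 1
        hit = ViralHit(
            query_id=query_id,
            virus_id=vid,
            score=int(score),
            identity=identity,
            q_start=qs,
            q_end=qe,
            r_start=rs,
            r_end=re_,
            strand=strand,
            aligned_columns=cols,
        )
        key = (hit.score, hit.identity)
        if (
            best_hit is None
            or key > (best_hit.score, best_hit.identity)
            or (key == (best_hit.score, best_hit.identity) and hit.virus_id < best_hit.virus_id)
        ):
            best_hit = hit
    return best_hit


def screen_sample(
    candidates: list,
    fragments: list,
    index: KmerIndex,
    sample_id: str = "sample",
    config: ScreenConfig | None = None,
) -> ViralScreenResult:
    """Assign each candidate read and soft-clip fragment to its best virus.

    Ties between viruses resolve by highest identity then lexicographically
    smallest virus_id (handled in align_to_panel); retained viruses are those
    with count >= min_virus_reads.
    """
    config = config or ScreenConfig()
    counts: Counter = Counter()
    assignments: dict[str, ViralHit] = {}
    for cand in candidates:
        hit = align_to_panel(cand.seq, index, query_id=cand.qname, config=config)
        if hit is not None:
            counts[hit.virus_id] += 1
            assignments[f"read:{cand.qname}"] = hit
    for frag in fragments:
        hit = align_to_panel(
            frag.clipped_seq, index, query_id=frag.fragment_id, config=config
        )
        if hit is not None:
            counts[hit.virus_id] += 1
            assignments[f"clip:{frag.fragment_id}"] = hit
    retained = {v for v, c in counts.items() if c >= config.min_virus_reads}
    return ViralScreenResult(
        sample_id=sample_id,
        counts=dict(counts),
        retained_viruses=retained,
        assignments=assignments,
    )
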