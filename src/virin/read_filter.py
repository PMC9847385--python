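"""Pre-alignment quality filter: sliding-window trimming and length removal.

Reproduces SLIDINGWINDOW-style semantics: scanning 5'->3', the read is cut at
the start of the first window whose mean base quality falls below the
threshold; reads whose surviving prefix is shorter than ``min_len`` are
removed entirely.  Defaults are mean Q30 over a 4-base window and a 50 nt
length floor.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from virin.config import TrimConfig

REMOVED = None  # sentinel: the read did not survive trimming


def sliding_window_trim(
    seq: str, qual: list[int] | str, params: TrimConfig | None = None
) -> tuple[str, str | list[int]] | None:
    """Trim a read at the first low-quality window; return None if removed.

    ``qual`` may be a list of Phred scores or an ASCII Phred+33 string.
    Reads shorter than the window are evaluated as a single window.
    """
    params = params or TrimConfig()
    was_str = isinstance(qual, str)
    q = [ord(c) - params.phred_offset for c in qual] if was_str else list(qual)
    if len(seq) != len(q):
        raise ValueError(f"seq/qual length mismatch: {len(seq)} vs {len(q)}")
    n = len(seq)
    w = min(params.window, n) if n else 0
    cut = n
    for start in range(0, n - w + 1):
        if sum(q[start : start + w]) / w < params.mean_q:
            # cut at the failing window, but keep leading bases inside it that
            # individually meet the threshold (upstream tool's behaviour)
            cut = start
            while cut < n and q[cut] >= params.mean_q:
                cut += 1
            break
    if cut < params.min_len:
        return REMOVED
    return seq[:cut], qual[:cut]


def filter_pairs(
    pairs: Iterable[tuple[tuple[str, str, str], tuple[str, str, str]]],
    params: TrimConfig | None = None,
    keep_orphans: bool = False,
) -> Iterator[tuple[tuple[str, str, str] | None, tuple[str, str, str] | None]]:
    """Trim read pairs; by default drop both mates when either is removed.

    With ``keep_orphans`` the surviving mate is emitted with the removed side
    as None.
    """
    params = params or TrimConfig()
    for (n1, s1, q1), (n2, s2, q2) in pairs:
        t1 = sliding_window_trim(s1, q1, params)
        t2 = sliding_window_trim(s2, q2, params)
        if t1 is REMOVED and t2 is REMOVED:
            continue
        if t1 is REMOVED or t2 is REMOVED:
            if not keep_orphans:
                continue
            yield (
                None if t1 is REMOVED else (n1, t1[0], t1[1]),
                None if t2 is REMOVED else (n2, t2[0], t2[1]),
            )
            continue
        yield (n1, t1[0], t1[1]), (n2, t2[0], t2[1])
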