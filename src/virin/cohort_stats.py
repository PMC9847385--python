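"""Group comparisons on per-sample breakpoint statistics.

Implements the two tests used for cohort contrasts — the Mann-Whitney U test
(exact by enumeration for small tieless samples, otherwise a tie- and
continuity-corrected normal approximation) and the two-sample t test (Welch
by default) — with significance declared at two-sided p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class GroupComparison:
    statistic_name: str  # {mannwhitney_u, t}
    statistic: float
    p_two_sided: float
    significant: bool
    detail: dict | None = None


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks and tie-group sizes."""
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na, nb = len(a), len(b)
    ranks, _ = _rank_with_ties(np.concatenate([a, b]))
    ra = ranks[:na].sum()
    ua = ra - na * (na + 1) / 2.0
    ub = na * nb - ua
    return ua, ub


def _exact_mw_p(a: np.ndarray, b: np.ndarray, u_min: float) -> float:
    """Two-sided exact p by enumerating all group-A labelings of the pooled data.

    p = P(min(U_a, U_b) <= u_min) under the permutation null.
    """
    pooled = np.concatenate([a, b])
    na = len(a)
    n = len(pooled)
    ranks, _ = _rank_with_ties(pooled)
    total = comb(n, na)
    hits = 0
    base = na * (na + 1) / 2.0
    nb = n - na
    for idx in combinations(range(n), na):
        ua = ranks[list(idx)].sum() - base
        ub = na * nb - ua
        if min(ua, ub) <= u_min + 1e-9:
            hits += 1
    return hits / total


def _normal_mw_p(a: np.ndarray, b: np.ndarray, u_min: float) -> float:
    """Normal approximation with continuity correction.

    Tieless data get an Edgeworth kurtosis correction (the U null
    distribution is platykurtic; the plain normal overshoots by up to ~0.01
    two-sided at n_a = n_b = 8).  With ties, the tie-corrected plain normal
    is used.
    """
    na, nb = len(a), len(b)
    n = na + nb
    _, tie_counts = _rank_with_ties(np.concatenate([a, b]))
    has_ties = bool((tie_counts > 1).any())
    mu = na * nb / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    if has_ties:
        z = max((abs(u_min - mu) - 0.5) / sqrt(var), 0.0)
        return float(min(1.0, 2.0 * sps.norm.sf(z)))
    # exact excess kurtosis of the tieless U null distribution
    g2 = -1.2 * (na * na + nb * nb + na * nb + na + nb) / (na * nb * (n + 1))
    z = (min(u_min, na * nb - u_min) + 0.5 - mu) / sqrt(var)
    cdf = sps.norm.cdf(z) - sps.norm.pdf(z) * g2 / 24.0 * (z**3 - 3.0 * z)
    return float(min(1.0, max(0.0, 2.0 * cdf)))


def mann_whitney_u(
    a, b, method: str = "auto", exact_max_n: int = 16
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U, two-sided p) with U = min(U_a, U_b).

    ``method`` is 'auto' (exact when n_a + n_b <= exact_max_n and tieless,
    else normal), 'exact', or 'normal'.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ua, ub = _u_statistics(a, b)
    u_min = min(ua, ub)
    pooled = np.concatenate([a, b])
    tieless = len(np.unique(pooled)) == len(pooled)
    if method == "exact" or (method == "auto" and tieless and len(pooled) <= exact_max_n):
        p = _exact_mw_p(a, b, u_min)
    else:
        p = _normal_mw_p(a, b, u_min)
    return float(u_min), float(p)


def two_sample_t(a, b, welch: bool = True) -> tuple[float, float, float]:
    """Two-sample t test; returns (t, df, two-sided p).

    Welch statistic with Welch-Satterthwaite df by default; Student pooled
    variant with welch=False.  Degenerate contracts: both variances zero and
    equal means -> p = 1; both zero and different means -> p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return float("inf"), float(na + nb - 2), 0.0
    if welch:
        se2a, se2b = va / na, vb / nb
        t = (a.mean() - b.mean()) / sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (
            (se2a**2) / (na - 1) + (se2b**2) / (nb - 1)
        )
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (a.mean() - b.mean()) / sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


def compare_groups(a, b, statistic: str = "mannwhitney_u", alpha: float = ALPHA) -> GroupComparison:
    if statistic == "mannwhitney_u":
        u, p = mann_whitney_u(a, b)
        return GroupComparison("mannwhitney_u", u, p, p < alpha)
    if statistic == "t":
        t, df, p = two_sample_t(a, b)
        return GroupComparison("t", t, p, p < alpha, detail={"df": df})
    raise ValueError(f"unknown statistic {statistic!r}")


def summarize_cohorts(
    case_tables: list[pd.DataFrame],
    control_tables: list[pd.DataFrame],
    alpha: float = ALPHA,
) -> dict:
    """Cohort report: per-sample counts, per-chromosome t-tests, DNase counts,
    region distribution, all flagged significant at p < alpha.

    Input tables follow the per-sample breakpoint TSV schema.
    """
    if not case_tables or not control_tables:
        raise ValueError("need >= 1 sample per group")

    def counts(tables: list[pd.DataFrame]) -> np.ndarray:
        return np.array([len(t) for t in tables], dtype=float)

    case_n, ctrl_n = counts(case_tables), counts(control_tables)
    u, p_counts = mann_whitney_u(case_n, ctrl_n)
    count_test = GroupComparison("mannwhitney_u", u, p_counts, p_counts < alpha)

    # per-chromosome per-sample counts, compared by t-test
    chroms = sorted(
        set().union(*(set(t["chrom"].astype(str)) for t in case_tables + control_tables))
        if any(len(t) for t in case_tables + control_tables)
        else set()
    )
    chrom_rows = []
    for chrom in chroms:
        ca = np.array([(t["chrom"].astype(str) == chrom).sum() for t in case_tables], float)
        cb = np.array([(t["chrom"].astype(str) == chrom).sum() for t in control_tables], float)
        try:
            t_stat, df_, p = two_sample_t(ca, cb)
        except ValueError:
            t_stat, p = float("nan"), float("nan")
        chrom_rows.append(
            {
                "chrom": chrom,
                "case_total": int(ca.sum()),
                "control_total": int(cb.sum()),
                "t": t_stat,
                "p": p,
                "significant": bool(p < alpha) if p == p else False,
            }
        )
    per_chrom = pd.DataFrame(
        chrom_rows, columns=["chrom", "case_total", "control_total", "t", "p", "significant"]
    )

    def dnase_counts(tables: list[pd.DataFrame]) -> np.ndarray:
        return np.array(
            [t["dnase"].sum() if "dnase" in t and len(t) else 0 for t in tables], float
        )

    da, db = dnase_counts(case_tables), dnase_counts(control_tables)
    u_d, p_d = mann_whitney_u(da, db)
    dnase_test = GroupComparison("mannwhitney_u", u_d, p_d, p_d < alpha)

    def region_dist(tables: list[pd.DataFrame]) -> pd.Series:
        all_bp = pd.concat(tables) if tables else pd.DataFrame()
        if not len(all_bp):
            return pd.Series(dtype=float)
        vc = all_bp["region_class"].value_counts()
        return (100.0 * vc / vc.sum()).round(2)

    region = pd.DataFrame(
        {"case_pct": region_dist(case_tables), "control_pct": region_dist(control_tables)}
    ).fillna(0.0)

    return {
        "per_sample_counts": pd.DataFrame(
            {
                "group": ["case"] * len(case_n) + ["control"] * len(ctrl_n),
                "n_breakpoints": np.concatenate([case_n, ctrl_n]).astype(int),
            }
        ),
        "breakpoint_count_test": count_test,
        "per_chromosome": per_chrom,
        "dnase_test": dnase_test,
        "dnase_counts": {"case": da.astype(int).tolist(), "control": db.astype(int).tolist()},
        "region_distribution": region,
    }
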