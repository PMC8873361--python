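"""Two-group comparison of editing levels and edited-form expression.

The workhorse is a Mann-Whitney U test: exact (full permutation enumeration
with midranks) for small groups, otherwise the normal approximation with tie
correction and continuity correction. Per-site p-values across the cohort
matrix are BH-corrected, and two significance tiers are reported (raw p and
FDR below alpha), with the direction of change in the first group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

from .cohort import CohortMatrix
from .stats import bh_adjust, percentage

__all__ = [
    "DifferentialRecord",
    "mann_whitney_u",
    "bh_adjust",
    "differential_editing",
    "differential_summary",
    "expression_compare",
    "EXACT_LIMIT",
]

#: largest pooled size for which the exact permutation null is enumerated
EXACT_LIMIT = 12


@dataclass(frozen=True)
class DifferentialRecord:
    site: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_stat: float
    p_raw: float
    fdr: float = float("nan")
    direction: str = ""  # increased | decreased (in group A)


def _u_statistic(pooled: np.ndarray, idx_a) -> float:
    ranks = rankdata(pooled)
    n_a = len(idx_a)
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U (for group a) and the two-sided p-value.

    For pooled sizes up to EXACT_LIMIT the p-value is computed by enumerating
    every assignment of the pooled values to the two groups (midranks, so
    ties are handled by the permutation null itself); larger samples use the
    normal approximation with tie-corrected variance and continuity
    correction. Degenerate data (all pooled values identical) gives p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    u_obs = _u_statistic(pooled, range(n_a))

    if n_a + n_b <= EXACT_LIMIT:
        n = n_a + n_b
        us = np.array(
            [_u_statistic(pooled, idx) for idx in combinations(range(n), n_a)]
        )
        eps = 1e-12
        lo = np.mean(us <= u_obs + eps)
        hi = np.mean(us >= u_obs - eps)
        return u_obs, float(min(1.0, 2.0 * min(lo, hi)))

    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = max(0.0, abs(u_obs - mu) - 0.5) / np.sqrt(var)
    return u_obs, float(min(1.0, 2.0 * norm.sf(z)))


def _group_values(matrix: CohortMatrix, site: str, sample_ids,
                  min_reads: int) -> np.ndarray:
    """Levels for one site over a sample list under the callable-zero policy.

    A missing cell counts as level 0 when the position was covered by at
    least ``min_reads`` weighted reads in that sample (the site was callable
    and simply not edited); uncovered samples are excluded.
    """
    vals = []
    for sid in sample_ids:
        lv = matrix.levels.at[site, sid]
        if not np.isnan(lv):
            vals.append(float(lv))
            continue
        cov = matrix.coverage.at[site, sid]
        if not np.isnan(cov) and cov >= min_reads:
            vals.append(0.0)
    return np.array(vals)


def _direction(median_a, median_b, u, n_a, n_b) -> str:
    if median_a > median_b:
        return "increased"
    if median_a < median_b:
        return "decreased"
    return "increased" if u >= n_a * n_b / 2.0 else "decreased"


def differential_editing(matrix: CohortMatrix, group_a: str, group_b: str,
                         alpha: float = 0.05, min_reads: int = 10):
    """Per-site two-group comparison over a (prevalence-filtered) cohort matrix.

    Returns one DifferentialRecord per testable site with BH-adjusted FDR
    over all tested sites.
    """
    ids_a = [s for s, g in matrix.groups.items() if g == group_a]
    ids_b = [s for s, g in matrix.groups.items() if g == group_b]
    if not ids_a:
        raise ValueError(f"unknown or empty group label: {group_a!r}")
    if not ids_b:
        raise ValueError(f"unknown or empty group label: {group_b!r}")

    records = []
    for site in matrix.site_names:
        va = _group_values(matrix, site, ids_a, min_reads)
        vb = _group_values(matrix, site, ids_b, min_reads)
        if va.size == 0 or vb.size == 0:
            continue
        u, p = mann_whitney_u(va, vb)
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        records.append(
            DifferentialRecord(
                site=site,
                n_a=va.size,
                n_b=vb.size,
                median_a=med_a,
                median_b=med_b,
                u_stat=u,
                p_raw=p,
                direction=_direction(med_a, med_b, u, va.size, vb.size),
            )
        )
    fdrs = bh_adjust([r.p_raw for r in records])
    return [
        DifferentialRecord(**{**r.__dict__, "fdr": f}) for r, f in zip(records, fdrs)
    ]


def differential_summary(records, alpha: float = 0.05,
                         categories: dict[str, str] | None = None) -> dict:
    """Counts and two-decimal percentages for the flagged sites.

    Reports both tiers (raw p < alpha and FDR < alpha); direction shares and
    optional category shares are computed over the raw-p tier, mirroring how
    cohort-level change tables are usually printed.
    """
    flagged = [r for r in records if r.p_raw < alpha]
    fdr_flagged = [r for r in records if r.fdr < alpha]
    n = len(flagged)
    inc = sum(1 for r in flagged if r.direction == "increased")
    dec = n - inc
    out = {
        "tested": len(records),
        "p_flagged": n,
        "fdr_flagged": len(fdr_flagged),
        "increased": inc,
        "decreased": dec,
        "pct_increased": percentage(inc, n, 2) if n else float("nan"),
        "pct_decreased": percentage(dec, n, 2) if n else float("nan"),
    }
    if categories is not None and n:
        cat_counts: dict[str, int] = {}
        for r in flagged:
            cat_counts[categories.get(r.site, "?")] = (
                cat_counts.get(categories.get(r.site, "?"), 0) + 1
            )
        out["category_counts"] = cat_counts
        out["category_pct"] = {c: percentage(k, n, 2) for c, k in cat_counts.items()}
    return out


def expression_compare(tptm: dict[str, float], groups: dict[str, str],
                       group_a: str, group_b: str,
                       variant: str = "variant") -> DifferentialRecord:
    """Apply the same U-test machinery to edited-form expression (TPTM) values.

    ``tptm`` maps sample id to the normalized expression of the edited mature
    form in that sample (missing samples count as 0 expression). An edited
    form never observed in any sample is an error.
    """
    ids_a = [s for s, g in groups.items() if g == group_a]
    ids_b = [s for s, g in groups.items() if g == group_b]
    if not ids_a or not ids_b:
        raise ValueError("unknown or empty group label")
    va = np.array([float(tptm.get(s, 0.0)) for s in ids_a])
    vb = np.array([float(tptm.get(s, 0.0)) for s in ids_b])
    if np.all(va == 0) and np.all(vb == 0):
        raise ValueError(f"variant {variant!r} absent from all samples")
    u, p = mann_whitney_u(va, vb)
    med_a, med_b = float(np.median(va)), float(np.median(vb))
    return DifferentialRecord(
        site=variant,
        n_a=va.size,
        n_b=vb.size,
        median_a=med_a,
        median_b=med_b,
        u_stat=u,
        p_raw=p,
        fdr=p,
        direction=_direction(med_a, med_b, u, va.size, vb.size),
    )
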