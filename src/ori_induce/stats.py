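"""Shared statistical helpers.

The rank-sum comparison used for gene-size enrichment and fibre-speed
comparisons: two-sided Mann-Whitney U, exact by enumeration when both samples
are small (n <= 8 each), normal approximation with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 8


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float  # U of the first sample
    pvalue: float     # two-sided
    method: str       # "exact" | "asymptotic"


def _exact_two_sided(x: np.ndarray, y: np.ndarray) -> MannWhitneyResult:
    # Permutation-exact null: every way of choosing which pooled observations
    # belong to the first sample; ties contribute through midranks, so
    # U_A = (sum of A's midranks) - nx(nx+1)/2 counts tied pairs as 1/2.
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    offset = nx * (nx + 1) / 2.0
    u_obs = float(ranks[:nx].sum() - offset)
    us = np.array([ranks[list(c)].sum() - offset
                   for c in combinations(range(nx + ny), nx)])
    tol = 1e-9
    p_le = float((us <= u_obs + tol).mean())
    p_ge = float((us >= u_obs - tol).mean())
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return MannWhitneyResult(u_obs, p, "exact")


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Exact null distribution (all ways of splitting the pooled sample, ties
    handled by midranks) when both n <= 8; otherwise scipy's normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N:
        return _exact_two_sided(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                             "asymptotic")


def median(values) -> float:
    """Sample median, midpoint convention for even n."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median of empty sample")
    return float(np.median(values))
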