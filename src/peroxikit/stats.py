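"""Supporting statistics: BH false-discovery-rate control and the
two-tailed Mann-Whitney U test used for per-figure group comparisons."""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["adjust_bh", "mann_whitney_two_tailed"]


def adjust_bh(p_values):
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving, capped at 1; equivalent to
    ``min over j >= i of p_(j) * m / j`` on the sorted vector.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


_EXACT_ENUM_CAP = 2_000_000  # combinations, not permutations


def _u_statistic(x, y):
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0), ranks


def mann_whitney_two_tailed(x, y, mode: str = "approx"):
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` enumerates all rank assignments (tie-free samples only,
    enumeration must be feasible); ``mode="approx"`` uses the tie-corrected
    normal approximation with continuity correction.  Returns ``(U, p)``
    where U is the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = len(x), len(y)
    u, ranks = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if mode == "exact":
        if has_ties:
            warnings.warn(
                "ties present: exact Mann-Whitney enumeration is invalid, "
                "falling back to the normal approximation",
                stacklevel=2,
            )
            mode = "approx"
        elif comb(n1 + n2, n1) > _EXACT_ENUM_CAP:
            raise ValueError("exact enumeration infeasible for these sample sizes")

    if mode == "exact":
        n = n1 + n2
        base = n1 * (n1 + 1) / 2.0
        u_min = min(u, n1 * n2 - u)
        count = 0
        total = 0
        for c in combinations(range(1, n + 1), n1):
            total += 1
            if sum(c) - base <= u_min + 1e-9:
                count += 1
        # the U null distribution is symmetric about n1*n2/2
        p = min(1.0, 2.0 * count / total)
        return u, p

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u, 1.0
    diff = u - mean_u
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - np.sign(diff) * cc) / np.sqrt(var_u)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return u, p
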