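"""Rank-sum testing and FDR helpers shared by the analysis stages.

The two-sided Wilcoxon-Mann-Whitney test is used throughout (group
comparisons of bacterial load, per-gene differential expression, component
score separation).  Columns are tested independently and vectorised:

* normal approximation with tie correction when either group exceeds
  ``exact_max`` observations (the default 8 matches where the exact null
  becomes indistinguishable from the approximation for practical purposes);
* otherwise an exact permutation enumeration of group assignments, which is
  tie-aware (mid-ranks), so tiny-fixture p-values equal the exact rank-sum
  tail.

The signed z statistic is always the tie-corrected normal-scale statistic,
positive when the first group tends larger; it is what downstream heatmaps
and consistency summaries consume.
"""

from __future__ import annotations

from itertools import combinations
from typing import Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def _tie_sum(ranks: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over tie groups, from a 2-D rank matrix."""
    n, g = ranks.shape
    out = np.zeros(g)
    srt = np.sort(ranks, axis=0)
    for j in range(g):
        col = srt[:, j]
        # run lengths of equal mid-ranks
        change = np.flatnonzero(np.diff(col) != 0)
        lengths = np.diff(np.concatenate(([0], change + 1, [n])))
        out[j] = float(np.sum(lengths**3 - lengths))
    return out


def rank_sum_matrix(
    a: np.ndarray, b: np.ndarray, exact_max: int = 8
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-sum test of ``a`` vs ``b`` column by column.

    Parameters
    ----------
    a, b
        Arrays of shape (n1, G) and (n2, G); column j of ``a`` is compared
        with column j of ``b``.
    exact_max
        Use exact permutation p-values when both groups have at most this
        many observations.

    Returns
    -------
    (z, p)
        Signed tie-corrected z statistics (positive = first group larger)
        and two-sided p-values, each of shape (G,).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n1, g = a.shape
    n2 = b.shape[0]
    n = n1 + n2
    combined = np.concatenate([a, b], axis=0)
    ranks = sps.rankdata(combined, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    ties = _tie_sum(ranks)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (r1 - mu) / np.where(sigma > 0, sigma, 1.0),
                     0.0)
    if max(n1, n2) <= exact_max:
        p = _exact_permutation_p(combined, ranks, n1)
    else:
        p = np.minimum(2.0 * sps.norm.sf(np.abs(z)), 1.0)
        p = np.where(sigma > 0, p, 1.0)
    return z, p


def _exact_permutation_p(
    combined: np.ndarray, ranks: np.ndarray, n1: int
) -> np.ndarray:
    """Exact two-sided p by enumerating all group-1 assignments (tie-aware:
    the permutation distribution of the mid-rank sum is used)."""
    n, g = combined.shape
    idx = np.array(list(combinations(range(n), n1)))  # (K, n1)
    mu = n1 * (n + 1) / 2.0
    obs = np.abs(ranks[:n1].sum(axis=0) - mu)  # (g,)
    perm = np.abs(ranks[idx, :].sum(axis=1) - mu)  # (K, g)
    # >= with a tolerance so mid-rank arithmetic does not drop ties
    return (perm >= obs[None, :] - 1e-9).mean(axis=0)


def rank_sum_test(x, y, exact_max: int = 8) -> Tuple[float, float]:
    """Scalar convenience wrapper around :func:`rank_sum_matrix`."""
    z, p = rank_sum_matrix(
        np.asarray(x, dtype=float)[:, None],
        np.asarray(y, dtype=float)[:, None],
        exact_max=exact_max,
    )
    return float(z[0]), float(p[0])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are passed through and do
    not count toward the number of tests."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
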