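"""Two-sample Kuiper test for circular data and the exact Wilcoxon rank-sum.

The Kuiper statistic V = D+ + D- (the sum of the largest positive and
largest negative ECDF differences) is invariant to a common rotation of
both samples around the circle, which makes it the appropriate two-sample
test for acrophases, unlike Kolmogorov-Smirnov whose D depends on where the
circle is cut.  The p-value is obtained by resampling: by default random
reassignment of the pooled values to two groups of the original sizes
(permutation, without replacement), with the add-one estimator
p = (1 + #{V* >= V}) / (1 + nboots) so p is never exactly zero.  Drawing
the resamples with replacement is available behind ``method="bootstrap"``.

MESOR and amplitude comparisons use the exact two-sided Wilcoxon rank-sum
test.  With ties in the pooled sample the exact null distribution is not
available; midranks with the normal approximation are used instead and the
result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["KuiperResult", "WilcoxonResult", "kuiper_two_sample", "wilcoxon_exact"]


@dataclass(frozen=True)
class KuiperResult:
    v: float
    p: float
    nboots: int
    seed: int
    method: str


@dataclass(frozen=True)
class WilcoxonResult:
    w: float  # rank sum of the first sample
    p_two_sided: float
    tied: bool = False


def _kuiper_v_sorted(labels: np.ndarray, keep: np.ndarray, n1: int, n2: int) -> float:
    """V for pre-sorted pooled data.

    ``labels`` marks first-sample membership at each sorted pooled position;
    ``keep`` marks the last position of each run of tied values (ECDF
    differences are only meaningful at distinct pooled values).
    """
    cum1 = np.cumsum(labels)[keep]
    pos = np.flatnonzero(keep) + 1
    d = cum1 / n1 - (pos - cum1) / n2
    return float(d.max(initial=0.0) + (-d).max(initial=0.0))


def kuiper_two_sample(
    x,
    y,
    *,
    nboots: int = 10000,
    seed: int,
    period: float = 24.0,
    method: str = "permutation",
) -> KuiperResult:
    """Two-sample Kuiper test on circular values (hours modulo ``period``).

    Parameters
    ----------
    x, y : array-like
        Circular observations in hours; reduced modulo ``period`` first.
    nboots : int
        Number of resamples for the p-value (10000 by default).
    seed : int
        Required; the resampling is fully reproducible.
    method : {"permutation", "bootstrap"}
        Resample by reassigning the pooled values without replacement
        (default) or by drawing with replacement.
    """
    x = np.mod(np.asarray(x, dtype=float).ravel(), period)
    y = np.mod(np.asarray(y, dtype=float).ravel(), period)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown method {method!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    labels0 = (order < n1).astype(np.int64)
    keep = np.empty(n1 + n2, dtype=bool)
    keep[:-1] = sorted_vals[:-1] != sorted_vals[1:]
    keep[-1] = True

    v_obs = _kuiper_v_sorted(labels0, keep, n1, n2)

    rng = np.random.default_rng(seed)
    if method == "permutation":
        # tie structure of the sorted pooled values is fixed; only the
        # group labels are shuffled
        label_mat = np.tile(labels0, (nboots, 1))
        label_mat = rng.permuted(label_mat, axis=1)
        cum1 = np.cumsum(label_mat, axis=1)[:, keep]
        pos = np.flatnonzero(keep) + 1
        d = cum1 / n1 - (pos[None, :] - cum1) / n2
        v_star = d.max(axis=1, initial=0.0) + (-d).max(axis=1, initial=0.0)
        exceed = int(np.sum(v_star >= v_obs - 1e-12))
    else:
        exceed = 0
        for _ in range(nboots):
            bx = rng.choice(pooled, size=n1, replace=True)
            by = rng.choice(pooled, size=n2, replace=True)
            exceed += _kuiper_v_brute(bx, by) >= v_obs - 1e-12

    p = (1 + exceed) / (1 + nboots)
    return KuiperResult(v=v_obs, p=float(p), nboots=nboots, seed=seed, method=method)


def _kuiper_v_brute(x: np.ndarray, y: np.ndarray) -> float:
    """V evaluated directly from both ECDFs at every pooled point."""
    pts = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), pts, side="right") / x.size
    fy = np.searchsorted(np.sort(y), pts, side="right") / y.size
    d = fx - fy
    return float(d.max(initial=0.0) + (-d).max(initial=0.0))


def wilcoxon_exact(x, y) -> WilcoxonResult:
    """Exact two-sided Wilcoxon rank-sum test (Mann-Whitney form).

    Returns the rank sum W of the first sample and the exact two-sided
    p-value from the null permutation distribution of W.  Ties fall back to
    midranks with the normal approximation (``tied=True`` in the result);
    cosinor parameter estimates are continuous so ties are measure-zero in
    this package's use.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tied = np.unique(pooled).size < pooled.size
    method = "asymptotic" if tied else "exact"
    mwu = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(mwu.statistic + x.size * (x.size + 1) / 2.0)
    return WilcoxonResult(w=w, p_two_sided=float(min(mwu.pvalue, 1.0)), tied=tied)
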