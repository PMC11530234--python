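"""Fixed-period single-component cosinor regression.

The single-component cosinor models a periodic signal as

    y(t) = M + A * cos(2*pi*(t - phi)/period) + eps,

where ``M`` is the MESOR (midline estimating statistic of rhythm, the
rhythm-adjusted mean), ``A >= 0`` the amplitude (half the peak-to-trough
extent) and ``phi`` the acrophase (clock time of the fitted peak, in hours).
Expanding the cosine turns this into an ordinary linear regression on
``cos(w t)`` and ``sin(w t)`` with ``w = 2*pi/period``:

    y = b0 + b1*cos(w t) + b2*sin(w t),    b1 = A cos(w phi), b2 = A sin(w phi)

so ``M = b0``, ``A = sqrt(b1^2 + b2^2)`` and ``phi = atan2(b2, b1)/w`` modulo
the period.  The period is fixed (24 h throughout this package); period
estimation is out of scope.

Rhythmicity is tested with the standard zero-amplitude F-test comparing the
cosinor fit to the intercept-only model (2 numerator degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CosinorFit", "DegenerateDesignError", "design_basis", "fit_cosinor"]


class DegenerateDesignError(ValueError):
    """Sampling times cannot identify the cosinor coefficients."""


@dataclass(frozen=True)
class CosinorFit:
    """Result of a fixed-period cosinor least-squares fit.

    ``sigma2_mle`` is the maximum-likelihood residual variance (rss/n), the
    quantity entering BIC; the rhythmicity F-test uses the unbiased
    denominator rss/(n-3) internally.  ``phase_defined`` is False only in
    the degenerate A == 0 case, where the acrophase is reported as 0 by
    convention.
    """

    mesor: float
    amplitude: float
    acrophase: float
    beta0: float
    beta1: float
    beta2: float
    sigma2_mle: float
    n: int
    rss: float
    p_rhythm: float
    period: float
    phase_defined: bool = True


def design_basis(times: np.ndarray, period: float) -> np.ndarray:
    """Two-column cosinor basis ``[cos(w t), sin(w t)]`` with ``w = 2*pi/period``."""
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size < 1:
        raise ValueError("at least one time is required")
    w = 2.0 * np.pi / period
    return np.column_stack([np.cos(w * t), np.sin(w * t)])


def acrophase_from_coefficients(beta1: float, beta2: float, period: float) -> float:
    """Peak time in hours, in [0, period); 0 by convention when A == 0."""
    if beta1 == 0.0 and beta2 == 0.0:
        return 0.0
    phi = (period / (2.0 * np.pi)) * np.arctan2(beta2, beta1)
    return float(phi % period)


def fit_cosinor(y: np.ndarray, times: np.ndarray, period: float = 24.0) -> CosinorFit:
    """Fit ``y = M + A*cos(2*pi*(t - phi)/period)`` by ordinary least squares.

    Parameters
    ----------
    y : array-like
        Response values (any real scale; this package feeds it
        log10(1 + normalized count) expression or wearable summaries).
    times : array-like
        Sampling times in hours, same length as ``y``.
    period : float
        Fixed oscillation period in hours (24 by default).

    Raises
    ------
    DegenerateDesignError
        If all times fall at the same circadian position so the cosine and
        sine columns are not identifiable.
    ValueError
        On fewer than 4 observations or mismatched lengths.
    """
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    if y.size != t.size:
        raise ValueError(f"y has {y.size} values but times has {t.size}")
    n = y.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")

    basis = design_basis(t, period)
    X = np.column_stack([np.ones(n), basis])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise DegenerateDesignError(
            "sampling times are congruent modulo the period; "
            "cosine/sine coefficients are not identifiable"
        )
    resid = y - X @ beta
    rss = float(resid @ resid)

    b0, b1, b2 = (float(b) for b in beta)
    amplitude = float(np.hypot(b1, b2))
    phase_defined = not (b1 == 0.0 and b2 == 0.0)
    acrophase = acrophase_from_coefficients(b1, b2, period)

    # zero-amplitude F-test against the intercept-only model
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df_den = n - 3
    # a numerically constant series is arrhythmic by definition; guard
    # against 0/0 in the F ratio from round-off-level sums of squares
    if rss0 <= 1e-12 * n * (1.0 + float(np.mean(y * y))):
        rss0 = rss = 0.0
    num = max(rss0 - rss, 0.0) / 2.0
    den = rss / df_den
    if den == 0.0:
        # perfect fit: flat data is trivially "explained" (F=0), any real
        # cosine structure is detected with certainty
        p_rhythm = 1.0 if num <= 1e-12 else 0.0
    else:
        f_stat = num / den
        p_rhythm = float(stats.f.sf(f_stat, 2, df_den))

    return CosinorFit(
        mesor=b0,
        amplitude=amplitude,
        acrophase=acrophase,
        beta0=b0,
        beta1=b1,
        beta2=b2,
        sigma2_mle=rss / n,
        n=n,
        rss=rss,
        p_rhythm=p_rhythm,
        period=period,
        phase_defined=phase_defined,
    )
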