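"""Four-model weighted-BIC rhythmicity classification for two groups.

For each gene, four nested Gaussian regression models are fit to the pooled
young + old observations:

- ``neither``     : group-specific intercepts only (2 regression parameters)
- ``young_only``  : young gets cosine/sine terms, old intercept only (4)
- ``old_only``    : the mirror image (4)
- ``both``        : group-specific intercepts and group-specific
                    cosine/sine terms (6)

Each model has one shared residual variance, so its parameter count for BIC
is the regression parameter count plus one.  BIC = k*ln(n) - 2*loglik with
n the total observations across both groups.  BIC values are converted to
Schwarz weights,

    w_i = exp(-(BIC_i - min BIC)/2) / sum_j exp(-(BIC_j - min BIC)/2),

interpretable as approximate posterior model probabilities.  A gene is
assigned a rhythmicity class when one model's weight exceeds a threshold
(0.75 by default); because the weights sum to 1, at most one weight can
exceed any threshold above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cosinor import DegenerateDesignError, design_basis

__all__ = [
    "MODEL_NAMES",
    "ModelFit",
    "ModelWeights",
    "RhythmClass",
    "bic",
    "bic_weights",
    "classify_rhythmicity",
    "fit_four_models",
]

MODEL_NAMES = ("neither", "young_only", "old_only", "both")

_CLASS_LABELS = {
    "neither": "arrhythmic",
    "young_only": "rhythmic_young_only",
    "old_only": "rhythmic_old_only",
    "both": "rhythmic_both",
}


@dataclass(frozen=True)
class ModelFit:
    name: str
    k: int  # regression parameters + 1 shared variance
    n: int
    rss: float
    loglik: float
    bic: float


@dataclass(frozen=True)
class ModelWeights:
    """BIC values and normalized Schwarz weights for the four models."""

    bic: dict[str, float]
    weight: dict[str, float]

    @property
    def best_model(self) -> str:
        return min(MODEL_NAMES, key=lambda m: self.bic[m])


@dataclass(frozen=True)
class RhythmClass:
    label: str
    threshold: float


def bic(loglik: float, k: int, n: int) -> float:
    """Schwarz Bayesian information criterion, ``k*ln(n) - 2*loglik``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return k * float(np.log(n)) - 2.0 * loglik


def _gaussian_loglik(rss: float, n: int) -> float:
    # maximized Gaussian log-likelihood with sigma^2 at its MLE rss/n
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def fit_four_models(
    y_young: np.ndarray,
    y_old: np.ndarray,
    times_young: np.ndarray,
    times_old: np.ndarray,
    period: float = 24.0,
) -> dict[str, ModelFit]:
    """Least-squares fit of the four rhythmicity models on pooled data.

    Returns a dict keyed by model name.  Raises
    :class:`~circadiff.cosinor.DegenerateDesignError` naming the first model
    whose required cosine/sine block is unidentifiable.
    """
    y_young = np.asarray(y_young, dtype=float).ravel()
    y_old = np.asarray(y_old, dtype=float).ravel()
    t_young = np.asarray(times_young, dtype=float).ravel()
    t_old = np.asarray(times_old, dtype=float).ravel()
    if y_young.size == 0 or y_old.size == 0:
        raise ValueError("both groups must be non-empty")
    if y_young.size != t_young.size or y_old.size != t_old.size:
        raise ValueError("response and time vectors must have matching lengths")

    n_y, n_o = y_young.size, y_old.size
    n = n_y + n_o
    y = np.concatenate([y_young, y_old])
    g_young = np.concatenate([np.ones(n_y), np.zeros(n_o)])
    g_old = 1.0 - g_young
    basis = design_basis(np.concatenate([t_young, t_old]), period)
    young_rhythm = basis * g_young[:, None]
    old_rhythm = basis * g_old[:, None]

    intercepts = np.column_stack([g_young, g_old])
    designs = {
        "neither": intercepts,
        "young_only": np.column_stack([intercepts, young_rhythm]),
        "old_only": np.column_stack([intercepts, old_rhythm]),
        "both": np.column_stack([intercepts, young_rhythm, old_rhythm]),
    }

    fits: dict[str, ModelFit] = {}
    for name in MODEL_NAMES:
        X = designs[name]
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise DegenerateDesignError(
                f"model {name!r}: design is rank-deficient "
                "(times congruent modulo the period in a required group)"
            )
        resid = y - X @ beta
        rss = float(resid @ resid)
        loglik = _gaussian_loglik(rss, n)
        k = X.shape[1] + 1
        fits[name] = ModelFit(
            name=name, k=k, n=n, rss=rss, loglik=loglik, bic=bic(loglik, k, n)
        )
    return fits


def bic_weights(bics: dict[str, float] | np.ndarray) -> ModelWeights:
    """Normalized Schwarz weights from the four BIC values.

    Stable under adding a constant to all BICs (the minimum is subtracted
    before exponentiation).
    """
    if isinstance(bics, dict):
        values = np.array([bics[m] for m in MODEL_NAMES], dtype=float)
    else:
        values = np.asarray(bics, dtype=float).ravel()
        if values.size != len(MODEL_NAMES):
            raise ValueError(f"expected {len(MODEL_NAMES)} BIC values, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"BIC values must be finite, got {values}")
    rel = np.exp(-0.5 * (values - values.min()))
    w = rel / rel.sum()
    return ModelWeights(
        bic=dict(zip(MODEL_NAMES, values.tolist())),
        weight=dict(zip(MODEL_NAMES, w.tolist())),
    )


def classify_rhythmicity(weights: ModelWeights, threshold: float = 0.75) -> RhythmClass:
    """Assign the rhythmicity class whose weight strictly exceeds ``threshold``.

    ``threshold`` must lie in (0.5, 1]; below 0.5 two weights could exceed it
    simultaneously.  Genes with no weight above the threshold are
    ``unclassified``.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    for name in MODEL_NAMES:
        if weights.weight[name] > threshold:
            return RhythmClass(label=_CLASS_LABELS[name], threshold=threshold)
    return RhythmClass(label="unclassified", threshold=threshold)
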