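"""Per-gene pipeline orchestration, subset filters, and heatmap normalization.

``run_pipeline`` composes, for every gene: the four-model weighted-BIC
rhythmicity classification, the joint two-group differential cosinor fit,
Benjamini-Hochberg adjustment per statistic family across genes, and the
log2 fold-change quantities behind the |log2 FC| screens.  ``subset_filters``
then derives the seven enrichment-input gene subsets and ``log2fc_screens``
the stricter effect-size screens.  ``heatmap_normalize`` applies the
three-round per-gene normalization used for heatmap display (donor mean
removal, replicate collapse, within-group Z-scores).

BH families: the MESOR- and amplitude-difference p-values are adjusted
across all successfully fitted genes; the phase-difference family includes
only genes rhythmic in both groups (phase is meaningless otherwise), with
the gate selectable between the weighted-BIC "both" call (default) and the
per-group rhythmicity q-values.

log2 fold-change conventions on the log10(1 + count) input scale:
``log2fc_mesor = (M_old - M_young)/log10(2)`` (the MESOR difference
re-expressed in log2 units of 1 + count) and
``log2fc_amplitude = log2(A_old / A_young)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .differential import bh_adjust, fit_joint
from .model_selection import MODEL_NAMES, bic_weights, classify_rhythmicity, fit_four_models

__all__ = [
    "HeatmapMatrix",
    "PipelineConfig",
    "heatmap_normalize",
    "log2fc_screens",
    "run_pipeline",
    "subset_filters",
]

_LOG10_2 = float(np.log10(2.0))


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the per-gene analysis.

    ``bic_threshold`` is the weighted-BIC classification cutoff (0.75).
    ``phase_gate`` selects which genes enter the phase-difference BH family:
    ``"bic"`` (weight of the "both" model > threshold) or ``"qvalue"``
    (per-group rhythmicity q < ``q_threshold`` in both groups).
    """

    period: float = 24.0
    bic_threshold: float = 0.75
    q_threshold: float = 0.05
    phase_gate: str = "bic"

    def __post_init__(self) -> None:
        if self.phase_gate not in ("bic", "qvalue"):
            raise ValueError(f"phase_gate must be 'bic' or 'qvalue', got {self.phase_gate!r}")


@dataclass(frozen=True)
class HeatmapMatrix:
    """Per-gene, per-group, per-timepoint Z-scores for display.

    ``values`` has genes as rows and a (group, timepoint) MultiIndex on the
    columns.  ``zero_variance`` flags genes x groups whose collapsed trace
    was constant; their rows are emitted as all zeros rather than NaN.
    """

    values: pd.DataFrame
    zero_variance: pd.DataFrame


def run_pipeline(dataset: ExpressionDataset, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the full per-gene analysis; returns one row per gene.

    Columns: the four BICs and weights, the rhythmicity class label, the
    joint-fit parameter estimates and standard errors, raw p-values,
    BH q-values per family, log2 fold-changes, and a ``fit_ok`` flag.
    Genes whose joint fit failed keep their row with NaN statistics; no
    silent drops.  Deterministic given dataset + config.
    """
    config = config or PipelineConfig()
    idx_young = dataset.group_columns("young")
    idx_old = dataset.group_columns("old")
    if idx_young.size == 0 or idx_old.size == 0:
        raise ValueError("dataset must contain both young and old samples")
    t_young = dataset.group_times("young")
    t_old = dataset.group_times("old")

    rows = []
    for gi, gene in enumerate(dataset.gene_ids):
        y_young = dataset.values[gi, idx_young]
        y_old = dataset.values[gi, idx_old]
        models = fit_four_models(y_young, y_old, t_young, t_old, config.period)
        weights = bic_weights({m: models[m].bic for m in MODEL_NAMES})
        label = classify_rhythmicity(weights, config.bic_threshold).label
        diff = fit_joint(y_young, y_old, t_young, t_old, config.period)

        row = {"gene_id": gene, "rhythm_class": label, "fit_ok": diff.converged}
        for m in MODEL_NAMES:
            row[f"bic_{m}"] = weights.bic[m]
            row[f"w_{m}"] = weights.weight[m]
        row.update(
            mesor_young=diff.mesor,
            mesor_old=diff.mesor_old,
            d_mesor=diff.d_mesor,
            amplitude_young=diff.amplitude,
            amplitude_old=diff.amplitude_old,
            d_amplitude=diff.d_amplitude,
            phase_young=diff.acrophase,
            phase_old=diff.acrophase_old,
            d_phase=diff.d_phase,
            se_d_mesor=diff.se_d_mesor,
            se_d_amplitude=diff.se_d_amplitude,
            se_d_phase=diff.se_d_phase,
            p_rhythm_young=diff.p_rhythm_young,
            p_rhythm_old=diff.p_rhythm_old,
            p_d_mesor=diff.p_d_mesor,
            p_d_amplitude=diff.p_d_amplitude,
            p_d_phase=diff.p_d_phase,
        )
        row["log2fc_mesor"] = diff.d_mesor / _LOG10_2
        if diff.amplitude > 0 and diff.amplitude_old > 0:
            row["log2fc_amplitude"] = float(np.log2(diff.amplitude_old / diff.amplitude))
        else:
            row["log2fc_amplitude"] = np.nan
        rows.append(row)

    report = pd.DataFrame(rows).set_index("gene_id")
    if report.empty:
        return report

    report["q_rhythm_young"] = bh_adjust(report["p_rhythm_young"])
    report["q_rhythm_old"] = bh_adjust(report["p_rhythm_old"])
    report["q_d_mesor"] = bh_adjust(report["p_d_mesor"])
    report["q_d_amplitude"] = bh_adjust(report["p_d_amplitude"])

    if config.phase_gate == "bic":
        gate = report["w_both"] > config.bic_threshold
    else:
        gate = (report["q_rhythm_young"] < config.q_threshold) & (
            report["q_rhythm_old"] < config.q_threshold
        )
    p_phase = report["p_d_phase"].where(gate)
    report["phase_gate"] = gate
    report["q_d_phase"] = bh_adjust(p_phase)
    return report


def subset_filters(
    report: pd.DataFrame,
    q_threshold: float = 0.05,
    bic_threshold: float = 0.75,
) -> dict[str, pd.Series]:
    """The seven enrichment-input gene subsets as boolean masks.

    1/2: decreased/increased MESOR in old — rhythmic q < 0.05 in both
    groups, MESOR-difference q < 0.05, signed by d_mesor.
    3/4: phase advance/delay in old — rhythmic q < 0.05 in both groups,
    phase-difference q < 0.05, signed by d_phase.
    5/6: loss/gain of rhythmicity in old — weighted BIC > 0.75 for the
    young-only / old-only model.
    7: rhythmic in both — weighted BIC > 0.75 for the "both" model.
    """
    rhythmic_q = (report["q_rhythm_young"] < q_threshold) & (
        report["q_rhythm_old"] < q_threshold
    )
    mesor_call = rhythmic_q & (report["q_d_mesor"] < q_threshold)
    phase_call = rhythmic_q & (report["q_d_phase"] < q_threshold)
    return {
        "decreased_mesor": mesor_call & (report["d_mesor"] < 0),
        "increased_mesor": mesor_call & (report["d_mesor"] > 0),
        "phase_advance": phase_call & (report["d_phase"] < 0),
        "phase_delay": phase_call & (report["d_phase"] > 0),
        "loss_of_rhythmicity": report["w_young_only"] > bic_threshold,
        "gain_of_rhythmicity": report["w_old_only"] > bic_threshold,
        "rhythmic_both": report["w_both"] > bic_threshold,
    }


def log2fc_screens(
    report: pd.DataFrame,
    mesor_threshold: float = 0.25,
    amplitude_threshold: float = 0.1,
    q_threshold: float = 0.05,
    bic_threshold: float = 0.75,
) -> dict[str, pd.Series]:
    """Effect-size screens on top of the q < 0.05 difference calls.

    The base population is genes rhythmic in both groups by the weighted-BIC
    call; direction comes from the sign of the difference estimate and the
    screens use strict |log2 FC| inequalities (> 0.25 for MESOR, > 0.1 for
    amplitude).
    """
    if mesor_threshold < 0 or amplitude_threshold < 0:
        raise ValueError("screen thresholds must be non-negative")
    both = report["w_both"] > bic_threshold
    mesor_call = both & (report["q_d_mesor"] < q_threshold)
    amp_call = both & (report["q_d_amplitude"] < q_threshold)
    abs_m = report["log2fc_mesor"].abs()
    abs_a = report["log2fc_amplitude"].abs()
    return {
        "mesor_increased": mesor_call & (report["d_mesor"] > 0),
        "mesor_decreased": mesor_call & (report["d_mesor"] < 0),
        "mesor_increased_screened": mesor_call
        & (report["d_mesor"] > 0)
        & (abs_m > mesor_threshold),
        "mesor_decreased_screened": mesor_call
        & (report["d_mesor"] < 0)
        & (abs_m > mesor_threshold),
        "amplitude_increased": amp_call & (report["d_amplitude"] > 0),
        "amplitude_decreased": amp_call & (report["d_amplitude"] < 0),
        "amplitude_decreased_screened": amp_call
        & (report["d_amplitude"] < 0)
        & (abs_a > amplitude_threshold),
        "amplitude_increased_screened": amp_call
        & (report["d_amplitude"] > 0)
        & (abs_a > amplitude_threshold),
    }


def heatmap_normalize(dataset: ExpressionDataset) -> HeatmapMatrix:
    """Three-round per-gene normalization for heatmap display.

    Round 1 subtracts each donor's mean within each age group (removing
    baseline differences between sera).  Round 2 collapses replicates by
    averaging within each group x timepoint.  Round 3 Z-scores each gene's
    trace across timepoints within each group (sample standard deviation).
    Genes constant within a group are emitted as an all-zero row and
    flagged.  Raises if any group x timepoint cell has no samples.
    """
    samples = dataset.samples
    groups = ("young", "old")
    timepoints = np.unique(samples["timepoint_hr"].to_numpy(dtype=float))
    for g in groups:
        present = set(samples.loc[samples["group"] == g, "timepoint_hr"])
        missing = [t for t in timepoints if t not in present]
        if missing:
            raise ValueError(f"group {g!r} has no samples at timepoint(s) {missing}")

    # round 1: remove per-donor means (within group)
    centered = dataset.values.copy()
    donor_key = (samples["group"] + "_" + samples["donor"]).to_numpy()
    for key in pd.unique(donor_key):
        cols = np.flatnonzero(donor_key == key)
        centered[:, cols] -= centered[:, cols].mean(axis=1, keepdims=True)

    # round 2: collapse replicates per group x timepoint
    columns = pd.MultiIndex.from_product([groups, timepoints], names=["group", "timepoint_hr"])
    collapsed = np.empty((dataset.n_genes, len(columns)))
    for j, (g, t) in enumerate(columns):
        cols = np.flatnonzero(
            ((samples["group"] == g) & (samples["timepoint_hr"] == t)).to_numpy()
        )
        collapsed[:, j] = centered[:, cols].mean(axis=1)

    # round 3: Z-score across timepoints within each group
    out = np.empty_like(collapsed)
    flags = {}
    for g in groups:
        cols = np.flatnonzero(columns.get_level_values("group") == g)
        block = collapsed[:, cols]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        zero = sd[:, 0] == 0
        sd[zero] = 1.0
        z = (block - mean) / sd
        z[zero] = 0.0
        out[:, cols] = z
        flags[g] = zero
    values = pd.DataFrame(out, index=pd.Index(dataset.gene_ids, name="gene_id"), columns=columns)
    zero_variance = pd.DataFrame(flags, index=values.index)
    return HeatmapMatrix(values=values, zero_variance=zero_variance)
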