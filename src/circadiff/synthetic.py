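"""Synthetic expression time-courses and wearable streams with ground truth.

The expression generator emulates a serum-entrainment time-course design:
cultured cells synchronized with serum from two donor groups (young and
old, four serum donors per group by default) and harvested every 2 hours
from 32 to 58 hours after serum addition (14 timepoints).  Each gene's
expression on the log10(1 + normalized count) scale is

    value = M_g + A_g * cos(2*pi*(t - phi_g)/period) + donor_offset + noise

with group-specific cosinor parameters (M, A, phi), a per-donor additive
intercept drawn once per donor (the baseline difference between sera that
the heatmap normalization removes), and i.i.d. Gaussian noise.  Genes are
assigned to the four rhythmicity classes (rhythmic in both groups, young
only, old only, neither) in deterministic proportions; a subset of the
"both" genes carries injected MESOR / amplitude / phase differences between
groups, recorded in the returned ground-truth table.

The wearable generator emulates per-subject actigraphy / heart-rate streams
as a truncated 24-h cosine plus noise, with group-level acrophases (so a
phase advance of the old group can be injected) and optional per-subject
phase jitter.

All randomness flows from a single integer seed through a documented
sub-seeding scheme (numpy SeedSequence spawning: gene parameters, donor
offsets, and observation noise each use their own child stream), so
regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

__all__ = [
    "SimulationConfig",
    "generate_expression_dataset",
    "generate_wearable_series",
    "write_wearables_csv",
]

CLASSES = ("both", "young_only", "old_only", "neither")
EFFECTS = ("mesor", "amplitude", "phase")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for the expression generator.

    Defaults mirror the emulated experiment: 14 timepoints (32-58 h every
    2 h), 4 serum donors per group, fixed 24-h period.  MESOR and amplitude
    ranges and the noise level are on the log10(1 + count) scale; with the
    defaults the amplitude-to-noise ratio spans 2.5-5, a regime where
    rhythmic genes are clearly detectable at this sampling density.
    """

    n_genes: int = 400
    frac_rhythmic_both: float = 0.25
    frac_young_only: float = 0.25
    frac_old_only: float = 0.25
    frac_neither: float = 0.25
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(32, 60, 2))
    n_donors_per_group: int = 4
    period: float = 24.0
    mesor_range: tuple[float, float] = (2.0, 4.0)
    amplitude_range: tuple[float, float] = (0.5, 1.0)
    phase_range: tuple[float, float] | None = None  # None -> uniform on [0, period)
    noise_sd: float = 0.2
    donor_offset_sd: float = 0.1
    delta_mesor: float = 0.5
    delta_amplitude: float = -0.25
    delta_phase_hours: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_rhythmic_both,
            self.frac_young_only,
            self.frac_old_only,
            self.frac_neither,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError(f"class fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-12:
            raise ValueError(f"class fractions must sum to 1, got {sum(fracs)!r}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.donor_offset_sd < 0:
            raise ValueError("donor_offset_sd must be non-negative")
        lo, hi = self.amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid amplitude_range {self.amplitude_range}")
        if self.delta_amplitude < 0 and lo + self.delta_amplitude < 0:
            raise ValueError(
                "delta_amplitude would drive some old-group amplitudes negative; "
                "raise the amplitude_range lower bound"
            )

    @property
    def class_counts(self) -> dict[str, int]:
        """Deterministic class sizes: floor(frac * n), remainder to 'neither'."""
        counts = {
            "both": int(np.floor(self.frac_rhythmic_both * self.n_genes)),
            "young_only": int(np.floor(self.frac_young_only * self.n_genes)),
            "old_only": int(np.floor(self.frac_old_only * self.n_genes)),
        }
        counts["neither"] = self.n_genes - sum(counts.values())
        return counts


_DONOR_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for group in ("young", "old"):
        for d in range(config.n_donors_per_group):
            donor = _DONOR_LETTERS[d]
            for t in config.timepoints:
                rows.append(
                    {
                        "sample_id": f"{group}_{donor}_t{int(t) if t == int(t) else t}",
                        "group": group,
                        "donor": donor,
                        "timepoint_hr": float(t),
                    }
                )
    return pd.DataFrame(rows)


def generate_expression_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate a genes x samples expression matrix plus a ground-truth table.

    Returns the dataset and a DataFrame with one row per gene: the true
    class, the true per-group cosinor parameters, and flags/values for the
    injected between-group effects.  Deterministic for a fixed config.
    """
    samples = _sample_table(config)
    n_samples = len(samples)
    counts = config.class_counts

    root = np.random.SeedSequence(config.seed)
    ss_params, ss_donor, ss_noise = root.spawn(3)
    rng_params = np.random.default_rng(ss_params)
    rng_donor = np.random.default_rng(ss_donor)
    rng_noise = np.random.default_rng(ss_noise)

    classes = np.concatenate(
        [np.repeat(c, counts[c]) for c in CLASSES]
    ) if config.n_genes else np.array([], dtype=object)

    n = config.n_genes
    mesor = rng_params.uniform(*config.mesor_range, size=n)
    amp = rng_params.uniform(*config.amplitude_range, size=n)
    phase_lo, phase_hi = config.phase_range or (0.0, config.period)
    phase = rng_params.uniform(phase_lo, phase_hi, size=n)

    # round-robin assignment of injected effects over the "both" genes,
    # cycling none -> mesor -> amplitude -> phase (skipping zero deltas)
    deltas = {
        "mesor": config.delta_mesor,
        "amplitude": config.delta_amplitude,
        "phase": config.delta_phase_hours,
    }
    active = [e for e in EFFECTS if deltas[e] != 0.0]
    cycle = ["none"] + active
    effect = np.array(["none"] * n, dtype=object)
    both_idx = np.flatnonzero(classes == "both")
    for j, gi in enumerate(both_idx):
        effect[gi] = cycle[j % len(cycle)]

    truth_rows = []
    values = np.empty((n, n_samples))
    t_hr = samples["timepoint_hr"].to_numpy()
    group_old = (samples["group"] == "old").to_numpy()
    donor_key = (samples["group"] + "_" + samples["donor"]).to_numpy()
    unique_donors = pd.unique(donor_key)
    offsets = dict(
        zip(unique_donors, rng_donor.normal(0.0, config.donor_offset_sd, len(unique_donors)))
    )
    donor_offset = np.array([offsets[k] for k in donor_key])
    w = 2.0 * np.pi / config.period

    for gi in range(n):
        cls = classes[gi]
        m_y = m_o = mesor[gi]
        a_y = amp[gi] if cls in ("both", "young_only") else 0.0
        a_o = amp[gi] if cls in ("both", "old_only") else 0.0
        p_y = phase[gi] if a_y > 0 else 0.0
        p_o = phase[gi] if a_o > 0 else 0.0
        eff = effect[gi]
        if eff == "mesor":
            m_o = m_y + config.delta_mesor
        elif eff == "amplitude":
            a_o = a_y + config.delta_amplitude
        elif eff == "phase":
            p_o = (p_y + config.delta_phase_hours) % config.period

        signal = np.where(
            group_old,
            m_o + a_o * np.cos(w * (t_hr - p_o)),
            m_y + a_y * np.cos(w * (t_hr - p_y)),
        )
        values[gi] = signal + donor_offset
        truth_rows.append(
            {
                "gene_id": f"gene_{gi:05d}",
                "true_class": cls,
                "mesor_young": m_y,
                "mesor_old": m_o,
                "amplitude_young": a_y,
                "amplitude_old": a_o,
                "phase_young": p_y,
                "phase_old": p_o,
                "has_delta_mesor": eff == "mesor",
                "has_delta_amplitude": eff == "amplitude",
                "has_delta_phase": eff == "phase",
                "delta_mesor": config.delta_mesor if eff == "mesor" else 0.0,
                "delta_amplitude": config.delta_amplitude if eff == "amplitude" else 0.0,
                "delta_phase_hours": config.delta_phase_hours if eff == "phase" else 0.0,
            }
        )

    if config.noise_sd > 0 and n:
        values += rng_noise.normal(0.0, config.noise_sd, size=values.shape)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "true_class",
            "mesor_young",
            "mesor_old",
            "amplitude_young",
            "amplitude_old",
            "phase_young",
            "phase_old",
            "has_delta_mesor",
            "has_delta_amplitude",
            "has_delta_phase",
            "delta_mesor",
            "delta_amplitude",
            "delta_phase_hours",
        ],
    )
    dataset = ExpressionDataset(
        gene_ids=truth["gene_id"].tolist() if n else [],
        values=values,
        samples=samples,
    )
    return dataset, truth


def generate_wearable_series(
    n_subjects_per_group: int | dict[str, int],
    days: int,
    cadence: float,
    diurnal_amplitude: float,
    phase_by_group: dict[str, float],
    noise_sd: float,
    seed: int,
    mesor: float = 200.0,
    subject_jitter_sd: float = 0.0,
    start: str = "2024-01-01 00:00:00",
) -> pd.DataFrame:
    """Per-subject timestamped wearable streams as a long-format table.

    Each subject's value at time t (hours since the start midnight) is
    ``max(0, mesor + A*cos(2*pi*(t - phi_group - jitter)/24) + noise)``.
    Returns columns subject_id, group, timestamp, value.

    ``n_subjects_per_group`` may be an int (same for both groups) or a
    mapping like ``{"young": 7, "old": 8}``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if diurnal_amplitude < 0:
        raise ValueError("diurnal_amplitude must be non-negative")
    if cadence <= 0 or (60.0 % cadence) != 0:
        raise ValueError("cadence must be a positive divisor of 60 seconds")
    if isinstance(n_subjects_per_group, int):
        n_by_group = {g: n_subjects_per_group for g in phase_by_group}
    else:
        n_by_group = dict(n_subjects_per_group)

    rng = np.random.default_rng(seed)
    n_samples = int(days * 24 * 3600 / cadence)
    t_hours = np.arange(n_samples) * cadence / 3600.0
    # integer-second timestamps, so minute binning downstream is exact
    timestamps = pd.Timestamp(start) + pd.to_timedelta(
        np.round(np.arange(n_samples) * cadence).astype(np.int64), unit="s"
    )

    frames = []
    for group, n_subj in n_by_group.items():
        phi_g = phase_by_group[group]
        for s in range(n_subj):
            jitter = rng.normal(0.0, subject_jitter_sd) if subject_jitter_sd > 0 else 0.0
            signal = mesor + diurnal_amplitude * np.cos(
                2.0 * np.pi * (t_hours - phi_g - jitter) / 24.0
            )
            if noise_sd > 0:
                signal = signal + rng.normal(0.0, noise_sd, size=n_samples)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": f"{group}_{s + 1:02d}",
                        "group": group,
                        "timestamp": timestamps,
                        "value": np.maximum(signal, 0.0),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_wearables_csv(df: pd.DataFrame, path) -> None:
    """Write a wearable long-format table with ISO-8601 timestamps."""
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
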