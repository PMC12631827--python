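"""Synthetic-data generators with planted, recoverable structure.

Every input the pipeline consumes can be simulated here: oscillatory EEG
epochs with a planted traveling-wave direction, single-trial activation
patterns with a planted condition separation and a latent feature axis,
piecewise-constant decoding time courses with a planted changepoint,
mediation triples with planted path coefficients, and binary behavioral
responses with subject-level heterogeneity.

All generators are pure functions of their spec (including its seed):
repeated calls return byte-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import MIDLINE_AXIS, EpochedEEG, TrialBetaMatrix

__all__ = [
    "WaveSpec",
    "PatternSpec",
    "MediationSpec",
    "gen_wave_eeg",
    "gen_beta_patterns",
    "gen_auc_curve",
    "gen_mediation_data",
    "gen_behavior",
    "gen_phase_betas",
]


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveSpec:
    """Planted oscillatory traveling wave.

    ``direction`` selects the sign of the spatial phase gradient along the
    electrode axis (row 0 = most posterior): ``forward`` waves propagate
    posterior-to-anterior, ``backward`` the reverse, ``standing`` has no
    gradient (``phase_step_rad_per_channel`` must then be 0).
    """

    frequency_hz: float
    direction: Literal["forward", "backward", "standing"]
    amplitude: float = 1.0
    phase_step_rad_per_channel: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.direction not in ("forward", "backward", "standing"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "standing" and self.phase_step_rad_per_channel != 0:
            raise ValueError("standing waves require phase_step_rad_per_channel == 0")


@dataclass(frozen=True)
class PatternSpec:
    """Planted structure for single-trial activation patterns.

    ``condition_separation`` is the Euclidean distance between the two
    condition mean patterns in units of the noise SD.  ``feature_coupling``
    is the fraction of trial-pattern variance carried by a single latent
    feature axis whose loading per trial is the (standardized) stimulus
    rating; 0 decouples patterns from ratings entirely, 1 makes them
    noiseless functions of the rating.

    Defaults mirror a typical rapid event-related design: 25 trials per
    condition spread over 5 runs (leave-one-run-out then trains on 40 trials,
    20 per condition, and tests on 10), with a region of ~100 voxels.
    """

    n_trials_per_condition: int = 25
    n_runs: int = 5
    n_features: int = 100
    condition_separation: float = 2.0
    feature_coupling: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_condition % self.n_runs != 0:
            raise ValueError(
                f"n_trials_per_condition={self.n_trials_per_condition} not divisible "
                f"by n_runs={self.n_runs}"
            )
        if not 0.0 <= self.feature_coupling <= 1.0:
            raise ValueError("feature_coupling must lie in [0, 1]")
        if self.condition_separation < 0:
            raise ValueError("condition_separation must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class MediationSpec:
    """Planted simple-mediation model X -> M -> Y with direct path c'."""

    n: int = 200
    path_a: float = 0.5
    path_b: float = 0.4
    path_c_prime: float = 0.2
    noise_sd_m: float = 1.0
    noise_sd_y: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be at least 4")
        if self.n % 2 != 0:
            raise ValueError("n must be even (balanced X coding)")
        if self.noise_sd_m <= 0 or self.noise_sd_y <= 0:
            raise ValueError("noise SDs must be positive")


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------

def gen_wave_eeg(
    spec: WaveSpec,
    n_channels: int = 7,
    duration_s: float = 1.0,
    fs_hz: float = 1000.0,
    n_trials: int = 1,
    channel_names: Sequence[str] | None = None,
) -> EpochedEEG:
    """Simulate epochs carrying a planted plane wave along the channel axis.

    Channel ``c`` carries ``amplitude * cos(2*pi*f*t - s*c*phase_step)`` plus
    i.i.d. Gaussian noise, where ``s`` is +1 for forward, -1 for backward and
    0 for standing.  With ``s=+1`` the oscillation peaks progressively later
    toward anterior channels, i.e. the wave travels posterior-to-anterior.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels for a spatial axis")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if spec.frequency_hz >= fs_hz / 2:
        raise ValueError(
            f"frequency {spec.frequency_hz} Hz is at or above Nyquist ({fs_hz / 2} Hz)"
        )
    n_samples_f = duration_s * fs_hz
    n_samples = int(round(n_samples_f))
    if abs(n_samples_f - n_samples) > 1e-9:
        raise ValueError("duration_s * fs_hz must be an integer number of samples")

    if channel_names is None:
        channel_names = (
            MIDLINE_AXIS if n_channels == 7 else tuple(f"ch{i:02d}" for i in range(n_channels))
        )
    elif len(channel_names) != n_channels:
        raise ValueError("channel_names length must equal n_channels")

    sign = {"forward": 1.0, "backward": -1.0, "standing": 0.0}[spec.direction]
    t = np.arange(n_samples) / fs_hz
    c = np.arange(n_channels)
    phase = 2 * np.pi * spec.frequency_hz * t[None, :] - sign * spec.phase_step_rad_per_channel * c[:, None]
    clean = spec.amplitude * np.cos(phase)

    rng = np.random.default_rng(spec.seed)
    data = clean[None, :, :] + rng.normal(0.0, spec.noise_sd, (n_trials, n_channels, n_samples))
    return EpochedEEG(data=data, channel_names=tuple(channel_names), fs_hz=fs_hz, t0_s=0.0)


def gen_beta_patterns(
    spec: PatternSpec,
    feature_ratings: np.ndarray | None = None,
    conditions: tuple[str, str] = ("IH", "NP"),
    structure_seed: int | None = None,
) -> TrialBetaMatrix:
    """Simulate single-trial patterns with planted condition and feature axes.

    The two condition means sit at ``+-(separation/2) * noise_sd`` along a
    random unit direction ``u``.  A second random unit direction ``v``
    (orthogonalized against ``u``) carries the latent feature axis: trial i
    receives ``sqrt(coupling) * noise_sd * z_i * v`` where ``z_i`` is the
    standardized rating of its stimulus, and residual noise
    ``sqrt(1 - coupling) * noise_sd`` per feature, so ``coupling`` is the
    fraction of (non-condition) pattern variance explained by the ratings.

    ``structure_seed`` fixes the directions ``u``/``v`` separately from the
    noise stream; two datasets sharing ``structure_seed`` but differing in
    ``seed`` emulate two modalities with a common representational geometry
    (the regime cross-modal decoding exploits).

    Run labels tile trials so every run contains equal per-condition counts.
    Stored ratings are the raw (unstandardized) values.
    """
    n_per = spec.n_trials_per_condition
    n_total = 2 * n_per
    rng = np.random.default_rng(spec.seed)
    struct_rng = (
        rng if structure_seed is None else np.random.default_rng(structure_seed)
    )

    u = struct_rng.normal(size=spec.n_features)
    u /= np.linalg.norm(u)
    v = struct_rng.normal(size=spec.n_features)
    v -= (v @ u) * u
    v /= np.linalg.norm(v)

    if feature_ratings is None:
        ratings = rng.uniform(1.0, 9.0, size=n_total)
    else:
        ratings = np.asarray(feature_ratings, dtype=float)
        if ratings.shape != (n_total,):
            raise ValueError(f"need one rating per trial ({n_total}), got shape {ratings.shape}")
    z = ratings - ratings.mean()
    sd = z.std()
    if sd > 0:
        z = z / sd

    condition = np.array([conditions[0]] * n_per + [conditions[1]] * n_per)
    per_run = n_per // spec.n_runs
    run = np.tile(np.repeat(np.arange(spec.n_runs), per_run), 2)

    half = 0.5 * spec.condition_separation * spec.noise_sd
    means = np.where(condition[:, None] == conditions[0], half, -half) * u[None, :]
    latent = np.sqrt(spec.feature_coupling) * spec.noise_sd * z[:, None] * v[None, :]
    noise = np.sqrt(1.0 - spec.feature_coupling) * spec.noise_sd * rng.normal(
        size=(n_total, spec.n_features)
    )
    return TrialBetaMatrix(
        patterns=means + latent + noise,
        condition=condition,
        run=run,
        ratings={"rating": ratings},
    )


def gen_auc_curve(
    n_samples: int,
    change_index: int,
    level_pre: float,
    level_post: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Piecewise-constant decoding time course with one planted step.

    Samples before ``change_index`` sit at ``level_pre``, samples from
    ``change_index`` on at ``level_post``, plus i.i.d. Gaussian noise.
    """
    if not 0 < change_index < n_samples:
        raise ValueError(f"change_index must lie strictly inside (0, {n_samples})")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    curve = np.full(n_samples, float(level_pre))
    curve[change_index:] = level_post
    rng = np.random.default_rng(seed)
    return curve + rng.normal(0.0, noise_sd, n_samples)


def gen_mediation_data(spec: MediationSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (X, M, Y) with planted paths.

    X is the balanced {0, -1} stimulation coding (0 = pre, -1 = post);
    M = a*X + noise; Y = c'*X + b*M + noise.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.tile([0.0, -1.0], spec.n // 2)
    m = spec.path_a * x + rng.normal(0.0, spec.noise_sd_m, spec.n)
    y = spec.path_c_prime * x + spec.path_b * m + rng.normal(0.0, spec.noise_sd_y, spec.n)
    return x, m, y


def gen_behavior(
    n_subjects: int,
    p_np: float,
    p_ih: float,
    n_trials: int = 40,
    subject_sd: float = 0.5,
    seed: int = 0,
    ih_logit_shift: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate per-trial binary responses under the two task conditions.

    Each subject's response probability is drawn on the logit scale around
    the condition mean (Gaussian random intercept of SD ``subject_sd``
    shared across conditions), and trials are Bernoulli draws.
    ``ih_logit_shift`` optionally adds a per-subject shift to the IH
    condition's logit only, planting a subject-level association between an
    external covariate and the behavioral IH-NP difference.

    Returns a tidy frame with columns subject, condition, trial, response.
    """
    for name, p in (("p_np", p_np), ("p_ih", p_ih)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie strictly inside (0, 1), got {p}")
    if ih_logit_shift is not None:
        ih_logit_shift = np.asarray(ih_logit_shift, dtype=float)
        if ih_logit_shift.shape != (n_subjects,):
            raise ValueError("ih_logit_shift needs one value per subject")
    else:
        ih_logit_shift = np.zeros(n_subjects)

    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, subject_sd, n_subjects)
    rows = []
    for s in range(n_subjects):
        for cond, base, shift in (("NP", p_np, 0.0), ("IH", p_ih, ih_logit_shift[s])):
            p_subj = expit(logit(base) + intercepts[s] + shift)
            resp = rng.random(n_trials) < p_subj
            for t_idx, r in enumerate(resp):
                rows.append((s, cond, t_idx, int(r)))
    return pd.DataFrame(rows, columns=["subject", "condition", "trial", "response"])


def gen_phase_betas(
    n_subjects: int,
    pre_contrast: float,
    post_contrast: float,
    noise_sd: float = 0.3,
    baseline: float = 1.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Simulate per-subject regional betas for the two phases and conditions.

    ``pre_contrast``/``post_contrast`` are the planted IH - NP contrasts
    before and after the phase boundary; the planted temporal deactivation
    index is their difference.  Each of the four betas gets independent
    Gaussian subject noise on top of a common task baseline.
    """
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, (4, n_subjects))
    return {
        "beta_pre_ih": baseline + pre_contrast + noise[0],
        "beta_pre_np": baseline + noise[1],
        "beta_post_ih": baseline + post_contrast + noise[2],
        "beta_post_np": baseline + noise[3],
    }
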