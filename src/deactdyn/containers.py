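"""In-memory containers shared across analysis stages.

Two containers travel through the whole pipeline: :class:`EpochedEEG`
(stimulus-locked multichannel epochs feeding the traveling-wave stage) and
:class:`TrialBetaMatrix` (single-trial activation patterns feeding decoding
and representational similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochedEEG", "TrialBetaMatrix"]

#: Midline occipital-to-frontal electrode axis (posterior first).
MIDLINE_AXIS = ("Oz", "POz", "Pz", "CPz", "Cz", "FCz", "Fz")
#: Left and right temporal-to-frontal axes.
LEFT_TEMPORAL_AXIS = ("FT7", "F7", "AF7", "AF3")
RIGHT_TEMPORAL_AXIS = ("FT8", "F8", "AF8", "AF4")


@dataclass
class EpochedEEG:
    """Stimulus-locked epochs: ``data[trial, channel, sample]``.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltage (arbitrary units).
    channel_names : sequence of str
        One name per channel, in the row order of ``data``.
    fs_hz : float
        Sampling rate in Hz.
    t0_s : float
        Time of the first sample relative to stimulus onset, seconds.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D (trial, channel, sample), got ndim={self.data.ndim}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present; available: {', '.join(self.channel_names)}"
            ) from None


@dataclass
class TrialBetaMatrix:
    """Single-trial activation patterns with condition and run labels.

    ``patterns`` is trials x features (e.g. voxels); ``condition`` holds one
    class label per trial; ``run`` the acquisition run each trial belongs to
    (the unit of leave-one-run-out cross-validation); ``ratings`` optional
    per-trial subjective feature ratings keyed by feature name.
    """

    patterns: np.ndarray
    condition: np.ndarray
    run: np.ndarray
    ratings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.condition = np.asarray(self.condition)
        self.run = np.asarray(self.run, dtype=int)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be 2D (trial, feature)")
        n = self.patterns.shape[0]
        if self.condition.shape != (n,) or self.run.shape != (n,):
            raise ValueError("condition and run must have one entry per trial")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns contain missing/non-finite values")
        self.ratings = {k: np.asarray(v, dtype=float) for k, v in self.ratings.items()}
        for name, vals in self.ratings.items():
            if vals.shape != (n,):
                raise ValueError(f"ratings[{name!r}] must have one value per trial")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"ratings[{name!r}] contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_features(self) -> int:
        return self.patterns.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.condition)

    def subset(self, idx: np.ndarray) -> "TrialBetaMatrix":
        """New matrix restricted to the given trial indices (copies data)."""
        idx = np.asarray(idx)
        return TrialBetaMatrix(
            patterns=self.patterns[idx].copy(),
            condition=self.condition[idx].copy(),
            run=self.run[idx].copy(),
            ratings={k: v[idx].copy() for k, v in self.ratings.items()},
        )
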