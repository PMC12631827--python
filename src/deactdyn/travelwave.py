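"""Traveling-wave quantification by the 2D-FFT quadrant method.

Signals from an ordered electrode axis (posterior first) are stacked into a
2D electrode-by-time map.  The 2D Fourier transform of that map separates
oscillations by propagation direction: the two spatial-frequency
half-planes at positive temporal frequency carry posterior-to-anterior
("forward") and anterior-to-posterior ("backward") waves respectively; the
assignment is fixed once by calibration against a planted forward wave.  For each
temporal frequency in 4-40 Hz the maximum power over nonzero spatial
frequencies in each quadrant yields a forward and a backward spectrum,
expressed in dB against the direction-blind baseline (the across-electrode
mean of the 1D temporal power spectra) and summarized in the canonical
theta (4-8), alpha (8-14), beta (14-30) and gamma (30-40 Hz) bands.

Conventions (documented, fixed by calibration tests):

* power = ``|FFT|^2``, dB = ``10*log10(power / baseline)``;
* the spatial zero line (standing energy) and the temporal DC bin are
  excluded from the quadrant maxima;
* quadrant power is normalized by ``n_electrodes^2 * n_samples`` and the 1D
  baseline by ``n_samples``, so a perfectly coherent plane wave scores
  ~equal to a single electrode's 1D power at the same frequency;
* no windowing/tapering is applied — epochs are transformed as-is;
* the frequency grid is the native DFT grid of the epoch length, and band
  membership is by bin center in ``[lo, hi)`` (gamma closed at 40 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .containers import EpochedEEG

__all__ = [
    "AxisMap",
    "WaveSpectrum",
    "BandPower",
    "ContrastResult",
    "BAND_EDGES",
    "build_axis_map",
    "wave_quadrant_power",
    "compute_baseline",
    "to_decibel",
    "wave_spectrum",
    "band_power",
    "condition_contrast",
]

#: Canonical band edges in Hz; upper edges are open except gamma (closed at 40).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 40.0),
}

# Quadrant powers below this fraction of the map's total spectral power are
# treated as exact zeros (pure numerical residue of cancelling FFT terms,
# e.g. a zero-phase-gradient oscillation has no off-axis spatial energy).
_POWER_FLOOR_REL = 1e-15


@dataclass
class AxisMap:
    """2D electrode-by-time map along one ordered axis (posterior first)."""

    values: np.ndarray
    channel_order: tuple[str, ...]
    fs_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channel_order = tuple(self.channel_order)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (electrode, time)")
        if self.values.shape[0] < 2:
            raise ValueError("an axis map needs at least 2 electrodes")
        if self.values.shape[1] < 8:
            raise ValueError("an axis map needs at least 8 time samples")
        if len(self.channel_order) != self.values.shape[0]:
            raise ValueError("channel_order length must match the electrode dimension")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")


@dataclass
class WaveSpectrum:
    """Per-frequency forward/backward power, optionally with dB vs baseline."""

    frequencies_hz: np.ndarray
    fw_power: np.ndarray
    bw_power: np.ndarray
    baseline: np.ndarray | None = None
    fw_db: np.ndarray | None = None
    bw_db: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.frequencies_hz)
        for name in ("fw_power", "bw_power"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must match the frequency grid length {n}")
            if np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, v)


@dataclass(frozen=True)
class BandPower:
    """Band-aggregated forward/backward dB values."""

    band: Literal["theta", "alpha", "beta", "gamma"]
    fw_db: float
    bw_db: float


@dataclass(frozen=True)
class ContrastResult:
    """Paired condition contrast of band dB values (per direction)."""

    mean_delta_fw: float
    t_fw: float
    p_fw: float
    mean_delta_bw: float
    t_bw: float
    p_bw: float
    n_pairs: int


def build_axis_map(
    epochs: EpochedEEG, axis_channels: Sequence[str], trial: int
) -> AxisMap:
    """Stack the requested channels of one trial into a 2D map.

    Rows follow ``axis_channels`` exactly (index 0 = most posterior element
    of the axis); values are copied.
    """
    if len(axis_channels) < 2:
        raise ValueError("an axis needs at least 2 channels")
    missing = [c for c in axis_channels if c not in epochs.channel_names]
    if missing:
        raise KeyError(f"channel(s) not in epochs: {', '.join(missing)}")
    rows = [epochs.channel_index(c) for c in axis_channels]
    return AxisMap(
        values=epochs.data[trial, rows, :].copy(),
        channel_order=tuple(axis_channels),
        fs_hz=epochs.fs_hz,
    )


def _temporal_grid(axis_map: AxisMap, f_min: float, f_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices and values of positive temporal DFT bins within [f_min, f_max]."""
    n_t = axis_map.values.shape[1]
    freqs = np.fft.fftfreq(n_t, d=1.0 / axis_map.fs_hz)
    sel = np.flatnonzero((freqs >= f_min) & (freqs <= f_max) & (freqs > 0))
    return sel, freqs[sel]


def wave_quadrant_power(
    axis_map: AxisMap, f_min: float = 4.0, f_max: float = 40.0
) -> WaveSpectrum:
    """Forward/backward power spectra from the 2D-FFT quadrants.

    For each temporal frequency bin in ``[f_min, f_max]`` the forward and
    backward powers are the maxima over nonzero spatial frequencies in the
    two opposite spatial half-planes at positive temporal frequency
    (spatial zero line and temporal DC excluded); which half-plane is
    "forward" is fixed once by calibration against a planted
    posterior-to-anterior wave (see inline comment).
    """
    if f_max >= axis_map.fs_hz / 2:
        raise ValueError(f"f_max={f_max} must be below Nyquist ({axis_map.fs_hz / 2} Hz)")
    n_el, n_t = axis_map.values.shape
    t_idx, freqs = _temporal_grid(axis_map, f_min, f_max)
    if len(t_idx) == 0:
        raise ValueError("no DFT bins fall inside the requested frequency range")

    power2d = np.abs(np.fft.fft2(axis_map.values)) ** 2 / (n_el**2 * n_t)
    # Spatial zero line (standing energy) excluded from both quadrants; for
    # even electrode counts the spatial Nyquist row (k = -1/2) is direction-
    # ambiguous and excluded as well, preserving the exact fw/bw swap under
    # row reversal.
    # Orientation calibrated on a planted posterior-to-anterior plane wave
    # cos(w*t - c*step): with the DFT kernel exp(-2*pi*i*(k*c/C + m*t/T)) its
    # energy sits at negative spatial frequency k = -C*step/(2*pi) and
    # positive temporal frequency, so the forward quadrant is k < 0.
    k = np.fft.fftfreq(n_el)
    fw_rows = np.flatnonzero((k < 0) & (k != -0.5))
    bw_rows = np.flatnonzero(k > 0)

    fw = power2d[np.ix_(fw_rows, t_idx)].max(axis=0)
    bw = power2d[np.ix_(bw_rows, t_idx)].max(axis=0)

    floor = _POWER_FLOOR_REL * power2d.sum()
    fw = np.where(fw > floor, fw, 0.0)
    bw = np.where(bw > floor, bw, 0.0)
    return WaveSpectrum(frequencies_hz=freqs, fw_power=fw, bw_power=bw)


def compute_baseline(
    axis_map: AxisMap, frequencies: np.ndarray | None = None,
    f_min: float = 4.0, f_max: float = 40.0,
) -> np.ndarray:
    """Direction-blind baseline: across-electrode mean of 1D temporal power.

    Evaluated on the same DFT grid as :func:`wave_quadrant_power`; if
    ``frequencies`` is given it must coincide with bins of that grid.
    """
    t_idx, freqs = _temporal_grid(axis_map, f_min, f_max)
    n_t = axis_map.values.shape[1]
    p1d = np.abs(np.fft.fft(axis_map.values, axis=1)) ** 2 / n_t
    baseline = p1d[:, t_idx].mean(axis=0)
    if frequencies is not None:
        frequencies = np.asarray(frequencies, dtype=float)
        pos = np.searchsorted(freqs, frequencies)
        if np.any(pos >= len(freqs)) or not np.allclose(freqs[np.clip(pos, 0, len(freqs) - 1)], frequencies):
            raise ValueError("requested frequencies do not match the map's DFT grid")
        baseline = baseline[pos]
    return baseline


def to_decibel(power: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """``10*log10(power / baseline)`` elementwise.

    Zero powers map to ``-inf`` (flagged with a warning); a nonpositive
    baseline is rejected outright.
    """
    power = np.asarray(power, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be strictly positive (constant map upstream?)")
    if np.any(power < 0):
        raise ValueError("power must be nonnegative")
    if np.any(power == 0):
        warnings.warn("zero power encountered; emitting -inf dB", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(power / baseline)


def wave_spectrum(
    axis_map: AxisMap, f_min: float = 4.0, f_max: float = 40.0
) -> WaveSpectrum:
    """Quadrant power plus baseline and dB conversion in one call."""
    spec = wave_quadrant_power(axis_map, f_min, f_max)
    spec.baseline = compute_baseline(axis_map, f_min=f_min, f_max=f_max)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spec.fw_db = to_decibel(spec.fw_power, spec.baseline)
        spec.bw_db = to_decibel(spec.bw_power, spec.baseline)
    return spec


def band_power(spectrum: WaveSpectrum, band: str) -> BandPower:
    """Mean forward/backward dB over the bins of one canonical band."""
    if band not in BAND_EDGES:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BAND_EDGES)}")
    if spectrum.fw_db is None or spectrum.bw_db is None:
        raise ValueError("spectrum has no dB values; run wave_spectrum or to_decibel first")
    lo, hi = BAND_EDGES[band]
    f = spectrum.frequencies_hz
    mask = (f >= lo) & ((f <= hi) if band == "gamma" else (f < hi))
    if not np.any(mask):
        raise ValueError(f"no frequency bins fall inside the {band} band ({lo}-{hi} Hz)")
    return BandPower(
        band=band,  # type: ignore[arg-type]
        fw_db=float(spectrum.fw_db[mask].mean()),
        bw_db=float(spectrum.bw_db[mask].mean()),
    )


def condition_contrast(
    bands_a: Sequence[BandPower], bands_b: Sequence[BandPower]
) -> ContrastResult:
    """Paired t-test of band dB between two conditions (A minus B).

    The resulting p-values are meant to enter a family-wise FDR correction
    downstream.  Zero-variance nonzero differences (a constant offset) make
    the t statistic undefined and are rejected; identical inputs yield t=0.
    """
    if len(bands_a) != len(bands_b):
        raise ValueError("paired lists must have equal length")
    n = len(bands_a)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")

    def paired(da: np.ndarray) -> tuple[float, float, float]:
        if np.allclose(da.std(), 0.0):
            if np.allclose(da.mean(), 0.0):
                return 0.0, 0.0, 1.0
            raise ValueError(
                "zero variance of paired differences with nonzero mean: t undefined"
            )
        t, p = stats.ttest_rel(da, np.zeros_like(da))
        return float(da.mean()), float(t), float(p)

    d_fw = np.array([a.fw_db - b.fw_db for a, b in zip(bands_a, bands_b)])
    d_bw = np.array([a.bw_db - b.bw_db for a, b in zip(bands_a, bands_b)])
    m_fw, t_fw, p_fw = paired(d_fw)
    m_bw, t_bw, p_bw = paired(d_bw)
    return ContrastResult(m_fw, t_fw, p_fw, m_bw, t_bw, p_bw, n)
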