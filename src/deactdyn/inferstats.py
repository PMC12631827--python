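"""Temporal deactivation index, brain-behavior correlation, and mediation.

The temporal deactivation index summarizes how the inhibition-vs-natural-
processing (IH - NP) contrast of regional activation changes across the
phase boundary (default 3 s):

    index = (beta_post_IH - beta_post_NP) - (beta_pre_IH - beta_pre_NP)

Negative values mean the IH-related deactivation deepens over time.  The
index correlates across participants with behavioral difference scores
(IH - NP response rates), with Benjamini-Hochberg FDR control over the
family of tests.  The causal chain stimulation -> deactivation -> behavior
is decomposed by a simple-mediation model (paths a, b, c'), with the
indirect effect a*b tested by a bias-corrected percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhaseBetas",
    "BehaviorDeltas",
    "MediationPaths",
    "MediationResult",
    "deactivation_index",
    "behavior_delta",
    "bh_fdr",
    "brain_behavior_correlation",
    "mediation_fit",
    "mediation_bootstrap",
]


@dataclass
class PhaseBetas:
    """Per-subject mean regional activation for each phase x condition cell.

    Values are GLM parameter estimates in arbitrary units; scalars or
    per-subject arrays are both accepted.  ``boundary_s`` records the phase
    boundary the pre/post split was made at.
    """

    beta_pre_ih: np.ndarray
    beta_pre_np: np.ndarray
    beta_post_ih: np.ndarray
    beta_post_np: np.ndarray
    region: str = ""
    boundary_s: float = 3.0

    def __post_init__(self) -> None:
        arrs = {}
        for name in ("beta_pre_ih", "beta_pre_np", "beta_post_ih", "beta_post_np"):
            a = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains missing/non-finite values")
            arrs[name] = a
        shapes = {a.shape for a in arrs.values()}
        if len(shapes) != 1:
            raise ValueError("all four beta arrays must have the same shape")
        for name, a in arrs.items():
            setattr(self, name, a)


@dataclass
class BehaviorDeltas:
    """Per-subject behavioral difference scores (each IH - NP, in [-1, 1])."""

    dp_sensed: np.ndarray
    dp_understood: np.ndarray
    dacc_objective: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dp_sensed", "dp_understood", "dacc_objective"):
            a = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(np.abs(a) > 1.0):
                raise ValueError(f"{name} must lie in [-1, 1]")
            setattr(self, name, a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dP_sensed": self.dp_sensed,
                "dP_understood": self.dp_understood,
                "dACC_objective": self.dacc_objective,
            }
        )


@dataclass(frozen=True)
class MediationPaths:
    """Least-squares path estimates of the simple mediation model."""

    a: float
    b: float
    c_prime: float
    c: float

    @property
    def indirect(self) -> float:
        return self.a * self.b


@dataclass(frozen=True)
class MediationResult:
    """Paths plus the bias-corrected bootstrap CI of the indirect effect."""

    a: float
    b: float
    c_prime: float
    c: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    level: float
    significant: bool


def deactivation_index(pb: PhaseBetas) -> np.ndarray:
    """(post IH - NP) minus (pre IH - NP); invariant to common offsets."""
    return (pb.beta_post_ih - pb.beta_post_np) - (pb.beta_pre_ih - pb.beta_pre_np)


def behavior_delta(ih_rate: float, np_rate: float) -> float:
    """IH minus NP response rate; both must be proportions in [0, 1]."""
    for name, r in (("ih_rate", ih_rate), ("np_rate", np_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {r}")
    return float(ih_rate) - float(np_rate)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a nonempty 1D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def brain_behavior_correlation(
    indices: np.ndarray | pd.DataFrame,
    deltas: BehaviorDeltas | pd.DataFrame,
    windows: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of neural indices with behavioral deltas.

    ``indices`` is either a per-subject vector (one window) or a DataFrame
    with one column per time window; ``deltas`` one column per behavioral
    measure.  Every (measure, window) cell gets r and a two-sided p; the
    whole table forms one FDR family (cells with a constant input are
    flagged undefined and excluded from the family).
    """
    if isinstance(indices, pd.DataFrame):
        idx_df = indices
    else:
        idx_df = pd.DataFrame({(windows[0] if windows else "0-6s"): np.asarray(indices)})
    if windows is not None:
        missing = set(windows) - set(idx_df.columns)
        if missing:
            raise ValueError(f"windows not present in indices: {sorted(missing)}")
        idx_df = idx_df[list(windows)]
    beh_df = deltas.to_frame() if isinstance(deltas, BehaviorDeltas) else deltas

    n = len(idx_df)
    if n < 5:
        raise ValueError(f"need at least 5 subjects, got {n}")
    if len(beh_df) != n:
        raise ValueError("indices and deltas must cover the same subjects in order")

    rows = []
    for measure in beh_df.columns:
        for window in idx_df.columns:
            x = idx_df[window].to_numpy(dtype=float)
            y = beh_df[measure].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((measure, window, np.nan, np.nan))
            else:
                r, p = stats.pearsonr(x, y)
                rows.append((measure, window, float(r), float(p)))
    table = pd.DataFrame(rows, columns=["measure", "window", "r", "p"])
    table["p_fdr"] = np.nan
    valid = table["p"].notna()
    if valid.any():
        table.loc[valid, "p_fdr"] = bh_fdr(table.loc[valid, "p"].to_numpy())
    table["significant"] = table["p_fdr"] < alpha
    return table


def _as_columns(x, m, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x, m, y = (np.asarray(v, dtype=float).ravel() for v in (x, m, y))
    if not len(x) == len(m) == len(y):
        raise ValueError("X, M, Y must have equal length")
    return x, m, y


def mediation_fit(x, m, y) -> MediationPaths:
    """Least-squares paths: a (M on X), b & c' (Y on X, M), c (Y on X).

    The nested least-squares identity ``c = c' + a*b`` holds exactly for
    any data with a single mediator.
    """
    x, m, y = _as_columns(x, m, y)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0:
        raise ValueError("X is constant; paths undefined")
    design = np.column_stack([np.ones(n), x, m])
    cond = np.linalg.cond(design)
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError(f"design matrix [1, X, M] is rank-deficient (cond={cond:.3g})")
    a = np.polyfit(x, m, 1)[0]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    c_prime, b = float(coef[1]), float(coef[2])
    c = float(np.polyfit(x, y, 1)[0])
    return MediationPaths(a=float(a), b=b, c_prime=c_prime, c=c)


def _batched_paths(
    x: np.ndarray, m: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (a, b) per bootstrap row; rows are resampled datasets."""
    xc = x - x.mean(axis=1, keepdims=True)
    mc = m - m.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    a = sxm / sxx
    det = sxx * smm - sxm**2
    b = (sxx * smy - sxm * sxy) / det
    return a, b


def mediation_bootstrap(
    x,
    m,
    y,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
    max_retries: int = 100,
) -> MediationResult:
    """Bias-corrected percentile bootstrap CI for the indirect effect a*b.

    Rows are resampled with replacement; per resample the product a*b is
    recomputed in closed form.  The bias correction uses
    ``z0 = Phi^-1(#{ab* < ab_hat} / n_boot)`` with a continuity guard at 0
    and 1; the acceleration term is omitted (BC, not BCa).  Degenerate
    resamples with constant X are redrawn up to ``max_retries`` times.
    ``significant`` is True iff the CI excludes zero.
    """
    x, m, y = _as_columns(x, m, y)
    paths = mediation_fit(x, m, y)
    n = len(x)
    rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    for _ in range(max_retries):
        bad = np.flatnonzero(xb.std(axis=1) == 0)
        if len(bad) == 0:
            break
        idx[bad] = rng.integers(0, n, size=(len(bad), n))
        xb = x[idx]
    else:
        raise ValueError(f"constant-X resamples persisted after {max_retries} redraws")

    a_b, b_b = _batched_paths(xb, m[idx], y[idx])
    ab = a_b * b_b
    ab_hat = paths.indirect

    if np.ptp(ab) == 0:
        # Noise-free data: every resample reproduces the estimate exactly.
        lo = hi = float(ab[0])
    else:
        prop = np.mean(ab < ab_hat)
        prop = float(np.clip(prop, 0.5 / n_boot, 1 - 0.5 / n_boot))
        z0 = stats.norm.ppf(prop)
        z_alpha = stats.norm.ppf((1 - level) / 2)
        q_lo = stats.norm.cdf(2 * z0 + z_alpha)
        q_hi = stats.norm.cdf(2 * z0 - z_alpha)
        lo, hi = (float(v) for v in np.quantile(ab, [q_lo, q_hi]))

    return MediationResult(
        a=paths.a,
        b=paths.b,
        c_prime=paths.c_prime,
        c=paths.c,
        indirect=ab_hat,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        level=level,
        significant=not (lo <= 0.0 <= hi),
    )
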