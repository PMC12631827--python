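"""Representational similarity analysis with decoupling inference.

Neural dissimilarity between trials is one minus the Pearson correlation of
their activation patterns; feature dissimilarity is the absolute difference
of per-stimulus ratings on a subjective dimension.  Dissimilarity matrices
(RDMs) convert to similarity matrices (RSMs) via ``RSM = 1 - RDM``.
Matrix-level comparisons correlate the vectorized lower triangles:
Spearman against a binary conceptual model (significance by joint row/column
label permutation) and Pearson/Spearman between RSMs.  Condition-wise
decoupling — does a feature track the neural geometry more under one
condition than another? — is tested with Steiger's z for two dependent
correlations sharing the feature RSM as the common variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RDM",
    "RSM",
    "DecouplingTest",
    "neural_rdm",
    "feature_rdm",
    "rdm_to_rsm",
    "vectorize",
    "model_comparison",
    "rsm_correlation",
    "steiger_decoupling",
    "steiger_z",
]

_SYM_TOL = 1e-10


def _check_square_symmetric(matrix: np.ndarray, what: str) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{what} must be square, got shape {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=_SYM_TOL):
        raise ValueError(f"{what} is not symmetric within tolerance {_SYM_TOL}")
    return matrix


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with an exactly zero diagonal."""

    matrix: np.ndarray
    item_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = _check_square_symmetric(self.matrix, "RDM")
        n = self.matrix.shape[0]
        if n < 3:
            raise ValueError("an RDM needs at least 3 items")
        if np.any(self.matrix < 0):
            raise ValueError("RDM entries must be nonnegative")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("RDM diagonal must be exactly zero")
        if not self.item_labels:
            self.item_labels = tuple(f"item{i}" for i in range(n))
        elif len(self.item_labels) != n:
            raise ValueError("item_labels length must match matrix size")

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RSM:
    """Similarity matrix, elementwise ``1 - RDM`` (unit diagonal)."""

    matrix: np.ndarray
    item_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = _check_square_symmetric(self.matrix, "RSM")
        n = self.matrix.shape[0]
        if not self.item_labels:
            self.item_labels = tuple(f"item{i}" for i in range(n))
        elif len(self.item_labels) != n:
            raise ValueError("item_labels length must match matrix size")

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DecouplingTest:
    """Steiger comparison of two feature-neural correlations.

    ``n_pairs`` is the number of vectorized matrix cells used as the
    effective sample size — conventional in RSA but the cells are not
    independent observations; see ``caveat``.
    """

    r_condition_a: float
    r_condition_b: float
    r_ab: float
    n_pairs: int
    z: float
    p: float
    delta_r: float
    caveat: str = field(
        default="effective n = vectorized RDM cells, which are not independent",
        compare=False,
    )


def neural_rdm(patterns: np.ndarray, item_labels: tuple[str, ...] = ()) -> RDM:
    """1 - Pearson correlation between all pairs of trial patterns."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError("patterns must be 2D (trial, feature)")
    n, p = patterns.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 trials and 2 features")
    sds = patterns.std(axis=1)
    flat = np.flatnonzero(sds == 0)
    if len(flat):
        raise ValueError(f"zero-variance trial vector(s) at index {flat.tolist()}")
    r = np.corrcoef(patterns)
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # symmetrize away rounding
    np.fill_diagonal(d, 0.0)
    return RDM(matrix=d, item_labels=item_labels)


def feature_rdm(ratings: np.ndarray, item_labels: tuple[str, ...] = ()) -> RDM:
    """Absolute rating difference between all pairs of stimuli."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 1 or len(ratings) < 3:
        raise ValueError("ratings must be a 1D vector of at least 3 items")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings contain missing/non-finite values")
    d = np.abs(ratings[:, None] - ratings[None, :])
    return RDM(matrix=d, item_labels=item_labels)


def rdm_to_rsm(rdm: RDM) -> RSM:
    """Elementwise ``1 - RDM`` (diagonal becomes 1)."""
    return RSM(matrix=1.0 - rdm.matrix, item_labels=rdm.item_labels)


def vectorize(matrix: RDM | RSM | np.ndarray) -> np.ndarray:
    """Lower triangle excluding the diagonal, fixed row-major order.

    Length ``n*(n-1)/2``; the order is stable across calls, so vectors from
    matrices over matched item sets are directly comparable.
    """
    m = matrix.matrix if isinstance(matrix, (RDM, RSM)) else np.asarray(matrix, dtype=float)
    m = _check_square_symmetric(m, "matrix")
    return m[np.tril_indices(m.shape[0], k=-1)]


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata_mid(x), rankdata_mid(y)
    return _pearson(rx, ry)


def rankdata_mid(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt((xs @ xs) * (ys @ ys))
    if denom == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    return float((xs @ ys) / denom)


def model_comparison(
    avg_rdm: RDM,
    model_rdm: RDM,
    n_perm: int = 5000,
    seed: int = 0,
    permute: str = "model",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Spearman correlation with a binary conceptual model RDM, permutation p.

    The null distribution jointly permutes the item labels (rows and
    columns) of one matrix — ``permute`` selects which — preserving matrix
    symmetry; ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1)``
    (one-sided variant drops the absolute values).
    """
    if avg_rdm.n_items != model_rdm.n_items:
        raise ValueError("matrices must cover the same items")
    off = vectorize(model_rdm)
    if not np.all(np.isin(off, (0.0, 1.0))):
        raise ValueError("model RDM must be binary (0/1 off-diagonal)")
    if permute not in ("model", "neural"):
        raise ValueError("permute must be 'model' or 'neural'")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")

    v_neural = vectorize(avg_rdm)
    v_model = off
    rho = _spearman(v_neural, v_model)

    n = avg_rdm.n_items
    iidx, jidx = np.tril_indices(n, k=-1)
    target = model_rdm.matrix if permute == "model" else avg_rdm.matrix
    fixed = rankdata_mid(v_neural if permute == "model" else v_model)
    fixed = fixed - fixed.mean()
    fixed_norm = np.sqrt(fixed @ fixed)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    permuted = target[perms[:, iidx], perms[:, jidx]]  # (n_perm, n_pairs)
    ranks = stats.rankdata(permuted, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", ranks, ranks))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_perm = (ranks @ fixed) / (norms * fixed_norm)
    rho_perm = np.nan_to_num(rho_perm)  # degenerate permutations count as 0

    if alternative == "two-sided":
        exceed = np.abs(rho_perm) >= np.abs(rho) - 1e-12
    else:
        exceed = rho_perm >= rho - 1e-12
    p = (1 + int(exceed.sum())) / (n_perm + 1)
    return rho, p


def rsm_correlation(rsm1: RSM, rsm2: RSM, method: str = "pearson") -> float:
    """Correlation of the vectorized lower triangles of two RSMs."""
    if rsm1.n_items != rsm2.n_items:
        raise ValueError("matrices must cover the same items")
    v1, v2 = vectorize(rsm1), vectorize(rsm2)
    if method == "pearson":
        return _pearson(v1, v2)
    if method == "spearman":
        return _spearman(v1, v2)
    raise ValueError(f"unknown method {method!r}")


def steiger_z(r_ja: float, r_jb: float, r_ab: float, n: int) -> tuple[float, float]:
    """Steiger's test for two dependent correlations sharing variable j.

    H0: rho_ja = rho_jb given the correlation r_ab between the two
    non-shared variables.  Uses Fisher-transformed correlations with the
    pooled-r covariance term; returns (z, two-sided p).
    """
    for name, r in (("r_ja", r_ja), ("r_jb", r_jb)):
        if abs(r) >= 1.0:
            raise ValueError(f"|{name}| = 1: Fisher transform undefined")
    if n < 4:
        raise ValueError("need n >= 4")
    rm = 0.5 * (r_ja + r_jb)
    rm2 = rm * rm
    cov = (r_ab * (1 - 2 * rm2) - 0.5 * rm2 * (1 - 2 * rm2 - r_ab * r_ab)) / (1 - rm2) ** 2
    z = (np.arctanh(r_ja) - np.arctanh(r_jb)) * np.sqrt((n - 3) / (2.0 - 2.0 * cov))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def steiger_decoupling(
    feature_rsm: RSM, neural_rsm_a: RSM, neural_rsm_b: RSM
) -> DecouplingTest:
    """Compare feature-neural alignment between two conditions.

    ``r_A = corr(feature, neural_A)``, ``r_B = corr(feature, neural_B)``,
    with ``r_AB = corr(neural_A, neural_B)`` capturing their dependence;
    Steiger's z tests ``r_A = r_B``.  Correlations are Spearman (the
    feature-neural convention); effective n is the number of vectorized
    cells.
    """
    if not (feature_rsm.n_items == neural_rsm_a.n_items == neural_rsm_b.n_items):
        raise ValueError("all three matrices must cover the same items")
    r_a = rsm_correlation(feature_rsm, neural_rsm_a, method="spearman")
    r_b = rsm_correlation(feature_rsm, neural_rsm_b, method="spearman")
    r_ab = rsm_correlation(neural_rsm_a, neural_rsm_b, method="spearman")
    n_pairs = len(vectorize(feature_rsm))
    if r_a == r_b:
        z, p = 0.0, 1.0
    else:
        z, p = steiger_z(r_a, r_b, r_ab, n_pairs)
    return DecouplingTest(
        r_condition_a=r_a,
        r_condition_b=r_b,
        r_ab=r_ab,
        n_pairs=n_pairs,
        z=z,
        p=p,
        delta_r=r_a - r_b,
    )
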