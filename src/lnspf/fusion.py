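"""Entropy-weighted feature fusion and the first score-propagation loop.

The four per-protein features (TP1, TP2, FP1, FP2) are stacked into an
N x 4 matrix Z and column-normalized so each feature forms a distribution
over proteins.  Each feature's Shannon entropy

    e_j = -Σ_i z_ij ln z_ij / ln N          (0·ln 0 := 0)

measures how uninformative it is; the fusion weights are
w_j = (1 - e_j) / Σ_k (1 - e_k).  The fused score
CScore(i) = Σ_j w_j z_ij seeds a dense coupling matrix

    H_ij = CScore(i)/Σ_l CScore(l)                    if i = j
         = min(CScore(i), CScore(j))/Σ_l CScore(l)    otherwise,

over which scores are spread from the conservation prior Y⁰ = FP2 by the
restart iteration Y^{t+1} = α H Y^t + (1 - α) Y⁰ until the update falls
below δ in Euclidean norm.  Because every row of H sums to at most 1, the
iteration is a contraction for any α ∈ (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError
from .functional import FunctionalFeatures
from .topology import TopologyFeatures

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("TP1", "TP2", "FP1", "FP2")


@dataclass
class FeatureMatrix:
    """Raw feature matrix Z and its column-normalized copy."""

    proteins: list
    Z: np.ndarray
    Znorm: np.ndarray
    zero_columns: np.ndarray  # boolean flags for all-zero raw columns
    feature_names: tuple = FEATURE_NAMES


@dataclass
class EntropyWeights:
    e: np.ndarray
    w: np.ndarray
    uniform_fallback: bool = False


@dataclass
class FusionMatrix:
    H: np.ndarray


@dataclass
class ScoreVector:
    """Per-protein scores at a named pipeline stage."""

    values: np.ndarray
    stage: str
    iterations_used: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite {self.stage} scores")


def build_feature_matrix(topo: TopologyFeatures, func: FunctionalFeatures,
                         proteins) -> FeatureMatrix:
    """Stack (TP1, TP2, FP1, FP2) columns and column-normalize to sum 1.

    An all-zero raw column stays all-zero and is flagged (it cannot be
    turned into a distribution).
    """
    proteins = list(proteins)
    z = np.column_stack([
        [topo.tp1[p] for p in proteins],
        [topo.tp2[p] for p in proteins],
        [func.fp1[p] for p in proteins],
        [func.fp2[p] for p in proteins],
    ]).astype(float)
    sums = z.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        logger.warning("all-zero feature column(s): %s",
                       [FEATURE_NAMES[j] for j in np.flatnonzero(zero)])
    znorm = np.divide(z, np.where(zero, 1.0, sums), where=~zero,
                      out=np.zeros_like(z))
    return FeatureMatrix(proteins=proteins, Z=z, Znorm=znorm,
                         zero_columns=zero)


def entropy_weights(fm: FeatureMatrix) -> EntropyWeights:
    """Shannon-entropy feature weights on the normalized columns.

    Uniform columns have entropy 1 and contribute weight 0; an all-zero
    (flagged) column is treated as entropy 1 too — a feature with no values
    carries no information.  If *every* column is uninformative the weights
    fall back to uniform 1/M (flagged).
    """
    n, m = fm.Znorm.shape
    if n < 2:
        raise ValueError("entropy weights need at least 2 proteins (ln N > 0)")
    z = fm.Znorm
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(z > 0, z * np.log(z), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    e = np.clip(e, 0.0, 1.0)
    e[fm.zero_columns] = 1.0
    denom = (1.0 - e).sum()
    if denom <= 1e-12:
        logger.warning("all features maximally entropic; uniform weights")
        return EntropyWeights(e=e, w=np.full(m, 1.0 / m),
                              uniform_fallback=True)
    return EntropyWeights(e=e, w=(1.0 - e) / denom)


def cscore(fm: FeatureMatrix, ew: EntropyWeights) -> ScoreVector:
    """Entropy-weighted fused score: weighted row sums of Znorm."""
    return ScoreVector(values=fm.Znorm @ ew.w, stage="CScore")


def build_h(cs: ScoreVector, adjacency: np.ndarray | None = None
            ) -> FusionMatrix:
    """Min-rule coupling matrix from fused scores.

    Dense by default: every off-diagonal entry is
    min(CScore(i), CScore(j)) / Σ CScore.  Passing ``adjacency`` restricts
    the off-diagonal entries to network edges (opt-in variant).
    """
    c = cs.values
    total = c.sum()
    if total <= 0:
        raise ValueError("sum of CScore must be positive to build H")
    h = np.minimum.outer(c, c) / total
    np.fill_diagonal(h, c / total)
    if adjacency is not None:
        mask = adjacency.astype(bool) | np.eye(len(c), dtype=bool)
        h = np.where(mask, h, 0.0)
    return FusionMatrix(H=h)


def _restart_iteration(m: np.ndarray, y0: np.ndarray, coef: float,
                       delta: float, max_iter: int, what: str,
                       hint: str = "") -> tuple[np.ndarray, int]:
    """Shared core of both propagation loops: x ← coef·M·x + (1-coef)·y0.

    Raises :class:`ConvergenceError` when the residual blows up (spectral
    radius of coef·M at or above 1) or max_iter is exhausted.
    """
    base = (1.0 - coef) * y0
    x = y0.astype(float).copy()
    first_resid = None
    resid = np.inf
    for t in range(1, max_iter + 1):
        x_new = coef * (m @ x) + base
        resid = float(np.linalg.norm(x_new - x))
        if resid < delta:
            return x_new, t
        if first_resid is None:
            first_resid = resid
        diverging = not np.isfinite(resid) or (
            t > 10 and resid > 10.0 * max(first_resid, 1e-300))
        if diverging:
            rho = _spectral_radius(m)
            raise ConvergenceError(
                f"{what} diverges (residual {resid:.3g} at iteration {t}; "
                f"coefficient {coef} x spectral radius ~{rho:.4g} = "
                f"{coef * rho:.4g} >= 1 is the likely cause).{hint}",
                residual=resid, spectral_radius=rho)
        x = x_new
    rho = _spectral_radius(m)
    raise ConvergenceError(
        f"{what} did not converge within {max_iter} iterations "
        f"(last residual {resid:.3g}; coefficient {coef} x spectral radius "
        f"~{rho:.4g}).{hint}", residual=resid, spectral_radius=rho)


def _spectral_radius(m: np.ndarray) -> float:
    if m.shape[0] <= 600:
        return float(np.max(np.abs(np.linalg.eigvals(m))))
    # power-iteration estimate for large matrices
    rng = np.random.default_rng(0)
    x = rng.standard_normal(m.shape[0])
    x /= np.linalg.norm(x)
    rho = 0.0
    for _ in range(60):
        y = m @ x
        nrm = np.linalg.norm(y)
        if nrm == 0:
            return 0.0
        rho, x = nrm, y / nrm
    return float(rho)


def propagate(h: FusionMatrix, y0: ScoreVector, alpha: float,
              delta: float = 1e-6, max_iter: int = 1000) -> ScoreVector:
    """First loop: Y^{t+1} = α H Y^t + (1-α) Y⁰ to the fixed point Y^Final."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    values, used = _restart_iteration(h.H, y0.values, alpha, delta, max_iter,
                                      what="fused-feature propagation")
    return ScoreVector(values=values, stage="Y_final", iterations_used=used)
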