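"""Linear neighborhood similarity (LNS) from gene-expression profiles.

Each protein i with expression profile g_i is reconstructed as a convex
combination of the profiles of its interaction partners by minimizing the
ridge-regularized squared reconstruction error

    ε_i = s_iᵀ (Gⁱ + μI) s_i,    Gⁱ_jl = (g_i - g_j)·(g_i - g_l),
    s.t. Σ_j s_ij = 1,  s_ij ≥ 0,

a strictly convex quadratic program over the probability simplex (for
μ > 0).  The optimal weights fill row i of the similarity matrix S, which
additionally has a unit diagonal; rows whose protein lacks an expression
profile, or has no reconstructable neighbor, keep only the diagonal 1.

A second restart iteration T^{σ+1} = β S T^σ + (1-β) T⁰ (with T⁰ the fused
score Y^Final) then smooths the ranking along co-expression structure.
Because a solvable row of S sums to 2 (diagonal + simplex weights), β·ρ(S)
can reach or exceed 1 for large β; divergence is detected and reported,
with optional row normalization of S as a stabilization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fusion import ScoreVector, _restart_iteration
from .io import ExpressionMatrix, PPINetwork
from .topology import NeighborIndex, neighbor_index

logger = logging.getLogger(__name__)


@dataclass
class LNSProblem:
    """One per-protein reconstruction QP.

    ``gram`` is the k×k neighbor Gram matrix Gⁱ; ``neighbors`` orders its
    rows/columns.
    """

    center: str
    neighbors: list
    gram: np.ndarray
    mu: float = 1.0

    def __post_init__(self):
        self.gram = np.asarray(self.gram, dtype=float)
        k = len(self.neighbors)
        if self.gram.shape != (k, k):
            raise ValueError("gram must be k x k for k neighbors")
        if not np.all(np.isfinite(self.gram)):
            raise ValueError("gram must be finite")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


@dataclass
class SimilarityMatrix:
    proteins: list
    S: np.ndarray
    degenerate_rows: list = field(default_factory=list)
    row_normalized: bool = False


def gram_matrix(center_profile: np.ndarray,
                neighbor_profiles: np.ndarray) -> np.ndarray:
    """Neighbor Gram matrix Gⁱ_jl = (g_i - g_j)·(g_i - g_l)."""
    d = center_profile[None, :] - neighbor_profiles
    return d @ d.T


def _simplex_qp(q: np.ndarray, tol: float = 1e-9,
                max_steps: int | None = None) -> np.ndarray:
    """Minimize sᵀ Q s over the probability simplex (primal active set).

    Exact for positive-semidefinite Q: repeatedly solves the
    equality-constrained KKT system on the current support, takes the
    longest feasible step toward that solution (dropping the blocking
    coordinate), and adds the most negative-reduced-cost coordinate until
    the KKT conditions hold to ``tol``.
    """
    k = q.shape[0]
    if k == 1:
        return np.ones(1)
    s = np.full(k, 1.0 / k)
    support = set(range(k))
    max_steps = max_steps or 20 * k + 50

    def kkt_solve(sup):
        idx = np.fromiter(sorted(sup), dtype=int)
        m = len(idx)
        a = np.zeros((m + 1, m + 1))
        a[:m, :m] = 2.0 * q[np.ix_(idx, idx)]
        a[:m, m] = -1.0
        a[m, :m] = 1.0
        b = np.zeros(m + 1)
        b[m] = 1.0
        try:
            x = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            x = np.linalg.lstsq(a, b, rcond=None)[0]
        return idx, x[:m], x[m]

    for _ in range(max_steps):
        idx, s_sup, lam = kkt_solve(support)
        cand = np.zeros(k)
        cand[idx] = s_sup
        if np.all(cand[idx] >= -tol):
            s = np.clip(cand, 0.0, None)
            s /= s.sum()
            grad = 2.0 * (q @ s)
            outside = [j for j in range(k) if j not in support]
            if not outside:
                return s
            reduced = grad[outside] - lam
            j_min = int(np.argmin(reduced))
            if reduced[j_min] >= -tol:
                return s
            support.add(outside[j_min])
        else:
            d = cand - s
            blocking, theta = None, 1.0
            for j in idx:
                if d[j] < 0 and cand[j] < -tol:
                    step = s[j] / -d[j]
                    if step < theta:
                        blocking, theta = j, step
            if blocking is None:
                # numerically degenerate; clip and fall through
                s = np.clip(cand, 0.0, None)
                s /= s.sum()
                support = {j for j in range(k) if s[j] > tol}
                continue
            s = np.clip(s + theta * d, 0.0, None)
            s[blocking] = 0.0
            s /= s.sum()
            support.discard(blocking)
            if not support:  # cannot happen for a bounded simplex QP
                support = {int(np.argmin(np.diag(q)))}
    logger.warning("active-set QP hit the step cap; returning best iterate")
    return s


def solve_lns(problem: LNSProblem, tol: float = 1e-9):
    """Solve one reconstruction QP.

    Returns
    -------
    s : ndarray of shape (k,)
        Simplex weights over ``problem.neighbors``.
    objective : float
        The attained regularized reconstruction error ε_i = sᵀ(Gⁱ+μI)s.
    """
    k = len(problem.neighbors)
    if k == 0:
        raise ValueError(
            f"protein {problem.center!r} has no reconstructable neighbors")
    q = problem.gram + problem.mu * np.eye(k)
    s = _simplex_qp(q, tol=tol)
    return s, float(s @ q @ s)


def build_similarity(net: PPINetwork, expr: ExpressionMatrix,
                     mu: float = 1.0, row_normalize: bool = False,
                     idx: NeighborIndex | None = None) -> SimilarityMatrix:
    """Assemble the N×N LNS matrix S over the network's protein order.

    S_ii = 1 for every protein; row i carries the QP weights on NG(i) when
    protein i has an expression profile and at least one neighbor does too,
    and stays diagonal-only otherwise (those rows are flagged).  With
    ``row_normalize`` each solvable row is divided by its sum (= 2), an
    opt-in stabilization of the second propagation loop.
    """
    idx = idx or neighbor_index(net)
    n = net.n_proteins
    s = np.eye(n)
    degenerate = []
    for i, p in enumerate(net.proteins):
        if p not in expr.index:
            degenerate.append(p)
            continue
        neighbors = [j for j in sorted(idx.one_hop[p], key=net.index.get)
                     if j in expr.index]
        if not neighbors:
            degenerate.append(p)
            continue
        g_i = expr.row(p)
        profiles = np.vstack([expr.row(j) for j in neighbors])
        problem = LNSProblem(center=p, neighbors=neighbors,
                             gram=gram_matrix(g_i, profiles), mu=mu)
        weights, _ = solve_lns(problem)
        for j, w in zip(neighbors, weights):
            s[i, net.index[j]] = w
    if degenerate:
        logger.warning("%d protein(s) kept a diagonal-only similarity row "
                       "(missing expression or no expressed neighbor)",
                       len(degenerate))
    if row_normalize:
        s = s / s.sum(axis=1, keepdims=True)
    return SimilarityMatrix(proteins=list(net.proteins), S=s,
                            degenerate_rows=degenerate,
                            row_normalized=row_normalize)


def propagate_lns(sim: SimilarityMatrix, t0: ScoreVector, beta: float,
                  delta: float = 1e-6, max_iter: int = 1000) -> ScoreVector:
    """Second loop: T^{σ+1} = β S T^σ + (1-β) T⁰ to the fixed point T^Final."""
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    hint = ("" if sim.row_normalized
            else " Consider row-normalizing S (row_normalize_s).")
    values, used = _restart_iteration(
        sim.S, t0.values, beta, delta, max_iter,
        what="linear-neighborhood propagation", hint=hint)
    return ScoreVector(values=values, stage="T_final", iterations_used=used)
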