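"""Scikit-learn-style estimator orchestrating the full ranking pipeline."""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from . import functional, fusion, neighborhood, topology
from .io import ExpressionMatrix, PPINetwork, RunConfig

logger = logging.getLogger(__name__)


class LNSPF(BaseEstimator):
    """Rank proteins of a PPI network by predicted essentiality.

    The estimator runs the whole pipeline in :meth:`fit`: topological
    (TP1, TP2) and functional (FP1, FP2) features are fused by entropy
    weighting into CScore; scores are propagated over the min-rule matrix H
    from the conservation prior Y⁰ = FP2 (restart weight ``alpha``); the
    converged Y^Final is then refined over the gene-expression linear
    neighborhood similarity matrix S (restart weight ``beta``) to T^Final,
    by which proteins are ranked in descending order.

    Parameters
    ----------
    alpha : float, default 0.6
        Restart weight of the fused-feature propagation, in (0, 1).
    beta : float, default 0.4
        Restart weight of the similarity propagation, in (0, 1).
    delta : float, default 1e-6
        Euclidean convergence tolerance of both loops.
    mu : float, default 1.0
        Ridge regularization of the neighborhood-reconstruction QP.
    max_iter : int, default 1000
        Iteration cap of each loop.
    row_normalize_s : bool, default False
        Divide solvable rows of S by their sum (= 2); stabilizes the second
        loop for large ``beta``.
    edge_restricted_h : bool, default False
        Restrict the off-diagonal entries of H to network edges instead of
        the dense min-rule matrix.

    Attributes
    ----------
    ranking_ : list of (protein, score)
        Proteins with T^Final, descending; ties keep input protein order.
    t_final_, y_final_, cscore_ : ndarray
        Stage scores aligned to ``proteins_``.
    n_iter_y_, n_iter_t_ : int
        Iterations used by each propagation loop.
    feature_weights_ : ndarray of shape (4,)
        Entropy weights of (TP1, TP2, FP1, FP2).

    Examples
    --------
    >>> from lnspf.synthetic import SyntheticSpec, generate
    >>> net, expr, sub, os_map, labels = generate(SyntheticSpec(seed=0))
    >>> model = LNSPF().fit(net, expr, sub, os_map)
    >>> model.ranking_[0][0] in net.proteins
    True
    """

    def __init__(self, alpha: float = 0.6, beta: float = 0.4,
                 delta: float = 1e-6, mu: float = 1.0, max_iter: int = 1000,
                 row_normalize_s: bool = False,
                 edge_restricted_h: bool = False):
        self.alpha = alpha
        self.beta = beta
        self.delta = delta
        self.mu = mu
        self.max_iter = max_iter
        self.row_normalize_s = row_normalize_s
        self.edge_restricted_h = edge_restricted_h

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "LNSPF":
        return cls(alpha=cfg.alpha, beta=cfg.beta, delta=cfg.delta,
                   mu=cfg.mu, max_iter=cfg.max_iter,
                   row_normalize_s=cfg.row_normalize_s,
                   edge_restricted_h=cfg.edge_restricted_h)

    def _validate_params(self) -> None:
        RunConfig(alpha=self.alpha, beta=self.beta, delta=self.delta,
                  mu=self.mu, max_iter=self.max_iter)

    def fit(self, network: PPINetwork, expression: ExpressionMatrix,
            subcellular: dict, homology: dict) -> "LNSPF":
        """Run the pipeline on one dataset; inputs outside V are ignored.

        Annotation keys absent from the network vocabulary are dropped with
        a warning (the method is defined on the network's proteins only);
        network proteins missing from a table get the documented defaults
        (empty compartment set, os = 0, diagonal-only similarity row).
        """
        self._validate_params()
        universe = set(network.proteins)
        for name, table in (("subcellular", subcellular),
                            ("homology", homology)):
            extra = set(table) - universe
            if extra:
                logger.warning("%d %s key(s) not in the PPI network; ignored",
                               len(extra), name)
        extra_expr = set(expression.proteins) - universe
        if extra_expr:
            logger.warning("%d expression row(s) not in the PPI network; "
                           "ignored", len(extra_expr))

        idx = topology.neighbor_index(network)
        topo = topology.topology_features(network, idx)
        func = functional.functional_features(network.proteins, idx,
                                              subcellular, homology)
        fm = fusion.build_feature_matrix(topo, func, network.proteins)
        ew = fusion.entropy_weights(fm)
        cs = fusion.cscore(fm, ew)
        adjacency = network.adjacency() if self.edge_restricted_h else None
        h = fusion.build_h(cs, adjacency=adjacency)
        y0 = fusion.ScoreVector(
            values=np.array([func.fp2[p] for p in network.proteins]),
            stage="Y0")
        y_final = fusion.propagate(h, y0, self.alpha, self.delta,
                                   self.max_iter)
        sim = neighborhood.build_similarity(
            network, expression, mu=self.mu,
            row_normalize=self.row_normalize_s, idx=idx)
        t_final = neighborhood.propagate_lns(sim, y_final, self.beta,
                                             self.delta, self.max_iter)

        self.proteins_ = list(network.proteins)
        self.feature_matrix_ = fm
        self.feature_weights_ = ew.w
        self.entropy_ = ew.e
        self.cscore_ = cs.values
        self.y_final_ = y_final.values
        self.t_final_ = t_final.values
        self.n_iter_y_ = y_final.iterations_used
        self.n_iter_t_ = t_final.iterations_used
        self.similarity_ = sim
        # stable sort on negated scores keeps input order among ties
        order = np.argsort(-self.t_final_, kind="stable")
        self.ranking_ = [(self.proteins_[i], float(self.t_final_[i]))
                         for i in order]
        self.tie_break_ = "input protein order"
        return self

    def score_dict(self) -> dict:
        """Final scores keyed by protein identifier."""
        return {p: float(v) for p, v in zip(self.proteins_, self.t_final_)}
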