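"""Topological features of the PPI network.

Essential proteins and their interaction partners tend to sit in densely
interconnected clusters, so for every protein we score how tightly it is
embedded among its neighbors:

* ``TZ1(i, j) = |NG(i) ∩ NG(j)| / |NG(i)|`` for j a neighbor of i — the
  fraction of i's partners shared with j (else 0).
* ``TZ2(i, j) = |THNG(i) ∩ NG(j)| / |THNG(i)|`` — the same idea one hop
  further out, with ``THNG(i) = ∪_{k ∈ NG(i)} NG(k)`` the two-hop
  neighborhood (taken literally: it may contain i itself and its one-hop
  neighbors).
* ``TP1(i) = Σ_{j ∈ NG(i)} TZ1(i, j)`` and ``TP2(i) = Σ TZ2(i, j)``.

A zero-size denominator (isolated or degenerate node) contributes 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PPINetwork


@dataclass
class NeighborIndex:
    """One-hop (``NG``) and two-hop (``THNG``) neighbor sets per protein."""

    one_hop: dict
    two_hop: dict


@dataclass
class TopologyFeatures:
    tp1: dict
    tp2: dict


def neighbor_index(net: PPINetwork) -> NeighborIndex:
    """Build NG and THNG for every protein of the network."""
    one_hop = {p: set() for p in net.proteins}
    for e in net.edges:
        u, v = tuple(e)
        one_hop[u].add(v)
        one_hop[v].add(u)
    two_hop = {}
    for p in net.proteins:
        th: set = set()
        for k in one_hop[p]:
            th |= one_hop[k]
        two_hop[p] = th
    return NeighborIndex(one_hop=one_hop, two_hop=two_hop)


def tz1(i, j, idx: NeighborIndex) -> float:
    """Shared-one-hop-neighbor fraction; 0 unless j is a neighbor of i."""
    ng_i = idx.one_hop[i]
    if j not in ng_i or not ng_i:
        return 0.0
    return len(ng_i & idx.one_hop[j]) / len(ng_i)


def tz2(i, j, idx: NeighborIndex) -> float:
    """Two-hop-neighborhood overlap fraction; 0 unless j is a neighbor of i."""
    if j not in idx.one_hop[i]:
        return 0.0
    th_i = idx.two_hop[i]
    if not th_i:
        return 0.0
    return len(th_i & idx.one_hop[j]) / len(th_i)


def topology_features(net: PPINetwork, idx: NeighborIndex | None = None
                      ) -> TopologyFeatures:
    """Compute TP1 and TP2 for every protein.

    Vectorized over the adjacency matrix: with A the adjacency and
    B = (A @ A > 0) the two-hop membership indicator,
    ``TP1(i) = Σ_{j: a_ij=1} (A²)_ij / deg(i)`` and
    ``TP2(i) = Σ_{j: a_ij=1} (B Aᵀ)_ij / |THNG(i)|``.
    """
    a = net.adjacency().astype(np.float64)
    n = net.n_proteins
    if n == 0:
        return TopologyFeatures(tp1={}, tp2={})
    deg = a.sum(axis=1)
    a2 = a @ a
    common = (a2 * a).sum(axis=1)            # Σ_j |NG(i) ∩ NG(j)| over neighbors
    with np.errstate(divide="ignore", invalid="ignore"):
        tp1_v = np.where(deg > 0, common / deg, 0.0)
    b = (a2 > 0).astype(np.float64)          # b[i, k] = 1 iff k ∈ THNG(i)
    th_size = b.sum(axis=1)
    overlap = ((b @ a) * a).sum(axis=1)      # Σ_j |THNG(i) ∩ NG(j)| over neighbors
    with np.errstate(divide="ignore", invalid="ignore"):
        tp2_v = np.where(th_size > 0, overlap / th_size, 0.0)
    return TopologyFeatures(
        tp1={p: float(tp1_v[k]) for k, p in enumerate(net.proteins)},
        tp2={p: float(tp2_v[k]) for k, p in enumerate(net.proteins)},
    )
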