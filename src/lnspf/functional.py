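"""Functional (biological) features: subcellular co-localization and orthology.

FP1 measures how strongly a protein shares subcellular compartments with its
interaction partners,

    FP1(i) = Σ_{j ∈ NG(i)} TZ3(i, j) / (|NG(i)| + 1),
    TZ3(i, j) = |Sub(i) ∩ Sub(j)|² / (|Sub(i)| · |Sub(j)|)   (0 if either empty),

and FP2 is the orthology (conservation) score normalized by its maximum over
the protein universe, FP2(i) = os(i) / max_j os(j).  FP2 doubles as the
restart vector Y⁰ of the first propagation loop, so an all-zero orthology
table is rejected rather than silently producing a zero ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

from .topology import NeighborIndex


@dataclass
class FunctionalFeatures:
    fp1: dict
    fp2: dict


def tz3(i, j, sub: dict) -> float:
    """Squared compartment overlap normalized by the set-size product."""
    si = sub.get(i, set())
    sj = sub.get(j, set())
    if not si or not sj:
        return 0.0
    return len(si & sj) ** 2 / (len(si) * len(sj))


def fp1(i, idx: NeighborIndex, sub: dict) -> float:
    """Neighborhood co-localization score of protein ``i``."""
    ng = idx.one_hop[i]
    if not ng:
        return 0.0
    return sum(tz3(i, j, sub) for j in ng) / (len(ng) + 1)


def fp2(os_map: dict) -> dict:
    """Max-normalized orthology scores over the whole mapping."""
    if not os_map:
        raise ValueError("empty orthology table")
    top = max(os_map.values())
    if top <= 0:
        raise ValueError(
            "all orthology scores are zero; the initial score vector Y0 "
            "would vanish — provide at least one protein with os > 0")
    return {p: v / top for p, v in os_map.items()}


def functional_features(proteins, idx: NeighborIndex, sub: dict,
                        os_map: dict) -> FunctionalFeatures:
    """FP1 and FP2 for every protein of the universe ``proteins``.

    Proteins missing from ``sub`` count as having no annotated compartment;
    proteins missing from ``os_map`` get os = 0 (they still receive a
    normalized FP2 of 0, not an error, as long as some protein has os > 0).
    """
    filled = {p: float(os_map.get(p, 0.0)) for p in proteins}
    norm = fp2(filled)
    return FunctionalFeatures(
        fp1={p: fp1(p, idx, sub) for p in proteins},
        fp2={p: norm[p] for p in proteins},
    )
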