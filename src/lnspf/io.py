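"""Input/output for PPI networks, expression tables, annotations and run configuration.

All on-disk formats are plain tab-separated text with optional ``#`` comment
lines.  The core in-memory types live here as lightweight dataclasses:

* :class:`PPINetwork` — the undirected, simple interaction graph ``G = (V, E)``
  with its binary adjacency matrix ``A``.
* :class:`ExpressionMatrix` — per-protein gene-expression profiles over ``T``
  time points (the yeast metabolic-cycle data the method was designed around
  has ``T = 36``).
* Subcellular annotations are a plain ``dict[str, set[str]]`` and orthology
  (homology) scores a ``dict[str, float]``; both get dedicated readers.
* :class:`RunConfig` — every tunable of the ranking pipeline in one place.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParseError

logger = logging.getLogger(__name__)

#: The 11 compartment labels used by the subcellular-localization feature.
COMPARTMENTS = (
    "extracellular", "peroxisome", "nucleus", "plasma", "endosome",
    "mitochondrion", "vacuole", "cytosol", "golgi", "cytoskeleton",
    "endoplasmic",
)


@dataclass
class PPINetwork:
    """Undirected simple graph over protein identifiers.

    Parameters
    ----------
    proteins : list of str
        Unique node identifiers; order is meaningful (it fixes row/column
        order of the adjacency matrix and breaks score ties downstream).
    edges : set of frozenset
        Unordered identifier pairs. Self-interactions are not allowed.
    """

    proteins: list
    edges: set

    def __post_init__(self):
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("duplicate protein identifiers")
        self.index = {p: i for i, p in enumerate(self.proteins)}
        norm = set()
        for e in self.edges:
            u, v = tuple(e)[0], tuple(e)[-1]
            if u == v:
                raise ValueError(f"self-interaction on {u!r} is not allowed")
            if u not in self.index or v not in self.index:
                raise ValueError(f"edge endpoint not in protein list: {e}")
            norm.add(frozenset((u, v)))
        self.edges = norm

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def neighbors(self, p) -> set:
        return {next(iter(e - {p})) for e in self.edges if p in e}

    def adjacency(self) -> np.ndarray:
        """Binary symmetric N x N adjacency matrix with zero diagonal."""
        n = self.n_proteins
        a = np.zeros((n, n), dtype=np.int8)
        for e in self.edges:
            u, v = tuple(e)
            i, j = self.index[u], self.index[v]
            a[i, j] = a[j, i] = 1
        return a

    @classmethod
    def from_edge_pairs(cls, pairs) -> "PPINetwork":
        """Build a network from (u, v) pairs, in first-appearance order.

        Duplicate pairs (in either order) and self-pairs are dropped; every
        identifier that occurs in the input becomes a node even if all its
        pairs were filtered out.
        """
        proteins, seen = [], set()
        edges = set()
        for u, v in pairs:
            for p in (u, v):
                if p not in seen:
                    seen.add(p)
                    proteins.append(p)
            if u != v:
                edges.add(frozenset((u, v)))
        return cls(proteins, edges)


@dataclass
class ExpressionMatrix:
    """Gene-expression profiles: one row g_i = <g_i1, ..., g_iT> per protein."""

    proteins: list
    values: np.ndarray
    timepoints: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, t = self.values.shape
        if n != len(self.proteins):
            raise ValueError("one expression row per protein required")
        if t != len(self.timepoints) or t < 2:
            raise ValueError("need T >= 2 labelled time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        self.index = {p: i for i, p in enumerate(self.proteins)}

    def row(self, protein) -> np.ndarray:
        return self.values[self.index[protein]]


@dataclass
class RunConfig:
    """All tunables of the ranking pipeline.

    alpha, beta : float in (0, 1)
        Restart weights of the two propagation loops (first over the fused
        feature matrix H, second over the expression-similarity matrix S).
    delta : float > 0
        Euclidean-norm convergence tolerance of both loops.
    mu : float >= 0
        Ridge regularization of the per-protein neighborhood reconstruction.
    """

    alpha: float = 0.6
    beta: float = 0.4
    delta: float = 1e-6
    mu: float = 1.0
    max_iter: int = 1000
    top_k_percents: tuple = (1, 5, 10, 15, 20, 25)
    seed: int = 0
    row_normalize_s: bool = False
    edge_restricted_h: bool = False

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        for k in self.top_k_percents:
            if not 0 < k <= 100:
                raise ValueError(f"top-K percentage out of (0, 100]: {k}")


# ---------------------------------------------------------------------------
# readers

def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_ppi(path) -> PPINetwork:
    """Read a two-column protein-pair file into a :class:`PPINetwork`.

    Repeated interactions (in either order) and self-interactions are
    filtered out; protein order follows first appearance in the file.
    """
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise ParseError("expected at least two tab-separated fields",
                             path=path, line=lineno)
        pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ParseError("no interaction lines found", path=path)
    net = PPINetwork.from_edge_pairs(pairs)
    dropped = len(pairs) - len(net.edges)
    if dropped:
        logger.info("filtered %d repeated/self interactions from %s",
                    dropped, path)
    return net


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression table (header row of time-point labels)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read expression table: {exc}", path=path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate protein key {dup!r}", path=path)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"non-numeric expression value: {exc}", path=path)
    return ExpressionMatrix(list(df.index.astype(str)), values,
                            [str(c) for c in df.columns])


def read_subcellular(path) -> dict:
    """Read protein→compartment pairs (one pair per line) into sets."""
    sub: dict = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise ParseError("expected protein<TAB>compartment", path=path,
                             line=lineno)
        sub.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return sub


def read_homology(path) -> dict:
    """Read protein→orthology-score pairs; scores must be >= 0."""
    os_map: dict = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise ParseError("expected protein<TAB>score", path=path,
                             line=lineno)
        key = fields[0].strip()
        if key in os_map:
            raise ParseError(f"duplicate protein key {key!r}", path=path,
                             line=lineno)
        try:
            value = float(fields[1])
        except ValueError:
            raise ParseError(f"non-numeric score {fields[1]!r}", path=path,
                             line=lineno)
        if not math.isfinite(value) or value < 0:
            raise ParseError(f"orthology score must be finite and >= 0, "
                             f"got {value}", path=path, line=lineno)
        os_map[key] = value
    return os_map


def read_labels(path) -> set:
    """Read a one-identifier-per-line essential-protein label list."""
    return {line.split("\t")[0].split()[0] for _, line in _data_lines(path)}


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers; used by the simulator and CLI)

def write_ppi(net: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for e in sorted(net.edges, key=lambda e: tuple(sorted(e))):
            u, v = sorted(e)
            fh.write(f"{u}\t{v}\n")
        # isolated nodes survive a round trip as degenerate self-pairs is NOT
        # an option (self-pairs are filtered); list them as comment metadata.
        isolated = [p for p in net.proteins if not net.neighbors(p)]
        for p in isolated:
            fh.write(f"{p}\t{p}\n")  # filtered on read, keeps the node in V


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.proteins,
                      columns=expr.timepoints)
    df.index.name = "protein"
    df.to_csv(path, sep="\t")


def write_subcellular(sub: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tcompartment\n")
        for p in sub:
            for c in sorted(sub[p]):
                fh.write(f"{p}\t{c}\n")


def write_homology(os_map: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tos\n")
        for p, v in os_map.items():
            fh.write(f"{p}\t{v:g}\n")


def write_labels(labels, path) -> None:
    with open(path, "w") as fh:
        for p in sorted(labels):
            fh.write(f"{p}\n")
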