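"""Thresholded network construction and graph-level summary statistics.

A connectivity matrix holds correlation weights ``w_ij`` between brain
regions.  Applying a threshold ``r_c`` to ``|w_ij|`` yields a binary
(topological) network; this module computes the node statistics (degree,
strength) and whole-network measures (largest component, transitivity,
characteristic path length, global efficiency, cost) used in the
threshold-sweep analysis.

Conventions
-----------
* Edges require the *strict* inequality ``|w_ij| > r_c``; ties at the
  threshold are excluded.
* Self-loops never count: the diagonal is zeroed on ingestion and excluded
  from every ratio, degree and strength.
* Unreachable node pairs: the characteristic path length substitutes
  ``L_ij = N`` (the node count); global efficiency by default uses the
  standard convention ``1/L_ij = 0`` (``unreachable="zero"``), with the
  substitution variant available via ``unreachable="substitute"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csgraph
from scipy.sparse import csr_matrix

from .errors import ValidationError

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "NodeStatVector",
    "GraphSummary",
    "binarize",
    "degree",
    "strength",
    "connection_ratio",
    "largest_component_fraction",
    "transitivity",
    "avg_path_length",
    "global_efficiency",
    "network_cost",
    "efficiency_per_cost",
    "graph_summary",
]

_SYMMETRY_TOL = 1e-9


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of correlation weights with zero diagonal.

    Validated on construction: the matrix must be square, symmetric within
    1e-9 (then symmetrised exactly by averaging), with ``|w_ij| <= 1``.
    The diagonal is forced to zero.
    """

    weights: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"connectivity matrix must be square, got {w.shape}")
        if w.shape[0] < 2:
            raise ValidationError("connectivity matrix needs at least 2 regions")
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValidationError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {_SYMMETRY_TOL}"
            )
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        if np.max(np.abs(w)) > 1.0 + 1e-12:
            raise ValidationError("connectivity weights must satisfy |w_ij| <= 1")
        if self.region_labels is not None and len(self.region_labels) != w.shape[0]:
            raise ValidationError("region_labels length does not match matrix size")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryNetwork:
    """Adjacency matrix obtained by thresholding ``|w_ij| > r_c``."""

    adjacency: np.ndarray
    threshold: float

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"adjacency must be square, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class NodeStatVector:
    """Per-node degree or strength values for one matrix at one threshold."""

    values: np.ndarray
    stat_kind: str  # "degree" | "strength"
    threshold: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.stat_kind not in ("degree", "strength"):
            raise ValidationError(f"unknown stat_kind {self.stat_kind!r}")
        if np.any(self.values < 0):
            raise ValidationError("node statistics must be nonnegative")


@dataclass
class GraphSummary:
    """Whole-network summary at one threshold."""

    threshold: float
    connection_ratio: float
    largest_component_fraction: float
    transitivity: float
    avg_path_length: float
    efficiency: float
    cost: int
    normalized_cost: float
    efficiency_per_cost: float = field(default=np.nan)


def _check_threshold(r_c: float) -> float:
    if not (0.0 <= r_c <= 1.0):
        raise ValidationError(f"threshold r_c must lie in [0, 1], got {r_c}")
    return float(r_c)


def binarize(matrix: ConnectivityMatrix, r_c: float) -> BinaryNetwork:
    """Threshold ``|w_ij| > r_c`` (strict) into a binary network."""
    r_c = _check_threshold(r_c)
    a = (np.abs(matrix.weights) > r_c).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryNetwork(adjacency=a, threshold=r_c)


def degree(net: BinaryNetwork) -> NodeStatVector:
    """Degree ``k_i``: number of supra-threshold neighbours of node i."""
    k = net.adjacency.sum(axis=1)
    return NodeStatVector(values=k, stat_kind="degree", threshold=net.threshold)


def strength(matrix: ConnectivityMatrix, r_c: float) -> NodeStatVector:
    """Node strength ``s_i = sum_{j != i, |w_ij| > r_c} |w_ij|``."""
    r_c = _check_threshold(r_c)
    aw = np.abs(matrix.weights)
    s = np.where(aw > r_c, aw, 0.0).sum(axis=1)
    return NodeStatVector(values=s, stat_kind="strength", threshold=r_c)


def connection_ratio(matrix: ConnectivityMatrix, r_c: float) -> float:
    """Fraction of unordered region pairs with ``|w_ij| > r_c``."""
    r_c = _check_threshold(r_c)
    n = matrix.n_regions
    iu = np.triu_indices(n, k=1)
    above = np.abs(matrix.weights[iu]) > r_c
    return float(above.sum()) / (n * (n - 1) / 2)


def _component_labels(net: BinaryNetwork) -> np.ndarray:
    _, labels = csgraph.connected_components(
        csr_matrix(net.adjacency), directed=False
    )
    return labels


def largest_component_fraction(net: BinaryNetwork) -> float:
    """Size of the largest connected component divided by node count."""
    labels = _component_labels(net)
    counts = np.bincount(labels)
    return float(counts.max()) / net.n_nodes


def transitivity(net: BinaryNetwork) -> float:
    """Global transitivity: 3 x triangles / connected triples (0 if none)."""
    a = net.adjacency.astype(float)
    k = a.sum(axis=1)
    triples = float((k * (k - 1)).sum())  # 2 x number of connected triples
    if triples == 0:
        return 0.0
    triangles6 = float(np.trace(a @ a @ a))  # 6 x number of triangles
    return triangles6 / triples


def _shortest_paths(net: BinaryNetwork) -> np.ndarray:
    return csgraph.shortest_path(
        csr_matrix(net.adjacency), method="D", unweighted=True, directed=False
    )


def avg_path_length(net: BinaryNetwork) -> float:
    """Mean shortest-path hop count over ordered pairs, ``L_ij := N`` if unreachable."""
    n = net.n_nodes
    if n < 2:
        raise ValidationError("path length needs at least 2 nodes")
    d = _shortest_paths(net)
    d[~np.isfinite(d)] = n
    np.fill_diagonal(d, 0.0)
    return float(d.sum()) / (n * (n - 1))


def global_efficiency(net: BinaryNetwork, unreachable: str = "zero") -> float:
    """Mean of ``1/L_ij`` over ordered pairs.

    ``unreachable="zero"`` (default) assigns ``1/L_ij = 0`` to disconnected
    pairs; ``"substitute"`` uses ``1/N`` via the ``L_ij = N`` substitution.
    """
    n = net.n_nodes
    if n < 2:
        raise ValidationError("efficiency needs at least 2 nodes")
    if unreachable not in ("zero", "substitute"):
        raise ValidationError(f"unknown unreachable policy {unreachable!r}")
    d = _shortest_paths(net)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    if unreachable == "zero":
        inv[~np.isfinite(d)] = 0.0
    else:
        inv[~np.isfinite(d)] = 1.0 / n
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum()) / (n * (n - 1))


def network_cost(net: BinaryNetwork) -> tuple[int, float]:
    """Edge count and its fraction of the ``N(N-1)/2`` maximum."""
    n = net.n_nodes
    cost = int(net.adjacency.sum()) // 2
    return cost, cost / (n * (n - 1) / 2)


def efficiency_per_cost(summary: GraphSummary) -> float:
    """Cost-effectiveness ``E / normalized_cost``; NaN (with warning) at zero cost."""
    if summary.normalized_cost == 0:
        warnings.warn(
            "efficiency_per_cost undefined for an edgeless network; returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return summary.efficiency / summary.normalized_cost


def graph_summary(
    matrix: ConnectivityMatrix, r_c: float, unreachable: str = "zero"
) -> GraphSummary:
    """Compute all whole-network measures for one matrix at one threshold."""
    net = binarize(matrix, r_c)
    cost, norm_cost = network_cost(net)
    summary = GraphSummary(
        threshold=net.threshold,
        connection_ratio=connection_ratio(matrix, r_c),
        largest_component_fraction=largest_component_fraction(net),
        transitivity=transitivity(net),
        avg_path_length=avg_path_length(net),
        efficiency=global_efficiency(net, unreachable=unreachable),
        cost=cost,
        normalized_cost=norm_cost,
    )
    if norm_cost > 0:
        summary.efficiency_per_cost = efficiency_per_cost(summary)
    return summary
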