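"""Weighted structural networks and nodal graph metrics.

A subject's connectome is a symmetric streamline-count matrix over
parcellated brain regions together with the regions' volumes. Connection
weights divide the streamline count by the combined volume of the two
connected regions (volume correction: large regions intersect more
streamlines by size alone), giving a weighted undirected network on which
four nodal metrics are computed:

* **strength** — sum of a region's connection weights;
* **betweenness centrality** — fraction of shortest paths between other
  region pairs passing through the region, normalized to [0, 1];
* **eigenvector centrality** — dominant eigenvector of the weight matrix
  (unit Euclidean norm, nonnegative orientation);
* **average path length** — mean shortest-path distance from the region to
  every other reachable region.

Shortest paths use the inverse-weight edge distance d_ij = 1/w_ij, so a
stronger connection is a shorter distance; a zero weight means no edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FiberConnectivity",
    "WeightedNetwork",
    "build_weighted_network",
    "node_strength",
    "betweenness_centrality",
    "eigenvector_centrality",
    "average_path_length",
    "compute_node_metrics",
    "flatten_metrics",
    "METRIC_TAGS",
    "DEFAULT_METRICS",
]

#: Column-name tag for each nodal metric, used in flattened feature names.
METRIC_TAGS = {
    "betweenness": "NodeBWCent",
    "avg_path_length": "AvPathLength",
    "strength": "Strength",
    "eigenvector": "EigCent",
}

#: The two metrics every reported discriminative brain feature belongs to.
DEFAULT_METRICS = ("betweenness", "avg_path_length")

#: Volume-correction conventions for the edge-weight denominator.
_VOLUME_COMBINERS = {
    "sum": lambda vi, vj: vi + vj,
    "mean": lambda vi, vj: (vi + vj) / 2.0,
    "product": lambda vi, vj: vi * vj,
}


def _check_square_symmetric(mat: np.ndarray, what: str) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{what} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{what} must be symmetric")
    if (mat < 0).any():
        raise ValueError(f"{what} must be nonnegative")


@dataclass
class FiberConnectivity:
    """Streamline counts between regions plus region volumes (mm³)."""

    counts: np.ndarray
    volumes: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.volumes = np.asarray(self.volumes, dtype=float)
        _check_square_symmetric(self.counts, "fiber count matrix")
        if np.diag(self.counts).any():
            raise ValueError("fiber count matrix must have zero diagonal")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.array_equal(self.counts, np.round(self.counts)):
                raise ValueError("fiber counts must be integers")
            self.counts = self.counts.astype(np.int64)
        R = self.counts.shape[0]
        if self.volumes.shape != (R,):
            raise ValueError(f"expected {R} region volumes, got {self.volumes.shape}")
        if (self.volumes <= 0).any():
            raise ValueError("region volumes must be positive")
        if len(self.region_names) != R or len(set(self.region_names)) != R:
            raise ValueError("region names must be unique and match matrix size")

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative connection-weight matrix with named regions."""

    weights: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        _check_square_symmetric(self.weights, "weight matrix")
        if np.diag(self.weights).any():
            raise ValueError("weight matrix must have zero diagonal")
        R = self.weights.shape[0]
        if len(self.region_names) != R or len(set(self.region_names)) != R:
            raise ValueError("region names must be unique and match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def to_graph(self) -> nx.Graph:
        """NetworkX view with ``weight`` and inverse-weight ``dist`` edge attributes."""
        G = nx.Graph()
        G.add_nodes_from(self.region_names)
        rows, cols = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(rows, cols):
            w = self.weights[i, j]
            G.add_edge(self.region_names[i], self.region_names[j], weight=w, dist=1.0 / w)
        return G


def build_weighted_network(
    fibers: FiberConnectivity, volume_convention: str = "sum"
) -> WeightedNetwork:
    """Normalize streamline counts by the volumes of the two connected regions.

    ``weights[i, j] = counts[i, j] / combine(volumes[i], volumes[j])`` with
    ``combine`` selected by ``volume_convention`` (``"sum"`` — the default
    volume-correction convention — ``"mean"`` or ``"product"``).
    """
    if volume_convention not in _VOLUME_COMBINERS:
        raise ValueError(
            f"unknown volume convention {volume_convention!r}; "
            f"choose from {sorted(_VOLUME_COMBINERS)}"
        )
    combine = _VOLUME_COMBINERS[volume_convention]
    denom = combine(fibers.volumes[:, None], fibers.volumes[None, :])
    weights = fibers.counts / denom
    np.fill_diagonal(weights, 0.0)
    return WeightedNetwork(weights=weights, region_names=list(fibers.region_names))


def node_strength(net: WeightedNetwork) -> pd.Series:
    """Sum of each region's connection weights."""
    return pd.Series(net.weights.sum(axis=1), index=net.region_names, name="strength")


def betweenness_centrality(net: WeightedNetwork) -> pd.Series:
    """Normalized weighted betweenness centrality per region.

    Shortest paths use the inverse-weight distance; values are normalized
    by (R−1)(R−2)/2, the number of region pairs a node could lie between,
    and shortest-path ties are split fractionally among equally short
    paths.
    """
    if net.n_regions < 3:
        raise ValueError("betweenness centrality requires at least 3 regions")
    bc = nx.betweenness_centrality(net.to_graph(), normalized=True, weight="dist")
    return pd.Series([bc[r] for r in net.region_names], index=net.region_names, name="betweenness")


def eigenvector_centrality(
    net: WeightedNetwork, tol: float = 1e-10, max_iter: int = 10000
) -> pd.Series:
    """Dominant eigenvector of the weight matrix by power iteration.

    Returns the Perron vector of the (symmetric, nonnegative) weight
    matrix, oriented nonnegative and scaled to unit Euclidean norm. The
    network must be connected on its nonzero edges; disconnected inputs
    raise an error naming the components rather than guessing how to
    handle them.
    """
    G = nx.from_numpy_array(net.weights)
    components = list(nx.connected_components(G))
    if len(components) > 1:
        named = [sorted(net.region_names[i] for i in comp) for comp in components]
        raise ValueError(
            f"eigenvector centrality undefined on a disconnected network; components: {named}"
        )
    W = net.weights
    R = net.n_regions
    x = np.full(R, 1.0 / np.sqrt(R))
    for _ in range(max_iter):
        y = W @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("weight matrix has no edges")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(f"power iteration did not converge within {max_iter} iterations")
    if x.sum() < 0:  # Perron vector is sign-definite; orient nonnegative
        x = -x
    x = np.clip(x, 0.0, None)
    x /= np.linalg.norm(x)
    return pd.Series(x, index=net.region_names, name="eigenvector")


def average_path_length(net: WeightedNetwork) -> pd.Series:
    """Mean inverse-weight shortest-path distance from each region to the rest.

    Unreachable pairs are excluded from the mean; a region with no
    reachable partner is reported as NaN (flagged undefined, never
    silently zero).
    """
    G = net.to_graph()
    out = {}
    for region in net.region_names:
        lengths = nx.single_source_dijkstra_path_length(G, region, weight="dist")
        dists = [d for other, d in lengths.items() if other != region]
        out[region] = float(np.mean(dists)) if dists else np.nan
    return pd.Series(out, name="avg_path_length").reindex(net.region_names)


_METRIC_FUNCS = {
    "strength": node_strength,
    "betweenness": betweenness_centrality,
    "eigenvector": eigenvector_centrality,
    "avg_path_length": average_path_length,
}


def compute_node_metrics(
    fibers: FiberConnectivity,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    volume_convention: str = "sum",
) -> pd.DataFrame:
    """Region × metric table for one subject's connectome."""
    unknown = set(metrics) - set(_METRIC_FUNCS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}; choose from {sorted(_METRIC_FUNCS)}")
    net = build_weighted_network(fibers, volume_convention=volume_convention)
    return pd.DataFrame({m: _METRIC_FUNCS[m](net) for m in metrics})


def flatten_metrics(
    tables: dict[str, pd.DataFrame], metrics: tuple[str, ...] = DEFAULT_METRICS
) -> pd.DataFrame:
    """Stack per-subject metric tables into a subjects × named-features block.

    Columns follow the ``<MetricTag>__<region>`` convention (for example
    ``NodeBWCent__ROI_042``), ordered by metric tag then region name. All
    subjects must share an identical region set.
    """
    if not tables:
        raise ValueError("no subject metric tables given")
    subjects = list(tables)
    regions = list(tables[subjects[0]].index)
    for sid, tab in tables.items():
        if list(tab.index) != regions:
            raise ValueError(f"subject {sid} has a different region set")
        missing = set(metrics) - set(tab.columns)
        if missing:
            raise ValueError(f"subject {sid} missing metrics {sorted(missing)}")
    columns = []
    for metric in sorted(metrics, key=lambda m: METRIC_TAGS[m]):
        tag = METRIC_TAGS[metric]
        for region in sorted(regions):
            columns.append((metric, region, f"{tag}__{region}"))
    data = {
        name: [tables[sid].at[region, metric] for sid in subjects]
        for metric, region, name in columns
    }
    block = pd.DataFrame(data, index=subjects)
    n_nan = int(block.isna().sum().sum())
    if n_nan:
        warnings.warn(f"{n_nan} undefined metric values (isolated regions) in flattened block")
    return block
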