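"""Graph-theoretic characterisation of binary functional-connectivity networks.

Nodal measures: degree, clustering coefficient, local efficiency
(Latora–Marchiori), normalized betweenness centrality.  Global measures:
network density, global efficiency, mean clustering, characteristic path
length (largest connected component, with coverage reported), and the
small-world coefficient sigma = (C/C_rand)/(L/L_rand) against an ensemble of
random null networks.

Efficiency-based measures handle disconnected pairs natively (1/inf = 0),
which is why they are preferred over path length when comparing networks
across thresholds of different stringency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError
from .network import Network

logger = logging.getLogger(__name__)

NULL_MODELS = ("er_matched", "degree_preserving")
#: Successful-swap budget of the degree-preserving null, per edge.
DEFAULT_SWAP_FACTOR = 10


def degree(net: Network) -> np.ndarray:
    """Per-region edge count (row sums of the adjacency)."""
    return net.adjacency.sum(axis=1).astype(int)


def network_density(net: Network) -> float:
    """Realized edges over possible edges, 2E / (N(N-1))."""
    n = net.n_regions
    if n < 2:
        raise ValidationError("density needs at least 2 regions")
    return 2.0 * net.n_edges / (n * (n - 1))


def global_efficiency(net: Network) -> float:
    """Mean inverse shortest-path length over ordered node pairs
    (0 contribution from disconnected pairs)."""
    if net.n_regions < 2:
        raise ValidationError("global efficiency needs at least 2 regions")
    return nx.global_efficiency(net.to_networkx())


def clustering_coefficient(net: Network) -> np.ndarray:
    """Per-region fraction of neighbour pairs that are connected; 0 for
    degree < 2."""
    g = net.to_networkx()
    c = nx.clustering(g)
    return np.array([c[r] for r in net.regions], dtype=float)


def local_efficiency(net: Network) -> np.ndarray:
    """Per-region global efficiency of the neighbour-induced subgraph;
    0 for degree < 2."""
    g = net.to_networkx()
    out = np.zeros(net.n_regions, dtype=float)
    for i, r in enumerate(net.regions):
        nbrs = list(g.neighbors(r))
        if len(nbrs) >= 2:
            out[i] = nx.global_efficiency(g.subgraph(nbrs))
    return out


def betweenness(net: Network) -> np.ndarray:
    """Per-region betweenness centrality, normalized by (N-1)(N-2)/2 so the
    values are comparable across equally sized networks."""
    g = net.to_networkx()
    b = nx.betweenness_centrality(g, normalized=True)
    return np.array([b[r] for r in net.regions], dtype=float)


def characteristic_path_length(net: Network) -> tuple[float, float]:
    """Mean unweighted shortest-path length over connected pairs of the
    largest component, plus the fraction of nodes that component covers.

    Returns (nan, coverage) when the largest component has < 2 nodes.
    """
    g = net.to_networkx()
    comp = max(nx.connected_components(g), key=len)
    coverage = len(comp) / net.n_regions
    if len(comp) < 2:
        return float("nan"), coverage
    return nx.average_shortest_path_length(g.subgraph(comp)), coverage


def small_world_sigma(net: Network, n_null: int = 100,
                      null_model: str = "er_matched", seed: int | None = None,
                      swap_factor: int = DEFAULT_SWAP_FACTOR) -> float:
    """Small-world coefficient sigma = (C/<C_rand>) / (L/<L_rand>).

    C is the mean clustering coefficient and L the characteristic path
    length, both computed on the largest connected component; the null
    averages come from ``n_null`` random networks, either Erdős–Rényi with
    matched node and edge counts (``er_matched``) or degree-preserving
    Maslov–Sneppen rewiring with ``swap_factor * E`` successful swaps
    (``degree_preserving``).  sigma > 1 indicates small-world-like topology.
    Deterministic for a fixed seed.

    Raises
    ------
    NumericalError
        When every null sample has zero clustering (sigma undefined), rather
        than dividing by zero.
    """
    if null_model not in NULL_MODELS:
        raise ValidationError(f"null_model must be one of {NULL_MODELS}, got {null_model!r}")
    if n_null < 1:
        raise ValidationError(f"n_null must be >= 1, got {n_null}")
    g = net.to_networkx()
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 4:
        raise ValidationError("largest component too small (< 4 nodes) for small-world analysis")
    gc = g.subgraph(comp).copy()
    c_obs = nx.average_clustering(gc)
    l_obs = nx.average_shortest_path_length(gc)

    rng = np.random.default_rng(seed)
    n_nodes, n_edges = gc.number_of_nodes(), gc.number_of_edges()
    c_null, l_null = [], []
    for _ in range(n_null):
        s = int(rng.integers(2**31))
        if null_model == "er_matched":
            rnd = nx.gnm_random_graph(n_nodes, n_edges, seed=s)
        else:
            rnd = nx.convert_node_labels_to_integers(gc)
            nx.double_edge_swap(rnd, nswap=swap_factor * n_edges,
                                max_tries=100 * swap_factor * n_edges, seed=s)
        rcomp = max(nx.connected_components(rnd), key=len)
        rsub = rnd.subgraph(rcomp)
        c_null.append(nx.average_clustering(rnd))
        if len(rcomp) >= 2:
            l_null.append(nx.average_shortest_path_length(rsub))
    c_rand = float(np.mean(c_null))
    l_rand = float(np.mean(l_null)) if l_null else float("nan")
    if c_rand == 0 or not np.isfinite(l_rand) or l_rand == 0:
        raise NumericalError(
            f"small-world sigma undefined: degenerate null ensemble "
            f"(<C_rand> = {c_rand}, <L_rand> = {l_rand})")
    return (c_obs / c_rand) / (l_obs / l_rand)


@dataclass
class MetricsReport:
    """Nodal and global graph measures for one network."""

    regions: list[str]
    degree: np.ndarray = field(repr=False)
    clustering: np.ndarray = field(repr=False)
    local_efficiency: np.ndarray = field(repr=False)
    betweenness: np.ndarray = field(repr=False)
    density: float = 0.0
    global_efficiency: float = 0.0
    mean_clustering: float = 0.0
    char_path_length: float = float("nan")
    component_coverage: float = 1.0
    small_world_sigma: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-region table (one row per region)."""
        return pd.DataFrame({
            "region": self.regions,
            "degree": self.degree,
            "clustering": self.clustering,
            "local_efficiency": self.local_efficiency,
            "betweenness": self.betweenness,
        })

    def global_dict(self) -> dict:
        return {
            "density": self.density,
            "global_efficiency": self.global_efficiency,
            "mean_clustering": self.mean_clustering,
            "char_path_length": self.char_path_length,
            "component_coverage": self.component_coverage,
            "small_world_sigma": self.small_world_sigma,
        }

    def to_json(self) -> str:
        d = dict(self.global_dict())
        d["per_region"] = {
            "region": list(self.regions),
            "degree": self.degree.tolist(),
            "clustering": self.clustering.tolist(),
            "local_efficiency": self.local_efficiency.tolist(),
            "betweenness": self.betweenness.tolist(),
        }
        return json.dumps(d, indent=2, allow_nan=True)


def compute_metrics(net: Network, sigma_nulls: int = 0,
                    null_model: str = "er_matched",
                    seed: int | None = None) -> MetricsReport:
    """All nodal and global measures in one report.

    Small-world sigma is computed only when ``sigma_nulls`` >= 1 (it needs a
    null ensemble and a connected component of useful size); failures there
    are logged and leave sigma as None rather than aborting the report.
    """
    cpl, coverage = characteristic_path_length(net)
    clust = clustering_coefficient(net)
    sigma = None
    if sigma_nulls >= 1:
        try:
            sigma = small_world_sigma(net, n_null=sigma_nulls,
                                      null_model=null_model, seed=seed)
        except (NumericalError, ValidationError) as exc:
            logger.warning("small-world sigma unavailable: %s", exc)
    return MetricsReport(
        regions=list(net.regions),
        degree=degree(net),
        clustering=clust,
        local_efficiency=local_efficiency(net),
        betweenness=betweenness(net),
        density=network_density(net),
        global_efficiency=global_efficiency(net),
        mean_clustering=float(clust.mean()),
        char_path_length=cpl,
        component_coverage=coverage,
        small_world_sigma=sigma,
    )
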