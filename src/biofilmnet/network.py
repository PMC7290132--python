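"""Spearman co-occurrence network construction, Erdős–Rényi null
comparison, module detection and Zi–Pi keystone classification.

The construction mirrors the common microbiome recipe: restrict to
prevalent, non-negligible OTUs (here >=11 of 22 samples and mean
relative abundance >=0.01%), compute all pairwise Spearman correlations,
BH-adjust the p-values over all candidate pairs, and keep only strong
significant edges (|rho| > 0.8 strictly, adjusted p < 0.05).  Topology
is compared against 99 G(n, m) random graphs of identical size via
Z-tests.  Node roles follow the Zi (within-module degree z-score) / Pi
(participation coefficient) plane with the classical 2.5 / 0.62
thresholds separating peripherals, module hubs, connectors and network
hubs.

Edges are treated as unweighted and sign-blind for every topological
quantity; the correlation sign survives only as an edge attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "select_network_otus",
    "spearman_matrix",
    "bh_adjust",
    "build_network",
    "TopologyStats",
    "topology",
    "fit_degree_power_law",
    "er_random_ensemble",
    "z_test_topology",
    "detect_modules",
    "zi_pi",
    "classify_roles",
]


def select_network_otus(
    rel_table: pd.DataFrame,
    min_prevalence: float = 11,
    min_mean_abundance: float = 1e-4,
) -> list:
    """OTUs eligible for the network: present in at least
    ``min_prevalence`` samples (an integer count, or a fraction of
    samples if < 1) and with mean relative abundance across *all*
    samples >= ``min_mean_abundance``."""
    if min_prevalence < 0 or min_mean_abundance < 0:
        raise ConfigError("thresholds must be non-negative")
    n = rel_table.shape[0]
    threshold = min_prevalence * n if 0 < min_prevalence < 1 else min_prevalence
    prevalence = (rel_table > 0).sum(axis=0)
    mean_ab = rel_table.mean(axis=0)
    keep = (prevalence >= threshold) & (mean_ab >= min_mean_abundance)
    return list(rel_table.columns[keep])


def spearman_matrix(rel_sub: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p (t-approximation, n-2 df).

    Constant OTU vectors leave rho undefined; their pairs come back NaN
    and are logged.
    """
    if rel_sub.shape[0] < 4:
        raise ValidationError("need >=4 samples for Spearman correlations")
    X = rel_sub.to_numpy(dtype=float)
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        logger.warning(
            "%d constant OTU vectors; their correlations are undefined",
            int(constant.sum()),
        )
    rho, p = sps.spearmanr(X)
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    ids = rel_sub.columns
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    flat = p.ravel()
    ok = ~np.isnan(flat)
    out = np.full(flat.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    return out.reshape(p.shape)


def build_network(
    rho: pd.DataFrame,
    p_adjusted: pd.DataFrame,
    r_threshold: float = 0.8,
    alpha: float = 0.05,
    classes: pd.Series | None = None,
    taxonomy: pd.Series | None = None,
) -> nx.Graph:
    """Keep edges with |rho| strictly above ``r_threshold`` and adjusted
    p below ``alpha``; OTUs left without any edge are dropped."""
    if rho.shape != p_adjusted.shape:
        raise ValidationError("rho and p matrices are not conformal")
    ids = list(rho.columns)
    R = rho.to_numpy()
    P = p_adjusted.to_numpy()
    net = nx.Graph()
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = (np.abs(R[iu, ju]) > r_threshold) & (P[iu, ju] < alpha)
    for i, j in zip(iu[mask], ju[mask]):
        r = float(R[i, j])
        net.add_edge(
            ids[i],
            ids[j],
            rho=r,
            sign="+" if r > 0 else "-",
            p_adjusted=float(P[i, j]),
        )
    for node in net.nodes:
        if classes is not None and node in classes.index:
            net.nodes[node]["abundance_class"] = str(classes[node])
        if taxonomy is not None and node in taxonomy.index:
            net.nodes[node]["taxonomy"] = str(taxonomy[node])
    return net


@dataclass
class TopologyStats:
    """Whole-network topological parameters."""

    n_nodes: int
    n_edges: int
    n_negative_edges: int
    average_degree: float
    average_path_length: float
    clustering_coefficient: float
    betweenness_centralization: float
    modularity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_negative_edges": self.n_negative_edges,
            "average_degree": self.average_degree,
            "average_path_length": self.average_path_length,
            "clustering_coefficient": self.clustering_coefficient,
            "betweenness_centralization": self.betweenness_centralization,
            "modularity": self.modularity,
        }


def _average_path_length(net: nx.Graph) -> float:
    """Mean shortest-path length over connected ordered pairs only."""
    A = nx.to_scipy_sparse_array(net, format="csr")
    D = shortest_path(A, method="D", unweighted=True, directed=False)
    reach = np.isfinite(D) & (D > 0)
    if not reach.any():
        return float("nan")
    return float(D[reach].mean())


def topology(net: nx.Graph, partition: dict | None = None) -> TopologyStats:
    """Compute the standard topological parameter set.

    Path lengths average over connected ordered pairs only; local
    clustering of degree<2 nodes counts as 0; betweenness centralization
    is Freeman's index on normalized betweenness; modularity is Newman's
    Q of ``partition`` (node -> module id) on the unweighted graph, NaN
    when no partition is supplied.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValidationError("topology of an empty graph is undefined")
    m = net.number_of_edges()
    n_neg = sum(
        1
        for _, _, a in net.edges(data=True)
        if a.get("sign") == "-" or a.get("rho", 0) < 0
    )
    bc = nx.betweenness_centrality(net, normalized=True)
    b = np.array(list(bc.values()))
    centralization = float((b.max() - b).sum() / (n - 1)) if n > 1 else 0.0
    if partition is not None:
        communities: dict[int, set] = {}
        for node, mod in partition.items():
            communities.setdefault(mod, set()).add(node)
        q = float(nx.community.modularity(net, communities.values(), weight=None))
    else:
        q = float("nan")
    return TopologyStats(
        n_nodes=n,
        n_edges=m,
        n_negative_edges=n_neg,
        average_degree=2 * m / n,
        average_path_length=_average_path_length(net),
        clustering_coefficient=float(nx.average_clustering(net, count_zeros=True)),
        betweenness_centralization=centralization,
        modularity=q,
    )


def fit_degree_power_law(degrees) -> tuple[float, float, float]:
    """Least-squares power-law fit of the degree distribution.

    Regresses log(frequency) on log(degree) over degrees >= 1 with
    positive frequency.  Returns (exponent, R2, slope p-value).
    """
    degrees = np.asarray(list(degrees))
    ks, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if len(ks) < 3:
        raise ValidationError(
            "need >=3 distinct positive degrees for a power-law fit"
        )
    res = sps.linregress(np.log(ks), np.log(counts))
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def er_random_ensemble(
    n_nodes: int, n_edges: int, n_graphs: int = 99, seed: int | None = None
) -> list[nx.Graph]:
    """Ensemble of uniform G(n, m) random simple graphs (fixed edge
    count — 'same size as the real network')."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ConfigError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_graphs)
    return [
        nx.gnm_random_graph(n_nodes, n_edges, seed=int(s % (2**31)))
        for s in child_seeds
    ]


def z_test_topology(
    real: TopologyStats, ensemble_stats: list[TopologyStats]
) -> pd.DataFrame:
    """Z-test of each real parameter against the null ensemble.

    ``z = (real - mean_random) / sd_random`` with a two-sided normal
    p-value; a degenerate ensemble (sd = 0) yields infinite z and p = 0.
    """
    if len(ensemble_stats) < 2:
        raise ValidationError("need an ensemble of >=2 graphs for a Z-test")
    rows = []
    real_d = real.as_dict()
    ens = pd.DataFrame([s.as_dict() for s in ensemble_stats])
    for param, value in real_d.items():
        mu = float(ens[param].mean())
        sd = float(ens[param].std(ddof=1))
        scale = max(abs(mu), abs(value), 1.0)
        if sd <= 1e-12 * scale:  # degenerate ensemble
            equal = abs(value - mu) <= 1e-9 * scale
            z = 0.0 if equal else float("inf") * np.sign(value - mu)
            p = 1.0 if equal else 0.0
        else:
            z = (value - mu) / sd
            p = float(2 * sps.norm.sf(abs(z)))
        rows.append((param, value, mu, sd, z, p))
    return pd.DataFrame(
        rows, columns=["parameter", "real", "random_mean", "random_sd", "z", "p"]
    )


def detect_modules(
    net: nx.Graph, algorithm: str = "louvain", seed: int | None = None
) -> dict:
    """Partition the network into modules by modularity optimization.

    ``louvain`` is multilevel Louvain optimization; ``greedy`` is
    Clauset-Newman-Moore agglomeration.  Module ids are integers ordered
    by module size descending (0 = largest).
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot detect modules in an empty graph")
    if algorithm == "louvain":
        comms = nx.community.louvain_communities(net, weight=None, seed=seed)
    elif algorithm == "greedy":
        comms = nx.community.greedy_modularity_communities(net, weight=None)
    else:
        raise ConfigError(f"unknown module-detection algorithm {algorithm!r}")
    comms = sorted((sorted(c, key=str) for c in comms), key=lambda c: (-len(c), str(c[0])))
    return {node: i for i, comm in enumerate(comms) for node in comm}


def zi_pi(net: nx.Graph, partition: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation
    coefficient (Pi) for every node.

    Zi standardizes a node's within-module degree against its module's
    mean and (population) standard deviation, 0 when the module is
    degree-homogeneous.  Pi = 1 - sum_t (k_it / k_i)^2 over modules t;
    an isolated node takes Pi = 0 by convention.
    """
    missing = [v for v in net.nodes if v not in partition]
    if missing:
        raise ValidationError(f"partition does not cover nodes {missing[:5]}")
    within = {}
    among: dict = {}
    for node in net.nodes:
        counts: dict[int, int] = {}
        for nb in net.neighbors(node):
            counts[partition[nb]] = counts.get(partition[nb], 0) + 1
        within[node] = counts.get(partition[node], 0)
        among[node] = counts
    modules: dict[int, list] = {}
    for node in net.nodes:
        modules.setdefault(partition[node], []).append(node)
    rows = []
    for node in net.nodes:
        mod = partition[node]
        peers = np.array([within[v] for v in modules[mod]], dtype=float)
        sd = peers.std()
        zi = 0.0 if sd == 0 else (within[node] - peers.mean()) / sd
        k = net.degree(node)
        if k == 0:
            logger.warning("isolated node %s: Pi set to 0", node)
            pi = 0.0
        else:
            pi = 1.0 - sum((c / k) ** 2 for c in among[node].values())
        rows.append((node, mod, int(k), within[node], float(zi), float(pi)))
    return pd.DataFrame(
        rows, columns=["node", "module", "degree", "within_degree", "Zi", "Pi"]
    ).set_index("node")


def classify_roles(
    roles: pd.DataFrame, zi_threshold: float = 2.5, pi_threshold: float = 0.62
) -> pd.DataFrame:
    """Assign topological roles from the Zi-Pi plane.

    module_hub: Zi > 2.5 and Pi <= 0.62; connector: Pi > 0.62 and
    Zi <= 2.5; network_hub: both exceeded; else peripheral.  Both
    boundaries are inclusive on the peripheral side.
    """
    out = roles.copy()
    hi_z = out["Zi"] > zi_threshold
    hi_p = out["Pi"] > pi_threshold
    role = np.where(
        hi_z & hi_p,
        "network_hub",
        np.where(hi_z, "module_hub", np.where(hi_p, "connector", "peripheral")),
    )
    out["role"] = role
    return out
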