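import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from biofilmnet import network as net
from biofilmnet.exceptions import ConfigError, ValidationError


# --- OTU selection ----------------------------------------------------------


def test_select_network_otus_prevalence_and_abundance():
    rel = pd.DataFrame(
        {
            "common": np.full(22, 1 / 3),
            "patchy": [1 / 3] * 10 + [0] * 12,       # 10 of 22 samples
            "faint": [0.00009] * 22,                 # mean below 0.01%
        }
    )
    rel["filler"] = 1 - rel.sum(axis=1)
    keep = net.select_network_otus(rel, min_prevalence=11, min_mean_abundance=1e-4)
    assert "common" in keep and "patchy" not in keep and "faint" not in keep


def test_select_network_otus_zero_thresholds_identity(rel_table):
    assert net.select_network_otus(rel_table, 0, 0) == list(rel_table.columns)


def test_select_network_otus_fractional_prevalence(rel_table):
    as_fraction = net.select_network_otus(rel_table, 0.5, 0)
    as_count = net.select_network_otus(rel_table, 11, 0)
    assert as_fraction == as_count


# --- Spearman + BH ----------------------------------------------------------


def test_spearman_monotone_pairs():
    x = np.arange(10.0)
    rel = pd.DataFrame({"up": x, "up2": x**2, "down": -x})
    rho, _ = net.spearman_matrix(rel)
    assert rho.loc["up", "up2"] == pytest.approx(1.0)
    assert rho.loc["up", "down"] == pytest.approx(-1.0)


def test_spearman_matches_rank_pearson(rng):
    rel = pd.DataFrame(rng.normal(size=(22, 6)))
    rho, p = net.spearman_matrix(rel)
    a, b = rel[2].to_numpy(), rel[5].to_numpy()
    expected = np.corrcoef(sps.rankdata(a), sps.rankdata(b))[0, 1]
    assert rho.loc[2, 5] == pytest.approx(expected, abs=1e-12)
    # p via t-approximation on n-2 df
    r = expected
    t = r * np.sqrt((22 - 2) / (1 - r**2))
    assert p.loc[2, 5] == pytest.approx(2 * sps.t.sf(abs(t), 20), rel=1e-9)


def test_spearman_constant_column_flagged(rng, caplog):
    rel = pd.DataFrame({"a": rng.normal(size=8), "c": np.ones(8)})
    with caplog.at_level("WARNING"):
        rho, _ = net.spearman_matrix(rel)
    assert np.isnan(rho.loc["a", "c"])


def test_bh_adjust_direct_and_oracle(rng):
    assert np.allclose(net.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert net.bh_adjust([0.2]) == pytest.approx([0.2])
    p = rng.uniform(size=57)
    # brute-force step-up oracle
    order = np.argsort(p)
    m = len(p)
    stepped = p[order] * m / (np.arange(m) + 1)
    monotone = np.minimum.accumulate(stepped[::-1])[::-1]
    expected = np.empty(m)
    expected[order] = np.minimum(monotone, 1)
    assert np.allclose(net.bh_adjust(p), expected, atol=1e-12)


def test_bh_adjust_rejects_out_of_range():
    with pytest.raises(ValidationError):
        net.bh_adjust([0.5, 1.2])


# --- edge thresholding ------------------------------------------------------


def _pair_matrices(rho_val, p_val):
    ids = ["x", "y"]
    rho = pd.DataFrame([[1.0, rho_val], [rho_val, 1.0]], index=ids, columns=ids)
    p = pd.DataFrame([[0.0, p_val], [p_val, 0.0]], index=ids, columns=ids)
    return rho, p


@pytest.mark.parametrize(
    "rho_val,p_val,has_edge",
    [(0.81, 0.01, True), (0.81, 0.06, False), (0.80, 0.01, False), (-0.85, 0.01, True)],
)
def test_build_network_threshold_rules(rho_val, p_val, has_edge):
    g = net.build_network(*_pair_matrices(rho_val, p_val))
    assert g.has_edge("x", "y") == has_edge
    if has_edge:
        assert g["x"]["y"]["sign"] == ("+" if rho_val > 0 else "-")
    else:
        assert g.number_of_nodes() == 0  # isolated OTUs dropped


# --- topology ---------------------------------------------------------------


def test_topology_average_degree_identity(rng):
    g = nx.gnm_random_graph(120, 431, seed=3)
    stats = net.topology(g)
    assert stats.average_degree == pytest.approx(2 * 431 / 120, abs=1e-12)


def test_topology_triangle():
    stats = net.topology(nx.complete_graph(3))
    assert stats.clustering_coefficient == pytest.approx(1.0)
    assert stats.average_path_length == pytest.approx(1.0)


def test_topology_path_graph_centralization():
    # A-B-C: only B lies on a shortest path; Freeman centralization = 1
    stats = net.topology(nx.path_graph(3))
    assert stats.betweenness_centralization == pytest.approx(1.0)


def test_topology_disconnected_pairs_excluded():
    g = nx.Graph([("a", "b"), ("c", "d")])
    stats = net.topology(g)
    assert stats.average_path_length == pytest.approx(1.0)


def test_topology_empty_graph_rejected():
    with pytest.raises(ValidationError):
        net.topology(nx.Graph())


def test_modularity_two_formula_equivalence(rng):
    """Newman Q from networkx equals the explicit sum over modules of
    (e_ss - a_s^2) on random partitions."""
    g = nx.gnm_random_graph(60, 150, seed=5)
    labels = rng.integers(0, 4, size=60)
    partition = {i: int(labels[i]) for i in g.nodes}
    stats = net.topology(g, partition)
    m = g.number_of_edges()
    e = np.zeros(4)
    a = np.zeros(4)
    for u, v in g.edges:
        if partition[u] == partition[v]:
            e[partition[u]] += 1
    for node in g.nodes:
        a[partition[node]] += g.degree(node)
    q = (e / m - (a / (2 * m)) ** 2).sum()
    assert stats.modularity == pytest.approx(q, abs=1e-12)


# --- power law --------------------------------------------------------------


def test_power_law_exact_frequencies():
    ks = np.arange(1, 8)
    freqs = np.round(1000 * ks**-2.0).astype(int)
    degrees = np.repeat(ks, freqs)
    slope, r2, p = net.fit_degree_power_law(degrees)
    assert slope == pytest.approx(-2.0, abs=0.01)
    assert r2 == pytest.approx(1.0, abs=1e-3)


def test_power_law_uniform_degrees_rejected():
    with pytest.raises(ValidationError):
        net.fit_degree_power_law([4] * 30)


def test_power_law_recovers_planted_exponent(rng):
    ks = np.arange(1, 40)
    weights = ks**-2.3
    degrees = rng.choice(ks, size=5000, p=weights / weights.sum())
    slope, _, p = net.fit_degree_power_law(degrees)
    assert abs(slope - (-2.3)) < 0.3
    assert p < 0.001


# --- ER nulls ---------------------------------------------------------------


def test_er_ensemble_sizes_and_determinism():
    ens = net.er_random_ensemble(50, 100, n_graphs=5, seed=9)
    assert len(ens) == 5
    for g in ens:
        assert g.number_of_nodes() == 50 and g.number_of_edges() == 100
        assert nx.number_of_selfloops(g) == 0
    again = net.er_random_ensemble(50, 100, n_graphs=5, seed=9)
    assert all(set(a.edges) == set(b.edges) for a, b in zip(ens, again))


def test_er_ensemble_complete_graph():
    g = net.er_random_ensemble(6, 15, n_graphs=1, seed=0)[0]
    assert nx.density(g) == 1.0


def test_er_ensemble_infeasible():
    with pytest.raises(ConfigError):
        net.er_random_ensemble(4, 7)


def _stats_with(value):
    return net.TopologyStats(10, 20, 0, 4.0, 2.0, value, 0.1, 0.3)


def test_z_test_zero_and_three_sigma():
    ens = [_stats_with(v) for v in (0.09, 0.10, 0.11)]
    real = _stats_with(0.10)
    tab = net.z_test_topology(real, ens).set_index("parameter")
    assert tab.loc["clustering_coefficient", "z"] == pytest.approx(0.0)
    assert tab.loc["clustering_coefficient", "p"] == pytest.approx(1.0)
    real3 = _stats_with(0.10 + 3 * tab.loc["clustering_coefficient", "random_sd"])
    tab3 = net.z_test_topology(real3, ens).set_index("parameter")
    assert tab3.loc["clustering_coefficient", "p"] == pytest.approx(0.0027, abs=2e-4)


def test_z_test_flags_inflated_clustering():
    """A real clustering of 0.531 against a null around 0.007 is
    overwhelmingly significant."""
    rng = np.random.default_rng(0)
    ens = [_stats_with(v) for v in rng.normal(0.007, 0.001, size=99)]
    tab = net.z_test_topology(_stats_with(0.531), ens).set_index("parameter")
    assert tab.loc["clustering_coefficient", "z"] > 100
    assert tab.loc["clustering_coefficient", "p"] < 1e-10


# --- modules and roles ------------------------------------------------------


def test_detect_modules_two_cliques():
    g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
    g.add_edge(0, 8)
    part = net.detect_modules(g, seed=1)
    assert len(set(part.values())) == 2
    assert len({part[i] for i in range(8)}) == 1
    assert len({part[i] for i in range(8, 16)}) == 1


def test_detect_modules_planted_partition_recovery():
    from sklearn.metrics import adjusted_rand_score

    g = nx.planted_partition_graph(4, 40, 0.3, 0.01, seed=7)
    part = net.detect_modules(g, seed=3)
    truth = [i // 40 for i in range(160)]
    found = [part[i] for i in range(160)]
    assert adjusted_rand_score(truth, found) >= 0.95


def test_detect_modules_beats_trivial_partition(rng):
    g = nx.gnm_random_graph(80, 200, seed=2)
    part = net.detect_modules(g, seed=2)
    q = net.topology(g, part).modularity
    assert q >= 0.0


def test_zi_pi_bookkeeping_and_conventions():
    # two cliques of 4 bridged through node 0 (which also links module 1)
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g.add_edge(0, 4)
    partition = {i: 0 if i < 4 else 1 for i in g.nodes}
    roles = net.zi_pi(g, partition)
    # degree conservation: within + among == degree
    for node in g.nodes:
        k_t = sum(
            1 for nb in g.neighbors(node) if partition[nb] != partition[node]
        )
        assert roles.loc[node, "within_degree"] + k_t == g.degree(node)
    # all edges inside own module -> Pi = 0
    assert roles.loc[5, "Pi"] == 0.0
    # node 0 splits 3/1 across modules: Pi = 1 - (3/4)^2 - (1/4)^2
    assert roles.loc[0, "Pi"] == pytest.approx(1 - 9 / 16 - 1 / 16)


def test_zi_pi_even_split():
    g = nx.star_graph(4)  # center 0 with degree 4
    partition = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
    roles = net.zi_pi(g, partition)
    assert roles.loc[0, "Pi"] == pytest.approx(0.5)


def test_zi_zero_in_degree_regular_module():
    g = nx.complete_graph(5)
    roles = net.zi_pi(g, {i: 0 for i in g.nodes})
    assert (roles["Zi"] == 0).all()


@pytest.mark.parametrize(
    "zi,pi,expected",
    [
        (3.0, 0.1, "module_hub"),
        (1.0, 0.7, "connector"),
        (3.0, 0.7, "network_hub"),
        (2.5, 0.62, "peripheral"),
        (1.0, 0.1, "peripheral"),
    ],
)
def test_classify_roles_thresholds(zi, pi, expected):
    roles = pd.DataFrame({"Zi": [zi], "Pi": [pi]}, index=["n"])
    assert net.classify_roles(roles)["role"].iloc[0] == expected
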