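import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from plsig.network import (
    build_graph,
    degree_distribution,
    fit_power_law,
    identify_hubs,
    induced_module,
    module_stats,
    read_interactions,
)


def _edge_file(tmp_path, rows, header="protein1\tprotein2\texperimental\tcombined_score"):
    path = tmp_path / "edges.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


def test_read_interactions_filters_and_dedups(tmp_path):
    path = _edge_file(tmp_path, [
        "A\tB\t700\t900",
        "B\tA\t650\t900",      # symmetric duplicate, lower score
        "A\tC\t0\t400",        # no experimental evidence
        "C\tD\t0\t300",
        "D\tE\t210\t500",
        "E\tF\t180\t450",
    ])
    edges = read_interactions(path)
    assert len(edges) == 3
    assert set(map(tuple, edges[["protein1", "protein2"]].values)) == {
        ("A", "B"), ("D", "E"), ("E", "F")}
    ab = edges.set_index(["protein1", "protein2"]).loc[("A", "B"), "score"]
    assert ab == 700  # keeps the better-scored duplicate
    strict = read_interactions(path, min_score=200)
    assert len(strict) == 2


def test_read_interactions_edge_cases(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    assert read_interactions(empty).empty
    bad = _edge_file(tmp_path, ["A\tB\t700\t900", "A\tB\t700"])
    with pytest.raises(ValueError, match=":3"):
        read_interactions(bad)
    noheader = tmp_path / "nh.tsv"
    noheader.write_text("a\tb\t1\t2\n")
    with pytest.raises(ValueError, match="protein1"):
        read_interactions(noheader)


def test_build_graph_annotations_and_isolates():
    sets = {
        "body_weight": {"G1", "G2"},
        "blood_glucose": {"G2", "G3"},
    }
    edges = pd.DataFrame(
        [("G1", "X1", 500.0), ("X1", "X2", 400.0), ("Z1", "Z2", 300.0)],
        columns=["protein1", "protein2", "score"],
    )
    g = build_graph(sets, edges)
    # G2 sits in two signatures: the multi-parameter ("magenta") case
    assert g.nodes["G2"]["multi"]
    assert set(g.nodes["G2"]["parameters"]) == {"body_weight", "blood_glucose"}
    # an unconnected signature gene is retained as an isolated node
    assert "G3" in g and g.degree("G3") == 0
    # edges not touching any signature gene are not pulled in
    assert "Z1" not in g
    # first-neighbour interactor chains only enter via a signature edge
    assert "X1" in g and "X2" not in g


def test_build_graph_components_respect_disjoint_partitions():
    sets = {"a": {"A1", "A2"}, "b": {"B1", "B2"}}
    edges = pd.DataFrame(
        [("A1", "A2", 1.0), ("B1", "B2", 1.0)],
        columns=["protein1", "protein2", "score"],
    )
    g = build_graph(sets, edges)
    comps = [set(c) for c in nx.connected_components(g)]
    assert {"A1", "A2"} in comps and {"B1", "B2"} in comps


def test_degree_distribution_star_closed_form():
    n = 9
    star = nx.star_graph(n - 1)  # 1 hub + 8 leaves
    dist = degree_distribution(star)
    assert dist.pk.sum() == pytest.approx(1.0)
    assert dist.pk[1] == pytest.approx((n - 1) / n)
    assert dist.pk[n - 1] == pytest.approx(1 / n)


def test_power_law_fit_recovers_exact_exponent():
    ks = np.arange(1, 21)
    pk = ks ** -2.5
    pk = pk / pk.sum()
    dist = degree_distribution(nx.path_graph(4))  # placeholder, overwritten
    dist.pk = pd.Series(pk, index=pd.Index(ks, name="k"))
    gamma, c, r2 = fit_power_law(dist)
    assert gamma == pytest.approx(2.5, abs=1e-6)
    assert r2 == pytest.approx(1.0, abs=1e-12)
    # MLE alternative lands near the same exponent on the same counts
    gamma_mle, _, _ = fit_power_law(dist, method="mle")
    assert gamma_mle == pytest.approx(2.5, abs=0.3)


def test_power_law_fit_requires_degree_spread():
    regular = nx.cycle_graph(10)  # all degrees equal
    with pytest.raises(ValueError, match="cannot fit"):
        fit_power_law(degree_distribution(regular))


def test_module_stats_closed_forms():
    k4 = module_stats(nx.complete_graph(4))
    assert k4.density == pytest.approx(1.0)
    assert k4.centralization == pytest.approx(0.0)
    assert k4.heterogeneity == pytest.approx(0.0)
    assert k4.avg_clustering == pytest.approx(1.0)

    star5 = module_stats(nx.star_graph(4))  # 5 nodes
    assert star5.centralization == pytest.approx(1.0)
    assert star5.density == pytest.approx(0.4)

    path3 = module_stats(nx.path_graph(3))
    assert path3.density == pytest.approx(2 / 3)
    assert path3.centralization == pytest.approx(1.0)
    assert path3.heterogeneity == pytest.approx(0.35355339, abs=1e-6)

    tiny = module_stats(nx.path_graph(2))
    assert tiny.centralization is None


def _brute_force_stats(g):
    nodes = list(g)
    n = len(nodes)
    adj = {v: set(g.neighbors(v)) for v in nodes}
    e = sum(len(adj[v]) for v in nodes) // 2
    k = [len(adj[v]) for v in nodes]
    density = 2 * e / (n * (n - 1))
    kmax = max(k)
    centralization = (n / (n - 2)) * (kmax / (n - 1) - density)
    mean_k = sum(k) / n
    var_k = sum((x - mean_k) ** 2 for x in k) / n
    heterogeneity = var_k**0.5 / mean_k if mean_k else 0.0
    return density, 2 * e / n, centralization, heterogeneity


def test_module_stats_match_brute_force_on_random_graphs():
    rng = np.random.default_rng(0)
    for trial in range(20):
        n = int(rng.integers(3, 13))
        p = float(rng.uniform(0.2, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        if g.number_of_edges() == 0 or max(d for _, d in g.degree()) == 0:
            continue
        stats = module_stats(g)
        density, avg_nb, central, hetero = _brute_force_stats(g)
        assert stats.density == pytest.approx(density, rel=1e-12)
        assert stats.avg_neighbors == pytest.approx(avg_nb, rel=1e-12)
        assert stats.centralization == pytest.approx(central, rel=1e-12)
        assert stats.heterogeneity == pytest.approx(hetero, rel=1e-12)
        assert 0 <= stats.density <= 1


def test_identify_hubs_counts_and_ties():
    # 166-node module at top 5% -> 8 hubs
    g = nx.barabasi_albert_graph(166, 2, seed=1)
    hubs = identify_hubs(g, 0.05)
    assert len(hubs) == 8
    degrees = dict(g.degree())
    assert list(hubs["degree"]) == sorted(degrees.values(), reverse=True)[:8]
    # 100 nodes at 5% -> exactly 5
    assert len(identify_hubs(nx.barabasi_albert_graph(100, 2, seed=2),
                             0.05)) == 5
    # all-equal degrees: lexicographically first nodes, flagged degenerate
    ring = nx.relabel_nodes(nx.cycle_graph(10), lambda v: f"n{v}")
    hubs = identify_hubs(ring, 0.25)
    assert list(hubs["node"]) == ["n0", "n1"]
    assert hubs.attrs["degenerate"]
    with pytest.raises(ValueError, match="top_fraction"):
        identify_hubs(ring, 1.5)


def test_hub_set_invariant_under_relabeling():
    g = nx.barabasi_albert_graph(60, 2, seed=3)
    mapping = {v: f"z{v:03d}" for v in g}
    h = nx.relabel_nodes(g, mapping)
    hubs_g = identify_hubs(g, 0.1)
    hubs_h = identify_hubs(h, 0.1)
    # the selected degree multiset is invariant; membership may differ only
    # among nodes tied at the cutoff degree (documented lexicographic rule)
    assert sorted(hubs_g["degree"]) == sorted(hubs_h["degree"])
    cutoff = hubs_g["degree"].min()
    above_g = {mapping[int(v)] for v, d in zip(hubs_g["node"], hubs_g["degree"])
               if d > cutoff}
    above_h = {v for v, d in zip(hubs_h["node"], hubs_h["degree"]) if d > cutoff}
    assert above_g == above_h


def test_induced_module_subsets_by_process():
    g = nx.path_graph(5)
    g = nx.relabel_nodes(g, {i: f"G{i}" for i in g})
    ann = pd.DataFrame(
        {"gene_symbol": ["G0", "G1", "G4"],
         "process_label": ["apoptosis", "apoptosis", "translation"],
         "p_value": [0.01, 0.02, 0.03]}
    )
    sub = induced_module(g, ann, "apoptosis")
    assert set(sub) == {"G0", "G1"}
    assert sub.number_of_edges() == 1
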