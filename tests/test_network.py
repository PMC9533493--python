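import numpy as np
import pandas as pd
import pytest

from microbreed import coda, network

from conftest import make_composition


# -- pre-correction -----------------------------------------------------------


def test_precorrect_single_level_is_plain_centering():
    df = pd.DataFrame({"y": [1.0, 2.0, 6.0]}, index=["a", "b", "c"])
    resid, r2 = network.precorrect_phenotypes(df, ["L1", "L1", "L1"])
    assert np.allclose(resid["y"], df["y"] - df["y"].mean())
    assert r2["y"] == pytest.approx(0.0, abs=1e-12)


def test_precorrect_hand_example_two_levels():
    # level A: 1, 3 (mean 2); level B: 10, 14 (mean 12)
    df = pd.DataFrame({"y": [1.0, 3.0, 10.0, 14.0]})
    resid, r2 = network.precorrect_phenotypes(df, ["A", "A", "B", "B"])
    assert np.allclose(resid["y"], [-1.0, 1.0, -2.0, 2.0])
    total = float(((df["y"] - df["y"].mean()) ** 2).sum())
    assert r2["y"] == pytest.approx(1.0 - 10.0 / total, abs=1e-12)


def test_precorrect_singleton_level_warns_zero_residual():
    df = pd.DataFrame({"y": [1.0, 3.0, 99.0]})
    with pytest.warns(UserWarning, match="single animal"):
        resid, _ = network.precorrect_phenotypes(df, ["A", "A", "B"])
    assert resid["y"].iloc[2] == 0.0


def test_precorrect_length_mismatch():
    with pytest.raises(ValueError):
        network.precorrect_phenotypes(pd.DataFrame({"y": [1.0, 2.0]}), ["A"])


# -- variance explained (one-way RDA) ----------------------------------------


def test_variance_explained_reduces_to_anova_r2_single_column():
    rng = np.random.default_rng(0)
    codes = np.repeat(["A", "B", "C"], 30)
    y = rng.standard_normal(90) + np.repeat([0.0, 1.0, 2.0], 30)
    df = pd.DataFrame({"y": y})
    got = network.variance_explained_multivariate(df, codes)
    # one-way ANOVA R^2 computed directly
    s = pd.Series(y)
    between = s.groupby(pd.Series(codes)).transform("mean") - s.mean()
    expected = float((between**2).sum() / ((s - s.mean()) ** 2).sum())
    assert got == pytest.approx(expected, abs=1e-12)


def test_variance_explained_null_expectation():
    # under pure noise E[R^2] = (L - 1)/(n - 1); average over replicates
    rng = np.random.default_rng(1)
    n, L = 60, 4
    codes = np.repeat(np.arange(L), n // L)
    vals = [
        network.variance_explained_multivariate(
            pd.DataFrame(rng.standard_normal((n, 3))), codes
        )
        for _ in range(60)
    ]
    assert np.mean(vals) == pytest.approx((L - 1) / (n - 1), abs=0.02)


def test_variance_explained_validation():
    with pytest.raises(ValueError, match="levels"):
        network.variance_explained_multivariate(
            pd.DataFrame({"y": [1.0, 2.0]}), ["A", "A"]
        )
    with pytest.raises(ValueError, match="variance"):
        network.variance_explained_multivariate(
            pd.DataFrame({"y": [1.0, 1.0]}), ["A", "B"]
        )


# -- co-abundance graph -------------------------------------------------------


def _three_feature_frame(n=40, seed=2):
    rng = np.random.default_rng(seed)
    f1 = rng.standard_normal(n)
    return pd.DataFrame(
        {"f1": f1, "f2": 2.0 * f1 + 1.0, "f3": rng.standard_normal(n)}
    )


def test_build_network_hand_edges():
    df = _three_feature_frame()
    g = network.build_network(df, r_threshold=0.30)
    assert set(g.nodes) == {"f1", "f2", "f3"}
    edges = {frozenset(e) for e in g.graph.edges}
    assert frozenset(("f1", "f2")) in edges
    assert g.graph["f1"]["f2"]["weight"] == pytest.approx(1.0, abs=1e-12)
    # f3 is independent noise: |r| with n=40 stays well below 0.30 here
    assert frozenset(("f1", "f3")) not in edges


def test_build_network_threshold_is_strict():
    df = _three_feature_frame()
    r13 = abs(np.corrcoef(df["f1"], df["f3"])[0, 1])
    below = network.build_network(df, r_threshold=r13 - 1e-9)
    at = network.build_network(df, r_threshold=r13)
    assert frozenset(("f1", "f3")) in {frozenset(e) for e in below.graph.edges}
    assert frozenset(("f1", "f3")) not in {frozenset(e) for e in at.graph.edges}


def test_build_network_negative_correlations_count():
    df = _three_feature_frame()
    df["f4"] = -df["f1"] + 0.0
    g = network.build_network(df, r_threshold=0.30)
    assert g.graph["f1"]["f4"]["weight"] == pytest.approx(-1.0, abs=1e-12)


def test_build_network_affine_invariance():
    df = _three_feature_frame()
    g1 = network.build_network(df, r_threshold=0.30)
    g2 = network.build_network(df * 3.5 - 7.0, r_threshold=0.30)
    assert {frozenset(e) for e in g1.graph.edges} == {
        frozenset(e) for e in g2.graph.edges
    }


def test_build_network_excludes_constant_features():
    df = _three_feature_frame()
    df["flat"] = 1.0
    with pytest.warns(UserWarning, match="zero-variance"):
        g = network.build_network(df)
    assert "flat" not in g.nodes and g.excluded == ["flat"]


def test_build_network_needs_three_animals():
    with pytest.raises(ValueError):
        network.build_network(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


# -- Markov clustering --------------------------------------------------------


def _clique_graph(groups, bridge=None, w=1.0):
    import networkx as nx

    g = nx.Graph()
    for grp in groups:
        g.add_nodes_from(grp)
        for i, a in enumerate(grp):
            for b in grp[i + 1 :]:
                g.add_edge(a, b, weight=w)
    if bridge:
        g.add_edge(*bridge[:2], weight=bridge[2])
    return g


def test_mcl_two_disconnected_triangles():
    g = _clique_graph([["a", "b", "c"], ["d", "e", "f"]])
    res = network.mcl_cluster(g)
    cl = res.clusters
    assert sorted(sorted(v) for v in cl.values()) == [
        ["a", "b", "c"],
        ["d", "e", "f"],
    ]
    assert res.converged


def test_mcl_weak_bridge_is_cut():
    g = _clique_graph([["a", "b", "c"], ["d", "e", "f"]], bridge=("c", "d", 0.1))
    cl = network.mcl_cluster(g, inflation=2.0).clusters
    assert sorted(sorted(v) for v in cl.values()) == [
        ["a", "b", "c"],
        ["d", "e", "f"],
    ]


def test_mcl_singleton_left_unclustered():
    g = _clique_graph([["a", "b", "c"]])
    g.add_node("lone")
    res = network.mcl_cluster(g, min_cluster_size=2)
    assert pd.isna(res.assignments["lone"])
    assert res.assignments[["a", "b", "c"]].nunique() == 1


def test_mcl_refines_connected_components():
    # every cluster must sit inside one connected component
    import networkx as nx

    rng = np.random.default_rng(7)
    g = nx.Graph()
    for block, names in enumerate((list("abcd"), list("efgh"), list("ij"))):
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                g.add_edge(a, b, weight=0.5 + 0.5 * rng.random())
    comp_of = {}
    for k, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of[node] = k
    cl = network.mcl_cluster(g).clusters
    for members in cl.values():
        assert len({comp_of[m] for m in members}) == 1


def test_mcl_matches_independent_reference_partition():
    # independently coded MCL (dense numpy, no shared helpers)
    import networkx as nx

    def reference_mcl(adj, inflation=2.0):
        m = adj.copy()
        np.fill_diagonal(m, 1.0)
        m = m / m.sum(0)
        for _ in range(500):
            nxt = np.linalg.matrix_power(m, 2) ** inflation
            nxt = nxt / nxt.sum(0)
            if np.abs(nxt - m).max() < 1e-8:
                m = nxt
                break
            m = nxt
        # union-find over attractor rows
        n = m.shape[0]
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in np.where(np.diag(m) > 1e-6)[0]:
            for j in np.where(m[i] > 1e-6)[0]:
                parent[find(j)] = find(i)
        return [find(k) for k in range(n)]

    rng = np.random.default_rng(11)
    g = _clique_graph(
        [list("abcd"), list("efg"), list("hij")],
        bridge=("d", "e", 0.15),
    )
    nodes = list(g.nodes)
    adj = np.abs(nx.to_numpy_array(g, nodelist=nodes, weight="weight"))
    ref_labels = reference_mcl(adj)
    ours = network.mcl_cluster(g, min_cluster_size=1).assignments
    ref_part = {}
    for node, lab in zip(nodes, ref_labels):
        ref_part.setdefault(lab, set()).add(node)
    our_part = {}
    for node, lab in ours.items():
        our_part.setdefault(lab, set()).add(node)
    assert sorted(map(sorted, ref_part.values())) == sorted(
        map(sorted, our_part.values())
    )


def test_mcl_empty_graph_rejected():
    import networkx as nx

    with pytest.raises(ValueError):
        network.mcl_cluster(nx.Graph())


# -- abundance filter ---------------------------------------------------------


def test_abundance_filter_inclusive_floor():
    # mean RAs: p0 = 0.70, p1 = 0.0001 (exactly the floor), p2 ~ 0.2999
    vals = np.array([[0.7, 1e-4, 0.2999], [0.7, 1e-4, 0.2999]])
    vals = vals / vals.sum(axis=1, keepdims=True)
    t = make_composition(vals)
    kept = network.abundance_filter(["p0", "p1", "p2"], t, min_mean_ra=1e-4)
    assert kept == ["p0", "p1", "p2"]  # floor is inclusive
    kept2 = network.abundance_filter(["p0", "p1"], t, min_mean_ra=2e-4)
    assert kept2 == ["p0"]


def test_abundance_filter_unknown_feature():
    t = make_composition([[0.5, 0.5]])
    with pytest.raises(KeyError, match="nope"):
        network.abundance_filter(["nope"], t)


# -- RDA redundancy pruning ---------------------------------------------------


def _rda_data(n=60, seed=3):
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    y = pd.DataFrame(
        {
            "t1": 1.0 * x1 + 0.1 * rng.standard_normal(n),
            "t2": 1.0 * x2 + 0.1 * rng.standard_normal(n),
        },
        index=[f"a{i}" for i in range(n)],
    )
    return y, x1, x2, rng


def test_rda_keeps_independent_true_predictors():
    y, x1, x2, rng = _rda_data()
    cand = pd.DataFrame({"x1": x1, "x2": x2}, index=y.index)
    kept, pvals = network.rda_redundancy_select(y, cand, n_perm=199, seed=1)
    assert set(kept) == {"x1", "x2"}
    assert (pvals[["x1", "x2"]] < 0.05).all()


def test_rda_discards_duplicate_candidate():
    y, x1, x2, rng = _rda_data()
    cand = pd.DataFrame(
        {"x1": x1, "x1_copy": x1 + 1e-9 * rng.standard_normal(len(x1)), "x2": x2},
        index=y.index,
    )
    kept, pvals = network.rda_redundancy_select(y, cand, n_perm=199, seed=1)
    # a near-duplicate adds no marginal explanatory power: at most one survives
    assert not {"x1", "x1_copy"} <= set(kept)
    assert "x2" in kept


def test_rda_discards_pure_noise_usually():
    y, x1, x2, rng = _rda_data()
    cand = pd.DataFrame(
        {"x1": x1, "noise": rng.standard_normal(len(x1))}, index=y.index
    )
    kept, pvals = network.rda_redundancy_select(y, cand, n_perm=199, seed=2)
    assert "x1" in kept
    assert pvals["noise"] > 0.05  # this seed's noise column is not significant


def test_rda_alpha_monotonicity():
    y, x1, x2, rng = _rda_data()
    cand = pd.DataFrame(
        {
            "x1": x1,
            "x2": x2,
            "weak": 0.2 * x1 + rng.standard_normal(len(x1)),
        },
        index=y.index,
    )
    kept_strict, _ = network.rda_redundancy_select(
        y, cand, alpha=0.001, n_perm=499, seed=3
    )
    kept_loose, _ = network.rda_redundancy_select(
        y, cand, alpha=0.5, n_perm=499, seed=3
    )
    assert set(kept_strict) <= set(kept_loose)


def test_rda_noise_false_positive_rate_calibrated():
    # marginal permutation p-values of pure-noise candidates should be
    # roughly uniform: FPR at alpha = 0.05 near 0.05 over many replicates
    rng = np.random.default_rng(5)
    hits = total = 0
    for _ in range(25):
        n = 30
        y = pd.DataFrame(rng.standard_normal((n, 2)), columns=["t1", "t2"])
        cand = pd.DataFrame(rng.standard_normal((n, 3)), columns=["c1", "c2", "c3"])
        _, pvals = network.rda_redundancy_select(
            y, cand, n_perm=99, seed=int(rng.integers(1 << 30))
        )
        hits += int((pvals < 0.05).sum())
        total += len(pvals)
    assert hits / total < 0.12


def test_rda_too_many_candidates_rejected():
    y = pd.DataFrame(np.random.default_rng(0).standard_normal((4, 2)))
    cand = pd.DataFrame(np.random.default_rng(1).standard_normal((4, 5)))
    with pytest.raises(ValueError):
        network.rda_redundancy_select(y, cand)
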