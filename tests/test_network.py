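"""PCIT significance versus a naive oracle, edge filtering, topology and
TF-trio selection."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import milknet as mk


# ---------------------------------------------------------------------------
# naive PCIT oracle: explicit triple loop, independent of the implementation
# ---------------------------------------------------------------------------

def pcit_oracle(r: np.ndarray) -> np.ndarray:
    n = r.shape[0]
    flags = np.ones((n, n), dtype=bool)
    np.fill_diagonal(flags, False)
    if n < 3:
        return flags

    def partial(a, b, c):
        denom = np.sqrt((1 - r[a, c] ** 2) * (1 - r[b, c] ** 2))
        return (r[a, b] - r[a, c] * r[b, c]) / max(denom, 1e-12)

    for x, y, z in itertools.combinations(range(n), 3):
        ratios = []
        for (a, b), c in (((x, y), z), ((x, z), y), ((y, z), x)):
            if abs(r[a, b]) > 1e-12:
                ratios.append(abs(partial(a, b, c) / r[a, b]))
        eps = sum(ratios) / len(ratios) if ratios else 0.0
        for (a, b), c in (((x, y), z), ((x, z), y), ((y, z), x)):
            if abs(r[a, b]) < abs(eps * r[a, c]) and abs(r[a, b]) < abs(eps * r[b, c]):
                flags[a, b] = flags[b, a] = False
    return flags


def random_corr(rng, n, k=6):
    x = rng.standard_normal((n, k))
    c = np.corrcoef(x)
    np.fill_diagonal(c, 1.0)
    return c


def test_pcit_three_node_direct_evaluation():
    """Hand-evaluated trio rule: x and y both correlate 0.9 with z but only
    0.65 with each other, so the x-y edge is explained by the indirect path
    (|r_xy| < eps*|r_xz| and < eps*|r_yz| with eps ~ 1.136) while the two
    strong legs survive."""
    r = np.array([[1.0, 0.65, 0.9], [0.65, 1.0, 0.9], [0.9, 0.9, 1.0]])
    flags = mk.pcit(r)
    assert not flags[0, 1]
    assert flags[0, 2] and flags[1, 2]
    np.testing.assert_array_equal(flags, pcit_oracle(r))


def test_pcit_weak_legs_survive_by_rule():
    """With r_xy = 0.9 and both legs at 0.05 the tolerance eps ~ 0.45 makes
    eps*|r_yz| = 0.023 < |r_xz| = 0.05, so by the stated rule no edge is
    dominated and all three survive (matches the oracle)."""
    r = np.array([[1.0, 0.9, 0.05], [0.9, 1.0, 0.05], [0.05, 0.05, 1.0]])
    flags = mk.pcit(r)
    assert flags.sum() == 6
    np.testing.assert_array_equal(flags, pcit_oracle(r))


def test_pcit_two_nodes_vacuously_significant():
    r = np.array([[1.0, 0.2], [0.2, 1.0]])
    flags = mk.pcit(r)
    assert flags[0, 1] and flags[1, 0]


def test_pcit_matches_oracle_on_random_matrices():
    rng = np.random.default_rng(41)
    for _ in range(50):
        c = random_corr(rng, 20)
        np.testing.assert_array_equal(mk.pcit(c), pcit_oracle(c))


def test_pcit_equal_offdiagonals_keeps_all_edges():
    """Equal positive correlations: |partial/direct| = 1/(1+v) < 1 and no
    edge is dominated, so all survive.  (For equal negative v the same
    ratio exceeds 1 and the rule symmetrically removes every edge.)"""
    for v in (0.3, 0.7):
        r = np.full((6, 6), v)
        np.fill_diagonal(r, 1.0)
        assert mk.pcit(r).sum() == 6 * 5
    r = np.full((6, 6), -0.15)
    np.fill_diagonal(r, 1.0)
    flags = mk.pcit(r)
    assert flags.sum() == 0
    np.testing.assert_array_equal(flags, pcit_oracle(r))


def test_pcit_permutation_equivariance():
    rng = np.random.default_rng(42)
    c = random_corr(rng, 12)
    perm = rng.permutation(12)
    f1 = mk.pcit(c)[np.ix_(perm, perm)]
    f2 = mk.pcit(c[np.ix_(perm, perm)])
    np.testing.assert_array_equal(f1, f2)


def test_pcit_rejects_asymmetric_input():
    r = np.eye(3)
    r[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        mk.pcit(r)


# ---------------------------------------------------------------------------
# Edge filtering
# ---------------------------------------------------------------------------

def _corr_df(r, names=None):
    names = names or [f"g{i}" for i in range(r.shape[0])]
    return pd.DataFrame(r, index=names, columns=names)


def test_filter_edges_boundary_and_sign():
    r = np.eye(4)
    r[0, 1] = r[1, 0] = 0.80   # exactly at the cut: retained (inclusive)
    r[0, 2] = r[2, 0] = -0.85  # negative edge retained with its sign
    r[1, 2] = r[2, 1] = 0.79   # below the cut
    flags = np.ones((4, 4), dtype=bool)
    np.fill_diagonal(flags, False)
    net = mk.filter_edges(_corr_df(r), flags, min_abs_r=0.80)
    edges = {tuple(sorted(e)): d["weight"] for *e, d in net.graph.edges(data=True)}
    assert set(edges) == {("g0", "g1"), ("g0", "g2")}
    assert edges[("g0", "g2")] == pytest.approx(-0.85)
    assert net.isolated == ["g3"]


def test_filter_edges_requires_pcit_significance():
    r = np.eye(3)
    r[0, 1] = r[1, 0] = 0.95
    flags = np.zeros((3, 3), dtype=bool)  # PCIT killed everything
    net = mk.filter_edges(_corr_df(r), flags, min_abs_r=0.80)
    assert net.n_edges == 0


def test_filter_edges_monotone_in_threshold():
    rng = np.random.default_rng(43)
    c = random_corr(rng, 15, k=4)
    flags = mk.pcit(c)
    counts = [
        mk.filter_edges(_corr_df(c), flags, min_abs_r=t).n_edges
        for t in (0.0, 0.4, 0.8, 0.95)
    ]
    assert counts[0] == flags.sum() // 2
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _net_from_edges(edges, tfs=()):
    names = sorted({a for e in edges for a in e[:2]})
    n = len(names)
    idx = {g: i for i, g in enumerate(names)}
    r = np.eye(n)
    flags = np.zeros((n, n), dtype=bool)
    for a, b, w in edges:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = w
        flags[idx[a], idx[b]] = flags[idx[b], idx[a]] = True
    return mk.filter_edges(_corr_df(r, names), flags, min_abs_r=0.0, tf_genes=set(tfs))


def test_topology_path_graph():
    net = _net_from_edges([("A", "B", 0.9), ("B", "C", 0.9)])
    topo = mk.topology(net).set_index("gene")
    assert topo.loc["B", "degree"] == 2
    assert topo.loc["B", "betweenness"] == pytest.approx(1.0)
    assert topo.loc["A", "betweenness"] == pytest.approx(0.0)
    # degree sum = 2 x edge count
    assert topo["degree"].sum() == 2 * net.n_edges


def test_topology_star_center_max_closeness():
    edges = [("HUB", f"L{i}", 0.85) for i in range(4)]
    topo = mk.topology(_net_from_edges(edges)).set_index("gene")
    assert topo["closeness"].idxmax() == "HUB"
    assert topo.loc["HUB", "closeness"] == pytest.approx(1.0)


def test_topology_empty_and_singleton():
    net = mk.filter_edges(
        _corr_df(np.eye(2)), np.zeros((2, 2), dtype=bool), min_abs_r=0.5
    )
    assert mk.topology(net).empty
    assert net.isolated == ["g0", "g1"]


# ---------------------------------------------------------------------------
# TF trio
# ---------------------------------------------------------------------------

def test_exactly_three_tfs_forced_trio():
    edges = [("T1", "a", 0.9), ("T2", "b", 0.9), ("T3", "c", -0.9), ("a", "b", 0.85)]
    net = _net_from_edges(edges, tfs=["T1", "T2", "T3"])
    trio = mk.best_tf_trio(net)
    assert trio.tf_ids == ("T1", "T2", "T3")
    assert trio.covered_targets == {"a", "b", "c"}
    assert trio.coverage_fraction == pytest.approx(1.0)


def test_fewer_than_three_tfs_raises():
    net = _net_from_edges([("T1", "a", 0.9)], tfs=["T1"])
    with pytest.raises(ValueError, match="found 1"):
        mk.best_tf_trio(net)


def test_greedy_counterexample_exhaustive_wins():
    """G has the largest single neighborhood (greedy's first pick) but
    overlaps both specialists; the optimal trio excludes G."""
    xs = [f"x{i}" for i in range(7)]
    edges = [("G", t, 0.9) for t in xs]                       # G: 7 targets
    edges += [("A", t, 0.9) for t in xs[:4] + ["a1", "a2"]]   # A: 6
    edges += [("B", t, 0.9) for t in xs[4:] + ["b1", "b2", "b3"]]  # B: 6
    edges += [("C", "c1", 0.9)]                               # C: 1
    net = _net_from_edges(edges, tfs=["G", "A", "B", "C"])
    # greedy: G first (7), then B (+3), then A (+2) -> 12 covered
    greedy_score = len(
        {t for tf in ("G", "A", "B") for t in net.graph.neighbors(tf)} - {"G", "A", "B"}
    )
    trio = mk.best_tf_trio(net)
    assert trio.tf_ids == ("A", "B", "C")
    assert len(trio.covered_targets) == 13
    assert len(trio.covered_targets) > greedy_score


def _trio_oracle(net):
    best = None
    for trio in itertools.combinations(net.tfs_in_network(), 3):
        covered = set()
        for tf in trio:
            covered.update(net.graph.neighbors(tf))
        covered -= set(trio)
        if best is None or len(covered) > best[0]:
            best = (len(covered), trio)
    return best[0]


def test_random_fixtures_match_enumeration_oracle():
    rng = np.random.default_rng(44)
    for _ in range(10):
        n = 15
        names = [f"g{i}" for i in range(n)]
        c = random_corr(rng, n, k=5)
        flags = mk.pcit(c)
        tfs = set(rng.choice(names, size=6, replace=False))
        net = mk.filter_edges(_corr_df(c, names), flags, min_abs_r=0.3, tf_genes=tfs)
        if len(net.tfs_in_network()) < 3:
            continue
        trio = mk.best_tf_trio(net)
        assert len(trio.covered_targets) == _trio_oracle(net)


# ---------------------------------------------------------------------------
# Regulation direction
# ---------------------------------------------------------------------------

def test_classify_regulation_fractions():
    edges = [("T", "a", -0.9), ("T", "b", -0.85), ("T", "c", 0.81)]
    edges += [("U", f"u{i}", 0.9) for i in range(3)]
    edges += [("V", f"v{i}", -0.9 if i < 8 else 0.9) for i in range(13)]
    net = _net_from_edges(edges, tfs=["T", "U", "V"])
    res = mk.classify_regulation(net, ("T", "U", "V")).set_index("tf")
    assert res.loc["T", "frac_repressed"] == pytest.approx(2 / 3)
    assert res.loc["U", "frac_repressed"] == 0.0
    assert res.loc["V", "frac_repressed"] == pytest.approx(8 / 13)
    assert res.loc["V", "n_targets"] == 13


def test_pairwise_correlation_hand_oracle():
    z = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [4.0, 3.0, 2.0, 1.0], [1.0, -1.0, 2.0, 0.5]],
        index=["g1", "g2", "g3", "g4"],
        columns=["t1", "t2", "t3", "t4"],
    )
    awm = mk.AWMatrix(
        z=z,
        key_trait="t1",
        ap=0.0,
        snp_of_gene=pd.Series(["s1", "s2", "s3", "s4"], index=z.index),
        mask=pd.DataFrame(False, index=z.index, columns=z.columns),
        selection=pd.DataFrame(),
    )
    corr = mk.pairwise_correlation(awm)
    assert corr.loc["g1", "g2"] == pytest.approx(1.0)    # duplicated direction
    assert corr.loc["g1", "g3"] == pytest.approx(-1.0)   # exact negation
    expected = np.corrcoef(z.to_numpy())
    np.testing.assert_allclose(corr.to_numpy(), expected, atol=1e-12)


def test_pairwise_correlation_constant_row_raises():
    z = pd.DataFrame(
        [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "g2"], columns=["a", "b", "c"]
    )
    awm = mk.AWMatrix(
        z=z,
        key_trait="a",
        ap=0.0,
        snp_of_gene=pd.Series(["s1", "s2"], index=z.index),
        mask=pd.DataFrame(False, index=z.index, columns=z.columns),
        selection=pd.DataFrame(),
    )
    with pytest.raises(ValueError, match="flat"):
        mk.pairwise_correlation(awm)


def test_sif_export(tmp_path):
    net = _net_from_edges([("A", "B", 0.9), ("B", "C", -0.9)])
    mk.network.write_sif(net, tmp_path / "n.sif")
    assert (tmp_path / "n.sif").read_text() == "A\tr\tB\nB\tr\tC\n"
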