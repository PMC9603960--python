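"""Correlation statistics, pair gates with strict boundaries, triplet
assembly vs brute force, network construction and hubs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cernakit as ck
from cernakit.model import CernakitError, CorrelationEdge, TargetPair

from conftest import make_matrix

# integer witnesses whose correlations are float-exact at the thresholds
RANKS_X11 = list(range(1, 12))
PERM_SCC_M070 = [9, 10, 11, 6, 2, 8, 5, 4, 3, 7, 1]        # SCC exactly -0.7
PERM_SCC_M0709 = [11, 6, 9, 10, 8, 5, 2, 4, 1, 7, 3]       # SCC ~ -0.709
VEC_X6 = [-4, -4, 1, 2, 2, 3]
VEC_PCC_090 = [-5, -2, 1, 0, 2, 4]                          # PCC exactly 0.9
VEC_PCC_092 = [-5, -2, 0, 1, 2, 4]                          # PCC = 0.92


class TestSpearman:
    def test_reversal(self):
        assert ck.spearman([1, 2, 3], [3, 2, 1]) == -1.0

    def test_single_swap_half(self):
        # 1 - 6*2/(3*8) by the sum-of-squared-rank-differences formula
        assert ck.spearman([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_self_correlation(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert ck.spearman(x, x) == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        assert ck.spearman([1, 1, 1, 1], [1, 2, 3, 4]) is None

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.integers(0, 5, size=8).astype(float)
            y = rng.integers(0, 5, size=8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert ck.spearman(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12
            )

    def test_exact_boundary_values(self):
        assert ck.spearman(RANKS_X11, PERM_SCC_M070) == -0.7
        assert ck.spearman(RANKS_X11, PERM_SCC_M0709) < -0.7


class TestPearson:
    def test_affine(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert ck.pearson(x, [3 * v + 1 for v in x]) == pytest.approx(1.0)
        assert ck.pearson(x, [-2 * v for v in x]) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x, y = rng.random(6), rng.random(6)
            xc, yc = x - x.mean(), y - y.mean()
            expect = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert ck.pearson(x, y) == pytest.approx(expect, abs=1e-12)

    def test_exact_boundary_values(self):
        assert ck.pearson(VEC_X6, VEC_PCC_090) == 0.9
        assert ck.pearson(VEC_X6, VEC_PCC_092) == pytest.approx(0.92)

    def test_too_short_rejected(self):
        with pytest.raises(CernakitError):
            ck.pearson([1, 2], [3, 4])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(-50, 50), min_size=3, max_size=12).flatmap(
    lambda xs: st.tuples(
        st.just(xs),
        st.lists(st.integers(-50, 50), min_size=len(xs), max_size=len(xs)),
    )
))
def test_correlations_bounded_and_symmetric(pair):
    x, y = pair
    r = ck.pearson(x, y)
    if r is not None:
        assert -1.0 <= r <= 1.0
        assert ck.pearson(y, x) == pytest.approx(r, abs=1e-12)
    s = ck.spearman(x, y)
    if s is not None:
        assert -1.0 <= s <= 1.0
        assert ck.spearman(y, x) == pytest.approx(s, abs=1e-12)


def _layers_from_rows(rows):
    # single shared layer; values shifted to be non-negative
    arr = np.asarray(list(rows.values()), dtype=float)
    arr = arr - arr.min() + 1.0
    return {"all": make_matrix(arr, list(rows.keys()))}


class TestPairGates:
    def test_scc_boundary_strict(self):
        layers = _layers_from_rows({
            "mirA": RANKS_X11, "tgt070": PERM_SCC_M070,
            "tgt0709": PERM_SCC_M0709,
        })
        pairs = [TargetPair("mirA", "tgt070"), TargetPair("mirA", "tgt0709")]
        edges = ck.negative_pairs(layers, pairs, scc_max=-0.7)
        assert [e.id_b for e in edges] == ["tgt0709"]

    def test_positive_scc_dropped(self):
        layers = _layers_from_rows({"mirA": [1, 2, 3, 4, 5, 6],
                                    "t": [1, 2, 3, 4, 5, 7]})
        assert ck.negative_pairs(layers, [TargetPair("mirA", "t")]) == []

    def test_pcc_boundary_strict(self):
        layers = _layers_from_rows({
            "c": VEC_X6, "m090": VEC_PCC_090, "m092": VEC_PCC_092,
        })
        edges = ck.positive_pairs(layers, [("c", "m090"), ("c", "m092")],
                                  pcc_min=0.9)
        assert [(e.id_a, e.id_b) for e in edges] == [("c", "m092")]

    def test_anticorrelated_pcc_dropped(self):
        layers = _layers_from_rows({"c": [1, 2, 3, 4, 5, 6],
                                    "m": [6, 5, 4, 3, 2, 1]})
        assert ck.positive_pairs(layers, [("c", "m")]) == []

    def test_de_gate_applied(self):
        layers = _layers_from_rows({"mirA": [6, 5, 4, 3, 2, 1],
                                    "t": [1, 2, 3, 4, 5, 6]})
        pairs = [TargetPair("mirA", "t")]
        assert ck.negative_pairs(layers, pairs,
                                 de_status={"mirA": "up", "t": "down"})
        assert ck.negative_pairs(layers, pairs,
                                 de_status={"mirA": "up", "t": "ns"}) == []

    def test_missing_feature_named(self):
        layers = _layers_from_rows({"mirA": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(CernakitError, match="ghost"):
            ck.negative_pairs(layers, [TargetPair("mirA", "ghost")])

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(12)
        n = 40
        rows = {f"mir{i}": rng.random(6) for i in range(10)}
        rows.update({f"g{i}": rng.random(6) for i in range(30)})
        layers = _layers_from_rows(rows)
        pairs = [TargetPair(f"mir{rng.integers(10)}", f"g{rng.integers(30)}")
                 for _ in range(100)]
        pairs = list({p.key: p for p in pairs}.values())
        got = {(e.id_a, e.id_b) for e in
               ck.negative_pairs(layers, pairs, scc_max=-0.3)}
        vals = layers["all"].values
        expect = set()
        for p in pairs:
            rho = stats.spearmanr(vals.loc[p.mirna_id],
                                  vals.loc[p.target_id]).statistic
            if rho < -0.3:
                expect.add(p.key)
        assert got == expect


def brute_force_triplets(neg, pos, targeted, biotypes):
    """O(n^3) enumeration over all id combinations."""
    neg_set = {(e.id_a, e.id_b) for e in neg}
    pos_set = set()
    for e in pos:
        pos_set |= {(e.id_a, e.id_b), (e.id_b, e.id_a)}
    ids = sorted(biotypes)
    out = set()
    for c in ids:
        if biotypes[c] not in ("lncRNA", "circRNA"):
            continue
        for m in ids:
            if biotypes[m] != "miRNA":
                continue
            for g in ids:
                if biotypes[g] != "mRNA":
                    continue
                if ((m, c) in neg_set and (m, g) in neg_set
                        and (m, c) in targeted and (m, g) in targeted
                        and ((c, g) in pos_set)):
                    out.add((c, m, g))
    return out


def random_instance(rng, n_nodes=30):
    n_mir = max(1, n_nodes // 5)
    n_cer = max(1, n_nodes // 3)
    n_mrna = max(1, n_nodes - n_mir - n_cer)
    biotypes = {}
    for i in range(n_mir):
        biotypes[f"m{i}"] = "miRNA"
    for i in range(n_cer):
        biotypes[f"c{i}"] = "lncRNA" if i % 2 else "circRNA"
    for i in range(n_mrna):
        biotypes[f"g{i}"] = "mRNA"
    mirs = [k for k, v in biotypes.items() if v == "miRNA"]
    cers = [k for k, v in biotypes.items() if v in ("lncRNA", "circRNA")]
    genes = [k for k, v in biotypes.items() if v == "mRNA"]
    p_neg, p_pos, p_tgt = rng.random(3) * 0.6 + 0.1
    neg, targeted = [], set()
    for m in mirs:
        for t in cers + genes:
            if rng.random() < p_tgt:
                targeted.add((m, t))
            if rng.random() < p_neg:
                neg.append(CorrelationEdge(m, t, "SCC",
                                           -0.71 - 0.2 * rng.random(), 6))
    pos = []
    for c in cers:
        for g in genes:
            if rng.random() < p_pos:
                pos.append(CorrelationEdge(c, g, "PCC",
                                           0.91 + 0.05 * rng.random(), 6))
    pairs = [TargetPair(m, t) for (m, t) in sorted(targeted)]
    return neg, pos, pairs, biotypes, targeted


class TestAssembleTriplets:
    def test_no_positive_edges_empty(self):
        neg = [CorrelationEdge("m1", "c1", "SCC", -0.9, 6),
               CorrelationEdge("m1", "g1", "SCC", -0.8, 6)]
        bt = {"m1": "miRNA", "c1": "lncRNA", "g1": "mRNA"}
        pairs = [TargetPair("m1", "c1"), TargetPair("m1", "g1")]
        assert ck.assemble_triplets(neg, [], pairs, bt) == []

    def test_single_sponge_triplet(self):
        neg = [CorrelationEdge("mirX", "lncX", "SCC", -0.95, 6),
               CorrelationEdge("mirX", "geneX", "SCC", -0.91, 6)]
        pos = [CorrelationEdge("lncX", "geneX", "PCC", 0.97, 6)]
        pairs = [TargetPair("mirX", "lncX"), TargetPair("mirX", "geneX")]
        bt = {"mirX": "miRNA", "lncX": "lncRNA", "geneX": "mRNA"}
        (t,) = ck.assemble_triplets(neg, pos, pairs, bt)
        assert t.key == ("lncX", "mirX", "geneX")
        assert (t.scc_mirna_cerna, t.scc_mirna_mrna, t.pcc_cerna_mrna) == \
               (-0.95, -0.91, 0.97)

    def test_untargeted_pair_excluded(self):
        neg = [CorrelationEdge("m1", "c1", "SCC", -0.9, 6),
               CorrelationEdge("m1", "g1", "SCC", -0.8, 6)]
        pos = [CorrelationEdge("c1", "g1", "PCC", 0.95, 6)]
        bt = {"m1": "miRNA", "c1": "lncRNA", "g1": "mRNA"}
        # m1 -> g1 never predicted as a target
        assert ck.assemble_triplets(neg, pos, [TargetPair("m1", "c1")],
                                    bt) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        neg, pos, pairs, bt, targeted = random_instance(
            rng, n_nodes=int(rng.integers(6, 50)))
        got = {t.key for t in ck.assemble_triplets(neg, pos, pairs, bt)}
        assert got == brute_force_triplets(neg, pos, targeted, bt)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(55)
        neg, pos, pairs, bt, _ = random_instance(rng, n_nodes=25)
        a = ck.assemble_triplets(neg, pos, pairs, bt)
        rng.shuffle(neg)
        rng.shuffle(pos)
        b = ck.assemble_triplets(neg, pos, pairs, bt)
        assert a == b

    def test_threshold_monotonicity(self):
        # tightening gates never adds a triplet; relaxing never removes one
        rng = np.random.default_rng(66)
        rows = {f"mir{i}": rng.random(6) for i in range(6)}
        rows.update({f"c{i}": rng.random(6) for i in range(8)})
        rows.update({f"g{i}": rng.random(6) for i in range(10)})
        layers = _layers_from_rows(rows)
        bt = {k: ("miRNA" if k.startswith("mir") else
                  "lncRNA" if k.startswith("c") else "mRNA") for k in rows}
        pairs = [TargetPair(m, t) for m in rows if m.startswith("mir")
                 for t in rows if not t.startswith("mir")]
        cand = [(c, g) for c in rows if c.startswith("c")
                for g in rows if g.startswith("g")]
        def run(scc_max, pcc_min):
            neg = ck.negative_pairs(layers, pairs, scc_max=scc_max)
            pos = ck.positive_pairs(layers, cand, pcc_min=pcc_min)
            return {t.key for t in ck.assemble_triplets(neg, pos, pairs, bt)}
        loose = run(-0.1, 0.1)
        mid = run(-0.3, 0.3)
        tight = run(-0.6, 0.6)
        assert tight <= mid <= loose


class TestBuildNetwork:
    def test_one_triplet(self):
        net = ck.build_network(
            [ck.CeRNATriplet("c1", "circRNA", "m1", "g1", -0.9, -0.8, 0.95)]
        )
        assert (net.n_nodes, net.n_edges) == (3, 3)
        assert net.nodes == {"c1": "circRNA", "m1": "miRNA", "g1": "mRNA"}

    def test_shared_edge_deduplicated(self):
        trips = [
            ck.CeRNATriplet("c1", "lncRNA", "m1", "g1", -0.9, -0.8, 0.95),
            ck.CeRNATriplet("c2", "lncRNA", "m1", "g1", -0.85, -0.8, 0.93),
        ]
        net = ck.build_network(trips)
        # hand dedup: nodes {c1, c2, m1, g1}; the shared m1-g1 edge counts
        # once, so 5 of the 6 triplet edges remain
        assert (net.n_nodes, net.n_edges) == (4, 5)

    def test_stats_match_independent_recount(self):
        rng = np.random.default_rng(77)
        trips = list({t.key: t for t in (
            ck.CeRNATriplet(f"c{rng.integers(12)}", "lncRNA",
                            f"m{rng.integers(8)}", f"g{rng.integers(15)}",
                            -0.9, -0.8, 0.95) for _ in range(40)
        )}.values())
        net = ck.build_network(trips)
        s = ck.network_stats(net)
        ids = set()
        edge_set = set()
        for t in trips:
            ids |= {t.cerna_id, t.mirna_id, t.mrna_id}
            edge_set |= {(t.mirna_id, t.cerna_id, "mirna_ceRNA"),
                         (t.mirna_id, t.mrna_id, "mirna_mRNA"),
                         (t.cerna_id, t.mrna_id, "coexpression")}
        assert s["n_nodes"] == len(ids)
        assert s["n_edges"] == len(edge_set)
        assert s["n_triplets"] == len(trips)
        assert sum(s["nodes_by_type"].values()) == s["n_nodes"]


class TestFindHubs:
    def test_star_center(self):
        edges = [("hub", "a"), ("hub", "b"), ("hub", "c")]
        assert ck.find_hubs(edges) == ["hub"]

    def test_cycle_has_no_hubs(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
        assert ck.find_hubs(edges) == []

    def test_self_loop_rejected(self):
        with pytest.raises(CernakitError):
            ck.find_hubs([("a", "a")])

    def test_matches_degree_recount(self):
        rng = np.random.default_rng(88)
        nodes = [f"n{i}" for i in range(30)]
        edges = set()
        while len(edges) < 60:
            a, b = rng.choice(nodes, size=2, replace=False)
            edges.add(tuple(sorted((a, b))))
        hubs = ck.find_hubs(sorted(edges))
        deg = {}
        for a, b in edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        assert set(hubs) == {n for n, d in deg.items() if d >= 3}
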