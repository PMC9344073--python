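import math
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from grntransfer.annotation_io import GRN, RegulatoryInteraction
from grntransfer.errors import UsageError
from grntransfer.network_eval import (
    N_TRIAD_CLASSES,
    RandomizationConfig,
    compare_edges,
    compare_graphlets,
    compute_metrics,
    consensus_rename,
    enumerate_graphlets,
    g_test,
    null_distribution,
    observed_counts,
    randomize_tf_labels,
)
from grntransfer.orthology import OrthologMap

from conftest import make_grn, random_grn

# Published edge- and graphlet-level comparison counts with the P/R/F1
# values printed alongside them; our formulas must reproduce each value
# at its printed precision.
EDGE_ROWS = [
    # organism, tp, fp, fn, recall, precision, f1
    ("B. subtilis", 254, 499, 2447, 0.094, 0.3373, 0.147),
    ("E. coli", 1538, 709, 1971, 0.4383, 0.6845, 0.5344),
    # the published F1 for this row (0.0822) disagrees with its own
    # printed counts: 2*51/(2*51+202+938) = 102/1242 = 0.0821
    ("P. aeruginosa", 51, 202, 938, 0.0516, 0.2016, 0.0821),
    ("S. typhimurium", 1491, 666, 1394, 0.5168, 0.6912, 0.5914),
    ("S. aureus", 229, 237, 466, 0.3295, 0.4914, 0.3945),
    ("M. tuberculosis", 71, 138, 2494, 0.0277, 0.3397, 0.0512),
]

GRAPHLET_ROWS = [
    ("B. subtilis", 2241, 10008, 145210, 0.0152, 0.183, 0.0281),
    ("E. coli", 57366, 38545, 185907, 0.2358, 0.5981, 0.3383),
    ("P. aeruginosa", 101, 2815, 12989, 0.0077, 0.0346, 0.0126),
    ("S. typhimurium", 56206, 50622, 134678, 0.2945, 0.5261, 0.3776),
    ("S. aureus", 2087, 5176, 19578, 0.0963, 0.2873, 0.1443),
    ("M. tuberculosis", 215, 1876, 234607, 0.0009, 0.1028, 0.0018),
]


def printed_close(computed: float, printed: float) -> bool:
    """Agreement at the precision the value was printed with."""
    decimals = len(str(printed).split(".")[1])
    return abs(computed - printed) <= 0.5 * 10 ** -decimals + 1e-12


class TestComputeMetrics:
    @pytest.mark.parametrize("org,tp,fp,fn,r,p,f1", EDGE_ROWS)
    def test_reproduces_published_edge_metrics(self, org, tp, fp, fn, r, p, f1):
        precision, recall, f1_ = compute_metrics(tp, fp, fn)
        assert printed_close(precision, p)
        assert printed_close(recall, r)
        assert printed_close(f1_, f1)

    @pytest.mark.parametrize("org,tp,fp,fn,r,p,f1", GRAPHLET_ROWS)
    def test_reproduces_published_graphlet_metrics(self, org, tp, fp, fn, r, p, f1):
        precision, recall, f1_ = compute_metrics(tp, fp, fn)
        assert printed_close(precision, p)
        assert printed_close(recall, r)
        assert printed_close(f1_, f1)

    def test_zero_counts_convention(self):
        assert compute_metrics(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_symmetric_half_case(self):
        assert compute_metrics(1, 1, 1) == (0.5, 0.5, 0.5)

    def test_negative_count_rejected(self):
        with pytest.raises(UsageError):
            compute_metrics(-1, 0, 0)

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(50):
            tp, fp, fn = (int(x) for x in rng.integers(0, 500, size=3))
            p, r, f1 = compute_metrics(tp, fp, fn)
            if p + r > 0:
                assert math.isclose(f1, 2 * p * r / (p + r))
                assert f1 <= min(2 * p, 2 * r) + 1e-12
                assert min(p, r) >= f1 / 2 - 1e-12


class TestCompareEdges:
    def test_identical_networks(self):
        grn = make_grn("o", [("a", "b"), ("c", "d")])
        cmp_ = compare_edges(grn, grn)
        assert (cmp_.tp, cmp_.fp, cmp_.fn) == (2, 0, 0)
        assert (cmp_.precision, cmp_.recall, cmp_.f1) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_set_algebra(self, trial):
        rng = np.random.default_rng(trial)
        ref = random_grn(rng, organism="r")
        pred = random_grn(rng, organism="p")
        cmp_ = compare_edges(ref, pred)
        er, ep = ref.edges(), pred.edges()
        assert (cmp_.tp, cmp_.fp, cmp_.fn) == (
            len(er & ep), len(ep - er), len(er - ep),
        )

    def test_swap_symmetry(self, rng):
        ref = random_grn(rng, organism="r")
        pred = random_grn(rng, organism="p")
        fwd = compare_edges(ref, pred)
        rev = compare_edges(pred, ref)
        assert (fwd.tp, fwd.fp, fwd.fn) == (rev.tp, rev.fn, rev.fp)
        assert (fwd.precision, fwd.recall) == (rev.recall, rev.precision)
        assert math.isclose(fwd.f1, rev.f1)

    def test_tn_needs_universe(self):
        grn = make_grn("o", [("a", "b")])
        assert compare_edges(grn, grn).tn is None
        assert compare_edges(grn, grn, node_universe=10).tn == 9


class TestGraphlets:
    def test_feed_forward_loop(self):
        grn = make_grn("o", [("x", "y"), ("x", "z"), ("y", "z")])
        (inst,) = enumerate_graphlets(grn)
        assert inst.motif_class == "030T"
        assert inst.nodes == frozenset({"x", "y", "z"})

    def test_cascade(self):
        grn = make_grn("o", [("x", "y"), ("y", "z")])
        (inst,) = enumerate_graphlets(grn)
        assert inst.motif_class == "021C"

    def test_self_loops_ignored(self):
        grn = make_grn("o", [("x", "x"), ("x", "y"), ("y", "z")])
        (inst,) = enumerate_graphlets(grn)
        assert inst.motif_class == "021C"

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_triple_scan(self, trial):
        rng = np.random.default_rng(900 + trial)
        n = int(rng.integers(5, 13))
        nodes = [f"n{i}" for i in range(n)]
        edges = {
            (u, v)
            for u in nodes
            for v in nodes
            if u != v and rng.random() < 0.25
        }
        grn = make_grn("o", sorted(edges))
        got = {
            (inst.nodes, inst.motif_class) for inst in enumerate_graphlets(grn)
        }
        # oracle: classify every C(n,3) triple with networkx triad_type
        g = nx.DiGraph(sorted(edges))
        g.add_nodes_from(nodes)
        expected = set()
        for triple in combinations(nodes, 3):
            sub = g.subgraph(triple)
            t = nx.triad_type(sub)
            if t not in ("003", "012", "102"):
                expected.add((frozenset(triple), t))
        assert got == expected

    def test_identical_networks_graphlet_f1_is_one(self, rng):
        grn = random_grn(rng)
        cmp_ = compare_graphlets(grn, grn)
        assert cmp_.fp == cmp_.fn == 0 and cmp_.f1 == 1.0

    @pytest.mark.parametrize("trial", range(5))
    def test_counts_match_instance_set_algebra(self, trial):
        rng = np.random.default_rng(300 + trial)
        ref = random_grn(rng, organism="r", n_genes=10, n_edges=15)
        pred = random_grn(rng, organism="p", n_genes=10, n_edges=15)
        cmp_ = compare_graphlets(ref, pred)
        gr = enumerate_graphlets(ref)
        gp = enumerate_graphlets(pred)
        assert (cmp_.tp, cmp_.fp, cmp_.fn) == (
            len(gr & gp), len(gp - gr), len(gr - gp),
        )
        n = len(ref.genes | pred.genes)
        universe = math.comb(n, 3) * N_TRIAD_CLASSES
        assert cmp_.tp + cmp_.fp + cmp_.fn + cmp_.tn == universe


class TestConsensusRename:
    def test_orthologous_edge_becomes_identical(self):
        g1 = make_grn("A", [("a_tf", "a_tg")])
        g2 = make_grn("B", [("b_tf", "b_tg")])
        omap = OrthologMap(
            "A", "B", pairs=[("a_tf", "b_tf", 1, 1), ("a_tg", "b_tg", 1, 1)]
        )
        r1, r2 = consensus_rename([g1, g2], [omap])
        assert r1.edges() == r2.edges() == {("a_tf", "a_tg")}

    def test_no_orthology_leaves_names(self):
        g1 = make_grn("A", [("x", "y")])
        (r1,) = consensus_rename([g1], [])
        assert r1.edges() == {("x", "y")}

    def test_groups_equal_connected_components(self, rng):
        # three genomes with random pairings; oracle = union-find via networkx
        genes = {o: [f"{o}_g{i}" for i in range(12)] for o in "ABC"}
        maps = []
        pair_graph = nx.Graph()
        for a, b in [("A", "B"), ("B", "C"), ("A", "C")]:
            pairs = []
            used_b = set()
            for ga in genes[a]:
                if rng.random() < 0.5:
                    gb = f"{b}_g{int(rng.integers(0, 12))}"
                    if gb in used_b:
                        continue
                    used_b.add(gb)
                    pairs.append((ga, gb, 1.0, 1.0))
                    pair_graph.add_edge(ga, gb)
            maps.append(OrthologMap(a, b, pairs=pairs))
        grns = [
            make_grn(o, [(genes[o][i], genes[o][i + 1]) for i in range(0, 10, 2)])
            for o in "ABC"
        ]
        renamed = consensus_rename(grns, maps)
        canonical = {}
        for comp in nx.connected_components(pair_graph):
            rep = min(comp)
            for g in comp:
                canonical[g] = rep
        for orig, ren in zip(grns, renamed):
            expected = {
                (canonical.get(tf, tf), canonical.get(tg, tg))
                for tf, tg in orig.edges()
            }
            assert ren.edges() == expected


class TestRandomization:
    def test_single_tf_identity(self):
        grn = make_grn("o", [("tf1", "a"), ("tf1", "b")])
        for rep in randomize_tf_labels(grn, RandomizationConfig(5, seed=1)):
            assert rep.edges() == grn.edges()

    def test_two_tf_swap_frequency(self):
        grn = make_grn("o", [("tf1", "a"), ("tf2", "b")])
        n = 400
        swaps = sum(
            rep.edges() == {("tf2", "a"), ("tf1", "b")}
            for rep in randomize_tf_labels(grn, RandomizationConfig(n, seed=3))
        )
        # binomial(400, 0.5): 4 sigma band
        assert abs(swaps - n / 2) < 4 * math.sqrt(n * 0.25)

    def test_replicates_preserve_characteristics(self, rng):
        grn = random_grn(rng, n_tfs=4, n_genes=12, n_edges=18)
        for rep in randomize_tf_labels(grn, RandomizationConfig(10, seed=5)):
            assert len(rep) == len(grn)
            assert rep.tfs == grn.tfs
            assert rep.genes == grn.genes
            assert sorted(
                rep.to_networkx().out_degree(t) for t in rep.tfs
            ) == sorted(grn.to_networkx().out_degree(t) for t in grn.tfs)

    def test_reproducible_from_seed(self, rng):
        grn = random_grn(rng)
        a = [r.edges() for r in randomize_tf_labels(grn, RandomizationConfig(5, 42))]
        b = [r.edges() for r in randomize_tf_labels(grn, RandomizationConfig(5, 42))]
        assert a == b


class TestGTest:
    def test_perfect_fit(self):
        g, p = g_test([10, 10], [10, 10])
        assert g == 0.0 and p == 1.0

    def test_hand_evaluated_statistic(self):
        g, p = g_test([12, 8], [10, 10])
        expected = 2 * (12 * math.log(12 / 10) + 8 * math.log(8 / 10))
        assert math.isclose(g, expected)
        assert math.isclose(p, float(stats.chi2.sf(expected, df=1)))

    def test_matches_scipy_when_sums_agree(self, rng):
        obs = rng.integers(1, 50, size=4).astype(float)
        exp = obs.mean() * np.ones(4)
        g, p = g_test(obs, exp)
        res = stats.power_divergence(obs, exp, lambda_="log-likelihood")
        assert math.isclose(g, float(res.statistic))
        assert math.isclose(p, float(res.pvalue))

    def test_zero_observed_contributes_nothing(self):
        g, _ = g_test([0, 20], [10, 10])
        assert math.isclose(g, 2 * 20 * math.log(2))

    def test_zero_expected_with_observed_raises(self):
        with pytest.raises(UsageError):
            g_test([5, 5], [0, 10])


class TestNullDistribution:
    def test_identity_prediction_beats_null(self, rng):
        grn = random_grn(rng, n_tfs=5, n_genes=20, n_edges=30)
        expected, _ = null_distribution(
            grn, grn, RandomizationConfig(100, seed=1)
        )
        observed = observed_counts(grn, grn)
        assert observed[0] > expected[0]  # TP under randomization collapses

    def test_single_replicate_deterministic(self, rng):
        ref = random_grn(rng, organism="r")
        pred = random_grn(rng, organism="p")
        e1, r1 = null_distribution(ref, pred, RandomizationConfig(1, seed=9))
        e2, r2 = null_distribution(ref, pred, RandomizationConfig(1, seed=9))
        assert np.array_equal(r1, r2) and np.array_equal(e1, e2)

    def test_mean_tp_matches_exhaustive_permutation(self):
        # <=4 TFs: enumerate all TF-label permutations exactly
        rng = np.random.default_rng(77)
        ref = random_grn(rng, organism="net", n_tfs=4, n_genes=10, n_edges=12)
        pred = random_grn(rng, organism="net", n_tfs=4, n_genes=10, n_edges=12)
        tfs = sorted(pred.tfs)
        tps = []
        for perm in permutations(range(len(tfs))):
            relabel = {tfs[i]: tfs[perm[i]] for i in range(len(tfs))}
            edges = {(relabel[tf], tg) for tf, tg in pred.edges()}
            tps.append(len(edges & ref.edges()))
        exact_mean = np.mean(tps)
        _, reps = null_distribution(
            ref, pred, RandomizationConfig(200, seed=4), include_tn=False
        )
        se = np.std(tps) / math.sqrt(200)
        assert abs(reps[:, 0].mean() - exact_mean) <= 3 * se + 1e-9
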