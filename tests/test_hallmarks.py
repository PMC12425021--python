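"""Hallmark gene sets, LCC modules, separation, overlap, longevity module."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sharp.hallmarks import (
    HALLMARKS,
    annotations_from_gmt,
    build_hallmark_sets,
    jaccard_overlap,
    largest_connected_component,
    lcc_significance,
    longevity_module,
    separation,
    validate_annotations,
)
from sharp.netcore import (
    DegreeMatchedSampler,
    Interactome,
    build_degree_bins,
    min_dist_to_set,
    spawn_seeds,
)

from conftest import heavy_tail_net, random_net

SEN = "Cell senescence"
GEN = "Genomic instability"


def ann_df(rows):
    return pd.DataFrame(rows, columns=["gene", "hallmark", "confidence"])


class TestAnnotations:
    def test_unknown_hallmark_lists_valid_names(self):
        df = ann_df([("X", "Not a hallmark", 1)])
        with pytest.raises(ValueError, match="Genomic instability"):
            validate_annotations(df)

    def test_duplicate_pair_rejected(self):
        df = ann_df([("X", SEN, 1), ("X", SEN, 2)])
        with pytest.raises(ValueError, match="duplicate"):
            validate_annotations(df)

    def test_confidence_range_enforced(self):
        with pytest.raises(ValueError, match="1-5"):
            validate_annotations(ann_df([("X", SEN, 6)]))

    def test_gmt_assembly_keeps_strongest_level(self, tmp_path):
        (tmp_path / "l1.gmt").write_text(f"{SEN}\tna\tA\tB\n")
        (tmp_path / "l3.gmt").write_text(f"{SEN}\tna\tB\tC\n")
        df = annotations_from_gmt({1: tmp_path / "l1.gmt",
                                   3: tmp_path / "l3.gmt"})
        conf = df.set_index("gene")["confidence"]
        assert conf["A"] == 1 and conf["B"] == 1 and conf["C"] == 3


class TestHallmarkSets:
    @pytest.fixture
    def net(self):
        return Interactome.from_edges(
            [(a, b) for a, b in zip("XYZWQ", "YZWQX")])

    def test_cumulative_rule(self, net):
        df = ann_df([("X", SEN, 2)])
        for level in (2, 3, 4, 5):
            assert "X" in build_hallmark_sets(df, net, level)[SEN].genes
        assert "X" not in build_hallmark_sets(df, net, 1)[SEN].genes

    def test_monotone_nesting(self, net):
        rng = np.random.default_rng(0)
        df = ann_df([(g, SEN, int(rng.integers(1, 6))) for g in "XYZWQ"])
        sets = [build_hallmark_sets(df, net, l)[SEN].genes for l in range(1, 6)]
        for lo, hi in zip(sets, sets[1:]):
            assert lo <= hi

    def test_empty_level_warns(self, net):
        df = ann_df([("X", "Disabled macroautophagy", 2)])
        with pytest.warns(UserWarning, match="no genes at confidence level 1"):
            sets = build_hallmark_sets(df, net, 1)
        assert sets["Disabled macroautophagy"].genes == frozenset()

    def test_absent_genes_reported_not_dropped_silently(self, net):
        df = ann_df([("X", SEN, 1), ("NOT_IN_NET", SEN, 1)])
        hs = build_hallmark_sets(df, net, 5)[SEN]
        assert hs.genes == {"X"}
        assert hs.absent == {"NOT_IN_NET"}

    def test_sizes_match_brute_force_filter(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(100)]
        net = Interactome.from_edges(
            [(genes[i], genes[(i + 1) % 100]) for i in range(100)])
        rows = [(g, rng.choice(HALLMARKS), int(rng.integers(1, 6)))
                for g in genes]
        df = ann_df(rows)
        for level in (1, 3, 5):
            sets = build_hallmark_sets(df, net, level)
            for h in HALLMARKS:
                expected = {g for g, hm_, c in rows
                            if hm_ == h and c <= level}
                assert sets[h].genes == expected


class TestLCC:
    def test_clique_is_whole_set(self):
        net = Interactome(nx.complete_graph(["a", "b", "c", "d"]))
        assert largest_connected_component(net, {"a", "b", "c"}) == {
            "a", "b", "c"}

    def test_no_induced_edges_lexicographic_tiebreak(self):
        net = Interactome.from_edges([("a", "x"), ("b", "x"), ("c", "x")])
        assert largest_connected_component(net, {"c", "b", "a"}) == {"a"}

    def test_empty_input(self, path_net=None):
        net = Interactome.from_edges([("a", "b")])
        assert largest_connected_component(net, set()) == set()

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(17)
        for seed in range(10):
            net = random_net(40, 0.08, seed=seed)
            genes = set(rng.choice(sorted(net.node_set), size=15,
                                   replace=False))
            # independent union-find oracle on the induced edges
            parent = {g: g for g in genes}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v in net.graph.edges:
                if u in genes and v in genes:
                    parent[find(u)] = find(v)
            comps = {}
            for g in genes:
                comps.setdefault(find(g), set()).add(g)
            best = max(len(c) for c in comps.values())
            result = largest_connected_component(net, genes)
            assert len(result) == best
            assert result in comps.values()


class TestLCCSignificance:
    def test_planted_clique_is_significant(self):
        net = heavy_tail_net(2000, seed=3)
        module = sorted(net.node_set)[:20]
        net.graph.add_edges_from(
            (module[i], module[j])
            for i in range(20) for j in range(i + 1, 20))
        res = lcc_significance(net, module, n_random=300, rng_seed=1)
        assert res.observed_size == 20
        assert res.z > 1.96
        assert res.significance == "significant"
        assert res.empirical_p <= 1 / 300 + 1e-9

    def test_whole_node_set_degenerate_null(self):
        net = Interactome(nx.complete_graph(list("abcdef")))
        res = lcc_significance(net, net.node_set, n_random=50, rng_seed=0)
        assert np.isnan(res.z)
        assert 0 <= res.empirical_p <= 1
        assert res.significance == "undefined"

    def test_threshold_semantics(self):
        from sharp.hallmarks import LCCResult

        def mk(z):
            return LCCResult(observed_size=5, members=set(), null_mean=0,
                             null_sd=1, z=z, empirical_p=0.5, n_random=10)

        assert mk(2.0).significance == "significant"
        assert mk(1.74).significance == "marginal"
        assert mk(1.67).significance == "marginal"
        assert mk(1.5).significance == "ns"

    def test_z_calibration_for_degree_matched_draws(self):
        """Random degree-matched gene sets should score z ~ N(0, 1)."""
        net = heavy_tail_net(1200, seed=8)
        bins = build_degree_bins(net, min_occupancy=100)
        rng = np.random.default_rng(2)
        template = list(rng.choice(sorted(net.node_set), size=20,
                                   replace=False))
        sampler = DegreeMatchedSampler(bins, template)
        zs = []
        for seed in spawn_seeds(77, 200):
            genes = sampler.sample(np.random.default_rng(seed))
            res = lcc_significance(net, genes, n_random=300,
                                   rng_seed=int(seed), bins=bins)
            if not np.isnan(res.z):
                zs.append(res.z)
        zs = np.array(zs)
        assert abs(zs.mean()) <= 0.15
        assert 0.8 <= zs.std() <= 1.2


class TestSeparation:
    def test_self_separation_is_zero(self):
        net = random_net(30, 0.15, seed=4)
        genes = sorted(net.node_set)[:8]
        res = separation(net, genes, genes)
        assert res.s_ab == pytest.approx(0.0)
        assert res.d_ab == pytest.approx(res.d_aa)

    def test_path_endpoints(self, path_net):
        res = separation(path_net, {"a"}, {"d"})
        assert (res.d_aa, res.d_bb, res.d_ab) == (0.0, 0.0, 3.0)
        assert res.s_ab == 3.0

    def test_two_cliques_with_bridge_match_bfs_oracle(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        g = nx.Graph()
        g.add_edges_from((x, y) for i, x in enumerate(a) for y in a[i + 1:])
        g.add_edges_from((x, y) for i, x in enumerate(b) for y in b[i + 1:])
        g.add_edge("a0", "b0")
        net = Interactome(g)
        res = separation(net, a, b)
        # oracle: exhaustive BFS under the nearest-neighbour convention
        spl = dict(nx.all_pairs_shortest_path_length(g))

        def nn(sources, targets):
            vals = [min(spl[s][t] for t in set(targets) - {s})
                    for s in sources if set(targets) - {s}]
            return float(np.mean(vals))

        d_aa, d_bb = nn(a, a), nn(b, b)
        d_ab = float(np.mean([min(spl[s][t] for t in set(b) - {s})
                              for s in a]
                             + [min(spl[s][t] for t in set(a) - {s})
                                for s in b]))
        assert res.d_aa == pytest.approx(d_aa)
        assert res.d_bb == pytest.approx(d_bb)
        assert res.d_ab == pytest.approx(d_ab)
        assert res.s_ab == pytest.approx(d_ab - (d_aa + d_bb) / 2)

    def test_symmetry_on_random_instances(self):
        rng = np.random.default_rng(6)
        for seed in range(10):
            net = random_net(40, 0.1, seed=seed)
            nodes = sorted(net.node_set)
            a = set(rng.choice(nodes, size=6, replace=False))
            b = set(rng.choice(nodes, size=8, replace=False))
            assert (separation(net, a, b).s_ab
                    == pytest.approx(separation(net, b, a).s_ab))

    def test_fully_unreachable_sets_flagged_infinite(self):
        net = Interactome.from_edges([("a", "b"), ("c", "d")])
        res = separation(net, {"a", "b"}, {"c", "d"})
        assert np.isinf(res.s_ab)
        assert res.n_unreachable > 0


class TestJaccard:
    def test_definition_examples(self):
        uni = {f"u{i}" for i in range(100)}
        a = {f"u{i}" for i in range(20)}
        b = {f"u{i}" for i in range(10, 40)}
        res = jaccard_overlap(a, b, uni, n_random=50, rng_seed=0)
        assert res.jaccard == pytest.approx(10 / 40)
        assert res.n_common == 10
        assert jaccard_overlap(a, a, uni, n_random=50).jaccard == 1.0
        disjoint = {f"u{i}" for i in range(50, 60)}
        assert jaccard_overlap(a, disjoint, uni, n_random=50).jaccard == 0.0

    def test_empty_union_convention(self):
        assert jaccard_overlap(set(), set(), {"x"}, n_random=10).jaccard == 0.0

    def test_large_overlap_significant_random_not(self):
        uni = {f"u{i}" for i in range(200)}
        a = {f"u{i}" for i in range(20)}
        b = {f"u{i}" for i in range(15)} | {"u100", "u101", "u102"}
        res = jaccard_overlap(a, b, uni, n_random=200, rng_seed=1)
        assert res.p_value < 0.05
        rng = np.random.default_rng(3)
        ra = set(rng.choice(sorted(uni), size=20, replace=False))
        rb = set(rng.choice(sorted(uni), size=18, replace=False))
        assert jaccard_overlap(ra, rb, uni, n_random=200,
                               rng_seed=1).p_value > 0.05


class TestLongevityModule:
    def test_union_of_overlapping_modules_with_connector(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        g = nx.Graph()
        g.add_edges_from((x, y) for i, x in enumerate(a) for y in a[i + 1:])
        g.add_edges_from((x, y) for i, x in enumerate(b) for y in b[i + 1:])
        g.add_edge("a0", "link")
        g.add_edge("link", "b0")
        net = Interactome(g)
        sets = {SEN: set(a) | {"link"}, GEN: set(b) | {"link"}}
        module, counts = longevity_module(net, sets)
        assert module == set(a) | set(b) | {"link"}
        assert counts["link"] == 2
        assert counts["a0"] == 1

    def test_single_hallmark_equals_its_lcc(self):
        net = random_net(30, 0.1, seed=5)
        genes = set(sorted(net.node_set)[:10])
        module, counts = longevity_module(net, {SEN: genes})
        assert module == largest_connected_component(net, genes)
        assert all(v == 1 for v in counts.values())
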