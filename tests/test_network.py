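import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from gutlinks import network as nw
from gutlinks.io import Config


def brute_force_spearman_p(x, y):
    """Independent oracle: direct enumeration of all orderings of y."""
    rx = rankdata(x)
    ry = rankdata(y)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))

    obs = rho(rx, ry)
    ge = le = abs_ge = total = 0
    for perm in itertools.permutations(ry):
        r = rho(rx, np.array(perm))
        ge += r >= obs - 1e-12
        le += r <= obs + 1e-12
        abs_ge += abs(r) >= abs(obs) - 1e-12
        total += 1
    one = (ge if obs >= 0 else le) / total
    return obs, one, abs_ge / total


def _group_meta(n=5, place="JM", bw_group="LBW"):
    return pd.DataFrame(
        {
            "sample_id": [f"b{i}_{place}" for i in range(n)],
            "bird_id": [f"b{i}" for i in range(n)],
            "place": place,
            "bw_group": bw_group,
            "body_weight_g": 2200.0 + np.arange(n),
        }
    )


def _rel(rows, meta, names=None):
    rows = np.atleast_2d(rows)
    names = names or [f"g{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=names, columns=list(meta["sample_id"]))


class TestExactSpearman:
    def test_perfect_monotone_five(self):
        res = nw.exact_spearman([1, 2, 3, 4, 5], [2, 4, 5, 7, 9])
        assert res.rho == pytest.approx(1.0)
        assert res.one_sided_p == pytest.approx(1 / 120)
        assert res.method == "exact"

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(6), rng.random(6)
        a = nw.exact_spearman(x, y)
        b = nw.exact_spearman(x[::-1], y)
        # reversing x negates rho against the same y ranks reversed
        c = nw.exact_spearman(-x, y)
        assert c.rho == pytest.approx(-a.rho)
        assert c.two_sided_p == pytest.approx(a.two_sided_p)

    def test_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        for case in range(1000):
            n = int(rng.integers(3, 7))
            x = rng.integers(0, 5, n).astype(float)  # ties common
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = nw.exact_spearman(x, y)
            rho, one, two = brute_force_spearman_p(x, y)
            assert res.rho == pytest.approx(rho)
            assert res.one_sided_p == pytest.approx(one)
            assert res.two_sided_p == pytest.approx(two)

    def test_constant_vector_flagged(self):
        res = nw.exact_spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.method == "undefined"
        assert math.isnan(res.rho)

    def test_large_n_falls_back_to_asymptotic(self):
        rng = np.random.default_rng(2)
        res = nw.exact_spearman(rng.random(20), rng.random(20))
        assert res.method == "asymptotic"


class TestPrevalenceFilter:
    def test_boundary_cases(self):
        meta = _group_meta()
        rel = _rel(
            [[0, 0, 1, 1, 1],  # 3 of 5 -> excluded
             [0, 1, 1, 1, 1],  # exactly 4 -> included
             [1, 1, 1, 1, 1]],
            meta,
        )
        kept = nw.prevalence_filter_group(rel, meta, "JM", "LBW", 4)
        assert kept == ["g1", "g2"]
        assert nw.prevalence_filter_group(rel, meta, "JM", "LBW", 0) == ["g0", "g1", "g2"]

    def test_too_few_samples_rejected(self):
        meta = _group_meta(n=3)
        rel = _rel([[1, 1, 1]], meta)
        with pytest.raises(ValueError, match="fewer than"):
            nw.prevalence_filter_group(rel, meta, "JM", "LBW", 4)


class TestGroupNetwork:
    def test_threshold_rule(self):
        meta = _group_meta()
        # g0 == g1 (rho 1), g2 agrees with g0 on ranks except one swap (rho 0.9)
        rel = _rel([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [1, 2, 3, 5, 4]], meta)
        net = nw.build_group_network(rel, meta, "JM", "LBW", Config())
        assert len(net.edges) == 3
        assert len(net.components) == 1 and set(net.components[0].nodes) == {
            "g0", "g1", "g2"
        }
        assert net.components[0].n_edges == 3

    def test_unreachable_threshold_empties_network(self):
        meta = _group_meta()
        rel = _rel([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]], meta)
        cfg = Config(cooc_edge_rho_min=1.01)
        net = nw.build_group_network(rel, meta, "JM", "LBW", cfg)
        assert net.edges == [] and net.components == []
        assert all(d == 0 for d in net.degrees.values())

    def test_negative_edges_recorded_with_sign(self):
        meta = _group_meta()
        rel = _rel([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]], meta)
        net = nw.build_group_network(rel, meta, "JM", "LBW", Config())
        assert len(net.edges) == 1 and net.edges[0].sign == -1
        no_neg = nw.build_group_network(rel, meta, "JM", "LBW", Config(),
                                        allow_negative=False)
        assert no_neg.edges == []

    def test_equivariant_under_sample_relabeling(self):
        rng = np.random.default_rng(3)
        meta = _group_meta()
        rel = _rel(rng.random((8, 5)) + 0.01, meta)
        net1 = nw.build_group_network(rel, meta, "JM", "LBW", Config())
        perm = rng.permutation(5)
        meta2 = meta.iloc[perm].reset_index(drop=True)
        rel2 = rel.iloc[:, perm]
        net2 = nw.build_group_network(rel2, meta2, "JM", "LBW", Config())
        edges1 = {frozenset((e.a, e.b)) for e in net1.edges}
        edges2 = {frozenset((e.a, e.b)) for e in net2.edges}
        assert edges1 == edges2


class TestMcDegree:
    def test_zero_degree_gives_p_one(self):
        meta = _group_meta()
        rng = np.random.default_rng(4)
        rel = _rel(rng.random((6, 5)), meta)
        cfg = Config(cooc_edge_rho_min=1.01)
        net = nw.build_group_network(rel, meta, "JM", "LBW", cfg)
        p = nw.mc_degree_significance(rel, net, B=199, seed=0)
        assert all(v == 1.0 for v in p.values())

    def test_deterministic_and_floored(self, demo_rel_genus):
        rel, meta = demo_rel_genus
        net = nw.build_group_network(rel, meta, "JC", "LBW", Config())
        p1 = nw.mc_degree_significance(rel, net, B=199, seed=5)
        p2 = nw.mc_degree_significance(rel, net, B=199, seed=5)
        assert p1 == p2
        assert min(p1.values()) >= 1 / 200

    def test_hub_with_five_partners_detected(self):
        # a genus perfectly correlated with 5 partners: MC degree p <= 0.01
        rng = np.random.default_rng(5)
        meta = _group_meta()
        detected = 0
        for sim in range(100):
            base = rng.random(5)
            hub_block = np.vstack([base + 0.001 * i for i in range(6)])
            noise = rng.random((10, 5)) + 0.01
            rel = _rel(np.vstack([hub_block, noise]), meta)
            net = nw.build_group_network(rel, meta, "JM", "LBW", Config())
            p = nw.mc_degree_significance(rel, net, B=1000, seed=sim)
            detected += p["g0"] <= 0.01
        assert detected >= 90

    def test_null_false_positive_rate_bounded(self):
        # 50 independent tables: per-genus degree test flags <= 7% at alpha 0.05
        rng = np.random.default_rng(6)
        meta = _group_meta()
        hits = total = 0
        for sim in range(50):
            rel = _rel(rng.random((25, 5)) + 0.01, meta)
            net = nw.build_group_network(rel, meta, "JM", "LBW", Config())
            p = nw.mc_degree_significance(rel, net, B=199, seed=sim)
            vals = np.array(list(p.values()))
            hits += (vals < 0.05).sum()
            total += len(vals)
        assert hits / total <= 0.07


class TestComponentSignificance:
    def test_saturated_null_gives_p_one(self):
        meta = _group_meta()
        rng = np.random.default_rng(7)
        rel = _rel(rng.random((6, 5)), meta)
        cfg = Config(cooc_edge_rho_min=0.0)  # every pair an edge, null included
        net = nw.build_group_network(rel, meta, "JM", "LBW", cfg)
        comps = nw.component_significance(rel, net, B=199, seed=0)
        assert comps and all(c.p_value == 1.0 for c in comps)

    def test_null_minimum_component_p_rarely_small(self):
        rng = np.random.default_rng(8)
        meta = _group_meta()
        small = 0
        for sim in range(100):
            rel = _rel(rng.random((25, 5)) + 0.01, meta)
            net = nw.build_group_network(rel, meta, "JM", "LBW", Config())
            comps = nw.component_significance(rel, net, B=199, seed=sim)
            if comps and min(c.p_value for c in comps) <= 0.05:
                small += 1
        assert small / 100 <= 0.12

    def test_planted_block_component_significant(self):
        # acceptance-scale power check lives in test_acceptance; here one seed
        from gutlinks.simulate import PlantedBlock, SyntheticDesign, genus_names, simulate_counts
        from gutlinks import composition as comp

        block = tuple(genus_names(40)[10:17])
        design = SyntheticDesign(seed=3, places=("JM",),
                                 planted_blocks=(PlantedBlock("JM", block, 2.0),))
        table, meta, _, _ = simulate_counts(design)
        rel = comp.to_relative(table)
        net = nw.build_group_network(rel, meta, "JM", "LBW", Config())
        nw.component_significance(rel, net, B=999, seed=0)
        hit = [c for c in net.components if set(block) <= set(c.nodes)]
        assert hit and hit[0].p_value <= 0.05


class TestCrossNetwork:
    def _paired_meta(self):
        rows = []
        for i in range(5):
            for place in ("JC", "JM"):
                rows.append({"sample_id": f"b{i}_{place}", "bird_id": f"b{i}",
                             "place": place, "bw_group": "LBW",
                             "body_weight_g": 2200.0 + i})
        return pd.DataFrame(rows)

    def test_identical_vectors_give_edge(self):
        meta = self._paired_meta()
        rng = np.random.default_rng(9)
        vals = rng.random(5)
        rel = pd.DataFrame(0.1 + np.zeros((2, 10)), index=["gA", "gB"],
                           columns=list(meta["sample_id"]))
        jc_cols = [f"b{i}_JC" for i in range(5)]
        jm_cols = [f"b{i}_JM" for i in range(5)]
        rel.loc["gA", jc_cols] = vals
        rel.loc["gB", jm_cols] = vals
        net = nw.cross_compartment_network(rel, rel, meta, "LBW", Config())
        pairs = {(e.genus_a, e.genus_b, e.sign) for e in net.edges}
        assert ("gA", "gB", 1) in pairs

    def test_bird_mismatch_rejected(self):
        meta = self._paired_meta()
        meta.loc[meta["sample_id"] == "b4_JM", "bird_id"] = "b9"
        rel = pd.DataFrame(np.random.default_rng(0).random((3, 10)),
                           index=["g0", "g1", "g2"], columns=list(meta["sample_id"]))
        with pytest.raises(ValueError, match="bird mismatch"):
            nw.cross_compartment_network(rel, rel, meta, "LBW", Config())

    def test_shuffled_alignment_destroys_planted_edges(self):
        from gutlinks.simulate import PlantedBlock, SyntheticDesign, genus_names, simulate_counts
        from gutlinks import composition as comp

        partners = tuple(genus_names(40)[21:27])
        aligned_edges, shuffled_edges = [], []
        rng = np.random.default_rng(10)
        for seed in range(20):
            design = SyntheticDesign(
                seed=seed, places=("JC", "JM"),
                planted_blocks=(PlantedBlock("JC", ("g021",), 2.0, factor="x"),
                                PlantedBlock("JM", partners, 2.0, factor="x")))
            table, meta, _, _ = simulate_counts(design)
            rel = comp.to_relative(table)
            net = nw.cross_compartment_network(rel, rel, meta, "LBW", Config())
            aligned_edges.append(
                sum(1 for e in net.edges if e.genus_a == "g021" and e.genus_b in partners)
            )
            # break the bird pairing in one group by permuting JM bird ids
            meta2 = meta.copy()
            jm = (meta2["place"] == "JM") & (meta2["bw_group"] == "LBW")
            ids = meta2.loc[jm, "bird_id"].to_numpy()
            meta2.loc[jm, "bird_id"] = ids[rng.permutation(len(ids))]
            net2 = nw.cross_compartment_network(rel, rel, meta2, "LBW", Config())
            shuffled_edges.append(
                sum(1 for e in net2.edges if e.genus_a == "g021" and e.genus_b in partners)
            )
        assert np.mean(aligned_edges) > 4
        assert np.mean(shuffled_edges) < 1.5

    def test_mc_out_degree_deterministic(self, demo_rel_genus):
        rel, meta = demo_rel_genus
        a = nw.cross_compartment_network(rel, rel, meta, "LBW", Config(),
                                         mc_reps=199, seed=2)
        b = nw.cross_compartment_network(rel, rel, meta, "LBW", Config(),
                                         mc_reps=199, seed=2)
        assert a.mc_out_p == b.mc_out_p
        assert min(a.mc_out_p.values()) >= 1 / 200
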