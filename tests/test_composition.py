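import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from gutlinks import composition as comp
from gutlinks import reference
from gutlinks.io import Config, CountTable


def _meta_balanced(n_per_cell=5, places=("JC", "JM", "CC")):
    rows = []
    for grp, prefix, w in (("LBW", "L", 2200.0), ("HBW", "H", 3000.0)):
        for i in range(1, n_per_cell + 1):
            for place in places:
                rows.append({"sample_id": f"{prefix}{i}_{place}", "bird_id": f"{prefix}{i}",
                             "place": place, "bw_group": grp, "body_weight_g": w + i})
    return pd.DataFrame(rows)


class TestAggregate:
    def _tax(self):
        return pd.DataFrame(
            {"kingdom": "Bacteria", "phylum": ["Firmicutes", "Firmicutes", "Bacteroidetes"],
             "class": "c", "order": "o", "family": "f",
             "genus": ["Lactobacillus", "Enterococcus", "Bacteroides"], "species": "s"},
            index=["f0", "f1", "f2"],
        )[["kingdom", "phylum", "class", "order", "family", "genus", "species"]]

    def test_additive_within_rank(self):
        t = CountTable([[3], [4], [5]], ["f0", "f1", "f2"], ["s0"])
        agg = comp.aggregate_to_rank(t, self._tax(), "phylum")
        assert agg.to_frame().loc["Firmicutes", "s0"] == 7

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(0)
        t = CountTable(rng.integers(0, 50, (3, 4)), ["f0", "f1", "f2"],
                       [f"s{j}" for j in range(4)])
        agg = comp.aggregate_to_rank(t, self._tax(), "genus")
        assert np.array_equal(agg.sample_sums(), t.sample_sums())

    def test_unmapped_features_pool_as_unclassified(self):
        t = CountTable([[1], [2]], ["x0", "x1"], ["s0"])
        agg = comp.aggregate_to_rank(t, self._tax(), "phylum")
        assert agg.feature_ids == ["Unclassified"]
        assert agg.counts[0, 0] == 3


class TestRelative:
    def test_simple_percentages(self):
        t = CountTable([[1], [3]], ["a", "b"], ["s0"])
        rel = comp.to_relative(t)
        assert rel["s0"].tolist() == [25.0, 75.0]

    def test_columns_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        t = CountTable(rng.integers(1, 100, (7, 5)), [f"f{i}" for i in range(7)],
                       [f"s{j}" for j in range(5)])
        assert np.allclose(comp.to_relative(t).sum(axis=0), 100.0)

    def test_single_taxon_is_hundred(self):
        t = CountTable([[4, 9]], ["a"], ["s0", "s1"])
        assert (comp.to_relative(t) == 100.0).all().all()

    def test_zero_sum_sample_rejected(self):
        t = CountTable([[0, 1]], ["a"], ["s0", "s1"])
        with pytest.raises(ValueError, match="s0"):
            comp.to_relative(t)


class TestGroupMeanTable:
    def test_printed_phylum_margins_recompute(self):
        # worked examples from the published phylum table
        cells, printed_sp, printed_bw = reference.phylum_table()
        mean_sp, mean_bw = comp.margins_from_cells(cells)
        bact = mean_bw.loc["Bacteroidetes", "LBW"]
        assert bact == pytest.approx(22.15, abs=0.005)
        assert mean_sp.loc["Proteobacteria", "JC"] == pytest.approx(6.83, abs=0.005)

    def test_constant_cells_give_constant_margins(self):
        cols = pd.MultiIndex.from_product([["JC", "JM"], ["LBW", "HBW"]],
                                          names=["place", "bw_group"])
        cells = pd.DataFrame([[3.0] * 4], index=["t"], columns=cols)
        mean_sp, mean_bw = comp.margins_from_cells(cells)
        assert (mean_sp == 3.0).all().all() and (mean_bw == 3.0).all().all()

    def test_margins_equal_mean_of_cells(self, demo_rel_genus):
        rel, meta = demo_rel_genus
        gmt = comp.group_mean_table(rel, meta)
        manual_sp = gmt.cells.T.groupby(level="place", sort=False).mean().T
        assert np.allclose(gmt.mean_sp, manual_sp)
        # mean over all 6 cells equals mean of either margin family
        assert np.allclose(gmt.mean_sp.mean(axis=1), gmt.mean_bw.mean(axis=1))

    def test_empty_cell_rejected(self, demo_rel_genus):
        rel, meta = demo_rel_genus
        broken = meta[~((meta["place"] == "JM") & (meta["bw_group"] == "HBW"))]
        with pytest.raises(ValueError, match="empty design cell"):
            comp.group_mean_table(rel, broken)


class TestBfRatio:
    def _rel(self, b, f):
        return pd.DataFrame([b, f], index=["Bacteroidetes", "Firmicutes"],
                            columns=[f"s{i}" for i in range(len(b))])

    def test_simple_ratio(self):
        assert comp.bf_ratio(self._rel([20.0], [40.0])).iloc[0] == pytest.approx(0.5)

    def test_zero_bacteroidetes(self):
        assert comp.bf_ratio(self._rel([0.0], [40.0])).iloc[0] == 0

    def test_zero_firmicutes_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            ratio = comp.bf_ratio(self._rel([10.0, 20.0], [0.0, 40.0]))
        assert list(ratio.index) == ["s1"]

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        # Jensen gap: (0.1/0.9 + 0.9/0.1)/2 != (0.5/0.5)
        rel = self._rel([10.0, 90.0], [90.0, 10.0])
        mean_of_ratios = comp.bf_ratio(rel).mean()
        ratio_of_means = rel.loc["Bacteroidetes"].mean() / rel.loc["Firmicutes"].mean()
        assert mean_of_ratios != pytest.approx(ratio_of_means)
        assert mean_of_ratios > ratio_of_means  # convexity direction


class TestTwoWayAnova:
    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(2)
        meta = _meta_balanced(n_per_cell=4, places=("JC", "JM"))
        y = rng.normal(size=len(meta)) + (meta["place"] == "JM") * 0.8
        codes_a = meta["place"].map({"JC": 0, "JM": 1}).to_numpy()
        codes_b = meta["bw_group"].map({"LBW": 0, "HBW": 1}).to_numpy()
        res = comp.twoway_anova_balanced(y.to_numpy()[None, :], codes_a, codes_b)
        df = pd.DataFrame({"y": y, "a": meta["place"], "b": meta["bw_group"]})
        tab = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", data=df).fit(), typ=2)
        assert res["F_a"][0] == pytest.approx(tab.loc["C(a)", "F"], rel=1e-10)
        assert res["F_b"][0] == pytest.approx(tab.loc["C(b)", "F"], rel=1e-10)
        assert res["F_ab"][0] == pytest.approx(tab.loc["C(a):C(b)", "F"], rel=1e-10)
        assert res["p_ab"][0] == pytest.approx(tab.loc["C(a):C(b)", "PR(>F)"], rel=1e-9)

    def test_null_p_uniform_and_fdr_controlled(self):
        # no effects: raw p uniform; FDR-positive proportion small
        rng = np.random.default_rng(3)
        meta = _meta_balanced()
        codes_a = meta["place"].map({"JC": 0, "JM": 1, "CC": 2}).to_numpy()
        codes_b = (meta["bw_group"] == "HBW").to_numpy().astype(int)
        pvals, fdr_hits = [], 0
        n_sims, n_taxa = 1000, 20
        for _ in range(n_sims):
            Y = rng.normal(size=(n_taxa, len(meta)))
            res = comp.twoway_anova_balanced(Y, codes_a, codes_b)
            pvals.extend(res["p_a"][:2])
            fdr_hits += (comp.bh_fdr(res["p_b"]) < 0.05).sum()
        assert kstest(pvals, "uniform").pvalue > 0.01
        assert fdr_hits / (n_sims * n_taxa) <= 0.05

    def test_place_effect_power(self):
        # the generator's compartment-specific baselines are a large place
        # effect: virtually every simulation flags SP-significant taxa
        from gutlinks.simulate import SyntheticDesign, simulate_counts

        detected = 0
        for seed in range(100):
            design = SyntheticDesign(n_genera=15, seed=seed, depth_range=(4000, 6000))
            table, meta, tax, _ = simulate_counts(design)
            rel = comp.to_relative(table)
            screen = comp.anova_screen(rel, meta, Config(), compute_letters=False)
            detected += (screen.table["class_sp"] == "significant").any()
        assert detected >= 90

    def test_constant_taxon_reported_missing(self, demo_rel_genus):
        rel, meta = demo_rel_genus
        rel = rel.copy()
        rel.loc["constant"] = 1.0
        screen = comp.anova_screen(rel, meta, Config(), compute_letters=False)
        assert np.isnan(screen.table.loc["constant", "p_sp"])
        assert screen.table.loc["constant", "class_sp"] == "na"


class TestTukey:
    def test_matches_statsmodels_on_oneway_data(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(4)
        groups = np.repeat(["a", "b", "c"], 8)
        y = rng.normal(size=24) + np.repeat([0.0, 1.2, 0.3], 8)
        sm_res = pairwise_tukeyhsd(y, groups)
        means = {g: y[groups == g].mean() for g in "abc"}
        mse = sum(((y[groups == g] - means[g]) ** 2).sum() for g in "abc") / (24 - 3)
        ours = comp.tukey_hsd(means, 8, mse, 24 - 3)
        assert np.allclose(sorted(ours["p"]), sorted(sm_res.pvalues), atol=1e-8)

    def test_two_levels_reduce_to_t_test(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        a, b = rng.normal(size=10), rng.normal(size=10) + 1
        t, p = stats.ttest_ind(a, b)
        means = {"a": a.mean(), "b": b.mean()}
        sp = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        mse = sp / 18
        ours = comp.tukey_hsd(means, 10, mse, 18)
        assert ours["q"].iloc[0] == pytest.approx(np.sqrt(2) * abs(t))
        assert ours["p"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_letters_respect_significance(self):
        letters = comp.compact_letters(
            ["hi", "mid", "lo"], nonsig_pairs=[("hi", "mid"), ("mid", "lo")]
        )
        assert set(letters["hi"]) & set(letters["mid"])
        assert set(letters["mid"]) & set(letters["lo"])
        assert not set(letters["hi"]) & set(letters["lo"])


class TestBhFdr:
    def test_matches_step_up_definition(self):
        # brute-force step-up: q_i = min over j>=i of p_(j) * m / j
        rng = np.random.default_rng(6)
        for _ in range(50):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            ours = comp.bh_fdr(p)
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                running = min(running, p[order[rank]] * m / (rank + 1))
                expected[order[rank]] = running
            assert np.allclose(ours, expected)

    def test_nan_passthrough(self):
        out = comp.bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[0])


class TestVenn:
    def test_region_counts_match_exhaustive_oracle(self):
        # 6 features with a crafted incidence pattern over 3 places
        incidence = {
            "f0": {"JC"}, "f1": {"JM"}, "f2": {"JC", "JM"},
            "f3": {"JC", "JM", "CC"}, "f4": {"CC"}, "f5": {"JM", "CC"},
        }
        meta = _meta_balanced(n_per_cell=1)
        counts = np.zeros((6, len(meta)), dtype=int)
        for i, f in enumerate(incidence):
            for j, row in meta.iterrows():
                if row["place"] in incidence[f]:
                    counts[i, j] = 1
        table = CountTable(counts, list(incidence), list(meta["sample_id"]))
        venn = comp.venn_unique_shared(table, meta, by="place")
        for r in range(1, 4):
            for combo in itertools.combinations(("JC", "JM", "CC"), r):
                expected = sum(1 for s in incidence.values() if s == set(combo))
                assert venn.regions[frozenset(combo)] == expected
        assert venn.unique["JC"] == 1
        assert venn.core == 1
        assert venn.aggregate["JM"] == 4

    def test_unique_and_core_membership(self, demo_dataset):
        venn = comp.venn_unique_shared(demo_dataset["table"], demo_dataset["meta"],
                                       by="place")
        # inclusion-exclusion: aggregate = sum of regions containing the group
        for g in venn.groups:
            total = sum(v for k, v in venn.regions.items() if g in k)
            assert total == venn.aggregate[g]
        assert venn.core == venn.regions[frozenset(venn.groups)]
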