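"""Design summaries, ratios, rankings, pooling effect, area test."""

import numpy as np
import pandas as pd
import pytest

from soilpool.design_eval import (
    area_subsampling_test,
    design_ratios,
    pooling_effect,
    rank_sites,
    summarise_design,
)
from conftest import toy_read_table


class TestSummariseDesign:
    def test_single_sample_equals_its_diversity(self):
        table = toy_read_table({"s1": {"A": 60, "B": 30, "C": 30}})
        s = summarise_design(table, "siteA", "D1", rarefy_to=120,
                             iterations=5, seed=0)
        assert s.mean_richness == 3.0
        assert s.site_richness == 3.0
        assert s.summary_depth == 120

    def test_disjoint_samples_union(self):
        table = toy_read_table({
            "s1": {"A": 50, "B": 50, "C": 50},
            "s2": {"D": 40, "E": 40, "F": 40, "G": 30},
        })
        s = summarise_design(table, "siteA", "D1", rarefy_to=150,
                             iterations=5, seed=0)
        assert s.site_richness == 7.0

    def test_site_at_least_max_sample_richness(self, small_survey):
        s = summarise_design(small_survey, "siteA", "N9t", iterations=20,
                             seed=1)
        assert s.site_richness >= s.mean_richness

    def test_low_read_samples_dropped(self):
        table = toy_read_table({
            "s1": {"A": 200, "B": 100},
            "s2": {"A": 3},
        })
        s = summarise_design(table, "siteA", "D1", iterations=5, seed=0)
        assert s.n_samples == 1


class TestDesignRatios:
    def make_summaries(self, values):
        out = []
        for (site, design), v in values.items():
            table = toy_read_table(
                {f"{site}_{design}": {f"o{i}": 100 for i in range(v)}},
                sites=[site], designs=[design],
            )
            out.append(summarise_design(table, site, design,
                                        rarefy_to=100 * v, iterations=2))
        return out

    def test_self_ratio_and_arithmetic(self):
        s = self.make_summaries({("s1", "ref"): 40, ("s1", "other"): 10})
        r = design_ratios(s, "ref")
        assert r.loc["ref", "s1"] == pytest.approx(1.0)
        assert r.loc["other", "s1"] == pytest.approx(4.0)

    def test_exclusions_honoured(self):
        s = self.make_summaries({("s1", "ref"): 4, ("s1", "sub"): 2})
        r = design_ratios(s, "ref", exclusions=["sub"])
        assert "sub" not in r.index


class TestRankSites:
    def make(self, table_values):
        recs = []
        for design, site_vals in table_values.items():
            for site, v in site_vals.items():
                t = toy_read_table(
                    {f"{site}{design}": {f"o{i}": 100 for i in range(v)}},
                    sites=[site], designs=[design],
                )
                recs.append(summarise_design(t, site, design,
                                             rarefy_to=100 * v, iterations=2))
        return recs

    def test_identical_orderings_fully_concordant(self):
        s = self.make({
            "d1": {"s1": 9, "s2": 6, "s3": 3},
            "d2": {"s1": 8, "s2": 5, "s3": 2},
        })
        res = rank_sites(s)
        assert res["rankings"]["d1"] == ["s1", "s2", "s3"]
        assert res["concordance"].loc["d1", "d2"] == pytest.approx(1.0)

    def test_reversed_orderings(self):
        s = self.make({
            "d1": {"s1": 9, "s2": 6, "s3": 3},
            "d2": {"s1": 2, "s2": 5, "s3": 8},
        })
        assert rank_sites(s)["concordance"].loc["d1", "d2"] == pytest.approx(-1.0)

    def test_single_site_rejected(self):
        s = self.make({"d1": {"s1": 5}})
        with pytest.raises(ValueError):
            rank_sites(s)


class TestPoolingEffect:
    def test_ratio_definition(self):
        # pooled richness 30 at full depth, unpooled site richness 40
        unpooled = {f"u{i}": {f"o{j}": 10 for j in range(i * 10, i * 10 + 10)}
                    for i in range(4)}
        pooled = {"p": {f"o{j}": 20 for j in range(30)}}
        table = toy_read_table(
            {**unpooled, **pooled},
            strategies=["unpooled"] * 4 + ["soil_pool"],
        )
        res = pooling_effect(table, "siteA", "D1", "soil_pool", q=0,
                             depth_fractions=(1.0,), iterations=5, seed=0)
        assert res[0].pe == pytest.approx(30 / 40)

    def test_self_consistency_pe_one(self):
        # pooled row literally equals the concatenated unpooled reads
        rng = np.random.default_rng(3)
        rows = {f"u{i}": {f"o{j}": int(c) for j, c in
                          enumerate(rng.integers(0, 40, 25)) if c}
                for i in range(5)}
        total = pd.DataFrame(rows).T.fillna(0).sum(axis=0)
        rows["pool"] = {k: int(v) for k, v in total.items() if v}
        table = toy_read_table(rows, strategies=["unpooled"] * 5 + ["dna_pool"])
        res = pooling_effect(table, "siteA", "D1", "dna_pool", q=0,
                             depth_fractions=(1.0,), iterations=5, seed=0)
        assert res[0].pe == pytest.approx(1.0)

    def test_insufficient_pooled_depth_flagged(self):
        table = toy_read_table(
            {"u1": {"A": 1000}, "p": {"A": 100}},
            strategies=["unpooled", "soil_pool"],
        )
        res = pooling_effect(table, "siteA", "D1", "soil_pool",
                             depth_fractions=(1.0,), iterations=2)
        assert np.isnan(res[0].pe) and res[0].flag

    def test_monotone_in_depth_fraction(self):
        rng = np.random.default_rng(1)
        unp = {"u1": {f"o{j}": int(v) + 1 for j, v in
                      enumerate(rng.integers(0, 50, 40))}}
        pool = {"p": {f"o{j}": int(v) + 1 for j, v in
                      enumerate(rng.integers(0, 120, 40))}}
        table = toy_read_table({**unp, **pool},
                               strategies=["unpooled", "soil_pool"])
        res = pooling_effect(table, "siteA", "D1", "soil_pool", q=0,
                             depth_fractions=(0.25, 0.5, 0.75, 1.0),
                             iterations=60, seed=2)
        pes = [r.pe for r in res]
        assert all(a <= b + 0.05 for a, b in zip(pes, pes[1:]))

    def test_missing_stratum_rejected(self):
        table = toy_read_table({"u1": {"A": 10}})
        with pytest.raises(ValueError):
            pooling_effect(table, "siteA", "D1", "soil_pool")


class TestAreaSubsamplingTest:
    def grid_table(self, n=36, side=30.0, seed=0):
        rng = np.random.default_rng(seed)
        g = int(np.sqrt(n))
        xs, ys = np.meshgrid(np.linspace(-side / 2, side / 2, g),
                             np.linspace(-side / 2, side / 2, g))
        counts = {}
        coords = []
        for i, (x, y) in enumerate(zip(xs.ravel(), ys.ravel())):
            counts[f"s{i}"] = {f"o{j}": int(v) for j, v in
                               enumerate(rng.integers(0, 4, 60)) if v}
            coords.append((x, y))
        table = toy_read_table(counts)
        table.sample_meta["x"] = [c[0] for c in coords]
        table.sample_meta["y"] = [c[1] for c in coords]
        return table

    def test_degenerate_geometry_rejected(self):
        table = toy_read_table(
            {f"s{i}": {"A": 10 + i} for i in range(6)}
        )  # all at (0, 0)
        with pytest.raises(ValueError):
            area_subsampling_test(table, k=3, area_min=1.0, area_max=10.0,
                                  n_combinations=5, n_permutations=19)

    def test_two_sample_rectangle_by_hand(self):
        # two samples 20 m apart on the diagonal: 20 x 20 bounding square
        table = toy_read_table({"s1": {"A": 10}, "s2": {"B": 10}})
        table.sample_meta.loc["s1", ["x", "y"]] = (0.0, 0.0)
        table.sample_meta.loc["s2", ["x", "y"]] = (20.0, 20.0)
        res = area_subsampling_test(table, k=2, area_min=399, area_max=401,
                                    aspect_tolerance=0.1, n_combinations=1,
                                    n_permutations=19, seed=0)
        assert res["combinations"]["area"].iloc[0] == pytest.approx(400.0)
        assert res["combinations"]["richness"].iloc[0] == 2

    def test_null_slope_usually_nonsignificant(self):
        ps = [
            area_subsampling_test(
                self.grid_table(seed=s), k=6, area_min=40, area_max=500,
                aspect_tolerance=8.0, n_combinations=20, n_permutations=99,
                seed=s,
            )["p"]
            for s in range(10)
        ]
        assert np.mean(np.array(ps) > 0.05) >= 0.8
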