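"""Distance, PERMANOVA, dispersion and correlogram oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilpool.commstats import (
    DistanceMatrix,
    bray_curtis,
    dispersion_homogeneity,
    mantel_correlogram,
    permanova,
)


def block_distance(within=1.0, between=2.0):
    """2+2 samples: within-group distance 1, between-group 2."""
    d = np.full((4, 4), between)
    d[0, 1] = d[1, 0] = within
    d[2, 3] = d[3, 2] = within
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list("abcd"), d)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis([[3, 2, 1], [3, 2, 1]])
        assert d.values[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        d = bray_curtis([[5, 0], [0, 7]])
        assert d.values[0, 1] == 1.0

    def test_hand_example(self):
        d = bray_curtis([[1, 1], [1, 3]])
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_double_zero_rows_flagged_nan(self):
        d = bray_curtis([[0, 0], [0, 0], [1, 2]])
        assert np.isnan(d.values[0, 1])
        assert d.values[0, 2] == 1.0

    def test_matches_scipy(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(3)
        rows = rng.integers(0, 20, (5, 12))
        d = bray_curtis(rows)
        for i in range(5):
            for j in range(i + 1, 5):
                assert d.values[i, j] == pytest.approx(
                    braycurtis(rows[i], rows[j])
                )

    @given(st.lists(st.integers(0, 30), min_size=4, max_size=10),
           st.integers(2, 9))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, row, c):
        x = np.array(row)
        y = x[::-1].copy()
        if (x + y).sum() == 0:
            return
        d1 = bray_curtis([x, y]).values[0, 1]
        d2 = bray_curtis([c * x, c * y]).values[0, 1]
        assert d1 == pytest.approx(d2)


class TestPermanova:
    def test_hand_partitioned_F(self):
        res = permanova(block_distance(), ["g1", "g1", "g2", "g2"],
                        n_permutations=99, seed=1)
        # SS_total = 18/4 = 4.5, SS_within = 1.0 -> F = (3.5/1)/(1/2) = 7
        assert res.pseudo_F == pytest.approx(7.0)
        assert res.R2 == pytest.approx(3.5 / 4.5)

    def test_r2_partition_identity(self):
        rng = np.random.default_rng(0)
        d = bray_curtis(rng.integers(1, 30, (8, 10)))
        res = permanova(d, [0, 0, 0, 0, 1, 1, 1, 1], n_permutations=49)
        assert 0 <= res.R2 <= 1

    def test_exhaustive_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        d = bray_curtis(rng.integers(0, 20, (6, 8)))
        groups = [0, 0, 0, 1, 1, 1]
        exact = permanova(d, groups, method="exhaustive")
        mc = permanova(d, groups, n_permutations=9999, seed=3)
        assert abs(exact.p - mc.p) < 0.02

    def test_label_order_invariance(self):
        d = block_distance()
        res1 = permanova(d, ["x", "x", "y", "y"], n_permutations=199, seed=5)
        res2 = permanova(d, ["y", "y", "x", "x"], n_permutations=199, seed=5)
        assert res1.pseudo_F == res2.pseudo_F and res1.p == res2.p

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(11)
        rows = rng.integers(0, 25, (10, 14))
        d = bray_curtis(rows)
        groups = list("aaaaabbbbb")
        ours = permanova(d, groups, n_permutations=99, seed=0)
        theirs = sk_permanova(
            skbio.DistanceMatrix(d.values, ids=d.labels), grouping=groups,
            permutations=99,
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"])

    def test_degenerate_within_ss(self):
        d = DistanceMatrix(
            list("abcd"),
            np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                      [1, 1, 0, 0], [1, 1, 0, 0]], float),
        )
        res = permanova(d, [0, 0, 1, 1], n_permutations=23, seed=0)
        assert np.isinf(res.pseudo_F)


class TestDispersion:
    def test_mirror_groups_equal_dispersion(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (8, 3))
        pts = np.vstack([a, -a])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = dispersion_homogeneity(
            DistanceMatrix([str(i) for i in range(16)], d),
            [0] * 8 + [1] * 8, n_permutations=99, seed=1,
        )
        assert res["group_dispersion"][0] == pytest.approx(
            res["group_dispersion"][1]
        )
        assert res["p"] > 0.5

    def test_euclidean_embedding_oracle(self):
        # for a Euclidean distance matrix, dispersion (centroid mode) must
        # match direct Euclidean distances to group centroids
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, (10, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        groups = [0] * 5 + [1] * 5
        res = dispersion_homogeneity(
            DistanceMatrix([str(i) for i in range(10)], d), groups,
            n_permutations=19, seed=0, centre="centroid",
        )
        direct = np.empty(10)
        for g in (0, 1):
            idx = np.flatnonzero(np.array(groups) == g)
            c = pts[idx].mean(axis=0)
            direct[idx] = np.linalg.norm(pts[idx] - c, axis=1)
        assert np.allclose(res["distances"], direct, atol=1e-8)

    def test_power_on_unequal_spread(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_trials = 30
        for t in range(n_trials):
            tight = rng.normal(0, 0.1, (10, 3))
            spread = rng.normal(0, 1.0, (10, 3))
            pts = np.vstack([tight, spread])
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            res = dispersion_homogeneity(
                DistanceMatrix([str(i) for i in range(20)], d),
                [0] * 10 + [1] * 10, n_permutations=99, seed=t,
            )
            hits += res["p"] <= 0.05
        assert hits / n_trials >= 0.9


class TestMantelCorrelogram:
    def test_positive_autocorrelation_detected(self):
        rng = np.random.default_rng(6)
        hits = 0
        for t in range(10):
            coords = rng.uniform(0, 10, (24, 2))
            # community turnover follows geography
            comm = np.sqrt(
                ((coords[:, None] - coords[None]) ** 2).sum(-1)
            ) / 15 + rng.normal(0, 0.02, (24, 24))
            comm = (comm + comm.T) / 2
            np.fill_diagonal(comm, 0)
            res = mantel_correlogram(
                np.abs(comm), coords, distance_classes=4,
                n_permutations=199, seed=t,
            )
            first = res.iloc[0]
            hits += (first["r"] > 0) and (first["p"] <= 0.05)
        assert hits >= 9

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(13)
        ps = []
        for t in range(20):
            coords = rng.uniform(0, 10, (16, 2))
            comm = rng.uniform(0.2, 1.0, (16, 16))
            comm = (comm + comm.T) / 2
            np.fill_diagonal(comm, 0)
            res = mantel_correlogram(comm, coords, 3, n_permutations=99,
                                     seed=t)
            ps.extend(res["p"].tolist())
        assert np.mean(np.array(ps) <= 0.05) < 0.2

    def test_duplicate_coordinates_allowed(self):
        coords = np.array([[0, 0], [0, 0], [5, 5], [5, 5]])
        comm = bray_curtis(np.random.default_rng(1).integers(0, 9, (4, 6)))
        res = mantel_correlogram(comm, coords, [0, 1, 10],
                                 n_permutations=49, seed=0)
        assert len(res) >= 1
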