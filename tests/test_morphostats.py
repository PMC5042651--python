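"""Statistical layer: z-score, PCA, rank-sum tests, variation, efficiency."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gastrumorph.morphostats import (
    MorphospacePoint,
    compare_groups,
    efficiency,
    pca,
    significance_stars,
    variation_decomposition,
    wilcoxon_rank_sum,
    zscore,
)


def enumeration_rank_sum_p(a, b):
    """Independent oracle: two-sided exact p by enumerating all rank splits."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = ranks[:n].sum()
    ws = [sum(c) for c in itertools.combinations(ranks, n)]
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestZscore:
    def test_mean_zero_sd_one(self):
        z = zscore(np.array([[1.0], [2.0], [3.0]]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_idempotence(self, rng):
        x = rng.normal(3, 7, (50, 4))
        z = zscore(x)
        assert np.allclose(zscore(z), z, atol=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="1"):
            zscore(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))


class TestPCA:
    def test_collinear_points_have_unit_pc1_fraction(self):
        t = np.linspace(0, 1, 40)
        pts = np.c_[t, 2 * t]
        res = pca(pts)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_isotropic_cloud_fractions_near_uniform(self):
        rng = np.random.default_rng(7)
        res = pca(rng.normal(size=(1000, 4)))
        assert np.all(np.abs(res.variance_fraction - 0.25) < 0.05)

    def test_matches_covariance_eigensolver_oracle(self, rng):
        x = rng.normal(size=(80, 5)) @ rng.normal(size=(5, 5))
        res = pca(x)
        cov = np.cov(x, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        total = evals.sum()
        assert np.allclose(res.variance_fraction, evals / total, atol=1e-9)
        for j in range(5):
            v = evecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(res.loadings[:, j], v, atol=1e-9)

    def test_loadings_orthonormal_and_fractions_sum_to_one(self, rng):
        x = rng.normal(size=(60, 4))
        res = pca(x)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-12)
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_scores_are_projection(self, rng):
        x = rng.normal(size=(30, 3))
        res = pca(x)
        assert np.allclose(res.scores, (x - x.mean(0)) @ res.loadings, atol=1e-12)


class TestWilcoxonRankSum:
    def test_textbook_case_p_one_third(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert w == 3.0
        assert p == pytest.approx(1 / 3)
        assert enumeration_rank_sum_p([1.0, 2.0], [3.0, 4.0]) == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 3), (2, 6)])
    def test_exact_p_equals_enumeration_oracle(self, n, m, rng):
        for _ in range(5):
            a = rng.normal(size=n)
            b = rng.normal(1.0, 1.0, size=m)
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(enumeration_rank_sum_p(a, b), abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCompareGroups:
    def test_star_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.00005) == "****"

    def test_identical_groups_all_ns(self, rng):
        vals = rng.normal(size=30)
        df = pd.DataFrame(
            {
                "group_label": ["a"] * 30 + ["b"] * 30,
                "internalization": np.concatenate([vals, vals]),
            }
        )
        out = compare_groups(df, parameters=("internalization",))
        assert (out["stars"] == "ns").all()
        assert np.allclose(out["median_a"], out["median_b"])

    def test_single_group_raises(self):
        df = pd.DataFrame({"group_label": ["a"] * 5, "integrity": range(5)})
        with pytest.raises(ValueError):
            compare_groups(df, parameters=("integrity",))


class TestVariationDecomposition:
    def mk(self, embryo, idx, coords, group="g"):
        return MorphospacePoint(embryo, idx, group, np.asarray(coords, float))

    def test_identical_points_give_zero_variation(self):
        pts = [self.mk("e1", i, [1.0, 2.0]) for i in range(3)] + [
            self.mk("e2", i, [1.0, 2.0]) for i in range(3)
        ]
        summary = variation_decomposition(pts)
        assert summary.group_variation == 0.0
        assert all(v == 0.0 for v in summary.between_embryo.values())
        assert all(v == 0.0 for v in summary.within_embryo.values())

    def test_two_single_section_embryos_at_distance_two(self):
        pts = [self.mk("e1", 0, [0.0, 0.0]), self.mk("e2", 0, [2.0, 0.0])]
        summary = variation_decomposition(pts)
        assert summary.group_variation == pytest.approx(2.0)
        assert summary.between_embryo_centroid[("e1", "e2")] == pytest.approx(2.0)
        assert summary.within_embryo == {}

    def test_rotation_invariance(self, rng):
        coords = rng.normal(size=(12, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        pts = [self.mk(f"e{i % 3}", i, c) for i, c in enumerate(coords)]
        rot = [self.mk(f"e{i % 3}", i, c @ q) for i, c in enumerate(coords)]
        a, b = variation_decomposition(pts), variation_decomposition(rot)
        assert a.group_variation == pytest.approx(b.group_variation, abs=1e-9)
        for k in a.within_embryo:
            assert a.within_embryo[k] == pytest.approx(b.within_embryo[k], abs=1e-9)

    def test_relabeling_invariance(self, rng):
        coords = rng.normal(size=(12, 3))
        pts = [self.mk(f"e{i % 3}", i, c) for i, c in enumerate(coords)]
        relabeled = [self.mk("x" + p.embryo_id, p.section_index, p.coords) for p in pts]
        a, b = variation_decomposition(pts), variation_decomposition(relabeled)
        assert a.group_variation == pytest.approx(b.group_variation)
        assert sorted(a.within_embryo.values()) == pytest.approx(
            sorted(b.within_embryo.values())
        )

    def test_distances_nonnegative_triangle_inequality(self, rng):
        coords = rng.normal(size=(9, 4))
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(coords))
        assert (dm >= 0).all()
        for i, j, k in itertools.combinations(range(9), 3):
            assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-12


class TestEfficiency:
    def make_table(self):
        return pd.DataFrame(
            {
                "embryo_id": ["a", "b", "c"],
                "group_label": ["g1", "g1", "g2"],
                "gbe_percent": [17.0, 30.0, 20.0],
                "n_roi": [100, 100, 100],
                "n_internalized": [40, 70, 55],
            }
        )

    def test_default_window_and_exclusion(self):
        out = efficiency(self.make_table())
        assert set(out["embryo_id"]) == {"a", "c"}  # 30% GBE excluded
        assert out.loc[out.embryo_id == "a", "efficiency_percent"].iloc[0] == 40.0

    def test_no_embryo_in_window_raises(self):
        table = self.make_table()
        table["gbe_percent"] = [40.0, 45.0, 50.0]
        with pytest.raises(ValueError):
            efficiency(table)
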