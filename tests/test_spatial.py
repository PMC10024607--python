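"""Proximity enrichment, gene-set scores, and distance-resolved curves."""

import numpy as np
import pandas as pd
import pytest

import merfishpipe as mp


def _obs(points, section="s0", prefix="c"):
    return pd.DataFrame(
        {
            "x_um": [p[0] for p in points],
            "y_um": [p[1] for p in points],
            "section": section,
        },
        index=[f"{prefix}{i}" for i in range(len(points))],
    )


class TestProximityEnrichment:
    def test_counts_match_brute_force(self):
        """mu_true equals an O(n^2) pairwise count on a random instance."""
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 500, size=(40, 2))
        B = rng.uniform(0, 500, size=(60, 2))
        res = mp.proximity_enrichment(A, B, radius_um=30, n_rand=10, seed=0)
        brute = np.mean(
            [(np.linalg.norm(B - a, axis=1) <= 30).sum() for a in A]
        )
        assert res.mu_true == pytest.approx(brute)

    def test_colocated_types_enriched(self):
        """B placed exactly at A positions on a dense background is enriched."""
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 2000, size=(150, 2))
        B = np.vstack([A + rng.normal(0, 1.0, A.shape), rng.uniform(0, 2000, size=(150, 2))])
        res = mp.proximity_enrichment(A, B, n_rand=200, seed=2)
        assert res.enrichment > 0
        assert res.p < 0.05

    def test_zero_null_variance_flagged(self):
        A = np.array([[0.0, 0.0]])
        B = np.array([[5000.0, 5000.0]])  # never within radius, jittered or not
        with pytest.warns(UserWarning):
            res = mp.proximity_enrichment(A, B, n_rand=20, seed=0)
        assert np.isnan(res.z) and np.isnan(res.p)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mp.proximity_enrichment(np.zeros((0, 2)), np.zeros((3, 2)))

    def test_pairs_table_has_fdr_and_both_orders(self):
        rng = np.random.default_rng(3)
        obs = _obs(list(map(tuple, rng.uniform(0, 1000, size=(200, 2)))))
        obs["cell_type"] = rng.choice(["A", "B"], size=200)
        out = mp.proximity_enrichment_pairs(obs, n_rand=50, seed=0)
        assert set(zip(out["type_a"], out["type_b"])) == {("A", "B"), ("B", "A")}
        assert out["fdr_p"].notna().all()
        # enrichment sign matches mu_true vs mu_background
        for _, row in out.iterrows():
            assert np.sign(row["enrichment"]) == np.sign(row["mu_true"] - row["mu_background"])


class TestGeneSetScore:
    @pytest.fixture
    def uniform_z(self):
        rng = np.random.default_rng(4)
        return pd.DataFrame(
            rng.normal(size=(100, 500)),
            index=[f"c{i}" for i in range(100)],
            columns=[f"g{i}" for i in range(500)],
        )

    def test_shift_detected(self, uniform_z):
        """Adding c to set genes in half the cells shifts their scores by about c."""
        z = uniform_z.copy()
        gene_set = ["g0", "g1", "g2", "g3"]
        half = z.index[:50]
        z.loc[half, gene_set] += 2.0
        score = mp.gene_set_score(z, gene_set, seed=0)
        diff = score.loc[half].mean() - score.drop(half).mean()
        assert diff == pytest.approx(2.0, abs=0.3)

    def test_single_gene_set_definition(self, uniform_z):
        score = mp.gene_set_score(uniform_z, ["g7"], n_ctrl=50, seed=1)
        # score = that gene's value minus the control-pool mean: perfectly
        # correlated with the gene itself
        assert np.corrcoef(score, uniform_z["g7"])[0, 1] > 0.9

    def test_deterministic_given_seed(self, uniform_z):
        a = mp.gene_set_score(uniform_z, ["g0", "g5"], seed=7)
        b = mp.gene_set_score(uniform_z, ["g0", "g5"], seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_empty_and_missing_sets_rejected(self, uniform_z):
        with pytest.raises(ValueError):
            mp.gene_set_score(uniform_z, [])
        with pytest.raises(KeyError, match="missing_gene"):
            mp.gene_set_score(uniform_z, ["missing_gene"])


class TestScoreVsDistance:
    def _setup(self, scores_fn, n=2000, seed=5):
        rng = np.random.default_rng(seed)
        scored = _obs(list(map(tuple, rng.uniform(0, 800, size=(n, 2)))), prefix="s")
        reference = _obs(list(map(tuple, rng.uniform(0, 800, size=(60, 2)))), prefix="r")
        from scipy.spatial import cKDTree

        d, _ = cKDTree(reference[["x_um", "y_um"]].to_numpy()).query(
            scored[["x_um", "y_um"]].to_numpy()
        )
        scores = pd.Series(scores_fn(d, rng), index=scored.index)
        return scores, scored, reference, d

    def test_uniform_scores_flat_after_subtraction(self):
        scores, scored, reference, _ = self._setup(lambda d, rng: np.full(len(d), 3.0))
        curve = mp.score_vs_distance(scores, scored, reference)
        np.testing.assert_allclose(curve.mean_score[~np.isnan(curve.mean_score)], 0.0, atol=1e-9)
        assert curve.subtracted_constant == pytest.approx(3.0)

    def test_planted_linear_gradient_recovered(self):
        """score = -d/80 recovered against a brute-force windowing oracle."""
        scores, scored, reference, d = self._setup(lambda d, rng: -d / 80.0)
        curve = mp.score_vs_distance(scores, scored, reference)
        keep = d <= 80
        dk, vk = d[keep], (-d / 80.0)[keep]
        expected = []
        for g in curve.grid_um:
            lo, hi = max(g - 15.0, 0.0), min(g + 15.0, 80.0)
            mask = (dk >= lo) & (dk <= hi)
            expected.append(vk[mask].mean() if mask.any() else np.nan)
        expected = np.array(expected)
        expected -= np.nanmean(expected)
        np.testing.assert_allclose(curve.mean_score, expected, atol=0.02)

    def test_grid_length_and_constant_definition(self):
        scores, scored, reference, _ = self._setup(lambda d, rng: rng.normal(size=len(d)))
        curve = mp.score_vs_distance(scores, scored, reference)
        assert len(curve.grid_um) == 81
        # mean of (curve + constant) over the grid equals the constant
        restored = curve.mean_score + curve.subtracted_constant
        assert np.nanmean(restored) == pytest.approx(curve.subtracted_constant, abs=1e-9)

    def test_translation_invariance(self):
        scores, scored, reference, _ = self._setup(lambda d, rng: -d / 80.0)
        c1 = mp.score_vs_distance(scores, scored, reference)
        c2 = mp.score_vs_distance(scores + 5.0, scored, reference)
        np.testing.assert_allclose(c1.mean_score, c2.mean_score, atol=1e-9)

    def test_out_of_range_warns_empty(self):
        scored = _obs([(0, 0)], prefix="s")
        reference = _obs([(500, 500)], prefix="r")
        scores = pd.Series([1.0], index=scored.index)
        with pytest.warns(UserWarning):
            curve = mp.score_vs_distance(scores, scored, reference)
        assert np.isnan(curve.mean_score).all()


class TestNeighborScoreCorrelation:
    def test_constant_neighbor_scores_undefined(self):
        rng = np.random.default_rng(6)
        obs_a = _obs(list(map(tuple, rng.uniform(0, 100, size=(20, 2)))), prefix="a")
        obs_b = _obs(list(map(tuple, rng.uniform(0, 100, size=(20, 2)))), prefix="b")
        r, pairs = mp.neighbor_score_correlation(
            pd.Series(rng.normal(size=20), index=obs_a.index),
            obs_a,
            pd.Series(1.0, index=obs_b.index),
            obs_b,
        )
        assert np.isnan(r) and len(pairs) > 0

    def test_exact_linear_dependence(self):
        """A and B cells co-located; B score = 2*A score -> R = 1."""
        rng = np.random.default_rng(7)
        pts = list(map(tuple, rng.uniform(0, 200, size=(30, 2))))
        obs_a = _obs(pts, prefix="a")
        obs_b = _obs(pts, prefix="b")
        base = pd.Series(rng.normal(size=30), index=obs_a.index)
        scores_b = pd.Series(2.0 * base.to_numpy(), index=obs_b.index)
        r, _ = mp.neighbor_score_correlation(base, obs_a, scores_b, obs_b, radius_um=0.5)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_scores_decorrelated(self):
        rng = np.random.default_rng(8)
        obs_a = _obs(list(map(tuple, rng.uniform(0, 300, size=(150, 2)))), prefix="a")
        obs_b = _obs(list(map(tuple, rng.uniform(0, 300, size=(150, 2)))), prefix="b")
        scores_a = pd.Series(rng.normal(size=150), index=obs_a.index)
        scores_b = pd.Series(rng.normal(size=150), index=obs_b.index)
        r, pairs = mp.neighbor_score_correlation(scores_a, obs_a, scores_b, obs_b)
        assert len(pairs) >= 3
        assert abs(r) < 0.3

    def test_too_few_pairs_undefined(self):
        obs_a = _obs([(0, 0)], prefix="a")
        obs_b = _obs([(1, 0)], prefix="b")
        r, pairs = mp.neighbor_score_correlation(
            pd.Series([1.0], index=obs_a.index),
            obs_a,
            pd.Series([2.0], index=obs_b.index),
            obs_b,
        )
        assert np.isnan(r) and len(pairs) == 1
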