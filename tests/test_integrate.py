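"""Joint embedding, kNN imputation, validation correlations, label transfer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import merfishpipe as mp


def _frames(n, genes, seed, prefix):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, len(genes))),
        index=[f"{prefix}{i}" for i in range(n)],
        columns=genes,
    )


class TestJointEmbed:
    def test_identical_modalities_centroids_coincide(self):
        genes = [f"g{i}" for i in range(6)]
        a = _frames(40, genes, 0, "m")
        b = a.copy()
        b.index = [f"s{i}" for i in range(40)]
        emb = mp.joint_embed(a, b, n_pcs=4)
        ca = emb.coordinates.loc[emb.cells("merfish")].mean()
        cb = emb.coordinates.loc[emb.cells("snrnaseq")].mean()
        np.testing.assert_allclose(ca.to_numpy(), cb.to_numpy(), atol=1e-9)

    def test_constant_offset_removed_exactly(self):
        genes = [f"g{i}" for i in range(5)]
        a = _frames(30, genes, 1, "m")
        b = a + 3.0
        b.index = [f"s{i}" for i in range(30)]
        emb = mp.joint_embed(a, b, n_pcs=5)
        ma = emb.coordinates.loc[emb.cells("merfish")].to_numpy()
        mb = emb.coordinates.loc[emb.cells("snrnaseq")].to_numpy()
        np.testing.assert_allclose(ma, mb, atol=1e-8)

    def test_full_rank_pca_preserves_distances(self):
        genes = [f"g{i}" for i in range(4)]
        a = _frames(20, genes, 2, "m")
        b = _frames(20, genes, 3, "s")
        emb = mp.joint_embed(a, b, n_pcs=10, aligner=None)  # capped at rank
        joint = pd.concat([a, b]).to_numpy()
        orig = np.linalg.norm(joint[:1] - joint[1:], axis=1)
        embd = emb.coordinates.to_numpy()
        new = np.linalg.norm(embd[:1] - embd[1:], axis=1)
        np.testing.assert_allclose(new, orig, rtol=1e-9)

    def test_mismatched_gene_sets_rejected(self):
        a = _frames(10, ["g0", "g1"], 0, "m")
        b = _frames(10, ["g0", "g2"], 1, "s")
        with pytest.raises(ValueError):
            mp.joint_embed(a, b)


class TestImputeExpression:
    def _embedding(self, coords_m, coords_s):
        nm, ns = len(coords_m), len(coords_s)
        idx = [f"m{i}" for i in range(nm)] + [f"s{i}" for i in range(ns)]
        coords = pd.DataFrame(
            np.vstack([coords_m, coords_s]),
            index=idx,
            columns=[f"pc{i + 1}" for i in range(coords_m.shape[1])],
        )
        modality = pd.Series(["merfish"] * nm + ["snrnaseq"] * ns, index=idx)
        return mp.JointEmbedding(coords, modality, modality.copy())

    def test_coincident_cell_exact(self):
        emb = self._embedding(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0], [50.0, 50.0]]))
        profiles = pd.DataFrame(
            {"gene_a": [7.0, 100.0], "gene_b": [3.0, 200.0]}, index=["s0", "s1"]
        )
        imputed = mp.impute_expression(emb, profiles, k=1, n_pcs=2)
        assert imputed.loc["m0", "gene_a"] == 7.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        cm, cs = rng.normal(size=(60, 5)), rng.normal(size=(200, 5))
        emb = self._embedding(cm, cs)
        profiles = pd.DataFrame(
            rng.normal(size=(200, 12)),
            index=[f"s{i}" for i in range(200)],
            columns=[f"g{i}" for i in range(12)],
        )
        imputed = mp.impute_expression(emb, profiles, k=10, n_pcs=5)
        for i in [0, 17, 59]:
            d = np.linalg.norm(cs - cm[i], axis=1)
            nn = np.argsort(d, kind="stable")[:10]
            expected = profiles.iloc[nn].mean(axis=0)
            np.testing.assert_allclose(imputed.iloc[i].to_numpy(), expected.to_numpy())

    def test_identical_profiles_reproduced(self):
        rng = np.random.default_rng(5)
        emb = self._embedding(rng.normal(size=(10, 3)), rng.normal(size=(30, 3)))
        profiles = pd.DataFrame(
            np.tile([1.0, 2.0, 3.0], (30, 1)),
            index=[f"s{i}" for i in range(30)],
            columns=["a", "b", "c"],
        )
        imputed = mp.impute_expression(emb, profiles, k=10, n_pcs=3)
        np.testing.assert_allclose(imputed.to_numpy(), np.tile([1.0, 2.0, 3.0], (10, 1)))

    def test_fewer_reference_cells_than_k_warns(self):
        rng = np.random.default_rng(6)
        emb = self._embedding(rng.normal(size=(5, 2)), rng.normal(size=(3, 2)))
        profiles = pd.DataFrame(
            rng.normal(size=(3, 2)), index=[f"s{i}" for i in range(3)], columns=["a", "b"]
        )
        with pytest.warns(UserWarning):
            mp.impute_expression(emb, profiles, k=10, n_pcs=2)


class TestValidationCorrelations:
    def _spatial_obs(self, n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "x_um": rng.uniform(0, 600, n),
                "y_um": rng.uniform(0, 600, n),
                "section": "s0",
            },
            index=[f"c{i}" for i in range(n)],
        )

    def test_self_correlation_is_one(self):
        obs = self._spatial_obs(200, 0)
        measured = _frames(200, ["g0", "g1"], 1, "c")
        measured.index = obs.index
        r = mp.validate_imputation_bins(measured, measured, obs)
        np.testing.assert_allclose(r.to_numpy(), 1.0)

    def test_anticorrelation_is_minus_one(self):
        obs = self._spatial_obs(200, 2)
        measured = _frames(200, ["g0"], 3, "c")
        measured.index = obs.index
        r = mp.validate_imputation_bins(measured, -measured, obs)
        np.testing.assert_allclose(r.to_numpy(), -1.0)

    def test_four_bin_toy_matches_direct_formula(self):
        obs = pd.DataFrame(
            {
                "x_um": [10, 160, 10, 160],
                "y_um": [10, 10, 160, 160],
                "section": "s0",
            },
            index=[f"c{i}" for i in range(4)],
        )
        measured = pd.DataFrame({"g": [1.0, 2.0, 3.0, 4.0]}, index=obs.index)
        imputed = pd.DataFrame({"g": [1.5, 1.0, 4.0, 3.0]}, index=obs.index)
        r = mp.validate_imputation_bins(measured, imputed, obs, bin_um=150)
        expected = stats.pearsonr([1, 2, 3, 4], [1.5, 1.0, 4.0, 3.0])[0]
        assert r["g"] == pytest.approx(expected)

    def test_celltype_region_identity_and_degenerate(self):
        measured = _frames(50, ["g0", "g1", "g2"], 7, "c")
        types = pd.Series(["A"] * 25 + ["B"] * 25, index=measured.index)
        regions = pd.Series(["r1"] * 50, index=measured.index)
        r = mp.validate_imputation_celltype_region(measured, measured, types, regions)
        np.testing.assert_allclose(r.to_numpy(), 1.0)
        # single-gene panel: correlation across one gene is undefined
        r1 = mp.validate_imputation_celltype_region(
            measured[["g0"]], measured[["g0"]], types, regions
        )
        assert r1.isna().all().all()

    def test_three_gene_hand_example(self):
        idx = ["c0", "c1"]
        measured = pd.DataFrame({"g0": [0.0, 2.0], "g1": [2.0, 2.0], "g2": [3.0, 5.0]}, index=idx)
        imputed = pd.DataFrame({"g0": [1.0, 1.0], "g1": [4.0, 2.0], "g2": [2.0, 2.0]}, index=idx)
        types = pd.Series(["A", "A"], index=idx)
        regions = pd.Series(["r", "r"], index=idx)
        out = mp.validate_imputation_celltype_region(measured, imputed, types, regions)
        expected = stats.pearsonr(measured.mean(), imputed.mean())[0]
        assert out.loc["A", "r"] == pytest.approx(expected)


class TestTransferLabels:
    def _separable(self, n_per, seed):
        rng = np.random.default_rng(seed)
        centers = np.array(
            [[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0], [20.0, 0.0], [0.0, 20.0]]
        )
        coords = np.vstack([c + rng.normal(0, 0.5, size=(n_per, 2)) for c in centers])
        labels = np.repeat(["a", "b", "c", "d", "e", "f"], n_per)
        idx = [f"r{i}" for i in range(len(coords))]
        return (
            pd.DataFrame(coords, index=idx, columns=["pc1", "pc2"]),
            pd.Series(labels, index=idx),
        )

    def test_separable_clusters_high_accuracy(self):
        coords, labels = self._separable(60, 0)
        preds = mp.transfer_labels(coords, labels, coords, n_pcs=2, seed=0)
        assert (preds.to_numpy() == labels.to_numpy()).mean() >= 0.95

    def test_single_class_reference(self):
        coords, labels = self._separable(20, 1)
        labels[:] = "only"
        preds = mp.transfer_labels(coords, labels, coords.iloc[:5], n_pcs=2, seed=0)
        assert (preds == "only").all()

    def test_permuted_labels_chance_level(self):
        """Training on shuffled labels predicts held-out truth at chance (1/6)."""
        coords, labels = self._separable(60, 2)
        query, query_labels = self._separable(60, 4)
        query.index = [f"q{i}" for i in range(len(query))]
        rng = np.random.default_rng(3)
        accs = []
        for seed in range(3):
            shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            preds = mp.transfer_labels(coords, shuffled, query, n_pcs=2, seed=seed)
            accs.append((preds.to_numpy() == query_labels.to_numpy()).mean())
        assert np.mean(accs) < 0.5  # chance is 1/6
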