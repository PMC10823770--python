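import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from immucast.datasets import simulate_study
from immucast.deconv import ScoreMatrix, zscore_vs_control
from immucast.stratify import (
    EmbeddingSet,
    assemble_trafficking_features,
    assemble_transcriptome_features,
    embed_candidates,
    filter_compounds_by_alt,
    hierarchical_cluster,
    meta_combine,
    summarize_time_course,
)


class TestAltFilter:
    def _meta(self, alts_by_compound):
        rows = []
        rows.append(
            dict(compound="vehicle", dose_group="high", time_h=9.0,
                 replicate=1, is_control=True, control_group_key="c",
                 alt=20.0)
        )
        for cmpd, alts in alts_by_compound.items():
            for i, (t, alt) in enumerate(alts):
                rows.append(
                    dict(compound=cmpd, dose_group="high", time_h=t,
                         replicate=i + 1, is_control=False,
                         control_group_key="c", alt=alt)
                )
        return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])

    def test_peak_above_threshold_retained(self):
        meta = self._meta({"a": [(9.0, 40.0), (24.0, 80.0)]})
        assert filter_compounds_by_alt(meta) == ["a"]

    def test_all_below_threshold_dropped(self):
        meta = self._meta({"a": [(9.0, 40.0), (24.0, 60.0)]})
        assert filter_compounds_by_alt(meta) == []

    def test_zero_threshold_keeps_everything(self):
        meta = self._meta({"a": [(9.0, 1.0)], "b": [(3.0, 2.0)]})
        assert filter_compounds_by_alt(meta, threshold=0.0) == ["a", "b"]

    def test_late_elevation_outside_window_ignored(self):
        meta = self._meta({"a": [(9.0, 40.0), (48.0, 500.0)]})
        assert filter_compounds_by_alt(meta) == []

    def test_missing_alt_is_an_error(self):
        meta = self._meta({"a": [(9.0, 40.0)]}).drop(columns=["alt"])
        with pytest.raises(ValueError, match="ALT"):
            filter_compounds_by_alt(meta)


class TestTraffickingFeatures:
    def test_feature_count_and_replicate_mean(self, small_study):
        z = zscore_vs_control(
            ScoreMatrix(small_study.truth.true_proportions),
            small_study.metadata,
        )
        feats = assemble_trafficking_features(z, small_study.metadata)
        assert feats.shape == (16, 16)
        # recompute one cell by hand
        meta = small_study.metadata
        cmpd = feats.index[0]
        samples = meta.index[
            (meta["compound"] == cmpd) & (meta["time_h"] == 3.0)
        ]
        assert feats.loc[cmpd, "Mon@3h"] == pytest.approx(
            z.data.loc["Mon", samples].mean()
        )

    def test_requires_control_zscored_input(self, small_study):
        raw = ScoreMatrix(small_study.truth.true_proportions, "raw")
        with pytest.raises(ValueError, match="scale_tag"):
            assemble_trafficking_features(raw, small_study.metadata)

    def test_null_study_features_near_zero(self):
        study = simulate_study(effect_scale=0.0, seed=21)
        z = zscore_vs_control(
            ScoreMatrix(study.truth.true_proportions), study.metadata
        )
        feats = assemble_trafficking_features(z, study.metadata)
        # shared-control z offsets are common to all compounds, so the
        # null bound scales with the replicate count only
        assert np.abs(feats.mean(axis=0)).max() < 3 / np.sqrt(3)


class TestTranscriptomeFeatures:
    def test_columns_standardized_and_counted(self, small_study):
        expr = small_study.expression.iloc[:30]
        feats = assemble_transcriptome_features(expr, small_study.metadata)
        assert feats.shape == (16, 30 * 4)
        np.testing.assert_allclose(feats.mean(axis=0), 0.0, atol=1e-12)

    def test_constant_gene_dropped_with_warning(self, small_study):
        expr = small_study.expression.iloc[:10].copy()
        expr.iloc[0] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            feats = assemble_transcriptome_features(expr, small_study.metadata)
        assert feats.shape[1] == 9 * 4


def _blob_features(rng, n=16, gap=30.0):
    labels = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1, (n, 6)) + labels[:, None] * gap
    return (
        pd.DataFrame(X, index=[f"c{i:02d}" for i in range(n)]),
        labels,
    )


class TestEmbedCandidates:
    def test_sixteen_compounds_give_six_candidates(self, rng):
        feats, _ = _blob_features(rng)
        emb = embed_candidates(feats, seed=0)
        assert len(emb.method_names) == 6
        assert all(c.shape == (16, 2) for c in emb.coords)

    def test_same_seed_reproduces_all_methods(self, rng):
        feats, _ = _blob_features(rng)
        a = embed_candidates(feats, seed=5)
        b = embed_candidates(feats, seed=5)
        for ca, cb in zip(a.coords, b.coords):
            np.testing.assert_allclose(ca, cb)

    def test_duplicate_rows_coincide_for_distance_preserving_methods(self, rng):
        feats, _ = _blob_features(rng)
        feats.iloc[1] = feats.iloc[0]
        emb = embed_candidates(feats, seed=0)
        # PCA is exact; SMACOF (MDS) converges to its iteration tolerance
        for name, atol in (("pca", 1e-8), ("mds", 1e-2)):
            c = emb.coords[emb.method_names.index(name)]
            np.testing.assert_allclose(c[0], c[1], atol=atol)

    def test_too_few_points_rejected(self, rng):
        feats, _ = _blob_features(rng)
        with pytest.raises(ValueError, match="at least 6"):
            embed_candidates(feats.iloc[:4], seed=0)


class TestMetaCombine:
    def test_single_candidate_identity(self, rng):
        coords = rng.normal(0, 1, (8, 2))
        emb = EmbeddingSet(
            point_ids=[f"p{i}" for i in range(8)],
            method_names=["only"],
            coords=[coords],
        )
        md = meta_combine(emb)
        D = squareform(pdist(coords))
        expected = D / np.linalg.norm(D, axis=1, keepdims=True)
        expected = (expected + expected.T) / 2
        np.testing.assert_allclose(md.matrix.to_numpy(), expected, atol=1e-12)
        np.testing.assert_allclose(md.weights.to_numpy(), 1.0)

    def test_duplicated_candidate_splits_weight_evenly(self, rng):
        coords = rng.normal(0, 1, (10, 2))
        emb = EmbeddingSet(
            point_ids=[f"p{i}" for i in range(10)],
            method_names=["a", "b"],
            coords=[coords, coords.copy()],
        )
        md = meta_combine(emb)
        np.testing.assert_allclose(md.weights.to_numpy(), 0.5, atol=1e-8)
        solo = meta_combine(
            EmbeddingSet(emb.point_ids, ["a"], [coords])
        )
        rho = spearmanr(
            squareform(md.matrix.to_numpy(), checks=False),
            squareform(solo.matrix.to_numpy(), checks=False),
        ).statistic
        assert rho == pytest.approx(1.0)

    def test_majority_of_copies_outweighs_dissident(self, rng):
        """Two copies of one embedding vs an unrelated one: the copies win.

        Cross-checked against a direct eigen-decomposition of each point's
        3x3 comparison matrix.
        """
        A = rng.normal(0, 1, (9, 2))
        B = rng.normal(0, 1, (9, 2))
        emb = EmbeddingSet(
            point_ids=[f"p{i}" for i in range(9)],
            method_names=["a1", "a2", "b"],
            coords=[A, A.copy(), B],
        )
        md = meta_combine(emb)
        w = md.weights
        assert (w["a1"] > w["b"]).all() and (w["a2"] > w["b"]).all()
        # independent oracle for point 0
        dA = np.delete(squareform(pdist(A))[0], 0)
        dB = np.delete(squareform(pdist(B))[0], 0)
        U = np.stack([dA / np.linalg.norm(dA)] * 2 + [dB / np.linalg.norm(dB)])
        evals, evecs = np.linalg.eigh(U @ U.T)
        expected = np.abs(evecs[:, -1])
        expected /= expected.sum()
        np.testing.assert_allclose(
            md.weights.iloc[0].to_numpy(), expected, atol=1e-10
        )

    def test_valid_dissimilarity_and_weight_simplex(self, rng):
        feats, _ = _blob_features(rng)
        emb = embed_candidates(feats, seed=1)
        md = meta_combine(emb)
        M = md.matrix.to_numpy()
        assert np.allclose(M, M.T, atol=1e-12)
        assert np.all(np.diag(M) == 0)
        assert (M >= 0).all()
        W = md.weights.to_numpy()
        assert (W >= 0).all()
        np.testing.assert_allclose(W.sum(axis=1), 1.0)

    def test_invariant_to_rigid_motion_of_candidates(self, rng):
        coords = [rng.normal(0, 1, (7, 2)) for _ in range(3)]
        ids = [f"p{i}" for i in range(7)]
        emb = EmbeddingSet(ids, ["x", "y", "z"], coords)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = [c @ R + np.array([3.0, -2.0]) for c in coords]
        emb2 = EmbeddingSet(ids, ["x", "y", "z"], moved)
        np.testing.assert_allclose(
            meta_combine(emb).matrix.to_numpy(),
            meta_combine(emb2).matrix.to_numpy(),
            atol=1e-9,
        )


class TestHierarchicalCluster:
    def _md(self, rng, n=16, gap=30.0):
        feats, labels = _blob_features(rng, n=n, gap=gap)
        emb = embed_candidates(feats, seed=0)
        return meta_combine(emb), labels

    def test_two_separated_blobs_split_perfectly(self, rng):
        md, labels = self._md(rng)
        assign = hierarchical_cluster(md, n_clusters=2)
        got = np.array([assign.labels[c] for c in md.matrix.index])
        assert len(set(zip(got, labels))) == 2

    def test_n_clusters_equal_n_gives_singletons(self, rng):
        md, _ = self._md(rng)
        assign = hierarchical_cluster(md, n_clusters=16)
        assert sorted(assign.labels.values()) == list(range(1, 17))

    def test_label_numbering_by_size_then_first_member(self):
        from immucast.stratify import MetaDistance

        # 2 tight points far from a tight 4-point group: smaller cluster
        # must receive label 1
        ids = ["u1", "u2", "v1", "v2", "v3", "v4"]
        pos = np.array([0.0, 0.1, 50.0, 50.1, 50.2, 50.3])[:, None]
        D = squareform(pdist(pos))
        md = MetaDistance(
            matrix=pd.DataFrame(D, index=ids, columns=ids),
            weights=pd.DataFrame(np.ones((6, 1)), index=ids, columns=["m"]),
        )
        assign = hierarchical_cluster(md, n_clusters=2)
        assert assign.labels == {
            "u1": 1, "u2": 1, "v1": 2, "v2": 2, "v3": 2, "v4": 2
        }

    def test_excessive_n_clusters_rejected(self, rng):
        md, _ = self._md(rng)
        with pytest.raises(ValueError, match="n_clusters"):
            hierarchical_cluster(md, n_clusters=17)


class TestSummarizeTimeCourse:
    def test_constant_values_zero_width_ci(self, small_study):
        from immucast.stratify import ClusterAssignment

        meta = small_study.metadata
        vals = pd.DataFrame(
            np.zeros((1, meta.shape[0])), index=["Mon"], columns=meta.index
        )
        compounds = sorted(meta.loc[~meta["is_control"], "compound"].unique())
        assign = ClusterAssignment({c: 1 for c in compounds})
        out = summarize_time_course(vals, meta, assign)
        assert (out["mean"] == 0).all()
        np.testing.assert_allclose(out["ci_high"] - out["ci_low"], 0.0)

    def test_single_sample_ci_flagged_undefined(self, toy_meta):
        from immucast.stratify import ClusterAssignment

        vals = pd.DataFrame(
            [np.arange(8.0)], index=["Mon"], columns=toy_meta.index
        )
        assign = ClusterAssignment({"drugA": 1})
        out = summarize_time_course(vals, toy_meta, assign)
        assert not out["ci_defined"].any()  # one treated sample per time
        assert out["mean"].notna().all()

    def test_ci_width_halves_when_n_quadruples(self, rng):
        from immucast.stratify import ClusterAssignment

        def build(n_rep):
            rows = []
            for r in range(1, 3):
                rows.append(dict(compound="vehicle", dose_group="h",
                                 time_h=3.0, replicate=r, is_control=True,
                                 control_group_key="c", alt=10.0))
            for r in range(n_rep):
                rows.append(dict(compound="a", dose_group="h", time_h=3.0,
                                 replicate=r + 1, is_control=False,
                                 control_group_key="c", alt=100.0))
            meta = pd.DataFrame(
                rows, index=[f"s{i}" for i in range(len(rows))]
            )
            vals = np.zeros(len(rows))
            # +/- pattern rescaled so the ddof=1 SD is exactly 1 at any n
            pattern = np.tile([1.0, -1.0], n_rep)[:n_rep]
            vals[2:] = pattern * np.sqrt((n_rep - 1) / n_rep)
            table = pd.DataFrame([vals], index=["Mon"], columns=meta.index)
            out = summarize_time_course(
                table, meta, ClusterAssignment({"a": 1})
            )
            return float((out["ci_high"] - out["ci_low"]).iloc[0])

        w4, w16 = build(4), build(16)
        assert w16 == pytest.approx(w4 / 2, rel=0.05)
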