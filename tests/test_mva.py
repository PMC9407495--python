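"""PCA, hierarchical clustering, newick export and OPLS-DA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from flavopath.sample_io import ANALYTE_CODES
from flavopath.mva import (
    altitude_split_labels,
    export_newick,
    run_hca,
    run_oplsda,
    run_pca,
)
from flavopath.synth import default_config, generate


class TestPCA:
    def test_fixture_pc1_near_published_value(self, fixture_table):
        res = run_pca(fixture_table, list(ANALYTE_CODES))
        assert res.explained_pct[0] == pytest.approx(48.36, abs=0.5)

    def test_rank_one_data_gives_single_component(self):
        x = np.arange(10.0)
        frame = pd.DataFrame({"u": x, "v": 2 * x + 3})
        res = run_pca(frame, ["u", "v"])
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_variance_conservation(self, fixture_table):
        res = run_pca(fixture_table, list(ANALYTE_CODES))
        assert res.explained_pct.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.explained_pct) <= 1e-10)
        assert res.cumulative_pct[-1] == pytest.approx(100.0)

    def test_scores_centered_with_diagonal_covariance(self, fixture_table):
        res = run_pca(fixture_table, list(ANALYTE_CODES))
        scores = res.scores.to_numpy()
        assert np.allclose(scores.mean(axis=0), 0, atol=1e-10)
        cov = scores.T @ scores
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_loading_columns_orthonormal(self, fixture_table):
        L = run_pca(fixture_table, list(ANALYTE_CODES)).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_sign_convention_dominant_loading_positive(self, fixture_table):
        L = run_pca(fixture_table, list(ANALYTE_CODES)).loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_unit_variance_pca_invariant_to_rescaling(self, fixture_table):
        frame = fixture_table.matrix(list(ANALYTE_CODES))
        scaled = frame * 7.5 + 2.0
        a = run_pca(frame, list(ANALYTE_CODES))
        b = run_pca(scaled, list(ANALYTE_CODES))
        assert np.allclose(a.explained_pct, b.explained_pct)
        assert np.allclose(a.scores, b.scores, atol=1e-8)

    def test_missing_cells_rejected(self):
        frame = pd.DataFrame({"u": [1.0, np.nan, 3.0], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            run_pca(frame, ["u", "v"])

    def test_constant_column_rejected_under_unit_variance(self):
        frame = pd.DataFrame({"u": [1.0, 1.0, 1.0], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            run_pca(frame, ["u", "v"])
        run_pca(frame, ["u", "v"], scaling="center_only")  # allowed


class TestHCA:
    def test_identical_rows_merge_at_zero(self):
        frame = pd.DataFrame({"u": [1.0, 1.0, 5.0], "v": [2.0, 2.0, 9.0]},
                             index=["s1", "s2", "s3"])
        res = run_hca(frame, ["u", "v"])
        assert res.merge_tree[0, 2] == pytest.approx(0.0)

    def test_three_point_line_first_merge(self):
        # distances after unit-variance scaling keep the {0,1} pair closest
        frame = pd.DataFrame({"u": [0.0, 1.0, 5.0], "v": [0.0, 1.0, 5.0]},
                             index=["p0", "p1", "p5"])
        res = run_hca(frame, ["u", "v"])
        first = sorted(res.merge_tree[0, :2].astype(int))
        assert [res.labels[i] for i in first] == ["p0", "p1"]

    def test_fixture_high_altitude_group_forms_one_clade(self, fixture_table):
        res = run_hca(fixture_table, list(ANALYTE_CODES))
        clades = res.leaf_sets()
        assert frozenset({f"A{i}" for i in range(1, 7)}) in clades

    def test_every_leaf_appears_once(self, fixture_table):
        res = run_hca(fixture_table, list(ANALYTE_CODES))
        assert sorted(res.order) == sorted(fixture_table.sample_ids)

    def test_merge_heights_nondecreasing_complete_linkage(self, fixture_table):
        res = run_hca(fixture_table, list(ANALYTE_CODES), linkage="complete")
        heights = res.merge_tree[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_complete_heights_dominate_single_brute_force(self):
        """Complete-linkage merge heights are >= single-linkage heights at
        every merge, checked against a brute-force linkage recomputation."""
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("uvw"),
                             index=[f"s{i}" for i in range(8)])
        complete = run_hca(frame, list("uvw"), linkage="complete")
        single = run_hca(frame, list("uvw"), linkage="single")
        assert np.all(complete.merge_tree[:, 2] >= single.merge_tree[:, 2] - 1e-12)

        # brute force single linkage: minimal spanning distances
        from scipy.spatial.distance import squareform, pdist
        Z = complete.scaled_matrix.to_numpy()
        D = squareform(pdist(Z))
        clusters = [{i} for i in range(8)]
        bf_heights = []
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(range(len(clusters)), 2):
                d = min(D[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
            d, a, b = best
            bf_heights.append(d)
            clusters = ([c for k, c in enumerate(clusters) if k not in (a, b)]
                        + [clusters[a] | clusters[b]])
        assert np.allclose(sorted(bf_heights), sorted(single.merge_tree[:, 2]))

    def test_too_few_samples_rejected(self):
        frame = pd.DataFrame({"u": [1.0], "v": [2.0]}, index=["s"])
        with pytest.raises(ValueError):
            run_hca(frame, ["u", "v"])


class TestNewick:
    def test_two_leaf_shape(self):
        frame = pd.DataFrame({"u": [0.0, 1.0], "v": [0.0, 1.0]},
                             index=["A", "B"])
        res = run_hca(frame, ["u", "v"])
        h = res.merge_tree[0, 2]
        nwk = export_newick(res)
        assert nwk == f"(A:{h/2:.10g},B:{h/2:.10g});"

    def test_leaf_count_preserved(self, fixture_table):
        res = run_hca(fixture_table, list(ANALYTE_CODES))
        nwk = export_newick(res)
        for sid in fixture_table.sample_ids:
            assert sid in nwk
        assert nwk.count(",") == 25  # 26 leaves

    def test_round_trip_recovers_topology(self, fixture_table):
        dendropy = pytest.importorskip("dendropy")
        res = run_hca(fixture_table, list(ANALYTE_CODES))
        tree = dendropy.Tree.get(data=export_newick(res), schema="newick")
        clades = set()
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.parent_node is not None:
                clades.add(frozenset(
                    leaf.taxon.label for leaf in node.leaf_iter()))
        expected = {c for c in res.leaf_sets() if len(c) < 26}
        assert clades == expected


class TestOPLSDA:
    @staticmethod
    def _shifted_cohort(seed=0, n=30, p=8, shift=3.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        cls = np.array(["high"] * (n // 2) + ["low"] * (n - n // 2))
        X[cls == "high", 0] += shift
        frame = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
        return frame, pd.Series(cls, index=frame.index)

    def test_orthogonal_scores_uncorrelated_with_class(self):
        frame, cls = self._shifted_cohort()
        res = run_oplsda(frame, list(frame.columns), cls, n_orth=2)
        y = np.where(cls == "low", 1.0, -1.0)
        y = y - y.mean()
        for col in res.orthogonal_scores:
            cov = float(res.orthogonal_scores[col] @ y)
            assert abs(cov) < 1e-10

    def test_mean_shift_separates_classes_perfectly(self):
        frame, cls = self._shifted_cohort(shift=3.0)
        res = run_oplsda(frame, list(frame.columns), cls)
        score_sign = np.sign(res.predictive_scores.to_numpy())
        labels = np.where(cls == cls.unique()[0], 1.0, -1.0)
        agreement = score_sign * np.sign(labels)
        assert abs(agreement.sum()) == len(frame)  # all same side

    def test_pure_noise_response_gives_nonpositive_q2(self):
        """With no real class structure, cross-validated Q2 is <= 0 in
        expectation (estimated over 100 seeded replicates)."""
        rng = np.random.default_rng(12)
        q2s = []
        for rep in range(100):
            X = rng.normal(size=(24, 6))
            cls = pd.Series(["a"] * 12 + ["b"] * 12)
            frame = pd.DataFrame(X, columns=[f"v{i}" for i in range(6)])
            res = run_oplsda(frame, list(frame.columns), cls, n_orth=1,
                             seed=rep)
            q2s.append(res.q2)
        assert np.mean(q2s) < 0

    def test_r2y_bounds_and_quality_on_separated_data(self):
        frame, cls = self._shifted_cohort()
        res = run_oplsda(frame, list(frame.columns), cls)
        assert 0.0 <= res.r2y <= 1.0
        assert res.q2 > 0.5

    def test_single_class_rejected(self):
        frame, _ = self._shifted_cohort()
        with pytest.raises(ValueError, match="2 classes"):
            run_oplsda(frame, list(frame.columns), ["x"] * len(frame))

    def test_n_orth_at_rank_rejected(self):
        frame, cls = self._shifted_cohort(n=10, p=3)
        with pytest.raises(ValueError, match="rank"):
            run_oplsda(frame, list(frame.columns), cls, n_orth=3)

    def test_zero_orthogonal_matches_pls_regression(self):
        """With no orthogonal filter the predictive component equals the
        first component of a plain PLS regression on the same data."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        frame, cls = self._shifted_cohort(seed=5, n=20, p=5, shift=1.0)
        res = run_oplsda(frame, list(frame.columns), cls, n_orth=0)
        X = frame.to_numpy()
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.where(cls == sorted(cls.unique())[1], 1.0, -1.0)
        y = y - y.mean()
        pls = sklearn.PLSRegression(n_components=1, scale=False).fit(X, y)
        t_ref = pls.x_scores_[:, 0]
        t_ours = res.predictive_scores.to_numpy()
        ratio = t_ours @ t_ref / (np.linalg.norm(t_ours) * np.linalg.norm(t_ref))
        assert abs(abs(ratio) - 1.0) < 1e-8

    def test_default_altitude_split_on_synthetic_cohort(self):
        table, _ = generate(default_config(), seed=21)
        labels = altitude_split_labels(table)
        assert set(labels.unique()) == {"high", "low"}
        assert (labels == "high").sum() == 10  # groups A + B: 5 + 5
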