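"""Sparse PLS-DA: dense equivalence, selection, prediction, tuning, AUROC."""

import itertools

import numpy as np
import pytest

import fibrospec as fs
from fibrospec.splsda import auroc, one_vs_rest_auroc


def nipals_pls2_scores(X, Y, ncomp):
    """Independent dense PLS2 oracle (classic NIPALS iteration)."""
    X = X.copy()
    Y = Y.copy()
    T = []
    for _ in range(ncomp):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        for _ in range(1000):
            w = X.T @ u / (u @ u)
            w /= np.linalg.norm(w)
            t = X @ w
            q = Y.T @ t / (t @ t)
            u_new = Y @ q / (q @ q)
            if np.linalg.norm(u_new - u) < 1e-12 * max(1.0, np.linalg.norm(u)):
                u = u_new
                break
            u = u_new
        t = X @ w
        p = X.T @ t / (t @ t)
        q = Y.T @ t / (t @ t)
        X -= np.outer(t, p)
        Y -= np.outer(t, q)
        T.append(t)
    return np.column_stack(T)


def make_classes(rng, n, p, separation=1.0, n_classes=3):
    y = np.repeat([f"c{i}" for i in range(n_classes)], int(np.ceil(n / n_classes)))[:n]
    means = rng.normal(size=(n_classes, p)) * separation
    X = rng.normal(size=(n, p))
    for i in range(n_classes):
        X[y == f"c{i}"] += means[i]
    return X, y


class TestFit:
    def test_dense_keepx_equals_nipals_scores(self, rng):
        for _ in range(5):
            n, p = int(rng.integers(12, 30)), int(rng.integers(5, 20))
            X, y = make_classes(rng, n, p)
            res = fs.splsda_fit(X, y, 2, [p, p])
            classes = sorted(np.unique(y))
            Y = np.column_stack([(y == c).astype(float) for c in classes])
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            T = nipals_pls2_scores(Xs, Y - Y.mean(0), 2)
            for c in range(2):
                err = min(
                    np.abs(res.x_scores[:, c] - T[:, c]).max(),
                    np.abs(res.x_scores[:, c] + T[:, c]).max(),
                )
                assert err < 1e-8

    def test_keepx_controls_sparsity_exactly(self, rng):
        X, y = make_classes(rng, 24, 50)
        res = fs.splsda_fit(X, y, 3, [7, 5, 3])
        for c, k in enumerate([7, 5, 3]):
            assert int(np.count_nonzero(res.x_weights[:, c])) == k
            assert np.linalg.norm(res.x_weights[:, c]) == pytest.approx(1.0)

    def test_single_informative_variable_selected(self, rng):
        n = 40
        y = np.array(["a"] * 20 + ["b"] * 20)
        X = rng.normal(size=(n, 50))
        X[:, 17] += np.where(y == "a", 3.0, -3.0)  # the one informative variable
        res = fs.splsda_fit(X, y, 1, [1])
        assert np.flatnonzero(res.x_weights[:, 0]).tolist() == [17]

    def test_informative_variable_recovery_rate(self):
        """5 informative variables among 200 (2 SD effect, n=60): component-1
        selection with keep_x=5 recovers >= 4 of 5 in >= 90% of seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.repeat(["a", "b"], 30)
            X = rng.normal(size=(60, 200))
            X[:, :5] += np.where(y == "a", 1.0, -1.0)[:, None]  # 2 SD separation
            res = fs.splsda_fit(X, y, 1, [5])
            sel = set(res.variable_index[np.flatnonzero(res.x_weights[:, 0])])
            if len(sel & {0, 1, 2, 3, 4}) >= 4:
                hits += 1
        assert hits >= 90

    def test_sixty_forty_twenty_shape_accepted(self, rng):
        X, y = make_classes(rng, 30, 100)
        res = fs.splsda_fit(X, y, 3, [60, 40, 20])
        assert res.x_weights.shape[1] == 3
        assert [int(np.count_nonzero(res.x_weights[:, c])) for c in range(3)] == [60, 40, 20]

    def test_scores_orthogonal(self, rng):
        X, y = make_classes(rng, 30, 40)
        res = fs.splsda_fit(X, y, 3, [10, 10, 10])
        G = res.x_scores.T @ res.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(G)).max()

    def test_constant_columns_dropped_with_warning(self, rng):
        X, y = make_classes(rng, 20, 10)
        X[:, 4] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            res = fs.splsda_fit(X, y, 1, [5])
        assert 4 not in res.variable_index

    def test_input_validation(self, rng):
        X, y = make_classes(rng, 12, 6)
        with pytest.raises(fs.SpectraError):
            fs.SparsePLSDA(X, y, n_components=50)
        with pytest.raises(fs.SpectraError):
            fs.SparsePLSDA(X, y, 1, keep_x=[99])
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(fs.SpectraError):
            fs.SparsePLSDA(Xn, y)

    def test_summary_mentions_shape(self, rng):
        X, y = make_classes(rng, 18, 12)
        text = fs.splsda_fit(X, y, 2, [4, 4]).summary()
        assert "keep_x" in text and "balanced error rate" in text


class TestPredict:
    def test_separable_training_error_zero(self, rng):
        X, y = make_classes(rng, 30, 20, separation=4.0)
        res = fs.splsda_fit(X, y, 2, [10, 10])
        assert res.balanced_error_rate(X, y) == 0.0

    def test_sample_at_centroid_gets_that_class(self, rng):
        X, y = make_classes(rng, 30, 20, separation=4.0)
        res = fs.splsda_fit(X, y, 2, [10, 10])
        # invert the projection approximately: use a training sample closest
        # to each centroid instead of reconstructing from scores
        for j, c in enumerate(res.classes_):
            d = np.linalg.norm(res.x_scores - res.centroids[j], axis=1)
            labels, _ = res.predict(X[int(np.argmin(d))])
            assert labels[0] == c

    def test_variable_permutation_equivariance(self, rng):
        X, y = make_classes(rng, 24, 15, separation=2.0)
        res = fs.splsda_fit(X, y, 2, [8, 8])
        X_new = rng.normal(size=(5, 15)) + X[:5]
        base = res.predict(X_new)[0]
        perm = rng.permutation(15)
        Xp = X[:, perm]
        res_p = fs.splsda_fit(Xp, y, 2, [8, 8])
        got = res_p.predict(X_new[:, perm])[0]
        assert np.array_equal(got, base)


class TestTune:
    def test_separable_data_reaches_zero_error(self, rng):
        X, y = make_classes(rng, 30, 30, separation=4.0)
        tr = fs.tune_splsda(X, y, grid=(5, 10), n_components_max=2, repeats=5, seed=3)
        assert tr.stage_errors[tr.n_components - 1] == 0.0

    def test_deterministic_under_seed(self, rng):
        X, y = make_classes(rng, 24, 25, separation=1.0)
        t1 = fs.tune_splsda(X, y, grid=(5, 10), n_components_max=2, repeats=4, seed=9)
        t2 = fs.tune_splsda(X, y, grid=(5, 10), n_components_max=2, repeats=4, seed=9)
        assert t1.keep_x == t2.keep_x and t1.n_components == t2.n_components
        assert t1.table.equals(t2.table)

    def test_label_permutation_is_chance_level(self, rng):
        X, y = make_classes(rng, 30, 40, separation=3.0)
        errs = []
        for i in range(30):
            yp = rng.permutation(y)
            tr = fs.tune_splsda(X, yp, grid=(10,), n_components_max=1,
                                repeats=2, seed=100 + i)
            errs.append(tr.stage_errors[0])
        assert np.mean(errs) == pytest.approx(2.0 / 3.0, abs=0.06)

    def test_class_smaller_than_folds_rejected(self, rng):
        X = rng.normal(size=(8, 5))
        y = np.array(["a"] * 2 + ["b"] * 6)
        with pytest.raises(fs.SpectraError, match="folds"):
            fs.tune_splsda(X, y, grid=(2,), folds=3, repeats=2)


class TestAuroc:
    def test_worked_example_eight_ninths(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        pos = [True, True, True, False, False, False]
        assert auroc(scores, pos).auc == pytest.approx(8.0 / 9.0)

    def test_perfect_and_all_tied(self):
        assert auroc([3, 2, 1, 0], [True, True, False, False]).auc == 1.0
        assert auroc([1, 1, 1, 1], [True, False, True, False]).auc == 0.5

    def test_equals_concordance_count_exhaustively(self, rng):
        """Discrete scores with every tie pattern, n <= 8: AUROC equals the
        brute-force pairwise concordance (ties counted 1/2)."""
        for _ in range(200):
            n = int(rng.integers(2, 9))
            scores = rng.integers(0, 4, size=n).astype(float)
            pos = rng.integers(0, 2, size=n).astype(bool)
            if pos.all() or not pos.any():
                continue
            brute = np.mean([
                1.0 if sp > sn else (0.5 if sp == sn else 0.0)
                for sp in scores[pos]
                for sn in scores[~pos]
            ])
            assert auroc(scores, pos).auc == pytest.approx(brute, abs=1e-12)

    def test_curve_monotone(self, rng):
        r = auroc(rng.normal(size=20), rng.integers(0, 2, 20).astype(bool))
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
        assert r.fpr[-1] == 1.0 and r.tpr[-1] == 1.0


class TestArtifacts:
    def test_tables_have_declared_shapes(self, rng):
        X, y = make_classes(rng, 24, 30, separation=2.0)
        res = fs.splsda_fit(X, y, 3, [6, 5, 4])
        art = fs.export_model_artifacts(res)
        assert art["scores"].shape == (24, 4)  # class + 3 components
        counts = art["loadings"].groupby("component").size()
        assert counts.tolist() == [6, 5, 4]
        assert set(art["correlations"].columns) == {"variable", "comp1", "comp2", "comp3"}

    def test_retained_variables_correlate_with_their_component(self, rng):
        n = 60
        y = np.array(["a"] * 30 + ["b"] * 30)
        X = rng.normal(size=(n, 30))
        X[:, :3] += np.where(y == "a", 2.0, -2.0)[:, None]
        res = fs.splsda_fit(X, y, 1, [3])
        art = fs.export_model_artifacts(res)
        retained = set(art["loadings"]["variable"])
        assert retained == {"v0", "v1", "v2"}
        mean_r = art["correlations"]["comp1"].abs().mean()
        # noise variables barely correlate with the score by construction
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        noise_r = np.abs(
            [np.corrcoef(Xs[:, j], res.x_scores[:, 0])[0, 1] for j in range(5, 30)]
        ).mean()
        assert mean_r > noise_r + 0.3


def test_cross_validated_values_deterministic(rng):
    X = rng.normal(size=(18, 20))
    y = np.repeat(["a", "b", "c"], 6)
    v1 = fs.cross_validated_values(X, y, 1, [5], repeats=3, seed=7)
    v2 = fs.cross_validated_values(X, y, 1, [5], repeats=3, seed=7)
    assert np.array_equal(v1, v2)
    rocs = one_vs_rest_auroc(v1, y)
    assert set(rocs) == {"a", "b", "c"}
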