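"""Sparse partial least squares-discriminant analysis (sPLS-DA).

The classifier used for spectral phenotyping: class labels are dummy-coded
into an indicator matrix Y, and sparse PLS2 components are extracted from the
(centered, optionally unit-variance scaled) spectra matrix X.  Per component
the dominant singular pair of X_d' Y_d gives the X-weight vector, which is
soft-thresholded so that exactly ``keep_x[c]`` variables stay nonzero, then
renormalized; both X and Y are deflated by regression on the score t = X_d w
(PLS2 regression mode).  Samples are classified by the nearest class centroid
in score space.  With ``keep_x = p`` the model reduces to dense PLS-DA.

Organisation follows the model/results convention: build a
:class:`SparsePLSDA` from data, call :meth:`~SparsePLSDA.fit`, and work with
the returned :class:`SPLSDAResults` (scores, loadings, centroids, prediction,
``summary()``).  Cross-validated tuning of ``keep_x`` and the component count
uses stratified M-fold CV with repeats, scored by the balanced error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .spectra import SpectraError

__all__ = [
    "SparsePLSDA",
    "SPLSDAResults",
    "TuneResult",
    "RocResult",
    "splsda_fit",
    "tune_splsda",
    "cross_validated_values",
    "auroc",
    "one_vs_rest_auroc",
    "export_model_artifacts",
]

DEFAULT_KEEPX_GRID = (5, 10, 20, 40, 60, 80)


# ---------------------------------------------------------------------------
# model


class SparsePLSDA:
    """sPLS-DA model specification.

    Parameters
    ----------
    X : (n_samples, n_variables) array
        Predictor matrix (e.g. second-derivative intensities).
    y : (n_samples,) array of labels
        Class labels; every class needs >= 2 samples.
    n_components : int
        Number of latent components; <= min(n - 1, p).
    keep_x : sequence of int, optional
        Retained-variable count per component (each in [1, p]).  Default: all
        variables (dense PLS-DA).
    scale : bool
        Unit-variance scale the columns of X (default True).  Constant
        columns are dropped with a warning either way.
    """

    def __init__(self, X, y, n_components: int = 2, keep_x=None, scale: bool = True):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise SpectraError("X must be 2-D")
        if np.isnan(X).any():
            raise SpectraError("X must not contain missing values")
        y = np.asarray(y)
        if y.shape != (X.shape[0],):
            raise SpectraError("y length must match X rows")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise SpectraError("need >= 2 classes")
        if counts.min() < 2:
            raise SpectraError("every class needs >= 2 samples")
        if not 1 <= n_components <= min(X.shape[0] - 1, X.shape[1]):
            raise SpectraError(
                f"n_components must be in [1, min(n-1, p)] = "
                f"[1, {min(X.shape[0] - 1, X.shape[1])}]"
            )
        self.X, self.y = X, y
        self.classes_ = [str(c) for c in classes]
        self.n_components = int(n_components)
        if keep_x is None:
            keep_x = [X.shape[1]] * n_components
        keep_x = [int(k) for k in keep_x]
        if len(keep_x) != n_components:
            raise SpectraError("keep_x must have one entry per component")
        if any(not 1 <= k <= X.shape[1] for k in keep_x):
            raise SpectraError(f"keep_x entries must be in [1, {X.shape[1]}]")
        self.keep_x = keep_x
        self.scale = bool(scale)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "SPLSDAResults":
        X, y = self.X, self.y
        classes = self.classes_
        Y = np.column_stack([(y.astype(str) == c).astype(float) for c in classes])

        std = X.std(axis=0, ddof=1)
        kept_cols = np.flatnonzero(std > 0)
        if kept_cols.size < X.shape[1]:
            warnings.warn(
                f"dropping {X.shape[1] - kept_cols.size} constant variable column(s)"
            )
        if kept_cols.size < max(self.keep_x):
            raise SpectraError("keep_x exceeds the number of non-constant variables")
        Xk = X[:, kept_cols]
        x_mean = Xk.mean(axis=0)
        x_std = std[kept_cols] if self.scale else np.ones(kept_cols.size)
        Xs = (Xk - x_mean) / x_std
        y_mean = Y.mean(axis=0)
        Yd = Y - y_mean
        Xd = Xs.copy()

        p = Xk.shape[1]
        A = self.n_components
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        Q = np.zeros((len(classes), A))
        T = np.zeros((X.shape[0], A))
        for c in range(A):
            M = Xd.T @ Yd
            U, s, Vt = np.linalg.svd(M, full_matrices=False)
            u = U[:, 0]
            keep = min(self.keep_x[c], p)
            if keep < p:
                lam = np.sort(np.abs(u))[::-1][keep]  # (keep+1)-th largest
                u = np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)
            norm = np.linalg.norm(u)
            if norm == 0.0:
                raise SpectraError(f"component {c + 1}: weight vector vanished")
            w = u / norm
            # reproducible sign: largest-magnitude entry positive
            if w[np.argmax(np.abs(w))] < 0:
                w = -w
            t = Xd @ w
            tt = float(t @ t)
            if tt <= 1e-12:
                raise SpectraError(f"component {c + 1}: degenerate score vector")
            p_load = Xd.T @ t / tt
            q_load = Yd.T @ t / tt
            Xd -= np.outer(t, p_load)
            Yd -= np.outer(t, q_load)
            W[:, c], P[:, c], Q[:, c], T[:, c] = w, p_load, q_load, t

        centroids = np.vstack([T[y.astype(str) == c].mean(axis=0) for c in classes])
        total_ss = float((Xs**2).sum())
        expl = np.array([
            float(T[:, c] @ T[:, c]) * float(P[:, c] @ P[:, c]) / total_ss
            for c in range(A)
        ])
        return SPLSDAResults(
            model=self,
            variable_index=kept_cols,
            x_mean=x_mean,
            x_std=x_std,
            y_mean=y_mean,
            x_weights=W,
            x_loadings=P,
            y_loadings=Q,
            x_scores=T,
            centroids=centroids,
            explained_x_variance=expl,
        )


def splsda_fit(X, y, n_components=2, keep_x=None, scale=True) -> "SPLSDAResults":
    """Convenience: build a :class:`SparsePLSDA` and fit it."""
    return SparsePLSDA(X, y, n_components, keep_x, scale).fit()


@dataclass
class SPLSDAResults:
    """Fitted sPLS-DA: loadings, scores, centroids, and prediction."""

    model: SparsePLSDA
    variable_index: np.ndarray  # columns of the original X that were kept
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray  # W, (p, A), unit-norm sparse columns
    x_loadings: np.ndarray  # P
    y_loadings: np.ndarray  # Q
    x_scores: np.ndarray  # T, (n, A)
    centroids: np.ndarray  # (n_classes, A)
    explained_x_variance: np.ndarray

    @property
    def classes_(self) -> list[str]:
        return self.model.classes_

    def _rotation(self) -> np.ndarray:
        """Regression-mode projection R = W (P'W)^-1; T_new = X_scaled R."""
        return self.x_weights @ np.linalg.inv(self.x_loadings.T @ self.x_weights)

    def transform(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] == self.model.X.shape[1]:
            X_new = X_new[:, self.variable_index]
        elif X_new.shape[1] != self.variable_index.size:
            raise SpectraError(
                f"X_new has {X_new.shape[1]} variables; expected "
                f"{self.model.X.shape[1]} (training map)"
            )
        return ((X_new - self.x_mean) / self.x_std) @ self._rotation()

    def decision_values(self, X_new) -> np.ndarray:
        """Predicted class-indicator values (one column per class)."""
        return self.transform(X_new) @ self.y_loadings.T + self.y_mean

    def predict(self, X_new, distance: str = "centroid") -> tuple[np.ndarray, np.ndarray]:
        """Assign each sample to the class of the nearest centroid.

        Returns (labels, score coordinates).  Exact distance ties go to the
        lexicographically first class (classes are stored sorted).
        """
        if distance != "centroid":
            raise SpectraError(f"unsupported distance {distance!r}")
        T_new = self.transform(X_new)
        d = np.linalg.norm(T_new[:, None, :] - self.centroids[None, :, :], axis=2)
        winners = np.array([int(np.flatnonzero(row == row.min())[0]) for row in d])
        labels = np.array([self.classes_[w] for w in winners])
        return labels, T_new

    def balanced_error_rate(self, X, y) -> float:
        labels, _ = self.predict(X)
        y = np.asarray(y).astype(str)
        errs = [np.mean(labels[y == c] != c) for c in self.classes_ if np.any(y == c)]
        return float(np.mean(errs))

    def summary(self) -> str:
        m = self.model
        lines = [
            "Sparse PLS-DA (centroid distance)",
            "=" * 40,
            f"samples: {m.X.shape[0]}   variables: {m.X.shape[1]} "
            f"({self.variable_index.size} non-constant)",
            f"classes: {', '.join(self.classes_)}",
            f"components: {m.n_components}   keep_x: {m.keep_x}   scale: {m.scale}",
            "",
            "comp  keep_x  nonzero  explained X var",
        ]
        for c in range(m.n_components):
            nz = int(np.count_nonzero(self.x_weights[:, c]))
            lines.append(
                f"{c + 1:>4}  {m.keep_x[c]:>6}  {nz:>7}  "
                f"{self.explained_x_variance[c]:>14.4f}"
            )
        ber = self.balanced_error_rate(m.X, m.y)
        lines += ["", f"training balanced error rate: {ber:.4f}"]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-validation and tuning


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random stratified fold assignment (0..folds-1 per sample)."""
    y = np.asarray(y).astype(str)
    assign = np.empty(y.size, dtype=int)
    offset = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size < folds:
            raise SpectraError(f"class {c!r} has {idx.size} samples < {folds} folds")
        idx = rng.permutation(idx)
        # rotate the fold labels between classes so fold sizes stay balanced
        assign[idx] = (np.arange(idx.size) + offset) % folds
        offset += idx.size
    return assign


def _cv_values_once(X, y, n_components, keep_x, scale, fold_assign) -> np.ndarray:
    """Out-of-fold decision values for every sample, one CV pass."""
    values = np.empty((X.shape[0], len(np.unique(y))))
    for f in np.unique(fold_assign):
        test = fold_assign == f
        res = SparsePLSDA(X[~test], y[~test], n_components, keep_x, scale).fit()
        values[test] = res.decision_values(X[test])
    return values


def _cv_ber_once(X, y, n_components, keep_x, scale, fold_assign) -> float:
    y = np.asarray(y).astype(str)
    classes = sorted(np.unique(y))
    labels = np.empty(y.size, dtype=object)
    for f in np.unique(fold_assign):
        test = fold_assign == f
        res = SparsePLSDA(X[~test], y[~test], n_components, keep_x, scale).fit()
        labels[test] = res.predict(X[test])[0]
    return float(np.mean([np.mean(labels[y == c] != c) for c in classes]))


def cross_validated_values(
    X, y, n_components, keep_x=None, scale=True, folds=3, repeats=50, seed=0
) -> np.ndarray:
    """Mean out-of-fold decision values over repeated stratified CV.

    Fold assignment is re-drawn each repeat from a generator seeded by
    ``(seed, repeat)``.  Returns an (n_samples, n_classes) array whose columns
    follow the sorted class order.
    """
    X = np.asarray(X, dtype=float)
    acc = np.zeros((X.shape[0], np.unique(np.asarray(y).astype(str)).size))
    for r in range(repeats):
        rng = np.random.default_rng([int(seed), r])
        fold_assign = _stratified_folds(y, folds, rng)
        acc += _cv_values_once(X, y, n_components, keep_x, scale, fold_assign)
    return acc / repeats


@dataclass
class TuneResult:
    """Outcome of sequential keep_x / component tuning."""

    table: pd.DataFrame  # component, keep_x, mean_error, sd_error
    keep_x: list[int]
    n_components: int
    stage_errors: list[float]  # chosen-candidate mean error per component count
    folds: int
    repeats: int
    seed: int


def tune_splsda(
    X,
    y,
    grid=DEFAULT_KEEPX_GRID,
    n_components_max: int = 3,
    folds: int = 3,
    repeats: int = 200,
    seed: int = 0,
    scale: bool = True,
) -> TuneResult:
    """Tune keep_x per component and the component count by repeated
    stratified M-fold CV on the balanced error rate.

    Selection is sequential (the standard scheme): component 1's keep_x is
    chosen over the grid, then frozen while component 2 is tuned, and so on.
    Every candidate within a stage is evaluated on the *same* fold draws, so
    comparisons are paired.  Ties go to fewer retained variables; the
    component count attaining the minimal error wins, ties to fewer
    components.
    """
    X = np.asarray(X, dtype=float)
    grid = sorted({int(g) for g in grid if 1 <= int(g) <= X.shape[1]})
    if not grid:
        raise SpectraError("empty keep_x grid after clipping to [1, p]")
    folds = int(folds)
    if folds < 2:
        raise SpectraError("folds must be >= 2")

    fold_draws = []
    for r in range(repeats):
        rng = np.random.default_rng([int(seed), r])
        fold_draws.append(_stratified_folds(y, folds, rng))

    chosen: list[int] = []
    stage_errors: list[float] = []
    rows = []
    for comp in range(1, n_components_max + 1):
        best_keep, best_err = None, np.inf
        for cand in grid:
            keep = chosen + [cand]
            errs = np.array([
                _cv_ber_once(X, y, comp, keep, scale, fa) for fa in fold_draws
            ])
            mean_err, sd_err = float(errs.mean()), float(errs.std(ddof=1)) if repeats > 1 else 0.0
            rows.append(
                {"component": comp, "keep_x": cand, "mean_error": mean_err, "sd_error": sd_err}
            )
            # strict < keeps the smaller candidate on ties (grid is ascending)
            if mean_err < best_err:
                best_keep, best_err = cand, mean_err
        chosen.append(best_keep)
        stage_errors.append(best_err)

    n_comp = int(np.argmin(stage_errors)) + 1  # argmin takes the first = fewest
    return TuneResult(
        table=pd.DataFrame(rows),
        keep_x=chosen[:n_comp],
        n_components=n_comp,
        stage_errors=stage_errors,
        folds=folds,
        repeats=repeats,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# ROC / AUROC


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


def auroc(scores, positives) -> RocResult:
    """One-vs-rest AUROC as the concordance probability (ties count 1/2).

    ``scores``: decision values; ``positives``: boolean mask of the positive
    class.  Computed through midranks, which is exactly the normalized
    Mann-Whitney U statistic.
    """
    s = np.asarray(scores, dtype=float).ravel()
    pos = np.asarray(positives, dtype=bool).ravel()
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise SpectraError("AUROC needs >= 1 positive and >= 1 negative")
    r = rankdata(s)
    auc = (r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    sorted_pos = pos[order]
    thresholds = s[order]
    distinct = np.r_[np.flatnonzero(np.diff(thresholds) != 0), thresholds.size - 1]
    tp = np.cumsum(sorted_pos)[distinct]
    fp = np.cumsum(~sorted_pos)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return RocResult(float(auc), fpr, tpr)


def one_vs_rest_auroc(values: np.ndarray, y, classes=None) -> dict[str, RocResult]:
    """Per-class one-vs-rest AUROC from an (n, n_classes) decision matrix."""
    y = np.asarray(y).astype(str)
    classes = list(classes) if classes is not None else sorted(np.unique(y))
    return {c: auroc(values[:, j], y == c) for j, c in enumerate(classes)}


# ---------------------------------------------------------------------------
# artifact export


def export_model_artifacts(
    results: SPLSDAResults, feature_names=None
) -> dict[str, pd.DataFrame]:
    """Numeric tables behind the standard plots: per-sample scores,
    per-component sparse loadings, and variable-component correlations
    (Pearson r of each retained variable with each score vector)."""
    m = results.model
    A = m.n_components
    if feature_names is None:
        feature_names = [f"v{j}" for j in range(m.X.shape[1])]
    feature_names = np.asarray(feature_names, dtype=object)

    scores = pd.DataFrame(
        results.x_scores, columns=[f"comp{c + 1}" for c in range(A)]
    )
    scores.insert(0, "class", np.asarray(m.y).astype(str))

    loadings = []
    for c in range(A):
        nz = np.flatnonzero(results.x_weights[:, c])
        loadings.append(
            pd.DataFrame(
                {
                    "component": c + 1,
                    "variable": feature_names[results.variable_index[nz]],
                    "weight": results.x_weights[nz, c],
                    "sign": np.sign(results.x_weights[nz, c]).astype(int),
                }
            )
        )
    loadings = pd.concat(loadings, ignore_index=True)

    Xs = (m.X[:, results.variable_index] - results.x_mean) / results.x_std
    retained = np.flatnonzero(np.any(results.x_weights != 0, axis=1))
    corr_rows = []
    for j in retained:
        row = {"variable": feature_names[results.variable_index[j]]}
        for c in range(A):
            t = results.x_scores[:, c]
            row[f"comp{c + 1}"] = float(np.corrcoef(Xs[:, j], t)[0, 1])
        corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)
    return {"scores": scores, "loadings": loadings, "correlations": correlations}
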