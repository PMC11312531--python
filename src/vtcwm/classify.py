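"""PCA embedding and leave-one-subject-out profile classification.

The classifier predicts a profile's cytoarchitectonic area, category
preference, or the participant's age group from its PCA scores with
multinomial logistic regression and a winner-take-all readout.
Cross-validation iterates over *subjects* (all sessions of the held-out
subject leave the training set together, respecting the longitudinal
structure), and correctness is aggregated to one accuracy per session.

PCA is fitted once on the full profile matrix by default; a leakage-free
per-fold refit is available behind ``refit_pca_per_fold``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from . import statcore
from .profiles import ProfileMatrix
from .synthetic import AGE_GROUP_ORDER, CATEGORY_ORDER, CYTO_ORDER

__all__ = [
    "PCAModel",
    "MultinomialModel",
    "ClassificationResult",
    "fit_pca",
    "find_elbow",
    "fit_multinomial",
    "predict_wta",
    "loo_classify",
    "compare_tasks",
    "accuracy_vs_chance",
    "TASK_LABELS",
]

TASK_LABELS: dict[str, list[str]] = {
    "cytoarchitecture": CYTO_ORDER,
    "category": CATEGORY_ORDER,
    "age_group": AGE_GROUP_ORDER,
}
TASK_COLUMN = {"cytoarchitecture": "cytoarchitecture", "category": "category", "age_group": "age_group"}


@dataclass
class PCAModel:
    """Centered (unscaled) PCA of the profile matrix.

    ``loadings`` is (parcels x components); ``scores = centered data @
    loadings`` reproduce the data at full rank.  Sign convention: the
    largest-magnitude entry of each loading vector is positive.
    """

    mean: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    variance_explained: np.ndarray  # percentages, non-increasing, sum 100
    n_components_elbow: int

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        S = (np.asarray(X, dtype=float) - self.mean) @ self.loadings
        return S if n_components is None else S[:, :n_components]


def fit_pca(X: np.ndarray) -> PCAModel:
    """SVD-based PCA with column-mean centering and no variance scaling."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|.| loading entry positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    loadings = Vt.T
    scores = Xc @ loadings
    var = s**2
    total = var.sum()
    if total > 0:
        ve = 100.0 * var / total
    else:  # constant matrix: all variance in no component
        ve = np.zeros_like(var)
        ve[0] = 100.0
    try:
        elbow = find_elbow(ve)
    except ValueError:
        elbow = 1
    return PCAModel(
        mean=mean, loadings=loadings, scores=scores, variance_explained=ve, n_components_elbow=elbow
    )


def find_elbow(curve) -> int:
    """Elbow of a non-increasing curve: the point with maximum perpendicular
    distance to the straight line joining the first and last points.

    Returns a 1-based component count; distance ties go to the smaller index.
    """
    y = np.asarray(curve, dtype=float)
    if y.size < 3:
        raise ValueError("curve must have at least 3 points")
    if np.any(np.diff(y) > 1e-9):
        raise ValueError("curve must be non-increasing")
    x = np.arange(1.0, y.size + 1.0)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    seg = p1 - p0
    norm = np.linalg.norm(seg)
    if norm == 0:
        return 1
    rel = np.column_stack([x, y]) - p0
    dist = np.abs(rel[:, 0] * seg[1] - rel[:, 1] * seg[0]) / norm
    return int(np.argmax(dist)) + 1  # argmax takes the first (smallest) index on ties


@dataclass
class MultinomialModel:
    """Per-class linear coefficients of a softmax classifier."""

    coef: np.ndarray        # (n_classes, n_features)
    intercept: np.ndarray   # (n_classes,)
    classes: list[str]
    converged: bool = True


def _canonical_classes(labels, canonical: list[str] | None) -> list[str]:
    present = list(pd.unique(pd.Series(labels)))
    if canonical is None:
        return sorted(present)
    missing = [c for c in present if c not in canonical]
    if missing:
        raise ValueError(f"labels outside canonical order: {missing}")
    return [c for c in canonical if c in present]


def fit_multinomial(
    X,
    y,
    ridge: float = 1e-6,
    max_iter: int = 1000,
    tol: float = 1e-8,
    class_order: list[str] | None = None,
) -> MultinomialModel:
    """Ridge-penalized multinomial logistic regression.

    Maximizes the multinomial log-likelihood minus ``ridge * ||W||^2`` by
    L-BFGS (scikit-learn backend; ``C = 1/(2*ridge)``).  The small default
    ridge keeps the optimum finite on linearly separable clusters.
    Non-convergence at ``max_iter`` is flagged, not silent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = _canonical_classes(y, class_order)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes present")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    C = np.inf if ridge == 0 else 1.0 / (2.0 * ridge)
    clf = LogisticRegression(C=C, max_iter=max_iter, tol=tol, solver="lbfgs")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(X, y)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)

    # reorder sklearn's lexical class order into the canonical order
    order = [list(clf.classes_).index(c) for c in classes]
    if len(classes) == 2:
        # sklearn stores one logit row for binary fits; expand to per-class
        # score rows (0, w) so the softmax reproduces sigmoid(x @ w + b)
        coef2 = np.vstack([np.zeros_like(clf.coef_[0]), clf.coef_[0]])
        icpt2 = np.array([0.0, clf.intercept_[0]])
        coef = coef2[order]
        intercept = icpt2[order]
    else:
        coef = clf.coef_[order]
        intercept = clf.intercept_[order]
    return MultinomialModel(coef=coef, intercept=intercept, classes=classes, converged=converged)


def predict_wta(model: MultinomialModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Winner-take-all softmax prediction.

    Returns (labels, probabilities); probability ties resolve to the first
    class in the model's canonical class order (argmax takes the first max).
    """
    X = np.asarray(X, dtype=float)
    Z = X @ model.coef.T + model.intercept
    Z = Z - Z.max(axis=1, keepdims=True)
    P = np.exp(Z)
    P /= P.sum(axis=1, keepdims=True)
    labels = np.asarray(model.classes, dtype=object)[np.argmax(P, axis=1)]
    return labels, P


@dataclass
class ClassificationResult:
    task: str
    per_session_accuracy: pd.Series       # indexed by session_id, in [0, 1]
    overall_mean: float
    overall_sd: float
    confusion: pd.DataFrame               # true x predicted, rows sum to 100
    chance: float
    predictions: pd.DataFrame = field(repr=False)  # per-profile truth/prediction

    def accuracy_test(self) -> statcore.TTestResult:
        return accuracy_vs_chance(self.per_session_accuracy.to_numpy(), self.chance)


def loo_classify(
    matrix: ProfileMatrix,
    task: str,
    n_components: int | str = "auto",
    balanced: bool = False,
    n_resample_per_label: int = 200,
    seed: int = 0,
    ridge: float = 1e-6,
    refit_pca_per_fold: bool = False,
    max_iter: int = 1000,
) -> ClassificationResult:
    """Leave-one-subject-out classification of profiles.

    PCA is fitted once on the full matrix (default) and the classifier is
    trained on the scores of all other subjects' profiles; all held-out
    profiles are predicted per fold.  With ``balanced=True`` the training set
    is resampled with replacement to ``n_resample_per_label`` rows per label.
    Correctness is averaged into one accuracy per session; the confusion
    matrix pools all predictions and is row-normalized to percent.
    """
    if task not in TASK_LABELS:
        raise ValueError(f"unknown task {task!r}")
    meta = matrix.meta
    y_all = meta[TASK_COLUMN[task]].to_numpy()
    class_order = TASK_LABELS[task]
    classes = [c for c in class_order if c in set(y_all)]
    chance = 1.0 / len(classes)

    pca_full = fit_pca(matrix.values)
    if n_components == "auto":
        K = pca_full.n_components_elbow
    else:
        K = int(n_components)
    if K > matrix.values.shape[1]:
        raise ValueError("n_components exceeds feature count")

    rng = np.random.default_rng(seed)
    subjects = list(pd.unique(meta["subject_id"]))
    pred = np.empty(matrix.n_rows, dtype=object)
    for subject in subjects:
        held = (meta["subject_id"] == subject).to_numpy()
        train = ~held
        # fold hygiene: no held-out profile may enter training
        assert not np.any(held & train)
        y_train = y_all[train]
        missing = [c for c in classes if c not in set(y_train)]
        if missing:
            raise ValueError(f"labels {missing} absent from training fold for subject {subject}")
        if refit_pca_per_fold:
            pca = fit_pca(matrix.values[train])
            X_train = pca.transform(matrix.values[train], K)
            X_test = pca.transform(matrix.values[held], K)
        else:
            scores = pca_full.scores[:, :K]
            X_train, X_test = scores[train], scores[held]
        if balanced:
            idx = []
            for c in classes:
                rows = np.flatnonzero(y_train == c)
                idx.append(rng.choice(rows, size=n_resample_per_label, replace=True))
            idx = np.concatenate(idx)
            X_train, y_train = X_train[idx], y_train[idx]
        model = fit_multinomial(
            X_train, y_train, ridge=ridge, max_iter=max_iter, class_order=class_order
        )
        labels, _ = predict_wta(model, X_test)
        pred[held] = labels

    correct = (pred == y_all).astype(float)
    predictions = meta[["froi_id", "subject_id", "session_id"]].copy()
    predictions["true"] = y_all
    predictions["predicted"] = pred
    predictions["correct"] = correct

    per_session = predictions.groupby("session_id", sort=False)["correct"].mean()
    counts = pd.crosstab(predictions["true"], predictions["predicted"])
    counts = counts.reindex(index=classes, columns=classes, fill_value=0)
    confusion = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    return ClassificationResult(
        task=task,
        per_session_accuracy=per_session,
        overall_mean=float(per_session.mean()),
        overall_sd=float(per_session.std(ddof=1)),
        confusion=confusion,
        chance=chance,
        predictions=predictions,
    )


def compare_tasks(correctness: pd.DataFrame) -> pd.DataFrame:
    """Pairwise between-task comparison of per-prediction correctness.

    ``correctness`` needs columns ``task`` and ``correct`` (0/1).  For each
    unordered task pair a binomial logistic regression of correctness on the
    task indicator yields the odds ratio (first task vs second) with a Wald
    95% CI.
    """
    tasks = list(pd.unique(correctness["task"]))
    rows = []
    for i, t1 in enumerate(tasks):
        for t2 in tasks[i + 1:]:
            sub = correctness[correctness["task"].isin([t1, t2])]
            x = (sub["task"] == t1).to_numpy(float)
            y = sub["correct"].to_numpy(float)
            fit = statcore.binomial_logit(x[:, None], y, names=["task"])
            rows.append(
                {
                    "task_a": t1,
                    "task_b": t2,
                    "odds_ratio": float(fit.odds_ratios["task"]),
                    "ci_lower": float(fit.or_conf_int.loc["task", "lower"]),
                    "ci_upper": float(fit.or_conf_int.loc["task", "upper"]),
                    "p": float(fit.pvalues["task"]),
                }
            )
    return pd.DataFrame(rows)


def accuracy_vs_chance(per_session_accuracy, chance: float) -> statcore.TTestResult:
    """One-sample t-test of session accuracies against the chance level."""
    return statcore.one_sample_t(np.asarray(per_session_accuracy, dtype=float), chance)
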