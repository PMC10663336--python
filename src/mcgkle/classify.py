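"""Fisher LDA with leave-one-out cross-validation on KLE features.

The classifier is the two-class Fisher discriminant: with pooled
within-class covariance S and class means mu_0 (healthy) and mu_1
(pathology), the weight vector is w = S^-1 (mu_1 - mu_0) and the decision
threshold is the midpoint of the projected class means (equal priors).  A
ridge term lambda * tr(S)/p * I guards folds where S is singular (more
features than training subjects).

Leave-one-out cross-validation is leakage-free in the strict sense: for
every fold the healthy reference map is rebuilt without the held-out
subject, all training features are recomputed against that reference, and
only then is the discriminant fitted.  The held-out subject therefore
influences neither the reference nor the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kle import EPS_REL, _column_distributions
from .segments import SegmentMaps
from .stats import MannWhitneyResult, mann_whitney_u
from .synth import CmfmRecording

__all__ = [
    "FeatureMatrix",
    "LdaModel",
    "ClassificationReport",
    "lda_fit",
    "loocv",
    "metrics",
    "pca_project",
    "heart_rate_test",
]

LABELS = ("healthy", "pathology")  # pathology is the positive class


@dataclass(frozen=True)
class FeatureMatrix:
    """Ordered subjects x features with group labels and feature provenance."""

    subjects: tuple
    X: np.ndarray
    y: np.ndarray  # 0 = healthy, 1 = pathology
    feature_names: tuple

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2 or X.shape[0] != len(self.subjects) or len(y) != X.shape[0]:
            raise ValueError("inconsistent FeatureMatrix shapes")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        n_groups = len(np.unique(y))
        if X.shape[0] < n_groups + 1:
            raise ValueError("need at least n_groups + 1 subjects")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))


@dataclass(frozen=True)
class LdaModel:
    """Two-class linear discriminant: score = x . w, predict 1 if score > threshold."""

    w: np.ndarray
    threshold: float
    mu0: np.ndarray
    mu1: np.ndarray

    def score(self, X) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.w

    def predict(self, X) -> np.ndarray:
        return (self.score(X) > self.threshold).astype(int)


@dataclass(frozen=True)
class ClassificationReport:
    """LOOCV outcome: per-subject predictions, confusion counts and metrics."""

    subjects: tuple
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    config: dict = field(default_factory=dict)
    fold_models: tuple | None = None


def lda_fit(X_train, y_train, regularization: float = 1e-3) -> LdaModel:
    """Fit the Fisher discriminant with optional ridge regularization.

    S is the pooled within-class covariance; with ``regularization`` > 0 it
    becomes S + lambda * tr(S)/p * I.  Deterministic.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present in the training set")
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n, p = X.shape
    scatter = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1))
    S = scatter / max(n - 2, 1)
    if regularization > 0:
        S = S + regularization * np.trace(S) / p * np.eye(p)
    try:
        w = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; use regularization > 0") from exc
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return LdaModel(w=w, threshold=threshold, mu0=mu0, mu1=mu1)


def metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity, specificity and accuracy from confusion counts.

    Zero-denominator ratios are reported as NaN with a warning, never
    silently as 0.
    """
    counts = {"tp": tp, "fn": fn, "tn": tn, "fp": fp}
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"negative confusion counts: {counts}")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    return {
        "sensitivity": _ratio(tp, tp + fn, "sensitivity"),
        "specificity": _ratio(tn, tn + fp, "specificity"),
        "accuracy": _ratio(tp + tn, total, "accuracy"),
    }


def _stack_segments(segment_sets: dict) -> tuple[tuple, np.ndarray, dict, tuple]:
    """Align per-segment SegmentMaps lists into arrays keyed by segment name."""
    names = list(segment_sets)
    subjects = tuple(s.subject_id for s in segment_sets[names[0]])
    groups = tuple(s.group for s in segment_sets[names[0]])
    arrays = {}
    for name in names:
        segs = segment_sets[name]
        if tuple(s.subject_id for s in segs) != subjects:
            raise ValueError("segment sets must list the same subjects in order")
        if len({(s.name, s.mode, s.maps.shape) for s in segs}) != 1:
            raise ValueError(f"mixed name/mode/shape within segment set {name!r}")
        arrays[name] = np.stack([s.maps for s in segs])  # (n_subj, 36, n_out)
    y = np.array([0 if g == "healthy" else 1 for g in groups], dtype=int)
    return subjects, y, arrays, groups


def loocv(segment_sets: dict, regularization: float = 1e-3,
          strategy: str = "abs", eps_rel: float = EPS_REL,
          reference_group: str = "healthy",
          keep_fold_models: bool = False,
          config: dict | None = None) -> ClassificationReport:
    """Leave-one-out cross-validation with per-fold reference rebuilding.

    ``segment_sets`` maps segment names to per-subject ``SegmentMaps``
    lists (same subject order); features of multiple segments are
    concatenated, which is how the joint QRS+STT evaluation is realized.
    For each fold the reference map is the mean over the *training*
    subjects of ``reference_group``, every subject's KLE features are
    computed against it, and the discriminant is fitted on the training
    rows only.  Deterministic.
    """
    if reference_group not in LABELS:
        raise ValueError(f"reference_group must be one of {LABELS}")
    subjects, y, arrays, groups = _stack_segments(segment_sets)
    n = len(subjects)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")

    ref_label = 0 if reference_group == "healthy" else 1
    ref_mask = y == ref_label
    if np.sum(ref_mask) < 3:
        raise ValueError("reference group too small to rebuild per fold")

    # Subject-side distributions do not depend on the reference; precompute.
    logP = {}
    P = {}
    for name, maps in arrays.items():
        p = _column_distributions(maps, strategy, eps_rel)
        P[name] = p
        logP[name] = np.log(p)

    y_pred = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    fold_models = [] if keep_fold_models else None
    for j in range(n):
        train = np.arange(n) != j
        if len(np.unique(y[train])) < 2:
            raise ValueError("a fold has a single-class training set")
        feats = []
        for name, maps in arrays.items():
            # fold reference: mean over *training* reference-group subjects
            # only, so the held-out subject can never influence it
            q_map = maps[ref_mask & train].mean(axis=0)
            logQ = np.log(_column_distributions(q_map, strategy, eps_rel))
            # KL per subject and time point against the fold reference
            feats.append(np.sum(P[name] * (logP[name] - logQ[None]), axis=1))
        F = np.concatenate(feats, axis=1)
        model = lda_fit(F[train], y[train], regularization=regularization)
        scores[j] = float(model.score(F[j][None, :])[0])
        y_pred[j] = int(scores[j] > model.threshold)
        if keep_fold_models:
            fold_models.append(model)

    tp = int(np.sum((y == 1) & (y_pred == 1)))
    fn = int(np.sum((y == 1) & (y_pred == 0)))
    tn = int(np.sum((y == 0) & (y_pred == 0)))
    fp = int(np.sum((y == 0) & (y_pred == 1)))
    m = metrics(tp, fn, tn, fp)
    cfg = dict(config or {})
    cfg.update({"segments": sorted(segment_sets), "strategy": strategy,
                "eps_rel": eps_rel, "regularization": regularization,
                "reference_group": reference_group})
    return ClassificationReport(
        subjects=subjects, y_true=y, y_pred=y_pred, scores=scores,
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        accuracy=m["accuracy"], config=cfg,
        fold_models=tuple(fold_models) if keep_fold_models else None)


def pca_project(features: FeatureMatrix, n_components: int = 2) -> dict:
    """Mean-centred PCA via eigen-decomposition of the covariance matrix.

    Sign convention: each component's largest-magnitude loading is made
    positive so projections are reproducible.  Returns per-subject
    coordinates and explained-variance fractions.
    """
    X = features.X
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)="
                         f"{min(n, p)}")
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / max(n - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    W = eigvecs[:, order][:, :n_components].copy()
    for k in range(n_components):
        i_max = int(np.argmax(np.abs(W[:, k])))
        if W[i_max, k] < 0:
            W[:, k] = -W[:, k]
    total = float(eigvals.sum())
    explained = eigvals[:n_components] / total if total > 0 else \
        np.zeros(n_components)
    return {
        "coordinates": Xc @ W,
        "components": W,
        "explained_variance_ratio": explained,
        "subjects": features.subjects,
        "y": features.y,
    }


def heart_rate_test(recordings: list[CmfmRecording]) -> dict:
    """Between-group Mann-Whitney U test on per-subject mean heart rate.

    A significant difference would mean the classifier could be picking up
    sinus tachycardia rather than field-map topology.
    """
    hr = {"healthy": [], "pathology": []}
    for rec in recordings:
        hr[rec.group].append(rec.mean_heart_rate_bpm())
    if not hr["healthy"] or not hr["pathology"]:
        raise ValueError("both groups must be non-empty")
    res: MannWhitneyResult = mann_whitney_u(hr["healthy"], hr["pathology"])
    return {
        "u": res.u,
        "p_value": res.p_value,
        "method": res.method,
        "hr_healthy_mean": float(np.mean(hr["healthy"])),
        "hr_pathology_mean": float(np.mean(hr["pathology"])),
    }
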