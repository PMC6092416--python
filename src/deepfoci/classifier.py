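"""PCA + RBF-SVM separation of real foci from noise candidates.

Candidates are labeled against expert point annotations, z-scored, projected
onto the principal components explaining ≥ 95% of the training variance and
classified with an RBF-kernel support vector machine. The two
hyper-parameters C and γ are selected by a leave-one-image-out grid search
over exponentially spaced grids: for each (C, γ) one training image is held
out, the model is fitted on the rest and the candidate-level detection
accuracy TP/(TP+FN+FP) on the held-out image is recorded; the (C, γ) with
the highest average held-out accuracy wins (ties broken toward smaller C,
then smaller γ) and the final model is refitted on all images.

The trained model serializes to versioned JSON carrying the scaler
statistics, PCA basis, support vectors and dual coefficients; the decision
function is evaluated directly from those arrays, so a save/load round trip
reproduces predictions exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .image_model import CandidateSet, FociAnnotation, FocusRecord

MODEL_FORMAT_VERSION = 1

#: powers-of-two default grids with exponential increments
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-15, 4, 2))


@dataclass
class TrainedModel:
    """Frozen scaler + PCA + RBF-SVM with training metadata."""

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (n_components, n_features)
    support_vectors: np.ndarray  # in PCA space
    dual_coef: np.ndarray  # (n_support,)
    intercept: float
    C: float
    gamma: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.pca_components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float64) - self.scaler_mean) / self.scaler_scale
        return (Z - self.pca_mean) @ self.pca_components.T

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed distance to the margin; > 0 means positive (real focus)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(self.scaler_mean):
            raise ValueError(
                f"feature matrix must have {len(self.scaler_mean)} columns, got {X.shape}"
            )
        if len(X) == 0:
            return np.empty(0)
        T = self.transform(X)
        d2 = ((T[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.gamma * d2)
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def save(self, path: str | os.PathLike) -> None:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "C": self.C,
            "gamma": self.gamma,
            "intercept": self.intercept,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "pca_components": self.pca_components.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrainedModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version in {path!r}")
        return cls(
            scaler_mean=np.array(doc["scaler_mean"]),
            scaler_scale=np.array(doc["scaler_scale"]),
            pca_mean=np.array(doc["pca_mean"]),
            pca_components=np.array(doc["pca_components"]),
            support_vectors=np.array(doc["support_vectors"]),
            dual_coef=np.array(doc["dual_coef"]),
            intercept=float(doc["intercept"]),
            C=float(doc["C"]),
            gamma=float(doc["gamma"]),
            metadata=doc.get("metadata", {}),
        )


def label_candidates(
    records: list[FocusRecord],
    candidates: CandidateSet,
    annotations: FociAnnotation | np.ndarray,
    match_radius_px: float = 30.0,
) -> list[FocusRecord]:
    """Assign positive/negative labels to candidates from point annotations.

    Each annotation claims at most one candidate: the one whose region
    contains the point, else the nearest candidate centroid within
    ``match_radius_px`` (exact centroid-distance ties go to the lower region
    id). Claimed candidates are positive, the rest negative.
    """
    pts = annotations.points if isinstance(annotations, FociAnnotation) else np.asarray(annotations)
    positive: set[int] = set()
    cents = np.array([r.centroid for r in records]) if records else np.empty((0, 2))
    rids = [r.region_id for r in records]
    h, w = candidates.parent_shape
    for x, y in pts.reshape(-1, 2):
        iy, ix = int(round(y)), int(round(x))
        if 0 <= iy < h and 0 <= ix < w:
            rid = int(candidates.labels[iy, ix])
            if rid > 0:
                positive.add(rid)
                continue
        if len(cents) == 0:
            continue
        d = np.hypot(cents[:, 0] - x, cents[:, 1] - y)
        order = sorted(range(len(records)), key=lambda i: (d[i], rids[i]))
        best = order[0]
        if d[best] <= match_radius_px:
            positive.add(rids[best])
    out = []
    for r in records:
        r.label = "positive" if r.region_id in positive else "negative"
        out.append(r)
    return out


def _candidate_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float | None:
    """Detection-style accuracy TP/(TP+FN+FP) of candidate classification."""
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    if tp + fn + fp == 0:
        return None
    return tp / (tp + fn + fp)


def _fit_pipeline(X: np.ndarray, y: np.ndarray, C: float, gamma: float):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - mean) / scale
    n_comp = min(Z.shape[0], Z.shape[1])
    pca = PCA(n_components=0.95, svd_solver="full") if n_comp > 1 else PCA(n_components=1)
    T = pca.fit_transform(Z)
    svm = SVC(C=C, gamma=gamma, kernel="rbf")
    svm.fit(T, y)
    return mean, scale, pca, svm


def fit_svm(
    per_image: list[tuple[np.ndarray, np.ndarray]],
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    seed: int | None = None,
) -> TrainedModel:
    """Leave-one-image-out grid search, then refit on all images.

    ``per_image`` holds one (feature matrix, 0/1 label vector) pair per
    training image. Raises if fewer than two images are given or a class is
    absent from the pooled training data.
    """
    if len(per_image) < 2:
        raise ValueError("need at least 2 training images for leave-one-image-out search")
    if not C_grid or not gamma_grid:
        raise ValueError("hyper-parameter grids must be nonempty")
    X_all = np.vstack([X for X, _ in per_image])
    y_all = np.concatenate([y for _, y in per_image])
    if len(np.unique(y_all)) < 2:
        raise ValueError("degenerate training set: a class is absent")

    table = []
    best: tuple[float, float, float] | None = None  # (acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            accs = []
            for hold in range(len(per_image)):
                X_tr = np.vstack([X for i, (X, _) in enumerate(per_image) if i != hold])
                y_tr = np.concatenate([y for i, (_, y) in enumerate(per_image) if i != hold])
                if len(np.unique(y_tr)) < 2:
                    continue
                mean, scale, pca, svm = _fit_pipeline(X_tr, y_tr, C, gamma)
                X_ho, y_ho = per_image[hold]
                if len(X_ho) == 0:
                    continue
                T_ho = pca.transform((X_ho - mean) / scale)
                acc = _candidate_accuracy(y_ho, svm.predict(T_ho))
                if acc is not None:
                    accs.append(acc)
            mean_acc = float(np.mean(accs)) if accs else 0.0
            table.append({"C": C, "gamma": gamma, "mean_heldout_accuracy": mean_acc})
            if best is None or mean_acc > best[0] + 1e-12:
                best = (mean_acc, C, gamma)
    assert best is not None
    _, C_star, gamma_star = best

    mean, scale, pca, svm = _fit_pipeline(X_all, y_all, C_star, gamma_star)
    # orient the decision function so score > 0 means class 1 (positive)
    sign = 1.0 if svm.classes_[1] == 1 else -1.0
    model = TrainedModel(
        scaler_mean=mean,
        scaler_scale=scale,
        pca_mean=pca.mean_,
        pca_components=pca.components_,
        support_vectors=svm.support_vectors_,
        dual_coef=sign * svm.dual_coef_.ravel(),
        intercept=sign * float(svm.intercept_[0]),
        C=C_star,
        gamma=gamma_star,
        metadata={
            "seed": seed,
            "n_images": len(per_image),
            "n_candidates": int(len(y_all)),
            "n_positive": int(y_all.sum()),
            "grid_search": table,
            "C_grid": list(C_grid),
            "gamma_grid": list(gamma_grid),
            "pca_n_components": int(pca.components_.shape[0]),
        },
    )
    return model


def train(
    images: list,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    seed: int | None = None,
    match_radius_px: float = 30.0,
    config=None,
):
    """Train from (TissueImage, FociAnnotation) pairs via the full pipeline.

    Runs candidate detection, fusion, feature extraction and annotation
    matching on every image, then delegates to :func:`fit_svm`.
    """
    from .candidate_detection import detect_candidates
    from .fusion_features import (
        deduplicate_candidates,
        extract_features,
        feature_matrix,
        fuse_candidates,
    )

    per_image = []
    for image, annotation in images:
        det = detect_candidates(image, config=config)
        fused = fuse_candidates(det.intensity, det.gradient)
        fused = deduplicate_candidates(fused, det.flow.values, match_radius_px)
        records = extract_features(fused, det.preprocessed, det.flow, det.mask)
        records = label_candidates(records, fused, annotation, match_radius_px)
        X = feature_matrix(records)
        y = np.array([1 if r.label == "positive" else 0 for r in records], dtype=int)
        per_image.append((X, y))
    return fit_svm(per_image, C_grid=C_grid, gamma_grid=gamma_grid, seed=seed)


def classify(model: TrainedModel, records: list[FocusRecord]) -> list[FocusRecord]:
    """Score records with the trained model; positive iff score > 0."""
    if not records:
        return []
    X = np.vstack([r.features for r in records])
    scores = model.decision_function(X)
    for r, s in zip(records, scores):
        r.score = float(s)
        r.label = "positive" if s > 0 else "negative"
    return records
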