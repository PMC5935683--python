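"""Subtype markers by differential expression and a nearest-centroid classifier.

Markers are selected per subtype by one-vs-rest Wilcoxon rank-sum tests
with Benjamini–Hochberg correction within the platform; a minimum absolute
mean difference keeps only features with a usable effect size. The
classifier is a correlation-based nearest-centroid model: it standardizes
marker features with training-set parameters, then assigns each sample to
the class whose centroid its marker profile correlates with best. Pearson
correlation is scale- and shift-invariant per sample, which makes the
model applicable one sample at a time — the property needed to classify an
external validation cohort.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats as sps

from .io import DataError, ExpressionMatrix
from .stats import bh_adjust

UNCLASSIFIED = 0  # label for samples with a degenerate (zero-variance) marker vector


@dataclasses.dataclass
class Marker:
    feature_id: str
    subtype: int
    direction: int       # +1 up in this subtype, -1 down
    adjusted_p: float
    mean_difference: float


@dataclasses.dataclass
class MarkerSet:
    markers: list[Marker]
    fdr: float
    min_abs_lfc: float

    def for_subtype(self, subtype: int) -> list[Marker]:
        return [m for m in self.markers if m.subtype == subtype]

    @property
    def feature_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.feature_id, None)
        return list(seen)


def differential_markers(
    expr: ExpressionMatrix,
    labels,
    fdr: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> MarkerSet:
    """One-vs-rest rank-sum marker selection with BH correction.

    For each subtype, every feature is tested subtype-vs-rest with a
    two-sided Wilcoxon rank-sum (Mann–Whitney) test; p-values are BH
    adjusted within the platform (all subtypes jointly) and features with
    adjusted p <= fdr and |mean difference| >= min_abs_lfc are kept, with
    the direction of the difference recorded.
    """
    labels = np.asarray(labels)
    if len(labels) != expr.n_samples:
        raise ValueError("labels length does not match sample count")
    subtypes = sorted(int(s) for s in np.unique(labels))
    for s in subtypes:
        if (labels == s).sum() < 2:
            raise ValueError(f"subtype {s} has fewer than 2 samples")

    X = expr.values
    raw_p = np.empty((len(subtypes), expr.n_features))
    mean_diff = np.empty_like(raw_p)
    for i, s in enumerate(subtypes):
        in_s = labels == s
        a, b = X[:, in_s], X[:, ~in_s]
        res = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        raw_p[i] = res.pvalue
        mean_diff[i] = a.mean(axis=1) - b.mean(axis=1)
    adj = bh_adjust(raw_p.ravel()).reshape(raw_p.shape)

    markers = []
    for i, s in enumerate(subtypes):
        keep = (adj[i] <= fdr) & (np.abs(mean_diff[i]) >= min_abs_lfc)
        for j in np.nonzero(keep)[0]:
            markers.append(
                Marker(
                    feature_id=expr.feature_ids[j],
                    subtype=s,
                    direction=int(np.sign(mean_diff[i, j]) or 1),
                    adjusted_p=float(adj[i, j]),
                    mean_difference=float(mean_diff[i, j]),
                )
            )
    return MarkerSet(markers=markers, fdr=fdr, min_abs_lfc=min_abs_lfc)


@dataclasses.dataclass
class CentroidModel:
    """Per-class mean marker profiles in training z-score space."""

    feature_ids: list[str]
    classes: list[int]
    centroids: np.ndarray      # classes x features
    train_mean: np.ndarray     # per-feature standardization parameters
    train_sd: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_ids": self.feature_ids,
                "classes": self.classes,
                "centroids": self.centroids.tolist(),
                "train_mean": self.train_mean.tolist(),
                "train_sd": self.train_sd.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CentroidModel":
        d = json.loads(text)
        return cls(
            feature_ids=list(d["feature_ids"]),
            classes=[int(c) for c in d["classes"]],
            centroids=np.asarray(d["centroids"], float),
            train_mean=np.asarray(d["train_mean"], float),
            train_sd=np.asarray(d["train_sd"], float),
        )


def _marker_rows(expr: ExpressionMatrix, feature_ids: list[str]) -> np.ndarray:
    index = {f: i for i, f in enumerate(expr.feature_ids)}
    missing = [f for f in feature_ids if f not in index]
    if missing:
        raise DataError(f"marker features absent from matrix: {missing[:5]}"
                        + ("..." if len(missing) > 5 else ""))
    return expr.values[[index[f] for f in feature_ids], :]


def train_centroid(expr: ExpressionMatrix, labels, markers: MarkerSet | list[str]) -> CentroidModel:
    """Per-class mean vectors over marker features, in training z-score space."""
    feature_ids = markers.feature_ids if isinstance(markers, MarkerSet) else list(markers)
    if not feature_ids:
        raise ValueError("marker set is empty")
    labels = np.asarray(labels)
    X = _marker_rows(expr, feature_ids)
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean[:, None]) / sd[:, None]
    classes = sorted(int(c) for c in np.unique(labels))
    centroids = np.vstack([Z[:, labels == c].mean(axis=1) for c in classes])
    return CentroidModel(feature_ids, classes, centroids, mean, sd)


def classify(
    expr: ExpressionMatrix, model: CentroidModel
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid prediction by Pearson correlation.

    Returns (predicted labels, confidence), where confidence is the margin
    between the best and second-best centroid correlations. A sample whose
    standardized marker vector has zero variance is unclassifiable and gets
    label :data:`UNCLASSIFIED` with confidence 0.
    """
    X = _marker_rows(expr, model.feature_ids)
    Z = (X - model.train_mean[:, None]) / model.train_sd[:, None]
    n = Z.shape[1]
    preds = np.full(n, UNCLASSIFIED, dtype=int)
    conf = np.zeros(n)
    C = model.centroids  # classes x features
    Cc = C - C.mean(axis=1, keepdims=True)
    Cn = np.linalg.norm(Cc, axis=1)
    if (Cn == 0).any():
        raise DataError("a centroid has zero variance over the marker features")
    for i in range(n):
        z = Z[:, i] - Z[:, i].mean()
        nz = np.linalg.norm(z)
        if nz == 0:
            continue
        r = (Cc @ z) / (Cn * nz)
        order = np.argsort(-r)
        preds[i] = model.classes[order[0]]
        conf[i] = float(r[order[0]] - r[order[1]]) if len(r) > 1 else 1.0
    return preds, conf


def evaluate_subtype2(pred, truth, positive: int = 2) -> tuple[float | None, float | None]:
    """Sensitivity and specificity of the subtype-2-vs-rest task.

    Any prediction other than ``positive`` (including unclassified) counts
    as a rest-call. With no positive (resp. negative) cases in the truth,
    sensitivity (resp. specificity) is undefined and reported as None.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    pos_pred, pos_true = pred == positive, truth == positive
    tp = int((pos_pred & pos_true).sum())
    fn = int((~pos_pred & pos_true).sum())
    tn = int((~pos_pred & ~pos_true).sum())
    fp = int((pos_pred & ~pos_true).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return sens, spec


def balanced_accuracy(pred, truth) -> float:
    """Mean per-class recall over the classes present in truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    recalls = [
        float((pred[truth == c] == c).mean()) for c in np.unique(truth)
    ]
    return float(np.mean(recalls))


def crossval_subtype2(
    expr: ExpressionMatrix,
    labels,
    fdr: float = 0.05,
    min_abs_lfc: float = 1.0,
    n_splits: int = 5,
    seed: int = 0,
) -> tuple[float | None, float | None]:
    """Stratified k-fold cross-validated sensitivity/specificity for subtype 2.

    Markers are re-selected inside every training fold so the estimate is
    honest about the full protocol, not just the final centroid fit.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(seed) % (2**31))
    preds = np.empty_like(labels)
    for train_idx, test_idx in skf.split(labels.reshape(-1, 1), labels):
        train = expr.subset_samples([expr.sample_ids[i] for i in train_idx])
        test = expr.subset_samples([expr.sample_ids[i] for i in test_idx])
        markers = differential_markers(train, labels[train_idx], fdr=fdr,
                                       min_abs_lfc=min_abs_lfc)
        model = train_centroid(train, labels[train_idx], markers)
        preds[test_idx], _ = classify(test, model)
    return evaluate_subtype2(preds, labels)
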