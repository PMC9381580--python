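"""Linear SVM training, freezing, and frozen-model application.

The deployment contract is built around a *zero training false-positive*
operating threshold: after fitting a soft-margin linear SVM on the extreme
responders (pCR vs poor response), the threshold is set just above the
largest decision value of any training negative, so no training
non-responder is ever called pCR. The trained model is frozen together with
its feature standardization parameters and (optionally) the reference
quantile distribution of its training cohort, so external cohorts can be
aligned and scored without any retraining.

Also provided: stratified k-fold cross-validation with pooled out-of-fold
scores, and a generic leave-one-out evaluator that measures the AUC of an
arbitrary gene list — the engine for benchmarking previously published
response signatures on a common footing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._linsvm import fit_linear_svm
from .core_data import CohortBundle, ExpressionMatrix, subset_to_signature
from .metrics import EvalReport, auc, evaluate_scores
from .preprocess import ReferenceQuantiles

__all__ = [
    "TrainedSVM",
    "train_svm",
    "svm_decision_values",
    "classify_pcr",
    "cross_validate",
    "evaluate_signature_loocv",
    "save_model",
    "load_model",
]

Engine = Literal["libsvm", "dcd"]


@dataclass
class TrainedSVM:
    """A frozen linear decision function.

    ``weights``/``bias`` act on features standardized with the *training*
    ``feature_means``/``feature_sds`` (frozen; never recomputed at apply
    time). ``operating_threshold`` sits just above the largest training-
    negative decision value, so ``decision > operating_threshold`` can never
    fire on a training negative.
    """

    feature_list: list[str]
    weights: np.ndarray
    bias: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    operating_threshold: float
    reference: ReferenceQuantiles | None = None
    training_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        n = len(self.feature_list)
        if not (len(self.weights) == len(self.feature_means) == len(self.feature_sds) == n):
            raise ValueError("feature_list/weights/means/sds lengths differ")
        if np.any(self.feature_sds <= 0):
            raise ValueError("feature standard deviations must be > 0")

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "feature_list": list(self.feature_list),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "operating_threshold": self.operating_threshold,
            "reference": self.reference.to_dict() if self.reference else None,
            "training_provenance": self.training_provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedSVM":
        return cls(
            feature_list=list(d["feature_list"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            operating_threshold=float(d["operating_threshold"]),
            reference=(
                ReferenceQuantiles.from_dict(d["reference"]) if d.get("reference") else None
            ),
            training_provenance=dict(d.get("training_provenance", {})),
        )


def save_model(model: TrainedSVM, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path) -> TrainedSVM:
    with open(path) as fh:
        return TrainedSVM.from_dict(json.load(fh))


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    return means, sds


def _fit_weights(
    X: np.ndarray, y: np.ndarray, C: float, engine: Engine
) -> tuple[np.ndarray, float]:
    if engine == "dcd":
        return fit_linear_svm(X, y, C=C)
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, np.asarray(y).astype(int))
    return svc.coef_[0].copy(), float(svc.intercept_[0])


def _design_matrix(
    matrix: ExpressionMatrix, feature_list: Sequence[str]
) -> np.ndarray:
    sub = subset_to_signature(matrix, list(feature_list), missing="fail")
    return sub.values.T  # samples x features


def train_svm(
    bundle: CohortBundle,
    signature: Sequence[str],
    C: float = 1.0,
    engine: Engine = "libsvm",
    reference: ReferenceQuantiles | None = None,
    seed: int | None = None,
) -> TrainedSVM:
    """Train and freeze the final classifier on positive/negative samples.

    Features are the signature genes (matrix rows resolved through the alias
    table), standardized to zero mean / unit variance on the training data.
    The operating threshold is placed one float step above the largest
    training-negative decision value.
    """
    extremes = bundle.restrict_to_extremes()
    y = extremes.positive_mask()
    if y.all() or (~y).all():
        raise ValueError("training requires both positive and negative samples")
    X = _design_matrix(extremes.expression, signature)
    means, sds = _standardize_fit(X)
    Xs = (X - means) / sds
    w, b = _fit_weights(Xs, y, C, engine)
    decisions = Xs @ w + b
    max_neg = decisions[~y].max()
    threshold = float(np.nextafter(max_neg, np.inf))
    return TrainedSVM(
        feature_list=list(signature),
        weights=w,
        bias=b,
        feature_means=means,
        feature_sds=sds,
        operating_threshold=threshold,
        reference=reference,
        training_provenance={
            "n_pos": int(y.sum()),
            "n_neg": int((~y).sum()),
            "C": C,
            "engine": engine,
            "seed": seed,
        },
    )


def svm_decision_values(model: TrainedSVM, matrix: ExpressionMatrix) -> np.ndarray:
    """Per-sample decision values ``w . standardized(x) + b`` with frozen scaling."""
    X = _design_matrix(matrix, model.feature_list)
    Xs = (X - model.feature_means) / model.feature_sds
    return Xs @ model.weights + model.bias


def classify_pcr(model: TrainedSVM, matrix: ExpressionMatrix) -> np.ndarray:
    """Call pCR iff the decision value exceeds the frozen operating threshold."""
    d = svm_decision_values(model, matrix)
    return np.where(d > model.operating_threshold, "pCR", "non-pCR")


def cross_validate(
    bundle: CohortBundle,
    signature: Sequence[str],
    k: int = 4,
    C: float = 1.0,
    engine: Engine = "libsvm",
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold CV; out-of-fold decision values pooled into one report."""
    extremes = bundle.restrict_to_extremes()
    y = extremes.positive_mask()
    n_min = min(int(y.sum()), int((~y).sum()))
    if k > n_min:
        raise ValueError(f"k={k} exceeds the smaller class size {n_min}")
    X = _design_matrix(extremes.expression, signature)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    for train_idx, test_idx in skf.split(X, y):
        means, sds = _standardize_fit(X[train_idx])
        w, b = _fit_weights((X[train_idx] - means) / sds, y[train_idx], C, engine)
        pooled[test_idx] = ((X[test_idx] - means) / sds) @ w + b
    return evaluate_scores(pooled, y)


def evaluate_signature_loocv(
    bundle: CohortBundle,
    gene_list: Sequence[str],
    C: float = 1.0,
    engine: Engine = "libsvm",
) -> float:
    """Leave-one-out AUC of a linear SVM restricted to ``gene_list``.

    The generic benchmark used to re-test any published response signature:
    n models, each trained on n-1 samples, held-out decision values pooled
    into a single AUC.
    """
    extremes = bundle.restrict_to_extremes()
    y = extremes.positive_mask()
    if int(y.sum()) < 2 or int((~y).sum()) < 2:
        raise ValueError("need >= 2 samples per class")
    X = _design_matrix(extremes.expression, gene_list)
    n = len(y)
    pooled = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        means, sds = _standardize_fit(X[tr])
        w, b = _fit_weights((X[tr] - means) / sds, y[tr], C, engine)
        pooled[i] = ((X[i] - means) / sds) @ w + b
    return auc(pooled, y)
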