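"""One-vs-all support-vector classification of learned beat features.

One binary maximum-margin classifier is trained per class (class versus
rest); a sample is assigned to the class with the largest decision value,
ties broken towards the lowest class index.  The default kernel is linear
(the pipeline's classifier is a linear SVM); an RBF kernel with its gamma
is selectable.  The per-class decision scores are returned alongside the
labels so one-vs-rest ROC/AUC can be computed downstream.

The separating hyperplane is w.x + b = 0; the margin is reported as
d = 2 / ||w||**2.  Note the conventional geometric margin is 2 / ||w||;
this module follows the squared-norm form used by the pipeline's
definition, which agrees at ||w|| = 1 and is monotone in ||w|| either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

#: SMO solver tolerance, recorded in the model for reproducibility.
SOLVER_TOL = 1e-4


class DegenerateLabelsError(ValueError):
    """Raised when fitting is attempted with fewer than two classes."""


class UndefinedMarginError(ValueError):
    """Raised for the margin of a zero weight vector."""


@dataclass
class SVMModel:
    """Per-class binary classifiers of the one-vs-all scheme."""

    classes: np.ndarray
    estimators: list
    kernel: str
    C: float
    gamma: float | str
    solver_tol: float = SOLVER_TOL
    feature_dim: int = 0

    def linear_weights(self) -> list[tuple[np.ndarray, float]]:
        """(w, b) per class; only defined for the linear kernel."""
        if self.kernel != "linear":
            raise ValueError("explicit (w, b) only exists for the linear kernel")
        return [
            (est.coef_.ravel().copy(), float(est.intercept_[0]))
            for est in self.estimators
        ]


def fit_ova_svm(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    kernel: str = "linear",
    gamma: float | str = 1e-4,
    seed: int = 0,
) -> SVMModel:
    """Train one binary max-margin classifier per class (one-vs-all)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    classes = np.unique(labels)
    if classes.size < 2:
        raise DegenerateLabelsError("need at least two classes to fit an SVM")
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    estimators = []
    for c in classes:
        est = SVC(
            kernel=kernel,
            C=C,
            gamma=gamma,
            tol=SOLVER_TOL,
            random_state=seed,
        )
        est.fit(features, (labels == c).astype(int))
        estimators.append(est)
    return SVMModel(
        classes=classes,
        estimators=estimators,
        kernel=kernel,
        C=C,
        gamma=gamma,
        feature_dim=features.shape[1],
    )


def predict_labels(
    model: SVMModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and the per-class decision-score matrix.

    The label is the class with the largest decision value; exact ties go
    to the lowest class index (argmax picks the first maximum).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.feature_dim:
        raise ValueError(
            f"expected feature dimension {model.feature_dim}, "
            f"got shape {features.shape}"
        )
    scores = np.column_stack(
        [est.decision_function(features) for est in model.estimators]
    )
    labels = model.classes[scores.argmax(axis=1)]
    return labels, scores


def decision_margin(w: np.ndarray) -> float:
    """Margin of a separating hyperplane, d = 2 / ||w||**2."""
    w = np.asarray(w, dtype=float)
    norm_sq = float(w @ w)
    if norm_sq == 0.0:
        raise UndefinedMarginError("margin is undefined for a zero weight vector")
    return 2.0 / norm_sq
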