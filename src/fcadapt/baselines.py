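"""Baseline classifiers: polynomial-kernel SVM and a plain MLP.

These are the conventional single-domain comparators: they train on
labeled source-domain features only and have no mechanism to absorb a
domain shift, which is exactly why they degrade when evaluated on a
differently distributed target domain.  Both are thin configurations of
scikit-learn estimators (SVC with a polynomial kernel at C=100,
one-vs-rest for three classes; MLPClassifier with 200- and 500-unit
hidden layers, ReLU, Adam) so they compose with sklearn tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = ["BaselineConfig", "make_baseline", "train_baseline", "predict_baseline"]


@dataclass
class BaselineConfig:
    kind: str = "svm"                  # "svm" or "mlp"
    svm_C: float = 100.0
    svm_degree: int = 3
    mlp_layers: tuple[int, ...] = (200, 500)
    learning_rate: float = 1e-4
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("svm", "mlp"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")
        if any(w <= 0 for w in self.mlp_layers):
            raise ValueError("mlp layer widths must be positive")


def make_baseline(config: BaselineConfig):
    """Unfitted sklearn estimator for the requested baseline."""
    if config.kind == "svm":
        return SVC(
            kernel="poly",
            C=config.svm_C,
            degree=config.svm_degree,
            decision_function_shape="ovr",
            random_state=config.seed,
        )
    return MLPClassifier(
        hidden_layer_sizes=tuple(config.mlp_layers),
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        random_state=config.seed,
    )


def train_baseline(features, labels, config: BaselineConfig):
    """Fit a baseline classifier; requires at least two classes."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("baseline training needs at least 2 classes")
    model = make_baseline(config)
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(features, dtype=np.float64), labels)
    return model


def predict_baseline(model, features) -> np.ndarray:
    """One predicted label per row; empty input yields empty output."""
    features = np.asarray(features, dtype=np.float64)
    if len(features) == 0:
        return np.array([], dtype=object)
    return model.predict(features)
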