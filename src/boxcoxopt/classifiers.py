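"""Uniform train/predict adapters for the five reference classifiers.

Every optimizer and pipeline step talks to a classifier only through the
:class:`ClassifierAdapter` contract (``train(X, Y)`` / ``predict(X)``), so any
object honouring it can be plugged in.  The built-in factory covers:

====================  =====================================================
name                  model
====================  =====================================================
``linear``            linear model with perceptron loss, SGD training
``knn``               k-nearest-neighbour vote, k = 5
``bayesian``          Gaussian naive Bayes
``svc``               C-support vector machine, radial-basis kernel
``nn``                multilayer network, 2 hidden layers of 10 ReLU units,
                      cross-entropy loss
====================  =====================================================

Library defaults are used otherwise; all seedable components take the spec
seed (default 42).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import SGDClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .transform import NotFittedError

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("linear", "knn", "bayesian", "svc", "nn")

DEFAULT_SEED = 42


class ConfigurationError(ValueError):
    """Unknown classifier name or invalid preset/configuration value."""


@dataclass
class ClassifierSpec:
    """Declarative description of one of the reference classifiers.

    ``hyperparameters`` are forwarded to the underlying estimator constructor
    (e.g. ``n_neighbors`` for knn, ``hidden_layer_sizes`` for nn, ``kernel``
    for svc).
    """

    name: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ConfigurationError(
                f"unknown classifier {self.name!r}; valid names: "
                f"{', '.join(CLASSIFIER_NAMES)}"
            )


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.name == "linear":
        hp.setdefault("loss", "perceptron")
        hp.setdefault("random_state", spec.seed)
        return SGDClassifier(**hp)
    if spec.name == "knn":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    if spec.name == "bayesian":
        return GaussianNB(**hp)
    if spec.name == "svc":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("random_state", spec.seed)
        return SVC(**hp)
    if spec.name == "nn":
        hp.setdefault("hidden_layer_sizes", (10, 10))
        hp.setdefault("random_state", spec.seed)
        return MLPClassifier(**hp)
    raise ConfigurationError(f"unknown classifier {spec.name!r}")


class ClassifierAdapter:
    """Stateful train/predict handle wrapping a scikit-learn estimator."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self._estimator = _build_estimator(spec)
        self._trained = False

    @property
    def trained(self) -> bool:
        return self._trained

    @property
    def estimator(self):
        return self._estimator

    def train(self, X: np.ndarray, Y: np.ndarray) -> "ClassifierAdapter":
        # Tiny fixtures rarely let the network converge; that is expected and
        # logged rather than surfaced as a warning.
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "always" if logger.isEnabledFor(logging.DEBUG) else "ignore",
                category=ConvergenceWarning,
            )
            self._estimator.fit(np.asarray(X, dtype=float), np.asarray(Y))
        self._trained = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._trained:
            raise NotFittedError(
                f"classifier {self.spec.name!r} must be trained before predict"
            )
        return self._estimator.predict(np.asarray(X, dtype=float))

    def fresh(self) -> "ClassifierAdapter":
        """An untrained copy with identical spec (for repeated refits)."""
        other = ClassifierAdapter.__new__(ClassifierAdapter)
        other.spec = self.spec
        other._estimator = clone(self._estimator)
        other._trained = False
        return other


def make_classifier(spec: ClassifierSpec | str) -> ClassifierAdapter:
    """Build a train/predict handle from a spec (or bare classifier name)."""
    if isinstance(spec, str):
        spec = ClassifierSpec(spec)
    return ClassifierAdapter(spec)
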