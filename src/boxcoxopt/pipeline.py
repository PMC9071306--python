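"""Train/predict pipeline around the Box-Cox transform.

Fitting runs the stages in a fixed order: range-standardize to [1, 2]
(guaranteeing positivity), optimize Lambda against the target classifier,
Box-Cox transform, standardize to zero mean / unit variance, train.
Prediction mirrors the path with the *fitted* scaler states and the stored
Lambda — nothing is refitted on test data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np

from .classifiers import ClassifierAdapter, ClassifierSpec, ConfigurationError, make_classifier
from .optimizers import (
    GridSpec,
    OptimizerConfig,
    SearchTrace,
    diagonal_search,
    grid_search_2d,
    iterative_search,
    mle_lambda_vector,
    spherical_search,
)
from .transform import (
    DimensionError,
    MeanVarianceScaler,
    RangeScaler,
    boxcox_matrix,
)

logger = logging.getLogger(__name__)

OPTIMIZER_NAMES = ("identity", "mle", "spherical", "diagonal", "grid2d", "iterative")


@dataclass
class FittedModel:
    """Everything needed to reproduce predictions: Lambda, trained classifier
    and the two fitted scaler states."""

    lambdas: np.ndarray
    classifier: ClassifierAdapter
    minmax: RangeScaler
    standard: MeanVarianceScaler
    optimizer_name: str
    config: OptimizerConfig | None = None
    trace: SearchTrace | None = None

    @property
    def p(self) -> int:
        return int(self.lambdas.shape[0])


def _run_optimizer(name: str, X: np.ndarray, Y: np.ndarray,
                   handle: ClassifierAdapter, config: OptimizerConfig,
                   grid: GridSpec) -> tuple[np.ndarray, SearchTrace | None]:
    if name == "identity":
        return np.ones(X.shape[1]), None
    if name == "mle":
        return mle_lambda_vector(X), None
    if name == "spherical":
        return spherical_search(X, Y, handle, grid), None
    if name == "diagonal":
        return diagonal_search(X, Y, handle, grid), None
    if name == "grid2d":
        return grid_search_2d(X, Y, handle, grid), None
    if name == "iterative":
        return iterative_search(X, Y, handle, config, grid)
    raise ConfigurationError(
        f"unknown optimizer {name!r}; valid names: {', '.join(OPTIMIZER_NAMES)}"
    )


def fit_model(X: np.ndarray, Y: np.ndarray,
              spec: ClassifierSpec | str,
              optimizer: str = "iterative",
              config: OptimizerConfig | None = None,
              grid: GridSpec | None = None) -> FittedModel:
    """Fit scalers, optimize Lambda for the classifier, train.

    Stage order: min-max scale -> optimize Lambda -> Box-Cox -> standard
    scale -> train classifier.  Scalers are fitted on the supplied (training)
    data only.  A single-class Y degenerates the criterion (constant 1.0);
    it is flagged with a warning and Lambda falls back to all ones.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    config = config or OptimizerConfig()
    grid = grid or config.make_grid()
    handle = make_classifier(spec)

    minmax = RangeScaler()
    X_m = minmax.fit_transform(X)

    if np.unique(Y).size < 2:
        warnings.warn(
            "single-class labels: criterion is constant, falling back to Lambda = ones",
            UserWarning,
            stacklevel=2,
        )
        lambdas, trace = np.ones(X.shape[1]), None
    else:
        lambdas, trace = _run_optimizer(optimizer, X_m, Y, handle, config, grid)
    logger.info("optimizer %s selected Lambda = %s", optimizer, np.round(lambdas, 4))

    X_b = boxcox_matrix(X_m, lambdas)
    standard = MeanVarianceScaler()
    X_s = standard.fit_transform(X_b)
    handle.train(X_s, Y)
    return FittedModel(
        lambdas=np.asarray(lambdas, dtype=float),
        classifier=handle,
        minmax=minmax,
        standard=standard,
        optimizer_name=optimizer,
        config=config,
        trace=trace,
    )


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Mirror the fitted pipeline on new data and predict labels."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != model.p:
        raise DimensionError(
            f"X has {X.shape[1]} columns but the model was fitted with {model.p}"
        )
    X_m = model.minmax.transform(X)
    X_b = boxcox_matrix(X_m, model.lambdas)
    X_s = model.standard.transform(X_b)
    return model.classifier.predict(X_s)


def save_model(model: FittedModel, directory: str | Path) -> Path:
    """Serialize Lambda + scaler states + config as JSON and the trained
    classifier with joblib alongside."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "lambdas": model.lambdas.tolist(),
        "optimizer": model.optimizer_name,
        "classifier_spec": {
            "name": model.classifier.spec.name,
            "hyperparameters": model.classifier.spec.hyperparameters,
            "seed": model.classifier.spec.seed,
        },
        "minmax": {
            "min": model.minmax.min_.tolist(),
            "scale": model.minmax.scale_.tolist(),
            "offset": model.minmax.offset_.tolist(),
        },
        "standard": {
            "mean": model.standard.mean_.tolist(),
            "scale": model.standard.scale_.tolist(),
        },
        "config": asdict(model.config) if model.config else None,
        "trace": model.trace.to_dict() if model.trace else None,
    }
    (directory / "model.json").write_text(json.dumps(payload, indent=2))
    joblib.dump(model.classifier.estimator, directory / "classifier.joblib")
    return directory / "model.json"


def load_model(directory: str | Path) -> FittedModel:
    directory = Path(directory)
    payload = json.loads((directory / "model.json").read_text())
    spec = ClassifierSpec(**payload["classifier_spec"])
    handle = ClassifierAdapter(spec)
    handle._estimator = joblib.load(directory / "classifier.joblib")
    handle._trained = True

    minmax = RangeScaler()
    minmax.min_ = np.asarray(payload["minmax"]["min"], dtype=float)
    minmax.scale_ = np.asarray(payload["minmax"]["scale"], dtype=float)
    minmax.offset_ = np.asarray(payload["minmax"]["offset"], dtype=float)

    standard = MeanVarianceScaler()
    standard.fit(np.zeros((1, len(payload["standard"]["mean"]))))
    standard._scaler.mean_ = np.asarray(payload["standard"]["mean"], dtype=float)
    standard._scaler.scale_ = np.asarray(payload["standard"]["scale"], dtype=float)

    config = OptimizerConfig(**payload["config"]) if payload["config"] else None
    return FittedModel(
        lambdas=np.asarray(payload["lambdas"], dtype=float),
        classifier=handle,
        minmax=minmax,
        standard=standard,
        optimizer_name=payload["optimizer"],
        config=config,
        trace=None,
    )
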