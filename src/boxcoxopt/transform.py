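"""Box-Cox power transformation and the two scalers that bracket it.

The Box-Cox transform T(y; lambda) = (y**lambda - 1)/lambda (natural log for
lambda = 0) is defined for strictly positive inputs only, so features are first
mapped affinely into the range [1, 2].  After the transform the data is
standardized to zero mean and unit variance before it reaches a classifier.
A matrix is transformed column-wise with one exponent per feature, collected
in the vector Lambda = [lambda_1, ..., lambda_p].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler as _SkStandardScaler

#: |lambda| below this uses the logarithmic branch.
ZERO_TOL = 1e-12

#: Positivity floor applied after min-max extrapolation on unseen data.
POSITIVITY_FLOOR = 1e-6


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


class DimensionError(ValueError):
    """Shape or length mismatch between related arrays."""


class NotFittedError(RuntimeError):
    """A scaler or model was applied before being fitted."""


@dataclass
class DataMatrix:
    """A numeric feature matrix with class labels.

    Attributes
    ----------
    X : (n, p) float array
        Feature values; no missing entries.
    Y : (n,) array
        Class labels; categorical with a finite label set.
    """

    X: np.ndarray
    Y: np.ndarray
    feature_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y)
        if self.X.ndim != 2:
            raise DimensionError(f"X must be 2-D, got shape {self.X.shape}")
        if self.X.shape[0] != self.Y.shape[0]:
            raise DimensionError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]} labels"
            )
        if self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise DimensionError("X must have at least one row and one column")
        if np.isnan(self.X).any():
            raise DomainError("X contains missing values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.Y)


def boxcox_vector(y: np.ndarray, lam: float) -> np.ndarray:
    """Apply the one-dimensional Box-Cox transform element-wise.

    Parameters
    ----------
    y : array of positive reals
    lam : float
        The exponent; values with ``abs(lam) < ZERO_TOL`` use ``ln(y)``.

    Raises
    ------
    DomainError
        If any element of ``y`` is not strictly positive.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(lam):
        raise DomainError(f"lambda must be finite, got {lam}")
    bad = np.flatnonzero(~(y > 0))
    if bad.size:
        raise DomainError(
            f"Box-Cox requires strictly positive input; first offending index "
            f"{bad[0]} has value {y.flat[bad[0]]!r}"
        )
    if abs(lam) < ZERO_TOL:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_matrix(X: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Apply Box-Cox column-wise with one exponent per feature.

    ``lambdas`` must have one entry per column of ``X``; column ``j`` of the
    result is ``boxcox_vector(X[:, j], lambdas[j])``.
    """
    X = np.asarray(X, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float).ravel()
    if X.ndim != 2:
        raise DimensionError(f"X must be 2-D, got shape {X.shape}")
    if lambdas.shape[0] != X.shape[1]:
        raise DimensionError(
            f"Lambda has length {lambdas.shape[0]} but X has {X.shape[1]} columns"
        )
    out = np.empty_like(X)
    for j, lam in enumerate(lambdas):
        out[:, j] = boxcox_vector(X[:, j], lam)
    return out


class RangeScaler:
    """Affine per-column rescaling of training data into [1, 2].

    The training minimum maps to 1 and the training maximum to 2.  Unseen data
    is extrapolated with the same affine map and then floored at
    ``POSITIVITY_FLOOR`` so the subsequent Box-Cox step stays defined.
    Constant training columns map to the range midpoint 1.5.
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.offset_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.min_ is not None

    def fit(self, X: np.ndarray) -> "RangeScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DimensionError(f"X must be 2-D, got shape {X.shape}")
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        rng = hi - lo
        constant = rng == 0
        with np.errstate(divide="ignore"):
            scale = np.where(constant, 0.0, 1.0 / np.where(constant, 1.0, rng))
        offset = np.where(constant, 1.5, 1.0 - lo * scale)
        self.min_ = lo
        self.scale_ = scale
        self.offset_ = offset
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("RangeScaler.transform called before fit")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.scale_.shape[0]:
            raise DimensionError(
                f"X has {X.shape[1]} columns; scaler was fitted on "
                f"{self.scale_.shape[0]}"
            )
        out = X * self.scale_ + self.offset_
        return np.maximum(out, POSITIVITY_FLOOR)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


class MeanVarianceScaler:
    """Zero-mean / unit-variance standardization (population divisor n).

    Thin stateful wrapper around scikit-learn's ``StandardScaler``: columns
    with zero variance are centered and left unscaled.
    """

    def __init__(self) -> None:
        self._scaler = _SkStandardScaler()
        self._fitted = False

    @property
    def fitted(self) -> bool:
        return self._fitted

    @property
    def mean_(self) -> np.ndarray:
        return self._scaler.mean_

    @property
    def scale_(self) -> np.ndarray:
        return self._scaler.scale_

    def fit(self, X: np.ndarray) -> "MeanVarianceScaler":
        self._scaler.fit(np.asarray(X, dtype=float))
        self._fitted = True
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError("MeanVarianceScaler.transform called before fit")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._scaler.mean_.shape[0]:
            raise DimensionError(
                f"X has {X.shape[1]} columns; scaler was fitted on "
                f"{self._scaler.mean_.shape[0]}"
            )
        return self._scaler.transform(X)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# Functional aliases mirroring the fit/apply operation names.

def minmax_fit(X: np.ndarray) -> RangeScaler:
    return RangeScaler().fit(X)


def minmax_apply(state: RangeScaler, X: np.ndarray) -> np.ndarray:
    return state.transform(X)


def standard_fit(X: np.ndarray) -> MeanVarianceScaler:
    return MeanVarianceScaler().fit(X)


def standard_apply(state: MeanVarianceScaler, X: np.ndarray) -> np.ndarray:
    return state.transform(X)
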