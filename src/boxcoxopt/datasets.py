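"""Synthetic 2-D binary generators, CSV loading and chi-square feature ranking.

The four generator families mirror the classic scikit-learn toy problems:
concentric Gaussian quantile shells, two interleaving half circles, isotropic
Gaussian blobs, and a generic linearly-mixed classification problem.  All are
2-feature, 2-class, seeded and class-balanced to within one sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.datasets import (
    make_blobs,
    make_classification,
    make_gaussian_quantiles,
    make_moons,
)
from sklearn.feature_selection import chi2 as _sk_chi2

from .classifiers import ConfigurationError
from .transform import DataMatrix, DimensionError, DomainError

FAMILIES = ("gaussian_quantiles", "half_circles", "blobs", "random_linear")


class ParseError(ValueError):
    """Malformed tabular input (missing or non-numeric cells)."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic 2-D binary dataset.

    ``noise`` is the additive Gaussian noise of the half circles, ``spread``
    the cluster standard deviation of the blobs, ``class_sep`` the class
    separation of the linearly-mixed problem.
    """

    family: str
    n_samples: int = 1000
    noise: float = 0.0
    spread: float = 1.5
    class_sep: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; valid families: {', '.join(FAMILIES)}"
            )
        if self.n_samples < 20:
            raise ConfigurationError("n_samples must be at least 20")


def make_synthetic(spec: SyntheticSpec) -> DataMatrix:
    """Generate a seeded 2-feature, 2-class dataset of the requested family."""
    if spec.family == "gaussian_quantiles":
        X, y = make_gaussian_quantiles(
            n_samples=spec.n_samples, n_features=2, n_classes=2,
            random_state=spec.seed,
        )
    elif spec.family == "half_circles":
        X, y = make_moons(
            n_samples=spec.n_samples,
            noise=spec.noise if spec.noise > 0 else None,
            random_state=spec.seed,
        )
    elif spec.family == "blobs":
        X, y = make_blobs(
            n_samples=spec.n_samples, n_features=2, centers=2,
            cluster_std=spec.spread, random_state=spec.seed,
        )
    else:  # random_linear
        X, y = make_classification(
            n_samples=spec.n_samples, n_features=2, n_informative=2,
            n_redundant=0, n_clusters_per_class=1, flip_y=0.0,
            class_sep=spec.class_sep, random_state=spec.seed,
        )
    return DataMatrix(X, y.astype(int), feature_names=["f1", "f2"])


def load_tabular(path: str | Path, label_column: str | int = "y",
                 header: str | int | None = "infer",
                 sep: str | None = None) -> DataMatrix:
    """Load a delimited numeric table with one label column.

    The delimiter is sniffed when ``sep`` is None (comma/semicolon/tab).
    Rows with missing values and non-numeric feature cells are rejected with
    their locations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python", header=header)
    if isinstance(label_column, int) and label_column not in df.columns:
        label = df.iloc[:, label_column]
        features = df.drop(columns=[df.columns[label_column]])
    else:
        if label_column not in df.columns:
            raise ParseError(
                f"label column {label_column!r} not found in {path.name}; "
                f"columns: {list(df.columns)}"
            )
        label = df[label_column]
        features = df.drop(columns=[label_column])

    n_missing = int(features.isna().sum().sum()) + int(label.isna().sum())
    if n_missing:
        rows = sorted(set(features.index[features.isna().any(axis=1)])
                      | set(label.index[label.isna()]))
        raise ParseError(
            f"{path.name} has {n_missing} missing value(s) in rows {rows[:10]}"
        )
    numeric = features.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & features.notna()
    if bad.to_numpy().any():
        r = int(bad.any(axis=1).idxmax())
        c = bad.columns[bad.loc[r].to_numpy().argmax()]
        raise ParseError(
            f"non-numeric feature value {features.loc[r, c]!r} at row {r}, column {c!r}"
        )
    return DataMatrix(numeric.to_numpy(dtype=float), label.to_numpy(),
                      feature_names=[str(c) for c in numeric.columns])


def chi2_rank(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Feature indices sorted by decreasing chi-square statistic.

    The statistic compares class-wise feature sums against their expectation
    under label independence; it requires non-negative features (range
    standardization upstream guarantees this).  Ties keep original index
    order (stable sort).
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise DomainError("chi-square ranking requires non-negative features")
    stats, _ = _sk_chi2(X, np.asarray(Y))
    return np.argsort(-stats, kind="stable")


def extract_feature_pair(data: DataMatrix, i: int, j: int) -> DataMatrix:
    """2-column sub-dataset of features ``i`` and ``j`` (row order kept)."""
    p = data.p
    if i == j:
        raise DimensionError("feature indices must be distinct")
    if not (0 <= i < p and 0 <= j < p):
        raise DimensionError(f"feature indices ({i}, {j}) out of range for p = {p}")
    names = None
    if data.feature_names is not None:
        names = [data.feature_names[i], data.feature_names[j]]
    return DataMatrix(data.X[:, [i, j]], data.Y, feature_names=names)


def save_csv(data: DataMatrix, path: str | Path) -> None:
    """Write features (f1, f2, ...) plus label column ``y`` as CSV."""
    names = data.feature_names or [f"f{k + 1}" for k in range(data.p)]
    df = pd.DataFrame(data.X, columns=names)
    df["y"] = data.Y
    df.to_csv(path, index=False)
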