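"""Repeated stratified cross-validation and 2-D accuracy-grid exploration.

Two evaluation paths exist on purpose:

* ``evaluate_cv`` runs the honest pipeline (scalers and Lambda fitted inside
  each training fold) and is the headline number.
* ``grid_exploration`` follows the exploratory protocol: the full
  (pre-range-standardized) matrix is Box-Cox transformed at a fixed
  (lambda1, lambda2) *before* splitting, then each fold standard-scales on
  its training part, trains and tests.  Since the transform at fixed Lambda
  is element-wise, only the global range standardization leaks across folds.

The heatmap cell at Lambda = [1, 1] is the no-transform baseline: lambda = 1
merely shifts the data by one, which the subsequent standardization removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec
from .optimizers import GridSpec, OptimizerConfig
from .pipeline import fit_model, predict
from .transform import DimensionError, MeanVarianceScaler, boxcox_matrix
from . import classifiers as _classifiers

logger = logging.getLogger(__name__)


class PartitionError(ValueError):
    """A class is too small for the requested number of folds."""


class AnnotationError(ValueError):
    """The heatmap axes do not contain the baseline value 1."""


@dataclass
class CVConfig:
    """Repeated stratified k-fold settings (defaults: 10 folds, 5 reps)."""

    kfolds: int = 10
    repetitions: int = 5
    base_seed: int = 42

    def __post_init__(self) -> None:
        if self.kfolds < 2:
            raise PartitionError("kfolds must be at least 2")
        if self.repetitions < 1:
            raise PartitionError("repetitions must be at least 1")


@dataclass
class CVResult:
    """Per-fold accuracies/F1 over repetitions x folds."""

    accuracies: np.ndarray
    f1_scores: np.ndarray
    label: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1_scores))


@dataclass
class HeatmapResult:
    """Mean CV accuracy over the (lambda1, lambda2) grid.

    ``accuracy[i, j]`` is the cell for ``lambda1_values[i]`` (rows) and
    ``lambda2_values[j]`` (columns).
    """

    lambda1_values: np.ndarray
    lambda2_values: np.ndarray
    accuracy: np.ndarray
    annotations: dict = field(default_factory=dict)


def _check_class_sizes(Y: np.ndarray, kfolds: int) -> None:
    labels, counts = np.unique(Y, return_counts=True)
    for lab, cnt in zip(labels, counts):
        if cnt < kfolds:
            raise PartitionError(
                f"class {lab!r} has only {cnt} members but {kfolds} folds were requested"
            )


def stratified_partitions(Y: np.ndarray, cvconfig: CVConfig,
                          repetition_index: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint stratified test folds covering all samples.

    Repetition ``r`` shuffles with seed ``base_seed + r``, so each repetition
    is a different, reproducible partition.
    """
    Y = np.asarray(Y)
    _check_class_sizes(Y, cvconfig.kfolds)
    skf = StratifiedKFold(
        n_splits=cvconfig.kfolds,
        shuffle=True,
        random_state=cvconfig.base_seed + repetition_index,
    )
    return [(tr, te) for tr, te in skf.split(np.zeros(len(Y)), Y)]


def metrics(y_true: np.ndarray, y_pred: np.ndarray,
            average: str = "binary") -> tuple[float, float]:
    """(accuracy, F1).

    For binary problems the positive class is the lexicographically larger
    label; pass ``average="macro"`` for the unweighted per-class mean.
    Problems with more than two classes always use macro F1.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] != y_pred.shape[0]:
        raise DimensionError(
            f"y_true has {y_true.shape[0]} entries, y_pred {y_pred.shape[0]}"
        )
    acc = float(accuracy_score(y_true, y_pred))
    labels = np.unique(np.concatenate([y_true, y_pred]))
    if average == "macro" or labels.size > 2:
        f1 = float(f1_score(y_true, y_pred, average="macro", zero_division=0))
    else:
        pos = sorted(labels.tolist())[-1]
        f1 = float(f1_score(y_true, y_pred, pos_label=pos, zero_division=0))
    return acc, f1


def evaluate_cv(X: np.ndarray, Y: np.ndarray,
                spec: ClassifierSpec | str,
                optimizer: str = "iterative",
                config: OptimizerConfig | None = None,
                cvconfig: CVConfig | None = None,
                grid: GridSpec | None = None,
                label: str = "") -> CVResult:
    """Repeated stratified CV of the full fit/predict pipeline.

    Per fold the model (scalers, Lambda, classifier) is fitted on the
    training split only; mean accuracy is the sum over repetitions x folds
    divided by ``repetitions * kfolds``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    cvconfig = cvconfig or CVConfig()
    accs: list[float] = []
    f1s: list[float] = []
    for rep in range(cvconfig.repetitions):
        for tr, te in stratified_partitions(Y, cvconfig, rep):
            model = fit_model(X[tr], Y[tr], spec, optimizer, config, grid)
            pred = predict(model, X[te])
            a, f = metrics(Y[te], pred)
            accs.append(a)
            f1s.append(f)
    return CVResult(np.asarray(accs), np.asarray(f1s), label=label)


def grid_exploration(X: np.ndarray, Y: np.ndarray,
                     spec: ClassifierSpec | str,
                     grid: GridSpec | None = None,
                     cvconfig: CVConfig | None = None) -> HeatmapResult:
    """Mean CV accuracy for every (lambda1, lambda2) cell of the grid.

    ``X`` must already be range-standardized to [1, 2] (strictly positive);
    the transform at each fixed Lambda is applied to the full matrix before
    splitting, per the exploratory protocol.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    if X.shape[1] != 2:
        raise DimensionError(
            f"grid exploration requires exactly 2 features, got {X.shape[1]}"
        )
    grid = grid or GridSpec.default()
    cvconfig = cvconfig or CVConfig()
    handle = _classifiers.make_classifier(spec)
    splits = [stratified_partitions(Y, cvconfig, rep)
              for rep in range(cvconfig.repetitions)]
    cands = grid.candidates
    A = np.zeros((cands.size, cands.size))
    total = cvconfig.repetitions * cvconfig.kfolds
    for i, l1 in enumerate(cands):
        for j, l2 in enumerate(cands):
            Xb = boxcox_matrix(X, np.array([l1, l2]))
            acc_sum = 0.0
            for rep_splits in splits:
                for tr, te in rep_splits:
                    scaler = MeanVarianceScaler()
                    Xtr = scaler.fit_transform(Xb[tr])
                    clf = handle.fresh().train(Xtr, Y[tr])
                    pred = clf.predict(scaler.transform(Xb[te]))
                    acc_sum += float(np.mean(pred == Y[te]))
            A[i, j] = acc_sum / total
        logger.info("grid exploration: lambda1 = %.3g done", l1)
    result = HeatmapResult(cands.copy(), cands.copy(), A)
    try:
        result.annotations = annotate_optima(result)
    except AnnotationError:
        # grids without the baseline value 1 cannot be annotated
        result.annotations = {}
    return result


def _axis_index_of_one(values: np.ndarray, name: str) -> int:
    idx = np.flatnonzero(np.isclose(values, 1.0))
    if idx.size == 0:
        raise AnnotationError(f"{name} axis does not contain the baseline value 1")
    return int(idx[0])


def annotate_optima(heatmap: HeatmapResult) -> dict:
    """Locate the spherical, diagonal and full optima on the heatmap.

    * full: argmax over all cells (first in row-major scan order on ties);
    * spherical: argmax over the diagonal cells lambda1 = lambda2;
    * diagonal: combine the argmax of the lambda2 = 1 column (choosing
      lambda1) with the argmax of the lambda1 = 1 row (choosing lambda2);
      axis ties are resolved by evaluating each tied combination's cell and
      keeping the best, remaining ties by scan order.
    """
    A = heatmap.accuracy
    l1 = heatmap.lambda1_values
    l2 = heatmap.lambda2_values
    j1 = _axis_index_of_one(l2, "lambda2")
    i1 = _axis_index_of_one(l1, "lambda1")

    flat = int(np.argmax(A))
    fi, fj = np.unravel_index(flat, A.shape)

    if A.shape[0] == A.shape[1] and np.allclose(l1, l2):
        diag_vals = np.diag(A)
        si = int(np.argmax(diag_vals))
        spherical = {"index": (si, si), "lambda": (float(l1[si]), float(l2[si])),
                     "accuracy": float(diag_vals[si])}
    else:
        spherical = None

    col = A[:, j1]  # vary lambda1, lambda2 fixed at 1
    row = A[i1, :]  # vary lambda2, lambda1 fixed at 1
    tied_i = np.flatnonzero(col == col.max())
    tied_j = np.flatnonzero(row == row.max())
    best = None
    for i in tied_i:
        for j in tied_j:
            if best is None or A[i, j] > A[best[0], best[1]]:
                best = (int(i), int(j))
    di, dj = best

    annotations = {
        "full": {"index": (int(fi), int(fj)),
                 "lambda": (float(l1[fi]), float(l2[fj])),
                 "accuracy": float(A[fi, fj])},
        "diagonal": {"index": (di, dj),
                     "lambda": (float(l1[di]), float(l2[dj])),
                     "accuracy": float(A[di, dj])},
        "baseline": {"index": (i1, j1), "lambda": (1.0, 1.0),
                     "accuracy": float(A[i1, j1])},
    }
    if spherical is not None:
        annotations["spherical"] = spherical
    return annotations


def heatmap_summary(heatmap: HeatmapResult) -> dict:
    """Before/after summary of a heatmap on the percent scale.

    Mirrors the before / after / full-delta / spherical-delta /
    diagonal-delta columns of the accuracy comparison tables: deltas are the
    annotated optima minus the baseline cell, in percentage points.
    """
    ann = heatmap.annotations or annotate_optima(heatmap)
    base = ann["baseline"]["accuracy"]
    out = {
        "before": base * 100.0,
        "after": ann["full"]["accuracy"] * 100.0,
        "full_delta": (ann["full"]["accuracy"] - base) * 100.0,
        "diagonal_delta": (ann["diagonal"]["accuracy"] - base) * 100.0,
    }
    if "spherical" in ann:
        out["spherical_delta"] = (ann["spherical"]["accuracy"] - base) * 100.0
    return out


def delta_table(results: dict[str, CVResult], baseline: CVResult) -> pd.DataFrame:
    """Accuracy deltas of each strategy vs the no-transform baseline.

    One row per strategy with mean accuracy and delta on the percent scale;
    full precision is kept, rounding is left to rendering.
    """
    rows = []
    for name, res in results.items():
        if res.accuracies.shape != baseline.accuracies.shape:
            raise DimensionError(
                f"strategy {name!r} has {res.accuracies.size} folds, baseline "
                f"{baseline.accuracies.size}"
            )
        rows.append({
            "strategy": name,
            "before": baseline.mean_accuracy * 100.0,
            "after": res.mean_accuracy * 100.0,
            "delta": (res.mean_accuracy - baseline.mean_accuracy) * 100.0,
            "f1": res.mean_f1 * 100.0,
        })
    return pd.DataFrame(rows)


def heatmap_to_csv(heatmap: HeatmapResult, path) -> None:
    """Write the accuracy matrix with axis values as first row/column."""
    df = pd.DataFrame(
        heatmap.accuracy,
        index=heatmap.lambda1_values,
        columns=heatmap.lambda2_values,
    )
    df.index.name = "lambda1\\lambda2"
    df.to_csv(path)


def render_heatmap(heatmap: HeatmapResult, path) -> None:
    """Optional matplotlib rendering with optimum markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    extent = [heatmap.lambda2_values[0], heatmap.lambda2_values[-1],
              heatmap.lambda1_values[-1], heatmap.lambda1_values[0]]
    im = ax.imshow(heatmap.accuracy, extent=extent, aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="mean CV accuracy")
    markers = {"spherical": "1", "diagonal": "2", "full": "3"}
    for key, sym in markers.items():
        if key in heatmap.annotations:
            lam = heatmap.annotations[key]["lambda"]
            ax.annotate(sym, xy=(lam[1], lam[0]), color="red",
                        fontsize=14, fontweight="bold", ha="center", va="center")
    ax.set_xlabel("lambda2")
    ax.set_ylabel("lambda1")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
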