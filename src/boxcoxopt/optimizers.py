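"""Lambda-selection strategies for the multi-dimensional Box-Cox transform.

The optimization criterion everywhere is L = 1 - ACC where ACC is the
*in-sample* (training-set) accuracy of the target classifier after Box-Cox
transforming and standardizing the data; minimizing L means maximizing ACC,
so all searches below keep the best accuracy seen and update the incumbent
only on strict improvement (ties keep the earliest candidate in scan order).

Strategies
----------
* ``grid_search_2d``   -- exhaustive search over the full lambda1 x lambda2 grid
                          (exponential in p, so restricted to p = 2).
* ``spherical_search`` -- one shared scalar lambda for all columns.
* ``diagonal_search``  -- each coordinate optimized independently with the
                          others held at 1, winners assembled into Lambda.
* ``mle_lambda``       -- the classical normality-maximizing profile
                          log-likelihood estimate, column-wise.
* ``iterative_search`` -- coordinate-wise grid descent over epochs, with
                          optional restart ("shift"), direction permutation
                          ("shuffle") and local grid refinement ("finer").

The iterative search costs exactly ``epochs * p * gridsize`` criterion
evaluations, linear in the number of features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .classifiers import ClassifierAdapter, ClassifierSpec, ConfigurationError, make_classifier
from .transform import DimensionError, MeanVarianceScaler, boxcox_matrix

logger = logging.getLogger(__name__)

GRID_BOUNDS = (-5.0, 5.0)


class EstimationError(ValueError):
    """Degenerate input for which an estimate is undefined."""


@dataclass
class GridSpec:
    """Candidate lambda values for one-dimensional scans.

    In ``global`` mode candidates are absolute values; in ``local`` mode
    (after refinement) they are offsets attached to the incumbent coordinate.
    """

    candidates: np.ndarray
    finer_factor: float = 0.5
    mode: str = "global"

    def __post_init__(self) -> None:
        self.candidates = np.asarray(self.candidates, dtype=float).ravel()
        if self.candidates.size < 1:
            raise ConfigurationError("grid needs at least one candidate")
        if np.any(np.diff(self.candidates) <= 0):
            raise ConfigurationError("grid candidates must be strictly increasing")
        if not (0.0 < self.finer_factor < 1.0):
            raise ConfigurationError("finer_factor must lie in (0, 1)")
        if self.mode not in ("global", "local"):
            raise ConfigurationError(f"unknown grid mode {self.mode!r}")

    @classmethod
    def default(cls, gridsize: int = 11, bounds: tuple[float, float] = GRID_BOUNDS,
                finer_factor: float = 0.5) -> "GridSpec":
        """``gridsize`` evenly spaced candidates on ``bounds`` (11 -> {-5,...,5})."""
        if gridsize < 2:
            raise ConfigurationError("gridsize must be at least 2")
        return cls(np.linspace(bounds[0], bounds[1], gridsize), finer_factor)

    def __len__(self) -> int:
        return self.candidates.size


def refine_grid(grid: GridSpec) -> GridSpec:
    """Scale every candidate by ``finer_factor`` and switch to local mode.

    Cardinality is preserved: {-5, -4, ..., 5} at factor 0.5 becomes
    {-2.5, -2, ..., 2.5}, attached as offsets to the incumbent coordinate.
    """
    return replace(grid, candidates=grid.candidates * grid.finer_factor, mode="local")


@dataclass
class OptimizerConfig:
    """Hyperparameters of the iterative coordinate search.

    ``shift_epoch`` / ``shuffle_epoch`` / ``finer_epoch`` give the epoch
    period after which a new start point is drawn, the direction order is
    permuted, and the grid is refined, respectively.
    """

    epochs: int = 4
    shift_epoch: int = 4
    shuffle_epoch: int = 4
    finer_epoch: int = 4
    gridsize: int = 11
    start_policy: str = "mle"
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("epochs", "shift_epoch", "shuffle_epoch", "finer_epoch", "gridsize"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.start_policy not in ("mle", "ones", "random"):
            raise ConfigurationError(
                f"unknown start_policy {self.start_policy!r}; use mle|ones|random"
            )

    def make_grid(self) -> GridSpec:
        return GridSpec.default(self.gridsize)


@dataclass
class SearchTrace:
    """Bookkeeping of an iterative search run.

    ``best_accuracy`` holds the running best after every criterion
    evaluation (non-decreasing by construction); ``incumbents`` the incumbent
    Lambda at the end of each epoch.
    """

    start_point: list[float] = field(default_factory=list)
    incumbents: list[list[float]] = field(default_factory=list)
    best_accuracy: list[float] = field(default_factory=list)
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "start_point": list(self.start_point),
            "incumbents": [list(v) for v in self.incumbents],
            "best_accuracy": list(self.best_accuracy),
            "n_evaluations": self.n_evaluations,
        }


Objective = Callable[[np.ndarray], float]


def _as_adapter(classifier: ClassifierAdapter | ClassifierSpec | str) -> ClassifierAdapter:
    if isinstance(classifier, ClassifierAdapter):
        return classifier
    return make_classifier(classifier)


def criterion_accuracy(X: np.ndarray, Y: np.ndarray, lambdas: Sequence[float],
                       classifier: ClassifierAdapter | ClassifierSpec | str) -> float:
    """In-sample accuracy after Box-Cox(Lambda) + standardization.

    Transform the (already positive, range-standardized) matrix, fit a fresh
    standard scaler, train the classifier and score it on the same data.
    """
    handle = _as_adapter(classifier).fresh()
    Xb = boxcox_matrix(X, np.asarray(lambdas, dtype=float))
    Xs = MeanVarianceScaler().fit_transform(Xb)
    pred = handle.train(Xs, Y).predict(Xs)
    return float(np.mean(pred == np.asarray(Y)))


def make_objective(X: np.ndarray, Y: np.ndarray,
                   classifier: ClassifierAdapter | ClassifierSpec | str) -> Objective:
    handle = _as_adapter(classifier)
    return lambda lambdas: criterion_accuracy(X, Y, lambdas, handle)


# ---------------------------------------------------------------------------
# Exhaustive / restricted searches
# ---------------------------------------------------------------------------

def grid_search_2d(X: np.ndarray, Y: np.ndarray,
                   classifier: ClassifierAdapter | ClassifierSpec | str,
                   grid: GridSpec | None = None) -> np.ndarray:
    """Exhaustive search over the full 2-D candidate grid.

    Scans lambda1 (outer, ascending) x lambda2 (inner, ascending) and keeps
    the first strict maximizer.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != 2:
        raise DimensionError(
            f"grid_search_2d requires exactly 2 features, got {X.shape[1]}"
        )
    grid = grid or GridSpec.default()
    objective = make_objective(X, Y, classifier)
    cands = grid.candidates
    best = np.array([cands[0], cands[0]])
    best_acc = 0.0
    for l1 in cands:
        for l2 in cands:
            acc = objective(np.array([l1, l2]))
            if acc > best_acc:
                best_acc = acc
                best = np.array([l1, l2])
    return best


def spherical_search(X: np.ndarray, Y: np.ndarray,
                     classifier: ClassifierAdapter | ClassifierSpec | str,
                     grid: GridSpec | None = None) -> np.ndarray:
    """One shared scalar lambda applied to every column."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    grid = grid or GridSpec.default()
    objective = make_objective(X, Y, classifier)
    best_lam = grid.candidates[0]
    best_acc = 0.0
    for lam in grid.candidates:
        acc = objective(np.full(p, lam))
        if acc > best_acc:
            best_acc = acc
            best_lam = lam
    return np.full(p, best_lam)


def diagonal_search(X: np.ndarray, Y: np.ndarray,
                    classifier: ClassifierAdapter | ClassifierSpec | str,
                    grid: GridSpec | None = None) -> np.ndarray:
    """Per-coordinate independent search, other coordinates fixed at 1.

    Each direction's winner is found on its own axis scan; the winners are
    then assembled into Lambda.  The joint accuracy of the assembled vector is
    *not* guaranteed to beat the baseline: independent axis optima can combine
    into a worse joint solution.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    grid = grid or GridSpec.default()
    objective = make_objective(X, Y, classifier)
    winners = np.empty(p)
    for d in range(p):
        best_lam = grid.candidates[0]
        best_acc = 0.0
        for lam in grid.candidates:
            trial = np.ones(p)
            trial[d] = lam
            acc = objective(trial)
            if acc > best_acc:
                best_acc = acc
                best_lam = lam
        winners[d] = best_lam
    return winners


# ---------------------------------------------------------------------------
# Classical maximum-likelihood estimate
# ---------------------------------------------------------------------------

def _profile_loglik(lam: float, y: np.ndarray) -> float:
    # scipy's boxcox_llf is exactly -(n/2) ln var(boxcox(y, lam)) + (lam-1) sum ln y
    return float(stats.boxcox_llf(lam, y))


def mle_lambda(y: np.ndarray, bounds: tuple[float, float] = GRID_BOUNDS) -> float:
    """Maximize the Box-Cox profile log-likelihood over ``bounds``.

    A 201-point grid pre-scan locates the global basin; a bounded scalar
    maximization then refines the estimate.  This is the classical
    normality-oriented lambda choice, used as a baseline strategy and as the
    default start point of the iterative search.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise EstimationError(f"need at least 3 observations, got {y.size}")
    if np.any(y <= 0):
        raise EstimationError("MLE requires strictly positive data")
    if np.ptp(y) == 0:
        raise EstimationError("constant vector: profile likelihood is degenerate")
    lo, hi = bounds
    scan = np.linspace(lo, hi, 201)
    ll = np.array([_profile_loglik(l, y) for l in scan])
    k = int(np.argmax(ll))
    step = scan[1] - scan[0]
    local_lo = max(lo, scan[k] - step)
    local_hi = min(hi, scan[k] + step)
    res = optimize.minimize_scalar(
        lambda l: -_profile_loglik(l, y), bounds=(local_lo, local_hi),
        method="bounded",
    )
    return float(res.x)


def mle_lambda_vector(X: np.ndarray, bounds: tuple[float, float] = GRID_BOUNDS) -> np.ndarray:
    """Column-wise ``mle_lambda``."""
    X = np.asarray(X, dtype=float)
    return np.array([mle_lambda(X[:, j], bounds) for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# Iterative coordinate search
# ---------------------------------------------------------------------------

def generate_initial_point(p: int, config: OptimizerConfig,
                           grid: GridSpec | None = None,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform draw per coordinate over the grid's bounding interval."""
    grid = grid or config.make_grid()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo = float(grid.candidates.min())
    hi = float(grid.candidates.max())
    return rng.uniform(lo, hi, size=p)


def resolve_start_point(X: np.ndarray, config: OptimizerConfig, grid: GridSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """Initial Lambda per the configured policy (mle | ones | random)."""
    p = X.shape[1]
    if config.start_policy == "mle":
        return mle_lambda_vector(X)
    if config.start_policy == "ones":
        return np.ones(p)
    return generate_initial_point(p, config, grid, rng)


def coordinate_descent(objective: Objective, p: int, config: OptimizerConfig,
                       grid: GridSpec, start: np.ndarray) -> tuple[np.ndarray, SearchTrace]:
    """The iterative grid search engine over an arbitrary objective.

    Per epoch, each direction (in the current order) is scanned over the
    candidate set with the other coordinates held at the incumbent; the
    incumbent and best accuracy update only on strict improvement.  Epoch
    triggers fire when the epoch index is divisible by the respective period,
    applied in the order finer -> shuffle -> shift:

    * finer: the grid is scaled by ``finer_factor`` and switches to local
      mode, attaching candidates as offsets to the incumbent coordinate;
    * shuffle: the direction order is permuted with the seeded RNG;
    * shift: a fresh uniform start point becomes the trial base until the
      next strict improvement clears shift mode.

    The total number of objective evaluations is exactly
    ``epochs * p * len(grid)``.
    """
    rng = np.random.default_rng(config.seed)
    incumbent = np.asarray(start, dtype=float).copy()
    trace = SearchTrace(start_point=[float(v) for v in incumbent])
    best_acc = 0.0
    dir_order = np.arange(p)
    shift = False
    shift_base = None

    for epoch in range(1, config.epochs + 1):
        if epoch % config.finer_epoch == 0:
            grid = refine_grid(grid)
        if epoch % config.shuffle_epoch == 0:
            dir_order = rng.permutation(p)
        if epoch % config.shift_epoch == 0:
            shift_base = generate_initial_point(p, config, grid, rng)
            shift = True
            logger.debug("epoch %d: shift restart at %s", epoch, shift_base)

        for d in dir_order:
            base = shift_base if shift else incumbent
            trial = base.copy()
            if grid.mode == "local":
                candidates = grid.candidates + incumbent[d]
            else:
                candidates = grid.candidates
            scan_best_acc = -np.inf
            scan_best_lam = candidates[0]
            for lam in candidates:
                trial[d] = lam
                acc = objective(trial)
                trace.n_evaluations += 1
                if acc > scan_best_acc:
                    scan_best_acc = acc
                    scan_best_lam = lam
                if acc > best_acc:
                    best_acc = acc
                    incumbent = trial.copy()
                    shift = False
                trace.best_accuracy.append(best_acc)
            if shift:
                # keep exploring from the restart point, carrying the best
                # coordinate found on this axis even without a global gain
                shift_base[d] = scan_best_lam
        trace.incumbents.append([float(v) for v in incumbent])
        logger.info("epoch %d: incumbent %s accuracy %.4f", epoch,
                    np.round(incumbent, 4), best_acc)
    return incumbent, trace


def iterative_search(X: np.ndarray, Y: np.ndarray,
                     classifier: ClassifierAdapter | ClassifierSpec | str,
                     config: OptimizerConfig | None = None,
                     grid: GridSpec | None = None) -> tuple[np.ndarray, SearchTrace]:
    """Coordinate-wise grid descent of the in-sample criterion."""
    config = config or OptimizerConfig()
    grid = grid or config.make_grid()
    X = np.asarray(X, dtype=float)
    objective = make_objective(X, Y, classifier)
    rng = np.random.default_rng(config.seed)
    start = resolve_start_point(X, config, grid, rng)
    return coordinate_descent(objective, X.shape[1], config, grid, start)
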