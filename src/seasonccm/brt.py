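"""Boosted-regression-tree influence ranking of candidate predators.

Fits a gradient-boosted regression-tree ensemble of the prey's seasonal
abundance on predator series, tuning learning rate, tree complexity
(interaction depth) and tree count by k-fold cross-validation.  Two
relative-influence measures are computed from the fitted ensemble's split
structure and normalized to 100%:

* selection frequency — the share of split nodes (across all trees) that
  use each predictor and improve the training fit; and
* split improvement — each predictor's summed squared-error reduction over
  its splits (the conventional BRT importance).

Partial dependence curves give the marginal response shape per predictor.
The tree fitting itself is delegated to scikit-learn's
``GradientBoostingRegressor``; influence and partial dependence are
derived here from the exported tree structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .errors import ConfigError, DegenerateSeriesError, InsufficientDataError

__all__ = ["BRTConfig", "BRTResult", "fit_brt", "partial_dependence"]


@dataclass
class BRTConfig:
    """Hyperparameter grids and CV layout for BRT fitting.

    Defaults follow the slow-learning best-practice protocol for
    ecological BRTs: small learning rates so that the optimal ensemble is
    large, shallow trees, 50% bagging, 10-fold CV.
    """

    learning_rates: tuple[float, ...] = (0.001, 0.005, 0.01)
    tree_complexities: tuple[int, ...] = (1, 2, 3)
    bag_fraction: float = 0.5
    k_folds: int = 10
    max_trees: int = 5000
    pd_grid_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(lr <= 0 for lr in self.learning_rates):
            raise ConfigError("learning rates must be positive")
        if any(tc < 1 for tc in self.tree_complexities):
            raise ConfigError("tree complexities must be >= 1")
        if not 0.0 < self.bag_fraction <= 1.0:
            raise ConfigError("bag_fraction must lie in (0, 1]")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if self.max_trees < 1:
            raise ConfigError("max_trees must be >= 1")


@dataclass
class BRTResult:
    """Fitted ensemble with influence measures and partial dependence.

    ``influence_selection`` and ``influence_improvement`` map predictor
    name to relative influence in percent; each measure sums to 100.
    ``partial_dependence`` maps predictor name to ``(grid, response)``
    arrays.
    """

    predictor_names: tuple[str, ...]
    influence_selection: dict[str, float]
    influence_improvement: dict[str, float]
    learning_rate: float
    tree_complexity: int
    n_trees: int
    cv_deviance: float
    partial_dependence: dict[str, tuple[np.ndarray, np.ndarray]]
    model: GradientBoostingRegressor = field(repr=False)


def _cv_tree_curve(
    y: np.ndarray,
    X: np.ndarray,
    lr: float,
    depth: int,
    cfg: BRTConfig,
) -> np.ndarray:
    """Mean held-out squared error per tree count, summed over CV folds."""
    folds = KFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
    err = np.zeros(cfg.max_trees)
    for train, test in folds.split(X):
        model = GradientBoostingRegressor(
            loss="squared_error",
            learning_rate=lr,
            max_depth=depth,
            n_estimators=cfg.max_trees,
            subsample=cfg.bag_fraction,
            random_state=cfg.seed,
        )
        model.fit(X[train], y[train])
        for i, pred in enumerate(model.staged_predict(X[test])):
            err[i] += np.sum((pred - y[test]) ** 2)
    return err / y.size


def _ensemble_influences(
    model: GradientBoostingRegressor, n_features: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (selection counts, summed split improvements) over all trees.

    For each internal node, the squared-error improvement is the weighted
    impurity decrease ``n*imp - n_L*imp_L - n_R*imp_R``; a node counts
    toward selection frequency when that improvement is positive.
    """
    counts = np.zeros(n_features)
    gains = np.zeros(n_features)
    for stage in model.estimators_:
        tree = stage[0].tree_
        internal = tree.children_left != -1
        left, right = tree.children_left[internal], tree.children_right[internal]
        w = tree.weighted_n_node_samples
        imp = tree.impurity
        gain = (
            w[internal] * imp[internal] - w[left] * imp[left] - w[right] * imp[right]
        )
        feats = tree.feature[internal]
        improving = gain > 0
        np.add.at(counts, feats[improving], 1)
        np.add.at(gains, feats, np.clip(gain, 0.0, None))
    return counts, gains


def fit_brt(
    y: np.ndarray,
    X: np.ndarray,
    cfg: BRTConfig | None = None,
    predictor_names: tuple[str, ...] | None = None,
) -> BRTResult:
    """Cross-validated BRT fit with influence ranking.

    Grid-searches (learning rate x tree complexity); for each candidate,
    k-fold CV picks the tree count minimizing held-out squared error, and
    the candidate with the lowest CV error wins.  The final ensemble is
    refit on all data at the winning setting and its split structure
    yields both influence measures and partial dependence curves.
    """
    cfg = cfg or BRTConfig()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_predictors) aligned with y")
    if X.shape[1] < 1:
        raise ConfigError("need at least one predictor")
    if y.size < 2 * cfg.k_folds:
        raise InsufficientDataError(
            f"need n >= 2*k_folds = {2 * cfg.k_folds} samples, got {y.size}"
        )
    if np.std(y) == 0:
        raise DegenerateSeriesError("response is constant")
    if predictor_names is None:
        predictor_names = tuple(f"x{j}" for j in range(X.shape[1]))
    if len(predictor_names) != X.shape[1]:
        raise ValueError("predictor_names length mismatch")

    best = None
    for lr in cfg.learning_rates:
        for depth in cfg.tree_complexities:
            curve = _cv_tree_curve(y, X, lr, depth, cfg)
            n_opt = int(np.argmin(curve)) + 1
            cand = (float(curve[n_opt - 1]), lr, depth, n_opt)
            if best is None or cand[0] < best[0]:
                best = cand
    cv_dev, lr, depth, n_trees = best

    model = GradientBoostingRegressor(
        loss="squared_error",
        learning_rate=lr,
        max_depth=depth,
        n_estimators=n_trees,
        subsample=cfg.bag_fraction,
        random_state=cfg.seed,
    )
    model.fit(X, y)

    counts, gains = _ensemble_influences(model, X.shape[1])
    if counts.sum() == 0:
        # no improving split anywhere: fall back to uniform shares
        counts = np.ones(X.shape[1])
    if gains.sum() == 0:
        gains = np.ones(X.shape[1])
    sel = 100.0 * counts / counts.sum()
    imp = 100.0 * gains / gains.sum()

    pd_curves = {}
    for j, name in enumerate(predictor_names):
        grid = np.linspace(X[:, j].min(), X[:, j].max(), cfg.pd_grid_size)
        pd_curves[name] = (grid, partial_dependence(model, X, j, grid))

    return BRTResult(
        predictor_names=tuple(predictor_names),
        influence_selection=dict(zip(predictor_names, sel)),
        influence_improvement=dict(zip(predictor_names, imp)),
        learning_rate=lr,
        tree_complexity=depth,
        n_trees=n_trees,
        cv_deviance=cv_dev,
        partial_dependence=pd_curves,
        model=model,
    )


def partial_dependence(
    model: GradientBoostingRegressor,
    X: np.ndarray,
    predictor: int,
    grid: np.ndarray,
) -> np.ndarray:
    """Brute-force partial dependence of the fitted model on one predictor.

    ``PD(v)`` is the mean prediction over the training rows with the
    predictor column overwritten by ``v``.  The grid must lie within the
    observed range of that predictor.
    """
    X = np.asarray(X, dtype=float)
    grid = np.asarray(grid, dtype=float)
    lo, hi = X[:, predictor].min(), X[:, predictor].max()
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid [{grid.min():g}, {grid.max():g}] outside observed range "
            f"[{lo:g}, {hi:g}] of predictor {predictor}"
        )
    out = np.empty(grid.size)
    work = X.copy()
    for i, v in enumerate(grid):
        work[:, predictor] = v
        out[i] = model.predict(work).mean()
    return out
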