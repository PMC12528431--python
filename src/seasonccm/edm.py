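"""Empirical dynamic modeling kernel.

Implements Takens-style time-delay embedding, simplex-projection
forecasting (used leave-one-out to select the embedding dimension E), and
convergent cross mapping (CCM): estimating a putative driver from the
time-delay embedding of its putative effect, with prediction skill tracked
across library sizes.  Rising skill with library size ("convergence") is
the CCM signature of dynamic coupling.

Conventions follow standard CCM practice: tau = 1; tp = 1 for E selection,
contemporaneous (tp = 0) estimation for cross mapping; E + 1 exponentially
weighted nearest neighbors; leave-one-out excludes only the target's own
embedding row (no Theiler window — series here are short annual records).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError, DegenerateSeriesError, InsufficientDataError

__all__ = [
    "EmbeddingSpec",
    "SimplexScan",
    "CCMResult",
    "delay_embed",
    "simplex_forecast",
    "select_E",
    "cross_map",
    "CrossMapOperator",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding geometry: dimension E, lag tau, prediction horizon tp."""

    E: int
    tau: int = 1
    tp: int = 0

    def __post_init__(self) -> None:
        if self.E < 1:
            raise ConfigError("embedding dimension E must be >= 1")
        if self.tau < 1:
            raise ConfigError("lag tau must be >= 1")
        if self.tp < 0:
            raise ConfigError("prediction horizon tp must be >= 0")

    def min_length(self) -> int:
        return (self.E - 1) * self.tau + 1


@dataclass
class SimplexScan:
    """Leave-one-out simplex forecast skill across candidate dimensions."""

    E_values: np.ndarray
    skills: np.ndarray
    selected_E: int

    def __post_init__(self) -> None:
        self.E_values = np.asarray(self.E_values, dtype=int)
        self.skills = np.asarray(self.skills, dtype=float)


@dataclass
class CCMResult:
    """Cross-map skill versus library size for one directed hypothesis.

    The hypothesis driver -> effect is tested by estimating the driver from
    the effect's embedding.  ``skills`` holds one row per library size L
    and one column per random library subsample; ``mean_skills`` its row
    means.  ``skill_at_max_L`` is the single deterministic full-library
    skill — the convergent cross-map skill — and ``convergence_delta`` the
    rise of the mean curve from the smallest to the largest L.
    """

    driver: str
    effect: str
    embedding: EmbeddingSpec
    library_sizes: np.ndarray
    skills: np.ndarray
    mean_skills: np.ndarray
    n_subsamples: int
    skill_at_max_L: float
    convergence_delta: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0 or not (np.isfinite(sa) and np.isfinite(sb)):
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def delay_embed(
    series: np.ndarray, spec: EmbeddingSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Build the delay-coordinate matrix of a scalar series.

    Row for time index t (0-based) is ``(x[t], x[t-tau], ...,
    x[t-(E-1)tau])``; valid t run from ``(E-1)*tau`` to ``n-1``, giving
    ``n - (E-1)*tau`` rows.  Returns ``(matrix, times)`` where ``times[i]``
    is the "present" index of row i.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    offset = (x.size - 1) - (spec.E - 1) * spec.tau
    if offset < 0:
        raise InsufficientDataError(
            f"series of length {x.size} too short for E={spec.E}, tau={spec.tau}"
        )
    times = np.arange((spec.E - 1) * spec.tau, x.size)
    cols = [x[times - j * spec.tau] for j in range(spec.E)]
    return np.column_stack(cols), times


def _neighbor_weights(dd: np.ndarray) -> np.ndarray:
    """Simplex weights from sorted neighbor distances (rows ascending).

    ``w = exp(-d/d1)`` with d1 the nearest distance; in the exact-match
    limit d1 = 0, weight collapses onto the zero-distance neighbors.
    """
    d1 = dd[:, :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(d1 > 0, np.exp(-dd / np.where(d1 > 0, d1, 1.0)), (dd == 0) * 1.0)
    return w / w.sum(axis=1, keepdims=True)


def _knn_predict(
    D: np.ndarray, values: np.ndarray, k: int
) -> np.ndarray:
    """Weighted k-NN prediction per row of a (targets x library) distance matrix.

    Entries set to +inf are excluded (self-matches).  ``values`` are the
    library's target values.
    """
    if D.shape[1] < k or np.any(np.isinf(D).sum(axis=1) >= D.shape[1] - k + 1):
        raise InsufficientDataError(
            f"need {k} neighbors but library has too few usable rows"
        )
    part = np.argpartition(D, k - 1, axis=1)[:, :k]
    dd = np.take_along_axis(D, part, axis=1)
    order = np.argsort(dd, axis=1, kind="stable")
    idx = np.take_along_axis(part, order, axis=1)
    dd = np.take_along_axis(dd, order, axis=1)
    w = _neighbor_weights(dd)
    return (w * values[idx]).sum(axis=1)


def simplex_forecast(
    series: np.ndarray,
    spec: EmbeddingSpec,
    return_predictions: bool = False,
):
    """Leave-one-out simplex projection skill for one series.

    Each embedded point predicts ``x[t + tp]`` from its E + 1 nearest
    embedded neighbors (excluding itself), weighted ``exp(-d/d1)``; skill
    is the Pearson correlation between predictions and observations.
    """
    if spec.tp < 1:
        raise ConfigError("simplex forecasting needs tp >= 1")
    x = np.asarray(series, dtype=float)
    M, times = delay_embed(x, spec)
    valid = times + spec.tp <= x.size - 1
    V = M[valid]
    obs = x[times[valid] + spec.tp]
    k = spec.E + 1
    if V.shape[0] < k + 1:
        raise InsufficientDataError(
            f"only {V.shape[0]} embedded points; need > E+1 = {k} for "
            "leave-one-out simplex"
        )
    D = cdist(V, V)
    np.fill_diagonal(D, np.inf)
    preds = _knn_predict(D, obs, k)
    rho = _pearson(preds, obs)
    if np.isnan(rho):
        raise DegenerateSeriesError("constant predictions or observations in simplex")
    if return_predictions:
        return rho, preds, obs
    return rho


def select_E(
    series: np.ndarray,
    E_range: "list[int] | np.ndarray | None" = None,
    tau: int = 1,
    tp: int = 1,
) -> SimplexScan:
    """Pick the embedding dimension maximizing simplex forecast skill.

    Default candidate range is 1..min(10, n // 3).  Ties go to the
    smallest E.
    """
    x = np.asarray(series, dtype=float)
    if E_range is None:
        E_range = list(range(1, max(2, min(10, x.size // 3)) + 1))
    E_values = np.asarray(sorted(set(int(e) for e in E_range)))
    if E_values.size == 0:
        raise ConfigError("E_range is empty")
    skills = np.array(
        [simplex_forecast(x, EmbeddingSpec(E=int(E), tau=tau, tp=tp)) for E in E_values]
    )
    selected = int(E_values[int(np.argmax(skills))])  # argmax returns first max
    return SimplexScan(E_values, skills, selected)


class CrossMapOperator:
    """Full-library cross-map estimator frozen on one effect embedding.

    Builds the effect series' delay embedding and each point's E + 1
    nearest-neighbor weights once; any driver series (e.g. seasonal
    surrogates) can then be scored with a single matrix product.  This is
    what makes large surrogate ensembles cheap: when only the driver
    changes, the effect manifold — and hence the neighbor geometry — is
    fixed.
    """

    def __init__(self, effect: np.ndarray, spec: EmbeddingSpec):
        y = np.asarray(effect, dtype=float)
        M, times = delay_embed(y, spec)
        k = spec.E + 1
        if M.shape[0] < k + 1:
            raise InsufficientDataError(
                f"only {M.shape[0]} embedded points; need > E+1 = {k}"
            )
        D = cdist(M, M)
        np.fill_diagonal(D, np.inf)
        part = np.argpartition(D, k - 1, axis=1)[:, :k]
        dd = np.take_along_axis(D, part, axis=1)
        order = np.argsort(dd, axis=1, kind="stable")
        self.neighbor_idx = np.take_along_axis(part, order, axis=1)
        self.weights = _neighbor_weights(np.take_along_axis(dd, order, axis=1))
        self.times = times
        self.spec = spec

    def estimate(self, driver: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cross-map estimates and observed driver values at embedded times."""
        x = np.asarray(driver, dtype=float)
        xv = x[self.times]
        preds = (self.weights * xv[self.neighbor_idx]).sum(axis=1)
        return preds, xv

    def skill(self, driver: np.ndarray) -> float:
        preds, xv = self.estimate(driver)
        return _pearson(preds, xv)


def default_library_sizes(E: int, n_rows: int, n_sizes: int = 8) -> np.ndarray:
    """Evenly spaced library-size grid from E + 2 up to the full library."""
    lo = E + 2
    if lo > n_rows:
        raise InsufficientDataError(
            f"embedding leaves {n_rows} rows; need at least E+2 = {lo}"
        )
    return np.unique(np.round(np.linspace(lo, n_rows, n_sizes)).astype(int))


def cross_map(
    driver: np.ndarray,
    effect: np.ndarray,
    spec: EmbeddingSpec,
    library_sizes: np.ndarray | None = None,
    n_subsamples: int = 100,
    rng: np.random.Generator | int | None = None,
    driver_label: str = "X",
    effect_label: str = "Y",
) -> CCMResult:
    """Convergent cross mapping for the hypothesis driver -> effect.

    The effect series is delay-embedded; for each library size L,
    ``n_subsamples`` random subsets of L embedding rows serve as the
    neighbor library from which every embedded point estimates the
    contemporaneous driver value (the target's own row never serves as its
    neighbor).  Skill is the Pearson correlation of estimates with the
    observed driver.  The full library is additionally evaluated once,
    deterministically, as ``skill_at_max_L``.

    Subsamples whose estimates are degenerate (constant) are recorded as
    NaN and skipped in the mean curve.
    """
    x = np.asarray(driver, dtype=float)
    y = np.asarray(effect, dtype=float)
    if x.size != y.size:
        raise ValueError("driver and effect must be aligned (same length)")
    rng = np.random.default_rng(rng)
    op = CrossMapOperator(y, spec)
    n_rows = op.times.size
    k = spec.E + 1
    xv = x[op.times]
    if xv.std() == 0:
        raise DegenerateSeriesError("driver series is constant at embedded times")
    skill_full = op.skill(x)
    if np.isnan(skill_full):
        raise DegenerateSeriesError("full-library cross-map estimates are constant")

    if library_sizes is None:
        library_sizes = default_library_sizes(spec.E, n_rows)
    library_sizes = np.asarray(sorted(set(int(L) for L in library_sizes)))
    if library_sizes[0] < k + 1:
        raise ConfigError(f"library sizes must be >= E+2 = {k + 1}")
    if library_sizes[-1] > n_rows:
        raise ConfigError(
            f"library size {library_sizes[-1]} exceeds {n_rows} embedding rows"
        )

    # Precompute the full pairwise distance matrix once; subsampling is then
    # column selection + top-k per row.
    M, _ = delay_embed(y, spec)
    D = cdist(M, M)
    np.fill_diagonal(D, np.inf)

    skills = np.full((library_sizes.size, n_subsamples), np.nan)
    for li, L in enumerate(library_sizes):
        for s in range(n_subsamples):
            lib = rng.choice(n_rows, size=L, replace=False)
            preds = _knn_predict(D[:, lib], xv[lib], k)
            skills[li, s] = _pearson(preds, xv)
    with np.errstate(invalid="ignore"):
        mean_skills = np.nanmean(skills, axis=1)
    return CCMResult(
        driver=driver_label,
        effect=effect_label,
        embedding=spec,
        library_sizes=library_sizes,
        skills=skills,
        mean_skills=mean_skills,
        n_subsamples=n_subsamples,
        skill_at_max_L=skill_full,
        convergence_delta=float(mean_skills[-1] - mean_skills[0]),
    )
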