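"""Seasonal-surrogate significance testing of cross-map skill.

The null model preserves a series' mean cyclical trend — the average
signal over a fixed period (default 12 steps) — while randomly permuting
the residuals around that cycle.  Cross-map skill on an ensemble of such
surrogates forms the null distribution against which the observed
full-library skill is ranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edm import CrossMapOperator, EmbeddingSpec
from .errors import ConfigError, DegenerateSeriesError, InsufficientDataError

__all__ = [
    "SurrogateConfig",
    "SurrogateNull",
    "seasonal_surrogate",
    "ccm_significance",
    "asterisks_for",
]


@dataclass
class SurrogateConfig:
    """Settings for the surrogate null ensemble.

    ``period`` is the cycle length in series steps; on annual series the
    default 12 means a 12-year cycle.  ``target`` selects which series is
    replaced by surrogates: the ``driver`` (default — the series being
    cross-mapped) or the ``effect`` (whose embedding would then be rebuilt
    per surrogate).  ``within_phase=True`` (default) permutes residuals
    within each phase class, conserving phase means, overall mean and
    variance exactly; ``False`` permutes globally — a harsher scramble that
    conserves only the residual multiset and overall mean.
    """

    n_surrogates: int = 500
    period: int = 12
    target: str = "driver"
    within_phase: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ConfigError("n_surrogates must be >= 1")
        if self.period < 2:
            raise ConfigError("period must be >= 2")
        if self.target not in ("driver", "effect"):
            raise ConfigError("target must be 'driver' or 'effect'")


@dataclass
class SurrogateNull:
    """Observed cross-map skill ranked against its surrogate null."""

    observed: float
    null_skills: np.ndarray
    p_value: float
    significant_95: bool
    significant_90: bool
    asterisks: str


def asterisks_for(p: float) -> str:
    """Significance marks: '**' for p <= 0.05, '*' for p <= 0.10, else ''."""
    if p <= 0.05:
        return "**"
    if p <= 0.10:
        return "*"
    return ""


def seasonal_cycle(series: np.ndarray, period: int) -> np.ndarray:
    """Phase means of a series: cycle[i] = mean of values at phase i % period."""
    x = np.asarray(series, dtype=float)
    if x.size < period:
        raise InsufficientDataError(
            f"series of length {x.size} shorter than period {period}"
        )
    phases = np.arange(x.size) % period
    means = np.array([x[phases == ph].mean() for ph in range(period)])
    return means[phases]


def seasonal_surrogate(
    series: np.ndarray,
    period: int,
    rng: np.random.Generator | int | None = None,
    within_phase: bool = True,
) -> np.ndarray:
    """One surrogate preserving the mean cycle, with permuted residuals.

    ``surrogate[i] = cycle[i % period] + residual[perm(i)]`` for a uniform
    random permutation drawn within each phase class (default), which
    conserves phase means, overall mean and variance exactly — or over all
    indices (``within_phase=False``), which conserves the residual multiset
    and overall mean only.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(series, dtype=float)
    cycle = seasonal_cycle(x, period)
    resid = x - cycle
    if within_phase:
        perm = np.arange(x.size)
        phases = np.arange(x.size) % period
        for ph in range(period):
            members = np.flatnonzero(phases == ph)
            perm[members] = members[rng.permutation(members.size)]
        return cycle + resid[perm]
    return cycle + resid[rng.permutation(x.size)]


def ccm_significance(
    driver: np.ndarray,
    effect: np.ndarray,
    spec: EmbeddingSpec,
    cfg: SurrogateConfig | None = None,
) -> SurrogateNull:
    """Test a cross-map skill against the seasonal-surrogate null.

    The observed statistic is the deterministic full-library cross-map
    skill of estimating ``driver`` from ``effect``'s embedding.  Each
    surrogate replaces the target series (per ``cfg.target``) with a fresh
    seasonal surrogate and the skill is recomputed at full library.  The
    p-value uses the add-one estimator ``(1 + #{null >= observed}) /
    (1 + n_surrogates)``, so it is always positive and conservative.

    A surrogate yielding a degenerate (constant-estimate) skill is redrawn
    once; a second failure raises.
    """
    cfg = cfg or SurrogateConfig()
    x = np.asarray(driver, dtype=float)
    y = np.asarray(effect, dtype=float)
    if x.size != y.size:
        raise ValueError("driver and effect must be aligned")
    if x.size < cfg.period:
        raise InsufficientDataError(
            f"series length {x.size} shorter than surrogate period {cfg.period}"
        )
    op = CrossMapOperator(y, spec)
    observed = op.skill(x)
    if np.isnan(observed):
        raise DegenerateSeriesError("observed cross-map skill is degenerate")

    # independently reproducible substream per surrogate
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_surrogates)
    null = np.empty(cfg.n_surrogates)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        for attempt in range(2):
            if cfg.target == "driver":
                x_s = seasonal_surrogate(x, cfg.period, rng, cfg.within_phase)
                skill = op.skill(x_s)
            else:
                y_s = seasonal_surrogate(y, cfg.period, rng, cfg.within_phase)
                skill = CrossMapOperator(y_s, spec).skill(x)
            if not np.isnan(skill):
                break
        else:
            raise DegenerateSeriesError(
                f"surrogate {i} degenerate twice (constant estimates)"
            )
        null[i] = skill

    p = (1.0 + np.sum(null >= observed)) / (1.0 + cfg.n_surrogates)
    return SurrogateNull(
        observed=float(observed),
        null_skills=null,
        p_value=float(p),
        significant_95=p <= 0.05,
        significant_90=p <= 0.10,
        asterisks=asterisks_for(p),
    )


def null_skill_quantiles(
    driver: np.ndarray,
    effect: np.ndarray,
    spec: EmbeddingSpec,
    library_sizes: np.ndarray,
    cfg: SurrogateConfig | None = None,
    q: tuple[float, ...] = (0.95,),
    n_subsamples: int = 10,
) -> dict[float, np.ndarray]:
    """Per-library-size null quantiles, for skill-vs-library plots.

    For each surrogate, the mean cross-map skill curve over the given
    library sizes is computed (with a light subsample count); returned are
    the requested quantiles of the null curves at each L.  This mirrors the
    shaded null envelope of skill-vs-library-size figures; the significance
    *decision* is taken at full library by :func:`ccm_significance`.
    """
    from .edm import cross_map  # local import to avoid cycle at module load

    cfg = cfg or SurrogateConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_surrogates)
    curves = np.empty((cfg.n_surrogates, len(library_sizes)))
    x = np.asarray(driver, dtype=float)
    y = np.asarray(effect, dtype=float)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if cfg.target == "driver":
            x_i, y_i = seasonal_surrogate(x, cfg.period, rng, cfg.within_phase), y
        else:
            x_i, y_i = x, seasonal_surrogate(y, cfg.period, rng, cfg.within_phase)
        res = cross_map(
            x_i, y_i, spec, library_sizes=library_sizes,
            n_subsamples=n_subsamples, rng=rng,
        )
        curves[i] = res.mean_skills
    return {qq: np.nanquantile(curves, qq, axis=0) for qq in q}
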