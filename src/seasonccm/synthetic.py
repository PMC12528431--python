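"""Synthetic communities with known directional coupling.

Two generators are provided:

* a coupled logistic map — the standard two-species benchmark for validating
  cross-mapping code, where the coupling direction and strength are planted
  in the update rule and exactly recoverable by regression on its monomials;
* a seasonally forced Ricker predator–prey model run at monthly resolution,
  emulating the dynamical structure that seasonal plankton-survey analyses
  assume: a spring prey bloom fuels a summer predator peak which in turn
  suppresses the prey's fall (overwintering) abundance.

A survey observation model turns latent monthly abundances into sparse
station-style records (sampled months, lognormal tow noise, whole missing
years), written as ``year,month,region,taxon,abundance_m3`` tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DivergenceError, EmptyOutputError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_coupled_logistic",
    "simulate_seasonal_pp",
    "simulate_community",
    "observe_survey",
    "DEFAULT_PP_PARAMS",
    "DEFAULT_LOGISTIC_PARAMS",
]

#: Ricker predator–prey defaults: prey growth r, seasonal amplitude alpha,
#: carrying capacity K, attack rate a, conversion efficiency b, predator
#: mortality m, multiplicative process noise (log-scale SD).
DEFAULT_PP_PARAMS: dict[str, float] = {
    "r": 1.2,
    "alpha": 0.9,
    "K": 1.0,
    "a": 2.0,
    "b": 1.0,
    "m": 0.6,
    "process_noise_sd": 0.1,
}

#: Coupled logistic map defaults (unidirectional X -> Y forcing).
DEFAULT_LOGISTIC_PARAMS: dict[str, float] = {
    "r_x": 3.8,
    "r_y": 3.5,
    "beta_xy": 0.0,
    "beta_yx": 0.32,
}

LOGISTIC_BURN_IN = 100  # map iterations discarded as transient
PP_BURN_IN_YEARS = 10   # years discarded as transient


@dataclass
class SimulationConfig:
    """Configuration for one synthetic simulation + observation run.

    ``n_years`` counts retained years for the seasonal model and retained
    iterations for the logistic-map benchmark.  ``params`` overrides the
    model's default rates.  Observation-model fields control the survey
    emulation only; set ``obs_noise_sd=0`` and ``missing_year_prob=0`` for a
    perfect census.
    """

    model: str = "seasonal_pp"
    n_years: int = 40
    params: dict[str, float] = field(default_factory=dict)
    obs_noise_sd: float = 0.0
    missing_year_prob: float = 0.0
    samples_per_month: int = 1
    sampled_months: tuple[int, ...] = (1, 3, 5, 7, 9, 11)
    region: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("seasonal_pp", "coupled_logistic"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")
        if not 0.0 <= self.missing_year_prob <= 1.0:
            raise ConfigError("missing_year_prob must lie in [0, 1]")
        if self.obs_noise_sd < 0:
            raise ConfigError("obs_noise_sd must be >= 0")
        if self.samples_per_month < 1:
            raise ConfigError("samples_per_month must be >= 1")
        if not all(1 <= m <= 12 for m in self.sampled_months):
            raise ConfigError("sampled_months must be within 1..12")
        for name, value in self.params.items():
            if not np.isfinite(value):
                raise ConfigError(f"parameter {name!r} is not finite")


@dataclass(frozen=True)
class GroundTruth:
    """Directed coupling labels for ordered taxon pairs.

    ``coupling`` maps (driver, effect) to a sign: ``"+"`` for bottom-up
    forcing (prey fuels predator) and ``"-"`` for top-down suppression.
    Pairs absent from the map are uncoupled.
    """

    coupling: dict[tuple[str, str], str]

    def is_coupled(self, driver: str, effect: str) -> bool:
        return (driver, effect) in self.coupling

    def sign(self, driver: str, effect: str) -> str | None:
        return self.coupling.get((driver, effect))


def _taxon_rng(seed: int, taxon: str) -> np.random.Generator:
    """Independent, reproducible substream per taxon name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(taxon.encode())])
    )


def simulate_coupled_logistic(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the two-species coupled logistic map benchmark.

    Update rule (``beta_xy`` = effect of Y on X, ``beta_yx`` = effect of X
    on Y)::

        X[t+1] = X[t] * (r_x - r_x*X[t] - beta_xy*Y[t])
        Y[t+1] = Y[t] * (r_y - r_y*Y[t] - beta_yx*X[t])

    The first ``LOGISTIC_BURN_IN`` iterations are discarded; ``n_years``
    iterations are retained.  Initial values may be supplied via params
    ``x0``/``y0``, otherwise drawn independently from U(0.2, 0.8).

    Raises
    ------
    DivergenceError
        If either state leaves the open interval (0, 1) at any step.
    """
    if config.model != "coupled_logistic":
        raise ConfigError("config.model must be 'coupled_logistic'")
    p = {**DEFAULT_LOGISTIC_PARAMS, **config.params}
    rng = np.random.default_rng(config.seed)
    x = float(p.get("x0", rng.uniform(0.2, 0.8)))
    y = float(p.get("y0", rng.uniform(0.2, 0.8)))
    n = int(p.get("n_steps", config.n_years))
    total = n + LOGISTIC_BURN_IN
    X = np.empty(total)
    Y = np.empty(total)
    for t in range(total):
        if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
            raise DivergenceError(
                f"coupled logistic map left (0,1) at step {t}: "
                f"x={x:.6g}, y={y:.6g}, params={p}"
            )
        X[t], Y[t] = x, y
        x_next = x * (p["r_x"] - p["r_x"] * x - p["beta_xy"] * y)
        y_next = y * (p["r_y"] - p["r_y"] * y - p["beta_yx"] * x)
        x, y = x_next, y_next
    return X[LOGISTIC_BURN_IN:], Y[LOGISTIC_BURN_IN:]


def _step_seasonal_pp(
    n: float,
    p_state: float,
    t: int,
    p: dict[str, float],
    rng: np.random.Generator | None,
) -> tuple[float, float]:
    forcing = 1.0 + p["alpha"] * np.sin(2.0 * np.pi * t / 12.0)
    n_next = n * np.exp(p["r"] * forcing * (1.0 - n / p["K"]) - p["a"] * p_state)
    p_next = p_state * np.exp(p["b"] * p["a"] * n - p["m"])
    sd = p.get("process_noise_sd", 0.0)
    if sd > 0 and rng is not None:
        n_next *= np.exp(rng.normal(0.0, sd))
        p_next *= np.exp(rng.normal(0.0, sd))
    return n_next, p_next


def simulate_seasonal_pp(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate monthly prey (N) and predator (P) latent abundances.

    A discrete Ricker-type predator–prey model with sinusoidal seasonal
    forcing of the prey's growth rate::

        N[t+1] = N[t] * exp( r*(1 + alpha*sin(2*pi*t/12))*(1 - N[t]/K) - a*P[t] )
        P[t+1] = P[t] * exp( b*a*N[t] - m )

    Month-of-year for index t is ``t % 12 + 1``, so the forcing peaks in
    early spring and the prey climatology peaks in months 3–6 while the
    predator, which integrates prey abundance, peaks in months 6–9.
    Optional multiplicative lognormal process noise (``process_noise_sd``)
    represents environmental stochasticity.  The first ``PP_BURN_IN_YEARS``
    years are discarded.

    Returns the retained monthly series (length ``12 * n_years``), both
    strictly positive.
    """
    if config.model != "seasonal_pp":
        raise ConfigError("config.model must be 'seasonal_pp'")
    p = {**DEFAULT_PP_PARAMS, **config.params}
    if not 0.0 <= p["alpha"] <= 1.0:
        raise ConfigError(f"seasonal amplitude alpha={p['alpha']} outside [0, 1]")
    rng = np.random.default_rng(config.seed)
    total = 12 * (config.n_years + PP_BURN_IN_YEARS)
    N = np.empty(total)
    P = np.empty(total)
    n_state = float(p.get("N0", 0.5))
    p_state = float(p.get("P0", 0.2))
    for t in range(total):
        if not (np.isfinite(n_state) and np.isfinite(p_state)):
            raise DivergenceError(
                f"seasonal predator–prey state non-finite at month {t}: "
                f"N={n_state}, P={p_state}"
            )
        N[t], P[t] = n_state, p_state
        n_state, p_state = _step_seasonal_pp(n_state, p_state, t, p, rng)
    start = 12 * PP_BURN_IN_YEARS
    return N[start:], P[start:]


def _simulate_uncoupled_taxon(
    config: SimulationConfig, taxon: str
) -> np.ndarray:
    """Independent seasonally forced Ricker population (no trophic links).

    Growth rate and forcing phase are drawn once from the taxon's substream,
    so different uncoupled taxa have distinct but reproducible seasonal
    profiles, typically peaking in summer like the survey's predator taxa.
    """
    p = {**DEFAULT_PP_PARAMS, **config.params}
    rng = _taxon_rng(config.seed, taxon)
    r = rng.uniform(0.5, 1.0)
    phase = rng.uniform(2.0, 5.0)  # months of delay relative to prey forcing
    sd = p.get("process_noise_sd", 0.0)
    total = 12 * (config.n_years + PP_BURN_IN_YEARS)
    out = np.empty(total)
    state = float(rng.uniform(0.3, 0.7))
    for t in range(total):
        if not np.isfinite(state):
            raise DivergenceError(f"uncoupled taxon {taxon!r} non-finite at month {t}")
        out[t] = state
        forcing = 1.0 + p["alpha"] * np.sin(2.0 * np.pi * (t - phase) / 12.0)
        state = state * np.exp(r * forcing * (1.0 - state / p["K"]))
        if sd > 0:
            state *= np.exp(rng.normal(0.0, sd))
    return out[12 * PP_BURN_IN_YEARS:]


def simulate_community(
    config: SimulationConfig,
    prey: str = "calfin",
    predators: tuple[str, ...] = (
        "chaetognaths",
        "euphausiids",
        "siphonophores",
        "paraeuchaeta",
        "herring",
    ),
    coupled_predator: str | None = "euphausiids",
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Build a multi-taxon latent community with one (or no) coupled predator.

    The prey and the coupled predator come from the seasonally forced
    predator–prey model; every other predator is an independent seasonal
    Ricker population with its own substream.  With
    ``coupled_predator=None`` the prey too is simulated without predation
    (attack rate forced to 0), giving a fully uncoupled community for
    false-positive testing.

    Returns the latent monthly series per taxon and the ground-truth
    coupling labels (prey -> predator ``"+"``, predator -> prey ``"-"``).
    """
    if coupled_predator is not None and coupled_predator not in predators:
        raise ConfigError(
            f"coupled_predator {coupled_predator!r} not among predators"
        )
    latent: dict[str, np.ndarray] = {}
    coupling: dict[tuple[str, str], str] = {}
    if coupled_predator is None:
        solo = SimulationConfig(
            model="seasonal_pp",
            n_years=config.n_years,
            params={**config.params, "a": 0.0},
            seed=int(_taxon_rng(config.seed, prey).integers(2**31)),
        )
        latent[prey], _ = simulate_seasonal_pp(solo)
    else:
        pair = SimulationConfig(
            model="seasonal_pp",
            n_years=config.n_years,
            params=dict(config.params),
            seed=int(_taxon_rng(config.seed, prey).integers(2**31)),
        )
        n_series, p_series = simulate_seasonal_pp(pair)
        latent[prey] = n_series
        latent[coupled_predator] = p_series
        coupling[(prey, coupled_predator)] = "+"
        coupling[(coupled_predator, prey)] = "-"
    for name in predators:
        if name not in latent:
            latent[name] = _simulate_uncoupled_taxon(config, name)
    return latent, GroundTruth(coupling)


def observe_survey(
    latent_series: dict[str, np.ndarray],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Sample latent monthly abundances into survey-style records.

    For each taxon, whole years are dropped independently with probability
    ``missing_year_prob`` (using the taxon's substream); in retained years,
    each month in ``sampled_months`` yields ``samples_per_month`` records
    with multiplicative lognormal observation noise:
    ``abundance = latent * exp(eps)``, ``eps ~ N(0, obs_noise_sd**2)``.

    Returns a DataFrame with columns ``year, month, region, taxon,
    abundance_m3`` (years numbered from 1).
    """
    rows: list[tuple[int, int, str, str, float]] = []
    for taxon, series in latent_series.items():
        series = np.asarray(series, dtype=float)
        if series.ndim != 1 or series.size % 12 != 0:
            raise ValueError(f"latent series for {taxon!r} must be monthly (12/yr)")
        if np.any(series < 0):
            raise ValueError(f"latent series for {taxon!r} has negative values")
        n_years = series.size // 12
        # salted so the observation stream is independent of the taxon's
        # dynamics stream, which uses the unsalted label
        rng = _taxon_rng(config.seed, taxon + "/obs")
        keep = rng.random(n_years) >= config.missing_year_prob
        for year in range(n_years):
            if not keep[year]:
                continue
            for month in config.sampled_months:
                value = series[12 * year + (month - 1)]
                for _ in range(config.samples_per_month):
                    eps = (
                        rng.normal(0.0, config.obs_noise_sd)
                        if config.obs_noise_sd > 0
                        else 0.0
                    )
                    rows.append(
                        (year + 1, month, config.region, taxon, value * np.exp(eps))
                    )
    if not rows:
        raise EmptyOutputError(
            "survey observation produced no records (all years dropped?)"
        )
    return pd.DataFrame(
        rows, columns=["year", "month", "region", "taxon", "abundance_m3"]
    )
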