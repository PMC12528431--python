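"""Seasonal series construction from station-level survey records.

The pipeline is fixed: ln(x+1) transform -> within-season annual mean ->
LOESS gap filling of missing years -> z-normalization.  Normalization is
always last.  Series are truncated to the observed year range; gaps are
interpolated, ends are never extrapolated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DegenerateSeriesError,
    ExtrapolationError,
    InsufficientDataError,
    NoRecordsError,
)

__all__ = [
    "SeasonDefinition",
    "SPRING",
    "SPRING_SUMMER",
    "FALL",
    "SEASONS",
    "SeasonalSeries",
    "PrepConfig",
    "seasonal_mean",
    "loess_fill",
    "normalize",
    "prepare_series",
]


@dataclass(frozen=True)
class SeasonDefinition:
    """A named window of calendar months used for annual averaging."""

    name: str
    months: frozenset[int]

    def __post_init__(self) -> None:
        if not self.months or not all(1 <= m <= 12 for m in self.months):
            raise ConfigError("season months must be within 1..12")


SPRING = SeasonDefinition("spring", frozenset({4, 5, 6}))
SPRING_SUMMER = SeasonDefinition("spring_summer", frozenset({4, 5, 6, 7, 8, 9}))
FALL = SeasonDefinition("fall", frozenset({10, 11, 12}))

SEASONS: dict[str, SeasonDefinition] = {
    s.name: s for s in (SPRING, SPRING_SUMMER, FALL)
}


def get_season(name: str | SeasonDefinition) -> SeasonDefinition:
    """Look up a season by name (case-insensitive); passes through definitions."""
    if isinstance(name, SeasonDefinition):
        return name
    key = name.strip().lower()
    if key not in SEASONS:
        raise ConfigError(f"unknown season {name!r}; expected one of {sorted(SEASONS)}")
    return SEASONS[key]


@dataclass
class SeasonalSeries:
    """Year-indexed seasonal mean series for one taxon/region/season.

    ``values`` are on the ln(abundance m^-3 + 1) scale until ``normalized``
    is set, after which they are unitless with mean 0 and SD 1.  Years are
    contiguous; missing years are NaN until filled, and ``interpolated``
    marks filled entries.
    """

    taxon: str
    region: str
    season: SeasonDefinition
    years: np.ndarray
    values: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.years.size, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if not (self.years.size == self.values.size == self.interpolated.size):
            raise ValueError("years/values/interpolated lengths differ")
        if self.years.size and np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous (step 1)")

    @property
    def interp_fraction(self) -> float:
        return float(self.interpolated.mean()) if self.years.size else 0.0

    @property
    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "value": self.values,
                "interpolated": self.interpolated,
            }
        )


@dataclass
class PrepConfig:
    """Controls for transform and gap filling.

    ``loess_span`` is the fraction of observed points entering each local
    fit; ``loess_degree`` the local polynomial degree.  ``transform_stage``
    selects whether ln(x+1) is applied per record before averaging
    (``"record"``, the plankton-survey convention) or to the seasonal mean
    (``"mean"``).  ``interp_warn_fraction``: warn when more than this
    fraction of years had to be interpolated.
    """

    loess_span: float = 0.5
    loess_degree: int = 2
    transform: str = "log1p"
    transform_stage: str = "record"
    interp_warn_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.loess_span <= 1.0:
            raise ConfigError("loess_span must lie in (0, 1]")
        if self.loess_degree not in (1, 2):
            raise ConfigError("loess_degree must be 1 or 2")
        if self.transform not in ("log1p", "none"):
            raise ConfigError("transform must be 'log1p' or 'none'")
        if self.transform_stage not in ("record", "mean"):
            raise ConfigError("transform_stage must be 'record' or 'mean'")


def seasonal_mean(
    records: pd.DataFrame,
    taxon: str,
    region: str,
    season: str | SeasonDefinition,
    cfg: PrepConfig | None = None,
) -> SeasonalSeries:
    """Annual within-season mean of transformed abundances.

    Selects records matching taxon/region whose month lies in the season
    window, applies ln(x+1) per record (default) and averages per year.
    Years inside the observed range with no in-season records are NaN.

    Raises :class:`NoRecordsError` if no record matches at all.
    """
    cfg = cfg or PrepConfig()
    season = get_season(season)
    sel = records[
        (records["taxon"] == taxon)
        & (records["region"] == region)
        & (records["month"].isin(season.months))
    ]
    if sel.empty:
        raise NoRecordsError(
            f"no records for taxon={taxon!r}, region={region!r}, "
            f"season={season.name!r}"
        )
    if (sel["abundance_m3"] < 0).any():
        raise ValueError("abundances must be non-negative")
    if cfg.transform == "log1p" and cfg.transform_stage == "record":
        grouped = np.log1p(sel["abundance_m3"]).groupby(sel["year"]).mean()
    else:
        grouped = sel.groupby("year")["abundance_m3"].mean()
        if cfg.transform == "log1p":
            grouped = np.log1p(grouped)
    years = np.arange(grouped.index.min(), grouped.index.max() + 1)
    values = np.full(years.size, np.nan)
    values[np.searchsorted(years, grouped.index.to_numpy())] = grouped.to_numpy()
    return SeasonalSeries(taxon, region, season, years, values)


def _loess_at(
    x_obs: np.ndarray,
    y_obs: np.ndarray,
    x0: float,
    span: float,
    degree: int,
) -> float:
    """Tricube-weighted local polynomial fit evaluated at ``x0``.

    The local window holds the ``ceil(span * n)`` observed points nearest
    to ``x0`` (at least ``degree + 1``); weights are
    ``(1 - (d/d_max)^3)^3`` with ``d_max`` the window radius.
    """
    n = x_obs.size
    k = max(int(math.ceil(span * n)), degree + 1)
    k = min(k, n)
    d = np.abs(x_obs - x0)
    order = np.argsort(d, kind="stable")[:k]
    xs, ys, ds = x_obs[order], y_obs[order], d[order]
    d_max = ds.max()
    if d_max == 0:
        return float(ys.mean())
    w = np.clip(1.0 - (ds / d_max) ** 3, 0.0, None) ** 3
    if np.count_nonzero(w) <= degree:
        if k >= n:
            # every point sits at the window edge: drop the taper entirely
            w = np.ones_like(w)
        else:
            # boundary ties can zero out the window edge; widen by one point
            return _loess_at(x_obs, y_obs, x0, (k + 1) / n, degree)
    # weighted least squares on centered powers for conditioning
    X = np.vander(xs - x0, degree + 1, increasing=True)
    W = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * W[:, None], ys * W, rcond=None)
    return float(beta[0])


def loess_fill(series: SeasonalSeries, cfg: PrepConfig | None = None) -> SeasonalSeries:
    """Fill missing interior years with a LOESS local-polynomial estimate.

    Only years with no observations are filled (observed values are never
    touched); the fit at each missing year uses observed points only.  The
    first and last year of the series must be observed — gaps are filled,
    ends are not extrapolated.
    """
    cfg = cfg or PrepConfig()
    observed = np.isfinite(series.values)
    n_obs = int(observed.sum())
    if n_obs == series.years.size:
        return replace(series)
    if n_obs < max(cfg.loess_degree + 2, 4):
        raise InsufficientDataError(
            f"LOESS fill needs >= {max(cfg.loess_degree + 2, 4)} observed years, "
            f"got {n_obs}"
        )
    if not observed[0] or not observed[-1]:
        raise ExtrapolationError(
            "missing years at the series ends cannot be filled; truncate the "
            "series to its observed range first"
        )
    x_obs = series.years[observed].astype(float)
    y_obs = series.values[observed]
    values = series.values.copy()
    filled = series.interpolated.copy()
    for i in np.flatnonzero(~observed):
        values[i] = _loess_at(x_obs, y_obs, float(series.years[i]), cfg.loess_span, cfg.loess_degree)
        filled[i] = True
    out = replace(series, values=values, interpolated=filled)
    if out.interp_fraction > cfg.interp_warn_fraction:
        warnings.warn(
            f"{out.taxon}/{out.region}/{out.season.name}: "
            f"{100 * out.interp_fraction:.0f}% of years interpolated",
            stacklevel=2,
        )
    return out


def normalize(series: SeasonalSeries) -> SeasonalSeries:
    """Scale a complete series to zero mean and unit variance (n-1 SD)."""
    if not series.is_complete:
        raise InsufficientDataError("series has unfilled years; run loess_fill first")
    if series.years.size < 2:
        raise InsufficientDataError("need >= 2 years to normalize")
    sd = series.values.std(ddof=1)
    if sd == 0:
        raise DegenerateSeriesError(
            f"{series.taxon}/{series.region}/{series.season.name}: constant series"
        )
    values = (series.values - series.values.mean()) / sd
    return replace(series, values=values, normalized=True)


def prepare_series(
    records: pd.DataFrame,
    taxon: str,
    region: str,
    season: str | SeasonDefinition,
    cfg: PrepConfig | None = None,
) -> SeasonalSeries:
    """Full prep pipeline: seasonal mean -> LOESS fill -> normalize."""
    cfg = cfg or PrepConfig()
    series = seasonal_mean(records, taxon, region, season, cfg)
    series = loess_fill(series, cfg)
    return normalize(series)
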