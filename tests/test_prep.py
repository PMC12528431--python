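"""Seasonal series construction: windows, transform, LOESS fill, normalize."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from seasonccm.errors import (
    DegenerateSeriesError,
    ExtrapolationError,
    InsufficientDataError,
    NoRecordsError,
)
from seasonccm.prep import (
    FALL,
    SPRING,
    SPRING_SUMMER,
    PrepConfig,
    SeasonalSeries,
    get_season,
    loess_fill,
    normalize,
    seasonal_mean,
)

from conftest import brute_loess_at


def records_from(rows):
    return pd.DataFrame(
        rows, columns=["year", "month", "region", "taxon", "abundance_m3"]
    )


class TestSeasonWindows:
    def test_canonical_month_sets(self):
        assert SPRING.months == frozenset({4, 5, 6})
        assert SPRING_SUMMER.months == frozenset({4, 5, 6, 7, 8, 9})
        assert FALL.months == frozenset({10, 11, 12})

    def test_case_insensitive_lookup(self):
        assert get_season("Spring") is SPRING
        assert get_season(" FALL ") is FALL

    def test_out_of_season_records_never_contribute(self):
        """A huge July value must not leak into the spring mean."""
        base = [(y, m, "WB", "t", 1.0) for y in (1, 2, 3) for m in (4, 5, 6)]
        spiked = base + [(2, 7, "WB", "t", 1e9)]
        a = seasonal_mean(records_from(base), "t", "WB", SPRING)
        b = seasonal_mean(records_from(spiked), "t", "WB", SPRING)
        assert np.array_equal(a.values, b.values)


class TestSeasonalMean:
    def test_zero_abundance_maps_to_zero(self):
        rec = records_from([(1, 5, "WB", "t", 0.0), (2, 5, "WB", "t", 0.0)])
        s = seasonal_mean(rec, "t", "WB", SPRING)
        assert np.allclose(s.values, 0.0)

    def test_log_transform_before_averaging(self):
        v = np.e - 1.0
        rec = records_from([(1, 4, "WB", "t", v), (1, 6, "WB", "t", v),
                            (2, 5, "WB", "t", v)])
        s = seasonal_mean(rec, "t", "WB", SPRING)
        assert np.allclose(s.values, 1.0)

    def test_mean_then_log_mode_differs_for_skewed_records(self):
        rec = records_from([(1, 4, "WB", "t", 0.0), (1, 6, "WB", "t", np.e**2 - 1)])
        per_record = seasonal_mean(rec, "t", "WB", SPRING)
        after_mean = seasonal_mean(
            rec, "t", "WB", SPRING, PrepConfig(transform_stage="mean")
        )
        assert per_record.values[0] == pytest.approx(1.0)
        assert after_mean.values[0] == pytest.approx(np.log1p((np.e**2 - 1) / 2))

    def test_spring_only_records_raise_for_fall(self):
        rec = records_from([(y, m, "WB", "t", 1.0) for y in (1, 2) for m in (4, 5, 6)])
        assert seasonal_mean(rec, "t", "WB", SPRING).years.size == 2
        with pytest.raises(NoRecordsError, match="fall"):
            seasonal_mean(rec, "t", "WB", FALL)

    def test_interior_missing_year_is_nan(self):
        rec = records_from([(1, 5, "WB", "t", 1.0), (3, 5, "WB", "t", 1.0)])
        s = seasonal_mean(rec, "t", "WB", SPRING)
        assert np.array_equal(s.years, [1, 2, 3])
        assert np.isnan(s.values[1]) and np.isfinite(s.values[[0, 2]]).all()


def make_series(years, values, **kw):
    return SeasonalSeries("t", "WB", SPRING, np.asarray(years),
                          np.asarray(values, dtype=float), **kw)


class TestLoessFill:
    def test_complete_series_unchanged(self):
        s = make_series(range(5), [1.0, 2.0, 1.5, 3.0, 2.5])
        out = loess_fill(s)
        assert np.array_equal(out.values, s.values)
        assert not out.interpolated.any()

    @pytest.mark.parametrize("degree", [1, 2])
    def test_exact_linear_series_reproduced(self, degree):
        years = np.arange(2000, 2010)
        values = 0.7 * (years - 2000) + 1.2
        v = values.astype(float).copy()
        v[4] = np.nan
        out = loess_fill(make_series(years, v), PrepConfig(loess_degree=degree))
        assert abs(out.values[4] - values[4]) < 1e-8
        assert out.interpolated[4] and out.interp_fraction == pytest.approx(0.1)

    @pytest.mark.parametrize("degree", [1, 2])
    @pytest.mark.parametrize("span", [0.3, 0.5, 0.9])
    def test_matches_brute_force_local_regression(self, rng, degree, span):
        """Seeded noisy series with gaps: filled values equal a direct
        tricube-weighted local regression oracle."""
        g = np.random.default_rng(11)
        years = np.arange(1980, 2000)
        values = np.sin(years / 3.0) + 0.3 * g.normal(size=20)
        v = values.copy()
        gaps = [5, 13]
        v[gaps] = np.nan
        out = loess_fill(
            make_series(years, v),
            PrepConfig(loess_span=span, loess_degree=degree),
        )
        obs = np.delete(years, gaps).astype(float)
        yobs = np.delete(values, gaps)
        for gap in gaps:
            expected = brute_loess_at(obs, yobs, float(years[gap]), span, degree)
            assert out.values[gap] == pytest.approx(expected, abs=1e-8)

    def test_end_gaps_refused(self):
        v = [np.nan, 1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ExtrapolationError):
            loess_fill(make_series(range(5), v))

    def test_too_few_points_refused(self):
        v = [1.0, np.nan, 2.0, 1.0]
        with pytest.raises(InsufficientDataError):
            loess_fill(make_series(range(4), v))

    def test_high_interpolation_warns(self):
        years = np.arange(12)
        v = np.linspace(0, 5, 12)
        v[[2, 3, 4, 6, 8]] = np.nan
        with pytest.warns(UserWarning, match="interpolated"):
            loess_fill(make_series(years, v))


class TestNormalize:
    def test_three_point_example(self):
        out = normalize(make_series([1, 2, 3], [1.0, 2.0, 3.0]))
        assert np.allclose(out.values, [-1.0, 0.0, 1.0])
        assert out.normalized

    def test_idempotent_to_rounding(self):
        g = np.random.default_rng(1)
        s = normalize(make_series(range(10), g.normal(size=10)))
        again = normalize(replace(s))
        assert np.allclose(s.values, again.values, atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            normalize(make_series([1, 2, 3], [5.0, 5.0, 5.0]))

    def test_zero_mean_unit_variance(self):
        g = np.random.default_rng(2)
        out = normalize(make_series(range(30), g.lognormal(size=30)))
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std(ddof=1) - 1.0) < 1e-9


def test_year_relabeling_leaves_values_unchanged():
    """Adding a constant to every year label shifts the index only."""
    rec = [(y, 5, "WB", "t", float(y)) for y in range(1, 9) if y != 4]
    a = loess_fill(seasonal_mean(records_from(rec), "t", "WB", SPRING))
    shifted = [(y + 100, m, r, t, v) for (y, m, r, t, v) in rec]
    b = loess_fill(seasonal_mean(records_from(shifted), "t", "WB", SPRING))
    assert np.allclose(a.values, b.values)
    assert np.array_equal(a.years + 100, b.years)
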