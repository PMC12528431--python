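"""Generator contracts: planted coupling, decoupled limits, determinism."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from seasonccm.errors import ConfigError, DivergenceError, EmptyOutputError
from seasonccm.synthetic import (
    SimulationConfig,
    observe_survey,
    simulate_community,
    simulate_coupled_logistic,
    simulate_seasonal_pp,
)


def logistic_config(n=500, seed=1, **params):
    return SimulationConfig(
        model="coupled_logistic", n_years=n, seed=seed, params=params
    )


class TestCoupledLogistic:
    def test_zero_coupling_gives_independent_chaos(self):
        X, Y = simulate_coupled_logistic(
            logistic_config(n=1000, beta_xy=0.0, beta_yx=0.0, r_x=3.8, r_y=3.8)
        )
        assert np.all((X > 0) & (X < 1)) and np.all((Y > 0) & (Y < 1))
        # chaotic trajectories from independent initials decorrelate
        assert abs(np.corrcoef(X, Y)[0, 1]) < 0.15

    def test_planted_coefficients_recovered_by_monomial_regression(self):
        """The map is linear in (Y, Y^2, XY): least squares on the exact
        update rule recovers (r_y, -r_y, -beta_yx) to machine precision."""
        r_y, beta_yx = 3.5, 0.32
        X, Y = simulate_coupled_logistic(
            logistic_config(n=1000, beta_xy=0.0, beta_yx=beta_yx, r_x=3.8, r_y=r_y)
        )
        A = np.column_stack([Y[:-1], Y[:-1] ** 2, X[:-1] * Y[:-1]])
        coef, *_ = np.linalg.lstsq(A, Y[1:], rcond=None)
        assert np.allclose(coef, [r_y, -r_y, -beta_yx], rtol=1e-10, atol=1e-10)

    def test_escape_raises_divergence_error(self):
        with pytest.raises(DivergenceError, match="step"):
            simulate_coupled_logistic(
                logistic_config(beta_xy=0.0, beta_yx=0.0, r_x=4.2, r_y=3.5, x0=0.5)
            )

    def test_seeded_determinism(self):
        a = simulate_coupled_logistic(logistic_config(seed=9))
        b = simulate_coupled_logistic(logistic_config(seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestSeasonalPP:
    def test_no_predation_limit(self):
        """With a=0 and no noise the predator decays geometrically and the
        prey follows the seasonally forced logistic independent of P0."""
        cfg = SimulationConfig(
            model="seasonal_pp", n_years=5, seed=0,
            params={"a": 0.0, "process_noise_sd": 0.0},
        )
        N, P = simulate_seasonal_pp(cfg)
        ratios = P[1:] / P[:-1]
        assert np.allclose(ratios, np.exp(-0.6), rtol=1e-12)
        cfg2 = SimulationConfig(
            model="seasonal_pp", n_years=5, seed=0,
            params={"a": 0.0, "process_noise_sd": 0.0, "P0": 7.7},
        )
        N2, _ = simulate_seasonal_pp(cfg2)
        assert np.allclose(N, N2)

    def test_climatology_peaks_and_antiphase_signal(self):
        """Prey climatology peaks in months 3-6, predator in 6-9, and the
        spring-vs-fall prey correlation is negative on a long run."""
        cfg = SimulationConfig(model="seasonal_pp", n_years=200, seed=7)
        N, P = simulate_seasonal_pp(cfg)
        assert np.all(N > 0) and np.all(P > 0)
        Nm, Pm = N.reshape(-1, 12), P.reshape(-1, 12)
        assert 3 <= np.argmax(Nm.mean(0)) + 1 <= 6
        assert 6 <= np.argmax(Pm.mean(0)) + 1 <= 9
        spring = np.log1p(Nm[:, 3:6].mean(axis=1))
        fall = np.log1p(Nm[:, 9:12].mean(axis=1))
        assert spearmanr(spring, fall).statistic < 0

    def test_alpha_out_of_range_rejected(self):
        cfg = SimulationConfig(
            model="seasonal_pp", n_years=5, params={"alpha": 1.5}
        )
        with pytest.raises(ConfigError, match="alpha"):
            simulate_seasonal_pp(cfg)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(model="seasonal_pp", n_years=30, seed=3)
        a = simulate_seasonal_pp(cfg)
        b = simulate_seasonal_pp(cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestObserveSurvey:
    def test_noiseless_census_reproduces_latent(self):
        cfg = SimulationConfig(
            model="seasonal_pp", n_years=3, seed=1, obs_noise_sd=0.0,
            missing_year_prob=0.0, samples_per_month=1,
            sampled_months=tuple(range(1, 13)),
        )
        latent = {"calfin": np.arange(1.0, 37.0)}
        rec = observe_survey(latent, cfg)
        assert len(rec) == 36
        got = rec.sort_values(["year", "month"])["abundance_m3"].to_numpy()
        assert np.array_equal(got, latent["calfin"])

    def test_dropped_year_fraction_is_binomial(self):
        """Mean dropped fraction over many seeds within 2 SE of the
        per-year drop probability."""
        p, years, n_seeds = 0.1, 40, 1000
        dropped = 0
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                model="seasonal_pp", n_years=years, seed=10_000 + seed,
                missing_year_prob=p, sampled_months=(6,),
            )
            rec = observe_survey({"t": np.ones(years * 12)}, cfg)
            dropped += years - rec["year"].nunique()
        frac = dropped / (n_seeds * years)
        se = np.sqrt(p * (1 - p) / (n_seeds * years))
        assert abs(frac - p) < 2 * se

    def test_negative_latent_rejected(self):
        cfg = SimulationConfig(model="seasonal_pp", n_years=1)
        with pytest.raises(ValueError, match="negative"):
            observe_survey({"t": -np.ones(12)}, cfg)

    def test_all_years_dropped_raises(self):
        cfg = SimulationConfig(
            model="seasonal_pp", n_years=2, missing_year_prob=1.0
        )
        with pytest.raises(EmptyOutputError):
            observe_survey({"t": np.ones(24)}, cfg)


class TestCommunity:
    def test_ground_truth_labels_match_generating_equations(self):
        cfg = SimulationConfig(model="seasonal_pp", n_years=25, seed=2)
        latent, truth = simulate_community(cfg, coupled_predator="siphonophores")
        assert truth.sign("calfin", "siphonophores") == "+"
        assert truth.sign("siphonophores", "calfin") == "-"
        assert not truth.is_coupled("calfin", "herring")
        assert set(latent) == {
            "calfin", "chaetognaths", "euphausiids", "siphonophores",
            "paraeuchaeta", "herring",
        }
        assert all(np.all(v > 0) for v in latent.values())

    def test_uncoupled_community_has_no_labels(self):
        cfg = SimulationConfig(model="seasonal_pp", n_years=25, seed=2)
        _, truth = simulate_community(cfg, coupled_predator=None)
        assert truth.coupling == {}

    def test_adding_taxa_preserves_existing_series(self):
        """Per-taxon substreams: a taxon's series does not change when the
        predator list around it changes."""
        cfg = SimulationConfig(model="seasonal_pp", n_years=25, seed=5)
        full, _ = simulate_community(cfg, coupled_predator="euphausiids")
        fewer, _ = simulate_community(
            cfg,
            predators=("euphausiids", "herring"),
            coupled_predator="euphausiids",
        )
        assert np.array_equal(full["herring"], fewer["herring"])
        assert np.array_equal(full["calfin"], fewer["calfin"])


def test_config_validation():
    with pytest.raises(ConfigError):
        SimulationConfig(model="nope")
    with pytest.raises(ConfigError):
        SimulationConfig(missing_year_prob=1.5)
    with pytest.raises(ConfigError):
        SimulationConfig(params={"r": np.inf})
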