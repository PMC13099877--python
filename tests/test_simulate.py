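import numpy as np
import pandas as pd
import pytest

from dlnmm.basis import CrossBasisSpec
from dlnmm.model import N_SEASONS
from dlnmm.simulate import (
    ExposureParams,
    GenerativeTruth,
    SimConfig,
    default_crossbasis_specs,
    default_truth,
    simulate_counts,
    simulate_exposures,
    simulate_grid_observations,
    zinb_mean,
    zinb_var,
)


def null_truth(n_sub, populations, beta0, kappa=None, pi=0.0, spec=None):
    """Truth with no covariate, seasonal, or random-intercept effects."""
    spec = spec or CrossBasisSpec.from_data("temperature", np.linspace(0, 1, 9),
                                            max_lag=2)
    return GenerativeTruth(
        beta0=beta0,
        gamma=np.zeros(N_SEASONS - 1),
        betas={"temperature": np.zeros((spec.exposure_df, spec.lag_df_effective))},
        sigma_b=0.0,
        kappa=kappa,
        pi=pi,
        populations=np.full(n_sub, populations),
    ), spec


class TestExposures:
    def test_seed_gives_byte_identical_panels(self):
        a = simulate_exposures(SimConfig(seed=5))
        b = simulate_exposures(SimConfig(seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_exposures(SimConfig(seed=6))
        assert not a["temperature"].equals(c["temperature"])

    def test_degenerate_noise_free_series_is_constant(self):
        cfg = SimConfig(
            n_subregions=2,
            n_weeks=60,
            exposures={"temperature": ExposureParams(
                baseline=25.0, baseline_spread=0.0, amplitude=0.0,
                ar_coef=0.0, noise_sd=0.0)},
            seed=0,
        )
        panel = simulate_exposures(cfg)
        assert np.all(panel["temperature"].to_numpy() == 25.0)

    def test_subregional_means_stay_in_climatology_envelope(self):
        panel = simulate_exposures(SimConfig(n_subregions=8, seed=3))
        means = panel.groupby("subregion")["temperature"].mean()
        assert means.between(18.7, 30.9).all()
        assert panel["precipitation"].min() >= 0.0
        assert panel["humidity"].between(0.0, 1.0).all()
        assert panel["aod"].min() >= 0.0

    def test_ar1_autocorrelation_matches_theory(self):
        cfg = SimConfig(
            n_subregions=1,
            n_weeks=10_000,
            exposures={"temperature": ExposureParams(
                baseline=0.0, amplitude=0.0, ar_coef=0.6, noise_sd=1.0)},
            seed=9,
        )
        x = simulate_exposures(cfg)["temperature"].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        # MC error of the lag-1 ACF at n = 10,000 is about 0.01
        assert abs(r1 - 0.6) < 0.03

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_subregions=0)
        with pytest.raises(ValueError):
            SimConfig(n_weeks=-1)
        with pytest.raises(ValueError):
            ExposureParams(baseline=0.0, ar_coef=1.0)


class TestCounts:
    def test_null_poisson_mean_recovers_analytic_value(self):
        # pi=0, Poisson kernel, no covariate effects, N=1000, rate 0.005
        truth, spec = null_truth(2, 1000.0, np.log(0.005))
        cfg = SimConfig(n_subregions=2, n_weeks=5002,
                        exposures={"temperature": ExposureParams(baseline=0.5)},
                        seed=1)
        exposures = simulate_exposures(cfg)
        counts = simulate_counts(exposures, truth, [spec], seed=2)
        n = len(counts)
        assert n == 2 * 5000  # burn-in excluded
        se = np.sqrt(5.0 / n)
        assert abs(counts["count"].mean() - 5.0) < 3 * se

    def test_zero_fraction_matches_closed_form(self):
        # pi + (1 - pi) NB(0; mu=5, kappa=1) = 0.3 + 0.7/6
        truth, spec = null_truth(2, 1000.0, np.log(0.005), kappa=1.0, pi=0.3)
        cfg = SimConfig(n_subregions=2, n_weeks=5002,
                        exposures={"temperature": ExposureParams(baseline=0.5)},
                        seed=1)
        exposures = simulate_exposures(cfg)
        counts = simulate_counts(exposures, truth, [spec], seed=3)
        p0 = 0.3 + 0.7 / 6.0
        frac = (counts["count"] == 0).mean()
        assert abs(frac - p0) < 3 * np.sqrt(p0 * (1 - p0) / len(counts))

    def test_zero_fraction_monotone_in_pi(self):
        cfg = SimConfig(n_subregions=3, n_weeks=520, seed=4)
        exposures = simulate_exposures(cfg)
        specs = default_crossbasis_specs(exposures, names=["temperature"],
                                         max_lags={"temperature": 4})
        fracs = []
        for pi in (0.0, 0.15, 0.4):
            truth = default_truth(specs, exposures, n_subregions=3, seed=4, pi=pi)
            counts = simulate_counts(exposures, truth, specs, seed=5)
            fracs.append((counts["count"] == 0).mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_moments_match_analytic_zinb(self):
        truth, spec = null_truth(1, 1000.0, np.log(0.005), kappa=2.0, pi=0.2)
        cfg = SimConfig(n_subregions=1, n_weeks=40_002,
                        exposures={"temperature": ExposureParams(baseline=0.5)},
                        seed=6)
        exposures = simulate_exposures(cfg)
        counts = simulate_counts(exposures, truth, [spec], seed=7)["count"]
        m, v = zinb_mean(5.0, 2.0, 0.2), zinb_var(5.0, 2.0, 0.2)
        assert abs(counts.mean() - m) < 3 * np.sqrt(v / counts.size)
        assert abs(counts.var() - v) / v < 0.1

    def test_dimension_mismatch_raises(self, small_panel):
        truth = small_panel["truth"]
        bad_spec = CrossBasisSpec.from_data(
            "temperature",
            small_panel["exposures"]["temperature"].to_numpy(),
            max_lag=9, exposure_df=4,
        )
        with pytest.raises(ValueError, match="shape"):
            simulate_counts(small_panel["exposures"], truth,
                            [bad_spec, small_panel["specs"][1]])

    def test_default_zero_share_is_low_and_population_concentrated(self):
        cfg = SimConfig(seed=8)
        exposures = simulate_exposures(cfg)
        specs = default_crossbasis_specs(exposures, max_lags={n: 6 for n in
                                         ("temperature", "precipitation",
                                          "humidity", "aod")})
        truth = default_truth(specs, exposures, seed=8)
        counts = simulate_counts(exposures, truth, specs, seed=9)
        share = (counts["count"] == 0).mean()
        assert 0.01 < share < 0.12  # low-count regime with excess zeros
        by_sub = counts.groupby("subregion").agg(
            zero=("count", lambda s: (s == 0).mean()), pop=("population", "first")
        )
        # smallest-population subregion has more zeros than the largest
        assert by_sub.loc[by_sub["pop"].idxmin(), "zero"] >= by_sub.loc[
            by_sub["pop"].idxmax(), "zero"]


class TestGrid:
    def test_missingness_fraction_and_determinism(self):
        cfg = SimConfig(n_subregions=2, n_weeks=520, missing_prob=0.2, seed=10)
        g1 = simulate_grid_observations(cfg, "humidity", n_cells=16)
        g2 = simulate_grid_observations(cfg, "humidity", n_cells=16)
        pd.testing.assert_frame_equal(g1, g2)
        miss = g1["value"].isna().mean()
        assert abs(miss - 0.2) < 0.02
        assert g1["value"].dropna().between(0, 1).all()
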