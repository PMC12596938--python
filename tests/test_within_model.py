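"""Within-species measurement-error regression."""

import numpy as np
import pandas as pd
import pytest

from avian_itv import covariates, within_model
from avian_itv.diagnostics import McmcConfig
from avian_itv.within_model import (
    fit_within_model,
    posterior_predictive_check,
    summarize_effect,
)

FAST = McmcConfig(iterations=2000, warmup=500, seed=2)


def _design(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def medium_design(medium_dataset):
    obs = medium_dataset.make_group_cv_observations(seed=4)
    return covariates.assemble_within_design(
        obs, medium_dataset.stations, medium_dataset.raster, medium_dataset.ranges
    )


@pytest.fixture(scope="module")
def medium_fit(medium_design):
    return fit_within_model(medium_design, FAST)


class TestSummarizeEffect:
    def test_constant_draws(self):
        s = summarize_effect(np.full((2, 100), 2.0))
        assert (s.mean, s.ci89, s.p_gt0) == (2.0, (2.0, 2.0), 1.0)

    def test_symmetric_draws(self):
        s = summarize_effect(np.random.default_rng(0).normal(size=(2, 4000)))
        assert abs(s.p_gt0 - 0.5) < 0.03

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_effect(np.zeros((1, 50)))


class TestFitValidation:
    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_within_model(_design([]), FAST)

    def test_single_species_rejected(self):
        rows = [
            {"species": "a", "location_id": f"L{i}", "cv_hat": 25.0, "tau_hat": 1.0,
             "Lat": i - 2.0, "DistEdge": 0.1 * i, "SpatVar": 0.01 * i,
             "TempVar": -0.01 * i}
            for i in range(6)
        ]
        with pytest.raises(ValueError, match=">= 2 species"):
            fit_within_model(_design(rows), FAST)

    def test_nonpositive_tau_rejected(self, medium_design):
        bad = medium_design.copy()
        bad.loc[bad.index[0], "tau_hat"] = 0.0
        with pytest.raises(ValueError, match="tau_hat"):
            fit_within_model(bad, FAST)

    def test_rank_deficient_species_design_rejected(self):
        rng = np.random.default_rng(3)
        rows = []
        for sp in ("a", "b"):
            for i in range(8):
                rows.append(
                    {"species": sp, "location_id": f"L{i}", "cv_hat": 25.0,
                     "tau_hat": 1.0, "Lat": rng.normal(), "DistEdge": rng.normal(),
                     "SpatVar": 0.0, "TempVar": 0.0}  # constant columns
                )
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_within_model(_design(rows), FAST)


class TestMeasurementErrorShrinkage:
    def test_larger_tau_shrinks_theta_harder(self):
        """Rows with identical cv_hat offsets but growing tau_hat have
        latent-state posteriors pulled further toward the regression mean."""
        rng = np.random.default_rng(4)
        rows = []
        taus = {}
        for sp in ("a", "b"):
            for i in range(12):
                rows.append(
                    {"species": sp, "location_id": f"{sp}{i}", "cv_hat": 25.0,
                     "tau_hat": 1.0, "Lat": rng.normal(), "DistEdge": rng.normal(),
                     "SpatVar": rng.normal(), "TempVar": rng.normal()}
                )
            for j, tau in enumerate((0.5, 2.0, 8.0)):
                loc = f"{sp}_probe{j}"
                taus[(sp, loc)] = tau
                rows.append(
                    {"species": sp, "location_id": loc, "cv_hat": 31.0,
                     "tau_hat": tau, "Lat": 0.0, "DistEdge": 0.0,
                     "SpatVar": 0.0, "TempVar": 0.0}
                )
        design = _design(rows)
        post = fit_within_model(design, FAST)
        theta = post.draws.flat("theta").mean(axis=0)
        pulls = {}
        for (sp, loc), tau in taus.items():
            i = design.index[(design["species"] == sp) & (design["location_id"] == loc)][0]
            pulls.setdefault(sp, []).append(31.0 - theta[i])
        for sp, pull in pulls.items():
            assert pull[0] < pull[1] < pull[2]  # monotone in tau


class TestIntervalsAndScaling:
    def test_89_interval_inside_95(self, medium_fit):
        for name in within_model.EFFECT_NAMES:
            draws = medium_fit.effect(name).ravel()
            lo89, hi89 = np.quantile(draws, [0.055, 0.945])
            lo95, hi95 = np.quantile(draws, [0.025, 0.975])
            assert lo95 <= lo89 and hi89 <= hi95

    def test_intercept_near_generated_grand_mean(self, medium_fit, medium_dataset):
        s = summarize_effect(medium_fit.effect("mu_alpha"))
        assert abs(s.mean - medium_dataset.config.kappa) < 4.0

    def test_scaling_equivariance(self, medium_design, medium_fit):
        """x10 on cv_hat, tau_hat and the prior scales multiplies every
        location-scale posterior by 10 (up to Monte-Carlo error).

        The model family is scale-equivariant; the priors must scale with
        the data for the posterior to follow (the inverse-Wishart scale is a
        variance, hence x100).
        """
        base = within_model.WithinPriors()
        scaled_priors = within_model.WithinPriors(
            intercept_sd=base.intercept_sd * 10,
            slope_sd=base.slope_sd * 10,
            sigma_theta_scale=base.sigma_theta_scale * 10,
            iw_df=base.iw_df,
            iw_scale=base.iw_scale * 100,
        )
        scaled = medium_design.copy()
        scaled["cv_hat"] *= 10.0
        scaled["tau_hat"] *= 10.0
        post10 = fit_within_model(scaled, FAST, priors=scaled_priors)
        m1 = medium_fit.draws.flat("mu").mean(axis=0)
        m10 = post10.draws.flat("mu").mean(axis=0)
        sd10 = post10.draws.flat("mu").std(axis=0)
        assert m10[0] / m1[0] == pytest.approx(10.0, rel=0.02)
        assert np.all(np.abs(m10 - 10.0 * m1) <= 0.2 * sd10 + 0.02 * np.abs(10 * m1))
        s1 = medium_fit.draws.flat("sigma_theta")
        s10 = post10.draws.flat("sigma_theta")
        assert s10.mean() / s1.mean() == pytest.approx(10.0, rel=0.1)


class TestPosteriorPredictiveCheck:
    def test_observed_mean_inside_replicate_spread(self, medium_fit):
        ppc = posterior_predictive_check(medium_fit, n_replicates=300, seed=0)
        lo, hi = np.quantile(ppc["replicate_means"], [0.025, 0.975])
        assert lo <= ppc["observed_mean"] <= hi

    def test_replicate_sd_brackets_observed_sd(self, medium_fit):
        ppc = posterior_predictive_check(medium_fit, n_replicates=300, seed=0)
        lo, hi = np.quantile(ppc["replicate_sds"], [0.01, 0.99])
        assert lo <= ppc["observed_sd"] <= hi

    def test_replicate_shapes(self, medium_fit):
        ppc = posterior_predictive_check(medium_fit, n_replicates=50, seed=1)
        assert ppc["replicates"].shape == (50, len(medium_fit.design))

    def test_empty_design_rejected(self, medium_fit):
        with pytest.raises(ValueError, match="empty"):
            posterior_predictive_check(medium_fit, design=_design([]))
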