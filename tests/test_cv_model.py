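"""Hierarchical CV model: consistency, CV derivation, propagation properties."""

import numpy as np
import pandas as pd
import pytest

from avian_itv import cv_model, filters
from avian_itv.cv_model import (
    CVPosterior,
    TraitObservationSet,
    derive_all_group_cvs,
    derive_group_cv,
    derive_species_cv,
    fit_cv_model,
)
from avian_itv.diagnostics import McmcConfig, PosteriorDraws

FAST = McmcConfig(iterations=2500, warmup=1000, seed=1)


def _manual_posterior(mu_draws, sigma_draws, groups):
    """CVPosterior from explicit draw arrays shaped (chain, draw, group)."""

    class _Stub:
        pass

    stub = _Stub()
    stub.groups = groups
    stub.species_names = groups["species"].unique().tolist()
    draws = PosteriorDraws({"mu": np.asarray(mu_draws), "sigma": np.asarray(sigma_draws)})
    return CVPosterior(draws, stub, trait="mass")


class TestObservationSet:
    def test_groups_with_single_observation_rejected(self):
        with pytest.raises(ValueError, match="< 2 observations"):
            TraitObservationSet(
                np.array([3.0, 3.1, 3.2]),
                np.array(["a", "a", "b"]),
                np.array(["L1", "L1", "L1"]),
            )

    def test_nonpositive_trait_rejected(self):
        df = pd.DataFrame(
            {"species": ["a"] * 3, "location_id": ["L"] * 3, "mass": [1.0, -2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="positive"):
            TraitObservationSet.from_captures(df, "mass")


@pytest.fixture(scope="module")
def oracle_fit():
    rng = np.random.default_rng(0)
    y = rng.normal(3.0, 0.06, 10_000)
    data = TraitObservationSet(y, np.repeat("spA", y.size), np.repeat("L1", y.size))
    post = fit_cv_model(data, FAST, trait="mass")
    return y, post


class TestLargeSampleConsistency:
    def test_group_parameters_recovered(self, oracle_fit):
        y, post = oracle_fit
        mu = post.draws.flat("mu")[:, 0]
        sigma = post.draws.flat("sigma")[:, 0]
        assert abs(mu.mean() - 3.0) < 0.005
        assert abs(sigma.mean() - 0.06) < 0.05 * 0.06

    def test_cv_matches_sample_ratio_oracle(self, oracle_fit):
        """Posterior mean CV agrees with sample SD / sample mean within 2%."""
        y, post = oracle_fit
        sample_ratio = y.std(ddof=1) / y.mean()
        g = derive_group_cv(post, "spA", "L1")
        assert abs(g.cv_hat - sample_ratio) < 0.02 * sample_ratio


class TestDeriveGroupCV:
    def test_point_mass_posterior(self):
        groups = pd.DataFrame(
            {"species": ["a"], "location_id": ["L1"], "n": [10]}
        )
        post = _manual_posterior(
            np.full((1, 4, 1), 100.0), np.full((1, 4, 1), 2.0), groups
        )
        g = derive_group_cv(post, "a", "L1")
        assert g.cv_hat == pytest.approx(0.02)
        assert g.tau_hat == 0.0

    def test_two_draw_formula(self):
        groups = pd.DataFrame({"species": ["a"], "location_id": ["L1"], "n": [10]})
        sigma = np.array([[[1.0], [3.0]]])
        mu = np.full((1, 2, 1), 100.0)
        g = derive_group_cv(_manual_posterior(mu, sigma, groups), "a", "L1")
        assert g.cv_hat == pytest.approx(0.02)
        assert g.tau_hat == pytest.approx(np.std([0.01, 0.03]))

    def test_nonpositive_mu_draw_rejected(self):
        groups = pd.DataFrame({"species": ["a"], "location_id": ["L1"], "n": [10]})
        mu = np.full((1, 4, 1), 100.0)
        mu[0, 2, 0] = -1.0
        post = _manual_posterior(mu, np.full((1, 4, 1), 2.0), groups)
        with pytest.raises(ValueError, match="<= 0"):
            derive_group_cv(post, "a", "L1")

    def test_unknown_group_rejected(self):
        groups = pd.DataFrame({"species": ["a"], "location_id": ["L1"], "n": [10]})
        post = _manual_posterior(np.full((1, 4, 1), 9.0), np.full((1, 4, 1), 1.0), groups)
        with pytest.raises(KeyError):
            derive_group_cv(post, "a", "L9")


class TestDeriveSpeciesCV:
    def test_single_group_equals_group_cv(self):
        groups = pd.DataFrame({"species": ["a"], "location_id": ["L1"], "n": [10]})
        rng = np.random.default_rng(1)
        mu = rng.uniform(90, 110, (2, 200, 1))
        sigma = rng.uniform(1, 3, (2, 200, 1))
        post = _manual_posterior(mu, sigma, groups)
        g = derive_group_cv(post, "a", "L1")
        s = derive_species_cv(post, "a")
        assert s.cvsp_hat == pytest.approx(g.cv_hat)
        assert s.tausp_hat == pytest.approx(g.tau_hat)

    def test_point_mass_groups_average(self):
        groups = pd.DataFrame(
            {"species": ["a", "a"], "location_id": ["L1", "L2"], "n": [10, 10]}
        )
        mu = np.full((1, 4, 2), 100.0)
        sigma = np.stack([np.full((1, 4), 2.0), np.full((1, 4), 4.0)], axis=-1)
        s = derive_species_cv(_manual_posterior(mu, sigma, groups), "a")
        assert s.cvsp_hat == pytest.approx(0.03)


class TestInformationPropagation:
    def test_small_groups_have_wider_cv_posteriors(self):
        """Matched true parameters, n=5 vs n=500: tau_hat larger at n=5."""
        rng = np.random.default_rng(5)
        y_small = rng.normal(3.4, 0.08, 5)
        y_big = rng.normal(3.4, 0.08, 500)
        data = TraitObservationSet(
            np.concatenate([y_small, y_big]),
            np.repeat("spA", 505),
            np.array(["L_small"] * 5 + ["L_big"] * 500),
        )
        post = fit_cv_model(data, FAST, trait="mass")
        tab = derive_all_group_cvs(post).set_index("location_id")
        assert tab.loc["L_small", "tau_hat"] > tab.loc["L_big", "tau_hat"]

    def test_log_scale_shift_equivariance(self, small_dataset):
        """Adding c to all log traits of every group shifts mu by c and
        leaves sigma unchanged."""
        kept, _ = filters.apply_filters(small_dataset.captures, trait="mass")
        one_sp = kept[kept["species"] == kept["species"].iloc[0]]
        y = np.log(one_sp["mass"].to_numpy())
        sp = one_sp["species"].to_numpy()
        loc = one_sp["location_id"].to_numpy()
        c = 0.7
        post0 = fit_cv_model(TraitObservationSet(y, sp, loc), FAST)
        post1 = fit_cv_model(TraitObservationSet(y + c, sp, loc), FAST)
        mu0 = post0.draws.flat("mu").mean(axis=0)
        mu1 = post1.draws.flat("mu").mean(axis=0)
        s0 = post0.draws.flat("sigma").mean(axis=0)
        s1 = post1.draws.flat("sigma").mean(axis=0)
        assert np.allclose(mu1 - mu0, c, atol=0.01)
        assert np.allclose(s1, s0, rtol=0.05)

    def test_isometric_traits_preserve_cv_ratio(self, medium_dataset):
        """Wing log-SDs are generated at one third of the mass CV; the two
        fitted CV sets preserve that x3 ratio within 10%."""
        caps = medium_dataset.captures
        fits = {}
        for trait in ("mass", "wing"):
            kept, _ = filters.apply_filters(caps, trait=trait)
            data = TraitObservationSet.from_captures(kept, trait)
            fits[trait] = derive_all_group_cvs(
                fit_cv_model(data, FAST, trait=trait)
            ).set_index(["species", "location_id"])
        ratio = fits["mass"]["cv_hat"] / fits["wing"]["cv_hat"]
        assert abs(ratio.mean() - 3.0) < 0.3
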