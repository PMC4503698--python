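import math

import numpy as np
import pytest

from occumix.data_io import SiteRecord, SiteSet, StudyDataset
from occumix.model_core import (
    ModelVariant,
    ParameterSet,
    conditional_deviance,
    detection_site_loglik,
    group_size_mean,
    log_prior,
    observation_logprob,
    occupancy_probability,
    site_marginal_loglik,
    ztpois_logpmf,
    ztpois_mean,
)

M2 = ModelVariant.from_name("M2")
M4 = ModelVariant.from_name("M4")


class TestZTPois:
    def test_logpmf_closed_form(self):
        expected = math.log(math.exp(-1.0) / (1.0 - math.exp(-1.0)))
        assert ztpois_logpmf(1, 1.0) == pytest.approx(expected, abs=1e-10)
        assert ztpois_logpmf(1, 1.0) == pytest.approx(-0.54132, abs=1e-5)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 20.0])
    def test_normalizes(self, lam):
        ns = np.arange(1, 501)
        total = np.sum(np.exp(ztpois_logpmf(ns, lam)))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            ztpois_logpmf(0, 2.0)

    def test_stable_extremes(self):
        assert np.isfinite(ztpois_logpmf(1, 1e-9))
        assert np.isfinite(ztpois_logpmf(700, 750.0))

    def test_mean_closed_form(self):
        assert ztpois_mean(1.0) == pytest.approx(1.58198, abs=1e-5)

    def test_mean_large_lambda(self):
        assert ztpois_mean(20.0) == pytest.approx(20.0, rel=1e-8)

    def test_mean_small_lambda_limit(self):
        assert ztpois_mean(1e-10) == pytest.approx(1.0, rel=1e-6)

    def test_mean_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ztpois_mean(0.0)


class TestOccupancyProbability:
    def test_all_zero_gives_half(self):
        params = ParameterSet()
        assert occupancy_probability(params, 0.0, 0.0, 0, SiteSet.SET1) == 0.5

    def test_intercept_anchors_probability(self):
        c = math.log(0.605 / 0.395)
        params = ParameterSet(c=c)
        psi = occupancy_probability(params, 0.0, 0.0, 0, SiteSet.SET1)
        assert psi == pytest.approx(0.605, abs=1e-9)

    def test_monotone_in_distance(self):
        params = ParameterSet(gamma1=-0.8)
        vals = [occupancy_probability(params, x, 0.0, 0, SiteSet.SET1)
                for x in np.linspace(-1, 1, 9)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_set2_intercept_only_by_default(self):
        params = ParameterSet(c=1.0, c_set2=-1.0, gamma1=2.0)
        psi = occupancy_probability(params, 0.7, 0.0, 0, SiteSet.SET2, M2)
        assert psi == pytest.approx(1.0 / (1.0 + math.e), abs=1e-12)

    def test_set2_linear_under_m6(self):
        m6 = ModelVariant.from_name("M6")
        params = ParameterSet(c=1.0, c_set2=-1.0, gamma1=2.0)
        psi = occupancy_probability(params, 0.7, 0.0, 0, SiteSet.SET2, m6)
        assert psi == pytest.approx(1.0 / (1.0 + math.exp(1.0 - 1.4)), abs=1e-12)


class TestGroupSizeMean:
    def test_all_zero_unity(self):
        params = ParameterSet()
        for year in (1995, 2008, 2009):
            assert group_size_mean(params, M2, year, 0, 0.0, 0.0) == 1.0

    def test_intercept_anchors_1995(self):
        params = ParameterSet(alpha=math.log(4.5))
        assert group_size_mean(params, M2, 1995, 0, 0.0, 0.0) == pytest.approx(4.5)

    def test_restoration_multiplier_2008(self):
        params = ParameterSet(alpha=1.0, beta3=-0.1, beta4=math.log(1.22))
        with_w = group_size_mean(params, M2, 2008, 1, 0.0, 0.0)
        without = group_size_mean(params, M2, 2008, 0, 0.0, 0.0)
        assert with_w / without == pytest.approx(1.22, abs=1e-12)

    def test_beta5_ignored_unless_m4(self):
        params = ParameterSet(alpha=1.0, beta5=0.5)
        plain = group_size_mean(params, M2, 1995, 1, 0.0, 0.0)
        with_b5 = group_size_mean(params, M4, 1995, 1, 0.0, 0.0)
        assert plain == pytest.approx(math.exp(1.0))
        assert with_b5 == pytest.approx(math.exp(1.5))

    def test_beta5_persists_into_2008_under_m4(self):
        # the baseline restoration term adds to the work effect in later years
        params = ParameterSet(beta4=0.2, beta5=0.5)
        lam = group_size_mean(params, M4, 2008, 1, 0.0, 0.0)
        assert lam == pytest.approx(math.exp(0.7), abs=1e-12)

    def test_log_linear_additivity(self):
        params = ParameterSet(alpha=1.2, beta1=-0.3, beta2=0.5, beta3=-0.1)
        a = group_size_mean(params, M2, 2008, 0, 0.4, -0.2)
        b = group_size_mean(params, M2, 2008, 0, 0.4 + 1.0, -0.2)
        assert math.log(b) - math.log(a) == pytest.approx(params.beta1, abs=1e-12)

    def test_set3_2009_builds_on_2008(self):
        params = ParameterSet(alpha=1.0, beta3=-0.2, beta4=0.3, beta6=0.1,
                              beta7=-0.05)
        lam2 = group_size_mean(params, M2, 2008, 1, site_set=SiteSet.SET3, eps=0.2)
        lam3 = group_size_mean(params, M2, 2009, 1, site_set=SiteSet.SET3, eps=0.2)
        assert lam3 / lam2 == pytest.approx(math.exp(0.1 - 0.05), abs=1e-12)

    def test_missing_covariates_raise(self):
        with pytest.raises(KeyError):
            group_size_mean(ParameterSet(), M2, 1995, 0)

    def test_set3_has_no_1995(self):
        with pytest.raises(ValueError):
            group_size_mean(ParameterSet(), M2, 1995, 0, site_set=SiteSet.SET3)


class TestObservationLogprob:
    def test_perfect_detection_certain(self):
        assert observation_logprob(3, 3, 1, 1.0) == 0.0

    def test_unavailable_cannot_be_counted(self):
        assert observation_logprob(2, 5, 0, 0.9) == -math.inf
        assert observation_logprob(0, 5, 0, 0.9) == 0.0

    def test_binomial_value(self):
        assert observation_logprob(2, 4, 1, 0.5) == pytest.approx(
            math.log(6 * 0.0625), abs=1e-9
        )
        assert observation_logprob(2, 4, 1, 0.5) == pytest.approx(-0.9808, abs=1e-4)

    def test_count_exceeding_group_rejected(self):
        with pytest.raises(ValueError):
            observation_logprob(5, 4, 1, 0.5)


def _toy_dataset():
    """Three covariate-bearing sites built so the middle one sits exactly at
    the covariate averages (scaled values 0)."""
    sites = [
        SiteRecord("lo", SiteSet.SET1, 0, dist=300.0, tree_1995=8, tree_2008=8,
                   y_1995=2, y_2008=1),
        SiteRecord("mid", SiteSet.SET1, 0, dist=400.0, tree_1995=10, tree_2008=10,
                   y_1995=3, y_2008=0),
        SiteRecord("hi", SiteSet.SET2, 0, dist=500.0, tree_1995=12, tree_2008=12,
                   y_2008=4),
    ]
    return StudyDataset(sites=sites)


class TestSiteMarginalLoglik:
    def test_hand_marginalized_zero_count(self):
        # at d=1 a 2008 zero can only come from non-occupancy or unavailability
        ds = _toy_dataset()
        site = ds.sites[1]  # scaled covariates exactly 0
        assert ds.scaled_dist(site) == pytest.approx(0.0, abs=1e-12)
        assert ds.scaled_tree(site, 2008) == pytest.approx(0.0, abs=1e-12)
        params = ParameterSet(c=0.0, alpha=math.log(4.5), p=0.8, d=1.0)
        ll = site_marginal_loglik(site, ds, params, M2)
        expected = ztpois_logpmf(3, 4.5) + math.log((1 - 0.5) + 0.5 * (1 - 0.8))
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_perfect_observation_reduces_to_mixture(self):
        ds = _toy_dataset()
        site = ds.sites[2]  # SET2: only a 2008 count
        params = ParameterSet(c_set2=0.3, alpha=math.log(4.0), p=1.0, d=1.0)
        psi = 1.0 / (1.0 + math.exp(-0.3))
        lam = math.exp(params.alpha + params.beta1 * ds.scaled_dist(site)
                       + params.beta2 * ds.scaled_tree(site, 2008) + params.beta3)
        expected = math.log(psi) + ztpois_logpmf(4, lam)
        assert site_marginal_loglik(site, ds, params, M2) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize("psi,p,d,lam", [(0.4, 0.8, 0.7, 3.0),
                                             (0.9, 0.5, 0.9, 1.2)])
    def test_counts_normalize(self, psi, p, d, lam):
        c2 = math.log(psi / (1 - psi))
        params = ParameterSet(c_set2=c2, alpha=math.log(lam), p=p, d=d)
        total = 0.0
        base = _toy_dataset()
        for y in range(0, 51):
            sites = list(base.sites)
            sites[2] = SiteRecord("hi", SiteSet.SET2, 0, dist=400.0, tree_1995=10,
                                  tree_2008=10, y_2008=y)
            ds = StudyDataset(sites=sites)
            site = ds.sites[2]
            # scaled covariates not 0 here; compute lambda the site actually has
            ll = site_marginal_loglik(site, ds, params, M2)
            total += math.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_nmax_below_count_rejected(self):
        ds = _toy_dataset()
        with pytest.raises(ValueError):
            site_marginal_loglik(ds.sites[0], ds, ParameterSet(), M2, n_max=1)


class TestDetectionSiteLoglik:
    def test_certain_detection(self):
        # p=d=1: all four counts must equal N; probability is ZTPois(N)
        ll = detection_site_loglik([3, 3, 3, 3], lam=2.5, p=1.0, d=1.0)
        assert ll == pytest.approx(ztpois_logpmf(3, 2.5), abs=1e-9)

    def test_unequal_counts_impossible_when_certain(self):
        ll = detection_site_loglik([3, 2, 3, 3], lam=2.5, p=1.0, d=1.0)
        assert ll == -math.inf

    def test_single_visit_matches_closed_form(self):
        lam, p, d = 3.0, 0.7, 0.6
        ll = detection_site_loglik([2], lam, p, d)
        # one visit: availability mixture over the thinned truncated Poisson
        direct = math.log(
            p * math.exp(2 * math.log(lam * d) - lam * d - math.lgamma(3))
            / (1 - math.exp(-lam))
        )
        assert ll == pytest.approx(direct, abs=1e-9)


class TestLogPrior:
    def test_cauchy_slope_contribution(self):
        base = log_prior(ParameterSet(p=0.5, d=0.5, sigma_eps=1.0), M2)
        moved = log_prior(ParameterSet(gamma1=2.5, p=0.5, d=0.5, sigma_eps=1.0), M2)
        # moving gamma1 one Cauchy scale from the mode halves its density
        assert base - moved == pytest.approx(math.log(2.0), abs=1e-12)

    def test_component_values(self):
        from occumix.inference import _prior_logpdf

        assert _prior_logpdf("gamma1", 0.0) == pytest.approx(
            -math.log(math.pi * 2.5), abs=1e-12
        )
        assert _prior_logpdf("c", 0.0) == pytest.approx(
            -math.log(math.pi * 10.0), abs=1e-12
        )
        assert _prior_logpdf("alpha", 0.0) == pytest.approx(
            -math.log(100.0 * math.sqrt(2 * math.pi)), abs=1e-12
        )
        assert _prior_logpdf("alpha", 0.0) == pytest.approx(-5.5241, abs=1e-4)

    def test_sigma_outside_support(self):
        bad = ParameterSet(sigma_eps=11.0, p=0.5, d=0.5)
        assert log_prior(bad, M2) == -math.inf

    def test_boundary_probabilities_excluded(self):
        assert log_prior(ParameterSet(p=1.0, d=0.5, sigma_eps=1.0), M2) == -math.inf


class TestConditionalDeviance:
    def test_perfect_fit_zero(self):
        obs = [(3, 3, 1), (5, 5, 1)]
        assert conditional_deviance(obs, d=1.0) == 0.0

    def test_single_observation_value(self):
        assert conditional_deviance([(2, 4, 1)], d=0.5) == pytest.approx(
            1.9616, abs=1e-4
        )

    def test_minimized_at_mle(self):
        devs = [conditional_deviance([(2, 4, 1)], d=d)
                for d in (0.3, 0.5, 0.7)]
        assert devs[1] < devs[0] and devs[1] < devs[2]

    def test_inconsistent_latents_raise(self):
        with pytest.raises(ValueError):
            conditional_deviance([(2, 5, 0)], d=0.5)
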