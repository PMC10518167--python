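import numpy as np
import pytest

from pamvlt import (
    DetectionFunction,
    MCMCSettings,
    apply_availability,
    esw_phat,
    fit_ds,
    fit_mrds,
    gfun,
)
from pamvlt.errors import EstimationError, EstimationWarning, InputError
from pamvlt.simulate import two_team_sightings


class TestGfun:
    def test_half_normal_closed_form(self):
        hn = DetectionFunction("half_normal", 1000.0)
        assert gfun(0.0, hn) == pytest.approx(1.0)
        assert gfun(1000.0, hn) == pytest.approx(np.exp(-0.5))

    def test_hazard_rate_is_one_at_zero_and_monotone(self):
        hr = DetectionFunction("hazard_rate", 1500.0, shape=3.0)
        y = np.linspace(0, 6000, 200)
        g = gfun(y, hr)
        assert g[0] == pytest.approx(1.0)
        assert np.all(np.diff(g) <= 1e-12)

    def test_half_normal_monotone(self):
        hn = DetectionFunction("half_normal", 700.0)
        y = np.linspace(0, 5000, 300)
        assert np.all(np.diff(gfun(y, hn)) <= 0)

    def test_bad_shape_rejected(self):
        with pytest.raises(InputError):
            DetectionFunction("hazard_rate", 1000.0, shape=-1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(InputError):
            gfun(-1.0, DetectionFunction("half_normal", 100.0))


class TestEswPhat:
    def test_flat_detection_gives_unit_phat(self):
        # sigma >> W: g is ~1 over the whole strip
        esw, p = esw_phat(DetectionFunction("half_normal", 1e9), 4000.0)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_half_normal_wide_truncation_limit(self):
        # W = 10 sigma: esw approaches sigma * sqrt(pi / 2)
        sigma = 1000.0
        esw, _ = esw_phat(DetectionFunction("half_normal", sigma), 10 * sigma)
        assert esw == pytest.approx(sigma * np.sqrt(np.pi / 2), abs=1e-4)

    def test_matches_bruteforce_trapezoid(self):
        sigma = W = 2500.0
        hn = DetectionFunction("half_normal", sigma)
        y = np.linspace(0, W, 100_001)
        brute = np.trapezoid(gfun(y, hn), y)
        esw, p = esw_phat(hn, W)
        assert p == pytest.approx(brute / W, abs=1e-6)


class TestFitDS:
    def test_recovers_scale_from_own_model(self, single_chain_mcmc):
        """Simulated half-normal distances recover sigma within 15%
        in at least 90% of seeded replicates."""
        sigma_true, W = 1000.0, 4000.0
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            x = rng.uniform(0, W, 2000)
            y = x[rng.uniform(size=x.size) < np.exp(-x**2 / (2 * sigma_true**2))]
            y = y[:200]
            fit = fit_ds(y, W, settings=single_chain_mcmc, seed=rng)
            hits += abs(fit.flat("sigma").mean() - sigma_true) < 0.15 * sigma_true
        assert hits >= 18

    def test_degenerate_distances_shrink_phat(self, single_chain_mcmc):
        # every detection exactly on the trackline: scale collapses to the
        # prior lower bound and the covered-strip probability is tiny
        fit = fit_ds(np.zeros(50), W=4000.0, settings=single_chain_mcmc, seed=0)
        assert fit.flat("p_hat").mean() < 0.2

    def test_empty_input_rejected(self):
        with pytest.raises(EstimationError):
            fit_ds([], W=1000.0)

    def test_distance_beyond_truncation_rejected(self):
        with pytest.raises(InputError):
            fit_ds([1500.0], W=1000.0)

    def test_phat_equals_esw_over_w_drawwise(self, single_chain_mcmc, rng):
        y = np.abs(rng.normal(0, 800, 100))
        y = y[y < 3000]
        fit = fit_ds(y, 3000.0, settings=single_chain_mcmc, seed=1)
        np.testing.assert_allclose(fit.flat("p_hat"),
                                   fit.flat("esw") / fit.W, rtol=1e-12)

    def test_wider_truncation_never_raises_phat(self, single_chain_mcmc, rng):
        sigma = 800.0
        x = rng.uniform(0, 2500, 3000)
        y = x[rng.uniform(size=x.size) < np.exp(-x**2 / (2 * sigma**2))]
        p1 = fit_ds(y, 2500.0, settings=single_chain_mcmc,
                    seed=3).flat("p_hat").mean()
        p2 = fit_ds(y, 4000.0, settings=single_chain_mcmc,
                    seed=3).flat("p_hat").mean()
        assert p2 <= p1 + 0.02

    def test_group_size_expansion(self, single_chain_mcmc, rng):
        y = np.abs(rng.normal(0, 500, 60))
        y = y[y < 2000]
        base = fit_ds(y, 2000.0, settings=single_chain_mcmc, seed=5)
        grouped = fit_ds(y, 2000.0, group_sizes=np.full(y.size, 3.0),
                         settings=single_chain_mcmc, seed=5)
        assert grouped.flat("n_hat").mean() == pytest.approx(
            3.0 * base.flat("n_hat").mean(), rel=1e-9)


class TestFitMRDS:
    def test_saturated_recapture_pins_g0_near_one(self, fast_mcmc):
        sightings = two_team_sightings(300, W=4000.0, sigma=1500.0,
                                       g0_team1=1.0, g0_team2=1.0, seed=0)
        # force every whale seen by both teams into a duplicate pair
        fit = fit_mrds(sightings, W=4000.0, settings=fast_mcmc, seed=1)
        assert fit.flat("g0").mean() > 0.93

    def test_recovers_g0(self, fast_mcmc):
        sightings = two_team_sightings(500, W=4000.0, sigma=1500.0,
                                       g0_team1=0.8, g0_team2=0.8, seed=2)
        fit = fit_mrds(sightings, W=4000.0, settings=fast_mcmc, seed=3)
        combined_true = 1 - 0.2 * 0.2
        assert abs(fit.flat("g0").mean() - combined_true) < 0.1

    def test_phat_identity(self, fast_mcmc):
        # p-hat = g(0) * esw / W draw-wise
        sightings = two_team_sightings(300, W=4000.0, sigma=1500.0,
                                       g0_team1=0.9, g0_team2=0.7, seed=4)
        fit = fit_mrds(sightings, W=4000.0, settings=fast_mcmc, seed=5)
        np.testing.assert_allclose(
            fit.flat("p_hat"),
            fit.flat("g0") * fit.flat("esw") / fit.W, rtol=1e-10)

    def test_no_duplicates_is_unidentifiable(self):
        from pamvlt import VisualSighting
        sightings = [VisualSighting("a", 1, 100.0),
                     VisualSighting("b", 2, 200.0)]
        with pytest.raises(EstimationError, match="g\\(0\\)"):
            fit_mrds(sightings, W=1000.0)

    def test_one_team_rejected(self):
        from pamvlt import VisualSighting
        with pytest.raises(EstimationError, match="both teams"):
            fit_mrds([VisualSighting("a", 1, 100.0)], W=1000.0)


class TestApplyAvailability:
    def _fake_fit(self, draws):
        from pamvlt.detection import DSFit
        arr = np.asarray(draws, float).reshape(1, -1)
        return DSFit(form="half_normal", W=1000.0, n_obs=10, param_draws={},
                     esw_draws=arr, p_hat_draws=arr / 1000.0,
                     n_hat_draws=arr, g0_draws=np.ones_like(arr))

    def test_unit_availability_is_identity(self):
        fit = self._fake_fit([100.0, 110.0, 90.0])
        out = apply_availability(fit, np.ones(3))
        np.testing.assert_allclose(out.n_hat_draws, fit.n_hat_draws)
        assert out.label == "MRDS_AV"

    def test_half_availability_doubles_abundance(self):
        fit = self._fake_fit([100.0, 120.0])
        out = apply_availability(fit, np.full(2, 0.5))
        np.testing.assert_allclose(out.n_hat_draws, 2 * fit.n_hat_draws)

    def test_uncertain_availability_inflates_cv(self, rng):
        from pamvlt.study import posterior_cv
        n = rng.normal(400, 40, 4000)
        fit = self._fake_fit(n)
        a = rng.beta(6.1, 3.9, 4000)  # mean 0.61
        out = apply_availability(fit, a, seed=rng)
        assert posterior_cv(out.n_hat_draws) > posterior_cv(fit.n_hat_draws)

    def test_invalid_draws_rejected_with_warning(self):
        fit = self._fake_fit([100.0, 120.0])
        with pytest.warns(EstimationWarning):
            apply_availability(fit, np.array([0.5, -0.1, 1.5]))
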