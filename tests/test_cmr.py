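import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import log_expit, logsumexp

from pamvlt import (
    AcousticEvent,
    CMRParams,
    MCMCSettings,
    SurveyConfig,
    ZoneOfOverlap,
    build_bin_grid,
    derived_counts,
    detection_prob,
    fit_cmr,
    make_zone,
    persistence_prob,
    state_loglik,
    time_in_state,
)
from pamvlt.cmr import LatentStateMatrix
from pamvlt.errors import (
    ConfigurationError,
    EstimationError,
    InputError,
    InvalidStateError,
)


def _params(**kw):
    base = dict(gamma=0.3, alpha0=0.5, alphaT=-0.001, beta0=0.0, beta1=0.0,
                max_time=600.0)
    base.update(kw)
    return CMRParams(**base)


def _valid_paths(J):
    for z in itertools.product([0, 1], repeat=J):
        ones = np.flatnonzero(z)
        if ones.size == 0 or np.array_equal(
                ones, np.arange(ones[0], ones[-1] + 1)):
            yield z


class TestStateKernels:
    @pytest.mark.parametrize(
        "z,entry,j,expected",
        [([1, 1, 1], 600.0, 3, 720.0),
         ([0, 1, 1], 999.0, 3, 60.0),
         ([0, 0, 0], 999.0, 3, 0.0)],
    )
    def test_time_in_state(self, z, entry, j, expected):
        assert time_in_state(z, entry, 60.0, j) == pytest.approx(expected)

    def test_persistence_prob(self):
        assert persistence_prob(0.0, 0.0, 123.0) == pytest.approx(0.5)
        assert persistence_prob(2.0, -0.05, 40.0) == pytest.approx(0.5)
        t = np.linspace(0, 2000, 50)
        phi = persistence_prob(1.0, -0.002, t)
        assert np.all(np.diff(phi) < 0)

    def test_detection_prob(self):
        assert detection_prob(0.0, 0.0, 500.0) == pytest.approx(0.5)
        assert detection_prob(0.0, -1 / 1000, 0.0) == pytest.approx(0.5)
        assert detection_prob(0.0, -1 / 1000, 1e7) < 1e-4
        r = np.linspace(0, 8000, 50)
        assert np.all(np.diff(detection_prob(1.0, -0.001, r)) < 0)

    def test_state_loglik_direct_substitution(self):
        p = _params(gamma=0.4, alpha0=1.0, alphaT=-0.01)
        T, et = 60.0, 120.0
        phi = persistence_prob(1.0, -0.01, et + T)
        expect = np.log(0.4) + np.log(phi)
        assert state_loglik([1, 1], p, T, entry_time=et) == pytest.approx(expect)
        expect0 = 2 * np.log(0.6)
        assert state_loglik([0, 0], p, T) == pytest.approx(expect0)

    def test_reentry_rejected(self):
        with pytest.raises(InvalidStateError):
            state_loglik([1, 0, 1], _params(), 60.0)
        with pytest.raises(InvalidStateError):
            LatentStateMatrix(np.array([[1, 0, 1]]), np.zeros(1), 1, 1)

    @given(
        gamma=st.floats(0.05, 0.9),
        alpha0=st.floats(-2, 3),
        alphaT=st.floats(-0.01, 0.0),
        entry=st.floats(0, 2000),
    )
    @settings(max_examples=40, derandomize=True)
    def test_path_probabilities_sum_to_one(self, gamma, alpha0, alphaT, entry):
        """Exhaustive enumeration over valid no-re-entry paths: the state
        process is a proper probability distribution."""
        for J in (3, 4):
            p = _params(gamma=gamma, alpha0=alpha0, alphaT=alphaT)
            tot = sum(
                np.exp(state_loglik(z, p, 60.0, entry_time=entry))
                for z in _valid_paths(J)
            )
            tot += np.exp(state_loglik([0] * J, p, 60.0))  # never in state
            # _valid_paths already includes the all-zero row once
            tot -= np.exp(state_loglik([0] * J, p, 60.0))
            assert tot == pytest.approx(1.0, abs=1e-10)

    def test_bin_specific_gamma_also_normalizes(self):
        p = _params(gamma=np.array([0.2, 0.5, 0.1]))
        tot = sum(np.exp(state_loglik(z, p, 60.0, entry_time=100.0))
                  for z in _valid_paths(3))
        assert tot == pytest.approx(1.0, abs=1e-12)


class TestDerivedCounts:
    def test_hand_counted_matrix(self):
        z = np.array([[0, 1, 1, 0], [1, 1, 0, 0], [0, 0, 0, 0]])
        out = derived_counts(z, ZoneOfOverlap.full_grid(4))
        np.testing.assert_array_equal(out["F_j"], [1, 1, 0, 0])
        np.testing.assert_array_equal(out["S_j"], [0, 0, 1, 1])
        assert out["F_T"] == 2 and out["S_T"] == 2 and out["N_B"] == 2

    def test_zone_restriction(self):
        z = np.array([[0, 1, 1, 0], [1, 1, 0, 0], [0, 0, 0, 0]])
        zone = ZoneOfOverlap(1, 4, 2, 3, 2, 3)
        out = derived_counts(z, zone)
        assert out["F_T"] == 1 and out["S_T"] == 1

    def test_all_zero(self):
        out = derived_counts(np.zeros((3, 4), int), ZoneOfOverlap.full_grid(4))
        assert out["F_T"] == 0 and out["S_T"] == 0 and out["N_B"] == 0

    def test_zone_bounds_validated(self):
        with pytest.raises(ConfigurationError):
            derived_counts(np.zeros((2, 4), int), ZoneOfOverlap(1, 9, 1, 4, 1, 4))


class TestMakeZone:
    def _cfg(self, ahead=1500, behind=1500, width=150, speed=2.5):
        return SurveyConfig(1000, 1000, ahead, behind, width, speed)

    def test_zero_durations_reduce_to_visual_window(self):
        cfg = self._cfg()
        zone = make_zone(cfg, 0.0, 0.0, visual_forward_max=900.0)
        mids = build_bin_grid(cfg)
        inside = np.flatnonzero((mids >= 0) & (mids <= 900))
        assert (zone.y_min_f, zone.y_max_f) == (inside[0] + 1, inside[-1] + 1)
        assert (zone.y_min_s, zone.y_max_s) == (zone.y_min_f, zone.y_max_f)

    def test_ascent_shifts_s_zone_by_five_bins(self):
        # 5 min silent ascent at 2.5 m/s with 150 m bins = 5 bins toward
        # the bow: the whale stops clicking well ahead of where it surfaces
        cfg = self._cfg(ahead=3000)
        base = make_zone(cfg, 0.0, 0.0, visual_forward_max=900.0)
        shifted = make_zone(cfg, 0.0, 300.0, visual_forward_max=900.0)
        assert base.y_min_s - shifted.y_min_s == 5
        assert base.y_max_s - shifted.y_max_s == 5

    def test_descent_shifts_f_zone_aft(self):
        cfg = self._cfg()
        base = make_zone(cfg, 0.0, 0.0, visual_forward_max=900.0)
        shifted = make_zone(cfg, 120.0, 0.0, visual_forward_max=900.0)
        # 120 s * 2.5 m/s = 300 m = 2 bins toward the stern (larger index)
        assert shifted.y_min_f - base.y_min_f == 2

    def test_surface_interval_widens_outer_edges(self):
        cfg = self._cfg()
        base = make_zone(cfg, 0.0, 0.0, visual_forward_max=900.0)
        wide = make_zone(cfg, 0.0, 0.0, visual_forward_max=900.0,
                         surface_interval=120.0)
        assert wide.y_max_f - base.y_max_f == 2   # F zone extends aft
        assert base.y_min_s - wide.y_min_s == 2   # S zone extends forward

    def test_empty_window_warns(self):
        cfg = self._cfg()
        with pytest.warns(UserWarning, match="empty"):
            zone = make_zone(cfg, 0.0, 4000.0, visual_forward_max=900.0)
        assert zone.n_bins_s == 0


def _toy_events(config, n=6, seed=0):
    rng = np.random.default_rng(seed)
    J = config.n_bins
    events = []
    for i in range(n):
        e = rng.integers(0, J - 1)
        d = rng.integers(e, J)
        hist = np.zeros(J, int)
        hist[e: d + 1] = rng.uniform(size=d + 1 - e) < 0.8
        if hist.sum() == 0:
            hist[e] = 1
        events.append(AcousticEvent.from_perp(
            f"e{i}", float(rng.uniform(0, 800)), hist, config))
    return events


class TestFitCMR:
    def test_no_events_rejected(self, config):
        with pytest.raises(EstimationError):
            fit_cmr([], config)

    def test_m_not_larger_than_n_rejected(self, config):
        events = _toy_events(config, n=4)
        with pytest.raises(EstimationError, match="M"):
            fit_cmr(events, config, M=4)

    def test_sampler_matches_exact_enumeration(self):
        """With fixed parameters on a tiny grid, the sampler's posterior
        over the superpopulation matches the exactly enumerated one."""
        cfg = SurveyConfig(1000, 1000, 300, 0, 100, 5)
        J = cfg.n_bins
        pars = dict(gamma=0.25, alpha0=1.0, alphaT=0.0, beta0=0.5,
                    beta1=-0.001, psi=0.5)
        ev = AcousticEvent.from_perp("e1", 200.0, [0, 1, 0], cfg)
        mids = build_bin_grid(cfg)

        # exact P(augmented individual holds an in-state path), x-marginal
        xs = np.linspace(0, cfg.truncation_perp_acoustic, 2001)
        p_obj = CMRParams(**{k: v for k, v in pars.items() if k != "psi"},
                          psi=pars["psi"])
        log_w = {"out": np.log(1 - pars["psi"]),
                 "never": np.log(pars["psi"])
                 + state_loglik([0] * J, p_obj, cfg.bin_duration)}
        for e in range(J):
            for d in range(e, J):
                z = [1 if e <= j <= d else 0 for j in range(J)]
                rr = np.hypot(xs[:, None], mids[None, :])
                ll = log_expit(-(pars["beta0"] + pars["beta1"] * rr))
                tot = ll[:, e: d + 1].sum(axis=1)
                log_w[(e, d)] = (np.log(pars["psi"])
                                 + state_loglik(z, p_obj, cfg.bin_duration)
                                 + logsumexp(tot) - np.log(xs.size))
        keys = list(log_w)
        w = np.exp(np.array([log_w[k] for k in keys]))
        w /= w.sum()
        p_in = sum(wi for k, wi in zip(keys, w) if isinstance(k, tuple))
        exact = {1 + k: np.exp(np.log([1.0, 2.0, 1.0][k])
                               + k * np.log(p_in)
                               + (2 - k) * np.log1p(-p_in)) for k in range(3)}

        fit = fit_cmr([ev], cfg, M=3,
                      settings=MCMCSettings(burn_in=1500, iterations=24000,
                                            thin=3, chains=2),
                      seed=5, fix_params=pars, max_time=600)
        nb = fit.flat("N_B").astype(int)
        for k, pk in exact.items():
            assert np.mean(nb == k) == pytest.approx(pk, abs=0.03)

    def test_perfect_detection_collapses_to_observed_count(self, config):
        events = _toy_events(config, n=8, seed=3)
        fit = fit_cmr(events, config, M=20,
                      settings=MCMCSettings(burn_in=300, iterations=600,
                                            thin=3, chains=2),
                      seed=7, fix_params={"beta0": 12.0, "beta1": 0.0})
        nb = fit.flat("N_B")
        assert np.all(nb == len(events))

    def test_transition_totals_bounded_by_superpopulation(self, config):
        events = _toy_events(config, n=10, seed=4)
        fit = fit_cmr(events, config, M=25,
                      settings=MCMCSettings(burn_in=300, iterations=600,
                                            thin=3, chains=2), seed=8)
        assert np.all(fit.flat("F_T") + fit.flat("S_T")
                      <= 2 * fit.flat("N_B"))
        assert np.all(fit.flat("N_B") >= len(events))

    def test_augmentation_sufficiency(self, config):
        """Raising M beyond posterior support leaves N_B unchanged."""
        events = _toy_events(config, n=10, seed=5)
        st_ = MCMCSettings(burn_in=500, iterations=1500, thin=3, chains=2)
        nb1 = fit_cmr(events, config, M=30, settings=st_,
                      seed=9).flat("N_B").mean()
        nb2 = fit_cmr(events, config, M=60, settings=st_,
                      seed=9).flat("N_B").mean()
        assert abs(nb1 - nb2) < 1.5

    def test_bin_specific_gamma_option(self, config):
        events = _toy_events(config, n=8, seed=12)
        fit = fit_cmr(events, config, M=20, gamma_structure="per_bin",
                      settings=MCMCSettings(burn_in=300, iterations=600,
                                            thin=3, chains=2), seed=13)
        g = fit.flat("gamma")
        assert g.shape[1] == config.n_bins
        assert np.all((g > 0) & (g < 1))

    def test_z_draws_respect_no_reentry_and_match_counts(self, config):
        events = _toy_events(config, n=6, seed=6)
        zone = ZoneOfOverlap.full_grid(config.n_bins)
        fit = fit_cmr(events, config, zone, M=15,
                      settings=MCMCSettings(burn_in=200, iterations=400,
                                            thin=4, chains=2), seed=10)
        z = fit.z_draws()
        # recomputing the derived counts from z reproduces the stored ones
        out = derived_counts(z, zone)
        np.testing.assert_allclose(out["F_T"], fit.flat("F_T"))
        np.testing.assert_allclose(out["S_T"], fit.flat("S_T"))
        np.testing.assert_allclose(out["N_B"], fit.flat("N_B"))
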