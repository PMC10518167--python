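import json

import numpy as np
import pytest

from pamvlt import (
    DiveCycleParams,
    SurveyConfig,
    default_scenario,
    simulate_dataset,
    simulate_survey,
    simulate_whales,
)
from pamvlt.errors import InputError
from pamvlt.simulate import state_at, two_team_sightings
from pamvlt.survey_data import events_from_tables, read_survey


def tiny_scenario(**kw):
    """A short transect with few whales, for fast simulator checks."""
    base = dict(transect_length=24_000.0, density=3.0e-7)
    base.update(kw)
    return default_scenario(**base)


class TestSimulateWhales:
    def test_same_seed_identical_placements(self):
        sc = tiny_scenario()
        w1 = simulate_whales(sc.density, sc.config, sc.transect_length,
                             sc.dive, seed=4)
        w2 = simulate_whales(sc.density, sc.config, sc.transect_length,
                             sc.dive, seed=4)
        assert w1.equals(w2)

    def test_timeline_partitions_the_cycle(self):
        sc = tiny_scenario()
        w = simulate_whales(sc.density, sc.config, sc.transect_length,
                            sc.dive, seed=1)
        wh = w.iloc[0]
        # phase boundaries land in the right states
        eps = 1e-6
        off = -wh["phase_offset"]
        assert state_at(wh, off + eps) == "surface"
        assert state_at(wh, off + wh["t_surface"] + eps) == "descent"
        assert state_at(wh, off + wh["t_surface"] + wh["t_descent"] + eps) \
            == "vocal"
        assert state_at(wh, off + wh["cycle"] - eps) == "ascent"

    def test_zero_silent_phases_mean_submerged_is_vocal(self):
        dive = DiveCycleParams(silent_descent=0.0, silent_ascent=0.0)
        sc = tiny_scenario(dive=dive)
        w = simulate_whales(sc.density, sc.config, sc.transect_length,
                            sc.dive, seed=2)
        t = np.linspace(0.0, 4 * 3600.0, 600)
        states = {state_at(w.iloc[0], ti) for ti in t}
        assert states <= {"surface", "vocal"}

    def test_long_run_surface_fraction_matches_renewal_theory(self):
        """Time-averaged surface occupancy equals E[surface] / E[cycle]."""
        sc = tiny_scenario(density=2e-6)
        w = simulate_whales(sc.density, sc.config, sc.transect_length,
                            sc.dive, seed=3)
        rng = np.random.default_rng(0)
        times = rng.uniform(0, 1e5, size=200)
        frac = np.mean([
            state_at(wh, t) == "surface"
            for _, wh in w.iterrows() for t in times[:50]
        ])
        expected = np.mean(w["t_surface"] / w["cycle"])
        assert frac == pytest.approx(expected, abs=0.02)

    def test_empty_strip_rejected(self):
        sc = tiny_scenario()
        with pytest.raises(InputError):
            simulate_whales(sc.density, sc.config, 5000.0, sc.dive, seed=0)


class TestSimulateDetections:
    def test_saturated_visual_detection_sights_every_available_whale(self):
        sc = tiny_scenario(visual_sigma=1e9, visual_g0=1.0)
        sim = simulate_survey(sc, seed=5)
        assert len(sim.sightings) == sim.truth.n_surface_available

    def test_zero_acoustic_scale_detects_nothing(self):
        sc = tiny_scenario(acoustic_sigma=1e-9)
        sim = simulate_survey(sc, seed=6)
        assert sim.truth.n_events == 0

    def test_acoustic_detection_frequency_matches_half_normal(self):
        """Per-bin detection frequency follows the half-normal curve in
        radial distance (Monte-Carlo check on always-vocal whales)."""
        dive = DiveCycleParams(surface_duration=0.0, silent_descent=0.0,
                               silent_ascent=0.0, individual_cv=0.0)
        sc = tiny_scenario(dive=dive, density=3e-6, acoustic_sigma=3000.0)
        sim = simulate_survey(sc, seed=7)
        # every whale is one full-grid event; pool detections by radial bin
        J = sc.config.n_bins
        rad = np.concatenate([e.radial for e in sim.events])
        det = np.concatenate([e.history for e in sim.events]).astype(float)
        for lo, hi in ((0, 2000), (2000, 4000), (4000, 7000)):
            sel = (rad >= lo) & (rad < hi)
            n = sel.sum()
            if n < 50:
                continue
            p_emp = det[sel].mean()
            p_true = np.exp(-rad[sel]**2 / (2 * sc.acoustic_sigma**2)).mean()
            assert abs(p_emp - p_true) < 4 * np.sqrt(p_true * (1 - p_true) / n)

    def test_doubling_density_doubles_event_count(self):
        ratios = []
        for seed in range(12):
            n1 = simulate_survey(tiny_scenario(), seed=seed).truth.n_events
            n2 = simulate_survey(tiny_scenario(density=6.0e-7),
                                 seed=seed + 500).truth.n_events
            ratios.append((n1, n2))
        tot1 = sum(r[0] for r in ratios)
        tot2 = sum(r[1] for r in ratios)
        # Poisson thinning: totals scale linearly with density
        assert abs(tot2 - 2 * tot1) < 3 * np.sqrt(tot2 + 4 * tot1)

    def test_availability_matches_renewal_expectation(self):
        """P(surface bout overlaps the visual window) is approximately
        (window transit + mean surface bout) / mean cycle."""
        sc = default_scenario(transect_length=400_000.0, density=3.0e-7,
                              dive=DiveCycleParams(individual_cv=0.0))
        sim = simulate_survey(sc, seed=8)
        d = sc.dive
        window_s = sc.visual_forward_max / sc.config.ship_speed
        expected = (window_s + d.surface_duration) / d.cycle
        n = sim.truth.n_true
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(sim.truth.a_true - expected) < 4 * se

    def test_duplicate_ledger_subset_of_population(self):
        sim = simulate_survey(tiny_scenario(), seed=9)
        ids = set(sim.whales["whale_id"])
        assert set(sim.truth.duplicate_ids) <= ids
        assert set(sim.truth.double_diver_ids) <= ids
        assert 0.0 <= sim.truth.a_true <= 1.0


class TestSimulateDataset:
    def test_bundle_roundtrips_through_readers(self, tmp_path):
        sc = tiny_scenario()
        sim = simulate_dataset(sc, seed=10, out_dir=tmp_path)
        tables = read_survey(tmp_path)
        assert set(tables) == {"sightings", "events", "histories"}
        events = events_from_tables(tables["events"], tables["histories"],
                                    sc.config)
        assert len(events) == sim.truth.n_events
        got = {e.event_id: e for e in events}
        for ev in sim.events:
            np.testing.assert_array_equal(got[ev.event_id].history, ev.history)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["n_true"] == sim.truth.n_true
        assert truth["seed"] == 10

    def test_seeds_change_data_not_conditions(self, tmp_path):
        sc = tiny_scenario()
        s1 = simulate_dataset(sc, seed=1, out_dir=tmp_path / "a")
        s2 = simulate_dataset(sc, seed=2, out_dir=tmp_path / "b")
        assert s1.scenario == s2.scenario
        assert (s1.truth.n_true != s2.truth.n_true
                or not s1.whales.equals(s2.whales))


class TestTwoTeamSightings:
    def test_duplicate_links_are_wellformed(self):
        sightings = two_team_sightings(200, 4000.0, 1500.0, 0.9, 0.8, seed=3)
        by_dup = {}
        for s in sightings:
            if s.duplicate_id:
                by_dup.setdefault(s.duplicate_id, []).append(s.team)
        assert by_dup  # some duplicates occurred
        for teams in by_dup.values():
            assert sorted(teams) == [1, 2]
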