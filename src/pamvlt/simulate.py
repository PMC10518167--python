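"""Dive-cycle and dual-platform detection simulator.

Whales cycle deterministically through surface -> silent descent -> vocal
foraging -> silent ascent with per-whale mean phase durations (individual
variation) and a uniformly random phase at the start of the survey, fixed
horizontal positions, and a simulated maximum depth that does not affect
detection.  The ship transits a straight trackline at constant speed; a
whale's ship-relative forward distance sweeps from ahead of the grid to
behind it.  Visual availability means the whale's surface bout overlaps
the time it spends inside the visual forward window; available whales are
sighted with probability g0 * half-normal(perpendicular).  A whale vocal
during a forward-distance bin is detected that bin with probability
half-normal(radial); each vocal bout intersecting the grid that is
detected in at least one bin becomes one acoustic event, so an
interrupted-and-resumed bout yields two events (a "double diver").

The acoustic detection process is half-normal in radial distance while
the CMR model fits a logit-linear curve: that misspecification is
deliberate, so estimator checks exercise robustness rather than a
self-fulfilling data-generating model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cmr import ZoneOfOverlap, make_zone
from .errors import InputError
from .survey_data import (
    AcousticEvent,
    SurveyConfig,
    VisualSighting,
    build_bin_grid,
    write_survey,
)

__all__ = [
    "DiveCycleParams",
    "Scenario",
    "SimTruth",
    "SimulatedSurvey",
    "default_scenario",
    "reduced_scenario",
    "simulate_whales",
    "simulate_detections",
    "simulate_survey",
    "simulate_dataset",
    "scenario_zone",
    "two_team_sightings",
]


@dataclass(frozen=True)
class DiveCycleParams:
    """Mean phase durations (s) of the dive cycle and individual spread.

    Defaults describe a sperm-whale foraging cycle: ~9 min at the surface,
    ~5 min of silent descent, ~35 min of vocally active foraging and ~8 min
    of silent ascent (a ~57 min cycle), with a 15% coefficient of
    variation on each per-whale mean duration and a ~800 m typical maximum
    depth.
    """

    surface_duration: float = 9.0 * 60
    silent_descent: float = 5.0 * 60
    vocal_phase: float = 35.0 * 60
    silent_ascent: float = 8.0 * 60
    max_depth: float = 800.0
    individual_cv: float = 0.15

    def __post_init__(self) -> None:
        for name in ("surface_duration", "silent_descent", "vocal_phase",
                     "silent_ascent"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.vocal_phase <= 0:
            raise InputError("vocal_phase must be > 0")
        if self.individual_cv < 0:
            raise InputError("individual_cv must be >= 0")

    @property
    def cycle(self) -> float:
        return (self.surface_duration + self.silent_descent
                + self.vocal_phase + self.silent_ascent)


@dataclass(frozen=True)
class Scenario:
    """Full description of one simulated dual-platform survey."""

    config: SurveyConfig
    dive: DiveCycleParams
    density: float                 # whales per m^2 of surveyed strip
    transect_length: float         # ship travel distance (m)
    visual_forward_max: float      # forward window available to observers (m)
    visual_sigma: float            # half-normal scale, visual platform (m)
    acoustic_sigma: float          # half-normal scale per bin, acoustic (m)
    visual_g0: float = 1.0
    annotated_fraction: float = 0.3
    acoustic_ds_form: str = "hazard_rate"

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InputError("density must be > 0")
        if self.transect_length <= (self.config.max_forward_ahead
                                    + self.config.max_forward_behind):
            raise InputError("transect too short to traverse the bin grid")
        if not (0 < self.visual_g0 <= 1):
            raise InputError("visual_g0 must lie in (0, 1]")
        if not (0 < self.annotated_fraction <= 1):
            raise InputError("annotated_fraction must lie in (0, 1]")


def default_scenario(**overrides) -> Scenario:
    """The standard simulation-study conditions.

    A 120 km transect at 5 m/s with 300 m (one-minute) forward bins from
    6 km ahead to 3 km astern, 6 km perpendicular truncation on both
    platforms, a 4 km visual forward window, half-normal detection scales
    of 2.5 km (visual) and 3 km (acoustic per bin), g0 = 1 and a whale
    density giving ~200 animals in the strip.
    """
    config = SurveyConfig(
        truncation_perp_visual=6000.0,
        truncation_perp_acoustic=6000.0,
        max_forward_ahead=6000.0,
        max_forward_behind=3000.0,
        bin_width=300.0,
        ship_speed=5.0,
    )
    base = dict(
        config=config,
        dive=DiveCycleParams(),
        density=3.0e-7,
        transect_length=120_000.0,
        visual_forward_max=4000.0,
        visual_sigma=2500.0,
        acoustic_sigma=3000.0,
    )
    base.update(overrides)
    return Scenario(**base)


def reduced_scenario(**overrides) -> Scenario:
    """Default geometry on a short (33 km) transect: ~55 whales in strip."""
    base = dict(transect_length=33_000.0, density=3.8e-7)
    base.update(overrides)
    return default_scenario(**base)


def scenario_zone(scenario: Scenario) -> ZoneOfOverlap:
    """Zone of overlap implied by the scenario's mean dive timing."""
    return make_zone(
        scenario.config,
        silent_descent=scenario.dive.silent_descent,
        silent_ascent=scenario.dive.silent_ascent,
        visual_forward_max=scenario.visual_forward_max,
        surface_interval=scenario.dive.surface_duration,
    )


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    n_true: int
    n_surface_available: int
    a_true: float
    n_events: int
    duplicate_ids: list[int]
    double_diver_ids: list[int]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class SimulatedSurvey:
    """In-memory simulated survey bundle."""

    sightings: pd.DataFrame
    events: list[AcousticEvent]
    whales: pd.DataFrame
    truth: SimTruth
    scenario: Scenario


def _individual_means(mean: float, cv: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-whale mean durations: lognormal with unit mean and given CV."""
    if mean == 0 or cv == 0:
        return np.full(size, float(mean))
    s2 = np.log1p(cv**2)
    return mean * rng.lognormal(-s2 / 2, np.sqrt(s2), size=size)


def simulate_whales(
    density: float,
    config: SurveyConfig,
    transect_length: float,
    params: DiveCycleParams,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Place whales in the strip and draw their dive-cycle timelines.

    Whales are uniform over the strip (perpendicular within the acoustic
    truncation, along-track positioned so each fully traverses the bin
    grid); the number placed is Poisson(density x strip area).  Phase
    durations are per-whale means drawn once; the cycle phase at time
    zero is uniform, so the population is stationary in dive state.
    """
    if density <= 0:
        raise InputError("density must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lo = config.max_forward_ahead
    hi = transect_length - config.max_forward_behind
    if hi <= lo:
        raise InputError("empty strip: transect shorter than the bin grid")
    area = config.truncation_perp_acoustic * (hi - lo)
    n = int(rng.poisson(density * area))
    t_surf = _individual_means(params.surface_duration, params.individual_cv,
                               n, rng)
    t_desc = _individual_means(params.silent_descent, params.individual_cv,
                               n, rng)
    t_voc = _individual_means(params.vocal_phase, params.individual_cv, n, rng)
    t_asc = _individual_means(params.silent_ascent, params.individual_cv,
                              n, rng)
    cycle = t_surf + t_desc + t_voc + t_asc
    return pd.DataFrame({
        "whale_id": np.arange(n),
        "perp": rng.uniform(0, config.truncation_perp_acoustic, size=n),
        "along": rng.uniform(lo, hi, size=n),
        "t_surface": t_surf,
        "t_descent": t_desc,
        "t_vocal": t_voc,
        "t_ascent": t_asc,
        "cycle": cycle,
        "phase_offset": rng.uniform(0, cycle),
        "max_depth": _individual_means(params.max_depth,
                                       params.individual_cv, n, rng),
    })


def _phase_overlap(t0: np.ndarray, t1: np.ndarray, offset: float,
                   cycle: float, lo: float, hi: float) -> np.ndarray:
    """Does cyclic phase position enter [lo, hi) during [t0, t1)?

    Phase position at time t is (t + offset) mod cycle; the state
    timeline partitions the cycle exactly, so [lo, hi) is one phase band.
    """
    if hi <= lo:
        return np.zeros_like(np.asarray(t0), dtype=bool)
    dur = np.asarray(t1) - np.asarray(t0)
    p0 = np.mod(np.asarray(t0) + offset, cycle)
    in_phase = (p0 >= lo) & (p0 < hi)
    gap = np.mod(lo - p0, cycle)
    return in_phase | (gap < dur)


def state_at(whale: pd.Series, t: float) -> str:
    """Dive state of one whale at time t (timeline partitions the cycle)."""
    p = (t + whale["phase_offset"]) % whale["cycle"]
    s, d, v = whale["t_surface"], whale["t_descent"], whale["t_vocal"]
    if p < s:
        return "surface"
    if p < s + d:
        return "descent"
    if p < s + d + v:
        return "vocal"
    return "ascent"


def simulate_detections(
    whales: pd.DataFrame,
    scenario: Scenario,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, list[AcousticEvent], SimTruth]:
    """Run the ship past the whales and apply both detection processes."""
    if scenario.visual_sigma <= 0 or scenario.acoustic_sigma < 0:
        raise InputError("detection scales must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cfg = scenario.config
    v = cfg.ship_speed
    J = cfg.n_bins
    mids = build_bin_grid(cfg)
    T = cfg.bin_duration
    upper_edges = cfg.max_forward_ahead - np.arange(J) * cfg.bin_width

    sightings = []
    events: list[AcousticEvent] = []
    duplicate_ids: list[int] = []
    double_divers: list[int] = []
    n_avail = 0

    for _, wh in whales.iterrows():
        s_al, perp = wh["along"], wh["perp"]
        cyc, off = wh["cycle"], wh["phase_offset"]
        s, d, vv = wh["t_surface"], wh["t_descent"], wh["t_vocal"]

        # visual availability: surface bout overlapping the forward window
        t_win0 = (s_al - scenario.visual_forward_max) / v
        t_win1 = s_al / v
        available = bool(_phase_overlap(np.array([t_win0]),
                                        np.array([t_win1]),
                                        off, cyc, 0.0, s)[0])
        sighted = False
        if available:
            n_avail += 1
            p_see = (scenario.visual_g0
                     * np.exp(-perp**2 / (2 * scenario.visual_sigma**2)))
            sighted = rng.uniform() < p_see
            if sighted:
                sightings.append({
                    "sighting_id": f"V{int(wh['whale_id'])}",
                    "team": 1,
                    "perp_distance_m": perp,
                    "group_size": 1,
                    "duplicate_id": "",
                    "whale_id": int(wh["whale_id"]),
                })

        # acoustic: vocal indicator per forward bin, then per-bin detection
        t_bins0 = (s_al - upper_edges) / v
        z_true = _phase_overlap(t_bins0, t_bins0 + T, off, cyc,
                                s + d, s + d + vv)
        vocal_any = z_true.any()
        radials = np.hypot(perp, mids)
        p_det = np.exp(-radials**2 / (2 * scenario.acoustic_sigma**2)) \
            if scenario.acoustic_sigma > 0 else np.zeros(J)
        Y = z_true & (rng.uniform(size=J) < p_det)

        # one event per contiguous vocal bout with >= 1 detected bin
        idx = np.flatnonzero(z_true)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1) \
            if idx.size else []
        n_ev_whale = 0
        for run in runs:
            if Y[run].any():
                hist = np.zeros(J, dtype=int)
                hist[run] = Y[run]
                events.append(AcousticEvent(
                    event_id=f"A{int(wh['whale_id'])}_{n_ev_whale}",
                    perp_distance=float(perp),
                    history=hist,
                    radial=radials,
                ))
                n_ev_whale += 1
        if len(runs) >= 2:
            double_divers.append(int(wh["whale_id"]))
        if available and vocal_any:
            duplicate_ids.append(int(wh["whale_id"]))

    # annotated subset: a seeded simple random sample of events
    n_ev = len(events)
    if n_ev:
        n_annot = max(1, int(round(scenario.annotated_fraction * n_ev)))
        annotated = set(rng.choice(n_ev, size=n_annot, replace=False))
        for k, ev in enumerate(events):
            ev.fully_annotated = k in annotated

    sightings_df = pd.DataFrame(
        sightings, columns=["sighting_id", "team", "perp_distance_m",
                            "group_size", "duplicate_id", "whale_id"])
    n_true = len(whales)
    truth = SimTruth(
        n_true=n_true,
        n_surface_available=n_avail,
        a_true=n_avail / n_true if n_true else np.nan,
        n_events=n_ev,
        duplicate_ids=duplicate_ids,
        double_diver_ids=double_divers,
        seed=-1,
    )
    return sightings_df, events, truth


def simulate_survey(scenario: Scenario, seed: int = 0) -> SimulatedSurvey:
    """Simulate one full dual-platform survey with truth bookkeeping."""
    rng = np.random.default_rng(seed)
    whales = simulate_whales(scenario.density, scenario.config,
                             scenario.transect_length, scenario.dive, rng)
    sightings, events, truth = simulate_detections(whales, scenario, rng)
    truth.seed = seed
    return SimulatedSurvey(sightings=sightings, events=events, whales=whales,
                           truth=truth, scenario=scenario)


def simulate_dataset(
    scenario: Scenario, seed: int, out_dir: str | Path
) -> SimulatedSurvey:
    """Simulate a survey and write it as a survey bundle directory.

    Emits ``sightings.csv``, ``events.csv``, ``histories.csv`` (schemas
    identical to the survey_data readers, so the estimators run on them
    unmodified) and ``truth.json``.
    """
    sim = simulate_survey(scenario, seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events_df = pd.DataFrame({
        "event_id": [e.event_id for e in sim.events],
        "perp_distance_m": [e.perp_distance for e in sim.events],
        "fully_annotated": [e.fully_annotated for e in sim.events],
    })
    J = scenario.config.n_bins
    hist_df = pd.DataFrame(
        {"event_id": [e.event_id for e in sim.events]}
        | {f"bin_{j + 1}": [int(e.history[j]) for e in sim.events]
           for j in range(J)})
    write_survey({"sightings": sim.sightings.drop(columns=["whale_id"]),
                  "events": events_df, "histories": hist_df}, out_dir)
    sim.truth.to_json(out_dir / "truth.json")
    return sim


def two_team_sightings(
    n_whales: int,
    W: float,
    sigma: float,
    g0_team1: float,
    g0_team2: float,
    seed: int | np.random.Generator = 0,
) -> list[VisualSighting]:
    """Two independent teams sighting surfaced whales (for MRDS fits).

    Each team detects a whale at perpendicular distance x with probability
    g0_t * exp(-x^2 / (2 sigma^2)); whales seen by both get a shared
    duplicate link.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = rng.uniform(0, W, size=n_whales)
    shape = np.exp(-x**2 / (2 * sigma**2))
    d1 = rng.uniform(size=n_whales) < g0_team1 * shape
    d2 = rng.uniform(size=n_whales) < g0_team2 * shape
    out: list[VisualSighting] = []
    for i in range(n_whales):
        if not (d1[i] or d2[i]):
            continue
        dup = f"D{i}" if (d1[i] and d2[i]) else None
        if d1[i]:
            out.append(VisualSighting(f"S{i}a", 1, float(x[i]),
                                      duplicate_id=dup))
        if d2[i]:
            out.append(VisualSighting(f"S{i}b", 2, float(x[i]),
                                      duplicate_id=dup))
    return out
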