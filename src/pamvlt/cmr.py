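"""State-space Jolly-Seber capture-mark-recapture model for click trains.

A whale tracked by the towed array yields a binary capture history over
forward-distance bins.  The latent state z[i, j] = 1 says whale i is below
the surface, vocally foraging, in bin j.  Whales enter the foraging state
at most once inside the survey window (a whale that stops clicking and
later re-dives is treated as a new individual, which is exactly how the
event-building step fragments it), persist with a probability that decays
with time already spent foraging (logit-linear), and are detected per bin
with a probability that declines with radial distance (logit-linear).
Parameter-expanded data augmentation adds M - n all-zero pseudo-individuals
so never-detected whales are estimated inside the MCMC.

The sampler is Metropolis-within-Gibbs.  Because a no-re-entry state path
is fully described by its (entry bin, exit bin) pair, each individual's
path is Gibbs-sampled by exhaustive enumeration over the O(J^2) pairs
(vectorized across individuals), which mixes far better than single-site
flips; entry probabilities and the inclusion probability are conjugate
Beta updates; the persistence/detection coefficients, pre-window foraging
times and augmented perpendicular distances move by adaptive random walks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from ._mcmc import MCMCSettings, summarize_draws
from .errors import (
    ConfigurationError,
    ConvergenceWarning,
    EstimationError,
    InputError,
    InvalidStateError,
)
from .survey_data import AcousticEvent, SurveyConfig, build_bin_grid

__all__ = [
    "CMRParams",
    "LatentStateMatrix",
    "ZoneOfOverlap",
    "CMRFit",
    "time_in_state",
    "persistence_prob",
    "detection_prob",
    "state_loglik",
    "derived_counts",
    "make_zone",
    "fit_cmr",
]

DEFAULT_MAX_TIME = 35.0 * 60.0  # vocal foraging phase of ~35 min, in seconds


@dataclass
class CMRParams:
    """Parameters of the dive-state CMR model.

    ``gamma`` may be a scalar (bin-constant entry probability) or a
    length-J vector; ``alpha0``/``alphaT`` set the logit-linear persistence
    in the foraging state as a function of time already spent foraging;
    ``beta0``/``beta1`` set the logit-linear per-bin detection probability
    as a function of radial distance; ``max_time`` bounds the uniform prior
    on the foraging time already accrued when a whale enters bin 1; ``psi``
    is the data-augmentation inclusion probability.
    """

    gamma: float | np.ndarray
    alpha0: float
    alphaT: float
    beta0: float
    beta1: float
    max_time: float = DEFAULT_MAX_TIME
    psi: float = 0.5

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if np.any((g < 0) | (g > 1)):
            raise InputError("gamma entries must lie in [0, 1]")
        if self.max_time <= 0:
            raise InputError("max_time must be > 0")
        if not (0 < self.psi < 1):
            raise InputError("psi must lie in (0, 1)")

    def gamma_vector(self, J: int) -> np.ndarray:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if g.size == 1:
            return np.full(J, g[0])
        if g.size != J:
            raise InputError(f"gamma vector must have length {J}")
        return g


@dataclass
class LatentStateMatrix:
    """Augmented M x J matrix of below-surface indicators."""

    z: np.ndarray
    entry_time: np.ndarray
    M: int
    n: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=int)
        self.entry_time = np.asarray(self.entry_time, dtype=float)
        if self.z.shape[0] != self.M or self.entry_time.shape[0] != self.M:
            raise InputError("z and entry_time must have M rows")
        if self.M < self.n:
            raise InputError("M must be >= n")
        for row in self.z:
            _validate_single_run(row)


def _validate_single_run(z_row: np.ndarray) -> None:
    """Raise unless the row is all-zero or a single contiguous run of 1s."""
    z = np.asarray(z_row, dtype=int)
    if not np.isin(z, (0, 1)).all():
        raise InvalidStateError("state entries must be 0 or 1")
    ones = np.flatnonzero(z)
    if ones.size and not np.array_equal(ones, np.arange(ones[0], ones[-1] + 1)):
        raise InvalidStateError(
            "state path re-enters the foraging state (pattern ...1,0,1...)"
        )


@dataclass(frozen=True)
class ZoneOfOverlap:
    """Bin-index bounds (1-based, inclusive) for the derived quantities.

    ``y_min``/``y_max`` bound the superpopulation count N_B; the F pair
    bounds the entry total F_T; the S pair bounds the surfacing total S_T.
    An empty zone is encoded as (min, max) = (1, 0).
    """

    y_min: int
    y_max: int
    y_min_f: int
    y_max_f: int
    y_min_s: int
    y_max_s: int

    def validate(self, J: int) -> None:
        for lo, hi, name in ((self.y_min, self.y_max, "N_B"),
                             (self.y_min_f, self.y_max_f, "F"),
                             (self.y_min_s, self.y_max_s, "S")):
            if lo > hi:
                continue  # explicitly empty zone
            if not (1 <= lo <= hi <= J):
                raise ConfigurationError(
                    f"{name} zone bounds ({lo}, {hi}) outside 1..{J}"
                )

    @property
    def n_bins_f(self) -> int:
        return max(0, self.y_max_f - self.y_min_f + 1)

    @property
    def n_bins_s(self) -> int:
        return max(0, self.y_max_s - self.y_min_s + 1)

    @classmethod
    def full_grid(cls, J: int) -> "ZoneOfOverlap":
        return cls(1, J, 1, J, 1, J)


def time_in_state(
    z_row: Sequence[int], entry_time: float, bin_duration: float, j: int
) -> float:
    """Foraging time already accrued by a whale when it enters bin j.

    The pre-window time ``entry_time`` counts only when the whale is
    already in state in bin 1; each in-state bin strictly before j adds one
    bin duration.  ``j`` is 1-based.
    """
    z = np.asarray(z_row, dtype=int)
    if not 1 <= j <= z.size:
        raise InputError(f"bin index {j} outside 1..{z.size}")
    return float(entry_time * z[0] + bin_duration * z[: j - 1].sum())


def persistence_prob(alpha0: float, alphaT: float, time: float):
    """P(remain in the foraging state), logit-linear in time in state."""
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise InputError("time in state must be >= 0")
    out = expit(alpha0 + alphaT * t)
    return float(out) if out.ndim == 0 else out


def detection_prob(beta0: float, beta1: float, radial):
    """Per-bin acoustic detection probability, logit-linear in radial distance."""
    r = np.asarray(radial, dtype=float)
    if np.any(r < 0):
        raise InputError("radial distance must be >= 0")
    out = expit(beta0 + beta1 * r)
    return float(out) if out.ndim == 0 else out


def state_loglik(
    z_row: Sequence[int],
    params: CMRParams,
    bin_duration: float,
    entry_time: float = 0.0,
) -> float:
    """Log-probability of one no-re-entry state path given the parameters.

    Bin 1 occupancy is a Bernoulli(gamma_1) trial; a whale not yet entered
    faces an entry trial gamma_j each later bin; a whale in state remains
    with the time-dependent persistence probability; once it exits it stays
    out.  Summing exp(state_loglik) over every valid path equals 1.
    """
    z = np.asarray(z_row, dtype=int)
    _validate_single_run(z)
    J = z.size
    gam = params.gamma_vector(J)
    ll = math.log(gam[0]) if z[0] == 1 else math.log1p(-gam[0])
    entered = z[0] == 1
    exited = False
    for j in range(2, J + 1):
        prev, cur = z[j - 2], z[j - 1]
        if exited:
            continue  # stays out with probability 1
        if prev == 1:
            t = time_in_state(z, entry_time, bin_duration, j)
            phi = persistence_prob(params.alpha0, params.alphaT, t)
            ll += math.log(phi) if cur == 1 else math.log1p(-phi)
            if cur == 0:
                exited = True
        else:
            ll += math.log(gam[j - 1]) if cur == 1 else math.log1p(-gam[j - 1])
            if cur == 1:
                entered = True
    return ll


def derived_counts(
    z: np.ndarray, zone: ZoneOfOverlap
) -> dict[str, np.ndarray]:
    """Entry/surfacing counts and the superpopulation from state draws.

    ``z`` has shape (..., M, J); leading axes are posterior draws.  With
    the convention z[i, 0] = 0, presence in bin 1 counts as an entry.
    F_T and S_T sum the per-bin counts only over their zone bounds; N_B
    counts individuals ever in state within [y_min, y_max].
    """
    z = np.asarray(z, dtype=int)
    J = z.shape[-1]
    zone.validate(J)
    zprev = np.concatenate([np.zeros(z.shape[:-1] + (1,), dtype=int),
                            z[..., :-1]], axis=-1)
    F_j = ((1 - zprev) * z).sum(axis=-2)
    S_j = (zprev * (1 - z)).sum(axis=-2)

    def _slice(vec, lo, hi):
        if lo > hi:
            return np.zeros(vec.shape[:-1])
        return vec[..., lo - 1: hi].sum(axis=-1)

    F_T = _slice(F_j, zone.y_min_f, zone.y_max_f)
    S_T = _slice(S_j, zone.y_min_s, zone.y_max_s)
    if zone.y_min > zone.y_max:
        N_B = np.zeros(z.shape[:-2])
    else:
        N_B = (z[..., zone.y_min - 1: zone.y_max].sum(axis=-1) > 0).sum(axis=-1)
    return {"F_j": F_j, "S_j": S_j, "F_T": F_T, "S_T": S_T, "N_B": N_B}


def _window_to_bins(config: SurveyConfig, lo: float, hi: float) -> tuple[int, int]:
    """1-based inclusive bin-index range whose midpoints fall in [lo, hi]."""
    mids = build_bin_grid(config)  # strictly decreasing
    inside = np.flatnonzero((mids >= lo) & (mids <= hi))
    if inside.size == 0:
        return (1, 0)
    return (int(inside[0] + 1), int(inside[-1] + 1))


def make_zone(
    config: SurveyConfig,
    silent_descent: float,
    silent_ascent: float,
    visual_forward_max: float,
    visual_forward_min: float = 0.0,
    surface_interval: float = 0.0,
    nb_window: tuple[float, float] | None = None,
) -> ZoneOfOverlap:
    """Derive the zone of overlap from dive timing and the visual window.

    The visual window [visual_forward_min, visual_forward_max] is the band
    of forward distances (m, ahead of the ship) over which a surfaced whale
    is available to the visual teams.  A whale seen there enters the vocal
    state one silent-descent later, by which time the ship has advanced, so
    candidate entries sit aft of the window by the silent-descent distance;
    symmetrically a whale that stops clicking surfaces into view one
    silent-ascent later, so candidate exits sit ahead of the window by the
    silent-ascent distance.  Passing the mean surface-bout duration widens
    each zone on its outer side, because a surface bout that merely
    straddles a window edge still puts the whale on view.  Durations are in
    seconds and are converted with the configured ship speed.

    An empty zone (shift pushes the window off the grid) is returned with
    a warning rather than an error.
    """
    if silent_descent < 0 or silent_ascent < 0 or surface_interval < 0:
        raise InputError("durations must be >= 0")
    if visual_forward_max < visual_forward_min:
        raise ConfigurationError("visual window bounds out of order")
    v = config.ship_speed
    d_desc = silent_descent * v
    d_asc = silent_ascent * v
    d_surf = surface_interval * v

    f_lo, f_hi = _window_to_bins(
        config, visual_forward_min - d_surf - d_desc, visual_forward_max - d_desc
    )
    s_lo, s_hi = _window_to_bins(
        config, visual_forward_min + d_asc, visual_forward_max + d_asc + d_surf
    )
    if nb_window is None:
        b_lo, b_hi = 1, config.n_bins
    else:
        b_lo, b_hi = _window_to_bins(config, nb_window[0], nb_window[1])
    zone = ZoneOfOverlap(b_lo, b_hi, f_lo, f_hi, s_lo, s_hi)
    if zone.n_bins_f == 0 or zone.n_bins_s == 0:
        warnings.warn("zone of overlap is empty after the silent-phase shift",
                      UserWarning)
    zone.validate(config.n_bins)
    return zone


@dataclass
class CMRFit:
    """Posterior draws and diagnostics of the dive-state CMR fit.

    Scalar draw arrays have shape (chains, draws); per-bin arrays
    (chains, draws, J); per-individual path draws (chains, draws, M) with
    entry/exit bins 0-based and -1 for individuals carrying no path.
    """

    draws: dict[str, np.ndarray]
    config: SurveyConfig
    zone: ZoneOfOverlap
    M: int
    n: int
    rhat: dict[str, float]
    converged: bool
    ppc: dict[str, np.ndarray]
    max_time: float

    def flat(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def z_draws(self) -> np.ndarray:
        """Reconstruct latent-state draws, shape (total draws, M, J)."""
        e = self.flat("entry").astype(int)
        d = self.flat("exit").astype(int)
        J = self.config.n_bins
        cols = np.arange(J)
        has = e >= 0
        z = (has[:, :, None]
             & (cols[None, None, :] >= e[:, :, None])
             & (cols[None, None, :] <= d[:, :, None]))
        return z.astype(np.uint8)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("alpha0", "alphaT", "beta0", "beta1", "psi",
                     "gamma_mean", "N_B", "F_T", "S_T"):
            s = summarize_draws(self.flat(name))
            s["parameter"] = name
            s["rhat"] = self.rhat.get(name, np.nan)
            rows.append(s)
        return pd.DataFrame(rows)[
            ["parameter", "mean", "sd", "cv", "lo95", "hi95", "rhat"]
        ]


def _prepare_events(
    events: Sequence[AcousticEvent], config: SurveyConfig
) -> tuple[np.ndarray, np.ndarray]:
    J = config.n_bins
    Y = np.zeros((len(events), J), dtype=np.int8)
    perp = np.zeros(len(events))
    for i, ev in enumerate(events):
        if ev.history.size != J:
            raise InputError(
                f"event {ev.event_id}: history length {ev.history.size} != J={J}"
            )
        Y[i] = ev.history
        perp[i] = ev.perp_distance
    return Y, perp


def fit_cmr(
    events: Sequence[AcousticEvent],
    config: SurveyConfig,
    zone: ZoneOfOverlap | None = None,
    M: int | None = None,
    settings: MCMCSettings | None = None,
    seed: int | np.random.Generator = 0,
    gamma_structure: str = "constant",
    max_time: float = DEFAULT_MAX_TIME,
    prior_sd: float = 10.0,
    fix_params: dict[str, float] | None = None,
) -> CMRFit:
    """Fit the Jolly-Seber dive-state model to acoustic capture histories.

    Parameters
    ----------
    events
        Observed events with full-length histories and radial vectors.
    zone
        Bin bounds for the derived quantities; defaults to the full grid.
    M
        Augmented population size (observed n plus pseudo-individuals).
    gamma_structure
        "constant" shares one entry probability across bins; "per_bin"
        gives each bin its own Beta(1, 1)-prior entry probability.
    fix_params
        Optional name -> value map fixing any of alpha0, alphaT, beta0,
        beta1, psi, gamma (their updates are skipped; used for validation
        against exhaustive enumeration on tiny problems).
    """
    n = len(events)
    if n == 0:
        raise EstimationError("no acoustic events: cannot fit the CMR model")
    J = config.n_bins
    if M is None:
        M = max(2 * n, n + 20)
    if M <= n:
        raise EstimationError(f"augmented size M={M} must exceed n={n}")
    settings = settings or MCMCSettings()
    if zone is None:
        zone = ZoneOfOverlap.full_grid(J)
    zone.validate(J)
    if gamma_structure not in ("constant", "per_bin"):
        raise InputError("gamma_structure must be 'constant' or 'per_bin'")
    fix = dict(fix_params or {})

    master = (seed if isinstance(seed, np.random.Generator)
              else np.random.default_rng(seed))
    chain_seeds = master.integers(0, 2**31 - 1, size=settings.chains)

    Y_obs, perp_obs = _prepare_events(events, config)
    mids = build_bin_grid(config)
    T = config.bin_duration
    W_ac = config.truncation_perp_acoustic

    Y = np.zeros((M, J), dtype=np.int8)
    Y[:n] = Y_obs
    det_any = Y.any(axis=1)
    first = np.where(det_any, Y.argmax(axis=1), J)          # e <= first
    last = np.where(det_any, J - 1 - Y[:, ::-1].argmax(axis=1), -1)  # d >= last
    obs_counts = Y[:n].sum(axis=0).astype(float)

    # option table: 0 = OUT, 1 = NEVER, then all (e, d) pairs with e <= d
    es, ds = np.triu_indices(J)
    P2 = es.size
    OPT_OUT, OPT_NEVER, OPT0 = 0, 1, 2
    e0_cols = OPT0 + np.flatnonzero(es == 0)        # pair options with e == 0
    pair_feasible = ((es[None, :] <= first[:, None])
                     & (ds[None, :] >= last[:, None]))     # (M, P2)
    is_aug = np.arange(M) >= n

    kvals = np.arange(1, J + 1, dtype=float)  # within-window foraging steps
    # pivot points for the decorrelating slope proposals (fixed constants)
    t_center = 0.5 * max_time + 0.5 * J * T
    r_center = float(np.mean(np.hypot(perp_obs[:, None], mids[None, :])))

    chains_out: list[dict[str, np.ndarray]] = []
    for c in range(settings.chains):
        rng = np.random.default_rng(chain_seeds[c])

        # ---- initial values (overdispersed across chains) ----
        alpha0 = fix.get("alpha0", rng.normal(1.0, 1.0))
        alphaT = fix.get("alphaT", rng.normal(0.0, 0.5) / max_time)
        beta0 = fix.get("beta0", rng.normal(0.0, 1.0))
        beta1 = fix.get("beta1", -abs(rng.normal(1.0, 0.5)) / max(W_ac, 1.0))
        psi = fix.get("psi", rng.uniform(0.3, 0.7))
        if "gamma" in fix:
            gamma = np.atleast_1d(np.asarray(fix["gamma"], float))
            gamma = np.full(J, gamma[0]) if gamma.size == 1 else gamma.copy()
        else:
            gamma = np.full(J, rng.uniform(0.05, 0.3))
        time1 = rng.uniform(0, max_time, size=M)
        perp = np.concatenate([perp_obs, rng.uniform(0, W_ac, size=M - n)])
        R = np.hypot(perp[:, None], mids[None, :])

        entry = np.where(det_any, first, -1)
        exit_ = np.where(det_any, last, -1)
        status = np.where(det_any, 2, 0)  # 0 OUT, 1 NEVER, 2 path

        scales = {"alpha0": 0.3, "alphaT": 0.5 / max_time,
                  "beta0": 0.3, "beta1": 0.5 / max(W_ac, 1.0)}
        acc = {k: 0 for k in scales}
        t1_scale = 0.2 * max_time
        x_scale = 0.2 * W_ac

        n_keep = settings.n_draws_per_chain
        rec = {
            "alpha0": np.empty(n_keep), "alphaT": np.empty(n_keep),
            "beta0": np.empty(n_keep), "beta1": np.empty(n_keep),
            "psi": np.empty(n_keep), "gamma_mean": np.empty(n_keep),
            "gamma": np.empty((n_keep, J)),
            "N_B": np.empty(n_keep), "F_T": np.empty(n_keep),
            "S_T": np.empty(n_keep),
            "F_j": np.empty((n_keep, J)), "S_j": np.empty((n_keep, J)),
            "n_included": np.empty(n_keep),
            "entry": np.empty((n_keep, M), dtype=np.int16),
            "exit": np.empty((n_keep, M), dtype=np.int16),
            "ppc_expected": np.empty((n_keep, J)),
            "ppc_replicate": np.empty((n_keep, J)),
        }
        kept = 0
        n_total = settings.burn_in + settings.iterations

        def _persist_loglik(a0, aT):
            """Persistence/exit log-likelihood over current paths."""
            sel = status == 2
            if not sel.any():
                return 0.0
            e_s, d_s = entry[sel], exit_[sel]
            base = np.where(e_s == 0, time1[sel], 0.0)
            m = d_s - e_s
            cs = np.concatenate([[0], np.cumsum(m)])
            k = (np.arange(cs[-1]) - np.repeat(cs[:-1], m) + 1).astype(float)
            t_cont = np.repeat(base, m) + k * T
            ll = log_expit(a0 + aT * t_cont).sum()
            hx = d_s < J - 1
            t_exit = base[hx] + (m[hx] + 1) * T
            ll += log_expit(-(a0 + aT * t_exit)).sum()
            return float(ll)

        def _detect_loglik(b0, b1):
            """Detection log-likelihood over in-state bins of current paths."""
            sel = status == 2
            if not sel.any():
                return 0.0
            cols = np.arange(J)
            mask = ((cols[None, :] >= entry[sel, None])
                    & (cols[None, :] <= exit_[sel, None]))
            eta = b0 + b1 * R[sel]
            ll = np.where(mask,
                          Y[sel] * log_expit(eta)
                          + (1 - Y[sel]) * log_expit(-eta), 0.0)
            return float(ll.sum())

        for it in range(n_total):
            # ---- per-individual path update by exhaustive enumeration ----
            eta = beta0 + beta1 * R
            lp, lq = log_expit(eta), log_expit(-eta)
            llik1 = Y * lp + (1 - Y) * lq
            C1 = np.concatenate(
                [np.zeros((M, 1)), np.cumsum(llik1, axis=1)], axis=1)
            det_pairs = C1[:, ds + 1] - C1[:, es]

            lg = np.log(np.clip(gamma, 1e-300, 1.0))
            l1mg = np.log1p(-np.clip(gamma, 0.0, 1 - 1e-15))
            cum1mg = np.concatenate([[0.0], np.cumsum(l1mg)])

            # shared (e >= 1) persistence chain: time = (j - e) * T
            logphi_off = log_expit(alpha0 + alphaT * kvals * T)
            log1mphi_off = log_expit(-(alpha0 + alphaT * kvals * T))
            cumphi = np.concatenate([[0.0], np.cumsum(logphi_off)])
            gamma_part = cum1mg[es] + lg[es]
            prior_pairs = gamma_part + cumphi[ds - es]
            has_exit = ds < J - 1
            prior_pairs[has_exit] += log1mphi_off[(ds - es)[has_exit]]

            logW = np.full((M, OPT0 + P2), -np.inf)
            lpsi = math.log(psi) if psi > 0 else -np.inf
            l1psi = math.log1p(-psi) if psi < 1 else -np.inf
            logW[is_aug, OPT_OUT] = l1psi
            logW[is_aug, OPT_NEVER] = lpsi + cum1mg[J]
            pair_block = lpsi + prior_pairs[None, :] + det_pairs

            # e == 0 paths carry the individual's pre-window foraging time
            t1 = alpha0 + alphaT * (time1[:, None] + kvals[None, :] * T)
            cnt1 = np.concatenate(
                [np.zeros((M, 1)), np.cumsum(log_expit(t1), axis=1)], axis=1)
            d0 = ds[es == 0]
            block0 = lpsi + lg[0] + cnt1[:, d0] + det_pairs[:, es == 0]
            hx0 = d0 < J - 1
            block0[:, hx0] += log_expit(-t1[:, d0[hx0]])
            pair_block[:, es == 0] = block0

            pair_block[~pair_feasible] = -np.inf
            logW[:, OPT0:] = pair_block

            gumb = rng.gumbel(size=logW.shape)
            choice = np.argmax(logW + gumb, axis=1)
            status = np.where(choice >= OPT0, 2, choice)
            picked = np.where(choice >= OPT0, choice - OPT0, 0)
            entry = np.where(status == 2, es[picked], -1).astype(int)
            exit_ = np.where(status == 2, ds[picked], -1).astype(int)

            # ---- conjugate updates: psi, gamma ----
            n_inc = int((status >= 1).sum())
            if "psi" not in fix:
                psi = rng.beta(1 + n_inc, 1 + M - n_inc)
            if "gamma" not in fix:
                on_path = status == 2
                n_never = int((status == 1).sum())
                if gamma_structure == "constant":
                    succ = int(on_path.sum())
                    fails = int(entry[on_path].sum()) + n_never * J
                    gamma = np.full(J, rng.beta(1 + succ, 1 + fails))
                else:
                    e_p = entry[on_path]
                    succ_j = np.bincount(e_p, minlength=J).astype(float)
                    at_risk = (np.bincount(e_p, minlength=J)[::-1].cumsum()[::-1]
                               + float(n_never))
                    gamma = rng.beta(1 + succ_j, 1 + at_risk - succ_j)

            # ---- random-walk updates: alpha, beta ----
            # slope proposals pivot about a centered covariate value so the
            # intercept/slope posterior correlation does not stall the walk
            if "alpha0" not in fix or "alphaT" not in fix:
                ll_cur = _persist_loglik(alpha0, alphaT)
                if "alpha0" not in fix:
                    prop = alpha0 + rng.normal() * scales["alpha0"]
                    ll_prop = _persist_loglik(prop, alphaT)
                    d_lp = (ll_prop - ll_cur
                            + (alpha0**2 - prop**2) / (2 * prior_sd**2))
                    if np.log(rng.uniform()) < d_lp:
                        alpha0, ll_cur = prop, ll_prop
                        acc["alpha0"] += 1
                if "alphaT" not in fix:
                    eps = rng.normal() * scales["alphaT"]
                    prop_t = alphaT + eps
                    prop_0 = alpha0 - (0.0 if "alpha0" in fix
                                       else eps * t_center)
                    ll_prop = _persist_loglik(prop_0, prop_t)
                    d_lp = (ll_prop - ll_cur
                            + (alphaT**2 - prop_t**2) / (2 * prior_sd**2)
                            + (alpha0**2 - prop_0**2) / (2 * prior_sd**2))
                    if np.log(rng.uniform()) < d_lp:
                        alphaT, alpha0, ll_cur = prop_t, prop_0, ll_prop
                        acc["alphaT"] += 1
            if "beta0" not in fix or "beta1" not in fix:
                ll_cur = _detect_loglik(beta0, beta1)
                if "beta0" not in fix:
                    prop = beta0 + rng.normal() * scales["beta0"]
                    ll_prop = _detect_loglik(prop, beta1)
                    d_lp = (ll_prop - ll_cur
                            + (beta0**2 - prop**2) / (2 * prior_sd**2))
                    if np.log(rng.uniform()) < d_lp:
                        beta0, ll_cur = prop, ll_prop
                        acc["beta0"] += 1
                if "beta1" not in fix:
                    eps = rng.normal() * scales["beta1"]
                    prop_1 = beta1 + eps
                    prop_0 = beta0 - (0.0 if "beta0" in fix
                                      else eps * r_center)
                    ll_prop = _detect_loglik(prop_0, prop_1)
                    d_lp = (ll_prop - ll_cur
                            + (beta1**2 - prop_1**2) / (2 * prior_sd**2)
                            + (beta0**2 - prop_0**2) / (2 * prior_sd**2))
                    if np.log(rng.uniform()) < d_lp:
                        beta1, beta0, ll_cur = prop_1, prop_0, ll_prop
                        acc["beta1"] += 1

            # ---- entry-time update (whales already in state at bin 1) ----
            sel0 = (status == 2) & (entry == 0)
            time1[~sel0] = rng.uniform(0, max_time, size=int((~sel0).sum()))
            if sel0.any():
                t_old = time1[sel0]
                t_new = np.abs(t_old + rng.normal(size=t_old.size) * t1_scale)
                t_new = np.where(t_new > max_time, 2 * max_time - t_new, t_new)
                t_new = np.clip(t_new, 0.0, max_time)
                d_sel = exit_[sel0]

                def _t1_ll(tv):
                    tt = alpha0 + alphaT * (tv[:, None] + kvals[None, :] * T)
                    cl = np.concatenate(
                        [np.zeros((tv.size, 1)),
                         np.cumsum(log_expit(tt), axis=1)], axis=1)
                    ll = cl[np.arange(tv.size), d_sel]
                    hx = d_sel < J - 1
                    ll = ll + np.where(
                        hx,
                        log_expit(-(alpha0 + alphaT
                                    * (tv + (d_sel + 1) * T))), 0.0)
                    return ll

                d_ll = _t1_ll(t_new) - _t1_ll(t_old)
                accept = np.log(rng.uniform(size=t_old.size)) < d_ll
                time1[sel0] = np.where(accept, t_new, t_old)

            # ---- latent perpendicular distances of augmented individuals ----
            aug_path = is_aug & (status == 2)
            off_path = is_aug & (status != 2)
            perp[off_path] = rng.uniform(0, W_ac, size=int(off_path.sum()))
            if aug_path.any():
                x_old = perp[aug_path]
                x_new = np.abs(x_old + rng.normal(size=x_old.size) * x_scale)
                x_new = np.where(x_new > W_ac, 2 * W_ac - x_new, x_new)
                cols = np.arange(J)
                mask = ((cols[None, :] >= entry[aug_path, None])
                        & (cols[None, :] <= exit_[aug_path, None]))

                def _x_ll(xv):
                    rr = np.hypot(xv[:, None], mids[None, :])
                    return np.where(
                        mask, log_expit(-(beta0 + beta1 * rr)), 0.0
                    ).sum(axis=1)

                d_ll = _x_ll(x_new) - _x_ll(x_old)
                accept = np.log(rng.uniform(size=x_old.size)) < d_ll
                perp[aug_path] = np.where(accept, x_new, x_old)
            R = np.hypot(perp[:, None], mids[None, :])

            # ---- burn-in adaptation ----
            if it < settings.burn_in and (it + 1) % 50 == 0:
                for kname in scales:
                    rate = acc[kname] / 50
                    scales[kname] *= np.exp(rate - 0.40)
                    acc[kname] = 0

            # ---- record ----
            if it >= settings.burn_in:
                jj = it - settings.burn_in
                if (jj + 1) % settings.thin == 0 and kept < n_keep:
                    on_path = status == 2
                    F_j = np.bincount(entry[on_path], minlength=J).astype(float)
                    exits = exit_[on_path]
                    surf = exits[exits < J - 1] + 1
                    S_j = np.bincount(surf, minlength=J).astype(float)
                    b_lo, b_hi = zone.y_min - 1, zone.y_max - 1
                    if zone.y_min <= zone.y_max:
                        nb = int(((entry[on_path] <= b_hi)
                                  & (exit_[on_path] >= b_lo)).sum())
                    else:
                        nb = 0

                    def _zsum(vec, lo, hi):
                        return float(vec[lo - 1: hi].sum()) if lo <= hi else 0.0

                    cols = np.arange(J)
                    zmask = ((cols[None, :] >= entry[:, None])
                             & (cols[None, :] <= exit_[:, None])
                             & on_path[:, None])
                    p_full = expit(beta0 + beta1 * R)
                    exp_j = (p_full * zmask).sum(axis=0)
                    rep_j = ((rng.uniform(size=p_full.shape) < p_full)
                             & zmask).sum(axis=0).astype(float)

                    rec["alpha0"][kept] = alpha0
                    rec["alphaT"][kept] = alphaT
                    rec["beta0"][kept] = beta0
                    rec["beta1"][kept] = beta1
                    rec["psi"][kept] = psi
                    rec["gamma_mean"][kept] = float(np.mean(gamma))
                    rec["gamma"][kept] = gamma
                    rec["N_B"][kept] = nb
                    rec["F_T"][kept] = _zsum(F_j, zone.y_min_f, zone.y_max_f)
                    rec["S_T"][kept] = _zsum(S_j, zone.y_min_s, zone.y_max_s)
                    rec["F_j"][kept] = F_j
                    rec["S_j"][kept] = S_j
                    rec["n_included"][kept] = n_inc
                    rec["entry"][kept] = entry
                    rec["exit"][kept] = exit_
                    rec["ppc_expected"][kept] = exp_j
                    rec["ppc_replicate"][kept] = rep_j
                    kept += 1
        for k in rec:
            rec[k] = rec[k][:kept]
        chains_out.append(rec)

    n_min = min(r["alpha0"].shape[0] for r in chains_out)
    draws = {
        k: np.stack([r[k][:n_min] for r in chains_out])
        for k in chains_out[0]
        if not k.startswith("ppc_")
    }
    ppc = {
        "expected": np.stack([r["ppc_expected"][:n_min] for r in chains_out]),
        "replicate": np.stack([r["ppc_replicate"][:n_min] for r in chains_out]),
        "observed": obs_counts,
    }

    from .study import gelman_rubin  # local import avoids a module cycle

    rhat = {}
    if settings.chains >= 2 and n_min >= 2:
        for name in ("alpha0", "alphaT", "beta0", "beta1", "psi",
                     "gamma_mean", "N_B", "F_T", "S_T"):
            if name in fix or (name == "gamma_mean" and "gamma" in fix):
                continue
            arr = draws[name]
            if np.ptp(arr) == 0:
                rhat[name] = 1.0
            else:
                rhat[name] = gelman_rubin(arr)
    converged = all(v < settings.rhat_threshold for v in rhat.values())
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items()
               if v >= settings.rhat_threshold}
        warnings.warn(f"CMR fit: R-hat at/above {settings.rhat_threshold} "
                      f"for {bad}", ConvergenceWarning)

    return CMRFit(draws=draws, config=config, zone=zone, M=M, n=n,
                  rhat=rhat, converged=converged, ppc=ppc, max_time=max_time)
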