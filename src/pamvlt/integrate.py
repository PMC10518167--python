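"""Combining surface and subsurface abundance into one estimate.

All three estimators share the identity N_T = N_S + N_B - N_D and define
surface availability as a_S = N_S / N_T:

* DS-DS ignores duplicates entirely (N_D = 0);
* CMR-DS takes N_B and N_D = F_T + S_T from the capture-mark-recapture
  fit's zone-of-overlap transition counts;
* Hybrid scales per-capita transition rates, estimated from an annotated
  subset of click trains, by the distance-sampling estimate of the
  subsurface abundance: F_T = N_B^(DS) * P_F * Zone_F (and likewise for
  surfacings).

Posterior combination is draw-wise arithmetic on equal-length chains;
mismatched draw counts are resampled with replacement.  Negative N_T
draws are retained (not truncated) so bias diagnostics stay honest; the
summaries report the fraction negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._mcmc import summarize_draws
from .cmr import CMRFit, ZoneOfOverlap
from .detection import DSFit
from .errors import ConfigurationError, EstimationError, EstimationWarning

__all__ = [
    "AbundanceEstimate",
    "HybridRates",
    "estimate_dsds",
    "estimate_cmrds",
    "hybrid_rates",
    "estimate_hybrid",
    "availability",
]


@dataclass
class AbundanceEstimate:
    """Draw-wise posterior of the combined abundance quantities.

    Per draw the identity n_t = n_s + n_b - n_d holds exactly and
    a_s = n_s / n_t (NaN where n_t <= 0).
    """

    method: str
    n_s: np.ndarray
    n_b: np.ndarray
    n_d: np.ndarray
    n_t: np.ndarray
    a_s: np.ndarray

    @property
    def fraction_negative(self) -> float:
        return float(np.mean(self.n_t <= 0))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, draws in (("N_S", self.n_s), ("N_B", self.n_b),
                            ("N_D", self.n_d), ("N_T", self.n_t),
                            ("a_S", self.a_s)):
            d = draws[np.isfinite(draws)]
            s = summarize_draws(d) if d.size else dict.fromkeys(
                ("mean", "sd", "cv", "lo95", "hi95"), np.nan)
            s["method"] = self.method
            s["quantity"] = name
            rows.append(s)
        df = pd.DataFrame(rows)[
            ["method", "quantity", "mean", "cv", "lo95", "hi95"]
        ]
        df.attrs["fraction_negative"] = self.fraction_negative
        return df


def _common_length(
    arrays: Sequence[np.ndarray], rng: np.random.Generator
) -> list[np.ndarray]:
    """Resample flattened draw arrays to a common length (the maximum)."""
    flats = [np.asarray(a, dtype=float).ravel() for a in arrays]
    sizes = {a.size for a in flats}
    if len(sizes) == 1:
        return flats
    warnings.warn("mismatched posterior draw counts; resampling with "
                  "replacement to the longest", EstimationWarning)
    target = max(sizes)
    return [a if a.size == target
            else rng.choice(a, size=target, replace=True) for a in flats]


def _assemble(method: str, n_s, n_b, n_d) -> AbundanceEstimate:
    n_t = n_s + n_b - n_d
    with np.errstate(divide="ignore", invalid="ignore"):
        a_s = np.where(n_t > 0, n_s / n_t, np.nan)
    return AbundanceEstimate(method=method, n_s=n_s, n_b=n_b, n_d=n_d,
                             n_t=n_t, a_s=a_s)


def estimate_dsds(
    ns_fit: DSFit,
    nb_fit: DSFit,
    seed: int | np.random.Generator = 0,
) -> AbundanceEstimate:
    """Sum independent surface and subsurface DS posteriors (N_D = 0)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_s, n_b = _common_length(
        [ns_fit.n_hat_draws, nb_fit.n_hat_draws], rng)
    return _assemble("DS-DS", n_s, n_b, np.zeros_like(n_s))


def estimate_cmrds(
    ns_fit: DSFit,
    cmr_fit: CMRFit,
    seed: int | np.random.Generator = 0,
) -> AbundanceEstimate:
    """Integrate the visual DS fit with the CMR fit's duplicate counts.

    N_B is the CMR superpopulation; N_D = F_T + S_T uses the
    zone-restricted transition totals, paired draw-wise within the CMR
    posterior.  Draws where N_D exceeds N_S + N_B are flagged; more than
    1% flagged raises an estimation warning.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_d_cmr = cmr_fit.flat("F_T") + cmr_fit.flat("S_T")
    n_b_cmr = cmr_fit.flat("N_B")
    n_s, n_b, n_d = _common_length(
        [ns_fit.n_hat_draws, n_b_cmr, n_d_cmr], rng)
    flagged = n_d > (n_s + n_b)
    if flagged.mean() > 0.01:
        warnings.warn(
            f"{100 * flagged.mean():.1f}% of draws have N_D > N_S + N_B",
            EstimationWarning,
        )
    return _assemble("CMR-DS", n_s, n_b, n_d)


@dataclass
class HybridRates:
    """Per-capita per-bin transition rates from an annotated subset.

    ``fbar``/``sbar`` are posterior means of the per-bin entry/surfacing
    counts averaged over the bins of the respective zones; ``n_b_subset``
    is the posterior-mean subset superpopulation; the per-capita rates are
    their ratios.  Draw arrays carry the full posterior for uncertainty
    propagation.
    """

    fbar: float
    sbar: float
    n_b_subset: float
    zone_f: int
    zone_s: int
    p_f_draws: np.ndarray = field(default=None, repr=False)
    p_s_draws: np.ndarray = field(default=None, repr=False)

    @property
    def p_f(self) -> float:
        return self.fbar / self.n_b_subset

    @property
    def p_s(self) -> float:
        return self.sbar / self.n_b_subset

    def __post_init__(self) -> None:
        if self.n_b_subset <= 0:
            raise EstimationError("subset superpopulation must be positive")
        if self.p_f_draws is None:
            self.p_f_draws = np.array([self.p_f])
        if self.p_s_draws is None:
            self.p_s_draws = np.array([self.p_s])


def hybrid_rates(subset_cmr_fit: CMRFit, zone: ZoneOfOverlap) -> HybridRates:
    """Per-capita entry/surfacing rates from the annotated-subset CMR fit.

    Only bins fully inside each zone enter the per-bin averages; rates are
    normalized draw-wise by the subset superpopulation, skipping draws
    with zero superpopulation (an error if no draws remain).
    """
    J = subset_cmr_fit.config.n_bins
    zone.validate(J)
    if zone.n_bins_f == 0 or zone.n_bins_s == 0:
        raise ConfigurationError("hybrid rates need non-empty F and S zones")
    F_j = subset_cmr_fit.flat("F_j")
    S_j = subset_cmr_fit.flat("S_j")
    n_b = subset_cmr_fit.flat("N_B")
    fbar_d = F_j[:, zone.y_min_f - 1: zone.y_max_f].mean(axis=1)
    sbar_d = S_j[:, zone.y_min_s - 1: zone.y_max_s].mean(axis=1)
    ok = n_b > 0
    if not ok.any():
        raise EstimationError(
            "subset superpopulation posterior is entirely at zero")
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} draw(s) with zero subset superpopulation "
            "skipped", EstimationWarning)
    return HybridRates(
        fbar=float(fbar_d[ok].mean()),
        sbar=float(sbar_d[ok].mean()),
        n_b_subset=float(n_b[ok].mean()),
        zone_f=zone.n_bins_f,
        zone_s=zone.n_bins_s,
        p_f_draws=fbar_d[ok] / n_b[ok],
        p_s_draws=sbar_d[ok] / n_b[ok],
    )


def estimate_hybrid(
    ns_fit: DSFit,
    nb_ds_fit: DSFit,
    rates: HybridRates,
    seed: int | np.random.Generator = 0,
) -> AbundanceEstimate:
    """Hybrid estimator: subset transition rates scale the DS estimate of N_B.

    ``nb_ds_fit`` must be the DS fit to *all* localized acoustic events
    (annotated or not).  Per draw F_T = N_B^(DS) * P_F * Zone_F and
    S_T = N_B^(DS) * P_S * Zone_S give N_D = F_T + S_T.
    """
    if rates.zone_f <= 0 or rates.zone_s <= 0:
        raise ConfigurationError("zone bin counts must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_s, n_b, p_f, p_s = _common_length(
        [ns_fit.n_hat_draws, nb_ds_fit.n_hat_draws,
         rates.p_f_draws, rates.p_s_draws], rng)
    n_d = n_b * (p_f * rates.zone_f + p_s * rates.zone_s)
    return _assemble("Hybrid", n_s, n_b, n_d)


def availability(estimate: AbundanceEstimate) -> np.ndarray:
    """Draw-wise surface availability a_S = N_S / N_T.

    Draws with non-positive N_T are dropped with a warning.
    """
    n_t = estimate.n_t
    ok = n_t > 0
    if not ok.any():
        raise EstimationError("no draws with positive total abundance")
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} draw(s) with N_T <= 0 dropped",
                      EstimationWarning)
    return estimate.n_s[ok] / n_t[ok]
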