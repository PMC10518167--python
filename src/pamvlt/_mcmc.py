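"""Generic adaptive random-walk Metropolis machinery used by the fits.

The samplers in this package are deliberately simple: low-dimensional
detection-function posteriors are explored with componentwise Gaussian
random walks whose step sizes are tuned during burn-in toward a ~40%
acceptance rate, after which the scales are frozen so the chain is a
valid Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["MCMCSettings", "rw_metropolis", "summarize_draws"]


@dataclass(frozen=True)
class MCMCSettings:
    """Iteration counts for an MCMC fit.

    Defaults follow the package's standard protocol: 10,000 burn-in
    iterations, 15,000 retained iterations thinned by 15, three chains,
    convergence flagged at R-hat >= 1.1.
    """

    burn_in: int = 10_000
    iterations: int = 15_000
    thin: int = 15
    chains: int = 3
    rhat_threshold: float = 1.1

    @property
    def n_draws_per_chain(self) -> int:
        return self.iterations // self.thin


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect a proposal into [lo, hi] (preserves RW symmetry)."""
    x = np.asarray(x, dtype=float)
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def rw_metropolis(
    logpost: Callable[[np.ndarray], float],
    x0: Sequence[float],
    lower: Sequence[float],
    upper: Sequence[float],
    settings: MCMCSettings,
    rng: np.random.Generator,
    init_scale: float = 0.1,
) -> np.ndarray:
    """Componentwise adaptive random-walk Metropolis within box bounds.

    Returns an array of shape (chains, n_draws_per_chain, dim).
    Proposals are reflected at the bounds, which keeps the kernel
    symmetric under a uniform-on-box prior truncation.
    """
    x0 = np.asarray(x0, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    dim = x0.size
    chains = []
    for c in range(settings.chains):
        # overdispersed starts: jitter within the box
        x = _reflect(x0 + (rng.normal(size=dim) * init_scale * (upper - lower)
                           * 0.05), lower, upper)
        lp = logpost(x)
        scales = np.full(dim, init_scale) * np.maximum(upper - lower, 1e-12) * 0.1
        draws = np.empty((settings.n_draws_per_chain, dim))
        n_total = settings.burn_in + settings.iterations
        kept = 0
        acc = np.zeros(dim)
        for it in range(n_total):
            for k in range(dim):
                prop = x.copy()
                prop[k] = _reflect(x[k] + rng.normal() * scales[k],
                                   lower[k], upper[k])
                lp_prop = logpost(prop)
                if np.log(rng.uniform()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    acc[k] += 1
            if it < settings.burn_in:
                if (it + 1) % 50 == 0:
                    rate = acc / 50
                    scales *= np.exp((rate - 0.40))
                    acc[:] = 0
            else:
                j = it - settings.burn_in
                if (j + 1) % settings.thin == 0 and kept < draws.shape[0]:
                    draws[kept] = x
                    kept += 1
        chains.append(draws[:kept])
    n = min(d.shape[0] for d in chains)
    return np.stack([d[:n] for d in chains])


def summarize_draws(draws: np.ndarray) -> dict[str, float]:
    """Posterior mean, sd, CV and central 95% interval of a 1-D draw set."""
    draws = np.asarray(draws, dtype=float).ravel()
    mean = float(np.mean(draws))
    sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if mean != 0 else np.nan,
        "lo95": float(lo),
        "hi95": float(hi),
    }
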