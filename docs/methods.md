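# Methods

`pamvlt` estimates cetacean abundance and surface availability from a
dual-platform line-transect survey: visual observers searching ahead of
the ship and a towed hydrophone array localizing vocally foraging whales
ahead of and behind it.  This note records the models, the simulator,
the numerical choices, and what the tests do and do not establish.

## Geometry and data

All positions are ship-relative.  Forward distance is signed (positive
ahead), perpendicular distance is the unsigned offset from the trackline,
and radial distance is their Euclidean combination.  The forward axis is
cut into J equal bins of width `bin_width`; bin 1 is the farthest-ahead
bin, at the maximum range of the array, and indices increase toward and
past the ship.  At constant ship speed every bin is also a fixed time
interval `bin_duration = bin_width / ship_speed` (the case protocol of
one-minute bins at ~5 m/s corresponds to the 300 m default).  A click
train becomes a binary capture history over this grid: 1 when at least
one click fell in a bin, with time converted to forward distance from
the first click's position and the ship speed, boundary clicks assigned
to the farther-ahead bin, and out-of-grid clicks dropped with a logged
count.  Whales are treated as horizontally stationary over an event.

## Detection models (distance sampling)

Surface abundance N_S and subsurface abundance N_B each come from the
canonical line-transect estimator.  The mean detection probability over
the truncated strip [0, W] is `p = g(0) * ESW / W` with
`ESW = integral of g(y) dy`; g is half-normal
(`exp(-y^2 / 2 sigma^2)`) or hazard-rate (`1 - exp(-(y/sigma)^-b)`,
b > 1).  Abundance uses the binomial likelihood `n ~ Bin(N, p)` with a
discrete-uniform prior on N, whose conditional posterior is sampled
exactly: `N - n ~ NegBin(n + 1, p)` per detection-parameter draw, so
CVs and credible intervals of every derived quantity come from one
posterior.  Visual abundance is multiplied by the mean observed group
size (a switch, default on); the acoustic estimate treats events as
single animals.

Two-team visual data are fitted with a full-independence
mark-recapture model: a shared half-normal shape with team-specific
logit intercepts, `p_t(y) = g0_t * exp(-y^2 / 2 sigma^2)`.  Duplicate
sightings identify `g(0) = 1 - (1 - g0_1)(1 - g0_2)`; with zero
duplicates the fit refuses (g(0) unidentifiable).  An external
availability correction can be applied draw-wise (the MRDS_AV
estimator), propagating its uncertainty.

Priors: the scale is log-uniform on (10^-3 W, 5W).  This was chosen
over a flat prior after a calibration check with exact grid posteriors:
flat-on-(0, W) imposes a hard ceiling of ~0.856 on p (not vague), and
flat-on-(0, 5W) piles prior mass onto huge scales and biases small-sample
abundance low by ~17%; the log-uniform prior is calibrated (mean
estimate/truth = 1.00 over 200 synthetic surveys at n~15) and imposes no
ceiling.  Logit/log-scale parameters get Normal(0, 10^2).  Covariates on
the visual detection function are accepted in the data schema but not
modelled.

## The dive-state CMR model

The acoustic capture histories are analyzed with a state-space
Jolly-Seber model under parameter-expanded data augmentation.  Latent
z[i, j] = 1 means whale i is below the surface, vocally foraging, in bin
j.  Entry into the foraging state is a Bernoulli(gamma) trial per bin
while not yet entered (bin-constant gamma by default; per-bin available);
persistence follows `logit(phi) = alpha0 + alphaT * Time[i, j]`, where
Time accumulates one bin duration per in-state bin plus, for whales
already in state at bin 1, a pre-window time with a Uniform(0, max_time)
prior (default 35 min, the length of the vocal foraging phase).
Detection is `logit(p[i, j]) = beta0 + beta1 * R[i, j]` with R the radial
distance at the bin midpoint, and the observation model is
`Y ~ Bernoulli(p * z)`.  M - n all-zero pseudo-individuals with latent
perpendicular distances (Uniform(0, W) prior) and a Uniform(0, 1)
inclusion probability psi absorb the never-detected whales.

Re-entry is disallowed: once a whale leaves the foraging state it stays
out for the remainder of the window.  A whale that genuinely dives again
produces a second acoustic event and is handled as a new individual,
which is exactly what the duplicate accounting needs (each extra event
is cancelled by one transition count).  The printed transition kernel is
read with the persistence term conditioned on the previous state, the
standard Jolly-Seber form.

Derived per draw, with z[i, 0] = 0: per-bin entries
`F_j = sum (1 - z[i, j-1]) z[i, j]`, surfacings
`S_j = sum z[i, j-1] (1 - z[i, j])`, their zone-restricted totals F_T and
S_T, and the superpopulation N_B (individuals ever in state within the
N_B bounds, default the full grid).

### Sampler

Discrete latent states preclude gradient samplers, so the fit is
Metropolis-within-Gibbs.  Because a no-re-entry path is fully described
by its (entry bin, exit bin) pair, each individual's path is Gibbs-drawn
by exhaustive enumeration over the O(J^2) pairs plus the
"not included" and "included but never enters" options, vectorized
across individuals with cumulative-sum algebra and Gumbel-max sampling.
gamma and psi have conjugate Beta updates.  alpha and beta move by
adaptive random walks in which the slope proposal pivots about a centered
covariate value (mid-range foraging time; mean observed radial), removing
the intercept-slope correlation that otherwise stalls mixing.  Entry
times and augmented perpendicular distances move by reflected random
walks; unused ones are refreshed from their priors.  Step sizes adapt
toward ~40% acceptance during burn-in only, so the retained chain is a
valid Markov chain.  Default protocol: 10,000 burn-in, 15,000 further
iterations thinned by 15, three chains, convergence flagged at
R-hat >= 1.1 (classic potential-scale-reduction factor, cross-checked
against arviz's rank-normalized version in tests).

Correctness anchor: on tiny problems (J = 3, M = 3) with fixed
parameters, the sampler's posterior over N_B matches the exactly
enumerated marginal (latent perpendicular distances integrated
numerically) to within Monte-Carlo error, and the path prior sums to one
over all valid paths for J <= 4 (property test).

### Zone of overlap

Duplicates are whales available to both platforms, and they reveal
themselves as state transitions in specific forward-distance bands.  A
whale last seen at the surface inside the visual window starts clicking
one silent descent later, by which time the ship has advanced: candidate
entries sit aft of the window by the silent-descent distance.
Symmetrically, a whale that stops clicking surfaces one silent ascent
later: candidate exits sit ahead of the window by the silent-ascent
distance.  `make_zone` also accepts the mean surface-bout duration and
widens each zone on its outer side by it, because a surface bout that
merely straddles a window edge still puts the whale on view; with zero
durations the zones reduce to the visual window itself.  With these
zones the identity N_S + N_B - (F_T + S_T) counts every whale exactly
once in the simulator's bookkeeping (verified by the
zero-silent-phase, perfect-detection end-to-end test), including double
divers, whose extra event is cancelled by the extra transition.

## The three integrated estimators

Draw-wise on equal-length chains (resampled with replacement when
lengths differ):

* **DS-DS**: N_T = N_S + N_B^(DS), N_D = 0.  Biased high by exactly the
  duplicated whales.
* **CMR-DS**: N_T = N_S + N_B^(CMR) - (F_T + S_T), pairing the CMR
  draws of N_B and N_D.
* **Hybrid**: from an annotated subset's CMR fit, per-capita rates
  P_F = mean(F_j over F-zone bins) / n_B and P_S likewise; then
  N_D = N_B^(DS) (P_F Zone_F + P_S Zone_S) with Zone the bin counts.
  Only bins fully inside a zone enter the averages.

Surface availability is a_S = N_S / N_T per draw.  Negative N_T draws
(possible when N_D is large) are retained, not truncated, so bias
diagnostics stay honest; summaries report the fraction negative, and
draws with N_D > N_S + N_B are flagged (warning above 1%).

## Simulator

The simulator is deliberately *not* the fitted model.  Whales are
uniform over the strip; each has per-whale mean phase durations (surface
~9 min, silent descent ~5 min, vocal foraging ~35 min, silent ascent
~8 min; ~57 min cycle) drawn once with a 15% lognormal CV (individual
variation), a uniformly random cycle phase (stationarity), a fixed
horizontal position, and a simulated maximum depth that does not affect
detection.  Visual availability means the surface bout overlaps the
whale's transit of the visual forward window; available whales are
sighted with probability g0 x half-normal(perpendicular), one trial per
whale.  Acoustic detection is per bin, half-normal in *radial* distance
-- while the CMR model fits a logit-linear curve, a preserved
misspecification so the estimator checks exercise robustness.  Each
contiguous vocal bout with at least one detected bin becomes one event
(interruption and resumption inside the grid yields two events, a double
diver); a bout detected in no bin is missed entirely and left to the
augmentation.  Cycle-to-cycle variation within a whale and
localization error are not simulated; group size is 1 (the acoustic
platform provides no group sizes, a stated limitation of the framework),
so what passes here says nothing about group-size or localization-error
robustness on real data.

Default conditions: 6 km perpendicular truncation on both platforms
(equal truncations keep the two strip abundances commensurable), grid
from 6 km ahead to 3 km astern in 300 m (one-minute) bins, 4 km visual
window, half-normal scales 2.5 km (visual) and 3 km (acoustic), g0 = 1,
5 m/s ship, and a density of 3e-7 whales/m^2, giving ~200 whales and
~180 events on the default 120 km transect -- the scale of the case
study.  Under these conditions roughly half the whales are
surface-available during their window transit, so ignoring duplicates
inflates abundance by ~50%.

## Study sizes and point estimates

`run_study` simulates, fits and tabulates per replicate; replicates are
independent and deterministic given the seed.  Bias is
(estimate - truth) / truth with the posterior mean as the point estimate
(median via flag).  The package's standard study is 100 replicates of
the full scenario; the bundled acceptance checks run a reduced study --
the default conditions on a 60 km transect (~100 whales, ~90 events,
~20 sightings per replicate) with 8 replicates and shortened chains --
which reproduces the qualitative structure: DS-DS abundance bias far
above +30% with strongly negative availability bias, CMR-DS and Hybrid
within +/-10% on both quantities.  At this reduced size the posterior
mean of the ratio a_S = N_S / N_T carries a small-sample Jensen skew of
order -CV(N_S)^2 * a(1-a) (a few percent); it shrinks with sample size
and is absent from the median.

Goodness of fit uses a posterior-predictive p-value,
P(D(replicate) >= D(observed)) with a Freeman-Tukey discrepancy on
per-bin detection counts (the discrepancy is a package choice; ties
count toward the p-value).  Convergence uses the classic Gelman-Rubin
PSRF with the 1.1 threshold.

## Known limitations

Depth is simulated but never corrects detection; acoustic group size is
not modelled; localization error is ignored; silent states are handled
geometrically through the zone shifts rather than as latent classes;
the hybrid rate estimator assumes transition rates homogeneous across
bins; and the CMR detection and persistence curves are simple
logit-linear forms.  These mirror the framework's stated scope; the
simulator's misspecification test covers the detection-curve assumption
but not the others.
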