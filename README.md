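# pamvlt

Integrated abundance and availability-bias estimation from simultaneous
visual line-transect (VLT) and towed-hydrophone passive-acoustic (PAM)
surveys of deep-diving cetaceans.

## The problem

Shipboard visual surveys only see whales at the surface; a sperm whale
spends most of its ~57-minute dive cycle submerged, ~35 minutes of it
echolocating on a foraging dive.  A towed hydrophone array surveys
exactly the complement — the vocal, submerged whales — so running both
platforms at once can, in principle, count everyone and measure the
surface-availability correction *in situ* instead of borrowing it from
a handful of tagged animals.  The catch is duplicates: a whale that
surfaces into view and then dives and starts clicking (or vice versa) is
counted by both platforms.  This package implements a statistical
framework for that design, built around

    N_T = N_S + N_B − N_D        a_S = N_S / N_T

where N_S is surface abundance from distance sampling (optionally
two-team mark-recapture distance sampling, MRDS, which estimates the
trackline detection probability g(0)), N_B is subsurface abundance from
the acoustic data, N_D the duplicates, and a_S the surface availability.
Three estimators differ in how they get N_D:

* **DS-DS** — ignore duplicates (N_D = 0); the naive baseline.
* **CMR-DS** — treat each click train as a capture history over
  forward-distance bins and fit a state-space Jolly–Seber
  capture–mark–recapture model with data augmentation: latent dive
  states z, bin-wise entry probability γ, time-decaying persistence
  logit(φ) = α₀ + α_T·Time, distance-decaying detection
  logit(p) = β₀ + β₁·R.  Whales entering (F_T) or leaving (S_T) the
  vocal state inside a *zone of overlap* with the visual window are the
  duplicates: N_D = F_T + S_T.
* **Hybrid** — when only a subset of click trains can be fully
  annotated: per-capita transition rates from the subset's CMR fit scale
  the acoustic distance-sampling abundance,
  N_D = N_B^(DS)(P_F·Zone_F + P_S·Zone_S).

Everything is Bayesian (hand-rolled Metropolis-within-Gibbs; the CMR
latent paths are Gibbs-sampled by exhaustive enumeration over
entry/exit-bin pairs), so CVs and credible intervals of all derived
quantities come from one posterior.  A dive-cycle simulator with silent
descent/ascent phases, individual variation and double divers — and
half-normal detection that deliberately mismatches the fitted
logit-linear curves — provides end-to-end validation.  See
`docs/methods.md` for the full model account.

The package is a library: import it, or start from the narrative
scripts in `examples/`.

## Worked example

`python examples/05_hybrid_arithmetic.py` prints:

```
S_j = 5 whales/bin over a 10-bin zone -> N_D = 50 duplicates; N_T = 350
a_S = N_S / N_T = 306/426 = 0.72
N_S exceeds N_B by 5.9%
integrated N_T sits 17.4% below the visual-only estimate corrected with tag-based availability (516)
```

The first line is the hybrid duplicate arithmetic: an estimated five
whales surfacing per forward bin across a ten-bin zone of overlap means
fifty of the whales counted by both platforms must be subtracted.  The
remaining lines run the published case-study abundance table through the
same draw-wise machinery: combining 306 surface whales with 289
subsurface whales and 169 duplicates gives 426 whales and a surface
availability of 0.72 — close to the tag-based value of 0.61 but derived
entirely from the survey itself.

A full pipeline on simulated data (`python
examples/04_integrated_abundance.py`) shows the bias structure the
estimators exist for:

```
DS-DS    N_T =   83.2   a_S = 0.229
CMR-DS   N_T =   58.1   a_S = 0.325
Hybrid   N_T =   58.2   a_S = 0.326
truth    N_T =   62.0   a_S = 0.403
```

Ignoring duplicates (DS-DS) overcounts abundance by a third and halves
availability; the duplicate-corrected estimators land near the truth.

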