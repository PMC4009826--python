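# Methods

## The compartment-exchange model

A budded cell is modelled as two well-mixed bodies — mother (relative
volume `volume_mother`, default 1.0) and bud (`volume_bud`, default
0.35) — with the bleach ROI split off from its body as a third state.
Writing `c = (c_roi, c_rest, c_other)` for the mobile reporter
concentrations and `v` for the state volumes, exchange is first-order in
concentration differences with two conductances:

- `g_mix = intra_mixing_rate · v_roi` couples the ROI to the rest of its
  body, so the ROI relaxes toward its surroundings at roughly
  `intra_mixing_rate` (1/s);
- `g_neck = exchange_rate · v_other` couples the two bodies, making
  `exchange_rate` (1/s) the relaxation rate of the distal body toward
  the proximal one.  It is the model's proxy for bud-neck barrier
  permeability: the shipped wild-type-like value is 0.0115 1/s and
  weakened barriers are expressed as multiples of it.

The generator `A` of `dc/dt = A c` conserves the volume-weighted total
exactly (the volume vector lies in its left null space), and states are
propagated between frames with `expm(A·Δt)` — exact for a linear
system, which is what makes the fine-step Runge–Kutta integration in the
test suite a meaningful independent oracle rather than a tautology.

Discrete events are interleaved with propagation:

- a **bleach pulse** multiplies the ROI states by `1 − pulse_efficiency`
  *after* the frame's acquisition, so the first FLIP frame is the
  unbleached 100 % reference;
- every **acquisition** multiplies all states (neighbor controls
  included) by `1 − acquisition_bleach_fraction` (default 0.002/frame).
  The magnitude of acquisition bleaching in the real experiments is not
  known; it is set non-zero precisely so that the neighbor-cell
  normalization has real work to do, and the per-frame control division
  cancels it exactly;
- an `immobile_fraction` of the initial signal is exempt from exchange
  but not from bleaching — this is what produces FRAP plateaus below
  the pre-bleach level.

Readout follows the experiments: FLIP records whole-compartment mean
intensities for mother and bud; FRAP records the bleached ROI itself
(recovery = exchange with the rest of the compartment).  Photoconversion
runs two channels under the same dynamics, with the conversion pulse
moving `pulse_efficiency` of the green ROI signal to red in place.  A
`preconverted_fraction` (default 2 %) of the pool starts red everywhere,
standing in for basal conversion and bleed-through; it keeps the
pre-conversion red level positive, which the chase normalization (scale
so frame 0 reads exactly 10, then subtract an equally normalized
unconverted control cell) divides by.

Noise is applied to measured traces only, never to the state:
multiplicative Gaussian readout noise (`multiplicative_cv`, default 5 %)
plus additive background (level 50 a.u., sd 2 a.u. against an initial
signal of 1000 a.u.), with the background also recorded as its own
trace.  Every stochastic function takes an integer seed and is
bit-reproducible; multi-cell stages derive per-cell seeds from one
master seed via `numpy.random.SeedSequence`.

Deliberately out of scope: spatial PDEs of the ER network,
photophysics (blinking, reversible dark states), and cell growth during
acquisition.  A consequence of the well-mixed assumption is that FLIP
depletion inside the mother is mono-exponential to a good
approximation; real cortical-ER geometry would add fast early
components that the one-phase fit absorbs into its rate.

## Shipped calibration

The default FLIP protocol (1 s frames, 200 frames, a pulse after every
frame, `pulse_efficiency` 0.55 on an ROI holding 15 % of the mother
volume, `intra_mixing_rate` 1.0 1/s) was calibrated once so that the
noiseless pipeline yields a mother half-loss time of ≈ 10 s and a
wild-type Barrier Index of ≈ 7.4, the regime reported for intact
barriers.  Under this calibration a 5-fold permeability increase drops
the BI to ≈ 2.1 and a fully open neck (≥ 100-fold) brings it to 1.08 —
slightly above 1 because the measured mother includes the bleached ROI
and therefore always runs marginally ahead of the bud.

`KAR2_LIKE_INTRA_MIXING = 0.0643` 1/s emulates a luminal chaperone-like
reporter: with the default FRAP protocol (0.5 s frames, 5 pre-bleach
frames, one 80 %-efficient bleach of a quarter of the mother) the fitted
recovery half-time is ≈ 8.5 s, the mobility scale of an unoccupied ER
Hsp70 reporter; slowed, client-occupied states are emulated by scaling
this rate down.  Note the fitted half-time is slightly faster than
`ln 2 / intra_mixing_rate` because the ROI holds a finite share of its
compartment (the effective relaxation rate carries a `1/(1 − roi_fraction)`
factor) — the constant is defined on the observable, not the raw rate.

Pedigree hazards are per-division death probabilities; the shipped
constants 0.0268 and 0.0368 give geometric lifespans with medians of 26
(unstressed) and 19 (ER-stressed) generations.  A hazard schedule may
be age-dependent (the last value persists beyond the schedule).

## Quantification and fitting

- Background is subtracted per frame as a trace, not a scalar, because
  background drifts within an experiment; negative results are clamped
  to zero and the clamp count logged.
- Mother and bud are divided per frame by the mean of five neighbor
  controls and rescaled so frame 0 is exactly 100 %.  Per-frame (not
  time-averaged) division is what cancels acquisition bleaching
  frame-exactly.
- The one-phase decay fit pins `y(0) = 100` structurally.  For each of
  13 log-spaced start rates (1e-4…1 1/s) the optimal plateau has a
  closed form; each start is refined by bounded least squares on
  (log rate, plateau) and the winner chosen by lowest residual, ties
  broken toward the lower rate — fits are deterministic.
- `t50` is read from the fitted curve,
  `t50 = ln((100 − plateau)/(50 − plateau))/rate`, undefined when the
  plateau is ≥ 50 %.  Traces that never cross 50 % in the acquisition
  window still yield a model t50 flagged `extrapolated`: intact-barrier
  buds routinely lose < 50 % within the window, and the Barrier Index
  needs their t50.  A model-free linear-interpolation crossing is
  provided as a cross-check utility only.
- FRAP traces are normalized so the pre-bleach mean is 100 and fitting
  starts at the post-bleach minimum.  The mobile fraction is
  (plateau − floor)/(pre-bleach − floor); for two-component fits the
  fast fraction is the amplitude share of the faster exponential, the
  half-time is found by root-bracketing on the fitted curve, and fits
  whose rate ratio is below 3 are flagged `unidentifiable_components`
  rather than reported silently.
- The Barrier Index is computed per cell and then averaged (mean ± SD)
  across cells, never from pooled average traces.

## Classification and counting

The exclusion classifier smooths the cortical transect with a 3-point
moving average, takes the minimum over the central third and divides by
the mean over the two outer flank windows (default 1 µm).  Ratio
thresholds 0.3 / 0.7 split total / partial / no exclusion; the visual
sorting they replace had no published criterion, so the thresholds are
config-exposed and the synthetic profile classes are defined
consistently with them (dip depth ≥ 0.7, 0.3–0.7, ≤ 0.3).  The 3-point
window is a bias compromise: wider smoothing shallows a
diffraction-scale dip and pushes deep dips across the total/partial
boundary, while no smoothing lets single-sample noise minima pull flat
profiles downward; at 5 % readout noise the classifier recovers ≥ 95 %
of labels on 200 simulated profiles per class.

Spot counting thresholds local maxima at the background median plus
`threshold_sd` robust standard deviations (1.4826·MAD of pixels outside
both masks), suppresses maxima within `min_separation` pixels, and
assigns peaks to the mask containing them.  The generator places
Gaussian spots at least 4·psf_sigma apart, so counts are exactly
recoverable at low noise — the round trip validates the detector, not
a clustered-aggregate regime, which real images do contain.

## Survival statistics

Pedigree data are complete (every mother followed to death), so the
survivor function is the empirical `#{divisions > a}/n`, the median is
the smallest age with ≤ 50 % surviving (a deterministic step-curve
reading), and censoring support is deliberately omitted.  The
Gehan–Breslow–Wilcoxon test uses Gehan's pairwise scores, which without
censoring reduce to `h_i = #{smaller} − #{larger}` over the pooled
sample; the statistic is the score sum of one group with the exact
permutation variance `mn/(N(N−1))·Σh²`, referred to chi-square(1), or a
label-permutation p-value with the add-one estimator `(b+1)/(B+1)` (so
p is never exactly 0, and is reproducible under a fixed seed).  The
test is two-sided.  The suite cross-checks the statistic against
lifelines' Wilcoxon-weighted log-rank test and against exhaustive
enumeration on a 3-vs-3 toy comparison (using the mid-p convention for
so discrete a null).

Because the geometric survivor curve drops only ~0.013 per generation
near 50 %, the sample median is a noisy statistic: its sd is about
`sqrt(0.25/n)/0.013` generations (≈ 1.7 at n = 60).  The demo keeps
n = 60 mothers per group to mirror dissection-scale experiments; the
acceptance script uses n = 8000 so the reported medians are stable to
half a generation.

## What passing tests do and do not show

The generator realizes exactly the statistical structure the estimators
assume — well-mixed compartments, mono-exponential kinetics, Gaussian
readout noise, geometric lifespans.  Passing tests therefore
demonstrate correctness of the estimators under the stated model and
calibrated noise, including their calibration (type-I error within
[0.035, 0.065] at α = 0.05; power ≥ 0.8 at a 2-fold hazard ratio with
50 mothers per group).  They do not demonstrate robustness to real-data
pathologies: focus drift, segmentation error, spatially structured ER
geometry, non-Gaussian camera noise, aggregates that wander between
ROIs, or age-dependent hazards other than those simulated.
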