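# Methods

## The model

`synpool` implements a single-pool, three-state compartment model of the
synaptic vesicle cycle. The pool is normalised to 1 and split into the
fraction ready for release (u1, the readily releasable pool), the fraction
fused with the presynaptic membrane (u2) and the fraction in the recycling
pathway (u3):

    du1/dt = −α·u1 + β·u3
    du2/dt = +α·u1 − σ·u2
    du3/dt = +σ·u2 − β·u3

with first-order rate constants α (exocytosis/activation), σ (endocytosis
after release) and β (recycling back into the releasable pool). Default
values are α = 0.008 s⁻¹, β = 0.5 s⁻¹, σ = 1.67 s⁻¹, literature estimates
for hippocampal boutons. The model is linear:
`d(state)/dt = M·state` with a column-conservative generator M, so the
total pool is conserved exactly and the simplex is forward-invariant.

Assumptions worth keeping in mind: a single homogeneous pool, first-order
(mass-action) transitions, no finite-size (stochastic) pool fluctuations —
stochasticity enters only at the event layer — and no spatial structure.

## Numerics

Propagation over any interval of constant rates is the exact matrix
exponential `expm(M·dt)`; piecewise-constant schedules are handled by
chaining exact propagations across breakpoints. There is therefore no step
size to tune, and trajectories are independent of output-grid refinement
(asserted to 1e-12). The conservation constraint is *checked* (tolerance
1e-9) and never repaired by renormalisation: a violated simplex indicates a
bug, not noise. The closed-form equilibrium
u1 = 1/(1 + α/σ + α/β), u2 = (α/σ)u1, u3 = (α/β)u1 is the default initial
condition (the pre-perturbation baseline is flat, i.e. the system starts at
rest); β = 0 or σ = 0 with α > 0 is rejected as degenerate. A first-order
forward-Euler integrator exists only as an independent test oracle; note
that its global truncation error at dt = 1e-4 s is of order 1e-5–1e-4 for
rate constants of order 1 s⁻¹, which bounds how tightly any Euler-based
comparison can be read.

Event-rate evaluation and time integrals used in likelihoods are computed
spectrally (eigendecomposition of M per segment, with a dense-expm fallback
near defective generators); the integral of the propagator uses the
φ(w) = (e^{w·dt} − 1)/w form with a series branch near the structurally
zero eigenvalue.

## The staged LPA perturbation

LPA exposure is encoded as a piecewise-constant schedule: at
t = t_exo_up − lead the recycling rate β changes; at t = t_exo_up the
exocytosis rate is multiplied by `alpha_factor` (default 1.5); σ is never
touched; defaults t_exo_up = 300 s, lead = 60 s, horizon 1080 s (18 min).
"Reduce β by 0.01" is read multiplicatively by default
(β → 0.01·β = 0.005 s⁻¹ — a near collapse of recycling); an absolute mode
(β → β − 0.01) is available as a configuration switch. Both rate changes
are steps; no ramp shape is modelled.

## Masking of the release increase

The observable tied to mEPSC frequency is the release flux α(t)·u1(t)
(events/s once scaled by the effective pool size `n_pool`). With β
collapsed 60 s before the α boost, the releasable pool has already drained
enough that the boosted flux does not rise meaningfully above the
pre-perturbation baseline — the release increase is *masked*.

One subtlety is intrinsic to the model and reported transparently: u1 is
continuous across the α step, so the instantaneous flux immediately after
the step is 1.5·u1(300)/u1(0) ≈ 1.0054× baseline — a 0.5% excursion lasting
under half a second before the flux falls below baseline and decreases
monotonically. An event-rate estimate (a count over a window of seconds)
cannot resolve this, so `masking_check` takes its verdict on
window-averaged flux (default 10 s windows; any window ≥ 1 s yields the
same verdict) and reports the instantaneous peak ratio alongside. Under
this definition the staged scenario is masked (windowed peak ratio 0.962)
while the α-only control is not (instantaneous jump exactly 1.5, windowed
peak ≈ 1.49).

## What the model does *not* reproduce

The perturbation leaves σ untouched, so the dwell time of an individual
fused vesicle (1/σ) is unchanged, and after the β collapse the drained pool
settles at a *lower* fused fraction than rest (u2: 0.0047 → 0.0021 at
1080 s). The experimentally observed accumulation of fused vesicles /
prolonged SynaptopHluorin decay is therefore not an emergent property of
this three-state model with this perturbation; reproducing it would require
perturbing σ or adding a distinct membrane state. The acceptance suite
contains a deliberately failing check documenting exactly this gap.

## Observables and quantification rules

- mEPSC rate: `n_pool·α(t)·u1(t)`; one fused vesicle ↔ one detected mini,
  detection losses folded into `n_pool` (amplitudes are drug-invariant, so
  detectability does not shift between conditions).
- SynaptopHluorin: F(t) = baseline_f + gain·u2(t) (the reporter is quenched
  at vesicular pH and visible only while fused).
- Ca²⁺ peak: mean of the five highest post-stimulus samples minus the
  baseline. The baseline is the mean of all pre-stimulus samples (the
  source procedure does not define it; this choice is configurable in
  effect by slicing the trace). The statistic is invariant under adding a
  constant to the whole trace.
- Dose–response: Boltzmann sigmoid fitted on log10 concentration with the
  slope in decades,
  R(c) = r_min + (r_max − r_min)/(1 + exp((log10EC50 − log10 c)/slope)).
  Initialisation: asymptotes from the data extremes, midpoint from the
  half-maximum crossing, slope 0.5; up to 10 deterministic perturbed
  restarts; degenerate (flat) responses raise an explicit fit error.
- Fluorescence decay: F(t) = A·exp(−(t−t₀)/τ) + C by bounded least squares;
  traces that do not decrease over the window are rejected as model
  mismatch rather than returning a meaningless τ.

## Synthetic data

Generators emulate the statistical structure the analyses assume, not raw
recordings: event trains are inhomogeneous Poisson (Lewis–Shedler thinning
under per-segment envelopes `n_pool·α_seg`, valid because u1 ≤ 1);
amplitudes are i.i.d. truncated log-normal (median ≈ 20 pA, log-sd 0.4,
5 pA floor — the amplitude scale is not constrained by any source data and
is documented as arbitrary); Ca²⁺ traces are a baseline (default 117, the
population-mean resting level in nM) plus a difference-of-exponentials
transient rescaled to peak 75–85 s after the stimulus, sampled every 2 s;
pHluorin traces add Gaussian noise to the clean u2 signal. Every generator
is deterministic given its seed, and independent substreams are spawned
from one root seed so adding a draw never perturbs a different stream.

Consequently, passing tests show that the *procedures* (quantification,
fitting, inference) are correct on data matching their own assumptions;
they say nothing about detection artefacts, bursting/correlated release,
bleaching, drift or any other structure real recordings add.

## Scenario inference

Trains are scored with the inhomogeneous-Poisson log-likelihood
Σ log rate(tᵢ) − ∫ rate dt, with the integral exact per schedule segment.
Any subset of {alpha_factor, beta_scale, lead, n_pool, t_exo_up} can be
estimated by bounded Nelder–Mead with 5 multi-starts (seeded uniform draws
within bounds; the first start at the defaults); beta_scale is searched on
log10 because the two textual readings of the perturbation differ by two
orders of magnitude. 95% intervals come from the profile likelihood at a
drop of 1.92 nats (χ², 1 df) — chosen over curvature because bounds can be
active — with other free parameters held at their estimates (a local
approximation when several parameters are free). t_exo_up is fixed by
default: jointly with `lead` it is weakly identified from a single train.
Recovery of alpha_factor from default-condition trains (n_pool = 200,
1080 s) has a median relative error well inside 20%, improving roughly as
1/√n_pool through 50 → 200 → 800.

## Problem sizes and tolerances

Default grids use 1 s output spacing over 1080 s. Seeded replicate counts
in tests and the acceptance script (20 fits per recovery experiment, 10–20
trains per statistic, 100–200 Poisson trains) were chosen as the smallest
sizes at which the asserted medians and dispersion statistics are stable;
parameter tolerances are 1e-6 (optimiser), conservation 1e-9, exactness
checks 1e-12.

## Known limitations

- Single pool, no vesicle identity: no release-site depletion statistics
  beyond the mean-field fractions.
- The masking verdict is resolution-dependent by nature; the package makes
  the resolution explicit instead of hiding it.
- The perturbed model cannot show prolonged membrane persistence (see
  above).
- Profile CIs are one-dimensional profiles around the MLE, not full joint
  profiles.
- The Fura-2 ratio→nM calibration is out of scope; Ca²⁺ traces are analysed
  in whatever units they carry.
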