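# synpool

Single-pool, three-state kinetics of synaptic vesicle cycling, with the
staged lysophosphatidic-acid (LPA) perturbation, synthetic
electrophysiology/imaging data generators, the standard quantification
procedures, and maximum-likelihood recovery of perturbation parameters.

It is written for synaptic physiologists and modellers who want a tested,
scriptable version of the classic vesicle-cycle compartment model and of
the analyses usually applied to miniature-EPSC and fluorescence data.

## The model

A normalised vesicle pool is split into fractions ready for release (u1),
fused with the membrane (u2) and recycling (u3), with first-order
exocytosis (α), endocytosis (σ) and recycling (β):

    du1/dt = −α·u1 + β·u3
    du2/dt = +α·u1 − σ·u2
    du3/dt = +σ·u2 − β·u3

Defaults: α = 0.008 s⁻¹, β = 0.5 s⁻¹, σ = 1.67 s⁻¹. The system is linear,
so the package propagates it *exactly* (matrix exponential per
constant-rate segment) — no integrator settings, no discretisation error.

LPA is modelled as a staged perturbation: recycling collapses
(β → 0.01·β) 60 s *before* exocytosis is boosted (α → 1.5·α). Because the
releasable pool drains during the lead time, the boosted release flux
α(t)·u1(t) never rises visibly above baseline: the release increase is
masked in the observed mini frequency. `masking_check` quantifies this on
window-averaged flux (what an event-rate estimate can resolve) and reports
the instantaneous ratios alongside.

Other components: inhomogeneous-Poisson mEPSC train generation (thinning),
drug-invariant log-normal amplitudes, SynaptopHluorin traces
(F = baseline + gain·u2), Ca²⁺ transients, the top-5-minus-baseline peak
rule, Boltzmann dose–response fits (EC50), single-exponential decay fits
(τ), and Poisson maximum-likelihood estimation of scenario parameters with
profile-likelihood intervals.

## Worked example

```python
import numpy as np
import synpool as sp

x0 = sp.steady_state(sp.DEFAULT_RATES)
print(x0)
# PoolState(u1=0.9796330189121968, u2=0.0046928527852081285, u3=0.01567412830259515)

grid = np.arange(0.0, 1081.0, 1.0)
full = sp.simulate(sp.build_lpa_schedule(sp.ScenarioParams()), x0, grid)
ctrl = sp.simulate(
    sp.build_lpa_schedule(sp.ScenarioParams(lead=0.0, beta_change_value=1.0)), x0, grid
)
rep = sp.masking_check(full, ctrl)
print(rep.masked_full, round(rep.peak_ratio_full, 4), rep.peak_inst_ratio_alpha_only)
# True 0.9621 1.5

rate = sp.ScenarioRate(sp.build_lpa_schedule(sp.ScenarioParams()), x0, 200.0, 1080.0)
train = sp.sample_event_train(rate, 1080.0, sp.AmplitudeModel(), seed=1)
est = sp.fit_scenario(train, sp.DEFAULT_RATES, free=("alpha_factor",), seed=0)
print(train.n_events, round(est.estimates["alpha_factor"], 3))
# 1079 1.582
```

Reading: at rest ~98% of the pool is release-ready. Under the staged
perturbation the window-averaged release flux peaks at 0.962× baseline
(masked), while the α-only control jumps by exactly the boost factor 1.5
(not masked). From one synthetic 18-min train of 1079 events, the
likelihood fit recovers the exocytosis boost as 1.58 (true value 1.5), with
a 95% profile interval available in `est.ci95`.

The same pipeline is available from the shell:

```sh
synpool simulate --out out/            # trajectory.csv, flux.csv, masking.json
synpool synth --seed 7 --out out/      # events.csv, traces, dose_response.csv, manifest.json
synpool fit boltzmann --data out/dose_response.csv --out out/
synpool fit scenario --data out/events.csv --out out/
```

All commands are deterministic given config + seed (byte-identical
reruns). See `docs/methods.md` for the model's assumptions, the numerical
choices and known limitations.

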