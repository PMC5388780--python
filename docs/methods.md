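# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical and design choices that were
genuinely open, and what the simulated protocols do and do not show.

## Circuit

Four circular arrays of `N` neurons (preferred directions 2πi/N) carry the
computation. The head-direction layer encodes the compass reading with a
cosine tuning curve; a speed gate subtracts a unit bias and rectifies, so
at walking speed s = 1 each timestep contributes a rectified-cosine bump
centred on the current heading; the memory layer accumulates these bumps
through a self-recurrent connection with leak λ; and a cosine kernel
projects the memory onto the output array. Because the kernel extracts
exactly the first circular harmonic, and because the rectified-cosine bump
has no odd harmonics above the first, the decoded population vector equals
the Cartesian sum of per-step displacement vectors for any *even* N — the
circuit is an exact vector integrator at zero noise, with no
discretization floor (tested to ~1e−13 of path length). Idealizations:
rate neurons, no attractor dynamics, no persistent-activity noise; the
rectifications in the memory and decode stages are kept as written even
where redundant.

The readout length convention is the population-vector norm; the summed
firing rate of the decoded array is proportional to it and is available
via `PIParams(readout_length="sum")` — only the calibration constant
changes.

## Metric calibration

κ (metres per unit of decoded vector length) is measured, not derived: a
scripted straight leg of 10 m is driven through the circuit and κ is the
true length divided by the decoded length, averaged over four headings
(they agree to well under 1% — enforced). κ scales with the distance
covered per timestep, so it is recomputed for each (N, speed) pair.

Two subtleties:

* **Speed sublinearity.** The gate `max(0, cos − 1 + s)` narrows its
  support as s drops, so the bump's first-harmonic amplitude is not
  proportional to s (≈ 0.39 instead of 0.5 at s = 0.5). The closed-loop
  agent always walks at s = 1, where κ is defined; at other constant
  speeds the integrator remains exact in *direction* but needs its own κ.
* **Calibration under noise.** Per-step heading noise of SD σ shrinks the
  expected decoded length by the mean resultant e^(−σ²/2) ≈ 0.952 at the
  5% noise level. This is a property of the decoder, not a positional
  error, so the accuracy experiments estimate κ under their own noise
  model (64 noisy repeats per heading); using the zero-noise κ would add a
  spurious radial bias of ~4.8% of the distance from home.

## Agent kinematics

The motor command Σ is interpreted as a commanded turning **rate** in
rad/s, capped at π rad/s and integrated over Δt = 0.1 s; the agent then
steps forward 0.0053 m (0.053 m/s), emulating a slow legged robot. Under
the naive exploration rate ε = 1 the per-step heading increment is
N(0, 0.1 rad), giving a correlated random walk with persistence
c = e^(−0.005); the forward speed was set so that the mean displacement
after 1,000 s of naive foraging is 9.3 m (verified against the
closed-form CRW mean-squared-displacement law and by Monte-Carlo, 20,000
walks). The alternative reading — Σ as a per-step heading increment with
~1 rad steps at 0.5 m/s — produces the same outbound displacement but an
order-of-magnitude larger PI error under compass noise (error variance
≈ T v² σ² Δt), inconsistent with the accuracy results this model is meant
to exhibit; the rate interpretation is also the natural interface to a
walking-robot controller.

## Noise models

*Sensory (correlated)* noise shifts the whole compass reading:
φ_noisy = φ + δφ with δφ ~ N(0, 2πζ_sens) drawn once per timestep
(ζ = 0.05 → SD 18°). *Neural (uncorrelated)* noise adds i.i.d. N(0,
ζ_neur) to each head-direction neuron each timestep. An exact consequence
of the ideal cosine code is that correlated noise leaves no N-dependence
for even N (the bump shifts rigidly), while uncorrelated noise is filtered
by the population with amplitude ∝ √(2/N): neuron-count effects are
therefore probed under neural noise, and the 18-vs-36-neuron accuracy
plateau under sensory noise.

## Trial protocol

A trial starts at the nest with a uniform random heading. The foraging
context σ flips outward→inward when the accumulated per-step reward
exceeds 20 (the agent feeds for a few seconds at the food — the threshold
is not critical but must be well above 1 for the reward low-pass to
register the find) or when t reaches t_forage; the trial ends on nest
entry (within 0.2 m) while inbound, or at T = 1.5 t_forage. Between trials
the path integrator and position reset; the GV weights, v and β persist
within a learning cycle. The per-trial positional-error metric is the
time-average of |estimated − true position| over *all* steps of the trial
(outbound and inbound).

The reward discount γ = 0.995 is applied **per second** of simulated time
(per-step factor γ^Δt), giving the reward estimate v a ~138 s half-life.
Applied per 0.1 s step instead, v would decay to zero within every trip
and the exploration rate would reopen to 1 at the start of each trial,
making across-trial exploitation impossible — a discount commensurate with
trip duration is required by the behavior the model is built to produce.
v and β update on every timestep, inbound included; σ gates only ε and
the weight updates.

## Scripted-course experiments

The L-shaped-course (two-channel) experiment scripts the trajectory
(10 m, then 5 m at angle α in 2.5° steps) instead of closing the loop,
with the legs traversed at 1 m/s (0.1 m per step) — ant running speed,
and necessary given that λ is a per-step leak: the first leg must retain
more than the golden-ratio fraction 0.618 of its weight relative to the
second leg's accumulation for the remembered path to keep pointing
outward on collinear courses. With λ = 0.0075 the angular error is zero
at α ∈ {0°, 180°}, antisymmetric in α, and peaks near ±40°; with λ = 0 it
vanishes. No behavioral dataset is bundled; the comparison to animal data
is qualitative (curve shape), not a fit performed here.

## Random environments

Learning cycles draw 50 feeders with radius uniform on [1, 40] m
(uniform in radius, not area — feeder density is higher near the nest)
and angle uniform. This emulates sparse, stationary food around a central
nest; it does not model depleting or moving food, landmarks, or other
agents, so convergence of the exploration rate here demonstrates the
learning rule's stability under realistic *geometry*, not under resource
dynamics. With t_forage = 1,000 s the nearest feeder (~2 m in
expectation) is typically found within the first few trials, after which
every trial ends at a feeder and at home.

## Problem sizes and tolerances

The test suite runs reduced but statistically sufficient sizes
(120–300 trials per accuracy condition, 5–10 learning cycles); the
acceptance script runs 1,000 trials per accuracy condition and 10 cycles
of 60 trials, completing in a couple of minutes on one CPU. Monte-Carlo
tolerances are set at 2–3 standard errors of the estimate. The undefined-
vector threshold is 1e−9 activity units; the population-vector angle is
computed with the two-argument arctangent (the single-argument form is
quadrant-ambiguous). All randomness flows from one integer seed through
deterministically spawned substreams; a (configuration, seed) pair
reproduces every output byte-for-byte.

## Known limitations

The agent is a point with constant speed; body dynamics, stride-based
odometry and locomotion control are outside scope. Homing relies on PI
alone — no landmark guidance, route memory, or systematic search spiral —
so with large integration errors the terminal search can miss the nest
radius; within the noise levels studied this is rare. A single GV array
is modelled: when several feeders reward the agent, one blended vector
results rather than a bank of memories. Exploration decays to pure
exploitation; real foragers retain residual exploration.
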