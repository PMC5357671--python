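# Methods

This note documents the model equations, the defaults and why they were
chosen, the numerical scheme, and what the synthetic-input generator does
and does not emulate.

## Cell model

The globular bushy cell is a single compartment:

    C dV/dt = −(I_leak + I_Na + I_Kht + I_Klt + I_h) + I_syn + I_ext

with the ventral-cochlear-nucleus Type II conductance complement:

| current | gating | g_max (nS) | E (mV) |
|---|---|---|---|
| Na (fast) | m³h | 2500 | +55 |
| K high-threshold | 0.85·n² + 0.15·p | 150 | −70 |
| K low-threshold | w⁴z, z floor 0.5 | 200 | −70 |
| h (HCN) | r | 20 | −43 |
| leak | — | 2 | −65 |

Capacitance 12 pF.  The sodium kinetics are the fast bushy-cell rate
functions (alpha/beta form); the slower "classic" Type II sodium produces
refractory periods that are too long for a cell that entrains at 500–700 Hz.
Rate functions are published at 22 °C; every gating time constant is divided
by q10^((37−22)/10) with q10 = 2.5 for sodium and 3 for the other channels.
Maximal conductances are not temperature-scaled.  g_Na = 2500 nS matches
measured firing thresholds; the resulting single-EPSG firing threshold is
≈20 nS and the single-pulse (0.1 ms) current threshold ≈1.7 nA.

**Resting state.** With all gates at steady state the membrane current is a
function of V alone; its zero (Brent's method, bracketed in [−90, −40] mV)
is the exact fixed point of the ODE (residual < 1e−6 nA).  Every simulation
additionally relaxes for 200 ms with no input before the analyzed window.

**Integration.** Gating variables advance by exponential Euler against
their voltage-dependent steady states; the voltage by an implicit (backward)
Euler step in which all conductances are taken at the updated gating state.
This keeps the stiff system stable at a fixed dt = 10 µs (20 µs hard cap).
Spike-time convergence under dt halving is better than 10 µs.  Spikes are
upward crossings of −20 mV with linearly interpolated crossing times and a
1 ms detector dead time.

**Refractory measurement.** Two identical 0.1 ms current pulses; the
inter-pulse interval is bisected (0.01 ms resolution) for the minimum
interval at which the second pulse still fires the cell.  The probe
amplitude defaults to 2.5x the measured single-pulse threshold: mapping the
second-spike threshold against the interval shows a sharp absolute-refractory
knee (threshold roughly triples within ~0.1 ms) followed by a long
relative-refractory/AHP tail, so a near-threshold probe would read the tail
rather than the absolute period, while above ~3x threshold the pulse itself
passively depolarizes the 12 pF compartment past the spike detector
(amp·width/C ≈ 42 mV at 5 nA).  Within the valid 2–3x band the measured
period varies by < ~0.1 ms.  Default parameters yield 0.69 ms.

## Endbulb synapses

Depression is modeled by the event-driven recursion given in the README;
state is updated only at presynaptic spikes.  Conventions:

* initial state g_0 = w/(1−u), so the first event delivers exactly w;
  u = 1 is rejected for depressing synapses (use the tonic kind);
* the single-exponential steady state under periodic stimulation at rate f
  has the closed form w(1−E)/(1−(1−u)E), E = exp(−1/(f τ)); the
  double-exponential fixed point is found by damped fixed-point iteration to
  1e−10 relative tolerance (the map is affine in g, so this converges
  geometrically);
* the depression level X% is defined against the 50/300 Hz steady states
  (both rates configurable via `DepressionSpec`); u for a requested X% is
  found by bisection (X% is strictly increasing in u).  With τ = 90 ms the
  attainable range is 0–81.7%, so the 0–70% sweep is covered while u = 0.6
  (≈80%) lies outside it;
* delivered conductances rise instantaneously and decay with a shared
  0.2 ms time constant; summation across events and across the N synapses
  of a cell is linear.  Synaptic reversal potential 0 mV (AMPA-type; chosen,
  not measured here).

## ANF surrogate

Fibers are high-spontaneous-rate ANFs generated as a thinned inhomogeneous
Poisson process with:

* **rate envelope**: 50 spikes/s spontaneous; during a tone, a
  cosine-squared-ramped (2.5 ms) rise to an onset peak of 700 spikes/s
  adapting with rapid (2 ms) and short-term (60 ms) components — split
  0.6/0.4 — toward the level-dependent steady driven rate (250 spikes/s at
  50 dB SPL, 300 at 60 dB, linear in between, clamped outside); after
  offset, suppression to 0.6x spontaneous recovering with τ = 100 ms.
  Adaptation resets at each tone onset (gaps are long relative to the rapid
  component).
* **phase locking**: during tones the intensity is multiplied by a von Mises
  modulation at the tone frequency, normalized to unit mean; its
  concentration κ solves I1(κ)/I0(κ) = VS_target.  The default target curve
  VS(cf) = 0.85/√(1+(cf/2500 Hz)⁴) gives a low-frequency plateau near 0.85
  with a multi-kHz rolloff, and is configurable as a table.
* **refractoriness**: absolute dead time 0.75 ms plus exponential relative
  recovery (τ = 0.6 ms), applied by sequential thinning.  The proposal
  intensity is compensated by 1/(1 − r·d_eff) with d_eff = 1.35 ms so
  realized stationary rates match the requested ones; the compensation load
  is capped at 0.65, so only the brief onset peak (700 spikes/s, near the
  refractory ceiling) undershoots.

**What the surrogate does not emulate** — and therefore what passing tests
do and do not show: there is no basilar membrane, hair cell, or power-law
adaptation, so gap activity is (refractory-corrected) Poisson with no
long-range rate fluctuations or overdispersion, and all fibers at one CF
share identical statistics and preferred phase.  Coincidence-driven
quantities that depend on the *variance* of the pooled background — most
visibly the spontaneous rate of the cell as a function of synaptic weight —
are therefore conservative: SR(w) rises later than it would with
overdispersed inputs, which biases fitted weights upward by roughly 25% for
the strongly depressing synapse.  This is the main reason the strongly
depressing in-vitro synapse in this implementation still entrains at CF
500 Hz (driven rate ≈ 500 spikes/s) while failing at 650 Hz (≈340 spikes/s),
i.e. the entrainment-failure boundary sits ~100–150 Hz higher than with a
full inner-ear model in front.  Directional results (EI degrading with
depression and improving with convergence, VS insensitivity, weight trends)
are unaffected.

## Metrics and windows

VS and EI are computed over full tone windows by default (a configurable
onset exclusion exists, default 0 ms); inter-spike intervals never span
separate tone bursts.  The driven-rate estimate excludes a 10 ms onset
guard; the spontaneous rate is measured in the inter-tone gaps excluding a
20 ms post-offset guard (adaptation recovery contaminates the early gap).
Metrics with too few spikes propagate as NaN, never as zero.  When several
runs are pooled, VS pools resultant vectors and EI pools interval counts.

## Fitting

All N synapses of a cell share one weight.  The scan uses a 16-point
logarithmic grid over 0.5–60 nS (full profile), identical fiber
realizations across weights (common random numbers, so monotone trends are
not masked by noise), and averages over 5 seeds; the optimum refines by
bisection between the bracketing grid points until |SR − 7.5| < 0.5
spikes/s or 8 evaluations, ties toward the smaller weight.  Weights are
fitted on the 25 ms/100 ms/50 dB fitting train and evaluated on the
50 ms/100 ms/60 dB ramped train.  An unbracketed target raises an explicit
error advising grid extension.  For the per-point experiments the smallest
input count whose fitted cell reaches EI_ref − 0.01 is reported
("not fittable" is a value, not an error); input counts are restricted to
the anatomical 10–70 range.

Problem sizes: the "desk" profile uses 30-repetition trains, 3 scan seeds
and a 10-point grid; the test suite's coarse property checks use
20 repetitions, 2 seeds and 8 points; `scripts/acceptance.py` fits on
100-repetition trains with 3 scan seeds and validates on 10 fresh seeds
(~55 s of analyzable silent time for the spontaneous-rate check).

## Known limitations

* Dendrites, axon and inhibitory inputs are not modeled; low/medium-SR
  fibers are not included.
* The surrogate's Poisson background understates coincidence drive (see
  above); the entrainment-failure boundary of strongly depressing synapses
  is accordingly conservative.
* The depression models are phenomenological; no vesicle-pool, facilitation
  or desensitization mechanics.
* Tone onsets sit at cycle starts; protocols with a leading silent interval
  are not expressible (use a separate silence run for baseline measures).
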