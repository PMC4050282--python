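# Methods

`axinit` models how sustained somatic depolarization, spreading
electrotonically into an unmyelinated axon, partially inactivates axonal Na⁺
channels in a distance-dependent way and thereby expands the action-potential
(AP) initiation zone away from the soma.  The package has three computational
pillars — a compartmental cable model of a dentate granule cell, a
single-compartment kinetic model of axonal Na⁺ reported by the indicator
SBFI, and a kinematic Monte Carlo model of stochastic AP initiation — plus
the analysis operations (spike detection, soma–axon latencies, thresholds,
Ca²⁺-entry ratios) that connect them to the experimental quantities.

## Compartmental model

### Cable equation and integration

The membrane potential obeys the spatially discretized cable equation on a
tree of cylindrical compartments,

    C_m dV_i/dt = −Σ_c ḡ_c(x_i) p_c(V_i, t) (V_i − E_c) + Σ_j g_ij (V_j − V_i)/A_i + I_inj,

with Hodgkin–Huxley-type channel open probabilities `p_c = Π_k x_k^{q_k}`,
first-order gates `dx/dt = (x_∞(V) − x)/τ_x(V)`.  Integration is
Crank–Nicolson on the voltage (θ = ½) with a tree-structured direct solve
(Hines elimination; compartments are ordered parents-before-children) and
staggered exponential (Rush–Larsen) gate updates.  The default step is
dt = 0.01 ms; halving dt moves spike times by < 1 µs, and refining the
proximal spatial grid 2× moves the detected initiation site by < 1 µm.
Divergence (V outside [−120, +80] mV) raises an error naming the time and
compartment.  An ideal one-site voltage clamp is implemented as a large
penalty conductance toward the command potential.

State initialization: a 500-ms settling run at zero stimulus (dt = 0.025 ms),
cached per model.  Because the stand-in channel kinetics do not exactly
cancel at the configured resting potential (−79 mV), the leak reversal is
calibrated per compartment (shifts < 1 mV from the configured −80 mV) so
that rest is an exact fixed point; with `calibrate_rest=False` the raw
reversal is used.

### Morphology

The default cell is a parametric stand-in for a reconstructed granule cell:
a 10×10 µm somatic cylinder, one dendritic equivalent cylinder (400 µm ×
6 µm — sized so the soma carries a realistic dendritic load; input
resistance ≈ 400 MΩ, rheobase ≈ 100 pA), a 1,000-µm main axon of 0.5 µm
diameter at 80 Ω·cm axial resistivity, and two 0.25-µm collaterals
(300 Ω·cm, Na⁺/K⁺ maxima 0.012/0.003 S·cm⁻²) branching at 100 and 200 µm.
Compartment length is 2.5 µm in the proximal 100 µm of axon, 5 µm to
200 µm, 20 µm beyond.  Distances are arc length from the soma–axon junction
(soma 0, dendrite negative).  SWC read/write is provided for exchanging the
section tree; collaterals are marked through a sidecar id set since SWC has
no collateral type code.

### Channels and densities

Reversal potentials are E_Na = 58, E_K = −95, E_leak = −80 mV; membrane
capacitance 1 µF·cm⁻²; leak density 2.5×10⁻⁵ S·cm⁻².  The exact rate
functions of the granule-cell channels are not redistributable, so a generic
formalism is used with every half-voltage, slope and time constant in
configuration; the defaults below were calibrated once so that the assembled
model reproduces the qualitative experimental signatures (see "What the
defaults reproduce"), and are documented as model defaults, not measured
values.

* Somatic Na⁺ (`na_s`, m³h + slow gate s): activation half −36 mV; fast
  inactivation half −52 mV.
* Axonal Na⁺ (`na_a`, m³h·s): activation half −41 mV; fast inactivation
  half −65 mV — 13 mV hyperpolarized relative to the somatic variant, so
  the axonal channels inactivate more readily during sustained
  depolarization.
* Slow inactivation gate `s` (both Na⁺ variants; toggleable): steady state
  near 1 at rest falling steeply (slope 3.5–4 mV) over the subthreshold
  depolarized range; its time constant is ~0.46 s at rest *and* at spike
  voltages but dips to ~35 ms in a narrow band around −55 mV (−50 mV for
  the somatic variant, preserving the axonal/somatic offset).  This voltage
  selectivity is the essential design choice: brief spikes barely engage
  the gate ("spikes only" leaves availability within 5%), sustained
  subthreshold depolarization engages it within tens of milliseconds, and
  recovery at rest takes hundreds of milliseconds.
* Delayed rectifier (`kdr`, n⁴): half −33 mV.  An optional slow
  inactivation gate `z` (off by default) emulates artificially increased
  depolarization-dependent K⁺ inactivation for the direction-of-effect
  control.
* Low-threshold axonal K⁺ (`kv1`, D-type, single gate, half −50 mV) at a
  low density (4×10⁻⁴ S·cm⁻²).  It steepens the spatial attenuation of
  sustained depolarization along the axon without blocking the distal
  axon's access to threshold; much higher densities prevent the distal
  ignition that underlies the initiation-zone shift.
* Generic Ca²⁺ channel (`ca`, m²h): uniform at the reported
  "100 nS cm⁻²" (10⁻⁷ S·cm⁻², a dimensionally unusual figure, implemented
  literally with a config override; since buffering is ignored the density only scales the
  Ca²⁺ readout linearly).  Activation is high-threshold (half −5 mV) so the
  flux reports the spike waveform; the inactivation gate sits at −30 mV
  with τ = 80 ms, making the channel effectively non-inactivating at
  subthreshold voltages — Ca²⁺ channels themselves are assumed not to
  inactivate under these conditions, so Ca²⁺ entry reads out the Na⁺/K⁺
  channel state.
* Axonal Na⁺ density: Gaussian hotspot (peak +0.40 S·cm⁻² over a
  0.20 S·cm⁻² baseline, centred 13 µm from the soma, width 10 µm).  The
  *conductance* peak sits proximal to the measured *initiation site*
  (23.75 µm) because the somatic current sink suppresses regeneration over
  the first ~1–2 space constants of the spike; the latency-curve minimum
  and earliest-onset compartment both land at 20–25 µm.

Temperature is metadata only (no Q10 machinery; both 25 °C and 33 °C
datasets exist but no Q10s are given).

### Protocols

* `current_step` — somatic step; 130 pA for 260 ms is the canonical
  depolarization-driven ("Depo+Spikes") protocol for initiation-site
  analyses: spikes arise from the depolarization itself, so the ignition
  point is threshold-selected.
* `forced_spike_protocol` — brief suprathreshold pulses (smooth-edged
  double-exponential, 0.3/0.8 ms, 2.5 nA) at 20 Hz, with
  (`hold_at_rest=False`, 90 pA — the strongest level that stays
  subthreshold) or without a holding depolarization.  This is the
  time-locked protocol for the Ca²⁺ ratio analyses.  Square pulses are
  available behind a flag; their instantaneous edges superimpose a
  capacitive dV/dt transient (~100 V/s at the soma) on the recordings.
  A *forced* somatic pulse always makes the somatic wavefront the earliest
  dV/dt event along the proximal axon, so initiation-site readouts are
  meaningful only for depolarization-driven spikes; the forced protocol is
  used for waveform and Ca²⁺ analyses where time-locking matters.
* `make_synaptic_train` — summed double-exponential currents (0.5/5 ms) at
  100 Hz; varying intensity moves the somatic depolarization rise time from
  a few ms to > 100 ms, reproducing the threshold-vs-rate adaptation
  (slower trains yield thresholds several mV higher).
* `voltage_step_clamp` — the −75 → +10 mV somatic step used for the k_on
  estimation protocol.

### Analyses

Spike onset is the time of the dV/dt maximum, refined to sub-sample
precision by parabolic interpolation (latencies are tens of µs; recordings
are sampled at 20–50 kHz).  The detection gate is 20 V·s⁻¹ with a 2-ms
refractory window (no gate is stated experimentally; both are
configurable), or 20% of the peak derivative for arbitrary-unit signals.
Rise time is 20–80% of baseline-to-peak by default.  The soma–axon latency
(t_a − t_s) pairs somatic and axonal spikes by index with a ±2 ms
conduction sanity window.  The initiation site is the main-axon compartment
with the earliest dV/dt maximum (somatic voltage carries the stimulus
artifact and is excluded); the latency-curve minimum and the
earliest-onset compartment agree within one compartment by construction and
by test.  The spiking threshold implements both a dV/dt-crossing criterion
and the stated d²V/dt² extremum (minimized on the pre-peak window as
stated, with a flag for the conventional maximum — the stated sign may be a
notation slip; both are exposed, intent not guessed).  The latency-shift
regression is OLS of Δ(t_a − t_s) on distance restricted to 0–200 µm with a
two-sided t-test on the slope; no multiple-testing correction (one test per
dataset).  Waveform statistics (first vs third spike amplitude and
rise-time changes, mono-exponential distance-decay fits with positive
length constant) are designed for loose-patch-like signals
(α·V + β·dV/dt); a non-decaying profile is flagged not-applicable rather
than raising.

## Na⁺–SBFI kinetic model

A single compartment couples spike-evoked entry, indicator binding and
removal:

    d[Na]/dt     = j_Na(t) − k_on[Na][SBFI] + k_off[NaSBFI] − (P_Na + D_Na)([Na] − Na_rest)
    d[NaSBFI]/dt =           k_on[Na][SBFI] − k_off[NaSBFI]

with `[SBFI] + [NaSBFI] = SBFI_total` and `k_off = k_on·K_D`
(K_D = 25 mM).  Influx is a train of Gaussian pulses (σ = 0.5 ms, the spike
half-width scale) whose integral is ΔNa per spike; twofold changes in σ
alter the fitted parameters by < 3%.  Removal acts on the *entered* Na⁺
([Na] − Na_rest), so the system is at equilibrium before the stimulus; the
longitudinal diffusion escape is reduced to the first-order rate
D_Na = 0.8 s⁻¹.  Integration is explicit forward Euler (dt = 0.01 ms for
simulation, 0.02 ms inside fits) with stability guards
(dt ≤ σ/10 and dt ≤ 0.1/(k_on·SBFI_total + k_off)); indicator mass is
conserved exactly, and the scheme agrees with an adaptive stiff integrator
to < 10⁻³ mM.  Defaults: SBFI_total = 1 mM (the loading concentration),
Na_rest = 10 mM (not printed anywhere; an exposed assumption), ΔNa = 0.4 mM
per spike, P_Na = 0.0022 ms⁻¹.

Fluorescence uses a two-species brightness model, F ∝ [SBFI] + r·[NaSBFI]
with bound:free brightness ratio r = 0.5 (the indicator dims on binding;
the magnitude is unprinted and all fits operate on relative ΔF/F, which is
gain-invariant).

### Staged fitting

1. `fit_kon`: the response to a single brief entry pulse (voltage-step
   protocol) is fitted on the rising (binding) phase only — a 25-ms window
   from the pulse — with extrusion set to zero, the estimation stage's own
   approximation (removal at the default 3 s⁻¹ would bias k_on by ~+10% if
   the window extended to the peak; a test documents this bound).  Free
   parameters (k_on, ΔNa); the pulse time is passed explicitly (detecting
   it from 2-kHz samples shifts the onset by up to half a sample and biases
   k_on upward).
2. `fit_dna_pna`: bounded trust-region least squares jointly over the
   5 AP @ 20 Hz and 100 AP @ 50 Hz traces with (ΔNa, P_Na) free and k_on,
   K_D, D_Na fixed.  The two parameters act orthogonally — ΔNa scales the
   (inverse) increment, P_Na the decay — which the test suite verifies
   numerically (cross-sensitivities an order of magnitude below direct
   ones).  Multi-starts over log-spaced initial values with a fixed
   ordering seed (20140523); bound-hitting and ΔNa ≈ 0 (P_Na
   unidentifiable) are flagged, not raised.

## Monte Carlo latency model

Each trial draws an initiation site x* from a zone on the proximal axon and
a recording position x; `t_a − t_s = T(x*, x) − δ_soma + ε`, where T is the
travel time at velocity v(x), ε is Gaussian measurement noise, and δ_soma
is a *constant* somatic lag: the soma is electrotonically compact and
driven by the whole proximal axon, so its spike time is modelled as a fixed
offset from initiation rather than as a propagation endpoint.  (This choice
makes the distal-latency s.d. equal L/(v√12) for a uniform zone of length
L, the analytic oracle used in the tests.)  Third-spike trials use an
expanded zone and optionally a decelerated proximal velocity
`v₃(x) = v(1 − a·e^{−x/λ})`; deceleration also delays the somatic spike by
the total excess travel time of the decelerated path, so a deceleration-only
configuration produces latency changes most negative proximally that return
toward zero (while staying negative) distally.

Defaults (the supplementary description of the original Monte Carlo is not
available; these are declared assumptions): first-spike zone 5 µm centred at
22.5 µm; third-spike zone 110 µm starting at 20 µm (the 100–120 µm
expansion scale); uniform site distribution (truncated Gaussian available);
v = 180 µm·ms⁻¹; recording positions uniform on 10–350 µm; noise s.d.
50 µs; somatic lag 150 µs; 1,000 paired points.  One seeded generator per
dataset; outputs are bit-reproducible from (config, seed).

## Synthetic data

All fixtures are generated at run time as pure functions of
(configuration, seed): SBFI ΔF/F traces for the step / 5 AP @ 20 Hz /
100 AP @ 50 Hz protocols at 2 kHz (linescan-equivalent) with additive
Gaussian noise (default 5% of baseline — a stand-in for photon noise, not a
calibrated camera model); loose-patch recordings α·V + β·dV/dt resampled to
20 kHz; Monte Carlo latency tables as delimited text with provenance
headers.  The generators emulate the statistical structure the analyses
assume (sampling rates, noise floors, signal mixtures) but not optical
artifacts, electrode drift, seal-quality variation or cell-to-cell
parameter spread — so passing tests demonstrate internal consistency of
the method chain, not robustness to every feature of real recordings.

## What the defaults reproduce (and what they do not)

With the default model and protocols, computed at run time by the test
suite and the acceptance script:

* first-AP initiation site / latency-curve minimum at 23.75 µm, inside the
  experimental 20–25 µm band, with propagation fidelity 1.0 at the highest
  sustainable rate;
* strict distal movement of the initiation site across a
  depolarization-driven train, and no movement for forced spikes at rest;
* ΔCa₃/ΔCa₁ ≈ 0.55–0.6 at the 20-µm canonical site, rising monotonically
  across the canonical sites (20/100/180/260 µm).  Within ~40 µm of the
  soma the forced-pulse waveform props the local spike amplitude, producing
  a shallow profile minimum near 45 µm that the coarser imaging-like site
  spacing does not resolve;
* threshold several mV higher for slow (> 50 ms rise) than fast (< 10 ms)
  synaptic trains;
* loose-patch third-spike rise time increased ~150% proximally, decaying
  along the axon, and amplitude reduced tens of percent with a longer decay
  length — the right signatures and ordering, though the reported
  experimental effect sizes (98 ± 23%, length constants 43/187 µm) are
  means over cells that are not individually reproducible from a single
  stand-in morphology.

The quantitative experimental statistics (5–8 mV threshold shifts,
60→180 µs latency s.d., 24 ± 7% Na⁺-entry reduction) depend on the
unavailable recordings and the full reconstruction; they are covered by
direction-of-effect and shape properties, not by numerical reproduction.

## Known limitations

* Channel kinetics are generic stand-ins; only their qualitative structure
  (half-voltage offsets, slow-gate voltage selectivity) is constrained.
* No Q10 scaling, no stochastic gating, no extracellular field, no ion
  accumulation feedback on reversal potentials, no myelination.
* Ca²⁺ handling has no buffering or extrusion by design; absolute Ca²⁺
  increments are linear in the (uncertain) channel density and only ratios
  are meaningful.
* The Na⁺–SBFI model is single-compartment; longitudinal diffusion is a
  first-order escape rate, not a PDE.
* Forced-pulse protocols contaminate proximal dV/dt readouts with the
  stimulus wavefront; initiation-site analyses must use
  depolarization-driven spiking.
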