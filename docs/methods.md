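# Methods

This note documents the model equations, the provenance and meaning of every
tunable parameter that matters, the numerical methods, and what the package's
tests do and do not establish.

## Model overview

The model is a conductance-based compartmental CA1 pyramidal neuron reduced
to a ball-and-stick: a spherical soma (20 μm) and a uniform apical trunk
(400 μm × 2 μm, 20 segments by default), optionally a basal stub.  Each
compartment obeys

    C_m dV/dt = −Σ I_ion + I_axial + I_inject

with I_ion the sum of eleven Ohmic currents (NaV, CaL, CaR, CaT, Kv1, Kv2,
KA, KIR, h, leak, TRPM4), axial coupling from the cable discretization, and
somatic current injection.  Units throughout: mV, ms, μM, S/cm², mA/cm².

The reduction is a deliberate modeling choice: the mechanisms under study —
somatic spike-rate adaptation via NaV long-term inactivation and its
reversal by a soma/proximal TRPM4 conductance — are electrically local to
the soma and proximal trunk, and a reduced cell makes the model fully
specified by a handful of documented parameters rather than an external
reconstruction file.  A reduced cell is *not* expected to reproduce absolute
currents or spike counts of a 144-compartment reconstruction; the package
therefore treats orderings, signs and index values (with stated bands) as
its quantitative surface, not absolute trace magnitudes.

### Spatial rules

Base (somatic) conductance densities are mapped to every segment with:

* h-conductance: linear rise with path distance to 7× the somatic value at
  350 μm, constant beyond;
* A-type K⁺: linear rise to 6× over the same span;
* Na⁺: 0.75× the somatic density on every dendritic segment;
* R_m and R_a: logistic fall with distance (midpoint 150 μm, slope 50 μm,
  distal floor 50% of somatic), implementing the distal drop in input
  resistance; the leak density is 1/R_m;
* spine factor 2.0 multiplying dendritic membrane area (1.0 at the soma);
* TRPM4: restricted to the soma and proximal apical trunk (≤ 100 μm),
  consistent with perisomatic expression.

Path distance is measured from the soma center to segment centers.  The
linear gradient and logistic forms are package choices: only the fold
changes (7×, 6×, 75%) and the qualitative sigmoidal fall are externally
constrained.

## Markov NaV channel

Four states: closed (C), open (O), short-term inactivated (I1), long-term
inactivated (I2).  Transitions (ms⁻¹; sigmoid shorthand
σ(v; h, k) = 1/(1+exp(−(v−h)/k))):

| transition | form | default | role |
|---|---|---|---|
| C→O  | 6·σ(V; −21, 5)      | — | activation |
| O→C  | 6·(1−σ(V; −51, −8)) | — | deactivation |
| O→I1 | constant            | 1.3 | fast inactivation (~0.8 ms open time) |
| C→I1 | 0 (optional σ)      | 0 | closed-state inactivation, off by default |
| I1→C | 0.35·(1−σ(V; −60, −6)) | — | fast recovery (τ ≈ 6 ms at −60 mV) |
| I1→I2 | constant           | 0.0015 | slow entry into long-term inactivation |
| I2→C | 0.003·(1−σ(V; −60, −6)) | — | slow recovery (τ ≈ 0.7 s at −60 mV) |

No printed rate set exists for this scheme; the defaults were tuned, as a
package design decision, to satisfy the qualitative constraints that define
it: recovery from I1 in milliseconds, recovery from I2 in hundreds of
milliseconds to seconds, I2 accumulation over a 1-s train at place-cell
rates sufficient to terminate firing on the down-ramp, and a sub-threshold
interspike open occupancy (~10⁻³) whose current — the persistent Na⁺
current — sets the interspike depolarization rate.  Changing these rates is
supported (`NavParams`); the spike-pattern results hold for a neighbourhood
of the defaults, not for arbitrary sets.

## HH-style channels

All other gated channels use Boltzmann steady states x∞(V) with bell-shaped
τ(V), advanced by the exact exponential relaxation update.  The table lives
in `channels.GATES` and is deliberately data-driven so alternative published
CA1 parameterizations can be swapped in.  Two choices matter for the firing
pattern and were made deliberately:

* **Kv1** (fast delayed rectifier) activates only at spike voltages
  (V½ = −5 mV): it repolarizes spikes but contributes no sub-threshold
  resonance.  With a fast K⁺ conductance active near threshold the model
  fires like a resonator — onset at ≥ 18 Hz and a firing window confined to
  the ramp peak — which contradicts the low-frequency onset that place-cell
  ramps show.
* **Kv2** (slow delayed rectifier, V½ = −30 mV, τ up to ~100 ms) provides
  slow sub-threshold negative feedback.  Together with the persistent Na⁺
  current this yields integrator-like (type-I) onset: sustained firing from
  ~13 Hz near rheobase to ~24 Hz at twice rheobase, so the calibrated ramp
  recruits spikes over a wide window rather than only at its apex.
* **CaT** (V½ = −45 mV) carries a sub-threshold window current.  Its density
  (7×10⁻⁴ S/cm²) was chosen so that, in carbachol mode, nanodomain Ca²⁺
  begins rising during the sub-threshold up-ramp — TRPM4 then shapes both
  limbs of the response instead of acting only after the spike train has
  charged the nanodomain.

KIR is an instantaneous rectifier (V½ = −95 mV); the h-current
(V½ = −82 mV, E = −30 mV) activates on hyperpolarization.

## Calcium handling

Each compartment carries four concentric shells (outermost 0.1 μm thick
when the radius permits, the remainder split equally — four equal shells in
thin processes).  Per shell: radial diffusion (D_Ca = 0.22 μm²/ms),
stationary buffer (150 μM, K_d 2 μM), mobile buffer (30 μM, K_d 0.5 μM,
bound form diffusing at 0.05 μm²/ms), SERCA uptake (Hill n = 2, K 0.4 μM),
ER leak and a constant-baseline IP₃R flux against a fixed 400 μM ER pool
(the leak coefficient is derived to balance SERCA at rest, so the resting
state is an equilibrium by construction), and, in the outer shell only, the
membrane extrusion pump (Michaelis–Menten, K 0.5 μM) and the voltage-gated
Ca²⁺ influx converted by area/(2F·volume).  Longitudinal diffusion couples
like-numbered shells of adjacent compartments.  Buffer kinetics and pump
rates are standard-order values, not fitted quantities; the bulk model's
role is to keep outer-shell Ca²⁺ in the hundreds-of-nM range during ramps,
which the recorded traces confirm.

### Nanodomain

The TRPM4 channel senses a privileged nanodomain obeying

    d[Ca]_ND/dt = X·max(0, −I_Ca)·k + ([Ca]_outer − [Ca]_ND)/τ_ND

with τ_ND = 400 ms (reflecting restricted diffusion between nanodomain and
bulk), X = 0 in control (the nanodomain then tracks the outer shell) and
X = 500 in simulated carbachol.  The influx term is clipped at zero so an
outward Ca²⁺ current cannot drain the domain.  The conversion factor
k (`nd_influx_scale`, default 3 μM·cm²/(mA·ms)) absorbs the unknown
effective nanodomain volume; only the product X·k·I_Ca is behaviourally
constrained (control: sub-μM nanodomain; carbachol: tens of μM, enough to
occupy the 87 μM binding site appreciably).  Its default was set so the
carbachol-mode nanodomain plateaus near 10²  μM during the calibrated ramp.

## TRPM4

Three states — unbound, Ca²⁺-bound closed, open — with binding treated as
instantaneous (K_d = 87 μM against nanodomain Ca²⁺) and voltage-dependent
gating α(V) = 0.0057·exp(0.0060·V), β(V) = 0.033·exp(−0.019·V) ms⁻¹:

    α′ = α/(1 + K_d/[Ca]_ND),  m∞ = α′/(α′+β),  τ = 1/(α′+β)

m∞ is strictly increasing in both V and Ca²⁺.  The current is
g·m·(V − E_CAN), E_CAN = 0 mV (nonselective cation convention,
configurable).  α and β are interpreted as ms⁻¹ (the simulation-time
convention; the steady-state quantities are unit-free).  "Removing the
voltage dependence" evaluates α, β at −60 mV while the Ca²⁺ dependence
stays live.  g_TRPM4 (3.3×10⁻³ S/cm² on soma + proximal trunk) is a free
parameter calibrated so that the carbachol protocol reverses the sign of
the adaptation index while the control protocol leaves TRPM4 silent
(open fraction < 10⁻³).

## Protocols and calibration

A protocol holds the soma at −60 mV — the holding current is found by
bisection, mirroring the experimenter's compensation of the
carbachol-induced depolarization — for 2 s plus however long stationarity
(max |dV/dt| < 0.01 mV/ms) requires, then injects a temporally symmetric
triangular ramp (1 s up / 1 s down by default; 5 s/5 s supported).  Ramp
amplitude is calibrated per mode by deterministic bisection (fixed bracket
0.02–3 nA, 0.01 nA resolution) to the smallest amplitude whose peak
instantaneous frequency reaches the 10–25 Hz band midpoint; the returned
run must land inside the band.  Because carbachol adds inward TRPM4
current, its calibrated amplitude is smaller than control's, as in the
experiments.

Mechanism dissection re-runs the calibrated carbachol protocol with
(1) TRPM4 voltage gating frozen at −60 mV, and (2) frozen gating plus the
full run's recorded nanodomain Ca²⁺ played back into every compartment.
Spike counts order full ≥ playback ≥ frozen (12 ≥ 9 ≥ 5 at the defaults),
separating the contributions of the voltage dependence and of the
spiking→Ca²⁺→TRPM4 positive feedback loop.

## Numerics

* Fixed step Δt = 25 μs.  Voltage: theta-method cable solve (Crank–Nicolson
  θ = ½ during protocols for second-order spike-time accuracy; backward
  Euler θ = 1 during equilibration, where its damping is an asset), with
  channel conductances frozen over the step and the branched system solved
  by Hines (tree-ordered) elimination.
* Markov NaV: propagators e^{QΔt} tabulated on a 0.2 mV grid with columns
  renormalized to sum to one; linear interpolation between grid matrices is
  a convex combination of stochastic matrices, so occupancies remain
  non-negative and conserved to ~10⁻¹¹ over 10-s runs (the engine faults at
  10⁻⁶ drift).  Steady states are cross-checked against the null space of
  the rate matrix.
* HH gates and TRPM4: exact exponential relaxation updates; gate steady
  states and time constants tabulated on the same voltage grid.
* Calcium: operator split — explicit membrane/ER sources, implicit radial
  diffusion (per-compartment 4×4 inverses precomputed; unconditionally
  stable, exactly conservative in the volume-weighted total), semi-implicit
  2×2 buffer binding (exact pair conservation), explicit longitudinal
  exchange.  Nanodomain: exact exponential update.
* Degenerate inputs: non-positive dt, negative concentrations/conductances
  and malformed occupancies raise immediately; a diverging membrane
  potential (|V| > 200 mV or NaN) aborts the run with the failing step.
* Convergence at the defaults: halving Δt leaves spike counts unchanged and
  moves spike times by < 0.5 ms in both modes; halving it again is
  supported but unnecessary.

Problem sizes were chosen as desk-scale defaults: 21 compartments, 2-s
ramps, single-cell runs — large enough for the mechanisms to express,
small enough that the full calibrated experiment runs in seconds.

## Synthetic data

The generators emulate the study's stimuli and recordings:

* triangular ramps (2 s and 10 s symmetric defaults);
* the synaptic stimulus train: 30 pulses whose instantaneous frequency
  ramps linearly *over stimulus index* from 6.7 Hz to 25 Hz at mid-train
  and back (palindromic ISIs, first ISI 149.3 ms, minimum 40 ms, ~2.2 s
  total).  Index-linear scheduling is the simplest rule meeting the three
  printed constraints (count, start and peak frequency);
* surrogate recordings: spike trains constructed to realize a target
  adaptation index (up/down counts rounded to the nearest achievable;
  flagged when rounding was needed), rendered as 2-ms triangular spikelets
  to +20 mV on a −65 mV baseline with seeded Gaussian noise.  Only the
  −40 mV crossing matters to the analysis, so no biophysical spike shape is
  attempted.

Surrogates validate the analysis pipeline (round-trip exactness at zero
noise, ±0.05 at 1 mV noise over 100 seeds).  They do not validate the
biophysics, and passing analysis tests on surrogates says nothing about
real recordings with drifting baselines, partial spikes or artifacts —
the trace-cleaning presets implement fixed thresholds, not artifact
detection.

## Known limitations

* The reduced morphology reproduces orderings, signs and index bands, not
  the absolute spike counts or current magnitudes of a full reconstruction
  (e.g. 10/12 spikes per ramp rather than ~17; interspike TRPM4 ≈ 2.3× the
  persistent Na⁺ current rather than ~4×).
* The NaV and HH rate sets are package defaults satisfying stated
  qualitative constraints, not fits to voltage-clamp data.
* The ER is a fixed reservoir: no IP₃R gating kinetics, store depletion or
  CICR (the modeled mechanism explicitly bypasses store release).
* Ca²⁺ channel driving force is Ohmic with fixed E_Ca = +120 mV (a GHK
  option is out of scope); no temperature corrections; no stochastic
  channel gating.
* Synaptic conductances are not modeled — the stimulus-train generator
  covers only the timing of the synaptic protocol, and the current-ramp
  protocol is the electrophysiological surface of the package.
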