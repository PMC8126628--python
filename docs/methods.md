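# Methods

## Model

`flysleep` simulates a population of `n` identical conductance-based neurons
coupled by electrical gap junctions and driven by a shared circadian gate,
as a minimal model of sleep/wake dynamics in the Drosophila brain.

### Membrane model

Each neuron is a Huber–Braun-type thermoreceptor cell with a leak, two fast
spike-generating currents (Na, K) and two slow subthreshold currents
(persistent Na and Ca-activated K):

    C dV_i/dt = −I_l − α (I_Na + I_K) − β (I_pNa + I_KCa) + I_gap,i + I_drive,i

with each voltage-gated current `I_j = g_j a_j (V − E_j)`.  The fast Na
activation is instantaneous (a logistic function of V); the K and persistent
Na gates relax toward logistic steady states with time constants τ_K =
0.875 ms and τ_pNa = 4.25 ms; the Ca-activated K gate integrates the
persistent Na current, `τ_KCa da_KCa/dt = −η I_pNa − k a_KCa` (τ_KCa =
8.75 ms).  The slow currents reuse the Na/K reversal potentials.  The scale
factors α = β = 4 weight the spike and subthreshold currents.  Units
throughout: mV, mS/cm², μA/cm², ms; with C in μF/cm², C/g is directly a time
constant in ms.

With the default parameter set and zero input, the interplay of the two slow
currents makes the isolated neuron burst spontaneously at ~8.5 Hz (clusters
of 2–4 spikes riding a subthreshold oscillation).  This rhythm is the sleep
signature of the network model.

### Gap-junction coupling

`I_gap,i = Σ_{k∈neighbors(i)} g_gj (V_k − V_i)` over an undirected coupling
graph.  The term is applied diffusively — a neuron below its neighbors is
pulled up — which is the orientation under which electrical coupling
synchronizes; written with the outward-current convention used for the other
membrane currents, this is the `−I_gj` term of the membrane equation.  The
network total of the gap current is exactly zero at all times.  Default
g_gj = 1e-4 mS/cm².

Seven coupling structures are provided: the complete graph (z = 99 at
n = 100), the periodic 10×10 grid (z = 4; periodic boundaries keep every
degree exactly 4), the grid overlaid with a uniformly random k-regular set of
long-range links per neuron (z = 9, 24, 54 for k = 5, 20, 50; the overlay
avoids existing grid edges so the degree increment is exactly k), and
Watts–Strogatz rings with z = 4, 24, 54 at rewiring probability p = 0.03.

### Circadian drive

The clock is a two-variable delay-differential system for the concentrations
of the transcription factor dCLOCK and its repressor PER:

    d[dCLOCK]/dt = v_sc · K2/(K2 + x(t−τ2)) − k_dc [dCLOCK]
    d[PER]/dt    = v_sp · x(t−τ1)/(K1 + x(t−τ1)) − k_dp [PER]

where `x = dCLOCK_free = max([dCLOCK] − [PER], 0)` is the unbound
transcription factor.  Free dCLOCK activates per transcription after the
synthesis delay τ1 and represses dclock transcription after τ2 (so falling x
releases dCLOCK synthesis — a delayed positive loop).  Defaults: v_sc = 0.25,
v_sp = 0.5 nM/h, k_dc = k_dp = 0.5 /h, K1 = 0.3, K2 = 0.1 nM,
τ1 = τ2 = 10 h.

With these values the clock is a relaxation oscillator with a converged
free-running period of 23.12 h (stable under dt refinement 0.02→0.005 h,
independent of initial conditions, and confirmed against an independent DDE
solver).  Each cycle splits into a clamped branch with x = 0 exactly
(10.88 h, "sleep") and a branch with x > 0 ("wake", x peaking near 0.5 nM).
Sleep/wake epoch labels use the clamp directly: sleep iff x ≤ 1e-6 nM (the
clamp makes the threshold value immaterial).

The drive current onto neuron i is

    I_drive,i = (g_dclock [dCLOCK] − g_per [PER]) (E_syn − V_i),  clamped to 0 when [PER] ≥ [dCLOCK]

with g_dclock = g_per = 0.05 mS/cm² and E_syn = +50 mV, i.e. a synaptic
conductance proportional to free dCLOCK with an excitatory reversal.  The
drive is exactly zero during sleep.  Its orientation is configurable
(`drive_sign`): the default `"excitatory"` depolarizes during wake, which is
the physiological reading of a positive-reversal synaptic input and the
orientation under which stronger drives push the network toward tonic wake
firing; `"literal"` applies the opposite (hyperpolarizing) sign.

### Two-timescale bridging

Membrane dynamics run in ms; the clock runs in "model hours".  A
compression factor (default 1 model hour = 1 s of fast time) maps the clock
onto the membrane simulation, so one circadian cycle spans ~23 s of fast
time and a sleep episode ~10.9 s.  Because the coupling is one-way (clock →
neurons), the clock is integrated first on its own grid and its gating
signal is interpolated onto the fast grid, held constant within each fast
step (the clock moves ~1e-8 of a cycle per fast step, so the freeze is
inconsequential).

## Numerics

* Clock: fixed-step RK4 (dt = 0.01 h) with the delayed variable linearly
  interpolated from a ring buffer spanning the delay window; initial history
  is constant at the initial state.  The buffer integration matches a
  dense-storage re-integration to <1e-9 nM.
* Membrane: fixed-step RK4, dt = 0.02 ms (the fastest gate, τ_K = 0.875 ms,
  is resolved by ~44 steps).  The compiled (numba) kernel matches an
  adaptive high-accuracy integration of the same ODE to <0.05 mV over the
  bulk of a trace (spike flanks magnify phase error to ~0.5 mV) and
  converges under step refinement.  Integration aborts with a diagnostic if
  |V| exceeds 500 mV.
* Activation exponents are clipped at ±500 before exponentiation —
  saturation only, far beyond representable overflow.
* Initial conditions: V uniform on [−70, −50] mV per neuron (seeded), fast
  gates at their steady state for that V, a_KCa = 0; clock at
  [dCLOCK] = 0.5, [PER] = 0.1 nM.  The first 24 model hours are discarded
  as burn-in.  Delay settings far from the default (e.g. τ1 = 1 h) have
  much longer transients before the clamped branch is reached; analysis
  windows are therefore planned from a cheap clock-only pre-integration
  (`experiments.choose_duration`) that guarantees the requested number of
  complete sleep episodes, wherever they occur.
* Outputs are downsampled to 2 kHz (500 Hz in sweeps) of fast time;
  epoch-boundary-touching episodes are excluded from duration and spectral
  statistics because their true extent is unknown.

## Analyses

* LFP estimators: network mean of V, and the distance-weighted sum
  Φ = Σ V_i f(r_i) with f(r) = 1 for r < θ and (θ/r)^γ beyond (γ = 2,
  θ = 10 μm defaults).  On the circle layout (all neurons at radius 100 μm,
  electrode at the center) every weight is (10/100)² = 0.01, so the
  distance-weighted LFP is exactly 0.01·n times the mean — the two
  estimators are interchangeable there by construction.
* Spectra: Welch periodograms (2-s Hann segments); band amplitudes are mean
  amplitude spectral density over 3–5, 7–10 and 12–15 Hz; the dominant
  frequency is the PSD argmax on 2–40 Hz.  Episodes shorter than 2 s are
  combined by length-weighted PSD averaging across episodes of the same
  epoch type.  Spectrograms use 1-s Hann windows with 90% overlap (STFT
  default) or a complex-Morlet CWT backend; both show the same sleep ridge.
* Spikes: upward crossings of −20 mV with a 2 ms refractory gap.
* Synchrony: variance-based population coherence
  χ = sqrt(Var_t(V̄)/mean_i Var_t(V_i)) ∈ [0, 1]; exactly 1 on the
  synchronous manifold, ~n^(−1/2) for independent traces.
* Sleep time: mean duration of complete circadian-gated sleep episodes
  (primary, deterministic given the clock); an LFP-scored alternative
  (7–10 Hz short-time power fraction above its record median) is provided
  and agrees with the gated measure when the two behavioral states are
  spectrally separated (see regimes below).
* Sweeps run repeated simulations per parameter value with per-run seeds
  derived as `(base_seed + 1000003·repeat + crc32(value)) mod 2^31` —
  independent across repeats and values, fully reproducible.

## Regimes and a known limitation

The wake drive conductance is g_dclock · x ≤ 0.05 × 0.5 = 0.025 mS/cm².
Mapping the isolated neuron against a constant conductance drive shows the
bursting regime persists up to ~0.075 mS/cm² and yields to tonic ~20 Hz
firing above that.  The default drive therefore leaves wake dynamics inside
the bursting regime: sleep and wake both carry the ~8 Hz rhythm, and the
wake spectrogram retains a 7–10 Hz ridge.  A drive four times stronger
(g_dclock = g_per = 0.2 mS/cm²) separates the states cleanly — sleep keeps
the 8.5 Hz bursting peak, wake switches to tonic firing with the dominant
frequency above 20 Hz and no 7–10 Hz ridge — which is the behavior usually
described for sleep/wake LFP contrast.  Both regimes are pinned by tests;
the default configuration keeps the face-value parameter set rather than
the rescaled drive.

Sleep *timing* statistics are unaffected by this: the gated sleep time is
set by the clock alone, which is why it is flat in g_gj (≈10.9 s across
1e-4…1e-3) and increases with either synthesis delay (τ1: 0.58 h → 13.4 h
of sleep per cycle as τ1 goes 1 → 15 h; τ2 similar).

## What the simulations do and do not show

All experiments are self-generated: the "data" are simulations of the model
itself, so passing tests demonstrate internal consistency (the implemented
equations produce the claimed rhythms, spectra and durations), not fidelity
to recorded fly electrophysiology.  Real LFP recordings contain measurement
noise, non-stationary drives, heterogeneous cell types and chemical
synapses, none of which are modeled.  Chemical synapses, per-neuron clock
heterogeneity, noise and temperature dependence are out of scope; the
Watts–Strogatz synchronization hysteresis is observable qualitatively in
raster scenarios but is not quantified.
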