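# Methods

## Model overview

`fearsim` simulates a rodent fear circuit as twenty interacting
populations of conductance-based leaky integrate-and-fire neurons.
Regions, population sizes, connection weight means and signs are
declared in `src/fearsim/data/default_network.yaml`; behavioural
protocols in `src/fearsim/data/protocols.yaml`.  A behavioural *episode*
is 8,000 integration steps of 0.5 ms (4 s of circuit time); the
behavioural clock that drives the stress hormones advances one minute
per episode plus the configured gaps between phases (15 min for
immediate extinction, 24 h between days).

### Membrane dynamics and integration

The membrane equation, normalised by the leak conductance, is

    τ dV/dt = (E − V) + g_E (E_E − V) + g_I (E_I − V) + η ,

with conductance ratios `g = Σ ω·a / g_leak`-style dimensionless sums.
The stated membrane constants are C = 5.5 pF and g_leak = 10 nS with
τ fixed at 0.5 ms; C and g_leak are retained as metadata and τ governs
both the dynamics and the step.  One iteration applies the **exponential
(exact) integrator**: with conductances frozen over the step, V relaxes
toward the balance potential `V* = (E + g_E·E_E + g_I·E_I)/(1 + g_E +
g_I)` by the factor `exp(−(1+g_E+g_I))`.  A plain forward-Euler update
with step τ is unstable here — synaptic conductance ratios exceed one,
and the Euler update overshoots past the reversal potentials, turning
strong shunting inhibition into a spurious two-step fire/floor
oscillation that lets excitation through.  The exact update is stable
for arbitrary conductances and reproduces the analytic leak relaxation
`E + (V₀−E)e^{−n}` exactly, which is what the integrator tests assert.

Parameters without published values are package choices:

| parameter | value | rationale |
|---|---|---|
| threshold V_th | −50 mV | standard LIF value; 20 mV above rest |
| reset V_reset | −70 mV | equal to the stated resting potential |
| E_E | 0 mV | glutamatergic reversal |
| E_I | −140 mV | effective hyperpolarising reversal; gives inhibitory driving forces parity with excitatory ones in a point-conductance model without slow conductance kernels |
| refractory | 0 steps | a one-step refractory makes driven populations fire on alternating steps, which lets excitation slip past inhibition in anti-phase — an integration artifact, not biology |
| membrane noise σ | 1.0 mV/step (ITC_V: 1.5 mV) | provides threshold flicker for gradual recruitment and replicate variability; ITC_V is the recruitment locus (below) |
| V_peak | 0 mV | spike-trace cosmetic value; computation uses boolean flags |

### Synaptic normalisation

Population input terms are read as *weight times relative source
activity*: each projection's weighted sum over presynaptic spikes is
divided by the source's **nominal active pool** — the k-WTA winner count
for gated layers, the population size for ungated layers, the active
pattern size for the context channel.  This keeps per-step drives on the
tens-of-millivolts scale regardless of layer size and makes the
published weight-table means directly meaningful.  CA1 is normalised by
its full population, so the stress-widened winner pool (10 % → 50 %)
genuinely multiplies CA1's downstream drive.

### Sparsity

k-WTA gating selects, per step, the k neurons with the largest net input
current; ties break toward the lowest index.  Winners keep their
excitatory conductance (scaled by `w_exc`); losers lose it and receive
the pooled global inhibition, so at most k neurons can be driven above
rest.  Fractions: EC_II 50 %, DG 30 %, CA3 5 %, CA1 dynamic (10–50 %),
EC_V 50 % (the "50 % sparsity" statement for EC_V is read as a winner
fraction, symmetric with EC_II), CeL_ON/CeL_OFF/CeM single-winner.

### Plasticity

Pair-based, nearest-neighbour STDP with soft bounds (amplitudes
A₊ = 1.2, A₋ = −0.4; time constants τ_ω = τ₊ = τ₋ = 10 steps; global
dynamic range [0, 10]).  As printed, the rule's exponents grow with the
pairing separation and the depression branch is positive; the
implementation uses the standard decaying windows and a depression
branch that moves weights toward ω_min, preserving the printed
soft-bound structure and the 3:1 amplitude ratio.  A stated zero
depression time constant is rejected at config load.  Pairings separated
by more than 100 steps (window factor ≤ e^{−10}) are dropped.

Two per-projection extensions make multi-episode learning curves
possible — with pairings available at every one of the 8,000 steps, an
unscaled rule saturates any weight within a single episode:

- **learning-rate multiplier** `lr` (scales 1/τ_ω): fear-side
  projections use 5·10⁻⁴ (≈ 2–4 episodes to acquire), hippocampal
  imprinting 2·10⁻³, the extinction gate BA_E→ITC_V 5·10⁻⁴.
- **per-projection bound** `w_max`: LA→BA_F is capped at 4.0 so that a
  fully engaged intercalated pathway can out-compete a fully potentiated
  fear memory; all other plastic projections use the global bound 6.0
  (static weights keep their configured scale and are not clipped).

**Reinforcement gating (`us_gated`).**  Extinction is new inhibitory
learning on *non-reinforced* trials.  The extinction-side projections
(IL ⇄ BA_E, CA1 → IL, BA_E → ITC_V) are flagged `us_gated`: their STDP
is paused in any episode that delivers a shock, the circuit-level
counterpart of aversive neuromodulation vetoing infralimbic plasticity
during reinforcement.  Without this gate, the CS-alone portions of
acquisition episodes are indistinguishable from extinction trials and
the safety circuit pre-saturates during acquisition.

### How the behavioural phenomena arise

- *Baseline:* with no context pattern (Home is a single half-drive
  channel) nothing reaches threshold; calibration terminates at the
  ten-episode minimum with ~0 % freezing.
- *Acquisition:* the US forces LA; LA→BA_F (initial mean 5.0, capped 4)
  drives CeM.  CS→LA potentiates from 0.35 across shock episodes, so
  fear expression builds over the first episodes.  During the US window
  the −US input holds IL down before the BA_E loop ignites, leaving the
  fear pathway unopposed.
- *Extinction:* on CS-alone trials the fear state ignites the
  PL/IL/BA_E tone; ITC_D (LA- and PL-driven) initially vetoes ITC_V.
  ITC_V neurons sit a few millivolts below threshold; membrane noise
  makes them flicker, each spike potentiates its BA_E→ITC_V row, and a
  positive feedback recruits them one by one.  Once enough of ITC_V is
  recruited, its strong projection onto BA_F (mean 8.0) and CeM
  suppresses fear.  The recruitment episode varies across replicates
  (weight draws and noise), producing the declining median extinction
  curve at fifteen replicates.
- *Stress:* the fifteenth cumulative shock episode records an onset;
  later episodes inside the hormonal windows run with (1+β_NE)-scaled
  LC drive on PL/IL and a widened CA1 winner pool, amplifying
  contextual drive onto BA_F.
- *Context specificity:* contexts are 6-of-16 binary patterns with
  pairwise Jaccard overlap 0.2; EC_II/DG k-WTA separates them, and the
  CA1 winner identity keys the plastic CA1→{BA_F, IL, PL} columns.

## Synthetic inputs

The context generator emulates discrete experimental chambers as fixed,
seed-deterministic binary patterns (shared channels model cross-context
generalisation; Home is a distinct low-activity pattern).  It does not
emulate continuous spatial codes, multisensory context drift, or
within-session habituation, so passing tests speak to the protocol
logic and circuit dynamics, not to quantitative freezing levels of real
rodents.

## Statistics

Freezing is the percentage of non-overlapping 125 ms windows (250
steps; ~8 Hz theta) containing ≥ 1 CeM spike.  Replicate batteries run
fifteen independent builds/calibrations per protocol group from seeds
derived off one master seed.  Boxplot summaries use
linear-interpolation quartiles and 1.5·IQR whiskers; the convergence
analysis reports the smallest replicate count from which the t-based
95 % CI half-width of the running mean stays within 5 percentage
points.  Ordering tests compare group medians, with one-sided sign
tests (α = 0.05) where the contrast is expected to be strict.  The
no-shock null control is asserted on the CFC groups (both groups, all
phases), the protocol that exercises every stimulus type.

## Problem sizes

The shipped test battery and the acceptance script use the
quarter-scale network (every population divided by four, minimum two
neurons; 275 neurons in total), the configuration the package treats as
its standard desk-scale setup.  Full-scale (1,112 neurons) runs are a
configuration switch (`scale="full"`).

## Known limitations

- The quarter-scale ITC_V population is five neurons, so extinction
  recruitment is quantal; extinction tends to complete rather than
  settle at intermediate freezing, which weakens context-renewal
  contrasts (extinction in this model is largely context-general).
- Fear-side learning saturates after ~10 shock episodes; very high
  shock counts differ mainly through the stress window, not further
  potentiation.
- The compiled episode kernel and the NumPy reference path are
  bit-compatible only with membrane noise disabled; with noise they use
  different random streams (and the kernel skips noise draws for
  neurons more than 6σ from threshold, where the draw cannot affect the
  spike decision).
- Hormone levels follow a single transient from the most recent onset;
  overlapping stressors do not superpose.
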