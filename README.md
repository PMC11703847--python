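# fearsim

A spiking-network simulator of fear conditioning, extinction and stress,
built around a conductance-based integrate-and-fire model of the rodent
fear circuit: entorhinal cortex and hippocampus (EC_II → DG → CA3 → CA1 →
EC_V), medial prefrontal cortex (prelimbic PL and infralimbic IL), the
nucleus reuniens (RE), and an amygdala microcircuit (LA with its PV/CCK
interneurons, basal fear and extinction populations BA_F / BA_E,
intercalated clusters ITC_D / ITC_V, and the central nuclei CeL / CeM).
The CeM is the behavioural output: freezing is the percentage of 125 ms
theta windows in which CeM emits at least one spike.

It is intended for computational neuroscientists who want a compact,
fully reproducible in-silico test bed for the classic behavioural
protocols — contextual fear conditioning (CFC), shock-magnitude scaling,
stress-enhanced fear learning (SEFL), shock-stress ordering, and the
immediate extinction deficit (IED) — without running animals.

## Model

Each population is a vector of leaky integrate-and-fire neurons obeying

    τ dV/dt = (E − V) + (g_E/g_leak)(E_E − V) + (g_I/g_leak)(E_I − V) + η

with τ = 0.5 ms (one simulation iteration), integrated with the
exponential (exact) update toward the conductance-weighted balance
potential.  Synaptic input is the signed sum of per-projection terms
`ω · a_src · (E_rev − V)`, where `a_src` is the source population's
activity relative to its nominal active pool and the weight means ω
transcribe the published circuit tables.  Hippocampal layers are
sparsified by k-winner-take-all gating (DG 30 %, CA3 5 %, CA1 10 %
baseline); CeL/CeM are single-winner layers.

Plastic projections follow pair-based STDP with soft bounds:

    Δω = (ω_max − ω) · A₊ · e^{−|Δt|/τ₊} / τ_ω    (pre before post)
    Δω = (ω_min − ω) · |A₋| · e^{−Δt/τ₋} / τ_ω    (post before pre)

with A₊ = 1.2 = 3·|A₋| and nearest-neighbour pairing.  Extinction-side
projections (IL ⇄ BA_E, CA1 → IL, BA_E → ITC_V) learn only on
non-reinforced trials — aversive neuromodulation vetoes their plasticity
in any episode containing a shock.

A footshock (US) injects a 1.00 nA current into the sensory layers for
2,000 of the 8,000 iterations of an episode, decaying 0.01 nA per
synaptic layer.  Fifteen cumulative shock-paired episodes trigger a
stress response: tonic norepinephrine β_NE (60-min transient) scales the
locus-coeruleus drive onto PL/IL by (1 + β_NE), and the corticosteroid
transient (120 min) widens CA1 sparsity from 10 % to 50 % at 40 min.

## Worked example

```python
import fearsim as fs

# contextual fear conditioning, group 1 (renewal group), one replicate
results = fs.run_group("cfc", 1, seed=1, scale="quarter")
for r in results[:11]:
    print(f"{r.phase:5s} {r.expression:4s} ep{r.phase_episode:2d} "
          f"freezing={r.freezing_percent:5.1f}%")
```

prints (seed 1, quarter-scale network):

```
CFC1  AX+  ep 0 freezing= 96.9%
CFC1  AX+  ep 1 freezing= 96.9%
CFC1  AX+  ep 2 freezing=100.0%
CFC1  AX+  ep 3 freezing=100.0%
CFC1  AX+  ep 4 freezing=100.0%
CFC2  BX-  ep 0 freezing=100.0%
CFC2  BX-  ep 1 freezing=100.0%
CFC2  BX-  ep 2 freezing=100.0%
CFC2  BX-  ep 3 freezing=100.0%
CFC2  BX-  ep 4 freezing= 25.0%
CFC2  BX-  ep 5 freezing=  3.1%
```

Shock-paired episodes (AX+) drive near-complete freezing as the CS→LA
and LA→BA_F projections potentiate.  The extinction phase (BX−) starts
at full fear expression and collapses once the infralimbic–intercalated
pathway recruits — here at the fifth extinction episode; the collapse
episode varies across replicates, which is what produces the declining
median extinction curve at fifteen replicates.

The same battery is available from the shell:

```
fearsim list-protocols
fearsim run --protocol cfc --replicates 15 --seed 42 --out results/
fearsim analyze results/cfc --convergence
```

`fearsim run` writes `episodes.csv` (one row per episode with the
freezing percentage and a hormone snapshot), `manifest.json` (seed and
configuration digest) and per-phase Tukey boxplot summaries.

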