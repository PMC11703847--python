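# Default fear/stress circuit: region sizes, connection weight means and the
# signed synaptic input sums of the amygdala-hippocampus-mPFC-reuniens model.
# Units here are mV / ms / pF / nS; they are converted to SI on load.
# Signs live in the connection entries (+1 excitatory, -1 inhibitory); weight
# values are non-negative magnitudes drawn from |N(mu, sd)| at build time.
name: default
context_units: 16
context_active_units: 6
context_shared_units: 2

neuron_defaults:
  capacitance_pF: 5.5
  leak_conductance_nS: 10.0
  leak_reversal_mV: -70.0
  exc_reversal_mV: 0.0
  inh_reversal_mV: -140.0
  threshold_mV: -50.0
  reset_mV: -70.0
  peak_mV: 0.0
  tau_ms: 0.5
  noise_mean_mV: 0.0
  noise_sd_mV: 1.0
  refractory_steps: 0

stdp:
  a_plus: 1.2
  a_minus: -0.4
  tau_w: 10.0
  tau_plus: 10.0
  tau_minus: 10.0
  w_min: 0.0
  w_max: 6.0

kwta_defaults:
  w_exc: 1.0
  w_inib: 1.0

regions:
  - {name: EC_II, n: 50, sparsity_fraction: 0.50}
  - {name: DG, n: 500, sparsity_fraction: 0.30}
  - {name: CA3, n: 160, sparsity_fraction: 0.05}
  - {name: CA1, n: 40, sparsity_dynamic: true}
  - {name: EC_V, n: 20, sparsity_fraction: 0.50}
  - {name: IL, n: 20}
  - {name: PL, n: 20}
  - {name: RE, n: 20}
  - {name: LA, n: 50}
  - {name: LA_PV, n: 10}
  - {name: LA_CCK, n: 10}
  - {name: BA_CCK, n: 10}
  - {name: BA_E, n: 50}
  - {name: BA_F, n: 80}
  - {name: BA_PV, n: 10}
  - {name: ITC_D, n: 20}
  - {name: ITC_V, n: 20, noise_sd_mV: 1.5}
  - {name: CeL_ON, n: 10, k: 1}
  - {name: CeL_OFF, n: 10, k: 1}
  - {name: CeM, n: 2, k: 1}

connections:
  # --- entorhinal / hippocampal contextual pathway ---
  - {source: Context, target: EC_II, sign: 1, mu: 1.2}
  - {source: RE, target: EC_II, sign: 1, mu: 3.0}
  - {source: EC_II, target: EC_II, sign: -1, mu: 1.0}
  - {source: EC_II, target: DG, sign: 1, mu: 1.2, plastic: true, lr: 2.0e-3}
  - {source: DG, target: DG, sign: -1, mu: 1.0}
  - {source: EC_II, target: CA3, sign: 1, mu: 1.2}
  - {source: DG, target: CA3, sign: 1, mu: 1.2, plastic: true, lr: 2.0e-3}
  - {source: CA3, target: CA3, sign: 1, mu: 1.2}
  - {source: CA3, target: CA1, sign: 1, mu: 1.2, plastic: true, lr: 2.0e-3}
  - {source: RE, target: CA1, sign: 1, mu: 3.0}
  - {source: BA_F, target: CA1, sign: 1, mu: 1.0}
  - {source: CA1, target: CA1, sign: -1, mu: 1.0}
  - {source: CA1, target: EC_V, sign: 1, mu: 1.2}
  - {source: EC_II, target: EC_V, sign: 1, mu: 1.2}
  - {source: EC_V, target: EC_V, sign: -1, mu: 1.0}
  # --- medial prefrontal cortex and reuniens ---
  - {source: PL, target: IL, sign: 1, mu: 1.2}
  - {source: BA_E, target: IL, sign: 1, mu: 3.3, plastic: true, lr: 5.0e-4, us_gated: true}
  - {source: US, target: IL, sign: -1, mu: 1.2}
  - {source: CA1, target: IL, sign: 1, mu: 1.2, plastic: true, lr: 5.0e-4, us_gated: true}
  - {source: LC, target: IL, sign: 1, mu: 0.2, sd: 0.01, ne_modulated: true}
  - {source: RE, target: PL, sign: 1, mu: 2.0}
  - {source: CA1, target: PL, sign: 1, mu: 0.6, plastic: true, lr: 5.0e-4}
  - {source: BA_F, target: PL, sign: 1, mu: 2.2, plastic: true, lr: 5.0e-4}
  - {source: LC, target: PL, sign: 1, mu: 0.2, sd: 0.01, ne_modulated: true}
  - {source: PL, target: RE, sign: 1, mu: 3.0}
  - {source: IL, target: RE, sign: 1, mu: 3.0}
  - {source: CA1, target: RE, sign: 1, mu: 3.0}
  # --- lateral amygdala sensory hub ---
  - {source: US, target: LA, sign: 1, mu: 1.52, plastic: true, lr: 5.0e-4}
  - {source: CS, target: LA, sign: 1, mu: 0.35, plastic: true, lr: 5.0e-4}
  - {source: LA_PV, target: LA, sign: -1, mu: 0.35}
  - {source: CS, target: LA_PV, sign: 1, mu: 0.5}
  - {source: LA_CCK, target: LA_PV, sign: -1, mu: 1.8}
  - {source: US, target: LA_CCK, sign: 1, mu: 1.8}
  # --- basal amygdala fear / extinction populations ---
  - {source: IL, target: BA_E, sign: 1, mu: 3.3, plastic: true, lr: 5.0e-4, us_gated: true}
  - {source: BA_CCK, target: BA_E, sign: -1, mu: 0.7}
  - {source: LA, target: BA_CCK, sign: 1, mu: 1.9}
  - {source: BA_F, target: BA_CCK, sign: 1, mu: 1.9}
  - {source: LA, target: BA_F, sign: 1, mu: 5.0, plastic: true, lr: 5.0e-4, w_max: 4.0}
  - {source: PL, target: BA_F, sign: 1, mu: 3.6}
  - {source: CA1, target: BA_F, sign: 1, mu: 1.0, plastic: true, lr: 1.0e-3}
  - {source: BA_PV, target: BA_F, sign: -1, mu: 2.0}
  - {source: ITC_V, target: BA_F, sign: -1, mu: 8.0}
  - {source: BA_E, target: BA_PV, sign: 1, mu: 2.0}
  - {source: IL, target: BA_PV, sign: 1, mu: 1.0}
  # --- intercalated clusters and central amygdala output ---
  - {source: LA, target: ITC_D, sign: 1, mu: 1.0}
  - {source: PL, target: ITC_D, sign: 1, mu: 1.0}
  - {source: BA_E, target: ITC_V, sign: 1, mu: 1.0, plastic: true, lr: 5.0e-4, us_gated: true}
  - {source: IL, target: ITC_V, sign: 1, mu: 1.0}
  - {source: ITC_D, target: ITC_V, sign: -1, mu: 1.0}
  - {source: LA, target: CeL_ON, sign: 1, mu: 0.8}
  - {source: CeL_ON, target: CeL_OFF, sign: -1, mu: 0.2}
  - {source: ITC_D, target: CeL_OFF, sign: -1, mu: 1.0}
  - {source: BA_F, target: CeM, sign: 1, mu: 1.9}
  - {source: ITC_V, target: CeM, sign: -1, mu: 1.0}
  - {source: CeL_OFF, target: CeM, sign: -1, mu: 2.3}
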