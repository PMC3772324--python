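# Default model parameters.  Every run configuration is merged over this
# file; unknown keys are rejected by the loader.

membrane:
  C_uF_cm2: 1.0          # specific membrane capacitance
  g_leak_S_cm2: 1.7e-5   # passive transmembrane conductance
  E_leak_mV: -70.0       # leak reversal potential
  g_a_Scm: 0.01          # axial conductance

temperature_K: 303.15    # 30 degC
ca_external_mM: 5.0      # extracellular calcium

morphology:
  swc: null              # path to an SWC file, or null to use `synthetic`
  synthetic:
    n_primary_dendrites: 4
    dendrite_length_um: 200.0
    soma_diameter_um: 16.0
    initial_diameter_um: 2.25
    final_diameter_um: 0.5
    sample_step_um: 5.0
  spines:                # explicit 1 um^3 spine heads
    - {site_um: 25.0, diameter_um: 1.0, length_um: 1.273, dendrite: 0}
    - {site_um: 100.0, diameter_um: 1.0, length_um: 1.273, dendrite: 0}
  f_lambda: 0.1
  lambda_freq_Hz: 100.0
  region_boundaries_um: [50.0, 100.0]   # proximal <= 50 < middle <= 100 < distal
  spine_factors: {proximal: 1.0, middle: 1.3, distal: 3.0}

# Maximal conductances (S cm^-2, ohmic) and permeabilities (cm s^-1, GHK).
# Region tiers: soma / dend (all dendrites) or soma / proximal / middle /
# distal; a plain number applies uniformly.  Explicit spine compartments use
# the tier of the dendrite region they sit in.
densities:
  NaF: {soma: 1.96, dend: 0.0185}
  NaP: {soma: 7.36e-5, dend: 2.86e-7}
  KAf: {soma: 0.247, proximal: 0.247, middle: 0.0429, distal: 0.0429}
  KAs: {soma: 0.0129, proximal: 0.0129, middle: 9.44e-4, distal: 9.44e-4}
  KIR: 4.18e-4
  KRP: 7.3e-3
  BK: 1.58e-3
  SK: 0.0910
  Cav1.2: 1.34e-5
  Cav1.3: 1.7e-6
  CaN: 2.0e-5
  CaQ: 1.2e-5
  CaR: 5.2e-5
  CaT: 8.0e-7

kinetics_file: null      # null -> bundled Wolf/Moyer-derived defaults

receptors:
  mg_mM: 1.0             # magnesium; set 0 for magnesium-free protocols
  # how the calcium-carrying fractions follow dopamine modulation:
  # mu_scaled -> c_z = c_z * mu_z(t); constant -> c_z fixed
  ca_fraction_scheme: mu_scaled
  overrides: {}          # e.g. {NMDA: {gbar_pS: 0.0}}

calcium:
  Ca_ER_mM: 0.20
  Ca_inf_uM: 0.01
  tau_diff_ms: 43.0
  K_CICR_uM: 0.2
  K_uptake_uM: 0.2
  K_pump_uM: 0.1
  V_pump_uM_per_ms: 0.02
  # ER rate constants: working values of the interpretation layer (see
  # docs/methods.md for the mapping from the verbatim literature values
  # recorded below to these per-ms scales).
  V_CICR_per_ms: 3.0e-5
  V_IP3_per_ms: 1.5e-3
  V_leak_per_ms: 1.35e-5
  V_uptake_uM_per_ms: 0.03
  # IP3 receptor dissociation constants (uM)
  d_IP3_uM: 0.13
  d_act_uM: 0.082
  d_inh_uM: 1.05
  d_dis_uM: 0.94
  # IP3 production/removal
  gamma_IP3_uM_per_ms2: 5.0e-3
  beta_IP3_per_ms: 0.2
  tau_IP3_ms: 220.0
  IP3_min_uM: 0.24
  verbatim:  # as-printed source values, kept for provenance (not used directly)
    V_CICR: "3e-12 s^-1"
    V_IP3: "1e-9 s^-1"
    V_uptake: "0.75e-9 uM/s"
    V_leak: "6.15e-14 s^-1"
    V_pump: "0.1 uM/ms"

modulation:
  t_peak_ms: 60.0
  tau_inc_ms: 30.0
  tau_dec_ms: 100.0
  continuous: false      # implement the rising branch verbatim (discontinuous)
  mu_peak:
    NaF: 0.95
    KIR: 1.25
    Cav1.2: 2.0
    CaN: 0.2
    CaQ: 0.5
    NMDA: 1.3
  cav13_shift_mV: -8.0   # peak shift of Cav1.3 activation half-voltage

solver:
  dt_ms: 0.025
  settle_ms: 500.0       # run-in before every protocol, excluded from analysis
  v_table_min_mV: -120.0
  v_table_max_mV: 60.0
  v_table_step_mV: 0.05

protocols:
  up_state_nA: 0.2       # steady somatic current defining the up-state
  post_pulse_ms: 2.0     # width of the spike-evoking somatic step
  post_amp_nA: null      # null -> auto-calibrated smallest multiple of 0.1 nA
  peak_window_ms: [-50.0, 1000.0]   # around first stimulus, baseline-subtracted

integrator:
  tau_ms: 600.0
  a: 20.0

blockades: {}            # channel/receptor name -> multiplier
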