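# Gating kinetics for the ionic channels and synaptic receptors.
#
# These are Wolf/Moyer-derived default reconstructions of the
# Hodgkin-Huxley-style gating used in published D1 medium-spiny-neuron
# models: steady-state sigmoids x_inf(V) = floor + (1-floor) /
# (1 + exp(-(V - vhalf)/k)) (k < 0 for inactivation / inward
# rectification) and time constants tau(V) = tau0 + amp /
# (exp((V-vt)/ka) + exp(-(V-vt)/kb)) (amp omitted -> constant tau0).
# The engine treats this file purely as data; corrected kinetics can be
# dropped in without code changes.
#
# Calcium-dependent gates:
#   hill:  x_inf = Ca^n / (Ca^n + ca_half^n)          (SK)
#   shift: x_inf(V) evaluated at V - s*ln(Ca/ca_ref)  (BK; s < 0 shifts
#          activation leftward as calcium rises)

channels:
  NaF:
    conduction: ohmic
    erev_mV: 50.0
    gates:
      - name: m
        exponent: 3
        inf: {vhalf_mV: -23.9, k_mV: 9.0}
        tau: {tau0_ms: 0.05, amp_ms: 0.30, vt_mV: -35.0, ka_mV: 12.0, kb_mV: 12.0}
      - name: h
        exponent: 1
        inf: {vhalf_mV: -67.0, k_mV: -9.0}
        tau: {tau0_ms: 0.25, amp_ms: 4.0, vt_mV: -55.0, ka_mV: 12.0, kb_mV: 12.0}
  NaP:
    conduction: ohmic
    erev_mV: 50.0
    gates:
      - name: m
        exponent: 1
        inf: {vhalf_mV: -52.6, k_mV: 4.6}
        tau: {tau0_ms: 3.0}
  KAf:
    conduction: ohmic
    erev_mV: -90.0
    gates:
      - name: m
        exponent: 2
        inf: {vhalf_mV: -10.0, k_mV: 17.7}
        tau: {tau0_ms: 0.5, amp_ms: 1.5, vt_mV: -30.0, ka_mV: 15.0, kb_mV: 15.0}
      - name: h
        exponent: 1
        inf: {vhalf_mV: -75.6, k_mV: -10.0, floor: 0.05}
        tau: {tau0_ms: 14.0}
  KAs:
    conduction: ohmic
    erev_mV: -90.0
    gates:
      - name: m
        exponent: 2
        inf: {vhalf_mV: -27.0, k_mV: 16.0}
        tau: {tau0_ms: 3.0, amp_ms: 8.0, vt_mV: -40.0, ka_mV: 20.0, kb_mV: 20.0}
      - name: h
        exponent: 1
        inf: {vhalf_mV: -33.5, k_mV: -21.5, floor: 0.3}
        tau: {tau0_ms: 600.0}
  KIR:
    conduction: ohmic
    erev_mV: -90.0
    gates:
      - name: m
        exponent: 1
        inf: {vhalf_mV: -102.0, k_mV: -8.0}
        tau: {tau0_ms: 5.0}
  KRP:
    conduction: ohmic
    erev_mV: -90.0
    gates:
      - name: m
        exponent: 1
        inf: {vhalf_mV: -13.5, k_mV: 11.8}
        tau: {tau0_ms: 10.0, amp_ms: 30.0, vt_mV: -30.0, ka_mV: 20.0, kb_mV: 20.0}
      - name: h
        exponent: 1
        inf: {vhalf_mV: -54.7, k_mV: -18.6, floor: 0.5}
        tau: {tau0_ms: 3000.0}
  SK:
    conduction: ohmic
    erev_mV: -90.0
    gates:
      - name: m
        exponent: 1
        ca_dependent: hill
        ca_half_uM: 0.65
        hill_coef: 4.0
        tau: {tau0_ms: 4.0}
  BK:
    conduction: ohmic
    erev_mV: -90.0
    gates:
      - name: m
        exponent: 1
        ca_dependent: shift
        ca_ref_uM: 1.0
        shift_mV_per_efold: -20.0
        inf: {vhalf_mV: 0.0, k_mV: 10.0}
        tau: {tau0_ms: 1.0}
  CaN:
    conduction: ghk
    gates:
      - name: m
        exponent: 2
        inf: {vhalf_mV: -8.7, k_mV: 7.4}
        tau: {tau0_ms: 8.0}
      - name: h
        exponent: 1
        inf: {vhalf_mV: -74.8, k_mV: -6.5, floor: 0.21}
        tau: {tau0_ms: 70.0}
  CaQ:
    conduction: ghk
    gates:
      - name: m
        exponent: 2
        inf: {vhalf_mV: -9.0, k_mV: 6.6}
        tau: {tau0_ms: 8.0}
  CaR:
    conduction: ghk
    gates:
      - name: m
        exponent: 3
        inf: {vhalf_mV: -10.3, k_mV: 6.6}
        tau: {tau0_ms: 2.5}
      - name: h
        exponent: 1
        inf: {vhalf_mV: -33.3, k_mV: -17.0}
        tau: {tau0_ms: 65.0}
  CaT:
    conduction: ghk
    gates:
      - name: m
        exponent: 2
        inf: {vhalf_mV: -64.0, k_mV: 4.5}
        tau: {tau0_ms: 1.8, amp_ms: 4.0, vt_mV: -60.0, ka_mV: 15.0, kb_mV: 15.0}
      - name: h
        exponent: 1
        inf: {vhalf_mV: -78.0, k_mV: -5.5}
        tau: {tau0_ms: 120.0}
  Cav1.2:
    conduction: ghk
    gates:
      - name: m
        exponent: 2
        inf: {vhalf_mV: -8.9, k_mV: 6.2}
        tau: {tau0_ms: 1.2}
  Cav1.3:
    conduction: ghk
    gates:
      - name: m
        exponent: 2
        inf: {vhalf_mV: -33.0, k_mV: 6.7}
        tau: {tau0_ms: 1.2}
      - name: h
        exponent: 1
        inf: {vhalf_mV: -45.0, k_mV: -8.0, floor: 0.3}
        tau: {tau0_ms: 30.0}

receptors:
  AMPA:
    gbar_pS: 447.0
    tau_rise_ms: 1.1
    tau_decay_ms: 5.75
    erev_mV: 0.0
    ca_fraction: 0.0005
  NMDA:
    gbar_pS: 226.0
    tau_rise_ms: 2.76
    tau_decay_ms: 150.0
    erev_mV: 0.0
    ca_fraction: 0.01
    mg_block:
      conc_mM: 1.0
      K0_mM: 160.0
      slope_per_mV: 0.10
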