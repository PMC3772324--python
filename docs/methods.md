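# Model and methods

This note records what the simulator computes, which parameters matter,
where the design was genuinely open and what was decided, and what the
synthetic test conditions do and do not establish about real neurons.

## Electrical model

The neuron is a branched graph of iso-potential compartments.  Each
compartment carries a leak current (`g_leak` = 1.7e-5 S cm⁻²,
`E_leak` = −70 mV, `C` = 1 µF cm⁻²), the fourteen active currents listed
in the README, synaptic currents at spine heads, and axial coupling to
its neighbours through the series-resistance conductance
`1/g = 2l_j/(g_a π d_j²) + 2l_{j+1}/(g_a π d_{j+1}²)` with
`g_a` = 0.01 S·cm.  Geometry is stored in µm and converted to cgs inside
the electrical formulas.

Sodium and potassium channels are ohmic with `E_rev` = +50 / −90 mV.
All six calcium channels use the Goldman–Hodgkin–Katz current equation at
T = 303.15 K with external calcium 5 mM; the removable singularity at
V = 0 is handled by a first-order series expansion for |2FV/RT| < 1e-4.

### Morphology and discretization

The default cell is synthetic: a 16 µm soma sphere (modeled as the
equal-area cylinder with l = d) and four straight dendrites of 200 µm,
tapering 2.25 → 0.5 µm, sampled every 5 µm.  Two explicit spine heads of
1 µm diameter × 1.273 µm length (1 µm³) sit at 25 µm and 100 µm path
distance on one dendrite.  Spines attach as single cylinder compartments;
the neck resistance is the axial term of that cylinder itself.

Sections are cut into an odd number of compartments no longer than
`f_lambda` × the AC length constant at 100 Hz (`f_lambda` = 0.1, the
conventional d_lambda values).  Sections additionally split at the region
boundaries so no compartment straddles a spine-correction tier; with
this, total corrected membrane area is conserved under re-discretization
to better than 0.1 %.  Region boundaries (not fixed by any published
value; declared assumption): proximal ≤ 50 µm < middle ≤ 100 µm < distal,
which places the 25 µm spine in "proximal" and the 100 µm spine at the
distal border.  Spine-factor values: proximal 1, middle 1.3, distal 3.
Explicit spine compartments take F = 1 and inherit the channel-density
tier of the dendritic region they sit in.  The default cell discretizes
to 46 compartments; the published tracings this family of models
descends from used finer morphologies (~156 compartments), but regional
homogeneity makes the compartment count non-critical.

### Numerics

One step of length dt (default 0.025 ms; timing scans use 0.05 ms):

1. synaptic dual-exponential states decay; events arriving in the step
   are injected;
2. gates relax exponentially toward their voltage- (and calcium-)
   dependent steady states, using tables precomputed on a 0.05 mV grid
   over [−120, +60] mV (the calcium-dependent SK/BK gates and the
   dopamine-shifted Cav1.3 gate are evaluated per step);
3. the cable system is solved implicitly (backward Euler) with ohmic and
   synaptic terms as conductances frozen at the new gate values and GHK
   currents as explicit sources; the branched linear system is solved
   exactly in one Hines-ordered sweep;
4. calcium and IP3 advance by an explicit flux-balance step (IP3 removal
   integrated exactly); cytosolic calcium is floored at 1e-6 µM.

The state carries a leading batch axis; timing grids, state comparisons
and amplitude searches run as one vectorized simulation.  There is no
randomness anywhere in the model: reruns are bit-identical.  Halving dt
from 0.05 to 0.025 ms changes the triplet-protocol spine calcium peak by
about 1 %.

Initialization: V = E_leak everywhere, gates at steady state, calcium at
its resting target (0.01 µM), IP3 at its floor; every protocol runs a
settling period (400–500 ms) before stimuli, excluded from analysis.

## Gating kinetics are data, with a calibration caveat

The published MSN models this package follows specify channel gating in
a supplementary formulation that is not reproduced here verbatim.  The
bundled `data/kinetics.yaml` is therefore a *reconstruction*: standard
sigmoid/bell parameterizations whose values started from the published
D1-MSN literature and were then calibrated, as the original models were,
against the target physiology — resting potential near −85 mV, an
up-state plateau near −65 mV under 0.2 nA, spike threshold and bAP
attenuation, the state-dependence of brief- versus wide-pulse spine
calcium, and the receptor-isolation orderings.  Two deliberate choices:

* **HVA calcium channel activation is slow relative to the spike**
  (τ_m 2.5–8 ms), so a 1–2 ms action potential opens only a fraction of
  the N/Q/R/L conductance.  This keeps single-bAP spine transients in a
  physiological range and shifts spike-driven influx toward R-type.
* **The T-type channel is a genuine low-threshold window channel**
  (activation V½ −64 mV, inactivation V½ −79 mV, τ_h ≈ 120 ms): fully
  available at −85 mV, almost fully inactivated at −65 mV.  This is the
  mechanism behind the wide-pulse inversion (below).

The NMDA conductance uses a normalized dual exponential with
τ_rise 2.76 ms and τ_decay 150 ms — the slow, NR2B-like decay typical of
corticostriatal NMDARs — rather than the faster cortical value; the slow
tail matters for the glutamate-timing results.  The magnesium block is a
sigmoid relief `1/(1 + (Mg/K0) e^{−sV})` with s = 0.10 mV⁻¹ and
K0 = 160 mM chosen so that block relief between down-state (−85 mV,
~3 % open) and up-state (−65 mV, ~19 % open) matches the observed
state-dependence of NMDAR-mediated spine calcium.  Anyone with the
original gating tables can drop them into the kinetics file without code
changes.

## Calcium parameters: the unit-interpretation layer

The literature values for the ER exchange rates are printed in units
that make the corresponding fluxes dynamically negligible
(e.g. V_CICR = 3e-12 s⁻¹, V_uptake = 0.75e-9 µM/s, and a pump rate
described as a "time constant" in µM/ms).  The dissociation constants
(K_CICR, K_uptake, K_pump, the IP3R d's), the IP3 production/removal
parameters, the ER store level (0.20 mM), the diffusion relaxation
(τ = 43 ms, Ca_∞ = 0.01 µM) and the compartment volumes are used exactly
as printed.  The five V-type rates are exposed in the configuration with
working values on a per-ms scale, chosen once so that each mechanism
operates in its intended dynamic range:

| constant | printed | working value | rationale |
|---|---|---|---|
| V_CICR | 3e-12 s⁻¹ | 3e-5 ms⁻¹ | CICR amplifies transients without self-regenerating at rest |
| V_IP3 | 1e-9 s⁻¹ | 1.5e-3 ms⁻¹ | post-glutamate ER release sustains the >200 ms calcium tail |
| V_uptake | 0.75e-9 µM/s | 0.03 µM/ms | SERCA comparable to extrusion at transient levels |
| V_leak | 6.15e-14 s⁻¹ | 1.35e-5 ms⁻¹ | balances resting efflux so rest calcium sits near 0.01–0.02 µM |
| V_pump | 0.1 µM/ms | 0.02 µM/ms | extrusion slow enough that spine transients persist for tens of ms |

The printed strings are retained in the configuration (`calcium.verbatim`)
for provenance.  The pump reinterpretation deserves emphasis: with the
printed 0.1 µM/ms the spine clears any transient within ~4 ms, which
erases the timing structure the model exists to study; at 0.02 µM/ms the
effective clearance time constant in the 0.1–1 µM range is a few tens of
ms, consistent with the slow transients the model family reports.  The
flux-level operations still honor the printed arithmetic (half-maxima at
the printed K values, saturation at the configured V).

IP3-receptor gates use the printed instantaneous quotient forms; the
release curve is bell-shaped in calcium with its maximum near 0.2 µM.
IP3 production is per-spine (driven by that spine's glutamate clock);
dendritic shafts see removal only.

## Dopamine modulation

µ_z(t̂) follows the published two-branch transient verbatim
(t_peak 60 ms, τ_inc 30 ms, τ_dec 100 ms); note the printed rising
branch does not quite reach µ_peak at t_peak, so the form is
discontinuous there — the default reproduces it as printed, and a
`continuous: true` option rescales the rising branch to join smoothly.
Multiple dopamine events restart the transient (time since the *last*
event).  Modulation applies globally.

Two open magnitudes were fixed here: the Cav1.3 activation shift, not
printed anywhere, defaults to −8 mV at peak with the same temporal
profile (configurable); and the calcium-carrying fractions follow
`c_AMPA = 0.0005 µ_AMPA`, `c_NMDA = 0.01 µ_NMDA` — the second printed
line evidently mislabels c_NMDA as c_AMPA, and the µ-scaled reading is
the default with a `constant` alternative exposed.

The "Post" stimulus is a 2 ms somatic step whose amplitude is the
smallest multiple of 0.1 nA that fires the resting soma, plus a fixed
0.3 nA margin so the pulse stays suprathreshold while dopamine
transiently reduces NaF and enhances KIR (without the margin, a
dopamine event 20–60 ms before Post silently aborts the spike and the
timing maps measure spike failure instead of calcium biology).  Wide
"Post" variants (the 30 ms pulse) reuse the standard 2 ms amplitude.

## What the timing experiments show, mechanistically

* **Up/down states.** KIR (V½ −102 mV) holds the rest near −85 mV; its
  closure under 0.2 nA, checked by the persistent K currents, yields a
  stable, non-spiking plateau near −65 to −67 mV.
* **Brief vs wide pulses.** A 2 ms suprathreshold pulse gives a larger
  spine transient in the up-state (broader spike — A-type inactivation —
  and L-type flux).  A 30 ms pulse inverts the ordering: in the
  down-state the post-spike plateau sits in the T-window for ~10–15 ms
  with inactivation still available, adding ~0.5 µM that the up-state
  (T inactivated) cannot recruit.  Blocking CaT restores the up-state
  advantage.
* **Receptor isolations.** AMPAR-only (sodium, calcium and NMDA currents
  zeroed, magnesium-free): larger in the down-state, a pure driving-force
  effect.  NMDAR-only: larger in the up-state via block relief.
* **Paired timing.** Glu-before-Post beats Post-before-Glu (NMDA
  conductance and accumulated NMDA calcium present at the spike);
  DA-before-Post beats Post-before-DA with the optimum at the µ peak
  (+60 ms), via Cav1.2 doubling and the Cav1.3 shift.
* **Triplet optima.** On the 10 ms grid the up-state proximal optimum
  lands at Δt_DA ≈ +60–70 ms, Δt_Glu = +50 ms; the down-state glutamate
  optimum shifts early (+10–20 ms).  The up-state late-glutamate
  preference comes from pre-spike NMDA calcium accumulating at −65 mV
  (partial block relief) — a pathway the down-state lacks — so the
  down-state optimum stays at the NMDA-conductance coincidence lag.
* **Integrator readout.** The leaky integrator (τ = 600 ms, a = 20)
  weights the sustained part of the transient; dopamine timing switches
  which glutamate order wins, and removing the DA→NMDAR modulation
  (µ_NMDA ≡ 1) collapses the glutamate-timing dependence several-fold.

## Problem sizes

Default analyses use the 46-compartment synthetic cell.  Membrane-state
runs are 2 s at dt 0.025 ms; timing scans run the full ±100 ms, 10 ms
grid (441 cells per state) at dt 0.05 ms as one batched simulation,
roughly three minutes per state on one core.  The test suite uses the
same morphology with shorter settling (400 ms) and windows, and
quadrant-restricted grids whose argmax was verified to coincide with the
full-grid argmax.

## Known limitations

* Gating kinetics are reconstructions; quantitative trace-level agreement
  with the original tables is not claimed, only the calibrated
  physiology and orderings above.
* Under the potassium/sodium blockade protocol the model shows an
  enhanced, plateau-like somatic calcium response rather than repetitive
  regenerative calcium spikes; the subthreshold persistent K currents
  still dominate the depolarized V range.
* Long depolarizing steps have a high rheobase (~1 nA); near-rheobase
  delayed firing of real MSNs is not reproduced, and hyperpolarizing
  responses are the validated half of the step family.
* Spine EPSP amplitude is driving-force-dominated, so the somatic EPSP is
  larger in the down-state even though the calcium response is larger in
  the up-state; and the glutamate-evoked spine calcium does not exceed
  the bAP-evoked response at the proximal spine.
* No explicit buffer species and no ER depletion (the store level is
  clamped); D2-type cells, GABAergic input, receptor desensitization and
  stochastic gating are out of scope.
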