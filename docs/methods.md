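# Methods

## Model structure and assumptions

The simulator integrates a single-compartment-per-organelle ("well-mixed")
neuron: cytosol, mitochondria and ER each carry one Ca²⁺ concentration,
with fast-buffer fractions f_i (cytosol/ER) and f_m (mitochondria)
scaling the free-ion balances. Three sub-models are composed:

1. **Mitochondrial Ca²⁺ handling and bioenergetics** (Fall–Keizer /
   Magnus–Keizer lineage). Ca²⁺ enters the matrix through a uniporter
   with MWC allosteric activation by cytosolic Ca²⁺ and a
   membrane-potential driving factor, and leaves through a Na⁺/Ca²⁺
   exchanger (fixed Na⁺ saturation factor, (9.4/30)²; no sodium state
   variable). Respiration, F₀/F₁-ATPase, the adenine nucleotide
   translocator, a proton leak and glycolysis/hydrolysis close the
   energetic loop; matrix Ca²⁺ activates pyruvate dehydrogenase and hence
   NADH production. The empirical constants inside these kinetic forms
   (1.35e18, 0.191, 1.71e9, …) are part of the published expressions and
   are kept literally.
2. **ER Ca²⁺ handling.** A reduced IP₃-receptor open probability
   `(IP3/(IP3+d_IP3))³ (CAC/(CAC+d_ACT))³ h³` plus a passive leak drives
   release down the ER→cytosol gradient; SERCA pumps back with Hill
   coefficient 2. The inhibition gate h relaxes toward
   d_INH/(CAC+d_INH) with time constant τ = 4, producing
   calcium-induced-calcium-release oscillations under stimulation.
3. **Amyloid feedback.** A single generic amyloid pool grows at a basal
   rate plus a Ca²⁺-stimulated Hill term, decays first-order, and feeds
   back on the cytosol through a quartic membrane-permeabilization term
   k_β·a⁴. At resting Ca²⁺ the Hill term is negligible, so the pool
   relaxes to V₁/K₁ = 0.65 nM on the 1/K₁ = 100-unit scale; the a⁴ entry
   term then supplies a slowly growing Ca²⁺ load.
4. **PTP gating** (Oster-type). The slow trigger y relaxes toward
   θ(CAM − CAM*) with τ_y = 1000·(1000/cosh(CAM/0.1) + 0.1): ~10⁶ at
   rest, 100 when the matrix is loaded, so only *sustained* overload
   advances y. The high-conductance gate follows θ(y − y*) with
   τ_h = τ_y/8. The low-conductance gate is pH-operated: a tanh target
   in the matrix proton concentration H_M with midpoint p1 and width p2,
   and a time constant sharply peaked (amp_τ = 26000) at H_M = p3, which
   makes it a fast threshold element once H_M drifts. Pore fluxes:
   protons via a GHK-style term, Ca²⁺ as a PTPₗ-proportional bypass of
   the uniporter whose sign flips once PTPₕ passes 1/postptp = 0.5.

The stimulus is an IP₃ square step (baseline 0.3 µM, amplitude 0.3 µM,
on at t = 10 for 100 time units) standing in for an action potential.

## Units and time convention

Rate expressions are implemented exactly as the source tables print them,
including the literal conversion constants uMmM = 1000 and τ_min = 60.
The integration variable t is the model's displayed time unit; no
dimensional reconciliation across sub-models is attempted, because the
composed tables mix per-second and per-minute conventions that only the
original authors' code could disambiguate. All milestone comparisons are
therefore made on the displayed-time axis. Within that convention the
model is fully determined and deterministic.

## Closures chosen where the source is silent

Three quantities appear in the equations without a defining relation;
each is an explicit, configurable parameter:

* **H_M(0)** — not tabulated. Default 0.0231 = p3, which puts the
  low-conductance gate target at ≈0, consistent with PTPₗ(0) = 0.
* **ATP_i** — consumed by glycolysis/hydrolysis but never defined.
  Default conservation ATP_i = A_tot_cyt − ADP_i with A_tot_cyt = 2 mM,
  mirroring the mitochondrial adenine conservation (12·d_mito/uMmM).
* **s_a** — the amyloid entry term couples an nM-scale quantity into the
  µM-scale calcium balance; the printed form has no conversion factor.
  Default s_a = 1 (as printed), exposed for sensitivity studies.

Also: the exchanger's `0.003·d_mito` factor is kept as an explicit
half-saturation K_nc = 3 µM; the duplicated leak constants (two names,
one value 0.1) are backed by a single field; h(0) printed as 95% is
stored as the fraction 0.95.

## Numerics

* **Stiffness.** Time constants span ~10 decades (τ_l ≈ 26000 down to
  gate relaxations of ~10⁻³ once H_M leaves p3). The integrator is
  scipy's BDF with rtol 1e-8, atol 1e-10, max step 0.5.
* **Discontinuities.** The Heaviside targets are kept sharp. The IP₃
  step edges partition the run; crossings of CAM = CAM* and y = y* are
  located by the solver's event root-finding, logged, and used as
  restart points, with a 1e-6 dead time so a restart at the root cannot
  immediately re-trigger the same event. Smoothing the steps instead
  would shift the opening milestones.
* **Removable singularities.** The uniporter's 0/0 at Ψ = 91 mV and the
  pore proton flux's pole at Ψ = 0 are evaluated by series/`expm1`
  forms, so every flux is finite on the physiological box.
* **Domain guards.** Inside flux evaluation (only), concentrations are
  clipped at zero; the integrated state is never modified. Conserved
  pools (total adenine, total pyridine) are algebraic closures, so their
  conservation is exact by construction. cosh-based time constants use
  an overflow-safe sech.
* **Determinism.** No randomness anywhere; identical configurations
  produce bit-identical trajectories, and the run manifest reproduces a
  CSV byte-for-byte.
* **Output.** Dense output on a uniform grid (default spacing 0.05).
  Milestone crossings are interpolated linearly between grid points;
  the spike peak is refined by a local quadratic fit.

## Metrics definitions

* *Spike peak*: maximum of the variable over [stimulus onset, onset+50].
* *Oscillation decay time*: last instant the series sits outside a band
  of 5% of its peak excursion around the pre-stimulus baseline — an
  envelope criterion robust to small residual ripples; a trajectory that
  ends outside the band is flagged "not decayed".
* *PTP opening*: first upward crossings of PTPₕ through 0.01 ("starts
  opening") and 0.99 ("open"), both thresholds exposed as options.

With the defaults, the pathology preset opens the pore at t ≈ 742.0 and
completes by ≈ 799.5; the no-pathology preset's oscillations decay by
≈ 102.4 and the cell returns to rest. The 0.01→0.99 transit is pinned by
the gate law itself: at the matrix-Ca²⁺ level prevailing at opening,
τ_h = τ_y/8 = 12.5, so the transit is τ_h·ln(99) ≈ 57.6 regardless of any
of the configurable closures above. A longer transit would require
τ_h ≈ 27, i.e. matrix Ca²⁺ near 1 µM at opening — excluded by the trigger
threshold CAM* = 4 µM — so reported transits of ~123 in this model family
must reflect different (unstated) crossing thresholds rather than
different dynamics.

## Problem sizes

The full pathology run integrates 13 states over 1000 time units
(≈20k output samples, ~10 s on one core); the healthy run spans 500
units. The test suite re-runs both presets once (shared fixtures), plus
tolerance-halved replicas for the robustness check.

## What the presets do and do not show

The presets are the model's own study conditions, not data. They
demonstrate the qualitative repertoire — rest stability, transient CICR
oscillations, amyloid-driven overload, one-way PTP switching — and exact
internal consistency (conservation laws, closed-form gate relaxations,
dual-route flux evaluation). They do not calibrate any parameter against
experimental recordings; absolute times and concentrations inherit the
composed tables' unit conventions and should be read comparatively, not
as physiological predictions.

## Known limitations

Spatially homogeneous compartments (no microdomains); no downstream
apoptosis machinery (cytochrome-c release, caspases) — the simulation
ends at the irreversible PTP opening; a fixed Na⁺ factor in the
exchanger; no parameter estimation. The XPP exporter emits the model but
does not parse `.ode` files.
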