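# neurocalc

A simulator for the coupled dynamics of neuronal calcium signaling,
mitochondrial bioenergetics, β-amyloid feedback and the mitochondrial
permeability transition pore (PTP) in a single neuron. It is aimed at
systems-biology modelers studying how chronic amyloid accumulation distorts
calcium homeostasis and drives a neuron across the irreversible,
apoptosis-triggering opening of the PTP — and at anyone who wants a tested,
scriptable implementation of this class of composite Ca²⁺/bioenergetics
models.

## The model

Thirteen coupled stiff ODEs describe cytosolic, mitochondrial and ER
calcium (CAC, CAM, CAER, in µM), a generic β-amyloid pool *a* (nM), the PTP
gating subsystem (high/low-conductance activations PTPₕ, PTPₗ, a slow
trigger *y*, matrix protons H_M), and the bioenergetic state (membrane
potential Ψ, NADH_m, ADP_m, ADP_i, plus the IP₃-receptor inhibition gate
*h*). The calcium balances take the Fall–Keizer form

```
dCAC/dt = f_i/(V_c τ) [ M (J_nc − J_uni − J_PTP^Ca) − E (J_serca − J_er,out) ] + k_β a^m
dCAM/dt = f_m M/(V_m τ) (J_uni − J_nc + J_PTP^Ca)
dCAER/dt = f_i E/(V_e τ) (J_serca − J_er,out)
```

with Magnus–Keizer kinetics for the uniporter (MWC allosteric form),
Na⁺/Ca²⁺ exchanger, respiration, F₀/F₁-ATPase, ANT, proton leak and
glycolysis. The amyloid pool obeys
`da/dt = V₁ + V_α/(1 + (K_α/CAC)ⁿ) − K₁ a`; the `k_β a⁴` entry term closes
a positive feedback loop between amyloid load and cytosolic calcium. The
PTP opens through a slow process `dy/dt = (θ(CAM − CAM*) − y)/τ_y` that
integrates sustained mitochondrial Ca²⁺ overload; once *y* crosses *y**,
the high-conductance gate relaxes to open on the faster constant τ_y/8 —
an effectively one-way switch. An IP₃ step stimulus (0.3 → 0.6 µM over
t = 10–110) plays the role of an action potential.

Two presets bracket the biology:

* **`no_pathology`** — amyloid synthesis disabled (V₁ = V_α = K₁ = 0): the
  stimulus evokes a Ca²⁺ spike and transient oscillations that die out,
  and the cell returns to rest; the PTP never opens.
* **`pathology`** — full defaults: amyloid accumulates, calcium entry
  grows, mitochondria load past threshold, and the PTP opens in the
  high-conductance state, after which CAM freezes ("the mitochondrion is
  no longer functional") while CAC and CAER escalate.

## Worked example

```sh
neurocalc simulate --scenario pathology --t-end 1000 --out run/
neurocalc metrics --in run/timeseries.csv --out run/metrics.json
```

prints (metrics summary line):

```
peak 1.487 uM at t=12.6; decay 1000.0; PTP onset 742.0, completion 799.5, duration 57.4
```

Meaning: the stimulus at t = 10 drives cytosolic Ca²⁺ to a 1.49 µM spike;
the PTP high-conductance gate starts opening (PTPₕ > 0.01) at t ≈ 742 and
is fully open (PTPₕ > 0.99) by t ≈ 799; cytosolic calcium never returns
to its pre-stimulus baseline in this scenario (decay time = the full
horizon, flagged `"decayed": false` in the JSON) because the dying
mitochondrion floods the cytosol. In the `no_pathology` scenario the same
metric reports ≈102 with `"decayed": true`. The same calls are available
in Python:

```python
from neurocalc import make_scenario, simulate, compute_metrics

sc = make_scenario("pathology")
traj = simulate(sc.params, sc.init, sc.stim, sc.solver)
print(compute_metrics(traj).to_json())
```

`neurocalc export-ode --out model.ode` writes the identical model as an
XPP/XPPAUT `.ode` file for cross-validation.

## Layout

| module | contents |
|---|---|
| `neurocalc.params` | parameter set (table defaults), initial state, scenario presets, compartment/nucleotide closures, TOML config IO |
| `neurocalc.fluxes` | bioenergetic fluxes (uniporter, exchanger, respiration, ATPase, ANT, leak, glycolysis, PDH coupling) |
| `neurocalc.er` | IP₃ stimulus, IP₃-receptor/leak release, SERCA, inhibition gate |
| `neurocalc.amyloid` | amyloid kinetics and the Ca²⁺-entry coupling |
| `neurocalc.ptp` | PTP gating (slow trigger, both gates, pore fluxes, matrix protons) |
| `neurocalc.simulate` | 13-variable RHS and event-aware stiff integration |
| `neurocalc.metrics` | spike peak, decay time, PTP opening times |
| `neurocalc.cli` / `neurocalc.xpp` | command line, manifests, `.ode` export |

See `docs/methods.md` for the modeling assumptions, unit conventions and
numerical choices.
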