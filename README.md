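# brswedge

Multiscale simulation of Brugada-syndrome (BrS) ST-elevation substrates
on synthetic wedge geometry.

BrS shows dynamic coved-type ST-elevation in ECG leads overlying the
right ventricular outflow tract (RVOT), and two mechanistic hypotheses
compete: **delayed depolarization** — slowed conduction in a thin
epicardial RVOT layer — and **early repolarization** — loss of the
epicardial action-potential dome through excess transient-outward
current I_to. `brswedge` implements both substrates in one pipeline so
they can be contrasted under identical conditions, at desk scale:

- **Cell**: the O'Hara–Rudy (ORd) human ventricular myocyte model
  (endo/epi variants), with multiplicative G_to / G_Ks / G_Na scaling,
  Rush–Larsen + forward-Euler integration at 50 µs, and a
  conduction-calibrated ten Tusscher I_Na variant for tissue runs.
- **Tissue**: anisotropic monodomain FEM,
  `beta*Cm dV/dt = div(sigma grad V) - beta*Iion`, linear simplicial
  elements, consistent mass matrix, Crank–Nicolson at the shared 50 µs
  step (σ_l/σ_t = 0.18/0.08 S/m, β = 140,000 m⁻¹, Cm = 1 µF/cm²).
- **Geometry**: jittered transmural wedge (2D sheet default, 3D slab
  supported) with rule-based fiber rotation (+60° → −60°), a 3-fold
  apex–base G_Ks gradient, and an epicardial substrate patch whose
  longitudinal conductivity falls linearly 0.09 → 0.009 S/m toward the
  center with 1000-fold transverse attenuation.
- **ECG**: reciprocity lead fields on a conforming box torso
  (Φ = −φᵀ K_i V_m), Wilson's-central-terminal referencing, and
  morphology readouts (J-point, coved/saddleback ST classification,
  T-wave metrics, activation maps).

## Worked example

Single-cell loss-of-dome bifurcation (epicardial cell, CL 800 ms,
steady-state pacing per integer G_to fold):

```python
>>> from brswedge.scenarios import single_cell_study
>>> res = single_cell_study(tuple(range(1, 21)))
>>> res["threshold_fold"], round(res["apd90_at_threshold_ms"], 1)
(13, 121.1)
>>> res["table"].iloc[[0, 11, 12]][["fold", "apd90_ms", "has_dome"]]
    fold    apd90_ms  has_dome
0      1  225.768230      True
11    12  308.916466      True
12    13  121.148359     False
```

Raising G_to first *prolongs* the AP (226 → 309 ms at 12-fold), then the
dome collapses abruptly: at 13-fold the AP is spiky and APD90 drops by
more than half. Electrotonic coupling shifts this threshold up in
tissue: the same scan inside the wedge substrate (see
`tissue_gto_threshold`) collapses only at substantially higher folds.

A full scenario with ECG readouts:

```bash
brs run delayed_depol --seed 1 --out out/
# delayed_depol: J(V2_ICS3) = 1.943 (threshold 1.476), ST class = coved,
#   substrate delay = 13.5 ms
```

The substrate-facing lead (`V2_ICS3`, directly over the patch) shows an
elevated J-point with a monotonically descending ST segment into a
negative T-wave — the coved BrS pattern — while the `healthy` scenario
classifies `none`. `brs sweep`, `brs cell-scan`, `brs cv-study` and
`brs fig3` cover the parameter sweeps, the bifurcation scan, the
conduction-velocity studies and a multi-panel ECG comparison plot.

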