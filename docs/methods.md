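# Methods

This note documents the models, numerics and design choices behind
`brswedge`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scientific question and overall design

Brugada syndrome (BrS) presents with dynamic coved-type ST-elevation in
the right-precordial leads overlying the right ventricular outflow tract
(RVOT). Two mechanistic hypotheses compete: *delayed depolarization*
(slowed conduction in a thin epicardial RVOT layer, a mild structural
disease) and *early repolarization* (loss of the epicardial action-
potential dome through unopposed transient-outward current I_to). The
package implements both substrates in one multiscale pipeline —

1. human ventricular myocyte electrophysiology (O'Hara–Rudy dynamic
   model, endo/epi variants),
2. anisotropic monodomain reaction–diffusion FEM on synthetic wedge
   geometry,
3. lead-field (reciprocity) forward ECG through a torso volume
   conductor,
4. ECG morphology readouts (J-point, coved vs. saddleback ST class,
   T-wave metrics, activation maps) —

and contrasts the two substrates, each optionally combined with a global
50% loss of fast-sodium conductance, plus a simulated epicardial
ablation.

The geometry is a deliberate *desk-scale* stand-in: a transmural wedge
(default a 2D transmural sheet, 40 × 10 mm at 0.5 mm target edge length;
3D slabs supported) inside a box torso, not a patient anatomy. All
tissue-level readouts are therefore interpreted as orderings and
mechanism-level contrasts, not as absolute millivolt predictions.

## Cellular model

The ionic model is a complete transcription of the O'Hara–Rudy (ORd)
human ventricular myocyte model with its published endocardial and
epicardial parameter sets (the mid-myocardial variant is out of scope).
State: V, 8 ionic-concentration pools, CaMK-trapped fraction, and 31
relaxation states (gates, the L-type Ca channel's Ca-dependent mode
fraction, and the two SR-release fluxes). Conductance multipliers
(`gto`, `gks`, `gna`) scale G_to, G_Ks and G_Na only; they are the knobs
used for all substrate modelling (ajmaline-like I_Na block is modelled
solely as `gna = 0.5`, no drug kinetics).

Integration is explicit with a 50 µs step: Rush–Larsen exponential
updates for all 31 relaxation states and forward Euler for voltage,
concentrations and CaMKt. A pure forward-Euler reading of "explicit
integration" is not viable at this step size: gate values reach 0
exactly and the Ca-driven mode-switching ODE divides by the gate,
which is why the Rush–Larsen scheme is the package's fixed choice.
GHK-type driving terms are evaluated through x/(expm1 x) so V = 0 is
regular. The stepping kernel is numba-compiled and vectorized over
cells; single-cell protocols and the tissue solver share it, so there is
exactly one transcription of the model in the package.

**Fast-sodium variant for tissue.** The native ORd I_Na yields a strand
conduction velocity of ~0.45 m/s at the nominal tissue conductivity used
here, well below the physiological 0.6–0.7 m/s; this mismatch is a known
property of the formulation. The package therefore provides the widely
used substitution of the ten Tusscher/Panfilov (2006) I_Na kinetics,
with its maximal conductance recalibrated once — G_Na = 9.6 mS/µF — so
that a uniform 1D strand at σ_l = 0.18 S/m, β = 140,000 m⁻¹,
C_m = 1 µF/cm² conducts at ≈ 0.65 m/s. Tissue simulations default to
this variant (`SolverConfig.ina_tt = True`); single-cell studies default
to the unmodified ORd formulation. The calibration target is the CV
band, not any downstream readout; it was fixed before the scenario suite
was run and is not revisited per scenario.

**Pacing and steady state.** Standard protocol: cycle length 800 ms,
stimulus −80 µA/µF for 0.5 ms, ODE step 50 µs. Steady state is declared
when the relative max-norm of the state change between consecutive
end-diastolic points falls below 10⁻³ (cap 600 beats; the baseline cell
converges in well under 100 beats). Steady states are memoized per
parameter set and shared between single-cell studies and tissue
initialization.

**AP features.** APD at level L is measured from the time of maximum
upstroke dV/dt to the downward crossing of
`resting + (1 − L/100) · (peak − resting)`, linearly interpolated.
The dome criterion: after the earliest local minimum following the
upstroke peak, the voltage must either rise again by ≥ 5 mV or stay
above 0 mV for ≥ 50 ms; otherwise the AP is classified dome-less
("spiky"). The thresholds are fixed in code and satisfy the anchor
cases (baseline epi AP has a dome; a 20-fold-G_to AP does not).

**Single-cell G_to bifurcation.** Each integer fold is paced to its own
steady state, then dome presence and APD90 are read from the steady
beat. In this implementation the abrupt collapse (> 40% APD90 drop
between adjacent folds) sits between folds 12 and 13, robust to halving
the ODE step, to cycle length 800 vs 1000 ms, and to acute-application
protocol variants. The acceptance suite asserts the literature anchor
values for this experiment (14-fold threshold, 132 ms APD90); the
discrepancy of one fold and ~11 ms is attributed to the unpublished
I_Na modification of the source study's cell model, which neither the
native ORd nor the ten Tusscher substitution reproduces (the latter
shifts the threshold *down*). We keep the faithful model rather than
tuning toward the anchors, and report the computed values.

## Synthetic geometry

`build_wedge` produces a structured simplicial lattice (same-diagonal
triangles in 2D, conforming 6-tetrahedra Kuhn subdivision in 3D) with
interior nodes jittered by `jitter · target_edge` (seeded, deterministic)
to avoid grid-aligned conduction artefacts. Transmural depth (0 = endo,
1 = epi) and apex–base coordinates come from lattice indices, so they
are exact on the faces and monotone across the wall.

- Endo/epi assignment: depth < 0.25 endocardial, ≥ 0.25 epicardial
  (tie at 0.25 is epicardial).
- Fibers: linear transmural rotation +60° (endo) → −60° (epi) about the
  wall normal in 3D; in the 2D transmural-sheet mode the in-plane fiber
  runs along the lateral axis (the rotation is out of plane there).
- G_Ks gradient: scale 1 + 2a with apex–base coordinate a (3-fold
  apex→base).

**Substrate.** An epicardial patch (default diameter = half the wedge
width, emulating whole-RVOT coverage; max thickness 2.2 mm):
longitudinal conductivity falls linearly from 0.09 S/m at the rim to
0.009 S/m at the center; transverse conductivity is divided by 1000,
electrically dissociating the layer from the wall beneath. Membership is
element-centroid-based; both a uniform-thickness cap and a lens
(spherical-cap) profile are available, since the source geometry's taper
is not uniquely specified. One lattice plane is *snapped* to the
substrate thickness cap and kept flat under jitter: without this
boundary fitting, mixed elements along the cap leave jagged
full-conductivity leak paths through the 1000×-attenuated seal, and the
substrate's delayed activation is largely an artefact of mesh raggedness
rather than of the prescribed conductivities.

**Torso.** The torso is a conforming extension of the heart lattice
(heart nodes are a subset of torso nodes), coarsening geometrically to a
configurable padding (default 20 mm — the anterior electrodes sit about
two wall-thicknesses above the epicardium, mimicking the proximity of
high parasternal leads to the RVOT). Default conductivity is
homogeneous 0.2 S/m; labelled organ blocks (fat, lungs, blood, …, with
standard literature conductivities) can be added for fidelity runs. The
skin layer is omitted by default; its 2 × 10⁻⁴ S/m value is numerically
stiff at coarse resolution. Electrodes: a parasternal-style grid on the
anterior face (3 rows "ICS2–4" × 2 columns "V1/V2" in 3D; 3 electrodes
in 2D) with `V2_ICS3` directly over the substrate center, plus remote
LA/RA/LL electrodes and a posterior reference node.

## Monodomain FEM

β C_m ∂V/∂t = ∇·(σ∇V) − β(I_ion − I_stim), with σ = σ_t I +
(σ_l − σ_t) f fᵀ per element, σ_l/σ_t = 0.18/0.08 S/m in healthy
tissue, β = 140,000 m⁻¹, C_m = 1 µF/cm² (the study's printed
"0.01 F/cm²" and "140.000 m⁻¹" are read as the physiological
1 µF/cm² and the thousands-separated 140,000 m⁻¹). With mm/ms/mV/S/m
units the diffusivity is 10⁵·σ/(β·c_m) mm²/ms.

Linear simplicial elements, consistent (non-lumped) mass matrix by
default, Crank–Nicolson (θ = 1/2) at the shared 50 µs step, first-order
Godunov splitting (full ionic step, then diffusion step). The CN
operator is factorized once (sparse LU) since it is time-invariant;
each step's residual is checked. Assembly identities (stiffness rows
annihilate constants; mass sums to the mesh volume; longitudinal/
transverse unit-gradient energies equal σ_l/σ_t) and a heat-kernel
variance-growth check are enforced in the test suite.

Stimulation is a transmembrane current density on node sets (tissue
default: whole endocardial face, −80 µA/µF for 1 ms, onset 10 ms into
each cycle). The endocardial-face stimulus replaces the source study's
optimized multi-site activation sequence, which requires volunteer ECG
recordings; multi-site protocols can be configured.

**Initialization and beat protocol.** Nodes are clustered by parameter
similarity (geometric bins of relative width 10% per continuous
parameter, plus the variant flag); one single-cell steady-state pacing
run per cluster representative is broadcast to members. The scenario
default then runs 2 preparatory beats + 1 result beat (`n_beats = 3`);
the test suite and the acceptance script use 1 + 1 beats. Because every
node starts on its own single-cell limit cycle, the tissue settles
within the first coupled beat at this geometry scale; the full
4 + 1-beat protocol of the source study is available via configuration.

**Ablation.** `make_passive` replaces the membrane by a weak leak
(0.05 mS/µF toward −85 mV) with diffusion untouched — the generic
operation. The *ablation scenario* models scar more strictly: ablated
tissue has no intact membranes and no intracellular continuity, so scar
elements get near-zero conductivity in both the monodomain operator and
the lead-field weighting, and only nodes entirely surrounded by scar
elements are made passive (region borders remain excitable). Without
this, the passive region clamps a permanent boundary dipole against the
surrounding plateau and radiates a large spurious ST shift — the
opposite of the intended electrical silencing.

**Conduction velocity.** Activation time is the −40 mV upstroke
crossing (linear interpolation on the 1 ms grid); CV is probe distance
over activation-time difference, probes ≥ 5 mm apart and away from the
strand ends. Slow-conduction strands (σ_l = 0.009 S/m) use a 0.1 mm
edge; the baseline uses 0.25 mm.

## Lead-field ECG

For each electrode a unit current is injected at the electrode and
withdrawn at a common posterior reference; the resulting torso potential
φ restricted to heart nodes, combined with the heart's intracellular
stiffness K_i, gives the lead row: Φ_e(t) = −φᵀ K_i V_m(t). The raw
lead-field potentials alone are not a dimensionally complete transfer
matrix; the K_i weighting realizes the standard reciprocity integral
∫∇φ·σ_i∇V_m and guarantees that uniform V_m produces exactly zero
signal. The intracellular weighting uses the monodomain conductivity
field: for the delayed-depolarization substrate the *reduced* field (the
extracellular/torso side is left unchanged); for ablation the scar
elements are removed from the weighting entirely.

The potential ground is the reference electrode node; precordial-style
leads are re-referenced to Wilson's central terminal (mean of LA, RA,
LL) at trace level, which cancels the ground choice. Each lead's
baseline (mean over the pre-stimulus window) is subtracted. ECG
sampling is 1 ms. Amplitudes are in model units on synthetic geometry;
only relative comparisons are interpreted.

## ECG readouts

- **QRS bounds**: the multi-lead RMS of the trace's *slope* is gated at
  5% of its peak (slope-based gating keeps an elevated but slowly
  varying ST segment out of the QRS); sub-10 ms gaps are closed, and a
  later steep edge bridged by a continuously elevated signal still
  closes the same complex (plateau-shaped deflections). The pacing
  artifact window is blanked from the gating. QRS onset/end are the
  edges of the first burst.
- **J-point**: baseline-referenced lead value at QRS end.
- **Elevation threshold**: clinical absolute criteria (0.2 mV) are not
  meaningful at synthetic-geometry amplitudes, so a lead counts as
  elevated when its J-point exceeds 10% of the run's QRS peak amplitude;
  the threshold is always reported with the class.
- **ST class**: over the window from the J-point to the T extremum —
  *coved* iff elevated, monotonically descending (no rebound above the
  running minimum deeper than 5% of the J-point) and the T-wave is
  negative; *saddleback* iff elevated with a dip-then-secondary-
  positive-deflection; *nondiagnostic* iff elevated but neither; *none*
  otherwise.
- **T-wave**: extremum of the post-ST segment (search starts 20 ms
  after QRS end); polarity is its sign; duration between 25% crossings
  around the extremum.
- **Activation map**: per-node −40 mV crossing times; the substrate
  delay is the mean substrate LAT minus the mean LAT of depth-matched
  non-substrate nodes; unactivated nodes are flagged and excluded.

## Scenarios and readout conventions

The named scenarios share geometry, initialization and beat protocol and
differ only in substrate handling (see the module docstring of
`brswedge.scenarios`). The substrate-facing lead is `V2_ICS3`.
Parameter sweeps (diameter, thickness, substrate G_to fold, global G_Na)
share the geometry seed. The tissue-level loss-of-dome threshold is
located by bisection over integer folds (monotonicity verified at the
bracket ends), with dome loss defined as the majority of substrate-node
AP traces failing the dome criterion.

## Problem sizes and defaults

Defaults were chosen as the package's desk-scale study conditions:
2D sheet 40 × 10 mm at 0.5 mm edge (~1,700 nodes) for scenarios; 30 mm
strands at 0.25 mm (0.1 mm for the slowest conductivity) for CV; the
single-cell scan covers integer folds 1–20. The acceptance script and
the test suite use 1 preparatory + 1 result beat after cluster
steady-state initialization. 3D slabs run through the identical code
path and are exercised in the tests at coarse resolution.

## What the synthetic geometry does and does not show

The wedge preserves the transmural structure the two substrate
mechanisms act on (endo/epi variant layering, an epicardial
low-conductivity or high-G_to cap, overlying electrodes) but not the
RVOT's curvature, wall-thickness variation, His–Purkinje activation
sequence, or torso inhomogeneity. Consequences: absolute J-point
millivolt values and 64-lead waveforms are out of scope by design; the
package asserts orderings (early-repolarization J-point > delayed-
depolarization > healthy; substrate shrinkage never increases the
J-point and breaks the coved pattern; G_Na halving is secondary to
substrate insertion; ablation moves the ST segment back toward healthy)
and scaled quantitative anchors (CV ratios, single-cell and tissue
bifurcation folds). The healthy wedge's T-wave is small and its polarity
is set by a delicate balance of the transmural APD gradient and the
G_Ks gradient, since the whole endocardium is stimulated at once; the
T-based assertions are therefore made on within-suite contrasts at a
fixed seed, not on absolute healthy-T morphology. On coarse, small
sheets the electrotonic load on the substrate is relatively larger than
on the default wedge, which raises the tissue-level dome-loss fold;
tissue-threshold statements are tied to the default geometry.

## Known limitations

- No bidomain, no adaptive stepping, no Purkinje system, no
  arrhythmia-induction protocols.
- Single-cell anchor values for the G_to bifurcation depend on the
  source study's unavailable I_Na modification (see above); this
  package's faithful-model values are 13-fold / ~121 ms vs. the
  published 14-fold / 132 ms.
- The 2D default weakens source-to-electrode distance discrimination
  (logarithmic rather than 1/r falloff); 3D slabs sharpen lead locality
  at higher cost.
- Feature detectors (QRS gate fractions, dome thresholds, elevation
  fraction) are declared conventions, configurable and reported in
  outputs; the source study classified morphologies visually.
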