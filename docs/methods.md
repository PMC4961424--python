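# Methods

## Model

`lafib` simulates electrical activity of a human left atrium (LA) as a
monodomain reaction–diffusion system on a triangulated surface,

    dV/dt = D ∇²V − (I_ion + I_stim) / C_m ,

where `V` is the transmembrane potential (mV), `D` a homogeneous diffusion
coefficient (mm²/ms) representing gap-junctional coupling, `C_m` = 100 pF,
and `I_ion` the total membrane current of the Courtemanche–Ramirez–Nattel
(CRN, 1998) human atrial myocyte model (12 membrane currents, 15 gating
variables, intracellular Na⁺/K⁺/Ca²⁺ and two SR Ca²⁺ compartments; 21 state
variables per node).  Currents are expressed per unit capacitance (pA/pF).
The baseline implementation reproduces the published model: resting
potential −81.2 mV, AP peak ≈ +27 mV, APD90 ≈ 296 ms at 1-Hz pacing.

Chronic-AF electrical remodeling is expressed as multipliers on maximal
conductances.  Two presets ship:

* `af_remodeled` — the standard chronic-AF set: I_to ×0.2, I_Kur ×0.5,
  I_CaL ×0.6, I_K1 ×1.5.  Under the unmodified CRN equations this yields
  APD90 = 186.5 ms at CL 500 ms (20 beats), saturating near 209 ms at very
  slow rates.
* `af_calibrated` — the same four multipliers plus I_Kr ×0.5825, fixed once
  by bisection so that APD90(CL 500 ms, 20 beats) = 215 ms, the midpoint of
  the standard 210–220 ms tissue-calibration band for remodeled human
  atrial substrate.  The four standard multipliers alone cannot reach that band at
  any pacing rate, so a calibration dial on the one major repolarizing
  current not constrained by the remodeling set (I_Kr) reconciles the two
  requirements.  The tissue-level study uses this preset.

Assumptions inherited from the monodomain surface formulation: a single
homogeneous layer (no wall thickness, fibers, or bidomain effects), spatially
uniform ionic properties, and isotropic coupling.

## Numerics

* **Spatial operator.**  Cotangent-weighted Laplace–Beltrami with barycentric
  lumped mass (each node owns one third of every incident triangle).
  Negative cotangent weights are clamped to zero (with a warning), which
  preserves positivity and the zero row-sum (no-flux) property.  Under pure
  diffusion the area-weighted mean of V is conserved to 10⁻⁶ relative.
* **Time stepping.**  Operator-unsplit explicit update: forward Euler for V
  and the ionic concentrations, Rush–Larsen exponential updates for all
  gates.  Single-cell work uses an adaptive step (0.005 ms whenever
  |dV/dt| > 1 mV/ms, else 0.05 ms).  Tissue runs use a fixed step chosen as
  the largest value ≤ 0.05 ms that divides the 1-ms sampling interval and
  satisfies the diffusion stability bound D·dt·max|diag| < 0.45; an adaptive
  controller keyed to any-node |dV/dt| would pin the whole tissue at
  0.005 ms throughout fibrillation for no measurable accuracy gain (APD90
  at the 0.05-ms cap agrees with the 0.005-ms solution within 1 ms).  Very
  fine meshes may require steps below 0.005 ms (warned, permitted:
  stability wins).
* **Lookup tables.**  The tissue kernel tabulates gate steady states,
  Rush–Larsen factors and voltage-only current factors on a 0.1-mV grid
  (linear interpolation, float32 so the table stays cache-resident), and the
  SR-release trigger sigmoids on their own grid.  Reversal potentials and
  the Na-pump saturation term are refreshed every 0.5 ms (the concentrations
  they depend on evolve on a seconds timescale).  A single-node tissue run
  agrees with the exact-formula integrator to < 0.2 mV in V and < 0.2 ms in
  APD90.
* **Stimuli** are injected as −40 pA/pF (tissue) for 2 ms into a node patch;
  single-cell pacing uses twice the diastolic threshold found by bisection.
  Planar waves are launched from a patch ≥ 2 edge lengths deep because a
  single node column cannot source enough current against physiological
  coupling.

## Calibration

The diffusion coefficient is calibrated by bisection so a planar wave on a
0.25-mm strip of remodeled tissue, paced at CL 500 ms (three conditioning
beats), conducts longitudinally at a target velocity; activation times are
−40-mV upward crossings at two central probes 10 mm apart.  The shipped
default `DEFAULT_DIFFUSION = 0.0927 mm²/ms` achieves 0.40 m/s (±1%);
targets 0.5 and 0.6 m/s converge within 2%.  Because explicit surface
discretizations under-resolve the upstroke, the numerical CV depends on the
edge length; `calibrate_diffusion` is therefore resolution-aware and the
study calibrates at its own mesh resolution (D ≈ 0.42 mm²/ms at 2-mm
edges for the same 0.4 m/s).  CV measured at matched time step changes by
< 5% from 0.125-mm to 0.0625-mm edges and scales as √D within 10% over a
4× range.

## Synthetic left atrium

Patient-derived atrial geometries are emulated parametrically: a
near-uniform triangulated ellipsoid (Fibonacci-lattice sphere, smoothed and
re-hulled; semi-axes 32 × 24 × 27 mm giving an anteroposterior dimension of
≈ 48 mm and a surface area ≈ 10 000–12 000 mm²), four pulmonary-vein (PV)
ostia (radius 5.5 mm) extended into 10-mm open sleeves, an open mitral
annulus (radius 12 mm), a narrow-necked appendage pouch (7-mm neck tapering
over 26 mm to a capped tip), a seeded smooth low-wavenumber radial roughness
field (2.5 mm RMS) standing in for anatomical irregularity, and small
vertex jitter.  The surface is a topological sphere with five boundary
loops (Euler characteristic −3) and is bit-for-bit reproducible per seed.

Ten anatomical sections label every node: R1 septum, R2 anterior wall,
R3 appendage (the pouch, pre-tagged), R4 peri-mitral band (geodesic cells of
the mitral rim), R5 posterior-inferior wall, R6 posterior wall, R7–R10 the
four PV sleeves (pre-tagged).  Wall sections are geodesic-nearest-landmark
cells, which makes them contiguous; the landmark layout is a qualitative
choice, as any fixed sectioning of a synthetic atrium must be.

What the generator does **not** emulate: wall-thickness variation,
trabeculation and pectinate networks, fibrosis, fiber anisotropy, true PV
antra, and inter-patient topology differences.  Consequences are discussed
under *Limitations*.  Triangle quality: minimum angle > 15° except the
~26 apex-fan triangles capping the appendage pouch (≈ 12.7°; a fan over an
m-node ring cannot exceed ~2·asin(π/m)); operator robustness is guaranteed
by the clamping above, not by this bound.

## AF induction and initiation

The induction protocol is ramp ("straight") pacing from a ~3-mm patch in the
high septum: consecutive trains at cycle lengths 200, 190 and 180 ms, eight
beats each (4560 ms total).  On this substrate the protocol does **not**
produce wavebreak: CRN rate accommodation keeps the propagating-tissue
refractory period below the pacing interval, every beat conducts (1:1 near
the site, 2:1 distally), and the final wave extinguishes.  This was
confirmed across remodeling calibrations, mesh resolutions (2.0 and 1.2 mm),
and geometry variants; it is a property of the homogeneous CRN substrate,
not a solver artifact.

Sustained reentry is nevertheless supported: transplanting one spatial
period of a travelling wave onto closed rings shows a minimal sustainable
circuit of ≈ 100 mm at CV 0.4 m/s — just below the synthetic LA's effective
size, and consistent with rapid self-termination when CV (hence wavelength)
is raised to 0.5–0.6 m/s.  The study therefore obtains fibrillatory
activity with a documented fallback, `initiate_reentry`: the tissue state is
phase-distributed with one travelling-wave cycle around an anatomical axis
(mitral annulus first; fixed variant order over axis/chirality/winding), and
a variant is accepted once activity outlasts a 3-s confirmation.  This is an
initial condition, not a pacing protocol; runs seeded this way show
self-sustained re-entrant activity that meanders over the rough surface, and
every geometry seed tested sustains ≥ 10 s with at most two variants.
Episodes self-terminate when no node leaves the resting range (V < −60 mV)
for 200 consecutive ms.

## DF mapping and virtual ablation

Per analysis window the dominant frequency of each node is the argmax of a
mean-removed, Hann-windowed periodogram of its membrane potential,
restricted to 1–20 Hz (frequency resolution = 1/window length, e.g.
1/6 Hz for 6-s windows); nodes with < 5 mV peak-to-peak are flagged
undefined.  The **high-DF area** at fraction f is the top-f fraction of
conducting *tissue area* ranked by nodal DF (ties broken DF-descending then
node-index-ascending), selected greedily until the lumped-area sum first
reaches f × total; masks at 10/15/20% are nested by construction and land
within one node-area granule of the target.  Regional proportions report
100 × (masked area in section)/(section area) for R1–R10.

Virtual ablation renders the masked nodes non-conducting (zero-flux rows and
columns, ionic dynamics frozen) — total block rather than partial
D-reduction.  Trials branch independently from a checkpoint taken at the end
of each analysis window, follow the tissue (30 s at study scale), and are
classified: *AF_terminated* when activity ceases (event time = onset of
silence), *AT_conversion* when the final 2 s are organized, else
*AF_maintained*.  The organized-rhythm (AT) criterion — at ≥ 90% of 20
area-weighted seeded probe nodes the inter-activation-interval coefficient
of variation is < 10% **and** probe DFs agree within one frequency bin — is
an operational definition; its thresholds are exposed as arguments.

## Statistics

Per geometry, the windows × sections table of % High DF Area is tested for
spatial consistency with a Friedman rank test (sections as treatments,
windows as blocks; average-rank tie correction, χ² approximation).  Temporal
instability per section is the coefficient of variation
(100 × sample SD/mean) across windows, undefined (and excluded) for
zero-mean series.  Sections are compared with tie-corrected Kruskal–Wallis;
the PV + appendage + peri-mitral group (R3, R4, R7–R10) is compared with the
remaining walls by a Welch two-sample t-test on pooled per-geometry-
per-section CoVs.  Ablation outcomes (maintained vs changed-or-terminated,
by ablation extent) are compared with a Pearson χ² test without continuity
correction.  Standard tests delegate to scipy.stats; the suite checks every
operation against independently hand-coded formula oracles and a permutation
calibration.

## Study scale

Full-scale conditions (≈ 280 s of AF, nine 6-s windows every 30 s, 30-s
follow-ups, ten geometries) are available behind `full_scale=True` but are
GPU-scale work.  The desk defaults run on one CPU: three geometries at 2-mm
edges (≈ 3 200 nodes), three 3-s windows, 6-s follow-ups; the test suite
uses a further-shortened variant (2-s windows, 3-s follow-ups).  Problem
sizes are stated in `StudyConfig` and chosen so a full run completes in
minutes; nothing about the pipeline changes with scale except durations and
counts.

## Known limitations

* The ramp protocol alone does not induce AF here (see above); study AF is
  initiated, not induced, and this is flagged per geometry (`af_source`).
* With the faithful AF presets, planar tissue cannot conduct 1:1 at a
  200-ms cycle length (distal 2:1), so pacing-rate/DF identity checks use a
  documented short-APD variant (I_CaL ×0.3) on which 1:1 capture holds.
* Re-entrant episodes on the smooth synthetic substrate are more organized
  than clinical AF; a substantial share of windows classify as AT-like and
  ablation outcomes skew toward AT_conversion.
* Homogeneous, isotropic, monolayer tissue; no fibrosis or wall structure.
* The single-geometry-family generator cannot reproduce patient-level
  statistical spread; cross-geometry statistics are exercised structurally,
  not clinically.
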