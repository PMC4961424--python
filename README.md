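# lafib — in-silico left-atrial fibrillation

`lafib` is a research code for computational cardiac electrophysiologists
studying atrial fibrillation (AF) dynamics and ablation strategy in silico.
It simulates AF on left-atrium-like triangulated surfaces, maps each node's
dominant frequency (DF), quantifies the spatiotemporal stability of high-DF
sites over ten anatomical LA sections, and evaluates virtual catheter
ablation of those sites.

## The model

Tissue is a monodomain reaction–diffusion system on a surface mesh,

    ∂V/∂t = D ∇²V − (I_ion + I_stim)/C_m ,

with the Courtemanche–Ramirez–Nattel human atrial myocyte supplying `I_ion`
(21 state variables per node) and chronic-AF electrical remodeling applied
as conductance multipliers (I_to ×0.2, I_Kur ×0.5, I_CaL ×0.6, I_K1 ×1.5;
an optional I_Kr calibration brings APD90 into the 210–220 ms substrate
band).  `D` is calibrated so a planar wave conducts at 0.4 m/s.  The spatial
operator is a cotangent Laplace–Beltrami with lumped mass; gates advance by
Rush–Larsen, V and concentrations by explicit Euler within the diffusion
stability bound.

Per 6-s analysis window, nodal DF is the argmax of a Hann-windowed
periodogram of the membrane potential in 1–20 Hz; the *high-DF area* is the
top 10% (or 15/20%) of tissue area ranked by DF.  Virtual ablation makes
that area non-conducting and the outcome within the follow-up is classified
AF maintained / converted to atrial tachycardia (AT) / terminated.
Regional stability statistics use Friedman, Kruskal–Wallis, Welch-t and
χ² tests.  See `docs/methods.md` for the full account, including the
synthetic-geometry generator that stands in for patient anatomies.

## Worked example

Single-cell calibration of the remodeled myocyte:

```text
$ lafib single-cell-apd --preset af_remodeled
APD90 (af_remodeled, CL 500 ms, 20 beats): 186.5 ms

$ lafib single-cell-apd --preset af_calibrated
APD90 (af_calibrated, CL 500 ms, 20 beats): 215.0 ms
```

The first line is the literal chronic-AF remodeling: its action potential at
a 500-ms cycle length lasts 186.5 ms, short of the standard 210–220 ms
calibration band for remodeled atrial substrate — with the published multipliers alone that
band is unreachable at any rate.  The `af_calibrated` preset adds an I_Kr
reduction fixed once by bisection, landing at 215.0 ms; the tissue study
uses it.

Tissue calibration of gap-junctional coupling:

```text
$ lafib calibrate-cv --target 0.4 --preset af_remodeled
D = 0.0927246 mm^2/ms achieves CV = 0.3985 m/s (target 0.4, edge 0.25 mm)
```

i.e. the shipped default diffusion coefficient conducts a planar wave at
0.40 m/s on the 0.25-mm calibration strip.

From Python, a scaled-down study (3 synthetic "patients" × 3 DF windows ×
3 ablation extents) runs end to end:

```python
from lafib.config import StudyConfig
from lafib.study import run_study

report = run_study(StudyConfig(out_dir="study_out"))
print(report.outcome_table[["AF_maintained", "AT_conversion",
                            "AF_terminated"]])
```

which writes per-geometry `% High DF Area` tables (windows × sections
R1–R10), the trial list, the fraction × outcome table and the statistical
summary (`report.json`) under `study_out/`.  Other entry points:
`lafib make-geometry`, `lafib induce`, `lafib dfmap`, `lafib ablate`,
`lafib full-study` (with `--full-scale` for the long schedule).

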