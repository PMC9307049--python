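# mycouptake

Modelling and correlative analysis of phosphorus uptake by mycorrhizal
hyphae in soil.

Arbuscular mycorrhizal fungi (AMF) extend hyphal networks from plant roots
into soil and trade phosphorus for plant carbon. Quantifying *how fast a
hypha takes up P* requires combining three kinds of measurement of the same
soil volume — the 3D hyphal network (synchrotron X-ray CT skeletons), the
hyphal length-density profile over time, and the spatial P field (X-ray
fluorescence maps) — with a mechanistic transport model. `mycouptake`
implements that full chain for researchers in rhizosphere biophysics and
soil imaging:

* **Growth model.** Tip density `n` and hyphal length density `ρ` obey
  `∂ₜn + v ∂ₓn = b n`, `∂ₜρ = n v − d ρ` with zero initial condition and a
  constant tip flux `v·n(0,t) = k` at the root-compartment interface.
  Solved exactly by the method of characteristics and cross-checked by a
  first-order upwind solver.
* **Uptake model.** Total soil P `c_TOT = c_s + θ c_l` obeys
  `∂ₜc_TOT = D_eff ∂ₓₓc_TOT − 2π r_m λ_h ρ c_TOT` with a Robin sink
  `D_eff ∂ₓc_TOT = F_max c_TOT` at the root boundary and `c_TOT → c_∞` in
  the far field (default `D_eff = 1.05 × 10⁻⁸ cm² s⁻¹`). Backward-Euler,
  unconditionally stable, with an exactly-closing discrete mass budget.
* **Inference.** Bounded multi-start least squares for the kinetics
  `(k, v, b[, d])` from length-density observations, and for the hyphal
  uptake coefficient `λ_h` from far-field-normalised P depletion profiles.
  Only the product `r_m·λ_h` is identified, so `r_m` is always disclosed.
* **Skeleton morphometrics.** 26-connected voxel skeletons → branch
  graphs: total length, length density, clusters, branches per cluster,
  arc–chord tortuosity, orientation angle to the compartment midline.
* **Correlative chemometrics.** 3D Euclidean distance transform of hyphal
  masks, registration of 2D XRF planes, air/primary/mixed phase labels,
  close (≤ 50 µm) vs far (> 200 µm) distance classes with t/KS statistics,
  and high/low compound elemental classes (e.g. high-P/low-Al) with
  distance summaries.
* **XANES speciation.** Edge-step normalisation and non-negative,
  sum-to-one linear-combination fitting against a standard library, with
  grouped speciation-fraction trends versus distance.
* **Synthetic data.** Seeded generators for every input above, emitting
  the planted ground truth alongside each dataset, so the whole pipeline
  is testable end to end without the original imaging volumes.

## Worked example

Run the bundled synthetic study replica (simulate → fit growth → fit
uptake → morphometrics → correlate → speciate):

```python
from mycouptake.workflow import run_study, _summary_text
report = run_study({"seed": 1})
print(_summary_text(report.body))
```

```
mycouptake synthetic study summary
====================================
growth [inoculated]:
  k         = 4.590e-04 ± 3.479e-05   (true 4.660e-04)
  v         = 1.526e-05 ± 1.702e-06   (true 1.640e-05)
  b_branch  = 2.137e-06 ± 5.947e-07   (true 2.070e-06)
uptake (true lambda_h = 1.050e-07 cm/s):
  rho source total : lambda_h = 1.061e-07 cm/s (r_m = 5.0e-04 cm)
  rho source pore  : lambda_h = 5.303e-06 cm/s (r_m = 5.0e-04 cm)
skeleton presets (branches per cluster):
  inoculated : 1.33 branches/cluster, mean angle 18.8 deg
  control    : 39.67 branches/cluster, mean angle 54.3 deg
XRF close-vs-far (mixed phase):
  P : close 1.04e+04, far 8.31e+03, t p=0.00e+00, KS p=0.00e+00
  S : close 600, far 599, t p=2.50e-01, KS p=1.08e-01
  Al: close 2.43e+03, far 2.99e+03, t p=0.00e+00, KS p=0.00e+00
```

Reading the numbers: the kinetics fitted from three replicates of the
noisy synthetic length-density design recover the planted `(k, v, b)` to
within replicate scatter; `λ_h` fitted with the *total* (destructive-style)
length density recovers the planted value, while feeding the sparser
*pore-space* (CT-style, 2% of total) density inflates the estimate by the
inverse of that fraction — only `ρ·λ_h` enters the sink, so the assumed
density scale sets the rate. The control skeleton preset branches far more
per cluster than the inoculated preset, and the mixed-phase P mean is
elevated close to hyphae (ratio ≈ 1.25) while Al is depressed and S shows
no contrast.

A thin CLI wraps the same functions: `mycouptake simulate obs|skeleton|maps|xanes|profile`,
`mycouptake fit-growth`, `mycouptake fit-uptake`, `mycouptake skeleton-metrics`,
`mycouptake correlate`, `mycouptake lcf`, `mycouptake lcf-trend`,
`mycouptake run --config study.json --out results/`.

## Layout

```
src/mycouptake/
  growth.py     tip/length-density model (closed form + upwind solver)
  uptake.py     P diffusion–uptake solver and mass balance
  inference.py  bounded least-squares fitting and replicate aggregation
  skeleton.py   voxel-skeleton tracing and morphometrics
  chem.py       distance transform, phase/distance classes, statistics
  xanes.py      spectrum preprocessing, LCF, speciation trends
  synthetic.py  seeded generators with planted truth
  workflow.py   end-to-end study orchestration
  cli.py, io.py thin command-line and file-format layers
docs/methods.md  model assumptions, parameter choices, limitations
```
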