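# Methods

This note records the models implemented in `mycouptake`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices a maintainer
would want to know.

## Hyphal growth model

Colonisation of the hyphal compartment is described along its midline
coordinate `x` (cm, from the mesh interface with the root compartment) by

```
∂t n + v ∂x n = b n          (tip density, tips cm⁻³)
∂t ρ = n v − d ρ             (length density, cm hyphae cm⁻³ = cm⁻²)
```

with `n = ρ = 0` at `t = 0` and a constant tip *flux* at the interface,
`v n(0, t) = k`. The flux form is the only dimensionally consistent
reading of a constant-production boundary with `k` in cm⁻² s⁻¹ and `n` in
cm⁻³. `|v|` reduces to `v` because no retraction is modelled. Units are cm
and s everywhere inside the package; file readers convert.

Along characteristics the model is exactly solvable:
`n = (k/v) e^{bx/v}` behind the front `x < v t` (zero on and ahead of it),
and `ρ = (n v / d)(1 − e^{−d(t − x/v)})` for `d > 0`
(`ρ = n v (t − x/v)` for `d = 0`). This closed form is the production
path; the upwind finite-difference solver exists to verify it and to
support future source terms that break the closed form.

**Numerical scheme.** First-order upwind with automatic sub-stepping to
the CFL limit `v dt ≤ cfl_fraction·dx`. The branching source is applied to
the *advected* value, which keeps the characteristic history exact at unit
CFL; and because the front speed is exactly `v`, the solver zeroes the
fields on `x ≥ v t` after every step, so no numerical dust leaks ahead of
the front. At unit CFL on aligned grids the front is sharp and the error
is first order in the smooth region (measured ≈ 0.4% of the field maximum
at a 400² grid, halving with the spacing). Fractional CFL smears the front
over a cell — expected for an upwind scheme and covered by a wider test
tolerance.

## Soil-P uptake model

Total P (`c_TOT = c_s + θ c_l = (b + θ) c_l`, with buffer power `b` and
mixed-phase volume fraction `θ`) moves by effective diffusion and is
consumed by hyphal surface area:

```
∂t c_TOT = D_eff ∂xx c_TOT − 2π r_m λ_h ρ(x,t) c_TOT
D_eff ∂x c_TOT = F_max c_TOT   at x = 0      (root-compartment sink)
c_TOT = c_∞                    at x = L      (far field)
c_TOT(x, 0) = c_∞
```

The sink acts on `c_TOT` (the equation is taken literally as written, not
rewritten in `c_l`). The far-field condition "`c_l → c_∞` as `x → ∞`" is
realised as a Dirichlet value at finite `L`; this is faithful whenever the
region near `L` is undisturbed — i.e. the diffusion length `√(D_eff t)`
(~0.16 cm at 4 weeks) plus the sink's reach stay well inside `L`. With a
spatially uniform sink the whole bulk depletes and no finite-domain
boundary can represent infinity, so `farfield_insensitivity` is provided
to check any given configuration by doubling `L`. Fits operate on
far-field-normalised profiles `c/c_∞` because XRF intensities carry
arbitrary units; absolute calibration is out of scope.

**Defaults.** `D_eff = 1.05 × 10⁻⁸ cm² s⁻¹` (the literature estimate for
this soil type, `D_eff = Dθf/(θ+b)`). `F_max = 0`: the root-sink strength
is not independently measured and the fitted quantity is `λ_h`, so the
default simulates the hyphal compartment alone. `r_m = 5 × 10⁻⁴ cm` (10 µm diameter, upper
runner-hypha range): the sink only ever contains the product `r_m λ_h`,
so `r_m` is configuration-exposed and reported beside every `λ_h`.
`θ` and the buffer power are optional and only needed to convert
`c_TOT` to solution-phase concentration.

**Numerical scheme.** Backward Euler with a second-order Laplacian, the
Robin row discretised by ghost-node elimination, and the reaction term
implicit. Each step solves a tridiagonal M-matrix system, so the scheme is
unconditionally stable and preserves `0 ≤ c ≤ c_∞`. The output times *are*
the time steps; `mass_balance` re-accumulates the budget with the solver's
own stencils (trapezoid storage, one-sided far-field flux, `F_max c₀` root
efflux, half-weighted Robin cell in the uptake integral), for which the
backward-Euler identity is exact — residuals sit at round-off (~10⁻¹²
relative), far inside the 10⁻⁸/10⁻⁶ verification bands.

## Parameter inference

`fit_growth` minimises `Σ(ρ_model − ρ_obs)²` with
`scipy.optimize.least_squares` (trust-region reflective, box bounds) from
16 (default) log-uniform starting points inside the bounds, seeded and
fully deterministic. Default bounds bracket the study-scale magnitudes by
at least a decade: `k ∈ [10⁻⁶, 10⁻²] cm⁻² s⁻¹`, `v ∈ [10⁻⁷, 10⁻³] cm s⁻¹`,
`b, d ∈ [0, 10⁻⁴] s⁻¹`. Multi-start is needed: the objective is
multi-modal on sparse designs. The destruction rate `d` defaults to fixed
at zero (`fix_d=True`): it is weakly identified by few-week data (its
Jacobian direction is near-flat at these magnitudes). A
condition number of the Gauss–Newton Hessian `JᵀJ` above 10⁶ at the
optimum raises an identifiability flag; dense three-parameter fits sit
near 10⁴, any `d`-free fit near 10⁷.

Replicates can be pooled into one fit or fitted separately and aggregated
as mean ± sample SD (`n−1`); both modes exist because reported
per-treatment dispersions are most naturally read as across-replicate SDs.

`fit_uptake` is a bounded one-parameter fit of `λ_h ∈ [0, 10⁻³] cm s⁻¹`:
a 25-point log-spaced scan of the objective selects starts for bounded
least-squares refinement, and the estimate snaps to zero when the
no-uptake model already fits as well (flat profiles). A profile entirely
above the far field triggers a no-depletion warning; `ρ ≡ 0` is an
explicit unidentifiability error. Supplying the sparse pore-space length
density instead of the total density scales `λ̂_h` up by the inverse
density ratio — the two sources bracket the true rate, and the workflow
reports both.

**Monte-Carlo recovery (pilot-fixed thresholds).** At the dense synthetic
design (10 positions × 5 times, 10% multiplicative lognormal noise, 100
replicates) the pilot gave median |relative error| ≈ 0.027 (k), 0.128 (v),
0.088 (b); `v` and `b` are partially confounded because `b x/v ≲ 0.6`
across the compartment. The recovery test thresholds are frozen at 0.05 /
0.25 / 0.20 with headroom for the seed-to-seed variation of the median.

## Skeleton morphometrics

A 26-connected, 1-voxel-wide skeleton is traced into a branch graph.
Junction voxels (≥ 3 skeleton neighbours) that touch are merged into one
node at their centroid — in 26-connectivity the first voxels of meeting
arms are mutually adjacent, so junctions are blobs, not single voxels.
Branch polylines follow the actual voxel chain from the junction-blob
voxel they attach to; arc length is the sum of inter-voxel Euclidean
steps times the voxel size. Components with no junction or endpoint
(pure cycles) are broken at their lexicographically smallest voxel, which
makes re-tracing deterministic. Thick masks are thinned with
`skimage.morphology.skeletonize` before tracing.

Metric conventions (the source descriptions leave them open):

* tortuosity = arc length / end-to-end chord (standard arc–chord filament
  convention, minimum 1); zero-chord loops are excluded with a count.
* orientation = `arccos|ê·m̂|` between the branch *end-to-end* vector and
  the compartment midline, folded to [0°, 90°]; per-branch, not
  per-cluster. Under isotropy its expectation is 1 rad ≈ 57.3°, which the
  tests verify by Monte Carlo.
* length density = total length / analysed volume, reported in cm⁻².

## Correlative chemometrics

Distances from hyphae come from the exact 3D Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`, verified against a brute-force
all-pairs oracle); an XRF plane is placed in the volume frame by an
externally supplied affine (the original registration was visual) and
sampled nearest-neighbour. Phase labels: air if the summed elemental
signal is low, primary mineral if Si is high, mixed otherwise — the Si
exclusion also keeps Si signal overflow out of neighbouring channels.
Distance classes are inclusive at 50 µm ("within") and strict at 200 µm
("further than"). Class statistics are restricted to mixed-phase pixels:
means, normalised histograms on shared edges, equal-variance two-sample t
test (Welch optional) and two-sample KS test. Compound elemental classes
(high-P/low-Al etc.) threshold each element at the mean of close
mixed-phase pixels by default ("from-close-means") or at explicit values;
each class reports count, mean distance, a 100 µm-binned distance
histogram and the fraction within 100 µm, with empty classes flagged
rather than returned as NaN. All class logic is unit-agnostic (raw counts
or µg g⁻¹).

The t/KS tests treat pixels as independent; spatially correlated
structures (e.g. large organic patches) violate that and can produce very
small p-values from modest mean differences. This matches how such maps
are conventionally analysed but should be kept in mind when reading
per-map significance.

## XANES linear-combination fitting

Spectra are interpolated to a common grid and edge-step normalised
(linear pre-edge subtraction over the leading 15% of the grid, scaling to
unit mean over the trailing 15%). The normalisation is a linear projection
followed by a scale, so it is idempotent and intensity-scale invariant.
The LCF solves non-negative least squares with the sum-to-one constraint
enforced by an augmented row weighted 10⁸ × the data norm — exact to
~10⁻¹², with no post-hoc renormalisation (renormalising an unconstrained
fit would bias the residuals). Energy alignment is deliberately omitted:
spectra are assumed calibrated against mineral standards upstream.
Rank-deficient standard sets warn with the condition number. Species
grouping for trend reports is configurable, defaulting to the sulphur
convention reduced = thiols, oxidized = sulfonate + sulfate.

## Synthetic data: what it does and does not emulate

Every generator takes one explicit seed, attaches a `SyntheticTruth`
record, and regenerates byte-identically. Defaults mirror the emulated
split-compartment assay:

* **Length densities** — 3 positions (13.5/28.5/43.5 mm) × 2 times
  (2/4 wk) × 3 replicates; 10% multiplicative lognormal noise
  (mean-1, CV-calibrated), matching the magnitude of reported error bars;
  truth kinetics at the destructive-measurement scale
  (`k = 4.66e-4`, `v = 1.64e-5`, `b = 2.07e-6`, `d = 0`), for which
  `ρ(h₁, 4 wk) ≈ 1.2 × 10³ cm⁻²` (≈ 12 m cm⁻³ — a realistic AMF density).
* **Skeletons** — persistent-random-walk tips launched from the interface
  face of a cylindrical domain, branching and stopping per step; presets
  `inoculated` (persistence 0.95, branch 0.01/step) vs `control`
  (0.80, 0.06) reproduce the observed straight-sparse vs wandering-branched
  contrast. Branch points split polylines so junctions are shared graph
  nodes. Voxelisation rasterises segments and thins the result. Tests and
  the acceptance script use reduced domains (300–400 µm length, 4 µm
  voxels) — the statistics of interest are scale-free ratios, and the
  full 1.6 µm compartment-scale domain is available by argument.
* **XRF maps** — 256² pixels at 10 µm by default: high-Si elliptical
  grains, near-zero pores, and a mixed phase whose P field is
  `base·(1 + a_P e^{−d/50 µm})` around planted in-plane hyphae; the
  default `a_P = 0.4` puts the close/far mean ratio near 1.24, the
  observed contrast. Al couples negatively (−0.3); S is uniform by
  default (it showed no systematic contrast), with optional organic
  patches. 10% lognormal pixel noise. Thresholds bracketing the planted
  levels ship with the truth record.
* **XANES** — arctan edge + Gaussian white line standards with sulphur
  peaks at 2473 / 2480.5 / 2482 eV (thiol / sulfonate / sulfate), so group
  separability is realistic; mixtures add white noise at SNR 50 by
  default. The P-K library is synthetic with apatite-like white-line
  semantics and is labelled as such.
* **P profiles** — `c_TOT(x, t_final)/c_∞` from the transport solver
  driven by the closed-form growth field, with additive Gaussian noise.

Not emulated: real soil microstructure, X-ray physics (absorption/phase
contrast), detector response, the CT segmentation chain, registration
error, and spatial noise correlation in maps. Passing tests therefore
demonstrate the *analysis chain* is correct and well-calibrated on data
with known truth — not that the segmentation or registration of real
volumes is.

## Workflow and determinism

`run_study` executes simulate → fit growth (per replicate, aggregated) →
simulate/fit the depletion profile with both `total` and `pore`
(2% of total, the pore-space fraction found for inoculated samples)
length densities → skeleton morphometrics per preset → XRF class
statistics and compound classes → XANES speciation trend. The default
uptake truth is `λ_h = 1.05 × 10⁻⁷ cm s⁻¹` — the destructive-scale
estimate — paired with the *total* length density, so the default profile
shows moderate (not total) depletion and the pore-source fit lands at the
CT-scale magnitude (~5 × 10⁻⁶ cm s⁻¹), reproducing the bracketing
contrast between the two measurement routes. Reports contain no
timestamps; stage outputs are cached under `out_dir/stages` keyed by a
hash of the stage config and seed, so partial reruns skip completed
stages and rerunning a study is byte-identical.

## Known limitations

* 1D transport only; no water flow, no sorption isotherms beyond
  first-order buffering, no pellet-dissolution kinetics.
* `λ_h` is identified only jointly with `r_m` and with the assumed
  length-density scale; absolute rates inherit those assumptions.
* The upwind solver requires uniform spatial grids.
* Per-pixel significance tests ignore spatial autocorrelation (above).
* LCF assumes energy-calibrated spectra; no edge-shift fitting.
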