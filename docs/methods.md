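# Methods

## Model

The reconstruction model is nonnegative least squares with a smoothed
total-variation prior:

    min_{x ≥ 0}  f(x) = ½ ‖A x − b‖₂² + λ TV_β(x),
    TV_β(x) = Σ_j √(‖∇x_j‖₂² + β²),

with `∇x_j` the forward-difference gradient along the three Cartesian
axes. The model assumes a monochromatic beam (line integrals of a
scalar attenuation map), an ideal point source and an ideal detector
(no blur, no scatter). These are the standard assumptions of
model-based DBT reconstruction; all deviations from them end up in
the residual and are handled by the regularizer.

### Coordinate conventions

Right-handed frame, detector in the plane Z = 0, X along detector
columns, Y along the source-motion direction, Z up. The source
rotates in the YZ plane about a configurable `arc_center`, by default
a point on the detector plane below the central source position (the
true rotation center of commercial units is not public; it is plain
config). Indexing is 0-based; cells are half-open boxes.

## Distance-driven projectors

Voxel weights follow the distance-driven construction: for each slice
the four pixel boundaries are centrally projected from the source
onto the slice **mid-plane** (slab approximation), and the voxel
weight is

    w = (overlap_x · overlap_y) / (footprint_x · footprint_y) · dz / cos φ,

φ being the obliquity of the pixel's central ray. Weights are
therefore effective path lengths in mm and `A x` approximates the
Beer–Lambert line integral; a uniform slab of attenuation μ projects
to ≈ μ·thickness. Because detector and slice planes are parallel,
the footprint overlap factorizes into independent 1D interval
overlaps in X and Y; the projectors build one sparse overlap matrix
per axis, per slice, per angle, and apply them as sparse-dense
products. The backward projector applies the transposes of the same
factors, so adjointness holds to rounding by construction (measured
≤ 1e-15 relative on random systems). `A` is never stored: the
factors are rebuilt at every application, and single rows
(`dd_row`) are extracted from the same construction, so the row view
and the operator view agree to rounding.

Accuracy of the slab approximation is checked against a brute-force
oracle (`oracle_row`): 32² stratified rays per pixel with exact
ray–box clipping lengths, averaged per voxel. On an 8×8×4 test grid
over all 11 arc angles, rows whose footprint lies inside the volume's
lateral extent agree with the oracle to better than 0.7% in total
weight; rows clipped by the lateral volume boundary (which carry
near-zero weight) can deviate by up to ~20%, because the mid-plane
approximation and exact clipping disagree about the truncated part of
the footprint. This boundary behavior is inherent to distance-driven
projectors, affects only rays grazing the edge of the reconstruction
volume, and is invisible in practice because the volume is chosen to
cover the breast shadow. Aggregate agreement over all rows is ~0.04%.

Numerical choices: all arithmetic is double precision; boundary ties
use half-open intervals so zero-length overlaps contribute nothing;
rays missing the volume give empty rows; degenerate geometry (slice
not below the source) raises. All reductions run in a fixed order, so
results are bitwise reproducible.

## Objective and gradient

Forward differences use replicate (Neumann) boundaries, which makes
constant volumes TV-stationary (no spurious boundary forces) and
gives the exact lower bound `TV_β ≥ N_v β`. The analytic gradient
assigns each voxel its own term's derivative plus the adjoint
contributions of its three backward neighbors; it sums to zero over
the volume and passes central-difference directional-derivative tests
at 1e-6 relative. The gradient splitting used by the solver's scaling
writes `∇TV = V_TV − U_TV` with `V_TV = c ⊙ x` (c ≥ 0 collecting the
inverse smoothed magnitudes of all terms involving the voxel), so
both parts are nonnegative on the feasible set.

`β` defaults to 1e-3 in reconstruction units (attenuation, mm⁻¹):
two orders of magnitude below the background level of the phantom,
small enough not to bias edges of interest, large enough to keep the
gradient Lipschitz constant (∝ λ/β) manageable. An optional
`z_weight` can scale the Z-differences (slices are ~10× thicker than
the in-plane pitch); the default treats all axes equally, matching
common DBT practice of regularizing slice-to-slice differences at
full strength.

`λ` has no universal value; it is required config, tuned per protocol
by trial and error (`lambda_sweep` automates the sweep). For the
desk-scale phantom study the packaged choice is λ = 0.05 with β =
1e-3: the sweep in `examples/05_lambda_sweep.py` shows 0.005 leaves
~10× more background noise, 0.5 over-smooths (recovery error more
than doubles), while 0.05 flattens the background to ~1e-5 StdDev
without suppressing the 3-voxel beads.

## Chunked evaluation

All volume-sized operations can run over contiguous Z-chunks, the
scheme used to bound working memory when volumes exceed device
memory. Forward projection is additive over chunks; backward
projection fills disjoint slabs; TV value and gradient extend each
chunk with one halo slice (one on each side for the gradient) so the
finite differences at block borders are computed from real data. All
four agree with the unchunked evaluation to ≤ 1e-12 relative — the
chunked paths are contractually identical, not approximations.

## SGP solver

The iteration is the standard five-step scheme: scaled projected
direction `d = P₊(x − α D ∇f) − x`; Armijo backtracking from η = 1
with shrink γ; iterate update; ρ/D update; BB steplength update.
Specifics:

* **Scaling.** `D_jj = clip(x_j / V_j, 1/ρ, ρ)` with `V = max(AᵀAx, 0)
  + λ V_TV`; entries with `x_j = 0` or `V_j = 0` default to 1.
  `AᵀAx` is recovered as `∇LS + Aᵀb` with `Aᵀb` precomputed, so the
  splitting costs no extra projections (the clamp at zero guards
  against noise-induced negative entries of `Aᵀb`). ρ follows
  `√(1 + 10¹⁵/(k+1)^2.1)`, huge initially (no effective restriction)
  and → 1, switching the scaling off asymptotically as convergence
  theory requires.
* **Steplengths.** Scaled BB rules `BB1 = ⟨D⁻¹s, D⁻¹s⟩/⟨D⁻¹s, z⟩`,
  `BB2 = ⟨s, Dz⟩/⟨Dz, Dz⟩` with adaptive alternation: when
  `BB2/BB1 < τ` the step is the minimum of the recently observed BB2
  values (memory 2) and τ shrinks by 0.9, otherwise BB1 is used and τ
  grows by 1.1; results are clipped to `[α_min, α_max]`. Nonpositive
  curvature in the scaled metric — either `⟨D⁻¹s, z⟩ ≤ 0` or
  `⟨s, Dz⟩ ≤ 0` — falls back to `α_max` and is kept out of the BB2
  memory. The second guard matters: a negative BB2 entering the
  min-memory clamps the step to `α_min` and stalls the iteration
  short of the minimum.
* **Cost.** One forward projection (of the direction) and one
  backward projection (for the new gradient) per iteration; `A x` is
  carried forward as `A x + η A d`, so backtracking trials re-evaluate
  only the TV term.
* **Initialization.** `x⁽⁰⁾ = P₊(Aᵀb)` rescaled so `‖A x⁽⁰⁾‖ = ‖b‖`:
  deterministic, geometry-aware, nonnegative.
* **Stopping.** `|f_k − f_{k−1}| < tol·|f_k|` (default 1e-6) or
  `k > maxiter`. Zero direction stops immediately. For
  fixed-iteration checkpoint studies (the 4/12/30-iteration
  snapshots) the tolerance is disabled (1e-16) so the cap is the
  control; on desk-scale problems the 1e-6 rule can fire before
  iteration 30.
* Defaults σ = 1e-4, γ = 0.4, α_min = 1e-10, α_max = 1e5, α₀ = 1.3,
  τ₀ = 0.5: canonical settings from the SGP literature, all plain
  config.

Guarantees verified on every run: iterates exactly feasible, `f`
monotone non-increasing, `D` entries within `[1/ρ_k, ρ_k]`, accepted
steplengths within bounds. On a 10×10×2 test problem the SGP limit
matches a 20000-iteration fixed-step projected-gradient reference
(built on a dense matrix assembled row-by-row) to ~1e-11 relative.

## Phantom simulator

The generator emulates a simulated breast-phantom study: a uniform
adipose-like slab (0.05 mm⁻¹) containing spheres ("beads", 0.300 mm,
10× background — microcalcification surrogates), larger mild spheres
("masses", 1.5×) and thin cylinders ("fibers", 2×), projected under
an 11-view ±15° Giotto-like geometry (source 690 mm above the
detector) and corrupted by white Gaussian noise at SNR 50 dB. The
attenuation ratios are surrogates for values measured off commercial
reconstructions of physical phantoms; they are config, not physics.
Rasterization uses 3³ stratified subvoxel sampling (deterministic),
giving partial-volume edges and total object mass accurate to ~1% and
grid-refinement consistent to <1%.

The SNR definition is literal "noisy over noise":
`SNR = 20 log₁₀(‖b+ε‖/‖ε‖)`; the noise scale solves the implied
quadratic in closed form, so the realized SNR matches the request to
~1e-9 dB (a `clean` convention switch uses ‖b‖ instead). The full
configuration is a 3000×1000×50 volume at 0.100/1.000 mm voxels under
a 3200×1100 detector at 0.100 mm pitch; `scale` shrinks the field of
view while keeping pitches fixed, so the beads stay 3 voxels wide at
every scale. The desk-test scale 0.05 (150×50×5 voxels, 160×55
detector) is what the test suite and acceptance script run; a full
30-iteration reconstruction takes a few seconds on one CPU.

What the simulator does **not** model: anatomical texture
(heterogeneous glandular background), detector blur/MTF, scatter,
polychromatic beam hardening, dose. Passing the phantom-recovery
tests therefore demonstrates the correctness of the operators, model
and solver on clean limited-angle data — not clinical image quality.

## Metrics

Background uniformity and noise are mean and *population* StdDev over
a rectangular ROI (the sample/population distinction is immaterial at
the ROI sizes used). Contrast is operationalized as
`(mean_obj − mean_bg)/mean_bg`. Line profiles are axis-aligned voxel
segments, exportable to CSV at full float precision. Recovery error
is relative L2 against the known phantom and is only defined for
simulated data.

## Known limitations

* The distance-driven slab approximation degrades for rows grazing
  the lateral volume boundary (see above); choose grids covering the
  full object shadow.
* Only axis-aligned detector/volume lattices and a stationary
  detector are supported (no detector tilt or rotation).
* The solver assumes the objective is evaluated in double precision;
  single-precision operation is unsupported.
* Full clinical-scale problems (1.5·10⁸ voxels) are out of reach of
  this pure-Python implementation's throughput; the package targets
  method development and validation at reduced scale.
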