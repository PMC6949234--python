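# tomosgp

Model-based iterative reconstruction for digital breast tomosynthesis
(DBT), in pure scientific Python: matched matrix-free distance-driven
cone-beam projectors, a smoothed-TV-regularized nonnegative
least-squares model, and the Scaled Gradient Projection (SGP) solver,
together with a digital breast phantom simulator and the
image-quality metrics used to judge DBT reconstructions.

## The problem

DBT images the compressed breast with a handful of X-ray projections
(typically 11 views over ±15°) from a source sweeping a short arc
above a stationary flat detector. The data are therefore heavily
undersampled, and analytic reconstruction (filtered back projection)
amplifies noise and limited-angle artifacts. Model-based
reconstruction instead discretizes the Beer–Lambert law into a linear
system `A x = b` — `x` the voxelized attenuation volume, `b` the
projection stack, `A` the (enormous, extremely sparse, never stored)
system matrix — and solves the constrained optimization problem

    min_{x ≥ 0}  f(x) = ½ ‖A x − b‖₂² + λ · Σ_j √(‖∇x_j‖₂² + β²)

where the second term is the total variation (TV) smoothed by a small
constant β > 0, and λ > 0 balances data fit against noise
suppression. The clinical figure of merit is the detectability of
sub-millimetre microcalcifications against the noisy background.

The solver is SGP: projected gradient descent whose direction is
premultiplied by a diagonal scaling matrix `D_k` built from a
splitting of the gradient into positive and negative parts, with
entries confined to `[1/ρ_k, ρ_k]`, `ρ_k = √(1 + 10¹⁵/(k+1)^2.1) → 1`,
Barzilai–Borwein steplengths with adaptive alternation, and Armijo
backtracking (monotone decrease guaranteed). Iterations stop when
`|f(x^k) − f(x^{k−1})| < 10⁻⁶ |f(x^k)|` or an iteration cap is hit.
Each iteration costs one forward and one backward projection; extra
backtracking trials re-evaluate only the TV term.

Both projectors use the distance-driven model: detector-pixel
boundaries are projected from the source onto each slice mid-plane,
voxel weights are fractional footprint overlaps times the effective
path length `dz/cos φ`, and the backward projector applies the exact
transpose, so the pair passes the adjoint test `⟨Ax, y⟩ = ⟨x, Aᵀy⟩` to
rounding. All operators support chunked evaluation over Z-blocks
(with halo slices for the TV finite differences) that reproduces the
unchunked result to rounding — the memory-bounded processing scheme
for volumes that exceed accelerator memory.

## Worked example

```python
from tomosgp import (ObjectiveConfig, SolverConfig, Volume, add_noise,
                     d3_preset, make_phantom, recovery_error, sgp_solve,
                     simulate_projections)

spec, geometry, noise = d3_preset(scale=0.05, seed=1)   # 150x50x5 voxel slab
phantom = make_phantom(spec)                            # beads, mass, fiber
noisy = add_noise(simulate_projections(phantom, geometry), noise)  # SNR 50 dB
x, state = sgp_solve(noisy, geometry, spec.grid,
                     ObjectiveConfig(lam=0.05, beta=1e-3),
                     SolverConfig(maxiter=30, tol=1e-16),
                     checkpoints=(4, 12, 30))
for n in (4, 12, 30):
    print(n, recovery_error(Volume(state.checkpoints[n], spec.grid), phantom))
```

prints

```
4  0.05897044283025771
12 0.039043436915523084
30 0.03735549284162376
```

— the relative L2 error against the known phantom falls as iterations
proceed, and 94.8% of the total objective decrease happens within the
first 4 iterations (`examples/03_reconstruct_sgp.py`). At 30
iterations the 0.300 mm beads (3 voxels wide on the 0.100 mm grid)
stand thousands of background standard deviations above the recovered
background, whose mean matches the true 0.05 mm⁻¹ to four decimals
(`examples/04_roi_and_profiles.py`).

The `examples/` directory has one short script per capability:
projection physics, phantom simulation, reconstruction, ROI/profile
analysis, and λ tuning. A thin CLI wraps the same workflow:

```sh
tomosgp simulate --preset d3 --scale 0.05 --seed 1 --out proj.h5 --truth-out truth.h5
tomosgp reconstruct --projections proj.h5 --iters 30 --checkpoints 4,12,30 --out recon.h5
tomosgp analyze --volume recon.h5 --truth truth.h5 --roi 2,2,12,2,22
```

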