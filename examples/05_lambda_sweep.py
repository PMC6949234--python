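"""Tune the TV regularization weight by a trial-and-error sweep.

There is no closed-form rule for the regularization weight; practice
is to sweep a few candidates and inspect the data-fit/smoothness
balance and (for simulations) the recovery error against ground truth.
"""

from tomosgp import SolverConfig, add_noise, d3_preset, lambda_sweep, make_phantom, simulate_projections

spec, geometry, noise = d3_preset(scale=0.05, seed=1)
phantom = make_phantom(spec)
noisy = add_noise(simulate_projections(phantom, geometry), noise)

results = lambda_sweep(
    noisy, geometry, spec.grid,
    lambdas=(0.005, 0.05, 0.5),
    truth=phantom,
    solver_config=SolverConfig(maxiter=30, tol=1e-16),
)
print(f"{'lambda':>8} {'f_final':>12} {'LS part':>12} {'recovery err':>13}")
for r in results:
    print(f"{r['lam']:8.3f} {r['f_final']:12.4f} {r['ls_final']:12.4f} {r['recovery_error']:13.4f}")
# the middle value balances noise suppression against over-smoothing;
# far larger weights wash out the low-contrast objects
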