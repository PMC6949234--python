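"""Scaled Gradient Projection (SGP) solver for the reconstruction model.

SGP is a first-order method for ``min_{x >= 0} f(x)`` that accelerates
projected gradient descent in two ways:

* a diagonal *scaling matrix* ``D_k``, built from a splitting of the
  gradient into positive and negative parts, premultiplies the
  gradient; its entries are confined to ``[1/rho_k, rho_k]`` with
  ``rho_k`` decreasing toward 1 so that ``D_k`` tends to the identity
  (a convergence requirement);
* Barzilai-Borwein (BB) steplengths with an adaptive alternation
  between the two classical rules.

Each iteration computes the scaled projected direction, performs an
Armijo backtracking line search along it (monotone decrease is
guaranteed), takes the step, and updates ``rho``, ``D`` and the
steplength. Iterations stop when the relative objective change falls
below a tolerance or an iteration cap is hit.

One iteration costs one forward projection (of the direction) and one
backward projection (for the new gradient): the forward projection of
the iterate is carried along as ``A x_{k+1} = A x_k + eta A d_k``, and
backtracking trials re-evaluate only the TV term of the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import ScanGeometry, VolumeGrid, validate
from .objective import Objective, ObjectiveConfig
from .projector import ProjectionStack, Volume

__all__ = [
    "SolverConfig",
    "SGPState",
    "project_nonneg",
    "update_rho",
    "scaling_matrix",
    "bb_steplength",
    "backtrack",
    "stop_check",
    "sgp_solve",
    "lambda_sweep",
]

RHO_0 = np.sqrt(1.0 + 1e15)


@dataclass
class SolverConfig:
    """SGP tuning parameters.

    Defaults are canonical settings from the scaled-gradient-projection
    literature; every field is plain config. ``sigma`` is the Armijo
    sufficient-decrease fraction, ``gamma`` the backtracking shrink
    factor, ``alpha*`` the steplength bounds and start, ``tol`` the
    relative objective-change stopping tolerance, ``bb_tau`` /
    ``bb_memory`` the BB alternation threshold and the number of recent
    BB2 values remembered.
    """

    sigma: float = 1e-4
    gamma: float = 0.4
    alpha_min: float = 1e-10
    alpha_max: float = 1e5
    alpha0: float = 1.3
    maxiter: int = 100
    tol: float = 1e-6
    bb_memory: int = 2
    bb_tau: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sigma < 1:
            raise ValueError("sigma must be in (0, 1)")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        if not 0 < self.alpha_min <= self.alpha0 <= self.alpha_max:
            raise ValueError("need 0 < alpha_min <= alpha0 <= alpha_max")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.bb_memory < 1:
            raise ValueError("bb_memory must be >= 1")


@dataclass
class SGPState:
    """Trajectory and memory of an SGP run."""

    x: Volume
    f_history: list[float] = field(default_factory=list)
    alpha: float = 0.0
    rho: float = RHO_0
    s: np.ndarray | None = None
    z: np.ndarray | None = None
    k: int = 0
    eta_last: float = 1.0
    alpha_history: list[float] = field(default_factory=list)
    eta_history: list[float] = field(default_factory=list)
    rho_history: list[float] = field(default_factory=list)
    ls_history: list[float] = field(default_factory=list)
    tv_history: list[float] = field(default_factory=list)
    d_min_history: list[float] = field(default_factory=list)
    d_max_history: list[float] = field(default_factory=list)
    checkpoints: dict[int, np.ndarray] = field(default_factory=dict)
    converged: bool = False


def project_nonneg(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the nonnegative orthant."""
    return np.maximum(v, 0.0)


def update_rho(k: int) -> float:
    """Scaling bound after iteration ``k``: sqrt(1 + 1e15 / (k+1)^2.1).

    Very loose early on (no effective restriction on ``D``), strictly
    decreasing, with limit 1 so the scaling is asymptotically switched
    off.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    return float(np.sqrt(1.0 + 1e15 / (k + 1) ** 2.1))


def scaling_matrix(x: np.ndarray, pos_part: np.ndarray, rho: float) -> np.ndarray:
    """Diagonal of the scaling matrix ``D``.

    ``D_jj = clip(x_j / V_j, 1/rho, rho)`` where ``V`` is the positive
    part of the gradient decomposition ``grad f = V - U``; entries with
    ``x_j = 0`` or ``V_j = 0`` default to 1.
    """
    if rho < 1:
        raise ValueError("rho must be >= 1")
    if np.any(pos_part < 0):
        raise ValueError("pos_part must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where((x > 0) & (pos_part > 0), x / np.where(pos_part > 0, pos_part, 1.0), 1.0)
    return np.clip(d, 1.0 / rho, rho)


def bb_steplength(
    s: np.ndarray,
    z: np.ndarray,
    d_diag: np.ndarray,
    config: SolverConfig,
    bb2_memory: Sequence[float],
    bb_tau: float,
) -> tuple[float, float, float | None]:
    """Scaled Barzilai-Borwein steplength with adaptive alternation.

    With ``s = x_k - x_{k-1}`` and ``z = grad_k - grad_{k-1}``:

        BB1 = <D^-1 s, D^-1 s> / <D^-1 s, z>
        BB2 = <s, D z> / <D z, D z>

    If either curvature denominator is nonpositive the steplength
    falls back to ``alpha_max``. Otherwise, when ``BB2/BB1 < tau`` the
    rule returns the minimum of the recently observed BB2 values and
    shrinks ``tau`` by 0.9; else it returns BB1 and grows ``tau`` by
    1.1. The result is clipped to ``[alpha_min, alpha_max]``.

    Returns ``(alpha, new_tau, bb2 or None)``; the caller appends the
    BB2 value to its memory.
    """
    dinv_s = s / d_diag
    dz = d_diag * z
    denom1 = float(np.vdot(dinv_s, z))
    denom2 = float(np.vdot(dz, dz))
    num2 = float(np.vdot(s, dz))
    # nonpositive curvature in the scaled metric (either product): no
    # meaningful BB step, fall back to the largest allowed steplength
    if denom1 <= 0 or denom2 <= 0 or num2 <= 0:
        return config.alpha_max, bb_tau, None
    bb1 = float(np.vdot(dinv_s, dinv_s)) / denom1
    bb2 = num2 / denom2
    if bb2 / bb1 < bb_tau:
        recent = list(bb2_memory)[-(config.bb_memory - 1):] if config.bb_memory > 1 else []
        alpha = min(recent + [bb2])
        new_tau = bb_tau * 0.9
    else:
        alpha = bb1
        new_tau = bb_tau * 1.1
    return float(np.clip(alpha, config.alpha_min, config.alpha_max)), new_tau, bb2


def backtrack(
    f_x: float,
    grad_dot_d: float,
    f_evaluator: Callable[[float], float],
    config: SolverConfig,
) -> tuple[float, float]:
    """Armijo backtracking along a descent direction.

    Starting from ``eta = 1`` and shrinking by ``gamma``, returns the
    first ``eta`` with ``f(x + eta d) <= f(x) + sigma eta <grad f, d>``
    together with the accepted objective value. ``f_evaluator(eta)``
    must evaluate the objective at the trial point (cheap when forward
    projections are cached). More than 60 shrinks signals a
    non-descent direction (typically a gradient bug) and raises.
    """
    if grad_dot_d >= 0:
        raise ValueError(f"not a descent direction: <grad, d> = {grad_dot_d}")
    eta = 1.0
    for _ in range(61):
        f_new = f_evaluator(eta)
        if f_new <= f_x + config.sigma * eta * grad_dot_d:
            return eta, f_new
        eta *= config.gamma
    raise RuntimeError("backtracking underflow: no Armijo step after 60 shrinks")


def stop_check(f_k: float, f_prev: float, k: int, config: SolverConfig) -> bool:
    """Stopping rule: ``|f_k - f_{k-1}| < tol |f_k|`` or ``k > maxiter``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return abs(f_k - f_prev) < config.tol * abs(f_k) or k > config.maxiter


def sgp_solve(
    b: ProjectionStack,
    geometry: ScanGeometry,
    grid: VolumeGrid,
    obj_config: ObjectiveConfig,
    solver_config: SolverConfig | None = None,
    checkpoints: Sequence[int] = (),
    callback: Callable[[SGPState], None] | None = None,
) -> tuple[Volume, SGPState]:
    """Run SGP on ``min_{x>=0} 1/2||Ax-b||^2 + lam TV_beta(x)``.

    Starts from ``x0 = P_+(A^T b)`` rescaled so ``||A x0|| = ||b||`` (a
    deterministic, geometry-aware initial guess). ``checkpoints`` are
    iteration numbers whose iterates are snapshotted into
    ``state.checkpoints`` (iteration ``n`` meaning the iterate after
    ``n`` SGP steps). Returns the final volume and the full state.
    """
    cfg = solver_config or SolverConfig()
    validate(geometry, grid)
    obj = Objective(b, geometry, grid, obj_config)
    checkpoints = set(int(c) for c in checkpoints)

    # --- initial iterate
    x = project_nonneg(obj.atb)
    ax = obj.forward(x)
    nax = float(np.linalg.norm(ax))
    nb = float(np.linalg.norm(b.values))
    if nax > 0 and nb > 0:
        x = x * (nb / nax)
        ax = ax * (nb / nax)
    res = ax - b.values
    g, V = obj.gradient_parts(res, x)
    f = obj.value_from_cached(res, x)

    state = SGPState(x=Volume(x, grid), alpha=cfg.alpha0, rho=RHO_0)
    state.f_history.append(f)
    state.rho_history.append(state.rho)
    if 0 in checkpoints:
        state.checkpoints[0] = x.copy()

    bb2_memory: list[float] = []
    bb_tau = cfg.bb_tau
    alpha = cfg.alpha0
    rho = RHO_0

    for k in range(cfg.maxiter):
        D = scaling_matrix(x, V, rho)
        state.d_min_history.append(float(D.min()))
        state.d_max_history.append(float(D.max()))
        d = project_nonneg(x - alpha * D * g) - x
        gd = float(np.vdot(g, d))
        if gd == 0.0 or not np.any(d):
            state.converged = True
            break
        ad = obj.forward(d)

        def f_trial(eta: float, _res=res, _ad=ad, _x=x, _d=d) -> float:
            r = _res + eta * _ad
            return obj.value_from_cached(r, _x + eta * _d)

        eta, f_new = backtrack(f, gd, f_trial, cfg)
        if not np.isfinite(f_new):
            raise FloatingPointError(f"non-finite objective at iteration {k + 1}")

        x_new = x + eta * d
        # exact feasibility: x + eta*(P_+(..) - x) with eta<=1 is a convex
        # combination of nonnegative points, but guard against rounding
        x_new = project_nonneg(x_new)
        res = (ax + eta * ad) - b.values
        ax = res + b.values
        g_new, V = obj.gradient_parts(res, x_new)

        rho = update_rho(k)
        D_new = scaling_matrix(x_new, V, rho)
        s = x_new - x
        z = g_new - g
        alpha, bb_tau, bb2 = bb_steplength(s, z, D_new, cfg, bb2_memory, bb_tau)
        if bb2 is not None:
            bb2_memory.append(bb2)
            del bb2_memory[: -cfg.bb_memory]

        x, g = x_new, g_new
        f_prev, f = f, f_new
        state.k = k + 1
        state.s, state.z = s, z
        state.alpha = alpha
        state.rho = rho
        state.eta_last = eta
        state.f_history.append(f)
        state.alpha_history.append(alpha)
        state.eta_history.append(eta)
        state.rho_history.append(rho)
        state.ls_history.append(0.5 * float(np.vdot(res, res)))
        state.tv_history.append(obj.tv(x))
        if state.k in checkpoints:
            state.checkpoints[state.k] = x.copy()
        state.x = Volume(x, grid)
        if callback is not None:
            callback(state)
        if stop_check(f, f_prev, state.k, cfg):
            state.converged = True
            break

    state.x = Volume(x, grid)
    return state.x, state


def lambda_sweep(
    b: ProjectionStack,
    geometry: ScanGeometry,
    grid: VolumeGrid,
    lambdas: Sequence[float],
    truth: Volume | None = None,
    beta: float = 1e-3,
    solver_config: SolverConfig | None = None,
) -> list[dict]:
    """Trial-and-error tuning helper for the regularization weight.

    Runs the solver once per candidate ``lam`` and reports, for each,
    the final objective with its data-fit and TV parts and (when a
    ground-truth volume is supplied) the relative L2 recovery error —
    the quantities one inspects to pick ``lam`` for a protocol. The
    choice itself stays with the caller.
    """
    results = []
    for lam in lambdas:
        x, state = sgp_solve(
            b, geometry, grid, ObjectiveConfig(lam=lam, beta=beta), solver_config
        )
        entry = {
            "lam": float(lam),
            "f_final": state.f_history[-1],
            "ls_final": state.ls_history[-1] if state.ls_history else None,
            "tv_final": state.tv_history[-1] if state.tv_history else None,
            "iterations": state.k,
        }
        if truth is not None:
            nt = float(np.linalg.norm(truth.values))
            entry["recovery_error"] = float(np.linalg.norm(x.values - truth.values) / nt)
        results.append(entry)
    return results
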