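"""Iterative optimal-force ramps on arbitrary two-state surfaces.

The engine grows, from an optimized structure of the initial state, the two
continuation branches of optimal points — gap-increasing and
gap-decreasing — by alternating:

* a **predictor** displacement along the continuation direction, scaled so
  the external-force magnitude grows by a fixed increment on the local
  second-order model of state 0;
* a **corrector** that, staying on the constant-force level set of the
  local model, removes the component of the gap gradient perpendicular to
  the constraint normal until ``∇ΔE`` and ``∇‖F_ext‖²`` are parallel
  (|cos α| above tolerance);
* an exact **verification** of the parallelism condition with gradients
  (and Hessians, per policy) recomputed directly from the surfaces at the
  candidate point; on failure the expansion is refreshed there and the
  corrector resumes;
* a **force-budget** check: the achieved force magnitude may deviate from
  the scheduled one by at most a configurable fraction (default 5%),
  otherwise the constant-force condition is recalibrated from the updated
  expansion;
* an optional quasi-Newton (BFGS) **Hessian update** between consecutive
  optimized points in place of exact Hessian evaluations.

On quadratic pairs every emitted point coincides with the closed-form
solution of :mod:`lgmf.quadratic` at the same force magnitude; on
anharmonic surfaces the ramp is exact up to the convergence tolerances,
which is the point of the method.

The engine is deterministic given its inputs; random seeds only ever enter
through fixture generation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from . import units
from .exceptions import ConvergenceError
from .quadratic import cos_angle, pencil_eigenvalues
from .surfaces import (
    Geometry,
    SurfacePoint,
    TwoStatePES,
    as_coords,
    gap_variation,
)

__all__ = [
    "LGMFConfig",
    "OptimalPoint",
    "Ramp",
    "Expansion",
    "predictor_step",
    "approx_gradients",
    "split_perp",
    "corrector_iterate",
    "run_corrector",
    "verify_exact",
    "enforce_force_budget",
    "bfgs_update",
    "run_ramp",
    "PredictorError",
]

logger = logging.getLogger(__name__)

_DEFAULT_FORCE_STEP = units.convert(0.05, "nN", "hartree/bohr")
_DEFAULT_FORCE_MAX = units.convert(2.0, "nN", "hartree/bohr")


class PredictorError(RuntimeError):
    """No positive step achieves the force increment along the direction."""


@dataclass
class LGMFConfig:
    """Run configuration for the iterative ramp (atomic units throughout).

    Parameters
    ----------
    force_step : float
        Increment Δ‖F_ext‖ of the scheduled force magnitude between
        consecutive optimized points, Hartree/Bohr.  The default is
        0.05 nN: small enough that the local second-order model stays
        valid between points (the useful range is tens to hundreds of pN).
    force_max : float
        Ramp ceiling, Hartree/Bohr (default 2 nN).
    cos_tolerance : float
        Convergence threshold on |cos α| between ``∇ΔE`` and ``∇‖F_ext‖²``;
        practical values run from 0.99 (loose) to 0.999 (tight, default);
        values arbitrarily close to 1 are accepted for high-accuracy work.
    force_budget : float
        Maximum relative deviation of the achieved from the scheduled
        force magnitude (default 0.05, i.e. the five-percent rule).
    corrector_constant : float
        Proportionality constant of the fallback corrector displacement
        along ``∇ΔE⊥`` (Bohr²/Hartree), used when the reduced Lagrangian
        curvature of the local model has the wrong sign for the branch;
        otherwise the step is the 1D Newton step of that curvature.  Every
        move obeys a trust radius — halved on rejection (growing
        perpendicular residual or failed retraction), doubled on
        acceptance, never beyond half the level-set radius — a
        trust-region reading of the first-order validity requirement.
    corrector_max_iter : int
        Iteration budget of one corrector solve.
    hessian_policy : {"exact", "bfgs"}
        Whether new expansion points evaluate exact Hessians or update the
        previous ones quasi-Newton-wise from gradient differences (both
        states treated symmetrically).
    seed : int
        Recorded for provenance; the engine itself is deterministic.
    """

    force_step: float = _DEFAULT_FORCE_STEP
    force_max: float = _DEFAULT_FORCE_MAX
    cos_tolerance: float = 0.999
    force_budget: float = 0.05
    corrector_constant: float = 0.5
    corrector_max_iter: int = 800
    hessian_policy: str = "exact"
    seed: int = 0

    def __post_init__(self):
        if not (0.99 <= self.cos_tolerance <= 1.0):
            raise ValueError("cos_tolerance must lie in [0.99, 1]")
        if self.force_step <= 0:
            raise ValueError("force_step must be positive")
        if not (0.0 < self.force_budget <= 0.05):
            raise ValueError("force_budget must lie in (0, 0.05]")
        if self.hessian_policy not in ("exact", "bfgs"):
            raise ValueError("hessian_policy must be 'exact' or 'bfgs'")


@dataclass(frozen=True)
class OptimalPoint:
    """One verified point of a ramp."""

    q: Geometry
    force_vector: np.ndarray
    force_magnitude: float
    gap_variation: float
    cos_alpha: float
    n_corrector_iters: int
    verified_exact: bool
    scheduled_force: float


@dataclass
class Ramp:
    """Ordered optimal points of one branch plus the termination reason."""

    branch: str  # "increase" | "decrease"
    points: list[OptimalPoint] = field(default_factory=list)
    termination_reason: str = "ceiling"


@dataclass
class Expansion:
    """Second-order data of both states at one expansion point."""

    q0: np.ndarray
    sp0: SurfacePoint  # gradient + hessian of state 0
    sp1: SurfacePoint  # gradient + hessian of state 1


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def predictor_step(
    state0_expansion: SurfacePoint,
    direction: np.ndarray,
    target_delta_force: float,
) -> np.ndarray:
    """Displacement along ``direction`` raising the model force by a target.

    Returns ``Δq = s·d̂`` with the positive scalar ``s`` solving
    ``‖g0 + s H0 d̂‖ − ‖g0‖ = target_delta_force`` on the local quadratic
    model, found by safeguarded 1D root bracketing.
    """
    d = np.asarray(direction, dtype=float).ravel()
    nd = np.linalg.norm(d)
    if nd < 1e-14:
        raise ValueError("predictor direction must be nonzero")
    if state0_expansion.hessian is None:
        raise ValueError("predictor needs the state-0 Hessian")
    if target_delta_force == 0.0:
        return np.zeros_like(d)
    dhat = d / nd
    g0 = state0_expansion.gradient
    hd = state0_expansion.hessian @ dhat
    base = np.linalg.norm(g0)

    def phi(s: float) -> float:
        return np.linalg.norm(g0 + s * hd) - base - target_delta_force

    nhd = np.linalg.norm(hd)
    if nhd < 1e-14:
        raise PredictorError(
            "force magnitude is stationary along this direction; "
            "flip or change the search direction"
        )
    s_hi = (abs(target_delta_force) + 2.0 * base) / nhd + 1e-30
    for _ in range(80):
        if phi(s_hi) > 0.0:
            break
        s_hi *= 2.0
    else:
        raise PredictorError(
            "no positive step achieves the force increment along this "
            "direction; flip the search direction"
        )
    s = brentq(phi, 0.0, s_hi, xtol=1e-16, rtol=8.9e-16, maxiter=200)
    return s * dhat


def approx_gradients(
    exp: Expansion, dq: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Model gradients of the gap and of the squared force at ``q0 + dq``.

    Both follow from the second-order expansions at ``q0``:
    ``∇ΔE = (g1 + H1 dq) − (g0 + H0 dq)`` and
    ``∇‖F‖² = 2 H0 (g0 + H0 dq)``.
    """
    dq = np.asarray(dq, dtype=float).ravel()
    g0 = exp.sp0.gradient + exp.sp0.hessian @ dq
    g1 = exp.sp1.gradient + exp.sp1.hessian @ dq
    return g1 - g0, 2.0 * exp.sp0.hessian @ g0


def split_perp(v: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose ``v`` into components parallel and perpendicular to ``w``."""
    v = np.asarray(v, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("constraint normal is undefined (‖w‖ < 1e-12)")
    what = w / nw
    v_par = (v @ what) * what
    return v_par, v - v_par


def _model_force(exp: Expansion, dq: np.ndarray) -> np.ndarray:
    return exp.sp0.gradient + exp.sp0.hessian @ dq


def _project_to_level(
    exp: Expansion, dq: np.ndarray, target: float,
    rtol: float = 1e-13, max_iter: int = 80,
) -> tuple[np.ndarray, bool]:
    """Retract a trial displacement onto the constant-force level set.

    Newton iteration on the model force magnitude along the (recomputed)
    local constraint normal ``∇‖F‖²``; each sub-step is the one-dimensional
    rescale along that normal.  Returns ``(dq, success)``; callers must
    treat a failed retraction as a rejected move.
    """
    dq = np.asarray(dq, dtype=float).ravel()
    tol = rtol * max(target, 1e-30)
    prev_dev = math.inf
    for _ in range(max_iter):
        f = _model_force(exp, dq)
        mag = float(np.linalg.norm(f))
        dev = mag - target
        if abs(dev) <= tol:
            return dq, True
        if abs(dev) > 4.0 * prev_dev:  # diverging
            return dq, False
        prev_dev = max(abs(dev), 1e-300)
        n = 2.0 * exp.sp0.hessian @ f  # ∇‖F‖² at the trial point
        nn = np.linalg.norm(n)
        if nn < 1e-14:
            # stationary constraint (model minimum): step along an
            # arbitrary stiff direction to pick up a nonzero force
            n = exp.sp0.hessian @ (
                dq if np.linalg.norm(dq) > 0 else np.ones_like(dq)
            )
            nn = np.linalg.norm(n)
            if nn < 1e-14:
                return dq, False
        nhat = n / nn
        h0n = np.linalg.norm(exp.sp0.hessian @ nhat)
        slope = float((f / mag) @ (exp.sp0.hessian @ nhat)) if mag > 0 else h0n
        if abs(slope) < 1e-14:
            return dq, False
        step = -dev / slope
        # damp large Newton steps: the magnitude is only locally linear
        limit = 0.5 * max(mag, target) / max(h0n, 1e-30) + 1e-30
        step = float(np.clip(step, -limit, limit))
        dq = dq + step * nhat
    f = _model_force(exp, dq)
    return dq, abs(np.linalg.norm(f) - target) <= tol


@dataclass
class CorrectorState:
    """Mutable trust-region bookkeeping carried across corrector iterates.

    ``trust`` bounds the displacement length of one move (Bohr); it is
    halved when a move is rejected (perpendicular residual grew, or the
    constant-force retraction failed) and doubled — never beyond half the
    level-set radius — after an accepted one.  Within the trust radius the
    step length is the 1D Newton step of the reduced (projected Lagrangian)
    curvature along ``∇ΔE⊥``, which the local model provides exactly; a
    proportional step seeds the iteration when that curvature has the wrong
    sign.
    """

    trust: float = -1.0  # Bohr; < 0 means "initialize from the radius cap"
    perp_norm: float = math.inf


def corrector_iterate(
    exp: Expansion,
    dq_i: np.ndarray,
    config: LGMFConfig,
    branch_sign: float = 1.0,
    target_force: Optional[float] = None,
    state: Optional[CorrectorState] = None,
) -> tuple[np.ndarray, float, bool]:
    """One corrector iteration on the constant-force level set.

    Displaces the trial point along ``±∇ΔE⊥`` (sign set by the branch being
    maximized or minimized) scaled by the adaptive proportionality
    constant, then rescales back onto the level set of the local model so
    the external-force magnitude stays constant.  Returns
    ``(dq_next, cos_alpha, converged)`` where ``cos_alpha`` is evaluated at
    the *input* point; a converged input is returned unchanged.
    """
    dq_i = np.asarray(dq_i, dtype=float).ravel()
    if target_force is None:
        target_force = float(np.linalg.norm(_model_force(exp, dq_i)))
    grad_gap, grad_fsq = approx_gradients(exp, dq_i)
    if np.linalg.norm(grad_fsq) < 1e-14:
        return dq_i, 1.0, True
    _, perp = split_perp(grad_gap, grad_fsq)
    cos = cos_angle(grad_gap, grad_fsq)
    gnorm = np.linalg.norm(grad_gap)
    if abs(cos) >= config.cos_tolerance or np.linalg.norm(perp) <= 1e-14 * max(
        gnorm, 1.0
    ):
        return dq_i, cos, True
    if state is None:
        state = CorrectorState()

    perp_norm = float(np.linalg.norm(perp))
    phat = perp / perp_norm
    # the level-set radius vector H0⁻¹F bounds any sensible move: the
    # retraction must stay a small perturbation of the constraint
    f_model = _model_force(exp, dq_i)
    radius = float(np.linalg.norm(
        np.linalg.solve(exp.sp0.hessian, f_model)
    ))
    cap = 0.5 * radius if radius > 0 else np.inf
    if state.trust <= 0.0:
        state.trust = cap if np.isfinite(cap) else 1.0

    # Lagrange-Newton (SQP) step of the constrained stationarity system on
    # the local model: with W = (H1−H0) − λ 2H0² the Lagrangian Hessian and
    # λ the least-squares multiplier, solve
    #     [W   ∇c] [δ ]   [−∇ΔE⊥]
    #     [∇cᵀ  0] [δλ] = [  0   ]
    # (the iterate already sits on the level set, hence the zero constraint
    # residual).  Moving along one tangent direction at a time zigzags on
    # ill-conditioned tangent spaces; the full δ removes all perpendicular
    # components at once and converges quadratically near the optimum.  A
    # singular KKT system falls back to the proportional ∇ΔE⊥ move.
    lam_est = float(grad_gap @ grad_fsq) / float(grad_fsq @ grad_fsq)
    h0sq2 = 2.0 * exp.sp0.hessian @ exp.sp0.hessian
    w = (exp.sp1.hessian - exp.sp0.hessian) - lam_est * h0sq2
    n = dq_i.size
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = w
    kkt[:n, n] = grad_fsq
    kkt[n, :n] = grad_fsq
    rhs = np.concatenate([-perp, [0.0]])
    delta = None
    try:
        sol = np.linalg.solve(kkt, rhs)
        if np.all(np.isfinite(sol)):
            delta = sol[:n]
    except np.linalg.LinAlgError:
        pass
    if delta is None or np.linalg.norm(delta) < 1e-300:
        delta = branch_sign * config.corrector_constant * perp
    limit = min(state.trust, cap)
    dnorm = float(np.linalg.norm(delta))
    step = min(dnorm, limit)
    if dnorm > limit:
        delta = delta * (limit / dnorm)

    trial = dq_i + delta
    trial, ok = _project_to_level(exp, trial, target_force)
    if ok:
        new_gap, new_fsq = approx_gradients(exp, trial)
        if np.linalg.norm(new_fsq) >= 1e-14:
            _, new_perp = split_perp(new_gap, new_fsq)
            new_norm = float(np.linalg.norm(new_perp))
        else:
            new_norm = 0.0
    if not ok or new_norm > perp_norm:
        # reject: shrink the trust radius, keep the iterate (the residual
        # sequence over accepted iterates stays monotone)
        state.trust = 0.5 * step
        state.perp_norm = perp_norm
        return dq_i, cos, False
    state.trust = min(2.0 * state.trust, cap)
    state.perp_norm = new_norm
    return trial, cos, False


def run_corrector(
    exp: Expansion,
    dq0: np.ndarray,
    config: LGMFConfig,
    branch_sign: float = 1.0,
    target_force: Optional[float] = None,
) -> tuple[np.ndarray, float, int]:
    """Iterate the corrector to convergence on the local model.

    Returns ``(dq, cos_alpha, n_iters)``; raises :class:`ConvergenceError`
    carrying the best |cos α| seen when the iteration budget runs out.
    """
    if target_force is None:
        target_force = float(np.linalg.norm(_model_force(exp, dq0)))
    dq, _ = _project_to_level(exp, np.asarray(dq0, dtype=float).ravel(),
                              target_force)
    state = CorrectorState()
    best_cos = -math.inf
    for it in range(1, config.corrector_max_iter + 1):
        dq, cos, converged = corrector_iterate(
            exp, dq, config, branch_sign, target_force, state
        )
        best_cos = max(best_cos, abs(cos))
        if converged:
            logger.debug(
                "corrector converged: iters=%d cos=%.12f force=%.6g",
                it, cos, target_force,
            )
            return dq, cos, it
    raise ConvergenceError(
        f"corrector exhausted {config.corrector_max_iter} iterations "
        f"(best |cos α| = {best_cos:.6f})",
        best_cos_alpha=best_cos,
    )


def verify_exact(
    pes: TwoStatePES,
    q1,
    config: LGMFConfig,
    h0_est: Optional[np.ndarray] = None,
    h1_est: Optional[np.ndarray] = None,
) -> tuple[bool, float, Expansion]:
    """Check the optimality condition with exact gradients at ``q1``.

    Gradients always come directly from the surfaces; the Hessian entering
    ``∇‖F_ext‖² = 2 H0 g0`` follows the configured policy (exact
    evaluation, or the caller-supplied quasi-Newton estimates).  Returns
    ``(verified, cos_alpha, expansion)`` where the expansion at ``q1`` lets
    the caller resume the corrector with refreshed data on failure.
    """
    coords = as_coords(q1)
    want_h = config.hessian_policy == "exact"
    sp0 = pes.state0.evaluate(coords, want_hessian=want_h)
    sp1 = pes.state1.evaluate(coords, want_hessian=want_h)
    if not want_h:
        if h0_est is None or h1_est is None:
            raise ValueError(
                "hessian_policy='bfgs' requires Hessian estimates"
            )
        sp0 = SurfacePoint(sp0.energy, sp0.gradient, h0_est)
        sp1 = SurfacePoint(sp1.energy, sp1.gradient, h1_est)
    grad_gap = sp1.gradient - sp0.gradient
    grad_fsq = 2.0 * sp0.hessian @ sp0.gradient
    cos = cos_angle(grad_gap, grad_fsq)
    return abs(cos) >= config.cos_tolerance, cos, Expansion(coords, sp0, sp1)


def enforce_force_budget(
    achieved_force: float, scheduled_force: float, config: LGMFConfig
) -> str:
    """Five-percent rule: 'ok' within budget, else 'recalibrate'."""
    if scheduled_force <= 0:
        raise ValueError("scheduled force must be positive")
    rel = abs(achieved_force - scheduled_force) / scheduled_force
    return "ok" if rel <= config.force_budget else "recalibrate"


def bfgs_update(h: np.ndarray, dq: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank-two quasi-Newton refresh of a Hessian.

    ``H' = H − (H dq dqᵀ H)/(dqᵀ H dq) + (y yᵀ)/(yᵀ dq)`` with ``y`` the
    gradient difference between consecutive optimized points.  The secant
    condition ``H' dq = y`` holds exactly and symmetry is preserved.

    Raises
    ------
    ValueError
        If the curvature ``dqᵀy`` is at or below the floor
        ``1e-12 ‖dq‖‖y‖`` (the caller should skip the update and request
        an exact Hessian instead).
    """
    h = np.asarray(h, dtype=float)
    dq = np.asarray(dq, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    curv = float(dq @ y)
    floor = 1e-12 * np.linalg.norm(dq) * np.linalg.norm(y)
    if curv <= floor:
        raise ValueError(
            f"curvature condition violated (dq·y = {curv:.3g} <= {floor:.3g})"
        )
    hdq = h @ dq
    denom = float(dq @ hdq)
    if abs(denom) < 1e-300:
        raise ValueError("degenerate dqᵀH dq in quasi-Newton update")
    h_new = h - np.outer(hdq, hdq) / denom + np.outer(y, y) / curv
    return 0.5 * (h_new + h_new.T)


# ---------------------------------------------------------------------------
# ramp driver
# ---------------------------------------------------------------------------


def _policy_expansion(
    pes: TwoStatePES,
    coords: np.ndarray,
    config: LGMFConfig,
    prev: Optional[Expansion],
) -> Expansion:
    """Fresh expansion at ``coords`` honouring the Hessian policy."""
    if config.hessian_policy == "exact" or prev is None:
        sp0 = pes.state0.evaluate(coords, want_hessian=True)
        sp1 = pes.state1.evaluate(coords, want_hessian=True)
        return Expansion(coords, sp0, sp1)
    sp0 = pes.state0.evaluate(coords, want_hessian=False)
    sp1 = pes.state1.evaluate(coords, want_hessian=False)
    dq = coords - prev.q0
    hs = []
    for sp_new, sp_old in ((sp0, prev.sp0), (sp1, prev.sp1)):
        y = sp_new.gradient - sp_old.gradient
        try:
            hs.append(bfgs_update(sp_old.hessian, dq, y))
        except ValueError as exc:
            logger.warning("quasi-Newton update skipped (%s); evaluating "
                           "exact Hessian", exc)
            hs.append(None)
    h0 = hs[0] if hs[0] is not None else pes.state0.evaluate(
        coords, want_hessian=True).hessian
    h1 = hs[1] if hs[1] is not None else pes.state1.evaluate(
        coords, want_hessian=True).hessian
    return Expansion(
        coords,
        SurfacePoint(sp0.energy, sp0.gradient, h0),
        SurfacePoint(sp1.energy, sp1.gradient, h1),
    )


def _start_point(pes: TwoStatePES, start: Expansion) -> OptimalPoint:
    f = start.sp0.gradient
    return OptimalPoint(
        q=Geometry(start.q0.copy(), pes.q_ref.atom_labels),
        force_vector=f.copy(),
        force_magnitude=float(np.linalg.norm(f)),
        gap_variation=float(gap_variation(pes, start.q0)),
        cos_alpha=1.0,
        n_corrector_iters=0,
        verified_exact=True,
        scheduled_force=float(np.linalg.norm(f)),
    )


def _run_branch(
    pes: TwoStatePES,
    config: LGMFConfig,
    start: Expansion,
    direction0: np.ndarray,
    branch_sign: float,
) -> Ramp:
    ramp = Ramp(branch="increase" if branch_sign > 0 else "decrease")
    ramp.points.append(_start_point(pes, start))

    exp = start
    prev_q = start.q0
    prev_disp: Optional[np.ndarray] = None
    base_force = float(np.linalg.norm(start.sp0.gradient))
    step = config.force_step

    while base_force + step <= config.force_max * (1.0 + 1e-12):
        scheduled = base_force + step
        direction = prev_disp if prev_disp is not None else direction0
        accepted = None
        try:
            try:
                dq = predictor_step(exp.sp0, direction,
                                    scheduled - np.linalg.norm(
                                        exp.sp0.gradient))
            except PredictorError:
                dq = predictor_step(exp.sp0, -direction,
                                    scheduled - np.linalg.norm(
                                        exp.sp0.gradient))
            work = exp
            for _outer in range(12):
                dq, _cos_model, iters = run_corrector(
                    work, dq, config, branch_sign, target_force=scheduled
                )
                q1 = work.q0 + dq
                verified, cos_exact, fresh = verify_exact(
                    pes, q1, config,
                    h0_est=work.sp0.hessian, h1_est=work.sp1.hessian,
                )
                achieved = float(np.linalg.norm(fresh.sp0.gradient))
                budget = enforce_force_budget(achieved, scheduled, config)
                if verified and budget == "ok":
                    accepted = (q1, fresh, achieved, cos_exact, iters)
                    break
                # refresh the expansion at the candidate and resume on the
                # (recalculated) constant-force condition
                logger.debug(
                    "re-expanding at candidate: verified=%s budget=%s "
                    "cos=%.6f achieved=%.6g scheduled=%.6g",
                    verified, budget, cos_exact, achieved, scheduled,
                )
                work = _policy_expansion(pes, q1, config, exp)
                dq, _ = _project_to_level(work, np.zeros_like(q1), scheduled)
            if accepted is None:
                raise ConvergenceError(
                    "verification/budget cycle did not settle",
                    best_cos_alpha=None,
                )
        except (ConvergenceError, PredictorError) as exc:
            if step > config.force_step / 4.0:  # two halvings allowed
                logger.info("halving force step after failure: %s", exc)
                step *= 0.5
                continue
            ramp.termination_reason = (
                "constraint-unreachable"
                if isinstance(exc, PredictorError)
                else "non-convergence"
            )
            logger.warning("branch %s truncated at ‖F‖=%.6g: %s",
                           ramp.branch, base_force, exc)
            return ramp

        q1, fresh, achieved, cos_exact, iters = accepted
        point = OptimalPoint(
            q=Geometry(q1, pes.q_ref.atom_labels),
            force_vector=fresh.sp0.gradient.copy(),
            force_magnitude=achieved,
            gap_variation=float(gap_variation(pes, q1)),
            cos_alpha=cos_exact,
            n_corrector_iters=iters,
            verified_exact=True,
            scheduled_force=scheduled,
        )
        ramp.points.append(point)
        prev_disp = q1 - prev_q
        prev_q = q1
        exp = fresh if config.hessian_policy == "exact" else _policy_expansion(
            pes, q1, config, exp
        )
        base_force = achieved
        step = config.force_step

    ramp.termination_reason = "ceiling"
    return ramp


def _branch_seed_directions(
    start: Expansion,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Initial search directions for the two branches.

    Normally ``(+∇ΔE, −∇ΔE)`` at the start.  When the gap gradient
    vanishes (stationary gap), the branches are seeded instead from the
    extreme eigenvectors of the pencil ``(H1 − H0) v = 2μ H0² v``: the
    largest-μ eigenvector raises the gap fastest at fixed force, the
    smallest-μ one lowers it fastest.
    """
    grad_gap = start.sp1.gradient - start.sp0.gradient
    if np.linalg.norm(grad_gap) > 1e-10:
        return grad_gap, -grad_gap, False
    lam_printed, vecs = pencil_eigenvalues(start.sp0.hessian,
                                           start.sp1.hessian)
    # printed λ ascending ⇒ μ = −λ descending: first column maximises μ
    return vecs[:, 0], vecs[:, -1], True


def run_ramp(pes: TwoStatePES, config: LGMFConfig) -> tuple[Ramp, Ramp]:
    """Grow both optimal-force branches from the state-0 minimum.

    Returns ``(increasing, decreasing)`` ramps.  The start must be an
    optimized structure of the initial state (gradient norm below 1e-6).
    The first search direction is ``±∇ΔE`` there; afterwards each branch
    continues along its previous displacement.  Every emitted point is
    verified against exact gradients and obeys the force budget.
    """
    coords = pes.q_ref.coordinates
    g0 = pes.state0.evaluate(coords).gradient
    if np.linalg.norm(g0) >= 1e-6:
        raise ValueError(
            "ramp must start from an optimized state-0 structure "
            f"(gradient norm {np.linalg.norm(g0):.3g} >= 1e-6)"
        )
    start = Expansion(
        coords.copy(),
        pes.state0.evaluate(coords, want_hessian=True),
        pes.state1.evaluate(coords, want_hessian=True),
    )
    d_up, d_dn, from_pencil = _branch_seed_directions(start)
    ramp_up = _run_branch(pes, config, start, d_up, +1.0)
    ramp_dn = _run_branch(pes, config, start, d_dn, -1.0)

    if (
        not from_pencil
        and len(ramp_up.points) > 1
        and len(ramp_dn.points) > 1
        and np.sign(ramp_up.points[1].gap_variation)
        == np.sign(ramp_dn.points[1].gap_variation)
    ):
        # degenerate seeding (e.g. the gap gradient has no symmetric
        # component): reseed from the pencil eigenvectors
        lam_printed, vecs = pencil_eigenvalues(start.sp0.hessian,
                                               start.sp1.hessian)
        if ramp_up.points[1].gap_variation < 0:
            ramp_up = _run_branch(pes, config, start, vecs[:, 0], +1.0)
        else:
            ramp_dn = _run_branch(pes, config, start, vecs[:, -1], -1.0)
    return ramp_up, ramp_dn
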