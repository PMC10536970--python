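"""Two-state potential energy surfaces, model surfaces and fixtures.

The central object is :class:`TwoStatePES`: a pair of evaluable surfaces for
the initial ("0") and final ("1") electronic states sharing one Cartesian
coordinate space.  The quantity of interest is the energy gap
``ΔE(q) = E1(q) − E0(q)`` and its variation relative to a reference
structure (normally the state-0 minimum).  An external mechanical force
holds a structure ``q`` as an equilibrium on state 0 exactly when it cancels
the internal force, i.e. ``F_ext(q) = ∇E0(q)``.

Concrete surfaces provided here:

* :class:`QuadraticSurface` — exact second-order expansion around a
  reference point (energy, gradient, Hessian);
* :class:`MorseSumSurface`, :class:`QuarticPerturbedSurface`,
  :class:`Model2DSurface` — anharmonic model surfaces with analytic
  gradients and Hessians, used to exercise the iterative optimizer beyond
  the quadratic regime.

The module also hosts the seeded fixture generator
(:func:`make_quadratic_pair`, :func:`make_model_2d_pair`) and a dense
constrained grid-search oracle (:func:`brute_force_optimum`) restricted to
one or two degrees of freedom, used only to validate the optimizers.

All quantities are in atomic units (Hartree, Bohr, Hartree/Bohr).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize

from .exceptions import ConstraintUnreachableError, DimensionMismatchError

__all__ = [
    "Geometry",
    "SurfacePoint",
    "Surface",
    "QuadraticSurface",
    "MorseSumSurface",
    "QuarticPerturbedSurface",
    "Model2DSurface",
    "TwoStatePES",
    "evaluate",
    "energy_gap",
    "gap_variation",
    "external_force",
    "make_quadratic_pair",
    "make_model_2d_pair",
    "brute_force_optimum",
    "BruteForceOptimum",
    "surface_to_dict",
    "surface_from_dict",
    "pes_to_dict",
    "pes_from_dict",
    "pes_to_json",
    "pes_from_json",
]

_HESS_SYM_RTOL = 1e-10


# ---------------------------------------------------------------------------
# geometry and evaluation containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Geometry:
    """A structure in Cartesian coordinates.

    Parameters
    ----------
    coordinates : array_like, shape (3N,) or (n,)
        Coordinate vector in Bohr.  Abstract (non-atomic) coordinate spaces
        of any dimension are allowed when ``atom_labels`` is empty.
    atom_labels : sequence of str, optional
        Element symbols.  When non-empty, the coordinate length must be
        ``3 * len(atom_labels)``.
    """

    coordinates: np.ndarray
    atom_labels: tuple[str, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float).ravel()
        if coords.size == 0:
            raise ValueError("coordinate vector must be non-empty")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))
        if self.atom_labels and coords.size != 3 * len(self.atom_labels):
            raise ValueError(
                f"{len(self.atom_labels)} atoms require "
                f"{3 * len(self.atom_labels)} coordinates, got {coords.size}"
            )

    @property
    def n_dof(self) -> int:
        return self.coordinates.size

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def positions(self) -> np.ndarray:
        """Per-atom positions, shape (n_atoms, 3)."""
        if not self.atom_labels:
            raise ValueError("geometry carries no atoms")
        return self.coordinates.reshape(-1, 3)

    def displaced(self, dq: np.ndarray) -> "Geometry":
        return Geometry(self.coordinates + np.asarray(dq, dtype=float).ravel(),
                        self.atom_labels)


def as_coords(q) -> np.ndarray:
    """Accept a Geometry or a bare array and return the coordinate vector."""
    if isinstance(q, Geometry):
        return q.coordinates
    return np.asarray(q, dtype=float).ravel()


@dataclass(frozen=True)
class SurfacePoint:
    """Energy, gradient and (optionally) Hessian of one state at one point."""

    energy: float
    gradient: np.ndarray
    hessian: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(
            self, "gradient", np.asarray(self.gradient, dtype=float).ravel()
        )
        if self.hessian is not None:
            h = np.asarray(self.hessian, dtype=float)
            scale = max(np.abs(h).max(), 1.0)
            if not np.allclose(h, h.T, atol=_HESS_SYM_RTOL * scale, rtol=0.0):
                raise ValueError("Hessian is not symmetric")
            object.__setattr__(self, "hessian", h)


class Surface:
    """Abstract evaluable potential energy surface."""

    n_dof: int

    def evaluate(self, q, want_hessian: bool = False) -> SurfacePoint:
        coords = as_coords(q)
        if coords.size != self.n_dof:
            raise DimensionMismatchError(
                f"geometry has {coords.size} dof, surface expects {self.n_dof}"
            )
        return self._evaluate(coords, want_hessian)

    def _evaluate(self, coords: np.ndarray, want_hessian: bool) -> SurfacePoint:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# concrete surfaces
# ---------------------------------------------------------------------------


class QuadraticSurface(Surface):
    """Exact second-order expansion around a reference structure.

    ``E(q) = e_ref + g_refᵀΔq + ½ ΔqᵀH_refΔq`` with ``Δq = q − q_ref``.
    Gradient and Hessian follow by differentiation; the Hessian is constant.
    """

    def __init__(self, q_ref, e_ref: float, g_ref, h_ref,
                 atom_labels: Sequence[str] = ()):
        q_ref = as_coords(q_ref)
        self.q_ref = Geometry(q_ref, tuple(atom_labels))
        self.e_ref = float(e_ref)
        self.g_ref = np.asarray(g_ref, dtype=float).ravel()
        h = np.asarray(h_ref, dtype=float)
        if h.shape == () and q_ref.size == 1:
            h = h.reshape(1, 1)
        scale = max(np.abs(h).max(), 1.0)
        if not np.allclose(h, h.T, atol=_HESS_SYM_RTOL * scale, rtol=0.0):
            raise ValueError("reference Hessian is not symmetric")
        self.h_ref = 0.5 * (h + h.T)
        if not (self.g_ref.size == q_ref.size == h.shape[0] == h.shape[1]):
            raise ValueError("inconsistent dimensions in quadratic surface")
        self.n_dof = q_ref.size

    def _evaluate(self, coords, want_hessian):
        dq = coords - self.q_ref.coordinates
        hdq = self.h_ref @ dq
        energy = self.e_ref + self.g_ref @ dq + 0.5 * dq @ hdq
        grad = self.g_ref + hdq
        return SurfacePoint(energy, grad, self.h_ref if want_hessian else None)


class MorseSumSurface(Surface):
    """Sum of independent 1D Morse wells: ``Σ_i D_i (1 − e^{−a_i δ_i})²``.

    ``δ_i = q_i − q_min,i``.  The declared minimum is ``q_min`` where the
    gradient vanishes exactly.  Curvature at the minimum is ``2 D_i a_i²``.
    """

    form = "morse-sum"

    def __init__(self, d, a, q_min, e_min: float = 0.0):
        self.d = np.asarray(d, dtype=float).ravel()
        self.a = np.asarray(a, dtype=float).ravel()
        self.q_min = Geometry(q_min)
        self.e_min = float(e_min)
        if not (self.d.size == self.a.size == self.q_min.n_dof):
            raise ValueError("inconsistent Morse parameter lengths")
        if np.any(self.d <= 0) or np.any(self.a <= 0):
            raise ValueError("Morse parameters must be positive")
        self.n_dof = self.d.size

    def _evaluate(self, coords, want_hessian):
        delta = coords - self.q_min.coordinates
        u = np.exp(-self.a * delta)
        energy = self.e_min + float(np.sum(self.d * (1.0 - u) ** 2))
        grad = 2.0 * self.d * self.a * (1.0 - u) * u
        hess = None
        if want_hessian:
            hess = np.diag(2.0 * self.d * self.a**2 * u * (2.0 * u - 1.0))
        return SurfacePoint(energy, grad, hess)


class QuarticPerturbedSurface(Surface):
    """Quadratic well plus diagonal quartic terms.

    ``E = e_min + ½ ΔqᵀHΔq + Σ_i c_i Δq_i⁴`` with ``Δq = q − q_min``; the
    declared minimum stays at ``q_min`` because the quartic term has zero
    gradient there.
    """

    form = "quartic-perturbed-quadratic"

    def __init__(self, h, c, q_min, e_min: float = 0.0):
        h = np.asarray(h, dtype=float)
        self.h = 0.5 * (h + h.T)
        self.c = np.asarray(c, dtype=float).ravel()
        self.q_min = Geometry(q_min)
        self.e_min = float(e_min)
        if not (self.h.shape[0] == self.c.size == self.q_min.n_dof):
            raise ValueError("inconsistent quartic surface dimensions")
        self.n_dof = self.c.size

    def _evaluate(self, coords, want_hessian):
        dq = coords - self.q_min.coordinates
        hdq = self.h @ dq
        energy = self.e_min + 0.5 * dq @ hdq + float(np.sum(self.c * dq**4))
        grad = hdq + 4.0 * self.c * dq**3
        hess = None
        if want_hessian:
            hess = self.h + np.diag(12.0 * self.c * dq**2)
        return SurfacePoint(energy, grad, hess)


class Model2DSurface(Surface):
    """Two-coordinate model with one stiff harmonic and one soft Morse mode.

    ``E(x, y) = e_min + ½ k_x Δx² + D (1 − e^{−a Δy})² + ½ k_y Δy² + b ΔxΔy``

    The soft Morse coordinate reproduces the characteristic failure of a
    single second-order expansion: moderate forces along a low-curvature
    anharmonic mode produce displacements far outside the quadratic regime.
    The weak harmonic ``k_y`` keeps the restoring force monotone along the
    soft coordinate (choose ``k_y > D a²/4``, the largest slope dip of the
    Morse force), so every force-magnitude level set is a single closed
    curve and continuation reaches the global constrained optimum.  ``b``
    is a bilinear coupling; the declared minimum stays at ``(x_min,
    y_min)`` since every term has zero gradient there.
    """

    form = "model-2d"

    def __init__(self, kx: float, d: float, a: float, q_min,
                 e_min: float = 0.0, b: float = 0.0, ky: float = 0.0):
        self.kx = float(kx)
        self.d = float(d)
        self.a = float(a)
        self.b = float(b)
        self.ky = float(ky)
        self.q_min = Geometry(q_min)
        self.e_min = float(e_min)
        if self.q_min.n_dof != 2:
            raise ValueError("model-2d surface is strictly two-dimensional")
        if self.kx <= 0 or self.d <= 0 or self.a <= 0:
            raise ValueError("model-2d stiffness parameters must be positive")
        self.n_dof = 2

    def _evaluate(self, coords, want_hessian):
        dx, dy = coords - self.q_min.coordinates
        u = np.exp(-self.a * dy)
        energy = (self.e_min + 0.5 * self.kx * dx**2
                  + self.d * (1.0 - u) ** 2 + 0.5 * self.ky * dy**2
                  + self.b * dx * dy)
        grad = np.array([
            self.kx * dx + self.b * dy,
            2.0 * self.d * self.a * (1.0 - u) * u + self.ky * dy
            + self.b * dx,
        ])
        hess = None
        if want_hessian:
            hyy = 2.0 * self.d * self.a**2 * u * (2.0 * u - 1.0) + self.ky
            hess = np.array([[self.kx, self.b], [self.b, hyy]])
        return SurfacePoint(energy, grad, hess)


# ---------------------------------------------------------------------------
# the two-state pair
# ---------------------------------------------------------------------------


class TwoStatePES:
    """A pair of surfaces for the initial ("0") and final ("1") states.

    Parameters
    ----------
    state0, state1 : Surface
        Evaluable surfaces sharing one coordinate dimension.
    q_ref : Geometry or array_like, optional
        Shared reference structure for gap variation; defaults to the
        state-0 expansion point or declared minimum.
    """

    def __init__(self, state0: Surface, state1: Surface, q_ref=None):
        if state0.n_dof != state1.n_dof:
            raise DimensionMismatchError(
                f"state dimensions differ: {state0.n_dof} vs {state1.n_dof}"
            )
        self.state0 = state0
        self.state1 = state1
        if q_ref is None:
            q_ref = getattr(state0, "q_ref", None) or getattr(
                state0, "q_min", None
            )
            if q_ref is None:
                raise ValueError("q_ref required for this surface type")
        coords = as_coords(q_ref)
        labels = q_ref.atom_labels if isinstance(q_ref, Geometry) else ()
        self.q_ref = Geometry(coords, labels)
        self.gap_at_ref = (
            state1.evaluate(self.q_ref).energy
            - state0.evaluate(self.q_ref).energy
        )

    @property
    def n_dof(self) -> int:
        return self.state0.n_dof

    def is_quadratic(self) -> bool:
        return isinstance(self.state0, QuadraticSurface) and isinstance(
            self.state1, QuadraticSurface
        )


def evaluate(surface: Surface, q, want_hessian: bool = False) -> SurfacePoint:
    """Evaluate a surface at a geometry (module-level convenience)."""
    return surface.evaluate(q, want_hessian=want_hessian)


def energy_gap(pes: TwoStatePES, q) -> float:
    """``ΔE(q) = E1(q) − E0(q)`` in Hartree."""
    return pes.state1.evaluate(q).energy - pes.state0.evaluate(q).energy


def gap_variation(pes: TwoStatePES, q) -> float:
    """Gap change relative to the reference: ``ΔE(q) − ΔE(q_ref)``."""
    return energy_gap(pes, q) - pes.gap_at_ref


def external_force(pes: TwoStatePES, q) -> tuple[np.ndarray, float]:
    """External force holding ``q`` as a state-0 equilibrium, with its norm.

    Under an applied force the relaxed structure satisfies
    ``∇E0(q) = F_ext``: the internal and external forces cancel.  Returns
    ``(force_vector, magnitude)`` in Hartree/Bohr.
    """
    f = pes.state0.evaluate(q).gradient
    return f, float(np.linalg.norm(f))


# ---------------------------------------------------------------------------
# fixture generators
# ---------------------------------------------------------------------------


def _random_spd(rng: np.random.Generator, n: int,
                spectrum: tuple[float, float]) -> np.ndarray:
    """Symmetric matrix with eigenvalues drawn uniformly in ``spectrum``,
    built by spectral synthesis in a random orthogonal basis so the
    conditioning is controlled exactly."""
    lo, hi = spectrum
    eigvals = rng.uniform(lo, hi, size=n)
    if n == 1:
        basis = np.ones((1, 1))
    else:
        mat = rng.standard_normal((n, n))
        basis, r = np.linalg.qr(mat)
        basis = basis * np.sign(np.diag(r))  # fix sign convention
    h = (basis * eigvals) @ basis.T
    return 0.5 * (h + h.T)


def make_quadratic_pair(
    n_dof: int,
    seed: int,
    spectrum0: tuple[float, float] = (0.2, 2.0),
    spectrum1: tuple[float, float] = (0.1, 2.5),
    g1_scale: float = 0.05,
    gap0: float = 0.35,
) -> TwoStatePES:
    """Seeded random quadratic two-state pair.

    State 0 is a positive-definite quadratic with its minimum at the origin
    and zero gradient (force-free reference).  State 1 has a random
    symmetric Hessian with eigenvalues in ``spectrum1`` and a random
    gradient of norm ``g1_scale``.  Defaults are typical molecular scales:
    force constants of a few tenths to a couple of Hartree/Bohr² and an
    excited-state gradient of a few hundredths of Hartree/Bohr.

    Identical seeds yield bit-identical pairs.
    """
    if n_dof < 1:
        raise ValueError("n_dof must be >= 1")
    if spectrum0[0] <= 0:
        raise ValueError(
            "state 0 must be expanded at a minimum: spectrum0 lower bound "
            f"must be positive, got {spectrum0[0]}"
        )
    rng = np.random.default_rng(seed)
    h0 = _random_spd(rng, n_dof, spectrum0)
    h1 = _random_spd(rng, n_dof, spectrum1)
    g1 = rng.standard_normal(n_dof)
    norm = np.linalg.norm(g1)
    g1 = g1 * (g1_scale / norm) if norm > 0 and g1_scale > 0 else np.zeros(n_dof)
    origin = np.zeros(n_dof)
    state0 = QuadraticSurface(origin, 0.0, origin.copy(), h0)
    state1 = QuadraticSurface(origin, gap0, g1, h1)
    return TwoStatePES(state0, state1)


def make_model_2d_pair(
    kx0: float = 0.9,
    d0: float = 0.04,
    a0: float = 1.2,
    ky0: float = 0.02,
    gap0: float = 0.22,
    kx1: float = 1.05,
    d1: float = 0.05,
    a1: float = 1.0,
    ky1: float = 0.03,
    q_min1: tuple[float, float] = (0.1, 0.45),
) -> TwoStatePES:
    """Anharmonic two-state fixture with one stiff and one soft direction.

    State 0 has a harmonic ``x`` (force constant ``kx0``) and a soft,
    strongly anharmonic ``y`` (Morse curvature ``2 d0 a0²`` plus the weak
    harmonic ``ky0``, together ≈ 0.14 Hartree/Bohr² — well below the stiff
    mode) with its minimum at the origin.  ``ky0`` exceeds the Morse force
    dip ``d0 a0²/4`` so the restoring force is monotone and the
    constant-force level sets are simply connected, keeping the
    continuation optimum global.  State 1 has its minimum displaced mostly
    along the soft coordinate, giving a substantial gap gradient.  This is
    the regime where a single second-order expansion at the minimum
    mispredicts the optimal force.
    """
    state0 = Model2DSurface(kx0, d0, a0, (0.0, 0.0), e_min=0.0, ky=ky0)
    state1 = Model2DSurface(kx1, d1, a1, q_min1, e_min=gap0, ky=ky1)
    return TwoStatePES(state0, state1, q_ref=(0.0, 0.0))


# ---------------------------------------------------------------------------
# brute-force constrained-search oracle (<= 2 dof by design)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BruteForceOptimum:
    """Result of the dense constrained search on the force level set."""

    q_increase: np.ndarray
    gap_increase: float
    q_decrease: np.ndarray
    gap_decrease: float
    force_magnitude: float

    def branch(self, name: str) -> tuple[np.ndarray, float]:
        if name == "increase":
            return self.q_increase, self.gap_increase
        if name == "decrease":
            return self.q_decrease, self.gap_decrease
        raise ValueError(f"unknown branch {name!r}")


def _force_mag(pes: TwoStatePES, coords: np.ndarray) -> float:
    return float(np.linalg.norm(pes.state0.evaluate(coords).gradient))


def brute_force_optimum(
    pes: TwoStatePES,
    force_magnitude: float,
    resolution: int = 201,
    halfwidth: float = 2.0,
) -> BruteForceOptimum:
    """Dense grid search over the level set ``‖∇E0(q)‖ = force_magnitude``.

    Independent validation oracle for the optimizers, restricted to one or
    two degrees of freedom.  The level set is extracted from a dense grid
    centred on the reference structure (box half-width ``halfwidth`` Bohr)
    and the best gap-increasing and gap-decreasing points are polished by
    constrained local optimization on the exact surfaces.

    Raises
    ------
    ConstraintUnreachableError
        If the level set does not intersect the search box.
    """
    n = pes.n_dof
    if n > 2:
        raise ValueError("brute-force oracle is limited to <= 2 dof")
    if force_magnitude < 0:
        raise ValueError("force magnitude must be non-negative")
    ref = pes.q_ref.coordinates
    if force_magnitude == 0.0:
        # zero force: every branch collapses onto the unforced reference
        return BruteForceOptimum(ref.copy(), 0.0, ref.copy(), 0.0, 0.0)

    axes = [np.linspace(r - halfwidth, r + halfwidth, resolution) for r in ref]
    if n == 1:
        return _brute_force_1d(pes, force_magnitude, axes[0])
    return _brute_force_2d(pes, force_magnitude, axes)


def _brute_force_1d(pes, f, grid) -> BruteForceOptimum:
    vals = np.array([_force_mag(pes, np.array([x])) for x in grid]) - f
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(
                brentq(lambda x: _force_mag(pes, np.array([x])) - f,
                       grid[i], grid[i + 1], xtol=1e-14)
            )
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:
        raise ConstraintUnreachableError(
            f"force level set ‖F‖={f} empty in search interval "
            f"[{grid[0]}, {grid[-1]}]"
        )
    gvs = [gap_variation(pes, np.array([x])) for x in roots]
    imax, imin = int(np.argmax(gvs)), int(np.argmin(gvs))
    return BruteForceOptimum(
        np.array([roots[imax]]), gvs[imax],
        np.array([roots[imin]]), gvs[imin], f,
    )


def _brute_force_2d(pes, f, axes) -> BruteForceOptimum:
    xs, ys = axes
    fx = np.empty((len(xs), len(ys)))
    gv = np.empty_like(fx)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            q = np.array([x, y])
            fx[i, j] = _force_mag(pes, q)
            gv[i, j] = gap_variation(pes, q)
    if not (fx.min() <= f <= fx.max()):
        raise ConstraintUnreachableError(
            f"force level set ‖F‖={f} empty in search box "
            f"(range [{fx.min():.3g}, {fx.max():.3g}])"
        )
    spacing = max(xs[1] - xs[0], ys[1] - ys[0])
    # keep grid points within a band around the level set; the band width
    # follows the local variation of ‖F‖ across one grid cell
    band = np.maximum(0.05 * f, 2.0 * spacing * _grad_scale(fx, spacing))
    mask = np.abs(fx - f) <= band
    if not mask.any():
        mask = np.abs(fx - f) <= np.abs(fx - f).min() + 1e-30
    cand = np.argwhere(mask)

    def polish(sign: float) -> tuple[np.ndarray, float]:
        # rank candidates on the raw grid, polish the best few
        order = np.argsort([sign * gv[i, j] for i, j in cand])[::-1]
        best_q, best_gv = None, -np.inf
        for idx in order[:5]:
            i, j = cand[idx]
            q0 = np.array([xs[i], ys[j]])
            res = minimize(
                lambda q: -sign * gap_variation(pes, q),
                q0,
                method="SLSQP",
                constraints=[{
                    "type": "eq",
                    "fun": lambda q: _force_mag(pes, q) ** 2 - f**2,
                }],
                options={"maxiter": 200, "ftol": 1e-14},
            )
            if res.success:
                ach = _force_mag(pes, res.x)
                if abs(ach - f) < 1e-6 * f:
                    cur = sign * gap_variation(pes, res.x)
                    if cur > best_gv:
                        best_q, best_gv = res.x, cur
        if best_q is None:  # fall back to the raw grid winner
            i, j = cand[order[0]]
            best_q = np.array([xs[i], ys[j]])
            best_gv = sign * gv[i, j]
        return best_q, sign * best_gv

    q_up, gv_up = polish(+1.0)
    q_dn, gv_dn = polish(-1.0)
    return BruteForceOptimum(q_up, gv_up, q_dn, gv_dn, f)


def _grad_scale(field: np.ndarray, spacing: float) -> float:
    gx, gy = np.gradient(field, spacing)
    return float(np.hypot(gx, gy).max())


# ---------------------------------------------------------------------------
# JSON serialization (documented schema, row-major Hessians, units field)
# ---------------------------------------------------------------------------


def surface_to_dict(surface: Surface) -> dict:
    """Serialize a surface to the documented JSON-compatible schema."""
    if isinstance(surface, QuadraticSurface):
        return {
            "kind": "quadratic",
            "units": {"energy": "hartree", "length": "bohr"},
            "q_ref": surface.q_ref.coordinates.tolist(),
            "atom_labels": list(surface.q_ref.atom_labels),
            "e_ref": surface.e_ref,
            "g_ref": surface.g_ref.tolist(),
            "h_ref": surface.h_ref.ravel().tolist(),  # row-major
        }
    if isinstance(surface, MorseSumSurface):
        return {
            "kind": "morse-sum",
            "units": {"energy": "hartree", "length": "bohr"},
            "d": surface.d.tolist(),
            "a": surface.a.tolist(),
            "q_min": surface.q_min.coordinates.tolist(),
            "e_min": surface.e_min,
        }
    if isinstance(surface, QuarticPerturbedSurface):
        return {
            "kind": "quartic-perturbed-quadratic",
            "units": {"energy": "hartree", "length": "bohr"},
            "h": surface.h.ravel().tolist(),
            "c": surface.c.tolist(),
            "q_min": surface.q_min.coordinates.tolist(),
            "e_min": surface.e_min,
        }
    if isinstance(surface, Model2DSurface):
        return {
            "kind": "model-2d",
            "units": {"energy": "hartree", "length": "bohr"},
            "kx": surface.kx,
            "d": surface.d,
            "a": surface.a,
            "b": surface.b,
            "ky": surface.ky,
            "q_min": surface.q_min.coordinates.tolist(),
            "e_min": surface.e_min,
        }
    raise TypeError(f"cannot serialize surface of type {type(surface).__name__}")


def surface_from_dict(data: dict) -> Surface:
    kind = data["kind"]
    if kind == "quadratic":
        n = len(data["q_ref"])
        return QuadraticSurface(
            np.array(data["q_ref"]),
            data["e_ref"],
            np.array(data["g_ref"]),
            np.array(data["h_ref"]).reshape(n, n),
            atom_labels=tuple(data.get("atom_labels", ())),
        )
    if kind == "morse-sum":
        return MorseSumSurface(data["d"], data["a"], data["q_min"],
                               data["e_min"])
    if kind == "quartic-perturbed-quadratic":
        n = len(data["q_min"])
        return QuarticPerturbedSurface(
            np.array(data["h"]).reshape(n, n), data["c"], data["q_min"],
            data["e_min"],
        )
    if kind == "model-2d":
        return Model2DSurface(data["kx"], data["d"], data["a"], data["q_min"],
                              data["e_min"], data.get("b", 0.0),
                              data.get("ky", 0.0))
    raise ValueError(f"unknown surface kind {kind!r}")


def pes_to_dict(pes: TwoStatePES) -> dict:
    return {
        "schema": "lgmf-two-state-pes-v1",
        "state0": surface_to_dict(pes.state0),
        "state1": surface_to_dict(pes.state1),
        "q_ref": pes.q_ref.coordinates.tolist(),
        "atom_labels": list(pes.q_ref.atom_labels),
    }


def pes_from_dict(data: dict) -> TwoStatePES:
    q_ref = Geometry(np.array(data["q_ref"]),
                     tuple(data.get("atom_labels", ())))
    return TwoStatePES(
        surface_from_dict(data["state0"]),
        surface_from_dict(data["state1"]),
        q_ref=q_ref,
    )


def pes_to_json(pes: TwoStatePES) -> str:
    """Deterministic JSON text: identical pairs serialize byte-for-byte."""
    return json.dumps(pes_to_dict(pes), sort_keys=True, indent=1)


def pes_from_json(text: str) -> TwoStatePES:
    return pes_from_dict(json.loads(text))
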