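"""Closed-form optimal forces on quadratic two-state surfaces.

On a pair of second-order surfaces expanded at the state-0 minimum, the
optimal structure for a fixed external-force magnitude follows from the
Lagrangian stationarity of the gap ``ΔE(q)`` under the constraint
``‖F_ext(q)‖² = const`` with ``F_ext = H0 q``.  Each Lagrange multiplier λ
labels one member of the optimal family through the linear system

    M(λ) Δq = g1,      M(λ) = 2λ H0² − H0 + H1.

Two sign bookkeepings of λ and of the gap curvature appear in the
literature for this system; they trace λ-reparametrized mirror families.
The convention-independent ground truth is the parallelism condition
``∇ΔE ∥ ∇‖F_ext‖²`` at the solution, so :func:`optimal_structure` solves
the matrix as written above, verifies the parallelism cosine numerically,
and falls back to the sign-resolved variant ``2λ H0² + H0 − H1`` (recording
which convention validated) if the first fails.  For the sign-resolved
variant one shows directly that ``∇ΔE = λ ∇‖F_ext‖²`` holds identically at
the solution, so λ is the sensitivity of the gap to the squared force.

The non-totally-symmetric subspace, where the gap gradient has no
component, turns the linear system into an eigenvalue problem: λ must match
an eigenvalue of ``½ H0⁻² (H0 − H1)`` restricted to that block for a
non-trivial distortion to exist (:func:`nosym_eigenvalues`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import brentq

from .exceptions import SingularMatrixError
from .surfaces import Geometry, TwoStatePES, as_coords

__all__ = [
    "QuadraticSolution",
    "SymmetryBasis",
    "ScanResult",
    "SolvabilityReport",
    "equilibrium_structure",
    "optimal_structure",
    "lambda_scan",
    "symmetry_split_solve",
    "nosym_eigenvalues",
    "initial_response_slope",
    "optimal_at_force",
    "pencil_eigenvalues",
    "quadratic_data",
    "cos_angle",
]

logger = logging.getLogger(__name__)

#: λ counts as singular when the smallest singular value of M(λ) falls
#: below this fraction of the largest.
SINGULARITY_RTOL = 1e-8

#: parallelism cosine below which the printed sign convention is rejected
#: and the sign-resolved variant is solved instead.
_CONVENTION_COS_TOL = 0.999


def cos_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 1.0 for a degenerate pair.

    A vanishing vector means the parallelism condition is trivially
    satisfied (e.g. at the unforced minimum), hence the 1.0 convention.
    """
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-14 or nb < 1e-14:
        return 1.0
    return float(np.dot(a, b) / (na * nb))


def quadratic_data(pes: TwoStatePES):
    """Extract (H0, H1, g1, g0) of a quadratic pair at its shared reference."""
    sp0 = pes.state0.evaluate(pes.q_ref, want_hessian=True)
    sp1 = pes.state1.evaluate(pes.q_ref, want_hessian=True)
    return sp0.hessian, sp1.hessian, sp1.gradient, sp0.gradient


def _require_minimum(g0: np.ndarray):
    if np.linalg.norm(g0) >= 1e-8:
        raise ValueError(
            "state-0 expansion must be at its minimum "
            f"(gradient norm {np.linalg.norm(g0):.3g} >= 1e-8)"
        )


def _check_positive_definite(h0: np.ndarray, what: str = "H0"):
    eigvals = np.linalg.eigvalsh(h0)
    scale = np.abs(eigvals).max() if eigvals.size else 0.0
    bad = eigvals[eigvals <= SINGULARITY_RTOL * max(scale, 1e-300)]
    if bad.size:
        raise SingularMatrixError(
            f"{what} is singular or indefinite: offending eigenvalue "
            f"{bad[0]:.6g}"
        )


# ---------------------------------------------------------------------------
# elementary solves
# ---------------------------------------------------------------------------


def equilibrium_structure(h0: np.ndarray, f_ext: np.ndarray) -> np.ndarray:
    """Displacement ``Δq`` of the relaxed structure under an applied force.

    Solves ``H0 Δq = F_ext`` by symmetric (Cholesky) factorization; the
    state-0 Hessian must be positive definite, i.e. the expansion point is
    a minimum.
    """
    h0 = np.atleast_2d(np.asarray(h0, dtype=float))
    f = np.asarray(f_ext, dtype=float).ravel()
    _check_positive_definite(h0)
    c, low = scipy.linalg.cho_factor(h0)
    return scipy.linalg.cho_solve((c, low), f)


@dataclass(frozen=True)
class QuadraticSolution:
    """One member of the closed-form optimal family, labelled by λ."""

    lambda_multiplier: float
    q_opt: Optional[Geometry]
    force_vector: Optional[np.ndarray]
    force_magnitude: float
    gap_variation: float
    branch: str  # "increase" | "decrease"
    singular_flag: bool
    cos_alpha: float
    convention: str  # "printed" | "sign-resolved"


def _matrix(lam: float, h0: np.ndarray, h1: np.ndarray,
            convention: str) -> np.ndarray:
    h0sq = h0 @ h0
    if convention == "printed":
        return 2.0 * lam * h0sq - h0 + h1
    if convention == "sign-resolved":
        return 2.0 * lam * h0sq + h0 - h1
    raise ValueError(f"unknown convention {convention!r}")


def _solve_convention(lam, h0, h1, g1, convention):
    m = _matrix(lam, h0, h1, convention)
    sv = np.linalg.svd(m, compute_uv=False)
    if sv[-1] == 0.0 or sv[-1] < SINGULARITY_RTOL * sv[0]:
        return None, True
    dq = np.linalg.solve(m, g1)
    return dq, False


def optimal_structure(lam: float, pes: TwoStatePES) -> QuadraticSolution:
    """Closed-form optimal displacement and force for one multiplier λ.

    Solves the optimality linear system, then self-validates by checking
    the parallelism of ``∇ΔE`` and ``∇‖F_ext‖²`` at the solution; when the
    first sign convention fails that check (generic in more than one
    dimension) the sign-resolved variant is solved instead and the choice
    is recorded in the solution's ``convention`` field.

    λ values at a spectrum point of the associated matrix pencil set
    ``singular_flag`` instead of raising.
    """
    h0, h1, g1, g0 = quadratic_data(pes)
    _require_minimum(g0)

    best = None
    for convention in ("printed", "sign-resolved"):
        dq, singular = _solve_convention(lam, h0, h1, g1, convention)
        if singular:
            if best is None:
                best = (None, convention, True, np.nan)
            continue
        grad_gap = g1 + (h1 - h0) @ dq
        grad_fsq = 2.0 * (h0 @ h0) @ dq
        cos = cos_angle(grad_gap, grad_fsq)
        if best is None or abs(cos) > abs(best[3]):
            best = (dq, convention, False, cos)
        if abs(cos) >= _CONVENTION_COS_TOL:
            break

    dq, convention, singular, cos = best
    if singular or dq is None:
        return QuadraticSolution(lam, None, None, np.nan, np.nan,
                                 "increase", True, np.nan, convention)
    force = h0 @ dq
    gv = float(g1 @ dq + 0.5 * dq @ ((h1 - h0) @ dq))
    branch = "increase" if gv >= 0 else "decrease"
    return QuadraticSolution(
        lam, Geometry(pes.q_ref.coordinates + dq, pes.q_ref.atom_labels),
        force, float(np.linalg.norm(force)), gv, branch, False, cos,
        convention,
    )


@dataclass
class ScanResult:
    """λ-scan output: the two branches sorted by force magnitude."""

    increase: list[QuadraticSolution] = field(default_factory=list)
    decrease: list[QuadraticSolution] = field(default_factory=list)
    dropped_lambdas: list[float] = field(default_factory=list)


def lambda_scan(pes: TwoStatePES, lambda_grid: Sequence[float]) -> ScanResult:
    """Trace the closed-form optimal family over a grid of multipliers.

    Singular λ values (at a pencil spectrum point) are dropped with a log
    message.  Solutions are partitioned into the gap-increasing and
    gap-decreasing branches by the sign of the gap variation and each
    branch is sorted by achieved force magnitude, which — unlike λ — orders
    the branch monotonically.
    """
    grid = list(lambda_grid)
    if not grid:
        raise ValueError("lambda grid is empty")
    out = ScanResult()
    for lam in grid:
        sol = optimal_structure(float(lam), pes)
        if sol.singular_flag:
            logger.info("dropping singular lambda %.6g", lam)
            out.dropped_lambdas.append(float(lam))
            continue
        (out.increase if sol.gap_variation >= 0 else out.decrease).append(sol)
    out.increase.sort(key=lambda s: s.force_magnitude)
    out.decrease.sort(key=lambda s: s.force_magnitude)
    return out


# ---------------------------------------------------------------------------
# symmetry-adapted split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymmetryBasis:
    """Orthonormal basis split into totally-symmetric / non-symmetric blocks.

    ``matrix`` holds the basis column-wise; the first ``n_sym`` columns span
    the totally symmetric subspace (which must contain the gap gradient
    g1), the rest its orthogonal complement.
    """

    matrix: np.ndarray
    n_sym: int
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if not (0 <= self.n_sym <= m.shape[1]):
            raise ValueError("n_sym outside basis size")
        gram = m.T @ m
        if not np.allclose(gram, np.eye(m.shape[1]), atol=1e-10):
            raise ValueError("symmetry basis is not orthonormal to 1e-10")

    @property
    def sym(self) -> np.ndarray:
        return self.matrix[:, : self.n_sym]

    @property
    def nosym(self) -> np.ndarray:
        return self.matrix[:, self.n_sym:]

    @classmethod
    def identity(cls, n: int, n_sym: Optional[int] = None) -> "SymmetryBasis":
        return cls(np.eye(n), n if n_sym is None else n_sym)

    @classmethod
    def from_coordinate_split(cls, n: int,
                              sym_indices: Sequence[int]) -> "SymmetryBasis":
        sym_idx = list(sym_indices)
        nosym_idx = [i for i in range(n) if i not in sym_idx]
        cols = np.eye(n)[:, sym_idx + nosym_idx]
        return cls(cols, len(sym_idx))


@dataclass(frozen=True)
class SolvabilityReport:
    """Whether the non-symmetric block admits non-trivial distortions at λ."""

    lambda_is_eigenvalue: bool
    free_directions: tuple[np.ndarray, ...]
    block_eigenvalues: tuple[float, ...]


def _block(mat: np.ndarray, basis_block: np.ndarray) -> np.ndarray:
    return basis_block.T @ mat @ basis_block


def symmetry_split_solve(
    lam: float, pes: TwoStatePES, basis: SymmetryBasis,
    eig_atol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, SolvabilityReport]:
    """Solve the optimality system block-wise in symmetry coordinates.

    The gap gradient must live in the totally-symmetric block (validated);
    the symmetric block then yields a unique solution for each λ, while the
    gradient-free non-symmetric block either forces a zero distortion or —
    when λ hits a block pencil eigenvalue — admits infinitely many
    solutions along the reported eigenvector directions, which are listed
    rather than resolved arbitrarily.

    Returns ``(q_sym, q_nosym, report)`` with both displacement components
    expressed in the original coordinates.
    """
    h0, h1, g1, g0 = quadratic_data(pes)
    _require_minimum(g0)
    u_s, u_n = basis.sym, basis.nosym

    g_n = u_n.T @ g1 if u_n.shape[1] else np.zeros(0)
    if g_n.size and np.linalg.norm(g_n) >= 1e-8:
        raise ValueError(
            "gap gradient has non-totally-symmetric components "
            f"(norm {np.linalg.norm(g_n):.3g}); the symmetry premise fails — "
            "use the general solver (optimal_structure) instead"
        )

    m = _matrix(lam, h0, h1, "printed")
    # the basis must actually block-diagonalize the problem
    if u_s.shape[1] and u_n.shape[1]:
        cross = u_s.T @ m @ u_n
        if np.abs(cross).max() > 1e-8 * max(np.abs(m).max(), 1.0):
            raise ValueError(
                "basis does not block-diagonalize the optimality matrix; "
                "the declared symmetry split is inconsistent with the pair"
            )

    # symmetric block: unique solution per λ
    if u_s.shape[1]:
        m_ss = _block(m, u_s)
        sv = np.linalg.svd(m_ss, compute_uv=False)
        if sv[-1] < SINGULARITY_RTOL * sv[0]:
            raise SingularMatrixError(
                f"symmetric block singular at lambda={lam:.6g}"
            )
        q_sym = u_s @ np.linalg.solve(m_ss, u_s.T @ g1)
    else:
        q_sym = np.zeros(pes.n_dof)

    # non-symmetric block: zero unless λ is a block pencil eigenvalue
    q_nosym = np.zeros(pes.n_dof)
    if u_n.shape[1]:
        eigs = nosym_eigenvalues(pes, basis)
        hits = [(lv, v) for lv, v in eigs if abs(lv - lam) <= eig_atol]
        report = SolvabilityReport(
            bool(hits),
            tuple(v for _, v in hits),
            tuple(lv for lv, _ in eigs),
        )
    else:
        report = SolvabilityReport(False, (), ())
    return q_sym, q_nosym, report


def nosym_eigenvalues(
    pes: TwoStatePES, basis: SymmetryBasis
) -> list[tuple[float, np.ndarray]]:
    """λ values admitting non-trivial non-symmetric optimal distortions.

    These are the λ making the non-symmetric block of the optimality
    matrix singular, i.e. the eigenvalues of ``½ H0⁻² (H0 − H1)`` restricted
    to the block, solved as the generalized symmetric problem
    ``(H0 − H1) v = 2λ H0² v``.  Returns ``(λ, unit eigenvector)`` pairs
    sorted ascending, eigenvectors in the original coordinates.
    """
    if basis.nosym.shape[1] == 0:
        raise ValueError("non-symmetric block is empty")
    h0, h1, _, _ = quadratic_data(pes)
    u_n = basis.nosym
    h0b = _block(h0, u_n)
    _check_positive_definite(h0b, what="H0 (non-symmetric block)")
    ab = _block(h0 - h1, u_n)
    bb = h0b @ h0b
    w, v = scipy.linalg.eigh(ab, 2.0 * bb)
    out = []
    for i in np.argsort(w):
        vec = u_n @ v[:, i]
        vec = vec / np.linalg.norm(vec)
        out.append((float(w[i]), vec))
    return out


def pencil_eigenvalues(h0: np.ndarray,
                       h1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full-space pencil spectrum: λ with ``(H0 − H1) v = 2λ H0² v``.

    Returns (ascending eigenvalues, eigenvectors as columns in matching
    order, original coordinates, H0²-orthonormal).
    """
    _check_positive_definite(h0)
    w, v = scipy.linalg.eigh(h0 - h1, 2.0 * (h0 @ h0))
    order = np.argsort(w)
    return w[order], v[:, order]


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def initial_response_slope(pes: TwoStatePES) -> float:
    """Zero-force slope of the gap variation vs force magnitude.

    In the small-force limit the optimal direction aligns the displacement
    with ``H0⁻¹ g1`` and the gap changes linearly with the applied force at
    rate ``‖H0⁻¹ g1‖`` (Hartree per Hartree/Bohr); both branches share the
    magnitude with opposite signs.
    """
    h0, _, g1, g0 = quadratic_data(pes)
    _require_minimum(g0)
    return float(np.linalg.norm(equilibrium_structure(h0, g1)))


def optimal_at_force(
    pes: TwoStatePES, force_magnitude: float, branch: str,
    lambda_span: float = 1e12,
) -> QuadraticSolution:
    """Closed-form optimum at a prescribed force magnitude on one branch.

    Follows the continuation family through the unforced minimum: in the
    sign-resolved convention the gap-increasing branch lives at λ above the
    whole pencil spectrum of ``½ H0⁻² (H1 − H0)`` and the decreasing branch
    below it, with the force magnitude a strictly monotone function of λ on
    each side.  The matching λ is found by safeguarded root bracketing.
    """
    if branch not in ("increase", "decrease"):
        raise ValueError(f"unknown branch {branch!r}")
    h0, h1, g1, g0 = quadratic_data(pes)
    _require_minimum(g0)
    if force_magnitude == 0.0:
        return QuadraticSolution(
            np.inf if branch == "increase" else -np.inf,
            pes.q_ref, np.zeros(pes.n_dof), 0.0, 0.0, branch, False, 1.0,
            "sign-resolved",
        )
    if np.linalg.norm(g1) < 1e-14:
        raise ValueError("gap gradient vanishes: the continuation family "
                         "through the minimum is degenerate")
    # sign-resolved pencil: μ with (H1 − H0) v = 2μ H0² v, i.e. μ = −λ of
    # the printed pencil with the same eigenvectors
    lam_printed, _ = pencil_eigenvalues(h0, h1)
    mu_lo, mu_hi = -lam_printed[-1], -lam_printed[0]

    def fmag(lam_: float) -> float:
        dq, singular = _solve_convention(lam_, h0, h1, g1, "sign-resolved")
        if singular:
            return np.inf
        return float(np.linalg.norm(h0 @ dq))

    scale = max(abs(mu_lo), abs(mu_hi), 1.0)
    if branch == "increase":
        a = mu_hi + 1e-9 * scale
        b = mu_hi + scale
        while fmag(b) > force_magnitude and b < lambda_span:
            b = mu_hi + (b - mu_hi) * 4.0
        while fmag(a) < force_magnitude:
            a = mu_hi + (a - mu_hi) / 4.0
    else:
        a = mu_lo - scale
        b = mu_lo - 1e-9 * scale
        while fmag(a) > force_magnitude and a > -lambda_span:
            a = mu_lo - (mu_lo - a) * 4.0
        while fmag(b) < force_magnitude:
            b = mu_lo - (mu_lo - b) / 4.0
    lam = brentq(lambda x: fmag(x) - force_magnitude, a, b,
                 xtol=1e-15, rtol=1e-15, maxiter=200)
    dq, _ = _solve_convention(lam, h0, h1, g1, "sign-resolved")
    force = h0 @ dq
    gv = float(g1 @ dq + 0.5 * dq @ ((h1 - h0) @ dq))
    grad_gap = g1 + (h1 - h0) @ dq
    grad_fsq = 2.0 * (h0 @ h0) @ dq
    return QuadraticSolution(
        float(lam),
        Geometry(pes.q_ref.coordinates + dq, pes.q_ref.atom_labels),
        force, float(np.linalg.norm(force)), gv, branch, False,
        cos_angle(grad_gap, grad_fsq), "sign-resolved",
    )
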