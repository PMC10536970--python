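"""Molecular-frame utilities: rigid-body projection and force pairs.

Experimentally realizable molecular forces are built from force pairs —
equal and opposite forces on two atoms along their connecting axis, as in
polymer-embedded mechanophores or molecular force probes.  Any net-force-
and net-torque-free Cartesian force field can be approximated by a linear
combination of such pairs; :func:`decompose_into_pairs` quantifies how well
a candidate set reproduces a given optimal force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surfaces import Geometry
from .units import convert  # re-exported here as part of the utility surface

__all__ = [
    "ForcePair",
    "tr_projector",
    "force_pair_vector",
    "decompose_into_pairs",
    "PairDecomposition",
    "convert",
]


@dataclass(frozen=True)
class ForcePair:
    """Equal-and-opposite force on two atoms along their connecting axis.

    ``sign='pulling'`` stretches the pair (forces point away from each
    other); ``'pushing'`` compresses it.  Magnitude in nN for I/O surfaces,
    in Hartree/Bohr when used internally.
    """

    atom_i: int
    atom_j: int
    magnitude: float
    sign: str = "pulling"

    def __post_init__(self):
        if self.atom_i == self.atom_j:
            raise ValueError("a force pair needs two distinct atoms")
        if self.sign not in ("pulling", "pushing"):
            raise ValueError("sign must be 'pulling' or 'pushing'")


def tr_projector(geometry: Geometry) -> np.ndarray:
    """Projector onto the complement of rigid translations and rotations.

    Builds the three translation generators and the (linearized,
    instantaneous) rotation generators at the current geometry,
    orthonormalizes them, and returns ``P = I − V Vᵀ``.  Collinear
    geometries carry only two independent rotations; the rank is detected
    numerically.  The projector is idempotent and symmetric.
    """
    if geometry.n_atoms < 2:
        raise ValueError("rigid-body projection needs at least two atoms")
    pos = geometry.positions()
    n = geometry.n_dof
    center = pos.mean(axis=0)
    rel = pos - center

    gens = []
    for k in range(3):  # translations
        t = np.zeros((len(pos), 3))
        t[:, k] = 1.0
        gens.append(t.ravel())
    axes = np.eye(3)
    for k in range(3):  # rotations: δr_a = e_k × (r_a − center)
        r = np.cross(np.broadcast_to(axes[k], rel.shape), rel)
        gens.append(r.ravel())

    g = np.column_stack(gens)
    # orthonormalize, discarding numerically dependent generators
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    v = u[:, :rank]
    return np.eye(n) - v @ v.T


def force_pair_vector(geometry: Geometry, pair: ForcePair) -> np.ndarray:
    """Cartesian 3N force field realizing one force pair.

    Forces of the pair's magnitude act along the i–j axis, directed to
    stretch ('pulling') or compress ('pushing') the pair; zero net force
    and zero net torque hold by construction.
    """
    pos = geometry.positions()
    na = geometry.n_atoms
    if not (0 <= pair.atom_i < na and 0 <= pair.atom_j < na):
        raise IndexError("force-pair atom index out of range")
    axis = pos[pair.atom_i] - pos[pair.atom_j]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("coincident atoms: force-pair axis undefined")
    axis = axis / norm
    if pair.sign == "pushing":
        axis = -axis
    f = np.zeros_like(pos)
    f[pair.atom_i] = pair.magnitude * axis
    f[pair.atom_j] = -pair.magnitude * axis
    return f.ravel()


@dataclass(frozen=True)
class PairDecomposition:
    """Least-squares expansion of a force field over candidate pairs."""

    pairs: tuple[ForcePair, ...]
    coefficients: np.ndarray
    residual_norm: float
    ranked: tuple[int, ...]  # candidate indices by decreasing contribution
    rank_deficient: bool


def decompose_into_pairs(
    f: np.ndarray, geometry: Geometry, candidate_pairs: list[ForcePair]
) -> PairDecomposition:
    """Expand a force field over a dictionary of unit force pairs.

    The target is first projected onto the rigid-body-free subspace (a
    force pair can never reproduce net force or torque).  Coefficients are
    the least-squares solution over unit-magnitude pair vectors; the
    residual norm quantifies the quality of the approximation, which is
    system dependent.  A rank-deficient dictionary yields the minimum-norm
    solution with ``rank_deficient=True``.
    """
    if not candidate_pairs:
        raise ValueError("candidate pair list is empty")
    p = tr_projector(geometry)
    target = p @ np.asarray(f, dtype=float).ravel()
    cols = np.column_stack([
        force_pair_vector(geometry, ForcePair(c.atom_i, c.atom_j, 1.0, c.sign))
        for c in candidate_pairs
    ])
    coef, _, rank, _ = np.linalg.lstsq(cols, target, rcond=None)
    residual = float(np.linalg.norm(target - cols @ coef))
    contrib = np.abs(coef) * np.linalg.norm(cols, axis=0)
    ranked = tuple(int(i) for i in np.argsort(contrib)[::-1])
    return PairDecomposition(
        tuple(candidate_pairs), coef, residual, ranked,
        rank_deficient=rank < len(candidate_pairs),
    )
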