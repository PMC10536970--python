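"""Adapter contract for external electronic-structure backends.

The package never computes electronic structure itself.  Any engine able to
return the energy and gradient of the two electronic states at a Cartesian
geometry can drive the optimizers by satisfying :class:`ElectronicBackend`.
Analytic Hessians are optional: when a backend declares none (common for
excited states), second derivatives are assembled by central finite
differences of its gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .io import finite_difference_hessian
from .surfaces import Geometry, Surface, SurfacePoint, TwoStatePES, as_coords

__all__ = [
    "BackendCapabilities",
    "ElectronicBackend",
    "BackendSurface",
    "make_backend_pes",
]


@dataclass(frozen=True)
class BackendCapabilities:
    """What the adapter can deliver."""

    n_states: int = 2
    analytic_gradient: bool = True
    analytic_hessian: bool = False


@runtime_checkable
class ElectronicBackend(Protocol):
    """Evaluation contract: ``(geometry, state index, want_hessian)`` →
    :class:`~lgmf.surfaces.SurfacePoint` in atomic units."""

    capabilities: BackendCapabilities

    def evaluate(self, geometry: Geometry, state: int,
                 want_hessian: bool = False) -> SurfacePoint:
        ...


class BackendSurface(Surface):
    """One electronic state of a backend exposed as an evaluable surface.

    Fills in missing analytic Hessians by finite differencing the backend
    gradients (step in Bohr, configurable).
    """

    def __init__(self, backend: ElectronicBackend, state: int,
                 n_dof: int, atom_labels=(), fd_step: float = 1e-3):
        if state >= backend.capabilities.n_states:
            raise ValueError(
                f"backend exposes {backend.capabilities.n_states} states, "
                f"state {state} requested"
            )
        self.backend = backend
        self.state = state
        self.n_dof = n_dof
        self.atom_labels = tuple(atom_labels)
        self.fd_step = fd_step

    def _geometry(self, coords: np.ndarray) -> Geometry:
        return Geometry(coords, self.atom_labels)

    def _evaluate(self, coords, want_hessian):
        sp = self.backend.evaluate(self._geometry(coords), self.state,
                                   want_hessian=want_hessian)
        if want_hessian and sp.hessian is None:
            if self.backend.capabilities.analytic_hessian:
                raise RuntimeError(
                    "backend declares analytic Hessians but returned none"
                )
            hess = finite_difference_hessian(
                lambda q: self.backend.evaluate(
                    self._geometry(q), self.state
                ).gradient,
                coords,
                step=self.fd_step,
            )
            sp = SurfacePoint(sp.energy, sp.gradient, hess)
        if sp.gradient.size != self.n_dof:
            raise ValueError(
                f"backend gradient has {sp.gradient.size} components, "
                f"expected {self.n_dof}"
            )
        return sp


def make_backend_pes(backend: ElectronicBackend, q_ref: Geometry,
                     fd_step: float = 1e-3) -> TwoStatePES:
    """Wrap a two-state backend into a :class:`TwoStatePES` at ``q_ref``."""
    n = as_coords(q_ref).size
    labels = q_ref.atom_labels if isinstance(q_ref, Geometry) else ()
    s0 = BackendSurface(backend, 0, n, labels, fd_step)
    s1 = BackendSurface(backend, 1, n, labels, fd_step)
    return TwoStatePES(s0, s1, q_ref=q_ref)
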