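"""File I/O: XYZ geometries, surface JSON, ramp CSV, run manifests.

Files store community units — Ångström for coordinates, nN for forces,
kcal/mol for energies — while everything in memory is atomic units; the
conversion happens here and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import units
from .surfaces import Geometry, TwoStatePES, pes_from_json, pes_to_json

__all__ = [
    "read_xyz",
    "write_xyz",
    "load_pes",
    "save_pes",
    "finite_difference_hessian",
    "ramp_to_dataframe",
    "scan_to_dataframe",
    "write_ramp_csv",
    "write_scan_csv",
    "write_trajectory_xyz",
    "write_manifest",
    "load_run_config",
]


class XYZParseError(ValueError):
    """Malformed XYZ file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_xyz(path) -> tuple[Geometry, Optional[np.ndarray]]:
    """Read a (possibly extended) XYZ file.

    Standard rows hold ``element x y z`` in Å; the extended variant
    appends three per-atom force columns in nN.  Returns the geometry in
    Bohr and, when force columns are present, the 3N force vector in
    Hartree/Bohr (else None).
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZParseError("empty file", 1)
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"bad atom count {lines[0]!r}", 1) from None
    rows = [ln for ln in lines[2:] if ln.strip()]
    if len(rows) != count:
        raise XYZParseError(
            f"count line says {count} atoms but {len(rows)} coordinate "
            "rows found", 2 + len(rows),
        )
    labels, coords, forces = [], [], []
    has_forces = None
    for i, ln in enumerate(rows):
        parts = ln.split()
        if len(parts) not in (4, 7):
            raise XYZParseError(
                f"expected 'element x y z [fx fy fz]', got {ln!r}", i + 3
            )
        row_has_forces = len(parts) == 7
        if has_forces is None:
            has_forces = row_has_forces
        elif has_forces != row_has_forces:
            raise XYZParseError("mixed plain and force-annotated rows", i + 3)
        labels.append(parts[0])
        try:
            coords.extend(float(x) for x in parts[1:4])
            if row_has_forces:
                forces.extend(float(x) for x in parts[4:7])
        except ValueError:
            raise XYZParseError(f"non-numeric field in {ln!r}", i + 3) from None
    geom = Geometry(
        units.convert(np.array(coords), "angstrom", "bohr"), tuple(labels)
    )
    fvec = (
        units.convert(np.array(forces), "nN", "hartree/bohr")
        if has_forces else None
    )
    return geom, fvec


def write_xyz(path, geometry: Geometry, forces=None, comment: str = ""):
    """Write standard XYZ (Å), optionally extended with force columns (nN).

    Coordinates are printed to 1e-8 Å so write/read round trips preserve
    them to that precision.
    """
    if not geometry.atom_labels:
        raise ValueError("XYZ output needs atom labels")
    pos = units.convert(geometry.positions(), "bohr", "angstrom")
    f_nn = None
    if forces is not None:
        f_nn = units.convert(
            np.asarray(forces, dtype=float).reshape(-1, 3),
            "hartree/bohr", "nN",
        )
        if f_nn.shape[0] != geometry.n_atoms:
            raise ValueError("force vector length does not match atom count")
    out = [str(geometry.n_atoms), comment]
    for a, label in enumerate(geometry.atom_labels):
        row = f"{label:<3s}" + "".join(f" {x:20.8f}" for x in pos[a])
        if f_nn is not None:
            row += "".join(f" {x:20.8f}" for x in f_nn[a])
        out.append(row)
    Path(path).write_text("\n".join(out) + "\n")


def save_pes(path, pes: TwoStatePES):
    Path(path).write_text(pes_to_json(pes) + "\n")


def load_pes(path) -> TwoStatePES:
    return pes_from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# numerical Hessian from a gradient callable
# ---------------------------------------------------------------------------


def finite_difference_hessian(
    gradient: Callable[[np.ndarray], np.ndarray],
    q,
    step: float = 1e-3,
) -> np.ndarray:
    """Central-difference Hessian column-by-column from analytic gradients.

    The standard fallback when a backend provides gradients but no
    analytic second derivatives (typical for excited states).  ``step`` is
    in Bohr.  The result is symmetrized by averaging; on an exact quadratic
    surface central differences are exact to round-off.
    """
    coords = np.asarray(
        q.coordinates if isinstance(q, Geometry) else q, dtype=float
    ).ravel()
    n = coords.size
    h = np.empty((n, n))
    for k in range(n):
        dq = np.zeros(n)
        dq[k] = step
        try:
            gp = np.asarray(gradient(coords + dq), dtype=float).ravel()
            gm = np.asarray(gradient(coords - dq), dtype=float).ravel()
        except Exception as exc:
            raise RuntimeError(
                f"gradient evaluation failed while displacing coordinate {k}"
            ) from exc
        h[:, k] = (gp - gm) / (2.0 * step)
    return 0.5 * (h + h.T)


# ---------------------------------------------------------------------------
# tabular export (ramps and λ scans share one CSV contract)
# ---------------------------------------------------------------------------


def ramp_to_dataframe(ramp) -> pd.DataFrame:
    """Ramp points as a table in reporting units (nN, kcal/mol)."""
    rows = []
    for i, p in enumerate(ramp.points):
        rows.append({
            "index": i,
            "branch": ramp.branch,
            "force_nN": units.convert(p.force_magnitude, "hartree/bohr",
                                      "nN"),
            "gap_variation_kcalmol": units.convert(p.gap_variation, "hartree",
                                                   "kcal/mol"),
            "cos_alpha": p.cos_alpha,
            "n_corrector_iters": p.n_corrector_iters,
            "verified": p.verified_exact,
        })
    return pd.DataFrame(rows)


def scan_to_dataframe(scan) -> pd.DataFrame:
    """λ-scan solutions as a table in reporting units."""
    rows = []
    for branch_name in ("increase", "decrease"):
        for s in getattr(scan, branch_name):
            rows.append({
                "lambda": s.lambda_multiplier,
                "force_nN": units.convert(s.force_magnitude, "hartree/bohr",
                                          "nN"),
                "gap_variation_kcalmol": units.convert(
                    s.gap_variation, "hartree", "kcal/mol"
                ),
                "branch": branch_name,
                "singular_flag": s.singular_flag,
            })
    return pd.DataFrame(rows)


def write_ramp_csv(path, ramp):
    ramp_to_dataframe(ramp).to_csv(path, index=False, float_format="%.12g")


def write_scan_csv(path, scan):
    scan_to_dataframe(scan).to_csv(path, index=False, float_format="%.12g")


def write_trajectory_xyz(path, ramp, atom_labels: Sequence[str]):
    """Concatenated extended-XYZ frames of the ramp structures with their
    per-atom optimal force vectors."""
    frames = []
    for i, p in enumerate(ramp.points):
        geom = Geometry(p.q.coordinates, tuple(atom_labels))
        pos = units.convert(geom.positions(), "bohr", "angstrom")
        f_nn = units.convert(p.force_vector.reshape(-1, 3), "hartree/bohr",
                             "nN")
        frames.append(str(geom.n_atoms))
        frames.append(
            f"frame {i} branch {ramp.branch} "
            f"force_nN {units.convert(p.force_magnitude, 'hartree/bohr', 'nN'):.8f}"
        )
        for a, label in enumerate(geom.atom_labels):
            frames.append(
                f"{label:<3s}"
                + "".join(f" {x:20.8f}" for x in pos[a])
                + "".join(f" {x:20.8f}" for x in f_nn[a])
            )
    Path(path).write_text("\n".join(frames) + "\n")


def write_manifest(path, config_dict: dict, extra: Optional[dict] = None):
    """JSON run manifest echoing the resolved configuration."""
    payload = {"config": config_dict}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1,
                                     default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj).__name__}")


def load_run_config(path) -> dict:
    """Key-value run configuration (YAML)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("run configuration must be a key-value mapping")
    return data
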