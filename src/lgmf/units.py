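"""Unit conversion between atomic units and reporting units.

All internal computation uses Hartree (energy), Bohr (length) and
Hartree/Bohr (force).  Community reporting units — kcal/mol for energies,
nanonewton for forces, Ångström for file geometries — are converted only at
the I/O boundary.  Every factor is derived from CODATA constants exposed by
:mod:`scipy.constants`; nothing is hard-coded at call sites.
"""

from __future__ import annotations

from scipy import constants as _c

# --- CODATA-derived base factors -------------------------------------------

#: Hartree energy in Joule.
HARTREE_J: float = _c.value("Hartree energy")

#: Bohr radius in metre.
BOHR_M: float = _c.value("Bohr radius")

#: 1 Hartree in kcal/mol (thermochemical calorie, 4.184 J).
HARTREE_TO_KCALMOL: float = HARTREE_J * _c.Avogadro / (_c.calorie * 1000.0)

#: 1 Bohr in Ångström.
BOHR_TO_ANGSTROM: float = BOHR_M / _c.angstrom

#: 1 Hartree/Bohr in nanonewton.
HARTREE_PER_BOHR_TO_NN: float = (HARTREE_J / BOHR_M) / 1e-9

# --- generic conversion -----------------------------------------------------

# scale of each known unit expressed in its atomic-unit reference, grouped by
# physical dimension so cross-dimension conversions are rejected.
_UNIT_TABLE: dict[str, tuple[str, float]] = {
    # energy (reference: Hartree)
    "hartree": ("energy", 1.0),
    "kcal/mol": ("energy", 1.0 / HARTREE_TO_KCALMOL),
    # length (reference: Bohr)
    "bohr": ("length", 1.0),
    "angstrom": ("length", 1.0 / BOHR_TO_ANGSTROM),
    # force (reference: Hartree/Bohr)
    "hartree/bohr": ("force", 1.0),
    "nn": ("force", 1.0 / HARTREE_PER_BOHR_TO_NN),
    # mechanical response = energy per force
    "hartree/(hartree/bohr)": ("response", 1.0),
    "kcal/mol/nn": (
        "response",
        (1.0 / HARTREE_TO_KCALMOL) / (1.0 / HARTREE_PER_BOHR_TO_NN),
    ),
    "dimensionless": ("none", 1.0),
}

# accepted spelling aliases
_ALIASES = {
    "ha": "hartree",
    "kcalmol": "kcal/mol",
    "kcal_mol": "kcal/mol",
    "a": "angstrom",
    "ang": "angstrom",
    "å": "angstrom",
    "nanonewton": "nn",
    "ha/bohr": "hartree/bohr",
    "au_force": "hartree/bohr",
    "kcal/(mol*nn)": "kcal/mol/nn",
    "kcal/mol/nN": "kcal/mol/nn",
}


def _canon(unit: str) -> str:
    u = unit.strip().lower()
    u = _ALIASES.get(u, u)
    if u not in _UNIT_TABLE:
        raise ValueError(f"unknown unit {unit!r}; known: {sorted(_UNIT_TABLE)}")
    return u


def convert(value, from_unit: str, to_unit: str):
    """Convert ``value`` between two units of the same physical dimension.

    Parameters
    ----------
    value : float or array_like
        Quantity in ``from_unit``.
    from_unit, to_unit : str
        Unit names among Hartree, kcal/mol, Bohr, Angstrom, Hartree/Bohr,
        nN, kcal/mol/nN and 'dimensionless' (case-insensitive, common
        aliases accepted).

    Returns
    -------
    float or ndarray
        ``value`` expressed in ``to_unit``.  Round trips are identities to
        1e-12 relative.
    """
    fu, tu = _canon(from_unit), _canon(to_unit)
    fdim, fscale = _UNIT_TABLE[fu]
    tdim, tscale = _UNIT_TABLE[tu]
    if fdim != tdim:
        raise ValueError(
            f"incompatible units: {from_unit!r} is {fdim}, {to_unit!r} is {tdim}"
        )
    return value * (fscale / tscale)
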