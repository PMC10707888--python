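"""Per-atom properties consumed by the energy model, and free-atom constants.

The model is agnostic to where the atoms-in-molecules properties come from
(density-partitioning calculations, learned predictors, or the synthetic
generator); they are inputs.  Each atom carries its net monopole, dipole,
traceless quadrupole, an effective nuclear charge Z used in the nuclear
electrostatic terms, a density width sigma, and a Hirshfeld volume ratio h
that rescales free-atom dispersion inputs:

    C6_i = C6_free * h^2,      alpha_i = alpha_free * h.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .chem import SUPPORTED_ELEMENTS, Monomer
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "AtomicProperties",
    "FreeAtomConstants",
    "FREE_ATOM_CONSTANTS",
    "VALENCE_CHARGE",
    "PropertyError",
    "load_properties",
    "save_properties",
    "scale_dispersion_inputs",
    "effective_Q",
]

_TRACE_TOL = 1e-8


class PropertyError(ValueError):
    """Invalid or misaligned atomic-property data."""


@dataclass
class AtomicProperties:
    """Atoms-in-molecules properties of one atom, in atomic units.

    ``q`` is the net atomic charge (effective nuclear Z plus electronic
    population); the electronic monopole entering the multipole vector is
    ``q - Z``.  ``mu`` is the dipole (e*bohr), ``theta`` the traceless
    symmetric quadrupole (e*bohr^2), ``sigma`` the density width (bohr),
    ``h`` the Hirshfeld ratio.
    """

    element: str
    q: float
    mu: np.ndarray
    theta: np.ndarray
    Z: float
    sigma: float
    h: float

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise PropertyError(f"unsupported element {self.element!r}")
        self.mu = np.asarray(self.mu, float)
        self.theta = np.asarray(self.theta, float)
        if self.mu.shape != (3,):
            raise PropertyError("dipole must be a 3-vector")
        if self.theta.shape != (3, 3):
            raise PropertyError("quadrupole must be a 3x3 matrix")
        if not np.allclose(self.theta, self.theta.T, atol=_TRACE_TOL):
            raise PropertyError("quadrupole must be symmetric")
        if abs(np.trace(self.theta)) > _TRACE_TOL:
            raise PropertyError(
                f"quadrupole trace {np.trace(self.theta):.2e} exceeds tolerance"
            )
        # exact detrace/symmetrize so downstream identities hold to fp precision
        self.theta = 0.5 * (self.theta + self.theta.T)
        self.theta = self.theta - np.eye(3) * (np.trace(self.theta) / 3.0)
        if not (self.sigma > 0):
            raise PropertyError(f"atomic width sigma must be > 0, got {self.sigma}")
        if not (self.h > 0):
            raise PropertyError(f"Hirshfeld ratio h must be > 0, got {self.h}")
        for val in (self.q, self.Z, self.sigma, self.h):
            if not np.isfinite(val):
                raise PropertyError("non-finite property value")

    @property
    def electronic_monopole(self) -> float:
        return self.q - self.Z

    def rotated(self, rotation: np.ndarray) -> "AtomicProperties":
        """Co-rotate the tensor-valued properties with the atom frame."""
        rotation = np.asarray(rotation, float)
        return replace(
            self, mu=rotation @ self.mu, theta=rotation @ self.theta @ rotation.T
        )


@dataclass(frozen=True)
class FreeAtomConstants:
    """Free-atom reference data for the dispersion model (atomic units)."""

    C6_free: float       # hartree*bohr^6
    alpha_free: float    # bohr^3
    r2: float            # <r^2>, bohr^2
    r4: float            # <r^4>, bohr^4
    Z_nuc: int           # atomic number

    def __post_init__(self) -> None:
        for name in ("C6_free", "alpha_free", "r2", "r4", "Z_nuc"):
            if not getattr(self, name) > 0:
                raise PropertyError(f"free-atom constant {name} must be > 0")


# Literature-typical free-atom magnitudes for the eight supported elements.
# These are configuration for the synthetic studies, not fitted claims.
FREE_ATOM_CONSTANTS: dict[str, FreeAtomConstants] = {
    "H": FreeAtomConstants(6.5, 4.5, 3.0, 22.5, 1),
    "C": FreeAtomConstants(46.6, 11.3, 13.8, 97.0, 6),
    "N": FreeAtomConstants(24.2, 7.4, 11.1, 62.0, 7),
    "O": FreeAtomConstants(15.6, 5.4, 9.6, 46.0, 8),
    "F": FreeAtomConstants(9.5, 3.8, 8.2, 34.0, 9),
    "S": FreeAtomConstants(134.0, 19.6, 28.0, 340.0, 16),
    "Cl": FreeAtomConstants(94.6, 14.6, 25.0, 260.0, 17),
    "Br": FreeAtomConstants(162.0, 21.0, 33.0, 470.0, 35),
}

#: Effective (valence) nuclear charge used by the synthetic generator.
VALENCE_CHARGE = {"H": 1.0, "C": 4.0, "N": 5.0, "O": 6.0,
                  "S": 6.0, "F": 7.0, "Cl": 7.0, "Br": 7.0}


def scale_dispersion_inputs(
    fac: FreeAtomConstants, h: float
) -> tuple[float, float]:
    """Hirshfeld-scale free-atom dispersion inputs: (C6_free h^2, alpha_free h)."""
    if not h > 0:
        raise PropertyError(f"Hirshfeld ratio must be > 0, got {h}")
    return fac.C6_free * h * h, fac.alpha_free * h


def effective_Q(fac: FreeAtomConstants) -> float:
    """Effective multipole-ratio charge Q = sqrt(Z) * <r^4>/<r^2> (bohr^2).

    Feeds the C8 combination rule; kept as a single function so the
    parse of the ratio can be swapped without touching callers.
    """
    return float(np.sqrt(fac.Z_nuc) * fac.r4 / fac.r2)


_HEADER_FIELDS = (
    "element q mux muy muz txx txy txz tyy tyz tzz Z sigma h"
)


def save_properties(props: list[AtomicProperties], path: str | Path) -> None:
    """Write a property file (atomic units), one record per atom."""
    lines = ["# units=au", "# " + _HEADER_FIELDS]
    for p in props:
        t = p.theta
        vals = [p.q, *p.mu, t[0, 0], t[0, 1], t[0, 2], t[1, 1], t[1, 2], t[2, 2],
                p.Z, p.sigma, p.h]
        lines.append(p.element + " " + " ".join(f"{v:.12g}" for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def load_properties(
    path: str | Path, expected: Monomer | int | None = None
) -> list[AtomicProperties]:
    """Load per-atom properties, in dimer/monomer atom order.

    The header declares units (``units=au`` or ``units=angstrom``); lengths
    are converted to bohr.  Record count is validated against ``expected``
    (a monomer or an atom count) when given.
    """
    text = Path(path).read_text()
    unit_scale = 1.0
    records = []
    for lineno, ln in enumerate(text.splitlines(), start=1):
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "units=angstrom" in stripped:
                unit_scale = BOHR_PER_ANGSTROM
            continue
        parts = stripped.split()
        if len(parts) != 14:
            raise PropertyError(
                f"line {lineno}: expected 14 fields ({_HEADER_FIELDS}), "
                f"got {len(parts)}"
            )
        el = parts[0]
        try:
            v = [float(x) for x in parts[1:]]
        except ValueError:
            raise PropertyError(f"line {lineno}: non-numeric value") from None
        q, mux, muy, muz, txx, txy, txz, tyy, tyz, tzz, Z, sigma, h = v
        s = unit_scale
        theta = np.array([[txx, txy, txz], [txy, tyy, tyz], [txz, tyz, tzz]]) * s * s
        records.append(
            AtomicProperties(
                element=el, q=q, mu=np.array([mux, muy, muz]) * s,
                theta=theta, Z=Z, sigma=sigma * s, h=h,
            )
        )
    n_expected = None
    if isinstance(expected, Monomer):
        n_expected = expected.n_atoms
    elif isinstance(expected, int):
        n_expected = expected
    if n_expected is not None and len(records) != n_expected:
        raise PropertyError(
            f"property record count {len(records)} does not match "
            f"geometry atom count {n_expected}"
        )
    if isinstance(expected, Monomer):
        for i, (rec, atom) in enumerate(zip(records, expected.atoms)):
            if rec.element != atom.element:
                raise PropertyError(
                    f"record {i}: element {rec.element} does not match "
                    f"geometry atom {atom.element}"
                )
    return records
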