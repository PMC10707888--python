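"""Molecular data model: atoms, monomers, dimers, XYZ I/O and atom typing.

Atoms are classified into a fixed 17-label species vocabulary that indexes
the global force-field parameters: heavy atoms by element plus total
bonded-neighbour count (``C4`` is a four-coordinate carbon, ``O1`` a
carbonyl-type oxygen), hydrogens by the heavy element they are attached to
(``HC`` … ``HS``), and halogens by element alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

__all__ = [
    "SUPPORTED_ELEMENTS",
    "SPECIES",
    "Atom",
    "Monomer",
    "Dimer",
    "ChemError",
    "ParseError",
    "TypingError",
    "parse_xyz",
    "monomer_to_xyz",
    "perceive_bonds",
    "assign_atom_types",
    "build_dimer",
    "parse_dimer_xyz",
    "dimer_to_xyz",
]

SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S", "F", "Cl", "Br")

#: The complete species vocabulary (17 labels) indexing global parameters.
SPECIES = (
    "C4", "C3", "C2",
    "N3", "N2", "N1",
    "O2", "O1",
    "S2", "S1",
    "HC", "HN", "HO", "HS",
    "F", "Cl", "Br",
)

# Single-bond covalent radii, angstrom (Cordero-type values).
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66,
    "S": 1.05, "F": 0.57, "Cl": 1.02, "Br": 1.20,
}

#: Minimum physically sensible interatomic distance, angstrom.
MIN_CONTACT_ANGSTROM = 0.4

_HALOGENS = frozenset({"F", "Cl", "Br"})
_HEAVY_MAX_NEIGHBORS = {"C": (2, 3, 4), "N": (1, 2, 3), "O": (1, 2), "S": (1, 2)}


class ChemError(ValueError):
    """Base class for molecular-model errors."""


class ParseError(ChemError):
    """Malformed XYZ or property text."""


class TypingError(ChemError):
    """Atom cannot be assigned a species label from the vocabulary."""


@dataclass
class Atom:
    """A typed atom.  ``position`` is stored in bohr."""

    element: str
    position: np.ndarray
    species: str | None = None

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise ChemError(f"unsupported element {self.element!r}")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ChemError(f"invalid position for {self.element}: {self.position}")


@dataclass
class Monomer:
    """An ordered collection of atoms with an optional bond graph."""

    atoms: list[Atom]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    class_label: str | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        """(n, 3) coordinates in bohr."""
        return np.array([a.position for a in self.atoms])

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def species(self) -> list[str]:
        out = []
        for i, a in enumerate(self.atoms):
            if a.species is None:
                raise TypingError(f"atom {i} ({a.element}) has no species label")
            out.append(a.species)
        return out

    def is_typed(self) -> bool:
        return all(a.species is not None for a in self.atoms)

    def neighbor_counts(self) -> list[int]:
        counts = [0] * self.n_atoms
        for i, j in self.bonds:
            counts[i] += 1
            counts[j] += 1
        return counts

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Monomer":
        """Rigidly transform: x -> R x + t (bohr)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        atoms = [
            replace(a, position=rotation @ a.position + translation)
            for a in self.atoms
        ]
        return Monomer(atoms=atoms, bonds=set(self.bonds), class_label=self.class_label)


@dataclass
class Dimer:
    """Two monomers; all energies must be invariant to the A/B order."""

    monomer_a: Monomer
    monomer_b: Monomer
    id: str = ""

    @property
    def n_atoms(self) -> int:
        return self.monomer_a.n_atoms + self.monomer_b.n_atoms

    def atoms(self) -> list[Atom]:
        return list(self.monomer_a.atoms) + list(self.monomer_b.atoms)

    def swapped(self) -> "Dimer":
        return Dimer(self.monomer_b, self.monomer_a, id=self.id)


def _parse_comment_meta(comment: str) -> dict[str, str]:
    meta = {}
    for token in comment.split():
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def parse_xyz(text: str) -> Monomer:
    """Parse XYZ-format text (count / comment / ``El x y z`` lines, angstrom).

    The comment line may carry ``class=<label>`` metadata.  Coordinates are
    converted to bohr.  Bonds and species are left unassigned.
    """
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ input")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"line 1: expected atom count, got {lines[0]!r}") from None
    if n < 1:
        raise ParseError(f"line 1: atom count must be positive, got {n}")
    comment = lines[1] if len(lines) > 1 else ""
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) != n:
        raise ParseError(
            f"atom count mismatch: header says {n}, found {len(atom_lines)} atom lines"
        )
    atoms = []
    for k, ln in enumerate(atom_lines):
        parts = ln.split()
        lineno = k + 3
        if len(parts) < 4:
            raise ParseError(f"line {lineno}: expected 'El x y z', got {ln!r}")
        el = parts[0]
        if el not in SUPPORTED_ELEMENTS:
            raise ParseError(f"line {lineno}: unknown element symbol {el!r}")
        try:
            xyz = np.array([float(p) for p in parts[1:4]])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric coordinate in {ln!r}") from None
        atoms.append(Atom(el, xyz * BOHR_PER_ANGSTROM))
    meta = _parse_comment_meta(comment)
    return Monomer(atoms=atoms, class_label=meta.get("class"))


def monomer_to_xyz(monomer: Monomer, comment: str = "") -> str:
    """Serialize a monomer to XYZ text (angstrom)."""
    if monomer.class_label and "class=" not in comment:
        comment = (comment + f" class={monomer.class_label}").strip()
    lines = [str(monomer.n_atoms), comment]
    for a in monomer.atoms:
        x, y, z = a.position * ANGSTROM_PER_BOHR
        lines.append(f"{a.element:2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(lines) + "\n"


def perceive_bonds(monomer: Monomer, tolerance: float = 1.2) -> Monomer:
    """Assign bonds: (i, j) bonded iff d_ij < tolerance * (r_cov_i + r_cov_j).

    Distances below 0.4 angstrom are rejected as degenerate geometry.
    """
    pos = monomer.positions() * ANGSTROM_PER_BOHR
    bonds: set[tuple[int, int]] = set()
    for i in range(monomer.n_atoms):
        for j in range(i + 1, monomer.n_atoms):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < MIN_CONTACT_ANGSTROM:
                raise ChemError(
                    f"degenerate geometry: atoms {i} and {j} are {d:.3f} A apart"
                )
            r_sum = COVALENT_RADII[monomer.atoms[i].element] + COVALENT_RADII[
                monomer.atoms[j].element
            ]
            if d < tolerance * r_sum:
                bonds.add((i, j))
    return Monomer(atoms=monomer.atoms, bonds=bonds, class_label=monomer.class_label)


def assign_atom_types(monomer: Monomer) -> Monomer:
    """Assign the 17-label species vocabulary from the bond graph.

    Heavy atoms get element + total neighbour count; hydrogens get H +
    attached heavy element; halogens are typed by element alone.
    """
    counts = monomer.neighbor_counts()
    neighbors: list[list[int]] = [[] for _ in range(monomer.n_atoms)]
    for i, j in monomer.bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    typed_atoms = []
    for i, atom in enumerate(monomer.atoms):
        el = atom.element
        if el in _HALOGENS:
            label = el
        elif el == "H":
            if counts[i] != 1:
                raise TypingError(
                    f"atom {i}: hydrogen with {counts[i]} neighbours (need exactly 1)"
                )
            heavy = monomer.atoms[neighbors[i][0]].element
            if heavy not in ("C", "N", "O", "S"):
                raise TypingError(
                    f"atom {i}: hydrogen bonded to {heavy}, outside the vocabulary"
                )
            label = "H" + heavy
        else:
            if counts[i] not in _HEAVY_MAX_NEIGHBORS[el]:
                raise TypingError(
                    f"atom {i}: {el} with {counts[i]} neighbours is outside "
                    f"the species vocabulary"
                )
            label = f"{el}{counts[i]}"
        assert label in SPECIES
        typed_atoms.append(replace(atom, species=label))
    return Monomer(atoms=typed_atoms, bonds=set(monomer.bonds),
                   class_label=monomer.class_label)


def prepare_monomer(monomer: Monomer, tolerance: float = 1.2) -> Monomer:
    """Convenience: perceive bonds then assign species."""
    return assign_atom_types(perceive_bonds(monomer, tolerance))


def build_dimer(monomer_a: Monomer, monomer_b: Monomer, id: str = "") -> Dimer:
    """Combine two typed monomers, rejecting steric clashes (< 0.4 A)."""
    for name, m in (("A", monomer_a), ("B", monomer_b)):
        if not m.is_typed():
            raise TypingError(f"monomer {name} has untyped atoms")
    pa = monomer_a.positions()
    pb = monomer_b.positions()
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    dmin = float(d.min()) * ANGSTROM_PER_BOHR
    if dmin < MIN_CONTACT_ANGSTROM:
        raise ChemError(
            f"intermolecular clash: closest contact {dmin:.3f} A < "
            f"{MIN_CONTACT_ANGSTROM} A"
        )
    return Dimer(monomer_a, monomer_b, id=id)


def parse_dimer_xyz(text: str) -> Dimer:
    """Parse a single-file dimer: XYZ whose comment carries ``natoms_A=<k>``.

    Both monomers are bond-perceived and typed.
    """
    lines = text.splitlines()
    if len(lines) < 2:
        raise ParseError("dimer XYZ needs a count and comment line")
    meta = _parse_comment_meta(lines[1])
    if "natoms_A" not in meta:
        raise ParseError("dimer XYZ comment must contain natoms_A=<k>")
    k = int(meta["natoms_A"])
    whole = parse_xyz(text)
    if not 0 < k < whole.n_atoms:
        raise ParseError(f"natoms_A={k} out of range for {whole.n_atoms} atoms")
    mon_a = Monomer(atoms=whole.atoms[:k], class_label=meta.get("class_A"))
    mon_b = Monomer(atoms=whole.atoms[k:], class_label=meta.get("class_B"))
    return build_dimer(
        prepare_monomer(mon_a), prepare_monomer(mon_b), id=meta.get("id", "")
    )


def dimer_to_xyz(dimer: Dimer) -> str:
    """Serialize a dimer to a single XYZ file with ``natoms_A`` metadata."""
    comment = f"natoms_A={dimer.monomer_a.n_atoms}"
    if dimer.id:
        comment += f" id={dimer.id}"
    if dimer.monomer_a.class_label:
        comment += f" class_A={dimer.monomer_a.class_label}"
    if dimer.monomer_b.class_label:
        comment += f" class_B={dimer.monomer_b.class_label}"
    lines = [str(dimer.n_atoms), comment]
    for a in dimer.atoms():
        x, y, z = a.position * ANGSTROM_PER_BOHR
        lines.append(f"{a.element:2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(lines) + "\n"
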