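"""Synthetic dimer datasets with known ground truth.

Emulates the structure of small-organic homodimer training sets and the
heterodimer test sets built from the same monomer pool: a library of
idealized small molecules grouped by functional-group class whose union of
atom species covers the full 17-label vocabulary, near-equilibrium dimer
configurations, plausible atoms-in-molecules properties, and reference
component energies produced by the forward model itself under a known
parameter set (optionally with Gaussian noise).  Because the generator
uses the model as ground truth, parameter fitting on its output is a
well-specified recovery problem; realism enters through the geometry and
property ranges only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .chem import SPECIES, Dimer, Monomer, Atom, build_dimer, prepare_monomer
from .energy import GlobalParameters, ModelConstants, SaptRecord, System
from .fitting import TrainingRecord, predict_components
from .properties import VALENCE_CHARGE, AtomicProperties
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "SyntheticSpec",
    "SUPPLEMENT_COMPOSITION",
    "make_class_manifest",
    "make_monomer_library",
    "sample_dimer_configurations",
    "sample_systems",
    "synth_atomic_properties",
    "ground_truth_parameters",
    "generate_reference_dataset",
    "split_train_test",
    "make_dataset",
]

# --------------------------------------------------------------- geometry

_S3 = 1.0 / np.sqrt(3.0)
_TET = [(_S3, _S3, _S3), (_S3, -_S3, -_S3), (-_S3, _S3, -_S3), (-_S3, -_S3, _S3)]


def _ch3_frame(x_dist: float, x_el: str) -> list[tuple[str, tuple]]:
    """A methyl carbon at the origin with substituent X along (1,1,1)."""
    mol = [("C", (0.0, 0.0, 0.0)),
           (x_el, tuple(x_dist * _S3 for _ in range(3)))]
    for v in _TET[1:]:
        mol.append(("H", tuple(1.09 * c for c in v)))
    return mol


# idealized geometries, angstrom; class labels are dataset metadata
_LIBRARY_GEOMETRIES: dict[str, tuple[str, list[tuple[str, tuple]]]] = {
    "methane": ("Alkane",
                [("C", (0.0, 0.0, 0.0))]
                + [("H", tuple(1.09 * c for c in v)) for v in _TET]),
    "ethylene": ("Alkene", [
        ("C", (0.0, 0.0, 0.0)), ("C", (1.33, 0.0, 0.0)),
        ("H", (-0.545, 0.944, 0.0)), ("H", (-0.545, -0.944, 0.0)),
        ("H", (1.875, 0.944, 0.0)), ("H", (1.875, -0.944, 0.0)),
    ]),
    "ethyne": ("Alkyne", [
        ("C", (0.0, 0.0, 0.0)), ("C", (1.20, 0.0, 0.0)),
        ("H", (-1.06, 0.0, 0.0)), ("H", (2.26, 0.0, 0.0)),
    ]),
    "methanol": ("Alcohol",
                 _ch3_frame(1.43, "O")
                 + [("H", (1.6504, 0.3703, 1.0104))]),
    "water": ("Water", [
        ("O", (0.0, 0.0, 0.0)), ("H", (0.96, 0.0, 0.0)),
        ("H", (-0.2400, 0.9295, 0.0)),
    ]),
    "formaldehyde": ("Aldehyde", [
        ("C", (0.0, 0.0, 0.0)), ("O", (1.21, 0.0, 0.0)),
        ("H", (-0.545, 0.944, 0.0)), ("H", (-0.545, -0.944, 0.0)),
    ]),
    "formic_acid": ("Acid", [
        ("C", (0.0, 0.0, 0.0)), ("O", (1.21, 0.0, 0.0)),
        ("O", (-0.67, 1.1605, 0.0)), ("H", (-0.55, -0.9526, 0.0)),
        ("H", (-0.0085, 1.8691, 0.0)),
    ]),
    "formamide": ("Amide", [
        ("C", (0.0, 0.0, 0.0)), ("O", (1.22, 0.0, 0.0)),
        ("N", (-0.675, 1.169, 0.0)), ("H", (-0.55, -0.953, 0.0)),
        ("H", (-0.17, 2.044, 0.0)), ("H", (-1.685, 1.169, 0.0)),
    ]),
    "methylamine": ("Amine",
                    _ch3_frame(1.47, "N")
                    + [("H", (1.7165, 1.0430, 0.3698)),
                       ("H", (1.0432, 0.3698, 1.7165))]),
    "methanimine": ("Imine", [
        ("C", (0.0, 0.0, 0.0)), ("N", (1.28, 0.0, 0.0)),
        ("H", (-0.55, 0.944, 0.0)), ("H", (-0.55, -0.944, 0.0)),
        ("H", (1.785, 0.8747, 0.0)),
    ]),
    "hydrogen_cyanide": ("Nitrile", [
        ("H", (-1.07, 0.0, 0.0)), ("C", (0.0, 0.0, 0.0)),
        ("N", (1.15, 0.0, 0.0)),
    ]),
    "methanethiol": ("Sulfide",
                     _ch3_frame(1.82, "S")
                     + [("H", (2.2021, 0.4152, 1.3088))]),
    "thioformaldehyde": ("Thiocarbonyl", [
        ("C", (0.0, 0.0, 0.0)), ("S", (1.61, 0.0, 0.0)),
        ("H", (-0.545, 0.944, 0.0)), ("H", (-0.545, -0.944, 0.0)),
    ]),
    "fluoromethane": ("Haloalkane", _ch3_frame(1.38, "F")),
    "chloromethane": ("Haloalkane", _ch3_frame(1.78, "Cl")),
    "bromomethane": ("Haloalkane", _ch3_frame(1.94, "Br")),
}

#: Class composition of the 47-homodimer supplement set (12 classes).
SUPPLEMENT_COMPOSITION: dict[str, int] = {
    "Ester": 2, "Ether": 4, "Nitrile": 3, "Sulfide": 5, "Disulfide": 2,
    "Amine": 5, "Cyclic Ether": 1, "Haloalkane": 3, "Cyclic Sulfide": 1,
    "Non-Aromatic Ring": 9, "Aromatic Ring": 10,
    "Aromatic Secondary Amine": 2,
}


def make_class_manifest(composition: dict[str, int] | None = None) -> list[str]:
    """Expand a class->count composition into a flat list of class labels."""
    composition = composition or SUPPLEMENT_COMPOSITION
    out = []
    for cls, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for class {cls!r}")
        out.extend([cls] * count)
    return out


def make_monomer_library(names: list[str] | None = None) -> dict[str, Monomer]:
    """Bond-perceived, typed idealized monomers keyed by name.

    The full library's union of atom species covers all 17 labels.
    """
    names = names or list(_LIBRARY_GEOMETRIES)
    library = {}
    for name in names:
        cls, atom_spec = _LIBRARY_GEOMETRIES[name]
        atoms = [
            Atom(el, np.asarray(xyz, float) * BOHR_PER_ANGSTROM)
            for el, xyz in atom_spec
        ]
        library[name] = prepare_monomer(
            Monomer(atoms=atoms, class_label=cls)
        )
    return library


# --------------------------------------------------------------- sampling

@dataclass
class SyntheticSpec:
    """Study conditions for synthetic dataset generation.

    Center-of-mass separations default to a compressed-to-equilibrium
    window for small organics: sampling into the repulsive wall keeps the
    short-range damping parameters identifiable, as in conventional
    force-field fitting practice.  noise_sd is the per-component Gaussian
    noise in kcal/mol.
    """

    seed: int
    monomer_names: list[str] | None = None
    separation: tuple[float, float] = (4.0, 8.0)   # bohr
    # distinct orientations per monomer pair; two can leave a species
    # pair's overlap equations near-tangent (non-unique exact fits)
    n_orientations: int = 3
    noise_sd: float = 0.0
    # placements with a closest intermolecular contact below this are
    # resampled.  The default corresponds to a strongly compressed but
    # still physical geometry (~1.5 A); contacts below 1.5 bohr are
    # always rejected as steric clashes.
    min_contact: float = 2.8                       # bohr

    def __post_init__(self) -> None:
        lo, hi = self.separation
        if not (3.0 <= lo <= hi <= 30.0):
            raise ValueError("separations must lie within [3, 30] bohr")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_contact < 1.5:
            raise ValueError("min_contact below the 1.5 bohr clash threshold")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _content_seed(monomer: Monomer, seed: int) -> int:
    """Stable seed derived from monomer content and a master seed."""
    digest = hashlib.md5()
    digest.update(str(seed).encode())
    for atom in monomer.atoms:
        digest.update(atom.element.encode())
        digest.update(np.round(atom.position, 6).tobytes())
    return int.from_bytes(digest.digest()[:4], "little") % (2**31)


def synth_atomic_properties(monomer: Monomer, seed: int) -> list[AtomicProperties]:
    """Plausible per-atom properties; deterministic in (content, seed).

    Net monopoles sum exactly to zero, widths fall in [0.5, 1.2] bohr,
    Hirshfeld ratios in [0.75, 1.25]; dipoles and quadrupoles are small.
    """
    rng = np.random.default_rng(_content_seed(monomer, seed))
    base_q = {"O": -0.40, "N": -0.35, "S": -0.15, "F": -0.25,
              "Cl": -0.15, "Br": -0.10, "C": 0.05, "H": 0.12}
    base_sigma = {"H": 0.55, "C": 0.95, "N": 0.90, "O": 0.85,
                  "F": 0.80, "S": 1.10, "Cl": 1.05, "Br": 1.15}
    els = monomer.elements()
    q = np.array([base_q[el] for el in els]) + rng.normal(0.0, 0.05, len(els))
    q -= q.mean()   # exact monomer neutrality
    props = []
    for k, el in enumerate(els):
        mu = rng.normal(0.0, 0.08, 3)
        raw = rng.normal(0.0, 0.12, (3, 3))
        theta = 0.5 * (raw + raw.T)
        theta -= np.eye(3) * (np.trace(theta) / 3.0)
        sigma = float(np.clip(base_sigma[el] + rng.uniform(-0.05, 0.05),
                              0.5, 1.2))
        props.append(
            AtomicProperties(
                element=el, q=float(q[k]), mu=mu, theta=theta,
                Z=VALENCE_CHARGE[el], sigma=sigma,
                h=float(rng.uniform(0.75, 1.25)),
            )
        )
    return props


def _pair_list(names: list[str]) -> list[tuple[str, str]]:
    pairs = [(n, n) for n in names]
    pairs += [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    return pairs


def sample_systems(spec: SyntheticSpec) -> list[System]:
    """Homodimer and heterodimer systems with aligned synthetic properties.

    Deterministic per seed.  Raises if a clash-free placement cannot be
    found in 100 attempts.
    """
    library = make_monomer_library(spec.monomer_names)
    names = list(library)
    props_canon = {
        name: synth_atomic_properties(mon, spec.seed)
        for name, mon in library.items()
    }
    rng = np.random.default_rng(spec.seed)
    systems = []
    for name_a, name_b in _pair_list(names):
        for orient in range(spec.n_orientations):
            mon_a, mon_b = library[name_a], library[name_b]
            for attempt in range(100):
                ra = _random_rotation(rng)
                rb = _random_rotation(rng)
                d = rng.uniform(*spec.separation)
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                com_a = mon_a.positions().mean(axis=0)
                com_b = mon_b.positions().mean(axis=0)
                placed_a = mon_a.transformed(ra, -ra @ com_a)
                placed_b = mon_b.transformed(rb, d * axis - rb @ com_b)
                pa, pb = placed_a.positions(), placed_b.positions()
                dmin = np.linalg.norm(
                    pa[:, None, :] - pb[None, :, :], axis=-1
                ).min()
                if dmin >= spec.min_contact:
                    break
            else:
                raise RuntimeError(
                    f"no clash-free placement for {name_a}/{name_b} "
                    f"in 100 attempts"
                )
            dimer = build_dimer(
                placed_a, placed_b, id=f"{name_a}--{name_b}-o{orient}"
            )
            props = (
                [p.rotated(ra) for p in props_canon[name_a]]
                + [p.rotated(rb) for p in props_canon[name_b]]
            )
            systems.append(System(dimer, props))
    return systems


def sample_dimer_configurations(spec: SyntheticSpec) -> list[Dimer]:
    """Geometries only (see :func:`sample_systems` for properties too)."""
    return [s.dimer for s in sample_systems(spec)]


def ground_truth_parameters(seed: int) -> GlobalParameters:
    """All 17 species set, drawn uniformly from ranges bracketing the
    magnitudes typical of fitted parameter tables."""
    rng = np.random.default_rng(seed)
    ranges = {"elst": (2.5, 5.5), "exch": (0.5, 7.0),
              "indu": (0.1, 2.5), "disp": (0.05, 1.0)}
    params = GlobalParameters()
    for sp in SPECIES:
        for comp, (lo, hi) in ranges.items():
            params.set(sp, comp, float(rng.uniform(lo, hi)))
    return params


def generate_reference_dataset(
    systems: list[System],
    params: GlobalParameters,
    noise_sd: float = 0.0,
    seed: int = 0,
    constants: ModelConstants | None = None,
) -> list[TrainingRecord]:
    """Forward-model reference components (+ optional Gaussian noise).

    The total is recomputed as the component sum after noising, so
    reference records remain internally consistent.
    """
    rng = np.random.default_rng(seed)
    comps = predict_components(params, systems, constants)
    records = []
    for system, row in zip(systems, comps):
        vals = row[:4].copy()
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, 4)
        records.append(TrainingRecord(system, SaptRecord(*vals)))
    return records


def split_train_test(
    records: list[TrainingRecord],
) -> tuple[list[TrainingRecord], list[TrainingRecord]]:
    """Homodimers become the training set, heterodimers the test set."""
    train = [r for r in records if r.is_homodimer]
    test = [r for r in records if not r.is_homodimer]
    if not train or not test:
        raise ValueError(
            f"degenerate split: {len(train)} homodimers / {len(test)} "
            f"heterodimers"
        )
    return train, test


@dataclass
class DatasetBundle:
    """A complete synthetic study: records, split, and the ground truth."""

    records: list[TrainingRecord]
    train: list[TrainingRecord]
    test: list[TrainingRecord]
    truth: GlobalParameters
    spec: SyntheticSpec = field(repr=False, default=None)


def make_dataset(spec: SyntheticSpec,
                 constants: ModelConstants | None = None) -> DatasetBundle:
    """Generate systems, ground truth and references, and split them."""
    systems = sample_systems(spec)
    truth = ground_truth_parameters(spec.seed)
    records = generate_reference_dataset(
        systems, truth, noise_sd=spec.noise_sd, seed=spec.seed + 1,
        constants=constants,
    )
    train, test = split_train_test(records)
    return DatasetBundle(records=records, train=train, test=test,
                         truth=truth, spec=spec)
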