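"""Atom-pairwise SAPT component energy models.

The four components mirror a symmetry-adapted perturbation theory
decomposition of the intermolecular interaction energy:

* electrostatics -- damped multipole interactions between the two
  monomers' nuclei and atomic multipole distributions;
* exchange-repulsion -- proportional to a pairwise density-overlap
  function S of the atomic widths;
* dispersion -- Tang-Toennies-damped C6/C8/C10 series with
  Hirshfeld-rescaled free-atom coefficients;
* induction -- Thole-smeared induced dipoles in the partner monomer's
  field, plus a short-range overlap term.

One global, species-indexed parameter per component (K_elst, K_exch,
K_indu, K_disp) scales the damping range or the short-range strength;
pair values are formed from the per-species scalars by a geometric mean.
Electrostatic, dispersion and polarization sums are evaluated in atomic
units and converted; the K*S short-range terms yield kcal/mol directly,
which places the fitted K's on the scale conventional for this model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import SPECIES, Dimer
from .properties import (
    FREE_ATOM_CONSTANTS,
    AtomicProperties,
    effective_Q,
    scale_dispersion_inputs,
)
from .tensors import (
    multipole_field,
    multipole_interaction,
    thole_dipole_tensor,
    thole_lambda7,
    thole_lambdas,
)
from .units import KCAL_PER_HARTREE

__all__ = [
    "GlobalParameters",
    "System",
    "SaptRecord",
    "ModelConstants",
    "MissingParameterError",
    "ConvergenceError",
    "damping_f1",
    "damping_f2",
    "overlap_S",
    "combine_C6",
    "compute_C8_C10",
    "tt_damping",
    "pair_parameter",
    "induced_dipoles",
    "elst_energy",
    "exch_energy",
    "disp_energy",
    "indu_energy",
    "total_energy",
]

COMPONENTS = ("elst", "exch", "indu", "disp")
_PARAM_COLUMNS = {"elst": "Kelst", "exch": "Kexch", "indu": "Kindu", "disp": "Kdisp"}

#: relative K difference below which the equal-exponent f2 branch is used
_F2_DEGENERATE_REL = 1e-6


@dataclass
class System:
    """A dimer together with its per-atom properties (A atoms then B atoms)."""

    dimer: Dimer
    props: list[AtomicProperties]

    def __post_init__(self) -> None:
        if len(self.props) != self.dimer.n_atoms:
            raise ValueError(
                f"{len(self.props)} property records for "
                f"{self.dimer.n_atoms} atoms"
            )

    def species(self) -> list[str]:
        return (self.dimer.monomer_a.species() + self.dimer.monomer_b.species())

    def swapped(self) -> "System":
        na = self.dimer.monomer_a.n_atoms
        return System(self.dimer.swapped(), self.props[na:] + self.props[:na])


class MissingParameterError(KeyError):
    """A species present in the system has no fitted parameter."""


class ConvergenceError(RuntimeError):
    """The induced-dipole fixed point did not converge."""


@dataclass
class ModelConstants:
    """Fixed model constants (not fitted)."""

    omega: float = 0.7          # successive-substitution mixing factor
    a_thole: float = 0.39       # Thole smearing coefficient
    # induced-dipole convergence; tight enough that the residual iteration
    # noise in the polarization energy stays below 1e-9 kcal/mol
    pol_tol: float = 1e-10
    pol_max_iter: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.omega <= 1:
            raise ValueError("omega must be in (0, 1]")
        if not self.a_thole > 0:
            raise ValueError("a_thole must be > 0")


@dataclass
class SaptRecord:
    """One dimer's four component energies and their total, kcal/mol."""

    elst: float
    exch: float
    indu: float
    disp: float
    total: float | None = None

    def __post_init__(self) -> None:
        s = self.elst + self.exch + self.indu + self.disp
        if self.total is None:
            self.total = s
        elif abs(self.total - s) > 1e-9:
            raise ValueError(
                f"total {self.total} differs from component sum {s} by "
                f"{abs(self.total - s):.2e} kcal/mol"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.elst, self.exch, self.indu, self.disp, self.total])


class GlobalParameters:
    """Per-species global parameters K_elst/K_exch/K_indu/K_disp.

    Species without data stay unset (NaN) and serialize as blanks, matching
    the published parameter-table layout.
    """

    def __init__(self, values: dict[str, dict[str, float]] | None = None):
        self._table = pd.DataFrame(
            np.nan, index=list(SPECIES), columns=list(_PARAM_COLUMNS.values())
        )
        if values:
            for sp, comps in values.items():
                for comp, val in comps.items():
                    self.set(sp, comp, val)

    def set(self, species: str, component: str, value: float) -> None:
        if species not in SPECIES:
            raise KeyError(f"unknown species {species!r}")
        col = _PARAM_COLUMNS[component]
        if not value > 0:
            raise ValueError(
                f"parameter {col}[{species}] must be > 0, got {value}"
            )
        self._table.loc[species, col] = float(value)

    def get(self, species: str, component: str) -> float:
        if species not in SPECIES:
            raise KeyError(f"unknown species {species!r}")
        val = self._table.loc[species, _PARAM_COLUMNS[component]]
        if np.isnan(val):
            raise MissingParameterError(
                f"no K_{component} parameter for species {species!r}"
            )
        return float(val)

    def is_set(self, species: str, component: str) -> bool:
        return not np.isnan(self._table.loc[species, _PARAM_COLUMNS[component]])

    def species_set(self) -> list[str]:
        """Species with at least one parameter set."""
        return [sp for sp in SPECIES if self._table.loc[sp].notna().any()]

    def as_frame(self) -> pd.DataFrame:
        return self._table.copy()

    def to_csv(self, path: str | Path) -> None:
        self._table.to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GlobalParameters":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        params = cls()
        for sp in df.index:
            for comp, col in _PARAM_COLUMNS.items():
                val = df.loc[sp, col]
                if pd.notna(val) and str(val).strip() not in ("", "-"):
                    params.set(sp, comp, float(val))
        return params

    def __eq__(self, other) -> bool:
        if not isinstance(other, GlobalParameters):
            return NotImplemented
        a, b = self._table.to_numpy(), other._table.to_numpy()
        return bool(np.all((np.isnan(a) & np.isnan(b)) | (a == b)))


# ----------------------------------------------------------------- damping

def damping_f1(K: float, r) -> float:
    """One-exponent charge-penetration damping, f1 = 1 - exp(-K r)."""
    if not K > 0:
        raise ValueError(f"damping exponent K must be > 0, got {K}")
    return 1.0 - np.exp(-K * np.asarray(r, float))


def damping_f2(K_i: float, K_j: float, r) -> float:
    """Two-exponent charge-penetration damping.

    f2 = 1 - Ki^2/(Ki^2-Kj^2) e^{-Ki r} - Kj^2/(Kj^2-Ki^2) e^{-Kj r},
    with the analytic equal-exponent limit 1 - e^{-Kr}(1 - Kr/2) used when
    the exponents are within 1e-6 relative.
    """
    if not (K_i > 0 and K_j > 0):
        raise ValueError("damping exponents must be > 0")
    r = np.asarray(r, float)
    if abs(K_i - K_j) < _F2_DEGENERATE_REL * max(K_i, K_j):
        K = 0.5 * (K_i + K_j)
        x = K * r
        return 1.0 - np.exp(-x) * (1.0 - 0.5 * x)
    ki2, kj2 = K_i * K_i, K_j * K_j
    return (
        1.0
        - ki2 / (ki2 - kj2) * np.exp(-K_i * r)
        - kj2 / (kj2 - ki2) * np.exp(-K_j * r)
    )


def overlap_S(sigma_i: float, sigma_j: float, r) -> float:
    """Density-overlap function of two atoms with widths sigma (bohr).

    B_ij = (sigma_i sigma_j)^{-1/2};  S = (1/3 (Br)^2 + Br + 1) e^{-Br}.
    S(0) = 1 and S decreases monotonically with distance.
    """
    if not (sigma_i > 0 and sigma_j > 0):
        raise ValueError("atomic widths must be > 0")
    b = 1.0 / math.sqrt(sigma_i * sigma_j)
    x = b * np.asarray(r, float)
    return (x * x / 3.0 + x + 1.0) * np.exp(-x)


def combine_C6(C6_i: float, C6_j: float, alpha_i: float, alpha_j: float) -> float:
    """Pairwise C6 from atomic C6's and polarizabilities (negative by convention).

    C6_ij = -2 C6_i C6_j / ((alpha_j/alpha_i) C6_i + (alpha_i/alpha_j) C6_j);
    reduces to -C6_i for identical atoms.
    """
    for name, v in (("C6_i", C6_i), ("C6_j", C6_j),
                    ("alpha_i", alpha_i), ("alpha_j", alpha_j)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return -2.0 * C6_i * C6_j / (
        (alpha_j / alpha_i) * C6_i + (alpha_i / alpha_j) * C6_j
    )


def compute_C8_C10(C6_ij: float, Q_i: float, Q_j: float) -> tuple[float, float]:
    """Higher dispersion coefficients from C6 and effective charges Q.

    C8 = 3 C6 sqrt(Q_i Q_j);  C10 = (49/40) C8^2 / C6, so the identity
    C10*C6/C8^2 = 49/40 holds exactly.
    """
    if C6_ij == 0:
        raise ValueError("C10 undefined for C6 = 0")
    if not (Q_i > 0 and Q_j > 0):
        raise ValueError("effective charges Q must be > 0")
    c8 = 3.0 * C6_ij * math.sqrt(Q_i * Q_j)
    c10 = (49.0 / 40.0) * c8 * c8 / C6_ij
    return c8, c10


_TT_FACTORIALS = {n: [math.factorial(k) for k in range(n + 1)] for n in (6, 8, 10)}


def tt_damping(n: int, B_ij: float, r) -> float:
    """Tang-Toennies damping f_n = 1 - e^{-x} sum_{k<=n} x^k/k!.

    The effective argument x = B r + r (2B^2 + 3B)/((Br)^2 + 3Br + 3)
    sharpens the short-range cutoff; f_n(0) = 0 and f_n -> 1 at long range.
    """
    if n not in _TT_FACTORIALS:
        raise ValueError(f"unsupported dispersion order n={n} (use 6, 8 or 10)")
    if not B_ij > 0:
        raise ValueError("B must be > 0")
    r = np.asarray(r, float)
    br = B_ij * r
    x = br + r * (2.0 * B_ij * B_ij + 3.0 * B_ij) / (br * br + 3.0 * br + 3.0)
    partial = sum(x**k / fk for k, fk in enumerate(_TT_FACTORIALS[n]))
    return 1.0 - partial * np.exp(-x)


def pair_parameter(params: GlobalParameters, component: str,
                   species_i: str, species_j: str) -> float:
    """Pair parameter K_ij = sqrt(K_i K_j) (symmetric, positivity-preserving)."""
    return math.sqrt(
        params.get(species_i, component) * params.get(species_j, component)
    )


# ------------------------------------------------------------- components

def _pair_iter(dimer: Dimer, props: list[AtomicProperties]):
    """Yield (i_global, j_global, atom_i, atom_j, r_vec, r) over A x B pairs."""
    na = dimer.monomer_a.n_atoms
    for i, ai in enumerate(dimer.monomer_a.atoms):
        for j, aj in enumerate(dimer.monomer_b.atoms):
            r_vec = aj.position - ai.position
            yield i, na + j, ai, aj, r_vec, float(np.linalg.norm(r_vec))


def _check_props(dimer: Dimer, props: list[AtomicProperties]) -> None:
    if len(props) != dimer.n_atoms:
        raise ValueError(
            f"got {len(props)} property records for {dimer.n_atoms} atoms"
        )


def elst_energy(dimer: Dimer, props: list[AtomicProperties],
                params: GlobalParameters) -> float:
    """Damped multipole electrostatic energy, kcal/mol.

    Per intermolecular pair: Z_i Z_j / r (undamped) + nucleus-multipole
    terms damped by f1 with the multipole-bearing atom's K_elst +
    multipole-multipole term damped by f2 with both K_elst's.  The
    multipole set is the electronic distribution (monopole q - Z).
    """
    _check_props(dimer, props)
    e = 0.0
    for ig, jg, ai, aj, r_vec, r in _pair_iter(dimer, props):
        pi, pj = props[ig], props[jg]
        ki = params.get(ai.species, "elst")
        kj = params.get(aj.species, "elst")
        mi = (pi.electronic_monopole, pi.mu, pi.theta)
        mj = (pj.electronic_monopole, pj.mu, pj.theta)
        zero = (0.0, np.zeros(3), np.zeros((3, 3)))
        e += pi.Z * pj.Z / r
        e += damping_f1(kj, r) * multipole_interaction((pi.Z, *zero[1:]), mj, r_vec)
        e += damping_f1(ki, r) * multipole_interaction(mi, (pj.Z, *zero[1:]), r_vec)
        e += damping_f2(ki, kj, r) * multipole_interaction(mi, mj, r_vec)
    return e * KCAL_PER_HARTREE


def exch_energy(dimer: Dimer, props: list[AtomicProperties],
                params: GlobalParameters) -> float:
    """Overlap-model exchange repulsion, kcal/mol: sum K_ij^exch S_ij."""
    _check_props(dimer, props)
    e = 0.0
    for ig, jg, ai, aj, _r_vec, r in _pair_iter(dimer, props):
        k = pair_parameter(params, "exch", ai.species, aj.species)
        e += k * overlap_S(props[ig].sigma, props[jg].sigma, r)
    return e


def disp_energy(dimer: Dimer, props: list[AtomicProperties],
                params: GlobalParameters) -> float:
    """Tang-Toennies damped C6/C8/C10 dispersion energy, kcal/mol.

    The C6 term is parameter-free; K_disp scales the C8/C10 contribution.
    """
    _check_props(dimer, props)
    e = 0.0
    for ig, jg, ai, aj, _r_vec, r in _pair_iter(dimer, props):
        pi, pj = props[ig], props[jg]
        faci = FREE_ATOM_CONSTANTS[pi.element]
        facj = FREE_ATOM_CONSTANTS[pj.element]
        c6i, alphai = scale_dispersion_inputs(faci, pi.h)
        c6j, alphaj = scale_dispersion_inputs(facj, pj.h)
        c6 = combine_C6(c6i, c6j, alphai, alphaj)
        c8, c10 = compute_C8_C10(c6, effective_Q(faci), effective_Q(facj))
        b = 1.0 / math.sqrt(pi.sigma * pj.sigma)
        kd = pair_parameter(params, "disp", ai.species, aj.species)
        e += c6 / r**6 * tt_damping(6, b, r)
        e += kd * (c8 / r**8 * tt_damping(8, b, r)
                   + c10 / r**10 * tt_damping(10, b, r))
    return e * KCAL_PER_HARTREE


def _polarizabilities(props: list[AtomicProperties]) -> np.ndarray:
    return np.array(
        [scale_dispersion_inputs(FREE_ATOM_CONSTANTS[p.element], p.h)[1]
         for p in props]
    )


def permanent_fields(dimer: Dimer, props: list[AtomicProperties],
                     constants: ModelConstants) -> np.ndarray:
    """(n, 3) Thole-damped field at every atom from the other monomer's
    permanent multipoles (net charge, dipole, quadrupole)."""
    _check_props(dimer, props)
    n = dimer.n_atoms
    na = dimer.monomer_a.n_atoms
    atoms = dimer.atoms()
    alphas = _polarizabilities(props)
    fields = np.zeros((n, 3))
    for i in range(n):
        other = range(na, n) if i < na else range(na)
        for j in other:
            r_vec = atoms[i].position - atoms[j].position
            r = float(np.linalg.norm(r_vec))
            u = r / (alphas[i] * alphas[j]) ** (1.0 / 6.0)
            l3, l5 = thole_lambdas(u, constants.a_thole)
            l7 = thole_lambda7(u, constants.a_thole)
            pj = props[j]
            fields[i] += multipole_field(
                (pj.q, pj.mu, pj.theta), r_vec, damped=(l3, l5, l7)
            )
    return fields


def induced_dipoles(dimer: Dimer, props: list[AtomicProperties],
                    constants: ModelConstants | None = None) -> np.ndarray:
    """Converged induced dipoles (n, 3) by damped successive substitution.

    mu'(0)_i = alpha_i * F_perm,i (partner-monomer field); each sweep mixes
    the mutual induced-dipole coupling over all other atoms with factor
    omega.  Raises ConvergenceError if the fixed point is not reached.
    """
    constants = constants or ModelConstants()
    _check_props(dimer, props)
    n = dimer.n_atoms
    atoms = dimer.atoms()
    alphas = _polarizabilities(props)
    f_perm = permanent_fields(dimer, props, constants)
    mu0 = alphas[:, None] * f_perm
    # pairwise damped dipole field tensors
    t = np.zeros((n, n, 3, 3))
    for i in range(n):
        for k in range(n):
            if k == i:
                continue
            r_vec = atoms[i].position - atoms[k].position
            t[i, k] = thole_dipole_tensor(
                alphas[i], alphas[k], r_vec, constants.a_thole
            )
    mu = mu0.copy()
    omega = constants.omega
    for _ in range(constants.pol_max_iter):
        mutual = np.einsum("ikab,kb->ia", t, mu)
        new = (1.0 - omega) * mu + omega * (mu0 + alphas[:, None] * mutual)
        resid = float(np.max(np.abs(new - mu)))
        mu = new
        if resid < constants.pol_tol:
            return mu
    raise ConvergenceError(
        f"induced dipoles not converged in {constants.pol_max_iter} sweeps "
        f"(last residual {resid:.3e} a.u.)"
    )


def solve_induced_dipoles(dimer: Dimer, props: list[AtomicProperties],
                          constants: ModelConstants | None = None) -> np.ndarray:
    """Direct dense solution of the coupled polarization equations.

    Independent of the fixed-point route; used as its oracle.
    """
    constants = constants or ModelConstants()
    _check_props(dimer, props)
    n = dimer.n_atoms
    atoms = dimer.atoms()
    alphas = _polarizabilities(props)
    f_perm = permanent_fields(dimer, props, constants)
    mu0 = (alphas[:, None] * f_perm).ravel()
    a = np.eye(3 * n)
    for i in range(n):
        for k in range(n):
            if k == i:
                continue
            r_vec = atoms[i].position - atoms[k].position
            tik = thole_dipole_tensor(alphas[i], alphas[k], r_vec,
                                      constants.a_thole)
            a[3 * i:3 * i + 3, 3 * k:3 * k + 3] = -alphas[i] * tik
    from scipy.linalg import solve

    return solve(a, mu0).reshape(n, 3)


def indu_energy(dimer: Dimer, props: list[AtomicProperties],
                params: GlobalParameters,
                constants: ModelConstants | None = None) -> float:
    """Induction energy, kcal/mol.

    Polarization part: -sum_i mu'_i . F_perm,i over all atoms (both
    polarization directions), in hartree; short-range part:
    sum_{iA,jB} K_ij^indu S_ij in kcal/mol.
    """
    constants = constants or ModelConstants()
    _check_props(dimer, props)
    f_perm = permanent_fields(dimer, props, constants)
    mu = induced_dipoles(dimer, props, constants)
    e_pol = -float(np.sum(mu * f_perm)) * KCAL_PER_HARTREE
    e_sr = 0.0
    for ig, jg, ai, aj, _r_vec, r in _pair_iter(dimer, props):
        k = pair_parameter(params, "indu", ai.species, aj.species)
        e_sr += k * overlap_S(props[ig].sigma, props[jg].sigma, r)
    return e_pol + e_sr


def total_energy(dimer: Dimer, props: list[AtomicProperties],
                 params: GlobalParameters,
                 constants: ModelConstants | None = None) -> SaptRecord:
    """All four components and their total as a SaptRecord (kcal/mol)."""
    constants = constants or ModelConstants()
    values = {}
    for name, fn in (
        ("elst", lambda: elst_energy(dimer, props, params)),
        ("exch", lambda: exch_energy(dimer, props, params)),
        ("indu", lambda: indu_energy(dimer, props, params, constants)),
        ("disp", lambda: disp_energy(dimer, props, params)),
    ):
        try:
            values[name] = fn()
        except Exception as exc:  # annotate with the component name
            raise type(exc)(f"[{name}] {exc}") from exc
    return SaptRecord(**values)
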