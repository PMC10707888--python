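"""Vectorized pair-sum evaluation used by the fitter.

For a fixed geometry and property set, every parameter-independent
quantity (multipole contractions, overlaps, dispersion coefficients,
polarization energy) is precomputed once per system; the component
energies then become cheap closed-form functions of the per-species K
arrays.  The functions are written to be holomorphic in the parameters so
that complex-step differentiation yields machine-precision gradients.

The readable per-pair implementation in :mod:`pairsapt.energy` is the
reference; tests assert the two routes agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem import SPECIES
from .energy import (
    ModelConstants,
    System,
    combine_C6,
    compute_C8_C10,
    induced_dipoles,
    overlap_S,
    permanent_fields,
    tt_damping,
)
from .properties import (
    FREE_ATOM_CONSTANTS,
    effective_Q,
    scale_dispersion_inputs,
)
from .tensors import multipole_interaction
from .units import KCAL_PER_HARTREE

SPECIES_INDEX = {sp: k for k, sp in enumerate(SPECIES)}

_F2_DEGENERATE_REL = 1e-6


@dataclass
class CompiledSystem:
    """Parameter-independent pair sums for one dimer."""

    si: np.ndarray        # species index of atom i (A side), per pair
    sj: np.ndarray        # species index of atom j (B side), per pair
    r: np.ndarray         # pair distance, bohr
    e_zz: float           # sum Z_i Z_j / r, hartree
    a_zm: np.ndarray      # nucleus(i)-multipole(j) contraction, hartree
    a_mz: np.ndarray      # multipole(i)-nucleus(j) contraction, hartree
    a_mm: np.ndarray      # multipole-multipole contraction, hartree
    s_pair: np.ndarray    # overlap S_ij
    e_c6: float           # damped C6 sum, hartree
    d_hi: np.ndarray      # damped C8/C10 pair terms, hartree
    e_pol: float          # polarization energy, kcal/mol
    species_present: frozenset[str]

    @property
    def n_pairs(self) -> int:
        return self.r.size


def compile_system(system: System,
                   constants: ModelConstants | None = None) -> CompiledSystem:
    constants = constants or ModelConstants()
    dimer, props = system.dimer, system.props
    na = dimer.monomer_a.n_atoms
    atoms = dimer.atoms()

    si, sj, rs = [], [], []
    a_zm, a_mz, a_mm, s_pair, d_hi = [], [], [], [], []
    e_zz = 0.0
    e_c6 = 0.0
    for i in range(na):
        for j in range(na, dimer.n_atoms):
            ai, aj = atoms[i], atoms[j]
            pi, pj = props[i], props[j]
            r_vec = aj.position - ai.position
            r = float(np.linalg.norm(r_vec))
            si.append(SPECIES_INDEX[ai.species])
            sj.append(SPECIES_INDEX[aj.species])
            rs.append(r)
            mi = (pi.electronic_monopole, pi.mu, pi.theta)
            mj = (pj.electronic_monopole, pj.mu, pj.theta)
            zero_v, zero_t = np.zeros(3), np.zeros((3, 3))
            e_zz += pi.Z * pj.Z / r
            a_zm.append(multipole_interaction((pi.Z, zero_v, zero_t), mj, r_vec))
            a_mz.append(multipole_interaction(mi, (pj.Z, zero_v, zero_t), r_vec))
            a_mm.append(multipole_interaction(mi, mj, r_vec))
            s_pair.append(overlap_S(pi.sigma, pj.sigma, r))
            faci = FREE_ATOM_CONSTANTS[pi.element]
            facj = FREE_ATOM_CONSTANTS[pj.element]
            c6i, ali = scale_dispersion_inputs(faci, pi.h)
            c6j, alj = scale_dispersion_inputs(facj, pj.h)
            c6 = combine_C6(c6i, c6j, ali, alj)
            c8, c10 = compute_C8_C10(c6, effective_Q(faci), effective_Q(facj))
            b = 1.0 / math.sqrt(pi.sigma * pj.sigma)
            e_c6 += c6 / r**6 * tt_damping(6, b, r)
            d_hi.append(c8 / r**8 * tt_damping(8, b, r)
                        + c10 / r**10 * tt_damping(10, b, r))

    f_perm = permanent_fields(dimer, props, constants)
    mu = induced_dipoles(dimer, props, constants)
    e_pol = -float(np.sum(mu * f_perm)) * KCAL_PER_HARTREE

    return CompiledSystem(
        si=np.array(si), sj=np.array(sj), r=np.array(rs),
        e_zz=e_zz,
        a_zm=np.array(a_zm), a_mz=np.array(a_mz), a_mm=np.array(a_mm),
        s_pair=np.array(s_pair),
        e_c6=e_c6, d_hi=np.array(d_hi), e_pol=e_pol,
        species_present=frozenset(system.species()),
    )


def _f2_vec(ki, kj, r):
    """Vectorized, complex-safe two-exponent damping with degenerate branch."""
    near = np.abs(np.real(ki) - np.real(kj)) < _F2_DEGENERATE_REL * np.maximum(
        np.abs(np.real(ki)), np.abs(np.real(kj))
    )
    km = 0.5 * (ki + kj)
    x = km * r
    limit = 1.0 - np.exp(-x) * (1.0 - 0.5 * x)
    ki2, kj2 = ki * ki, kj * kj
    denom = np.where(near, 1.0, ki2 - kj2)  # placeholder avoids 0/0
    general = (
        1.0
        - ki2 / denom * np.exp(-ki * r)
        + kj2 / denom * np.exp(-kj * r)
    )
    return np.where(near, limit, general)


class CompiledDataset:
    """All systems' pair sums stacked for vectorized loss evaluation.

    Pairs of consecutive systems occupy contiguous slices, so per-record
    sums are ``np.add.reduceat`` segment reductions (complex-safe, which
    :func:`numpy.bincount` is not).
    """

    def __init__(self, systems_compiled: list[CompiledSystem]):
        if not systems_compiled:
            raise ValueError("no compiled systems")
        self.n_records = len(systems_compiled)
        self.offsets = np.cumsum([0] + [cs.n_pairs for cs in systems_compiled])[:-1]
        cat = lambda name: np.concatenate([getattr(cs, name) for cs in systems_compiled])
        self.si, self.sj, self.r = cat("si"), cat("sj"), cat("r")
        self.a_zm, self.a_mz, self.a_mm = cat("a_zm"), cat("a_mz"), cat("a_mm")
        self.s_pair, self.d_hi = cat("s_pair"), cat("d_hi")
        self.e_zz = np.array([cs.e_zz for cs in systems_compiled])
        self.e_c6 = np.array([cs.e_c6 for cs in systems_compiled])
        self.e_pol = np.array([cs.e_pol for cs in systems_compiled])
        self.species_present = frozenset().union(
            *(cs.species_present for cs in systems_compiled)
        )

    def component_matrix(self, k: dict[str, np.ndarray]) -> np.ndarray:
        """(n_records, 4) component energies for per-species K arrays."""
        seg = lambda v: np.add.reduceat(v, self.offsets)
        kel_i, kel_j = k["elst"][self.si], k["elst"][self.sj]
        f1_i = 1.0 - np.exp(-kel_i * self.r)
        f1_j = 1.0 - np.exp(-kel_j * self.r)
        elst = (
            self.e_zz
            + seg(self.a_zm * f1_j + self.a_mz * f1_i
                  + self.a_mm * _f2_vec(kel_i, kel_j, self.r))
        ) * KCAL_PER_HARTREE
        exch = seg(np.sqrt(k["exch"][self.si] * k["exch"][self.sj]) * self.s_pair)
        indu = self.e_pol + seg(
            np.sqrt(k["indu"][self.si] * k["indu"][self.sj]) * self.s_pair
        )
        disp = (
            self.e_c6
            + seg(np.sqrt(k["disp"][self.si] * k["disp"][self.sj]) * self.d_hi)
        ) * KCAL_PER_HARTREE
        return np.stack([elst, exch, indu, disp], axis=1)


def component_energies(cs: CompiledSystem, k: dict[str, np.ndarray]):
    """(elst, exch, indu, disp) in kcal/mol from per-species K arrays.

    ``k`` maps component name to an array of length len(SPECIES); entries
    may be complex (for complex-step derivatives).
    """
    kel_i = k["elst"][cs.si]
    kel_j = k["elst"][cs.sj]
    f1_i = 1.0 - np.exp(-kel_i * cs.r)
    f1_j = 1.0 - np.exp(-kel_j * cs.r)
    elst = (
        cs.e_zz
        + np.sum(cs.a_zm * f1_j + cs.a_mz * f1_i
                 + cs.a_mm * _f2_vec(kel_i, kel_j, cs.r))
    ) * KCAL_PER_HARTREE

    exch = np.sum(np.sqrt(k["exch"][cs.si] * k["exch"][cs.sj]) * cs.s_pair)
    indu = cs.e_pol + np.sum(
        np.sqrt(k["indu"][cs.si] * k["indu"][cs.sj]) * cs.s_pair
    )
    disp = (
        cs.e_c6
        + np.sum(np.sqrt(k["disp"][cs.si] * k["disp"][cs.sj]) * cs.d_hi)
    ) * KCAL_PER_HARTREE
    return elst, exch, indu, disp
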