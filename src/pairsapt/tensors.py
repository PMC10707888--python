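"""Cartesian multipole interaction tensors and Thole-damped variants.

The rank-n tensor T^(n) is the n-th derivative of 1/r with respect to the
separation vector r = r_b - r_a.  With traceless quadrupoles in the
Buckingham convention, the potential of a multipole set M = (q, mu, theta)
at separation r is

    V(r) = q T - mu_a T_a + (1/3) theta_ab T_ab

and interaction energies / fields follow by further differentiation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "t_tensors",
    "multipole_interaction",
    "multipole_field",
    "thole_dipole_tensor",
    "thole_lambdas",
]

_EYE = np.eye(3)


def t_tensors(r_vec: np.ndarray, max_rank: int = 4):
    """Interaction tensors T^(0)..T^(max_rank), derivatives of 1/r.

    max_rank 4 suffices for quadrupole-quadrupole coupling.  Raises on zero
    separation.
    """
    r_vec = np.asarray(r_vec, float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise ZeroDivisionError("interaction tensors undefined at zero separation")
    if max_rank > 4:
        raise ValueError("tensors implemented up to rank 4 (quadrupole-quadrupole)")
    x = r_vec
    out = [1.0 / r]
    if max_rank >= 1:
        out.append(-x / r**3)
    if max_rank >= 2:
        out.append((3.0 * np.outer(x, x) - r * r * _EYE) / r**5)
    if max_rank >= 3:
        xxx = np.einsum("a,b,c->abc", x, x, x)
        sym = (
            np.einsum("a,bc->abc", x, _EYE)
            + np.einsum("b,ac->abc", x, _EYE)
            + np.einsum("c,ab->abc", x, _EYE)
        )
        out.append(-(15.0 * xxx - 3.0 * r * r * sym) / r**7)
    if max_rank >= 4:
        xxxx = np.einsum("a,b,c,d->abcd", x, x, x, x)
        xxd = (
            np.einsum("a,b,cd->abcd", x, x, _EYE)
            + np.einsum("a,c,bd->abcd", x, x, _EYE)
            + np.einsum("a,d,bc->abcd", x, x, _EYE)
            + np.einsum("b,c,ad->abcd", x, x, _EYE)
            + np.einsum("b,d,ac->abcd", x, x, _EYE)
            + np.einsum("c,d,ab->abcd", x, x, _EYE)
        )
        dd = (
            np.einsum("ab,cd->abcd", _EYE, _EYE)
            + np.einsum("ac,bd->abcd", _EYE, _EYE)
            + np.einsum("ad,bc->abcd", _EYE, _EYE)
        )
        out.append((105.0 * xxxx - 15.0 * r * r * xxd + 3.0 * r**4 * dd) / r**9)
    return out


def multipole_interaction(
    ma: tuple[float, np.ndarray, np.ndarray],
    mb: tuple[float, np.ndarray, np.ndarray],
    r_vec: np.ndarray,
) -> float:
    """Energy of multipole sets a and b separated by r_vec = r_b - r_a.

    Each multipole set is (q, mu, theta) with theta traceless symmetric.
    All quantities in atomic units; result in hartree.
    """
    qa, mua, tha = ma
    qb, mub, thb = mb
    t0, t1, t2, t3, t4 = t_tensors(r_vec, 4)
    # derivatives of the potential of a, evaluated at b
    v = qa * t0 - mua @ t1 + np.einsum("ab,ab->", tha, t2) / 3.0
    dv = qa * t1 - t2 @ mua + np.einsum("bc,abc->a", tha, t3) / 3.0
    d2v = (
        qa * t2
        - np.einsum("c,abc->ab", mua, t3)
        + np.einsum("cd,abcd->ab", tha, t4) / 3.0
    )
    return float(qb * v + mub @ dv + np.einsum("ab,ab->", thb, d2v) / 3.0)


def thole_lambdas(u: float, a_thole: float) -> tuple[float, float]:
    """Thole damping multipliers (lambda3, lambda5) for exponential smearing.

    u is the polarizability-reduced distance; lambda5 <= lambda3 <= 1 and
    both approach 1 as u grows.
    """
    au3 = a_thole * u**3
    e = np.exp(-au3)
    return 1.0 - e, 1.0 - (1.0 + au3) * e


def thole_dipole_tensor(
    alpha_i: float, alpha_j: float, r_vec: np.ndarray, a_thole: float
) -> np.ndarray:
    """Thole-damped dipole-dipole (field) tensor.

    Bare tensor T_ab = (3 r_a r_b - r^2 delta)/r^5; the two radial
    structures are damped by lambda5 and lambda3 respectively.  Reduces to
    the bare tensor as u -> infinity.
    """
    if not (alpha_i > 0 and alpha_j > 0):
        raise ValueError("polarizabilities must be positive")
    r_vec = np.asarray(r_vec, float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise ZeroDivisionError("Thole tensor undefined at zero separation")
    u = r / (alpha_i * alpha_j) ** (1.0 / 6.0)
    l3, l5 = thole_lambdas(u, a_thole)
    return l5 * 3.0 * np.outer(r_vec, r_vec) / r**5 - l3 * _EYE / r**3


def multipole_field(
    m: tuple[float, np.ndarray, np.ndarray],
    r_vec: np.ndarray,
    damped: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Electric field at r_vec due to multipole set m at the origin.

    F = -grad V.  ``damped`` optionally supplies (lambda3, lambda5, lambda7)
    multipliers applied Thole-style to the charge, dipole and quadrupole
    contributions of the field.
    """
    q, mu, th = m
    t0, t1, t2, t3 = t_tensors(r_vec, 3)
    if damped is None:
        f_q = -q * t1
        f_mu = t2 @ mu
        f_th = -np.einsum("bc,abc->a", th, t3) / 3.0
    else:
        l3, l5, l7 = damped
        r = float(np.linalg.norm(r_vec))
        x = np.asarray(r_vec, float)
        f_q = q * l3 * x / r**3
        t2d = l5 * 3.0 * np.outer(x, x) / r**5 - l3 * _EYE / r**3
        f_mu = t2d @ mu
        # damped rank-3: r^3-structure gets lambda7, delta-structures lambda5
        xxx = np.einsum("a,b,c->abc", x, x, x)
        sym = (
            np.einsum("a,bc->abc", x, _EYE)
            + np.einsum("b,ac->abc", x, _EYE)
            + np.einsum("c,ab->abc", x, _EYE)
        )
        t3d = -(15.0 * l7 * xxx / r**7 - 3.0 * l5 * sym / r**5)
        f_th = -np.einsum("bc,abc->a", th, t3d) / 3.0
    return f_q + f_mu + f_th


def thole_lambda7(u: float, a_thole: float) -> float:
    """Third Thole multiplier, damping the r^-7 radial structure."""
    au3 = a_thole * u**3
    return 1.0 - (1.0 + au3 + 0.6 * au3 * au3) * np.exp(-au3)
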