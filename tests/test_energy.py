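"""Component energy models: damping, overlap, dispersion, induction,
electrostatics, and their invariances."""

import math

import numpy as np
import pytest

import pairsapt as ps
from pairsapt.chem import Atom, Dimer, Monomer
from pairsapt.energy import (
    ConvergenceError,
    GlobalParameters,
    MissingParameterError,
    ModelConstants,
    SaptRecord,
    System,
    combine_C6,
    compute_C8_C10,
    damping_f1,
    damping_f2,
    elst_energy,
    exch_energy,
    disp_energy,
    indu_energy,
    induced_dipoles,
    overlap_S,
    permanent_fields,
    solve_induced_dipoles,
    total_energy,
    tt_damping,
)
from pairsapt.properties import AtomicProperties
from pairsapt.units import KCAL_PER_HARTREE
from conftest import random_rotation, rotate_system


def _bare_atom(element="H", species="HC", pos=(0, 0, 0), q=0.0, Z=0.0,
               mu=None, theta=None, sigma=0.8, h=1e-12):
    atom = Atom(element, np.asarray(pos, float), species=species)
    prop = AtomicProperties(
        element=element, q=q,
        mu=np.zeros(3) if mu is None else np.asarray(mu, float),
        theta=np.zeros((3, 3)) if theta is None else np.asarray(theta, float),
        Z=Z, sigma=sigma, h=h,
    )
    return atom, prop


def _two_atom_system(atom_a, prop_a, atom_b, prop_b, id="pair"):
    dimer = Dimer(Monomer(atoms=[atom_a]), Monomer(atoms=[atom_b]), id=id)
    return System(dimer, [prop_a, prop_b])


def _uniform_params(**kwargs):
    params = GlobalParameters()
    defaults = {"elst": 3.0, "exch": 2.0, "indu": 1.0, "disp": 0.5}
    defaults.update(kwargs)
    for sp in ps.SPECIES:
        for comp, val in defaults.items():
            params.set(sp, comp, val)
    return params


class TestDampingF1:
    def test_zero_at_contact(self):
        assert damping_f1(2.5, 0.0) == 0.0

    def test_asymptote(self):
        assert damping_f1(2.5, 1e3) == pytest.approx(1.0, abs=1e-12)

    def test_reference_value(self):
        assert damping_f1(1.0, 1.0) == pytest.approx(0.6321205588285577, rel=1e-12)

    def test_strictly_increasing(self):
        r = np.linspace(0, 20, 500)
        f = damping_f1(1.7, r)
        assert np.all(np.diff(f) > 0)

    def test_nonpositive_K_rejected(self):
        with pytest.raises(ValueError):
            damping_f1(0.0, 1.0)


class TestDampingF2:
    def test_zero_at_contact_any_exponents(self):
        for ki, kj in [(1.0, 2.0), (3.3, 0.7), (5.0, 5.0)]:
            assert damping_f2(ki, kj, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_in_exponents(self):
        r = np.linspace(0.1, 15, 50)
        assert np.allclose(damping_f2(1.3, 4.1, r), damping_f2(4.1, 1.3, r))

    def test_asymptote(self):
        assert damping_f2(2.0, 3.0, 1e3) == pytest.approx(1.0)

    @pytest.mark.parametrize("eps", [1e-4, 1e-5, 1e-6, 1e-7, 1e-8])
    def test_equal_exponent_branch_matches_numerical_limit(self, eps):
        # the analytic limit must agree with the two-exponent formula as
        # the exponents approach each other
        k, r = 1.8, 2.3
        general = damping_f2(k * (1 + 10 * eps), k, r)  # outside branch for large eps
        limit = 1.0 - math.exp(-k * r) * (1.0 - 0.5 * k * r)
        assert damping_f2(k, k, r) == pytest.approx(limit, rel=1e-12)
        if 10 * eps > 1e-6:
            assert general == pytest.approx(limit, rel=1e-3 * max(1, 1 / (10 * eps * 1e6)))

    def test_equal_branch_continuity(self):
        # values just outside the degenerate branch agree with the limit
        k, r = 2.2, 3.7
        inside = damping_f2(k, k, r)
        outside = damping_f2(k * (1 + 5e-6), k, r)
        assert outside == pytest.approx(inside, abs=1e-6)

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValueError):
            damping_f2(1.0, -2.0, 1.0)


class TestOverlap:
    def test_unity_at_contact(self):
        assert overlap_S(0.7, 1.1, 0.0) == 1.0

    def test_reference_value(self):
        # sigma_i = sigma_j = 1 bohr -> B = 1; S(1) = (7/3) e^-1
        assert overlap_S(1.0, 1.0, 1.0) == pytest.approx(7.0 / 3.0 * math.exp(-1.0))

    def test_monotone_decreasing_positive(self):
        r = np.linspace(0, 30, 800)
        s = overlap_S(0.9, 0.6, r)
        assert np.all(np.diff(s) <= 0)
        assert np.all(s > 0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            overlap_S(-1.0, 1.0, 1.0)


class TestDispersionCoefficients:
    def test_homoatomic_returns_minus_C6(self):
        assert combine_C6(46.6, 46.6, 11.3, 11.3) == pytest.approx(-46.6)

    def test_equal_polarizability_arithmetic(self):
        assert combine_C6(2.0, 8.0, 5.0, 5.0) == pytest.approx(-3.2)

    def test_symmetric(self):
        assert combine_C6(3.0, 7.0, 2.0, 9.0) == pytest.approx(
            combine_C6(7.0, 3.0, 9.0, 2.0)
        )

    def test_c8_c10_reference_values(self):
        c8, c10 = compute_C8_C10(-1.0, 1.0, 1.0)
        assert c8 == pytest.approx(-3.0)
        assert c10 == pytest.approx(-11.025)

    def test_c8_under_unequal_Q(self):
        c8, _ = compute_C8_C10(-2.0, 4.0, 1.0)
        assert c8 == pytest.approx(3.0 * (-2.0) * 2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_c10_c6_over_c8_squared_identity(self, seed):
        rng = np.random.default_rng(seed)
        c6 = combine_C6(*rng.uniform(1, 100, 2), *rng.uniform(1, 30, 2))
        c8, c10 = compute_C8_C10(c6, *rng.uniform(0.5, 20, 2))
        assert c10 * c6 / c8**2 == pytest.approx(49.0 / 40.0, rel=1e-13)
        assert np.sign(c8) == np.sign(c6) == np.sign(c10)

    def test_zero_C6_rejected(self):
        with pytest.raises(ValueError):
            compute_C8_C10(0.0, 1.0, 1.0)


class TestTangToennies:
    def test_zero_at_contact(self):
        for n in (6, 8, 10):
            assert tt_damping(n, 1.3, 0.0) == pytest.approx(0.0)

    def test_asymptote(self):
        for n in (6, 8, 10):
            assert tt_damping(n, 1.3, 100.0) == pytest.approx(1.0)

    def test_bounds_and_order_ordering(self):
        r = np.linspace(0, 40, 1000)
        f6 = tt_damping(6, 1.1, r)
        f8 = tt_damping(8, 1.1, r)
        f10 = tt_damping(10, 1.1, r)
        for f in (f6, f8, f10):
            assert np.all((f >= 0) & (f <= 1))
        assert np.all(f6 >= f8 - 1e-14)
        assert np.all(f8 >= f10 - 1e-14)

    def test_series_evaluation_oracle(self):
        # independent evaluation of 1 - e^-x sum x^k/k! at the effective x
        b, r = 0.9, 3.0
        x = b * r + r * (2 * b * b + 3 * b) / ((b * r) ** 2 + 3 * b * r + 3)
        expected = 1.0 - math.exp(-x) * sum(x**k / math.factorial(k) for k in range(7))
        assert tt_damping(6, b, r) == pytest.approx(expected, rel=1e-13)

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError):
            tt_damping(7, 1.0, 1.0)


class TestElstEnergy:
    def test_bare_coulomb_pair(self):
        # two nuclei Z=+1 with vanishing electronic multipoles at 1 bohr
        a, pa = _bare_atom(pos=(0, 0, 0), q=1.0, Z=1.0)
        b, pb = _bare_atom(pos=(0, 0, 1.0), q=1.0, Z=1.0)
        system = _two_atom_system(a, pa, b, pb)
        e = elst_energy(system.dimer, system.props, _uniform_params())
        assert e == pytest.approx(KCAL_PER_HARTREE, rel=1e-12)

    def test_all_charges_zero(self):
        a, pa = _bare_atom(pos=(0, 0, 0))
        b, pb = _bare_atom(pos=(0, 0, 2.0))
        system = _two_atom_system(a, pa, b, pb)
        assert elst_energy(system.dimer, system.props, _uniform_params()) == 0.0

    def test_damped_matches_undamped_coulomb_at_long_range(self):
        # K r approx 40 -> damping saturated; compare with the 1/r oracle
        # for two neutral atoms carrying electronic monopoles only
        a, pa = _bare_atom(pos=(0, 0, 0), q=0.3, Z=1.0)
        b, pb = _bare_atom(pos=(0, 0, 14.0), q=-0.2, Z=1.0)
        system = _two_atom_system(a, pa, b, pb)
        params = _uniform_params(elst=3.0)  # K r = 42
        e = elst_energy(system.dimer, system.props, params)
        # oracle: undamped multipole electrostatics of net charges
        oracle = (0.3 * -0.2) / 14.0 * KCAL_PER_HARTREE
        assert e == pytest.approx(oracle, rel=1e-6)

    def test_missing_species_parameter_names_species(self, water_dimer_system):
        params = _uniform_params()
        params._table.loc["HO", "Kelst"] = np.nan
        with pytest.raises(MissingParameterError, match="HO"):
            elst_energy(water_dimer_system.dimer, water_dimer_system.props, params)


class TestExchEnergy:
    def test_single_pair_arithmetic(self):
        a, pa = _bare_atom(pos=(0, 0, 0), sigma=1.0)
        b, pb = _bare_atom(pos=(0, 0, 2.0), sigma=1.0)
        system = _two_atom_system(a, pa, b, pb)
        params = _uniform_params(exch=4.0)  # geometric mean -> 4
        s = overlap_S(1.0, 1.0, 2.0)
        e = exch_energy(system.dimer, system.props, params)
        assert e == pytest.approx(4.0 * s, rel=1e-12)

    def test_vanishes_at_long_range(self, water_dimer_system, truth_params):
        far = rotate_system(water_dimer_system, np.eye(3), np.zeros(3))
        shifted = System(
            Dimer(
                far.dimer.monomer_a,
                far.dimer.monomer_b.transformed(np.eye(3), np.array([80.0, 0, 0])),
                id="far",
            ),
            far.props,
        )
        assert exch_energy(shifted.dimer, shifted.props, truth_params) < 1e-10

    def test_positive_and_decreasing_under_separation(self, water_dimer_system,
                                                      truth_params):
        base = water_dimer_system
        vals = []
        for extra in (0.0, 2.0, 4.0, 8.0):
            shifted = System(
                Dimer(
                    base.dimer.monomer_a,
                    base.dimer.monomer_b.transformed(
                        np.eye(3), np.array([0, 0, extra])
                    ),
                    id="scan",
                ),
                base.props,
            )
            vals.append(exch_energy(shifted.dimer, shifted.props, truth_params))
        assert all(v > 0 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestDispEnergy:
    def test_asymptotic_c6_recovery(self):
        a, pa = _bare_atom("C", "C4", (0, 0, 0), sigma=1.0, h=1.0)
        b, pb = _bare_atom("C", "C4", (0, 0, 60.0), sigma=1.0, h=1.0)
        system = _two_atom_system(a, pa, b, pb)
        # negligible K_disp isolates the C6 channel at long range
        params = _uniform_params(disp=1e-12)
        e = disp_energy(system.dimer, system.props, params) / KCAL_PER_HARTREE
        # E r^6 -> C6_ij at long range
        from pairsapt.properties import FREE_ATOM_CONSTANTS

        c6 = -FREE_ATOM_CONSTANTS["C"].C6_free  # homoatomic, h = 1
        assert e * 60.0**6 == pytest.approx(c6, rel=1e-4)

    def test_negative_at_all_sampled_geometries(self, small_systems, truth_params):
        for s in small_systems:
            assert disp_energy(s.dimer, s.props, truth_params) < 0

    def test_k_disp_scales_only_higher_orders(self):
        a, pa = _bare_atom("C", "C4", (0, 0, 0), sigma=1.0, h=1.0)
        b, pb = _bare_atom("C", "C4", (0, 0, 7.0), sigma=1.0, h=1.0)
        system = _two_atom_system(a, pa, b, pb)
        e_small = disp_energy(system.dimer, system.props,
                              _uniform_params(disp=1e-12))
        e_one = disp_energy(system.dimer, system.props, _uniform_params(disp=1.0))
        e_four = disp_energy(system.dimer, system.props, _uniform_params(disp=4.0))
        # uniform K_disp: the pair geometric mean equals K, so the
        # higher-order contribution scales linearly in K
        assert (e_four - e_small) == pytest.approx(4 * (e_one - e_small), rel=1e-9)


class TestInduction:
    def test_zero_permanent_multipoles_give_zero_dipoles(self):
        a, pa = _bare_atom(pos=(0, 0, 0), h=1.0)
        b, pb = _bare_atom(pos=(0, 0, 3.0), h=1.0)
        system = _two_atom_system(a, pa, b, pb)
        mu = induced_dipoles(system.dimer, system.props)
        assert np.allclose(mu, 0.0)

    def test_single_polarizable_atom_closed_form(self):
        # polarizable atom at origin, point charge q at 5 bohr; the charge
        # carries negligible polarizability so mutual coupling vanishes
        a, pa = _bare_atom("H", "HC", (0, 0, 0), q=0.0, Z=0.0, h=1.0)
        b, pb = _bare_atom("H", "HC", (0, 0, 5.0), q=0.8, Z=0.0, h=1e-12)
        system = _two_atom_system(a, pa, b, pb)
        constants = ModelConstants()
        mu = induced_dipoles(system.dimer, system.props, constants)
        f = permanent_fields(system.dimer, system.props, constants)
        alpha = 4.5  # H free-atom polarizability, h = 1
        assert np.allclose(mu[0], alpha * f[0], atol=1e-10)
        # field magnitude approaches q/r^2 (Thole damping saturated)
        assert np.linalg.norm(f[0]) == pytest.approx(0.8 / 25.0, rel=1e-6)
        # polarization energy is -alpha E^2 and negative
        e_pol = -float(np.sum(mu * f)) * KCAL_PER_HARTREE
        assert e_pol == pytest.approx(
            -alpha * (0.8 / 25.0) ** 2 * KCAL_PER_HARTREE, rel=1e-6
        )
        assert e_pol < 0

    @pytest.mark.parametrize("idx", range(3))
    def test_fixed_point_equals_direct_solve(self, small_systems, idx):
        system = small_systems[idx]
        constants = ModelConstants()
        mu_iter = induced_dipoles(system.dimer, system.props, constants)
        mu_solve = solve_induced_dipoles(system.dimer, system.props, constants)
        assert np.max(np.abs(mu_iter - mu_solve)) < 10 * constants.pol_tol

    def test_nonconvergence_reported(self, small_systems):
        constants = ModelConstants(pol_max_iter=1)
        with pytest.raises(ConvergenceError, match="residual"):
            induced_dipoles(
                small_systems[2].dimer, small_systems[2].props, constants
            )


class TestTotalAndSymmetry:
    def test_record_total_is_component_sum(self):
        rec = SaptRecord(-1.0, 2.0, -0.5, -0.8)
        assert rec.total == pytest.approx(-0.3)
        with pytest.raises(ValueError):
            SaptRecord(-1.0, 2.0, -0.5, -0.8, total=5.0)

    def test_monomer_swap_invariance(self, small_systems, truth_params):
        for system in small_systems[:4]:
            rec = total_energy(system.dimer, system.props, truth_params)
            swapped = system.swapped()
            rec2 = total_energy(swapped.dimer, swapped.props, truth_params)
            assert np.allclose(rec.as_array(), rec2.as_array(), atol=1e-9)

    def test_rigid_rotation_translation_invariance(self, small_systems,
                                                   truth_params):
        rng = np.random.default_rng(42)
        system = small_systems[2]
        rec = total_energy(system.dimer, system.props, truth_params)
        rot = random_rotation(rng)
        moved = rotate_system(system, rot, np.array([5.0, -3.0, 11.0]))
        rec2 = total_energy(moved.dimer, moved.props, truth_params)
        assert np.allclose(rec.as_array(), rec2.as_array(), atol=1e-9)

    def test_atom_reordering_invariance(self, small_systems, truth_params):
        system = small_systems[1]
        rng = np.random.default_rng(3)
        mon = system.dimer.monomer_a
        perm = rng.permutation(mon.n_atoms)
        reordered = Monomer(
            atoms=[mon.atoms[i] for i in perm],
            class_label=mon.class_label,
        )
        props = ([system.props[i] for i in perm]
                 + system.props[mon.n_atoms:])
        dimer = Dimer(reordered, system.dimer.monomer_b, id="perm")
        rec = total_energy(system.dimer, system.props, truth_params)
        rec2 = total_energy(dimer, props, truth_params)
        assert np.allclose(rec.as_array(), rec2.as_array(), atol=1e-9)

    def test_all_components_vanish_at_long_range(self, water_dimer_system,
                                                 truth_params):
        base = water_dimer_system
        prev = None
        for extra in (30.0, 60.0, 120.0):
            shifted = System(
                Dimer(
                    base.dimer.monomer_a,
                    base.dimer.monomer_b.transformed(
                        np.eye(3), np.array([0, 0, extra])
                    ),
                    id="far",
                ),
                base.props,
            )
            rec = total_energy(shifted.dimer, shifted.props, truth_params)
            mags = np.abs(rec.as_array())
            if prev is not None:
                assert np.all(mags <= prev + 1e-15)
            prev = mags
        assert np.all(prev < 1e-4)

    def test_compiled_path_matches_reference_implementation(
        self, small_systems, truth_params
    ):
        from pairsapt._compiled import compile_system, component_energies
        from pairsapt.fitting import _params_arrays

        k = _params_arrays(truth_params)
        for system in small_systems:
            cs = compile_system(system)
            fast = np.array(component_energies(cs, k))
            slow = total_energy(system.dimer, system.props, truth_params)
            assert np.allclose(fast, slow.as_array()[:4], rtol=1e-10, atol=1e-10)
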