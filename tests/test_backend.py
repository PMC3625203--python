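import math

import numpy as np
import pytest

from efmoscan.backend import (MOCK_CONSTANTS, MockBackend, cap_fragment,
                              make_backend, LevelSpec)
from efmoscan.constants import ANGSTROM_TO_BOHR
from efmoscan.synth import make_bonded_chain
from efmoscan.system_model import Fragment

from conftest import random_rotation_matrix, water_system


def fd_gradient_of_monomer(system, frag, h_bohr=1e-4):
    """Central finite differences of the monomer energy, hartree/bohr."""
    c0 = system.coordinates()
    grad = {}
    deps = sorted({i for i in range(system.n_atoms)})
    for i in deps:
        g = np.zeros(3)
        for a in range(3):
            for sgn in (1, -1):
                c = c0.copy()
                c[i, a] += sgn * h_bohr / ANGSTROM_TO_BOHR
                system.set_coordinates(c)
                g[a] += sgn * MockBackend().monomer(frag, system).energy
        g /= 2 * h_bohr
        if np.any(np.abs(g) > 1e-12):
            grad[i] = g
    system.set_coordinates(c0)
    return grad


class TestMockMonomer:
    def test_equilibrium_water_energy_is_zero(self, equilibrium_water):
        res = MockBackend().monomer(equilibrium_water.fragments[0],
                                    equilibrium_water)
        assert abs(res.energy) < 1e-12

    def test_stretched_oh_matches_harmonic_closed_form(self, equilibrium_water):
        s = equilibrium_water.copy()
        s.atoms[1].position = np.array([1.05, 0.0, 0.0])
        res = MockBackend().monomer(s.fragments[0], s)
        dr = 0.10 * ANGSTROM_TO_BOHR
        expected = 0.5 * MOCK_CONSTANTS["k_bond"] * dr ** 2
        assert res.energy == pytest.approx(expected, rel=1e-12)

    def test_translation_invariance(self, equilibrium_water):
        s = equilibrium_water.copy()
        res0 = MockBackend().monomer(s.fragments[0], s)
        s.set_coordinates(s.coordinates() + [3.0, -2.0, 7.0])
        res1 = MockBackend().monomer(s.fragments[0], s)
        assert res1.energy == pytest.approx(res0.energy, abs=1e-14)
        for i in res0.gradient:
            assert np.allclose(res0.gradient[i], res1.gradient[i], atol=1e-12)

    def test_rotation_invariance(self, equilibrium_water):
        rng = np.random.default_rng(11)
        s = equilibrium_water.copy()
        e0 = MockBackend().monomer(s.fragments[0], s).energy
        for _ in range(10):
            rot = random_rotation_matrix(rng)
            s.set_coordinates(s.coordinates() @ rot.T)
            e = MockBackend().monomer(s.fragments[0], s).energy
            assert e == pytest.approx(e0, abs=1e-10)

    def test_net_force_and_torque_vanish(self):
        rng = np.random.default_rng(5)
        s = water_system([[0, 0, 0]], seed=1)
        s.set_coordinates(s.coordinates() + rng.normal(0, 0.05, (3, 3)))
        res = MockBackend().monomer(s.fragments[0], s)
        force = -np.sum(list(res.gradient.values()), axis=0)
        assert np.abs(force).max() < 1e-8
        coords = s.coordinates() * ANGSTROM_TO_BOHR
        torque = sum(np.cross(coords[i], -g) for i, g in res.gradient.items())
        assert np.abs(torque).max() < 1e-8

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        s = water_system([[0, 0, 0]], seed=2)
        s.set_coordinates(s.coordinates() + rng.normal(0, 0.04, (3, 3)))
        res = MockBackend().monomer(s.fragments[0], s)
        fd = fd_gradient_of_monomer(s, s.fragments[0])
        for i, g in fd.items():
            assert np.abs(res.gradient[i] - g).max() < 1e-7


class TestCapping:
    def test_chain_fragment_gets_cap_on_cut_axis(self):
        s = make_bonded_chain(2, seed=0, jitter=0.0)
        frag0 = s.fragments[0]
        capped = cap_fragment(frag0, s)
        assert len(capped.caps) == 1
        (a, b) = capped.caps[0]
        pos = capped.positions(s)
        cap = pos[-1]
        pa, pb = s.coordinates()[a], s.coordinates()[b]
        u = (pb - pa) / np.linalg.norm(pb - pa)
        assert np.allclose(cap, pa + MOCK_CONSTANTS["d_cap"] * u, atol=1e-12)

    def test_fragment_without_cuts_is_identity(self, equilibrium_water):
        capped = cap_fragment(equilibrium_water.fragments[0], equilibrium_water)
        assert capped.caps == []
        assert capped.atom_indices == [0, 1, 2]

    def test_dcap_equal_to_bond_length_reaches_partner(self):
        s = make_bonded_chain(2, seed=0, jitter=0.0)
        frag0 = s.fragments[0]
        (a, b) = cap_fragment(frag0, s).caps[0]
        L = float(np.linalg.norm(s.coordinates()[b] - s.coordinates()[a]))
        capped = cap_fragment(frag0, s, d_cap=L)
        assert np.allclose(capped.positions(s)[-1], s.coordinates()[b])

    def test_capped_gradient_chain_rule_vs_finite_differences(self):
        s = make_bonded_chain(2, seed=3)
        frag1 = s.fragments[1]        # roster includes the shared atom
        res = MockBackend().monomer(frag1, s)
        fd = fd_gradient_of_monomer(s, frag1)
        for i, g in fd.items():
            assert np.abs(res.gradient.get(i, np.zeros(3)) - g).max() < 1e-7


class TestMockDimer:
    def test_two_waters_interaction_equals_pair_sum_oracle(self, water_pair_3A):
        s = water_pair_3A
        bk = MockBackend()
        e_i = bk.monomer(s.fragments[0], s).energy
        e_j = bk.monomer(s.fragments[1], s).energy
        e_ij = bk.dimer(s.fragments[0], s.fragments[1], s).energy
        q = MOCK_CONSTANTS["charges"]
        eps, sig = MOCK_CONSTANTS["lj_epsilon"], MOCK_CONSTANTS["lj_sigma"]
        c = s.coordinates() * ANGSTROM_TO_BOHR
        el = s.elements()
        oracle = 0.0
        for i in range(3):
            for j in range(3, 6):
                r = np.linalg.norm(c[i] - c[j])
                oracle += (q[el[i]] * q[el[j]] / r
                           + 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6))
        assert e_ij - e_i - e_j == pytest.approx(oracle, abs=1e-14)

    def test_distant_waters_reduce_to_point_charge_coulomb(self):
        s = water_system([[0, 0, 0], [50.0, 0, 0]], seed=8)
        bk = MockBackend()
        inter = (bk.dimer(s.fragments[0], s.fragments[1], s).energy
                 - bk.monomer(s.fragments[0], s).energy
                 - bk.monomer(s.fragments[1], s).energy)
        q = MOCK_CONSTANTS["charges"]
        c = s.coordinates() * ANGSTROM_TO_BOHR
        el = s.elements()
        coulomb = sum(q[el[i]] * q[el[j]] / np.linalg.norm(c[i] - c[j])
                      for i in range(3) for j in range(3, 6))
        assert inter == pytest.approx(coulomb, abs=1e-10)

    def test_self_dimer_is_an_error(self, water_pair_3A):
        with pytest.raises(ValueError):
            MockBackend().dimer(water_pair_3A.fragments[0],
                                water_pair_3A.fragments[0], water_pair_3A)


class TestBackendContract:
    def test_purity_bit_identical_results(self, water_pair_3A):
        b1, b2 = MockBackend(), MockBackend()
        r1 = b1.monomer(water_pair_3A.fragments[0], water_pair_3A)
        r2 = b2.monomer(water_pair_3A.fragments[0], water_pair_3A)
        assert r1.energy == r2.energy
        for i in r1.gradient:
            assert np.array_equal(r1.gradient[i], r2.gradient[i])

    def test_cache_avoids_recomputation(self, water_pair_3A):
        bk = MockBackend()
        bk.dimer(water_pair_3A.fragments[0], water_pair_3A.fragments[1],
                 water_pair_3A)
        bk.dimer(water_pair_3A.fragments[0], water_pair_3A.fragments[1],
                 water_pair_3A)
        assert bk.n_calls("dimer") == 1

    def test_cache_invalidated_by_moved_fragment(self, water_pair_3A):
        s = water_pair_3A
        bk = MockBackend()
        bk.monomer(s.fragments[0], s)
        c = s.coordinates()
        c[0] += 0.01
        s.set_coordinates(c)
        bk.monomer(s.fragments[0], s)
        assert bk.n_calls("monomer") == 2
        # the untouched fragment still hits the cache
        bk.monomer(s.fragments[1], s)
        bk.monomer(s.fragments[1], s)
        assert bk.n_calls("monomer") == 3

    def test_registry_and_unknown_backend(self):
        assert isinstance(make_backend(LevelSpec(method="mock")), MockBackend)
        pol = make_backend(LevelSpec(method="mock-pol"))
        assert pol.polarizable
        with pytest.raises(KeyError, match="not registered"):
            make_backend(LevelSpec(method="dft-imaginary"))

    def test_moments_are_neutralized_point_charges(self, equilibrium_water):
        mset, pset = MockBackend().moments(equilibrium_water.fragments[0],
                                           equilibrium_water)
        assert mset.q.sum() == pytest.approx(0.0, abs=1e-14)
        assert mset.q[0] == pytest.approx(-0.8)
        assert not np.any(mset.mu)
        assert not np.any(mset.theta)
        assert pset.is_zero

    def test_mock_pol_reports_element_polarizabilities(self, equilibrium_water):
        _, pset = MockBackend(polarizable=True).moments(
            equilibrium_water.fragments[0], equilibrium_water)
        table = MOCK_CONSTANTS["polarizabilities"]
        assert pset.alpha[0, 0, 0] == pytest.approx(table["O"])
        assert pset.alpha[1, 1, 1] == pytest.approx(table["H"])

    def test_charged_fragment_charge_is_distributed(self):
        from efmoscan.synth import make_toy_reaction
        toy = make_toy_reaction(0)
        mset, _ = MockBackend().moments(toy.system.fragments[1], toy.system)
        assert mset.q.sum() == pytest.approx(-1.0, abs=1e-14)
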