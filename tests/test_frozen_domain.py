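import numpy as np
import pytest

from efmoscan.backend import MockBackend
from efmoscan.constants import ANGSTROM_TO_BOHR
from efmoscan.efmo_core import efmo_energy
from efmoscan.frozen_domain import (RegionError, assign_regions, fd_energy,
                                    fd_gradient)
from efmoscan.synth import (make_bonded_chain, make_toy_protein,
                            make_toy_reaction)

from conftest import water_system


@pytest.fixture
def toy():
    return make_toy_reaction(0)


@pytest.fixture
def toy_regions(toy):
    return toy.regions()


class TestAssignRegions:
    def test_linear_water_chain_active_set(self):
        # five waters in a line, 2.5 A apart, target the middle one
        s = water_system([[2.5 * k, 0, 0] for k in range(5)], seed=0)
        regions = assign_regions(s, {2}, R_active=3.0, R_buffer=2.5)
        assert regions.active == {1, 2, 3}
        assert regions.active | regions.buffer | regions.frozen == \
            {0, 1, 2, 3, 4}
        assert not regions.active & regions.buffer

    def test_infinite_active_radius_swallows_everything(self, five_waters):
        regions = assign_regions(five_waters, {0}, R_active=1e6)
        assert regions.active == {0, 1, 2, 3, 4}
        assert regions.buffer == set() and regions.frozen == set()

    def test_unknown_target_rejected(self, five_waters):
        with pytest.raises(RegionError, match="not found"):
            assign_regions(five_waters, {42})

    def test_frozen_flags_follow_regions(self, toy, toy_regions):
        for frag in toy.system.fragments:
            region = toy_regions.region_of(frag.id)
            for i in frag.owned_atom_indices:
                if i in toy.anchor_atoms:
                    assert toy.system.atoms[i].frozen
                elif region == "A":
                    assert not toy.system.atoms[i].frozen
                else:
                    assert toy.system.atoms[i].frozen

    def test_shared_atom_frozen_unless_both_owners_active(self):
        chain = make_bonded_chain(4, seed=0)
        regions = assign_regions(chain, {0}, R_active=2.0, R_buffer=6.0)
        # fragments 0,1 are active (they share an atom at a bonded junction)
        assert {0, 1} <= regions.active
        junction_01 = chain.fragments[0].shared_atoms[0][0]
        boundary = [i for i, p in chain.fragments[1].shared_atoms if p == 2]
        assert not chain.atoms[junction_01].frozen
        assert all(chain.atoms[i].frozen for i in boundary)

    def test_active_bonded_to_frozen_is_an_error(self):
        chain = make_bonded_chain(3, seed=0)
        with pytest.raises(RegionError, match="bonded"):
            assign_regions(chain, {0}, R_active=0.1, R_buffer=0.1)

    def test_partition_is_complete_on_toy_protein(self):
        s = make_toy_protein(4, 6, seed=1)
        regions = assign_regions(s, {1}, R_active=2.0, R_buffer=2.5)
        n_frags = len(s.fragments)
        assert len(regions.active) + len(regions.buffer) + \
            len(regions.frozen) == n_frags
        report = regions.report(s)
        assert sum(report["atom_counts"].values()) == s.n_atoms
        assert report["atom_counts"]["A"] > 0

    def test_report_lists_fragment_regions(self, toy, toy_regions):
        report = toy_regions.report(toy.system)
        assert set(report["fragment_regions"]) == \
            {f.id for f in toy.system.fragments}
        assert report["n_mobile_atoms"] == len(toy_regions.mobile_atoms)


class TestFDEnergy:
    def test_empty_buffer_and_frozen_reduce_to_efmo(self, five_waters):
        regions = assign_regions(five_waters, set(range(5)), R_active=1e6)
        e_fd = fd_energy(five_waters, regions, MockBackend(), 1.5, "FD")
        e_ref = efmo_energy(five_waters, MockBackend(), 1.5)
        assert e_fd.E_total == pytest.approx(e_ref.E_total, abs=1e-12)

    def test_fdd_drops_exactly_the_bb_dimer_sum(self, toy, toy_regions):
        bk = MockBackend()
        fd = fd_energy(toy.system, toy_regions, bk, 1.5, "FD")
        fdd = fd_energy(toy.system, toy_regions, bk, 1.5, "FDD")
        bb_sum = sum(v for (i, j), v in fd.dE_dimer.items()
                     if toy_regions.region_of(i) == "b"
                     and toy_regions.region_of(j) == "b")
        assert fdd.skipped_bb_pairs   # the toy has near b-b pairs
        assert fdd.E_total - fd.E_total == pytest.approx(-bb_sum, abs=1e-12)

    def test_decomposition_consistency(self, toy, toy_regions):
        rep = fd_energy(toy.system, toy_regions, MockBackend(), 1.5, "FDD")
        rep.check_consistency(tol=1e-12)

    def test_moving_frozen_atoms_changes_only_classical_terms(self, toy,
                                                              toy_regions):
        bk = MockBackend()
        rep1 = fd_energy(toy.system, toy_regions, bk, 1.5, "FDD")
        n_mono, n_dim = bk.n_calls("monomer"), bk.n_calls("dimer")
        c = toy.system.coordinates()
        f_atoms = [i for f in toy.system.fragments
                   if f.id in toy_regions.frozen for i in f.atom_indices]
        c[f_atoms] += 0.25
        toy.system.set_coordinates(c)
        rep2 = fd_energy(toy.system, toy_regions, bk, 1.5, "FDD")
        assert bk.n_calls("monomer") == n_mono      # no new QM calls
        assert bk.n_calls("dimer") == n_dim
        d_total = rep2.E_total - rep1.E_total
        d_classical = (sum(rep2.E_es.values()) + rep2.E_pol_tot) \
            - (sum(rep1.E_es.values()) + rep1.E_pol_tot)
        assert d_total == pytest.approx(d_classical, abs=1e-12)

    def test_no_qm_calls_touch_frozen_fragments(self, toy, toy_regions):
        bk = MockBackend()
        fd_energy(toy.system, toy_regions, bk, 1.5, "FDD")
        fd_gradient(toy.system, toy_regions, bk, 1.5, "FDD")
        f_region = toy_regions.frozen
        assert not [f for f in bk.calls["monomer"] if f in f_region]
        assert not [p for p in bk.calls["dimer"]
                    if p[0] in f_region or p[1] in f_region]

    def test_fdd_issues_no_bb_dimer_calls(self, toy, toy_regions):
        bk = MockBackend()
        fd_energy(toy.system, toy_regions, bk, 1.5, "FDD")
        bb = [p for p in bk.calls["dimer"]
              if toy_regions.region_of(p[0]) == "b"
              and toy_regions.region_of(p[1]) == "b"]
        assert bb == []

    def test_invalid_mode_rejected(self, toy, toy_regions):
        with pytest.raises(ValueError, match="mode"):
            fd_energy(toy.system, toy_regions, MockBackend(), 1.5, "FDX")


class TestFDGradient:
    def test_matches_finite_differences_on_toy(self, toy, toy_regions):
        g = fd_gradient(toy.system, toy_regions, MockBackend(), 1.5, "FDD")
        c0 = toy.system.coordinates()
        h = 1e-4
        maxdev = 0.0
        for i in toy_regions.mobile_atoms:
            for a in range(3):
                cp = c0.copy(); cp[i, a] += h / ANGSTROM_TO_BOHR
                cm = c0.copy(); cm[i, a] -= h / ANGSTROM_TO_BOHR
                toy.system.set_coordinates(cp)
                ep = fd_energy(toy.system, toy_regions, MockBackend(),
                               1.5, "FDD").E_total
                toy.system.set_coordinates(cm)
                em = fd_energy(toy.system, toy_regions, MockBackend(),
                               1.5, "FDD").E_total
                maxdev = max(maxdev, abs((ep - em) / (2 * h) - g[i, a]))
        toy.system.set_coordinates(c0)
        assert maxdev < 1e-6

    def test_matches_finite_differences_on_chain_regions(self):
        chain = make_bonded_chain(7, seed=4)
        regions = assign_regions(chain, {3}, R_active=2.0, R_buffer=2.5)
        assert regions.buffer and regions.frozen  # nontrivial partition
        g = fd_gradient(chain, regions, MockBackend(), 1.5, "FDD")
        c0 = chain.coordinates()
        h = 1e-4
        maxdev = 0.0
        for i in regions.mobile_atoms:
            for a in range(3):
                cp = c0.copy(); cp[i, a] += h / ANGSTROM_TO_BOHR
                cm = c0.copy(); cm[i, a] -= h / ANGSTROM_TO_BOHR
                chain.set_coordinates(cp)
                ep = fd_energy(chain, regions, MockBackend(), 1.5,
                               "FDD").E_total
                chain.set_coordinates(cm)
                em = fd_energy(chain, regions, MockBackend(), 1.5,
                               "FDD").E_total
                maxdev = max(maxdev, abs((ep - em) / (2 * h) - g[i, a]))
        chain.set_coordinates(c0)
        assert maxdev < 1e-6

    def test_fd_and_fdd_gradients_agree_on_active_atoms(self, toy,
                                                        toy_regions):
        g_fd = fd_gradient(toy.system, toy_regions, MockBackend(), 1.5, "FD")
        g_fdd = fd_gradient(toy.system, toy_regions, MockBackend(), 1.5, "FDD")
        assert np.abs(g_fd - g_fdd).max() < 1e-8

    def test_frozen_rows_are_zero(self, toy, toy_regions):
        g = fd_gradient(toy.system, toy_regions, MockBackend(), 1.5, "FDD")
        frozen_rows = [i for i in range(toy.system.n_atoms)
                       if i not in toy_regions.mobile_atoms]
        assert not np.any(g[frozen_rows])


class TestRegionReportRoundTrip:
    def test_report_rebuilds_identical_assignment(self, toy, toy_regions):
        import json
        from efmoscan.frozen_domain import regions_from_report
        report = json.loads(json.dumps(toy_regions.report(toy.system)))
        rebuilt = regions_from_report(toy.system, report)
        assert rebuilt.active == toy_regions.active
        assert rebuilt.buffer == toy_regions.buffer
        assert rebuilt.frozen == toy_regions.frozen
        assert rebuilt.frozen_atoms == toy_regions.frozen_atoms
        assert rebuilt.mobile_atoms == toy_regions.mobile_atoms

    def test_report_for_wrong_system_rejected(self, toy):
        from efmoscan.frozen_domain import RegionError, regions_from_report
        from conftest import water_system
        other = water_system([[0, 0, 0], [3.0, 0, 0]], seed=0)
        report = toy.regions().report(toy.system)
        with pytest.raises(RegionError, match="fragment set"):
            regions_from_report(other, report)
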