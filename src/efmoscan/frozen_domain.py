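"""Frozen-domain EFMO: region assignment, E_FD / E_FDD energies, gradients.

For geometry optimization of a local event (an enzyme active site) the
fragment set is partitioned into three regions measured from one or more
target fragments:

* **A** (active): fragments whose atoms are optimized;
* **b** (buffer): frozen fragments close enough to A that their QM pair
  terms with A still matter for the gradient;
* **F** (frozen): the remainder, coupled to everything classically.

The frozen-domain energy keeps the EFMO form inside A and b, treats every
pair with one member in F by classical multipole electrostatics, and drops
the internal energy of F (a constant).  The FDD variant additionally skips
QM dimers with both members in the buffer — their corrections are
constants that contribute nothing to the energy differences or gradients
of A.  F-region multipoles and polarizabilities are computed once at the
start of an optimization session and cached; the many-body polarization
energy still spans the whole system every step.

A shared atom at a region boundary is mobile only when *both* owning
fragments are active; A fragments covalently bonded to F fragments are a
configuration error (F must be separated from A for the classical
treatment of the coupling to be valid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backend import FragmentBackend
from .constants import BOHR_TO_ANGSTROM
from .efmo_core import (BackendSet, DEFAULT_R_RESDIM, _accumulate,
                        _es_pair_gradient, _lower_layer, fragment_statics,
                        select_dimers)
from .polarization import pol_energy_pair, pol_energy_total
from .system_model import MolecularSystem


class RegionError(ValueError):
    """Invalid region configuration (e.g. active bonded to frozen)."""


@dataclass
class RegionAssignment:
    """Partition of fragments into active / buffer / frozen regions."""

    active: set[int]
    buffer: set[int]
    frozen: set[int]
    target: set[int]
    frozen_atoms: set[int]          # per-atom frozen flags
    mobile_atoms: list[int] = field(default_factory=list)
    # frozen-region classical state captured at session start:
    # fragment id -> (q, mu, theta, alpha) values
    statics_cache: dict[int, tuple] = field(default_factory=dict)

    def region_of(self, fragment_id: int) -> str:
        if fragment_id in self.active:
            return "A"
        if fragment_id in self.buffer:
            return "b"
        return "F"

    def reset_cache(self) -> None:
        """Invalidate cached frozen-region moments (new optimization session)."""
        self.statics_cache.clear()

    def report(self, system: MolecularSystem) -> dict:
        """Region report: per-fragment tags and per-region atom counts."""
        per_fragment = {f.id: self.region_of(f.id) for f in system.fragments}
        counts = {"A": 0, "b": 0, "F": 0}
        owner = {}
        for f in system.fragments:
            for i in f.owned_atom_indices:
                owner[i] = f.id
        for i, fid in owner.items():
            counts[self.region_of(fid)] += 1
        return {
            "fragment_regions": per_fragment,
            "atom_counts": counts,
            "n_mobile_atoms": len(self.mobile_atoms),
            "frozen_atoms": sorted(self.frozen_atoms),
            "target": sorted(self.target),
        }


def assign_regions(system: MolecularSystem,
                   target_fragments: set[int] | list[int],
                   R_active: float = 2.0,
                   R_buffer: float = 2.5,
                   extra_frozen: set[int] | None = None) -> RegionAssignment:
    """Assign A/b/F regions by minimum atom-atom distance (Angstrom).

    ``A`` = fragments with an atom within ``R_active`` of any target atom
    (targets included); ``b`` = remaining fragments with an atom within
    ``R_buffer`` of any A atom; ``F`` = the rest.

    ``extra_frozen`` pins individual atoms inside the active region (A may
    contain frozen atoms, e.g. anchors at a truncation boundary).
    """
    if R_active <= 0 or R_buffer <= 0:
        raise ValueError("region radii must be positive")
    if system.fragments is None:
        raise ValueError("system is not fragmented")
    frag_ids = {f.id for f in system.fragments}
    targets = set(target_fragments)
    if not targets <= frag_ids:
        raise RegionError(f"target fragment(s) not found: {sorted(targets - frag_ids)}")

    coords = system.coordinates()
    owned = {f.id: f.owned_atom_indices for f in system.fragments}

    def min_dist(atom_set_a: list[int], atom_set_b: list[int]) -> float:
        d = coords[atom_set_a][:, None, :] - coords[atom_set_b][None, :, :]
        return float(np.sqrt((d ** 2).sum(-1)).min())

    target_atoms = [i for t in targets for i in owned[t]]
    active = set(targets)
    for f in system.fragments:
        if f.id not in active and min_dist(owned[f.id], target_atoms) <= R_active:
            active.add(f.id)

    active_atoms = [i for a in active for i in owned[a]]
    buffer_set: set[int] = set()
    for f in system.fragments:
        if f.id in active:
            continue
        if min_dist(owned[f.id], active_atoms) <= R_buffer:
            buffer_set.add(f.id)
    frozen = frag_ids - active - buffer_set

    frozen_atoms: set[int] = set()
    for f in system.fragments:
        region = "A" if f.id in active else ("b" if f.id in buffer_set else "F")
        for i in f.owned_atom_indices:
            if region != "A":
                frozen_atoms.add(i)
    if extra_frozen:
        frozen_atoms |= set(extra_frozen)
    # shared atoms: mobile only when every owning fragment is active
    membership = system.fragment_of()
    for f in system.fragments:
        for atom_idx, partner in f.shared_atoms:
            owners = membership[atom_idx]
            if not all(fid in active for fid in owners):
                frozen_atoms.add(atom_idx)

    for atom in system.atoms:
        atom.frozen = atom.index in frozen_atoms
    mobile = [a.index for a in system.atoms if not a.frozen]

    regions = RegionAssignment(active, buffer_set, frozen, targets,
                               frozen_atoms, mobile)
    _check_adjacency(system, regions)
    return regions


def regions_from_report(system: MolecularSystem, report: dict
                        ) -> RegionAssignment:
    """Rebuild a region assignment from its report (pins regions across a
    scan or between runs instead of re-deriving them from distances)."""
    tags = {int(k): v for k, v in report["fragment_regions"].items()}
    known = {f.id for f in system.fragments}
    if set(tags) != known:
        raise RegionError("region report does not match the fragment set")
    active = {fid for fid, t in tags.items() if t == "A"}
    buffer_set = {fid for fid, t in tags.items() if t == "b"}
    frozen = {fid for fid, t in tags.items() if t == "F"}
    frozen_atoms = set(report["frozen_atoms"])
    for atom in system.atoms:
        atom.frozen = atom.index in frozen_atoms
    mobile = [a.index for a in system.atoms if not a.frozen]
    regions = RegionAssignment(active, buffer_set, frozen,
                               set(report.get("target", [])) or set(active),
                               frozen_atoms, mobile)
    _check_adjacency(system, regions)
    return regions


def _check_adjacency(system: MolecularSystem, regions: RegionAssignment) -> None:
    for f in system.fragments:
        if f.id not in regions.active:
            continue
        for _, partner in f.shared_atoms:
            if partner in regions.frozen:
                raise RegionError(
                    f"active fragment {f.id} is covalently bonded to frozen "
                    f"fragment {partner}; enlarge the buffer so A and F are "
                    f"separated")


@dataclass
class FDEnergyReport:
    """Decomposed frozen-domain energy (hartree)."""

    E_total: float
    mode: str                                  # "FD" or "FDD"
    E_monomers: dict[int, float]               # A and b fragments
    dE_dimer: dict[tuple[int, int], float]     # QM-corrected pairs
    E_es: dict[tuple[int, int], float]         # classical pairs
    E_pol_pairs: dict[tuple[int, int], float]
    E_pol_tot: float
    skipped_bb_pairs: list[tuple[int, int]]    # near b-b pairs dropped in FDD
    pair_layer: dict[tuple[int, int], str] = field(default_factory=dict)

    def check_consistency(self, tol: float = 1e-10) -> None:
        total = (sum(self.E_monomers.values()) + sum(self.dE_dimer.values())
                 + sum(self.E_es.values()) + self.E_pol_tot)
        if abs(total - self.E_total) > tol:
            raise AssertionError("frozen-domain decomposition inconsistent")


def _classify_pairs(system: MolecularSystem, regions: RegionAssignment,
                    R_resdim: float, mode: str):
    """Sort fragment pairs into QM, classical-ES, skipped-constant buckets."""
    near, far = select_dimers(system, R_resdim)
    frags = {f.id: f for f in system.fragments}
    qm, classical, skipped_bb, dropped = [], [], [], []
    for pair in near + far:
        i, j = pair
        ri, rj = regions.region_of(i), regions.region_of(j)
        is_near = pair in near
        bonded = bool(set(frags[i].atom_indices) & set(frags[j].atom_indices))
        if ri == "F" and rj == "F":
            dropped.append(pair)                    # constant, neglected
        elif "F" in (ri, rj):
            other = rj if ri == "F" else ri
            if bonded and other == "A":
                raise RegionError(
                    f"active fragment bonded to frozen fragment in pair {pair}")
            if bonded:                              # b-F bonded: constant
                dropped.append(pair)
            else:
                classical.append(pair)              # always classical with F
        elif ri == "b" and rj == "b":
            if is_near:
                if mode == "FDD":
                    skipped_bb.append(pair)         # the FDD approximation
                else:
                    qm.append(pair)
            else:
                classical.append(pair)
        else:                                       # at least one in A
            (qm if is_near else classical).append(pair)
    return qm, classical, skipped_bb, dropped


def fd_energy(system: MolecularSystem,
              regions: RegionAssignment,
              backends: FragmentBackend | dict[str, FragmentBackend],
              R_resdim: float = DEFAULT_R_RESDIM,
              mode: str = "FDD",
              pol_tol: float = 1e-8) -> FDEnergyReport:
    """Frozen-domain EFMO energy (E_FD or E_FDD).

    With empty buffer and frozen regions this reduces exactly to
    :func:`efmo_core.efmo_energy`.
    """
    if mode not in ("FD", "FDD"):
        raise ValueError("mode must be 'FD' or 'FDD'")
    bset = BackendSet(backends) if not isinstance(backends, BackendSet) else backends
    frags = {f.id: f for f in system.fragments}

    # frozen-region moments come from the session cache (no new QM calls)
    cache = regions.statics_cache
    non_frozen = {fid for fid in frags if regions.region_of(fid) != "F"}
    live_cache = {fid: v for fid, v in cache.items() if fid not in non_frozen}
    statics = fragment_statics(system, bset, cache=live_cache)
    for fid, v in live_cache.items():
        cache[fid] = v

    qm_pairs, classical, skipped_bb, _ = _classify_pairs(
        system, regions, R_resdim, mode)

    E_monomers = {
        fid: bset.for_layer(frags[fid].layer).monomer(frags[fid], system).energy
        for fid in frags if regions.region_of(fid) != "F"
    }
    dE_dimer: dict[tuple[int, int], float] = {}
    E_pol_pairs: dict[tuple[int, int], float] = {}
    pair_layer: dict[tuple[int, int], str] = {}
    for i, j in qm_pairs:
        layer = _lower_layer(frags[i].layer, frags[j].layer)
        b = bset.for_layer(layer)
        pair_layer[(i, j)] = layer
        e_ij = b.dimer(frags[i], frags[j], system).energy
        e_i = b.monomer(frags[i], system).energy
        e_j = b.monomer(frags[j], system).energy
        e_pol_ij = pol_energy_pair(statics[i], statics[j], pol_tol)
        E_pol_pairs[(i, j)] = e_pol_ij
        dE_dimer[(i, j)] = (e_ij - e_i - e_j) - e_pol_ij

    from .electrostatics import pair_es_energy
    E_es = {
        (i, j): pair_es_energy(statics[i].multipoles, statics[j].multipoles)
        for i, j in classical
    }
    E_pol_tot = pol_energy_total(list(statics.values()), pol_tol) \
        if len(statics) > 1 else 0.0

    E_total = (sum(E_monomers.values()) + sum(dE_dimer.values())
               + sum(E_es.values()) + E_pol_tot)
    report = FDEnergyReport(E_total, mode, E_monomers, dE_dimer, E_es,
                            E_pol_pairs, E_pol_tot, skipped_bb, pair_layer)
    report.check_consistency()
    return report


def fd_gradient(system: MolecularSystem,
                regions: RegionAssignment,
                backends: FragmentBackend | dict[str, FragmentBackend],
                R_resdim: float = DEFAULT_R_RESDIM,
                mode: str = "FDD",
                pol_tol: float = 1e-8) -> np.ndarray:
    """Frozen-domain gradient on mobile atoms, (n_atoms, 3) hartree/bohr.

    Rows of frozen atoms are zero.  Terms that cannot touch a mobile atom
    (buffer-buffer dimer corrections, classical pairs among b and F) are
    skipped; this is exact, not an approximation, because those terms
    depend only on frozen coordinates.
    """
    if mode not in ("FD", "FDD"):
        raise ValueError("mode must be 'FD' or 'FDD'")
    bset = BackendSet(backends) if not isinstance(backends, BackendSet) else backends
    frags = {f.id: f for f in system.fragments}
    cache = regions.statics_cache
    non_frozen = {fid for fid in frags if regions.region_of(fid) != "F"}
    live_cache = {fid: v for fid, v in cache.items() if fid not in non_frozen}
    statics = fragment_statics(system, bset, cache=live_cache)

    qm_pairs, classical, _, _ = _classify_pairs(system, regions, R_resdim, mode)
    n = system.n_atoms
    total = np.zeros((n, 3))
    mobile = set(system.atoms[i].index for i in regions.mobile_atoms)

    def touches_mobile(fid: int) -> bool:
        # via caps, a fragment's energy can depend on bond partners outside
        # its roster; include one bond shell around the roster
        roster = set(frags[fid].atom_indices)
        if roster & mobile:
            return True
        for a, b in system.bonds:
            if (a in roster and b in mobile) or (b in roster and a in mobile):
                return True
        return False

    for fid in frags:
        if regions.region_of(fid) == "F":
            continue
        if touches_mobile(fid):
            b = bset.for_layer(frags[fid].layer)
            _accumulate(total, b.monomer(frags[fid], system).gradient)
    for i, j in qm_pairs:
        if not (touches_mobile(i) or touches_mobile(j)):
            continue
        b = bset.for_layer(_lower_layer(frags[i].layer, frags[j].layer))
        _accumulate(total, b.dimer(frags[i], frags[j], system).gradient)
        _accumulate(total, b.monomer(frags[i], system).gradient, -1.0)
        _accumulate(total, b.monomer(frags[j], system).gradient, -1.0)
    for i, j in classical:
        ri, rj = regions.region_of(i), regions.region_of(j)
        if ri != "A" and rj != "A":
            continue
        _es_pair_gradient(total, statics[i], statics[j], frags[i], frags[j])

    polarizable = any(not s.polarizabilities.is_zero for s in statics.values())
    if polarizable and len(frags) > 1:
        from .efmo_core import _pol_fd_gradient

        def e_pol_terms() -> float:
            lc = {fid: v for fid, v in cache.items() if fid not in non_frozen}
            st = fragment_statics(system, bset, cache=lc)
            e = pol_energy_total(list(st.values()), pol_tol)
            for i, j in qm_pairs:
                e -= pol_energy_pair(st[i], st[j], pol_tol)
            return e
        total += _pol_fd_gradient(system, bset, e_pol_terms,
                                  sorted(mobile))

    total[[i for i in range(n) if i not in mobile]] = 0.0
    return total
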