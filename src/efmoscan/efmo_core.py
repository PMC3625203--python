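"""Assembly of the full EFMO energy and gradient.

The EFMO total energy of N fragments is

    E = sum_I E_I
      + sum_{R_IJ < R_resdim} [ (E_IJ - E_I - E_J) - E_pol,IJ ]
      + sum_{R_IJ >= R_resdim} E_ES,IJ
      + E_pol,tot

Monomer and near-dimer energies come from the backend; distant pairs
interact through classical multipole electrostatics; the many-body
polarization energy of the whole system is added once, with the
double-counted pair induction removed from each QM dimer correction.
Fragment pairs connected by a covalent bond (shared atoms) are always
treated as near pairs regardless of ``R_IJ``.

Multilayer runs tag fragments with a layer; a pair spanning two layers is
computed at the lower layer (standard multilayer FMO convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backend import FragmentBackend
from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM
from .electrostatics import pair_es_energy, pair_es_gradient
from .polarization import (FragmentStatics, pol_energy_pair, pol_energy_total,
                           solve_induced)
from .system_model import Fragment, MolecularSystem, interfragment_distance

DEFAULT_R_RESDIM = 1.5  # unitless interfragment-distance threshold

_LAYER_RANK = {"low": 0, "high": 1}


def _lower_layer(a: str | None, b: str | None) -> str:
    a = a or "low"
    b = b or "low"
    return a if _LAYER_RANK.get(a, 0) <= _LAYER_RANK.get(b, 0) else b


class BackendSet:
    """One backend per layer; a plain backend means a single layer."""

    def __init__(self, backends: FragmentBackend | dict[str, FragmentBackend]):
        if isinstance(backends, dict):
            self._by_layer = dict(backends)
        else:
            self._by_layer = {"low": backends, "high": backends}

    def for_layer(self, layer: str | None) -> FragmentBackend:
        return self._by_layer[layer or "low"]

    def all(self) -> list[FragmentBackend]:
        seen, out = set(), []
        for b in self._by_layer.values():
            if id(b) not in seen:
                seen.add(id(b))
                out.append(b)
        return out


@dataclass
class EnergyReport:
    """Fully decomposed EFMO energy (hartree) and optional gradient."""

    E_total: float
    E_monomers: dict[int, float]
    dE_dimer: dict[tuple[int, int], float]
    E_es_far: dict[tuple[int, int], float]
    E_pol_pairs: dict[tuple[int, int], float]
    E_pol_tot: float
    near_pairs: list[tuple[int, int]]
    far_pairs: list[tuple[int, int]]
    pair_layer: dict[tuple[int, int], str] = field(default_factory=dict)
    gradient: np.ndarray | None = None

    def check_consistency(self, tol: float = 1e-10) -> None:
        total = (sum(self.E_monomers.values()) + sum(self.dE_dimer.values())
                 + sum(self.E_es_far.values()) + self.E_pol_tot)
        if abs(total - self.E_total) > tol:
            raise AssertionError(
                f"decomposition sums to {total!r}, total is {self.E_total!r}")


def select_dimers(system: MolecularSystem, R_resdim: float
                  ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Classify every unordered fragment pair as near (QM) or far (classical).

    Near means ``R_IJ < R_resdim``; covalently bonded pairs (shared atoms)
    are forced into the near list.  Ordering is deterministic (I < J).
    """
    frags = system.fragments
    if not frags:
        raise ValueError("system is not fragmented")
    near, far = [], []
    for x in range(len(frags)):
        for y in range(x + 1, len(frags)):
            I, J = frags[x], frags[y]
            pair = (I.id, J.id)
            bonded = bool(set(I.atom_indices) & set(J.atom_indices))
            if bonded or (R_resdim > 0
                          and interfragment_distance(I, J, system) < R_resdim):
                near.append(pair)
            else:
                far.append(pair)
    return near, far


def fragment_statics(system: MolecularSystem, backends: BackendSet,
                     cache: dict | None = None) -> dict[int, FragmentStatics]:
    """Per-fragment multipoles/polarizabilities at each fragment's own layer.

    ``cache`` maps fragment id -> (q, mu, theta, alpha) *values* captured
    earlier (frozen-region moments); positions always track the current
    geometry.
    """
    out: dict[int, FragmentStatics] = {}
    for frag in system.fragments:
        if cache is not None and frag.id in cache:
            from .electrostatics import MultipoleSet
            from .polarization import PolarizabilitySet
            q, mu, theta, alpha = cache[frag.id]
            pos = system.coordinates()[frag.owned_atom_indices] * ANGSTROM_TO_BOHR
            mset = MultipoleSet(pos, q, mu, theta)
            pset = PolarizabilitySet(pos, alpha)
        else:
            backend = backends.for_layer(frag.layer)
            mset, pset = backend.moments(frag, system)
            if cache is not None:
                cache[frag.id] = (mset.q.copy(), mset.mu.copy(),
                                  mset.theta.copy(), pset.alpha.copy())
        out[frag.id] = FragmentStatics(frag.id, mset, pset)
    return out


def assign_layers(system: MolecularSystem,
                  high_fragments: set[int]) -> MolecularSystem:
    """Tag fragments as high/low layer; an empty high set means all-low."""
    known = {f.id for f in system.fragments}
    missing = set(high_fragments) - known
    if missing:
        raise ValueError(f"unknown fragment ids in high layer: {sorted(missing)}")
    for frag in system.fragments:
        frag.layer = "high" if frag.id in high_fragments else "low"
    return system


def efmo_energy(system: MolecularSystem,
                backends: FragmentBackend | dict[str, FragmentBackend],
                R_resdim: float = DEFAULT_R_RESDIM,
                pol_tol: float = 1e-8) -> EnergyReport:
    """The EFMO total energy with full decomposition."""
    bset = BackendSet(backends) if not isinstance(backends, BackendSet) else backends
    frags = {f.id: f for f in system.fragments}
    statics = fragment_statics(system, bset)
    near, far = select_dimers(system, R_resdim)

    E_monomers = {
        fid: bset.for_layer(frags[fid].layer).monomer(frags[fid], system).energy
        for fid in frags
    }
    dE_dimer: dict[tuple[int, int], float] = {}
    E_pol_pairs: dict[tuple[int, int], float] = {}
    pair_layer: dict[tuple[int, int], str] = {}
    for i, j in near:
        layer = _lower_layer(frags[i].layer, frags[j].layer)
        b = bset.for_layer(layer)
        pair_layer[(i, j)] = layer
        e_ij = b.dimer(frags[i], frags[j], system).energy
        e_i = b.monomer(frags[i], system).energy
        e_j = b.monomer(frags[j], system).energy
        e_pol_ij = pol_energy_pair(statics[i], statics[j], pol_tol)
        E_pol_pairs[(i, j)] = e_pol_ij
        dE_dimer[(i, j)] = (e_ij - e_i - e_j) - e_pol_ij

    E_es_far = {
        (i, j): pair_es_energy(statics[i].multipoles, statics[j].multipoles)
        for i, j in far
    }
    E_pol_tot = pol_energy_total(list(statics.values()), pol_tol) \
        if len(statics) > 1 else 0.0

    E_total = (sum(E_monomers.values()) + sum(dE_dimer.values())
               + sum(E_es_far.values()) + E_pol_tot)
    report = EnergyReport(E_total, E_monomers, dE_dimer, E_es_far, E_pol_pairs,
                          E_pol_tot, near, far, pair_layer)
    report.check_consistency()
    return report


# --------------------------------------------------------------------------
# gradient
# --------------------------------------------------------------------------

def _accumulate(total: np.ndarray, grad: dict[int, np.ndarray],
                sign: float = 1.0) -> None:
    for idx, g in grad.items():
        total[idx] += sign * g


def _es_pair_gradient(total: np.ndarray, stat_i: FragmentStatics,
                      stat_j: FragmentStatics, frag_i: Fragment,
                      frag_j: Fragment) -> None:
    g_i, g_j = pair_es_gradient(stat_i.multipoles, stat_j.multipoles)
    for row, atom in zip(g_i, frag_i.owned_atom_indices):
        total[atom] += row
    for row, atom in zip(g_j, frag_j.owned_atom_indices):
        total[atom] += row


def _pol_fd_gradient(system: MolecularSystem, bset: BackendSet,
                     statics_fn, atoms: list[int],
                     h_bohr: float = 1e-5) -> np.ndarray:
    """Central finite differences of a polarization energy w.r.t. atoms.

    ``statics_fn()`` must rebuild statics from the *current* coordinates
    and return the polarization energy.  Analytic response gradients are
    out of scope; with the default alpha = 0 mock this is skipped entirely.
    """
    n = system.n_atoms
    grad = np.zeros((n, 3))
    h_ang = h_bohr * BOHR_TO_ANGSTROM
    coords0 = system.coordinates()
    for i in atoms:
        for a in range(3):
            for sgn in (1.0, -1.0):
                c = coords0.copy()
                c[i, a] += sgn * h_ang
                system.set_coordinates(c)
                grad[i, a] += sgn * statics_fn()
        system.set_coordinates(coords0)
        grad[i] /= 2.0 * h_bohr
    return grad


def efmo_gradient(system: MolecularSystem,
                  backends: FragmentBackend | dict[str, FragmentBackend],
                  R_resdim: float = DEFAULT_R_RESDIM,
                  pol_tol: float = 1e-8) -> np.ndarray:
    """Analytic EFMO gradient, (n_atoms, 3) in hartree/bohr.

    Backend terms are analytic; far-pair electrostatics use the
    frozen-moment complex-step gradient; polarization terms (if any sites
    are polarizable) use central finite differences of E_pol.
    """
    bset = BackendSet(backends) if not isinstance(backends, BackendSet) else backends
    frags = {f.id: f for f in system.fragments}
    statics = fragment_statics(system, bset)
    near, far = select_dimers(system, R_resdim)
    n = system.n_atoms
    total = np.zeros((n, 3))

    for fid, frag in frags.items():
        b = bset.for_layer(frag.layer)
        _accumulate(total, b.monomer(frag, system).gradient)
    for i, j in near:
        b = bset.for_layer(_lower_layer(frags[i].layer, frags[j].layer))
        _accumulate(total, b.dimer(frags[i], frags[j], system).gradient)
        _accumulate(total, b.monomer(frags[i], system).gradient, -1.0)
        _accumulate(total, b.monomer(frags[j], system).gradient, -1.0)
    for i, j in far:
        _es_pair_gradient(total, statics[i], statics[j], frags[i], frags[j])

    polarizable = any(not s.polarizabilities.is_zero for s in statics.values())
    if polarizable and len(frags) > 1:
        def e_pol_terms() -> float:
            st = fragment_statics(system, bset)
            e = pol_energy_total(list(st.values()), pol_tol)
            for i, j in near:
                e -= pol_energy_pair(st[i], st[j], pol_tol)
            return e
        total += _pol_fd_gradient(system, bset, e_pol_terms, list(range(n)))

    return total
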