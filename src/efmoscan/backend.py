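"""Fragment-energy backend contract and the deterministic mock engine.

EFMO needs four things from an electronic-structure engine: monomer
energies/gradients, dimer energies/gradients, distributed multipoles and
distributed polarizabilities.  This module defines that contract
(:class:`FragmentBackend`) and provides a pure, analytic mock engine so the
whole EFMO formalism is testable at desk scale.

The mock "QM" energy of any atom roster is a tiny classical model::

    E = sum_bonds 1/2 k_b (r - r0)^2
      + sum_angles 1/2 k_theta (theta - theta0)^2
      + sum_nonbonded [ 4 eps ((sigma/r)^12 - (sigma/r)^6) + q_i q_j / r ]

with r in bohr, charges in e and energies in hartree.  Equilibrium bond
lengths come from the covalent-radius table; 1-2 and 1-3 pairs are
excluded from the nonbonded sum.  Element charges are neutralized per
fragment so every fragment carries exactly its integer net charge.  The
reported multipoles are exactly these point charges (dipoles and
quadrupoles zero); polarizabilities are per-element isotropic constants,
zero by default and nonzero in the ``mock-pol`` variant.

Covalent cuts are realized with hydrogen link atoms ("caps") placed along
the severed bond; gradients are projected back onto the real atoms by the
chain rule through the cap position.  In dimer calculations the caps of
one fragment do not interact with the other fragment: a cap models the
local severed bond, and keeping it out of the cross-fragment sums makes
dimer corrections depend only on the two fragments' own atoms (which in
turn keeps frozen-region dimers exactly constant when only distant atoms
move).
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR, covalent_radius
from .electrostatics import MultipoleSet
from .polarization import PolarizabilitySet
from .system_model import Fragment, MolecularSystem

# one versioned table of every mock-model constant
MOCK_CONSTANTS: dict = {
    "version": 1,
    "k_bond": 0.5,            # hartree / bohr^2
    "k_angle": 0.1,           # hartree / rad^2
    "lj_epsilon": 3.0e-4,     # hartree
    "lj_sigma": 3.0,          # bohr
    "theta0_oxygen": math.radians(104.52),
    "theta0_default": math.radians(109.47122),
    "charges": {"O": -0.8, "H": 0.4, "C": 0.0, "N": -0.4},  # e, pre-neutralization
    # isotropic site polarizabilities for the "mock-pol" variant, bohr^3;
    # deliberately small so bare (undamped) induced-dipole coupling stays
    # far from the polarization catastrophe at bonded distances
    "polarizabilities": {"H": 0.4, "C": 1.2, "N": 1.0, "O": 0.8},
    "d_cap": 1.09,            # Angstrom, link-atom bond length
}


@dataclass(frozen=True)
class LevelSpec:
    """A named level of theory.  The mock engine ignores ``basis``."""

    method: str = "mock"
    basis: str = ""
    role: str = "low"
    params: tuple = ()  # extra backend kwargs as a sorted tuple of items

    def label(self) -> str:
        return f"{self.method}/{self.basis}" if self.basis else self.method


@dataclass
class BackendResult:
    """Energy (hartree) and gradient (hartree/bohr) of one calculation.

    ``gradient`` maps *original* atom indices to 3-vectors; cap
    contributions have already been projected back through the chain rule,
    so the map can include the cap's outside bond partner.
    """

    energy: float
    gradient: dict[int, np.ndarray]
    multipoles: MultipoleSet | None = None
    polarizabilities: PolarizabilitySet | None = None


@dataclass
class CappedFragment:
    """A fragment roster plus hydrogen caps on its severed bonds."""

    atom_indices: list[int]                   # original indices, deduplicated
    caps: list[tuple[int, int]]               # (inside atom, outside atom)
    d_cap: float                              # Angstrom

    @property
    def n_real(self) -> int:
        return len(self.atom_indices)

    def positions(self, system: MolecularSystem) -> np.ndarray:
        """Capped-roster coordinates in Angstrom (real atoms then caps)."""
        coords = system.coordinates()
        real = coords[self.atom_indices]
        caps = []
        for a, b in self.caps:
            delta = coords[b] - coords[a]
            norm = np.linalg.norm(delta)
            if norm == 0.0:
                raise ValueError(f"coincident atoms {a} and {b} on a severed bond")
            caps.append(coords[a] + self.d_cap * delta / norm)
        if caps:
            return np.vstack([real, np.array(caps)])
        return real

    def project_gradient(self, system: MolecularSystem,
                         grad_capped: np.ndarray) -> dict[int, np.ndarray]:
        """Chain-rule a capped-roster gradient back onto original atoms."""
        out: dict[int, np.ndarray] = {}
        for local, orig in enumerate(self.atom_indices):
            out[orig] = out.get(orig, 0.0) + grad_capped[local]
        coords = system.coordinates()
        for k, (a, b) in enumerate(self.caps):
            g_cap = grad_capped[self.n_real + k]
            delta = coords[b] - coords[a]
            norm = np.linalg.norm(delta)
            u = delta / norm
            # cap = a + d (b - a)/|b - a|  (d, positions in Angstrom; the
            # Jacobian is dimensionless so it applies to bohr gradients too)
            perp = (self.d_cap / norm) * (np.eye(3) - np.outer(u, u))
            out[a] = out.get(a, 0.0) + (np.eye(3) - perp) @ g_cap
            out[b] = out.get(b, 0.0) + perp @ g_cap
        return {i: np.asarray(g, float) for i, g in out.items()}


def cap_fragment(fragment: Fragment, system: MolecularSystem,
                 d_cap: float = MOCK_CONSTANTS["d_cap"]) -> CappedFragment:
    """Cap every bond from the fragment roster to the outside with H."""
    roster = set(fragment.atom_indices)
    caps = [
        (a, b) if a in roster else (b, a)
        for a, b in sorted(system.bonds)
        if (a in roster) != (b in roster)
    ]
    return CappedFragment(sorted(roster), caps, d_cap)


def _cap_union(rosters: list[list[int]], system: MolecularSystem,
               d_cap: float) -> CappedFragment:
    union = sorted(set().union(*map(set, rosters)))
    uset = set(union)
    caps = [
        (a, b) if a in uset else (b, a)
        for a, b in sorted(system.bonds)
        if (a in uset) != (b in uset)
    ]
    return CappedFragment(union, caps, d_cap)


# --------------------------------------------------------------------------
# the mock potential on a fixed roster/topology
# --------------------------------------------------------------------------

class _MockPotential:
    """Vectorized mock energy/gradient for one capped roster.

    Topology (bonds, angles, nonbonded pair list) is fixed at construction;
    only coordinates vary between calls.
    """

    def __init__(self, elements: list[str], bonds: list[tuple[int, int]],
                 charges: np.ndarray, k_bond: float,
                 excluded_pairs: set[tuple[int, int]] | None = None):
        c = MOCK_CONSTANTS
        n = len(elements)
        self.k_bond = k_bond
        self.k_angle = c["k_angle"]
        self.eps = c["lj_epsilon"]
        self.sigma = c["lj_sigma"]
        self.charges = np.asarray(charges, float)

        self.bond_idx = np.array(sorted(bonds), dtype=int).reshape(-1, 2)
        self.bond_r0 = np.array([
            (covalent_radius(elements[i]) + covalent_radius(elements[j]))
            * ANGSTROM_TO_BOHR
            for i, j in self.bond_idx
        ])

        neigh: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, j in self.bond_idx:
            neigh[int(i)].append(int(j))
            neigh[int(j)].append(int(i))
        angles = []
        for j in range(n):
            nb = sorted(neigh[j])
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    angles.append((nb[x], j, nb[y]))
        self.angle_idx = np.array(angles, dtype=int).reshape(-1, 3)
        self.angle_t0 = np.array([
            c["theta0_oxygen"] if elements[j] == "O" else c["theta0_default"]
            for _, j, _ in self.angle_idx
        ])

        bonded = {tuple(sorted(b)) for b in map(tuple, self.bond_idx)}
        onethree = set()
        for i, j, k in self.angle_idx:
            onethree.add(tuple(sorted((int(i), int(k)))))
        excluded = excluded_pairs or set()
        nb_pairs = [
            (i, j) for i in range(n) for j in range(i + 1, n)
            if (i, j) not in bonded and (i, j) not in onethree
            and (i, j) not in excluded
        ]
        self.nb_idx = np.array(nb_pairs, dtype=int).reshape(-1, 2)
        self.nb_qq = (self.charges[self.nb_idx[:, 0]]
                      * self.charges[self.nb_idx[:, 1]]) if len(nb_pairs) else \
            np.empty(0)

    def energy_gradient(self, coords_bohr: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords_bohr, float)
        energy = 0.0
        grad = np.zeros_like(x)

        if len(self.bond_idx):
            i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.bond_r0
            energy += 0.5 * self.k_bond * float(dr @ dr)
            f = (self.k_bond * dr / r)[:, None] * d
            np.add.at(grad, i, f)
            np.add.at(grad, j, -f)

        for ia, ja, ka, t0 in zip(self.angle_idx[:, 0], self.angle_idx[:, 1],
                                  self.angle_idx[:, 2], self.angle_t0):
            u = x[ia] - x[ja]
            v = x[ka] - x[ja]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            cos_t = np.clip(u @ v / (nu * nv), -1.0, 1.0)
            theta = math.acos(cos_t)
            dt = theta - t0
            energy += 0.5 * self.k_angle * dt * dt
            sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-14))
            uh, vh = u / nu, v / nv
            dth_di = (cos_t * uh - vh) / (nu * sin_t)
            dth_dk = (cos_t * vh - uh) / (nv * sin_t)
            pref = self.k_angle * dt
            grad[ia] += pref * dth_di
            grad[ka] += pref * dth_dk
            grad[ja] -= pref * (dth_di + dth_dk)

        if len(self.nb_idx):
            i, j = self.nb_idx[:, 0], self.nb_idx[:, 1]
            d = x[i] - x[j]
            r2 = (d * d).sum(1)
            r = np.sqrt(r2)
            s6 = (self.sigma ** 2 / r2) ** 3
            energy += float(np.sum(4.0 * self.eps * (s6 * s6 - s6)))
            energy += float(np.sum(self.nb_qq / r))
            # dE/dr for LJ and Coulomb
            dEdr = (4.0 * self.eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
                    - self.nb_qq / r2)
            f = (dEdr / r)[:, None] * d
            np.add.at(grad, i, f)
            np.add.at(grad, j, -f)

        return energy, grad


def neutralized_charges(elements: list[str], groups: np.ndarray,
                        group_net: dict[int, float]) -> np.ndarray:
    """Per-element base charges shifted so each group sums to its net charge."""
    base = MOCK_CONSTANTS["charges"]
    q = np.array([base.get(el, 0.0) for el in elements], float)
    for g, net in group_net.items():
        mask = groups == g
        n = int(mask.sum())
        if n:
            q[mask] += (net - q[mask].sum()) / n
    return q


# --------------------------------------------------------------------------
# backend contract
# --------------------------------------------------------------------------

class FragmentBackend(ABC):
    """What EFMO requires of any electronic-structure engine.

    An adapter for a real SCF engine implements these four calls, returns
    hartree / hartree-per-bohr, and plugs into the registry.  The contract
    leaves the bond-detachment scheme to the engine (the mock uses link
    atoms; a frozen-bond-orbital engine would need no caps).
    """

    @abstractmethod
    def monomer(self, fragment: Fragment, system: MolecularSystem) -> BackendResult:
        """Gas-phase energy and gradient of one capped fragment."""

    @abstractmethod
    def dimer(self, I: Fragment, J: Fragment,
              system: MolecularSystem) -> BackendResult:
        """Energy and gradient of the deduplicated, capped union of I and J."""

    @abstractmethod
    def moments(self, fragment: Fragment, system: MolecularSystem
                ) -> tuple[MultipoleSet, PolarizabilitySet]:
        """Distributed multipoles and polarizabilities at the owned atoms."""


class MockBackend(FragmentBackend):
    """The analytic mock engine (pure: identical inputs give identical bits).

    Parameters
    ----------
    polarizable:
        If true ("mock-pol"), report the nonzero per-element isotropic
        polarizabilities from :data:`MOCK_CONSTANTS`.
    k_bond:
        Harmonic bond constant override (hartree/bohr^2), used by tests
        that need a stiffer "high level".
    energy_shift:
        Constant added to every energy (hartree); models a level offset.
    """

    def __init__(self, polarizable: bool = False,
                 k_bond: float = MOCK_CONSTANTS["k_bond"],
                 energy_shift: float = 0.0,
                 d_cap: float = MOCK_CONSTANTS["d_cap"]):
        self.polarizable = polarizable
        self.k_bond = k_bond
        self.energy_shift = energy_shift
        self.d_cap = d_cap
        self._cache: dict = {}
        self.calls: dict[str, list] = {"monomer": [], "dimer": [], "moments": []}

    # -- bookkeeping --------------------------------------------------------

    def reset_counters(self) -> None:
        self.calls = {"monomer": [], "dimer": [], "moments": []}

    def n_calls(self, kind: str) -> int:
        return len(self.calls[kind])

    def _cache_key(self, kind: str, ids: tuple, system: MolecularSystem,
                   atom_indices: list[int]) -> tuple:
        coords = system.coordinates()[atom_indices]
        return (kind, ids, tuple(atom_indices), coords.tobytes())

    # -- contract -----------------------------------------------------------

    def monomer(self, fragment: Fragment, system: MolecularSystem) -> BackendResult:
        capped = cap_fragment(fragment, system, self.d_cap)
        key = self._cache_key("monomer", (fragment.id,), system,
                              self._dependency_roster(capped))
        if key in self._cache:
            return self._cache[key]
        self.calls["monomer"].append(fragment.id)
        result = self._evaluate([capped], [fragment], system)
        self._cache[key] = result
        return result

    def dimer(self, I: Fragment, J: Fragment,
              system: MolecularSystem) -> BackendResult:
        if I.id == J.id:
            raise ValueError("a dimer requires two distinct fragments")
        a, b = (I, J) if I.id < J.id else (J, I)
        capped = _cap_union([a.atom_indices, b.atom_indices], system, self.d_cap)
        key = self._cache_key("dimer", (a.id, b.id), system,
                              self._dependency_roster(capped))
        if key in self._cache:
            return self._cache[key]
        self.calls["dimer"].append((a.id, b.id))
        result = self._evaluate([capped], [a, b], system)
        self._cache[key] = result
        return result

    def moments(self, fragment: Fragment, system: MolecularSystem
                ) -> tuple[MultipoleSet, PolarizabilitySet]:
        owned = fragment.owned_atom_indices
        key = self._cache_key("moments", (fragment.id,), system, owned)
        if key in self._cache:
            return self._cache[key]
        self.calls["moments"].append(fragment.id)
        elements = [system.atoms[i].element for i in owned]
        q = neutralized_charges(elements, np.zeros(len(owned), int),
                                {0: float(fragment.net_charge)})
        positions = system.coordinates()[owned] * ANGSTROM_TO_BOHR
        mset = MultipoleSet.point_charges(positions, q)
        alphas = np.zeros((len(owned), 3, 3))
        if self.polarizable:
            table = MOCK_CONSTANTS["polarizabilities"]
            for k, el in enumerate(elements):
                alphas[k] = np.eye(3) * table.get(el, 0.0)
        pset = PolarizabilitySet(positions, alphas)
        result = (mset, pset)
        self._cache[key] = result
        return result

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _dependency_roster(capped: CappedFragment) -> list[int]:
        """All original atoms the calculation depends on (incl. cap partners)."""
        deps = set(capped.atom_indices)
        for a, b in capped.caps:
            deps.add(b)
        return sorted(deps)

    def _evaluate(self, capped_list: list[CappedFragment],
                  fragments: list[Fragment],
                  system: MolecularSystem) -> BackendResult:
        capped = capped_list[0]
        n_real, n_cap = capped.n_real, len(capped.caps)
        n_total = n_real + n_cap
        elements = [system.atoms[i].element for i in capped.atom_indices]
        elements += ["H"] * n_cap

        # group atoms per fragment for charge neutralization; shared atoms
        # go with their owner (ties break to the lower fragment id)
        groups = np.zeros(n_total, int)
        group_net: dict[int, float] = {}
        if len(fragments) == 1:
            group_net[0] = float(fragments[0].net_charge)
        else:
            local = {orig: k for k, orig in enumerate(capped.atom_indices)}
            for g, frag in enumerate(fragments):
                group_net[g] = float(frag.net_charge)
            for orig, k in local.items():
                owners = [g for g, f in enumerate(fragments)
                          if orig in f.atom_indices and orig not in f.guest_atoms]
                members = [g for g, f in enumerate(fragments)
                           if orig in f.atom_indices]
                groups[k] = (owners or members)[0]
            for c, (a, _) in enumerate(capped.caps):
                groups[n_real + c] = groups[local[a]]
        charges = neutralized_charges(elements, groups, group_net)

        # roster topology: internal bonds plus cap bonds
        local = {orig: k for k, orig in enumerate(capped.atom_indices)}
        bonds = [(local[a], local[b]) for a, b in system.bonds
                 if a in local and b in local]
        for c, (a, _) in enumerate(capped.caps):
            bonds.append((local[a], n_real + c))

        # caps never interact across fragments (see module docstring)
        excluded: set[tuple[int, int]] = set()
        if len(fragments) > 1 and n_cap:
            for c in range(n_cap):
                ci = n_real + c
                for k in range(n_total):
                    if k != ci and groups[k] != groups[ci]:
                        excluded.add((min(ci, k), max(ci, k)))

        pot = _MockPotential(elements, bonds, charges, self.k_bond, excluded)
        coords = capped.positions(system) * ANGSTROM_TO_BOHR
        energy, grad = pot.energy_gradient(coords)
        energy += self.energy_shift
        gradient = capped.project_gradient(system, grad)
        return BackendResult(energy=energy, gradient=gradient)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

_REGISTRY: dict[str, type] = {}


def register_backend(name: str, cls: type) -> None:
    _REGISTRY[name] = cls


def make_backend(level: LevelSpec) -> FragmentBackend:
    """Instantiate the backend named by ``level.method``."""
    try:
        cls = _REGISTRY[level.method]
    except KeyError:
        raise KeyError(f"backend {level.method!r} is not registered "
                       f"(known: {sorted(_REGISTRY)})")
    kwargs = dict(level.params)
    if level.method == "mock-pol":
        kwargs.setdefault("polarizable", True)
    return cls(**kwargs)


register_backend("mock", MockBackend)
register_backend("mock-pol", MockBackend)


def supermolecule_energy(system: MolecularSystem,
                         backend: FragmentBackend) -> BackendResult:
    """Treat the whole system as one fragment and call the backend once."""
    net = 0
    if system.fragments:
        net = sum(f.net_charge for f in system.fragments)
    whole = Fragment(id=0, atom_indices=[a.index for a in system.atoms],
                     net_charge=net)
    return backend.monomer(whole, system)
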