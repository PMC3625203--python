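"""Synthetic desk-scale systems: water clusters, bonded chains, a toy
reaction, and a toy protein.

These generators stand in for the large solvated-enzyme models the method
targets.  Everything is deterministic under its seed: the same (kind,
parameters, seed) yields bit-identical coordinates.

* ``make_water_cluster`` — n rigid waters placed randomly with a minimum
  O-O separation, one fragment each.  The default box corresponds to
  liquid-water density (about 30 A^3 per molecule).
* ``make_bonded_chain`` — a covalent chain of 4-carbon units, one shared
  atom per junction, exercising the cross-region shared-atom machinery.
* ``make_toy_reaction`` — a proton-transfer-like exchange C-H...O(-) in a
  small water shell, with the breaking C-H and forming H-O bonds defining
  a two-bond reaction coordinate that runs from about -1.5 A (reactant)
  to +1.5 A (product).
* ``make_toy_protein`` — a small peptide-like backbone chain plus waters,
  for region-assignment reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .path_scan import RestraintSpec
from .system_model import (Atom, MolecularSystem, detect_bonds,
                           fragment_by_residue)

WATER_OH = 0.95            # A, equals the covalent-radius sum (mock equilibrium)
WATER_ANGLE = math.radians(104.52)
MIN_OO_SEPARATION = 2.6    # A
VOLUME_PER_WATER = 30.0    # A^3, liquid density


def _water_template() -> np.ndarray:
    return np.array([
        [0.0, 0.0, 0.0],
        [WATER_OH, 0.0, 0.0],
        [WATER_OH * math.cos(WATER_ANGLE), WATER_OH * math.sin(WATER_ANGLE), 0.0],
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-random rotation
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _place_waters(n: int, rng: np.random.Generator, box: float,
                  existing_O: list[np.ndarray] | None = None,
                  center: np.ndarray | None = None,
                  min_sep: float = MIN_OO_SEPARATION,
                  max_tries: int = 20000) -> list[np.ndarray]:
    """Rejection-sample n oxygen positions in a cube of edge ``box``."""
    origin = (center if center is not None else np.zeros(3)) - box / 2.0
    placed: list[np.ndarray] = []
    anchors = list(existing_O or [])
    for _ in range(max_tries):
        if len(placed) == n:
            break
        cand = origin + rng.random(3) * box
        if all(np.linalg.norm(cand - p) >= min_sep for p in placed + anchors):
            placed.append(cand)
    if len(placed) < n:
        raise ValueError(
            f"box {box:.2f} A too small for {n} waters at "
            f"{min_sep} A minimum separation")
    return placed


def _add_water(atoms: list[Atom], origin: np.ndarray, R: np.ndarray,
               residue_id: int) -> None:
    for el, pos in zip("OHH", _water_template() @ R.T + origin):
        atoms.append(Atom(len(atoms), el, pos, residue_id=residue_id,
                          residue_name="HOH"))


def make_water_cluster(n: int, seed: int, box: float | None = None
                       ) -> MolecularSystem:
    """n rigid waters, random placement/orientation, one fragment each."""
    if n < 1:
        raise ValueError("need at least one water")
    rng = np.random.default_rng(seed)
    if box is None:
        box = (n * VOLUME_PER_WATER) ** (1.0 / 3.0)
    atoms: list[Atom] = []
    if n == 1:
        _add_water(atoms, np.zeros(3), np.eye(3), 0)
    else:
        for w, origin in enumerate(_place_waters(n, rng, box)):
            _add_water(atoms, origin, _random_rotation(rng), w)
    system = MolecularSystem(atoms)
    detect_bonds(system)
    fragment_by_residue(system)
    return system


def make_bonded_chain(n_frag: int, seed: int, jitter: float = 0.02
                      ) -> MolecularSystem:
    """A covalent chain of n_frag 4-carbon units sharing one atom per junction.

    Backbone carbons zig-zag at the mock equilibrium angle with bond
    length equal to the C-C covalent-radius sum, plus a small seeded
    jitter so gradients are generically nonzero.
    """
    if n_frag < 2:
        raise ValueError("a chain needs at least two fragments")
    rng = np.random.default_rng(seed)
    bond = 1.50   # A = 2 x C covalent radius
    half = math.radians(109.47122) / 2.0
    step = np.array([bond * math.sin(half), 0.0, 0.0])
    atoms: list[Atom] = []
    pos = np.zeros(3)
    for k in range(4 * n_frag):
        z = bond * math.cos(half) * (0.5 if k % 2 == 0 else -0.5)
        p = pos + [0.0, 0.0, z] + rng.normal(0.0, jitter, 3)
        atoms.append(Atom(k, "C", p, residue_id=k // 4, residue_name="UNT"))
        pos = pos + step
    system = MolecularSystem(atoms)
    for k in range(4 * n_frag - 1):
        system.bonds.add((k, k + 1))
    fragment_by_residue(system)
    return system


@dataclass
class ToyReaction:
    """A generated reactive system with its scan settings.

    The reference barrier is *computed*, not stored: call
    :meth:`grid_reference_barrier` (in ``synth_oracle``) or run
    :func:`path_scan.scan_path` with :attr:`restraints`.
    """

    system: MolecularSystem
    restraints: RestraintSpec
    target_fragments: set[int]
    R_start: float
    R_end: float
    # canonical region radii for this system (Angstrom): the active radius
    # follows the enzyme-study default; the buffer radius is widened so the
    # near solvent shell always lands in the buffer region
    R_active: float = 2.0
    R_buffer: float = 3.5
    # anchor atoms inside the active region held frozen (the stand-in for
    # the enzyme scaffold that keeps donor and acceptor in place)
    anchor_atoms: frozenset[int] = frozenset()

    def regions(self):
        """Canonical region assignment for this system."""
        from .frozen_domain import assign_regions
        return assign_regions(self.system, self.target_fragments,
                              self.R_active, self.R_buffer,
                              extra_frozen=set(self.anchor_atoms))


def make_toy_reaction(seed: int, n_buffer_waters: int = 2,
                      n_frozen_waters: int = 1) -> ToyReaction:
    """A proton-transfer-like exchange in a small water shell.

    The reactive core is C1-C2-H ... O-C3: the transferred hydrogen is
    bonded to the donor carbon C2 and approaches the acceptor oxygen of an
    anionic O-C3 group.  C1 and C3 are frozen anchors standing in for the
    scaffold that holds donor and acceptor in an enzyme pocket; C2, H and
    O are mobile.  The breaking C2-H bond and the forming H-O bond define
    the reaction coordinate, exactly -1.5 A at the generated reactant
    geometry (the core orientation is energy-minimized at fixed reactant
    bond lengths before the system is returned).  Waters are placed in
    two shells around the constructed core, near ones for the buffer
    region and far ones for the frozen region; after the reactant
    relaxes, a near water occasionally ends up just outside the buffer
    radius and freezes instead.
    """
    rng = np.random.default_rng(seed)
    r_cc = 1.50                       # C-C covalent equilibrium
    r_ch = 1.07                       # C-H covalent equilibrium
    r_ho = 2.57                       # reactant H...O distance => R ~ -1.5
    r_co = 1.38                       # C-O covalent equilibrium
    theta = math.radians(109.47122)   # mock tetrahedral angle at C2
    x_o = r_ch + r_ho
    tilt = math.radians(20.0)         # acceptor anchor off-axis
    positions = {
        0: np.array([r_cc * math.cos(theta), r_cc * math.sin(theta), 0.0]),
        1: np.zeros(3),
        2: np.array([r_ch, 0.0, 0.0]),
        3: np.array([x_o, 0.0, 0.0]),
        4: np.array([x_o + r_co * math.cos(tilt), r_co * math.sin(tilt), 0.0]),
    }
    atoms = [
        Atom(0, "C", positions[0], residue_id=0, residue_name="DON"),
        Atom(1, "C", positions[1], residue_id=0, residue_name="DON"),
        Atom(2, "H", positions[2], residue_id=0, residue_name="DON"),
        Atom(3, "O", positions[3], residue_id=1, residue_name="ACC"),
        Atom(4, "C", positions[4], residue_id=1, residue_name="ACC"),
    ]
    core_center = np.array([x_o / 2.0, 0.0, 0.0])
    core_O: list[np.ndarray] = [a.position for a in atoms]

    def shell_positions(count: int, core_lo: float, core_hi: float
                        ) -> list[np.ndarray]:
        """Water oxygens with min core-atom distance in [core_lo, core_hi]."""
        placed: list[np.ndarray] = []
        anchors = [np.asarray(p) for p in core_O]
        tries = 0
        while len(placed) < count:
            tries += 1
            if tries > 100000:
                raise RuntimeError("could not place solvent shell")
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = core_center + u * rng.uniform(core_lo, core_hi + 2.0)
            d_core = min(np.linalg.norm(cand - p) for p in anchors)
            if not (core_lo <= d_core <= core_hi):
                continue
            if all(np.linalg.norm(cand - p) >= MIN_OO_SEPARATION
                   for p in placed):
                placed.append(cand)
        return placed

    # the relaxed core can drift toward the shell, so placements are
    # validated against the *relaxed* reactant and redrawn if a water
    # would end up inside the active radius
    for _attempt in range(50):
        shell_atoms = list(atoms)
        rid = 2
        # near shell: outside the active radius even via an inward-pointing
        # H (3.1 - 0.95 > 2.0), inside the buffer radius via the O (3.4 < 3.5)
        for origin in shell_positions(n_buffer_waters, 3.1, 3.4):
            _add_water(shell_atoms, origin, _random_rotation(rng), rid)
            rid += 1
        for origin in shell_positions(n_frozen_waters, 7.5, 8.5):
            _add_water(shell_atoms, origin, _random_rotation(rng), rid)
            rid += 1

        system = MolecularSystem([
            Atom(a.index, a.element, a.position.copy(), a.residue_id,
                 a.residue_name) for a in shell_atoms])
        detect_bonds(system)
        fragment_by_residue(system)
        system.fragments[1].net_charge = -1   # the acceptor is an anion
        toy = ToyReaction(
            system=system,
            restraints=RestraintSpec(bond1=(1, 2), bond2=(2, 3)),
            target_fragments={0, 1},
            R_start=-1.5,
            R_end=1.5,
            anchor_atoms=frozenset({0, 4}),
        )
        _orient_reactant(toy, r_ch, r_ho)
        regions = toy.regions()
        if regions.active == {0, 1} and regions.buffer:
            return toy
    raise RuntimeError("could not generate a valid solvated toy reaction")


def _orient_reactant(toy: ToyReaction, r1: float, r2: float) -> None:
    """Relax the reactive core's orientation at the reactant bond lengths.

    The generated structure is energy-minimized before any scan (the usual
    workflow for a truncated reactive model): the breaking and forming
    bond lengths are held at their reactant values exactly while the
    donor position and the two bond directions relax, starting from a
    small deterministic set of orientations so the reactant sits in the
    globally best orientation basin rather than the construction's.
    """
    from .backend import MockBackend
    from .frozen_domain import assign_regions

    work = toy.system
    regions = assign_regions(work, toy.target_fragments, toy.R_active,
                             toy.R_buffer, extra_frozen=set(toy.anchor_atoms))
    c = work.coordinates()
    u = c[2] - c[1]
    v = c[3] - c[2]
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    p0 = np.array([*c[1],
                   math.acos(np.clip(u[2], -1, 1)), math.atan2(u[1], u[0]),
                   math.acos(np.clip(v[2], -1, 1)), math.atan2(v[1], v[0])])
    best = (np.inf, c)
    backend = MockBackend()
    for dth in (0.0, 0.9):
        for dph in (0.0, 2.0, 4.0):
            start = p0 + [0, 0, 0, dth, dph, dth, dph]
            e, _ = _relax_core_at(work, regions, backend, 1.5, "FDD",
                                  1, 2, 3, r1, r2, start, maxiter=60)
            if e < best[0]:
                best = (e, work.coordinates())
    work.set_coordinates(best[1])


def make_toy_protein(n_residues: int = 4, n_waters: int = 6,
                     seed: int = 0) -> MolecularSystem:
    """A peptide-like backbone chain (N-CA-C-O per residue) plus waters.

    Atom names are set so the fragmenter applies the peptide cut at the
    Calpha-C(carbonyl) bond with Calpha shared.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    names: dict[int, str] = {}
    bonds: set[tuple[int, int]] = set()
    x = 0.0
    prev_c = None
    for r in range(n_residues):
        base = np.array([x, 0.0, 0.0])
        offsets = {
            "N": np.array([0.0, 0.0, 0.0]),
            "CA": np.array([1.25, 0.55, 0.0]),
            "C": np.array([2.55, 0.0, 0.0]),
            "O": np.array([2.75, -1.15, 0.35]),
        }
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
        idx_of = {}
        for name in ("N", "CA", "C", "O"):
            idx = len(atoms)
            jit = rng.normal(0.0, 0.02, 3)
            atoms.append(Atom(idx, elements[name], base + offsets[name] + jit,
                              residue_id=r, residue_name="GLY"))
            names[idx] = name
            idx_of[name] = idx
        bonds |= {(idx_of["N"], idx_of["CA"]), (idx_of["CA"], idx_of["C"]),
                  (idx_of["C"], idx_of["O"])}
        if prev_c is not None:
            bonds.add((prev_c, idx_of["N"]))
        prev_c = idx_of["C"]
        x += 4.0  # puts C(i)-N(i+1) near the covalent-radius sum (1.46 A)

    chain_extent = x
    rid = n_residues
    centers = _place_waters(
        n_waters, rng, box=chain_extent + 10.0,
        existing_O=[a.position for a in atoms],
        center=np.array([chain_extent / 2.0, 0.0, 0.0]),
        min_sep=MIN_OO_SEPARATION)
    for origin in centers:
        _add_water(atoms, origin, _random_rotation(rng), rid)
        rid += 1

    system = MolecularSystem(atoms, bonds)
    # waters need their internal bonds detected without touching the chain
    detect_bonds(system)
    system.bonds = {b for b in system.bonds
                    if not _spurious_chain_bond(b, atoms, bonds)}
    system._atom_names = names
    fragment_by_residue(system)
    return system


def _spurious_chain_bond(bond: tuple[int, int], atoms: list[Atom],
                         declared: set[tuple[int, int]]) -> bool:
    i, j = bond
    both_chain = atoms[i].residue_name == "GLY" and atoms[j].residue_name == "GLY"
    return both_chain and bond not in declared


def make(kind: str, **params) -> MolecularSystem | ToyReaction:
    """Dispatch by kind: water_cluster | bonded_chain | toy_reaction | toy_protein."""
    factory = {
        "water_cluster": lambda: make_water_cluster(
            params.get("n", 5), params.get("seed", 0), params.get("box")),
        "bonded_chain": lambda: make_bonded_chain(
            params.get("n", 5), params.get("seed", 0)),
        "toy_reaction": lambda: make_toy_reaction(params.get("seed", 0)),
        "toy_protein": lambda: make_toy_protein(
            params.get("n", 4), params.get("n_waters", 6),
            params.get("seed", 0)),
    }
    try:
        return factory[kind]()
    except KeyError:
        raise ValueError(f"unknown synthetic kind {kind!r}")


# --------------------------------------------------------------------------
# brute-force grid reference for the toy reaction
# --------------------------------------------------------------------------

def _spherical(theta: float, phi: float) -> np.ndarray:
    st, ct = math.sin(theta), math.cos(theta)
    sp, cp = math.sin(phi), math.cos(phi)
    return np.array([st * cp, st * sp, ct])


def _spherical_jac(theta: float, phi: float) -> tuple[np.ndarray, np.ndarray]:
    st, ct = math.sin(theta), math.cos(theta)
    sp, cp = math.sin(phi), math.cos(phi)
    du_dth = np.array([ct * cp, ct * sp, -st])
    du_dph = np.array([-st * sp, st * cp, 0.0])
    return du_dth, du_dph


def _relax_core_at(system, regions, backend, R_resdim, mode,
                   a: int, h: int, o: int, r1: float, r2: float,
                   p0: np.ndarray, maxiter: int = 40) -> tuple[float, np.ndarray]:
    """Minimize the frozen-domain energy over the 7 core degrees of freedom
    left after fixing both bond lengths exactly (donor position plus two
    bond directions).  Returns (energy, optimal params)."""
    from scipy.optimize import minimize as _minimize

    from .constants import ANGSTROM_TO_BOHR
    from .frozen_domain import fd_energy, fd_gradient

    def set_geometry(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = p[:3]
        u = _spherical(p[3], p[4])
        v = _spherical(p[5], p[6])
        coords = system.coordinates()
        coords[a] = c
        coords[h] = c + r1 * u
        coords[o] = c + r1 * u + r2 * v
        system.set_coordinates(coords)
        return u, v

    def fun(p: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = set_geometry(p)
        e = fd_energy(system, regions, backend, R_resdim, mode).E_total
        g = fd_gradient(system, regions, backend, R_resdim, mode)
        # hartree/bohr -> hartree/Angstrom for Angstrom-valued parameters
        ga, gh, go = (g[a] * ANGSTROM_TO_BOHR, g[h] * ANGSTROM_TO_BOHR,
                      g[o] * ANGSTROM_TO_BOHR)
        du_dth, du_dph = _spherical_jac(p[3], p[4])
        dv_dth, dv_dph = _spherical_jac(p[5], p[6])
        grad = np.empty(7)
        grad[:3] = ga + gh + go
        grad[3] = (gh + go) @ (r1 * du_dth)
        grad[4] = (gh + go) @ (r1 * du_dph)
        grad[5] = go @ (r2 * dv_dth)
        grad[6] = go @ (r2 * dv_dph)
        return e, grad

    res = _minimize(fun, p0, jac=True, method="L-BFGS-B",
                    options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-6})
    set_geometry(res.x)
    return float(res.fun), res.x


def grid_reference_path(toy: ToyReaction, backend,
                        dR: float = 0.1,
                        R_resdim: float = 1.5,
                        mode: str = "FDD",
                        n_grid: int = 7,
                        half_width: float = 0.3,
                        opttol: float = 5.0e-4):
    """Brute-force reference profile for the toy reaction.

    For every step of the scan schedule, the restrained objective is
    searched globally: a dense (r1, r2) grid (bond lengths fixed exactly,
    the remaining core degrees of freedom relaxed) locates the basin, and
    the best grid point seeds a full restrained minimization.  This is
    independent of the adiabatic scan's warm-start continuation, so
    agreement certifies that the scan found the global restrained minimum
    at every step.  Returns a :class:`path_scan.ReactionPath`.
    """
    from .frozen_domain import assign_regions
    from .path_scan import (ReactionPath, restrained_minimize,
                            target_schedule)

    work = toy.system.copy()
    regions = assign_regions(work, toy.target_fragments,
                             toy.R_active, toy.R_buffer,
                             extra_frozen=set(toy.anchor_atoms))
    rest = toy.restraints
    # orient the three-atom core: a-h bonded (breaking), h-o forming
    common = set(rest.bond1) & set(rest.bond2)
    if len(common) != 1:
        raise ValueError("toy restraints must share the transferred atom")
    h = common.pop()
    a = (set(rest.bond1) - {h}).pop()
    o = (set(rest.bond2) - {h}).pop()

    c = work.coordinates()
    r1_0 = float(np.linalg.norm(c[a] - c[h]))
    r2_0 = float(np.linalg.norm(c[h] - c[o]))
    R_0 = r1_0 - r2_0
    k = rest.k_force
    from .constants import KCALMOL_TO_HARTREE
    k_h = k * KCALMOL_TO_HARTREE   # hartree / A^2

    def p_from_geometry() -> np.ndarray:
        cc = work.coordinates()
        u = cc[h] - cc[a]
        v = cc[o] - cc[h]
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        return np.array([*cc[a],
                         math.acos(np.clip(u[2], -1, 1)),
                         math.atan2(u[1], u[0]),
                         math.acos(np.clip(v[2], -1, 1)),
                         math.atan2(v[1], v[0])])

    frames = []
    for R_t, t1, t2 in target_schedule(r1_0, r2_0, R_0,
                                       toy.R_start, toy.R_end, dR):
        r1_grid = np.linspace(max(t1 - half_width, 0.8), t1 + half_width, n_grid)
        r2_grid = np.linspace(max(t2 - half_width, 0.8), t2 + half_width, n_grid)
        best = (np.inf, None)
        p_row = p_from_geometry()
        for r1 in r1_grid:
            p_warm = p_row.copy()
            for j, r2 in enumerate(r2_grid):
                e, p_opt = _relax_core_at(work, regions, backend, R_resdim,
                                          mode, a, h, o, r1, r2, p_warm,
                                          maxiter=25)
                obj = e + 0.5 * k_h * ((r1 - t1) ** 2 + (r2 - t2) ** 2)
                if obj < best[0]:
                    best = (obj, work.coordinates())
                p_warm = p_opt
                if j == 0:
                    p_row = p_opt.copy()
        work.set_coordinates(best[1])
        frame = restrained_minimize(work, regions, rest, (t1, t2), backend,
                                    R_resdim, mode, opttol)
        frames.append(frame)
    frames.sort(key=lambda f: f.R)
    path = ReactionPath(frames, provenance="grid-reference")
    path.validate()
    return path
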