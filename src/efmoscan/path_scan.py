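"""Adiabatic reaction-path mapping by restrained frozen-domain minimization.

The reaction coordinate is the difference between the breaking and the
forming bond length,

    R = r(bond1) - r(bond2)        (Angstrom; negative at the reactant)

A path is mapped by stepping R from reactant to product in fixed
increments (default 0.1 A), harmonically restraining both bond lengths at
per-step targets (default force constant 500 kcal/mol/A^2) and minimizing
the frozen-domain energy over the mobile (active-region) atoms at each
step, starting from the previous step's optimized geometry.  A frame
stores the *unrestrained* energy and the restraint penalty separately:
profiles are reported without the penalty.

The per-step bond targets advance symmetrically: each 0.1 A step moves
the breaking-bond target up and the forming-bond target down by 0.05 A.

Convergence follows the max-gradient-component criterion (default
threshold 5.0e-4 hartree/bohr) on the mobile coordinates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .backend import FragmentBackend
from .constants import (ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM,
                        KCALMOL_TO_HARTREE)
from .efmo_core import BackendSet, DEFAULT_R_RESDIM
from .frozen_domain import RegionAssignment, fd_energy, fd_gradient
from .system_model import MolecularSystem

DEFAULT_OPTTOL = 5.0e-4       # hartree/bohr, max abs gradient component
DEFAULT_K_FORCE = 500.0       # kcal/mol/A^2
DEFAULT_STEP = 0.1            # Angstrom
MAX_ITERATIONS = 200


@dataclass
class RestraintSpec:
    """Two harmonically restrained bonds defining the reaction coordinate."""

    bond1: tuple[int, int]          # breaking bond (atom indices)
    bond2: tuple[int, int]          # forming bond
    k_force: float = DEFAULT_K_FORCE  # kcal/mol/A^2

    def __post_init__(self) -> None:
        if self.k_force <= 0:
            raise ValueError("k_force must be positive")
        if len({*self.bond1}) != 2 or len({*self.bond2}) != 2:
            raise ValueError("restraint bonds need two distinct atoms each")


@dataclass
class PathFrame:
    """One optimized point on the reaction path."""

    geometry: MolecularSystem
    R: float                        # Angstrom, recomputed from geometry
    E: float                        # hartree, unrestrained FD/FDD energy
    E_restraint: float              # hartree, harmonic penalty at the minimum
    converged: bool
    n_gradient_calls: int
    targets: tuple[float, float] = (0.0, 0.0)
    extras: dict = field(default_factory=dict)


@dataclass
class ReactionPath:
    """Frames ordered by increasing reaction coordinate."""

    frames: list[PathFrame]
    provenance: str = ""

    @property
    def R(self) -> np.ndarray:
        return np.array([f.R for f in self.frames])

    @property
    def E(self) -> np.ndarray:
        return np.array([f.E for f in self.frames])

    @property
    def converged(self) -> bool:
        return all(f.converged for f in self.frames)

    def profile_kcal(self) -> tuple[np.ndarray, np.ndarray]:
        """(R, E) with E in kcal/mol relative to the first frame."""
        e = self.E
        return self.R, (e - e[0]) / KCALMOL_TO_HARTREE

    def validate(self) -> None:
        rosters = {tuple(f.geometry.elements()) for f in self.frames}
        if len(rosters) > 1:
            raise ValueError("frames do not share an atom roster")
        r = self.R
        if len(r) > 1 and not np.all(np.diff(r) > 0):
            raise ValueError("reaction coordinate is not strictly increasing")

    def to_dataframe(self):
        import pandas as pd
        e = self.E
        return pd.DataFrame({
            "step": np.arange(len(self.frames)),
            "R_angstrom": self.R,
            "E_hartree": e,
            "E_rel_kcal": (e - e[0]) / KCALMOL_TO_HARTREE,
            "E_restraint_hartree": [f.E_restraint for f in self.frames],
            "converged": [f.converged for f in self.frames],
        })


def reaction_coordinate(system: MolecularSystem,
                        bond1: tuple[int, int],
                        bond2: tuple[int, int]) -> float:
    """R = r(bond1) - r(bond2) in Angstrom."""
    c = system.coordinates()
    r1 = float(np.linalg.norm(c[bond1[0]] - c[bond1[1]]))
    r2 = float(np.linalg.norm(c[bond2[0]] - c[bond2[1]]))
    return r1 - r2


def _restraint_energy_gradient(coords_ang: np.ndarray,
                               restraints: RestraintSpec,
                               targets: tuple[float, float]
                               ) -> tuple[float, np.ndarray]:
    """Harmonic penalty (hartree) and its gradient (hartree/bohr)."""
    k = restraints.k_force * KCALMOL_TO_HARTREE    # hartree / A^2
    e = 0.0
    grad = np.zeros_like(coords_ang)
    for (i, j), target in zip((restraints.bond1, restraints.bond2), targets):
        d = coords_ang[i] - coords_ang[j]
        r = float(np.linalg.norm(d))
        e += 0.5 * k * (r - target) ** 2
        # dE/dx in hartree/A, converted to hartree/bohr
        g = k * (r - target) * d / r * BOHR_TO_ANGSTROM
        grad[i] += g
        grad[j] -= g
    return e, grad


def restrained_minimize(system: MolecularSystem,
                        regions: RegionAssignment,
                        restraints: RestraintSpec,
                        targets: tuple[float, float],
                        backends: FragmentBackend | dict,
                        R_resdim: float = DEFAULT_R_RESDIM,
                        mode: str = "FDD",
                        opttol: float = DEFAULT_OPTTOL,
                        max_iterations: int = MAX_ITERATIONS) -> PathFrame:
    """Minimize E_FD(D) + restraints over mobile Cartesians (L-BFGS).

    The input system is left at the optimized geometry.  Frozen atoms are
    bit-identical before and after.
    """
    bset = BackendSet(backends) if not isinstance(backends, BackendSet) else backends
    mobile = list(regions.mobile_atoms)
    if not mobile:
        raise ValueError("no mobile atoms to optimize")
    for i, j in (restraints.bond1, restraints.bond2):
        for a in (i, j):
            if a not in mobile:
                raise ValueError(f"restrained atom {a} is frozen")

    n_calls = 0

    def objective(x_bohr: np.ndarray) -> tuple[float, np.ndarray]:
        nonlocal n_calls
        n_calls += 1
        coords = system.coordinates()
        coords[mobile] = x_bohr.reshape(-1, 3) * BOHR_TO_ANGSTROM
        system.set_coordinates(coords)
        rep = fd_energy(system, regions, bset, R_resdim, mode)
        grad = fd_gradient(system, regions, bset, R_resdim, mode)
        e_r, g_r = _restraint_energy_gradient(coords, restraints, targets)
        total_grad = (grad + g_r)[mobile].ravel()
        return rep.E_total + e_r, total_grad

    x0 = (system.coordinates()[mobile] * ANGSTROM_TO_BOHR).ravel()
    frozen_before = system.coordinates()[
        [i for i in range(system.n_atoms) if i not in mobile]].copy()

    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iterations, "ftol": 1e-16,
                            "gtol": opttol, "maxcor": 30})
    # leave the system at the optimized geometry
    coords = system.coordinates()
    coords[mobile] = res.x.reshape(-1, 3) * BOHR_TO_ANGSTROM
    system.set_coordinates(coords)

    frozen_after = system.coordinates()[
        [i for i in range(system.n_atoms) if i not in mobile]]
    assert np.array_equal(frozen_before, frozen_after)

    rep = fd_energy(system, regions, bset, R_resdim, mode)
    grad = fd_gradient(system, regions, bset, R_resdim, mode)
    e_r, g_r = _restraint_energy_gradient(system.coordinates(), restraints,
                                          targets)
    max_grad = float(np.max(np.abs((grad + g_r)[mobile])))
    converged = max_grad <= opttol

    return PathFrame(
        geometry=system.copy(),
        R=reaction_coordinate(system, restraints.bond1, restraints.bond2),
        E=rep.E_total,
        E_restraint=e_r,
        converged=converged,
        n_gradient_calls=n_calls,
        targets=targets,
        extras={"max_gradient": max_grad, "objective": rep.E_total + e_r},
    )


def target_schedule(r1_0: float, r2_0: float, R_0: float,
                    R_start: float, R_end: float, dR: float,
                    R_current: float | None = None
                    ) -> list[tuple[float, float, float]]:
    """Per-step (R_target, r1_target, r2_target) for a scan.

    Targets move symmetrically (+-dR/2 per step) from the reference bond
    lengths ``(r1_0, r2_0)`` at ``R_0``; the list runs from the end closer
    to ``R_current`` (the geometry the scan starts from).
    """
    if dR <= 0:
        raise ValueError("dR must be positive")
    if R_current is None:
        R_current = R_0
    if R_start == R_end:
        r_targets = [R_start]
    else:
        n_steps = int(round(abs(R_end - R_start) / dR))
        r_targets = list(np.linspace(R_start, R_end, n_steps + 1))
    if abs(r_targets[-1] - R_current) < abs(r_targets[0] - R_current):
        r_targets = r_targets[::-1]
    return [(R_t, r1_0 + (R_t - R_0) / 2.0, r2_0 - (R_t - R_0) / 2.0)
            for R_t in r_targets]


def scan_path(system: MolecularSystem,
              regions: RegionAssignment,
              restraints: RestraintSpec,
              R_start: float,
              R_end: float,
              dR: float = DEFAULT_STEP,
              backends: FragmentBackend | dict = None,
              R_resdim: float = DEFAULT_R_RESDIM,
              mode: str = "FDD",
              opttol: float = DEFAULT_OPTTOL,
              max_iterations: int = MAX_ITERATIONS,
              reference_bonds: tuple[float, float] | None = None,
              resume_from: "ReactionPath | None" = None) -> ReactionPath:
    """Map the adiabatic path from R_start to R_end in steps of dR.

    Each step starts from the previous optimized geometry.  Bond targets
    interpolate linearly (symmetrically, +-dR/2 per step) from
    ``reference_bonds`` — the (r1, r2) anchor of the target line, by
    default the initial geometry's bond lengths.  Pass the same anchor to
    a forward and a backward scan to sample identical restrained
    objectives in the two directions.  Frames are returned ordered by
    increasing R regardless of scan direction.

    ``resume_from`` restarts an interrupted scan: converged frames of the
    previous path are kept, the continuation starts from the last of
    them, and a provenance hash guards against settings drift.
    """
    work = system.copy()
    # carry frozen flags over to the working copy
    for i, atom in enumerate(work.atoms):
        atom.frozen = system.atoms[i].frozen

    c = work.coordinates()
    if reference_bonds is not None:
        r1_0, r2_0 = reference_bonds
    else:
        r1_0 = float(np.linalg.norm(c[restraints.bond1[0]]
                                    - c[restraints.bond1[1]]))
        r2_0 = float(np.linalg.norm(c[restraints.bond2[0]]
                                    - c[restraints.bond2[1]]))
    R_0 = r1_0 - r2_0
    R_current = reaction_coordinate(work, restraints.bond1, restraints.bond2)

    settings = (f"{restraints.bond1}{restraints.bond2}{restraints.k_force}"
                f"{R_start}{R_end}{dR}{R_resdim}{mode}{opttol}"
                f"{r1_0:.12f}{r2_0:.12f}")
    provenance = hashlib.sha256(settings.encode()).hexdigest()

    frames = []
    schedule = target_schedule(r1_0, r2_0, R_0, R_start, R_end, dR, R_current)
    if resume_from is not None:
        if resume_from.provenance != provenance:
            raise ValueError("cannot resume: scan settings differ from the "
                             "path being resumed (provenance mismatch)")
        done = [f for f in resume_from.frames if f.converged]
        if done:
            frames.extend(done)
            ascending = len(schedule) < 2 or schedule[0][0] < schedule[-1][0]
            last = done[-1] if ascending else done[0]
            work.set_coordinates(last.geometry.coordinates())
            finished = {round(t.targets[0] - t.targets[1], 9) for t in done}
            schedule = [step for step in schedule
                        if round(step[1] - step[2], 9) not in finished]

    for _, t1, t2 in schedule:
        frame = restrained_minimize(work, regions, restraints, (t1, t2),
                                    backends, R_resdim, mode, opttol,
                                    max_iterations)
        frames.append(frame)

    frames.sort(key=lambda f: f.R)
    path = ReactionPath(frames, provenance=provenance)
    path.validate()
    return path
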