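"""Many-body induced-dipole polarization.

Every fragment carries distributed polarizability tensors at its atomic
sites.  The induced dipoles satisfy the self-consistency condition

    mu_i = alpha_i ( F_static,i + sum_{j != i} T_ij mu_j )

where ``F_static,i`` is the field of the *other* fragments' permanent
multipoles (a site is never polarized by its own fragment's moments) and
``T_ij`` is the bare point-dipole interaction tensor; mutual induced
coupling spans all sites including those within one fragment.  No Thole
damping is applied — a diverging solution is reported as a polarization
catastrophe rather than damped away.

The polarization energy is ``E_pol = -1/2 sum_i mu_i . F_static,i``; it is
non-positive for positive-semidefinite polarizabilities whenever the
coupled problem is stable.

Systems small enough for a dense solve (<= 300 sites) use direct linear
algebra; larger ones use fixed-point iteration.  Units: bohr, e, hartree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .electrostatics import MultipoleSet, field_at_points

DENSE_SITE_LIMIT = 300
DEFAULT_TOL = 1e-8  # e bohr, max-norm on the self-consistency residual


class PolarizationDivergenceError(RuntimeError):
    """The induced-dipole iteration diverged (polarization catastrophe)."""


@dataclass
class PolarizabilitySet:
    """Distributed polarizability tensors at sites.

    positions : (n, 3) bohr
    alpha     : (n, 3, 3) bohr^3, symmetric with non-negative eigenvalues
    """

    positions: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        n = len(self.positions)
        self.alpha = np.asarray(self.alpha, float).reshape(n, 3, 3)
        if np.max(np.abs(self.alpha - np.transpose(self.alpha, (0, 2, 1))),
                  initial=0.0) > 1e-10:
            raise ValueError("polarizability tensors must be symmetric")
        if n and np.linalg.eigvalsh(self.alpha).min() < -1e-10:
            raise ValueError("polarizability tensors must be positive-semidefinite")

    @property
    def is_zero(self) -> bool:
        return not len(self.positions) or not np.any(self.alpha)


@dataclass
class FragmentStatics:
    """One fragment's classical state: permanent moments and polarizabilities."""

    fragment_id: int
    multipoles: MultipoleSet
    polarizabilities: PolarizabilitySet


@dataclass
class InducedState:
    """Converged induced dipoles and the polarization energy."""

    dipoles: np.ndarray      # (n, 3), e bohr
    residual: float          # e bohr, max-norm
    iterations: int
    E_pol: float             # hartree


def _dipole_coupling(positions: np.ndarray) -> np.ndarray:
    """(3n, 3n) block matrix of T_ij = (3 rr - r^2 I)/r^5, zero diagonal."""
    n = len(positions)
    K = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            d = positions[i] - positions[j]
            r2 = d @ d
            r = np.sqrt(r2)
            T = (3.0 * np.outer(d, d) - r2 * np.eye(3)) / (r2 * r2 * r)
            K[3 * i:3 * i + 3, 3 * j:3 * j + 3] = T
            K[3 * j:3 * j + 3, 3 * i:3 * i + 3] = T
    return K


def _closest_pair(positions: np.ndarray) -> tuple[int, int, float]:
    n = len(positions)
    best = (0, 1, np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(positions[i] - positions[j]))
            if d < best[2]:
                best = (i, j, d)
    return best


def solve_induced(statics: list[FragmentStatics],
                  tol: float = DEFAULT_TOL,
                  max_iterations: int = 500) -> InducedState:
    """Solve the coupled induced-dipole equations over the given fragments.

    The static field at each polarizable site comes from the permanent
    multipoles of every *other* fragment in ``statics``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    positions = []
    alphas = []
    frag_of_site = []
    for st in statics:
        for p, a in zip(st.polarizabilities.positions, st.polarizabilities.alpha):
            positions.append(p)
            alphas.append(a)
            frag_of_site.append(st.fragment_id)
    n = len(positions)
    if n == 0 or not np.any(alphas):
        return InducedState(np.zeros((n, 3)), 0.0, 1, 0.0)
    positions = np.array(positions)
    alphas = np.array(alphas)

    F_static = np.zeros((n, 3))
    for st in statics:
        mask = [k for k in range(n) if frag_of_site[k] != st.fragment_id]
        if mask:
            F_static[mask] += field_at_points(st.multipoles, positions[mask])

    A = np.zeros((3 * n, 3 * n))
    for i in range(n):
        A[3 * i:3 * i + 3, 3 * i:3 * i + 3] = alphas[i]
    K = _dipole_coupling(positions)
    f = F_static.ravel()

    if n <= DENSE_SITE_LIMIT:
        mu = np.linalg.solve(np.eye(3 * n) - A @ K, A @ f)
        iterations = 1
    else:
        mu = A @ f
        prev_res = np.inf
        for iterations in range(1, max_iterations + 1):
            mu_new = A @ (f + K @ mu)
            res = np.max(np.abs(mu_new - mu))
            mu = mu_new
            if res <= tol:
                break
            if res > 10.0 * prev_res or not np.isfinite(res):
                i, j, d = _closest_pair(positions)
                raise PolarizationDivergenceError(
                    f"induced dipoles diverged; closest site pair "
                    f"({i}, {j}) at {d:.3f} bohr")
            prev_res = min(prev_res, res)
        else:
            i, j, d = _closest_pair(positions)
            raise PolarizationDivergenceError(
                f"no convergence in {max_iterations} iterations; closest "
                f"site pair ({i}, {j}) at {d:.3f} bohr")

    residual = float(np.max(np.abs(mu - A @ (f + K @ mu))))
    if residual > max(tol, 1e-10 * max(1.0, np.max(np.abs(mu)))):
        i, j, d = _closest_pair(positions)
        raise PolarizationDivergenceError(
            f"residual {residual:.3e} exceeds tolerance; closest site pair "
            f"({i}, {j}) at {d:.3f} bohr")
    E_pol = -0.5 * float(mu @ f)
    return InducedState(mu.reshape(n, 3), residual, iterations, E_pol)


def pol_energy_total(statics: list[FragmentStatics],
                     tol: float = DEFAULT_TOL) -> float:
    """Total many-body polarization energy over all fragments, hartree."""
    return solve_induced(statics, tol).E_pol


def pol_energy_pair(stat_I: FragmentStatics, stat_J: FragmentStatics,
                    tol: float = DEFAULT_TOL) -> float:
    """Pair polarization energy of the isolated dimer I-J, hartree.

    Used to remove induction double-counted inside the QM dimer
    correction; computed with the pair's own sites and sources only.
    """
    if stat_I.fragment_id == stat_J.fragment_id:
        raise ValueError("pair polarization requires two distinct fragments")
    return solve_induced([stat_I, stat_J], tol).E_pol
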