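"""Classical electrostatics between atom-centered distributed multipoles.

Each fragment carries point multipoles (charge, dipole, traceless
Cartesian quadrupole in the Buckingham convention) at its atomic sites.
Pair energies use the standard interaction-tensor bilinear form through
quadrupole-quadrupole; fields drive the induced-dipole polarization model.

Gradients follow the frozen-moment convention: multipole magnitudes and
orientations are treated as geometry-independent within a step, matching
the once-per-step moment evaluation of EFMO.  They are evaluated by
complex-step differentiation of the (holomorphic) pair-energy expression,
which is exact to machine precision.

All quantities are atomic units: bohr, e, hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np

SINGULAR_DISTANCE = 1e-6  # bohr


class SingularGeometryError(ValueError):
    """Two interaction sites (nearly) coincide."""


@dataclass
class MultipoleSet:
    """Point multipoles at a list of sites.

    positions : (n, 3) bohr
    q         : (n,) e
    mu        : (n, 3) e bohr
    theta     : (n, 3, 3) e bohr^2, symmetric and traceless (Buckingham)
    """

    positions: np.ndarray
    q: np.ndarray
    mu: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        n = len(self.positions)
        self.q = np.asarray(self.q, float).reshape(n)
        self.mu = np.asarray(self.mu, float).reshape(n, 3)
        self.theta = np.asarray(self.theta, float).reshape(n, 3, 3)
        if not np.all(np.isfinite(self.positions)) or not np.all(
                np.isfinite(self.q)):
            raise ValueError("non-finite multipole data")
        if np.max(np.abs(self.theta - np.transpose(self.theta, (0, 2, 1)))) > 1e-12:
            raise ValueError("quadrupoles must be symmetric")
        if np.max(np.abs(np.trace(self.theta, axis1=1, axis2=2))) > 1e-12:
            raise ValueError("quadrupoles must be traceless")

    @classmethod
    def point_charges(cls, positions: np.ndarray, q: np.ndarray) -> "MultipoleSet":
        positions = np.atleast_2d(np.asarray(positions, float))
        n = len(positions)
        return cls(positions, q, np.zeros((n, 3)), np.zeros((n, 3, 3)))

    @classmethod
    def from_point_charge_cloud(cls, center: np.ndarray,
                                positions: np.ndarray,
                                q: np.ndarray) -> "MultipoleSet":
        """Condense a charge cloud into one site's multipoles about ``center``.

        Second moments are converted to the traceless Buckingham form
        ``Theta = 1/2 sum q (3 d d - d^2 I)`` at ingestion.
        """
        center = np.asarray(center, float)
        d = np.atleast_2d(np.asarray(positions, float)) - center
        q = np.asarray(q, float)
        total = q.sum()
        mu = (q[:, None] * d).sum(0)
        theta = 0.5 * sum(
            qk * (3.0 * np.outer(dk, dk) - (dk @ dk) * np.eye(3))
            for qk, dk in zip(q, d)
        )
        return cls(center[None, :], [total], mu[None, :], theta[None, :, :])

    def rotated(self, R: np.ndarray, about: np.ndarray | None = None
                ) -> "MultipoleSet":
        """Rigidly rotate sites and co-rotate the moments."""
        about = np.zeros(3) if about is None else np.asarray(about, float)
        pos = (self.positions - about) @ R.T + about
        mu = self.mu @ R.T
        theta = np.einsum("ab,nbc,dc->nad", R, self.theta, R)
        return MultipoleSet(pos, self.q.copy(), mu, theta)

    def translated(self, shift: np.ndarray) -> "MultipoleSet":
        return MultipoleSet(self.positions + np.asarray(shift, float),
                            self.q.copy(), self.mu.copy(), self.theta.copy())

    # plain-text dump/restore for debugging and cross-validation
    def to_text(self) -> str:
        buf = StringIO()
        for p, q, m, t in zip(self.positions, self.q, self.mu, self.theta):
            upper = [t[0, 0], t[0, 1], t[0, 2], t[1, 1], t[1, 2], t[2, 2]]
            fields = list(p) + [q] + list(m) + upper
            buf.write(" ".join(f"{v:.16e}" for v in fields) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "MultipoleSet":
        pos, qs, mus, thetas = [], [], [], []
        for line in text.strip().splitlines():
            v = [float(tok) for tok in line.split()]
            pos.append(v[0:3])
            qs.append(v[3])
            mus.append(v[4:7])
            xx, xy, xz, yy, yz, zz = v[7:13]
            thetas.append([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])
        return cls(np.array(pos), np.array(qs), np.array(mus), np.array(thetas))


# --------------------------------------------------------------------------
# interaction tensors (derivatives of 1/R with respect to R = r_j - r_i)
# --------------------------------------------------------------------------

def _tensors(R):
    """T^(0)..T^(4) for one separation vector; complex-safe."""
    R = np.asarray(R)
    r2 = R @ R
    r1 = np.sqrt(r2)
    r3, r5, r7, r9 = r1 * r2, None, None, None
    r5 = r3 * r2
    r7 = r5 * r2
    r9 = r7 * r2
    eye = np.eye(3)
    T0 = 1.0 / r1
    T1 = -R / r3
    T2 = (3.0 * np.outer(R, R) - r2 * eye) / r5
    RRR = np.einsum("a,b,c->abc", R, R, R)
    sym3 = (np.einsum("a,bc->abc", R, eye)
            + np.einsum("b,ac->abc", R, eye)
            + np.einsum("c,ab->abc", R, eye))
    T3 = -(15.0 * RRR - 3.0 * r2 * sym3) / r7
    RRRR = np.einsum("a,b,c,d->abcd", R, R, R, R)
    sym4_rr = (np.einsum("a,b,cd->abcd", R, R, eye)
               + np.einsum("a,c,bd->abcd", R, R, eye)
               + np.einsum("a,d,bc->abcd", R, R, eye)
               + np.einsum("b,c,ad->abcd", R, R, eye)
               + np.einsum("b,d,ac->abcd", R, R, eye)
               + np.einsum("c,d,ab->abcd", R, R, eye))
    sym4_dd = (np.einsum("ab,cd->abcd", eye, eye)
               + np.einsum("ac,bd->abcd", eye, eye)
               + np.einsum("ad,bc->abcd", eye, eye))
    T4 = (105.0 * RRRR - 15.0 * r2 * sym4_rr + 3.0 * r2 * r2 * sym4_dd) / r9
    return T0, T1, T2, T3, T4


def _site_pair_energy(pos_i, q_i, mu_i, th_i, pos_j, q_j, mu_j, th_j):
    """Buckingham-convention multipole interaction of two sites (complex-safe)."""
    R = pos_j - pos_i
    T0, T1, T2, T3, T4 = _tensors(R)
    e = q_i * q_j * T0
    e += T1 @ (q_i * mu_j - q_j * mu_i)
    e += np.einsum("ab,ab->", T2,
                   (q_i * th_j + q_j * th_i) / 3.0) \
        - mu_i @ T2 @ mu_j
    e += np.einsum("ab,abc,c->", th_i, T3, mu_j) / 3.0 \
        - np.einsum("a,abc,bc->", mu_i, T3, th_j) / 3.0
    e += np.einsum("ab,abcd,cd->", th_i, T4, th_j) / 9.0
    return e


def _check_separations(M_I: MultipoleSet, M_J: MultipoleSet) -> None:
    diff = M_I.positions[:, None, :] - M_J.positions[None, :, :]
    dmin = np.sqrt((diff ** 2).sum(-1)).min()
    if dmin < SINGULAR_DISTANCE:
        raise SingularGeometryError(
            f"site pair at {dmin:.3e} bohr (< {SINGULAR_DISTANCE} bohr)")


def _charge_only(M: MultipoleSet) -> bool:
    return not (np.any(M.mu) or np.any(M.theta))


def pair_es_energy(M_I: MultipoleSet, M_J: MultipoleSet) -> float:
    """Classical electrostatic energy between two multipole sets, hartree."""
    _check_separations(M_I, M_J)
    if _charge_only(M_I) and _charge_only(M_J):
        diff = M_I.positions[:, None, :] - M_J.positions[None, :, :]
        r = np.sqrt((diff ** 2).sum(-1))
        return float((np.outer(M_I.q, M_J.q) / r).sum())
    e = 0.0
    for i in range(len(M_I.positions)):
        for j in range(len(M_J.positions)):
            e += _site_pair_energy(
                M_I.positions[i], M_I.q[i], M_I.mu[i], M_I.theta[i],
                M_J.positions[j], M_J.q[j], M_J.mu[j], M_J.theta[j])
    return float(np.real(e))


def pair_es_gradient(M_I: MultipoleSet, M_J: MultipoleSet
                     ) -> tuple[np.ndarray, np.ndarray]:
    """dE/dx per site (frozen moments), as (grad_I, grad_J) in hartree/bohr.

    Computed by complex-step differentiation; Newton's third law
    (sum of all site gradients = 0) holds to machine precision.
    """
    _check_separations(M_I, M_J)
    if _charge_only(M_I) and _charge_only(M_J):
        diff = M_I.positions[:, None, :] - M_J.positions[None, :, :]
        r2 = (diff ** 2).sum(-1)
        r = np.sqrt(r2)
        qq = np.outer(M_I.q, M_J.q)
        f = -(qq / (r2 * r))[:, :, None] * diff     # dE/dx_I per site pair
        grad_I = f.sum(axis=1)
        grad_J = -f.sum(axis=0)
        return grad_I, grad_J
    h = 1e-30
    nI, nJ = len(M_I.positions), len(M_J.positions)
    grad_I = np.zeros((nI, 3))
    grad_J = np.zeros((nJ, 3))
    for i in range(nI):
        for j in range(nJ):
            args = (M_I.q[i], M_I.mu[i], M_I.theta[i],
                    M_J.q[j], M_J.mu[j], M_J.theta[j])
            pi = M_I.positions[i].astype(complex)
            pj = M_J.positions[j].astype(complex)
            for a in range(3):
                step = np.zeros(3, complex)
                step[a] = 1j * h
                grad_I[i, a] += np.imag(_site_pair_energy(
                    pi + step, args[0], args[1], args[2],
                    pj, args[3], args[4], args[5])) / h
                grad_J[j, a] += np.imag(_site_pair_energy(
                    pi, args[0], args[1], args[2],
                    pj + step, args[3], args[4], args[5])) / h
    return grad_I, grad_J


def field_at_points(sources: MultipoleSet | list[MultipoleSet],
                    probes: np.ndarray) -> np.ndarray:
    """Electric field (hartree/e/bohr) at probe points from source multipoles.

    Charges, dipoles and quadrupoles all contribute; superposition over a
    list of sets.
    """
    if isinstance(sources, MultipoleSet):
        sources = [sources]
    probes = np.atleast_2d(np.asarray(probes, float))
    F = np.zeros_like(probes)
    for src in sources:
        has_mu = bool(np.any(src.mu))
        has_theta = bool(np.any(src.theta))
        for p, q, mu, th in zip(src.positions, src.q, src.mu, src.theta):
            d = probes - p          # from source to probe
            r2 = (d * d).sum(1)
            if np.any(r2 < SINGULAR_DISTANCE ** 2):
                raise SingularGeometryError("probe coincides with a source site")
            r = np.sqrt(r2)
            r3 = r * r2
            r5 = r3 * r2
            # charge: q r / r^3
            F += q * d / r3[:, None]
            if has_mu:
                # dipole: (3 (mu.rhat) rhat - mu) / r^3
                mud = d @ mu
                F += (3.0 * mud / r5)[:, None] * d - mu / r3[:, None]
            if has_theta:
                # quadrupole: F_c = -(1/3) Theta_ab T3_abc(d)
                for k in range(len(probes)):
                    _, _, _, T3, _ = _tensors(d[k])
                    F[k] += -np.einsum("ab,abc->c", th, T3) / 3.0
    return F
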