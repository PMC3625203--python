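"""Activation-enthalpy estimators over an ensemble of reaction paths.

Two standard estimators for the barrier from N adiabatic profiles
E_i(R):

* per-path barriers, then average (the "mean of extrema"):

      dH1 = < max_R E_i(R) - min_{R<0} E_i(R) >_i - correction

* average profile, then its barrier (the "extrema of the mean"):

      dH2 = max_R <E(R)> - min_{R<0} <E(R)> - correction

The reactant minimum is always taken among frames with a *negative*
reaction coordinate.  The first estimator dominates the second
(max/min do not commute with averaging); their gap diagnoses how well the
transition-state position aligns across paths.  The correction (default
1.6 kcal/mol, subtracted) accounts for zero-point and thermal
contributions, turning an electronic barrier into an activation enthalpy.

Profiles are (R, E) arrays with E in kcal/mol; both estimators are
invariant under a constant shift of every profile, and the per-path
estimator also under per-path shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .path_scan import ReactionPath

DEFAULT_CORRECTION = 1.6  # kcal/mol, subtracted from the electronic barrier

Profile = tuple[np.ndarray, np.ndarray]


def _as_profiles(paths) -> list[Profile]:
    out = []
    for p in paths:
        if isinstance(p, ReactionPath):
            if not p.converged:
                raise ValueError(
                    "path contains unconverged frames; refusing to compute "
                    "barrier statistics (override by passing raw profiles)")
            r, e = p.profile_kcal()
        else:
            r, e = p
        r = np.asarray(r, float)
        e = np.asarray(e, float)
        if r.shape != e.shape or r.ndim != 1 or len(r) == 0:
            raise ValueError("a profile must be two equal-length 1-D arrays")
        out.append((r, e))
    return out


def _path_barrier(r: np.ndarray, e: np.ndarray) -> tuple[float, float, float, float]:
    """(E_max, R_at_max, E_reactant, R_at_reactant) of one profile, kcal/mol."""
    neg = r < 0
    if not np.any(neg):
        raise ValueError("path has no frame with a negative reaction coordinate")
    i_max = int(np.argmax(e))
    e_neg = np.where(neg, e, np.inf)
    i_min = int(np.argmin(e_neg))
    return float(e[i_max]), float(r[i_max]), float(e[i_min]), float(r[i_min])


def barrier_per_path(paths, correction: float = DEFAULT_CORRECTION
                     ) -> tuple[float, float]:
    """Mean and sample sd of the per-path barriers, kcal/mol."""
    profiles = _as_profiles(paths)
    barriers = []
    for k, (r, e) in enumerate(profiles):
        try:
            e_max, _, e_min, _ = _path_barrier(r, e)
        except ValueError as err:
            raise ValueError(f"path {k}: {err}") from None
        barriers.append(e_max - e_min)
    barriers = np.array(barriers)
    sd = float(barriers.std(ddof=1)) if len(barriers) > 1 else 0.0
    return float(barriers.mean()) - correction, sd


def barrier_mean_profile(paths, correction: float = DEFAULT_CORRECTION,
                         grid_tol: float = 1e-8) -> float:
    """Barrier of the averaged profile, kcal/mol.

    Paths must share a common reaction-coordinate grid (the scan grid
    guarantees this); paths on different grids are linearly resampled
    onto their common overlap, which raises if the overlap is empty.
    """
    profiles = _as_profiles(paths)
    grids = [r for r, _ in profiles]
    same = all(len(g) == len(grids[0]) and np.allclose(g, grids[0], atol=grid_tol)
               for g in grids)
    if same:
        R = grids[0]
        E = np.mean([e for _, e in profiles], axis=0)
    else:
        lo = max(g.min() for g in grids)
        hi = min(g.max() for g in grids)
        if hi <= lo:
            raise ValueError("path grids do not overlap; cannot average")
        R = np.linspace(lo, hi, max(len(g) for g in grids))
        E = np.mean([np.interp(R, r, e) for r, e in profiles], axis=0)
    e_max, _, e_min, _ = _path_barrier(R, E)
    return e_max - e_min - correction


@dataclass
class EnsembleResult:
    """Barrier statistics over an ensemble of adiabatic paths."""

    n_paths: int
    barrier_per_path: float         # kcal/mol, mean of per-path barriers
    barrier_per_path_sd: float
    barrier_mean_profile: float     # kcal/mol, barrier of the mean profile
    uncertainty_of_mean: float      # sd / sqrt(N)
    correction: float
    per_path: list[dict]            # E_max, R_at_max, E_min_negR, R_at_min

    @property
    def ts_alignment_gap(self) -> float:
        """Per-path minus mean-profile estimate (>= 0); small when the
        transition-state position aligns across paths."""
        return self.barrier_per_path - self.barrier_mean_profile


def ensemble_statistics(paths, correction: float = DEFAULT_CORRECTION
                        ) -> EnsembleResult:
    """Both estimators plus per-path extrema in one report."""
    profiles = _as_profiles(paths)
    per_path = []
    for r, e in profiles:
        e_max, r_max, e_min, r_min = _path_barrier(r, e)
        per_path.append({"E_max": e_max, "R_at_max": r_max,
                         "E_min_negR": e_min, "R_at_min": r_min})
    mean_pp, sd = barrier_per_path(profiles, correction)
    mean_mp = barrier_mean_profile(profiles, correction)
    n = len(profiles)
    return EnsembleResult(
        n_paths=n, barrier_per_path=mean_pp, barrier_per_path_sd=sd,
        barrier_mean_profile=mean_mp,
        uncertainty_of_mean=sd / np.sqrt(n) if n else 0.0,
        correction=correction, per_path=per_path)
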