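"""Subtractive two-layer ONIOM refinement of reaction-path energies.

The refined energy of a frame is

    E = E_low(total) + E_high(model) - E_low(model)

where the model region (the reactive fragment, e.g. the substrate) is
extracted from the frame with the same hydrogen-capping rule used by the
backend and computed *in the gas phase* — no environment multipoles are
passed to the model calculations.  Only single-point energies are refined;
geometries are untouched, and barriers (frame-to-frame differences) are
invariant under any constant shift of either level.
"""

from __future__ import annotations

from dataclasses import dataclass

from .backend import FragmentBackend
from .path_scan import PathFrame, ReactionPath
from .system_model import Fragment, MolecularSystem


@dataclass
class OniomSpec:
    """Model region (fragment ids) and the two levels."""

    model_fragments: set[int]
    high: FragmentBackend
    low: FragmentBackend

    def __post_init__(self) -> None:
        if not self.model_fragments:
            raise ValueError("ONIOM model region is empty")


def oniom_combine(E_low_total: float, E_high_model: float,
                  E_low_model: float) -> float:
    """E = E_low_total + E_high_model - E_low_model (all hartree)."""
    return E_low_total + E_high_model - E_low_model


def _model_fragment(system: MolecularSystem, model_ids: set[int]) -> Fragment:
    frags = {f.id: f for f in system.fragments}
    missing = model_ids - frags.keys()
    if missing:
        raise ValueError(f"model fragments not in system: {sorted(missing)}")
    atoms = sorted({i for fid in model_ids for i in frags[fid].atom_indices})
    net = sum(frags[fid].net_charge for fid in model_ids)
    return Fragment(id=-1, atom_indices=atoms, net_charge=net)


def refine_path(path: ReactionPath, spec: OniomSpec,
                template: MolecularSystem) -> ReactionPath:
    """ONIOM-refine every frame energy; geometries are preserved bit-exactly.

    ``template`` supplies fragmentation and bonds (scan frames carry bare
    geometries).  The original energy of each frame is kept in
    ``extras["E_unrefined"]``.
    """
    refined = []
    for frame in path.frames:
        work = template.copy()
        work.set_coordinates(frame.geometry.coordinates())
        model = _model_fragment(work, spec.model_fragments)
        e_high = spec.high.monomer(model, work).energy
        e_low = spec.low.monomer(model, work).energy
        e = oniom_combine(frame.E, e_high, e_low)
        extras = dict(frame.extras)
        extras.update({"E_unrefined": frame.E, "E_high_model": e_high,
                       "E_low_model": e_low})
        refined.append(PathFrame(
            geometry=frame.geometry, R=frame.R, E=e,
            E_restraint=frame.E_restraint, converged=frame.converged,
            n_gradient_calls=frame.n_gradient_calls,
            targets=frame.targets, extras=extras))
    return ReactionPath(refined, provenance=path.provenance)
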