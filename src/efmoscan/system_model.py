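"""Molecular data model, structure I/O and residue-granular fragmentation.

The model is built around three ideas from fragment-based quantum chemistry:

* a :class:`MolecularSystem` is a flat list of atoms plus a covalent bond
  list;
* fragments are one amino-acid residue or one water molecule each; a
  covalent bond between two fragments is never cut — instead the boundary
  atom is *shared* by both fragments (for peptides the cut is placed at the
  Calpha–C(carbonyl) bond with Calpha as the shared atom);
* the unitless interfragment distance ``R_IJ`` is the minimum over atom
  pairs of ``r_ij / (Rvdw_i + Rvdw_j)`` and decides whether a fragment pair
  is treated quantum mechanically or classically.

Coordinates are in Angstrom throughout this module.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import covalent_radius, vdw_radius, KNOWN_ELEMENTS


class ParseError(ValueError):
    """Malformed structure file; message names the offending line."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Atom:
    """A single atom.

    ``index`` is 0-based and stable for the lifetime of the system; all
    user-facing reports add 1.
    """

    index: int
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    residue_id: int = 0
    residue_name: str = "UNK"
    frozen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.index}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index}: non-finite position")
        if self.element not in KNOWN_ELEMENTS:
            raise ValueError(f"atom {self.index}: unknown element {self.element!r}")


@dataclass
class Fragment:
    """A fragment: a residue or water, possibly sharing boundary atoms.

    ``atom_indices`` is the fragment's full roster including shared atoms.
    ``shared_atoms`` lists ``(atom_index, partner_fragment_id)`` pairs for
    every atom this fragment has in common with a covalently bonded
    neighbour.  ``guest_atoms`` are the shared atoms *owned* by the partner
    (they count toward the partner's charge, not this fragment's).
    """

    id: int
    atom_indices: list[int]
    shared_atoms: list[tuple[int, int]] = field(default_factory=list)
    guest_atoms: set[int] = field(default_factory=set)
    net_charge: int = 0
    layer: str | None = None

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValueError(f"fragment {self.id}: empty atom roster")

    @property
    def owned_atom_indices(self) -> list[int]:
        return [i for i in self.atom_indices if i not in self.guest_atoms]


@dataclass
class MolecularSystem:
    """Atoms, bonds and (after fragmentation) fragments."""

    atoms: list[Atom]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    fragments: list[Fragment] | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float).reshape(len(self.atoms), 3)
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def neighbours(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def fragment_of(self) -> dict[int, list[int]]:
        """Map atom index -> list of fragment ids containing it."""
        if self.fragments is None:
            raise ValueError("system is not fragmented")
        out: dict[int, list[int]] = {a.index: [] for a in self.atoms}
        for frag in self.fragments:
            for i in frag.atom_indices:
                out[i].append(frag.id)
        return out

    def copy(self) -> "MolecularSystem":
        atoms = [
            Atom(a.index, a.element, a.position.copy(), a.residue_id,
                 a.residue_name, a.frozen)
            for a in self.atoms
        ]
        frags = None
        if self.fragments is not None:
            frags = [
                Fragment(f.id, list(f.atom_indices), list(f.shared_atoms),
                         set(f.guest_atoms), f.net_charge, f.layer)
                for f in self.fragments
            ]
        return MolecularSystem(atoms, set(self.bonds), frags)

    def validate_fragmentation(self) -> None:
        """Check the partition-up-to-shared-atoms identity."""
        if self.fragments is None:
            raise ValueError("system is not fragmented")
        counts: dict[int, int] = {}
        for frag in self.fragments:
            for i in frag.atom_indices:
                counts[i] = counts.get(i, 0) + 1
        if set(counts) != {a.index for a in self.atoms}:
            raise ValueError("fragmentation does not cover every atom")
        if any(c > 2 for c in counts.values()):
            raise ValueError("an atom belongs to more than two fragments")
        n_shared_pairs = sum(1 for c in counts.values() if c == 2)
        total = sum(len(f.atom_indices) for f in self.fragments)
        if total - n_shared_pairs != self.n_atoms:
            raise ValueError("fragment rosters are inconsistent with shared atoms")


# --------------------------------------------------------------------------
# XYZ I/O
# --------------------------------------------------------------------------

_ANNOT_RE = re.compile(r"(\w+)=\s*(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)")


def parse_annotation(comment: str) -> dict[str, float]:
    """Parse ``R= -1.95 E= -10.0`` style key/value pairs from a comment line."""
    return {k: float(v) for k, v in _ANNOT_RE.findall(comment)}


def _read_xyz_blocks(path: str | Path) -> list[tuple[list[str], np.ndarray, str]]:
    lines = Path(path).read_text().splitlines()
    blocks = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError(f"line {pos + 1}: expected an atom count, got "
                             f"{lines[pos]!r}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        rows = lines[pos + 2: pos + 2 + natoms]
        if len(rows) < natoms:
            raise ParseError(f"line {pos + 1}: atom count {natoms} but only "
                             f"{len(rows)} atom rows follow")
        elements, coords = [], np.empty((natoms, 3))
        for k, row in enumerate(rows):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"line {pos + 3 + k}: expected 'element x y z'")
            elements.append(parts[0].capitalize())
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {pos + 3 + k}: non-numeric coordinate")
        blocks.append((elements, coords, comment))
        pos += 2 + natoms
    if not blocks:
        raise ParseError("empty XYZ file")
    return blocks


def _system_from_block(elements: list[str], coords: np.ndarray) -> MolecularSystem:
    atoms = [Atom(i, el, xyz) for i, (el, xyz) in enumerate(zip(elements, coords))]
    return MolecularSystem(atoms)


def read_xyz(path: str | Path, frame: int = 0) -> MolecularSystem:
    """Read one frame (default: the first) of a standard XYZ file."""
    blocks = _read_xyz_blocks(path)
    try:
        elements, coords, _ = blocks[frame]
    except IndexError:
        raise ParseError(f"frame {frame} requested but file has {len(blocks)} frames")
    return _system_from_block(elements, coords)


def read_frames(path: str | Path) -> list[tuple[MolecularSystem, dict[str, float]]]:
    """Read every frame of a multi-frame XYZ with annotated comment lines."""
    return [
        (_system_from_block(el, xyz), parse_annotation(comment))
        for el, xyz, comment in _read_xyz_blocks(path)
    ]


def write_frames(
    frames: list[tuple[MolecularSystem, dict[str, float]]],
    path: str | Path,
) -> None:
    """Write annotated multi-frame XYZ; round-trips through :func:`read_frames`.

    ``frames`` is a list of ``(system, annotations)`` pairs; annotation
    values are written as ``key= value`` on the comment line.
    """
    roster = None
    out = []
    for system, annot in frames:
        els = system.elements()
        if roster is None:
            roster = els
        elif els != roster:
            raise ValueError("all frames must share the same atom roster")
        comment = " ".join(f"{k}= {v:.10g}" for k, v in annot.items())
        out.append(f"{system.n_atoms}")
        out.append(comment)
        for a in system.atoms:
            x, y, z = a.position
            out.append(f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# --------------------------------------------------------------------------
# PDB I/O (Biopython for records, plus a CONECT pass)
# --------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "H2O", "TIP3", "SOL"}


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in KNOWN_ELEMENTS:
        # two-letter element only when the PDB name starts in column 13
        if stripped[:2].capitalize() in {"Cl", "Br", "Na", "Fe", "Zn", "Mg", "Ca"}:
            return stripped[:2].capitalize()
    return stripped[0].upper()


def read_pdb(path: str | Path) -> MolecularSystem:
    """Read ATOM/HETATM (and CONECT) records of a PDB file.

    Residue identity is ``(chain, resSeq, iCode)``; waters keep their
    residue name so :func:`fragment_by_residue` can treat them as one
    fragment each.  Alternate locations collapse to the highest occupancy
    (with a warning); ANISOU/TER records are ignored.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("system", str(path))
    model = next(structure.get_models())

    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    residue_key_to_id: dict[tuple, int] = {}
    for chain in model:
        for residue in chain:
            het, resseq, icode = residue.id
            key = (chain.id, resseq, icode)
            if key not in residue_key_to_id:
                residue_key_to_id[key] = len(residue_key_to_id)
            rid = residue_key_to_id[key]
            for pdb_atom in residue:
                if pdb_atom.is_disordered():
                    warnings.warn(
                        f"altloc collision at {residue.resname}{resseq} "
                        f"{pdb_atom.get_name()}: keeping highest occupancy")
                    pdb_atom = pdb_atom.selected_child
                element = (pdb_atom.element or "").strip().capitalize()
                if element not in KNOWN_ELEMENTS:
                    element = _element_from_name(pdb_atom.get_name())
                if pdb_atom.coord is None or not np.all(np.isfinite(pdb_atom.coord)):
                    raise ParseError(
                        f"missing coordinates for atom {pdb_atom.get_serial_number()}")
                idx = len(atoms)
                atoms.append(Atom(idx, element, np.asarray(pdb_atom.coord, float),
                                  residue_id=rid,
                                  residue_name=residue.resname.strip()))
                serial_to_index[pdb_atom.get_serial_number()] = idx

    bonds: set[tuple[int, int]] = set()
    for line in Path(path).read_text().splitlines():
        if not line.startswith("CONECT"):
            continue
        serials = [int(tok) for tok in line[6:].split()]
        if not serials:
            continue
        a = serial_to_index.get(serials[0])
        for s in serials[1:]:
            b = serial_to_index.get(s)
            if a is not None and b is not None and a != b:
                bonds.add((min(a, b), max(a, b)))

    system = MolecularSystem(atoms, bonds)
    system._atom_names = {  # kept for peptide-boundary detection
        a.index: name for a, name in zip(
            atoms, [at.get_name().strip() for ch in model for res in ch for at in res])
    }
    return system


# --------------------------------------------------------------------------
# bond detection and fragmentation
# --------------------------------------------------------------------------

def detect_bonds(system: MolecularSystem, scale: float = 1.2) -> MolecularSystem:
    """Add a bond for every pair with ``r <= scale * (r_cov_i + r_cov_j)``."""
    coords = system.coordinates()
    radii = np.array([covalent_radius(a.element) for a in system.atoms])
    n = system.n_atoms
    if n > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        cutoff = scale * (radii[:, None] + radii[None, :])
        ii, jj = np.nonzero(dist <= cutoff)
        for i, j in zip(ii, jj):
            if i < j:
                system.bonds.add((int(i), int(j)))
    return system


def _peptide_boundary(system: MolecularSystem, names: dict[int, str],
                      rid_atoms: dict[int, list[int]]) -> dict[int, int]:
    """Reassign carbonyl C/O across peptide bonds to the next residue.

    Returns a map atom index -> fragment (residue) index it moves to, so
    the crossing bond becomes Calpha-C(carbonyl) with Calpha shared.
    """
    moves: dict[int, int] = {}
    rid_of = {a.index: a.residue_id for a in system.atoms}
    for i, j in system.bonds:
        ri, rj = rid_of[i], rid_of[j]
        if ri == rj:
            continue
        # orient: c_atom in earlier residue named C bonded to N in later one
        for c, nn in ((i, j), (j, i)):
            if names.get(c) == "C" and names.get(nn) == "N" and rid_of[c] < rid_of[nn]:
                moves[c] = rid_of[nn]
                # carbonyl O follows its C
                for o in system.neighbours(c):
                    if names.get(o) == "O" and rid_of[o] == rid_of[c]:
                        moves[o] = rid_of[nn]
    return moves


def fragment_by_residue(system: MolecularSystem) -> MolecularSystem:
    """One fragment per residue/water, with shared atoms at covalent cuts.

    For peptides (atom names available) the cut is placed at the
    Calpha-C(carbonyl) bond and Calpha is the shared atom; for any other
    inter-residue covalent bond the bond atom belonging to the
    earlier-indexed fragment is shared into the later one.  Shared-atom
    ownership (for charge bookkeeping) stays with the atom's own residue.
    """
    rid_atoms: dict[int, list[int]] = {}
    for a in system.atoms:
        rid_atoms.setdefault(a.residue_id, []).append(a.index)
    if any(not v for v in rid_atoms.values()):
        raise ValueError("residue with zero atoms")

    names = getattr(system, "_atom_names", {})
    if names:
        for atom_idx, new_rid in _peptide_boundary(system, names, rid_atoms).items():
            old = system.atoms[atom_idx].residue_id
            rid_atoms[old].remove(atom_idx)
            rid_atoms.setdefault(new_rid, []).append(atom_idx)

    rids = sorted(rid_atoms)
    frag_id_of_rid = {rid: k for k, rid in enumerate(rids)}
    rosters = {frag_id_of_rid[rid]: sorted(rid_atoms[rid]) for rid in rids}
    frag_of_atom = {i: fid for fid, roster in rosters.items() for i in roster}

    shared: dict[int, list[tuple[int, int]]] = {fid: [] for fid in rosters}
    guests: dict[int, set[int]] = {fid: set() for fid in rosters}
    for i, j in sorted(system.bonds):
        fi, fj = frag_of_atom[i], frag_of_atom[j]
        if fi == fj:
            continue
        # boundary atom = the bond atom in the earlier fragment, shared into
        # the later fragment (for peptides this is Calpha after the carbonyl
        # reassignment above)
        (lo_fid, lo_atom), (hi_fid, _) = sorted([(fi, i), (fj, j)])
        if lo_atom in guests[hi_fid]:
            continue  # bond already represented by this shared atom
        rosters[hi_fid].append(lo_atom)
        guests[hi_fid].add(lo_atom)
        shared[lo_fid].append((lo_atom, hi_fid))
        shared[hi_fid].append((lo_atom, lo_fid))

    system.fragments = [
        Fragment(fid, sorted(rosters[fid]), sorted(shared[fid]),
                 guests[fid], net_charge=0)
        for fid in sorted(rosters)
    ]
    system.validate_fragmentation()
    return system


def assign_residues_by_connectivity(system: MolecularSystem) -> MolecularSystem:
    """Give every covalently connected component its own residue id.

    Used for bare-XYZ input, where residues are unknown: after bond
    detection each molecule becomes one residue (hence one fragment).
    """
    parent = list(range(system.n_atoms))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in system.bonds:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots: dict[int, int] = {}
    for atom in system.atoms:
        root = find(atom.index)
        if root not in roots:
            roots[root] = len(roots)
        atom.residue_id = roots[root]
        if atom.residue_name == "UNK":
            atom.residue_name = "MOL"
    return system


def write_fragment_map(system: MolecularSystem, path: str | Path) -> None:
    """Plain-text fragment map: ``fragment_id atom_indices... charge``.

    Atom indices are written 1-based (user-facing convention).
    """
    if system.fragments is None:
        raise ValueError("system is not fragmented")
    lines = []
    for f in system.fragments:
        idx = " ".join(str(i + 1) for i in f.atom_indices)
        lines.append(f"{f.id} {idx} {f.net_charge}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fragment_map(system: MolecularSystem, path: str | Path
                      ) -> MolecularSystem:
    """Apply a fragment map file (see :func:`write_fragment_map`).

    Shared atoms are inferred: an atom listed in two fragments is shared,
    owned by the fragment whose residue contains it (falling back to the
    first listing).
    """
    rows: list[tuple[int, list[int], int]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"line {ln}: need 'fragment_id atoms... charge'")
        rows.append((int(parts[0]), [int(p) - 1 for p in parts[1:-1]],
                     int(parts[-1])))

    membership: dict[int, list[int]] = {}
    for fid, atom_idx, _ in rows:
        for i in atom_idx:
            membership.setdefault(i, []).append(fid)

    fragments = []
    for fid, atom_idx, charge in rows:
        shared = sorted(
            (i, next(p for p in membership[i] if p != fid))
            for i in atom_idx if len(membership[i]) > 1)
        # owner = the first fragment listing the atom (deterministic; maps
        # written by write_fragment_map list owners first)
        guests = {i for i, _ in shared if membership[i][0] != fid}
        fragments.append(Fragment(fid, sorted(atom_idx), shared, guests,
                                  net_charge=charge))
    system.fragments = fragments
    system.validate_fragmentation()
    return system


def interfragment_distance(I: Fragment, J: Fragment,
                           system: MolecularSystem) -> float:
    """Unitless interfragment distance.

    ``R_IJ = min over (i in I, j in J) of r_ij / (Rvdw_i + Rvdw_j)``,
    excluding atoms the two fragments share.  Symmetric and invariant under
    rigid motion.
    """
    if I.id == J.id:
        raise ValueError("interfragment distance requires two distinct fragments")
    common = set(I.atom_indices) & set(J.atom_indices)
    ai = [i for i in I.atom_indices if i not in common]
    aj = [j for j in J.atom_indices if j not in common]
    if not ai or not aj:
        raise ValueError(
            f"fragments {I.id} and {J.id}: one side has only shared atoms")
    coords = system.coordinates()
    radii = np.array([vdw_radius(a.element) for a in system.atoms])
    diff = coords[ai][:, None, :] - coords[aj][None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    denom = radii[ai][:, None] + radii[aj][None, :]
    return float((dist / denom).min())
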