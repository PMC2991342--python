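"""Assemble a 3D peptide ligand from a one-letter sequence, then relax it.

The assembly walks the sequence once: place the beginning hydrogen cap, then
for each residue a backbone fragment (skipped for proline, whose side-chain
fragment embeds the backbone) followed by the residue's side-chain fragment,
alternating the fragment orientation up/down with residue parity so
neighboring side chains leave on opposite sides of the backbone plane, and
finally the carboxyl cap. Fragments are placed by rigid transforms: the
incoming attach_in atom lands exactly one ideal bond from the previous
fragment's attach_out atom.

The optimizer is a deterministic greedy coordinate search over side-chain
torsions (30° grid then 5° refinement) that minimizes a steric clash score —
the sum over atom pairs at graph distance ≥ 3 bonds of
max(0, threshold − d)². It never increases the score and leaves all bonded
geometry untouched; a different conformer engine can be substituted through
the ``optimizer`` hook of :func:`build_peptide`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import networkx as nx
import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .fragment_library import Fragment, FragmentLibrary
from .structure_io import Atom, PeptideStructure

ONE_TO_THREE = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

BACKBONE_ATOM_NAMES = frozenset({"N", "H", "H2", "CA", "C", "O", "OXT", "HXT"})

# bond-detection cutoffs, Å: pairs closer than this are considered bonded
_HEAVY_BOND_CUTOFF = 1.95
_HYDROGEN_BOND_CUTOFF = 1.45


class SequenceError(ValueError):
    """A ligand sequence string is not a valid peptide sequence."""


@dataclass
class BuildOptions:
    """Knobs for assembly and steric relaxation."""

    optimize: bool = True
    clash_threshold: float = 2.0  # Å; pairs closer than this are penalized
    max_optimizer_iterations: int = 200
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not self.clash_threshold > 0:
            raise ValueError("clash_threshold must be > 0")
        if self.max_optimizer_iterations < 1:
            raise ValueError("max_optimizer_iterations must be positive")


@dataclass
class AssemblyInfo:
    """Provenance of one build: what was placed where."""

    sequence: str
    orientations: list[str] = field(default_factory=list)
    backbone_placements: int = 0
    ca_indices: list[int] = field(default_factory=list)
    residue_ranges: list[tuple[int, int]] = field(default_factory=list)


def validate_sequence(sequence: str) -> None:
    """Accept iff every character is a standard one-letter residue code.

    Case-insensitive; reports every offending position in one error.
    """
    if not sequence:
        raise SequenceError("empty sequence")
    bad = [
        (i, c)
        for i, c in enumerate(sequence, start=1)
        if c.upper() not in ONE_TO_THREE
    ]
    if bad:
        detail = "; ".join(f"illegal character {c!r} at position {i}" for i, c in bad)
        raise SequenceError(f"invalid sequence {sequence!r}: {detail}")


def _assemble(
    sequence: str, library: FragmentLibrary
) -> tuple[PeptideStructure, AssemblyInfo]:
    seq = sequence.upper()
    info = AssemblyInfo(sequence=seq)
    names: list[str] = []
    elements: list[str] = []
    resseqs: list[int] = []
    resnames: list[str] = []
    coords: list[np.ndarray] = []
    mirror_y = np.array([1.0, -1.0, 1.0])

    def place(frag: Fragment, offset: np.ndarray, resseq: int, resname: str,
              flip_y: bool = False) -> tuple[int, int]:
        start = len(names)
        for a in frag.atoms:
            pos = a.position * mirror_y if flip_y else a.position
            names.append(a.name)
            elements.append(a.element)
            resseqs.append(resseq)
            resnames.append(resname)
            coords.append(pos + offset)
        return start, len(names)

    # step 1: add beginning
    beg = library.beginning
    place(beg, np.zeros(3), 1, ONE_TO_THREE[seq[0]])
    cursor = beg.atoms[beg.attach_out].position + beg.out_bond

    for i, letter in enumerate(seq, start=1):
        orientation = "up" if i % 2 == 1 else "down"
        info.orientations.append(orientation)
        resname = ONE_TO_THREE[letter]
        if letter != "P":
            # steps 2-3: backbone fragment, then the side chain off its CA
            bb = library.backbone(orientation)
            start, _ = place(bb, cursor - bb.atoms[bb.attach_in].position,
                             i, resname)
            info.backbone_placements += 1
            ca_index = start + bb.atom_names.index("CA")
            info.ca_indices.append(ca_index)
            ca_pos = coords[ca_index]
            sc = library.sidechain(letter, orientation)
            s0, s1 = place(sc, ca_pos, i, resname)
            info.residue_ranges.append((start, s1))
            cursor = coords[start + bb.attach_out] + bb.out_bond
        else:
            # proline: no standalone backbone — it lives in the side chain
            # fragment; at even positions the fragment is reflected through
            # the chain plane to keep the backbone zig-zag phase
            pro = library.sidechain("P", orientation)
            flip = orientation == "down"
            start, s1 = place(pro, cursor - pro.atoms[pro.attach_in].position,
                              i, resname, flip_y=flip)
            info.ca_indices.append(start + pro.atom_names.index("CA"))
            info.residue_ranges.append((start, s1))
            out_bond = pro.out_bond * mirror_y if flip else pro.out_bond
            cursor = coords[start + pro.attach_out] + out_bond

    # step 5: add end (the carboxyl O and its hydrogen at the final C)
    end = library.end
    place(end, cursor - end.atoms[end.attach_in].position, len(seq),
          ONE_TO_THREE[seq[-1]])

    atoms = [
        Atom(serial=k + 1, name=names[k], residue_name=resnames[k], chain_id="A",
             residue_seq=resseqs[k], x=float(coords[k][0]), y=float(coords[k][1]),
             z=float(coords[k][2]), element=elements[k])
        for k in range(len(names))
    ]
    return PeptideStructure(atoms, title=seq), info


# ---------------------------------------------------------------------------
# bond graph and torsions


def infer_bonds(structure: PeptideStructure) -> list[tuple[int, int]]:
    """Covalent bonds by interatomic distance (idealized template geometry).

    Heavy-heavy pairs bond below 1.95 Å, hydrogen-heavy below 1.45 Å
    (covers S–H at 1.34 Å); hydrogens never bond each other.
    """
    coords = structure.coordinates()
    is_h = np.array([a.element.upper() == "H" for a in structure.atoms])
    d = cdist(coords, coords)
    cutoff = np.full(d.shape, _HEAVY_BOND_CUTOFF)
    cutoff[is_h, :] = _HYDROGEN_BOND_CUTOFF
    cutoff[:, is_h] = _HYDROGEN_BOND_CUTOFF
    cutoff[np.ix_(is_h, is_h)] = 0.0
    i_idx, j_idx = np.where((d < cutoff) & (d > 1e-6))
    return sorted({(int(i), int(j)) for i, j in zip(i_idx, j_idx) if i < j})


def nonbonded_pairs(
    structure: PeptideStructure, bonds: Optional[list[tuple[int, int]]] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of atom pairs separated by ≥ 3 bonds in the bond graph."""
    n = len(structure.atoms)
    if bonds is None:
        bonds = infer_bonds(structure)
    adj = np.zeros((n, n), dtype=bool)
    for i, j in bonds:
        adj[i, j] = adj[j, i] = True
    two = adj @ adj
    excluded = adj | two | np.eye(n, dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    keep = ~excluded[iu, ju]
    return iu[keep], ju[keep]


def clash_score(
    structure: PeptideStructure,
    threshold: float = 2.0,
    pairs: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Sum over non-bonded pairs of max(0, threshold − d)²."""
    if pairs is None:
        pairs = nonbonded_pairs(structure)
    coords = structure.coordinates()
    return _clash_score_coords(coords, pairs, threshold)


def _clash_score_coords(coords, pairs, threshold) -> float:
    i_idx, j_idx = pairs
    if len(i_idx) == 0:
        return 0.0
    d = np.linalg.norm(coords[i_idx] - coords[j_idx], axis=1)
    return float(np.sum(np.clip(threshold - d, 0.0, None) ** 2))


@dataclass(frozen=True)
class Torsion:
    """A rotatable side-chain bond: axis atoms and the atoms that move."""

    axis: tuple[int, int]
    moving: tuple[int, ...]


def find_sidechain_torsions(
    structure: PeptideStructure, bonds: Optional[list[tuple[int, int]]] = None
) -> list[Torsion]:
    """Rotatable torsions: acyclic heavy-atom bonds whose distal side is
    entirely side-chain atoms with at least two of them (ring bonds, e.g.
    proline's, are excluded automatically because they are not bridges)."""
    if bonds is None:
        bonds = infer_bonds(structure)
    g = nx.Graph(bonds)
    g.add_nodes_from(range(len(structure.atoms)))
    is_h = [a.element.upper() == "H" for a in structure.atoms]
    is_backbone = [a.name in BACKBONE_ATOM_NAMES for a in structure.atoms]
    torsions: list[Torsion] = []
    for a, b in nx.bridges(g):
        if is_h[a] or is_h[b]:
            continue
        h = g.copy()
        h.remove_edge(a, b)
        comp_b = nx.node_connected_component(h, b)
        comp_a = nx.node_connected_component(h, a)
        # orient the axis so the moving side excludes the chain start
        if 0 in comp_b:
            a, b = b, a
            comp_b = comp_a
        if len(comp_b) < 2:
            continue
        if any(is_backbone[k] for k in comp_b):
            continue
        torsions.append(Torsion(axis=(a, b), moving=tuple(sorted(comp_b))))
    torsions.sort(key=lambda t: t.axis)
    return torsions


def _rotated(coords: np.ndarray, torsion: Torsion, angle_deg: float) -> np.ndarray:
    a, b = torsion.axis
    axis = coords[b] - coords[a]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return coords
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm)
    out = coords.copy()
    moving = list(torsion.moving)
    out[moving] = rot.apply(coords[moving] - coords[a]) + coords[a]
    return out


def optimize_structure(
    structure: PeptideStructure,
    options: Optional[BuildOptions] = None,
    bonds: Optional[list[tuple[int, int]]] = None,
) -> PeptideStructure:
    """Greedy torsion search minimizing the clash score.

    Identical topology and bonded geometry are preserved exactly (rigid
    rotations about bonds); the clash score never increases; the result is
    deterministic. Structures with no rotatable torsions (or already
    clash-free) are returned unchanged.
    """
    options = options or BuildOptions()
    if bonds is None:
        bonds = infer_bonds(structure)
    pairs = nonbonded_pairs(structure, bonds)
    torsions = find_sidechain_torsions(structure, bonds)
    threshold = options.clash_threshold
    coords = structure.coordinates()
    best = _clash_score_coords(coords, pairs, threshold)
    if not torsions or best == 0.0:
        return structure

    for _ in range(options.max_optimizer_iterations):
        improved = False
        for torsion in torsions:
            # coarse 30° grid, then 5° refinement around the winner
            best_angle = 0.0
            local_best = best
            for angle in range(30, 360, 30):
                s = _clash_score_coords(_rotated(coords, torsion, angle), pairs, threshold)
                if s < local_best - 1e-12:
                    local_best, best_angle = s, float(angle)
            for delta in range(-25, 30, 5):
                if delta == 0 and best_angle == 0.0:
                    continue
                angle = best_angle + delta
                s = _clash_score_coords(_rotated(coords, torsion, angle), pairs, threshold)
                if s < local_best - 1e-12:
                    local_best, best_angle = s, angle
            if local_best < best - 1e-12:
                coords = _rotated(coords, torsion, best_angle)
                best = local_best
                improved = True
        if not improved or best == 0.0:
            break
    return structure.with_coordinates(coords)


# ---------------------------------------------------------------------------
# the public build entry point

Optimizer = Callable[[PeptideStructure, BuildOptions], PeptideStructure]


def build_peptide(
    sequence: str,
    library: Optional[FragmentLibrary] = None,
    options: Optional[BuildOptions] = None,
    *,
    optimizer: Optional[Optimizer] = None,
    with_info: bool = False,
):
    """Build a 3D ligand structure for a one-letter residue sequence.

    Returns a :class:`PeptideStructure` with one residue per letter
    (``residue_seq`` 1..n), chain A, serials from 1. With ``with_info=True``
    also returns the :class:`AssemblyInfo` provenance record. ``optimizer``
    replaces the internal steric relaxation when given.
    """
    validate_sequence(sequence)
    library = library or FragmentLibrary.create()
    library.validate()
    options = options or BuildOptions()
    structure, info = _assemble(sequence, library)
    if options.optimize:
        if optimizer is not None:
            structure = optimizer(structure, options)
        else:
            structure = optimize_structure(structure, options)
    return (structure, info) if with_info else structure
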