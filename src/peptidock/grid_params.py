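"""Complete a grid-box template into a fully prepared grid parameter file.

The user supplies only the grid box (npts / spacing / gridcenter); this
module fills in the receptor path, the ligand's docking atom types, and one
affinity-map line per type, which is what the grid engine needs. Computing
the affinity maps themselves is the grid engine's job, not ours.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from .peptide_builder import infer_bonds
from .structure_io import PeptideStructure, parse_gpf_template

# element → docking atom type; hydrogens are typed by what they are bonded to
_ELEMENT_TYPES = {"C": "C", "N": "N", "O": "OA", "S": "SA"}

# lines the preparation step owns and therefore rewrites
_MANAGED_KEYWORDS = {"receptor", "ligand_types", "map"}

_RING_PLANARITY_TOL = 0.1  # Å max deviation from the best-fit ring plane


class AtomTypingError(ValueError):
    pass


def _planar(coords: np.ndarray, tol: float = _RING_PLANARITY_TOL) -> bool:
    centered = coords - coords.mean(axis=0)
    # smallest singular direction is the plane normal; its projection is the deviation
    _, _, vt = np.linalg.svd(centered)
    dev = centered @ vt[-1]
    return bool(np.max(np.abs(dev)) < tol)


def _aromatic_carbons(structure: PeptideStructure, bonds: list[tuple[int, int]]) -> set[int]:
    """Carbons in flat 5/6-membered C/N rings (proline's puckered ring is not)."""
    g = nx.Graph(bonds)
    g.add_nodes_from(range(len(structure.atoms)))
    coords = structure.coordinates()
    aromatic: set[int] = set()
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        elements = {structure.atoms[i].element.upper() for i in cycle}
        if not elements <= {"C", "N"}:
            continue
        if _planar(coords[cycle]):
            aromatic |= {i for i in cycle if structure.atoms[i].element.upper() == "C"}
    return aromatic


def extract_atom_types(
    ligand: PeptideStructure, bonds: Optional[list[tuple[int, int]]] = None
) -> list[str]:
    """Docking atom types of a ligand, deduplicated in first-occurrence order.

    Element-based: C→C (flat-ring carbons→A), N→N, O→OA, S→SA; hydrogens
    bonded to N/O/S→HD, while carbon-bonded (nonpolar) hydrogens carry no
    affinity map of their own under the polar-hydrogen united-atom
    convention and contribute no type. Unmappable elements raise.
    """
    if bonds is None:
        bonds = infer_bonds(ligand)
    aromatic = _aromatic_carbons(ligand, bonds)
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(ligand.atoms))}
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    types: list[str] = []
    for idx, atom in enumerate(ligand.atoms):
        el = atom.element.upper()
        if el == "H":
            partners = {ligand.atoms[k].element.upper() for k in neighbors[idx]}
            if partners & {"N", "O", "S"}:
                t = "HD"
            else:
                continue  # nonpolar hydrogen: no map
        elif el in _ELEMENT_TYPES:
            t = "A" if (el == "C" and idx in aromatic) else _ELEMENT_TYPES[el]
        else:
            raise AtomTypingError(f"no docking atom type for element '{atom.element}'")
        if t not in types:
            types.append(t)
    return types


def prepare_gpf(template: str, ligand: PeptideStructure, receptor_path: str | Path) -> str:
    """Fill a grid template: keep the box verbatim, add receptor/types/maps.

    Deterministic and idempotent — stale receptor/ligand_types/map lines in
    the template are replaced, never duplicated, and the grid box re-parses
    unchanged.
    """
    import io

    parse_gpf_template(io.StringIO(template))  # validates npts/spacing/gridcenter
    kept: list[str] = []
    for line in template.splitlines():
        keyword = line.split("#", 1)[0].split()[:1]
        if keyword and keyword[0].lower() in _MANAGED_KEYWORDS:
            continue
        kept.append(line)
    while kept and not kept[-1].strip():
        kept.pop()
    types = extract_atom_types(ligand)
    receptor_path = Path(receptor_path)
    out = list(kept)
    out.append(f"receptor {receptor_path}")
    out.append("ligand_types " + " ".join(types))
    for t in types:
        out.append(f"map {receptor_path.stem}.{t}.map")
    return "\n".join(out) + "\n"
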