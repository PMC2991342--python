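"""The 44 template fragments concatenated to form a peptide ligand.

Composition: one beginning cap (the hydrogen that starts the chain), one end
cap (the hydrogen and oxygen completing the carboxyl terminus), a backbone in
two orientations, and a side chain for each of the twenty standard residues
in two orientations (up and down). Proline's side-chain fragments embed the
backbone atoms, because the ring bonds the side chain back to the backbone
nitrogen and the chain takes its characteristic bend there.

Geometry is idealized: standard bond lengths (peptide C–N 1.33 Å, N–CA
1.46 Å, CA–C 1.52 Å, C=O 1.23 Å), a planar extended backbone zig-zag in the
fragment xy-plane, and side chains grown with tetrahedral zig-zags and
regular polygon rings in the fragment xz-plane. "Up" means the side chain
extends toward +z; the down fragment is the reflection of the up fragment
through the backbone plane (z → −z). Only polar hydrogens (on N, O, S) are
carried, plus the terminal caps and glycine's single side-group hydrogen.

Generation is seed-free and byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .structure_io import Atom, format_atom_record, read_pdb

# idealized bond lengths, Å
BOND_LENGTHS = {
    "C-N": 1.33,   # peptide bond
    "N-CA": 1.46,
    "CA-C": 1.52,
    "C=O": 1.23,
    "N-H": 1.01,
    "O-H": 0.96,
    "S-H": 1.34,
    "C-C": 1.52,
    "C-O": 1.42,
    "C-S": 1.81,
    "C-Nsc": 1.47,  # aliphatic C–N in side chains
    "Car-Car": 1.39,  # aromatic ring edge
    "Cam-N": 1.33,  # amide / guanidinium C–N
    "C-Ocarb": 1.25,  # carboxylate C–O
}

# planar backbone zig-zag directions (unit vectors in the xy-plane)
_DP = np.array([math.cos(math.pi / 6), 0.5, 0.0])   # "d+": up-right
_DM = np.array([math.cos(math.pi / 6), -0.5, 0.0])  # "d−": down-right

# tetrahedral side-chain zig-zag directions (unit vectors in the xz-plane)
_SU = np.array([1.0 / math.sqrt(3.0), 0.0, math.sqrt(2.0 / 3.0)])
_SW = np.array([-1.0 / math.sqrt(3.0), 0.0, math.sqrt(2.0 / 3.0)])
_ZUP = np.array([0.0, 0.0, 1.0])  # rings grow straight up from their entry atom

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

KIND_BEGINNING = "beginning"
KIND_END = "end"
KIND_BACKBONE = "backbone"
KIND_SIDECHAIN = "sidechain"


@dataclass(frozen=True)
class FragmentAtom:
    """An atom in the fragment's local frame."""

    name: str
    element: str
    position: np.ndarray


@dataclass(frozen=True)
class Fragment:
    """One assembly template with its attachment bookkeeping.

    ``attach_in`` indexes the atom that bonds to the preceding fragment
    (absent for the beginning cap); ``attach_out`` the atom that bonds to the
    following fragment (absent for the end cap and for side chains other than
    proline). ``out_bond`` is the local-frame vector from the attach_out atom
    to where the next fragment's attach_in atom belongs. Side-chain local
    frames are relative to the CA attachment point at the origin; backbone
    and cap frames put their attach_in atom at the origin.
    """

    kind: str
    atoms: tuple[FragmentAtom, ...]
    residue_code: Optional[str] = None
    orientation: Optional[str] = None
    attach_in: Optional[int] = None
    attach_out: Optional[int] = None
    out_bond: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("fragment must contain at least one atom")
        if self.kind in (KIND_BEGINNING, KIND_END) and self.orientation is not None:
            raise ValueError(f"{self.kind} fragment carries no orientation")
        for idx in (self.attach_in, self.attach_out):
            if idx is not None and not (0 <= idx < len(self.atoms)):
                raise ValueError(f"attachment index {idx} out of range")

    @property
    def key(self) -> tuple:
        return (self.kind, self.residue_code, self.orientation)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def filename(self) -> str:
        if self.kind == KIND_BACKBONE:
            return f"backbone_{self.orientation}.pdb"
        if self.kind == KIND_SIDECHAIN:
            return f"sidechain_{self.residue_code}_{self.orientation}.pdb"
        return f"{self.kind}.pdb"


def _frag_atoms(entries: list[tuple[str, np.ndarray]]) -> tuple[FragmentAtom, ...]:
    out = []
    for name, pos in entries:
        element = name.lstrip("0123456789")[0].upper()
        out.append(FragmentAtom(name=name, element=element, position=np.asarray(pos, float)))
    return tuple(out)


def _mirror_z(fragment: Fragment) -> Fragment:
    atoms = tuple(
        FragmentAtom(a.name, a.element, a.position * np.array([1.0, 1.0, -1.0]))
        for a in fragment.atoms
    )
    out_bond = None
    if fragment.out_bond is not None:
        out_bond = fragment.out_bond * np.array([1.0, 1.0, -1.0])
    return Fragment(
        kind=fragment.kind,
        atoms=atoms,
        residue_code=fragment.residue_code,
        orientation="down",
        attach_in=fragment.attach_in,
        attach_out=fragment.attach_out,
        out_bond=out_bond,
    )


def _mirror_y(fragment: Fragment) -> Fragment:
    atoms = tuple(
        FragmentAtom(a.name, a.element, a.position * np.array([1.0, -1.0, 1.0]))
        for a in fragment.atoms
    )
    out_bond = None
    if fragment.out_bond is not None:
        out_bond = fragment.out_bond * np.array([1.0, -1.0, 1.0])
    return Fragment(
        kind=fragment.kind,
        atoms=atoms,
        residue_code=fragment.residue_code,
        orientation="down",
        attach_in=fragment.attach_in,
        attach_out=fragment.attach_out,
        out_bond=out_bond,
    )


# ---------------------------------------------------------------------------
# geometry helpers (all in the canonical "up" fragment frame)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _branch_pair(
    origin: np.ndarray, direction: np.ndarray, length_a: float, length_b: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two substituents splayed symmetrically out of the xz-plane (±y)."""
    d = _unit(direction)
    da = _unit(d + 1.4 * np.array([0.0, 1.0, 0.0]))
    db = _unit(d - 1.4 * np.array([0.0, 1.0, 0.0]))
    return origin + length_a * da, origin + length_b * db


def _hexagon(entry: np.ndarray, direction: np.ndarray, side: float) -> list[np.ndarray]:
    """Regular hexagon in the xz-plane; vertex 0 is ``entry``."""
    d = _unit(direction)
    m = np.array([d[2], 0.0, -d[0]])  # in-plane perpendicular
    center = entry + side * d
    verts = []
    for k in range(6):
        theta = math.pi - k * math.pi / 3.0
        verts.append(center + side * (math.cos(theta) * d + math.sin(theta) * m))
    return verts


def _pentagon(entry: np.ndarray, direction: np.ndarray, side: float) -> list[np.ndarray]:
    """Regular pentagon in the xz-plane; vertex 0 is ``entry``."""
    d = _unit(direction)
    m = np.array([d[2], 0.0, -d[0]])
    radius = side / (2.0 * math.sin(math.pi / 5.0))
    center = entry + radius * d
    verts = []
    for k in range(5):
        theta = math.pi - k * 2.0 * math.pi / 5.0
        verts.append(center + radius * (math.cos(theta) * d + math.sin(theta) * m))
    return verts


def _hexagon_from_edge(
    a: np.ndarray, b: np.ndarray, away: np.ndarray
) -> list[np.ndarray]:
    """Four new vertices completing a regular hexagon on shared edge a–b."""
    side = float(np.linalg.norm(b - a))
    mid = (a + b) / 2.0
    center = mid + (math.sqrt(3.0) / 2.0) * side * _unit(away)
    e1 = _unit(a - center)
    ortho = (b - center) - np.dot(b - center, e1) * e1
    e2 = _unit(ortho)
    verts = []
    for k in range(2, 6):  # k=0 is a, k=1 is b
        theta = k * math.pi / 3.0
        verts.append(center + side * (math.cos(theta) * e1 + math.sin(theta) * e2))
    return verts


def _nh_position(n: np.ndarray, neighbors: list[np.ndarray], length: float) -> np.ndarray:
    """Place a hydrogen on a trigonal N opposite the mean neighbor direction."""
    mean = np.mean([_unit(p - n) for p in neighbors], axis=0)
    return n + length * _unit(-mean)


# ---------------------------------------------------------------------------
# fragment construction


def _make_beginning() -> Fragment:
    # the hydrogen that starts the chain; bonds to the first backbone N
    return Fragment(
        kind=KIND_BEGINNING,
        atoms=_frag_atoms([("H2", np.zeros(3))]),
        attach_out=0,
        out_bond=BOND_LENGTHS["N-H"] * _DP,
    )


def _make_end() -> Fragment:
    # the hydrogen and oxygen completing the carboxyl at the final backbone C
    oxt = np.zeros(3)
    hxt = oxt + BOND_LENGTHS["O-H"] * np.array([1.0, 0.0, 0.0])
    return Fragment(
        kind=KIND_END,
        atoms=_frag_atoms([("OXT", oxt), ("HXT", hxt)]),
        attach_in=0,
    )


def _backbone_coords() -> dict[str, np.ndarray]:
    n = np.zeros(3)
    h = n + BOND_LENGTHS["N-H"] * np.array([0.0, 1.0, 0.0])
    ca = n + BOND_LENGTHS["N-CA"] * _DM
    c = ca + BOND_LENGTHS["CA-C"] * _DP
    o = c + BOND_LENGTHS["C=O"] * np.array([0.0, 1.0, 0.0])
    return {"N": n, "H": h, "CA": ca, "C": c, "O": o}


def _make_backbone_up() -> Fragment:
    bb = _backbone_coords()
    atoms = _frag_atoms([(k, bb[k]) for k in ("N", "H", "CA", "C", "O")])
    return Fragment(
        kind=KIND_BACKBONE,
        atoms=atoms,
        orientation="up",
        attach_in=0,
        attach_out=3,
        out_bond=BOND_LENGTHS["C-N"] * _DM,
    )


_CA = _backbone_coords()["CA"]  # side-chain frames are CA-relative; CB leaves from here


def _sidechain_entries(code: str) -> list[tuple[str, np.ndarray]]:
    """Side-chain atom layout in the canonical up frame, CA at the origin."""
    L = BOND_LENGTHS
    # CB leaves CA perpendicular to the backbone plane: equidistant from the
    # flanking N and C whichever parity the residue lands on
    cb = L["C-C"] * _ZUP
    if code == "G":
        # glycine's entire side group is a single hydrogen on CA
        return [("HA2", 1.09 * _ZUP)]
    if code == "A":
        return [("CB", cb)]
    if code == "S":
        og = cb + L["C-O"] * _SW
        return [("CB", cb), ("OG", og), ("HG", og + L["O-H"] * _SU)]
    if code == "C":
        sg = cb + L["C-S"] * _SW
        return [("CB", cb), ("SG", sg), ("HG", sg + L["S-H"] * _SU)]
    if code == "T":
        og1, cg2 = _branch_pair(cb, _SW, L["C-O"], L["C-C"])
        hg1 = og1 + L["O-H"] * _unit(og1 - cb)
        return [("CB", cb), ("OG1", og1), ("HG1", hg1), ("CG2", cg2)]
    if code == "V":
        cg1, cg2 = _branch_pair(cb, _SW, L["C-C"], L["C-C"])
        return [("CB", cb), ("CG1", cg1), ("CG2", cg2)]
    if code == "L":
        cg = cb + L["C-C"] * _SW
        cd1, cd2 = _branch_pair(cg, _SU, L["C-C"], L["C-C"])
        return [("CB", cb), ("CG", cg), ("CD1", cd1), ("CD2", cd2)]
    if code == "I":
        cg1, cg2 = _branch_pair(cb, _SW, L["C-C"], L["C-C"])
        d = _unit(cg1 - cb)
        cd1 = cg1 + L["C-C"] * _unit(d * np.array([1.0, -1.0, 1.0]))
        return [("CB", cb), ("CG1", cg1), ("CG2", cg2), ("CD1", cd1)]
    if code == "M":
        cg = cb + L["C-C"] * _SW
        sd = cg + L["C-S"] * _SU
        ce = sd + 1.79 * _SW
        return [("CB", cb), ("CG", cg), ("SD", sd), ("CE", ce)]
    if code == "D":
        cg = cb + L["C-C"] * _SW
        od1, od2 = _branch_pair(cg, _SU, L["C-Ocarb"], L["C-Ocarb"])
        return [("CB", cb), ("CG", cg), ("OD1", od1), ("OD2", od2)]
    if code == "E":
        cg = cb + L["C-C"] * _SW
        cd = cg + L["C-C"] * _SU
        oe1, oe2 = _branch_pair(cd, _SW, L["C-Ocarb"], L["C-Ocarb"])
        return [("CB", cb), ("CG", cg), ("CD", cd), ("OE1", oe1), ("OE2", oe2)]
    if code == "N":
        cg = cb + L["C-C"] * _SW
        od1, nd2 = _branch_pair(cg, _SU, L["C=O"], L["Cam-N"])
        h1, h2 = _branch_pair(nd2, _unit(nd2 - cg), L["N-H"], L["N-H"])
        return [("CB", cb), ("CG", cg), ("OD1", od1), ("ND2", nd2),
                ("HD21", h1), ("HD22", h2)]
    if code == "Q":
        cg = cb + L["C-C"] * _SW
        cd = cg + L["C-C"] * _SU
        oe1, ne2 = _branch_pair(cd, _SW, L["C=O"], L["Cam-N"])
        h1, h2 = _branch_pair(ne2, _unit(ne2 - cd), L["N-H"], L["N-H"])
        return [("CB", cb), ("CG", cg), ("CD", cd), ("OE1", oe1), ("NE2", ne2),
                ("HE21", h1), ("HE22", h2)]
    if code == "K":
        cg = cb + L["C-C"] * _SW
        cd = cg + L["C-C"] * _SU
        ce = cd + L["C-C"] * _SW
        nz = ce + L["C-Nsc"] * _SU
        hz1, hz2 = _branch_pair(nz, _SW, L["N-H"], L["N-H"])
        return [("CB", cb), ("CG", cg), ("CD", cd), ("CE", ce), ("NZ", nz),
                ("HZ1", hz1), ("HZ2", hz2)]
    if code == "R":
        cg = cb + L["C-C"] * _SW
        cd = cg + L["C-C"] * _SU
        ne = cd + L["C-Nsc"] * _SW
        cz = ne + L["Cam-N"] * _SU
        he = _nh_position(ne, [cd, cz], L["N-H"])
        nh1, nh2 = _branch_pair(cz, _SW, L["Cam-N"], L["Cam-N"])
        h11, h12 = _branch_pair(nh1, _unit(nh1 - cz), L["N-H"], L["N-H"])
        h21, h22 = _branch_pair(nh2, _unit(nh2 - cz), L["N-H"], L["N-H"])
        return [("CB", cb), ("CG", cg), ("CD", cd), ("NE", ne), ("HE", he),
                ("CZ", cz), ("NH1", nh1), ("HH11", h11), ("HH12", h12),
                ("NH2", nh2), ("HH21", h21), ("HH22", h22)]
    if code == "F" or code == "Y":
        cg_entry = cb + 1.50 * _SW
        verts = _hexagon(cg_entry, _ZUP, L["Car-Car"])
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        entries = [("CB", cb)] + list(zip(names, verts))
        if code == "Y":
            center = np.mean(verts, axis=0)
            cz = verts[3]
            oh = cz + 1.36 * _unit(cz - center)
            hh = oh + L["O-H"] * _unit(cz - center)
            entries += [("OH", oh), ("HH", hh)]
        return entries
    if code == "H":
        cg_entry = cb + 1.50 * _SW
        verts = _pentagon(cg_entry, _ZUP, 1.37)
        names = ["CG", "ND1", "CE1", "NE2", "CD2"]
        center = np.mean(verts, axis=0)
        nd1 = verts[1]
        hd1 = nd1 + L["N-H"] * _unit(nd1 - center)
        return [("CB", cb)] + list(zip(names, verts)) + [("HD1", hd1)]
    if code == "W":
        cg_entry = cb + 1.50 * _SW
        verts = _pentagon(cg_entry, _ZUP, 1.40)
        cg, cd1, ne1, ce2, cd2 = verts
        pent_center = np.mean(verts, axis=0)
        he1 = ne1 + L["N-H"] * _unit(ne1 - pent_center)
        away = _unit((cd2 + ce2) / 2.0 - pent_center)
        cz2, ch2, cz3, ce3 = _hexagon_from_edge(ce2, cd2, away)
        return [("CB", cb), ("CG", cg), ("CD1", cd1), ("NE1", ne1), ("HE1", he1),
                ("CE2", ce2), ("CD2", cd2), ("CE3", ce3), ("CZ3", cz3),
                ("CH2", ch2), ("CZ2", cz2)]
    raise ValueError(f"no side-chain template for residue code {code!r}")


def _make_sidechain_up(code: str) -> Fragment:
    if code == "P":
        return _make_proline_up()
    entries = _sidechain_entries(code)
    return Fragment(
        kind=KIND_SIDECHAIN,
        atoms=_frag_atoms(entries),
        residue_code=code,
        orientation="up",
        attach_in=0,
    )


def _make_proline_up() -> Fragment:
    """Proline carries its backbone in the fragment: the ring closes onto N.

    The ring is puckered (CG pushed out of the N/CA/CB/CD plane) — this is
    both chemically right and what distinguishes it from the flat aromatic
    rings during atom typing.
    """
    L = BOND_LENGTHS
    bb = _backbone_coords()
    n, ca, c, o = bb["N"], bb["CA"], bb["C"], bb["O"]
    yhat = np.array([0.0, 1.0, 0.0])
    # CB and CD lean apart within the backbone plane (±y keeps both clear of
    # the flanking carbonyl carbons) and the ring apex CG closes it above
    cb = ca + L["C-C"] * _unit(_ZUP - 0.25 * yhat)
    cd = n + L["C-Nsc"] * _unit(_ZUP + 0.45 * yhat)
    mid = (cb + cd) / 2.0
    half = float(np.linalg.norm(cb - cd)) / 2.0
    height = math.sqrt(max(L["C-C"] ** 2 - half ** 2, 0.04))
    axis = _unit(cb - cd)
    normal = _unit(_ZUP - np.dot(_ZUP, axis) * axis)
    cg = mid + height * normal
    entries = [("N", n), ("CA", ca), ("C", c), ("O", o),
               ("CB", cb), ("CG", cg), ("CD", cd)]
    return Fragment(
        kind=KIND_SIDECHAIN,
        atoms=_frag_atoms(entries),
        residue_code="P",
        orientation="up",
        attach_in=0,
        attach_out=2,
        out_bond=L["C-N"] * _DM,
    )


def build_fragments() -> dict[tuple, Fragment]:
    """Construct the complete 44-fragment set in memory (deterministic)."""
    frags: dict[tuple, Fragment] = {}
    for f in (_make_beginning(), _make_end()):
        frags[f.key] = f
    up = _make_backbone_up()
    frags[up.key] = up
    frags[_mirror_y(up).key] = _mirror_y(up)
    for code in STANDARD_RESIDUES:
        scu = _make_sidechain_up(code)
        frags[scu.key] = scu
        scd = _mirror_z(scu)
        frags[scd.key] = scd
    return frags


# ---------------------------------------------------------------------------
# the library container and its on-disk form

EXPECTED_SIZE = 44


class IncompleteLibraryError(ValueError):
    pass


@dataclass
class FragmentLibrary:
    """The 44 fragments keyed by (kind, residue_code, orientation)."""

    fragments: dict[tuple, Fragment] = field(default_factory=dict)

    @classmethod
    def create(cls) -> "FragmentLibrary":
        """The built-in idealized library, generated in memory."""
        lib = cls(build_fragments())
        lib.validate()
        return lib

    def validate(self) -> None:
        missing = [k for k in expected_keys() if k not in self.fragments]
        if missing:
            raise IncompleteLibraryError(
                f"incomplete library: missing fragment {missing[0]}"
                + (f" (+{len(missing) - 1} more)" if len(missing) > 1 else "")
            )
        if len(self.fragments) != EXPECTED_SIZE:
            raise IncompleteLibraryError(
                f"library has {len(self.fragments)} fragments, expected {EXPECTED_SIZE}"
            )
        for orientation in ("up", "down"):
            pro = self.sidechain("P", orientation)
            if not {"N", "CA", "C", "O"} <= set(pro.atom_names):
                raise IncompleteLibraryError(
                    "proline side-chain fragment must embed the backbone atoms"
                )

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def beginning(self) -> Fragment:
        return self.fragments[(KIND_BEGINNING, None, None)]

    @property
    def end(self) -> Fragment:
        return self.fragments[(KIND_END, None, None)]

    def backbone(self, orientation: str) -> Fragment:
        return self.fragments[(KIND_BACKBONE, None, orientation)]

    def sidechain(self, code: str, orientation: str) -> Fragment:
        return self.fragments[(KIND_SIDECHAIN, code.upper(), orientation)]


def expected_keys() -> list[tuple]:
    keys = [(KIND_BEGINNING, None, None), (KIND_END, None, None)]
    keys += [(KIND_BACKBONE, None, o) for o in ("up", "down")]
    keys += [
        (KIND_SIDECHAIN, code, o)
        for code in STANDARD_RESIDUES
        for o in ("up", "down")
    ]
    return keys


_RESNAME_FOR_FILE = {KIND_BEGINNING: "BEG", KIND_END: "CAP", KIND_BACKBONE: "BBN"}


def _fragment_text(fragment: Fragment) -> str:
    lines = [f"REMARK KIND {fragment.kind}"]
    if fragment.residue_code is not None:
        lines.append(f"REMARK RESIDUE {fragment.residue_code}")
    if fragment.orientation is not None:
        lines.append(f"REMARK ORIENTATION {fragment.orientation}")
    if fragment.attach_in is not None:
        lines.append(f"REMARK ATTACH_IN {fragment.attach_in + 1}")
    if fragment.attach_out is not None:
        lines.append(f"REMARK ATTACH_OUT {fragment.attach_out + 1}")
    if fragment.out_bond is not None:
        b = fragment.out_bond
        lines.append(f"REMARK OUT_BOND {b[0]:.6f} {b[1]:.6f} {b[2]:.6f}")
    resname = _RESNAME_FOR_FILE.get(fragment.kind) or three_letter(fragment.residue_code)
    for i, a in enumerate(fragment.atoms, start=1):
        atom = Atom(
            serial=i, name=a.name, residue_name=resname, chain_id="A",
            residue_seq=1, x=round(a.position[0], 3), y=round(a.position[1], 3),
            z=round(a.position[2], 3), element=a.element,
        )
        lines.append(format_atom_record(atom))
    lines.append("END")
    return "\n".join(lines) + "\n"


def three_letter(code: Optional[str]) -> str:
    from Bio.Data.IUPACData import protein_letters_1to3

    if code is None:
        raise ValueError("residue code missing")
    return protein_letters_1to3[code.upper()].upper()


def generate_fragment_library(dest: str | Path) -> FragmentLibrary:
    """Write the 44 fragment PDB files to ``dest`` and return the library.

    Deterministic: repeated calls produce byte-identical files.
    """
    dest = Path(dest)
    try:
        dest.mkdir(parents=True, exist_ok=True)
        lib = FragmentLibrary.create()
        for frag in lib.fragments.values():
            (dest / frag.filename()).write_text(_fragment_text(frag))
    except OSError as exc:
        raise OSError(f"cannot write fragment library to {dest}: {exc}") from exc
    return lib


def _parse_fragment_file(path: Path) -> Fragment:
    meta: dict[str, list[str]] = {}
    for line in path.read_text().splitlines():
        if line.startswith("REMARK "):
            tokens = line.split()
            if len(tokens) >= 2:
                meta[tokens[1]] = tokens[2:]
    structure = read_pdb(path)
    atoms = tuple(
        FragmentAtom(a.name, a.element, a.position) for a in structure.atoms
    )
    out_bond = None
    if "OUT_BOND" in meta:
        out_bond = np.array([float(v) for v in meta["OUT_BOND"]], dtype=float)
    return Fragment(
        kind=meta["KIND"][0],
        atoms=atoms,
        residue_code=meta.get("RESIDUE", [None])[0],
        orientation=meta.get("ORIENTATION", [None])[0],
        attach_in=int(meta["ATTACH_IN"][0]) - 1 if "ATTACH_IN" in meta else None,
        attach_out=int(meta["ATTACH_OUT"][0]) - 1 if "ATTACH_OUT" in meta else None,
        out_bond=out_bond,
    )


def load_fragment_library(src: str | Path) -> FragmentLibrary:
    """Load a generated library directory, validating completeness."""
    src = Path(src)
    fragments: dict[tuple, Fragment] = {}
    reference = FragmentLibrary.create()
    for key in expected_keys():
        path = src / reference.fragments[key].filename()
        if not path.exists():
            raise IncompleteLibraryError(f"incomplete library: missing fragment {key}")
        frag = _parse_fragment_file(path)
        fragments[frag.key] = frag
    lib = FragmentLibrary(fragments)
    lib.validate()
    return lib
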