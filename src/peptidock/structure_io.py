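"""Text formats the toolkit touches: PDB, GPF grid templates, and docking logs.

All coordinates are Å in the right-handed PDB convention; inhibition
constants are normalized to molar internally regardless of the unit the
docking log printed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np

Source = Union[str, Path, IO[str]]

# gas constant in cal mol^-1 K^-1 and the reference temperature used by
# docking engines when converting a binding free energy into Ki
R_CAL = 1.987
T_KELVIN = 298.15
RT_KCAL = R_CAL * T_KELVIN / 1000.0

_KI_UNIT_FACTORS = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
}


class PdbFormatError(ValueError):
    """A PDB/DLG record could not be parsed or written."""


class GpfFormatError(ValueError):
    """A grid parameter template is incomplete or invalid."""


class DlgFormatError(ValueError):
    """A docking log could not be parsed."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record: name, residue assignment, and Å coordinates."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    x: float
    y: float
    z: float
    element: str

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not self.name or len(self.name) > 4:
            raise PdbFormatError(f"atom name {self.name!r} must be 1-4 characters")
        if self.residue_seq < 1:
            raise ValueError(f"residue_seq must be positive, got {self.residue_seq}")
        if not self.element:
            raise ValueError("atom element must be non-empty")
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError(f"non-finite coordinate in atom {self.serial}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def moved_to(self, xyz: Sequence[float]) -> "Atom":
        x, y, z = (float(v) for v in xyz)
        return replace(self, x=x, y=y, z=z)


@dataclass
class PeptideStructure:
    """An ordered set of atoms representing a built ligand or a receptor."""

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")
        seqs = [a.residue_seq for a in self.atoms]
        if any(b < a for a, b in zip(seqs, seqs[1:])):
            raise ValueError("residue_seq values must be non-decreasing in atom order")

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions in Å."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "PeptideStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coordinates of shape {(len(self.atoms), 3)}")
        return PeptideStructure(
            [a.moved_to(xyz) for a, xyz in zip(self.atoms, coords)], title=self.title
        )

    def normalized(self) -> "PeptideStructure":
        """Copy with serials renumbered contiguously from 1 in atom order."""
        return PeptideStructure(
            [replace(a, serial=i + 1) for i, a in enumerate(self.atoms)],
            title=self.title,
        )

    def centroid(self) -> np.ndarray:
        return self.coordinates().mean(axis=0)

    def residue_sequence(self) -> list[str]:
        """Residue names in residue_seq order, one per residue."""
        out: list[str] = []
        seen: set[int] = set()
        for a in self.atoms:
            if a.residue_seq not in seen:
                seen.add(a.residue_seq)
                out.append(a.residue_name)
        return out


@dataclass(frozen=True)
class GridBox:
    """Axis-aligned docking search volume: grid intervals, spacing, center."""

    npts: tuple[int, int, int]
    spacing: float
    center: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.npts) != 3 or any(n <= 0 for n in self.npts):
            raise GpfFormatError(f"npts must be three positive integers, got {self.npts}")
        if any(n % 2 for n in self.npts):
            raise GpfFormatError(f"npts must all be even (grid convention), got {self.npts}")
        if not self.spacing > 0:
            raise GpfFormatError(f"spacing must be > 0, got {self.spacing}")
        if len(self.center) != 3 or any(not math.isfinite(c) for c in self.center):
            raise GpfFormatError(f"gridcenter must be a finite 3D point, got {self.center}")

    @property
    def extent(self) -> np.ndarray:
        """Edge length per axis in Å: npts × spacing."""
        return np.array(self.npts, dtype=float) * self.spacing

    def contains(self, point: Sequence[float]) -> bool:
        """Closed-bound test: points exactly on a face count as inside."""
        p = np.asarray(point, dtype=float)
        half = self.extent / 2.0
        return bool(np.all(np.abs(p - np.asarray(self.center)) <= half + 1e-12))


@dataclass
class DockedConformation:
    """One docking run's pose with its score and inhibition constant."""

    run_index: int
    energy: float  # estimated free energy of binding, kcal/mol
    ki: float  # estimated inhibition constant, molar
    atoms: list[Atom]
    cluster_rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.run_index < 1:
            raise ValueError(f"run_index must be ≥ 1, got {self.run_index}")
        if not self.ki > 0:
            raise ValueError(f"ki must be > 0, got {self.ki}")
        if not self.atoms:
            raise ValueError("conformation must have atoms")

    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def centroid(self) -> np.ndarray:
        return self.coordinates().mean(axis=0)


# ---------------------------------------------------------------------------
# PDB


def _open_lines(source: Source) -> list[str]:
    if isinstance(source, (str, Path)):
        return Path(source).read_text().splitlines()
    return source.read().splitlines()


def _parse_atom_record(line: str, lineno: int) -> Atom:
    # wwPDB v3.3 fixed columns for ATOM/HETATM
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip() or " "
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip()
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(f"malformed ATOM record at line {lineno}: {line!r}") from exc
    if not element:
        # fall back on the atom-name convention; peptide elements are single letters
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else ""
    try:
        return Atom(serial, name, residue_name, chain_id, residue_seq, x, y, z, element)
    except ValueError as exc:
        raise PdbFormatError(f"invalid ATOM record at line {lineno}: {exc}") from exc


def read_pdb(source: Source, title: str = "") -> PeptideStructure:
    """Read all ATOM/HETATM records in file order; other records are ignored.

    Raises :class:`PdbFormatError` if the input contains no atoms or a
    malformed fixed-width record (the error names the offending line).
    """
    atoms: list[Atom] = []
    for lineno, line in enumerate(_open_lines(source), start=1):
        if line.startswith(("ATOM  ", "HETATM", "ATOM ")):
            atoms.append(_parse_atom_record(line, lineno))
    if not atoms:
        raise PdbFormatError("no atoms: input contains no ATOM or HETATM records")
    return PeptideStructure(atoms, title=title)


def format_atom_record(atom: Atom, serial: Optional[int] = None, record: str = "ATOM") -> str:
    """One fixed-column ATOM/HETATM line (wwPDB v3.3 columns)."""
    if len(atom.name) > 4:
        raise PdbFormatError(f"atom name {atom.name!r} longer than 4 characters")
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    return (
        f"{record:<6s}{serial if serial is not None else atom.serial:>5d} "
        f"{name}{'':1s}{atom.residue_name:>3s} {atom.chain_id:1s}"
        f"{atom.residue_seq:>4d}{'':1s}   "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(structure: PeptideStructure, dest: Union[str, Path, IO[str]]) -> None:
    """Write fixed-column ATOM records (serials renumbered from 1), TER, END."""
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    for i, atom in enumerate(structure.atoms, start=1):
        lines.append(format_atom_record(atom, serial=i))
    last = structure.atoms[-1]
    lines.append(
        f"TER   {len(structure.atoms) + 1:>5d}      {last.residue_name:>3s} "
        f"{last.chain_id:1s}{last.residue_seq:>4d}"
    )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


# ---------------------------------------------------------------------------
# GPF grid templates


def _gpf_fields(source: Source) -> dict[str, list[str]]:
    found: dict[str, list[str]] = {}
    for line in _open_lines(source):
        tokens = line.split("#", 1)[0].split()
        if tokens:
            found.setdefault(tokens[0].lower(), tokens[1:])
    return found


def parse_gpf_template(source: Source) -> GridBox:
    """Extract the grid box from a GPF template.

    The template must carry ``npts``, ``spacing`` and ``gridcenter`` keyword
    lines; everything else is preserved verbatim by the template-completion
    step in :mod:`peptidock.grid_params`.
    """
    fields = _gpf_fields(source)
    missing = [k for k in ("npts", "spacing", "gridcenter") if k not in fields]
    if missing:
        raise GpfFormatError(f"incomplete template: missing {', '.join(missing)}")
    try:
        npts = tuple(int(v) for v in fields["npts"][:3])
        spacing = float(fields["spacing"][0])
        center = tuple(float(v) for v in fields["gridcenter"][:3])
    except (ValueError, IndexError) as exc:
        raise GpfFormatError(f"unparseable grid keyword values: {exc}") from exc
    if len(npts) != 3 or len(center) != 3:
        raise GpfFormatError("npts and gridcenter need three values each")
    return GridBox(npts=npts, spacing=spacing, center=center)


# ---------------------------------------------------------------------------
# DLG docking logs

_RUN_RE = re.compile(r"^Run:\s+(\d+)\s*$")
_ENERGY_RE = re.compile(
    r"Estimated Free Energy of Binding\s*=\s*([-+0-9.eE]+)\s*kcal/mol"
)
_KI_RE = re.compile(
    r"Estimated Inhibition Constant,\s*Ki\s*=\s*([-+0-9.eE]+)\s*([mMuUnNpPµ]?M)\b"
)
_CLUSTER_ROW_RE = re.compile(
    r"^\s*(\d+)\s*\|\s*([-+0-9.eE]+)\s*\|\s*(\d+)\s*\|\s*([-+0-9.eE]+)\s*\|\s*(\d+)"
)


def ki_to_molar(value: float, unit: str) -> float:
    """Normalize a printed Ki to molar; accepts M/mM/uM/µM/nM/pM, case-insensitive."""
    factor = _KI_UNIT_FACTORS.get(unit.strip().lower())
    if factor is None:
        raise DlgFormatError(f"unknown Ki unit {unit!r}")
    return value * factor


@dataclass(frozen=True)
class ClusterRow:
    """One clustering-histogram row: rank, lowest energy, its run, mean, size."""

    rank: int
    lowest_energy: float
    run_of_lowest: int
    mean_energy: float
    count: int


def parse_dlg(source: Source) -> list[DockedConformation]:
    """Parse a docking log into one conformation per run, in run order.

    Energy and Ki come from the ``DOCKED: USER`` header lines of each run;
    pose atoms from ``DOCKED: ATOM`` records. A trailing clustering histogram,
    when present, assigns each cluster's rank to its lowest-energy run.
    """
    runs: list[dict] = []
    current: Optional[dict] = None
    cluster_rows: list[ClusterRow] = []
    in_histogram = False
    for lineno, line in enumerate(_open_lines(source), start=1):
        m = _RUN_RE.match(line)
        if m:
            current = {"run": int(m.group(1)), "energy": None, "ki": None, "atoms": []}
            runs.append(current)
            in_histogram = False
            continue
        if "CLUSTERING HISTOGRAM" in line:
            in_histogram = True
            current = None
            continue
        if in_histogram:
            row = _CLUSTER_ROW_RE.match(line)
            if row:
                cluster_rows.append(
                    ClusterRow(
                        rank=int(row.group(1)),
                        lowest_energy=float(row.group(2)),
                        run_of_lowest=int(row.group(3)),
                        mean_energy=float(row.group(4)),
                        count=int(row.group(5)),
                    )
                )
            continue
        if current is None or not line.startswith("DOCKED: "):
            continue
        payload = line[len("DOCKED: "):]
        if payload.startswith(("ATOM", "HETATM")):
            current["atoms"].append(_parse_atom_record(payload, lineno))
        elif "Estimated Free Energy of Binding" in payload:
            m = _ENERGY_RE.search(payload)
            if not m:
                raise DlgFormatError(
                    f"unparseable energy line in run {current['run']} (line {lineno})"
                )
            current["energy"] = float(m.group(1))
        elif "Estimated Inhibition Constant" in payload:
            m = _KI_RE.search(payload)
            if not m:
                raise DlgFormatError(
                    f"unparseable Ki line in run {current['run']} (line {lineno})"
                )
            current["ki"] = ki_to_molar(float(m.group(1)), m.group(2))

    if not runs:
        raise DlgFormatError("empty log: no docking runs found")

    rank_of_run = {row.run_of_lowest: row.rank for row in cluster_rows}
    conformations = []
    for r in runs:
        if r["energy"] is None:
            raise DlgFormatError(f"run {r['run']}: missing binding energy")
        if r["ki"] is None:
            raise DlgFormatError(f"run {r['run']}: missing inhibition constant")
        if not r["atoms"]:
            raise DlgFormatError(f"run {r['run']}: no pose coordinates")
        conformations.append(
            DockedConformation(
                run_index=r["run"],
                energy=r["energy"],
                ki=r["ki"],
                atoms=r["atoms"],
                cluster_rank=rank_of_run.get(r["run"]),
            )
        )
    return conformations


def format_ki(ki_molar: float) -> str:
    """Render a molar Ki in the largest human unit with a mantissa ≥ 1."""
    for unit, factor in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9)):
        if ki_molar >= factor:
            return f"{ki_molar / factor:.10g} {unit}"
    return f"{ki_molar / 1e-12:.10g} pM"


def write_dlg(
    poses: Iterable[tuple[int, float, float, Sequence[Atom]]],
    dest: Union[str, Path, IO[str]],
    cluster_rows: Optional[Sequence[ClusterRow]] = None,
) -> None:
    """Write the docking-log dialect: (run_index, energy, ki_molar, atoms) per run."""
    lines: list[str] = []
    count = 0
    for run_index, energy, ki, atoms in poses:
        count += 1
        lines.append(f"Run:   {run_index}")
        lines.append(
            "DOCKED: USER    Estimated Free Energy of Binding    ="
            f"   {energy:+.7f} kcal/mol"
        )
        lines.append(
            "DOCKED: USER    Estimated Inhibition Constant, Ki   ="
            f"   {format_ki(ki)}"
        )
        lines.append("DOCKED: USER")
        for i, atom in enumerate(atoms, start=1):
            lines.append("DOCKED: " + format_atom_record(atom, serial=i))
        lines.append("DOCKED: TER")
        lines.append("")
    if count == 0:
        raise DlgFormatError("refusing to write a docking log with zero runs")
    if cluster_rows:
        lines.append("CLUSTERING HISTOGRAM")
        lines.append("Rank | Lowest Energy | Run | Mean Energy | Count")
        lines.append("_____|_______________|_____|_____________|______")
        for row in cluster_rows:
            lines.append(
                f"{row.rank:>4d} | {row.lowest_energy:>13.4f} | {row.run_of_lowest:>3d}"
                f" | {row.mean_energy:>11.4f} | {row.count:>5d}"
            )
        lines.append("")
    text = "\n".join(lines)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
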