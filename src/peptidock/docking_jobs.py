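"""Docking-campaign management over a pluggable backend.

A campaign is the cross-product of ligands × receptors × grid boxes, each
combination one job with a lifecycle (created → queued → running →
complete/failed). A backend is anything with
``run(ligand_path, receptor_path, gpf_path, n_runs, output_dir) →
BackendResult``; the shipped :class:`MockDockingBackend` emits valid docking
logs offline so campaigns are testable without a docking engine, and a real
engine adapter (see :class:`CommandBackend`) is the documented extension
point. Competitive-binding experiments chain two jobs: the best pose of
ligand A is merged into the receptor and ligand B is docked against the
complex, reusing the same grid-box template.
"""

from __future__ import annotations

import math
import shlex
import string
import subprocess
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np

from .fragment_library import FragmentLibrary
from .peptide_builder import BuildOptions, build_peptide, validate_sequence
from .results_analysis import rank_conformations
from .structure_io import (
    Atom,
    DockedConformation,
    PeptideStructure,
    RT_KCAL,
    parse_dlg,
    parse_gpf_template,
    read_pdb,
    write_dlg,
    write_pdb,
)

DEFAULT_N_RUNS = 100  # stochastic docking simulations per job
DEFAULT_POLL_INTERVAL = 10.0  # seconds between status checks


class JobStatus(str, Enum):
    CREATED = "created"
    QUEUED = "queued"
    RUNNING = "running"
    COMPLETE = "complete"
    FAILED = "failed"


_ALLOWED_TRANSITIONS = {
    JobStatus.CREATED: {JobStatus.QUEUED},
    JobStatus.QUEUED: {JobStatus.RUNNING},
    JobStatus.RUNNING: {JobStatus.COMPLETE, JobStatus.FAILED},
    JobStatus.COMPLETE: set(),
    JobStatus.FAILED: set(),
}


@dataclass
class DockingJob:
    """One (ligand, receptor, grid box) combination with lifecycle status."""

    job_id: int
    ligand_ref: str
    receptor_path: str
    gpf_path: str
    output_dir: str
    secondary_ligand_ref: Optional[str] = None
    n_runs: int = DEFAULT_N_RUNS
    status: JobStatus = JobStatus.CREATED
    error: Optional[str] = None
    ligand_path: Optional[str] = None
    dlg_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.job_id < 1:
            raise ValueError("job_id must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be ≥ 1")

    def advance(self, new: JobStatus) -> None:
        if new not in _ALLOWED_TRANSITIONS[self.status]:
            raise ValueError(f"illegal status transition {self.status.value} → {new.value}")
        self.status = new


@dataclass
class BackendResult:
    dlg_path: str
    exit_ok: bool
    message: str = ""


class DockingBackend(Protocol):
    def run(
        self, ligand_path: str, receptor_path: str, gpf_path: str,
        n_runs: int, output_dir: str,
    ) -> BackendResult: ...


@dataclass
class JobDefaults:
    n_runs: int = DEFAULT_N_RUNS
    output_dir: str = "."


def create_job_matrix(
    ligands: Sequence[str],
    receptors: Sequence[str],
    boxes: Sequence[str],
    defaults: Optional[JobDefaults] = None,
    secondaries: Optional[Sequence[Optional[str]]] = None,
) -> list[DockingJob]:
    """One job per (ligand, receptor, box), ids 1..N in ligand-major order.

    ``secondaries`` pairs a competitive secondary ligand with each primary
    ligand (same length as ``ligands``, entries may be None).
    """
    for name, axis in (("ligands", ligands), ("receptors", receptors), ("boxes", boxes)):
        if not axis:
            raise ValueError(f"empty axis: {name}")
    if secondaries is not None and len(secondaries) != len(ligands):
        raise ValueError("secondaries must pair one entry per ligand")
    defaults = defaults or JobDefaults()
    jobs = []
    job_id = 1
    for li, ligand in enumerate(ligands):
        for receptor in receptors:
            for box in boxes:
                jobs.append(
                    DockingJob(
                        job_id=job_id,
                        ligand_ref=str(ligand),
                        receptor_path=str(receptor),
                        gpf_path=str(box),
                        output_dir=defaults.output_dir,
                        secondary_ligand_ref=(
                            secondaries[li] if secondaries is not None else None
                        ),
                        n_runs=defaults.n_runs,
                    )
                )
                job_id += 1
    return jobs


# ---------------------------------------------------------------------------
# backends


class MockDockingBackend:
    """An offline docking engine double that emits valid docking logs.

    Per-run binding energies come from an explicit list or a seeded normal
    distribution; Ki follows from the energy through
    Ki = exp(ΔG·1000 / (R·T)) with R = 1.987 cal·mol⁻¹·K⁻¹, T = 298.15 K.
    Pose coordinates are the input ligand rigidly translated to a seeded
    uniform-random centroid inside the grid box. Output is byte-identical
    for a fixed configuration.
    """

    def __init__(
        self,
        energies: Optional[Sequence[float]] = None,
        seed: Optional[int] = None,
        energy_mean: float = -7.0,
        energy_sd: float = 1.5,
    ) -> None:
        if energies is None and seed is None:
            raise ValueError("mock backend needs an explicit energy list or a seed")
        self.energies = list(energies) if energies is not None else None
        self.seed = seed if seed is not None else 0
        self.energy_mean = energy_mean
        self.energy_sd = energy_sd

    @staticmethod
    def ki_from_energy(energy_kcal: float) -> float:
        return math.exp(energy_kcal / RT_KCAL)

    def run(
        self, ligand_path: str, receptor_path: str, gpf_path: str,
        n_runs: int, output_dir: str,
    ) -> BackendResult:
        ligand = read_pdb(ligand_path)
        box = parse_gpf_template(gpf_path)
        if self.energies is not None and len(self.energies) < n_runs:
            raise ValueError(
                f"mock backend configured with {len(self.energies)} energies "
                f"but {n_runs} runs requested"
            )
        rng = np.random.default_rng(self.seed)
        center = np.asarray(box.center, dtype=float)
        half = box.extent / 2.0
        coords = ligand.coordinates()
        centroid = coords.mean(axis=0)
        poses = []
        for i in range(1, n_runs + 1):
            if self.energies is not None:
                energy = float(self.energies[i - 1])
            else:
                energy = float(rng.normal(self.energy_mean, self.energy_sd))
            target = center + rng.uniform(-half, half)
            shift = target - centroid
            atoms = [a.moved_to(a.position + shift) for a in ligand.atoms]
            poses.append((i, energy, self.ki_from_energy(energy), atoms))
        dlg_path = (
            Path(output_dir)
            / f"{Path(ligand_path).stem}_{Path(receptor_path).stem}.dlg"
        )
        write_dlg(poses, dlg_path)
        return BackendResult(dlg_path=str(dlg_path), exit_ok=True)


class CommandBackend:
    """Adapter that shells out to a real docking engine.

    ``template`` is a command line with ``{ligand} {receptor} {gpf} {n_runs}
    {out_dir} {dlg}`` placeholders; the command must leave a docking log at
    ``{dlg}`` and exit 0.
    """

    def __init__(self, template: str) -> None:
        self.template = template

    def run(
        self, ligand_path: str, receptor_path: str, gpf_path: str,
        n_runs: int, output_dir: str,
    ) -> BackendResult:
        dlg = str(
            Path(output_dir)
            / f"{Path(ligand_path).stem}_{Path(receptor_path).stem}.dlg"
        )
        cmd = self.template.format(
            ligand=ligand_path, receptor=receptor_path, gpf=gpf_path,
            n_runs=n_runs, out_dir=output_dir, dlg=dlg,
        )
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        ok = proc.returncode == 0 and Path(dlg).exists()
        return BackendResult(dlg_path=dlg, exit_ok=ok, message=proc.stderr.strip())


# ---------------------------------------------------------------------------
# receptor-complex merging for competitive binding

_CHAIN_ALPHABET = string.ascii_uppercase + string.digits


def merge_complex(
    receptor: PeptideStructure, best_pose: DockedConformation
) -> PeptideStructure:
    """Receptor plus a docked pose as one structure (the new receptor).

    Pose atoms take the next unused chain id and residue numbers continuing
    past the receptor's; serials are renumbered contiguously.
    """
    if not best_pose.atoms:
        raise ValueError("pose has no atoms")
    used_chains = {a.chain_id for a in receptor.atoms}
    free = [c for c in _CHAIN_ALPHABET if c not in used_chains]
    if not free:
        raise ValueError("chain alphabet exhausted: no free chain id for the pose")
    chain = free[0]
    max_seq = max(a.residue_seq for a in receptor.atoms)
    min_pose_seq = min(a.residue_seq for a in best_pose.atoms)
    merged: list[Atom] = list(receptor.atoms)
    for a in best_pose.atoms:
        merged.append(
            Atom(
                serial=len(merged) + 1,
                name=a.name,
                residue_name=a.residue_name,
                chain_id=chain,
                residue_seq=max_seq + (a.residue_seq - min_pose_seq) + 1,
                x=a.x, y=a.y, z=a.z,
                element=a.element,
            )
        )
    return PeptideStructure(merged, title=receptor.title or "merged complex").normalized()


# ---------------------------------------------------------------------------
# the campaign runner


class Campaign:
    """Run jobs through a backend and track their statuses.

    Jobs are independent: one failure never touches another job's status or
    outputs, and serial execution order defines the observable results.
    ``poll_interval`` (seconds) is the cadence a watcher would re-check
    statuses at; the in-process tracker answers immediately.
    """

    def __init__(
        self,
        backend: DockingBackend,
        jobs: Optional[Sequence[DockingJob]] = None,
        poll_interval: float = DEFAULT_POLL_INTERVAL,
        library: Optional[FragmentLibrary] = None,
        build_options: Optional[BuildOptions] = None,
    ) -> None:
        self.backend = backend
        self.jobs: list[DockingJob] = list(jobs) if jobs else []
        self.poll_interval = poll_interval
        self.build_options = build_options or BuildOptions()
        self._library = library

    @property
    def library(self) -> FragmentLibrary:
        if self._library is None:
            self._library = FragmentLibrary.create()
        return self._library

    def add_jobs(self, jobs: Sequence[DockingJob]) -> None:
        self.jobs.extend(jobs)

    def poll_status(self) -> dict[int, JobStatus]:
        """Per-job status snapshot, keyed by job id."""
        return {job.job_id: job.status for job in self.jobs}

    def _next_job_id(self) -> int:
        return max((j.job_id for j in self.jobs), default=0) + 1

    def _resolve_ligand(self, ref: str, out_dir: Path) -> Path:
        """A ligand reference is either a PDB path or a residue sequence."""
        looks_like_path = (
            ref.lower().endswith(".pdb") or "/" in ref or "\\" in ref or Path(ref).exists()
        )
        if looks_like_path:
            path = Path(ref)
            if not path.exists():
                raise FileNotFoundError(f"ligand file not found: {ref}")
            return path
        validate_sequence(ref)
        seq = ref.upper()
        path = out_dir / f"{seq}.pdb"
        structure = build_peptide(seq, self.library, self.build_options)
        write_pdb(structure, path)
        return path

    @staticmethod
    def _fail(job: DockingJob, message: str) -> None:
        # walk the lifecycle forward to failed, whatever state we died in
        if job.status is JobStatus.CREATED:
            job.advance(JobStatus.QUEUED)
        if job.status is JobStatus.QUEUED:
            job.advance(JobStatus.RUNNING)
        if job.status is JobStatus.RUNNING:
            job.advance(JobStatus.FAILED)
        job.error = message

    def run_job(self, job: DockingJob) -> BackendResult:
        """Run one job to completion; failures are recorded, never raised."""
        if job.status not in (JobStatus.CREATED, JobStatus.QUEUED):
            raise ValueError(f"job {job.job_id} is {job.status.value}, cannot run")
        if job not in self.jobs:
            self.jobs.append(job)
        try:
            out_dir = Path(job.output_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            ligand_path = self._resolve_ligand(job.ligand_ref, out_dir)
            job.ligand_path = str(ligand_path)
            ligand = read_pdb(ligand_path)
            prepared = _prepare_job_gpf(job, ligand, out_dir)
            if job.status is JobStatus.CREATED:
                job.advance(JobStatus.QUEUED)
            job.advance(JobStatus.RUNNING)
            result = self.backend.run(
                str(ligand_path), str(job.receptor_path), str(prepared),
                job.n_runs, str(out_dir),
            )
            if result.exit_ok and Path(result.dlg_path).exists():
                n_parsed = len(parse_dlg(result.dlg_path))
                if n_parsed == job.n_runs:
                    job.dlg_path = result.dlg_path
                    job.advance(JobStatus.COMPLETE)
                    return result
                result.message = (
                    f"log has {n_parsed} runs, expected {job.n_runs}"
                )
            job.advance(JobStatus.FAILED)
            job.error = result.message or "backend reported failure"
            return result
        except Exception as exc:  # noqa: BLE001 — campaign must keep going
            self._fail(job, str(exc))
            return BackendResult(dlg_path="", exit_ok=False, message=str(exc))

    def run_all(self) -> list[BackendResult]:
        """Run every runnable job serially; competitive jobs chain."""
        results = []
        for job in list(self.jobs):
            if job.status not in (JobStatus.CREATED, JobStatus.QUEUED):
                continue
            if job.secondary_ligand_ref:
                results.extend(r for r in self.run_competitive(job) if r is not None)
            else:
                results.append(self.run_job(job))
        return results

    def run_competitive(
        self, job: DockingJob
    ) -> tuple[BackendResult, Optional[BackendResult]]:
        """Dock the primary ligand, merge its best pose into the receptor,
        then dock the secondary ligand against the complex (same grid box)."""
        if not job.secondary_ligand_ref:
            raise ValueError(f"job {job.job_id} has no secondary ligand")
        first = self.run_job(job)
        if job.status is not JobStatus.COMPLETE:
            return first, None
        conformations = parse_dlg(job.dlg_path)
        best = rank_conformations(conformations)[0].conformation
        receptor = read_pdb(job.receptor_path)
        merged = merge_complex(receptor, best)
        out_dir = Path(job.output_dir)
        merged_path = out_dir / f"merged_receptor_job{job.job_id}.pdb"
        write_pdb(merged, merged_path)
        second = DockingJob(
            job_id=self._next_job_id(),
            ligand_ref=job.secondary_ligand_ref,
            receptor_path=str(merged_path),
            gpf_path=job.gpf_path,
            output_dir=job.output_dir,
            n_runs=job.n_runs,
        )
        self.jobs.append(second)
        return first, self.run_job(second)


def _prepare_job_gpf(job: DockingJob, ligand: PeptideStructure, out_dir: Path) -> Path:
    from .grid_params import prepare_gpf

    template = Path(job.gpf_path).read_text()
    prepared = prepare_gpf(template, ligand, job.receptor_path)
    path = out_dir / f"{Path(job.gpf_path).stem}_job{job.job_id}_prepared.gpf"
    path.write_text(prepared)
    return path
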