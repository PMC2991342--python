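"""Rank docking poses, write per-run files and summaries, cluster, screen.

Rank 1 is the lowest estimated binding free energy; ties break toward the
lower run index. Clustering is the greedy energy-ordered scheme: walk poses
from best to worst energy and join the first existing cluster whose seed
pose is within an RMSD tolerance (plain coordinate RMSD, no superposition —
poses from one docking log share a frame), else found a new cluster.
Secondary-box screening reports which fraction of runs landed inside a
second, smaller grid box around a putative site, with best/average energy
and Ki over the runs inside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .structure_io import (
    DockedConformation,
    GridBox,
    PeptideStructure,
    write_pdb,
)

SUMMARY_HEADER = ("rank", "run", "energy_kcal_mol", "ki_molar", "cluster_rank")
DEFAULT_RMSD_TOLERANCE = 2.0  # Å


@dataclass(frozen=True)
class RankedResult:
    rank: int
    conformation: DockedConformation


@dataclass
class ScreeningReport:
    """Secondary-box screening: occupancy plus inside-run statistics.

    Statistics are over the runs whose pose centroid lies inside the box;
    when no run is inside they are left unset and ``has_inside`` is False.
    """

    fraction_inside: float
    n_inside: int
    n_total: int
    best_energy: Optional[float] = None
    mean_energy: Optional[float] = None
    best_ki: Optional[float] = None
    mean_ki: Optional[float] = None

    @property
    def has_inside(self) -> bool:
        return self.n_inside > 0


def rank_conformations(
    conformations: Sequence[DockedConformation],
) -> list[RankedResult]:
    """Stable ascending sort by energy, ties by run index; ranks 1..n."""
    if not conformations:
        raise ValueError("cannot rank an empty conformation list")
    ordered = sorted(conformations, key=lambda c: (c.energy, c.run_index))
    return [RankedResult(rank=i + 1, conformation=c) for i, c in enumerate(ordered)]


@dataclass
class ClusterResult:
    """Partition of poses into clusters ranked by their seed's energy."""

    clusters: list[list[DockedConformation]]
    rank_of_run: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def pose_rmsd(a: DockedConformation, b: DockedConformation) -> float:
    """Coordinate RMSD without superposition; atom counts must match."""
    ca, cb = a.coordinates(), b.coordinates()
    if ca.shape != cb.shape:
        raise ValueError(
            f"mismatched atom counts: run {a.run_index} has {len(ca)}, "
            f"run {b.run_index} has {len(cb)}"
        )
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def cluster_conformations(
    conformations: Sequence[DockedConformation],
    rmsd_tolerance: float = DEFAULT_RMSD_TOLERANCE,
) -> ClusterResult:
    """Greedy energy-ordered clustering against each cluster's seed pose."""
    if not conformations:
        raise ValueError("cannot cluster an empty conformation list")
    ordered = [r.conformation for r in rank_conformations(conformations)]
    seeds: list[DockedConformation] = []
    clusters: list[list[DockedConformation]] = []
    rank_of_run: dict[int, int] = {}
    for conf in ordered:
        for ci, seed in enumerate(seeds):
            if pose_rmsd(conf, seed) <= rmsd_tolerance:
                clusters[ci].append(conf)
                rank_of_run[conf.run_index] = ci + 1
                break
        else:
            seeds.append(conf)
            clusters.append([conf])
            rank_of_run[conf.run_index] = len(clusters)
    return ClusterResult(clusters=clusters, rank_of_run=rank_of_run)


def write_result_files(
    ranked: Sequence[RankedResult],
    out_dir: str | Path,
    cluster_result: Optional[ClusterResult] = None,
) -> Path:
    """One PDB per pose (``rank_<rank>_run_<run>.pdb``) plus a summary table.

    Cluster ranks come from the docking log when it carried a clustering
    histogram; otherwise the greedy clustering at the default tolerance
    fills them in. Returns the summary path.
    """
    if not ranked:
        raise ValueError("no ranked results to write")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create result directory {out_dir}: {exc}") from exc
    if cluster_result is None and any(
        r.conformation.cluster_rank is None for r in ranked
    ):
        cluster_result = cluster_conformations([r.conformation for r in ranked])
    rows = []
    for r in ranked:
        conf = r.conformation
        cluster_rank = conf.cluster_rank
        if cluster_rank is None and cluster_result is not None:
            cluster_rank = cluster_result.rank_of_run.get(conf.run_index)
        pdb_path = out_dir / f"rank_{r.rank}_run_{conf.run_index}.pdb"
        structure = PeptideStructure(
            list(conf.atoms),
            title=f"rank {r.rank} run {conf.run_index} "
            f"energy {conf.energy:.4f} kcal/mol",
        )
        try:
            write_pdb(structure, pdb_path)
        except OSError as exc:
            raise OSError(f"cannot write {pdb_path}: {exc}") from exc
        rows.append(
            (r.rank, conf.run_index, f"{conf.energy:.4f}", f"{conf.ki:.6e}",
             cluster_rank if cluster_rank is not None else "NA")
        )
    summary_path = out_dir / "summary.txt"
    lines = ["\t".join(SUMMARY_HEADER)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    summary_path.write_text("\n".join(lines) + "\n")
    return summary_path


def screen_secondary_box(
    conformations: Sequence[DockedConformation], box: GridBox
) -> ScreeningReport:
    """Occupancy of a secondary grid box and statistics over inside runs.

    A run is inside iff its pose's unweighted atom centroid lies within the
    closed box volume (points exactly on a face count as inside).
    """
    if not conformations:
        raise ValueError("cannot screen an empty conformation list")
    inside = [c for c in conformations if box.contains(c.centroid())]
    report = ScreeningReport(
        fraction_inside=len(inside) / len(conformations),
        n_inside=len(inside),
        n_total=len(conformations),
    )
    if inside:
        energies = np.array([c.energy for c in inside])
        kis = np.array([c.ki for c in inside])
        report.best_energy = float(energies.min())
        report.mean_energy = float(energies.mean())
        report.best_ki = float(kis.min())
        report.mean_ki = float(kis.mean())
    return report


def format_screening_report(report: ScreeningReport) -> str:
    """Plain-text rendering in the style of the ranked-results summary."""
    lines = [
        f"runs_total\t{report.n_total}",
        f"runs_inside\t{report.n_inside}",
        f"percent_inside\t{100.0 * report.fraction_inside:.1f}",
    ]
    if report.has_inside:
        lines += [
            f"best_energy_kcal_mol\t{report.best_energy:.4f}",
            f"mean_energy_kcal_mol\t{report.mean_energy:.4f}",
            f"best_ki_molar\t{report.best_ki:.6e}",
            f"mean_ki_molar\t{report.mean_ki:.6e}",
        ]
    else:
        lines.append("note\tno runs inside the secondary box")
    return "\n".join(lines) + "\n"
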