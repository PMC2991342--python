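"""Job cross-product, lifecycle, mock backend, and competitive chaining."""

import math
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptidock import (
    Campaign,
    DockingJob,
    JobDefaults,
    JobStatus,
    MockDockingBackend,
    create_job_matrix,
    merge_complex,
    parse_dlg,
    rank_conformations,
    read_pdb,
    write_pdb,
)
from peptidock.structure_io import RT_KCAL


class FailingBackend:
    def run(self, *args, **kwargs):
        raise RuntimeError("engine exploded")


class TestJobMatrix:
    def test_ten_by_one_by_three_is_thirty(self):
        jobs = create_job_matrix([f"L{i}" for i in range(10)], ["r.pdb"],
                                 ["a.gpf", "b.gpf", "c.gpf"])
        assert len(jobs) == 30
        assert [j.job_id for j in jobs] == list(range(1, 31))

    def test_single_combination(self):
        jobs = create_job_matrix(["A"], ["r"], ["b"])
        assert len(jobs) == 1 and jobs[0].job_id == 1
        assert jobs[0].status is JobStatus.CREATED

    def test_five_ligands_one_receptor_one_box(self):
        seqs = ["CCMWF", "CDCMW", "CFWMW", "CHMWW", "CHWWM"]
        jobs = create_job_matrix(seqs, ["r"], ["b"])
        assert len(jobs) == 5
        assert [j.ligand_ref for j in jobs] == seqs

    def test_ligand_major_ordering(self):
        jobs = create_job_matrix(["L1", "L2"], ["R1"], ["B1", "B2"])
        assert [(j.ligand_ref, j.gpf_path) for j in jobs] == [
            ("L1", "B1"), ("L1", "B2"), ("L2", "B1"), ("L2", "B2")
        ]

    @pytest.mark.parametrize("axis", ["ligands", "receptors", "boxes"])
    def test_empty_axis_named(self, axis):
        kwargs = {"ligands": ["l"], "receptors": ["r"], "boxes": ["b"]}
        kwargs[axis] = []
        with pytest.raises(ValueError, match=f"empty axis: {axis}"):
            create_job_matrix(**kwargs)

    @settings(max_examples=30, deadline=None)
    @given(nl=st.integers(1, 6), nr=st.integers(1, 6), nb=st.integers(1, 6))
    def test_cardinality_property(self, nl, nr, nb):
        jobs = create_job_matrix([f"l{i}" for i in range(nl)],
                                 [f"r{i}" for i in range(nr)],
                                 [f"b{i}" for i in range(nb)])
        assert len(jobs) == nl * nr * nb
        assert sorted(j.job_id for j in jobs) == list(range(1, nl * nr * nb + 1))

    def test_default_runs_is_100(self):
        job = create_job_matrix(["l"], ["r"], ["b"])[0]
        assert job.n_runs == 100

    def test_status_transitions_enforced(self):
        job = DockingJob(1, "l", "r", "b", ".")
        with pytest.raises(ValueError, match="illegal status transition"):
            job.advance(JobStatus.COMPLETE)
        job.advance(JobStatus.QUEUED)
        job.advance(JobStatus.RUNNING)
        job.advance(JobStatus.COMPLETE)


class TestMockBackend:
    def test_ki_formula(self):
        # independent evaluation: exp(-6.0 / (1.987 * 298.15 / 1000))
        assert MockDockingBackend.ki_from_energy(-6.0) == pytest.approx(3.995e-5, rel=1e-3)
        assert MockDockingBackend.ki_from_energy(0.0) == 1.0

    def test_requires_energies_or_seed(self):
        with pytest.raises(ValueError, match="energy list or a seed"):
            MockDockingBackend()

    def test_thermodynamic_consistency_through_the_file(self, mock_dlg):
        confs = mock_dlg(seed=13, n_runs=50)
        for c in confs:
            assert abs(math.log(c.ki) - c.energy / RT_KCAL) < 1e-6

    def test_explicit_energies_recovered_exactly(self, mock_dlg):
        energies = [-5.25, -9.1, -7.004, -6.5]
        confs = mock_dlg(energies=energies)
        assert [c.energy for c in confs] == energies

    def test_byte_identical_for_fixed_seed(self, tmp_path, library, gpf_template):
        from peptidock import BuildOptions, build_peptide

        lig = tmp_path / "GA.pdb"
        write_pdb(build_peptide("GA", library, BuildOptions(optimize=False)), lig)
        backend = MockDockingBackend(seed=99)
        r1 = backend.run(str(lig), str(lig), str(gpf_template), 10, str(tmp_path))
        first = Path(r1.dlg_path).read_bytes()
        r2 = backend.run(str(lig), str(lig), str(gpf_template), 10, str(tmp_path))
        assert Path(r2.dlg_path).read_bytes() == first

    def test_poses_land_inside_the_grid_box(self, mock_dlg, gpf_template):
        from peptidock import parse_gpf_template

        box = parse_gpf_template(gpf_template)
        for c in mock_dlg(seed=5, n_runs=25):
            assert box.contains(c.centroid())


class TestCampaign:
    def _campaign(self, tmp_path, receptor_pdb, gpf_template, **kw):
        defaults = JobDefaults(n_runs=kw.pop("n_runs", 10),
                               output_dir=str(tmp_path / "out"))
        jobs = create_job_matrix(kw.pop("ligands", ["CCMWF"]),
                                 [str(receptor_pdb)], [str(gpf_template)], defaults)
        backend = kw.pop("backend", MockDockingBackend(seed=1))
        return Campaign(backend, jobs, **kw)

    def test_run_job_completes_and_builds_ligand(self, tmp_path, receptor_pdb, gpf_template):
        camp = self._campaign(tmp_path, receptor_pdb, gpf_template)
        result = camp.run_job(camp.jobs[0])
        assert camp.jobs[0].status is JobStatus.COMPLETE
        assert (tmp_path / "out" / "CCMWF.pdb").exists()
        assert len(parse_dlg(result.dlg_path)) == 10

    def test_default_simulation_count_flows_to_the_log(self, tmp_path, receptor_pdb, gpf_template):
        jobs = create_job_matrix(["GA"], [str(receptor_pdb)], [str(gpf_template)],
                                 JobDefaults(output_dir=str(tmp_path)))
        assert jobs[0].n_runs == 100
        camp = Campaign(MockDockingBackend(seed=2), jobs)
        result = camp.run_job(jobs[0])
        assert len(parse_dlg(result.dlg_path)) == 100

    def test_failure_is_recorded_not_raised_and_isolated(self, tmp_path, receptor_pdb, gpf_template):
        camp = self._campaign(tmp_path, receptor_pdb, gpf_template,
                              ligands=["GA", "AG"], backend=FailingBackend())
        first = camp.run_job(camp.jobs[0])
        assert not first.exit_ok
        assert camp.jobs[0].status is JobStatus.FAILED
        assert "engine exploded" in camp.jobs[0].error
        assert camp.jobs[1].status is JobStatus.CREATED  # untouched
        camp.backend = MockDockingBackend(seed=4)
        camp.run_job(camp.jobs[1])
        assert camp.jobs[1].status is JobStatus.COMPLETE

    def test_poll_interval_default_and_snapshot(self, tmp_path, receptor_pdb, gpf_template):
        camp = self._campaign(tmp_path, receptor_pdb, gpf_template)
        assert camp.poll_interval == 10.0
        assert camp.poll_status() == {1: JobStatus.CREATED}
        camp.run_job(camp.jobs[0])
        assert camp.poll_status() == {1: JobStatus.COMPLETE}

    def test_empty_campaign_snapshot(self):
        camp = Campaign(MockDockingBackend(seed=0))
        assert camp.poll_status() == {}

    def test_configurable_interval(self):
        camp = Campaign(MockDockingBackend(seed=0), poll_interval=2.5)
        assert camp.poll_interval == 2.5


class TestMergeComplex:
    def test_atom_counts_and_chain(self, library, mock_dlg):
        from peptidock import build_peptide

        receptor = build_peptide("GAG", library)
        pose = mock_dlg(seed=8, n_runs=3)[0]
        merged = merge_complex(receptor, pose)
        assert len(merged) == len(receptor) + len(pose.atoms)
        assert {a.chain_id for a in merged.atoms} == {"A", "B"}

    def test_next_free_chain_letter(self, library, mock_dlg):
        from dataclasses import replace

        from peptidock import PeptideStructure, build_peptide

        receptor = build_peptide("GA", library)
        atoms = [replace(a, chain_id="B" if a.residue_seq == 2 else "A")
                 for a in receptor.atoms]
        receptor = PeptideStructure(atoms)
        pose = mock_dlg(seed=8, n_runs=1)[0]
        merged = merge_complex(receptor, pose)
        assert {a.chain_id for a in merged.atoms} == {"A", "B", "C"}

    def test_merged_structure_round_trips(self, library, mock_dlg, tmp_path):
        import io

        from peptidock import build_peptide, write_pdb

        merged = merge_complex(build_peptide("GAG", library),
                               mock_dlg(seed=8, n_runs=1)[0])
        buf = io.StringIO()
        write_pdb(merged, buf)
        reread = read_pdb(io.StringIO(buf.getvalue()))
        assert len(reread) == len(merged)
        assert reread.residue_sequence() == merged.residue_sequence()


class TestCompetitive:
    def _competitive_campaign(self, tmp_path, receptor_pdb, gpf_template, backend):
        job = DockingJob(1, "CCMWF", str(receptor_pdb), str(gpf_template),
                         str(tmp_path / "out"), secondary_ligand_ref="CDCMW",
                         n_runs=5)
        return Campaign(backend, [job]), job

    def test_chains_two_jobs_and_merges_pose(self, tmp_path, receptor_pdb, gpf_template):
        camp, job = self._competitive_campaign(
            tmp_path, receptor_pdb, gpf_template, MockDockingBackend(seed=6))
        r1, r2 = camp.run_competitive(job)
        assert r1.exit_ok and r2.exit_ok
        assert Path(r1.dlg_path) != Path(r2.dlg_path)
        receptor = read_pdb(receptor_pdb)
        pose = rank_conformations(parse_dlg(r1.dlg_path))[0].conformation
        merged = read_pdb(tmp_path / "out" / "merged_receptor_job1.pdb")
        assert len(merged) == len(receptor) + len(pose.atoms)
        second = camp.jobs[1]
        assert second.receptor_path.endswith("merged_receptor_job1.pdb")
        assert second.gpf_path == job.gpf_path  # same grid box reused

    def test_rank1_selection_is_argmin_energy(self, tmp_path, receptor_pdb, gpf_template):
        backend = MockDockingBackend(energies=[-5.0, -9.0, -7.0], seed=6)
        camp, job = self._competitive_campaign(
            tmp_path, receptor_pdb, gpf_template, backend)
        job.n_runs = 3
        r1, _ = camp.run_competitive(job)
        best = rank_conformations(parse_dlg(r1.dlg_path))[0].conformation
        assert best.energy == -9.0 and best.run_index == 2
        merged = read_pdb(tmp_path / "out" / "merged_receptor_job1.pdb")
        pose_atoms = [a for a in merged.atoms if a.chain_id == "B"]
        assert np.allclose(
            np.array([[a.x, a.y, a.z] for a in pose_atoms]), best.coordinates()
        )

    def test_primary_failure_stops_the_chain(self, tmp_path, receptor_pdb, gpf_template):
        camp, job = self._competitive_campaign(
            tmp_path, receptor_pdb, gpf_template, FailingBackend())
        r1, r2 = camp.run_competitive(job)
        assert not r1.exit_ok
        assert r2 is None
        assert job.status is JobStatus.FAILED
        assert len(camp.jobs) == 1  # no second job created
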