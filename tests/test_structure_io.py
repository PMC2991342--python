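"""PDB/GPF/DLG reading and writing."""

import io
import math

import pytest

from peptidock import (
    Atom,
    GridBox,
    PeptideStructure,
    build_peptide,
    parse_dlg,
    parse_gpf_template,
    read_pdb,
    write_pdb,
)
from peptidock.structure_io import (
    DlgFormatError,
    GpfFormatError,
    PdbFormatError,
    format_atom_record,
    ki_to_molar,
    write_dlg,
)

ATOM_LINE = (
    "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N"
)


def atom(serial=1, name="N", res="GLY", seq=1, xyz=(0.0, 0.0, 0.0), element="N"):
    return Atom(serial, name, res, "A", seq, *xyz, element)


class TestPdb:
    def test_single_record(self):
        s = read_pdb(io.StringIO(ATOM_LINE))
        assert len(s) == 1
        a = s.atoms[0]
        assert (a.name, a.residue_name, a.residue_seq, a.element) == ("N", "GLY", 1, "N")
        assert (a.x, a.y, a.z) == (0.0, 0.0, 0.0)

    def test_two_residue_fixture_counts(self):
        lines = []
        for i, (name, seq) in enumerate(
            [("N", 1), ("CA", 1), ("C", 1), ("O", 1), ("CB", 1),
             ("N", 2), ("CA", 2), ("C", 2), ("O", 2)], start=1
        ):
            lines.append(format_atom_record(atom(serial=i, name=name, res="ALA", seq=seq)))
        s = read_pdb(io.StringIO("\n".join(lines)))
        assert len(s) == 9
        assert max(a.residue_seq for a in s.atoms) == 2

    def test_round_trip_identity(self, library):
        original = build_peptide("CWK", library)
        buf = io.StringIO()
        write_pdb(original, buf)
        reread = read_pdb(io.StringIO(buf.getvalue()))
        assert len(reread) == len(original)
        for a, b in zip(original.normalized().atoms, reread.atoms):
            assert (a.serial, a.name, a.residue_name, a.chain_id, a.residue_seq,
                    a.element) == (b.serial, b.name, b.residue_name, b.chain_id,
                                   b.residue_seq, b.element)
            assert max(abs(a.x - b.x), abs(a.y - b.y), abs(a.z - b.z)) <= 0.0005 + 1e-12

    def test_serials_renumbered_in_atom_order(self):
        s = PeptideStructure([
            atom(serial=5, name="N"),
            atom(serial=9, name="CA", element="C"),
            atom(serial=2, name="C", element="C"),
        ])
        buf = io.StringIO()
        write_pdb(s, buf)
        serials = [int(ln[6:11]) for ln in buf.getvalue().splitlines()
                   if ln.startswith("ATOM")]
        assert serials == [1, 2, 3]

    def test_write_ends_with_ter_end(self):
        buf = io.StringIO()
        write_pdb(PeptideStructure([atom()]), buf)
        lines = buf.getvalue().splitlines()
        assert sum(ln.startswith("ATOM") for ln in lines) == 1
        assert lines[-2].startswith("TER")
        assert lines[-1] == "END"

    def test_no_atoms_is_an_error(self):
        with pytest.raises(PdbFormatError, match="no atoms"):
            read_pdb(io.StringIO("HEADER    nothing here\n"))

    def test_malformed_record_names_line(self):
        text = ATOM_LINE + "\nATOM      2  CA  GLY A   1      bad coords\n"
        with pytest.raises(PdbFormatError, match="line 2"):
            read_pdb(io.StringIO(text))

    def test_overlong_atom_name_rejected_on_write(self):
        with pytest.raises(PdbFormatError, match="1-4 characters"):
            atom(name="HD211")

    def test_biopython_reads_our_output(self, library, tmp_path):
        """Cross-check the writer against an independent PDB implementation."""
        Bio = pytest.importorskip("Bio.PDB")
        path = tmp_path / "CCMWF.pdb"
        original = build_peptide("CCMWF", library)
        write_pdb(original, path)
        parser = Bio.PDBParser(QUIET=True)
        model = parser.get_structure("x", str(path))[0]
        bio_atoms = list(model.get_atoms())
        assert len(bio_atoms) == len(original)
        for ours, theirs in zip(original.atoms, bio_atoms):
            assert ours.name == theirs.get_name()
            assert ours.position == pytest.approx(theirs.get_coord(), abs=1e-3)


class TestGpf:
    def test_extent_from_npts_and_spacing(self, gpf_template):
        box = parse_gpf_template(gpf_template)
        assert box.npts == (40, 40, 40)
        assert box.extent == pytest.approx([15.0, 15.0, 15.0])

    def test_center_parsed(self):
        box = parse_gpf_template(
            io.StringIO("npts 40 40 40\nspacing 0.375\ngridcenter 1.0 2.0 3.0\n")
        )
        assert box.center == (1.0, 2.0, 3.0)

    @pytest.mark.parametrize("missing", ["npts", "spacing", "gridcenter"])
    def test_missing_keyword_is_incomplete(self, missing):
        lines = {
            "npts": "npts 40 40 40",
            "spacing": "spacing 0.375",
            "gridcenter": "gridcenter 0 0 0",
        }
        text = "\n".join(v for k, v in lines.items() if k != missing)
        with pytest.raises(GpfFormatError, match=f"incomplete template.*{missing}"):
            parse_gpf_template(io.StringIO(text))

    def test_odd_npts_rejected(self):
        with pytest.raises(GpfFormatError, match="even"):
            parse_gpf_template(
                io.StringIO("npts 41 40 40\nspacing 0.375\ngridcenter 0 0 0\n")
            )

    def test_extent_strictly_positive(self):
        box = parse_gpf_template(
            io.StringIO("npts 2 4 6\nspacing 0.1\ngridcenter -1 2 0\n")
        )
        assert (box.extent > 0).all()

    def test_boundary_point_counts_inside(self):
        box = GridBox((10, 10, 10), 1.0, (0.0, 0.0, 0.0))
        assert box.contains((5.0, 0.0, 0.0))
        assert not box.contains((5.001, 0.0, 0.0))


class TestDlg:
    def test_ki_unit_normalization(self):
        text = (
            "Run:   1\n"
            "DOCKED: USER    Estimated Free Energy of Binding    =   -6.00 kcal/mol\n"
            "DOCKED: USER    Estimated Inhibition Constant, Ki   =   39.87 uM\n"
            "DOCKED: " + ATOM_LINE + "\n"
        )
        confs = parse_dlg(io.StringIO(text))
        assert confs[0].ki == pytest.approx(3.987e-5)
        assert confs[0].energy == -6.00

    @pytest.mark.parametrize(
        "unit,factor",
        [("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("µM", 1e-6),
         ("nM", 1e-9), ("pM", 1e-12), ("NM", 1e-9)],
    )
    def test_unit_factors(self, unit, factor):
        assert ki_to_molar(2.0, unit) == pytest.approx(2.0 * factor)

    def test_empty_log_is_an_error(self):
        with pytest.raises(DlgFormatError, match="empty log"):
            parse_dlg(io.StringIO(""))

    def test_missing_energy_names_run(self):
        text = (
            "Run:   3\n"
            "DOCKED: USER    Estimated Inhibition Constant, Ki   =   1.0 uM\n"
            "DOCKED: " + ATOM_LINE + "\n"
        )
        with pytest.raises(DlgFormatError, match="run 3"):
            parse_dlg(io.StringIO(text))

    def test_write_parse_round_trip_with_histogram(self):
        from peptidock.structure_io import ClusterRow

        poses = [
            (1, -5.25, math.exp(-5.25 / 0.5924), [atom()]),
            (2, -7.5, math.exp(-7.5 / 0.5924), [atom()]),
        ]
        buf = io.StringIO()
        write_dlg(poses, buf, cluster_rows=[ClusterRow(1, -7.5, 2, -6.4, 2)])
        confs = parse_dlg(io.StringIO(buf.getvalue()))
        assert [c.run_index for c in confs] == [1, 2]
        assert [c.energy for c in confs] == [-5.25, -7.5]
        assert confs[1].cluster_rank == 1
        assert confs[0].cluster_rank is None

    def test_mock_backend_run_count(self, mock_dlg):
        confs = mock_dlg(seed=11, n_runs=100)
        assert len(confs) == 100
        assert [c.run_index for c in confs] == list(range(1, 101))
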