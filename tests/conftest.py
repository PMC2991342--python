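from pathlib import Path

import pytest

from peptidock import (
    BuildOptions,
    FragmentLibrary,
    MockDockingBackend,
    build_peptide,
    generate_fragment_library,
    parse_dlg,
    write_pdb,
)

GPF_TEMPLATE = "npts 40 40 40\nspacing 0.375\ngridcenter 0.0 0.0 0.0\n"


@pytest.fixture(scope="session")
def library() -> FragmentLibrary:
    return FragmentLibrary.create()


@pytest.fixture(scope="session")
def library_dir(tmp_path_factory) -> Path:
    dest = tmp_path_factory.mktemp("fragments")
    generate_fragment_library(dest)
    return dest


@pytest.fixture(scope="session")
def receptor_pdb(tmp_path_factory, library) -> Path:
    path = tmp_path_factory.mktemp("receptor") / "receptor.pdb"
    write_pdb(build_peptide("GAG", library), path)
    return path


@pytest.fixture(scope="session")
def gpf_template(tmp_path_factory) -> Path:
    path = tmp_path_factory.mktemp("gpf") / "box.gpf"
    path.write_text(GPF_TEMPLATE)
    return path


@pytest.fixture()
def mock_dlg(tmp_path, library, gpf_template):
    """Factory: run the mock backend and return the parsed conformations."""

    def run(energies=None, seed=0, n_runs=None, sequence="GA"):
        ligand = tmp_path / f"{sequence}.pdb"
        write_pdb(build_peptide(sequence, library, BuildOptions(optimize=False)), ligand)
        n = n_runs if n_runs is not None else (len(energies) if energies else 10)
        backend = MockDockingBackend(energies=energies, seed=seed)
        result = backend.run(str(ligand), str(ligand), str(gpf_template), n, str(tmp_path))
        return parse_dlg(result.dlg_path)

    return run
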