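import gemmi
import pytest
from hypothesis import HealthCheck, settings

from dmscreen.library_design import DesignConstraints, design_saturation_library
from dmscreen.sequence_core import BAMHI, NHEI, ORFSequence
from dmscreen.synthetic_screen import random_orf

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_orf() -> ORFSequence:
    """A 60-codon stop-free ORF, free of NheI/BamHI sites."""
    return random_orf(60, seed=42, id="toy", avoid_sites=(NHEI, BAMHI))


@pytest.fixture(scope="session")
def toy_design(toy_orf):
    return design_saturation_library(
        toy_orf, DesignConstraints(1, toy_orf.last_codon, silent_count=6)
    )


def build_structure(chains, ligands=()) -> gemmi.Structure:
    """Assemble a synthetic structure from explicit coordinates.

    chains: {chain_name: [(residue_number, residue_name, [(x, y, z), ...])]}
    ligands: [(chain_name, residue_name, residue_number, [(x, y, z), ...])]
    """
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    for name, residues in chains.items():
        chain = gemmi.Chain(name)
        for resnum, resname, coords in residues:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            for k, xyz in enumerate(coords):
                atom = gemmi.Atom()
                atom.name = f"C{k}"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    for cname, resname, resnum, coords in ligands:
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(resnum, " ")
        for k, xyz in enumerate(coords):
            atom = gemmi.Atom()
            atom.name = f"X{k}"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        model[cname].add_residue(res)
    st.add_model(model)
    return st


@pytest.fixture()
def structure_builder(tmp_path):
    def _build(chains, ligands=(), name="toy.pdb"):
        path = tmp_path / name
        build_structure(chains, ligands).write_pdb(str(path))
        return str(path)

    return _build
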