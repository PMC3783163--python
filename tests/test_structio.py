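import warnings

import numpy as np
import pytest

from attarch.structio import (AtomRecord, CellContents, StructureModel,
                              StructureParseError, annotate_domains,
                              default_li_scheme, domain_of, get_annotation,
                              infer_chain_roles, load_annotation_scheme,
                              read_structure, solvent_fraction, write_structure)
from attarch.synthetic import reference_crystal_form


def _full_chain_model():
    atoms = [AtomRecord("CA", "C", "ALA", r, "A", [float(r), 0.0, 0.0])
             for r in range(133, 453)]
    return StructureModel(atoms, {"A": "integrase"})


def test_pdb_roundtrip(tmp_path, reference):
    half, _ = reference
    model = half.structure
    path = write_structure(model, tmp_path / "halfsite.pdb")
    back = read_structure(path)
    assert len(back.atoms) == len(model.atoms)
    key = lambda a: (a.chain_id, a.residue_number, a.residue_name, a.atom_name)
    orig = {key(a): a for a in model.atoms}
    assert len(orig) == len(model.atoms)
    for a in back.atoms:
        np.testing.assert_allclose(a.position, orig[key(a)].position, atol=2e-3)


def test_mmcif_roundtrip(tmp_path, reference):
    half, _ = reference
    path = write_structure(half.protein, tmp_path / "prot.cif", "mmcif")
    back = read_structure(path)
    assert len(back.atoms) == len(half.protein.atoms)


def test_chain_role_inference(reference):
    half, _ = reference
    roles = infer_chain_roles(half.structure.atoms)
    assert roles["A"] == "integrase"
    dna_roles = {roles[c] for c in roles if c != "A"}
    assert dna_roles == {"dna_top", "dna_bottom"}


def test_read_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_structure(tmp_path / "missing.pdb")
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a coordinate file\n")
    with pytest.raises(StructureParseError):
        read_structure(bad, dialect="mmcif")
    with pytest.raises(ValueError):
        read_structure(bad, dialect="xml")


def test_write_validation(tmp_path):
    atoms = [AtomRecord("CA", "C", "ALA", 1, "AB", [0.0, 0.0, 0.0])]
    model = StructureModel(atoms, {})
    with pytest.raises(ValueError):
        write_structure(model, tmp_path / "x.pdb")  # 2-char chain id
    with pytest.raises(ValueError):
        write_structure(StructureModel([], {}), tmp_path / "y.pdb")


def test_annotation_scheme_and_anchors():
    scheme = default_li_scheme()
    assert scheme["domains"]["RD"] == [133, 264]
    assert scheme["domains"]["ZD"] == [265, 452]
    assert scheme["domains"]["CC"] == [342, 416]
    assert scheme["anchors"] == {"ZD_anchor": 338, "CC_tip": 374}
    model = _full_chain_model()
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # complete chain: no warnings expected
        anns = annotate_domains(model, "A", scheme)
    assert get_annotation(anns, "ZD_anchor").residue_range == (338, 338)
    assert get_annotation(anns, "ZD").metadata["zinc_cysteines"] == [274, 277, 302, 314]


def test_annotation_missing_anchor_errors_and_sparse_warns():
    atoms = [AtomRecord("CA", "C", "ALA", r, "A", [float(r), 0.0, 0.0])
             for r in (200, 300, 338)]
    model = StructureModel(atoms, {"A": "integrase"})
    with pytest.raises(ValueError, match="CC_tip"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            annotate_domains(model, "A")
    atoms.append(AtomRecord("CA", "C", "TYR", 374, "A", [374.0, 0.0, 0.0]))
    model = StructureModel(atoms, {"A": "integrase"})
    with pytest.warns(UserWarning, match="missing"):
        annotate_domains(model, "A")


def test_domain_of_cc_carve_out():
    anns = annotate_domains(_full_chain_model(), "A")
    assert domain_of(380, anns) == "CC"   # inside both ZD and CC: CC wins
    assert domain_of(338, anns) == "ZD"   # between ZD start and CC start
    assert domain_of(200, anns) == "RD"
    assert domain_of(100, anns) is None


def test_load_scheme_validation(tmp_path):
    with pytest.raises(ValueError):
        load_annotation_scheme({"anchors": {}})
    p = tmp_path / "s.yaml"
    p.write_text("domains:\n  X: [1, 10]\n")
    assert load_annotation_scheme(p)["domains"]["X"] == [1, 10]


def test_cell_contents_mass():
    contents = CellContents(protein_copies=[(320, 4)], dna_duplexes=[(26, 4)],
                            zinc_ions=4)
    assert contents.mass_da() == pytest.approx(4 * (320 * 110 + 26 * 660) + 4 * 65.38)
    with pytest.raises(ValueError):
        CellContents(protein_copies=[(320, -1)]).mass_da()


def test_solvent_fraction_reference_form():
    cf = reference_crystal_form()
    sf = solvent_fraction(cf["cell"], cf["space_group"], cf["contents"])
    assert sf == pytest.approx(0.748, abs=0.005)


def test_solvent_fraction_edge_cases():
    cell = (100.0, 100.0, 100.0, 90.0, 90.0, 90.0)
    assert solvent_fraction(cell, "P 1", CellContents()) == 1.0
    with pytest.raises(ValueError):
        solvent_fraction(cell, "NOT A GROUP", CellContents(protein_copies=[(10, 1)]))
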