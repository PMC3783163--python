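import warnings

import numpy as np
import pytest

from attarch.architecture import cc_span
from attarch.assembly import (Scaffold, SynapticModel, build_full_site,
                              build_hybrid_site, build_synaptic, shift_zd,
                              site_footprint)
from attarch.synthetic import make_mock_scaffold


def test_full_site_exact_fit(built_models):
    sites, _ = built_models
    attp = sites["attP"]
    assert set(attp.halves) == {"P", "P'"}
    for r in attp.fit_rmsds.values():
        assert r < 1e-6
    assert attp.crossover_gap() < 14.0


def test_full_site_needs_dimer(reference, tetramer_scaffold):
    half, _ = reference
    with pytest.raises(ValueError, match="dimer"):
        build_full_site(half, tetramer_scaffold, "attP")
    with pytest.raises(ValueError):
        build_full_site(half, make_mock_scaffold("dimer"), "attL")


def test_footprints(built_models, reference):
    sites, _ = built_models
    _, expected = reference
    assert site_footprint(sites["attP"]) == 2 * expected["footprint_span"]
    assert site_footprint(sites["attB"]) == 2 * expected["attB_footprint_span"]


def test_shift_zd_moves_only_zd(built_models):
    sites, _ = built_models
    attp, attb = sites["attP"], sites["attB"]
    assert attb.site_type == "attB"
    assert set(attb.halves) == {"B", "B'"}
    assert attb.clash_count == 0
    for p_arm, b_arm in (("P", "B"), ("P'", "B'")):
        before = attp.halves[p_arm].protein
        after = attb.halves[b_arm].protein
        # RD atoms (resnum < 265) untouched, ZD atoms moved
        for a, b in zip(before.atoms, after.atoms):
            assert a.residue_number == b.residue_number
            moved = np.linalg.norm(a.position - b.position) > 1.0
            assert moved == (a.residue_number >= 265)
        # DNA untouched
        np.testing.assert_allclose(attp.halves[p_arm].duplex.range_points(0, 24),
                                   attb.halves[b_arm].duplex.range_points(0, 24))


def test_shift_zd_validation(built_models, reference):
    sites, _ = built_models
    with pytest.raises(ValueError, match="attP"):
        shift_zd(sites["attB"])
    unchanged = shift_zd(sites["attP"], n_bp=0)
    assert unchanged.site_type == "attP"
    with pytest.raises(ValueError, match="outside"):
        shift_zd(sites["attP"], n_bp=20)


def test_hybrid_site_composition(built_models):
    sites, _ = built_models
    attl = sites["attL"]
    assert set(attl.halves) == {"P", "B'"}
    assert attl.ordered_arms() == ("P", "B'")
    p = sites["attP"].halves["P"]
    b = sites["attB"].halves["B"]
    with pytest.raises(ValueError):
        build_hybrid_site(p, b, "attL")  # B is not a valid attL arm
    with pytest.raises(ValueError):
        build_hybrid_site(b, p, "attR")  # P-derived half must come first
    with pytest.raises(ValueError):
        build_hybrid_site(p, b, "attP")


def test_scaffold_validation(dimer_scaffold):
    with pytest.raises(ValueError):
        Scaffold("x", "trimer", dimer_scaffold.segments)
    with pytest.raises(ValueError):
        Scaffold("x", "tetramer", dimer_scaffold.segments)
    with pytest.raises(KeyError):
        dimer_scaffold.segment("nope")


def test_synaptic_pairing_and_alignment(built_models):
    _, synapses = built_models
    pxb = synapses[("PxB", "parallel")]
    assert pxb.pairing == "PxB"
    assert pxb.decompose() == {"A-left": "P", "A-right": "P'",
                               "B-left": "B", "B-right": "B'"}
    anti = synapses[("PxB", "antiparallel")]
    assert anti.decompose() == {"A-left": "P", "A-right": "P'",
                                "B-left": "B'", "B-right": "B"}
    assert synapses[("LxR", "parallel")].pairing == "LxR"


def test_synaptic_pairing_is_order_insensitive(built_models, tetramer_scaffold):
    sites, _ = built_models
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ab = build_synaptic(sites["attP"], sites["attB"], tetramer_scaffold)
        ba = build_synaptic(sites["attB"], sites["attP"], tetramer_scaffold)
    assert ab.pairing == ba.pairing == "PxB"


def test_juxtaposition_map_must_be_perfect_matching(built_models):
    _, synapses = built_models
    syn = synapses[("PxB", "parallel")]
    with pytest.raises(ValueError, match="facing pairs"):
        SynapticModel(syn.halves, syn.pairing, syn.alignment,
                      [("A-left", "A-right"), ("A-left", "B-right")],
                      syn.scaffold_id)


def test_rigidity_of_placements(built_models, reference):
    """Internal geometry of the half-site survives every placement."""
    sites, synapses = built_models
    _, expected = reference
    halves = [h for m in sites.values() for h in m.halves.values()]
    halves += [h for s in synapses.values() for h in s.halves.values()]
    assert len(halves) == 4 * 2 + 8 * 4  # 4 sites x 2 arms + 8 synapses x 4 arms
    for h in halves:
        assert cc_span(h) == pytest.approx(expected["cc_span"], abs=1e-6)


def test_structure_merging_renames_chains(built_models):
    sites, synapses = built_models
    merged = sites["attP"].structure
    assert {"A", "B"} <= set(merged.chain_ids())
    syn = synapses[("PxB", "parallel")]
    assert len(syn.structure.chain_ids()) == 12  # 4 proteins + 8 DNA strands
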