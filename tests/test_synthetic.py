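import warnings

import numpy as np
import pytest

from attarch.architecture import measure_architecture
from attarch.assembly import (build_full_site, build_hybrid_site, build_synaptic,
                              shift_zd)
from attarch.superpose import kabsch_fit
from attarch.synthetic import (MockComplexSpec, expected_anchor_distances,
                               make_mock_halfsite, make_mock_ncs_copies,
                               make_mock_scaffold, make_mock_sites,
                               reference_att_sites, synthetic_integrase_pair)


def _pipeline_distances(spec):
    """The seven anchor distances measured through the full model-building
    pipeline (the quantity expected_anchor_distances predicts analytically)."""
    half, _ = make_mock_halfsite(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        attp = build_full_site(half, make_mock_scaffold("dimer", spec), "attP")
        shift = spec.anchor_bp - spec.facing_anchor_bp
        lo = spec.anchor_bp - 4  # 9-bp ZD register centred on the anchor bp
        attb = shift_zd(attp, n_bp=shift, zd_register=(lo, lo + 8))
        attl = build_hybrid_site(attp.halves["P"], attb.halves["B'"], "attL")
        attr_ = build_hybrid_site(attp.halves["P'"], attb.halves["B"], "attR")
        tet = make_mock_scaffold("tetramer", spec)
        out = {
            "dimer_attP": measure_architecture(attp).entries[0].distance,
            "dimer_attB": measure_architecture(attb).entries[0].distance,
            "dimer_attL": measure_architecture(attl).entries[0].distance,
            "dimer_attR": measure_architecture(attr_).entries[0].distance,
        }
        for name, s1, s2 in (("PxP", attp, attp), ("BxB", attb, attb),
                             ("PxB", attp, attb)):
            rep = measure_architecture(build_synaptic(s1, s2, tet))
            out[f"tetramer_facing_{name}"] = rep.facing_distances()[0]
    return out


def test_generator_closed_form_agreement_default_spec():
    spec = MockComplexSpec()
    measured = _pipeline_distances(spec)
    expected = expected_anchor_distances(spec)
    for key, value in expected.items():
        assert measured[key] == pytest.approx(value, abs=1e-6), key


def test_generator_closed_form_agreement_random_specs():
    """Pipeline-measured distances equal the closed form on 100 random specs."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        anchor_bp = int(rng.integers(17, 21))  # keeps the 9-bp register on the arm
        spec = MockComplexSpec(
            anchor_bp=anchor_bp,
            facing_anchor_bp=anchor_bp - 5,
            anchor_radius=float(rng.uniform(20.0, 40.0)),
            arm_angle_deg=float(rng.uniform(90.0, 150.0)),
            anchor_azimuth_deg=float(rng.uniform(0.0, 360.0)),
            plane_separation=float(rng.uniform(80.0, 120.0)),
        )
        measured = _pipeline_distances(spec)
        expected = expected_anchor_distances(spec)
        for key, value in expected.items():
            assert measured[key] == pytest.approx(value, abs=1e-6), (key, spec)


def test_mock_halfsite_expected_observables(reference):
    half, expected = reference
    assert expected["cc_span"] == 54.0
    anchor = half.anchor_point("ZD_anchor")
    np.testing.assert_allclose(anchor, expected["anchor_local"])
    assert expected["footprint_span"] == 25
    assert expected["attB_footprint_span"] == 20


def test_mock_halfsite_determinism():
    a, _ = make_mock_halfsite()
    b, _ = make_mock_halfsite()
    np.testing.assert_array_equal(a.structure.coords(), b.structure.coords())


def test_spec_validation():
    with pytest.raises(ValueError):
        MockComplexSpec(anchor_bp=40)
    with pytest.raises(ValueError):
        MockComplexSpec(anchor_radius=-1.0)
    with pytest.raises(ValueError):
        make_mock_scaffold("trimer")


def test_ncs_copies_rmsd_and_determinism():
    copies = make_mock_ncs_copies(n=4, sigma=0.17, seed=3)
    assert [c.ncs_copy_id for c in copies] == [0, 1, 2, 3]
    rmsds = []
    for i in range(4):
        for j in range(i + 1, 4):
            _, r = kabsch_fit(moving=copies[j].structure.coords(),
                              fixed=copies[i].structure.coords())
            rmsds.append(r)
    mean = float(np.mean(rmsds))
    # expected fitted RMSD ~ sqrt(6) * sigma = 0.416
    assert mean == pytest.approx(np.sqrt(6) * 0.17, abs=0.08)
    again = make_mock_ncs_copies(n=4, sigma=0.17, seed=3)
    np.testing.assert_array_equal(copies[2].structure.coords(),
                                  again[2].structure.coords())
    different = make_mock_ncs_copies(n=4, sigma=0.17, seed=4)
    assert not np.array_equal(copies[2].structure.coords(),
                              different[2].structure.coords())


def test_mock_sites_generation():
    sites = make_mock_sites(10, register=16, seed=1)
    assert len(sites) == 10
    for s in sites:
        assert len(s["sequence"]) == 25
        assert s["sequence"][16:25] == "GATACTAAA"
    again = make_mock_sites(10, register=16, seed=1)
    assert [s["sequence"] for s in again] == [s["sequence"] for s in sites]
    with pytest.raises(ValueError):
        make_mock_sites(1, register=20)
    with pytest.raises(ValueError):
        make_mock_sites(1, mutation_rate=2.0)


def test_reference_sites_crossover_dinucleotide():
    sites = reference_att_sites()
    for s in sites.values():
        assert s.crossover_dinucleotide == "GC"


def test_synthetic_integrase_pair_properties():
    pair = synthetic_integrase_pair()
    ref, hom = pair["reference"], pair["homolog"]
    assert len(ref) == len(hom) == 452
    diffs = [i + 1 for i, (a, b) in enumerate(zip(ref, hom)) if a != b]
    assert diffs == pair["positions"]
    assert len(diffs) == pair["differences"] == 11
    for seq in (ref, hom):
        for r in (274, 277, 302, 314):
            assert seq[r - 1] == "C"
        assert seq[338 - 1] == "A" and seq[374 - 1] == "Y"
    assert synthetic_integrase_pair()["reference"] == ref  # deterministic
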