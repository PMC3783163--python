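import numpy as np
import pytest

from attarch.architecture import (DistanceEntry, DistanceReport, ReachModel,
                                  SynapsisVerdict, cc_span, classify_synapsis,
                                  combine_verdicts, enumerate_alignments,
                                  measure_architecture, zd_anchor_point)


def test_reach_model_defaults_and_validation():
    reach = ReachModel()
    assert reach.cc_length == 54.0
    assert reach.d_max == 108.0
    assert reach.d_min == 50.0
    assert ReachModel(cc_length=40.0).d_max == 80.0
    with pytest.raises(ValueError):
        ReachModel(d_min=200.0)


def test_anchor_point_and_cc_span(reference):
    half, expected = reference
    np.testing.assert_allclose(zd_anchor_point(half), expected["anchor_local"])
    assert cc_span(half) == pytest.approx(expected["cc_span"])


def test_measure_full_site(built_models):
    sites, _ = built_models
    rep = measure_architecture(sites["attP"])
    assert rep.source_kind == "full_site" and rep.site_type == "attP"
    assert [e.relation for e in rep.entries] == ["intramolecular"]


def test_measure_synaptic_relations(built_models):
    _, synapses = built_models
    rep = measure_architecture(synapses[("PxB", "parallel")])
    by = {rel: len(rep.by_relation(rel))
          for rel in ("facing", "diagonal", "intramolecular")}
    assert by == {"facing": 2, "diagonal": 2, "intramolecular": 2}
    df = rep.to_frame()
    assert list(df.columns) == ["half_i", "half_j", "relation", "distance_A"]
    assert len(df) == 6


def _synaptic_report(facing):
    entries = [DistanceEntry(f"a{i}", f"b{i}", "facing", d)
               for i, d in enumerate(facing)]
    return DistanceReport(entries, "synaptic", pairing="XxY", alignment="parallel")


def test_classification_rules_in_order():
    reach = ReachModel()
    assert classify_synapsis(_synaptic_report([90.0, 100.0]), reach).verdict == "competent"
    assert classify_synapsis(_synaptic_report([90.0, 120.0]), reach).verdict == "blocked_far"
    assert classify_synapsis(_synaptic_report([90.0, 30.0]), reach).verdict == "blocked_near"
    # far takes precedence over near when both occur
    assert classify_synapsis(_synaptic_report([30.0, 120.0]), reach).verdict == "blocked_far"
    full = DistanceReport([DistanceEntry("P", "B'", "intramolecular", 101.0)],
                          "full_site", site_type="attL")
    assert classify_synapsis(full, reach).verdict == "autoinhibited"
    wide = DistanceReport([DistanceEntry("P", "B'", "intramolecular", 130.0)],
                          "full_site", site_type="attL")
    assert classify_synapsis(wide, reach).verdict == "competent"


def test_classification_validation(built_models):
    sites, _ = built_models
    with pytest.raises(ValueError, match="attL/attR"):
        classify_synapsis(measure_architecture(sites["attP"]))
    with pytest.raises(ValueError, match="empty"):
        classify_synapsis(DistanceReport([], "synaptic"))
    with pytest.raises(ValueError):
        SynapsisVerdict("PxB", None, "nonsense", ["x"])
    with pytest.raises(ValueError):
        SynapsisVerdict("PxB", None, "competent", [])


def test_emergent_verdict_landscape(built_models):
    """The full qualitative pattern: only attP x attB is synapsis-competent;
    the product sites are autoinhibited."""
    sites, synapses = built_models
    verdicts = {}
    for name in ("attL", "attR"):
        verdicts[name] = classify_synapsis(measure_architecture(sites[name])).verdict
    site_v = [classify_synapsis(measure_architecture(sites[n])) for n in ("attL", "attR")]
    for (pairing, alignment), syn in synapses.items():
        v = classify_synapsis(measure_architecture(syn))
        if pairing == "LxR":
            v = combine_verdicts(v, site_v)
        verdicts[(pairing, alignment)] = v.verdict
    assert verdicts["attL"] == "autoinhibited"
    assert verdicts["attR"] == "autoinhibited"
    assert verdicts[("PxB", "parallel")] == "competent"
    assert verdicts[("PxB", "antiparallel")] == "competent"
    assert verdicts[("PxP", "parallel")] == "blocked_far"
    assert verdicts[("PxP", "antiparallel")] == "blocked_far"
    assert verdicts[("BxB", "parallel")] == "blocked_near"
    assert verdicts[("BxB", "antiparallel")] == "blocked_near"
    assert verdicts[("LxR", "parallel")] == "autoinhibited"
    assert verdicts[("LxR", "antiparallel")] == "autoinhibited"
    competent = [k for k, v in verdicts.items() if v == "competent"]
    assert all(k[0] == "PxB" for k in competent)


def test_combine_verdicts_no_inhibition_passthrough():
    pair = SynapsisVerdict("PxB", "parallel", "competent", ["fine"])
    ok = SynapsisVerdict("attP", None, "competent", ["fine"])
    assert combine_verdicts(pair, [ok]) is pair


def test_enumerate_alignments_pxb():
    out = enumerate_alignments("PxB")
    assert [o["alignment"] for o in out] == ["parallel", "antiparallel"]
    for o in out:  # every juxtaposed pair mixes P- and B-derived arms
        assert "same face" in o["face_summary"]
    assert out[0]["juxtaposition_map"] == [("P", "B"), ("P'", "B'")]
    assert out[1]["juxtaposition_map"] == [("P", "B'"), ("P'", "B")]


def test_enumerate_alignments_lxr():
    out = enumerate_alignments("LxR")
    parallel, anti = out
    assert parallel["juxtaposition_map"] == [("P", "B"), ("B'", "P'")]
    assert "same face" in parallel["face_summary"]
    assert anti["juxtaposition_map"] == [("P", "P'"), ("B'", "B")]
    assert "opposite faces" in anti["face_summary"]
    with pytest.raises(ValueError):
        enumerate_alignments("QxZ")


def test_distance_report_summaries(built_models):
    _, synapses = built_models
    rep = measure_architecture(synapses[("BxB", "parallel")])
    assert rep.mean_facing() == pytest.approx(35.0, abs=0.01)
    assert rep.mean_diagonal() > rep.mean_facing()
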