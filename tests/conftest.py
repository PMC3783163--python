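import warnings

import pytest

from attarch.synthetic import make_mock_halfsite, make_mock_scaffold


@pytest.fixture(scope="session")
def reference():
    """Reference half-site + expected observables, shared across tests."""
    half, expected = make_mock_halfsite()
    return half, expected


@pytest.fixture(scope="session")
def dimer_scaffold():
    return make_mock_scaffold("dimer")


@pytest.fixture(scope="session")
def tetramer_scaffold():
    return make_mock_scaffold("tetramer")


@pytest.fixture(scope="session")
def built_models(reference, dimer_scaffold, tetramer_scaffold):
    """All site and synaptic models, built once."""
    from attarch.assembly import (build_full_site, build_hybrid_site,
                                  build_synaptic, shift_zd)

    half, _ = reference
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        attp = build_full_site(half, dimer_scaffold, "attP")
        attb = shift_zd(attp)
        attl = build_hybrid_site(attp.halves["P"], attb.halves["B'"], "attL")
        attr_ = build_hybrid_site(attp.halves["P'"], attb.halves["B"], "attR")
        sites = {"attP": attp, "attB": attb, "attL": attl, "attR": attr_}
        synapses = {}
        for name, (a, b) in (("PxB", ("attP", "attB")), ("PxP", ("attP", "attP")),
                             ("BxB", ("attB", "attB")), ("LxR", ("attL", "attR"))):
            for alignment in ("parallel", "antiparallel"):
                synapses[(name, alignment)] = build_synaptic(
                    sites[a], sites[b], tetramer_scaffold, alignment)
    return sites, synapses
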