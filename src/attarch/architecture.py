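"""Distance metrics and the synapsis-competence classification.

The directionality model encoded here is purely architectural: whether two
integrase-bound attachment sites can be locked into a productive synaptic
complex is decided by whether the coiled-coil (CC) motifs protruding from the
zinc-ribbon domains (ZDs) of juxtaposed half-sites can physically pair.  Each
CC spans about 54 A from its ZD anchor (the C-alpha of the residue closing
helix alpha-J, Ala338 in the LI integrase scheme) to the tip of the
helix-turn-helix hairpin (Tyr374), so two CCs reaching toward each other can
bridge at most roughly twice that distance.  Anchor–anchor distances above
that ceiling leave the CCs unable to meet (``blocked_far``); distances far
below the productive regime force incompatible CC geometries and steric
interference (``blocked_near``); and product sites (attL/attR) whose own two
anchors are within CC reach form intramolecular CC pairs that compete with
synapsis (``autoinhibited``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .assembly import ARM_ORDER, B_DERIVED, P_DERIVED, FullSiteModel, HalfSiteComplex, SynapticModel

__all__ = [
    "ReachModel",
    "DistanceEntry",
    "DistanceReport",
    "SynapsisVerdict",
    "zd_anchor_point",
    "cc_span",
    "measure_architecture",
    "classify_synapsis",
    "combine_verdicts",
    "enumerate_alignments",
]


@dataclass(frozen=True)
class ReachModel:
    """Geometric reach of the CC motifs.

    ``cc_length`` is the anchor-to-tip span of one CC (54 A as measured on the
    best-ordered copy); ``d_max`` defaults to twice that, the ceiling for two
    CCs meeting tip-to-tip.  ``d_min`` is the floor below which facing CC
    pairs are treated as geometrically incompatible/sterically blocked; the
    default 50 A sits between the ~35 A self-paired attB regime and the
    ~77 A productive regime and is configurable.
    """

    cc_length: float = 54.0
    d_max: Optional[float] = None
    d_min: float = 50.0

    def __post_init__(self) -> None:
        if self.d_max is None:
            object.__setattr__(self, "d_max", 2.0 * self.cc_length)
        if not (0.0 < self.d_min < self.d_max):
            raise ValueError(f"need 0 < d_min ({self.d_min}) < d_max ({self.d_max})")


@dataclass(frozen=True)
class DistanceEntry:
    half_i: str
    half_j: str
    relation: str  # facing | diagonal | intramolecular
    distance: float

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("negative distance")
        if self.relation not in ("facing", "diagonal", "intramolecular"):
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass
class DistanceReport:
    """Labelled anchor–anchor distances for one model."""

    entries: list[DistanceEntry]
    source_kind: str  # full_site | synaptic
    site_type: Optional[str] = None
    pairing: Optional[str] = None
    alignment: Optional[str] = None

    def by_relation(self, relation: str) -> list[DistanceEntry]:
        return [e for e in self.entries if e.relation == relation]

    def facing_distances(self) -> list[float]:
        return [e.distance for e in self.by_relation("facing")]

    def mean_facing(self) -> float:
        d = self.facing_distances()
        return float(np.mean(d)) if d else float("nan")

    def mean_diagonal(self) -> float:
        d = [e.distance for e in self.by_relation("diagonal")]
        return float(np.mean(d)) if d else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "half_i": e.half_i, "half_j": e.half_j,
            "relation": e.relation, "distance_A": round(e.distance, 2),
        } for e in self.entries])


@dataclass
class SynapsisVerdict:
    pairing: str
    alignment: Optional[str]
    verdict: str  # competent | blocked_far | blocked_near | autoinhibited
    evidence: list[str]

    def __post_init__(self) -> None:
        allowed = ("competent", "blocked_far", "blocked_near", "autoinhibited")
        if self.verdict not in allowed:
            raise ValueError(f"unknown class {self.verdict!r}")
        if not self.evidence:
            raise ValueError("verdict requires non-empty evidence")


def zd_anchor_point(half: HalfSiteComplex, anchor: str = "ZD_anchor") -> np.ndarray:
    """C-alpha position of the ZD anchor residue of one half-site complex."""
    return half.anchor_point(anchor)


def cc_span(half: HalfSiteComplex) -> float:
    """Anchor-to-tip length of the CC motif (Ala338 CA to Tyr374 CA in the
    default scheme)."""
    return float(np.linalg.norm(half.anchor_point("ZD_anchor")
                                - half.anchor_point("CC_tip")))


def measure_architecture(model: Union[FullSiteModel, SynapticModel],
                         anchor: str = "ZD_anchor") -> DistanceReport:
    """All pairwise ZD-anchor distances of a model, labelled by relation.

    Full-site models yield a single intramolecular entry.  Synaptic models
    yield two facing entries (from the juxtaposition map), two diagonal
    entries (cross-site, non-facing) and two intramolecular entries.
    """
    if isinstance(model, FullSiteModel):
        a, b = model.ordered_arms()
        d = model.intramolecular_anchor_distance(anchor)
        return DistanceReport([DistanceEntry(a, b, "intramolecular", d)],
                              "full_site", site_type=model.site_type)
    points = {seg: model.halves[seg].anchor_point(anchor) for seg in model.halves}
    facing_pairs = {frozenset(p) for p in model.juxtaposition_map}
    entries = []
    for seg_i, seg_j in combinations(sorted(points), 2):
        same_site = model.site_of.get(seg_i) == model.site_of.get(seg_j)
        if frozenset((seg_i, seg_j)) in facing_pairs:
            relation = "facing"
        elif same_site:
            relation = "intramolecular"
        else:
            relation = "diagonal"
        label_i = f"{seg_i}:{model.halves[seg_i].arm_type}"
        label_j = f"{seg_j}:{model.halves[seg_j].arm_type}"
        entries.append(DistanceEntry(label_i, label_j, relation,
                                     float(np.linalg.norm(points[seg_i] - points[seg_j]))))
    return DistanceReport(entries, "synaptic", pairing=model.pairing,
                          alignment=model.alignment)


def classify_synapsis(report: DistanceReport, reach: ReachModel = ReachModel()) -> SynapsisVerdict:
    """Classify a model's synapsis competence from its distance report.

    Rules, applied in order:

    1. an attL/attR full-site report with intramolecular anchor distance
       <= d_max is ``autoinhibited`` (the CCs can pair within the site);
    2. a synaptic report with any facing distance > d_max is ``blocked_far``;
    3. any facing distance < d_min is ``blocked_near``;
    4. otherwise ``competent``.
    """
    if not report.entries:
        raise ValueError("empty distance report")
    if report.source_kind == "full_site":
        if report.site_type not in ("attL", "attR"):
            raise ValueError("full-site classification is defined for attL/attR "
                             f"(got {report.site_type}); synapse other sites first")
        d = report.entries[0].distance
        if d <= reach.d_max:
            return SynapsisVerdict(report.site_type, None, "autoinhibited",
                                   [f"intramolecular anchor distance {d:.1f} A <= "
                                    f"d_max {reach.d_max:.0f} A: CC motifs can pair "
                                    f"within the site"])
        return SynapsisVerdict(report.site_type, None, "competent",
                               [f"intramolecular anchor distance {d:.1f} A > "
                                f"d_max {reach.d_max:.0f} A"])
    facing = report.by_relation("facing")
    if not facing:
        raise ValueError("synaptic report has no facing entries")
    far = [e for e in facing if e.distance > reach.d_max]
    if far:
        e = max(far, key=lambda e: e.distance)
        return SynapsisVerdict(report.pairing or "?", report.alignment, "blocked_far",
                               [f"facing {e.half_i}–{e.half_j} at {e.distance:.1f} A > "
                                f"d_max {reach.d_max:.0f} A: CC motifs cannot meet"])
    near = [e for e in facing if e.distance < reach.d_min]
    if near:
        e = min(near, key=lambda e: e.distance)
        return SynapsisVerdict(report.pairing or "?", report.alignment, "blocked_near",
                               [f"facing {e.half_i}–{e.half_j} at {e.distance:.1f} A < "
                                f"d_min {reach.d_min:.0f} A: CC geometry incompatible/steric"])
    ev = [f"facing {e.half_i}–{e.half_j} at {e.distance:.1f} A within "
          f"[{reach.d_min:.0f}, {reach.d_max:.0f}] A" for e in facing]
    return SynapsisVerdict(report.pairing or "?", report.alignment, "competent", ev)


def combine_verdicts(pair_verdict: SynapsisVerdict,
                     constituent_verdicts: Sequence[SynapsisVerdict]) -> SynapsisVerdict:
    """Effective verdict of a pairing given its constituent full-site verdicts.

    Intramolecular CC pairing within a product site pre-empts synapsis: if any
    constituent site is autoinhibited, the pairing is autoinhibited regardless
    of how well its anchors would be juxtaposed across the interface.
    """
    inhibited = [v for v in constituent_verdicts if v.verdict == "autoinhibited"]
    if not inhibited:
        return pair_verdict
    evidence = [f"constituent {v.pairing}: {v.evidence[0]}" for v in inhibited]
    return SynapsisVerdict(pair_verdict.pairing, pair_verdict.alignment,
                           "autoinhibited", evidence + pair_verdict.evidence)


_SITE_OF_PAIRING = {
    "PxB": ("attP", "attB"), "PxP": ("attP", "attP"), "BxB": ("attB", "attB"),
    "LxR": ("attL", "attR"), "LxL": ("attL", "attL"), "RxR": ("attR", "attR"),
}


def _derivation(arm: str) -> str:
    return "P-derived" if arm in P_DERIVED else "B-derived"


def enumerate_alignments(pairing: str) -> list[dict]:
    """Both alignments of a pairing with juxtaposed arm types and a face
    summary.

    A juxtaposed pair mixing a P-derived and a B-derived arm presents both
    ZDs on the synaptic-interface face (the CC-pairable arrangement); when all
    juxtaposed pairs are mixed the four ZDs share one face.
    """
    if pairing not in _SITE_OF_PAIRING:
        raise ValueError(f"unknown pairing {pairing!r} "
                         f"(known: {sorted(_SITE_OF_PAIRING)})")
    t1, t2 = _SITE_OF_PAIRING[pairing]
    arms1, arms2 = ARM_ORDER[t1], ARM_ORDER[t2]
    out = []
    for alignment in ("parallel", "antiparallel"):
        a2 = arms2 if alignment == "parallel" else arms2[::-1]
        juxtaposed = list(zip(arms1, a2))
        mixed = [_derivation(x) != _derivation(y) for x, y in juxtaposed]
        if all(mixed):
            face = ("all four ZDs on the same face of the synaptic complex "
                    "(P-derived arms juxtaposed with B-derived arms)")
        elif not any(mixed):
            face = ("ZDs segregated on opposite faces: "
                    + " and ".join(f"{x}–{y} half-sites juxtaposed" for x, y in juxtaposed))
        else:
            face = "mixed arrangement: " + ", ".join(f"{x}–{y}" for x, y in juxtaposed)
        out.append({
            "alignment": alignment,
            "juxtaposition_map": juxtaposed,
            "face_summary": face,
        })
    return out
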