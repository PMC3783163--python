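"""Deterministic synthetic stand-ins with closed-form expected values.

Every generator here produces coordinates or sequences whose key observables
are known analytically, so the model-building and measurement code can be
exercised — and graded — without any deposited data.  The reference half-site
complex, scaffolds and crystal form are *calibrated synthetic* objects: their
free parameters (anchor register and radius, CC span, inter-site plane
separation, dimer arm angle, anchor elevation) were fixed once, before any
test was written, from the published hallmark measurements of the serine
integrase system they emulate (CC anchor-to-tip span 54 A, attP-dimer ZD
anchor separation 126 A, attB-register anchor juxtaposition 35 A in the
synaptic tetramer).  All remaining distances are emergent, not fitted.

Calibration, in closed form (twist 34.3 deg/bp, rise 3.38 A/bp):

* anchor register: bp 20 on an attP arm (center of the 16-24 ZD motif),
  bp 15 after the 5-bp shift to the attB register;
* anchor radius ``r = 30 A``: the synaptic tetramer separates the two DNA
  planes by ``D`` and juxtaposes attB-register anchors across them at
  ``D - 2r = 35 A``, while ``D = 95 A`` was chosen as ``35 + 2r``;
* dimer scaffold: the two arms lie in the horizontal plane at an inter-arm
  angle ``a``, related by the site's in-plane two-fold axis, and the
  attP-register anchor of the left arm points at azimuth ``phi`` from the
  horizontal (its two-fold mate points at ``phi + 180``).  ``a = 107 deg``
  and ``phi = 90 deg`` (anchors exactly vertical, one up, one down) were
  solved, before any test was written, against the published anchor
  separations attP 126 / attB 109 / attL = attR 101 A; the frozen constants
  reproduce them as 126.5 / 107.4 / 101.4 A.

Everything is rebuilt from these numbers at call time; no coordinates are
shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .assembly import HalfSiteComplex, Scaffold, ScaffoldSegment
from .attseq import ZD_MOTIF, AttSite
from .dna import DuplexModel, HelicalParams, build_ideal_bdna, complement, revcomp
from .structio import (AtomRecord, CellContents, DomainAnnotation, StructureModel,
                       default_li_scheme)
from .superpose import RigidTransform

__all__ = [
    "MockComplexSpec",
    "REFERENCE_ARM_SEQUENCE",
    "make_mock_halfsite",
    "make_reference_halfsite",
    "make_mock_scaffold",
    "make_mock_ncs_copies",
    "make_mock_sites",
    "reference_att_sites",
    "reference_crystal_form",
    "synthetic_integrase_pair",
    "scheme_annotations",
]

# Positional top strand of the reference attP left (P) arm: position 0 is the
# crossover G, positions increase outward.  The ZD motif occupies register
# 16-24 on the outward-reading strand.
P_LEFT_OUT = "CATCGTTCTAAAACCAGATACTAAA"
P_RIGHT_OUT = "CAGCGATCCAAAACCAGATACTAAA"
B_LEFT_OUT = "CATCGTTCTAAGATACTAAA"
B_RIGHT_OUT = "CAGCGATCCAAGATACTAAA"
REFERENCE_ARM_SEQUENCE = complement(P_LEFT_OUT)

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CONSERVATIVE = {
    "A": "S", "S": "T", "T": "S", "D": "E", "E": "D", "K": "R", "R": "K",
    "I": "L", "L": "I", "V": "I", "F": "Y", "Y": "F", "N": "Q", "Q": "N",
    "G": "A", "M": "L", "W": "F", "H": "N", "P": "A", "C": "S",
}


@dataclass(frozen=True)
class MockComplexSpec:
    """Calibrated parameters of the synthetic reference system (see module
    docstring for the derivation of each default)."""

    arm_sequence: str = REFERENCE_ARM_SEQUENCE
    helical: HelicalParams = field(default_factory=HelicalParams)
    protein_chain: str = "A"
    anchor_bp: int = 20                 # attP-register ZD anchor base pair
    facing_anchor_bp: int = 15          # attB register after the 5-bp shift
    anchor_radius: float = 30.0         # A, anchor distance from the helix axis
    cc_span: float = 54.0               # A, ZD anchor to CC tip
    arm_angle_deg: float = 107.0        # dimer scaffold inter-arm angle
    anchor_azimuth_deg: float = 90.0    # left-arm attP anchor azimuth (vertical)
    plane_separation: float = 95.0      # A between tetramer DNA planes (35 + 2r)
    rd_trace_bps: tuple[int, int] = (0, 12)   # bp tracked by RD contact atoms
    zd_trace_bps: tuple[int, int] = (13, 24)  # bp tracked by ZD contact atoms

    def __post_init__(self) -> None:
        n = len(self.arm_sequence)
        if self.anchor_bp >= n or self.zd_trace_bps[1] >= n:
            raise ValueError("anchor/trace registers outside the arm")
        if self.anchor_radius <= 0 or self.cc_span <= 0:
            raise ValueError("radii must be positive")


def scheme_annotations(scheme: Optional[dict] = None) -> list[DomainAnnotation]:
    """Domain annotations straight from a scheme, without presence checks
    (the synthetic protein is a sparse pseudo-atom trace by design)."""
    scheme = scheme or default_li_scheme()
    anns = [DomainAnnotation(name, (int(r[0]), int(r[1])),
                             {"zinc_cysteines": list(scheme.get("metadata", {})
                                                     .get("zinc_cysteines", []))}
                             if name == "ZD" else {})
            for name, r in scheme["domains"].items()]
    anns += [DomainAnnotation(name, (int(r), int(r)), {})
             for name, r in scheme.get("anchors", {}).items()]
    return anns


def _cyl(radius: float, az_deg: float, z: float) -> np.ndarray:
    a = np.deg2rad(az_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), z])


def make_mock_halfsite(spec: Optional[MockComplexSpec] = None, arm_type: str = "P",
                       ncs_copy_id: int = 0) -> tuple[HalfSiteComplex, dict]:
    """One synthetic half-site complex in the canonical duplex frame, plus a
    dictionary of its closed-form expected observables.

    The pseudo-protein is a CA-only trace on chain ``A``: contact atoms
    following the duplex backbone (RD-numbered over bp 0-12, ZD-numbered over
    bp 13-24, within 5 A of DNA but clash-free), compact RD/ZD body clusters,
    the four zinc cysteines, the ZD anchor at the calibrated radius, and the
    CC shaft/tip extending ``cc_span`` A further out.
    """
    spec = spec or MockComplexSpec()
    tw, rise = spec.helical.twist_deg, spec.helical.rise
    duplex = build_ideal_bdna(spec.arm_sequence, spec.helical)

    atoms: list[AtomRecord] = []

    def add(resnum: int, pos: np.ndarray, resname: str = "ALA") -> None:
        atoms.append(AtomRecord("CA", "C", resname, resnum, spec.protein_chain, pos))

    # contact-trace atoms: RD-numbered near the top-strand C1', ZD-numbered
    # near the top-strand phosphate (so they ride along with a ZD shift)
    for i in range(spec.rd_trace_bps[0], spec.rd_trace_bps[1] + 1):
        add(150 + i, _cyl(12.9, i * tw + 34.0, i * rise), "GLY")
    for i in range(spec.zd_trace_bps[0], spec.zd_trace_bps[1] + 1):
        add(265 + i, _cyl(12.2, i * tw + 52.0, (i - 0.5) * rise), "GLY")

    # compact domain bodies
    for k in range(5):
        add(200 + k, _cyl(15.0, 7 * tw + (k - 2) * 20.0, 7 * rise + (k - 2) * 1.0))
        add(300 + k, _cyl(20.0, spec.anchor_bp * tw + (k - 2) * 20.0,
                          spec.anchor_bp * rise + (k - 2) * 1.0))
    for resnum, daz, dz in ((274, -50.0, -2.0), (277, -40.0, -1.0),
                            (302, 40.0, 1.0), (314, 50.0, 2.0)):
        add(resnum, _cyl(20.0, spec.anchor_bp * tw + daz, spec.anchor_bp * rise + dz),
            "CYS")

    # ZD anchor, CC shaft and CC tip, all on the bp-`anchor_bp` radial ray
    az, z = spec.anchor_bp * tw, spec.anchor_bp * rise
    anchor_local = _cyl(spec.anchor_radius, az, z)
    add(338, anchor_local)
    for k in range(1, 10):
        add(349 + k, _cyl(spec.anchor_radius + spec.cc_span * k / 10.0, az, z))
    add(374, _cyl(spec.anchor_radius + spec.cc_span, az, z), "TYR")

    protein = StructureModel(atoms, {spec.protein_chain: "integrase"})
    half = HalfSiteComplex(protein, duplex, arm_type, scheme_annotations(),
                           spec.protein_chain, ncs_copy_id)

    expected = {
        "cc_span": spec.cc_span,
        "anchor_local": anchor_local,
        "contact_first": 0,
        "contact_last": spec.zd_trace_bps[1],
        "footprint_span": spec.zd_trace_bps[1] + 1,
        "attB_footprint_span": spec.zd_trace_bps[1] + 1 - (spec.anchor_bp - spec.facing_anchor_bp),
        **expected_anchor_distances(spec),
    }
    return half, expected


def expected_anchor_distances(spec: Optional[MockComplexSpec] = None) -> dict[str, float]:
    """Closed-form anchor-anchor distances implied by the calibration, computed
    directly from the spec's geometry without building any model.

    Dimer entries are the intramolecular ZD-anchor separations of the four
    site models built on the default dimer scaffold; tetramer entries are the
    facing separations across the synaptic interface for each pairing.
    """
    spec = spec or MockComplexSpec()
    rise, tw = spec.helical.rise, spec.helical.twist_deg
    r = spec.anchor_radius
    s_p = (spec.anchor_bp + 0.5) * rise
    s_b = (spec.facing_anchor_bp + 0.5) * rise
    shift = np.deg2rad((spec.anchor_bp - spec.facing_anchor_bp) * tw)
    h = np.deg2rad(spec.arm_angle_deg / 2.0)
    alpha = np.deg2rad(spec.anchor_azimuth_deg)
    z = np.array([0.0, 0.0, 1.0])
    u = {"L": np.array([-np.sin(h), np.cos(h), 0.0]),
         "R": np.array([np.sin(h), np.cos(h), 0.0])}
    e1 = {side: np.cross(z, u[side]) for side in u}

    def anchor(side, s, phi):
        return s * u[side] + r * (np.cos(phi) * e1[side] + np.sin(phi) * z)

    beta = alpha + np.pi  # two-fold mate
    p_l, p_r = anchor("L", s_p, alpha), anchor("R", s_p, beta)
    b_l, b_r = anchor("L", s_b, alpha - shift), anchor("R", s_b, beta - shift)
    dist = lambda x, y: float(np.linalg.norm(x - y))

    # tetramer: attB-register anchors vertical toward the partner plane,
    # attP-register anchors `shift` degrees away from that vertical
    d = spec.plane_separation
    top_p = np.array([-s_p, -r * np.cos(shift - np.pi / 2.0), r * np.sin(shift - np.pi / 2.0)])
    top_b = np.array([-s_b, 0.0, -r])
    bot_p = np.array([-s_p, r * np.cos(shift - np.pi / 2.0), -d - r * np.sin(shift - np.pi / 2.0)])
    bot_b = np.array([-s_b, 0.0, -d + r])
    return {
        "dimer_attP": dist(p_l, p_r),
        "dimer_attB": dist(b_l, b_r),
        "dimer_attL": dist(p_l, b_r),
        "dimer_attR": dist(b_l, p_r),
        "tetramer_facing_PxP": dist(top_p, bot_p),
        "tetramer_facing_BxB": dist(top_b, bot_b),
        "tetramer_facing_PxB": dist(top_p, bot_b),
    }


def make_reference_halfsite(spec: Optional[MockComplexSpec] = None) -> HalfSiteComplex:
    """The calibrated synthetic reference half-site complex (attP P arm)."""
    return make_mock_halfsite(spec)[0]


def _segment_frame(u: np.ndarray, phase_deg: float, origin: np.ndarray) -> RigidTransform:
    """Frame placing a canonical duplex along axis ``u`` with its azimuth 0
    rotated by ``phase_deg`` and bp 0 at ``origin``.

    The azimuth basis is (e1, e2) with e1 = z_hat x u (horizontal for
    horizontal axes) and e2 completing the right-handed triad (vertical for
    horizontal axes).
    """
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    e1 = np.cross([0.0, 0.0, 1.0], u)
    n = np.linalg.norm(e1)
    if n < 1e-9:
        raise ValueError("segment axis must not be vertical")
    e1 /= n
    e2 = np.cross(u, e1)
    basis = np.column_stack([e1, e2, u])
    p = np.deg2rad(phase_deg)
    rz = np.array([[np.cos(p), -np.sin(p), 0.0],
                   [np.sin(p), np.cos(p), 0.0],
                   [0.0, 0.0, 1.0]])
    return RigidTransform(basis @ rz, origin)


def make_mock_scaffold(kind: str = "dimer",
                       spec: Optional[MockComplexSpec] = None) -> Scaffold:
    """A calibrated synthetic scaffold.

    ``dimer``: two arms in the horizontal plane meeting at the site center
    with the spec's inter-arm angle; the azimuthal phases put the
    attP-register anchor of a fitted half-site at ``anchor_azimuth_deg`` on
    the left arm and 180 degrees away on the right arm, the two placements
    being related by the site's in-plane two-fold axis.

    ``tetramer``: two sites with parallel horizontal axes, stacked
    ``plane_separation`` apart; phases put the attB-register (bp-15) anchor
    ray of each arm exactly on the vertical toward the partner site, which is
    what juxtaposes attB-register anchors at ``D - 2r`` and banishes
    attP-register anchors (a ~171.5 deg azimuth away) to the outside.
    """
    spec = spec or MockComplexSpec()
    tw, rise = spec.helical.twist_deg, spec.helical.rise
    seq = spec.arm_sequence
    chains = [("T", "U"), ("V", "W"), ("X", "Y"), ("Z", "S")]

    def seg(label: str, u, phase_deg: float, origin, ci: int) -> ScaffoldSegment:
        frame = _segment_frame(np.asarray(u, float), phase_deg, np.asarray(origin, float))
        top, bot = chains[ci]
        return ScaffoldSegment(label, build_ideal_bdna(seq, spec.helical, top, bot, frame))

    if kind == "dimer":
        h = np.deg2rad(spec.arm_angle_deg / 2.0)
        u_l = np.array([-np.sin(h), np.cos(h), 0.0])
        u_r = np.array([np.sin(h), np.cos(h), 0.0])
        theta_a = spec.anchor_bp * tw
        phi = spec.anchor_azimuth_deg
        segments = [
            seg("left", u_l, phi - theta_a, (rise / 2.0) * u_l, 0),
            seg("right", u_r, phi + 180.0 - theta_a, (rise / 2.0) * u_r, 1),
        ]
        return Scaffold("synthetic-bent-dimer", "dimer", segments)
    if kind == "tetramer":
        theta_f = spec.facing_anchor_bp * tw
        d = spec.plane_separation
        x0 = rise / 2.0
        segments = [
            seg("A-left", (-1, 0, 0), -90.0 - theta_f, (-x0, 0.0, 0.0), 0),
            seg("A-right", (1, 0, 0), -90.0 - theta_f, (x0, 0.0, 0.0), 1),
            seg("B-left", (-1, 0, 0), 90.0 - theta_f, (-x0, 0.0, -d), 2),
            seg("B-right", (1, 0, 0), 90.0 - theta_f, (x0, 0.0, -d), 3),
        ]
        return Scaffold("synthetic-synaptic-tetramer", "tetramer", segments,
                        [("A-left", "B-left"), ("A-right", "B-right")])
    raise ValueError(f"unknown scaffold kind {kind!r}")


def _jittered(structure: StructureModel, rng: np.random.Generator,
              sigma: float) -> StructureModel:
    atoms = [a.moved_to(a.position + rng.normal(0.0, sigma, 3)) for a in structure.atoms]
    return StructureModel(atoms, dict(structure.chain_roles), structure.cell,
                          structure.space_group)


def make_mock_ncs_copies(half: Optional[HalfSiteComplex] = None, n: int = 4,
                         sigma: float = 0.17, seed: int = 0) -> list[HalfSiteComplex]:
    """``n`` rigidly scattered, coordinate-jittered copies of a half-site.

    Each copy is the input moved by a random rigid transform with independent
    Gaussian noise (sd ``sigma`` A per coordinate) added to every atom,
    emulating non-crystallographic-symmetry copies; the expected pairwise
    fitted RMSD is ~``sqrt(6) * sigma`` (two jittered copies, three
    coordinates each).
    """
    from scipy.spatial.transform import Rotation

    if half is None:
        half = make_reference_halfsite()
    rng = np.random.default_rng(seed)
    copies = []
    for i in range(n):
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-50.0, 50.0, 3)
        moved = half.transformed(RigidTransform(rot, t))
        moved = replace(moved,
                        protein=_jittered(moved.protein, rng, sigma),
                        duplex=replace(moved.duplex,
                                       structure=_jittered(moved.duplex.structure, rng, sigma)),
                        ncs_copy_id=i)
        copies.append(moved)
    return copies


def make_mock_sites(n: int, motif: str = ZD_MOTIF, register: int = 16,
                    length: int = 25, mutation_rate: float = 0.0,
                    seed: int = 0) -> list[dict]:
    """Random positional half-site strings with the ZD motif planted on the
    minus strand at a known register.

    Returns one dict per site: the string, the planted register and strand,
    and how many planted-window bases were subsequently mutated.
    """
    motif = motif.upper()
    k = len(motif)
    if register < 0 or register + k > length:
        raise ValueError(f"register {register} does not fit a {k}-mer in {length} bp")
    if not (0.0 <= mutation_rate <= 1.0):
        raise ValueError("mutation_rate must be in [0, 1]")
    window = revcomp(motif)
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out = []
    for _ in range(n):
        seq = list(rng.choice(bases, length))
        seq[register:register + k] = list(window)
        window_muts = 0
        for i in range(length):
            if rng.random() < mutation_rate:
                seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
                if register <= i < register + k:
                    window_muts += 1
        out.append({"sequence": "".join(seq), "register": register,
                    "strand": "-", "window_mutations": window_muts})
    return out


def reference_att_sites() -> dict[str, AttSite]:
    """The four synthetic reference attachment sites (attP 50 bp, attB 40 bp,
    attL/attR hybrids), assembled from their outward half-site strings."""
    return {
        "attP": AttSite.from_halves("attP", P_LEFT_OUT, P_RIGHT_OUT),
        "attB": AttSite.from_halves("attB", B_LEFT_OUT, B_RIGHT_OUT),
        "attL": AttSite.from_halves("attL", P_LEFT_OUT, B_RIGHT_OUT),
        "attR": AttSite.from_halves("attR", B_LEFT_OUT, P_RIGHT_OUT),
    }


def reference_crystal_form() -> dict:
    """The synthetic reference crystal form for solvent-fraction bookkeeping:
    a cubic I23 cell holding four half-site complexes (four 320-residue CTD
    copies, four 26-bp duplex arms, four zinc ions) per asymmetric unit."""
    return {
        "cell": (290.8, 290.8, 290.8, 90.0, 90.0, 90.0),
        "space_group": "I 2 3",
        "contents": CellContents(protein_copies=[(320, 4)],
                                 dna_duplexes=[(26, 4)], zinc_ions=4),
    }


def synthetic_integrase_pair(seed: int = 20130417) -> dict:
    """A deterministic 452-residue synthetic integrase sequence and a close
    homolog differing by 11 conservative substitutions in the CTD.

    The zinc cysteines (274/277/302/314), the ZD anchor (Ala338) and the CC
    tip (Tyr374) are fixed in both sequences.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(_AA_ALPHABET), 452))
    seq[0] = "M"
    for r in (274, 277, 302, 314):
        seq[r - 1] = "C"
    seq[338 - 1] = "A"
    seq[374 - 1] = "Y"
    reference = "".join(seq)
    positions = [140, 171, 205, 233, 258, 281, 329, 355, 390, 421, 440]
    homolog = list(reference)
    for r in positions:
        homolog[r - 1] = _CONSERVATIVE[homolog[r - 1]]
    return {
        "reference": reference,
        "homolog": "".join(homolog),
        "differences": len(positions),
        "positions": positions,
    }
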