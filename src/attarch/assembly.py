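"""Model building: full attachment-site dimer models and synaptic tetramer
models from a single half-site complex.

The procedures mirror how serine-integrase site models are built from one
crystallographic half-site complex:

* ``build_full_site`` places two copies of the half-site complex on a bent
  dimer scaffold by superposing the innermost base pairs (1-5 by default) of
  the half-site duplex onto the corresponding base pairs of each scaffold
  half, giving an integrase-bound symmetric attP model.
* ``shift_zd`` converts an attP model into an attB model by moving the
  zinc-ribbon domain (with its coiled-coil insertion) of each subunit 5 bp
  toward the crossover, using the screw transform derived from the subunit's
  own duplex (register 16-24 onto 11-19); the recombinase domain stays put.
* ``build_hybrid_site`` composes the attL (P + B') and attR (B + P') product
  sites from placed attP/attB half-sites.
* ``build_synaptic`` places four half-site complexes on the duplex segments
  of a tetramer scaffold, recording which half-sites face each other across
  the synaptic interface.

All placements are rigid: the internal geometry of a half-site complex is
never deformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .dna import DuplexModel, derive_step_transform, contact_footprint
from .structio import DomainAnnotation, StructureModel, get_annotation
from .superpose import Correspondence, RigidTransform, kabsch_fit

__all__ = [
    "HalfSiteComplex",
    "ScaffoldSegment",
    "Scaffold",
    "FullSiteModel",
    "SynapticModel",
    "build_full_site",
    "shift_zd",
    "build_hybrid_site",
    "build_synaptic",
    "site_footprint",
]

P_DERIVED = {"P", "P'"}
B_DERIVED = {"B", "B'"}
ARM_ORDER = {  # left-to-right arm composition of each site type
    "attP": ("P", "P'"),
    "attB": ("B", "B'"),
    "attL": ("P", "B'"),
    "attR": ("B", "P'"),
}
CROSSOVER_GAP_DEFAULT = 14.0  # A; coarse-duplex bond-forming distance, see docs


@dataclass
class HalfSiteComplex:
    """One integrase CTD copy bound to one numbered ~25-bp att arm."""

    protein: StructureModel
    duplex: DuplexModel
    arm_type: str
    annotations: list[DomainAnnotation]
    protein_chain: str
    ncs_copy_id: int = 0

    def __post_init__(self) -> None:
        prot_chains = [c for c, r in self.protein.chain_roles.items() if r == "integrase"]
        if prot_chains and len(prot_chains) != 1:
            raise ValueError(f"half-site must hold exactly one integrase chain, got {prot_chains}")
        if 0 not in self.duplex.bp_index:
            raise ValueError("half-site duplex must be numbered with the crossover at position 0")

    @property
    def structure(self) -> StructureModel:
        return self.protein.merged_with(self.duplex.structure)

    def transformed(self, transform: RigidTransform) -> "HalfSiteComplex":
        return replace(self, protein=self.protein.transformed(transform),
                       duplex=self.duplex.transformed(transform))

    def with_arm_type(self, arm_type: str) -> "HalfSiteComplex":
        return replace(self, arm_type=arm_type)

    def anchor_point(self, anchor: str = "ZD_anchor") -> np.ndarray:
        """C-alpha position of a single-residue anchor (e.g. Ala338)."""
        ann = get_annotation(self.annotations, anchor)
        resnum = ann.residue_range[0]
        atoms = self.protein.select(self.protein_chain, [resnum], ["CA"])
        if not atoms:
            raise ValueError(f"anchor {anchor} (residue {resnum}) absent or disordered "
                             f"in copy {self.ncs_copy_id}")
        return atoms[0].position.copy()

    def domain_residues(self, name: str) -> range:
        ann = get_annotation(self.annotations, name)
        return range(ann.residue_range[0], ann.residue_range[1] + 1)


@dataclass
class ScaffoldSegment:
    label: str
    duplex: DuplexModel


@dataclass
class Scaffold:
    """A reference arrangement of numbered duplex segments.

    ``kind`` is ``dimer`` (a bent full site: two arms meeting at a crossover)
    or ``tetramer`` (four segments with labelled facing pairs across a
    synaptic interface).
    """

    scaffold_id: str
    kind: str
    segments: list[ScaffoldSegment]
    facing_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = 2 if self.kind == "dimer" else 4
        if self.kind not in ("dimer", "tetramer"):
            raise ValueError(f"unknown scaffold kind {self.kind!r}")
        if len(self.segments) != expected:
            raise ValueError(f"{self.kind} scaffold needs {expected} segments")
        if self.kind == "tetramer" and len(self.facing_pairs) != 2:
            raise ValueError("tetramer scaffold needs two facing pairs")

    def segment(self, label: str) -> ScaffoldSegment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(f"no scaffold segment {label!r}")

    @property
    def structure(self) -> StructureModel:
        merged = self.segments[0].duplex.structure
        for seg in self.segments[1:]:
            merged = merged.merged_with(seg.duplex.structure)
        return merged


def _duplex_correspondence(moving: DuplexModel, fixed: DuplexModel,
                           start: int, end: int) -> Correspondence:
    """Atom correspondence between two duplexes over a bp range, matched by
    (position, strand role, atom name); unmatched atoms are dropped."""
    def keyed(d: DuplexModel):
        out = {}
        for p in range(start, end + 1):
            for a in d.bp_atoms(p):
                strand = "top" if a.chain_id == d.top_chain else "bottom"
                out[(p, strand, a.atom_name)] = a.position
        return out

    m, f = keyed(moving), keyed(fixed)
    common = sorted(set(m) & set(f))
    if len(common) < len(m):
        warnings.warn(f"{len(m) - len(common)} unmatched duplex atoms dropped from fit")
    return Correspondence(np.stack([m[k] for k in common]),
                          np.stack([f[k] for k in common]))


@dataclass
class FullSiteModel:
    """Two half-site complexes placed in a common frame as one att site."""

    halves: dict[str, HalfSiteComplex]  # arm label -> placed complex
    site_type: str
    scaffold_id: str
    segment_of: dict[str, str] = field(default_factory=dict)
    fit_rmsds: dict[str, float] = field(default_factory=dict)
    clash_count: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = set(ARM_ORDER[self.site_type])
        if set(self.halves) != expected:
            raise ValueError(f"{self.site_type} needs arms {sorted(expected)}, "
                             f"got {sorted(self.halves)}")

    def ordered_arms(self) -> tuple[str, str]:
        return ARM_ORDER[self.site_type]

    def ordered_halves(self) -> list[HalfSiteComplex]:
        return [self.halves[a] for a in self.ordered_arms()]

    @property
    def structure(self) -> StructureModel:
        merged = StructureModel([], {})
        for i, (arm, half) in enumerate(sorted(self.halves.items())):
            rename = {half.protein_chain: chr(ord("A") + i),
                      half.duplex.top_chain: chr(ord("E") + 2 * i),
                      half.duplex.bottom_chain: chr(ord("F") + 2 * i)}
            merged = merged.merged_with(half.structure, rename)
        return merged

    def crossover_gap(self) -> float:
        """Smallest distance between backbone atoms of the two arms' crossover
        base pairs (position 0)."""
        arms = list(self.halves.values())
        a0 = [a.position for a in arms[0].duplex.bp_atoms(0) if a.atom_name in ("P", "C1'")]
        a1 = [a.position for a in arms[1].duplex.bp_atoms(0) if a.atom_name in ("P", "C1'")]
        return float(min(np.linalg.norm(x - y) for x in a0 for y in a1))

    def intramolecular_anchor_distance(self, anchor: str = "ZD_anchor") -> float:
        h = self.ordered_halves()
        return float(np.linalg.norm(h[0].anchor_point(anchor) - h[1].anchor_point(anchor)))


def build_full_site(half: HalfSiteComplex, scaffold: Scaffold, site_type: str = "attP",
                    fit_range: tuple[int, int] = (1, 5),
                    rmsd_warn: float = 1.0,
                    continuity_threshold: float = CROSSOVER_GAP_DEFAULT) -> FullSiteModel:
    """Place two copies of a half-site complex on a bent dimer scaffold.

    Each copy is positioned by a rigid superposition of its duplex base pairs
    ``fit_range`` onto the corresponding base pairs of one scaffold segment;
    a symmetric attP is produced from two P arms.  A fit RMSD above
    ``rmsd_warn`` or a crossover gap above ``continuity_threshold`` produces a
    warning with the measured value.
    """
    if scaffold.kind != "dimer":
        raise ValueError(f"full-site building needs a dimer scaffold, got {scaffold.kind}")
    if site_type not in ("attP", "attB"):
        raise ValueError(f"build_full_site builds attP/attB, not {site_type}")
    arms = ARM_ORDER[site_type]
    halves: dict[str, HalfSiteComplex] = {}
    segment_of: dict[str, str] = {}
    rmsds: dict[str, float] = {}
    for arm, segment in zip(arms, scaffold.segments):
        corr = _duplex_correspondence(half.duplex, segment.duplex, *fit_range)
        transform, fit_rmsd = kabsch_fit(corr)
        if fit_rmsd > rmsd_warn:
            warnings.warn(f"half-site fit onto {segment.label} has RMSD {fit_rmsd:.2f} A")
        halves[arm] = half.transformed(transform).with_arm_type(arm)
        segment_of[arm] = segment.label
        rmsds[arm] = fit_rmsd
    model = FullSiteModel(halves, site_type, scaffold.scaffold_id, segment_of, rmsds,
                          provenance={"fit_range": list(fit_range)})
    gap = model.crossover_gap()
    if gap > continuity_threshold:
        warnings.warn(f"crossover backbone gap {gap:.1f} A exceeds bond-forming "
                      f"threshold {continuity_threshold:.1f} A")
    return model


def _count_clashes(moved: np.ndarray, static: np.ndarray, cutoff: float) -> int:
    if len(moved) == 0 or len(static) == 0:
        return 0
    tree = cKDTree(static)
    return int(sum(len(hits) for hits in tree.query_ball_point(moved, cutoff)))


def shift_zd(model: FullSiteModel, n_bp: int = 5,
             zd_register: tuple[int, int] = (16, 24),
             clash_cutoff: float = 2.5) -> FullSiteModel:
    """Shift the zinc-ribbon domains (with their CC insertions) of an attP
    model ``n_bp`` base pairs toward the crossover, producing the attB model.

    Each subunit's ZD body is moved by the screw transform derived from its
    own duplex (register ``zd_register`` superposed onto the register shifted
    by ``n_bp``); recombinase-domain atoms are untouched.  Steric clashes
    (heavy-atom pairs closer than ``clash_cutoff``) between the moved body and
    the static remainder are counted and reported, not repaired.
    """
    if model.site_type != "attP":
        raise ValueError(f"ZD shift is defined on attP models, got {model.site_type}")
    if n_bp == 0:
        return replace(model)
    lo, hi = zd_register
    to_range = (lo - n_bp, hi - n_bp)
    positions = model.ordered_halves()[0].duplex.positions()
    if to_range[0] < min(positions) or hi > max(positions):
        raise ValueError(f"{n_bp}-bp shift moves register {zd_register} outside the "
                         f"duplex ({min(positions)}..{max(positions)})")
    new_halves: dict[str, HalfSiteComplex] = {}
    clashes = 0
    arm_map = dict(zip(ARM_ORDER["attP"], ARM_ORDER["attB"]))
    for arm, half in model.halves.items():
        transform = derive_step_transform(half.duplex, zd_register, to_range)
        zd = set(half.domain_residues("ZD"))
        moved_atoms, static_atoms, new_prot = [], [], []
        for a in half.protein.atoms:
            if a.residue_number in zd:
                moved = a.moved_to(transform.apply(a.position))
                new_prot.append(moved)
                moved_atoms.append(moved.position)
            else:
                new_prot.append(a)
                static_atoms.append(a.position)
        static_atoms.extend(at.position for at in half.duplex.structure.atoms)
        clashes += _count_clashes(np.asarray(moved_atoms), np.asarray(static_atoms),
                                  clash_cutoff)
        new_protein = StructureModel(new_prot, dict(half.protein.chain_roles))
        new_halves[arm_map[arm]] = replace(half, protein=new_protein,
                                           arm_type=arm_map[arm])
    return FullSiteModel(new_halves, "attB", model.scaffold_id,
                         {arm_map[a]: s for a, s in model.segment_of.items()},
                         dict(model.fit_rmsds), clashes,
                         {**model.provenance, "zd_shift_bp": n_bp})


def build_hybrid_site(p_half: HalfSiteComplex, b_half: HalfSiteComplex,
                      site_type: str) -> FullSiteModel:
    """Compose a product site from placed attP- and attB-model half-sites.

    attL is built from the P and B' half-sites, attR from B and P'.  The two
    inputs must already be placed in a common frame (i.e. taken from full-site
    models built on the same dimer scaffold).
    """
    if site_type not in ("attL", "attR"):
        raise ValueError(f"hybrid sites are attL/attR, got {site_type}")
    types = {p_half.arm_type, b_half.arm_type}
    if p_half.arm_type in B_DERIVED or b_half.arm_type in P_DERIVED:
        raise ValueError(f"need one P-derived and one B-derived half-site, got {sorted(types)}")
    expected = set(ARM_ORDER[site_type])
    if types != expected:
        raise ValueError(f"{site_type} is composed of arms {sorted(expected)}, got {sorted(types)}")
    halves = {p_half.arm_type: p_half, b_half.arm_type: b_half}
    model = FullSiteModel(halves, site_type, scaffold_id="hybrid")
    model.provenance["intramolecular_anchor_distance"] = model.intramolecular_anchor_distance()
    return model


@dataclass
class SynapticModel:
    """Four half-site complexes placed on a tetramer scaffold."""

    halves: dict[str, HalfSiteComplex]  # segment label -> placed complex
    pairing: str
    alignment: str
    juxtaposition_map: list[tuple[str, str]]
    scaffold_id: str
    site_of: dict[str, str] = field(default_factory=dict)
    fit_rmsds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        segs = set(self.halves)
        paired = [s for pair in self.juxtaposition_map for s in pair]
        if sorted(paired) != sorted(segs) or len(paired) != 4:
            raise ValueError("juxtaposition_map must perfectly match the four half-sites "
                             "into two facing pairs")

    def decompose(self) -> dict[str, str]:
        """Segment label -> arm type of the half-site placed there."""
        return {seg: h.arm_type for seg, h in self.halves.items()}

    @property
    def structure(self) -> StructureModel:
        merged = StructureModel([], {})
        for i, seg in enumerate(sorted(self.halves)):
            half = self.halves[seg]
            rename = {half.protein_chain: chr(ord("A") + i),
                      half.duplex.top_chain: chr(ord("E") + 2 * i),
                      half.duplex.bottom_chain: chr(ord("F") + 2 * i)}
            merged = merged.merged_with(half.structure, rename)
        return merged


def _pairing_name(t1: str, t2: str) -> str:
    short = {"attP": "P", "attB": "B", "attL": "L", "attR": "R"}
    rank = {"P": 0, "B": 1, "L": 2, "R": 3}
    a, b = sorted((short[t1], short[t2]), key=rank.__getitem__)
    return f"{a}x{b}"


def build_synaptic(site1: FullSiteModel, site2: FullSiteModel, scaffold: Scaffold,
                   alignment: str = "parallel",
                   fit_range: tuple[int, int] = (1, 5)) -> SynapticModel:
    """Place the half-sites of two full-site models on a tetramer scaffold.

    Site 1 occupies the first two scaffold segments; site 2 occupies the
    other two, in site order for ``parallel`` alignment and reversed for
    ``antiparallel``.  Facing pairs come from the scaffold.
    """
    if scaffold.kind != "tetramer":
        raise ValueError(f"synaptic building needs a tetramer scaffold, got {scaffold.kind}")
    if alignment not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown alignment {alignment!r}")
    seg1 = scaffold.segments[:2]
    seg2 = scaffold.segments[2:]
    order2 = site2.ordered_halves()
    if alignment == "antiparallel":
        order2 = order2[::-1]
    placements = list(zip(seg1, site1.ordered_halves())) + list(zip(seg2, order2))
    halves: dict[str, HalfSiteComplex] = {}
    site_of: dict[str, str] = {}
    rmsds: dict[str, float] = {}
    for segment, half in placements:
        corr = _duplex_correspondence(half.duplex, segment.duplex, *fit_range)
        transform, fit_rmsd = kabsch_fit(corr)
        halves[segment.label] = half.transformed(transform)
        site_of[segment.label] = "site1" if segment in seg1 else "site2"
        rmsds[segment.label] = fit_rmsd
    return SynapticModel(halves, _pairing_name(site1.site_type, site2.site_type),
                         alignment, list(scaffold.facing_pairs), scaffold.scaffold_id,
                         site_of, rmsds)


def site_footprint(model: FullSiteModel, cutoff: float = 5.0) -> int:
    """Total protein–DNA footprint of a full-site model in bp.

    Each arm's span is measured against its own duplex (first-to-last
    contacted position) and mapped into site coordinates around the crossover;
    the headline number is the overall span of the dimer on the site.
    """
    arms = model.ordered_arms()
    spans = []
    for idx, arm in enumerate(arms):
        half = model.halves[arm]
        fp = contact_footprint(half.structure, half.protein_chain, half.duplex, cutoff)
        if fp.first is None:
            spans.append((None, None))
            continue
        if idx == 0:  # left arm: position p sits at site coordinate -(p+1)
            spans.append((-(fp.last + 1), -(fp.first + 1)))
        else:
            spans.append((fp.first, fp.last))
    bounds = [b for pair in spans for b in pair if b is not None]
    if not bounds:
        return 0
    return max(bounds) - min(bounds) + 1
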