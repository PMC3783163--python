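"""Base-pair bookkeeping, ideal B-DNA generation and helical step transforms.

The attachment-site arithmetic in this package lives in base-pair registers:
position 0 is the crossover guanine of a half-site and positions increase
toward the distal end of the arm.  A half-site duplex is represented coarsely
— per base pair, a C1' atom, a glycosidic nitrogen and a phosphate on each
strand — which is sufficient for every superposition-based recipe (placing a
half-site on a scaffold by base pairs 1–5, deriving the 5-bp register-shift
screw from base pairs 16–24 vs 11–19, measuring protein–DNA footprints).

Frame convention (documented because no standard is imposed by the recipes):
the frame of a base pair has its origin at the C1'–C1' midpoint, its first
axis along the top-to-bottom C1' vector, its second axis toward the glycosidic
nitrogens (major-groove side negative), and the third completing a
right-handed triad.  On an ideal duplex consecutive frames are related by the
exact helical screw (twist about the axis, rise along it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import AtomRecord, StructureModel
from .superpose import Correspondence, RigidTransform, kabsch_fit

__all__ = [
    "HelicalParams",
    "BasePairFrame",
    "DuplexModel",
    "build_ideal_bdna",
    "assign_bp_numbering",
    "derive_step_transform",
    "contact_footprint",
    "FootprintResult",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}

# Coarse cylindrical placement of the per-bp atoms (radius A, azimuth deg).
# Chosen to give a C1'-C1' separation of ~10.5 A and an asymmetric groove;
# any consistent convention works for superposition-derived transforms.
_ATOM_SITES = {
    ("C1'", "top"): (9.4, +34.0, 0.0),
    ("C1'", "bottom"): (9.4, -34.0, 0.0),
    ("N9", "top"): (6.2, +25.0, 0.0),
    ("N9", "bottom"): (6.2, -25.0, 0.0),
    ("P", "top"): (9.5, +52.0, -0.5),     # axial offset in fraction of rise
    ("P", "bottom"): (9.5, -52.0, +0.5),
}


def complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in seq)


def revcomp(seq: str) -> str:
    return complement(seq)[::-1]


@dataclass(frozen=True)
class HelicalParams:
    """Idealized B-DNA step: twist in degrees/bp, rise in A/bp."""

    twist_deg: float = 34.3
    rise: float = 3.38

    def __post_init__(self) -> None:
        if not (0.0 < self.twist_deg < 60.0):
            raise ValueError(f"twist {self.twist_deg} outside (0, 60) deg/bp")
        if not (2.0 < self.rise < 5.0):
            raise ValueError(f"rise {self.rise} outside (2, 5) A/bp")

    def screw(self, n_steps: float) -> RigidTransform:
        """The exact transform relating base pair i to base pair i+n on an
        ideal duplex built in the canonical frame (axis = z)."""
        return RigidTransform.from_rotvec_deg(
            (0, 0, 1), n_steps * self.twist_deg, (0, 0, n_steps * self.rise))


@dataclass(frozen=True)
class BasePairFrame:
    origin: np.ndarray
    axes: np.ndarray  # rows: (C1'-C1' axis, groove axis, helix axis)

    def __post_init__(self) -> None:
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "axes", axes)
        if np.abs(axes @ axes.T - np.eye(3)).max() > 1e-8:
            raise ValueError("frame axes not orthonormal")


@dataclass
class DuplexModel:
    """A numbered double helix: sequence, coordinates and bp registers.

    ``sequence_top`` is the top strand in increasing-position order, i.e. the
    base at position ``p`` of the arm; ``bp_index`` maps each position to the
    (top, bottom) residue numbers holding its atoms.  ``numbering_origin``
    records which top-strand residue is position 0 (the crossover G).
    """

    sequence_top: str
    structure: StructureModel
    top_chain: str
    bottom_chain: str
    bp_index: dict[int, tuple[int, int]]
    numbering_origin: int
    helical: HelicalParams = field(default_factory=HelicalParams)

    def __post_init__(self) -> None:
        if len(self.bp_index) != len(self.sequence_top):
            raise ValueError("bp_index must cover every position exactly once")
        positions = sorted(self.bp_index)
        if positions != list(range(positions[0], positions[0] + len(positions))):
            raise ValueError("bp positions must be contiguous")

    def positions(self) -> list[int]:
        return sorted(self.bp_index)

    def base_at(self, position: int) -> str:
        pos = self.positions()
        return self.sequence_top[pos.index(position)]

    def bp_atoms(self, position: int) -> list[AtomRecord]:
        """All atoms of one base pair, in a deterministic strand/name order."""
        t, b = self.bp_index[position]
        atoms = (self.structure.select(self.top_chain, [t])
                 + self.structure.select(self.bottom_chain, [b]))
        return sorted(atoms, key=lambda a: (a.chain_id, a.atom_name))

    def range_points(self, start: int, end: int,
                     atom_names: Optional[Sequence[str]] = None) -> np.ndarray:
        """Stacked coordinates of positions start..end inclusive, in a
        deterministic (position, strand, atom name) order."""
        names = set(atom_names) if atom_names is not None else None
        pts = []
        for p in range(start, end + 1):
            if p not in self.bp_index:
                raise KeyError(f"position {p} not in duplex (has {self.positions()[0]}.."
                               f"{self.positions()[-1]})")
            for a in self.bp_atoms(p):
                if names is None or a.atom_name in names:
                    pts.append(a.position)
        return np.stack(pts)

    def frames(self) -> dict[int, BasePairFrame]:
        """Per-bp frames from the C1' pair and glycosidic nitrogens."""
        out = {}
        for p in self.positions():
            atoms = {(a.chain_id, a.atom_name): a.position for a in self.bp_atoms(p)}
            c1t = atoms[(self.top_chain, "C1'")]
            c1b = atoms[(self.bottom_chain, "C1'")]
            nt = atoms[(self.top_chain, "N9")]
            nb = atoms[(self.bottom_chain, "N9")]
            origin = 0.5 * (c1t + c1b)
            e1 = c1t - c1b
            e1 = e1 / np.linalg.norm(e1)
            g = 0.5 * (nt + nb) - origin
            e2 = g - (g @ e1) * e1
            e2 = e2 / np.linalg.norm(e2)
            e3 = np.cross(e1, e2)
            out[p] = BasePairFrame(origin, np.stack([e1, e2, e3]))
        return out

    def transformed(self, transform: RigidTransform) -> "DuplexModel":
        return replace(self, structure=self.structure.transformed(transform))

    def terminal_backbone_atoms(self, position: int) -> list[AtomRecord]:
        return [a for a in self.bp_atoms(position) if a.atom_name == "P"]


def build_ideal_bdna(sequence: str,
                     params: HelicalParams = HelicalParams(),
                     top_chain: str = "T", bottom_chain: str = "U",
                     frame: Optional[RigidTransform] = None) -> DuplexModel:
    """Straight-axis ideal B-DNA duplex from a top-strand sequence.

    The duplex is built in the canonical frame (axis +z, position 0 at the
    origin) and optionally moved as a rigid body by ``frame``.  Positions are
    numbered 0..N-1 with residue numbers 1..N on both strands.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("need at least 2 bp")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)} in sequence")
    frame = frame or RigidTransform.identity()
    atoms: list[AtomRecord] = []
    bp_index: dict[int, tuple[int, int]] = {}
    for i, base in enumerate(sequence):
        theta = np.deg2rad(i * params.twist_deg)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                        [np.sin(theta), np.cos(theta), 0.0],
                        [0.0, 0.0, 1.0]])
        z = i * params.rise
        for (name, strand), (radius, az_deg, ax_frac) in _ATOM_SITES.items():
            if name == "P" and ((strand == "top" and i == 0)
                                or (strand == "bottom" and i == len(sequence) - 1)):
                continue  # 5' ends carry no phosphate
            az = np.deg2rad(az_deg)
            local = np.array([radius * np.cos(az), radius * np.sin(az),
                              ax_frac * params.rise])
            pos = rot @ local + np.array([0.0, 0.0, z])
            resname = _RESNAME[base if strand == "top" else COMPLEMENT[base]]
            element = name[0]
            atoms.append(AtomRecord(
                atom_name=name, element=element, residue_name=resname,
                residue_number=i + 1,
                chain_id=top_chain if strand == "top" else bottom_chain,
                position=frame.apply(pos)))
        bp_index[i] = (i + 1, i + 1)
    roles = {top_chain: "dna_top", bottom_chain: "dna_bottom"}
    structure = StructureModel(atoms, roles)
    return DuplexModel(sequence, structure, top_chain, bottom_chain, bp_index, 1, params)


def assign_bp_numbering(duplex: DuplexModel, crossover_top_residue: int) -> DuplexModel:
    """Renumber positions so the base pair holding ``crossover_top_residue``
    (a top-strand residue number, the crossover G) becomes position 0."""
    top_residues = {rn for rn, _ in duplex.bp_index.values()}
    for p, (t, _) in duplex.bp_index.items():
        if t == crossover_top_residue:
            return replace(duplex, bp_index={q - p: rn for q, rn in duplex.bp_index.items()},
                           numbering_origin=crossover_top_residue)
    bottom_residues = {rn for _, rn in duplex.bp_index.values()}
    if crossover_top_residue in bottom_residues:
        raise KeyError(
            f"residue {crossover_top_residue} is on the bottom strand; flip strands "
            f"(swap top/bottom chains) before assigning the crossover origin")
    raise KeyError(f"top-strand residue {crossover_top_residue} not found "
                   f"(has {sorted(top_residues)[:3]}..)")


def derive_step_transform(duplex: DuplexModel, from_range: tuple[int, int],
                          to_range: tuple[int, int],
                          atom_names: Optional[Sequence[str]] = None) -> RigidTransform:
    """Rigid transform superposing the atoms of ``from_range`` onto
    ``to_range`` of the same duplex.

    On ideal B-DNA this equals the (k-i)-step helical screw; on a deposited
    duplex it is the empirical register-shift transform the attB model
    construction calls for.  ``atom_names`` restricts the fit (e.g. backbone
    only); by default all duplex atoms of the ranges are used.
    """
    (i, j), (k, l) = from_range, to_range
    if j - i != l - k:
        raise ValueError(f"ranges differ in length: {from_range} vs {to_range}")
    if j < i:
        raise ValueError("empty range")
    moving = duplex.range_points(i, j, atom_names)
    fixed = duplex.range_points(k, l, atom_names)
    if len(moving) != len(fixed):
        # 5'-terminal base pairs lack a phosphate; fall back to atoms present
        # at every position of both ranges.
        names = ["C1'", "N9"]
        moving = duplex.range_points(i, j, names)
        fixed = duplex.range_points(k, l, names)
    transform, _ = kabsch_fit(Correspondence(moving, fixed))
    return transform


@dataclass
class FootprintResult:
    contacted: dict[int, bool]
    span: int
    first: Optional[int]
    last: Optional[int]

    def contacted_positions(self) -> list[int]:
        return [p for p, c in sorted(self.contacted.items()) if c]


def contact_footprint(model: StructureModel, protein_chains: str | Sequence[str],
                      duplex: DuplexModel, cutoff: float = 5.0) -> FootprintResult:
    """Per-bp protein contact flags and the first-to-last contacted span.

    A base pair is contacted when any heavy atom of the named protein chain(s)
    lies within ``cutoff`` A of any of its atoms.  The headline footprint is
    the span (last - first + 1), which is robust to single uncontacted base
    pairs inside an otherwise contiguous interface.
    """
    if isinstance(protein_chains, str):
        protein_chains = [protein_chains]
    prot = [a for a in model.atoms
            if a.chain_id in protein_chains and a.element != "H"]
    if not prot:
        raise ValueError(f"no protein atoms in chains {list(protein_chains)}")
    contacted: dict[int, bool] = {}
    if cutoff <= 0:
        contacted = {p: False for p in duplex.positions()}
        return FootprintResult(contacted, 0, None, None)
    tree = cKDTree(np.stack([a.position for a in prot]))
    for p in duplex.positions():
        pts = np.stack([a.position for a in duplex.bp_atoms(p)])
        d, _ = tree.query(pts, k=1)
        contacted[p] = bool(np.min(d) <= cutoff)
    hit = [p for p, c in contacted.items() if c]
    if not hit:
        return FootprintResult(contacted, 0, None, None)
    first, last = min(hit), max(hit)
    return FootprintResult(contacted, last - first + 1, first, last)
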