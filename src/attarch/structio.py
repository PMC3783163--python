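"""Coordinate I/O, chain-role inference, domain annotation and crystallographic
bookkeeping for integrase–DNA complexes.

Parsing and writing of PDB/mmCIF goes through gemmi; this module wraps the
first model of a file into a flat, immutable-ish :class:`StructureModel` of
:class:`AtomRecord` entries, which is the coordinate currency used by the
assembly and architecture modules.  Domain annotation schemes (recombinase
domain, zinc-ribbon domain, coiled-coil insertion, anchor residues) are plain
YAML mappings; the default scheme describes the Listeria phage (LI) integrase
C-terminal domain in deposit numbering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import yaml

from .superpose import RigidTransform

__all__ = [
    "AtomRecord",
    "StructureModel",
    "DomainAnnotation",
    "CellContents",
    "read_structure",
    "write_structure",
    "annotate_domains",
    "load_annotation_scheme",
    "default_li_scheme",
    "solvent_fraction",
    "StructureParseError",
]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
NUCLEOTIDES = {"DA", "DC", "DG", "DT", "DI", "DU", "A", "C", "G", "T", "U", "I"}

PROTEIN_DA_PER_RESIDUE = 110.0
DNA_DA_PER_BP = 660.0
ZINC_DA = 65.38
HIS6_TAG_DA = 6 * 137.1


class StructureParseError(ValueError):
    """A coordinate file could not be parsed under the requested dialect."""


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        object.__setattr__(self, "position", pos)

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass
class StructureModel:
    """A flat collection of atoms plus chain roles and cell metadata."""

    atoms: list[AtomRecord]
    chain_roles: dict[str, str] = field(default_factory=dict)
    cell: Optional[tuple[float, float, float, float, float, float]] = None
    space_group: Optional[str] = None

    def __post_init__(self) -> None:
        present = {a.chain_id for a in self.atoms}
        for cid in self.chain_roles:
            if cid not in present:
                raise ValueError(f"chain_roles names absent chain {cid!r}")

    # -- selection ---------------------------------------------------------
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def select(self, chain_id: Optional[str] = None,
               residue_numbers: Optional[Iterable[int]] = None,
               atom_names: Optional[Iterable[str]] = None) -> list[AtomRecord]:
        resnums = set(residue_numbers) if residue_numbers is not None else None
        names = set(atom_names) if atom_names is not None else None
        out = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if resnums is not None and a.residue_number not in resnums:
                continue
            if names is not None and a.atom_name not in names:
                continue
            out.append(a)
        return out

    def coords(self, atoms: Optional[Sequence[AtomRecord]] = None) -> np.ndarray:
        pool = self.atoms if atoms is None else atoms
        if not pool:
            return np.zeros((0, 3))
        return np.stack([a.position for a in pool])

    def protein_chain_ids(self) -> list[str]:
        return [c for c, r in self.chain_roles.items() if r == "integrase"]

    def dna_chain_ids(self) -> list[str]:
        return [c for c, r in self.chain_roles.items() if r in ("dna_top", "dna_bottom")]

    # -- geometry ----------------------------------------------------------
    def transformed(self, transform: RigidTransform) -> "StructureModel":
        new_atoms = [a.moved_to(transform.apply(a.position)) for a in self.atoms]
        return StructureModel(new_atoms, dict(self.chain_roles), self.cell, self.space_group)

    def merged_with(self, other: "StructureModel",
                    rename: Optional[Mapping[str, str]] = None) -> "StructureModel":
        rename = dict(rename or {})
        atoms = list(self.atoms)
        roles = dict(self.chain_roles)
        for a in other.atoms:
            cid = rename.get(a.chain_id, a.chain_id)
            atoms.append(replace(a, chain_id=cid))
        for cid, role in other.chain_roles.items():
            roles[rename.get(cid, cid)] = role
        return StructureModel(atoms, roles, self.cell, self.space_group)

    def residue_numbers(self, chain_id: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.chain(chain_id):
            seen.setdefault(a.residue_number, None)
        return list(seen)


def _infer_role(residue_names: set[str]) -> str:
    aa = len(residue_names & AMINO_ACIDS)
    nt = len(residue_names & NUCLEOTIDES)
    if aa > 0 and aa >= nt:
        return "integrase"
    if nt > 0:
        return "dna"
    return "other"


def infer_chain_roles(atoms: Sequence[AtomRecord]) -> dict[str, str]:
    """Chain roles from residue chemistry.

    DNA chains are split into ``dna_top``/``dna_bottom`` in order of first
    appearance (the labels can be overridden by the caller); mixed or unknown
    chemistry maps to ``other``.
    """
    by_chain: dict[str, set[str]] = {}
    order: list[str] = []
    for a in atoms:
        if a.chain_id not in by_chain:
            order.append(a.chain_id)
        by_chain.setdefault(a.chain_id, set()).add(a.residue_name)
    roles: dict[str, str] = {}
    dna_seen = 0
    for cid in order:
        role = _infer_role(by_chain[cid])
        if role == "dna":
            role = "dna_top" if dna_seen % 2 == 0 else "dna_bottom"
            dna_seen += 1
        roles[cid] = role
    return roles


def _dialect_for(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("pdb", "mmcif"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower()
    return "mmcif" if suffix in (".cif", ".mmcif") else "pdb"


def read_structure(path, dialect: Optional[str] = None,
                   chain_roles: Optional[Mapping[str, str]] = None) -> StructureModel:
    """Read the first model of a PDB/mmCIF file.

    Alternate locations keep the highest-occupancy conformer (first encountered
    on ties).  Chain roles are inferred from residue chemistry unless
    ``chain_roles`` overrides them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _dialect_for(path, dialect)
    fmt = gemmi.CoorFormat.Pdb if dialect == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {dialect}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            best: dict[str, AtomRecord] = {}
            best_occ: dict[str, float] = {}
            for atom in residue:
                rec = AtomRecord(
                    atom_name=atom.name,
                    element=atom.element.name,
                    residue_name=residue.name.strip(),
                    residue_number=residue.seqid.num,
                    chain_id=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    is_hetero=(residue.het_flag == "H"),
                )
                occ = atom.occ if atom.occ is not None else 1.0
                if atom.name not in best or occ > best_occ[atom.name]:
                    best[atom.name] = rec
                    best_occ[atom.name] = occ
            atoms.extend(best.values())
    if not atoms:
        raise StructureParseError(f"{path}: no ATOM/HETATM records in first model")
    roles = infer_chain_roles(atoms)
    if chain_roles:
        roles.update(chain_roles)
    cell = None
    if st.cell and st.cell.a > 1.0:
        cell = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = st.spacegroup_hm or None
    return StructureModel(atoms, roles, cell, sg)


def write_structure(model: StructureModel, path, dialect: Optional[str] = None) -> Path:
    """Write a model as PDB or mmCIF; round-trips names, numbers and coordinates
    (PDB coordinates at 3-decimal precision).
    """
    path = Path(path)
    dialect = _dialect_for(path, dialect)
    if not model.atoms:
        raise ValueError("refusing to write an empty model")
    if dialect == "pdb":
        if len(model.atoms) > 99999:
            raise ValueError("PDB dialect cannot serialize >99999 atoms; use mmcif")
        too_long = sorted({a.chain_id for a in model.atoms if len(a.chain_id) > 1})
        if too_long:
            raise ValueError(f"PDB dialect needs 1-character chain ids; got {too_long}")
    st = gemmi.Structure()
    st.name = "attarch"
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
    if model.space_group:
        st.spacegroup_hm = model.space_group
    gm = gemmi.Model("1")
    # gemmi's add_residue/add_chain copy their argument, so each object must be
    # fully populated before it is added.
    grouped: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
    for a in model.atoms:
        grouped.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.residue_name), []).append(a)
    for chain_id, res_atoms in grouped.items():
        ch = gemmi.Chain(chain_id)
        for (resnum, resname), atoms in res_atoms.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "H" if atoms[0].is_hetero else "A"
            for a in atoms:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                atom.occ = 1.0
                res.add_atom(atom)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    try:
        if dialect == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Domain annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainAnnotation:
    """A named residue range in integrase numbering.

    The coiled-coil (CC) insertion lies inside the zinc-ribbon domain (ZD)
    span; membership resolution treats CC as a carve-out of ZD, so the two
    sibling annotations never both claim a residue.
    """

    name: str
    residue_range: tuple[int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        start, end = self.residue_range
        if end < start:
            raise ValueError(f"empty residue range for {self.name}: {self.residue_range}")

    def contains(self, resnum: int) -> bool:
        return self.residue_range[0] <= resnum <= self.residue_range[1]


def load_annotation_scheme(source) -> dict:
    """Load a domain annotation scheme from a YAML file path or mapping."""
    if isinstance(source, Mapping):
        scheme = dict(source)
    else:
        with open(source) as fh:
            scheme = yaml.safe_load(fh)
    if not scheme or "domains" not in scheme:
        raise ValueError("annotation scheme must define 'domains'")
    return scheme


def default_li_scheme() -> dict:
    """The shipped LI integrase CTD scheme (deposit numbering)."""
    from importlib.resources import files

    return load_annotation_scheme(str(files("attarch.data") / "li_domains.yaml"))


def annotate_domains(model: StructureModel, chain_id: str,
                     scheme: Optional[dict] = None) -> list[DomainAnnotation]:
    """Annotate an integrase chain with domain ranges and anchor residues.

    Residues listed in a range but absent from the chain (disordered regions)
    produce a warning; a missing single-residue anchor is an error because all
    downstream distance metrics depend on it.
    """
    scheme = scheme if scheme is not None else default_li_scheme()
    scheme = load_annotation_scheme(scheme)
    role = model.chain_roles.get(chain_id)
    if role is not None and role != "integrase":
        raise ValueError(f"chain {chain_id!r} has role {role!r}, not integrase")
    present = set(model.residue_numbers(chain_id))
    if not present:
        raise ValueError(f"chain {chain_id!r} has no residues")
    annotations: list[DomainAnnotation] = []
    meta_all = dict(scheme.get("metadata", {}))
    for name, rng in scheme["domains"].items():
        start, end = int(rng[0]), int(rng[1])
        if end < start:
            raise ValueError(f"empty range for domain {name}: {rng}")
        covered = [r for r in range(start, end + 1) if r in present]
        missing = sorted(set(range(start, end + 1)) - present)
        if not covered:
            warnings.warn(f"domain {name} [{start},{end}] entirely absent from chain {chain_id}")
        elif missing:
            warnings.warn(
                f"domain {name} [{start},{end}] missing {len(missing)} residues "
                f"from chain {chain_id}: {missing[:10]}{'...' if len(missing) > 10 else ''}")
        meta = {}
        if name == "ZD" and "zinc_cysteines" in meta_all:
            meta["zinc_cysteines"] = list(meta_all["zinc_cysteines"])
        annotations.append(DomainAnnotation(name, (start, end), meta))
    for anchor_name, resnum in scheme.get("anchors", {}).items():
        resnum = int(resnum)
        if resnum not in present:
            raise ValueError(f"anchor residue {anchor_name}={resnum} absent from chain {chain_id}")
        annotations.append(DomainAnnotation(anchor_name, (resnum, resnum), {}))
    return annotations


def domain_of(resnum: int, annotations: Sequence[DomainAnnotation]) -> Optional[str]:
    """Resolve the domain owning a residue; CC wins over the enclosing ZD."""
    ranges = {a.name: a for a in annotations if a.residue_range[0] != a.residue_range[1]
              or a.name not in ("ZD_anchor", "CC_tip")}
    if "CC" in ranges and ranges["CC"].contains(resnum):
        return "CC"
    for name, ann in ranges.items():
        if name != "CC" and ann.contains(resnum):
            return name
    return None


def get_annotation(annotations: Sequence[DomainAnnotation], name: str) -> DomainAnnotation:
    for a in annotations:
        if a.name == name:
            return a
    raise KeyError(f"no annotation named {name!r}")


# ---------------------------------------------------------------------------
# Crystallographic bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class CellContents:
    """Macromolecular contents of one asymmetric unit.

    ``protein_copies`` entries are ``(sequence_or_residue_count, copies)``;
    ``dna_duplexes`` entries are ``(bp_count, copies)``.
    """

    protein_copies: list[tuple] = field(default_factory=list)
    dna_duplexes: list[tuple] = field(default_factory=list)
    zinc_ions: int = 0

    def mass_da(self, da_per_residue: float = PROTEIN_DA_PER_RESIDUE,
                da_per_bp: float = DNA_DA_PER_BP,
                include_his_tag: bool = False) -> float:
        total = 0.0
        for entry, copies in self.protein_copies:
            if copies < 0:
                raise ValueError("negative copy count")
            if isinstance(entry, str):
                from Bio.SeqUtils import molecular_weight

                mass = molecular_weight(entry, seq_type="protein")
            else:
                mass = float(entry) * da_per_residue
            if include_his_tag:
                mass += HIS6_TAG_DA
            total += mass * copies
        for bp, copies in self.dna_duplexes:
            if copies < 0 or bp < 0:
                raise ValueError("negative DNA count")
            total += float(bp) * da_per_bp * copies
        if self.zinc_ions < 0:
            raise ValueError("negative zinc count")
        total += self.zinc_ions * ZINC_DA
        return total


def _space_group_multiplicity(space_group: str) -> int:
    sg = gemmi.find_spacegroup_by_name(space_group)
    if sg is None:
        raise ValueError(f"unknown space group symbol {space_group!r}")
    return len(sg.operations())


def solvent_fraction(cell: tuple, space_group: str, contents: CellContents,
                     da_per_residue: float = PROTEIN_DA_PER_RESIDUE,
                     da_per_bp: float = DNA_DA_PER_BP,
                     include_his_tag: bool = False,
                     matthews_constant: float = 1.23) -> float:
    """Crystal solvent fraction from the Matthews relation.

    ``fraction = 1 - matthews_constant / Vm`` with ``Vm = V_cell / (Z * M_AU)``
    in A^3/Da.  The 1.23/Vm convention (partial specific volume 0.74 cm^3/g)
    is applied to the total macromolecular mass, DNA included; with DNA mass at
    660 Da/bp this slightly overestimates the DNA volume but changes the result
    by well under the +/-2 percentage points the bookkeeping is used for.
    """
    a, b, c, al, be, ga = cell
    volume = gemmi.UnitCell(a, b, c, al, be, ga).volume
    if volume <= 0 or not math.isfinite(volume):
        raise ValueError("zero or invalid cell volume")
    z = _space_group_multiplicity(space_group)
    mass = contents.mass_da(da_per_residue, da_per_bp, include_his_tag)
    if mass == 0:
        return 1.0
    vm = volume / (z * mass)
    return float(min(1.0, max(0.0, 1.0 - matthews_constant / vm)))
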