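"""Attachment-site sequence arithmetic: half-site registers, ZD-motif
scanning and register shifts.

Conventions.  An :class:`AttSite` stores one top-strand sequence (5'->3') and
the indices of its central crossover dinucleotide.  Each site decomposes into
two half-sites; every half-site is re-expressed as a *positional string* read
5'->3' *outward* from the crossover, so that index ``p`` of the string is the
base ``p`` steps from the crossover on the strand leaving it.  In this
coordinate system the two halves of a site are directly comparable, motif
registers measured on different sites are directly comparable, and the
left/right distinction reduces to which physical strand supplies the outward
read (the bottom strand on the left, the top strand on the right).

The ZD recognition motif is reported at the register (distance of its first
base from the crossover) and strand ('+' if the motif matches the positional
string itself, '-' if it matches its reverse complement) of each hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Iterable, Optional, Sequence

import numpy as np

from .dna import COMPLEMENT, complement, revcomp

__all__ = [
    "AttSite",
    "MotifHit",
    "ZD_MOTIF",
    "load_att_sites",
    "scan_zd_motif",
    "best_motif_register",
    "register_shift",
    "half_site_symmetry",
    "conservation_profile",
    "pairwise_identity",
]

ZD_MOTIF = "TTTAGTATC"  # zinc-ribbon recognition motif, 5'->3' outward read


@dataclass(frozen=True)
class AttSite:
    """One attachment site: top strand plus crossover dinucleotide indices."""

    name: str
    sequence: str
    crossover: tuple[int, int]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)} in {self.name}")
        i, j = self.crossover
        if j != i + 1 or i < 0 or j >= len(seq):
            raise ValueError(f"crossover {self.crossover} is not an internal "
                             f"adjacent index pair of a {len(seq)}-bp site")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def crossover_dinucleotide(self) -> str:
        i, j = self.crossover
        return self.sequence[i:j + 1]

    def left_half(self) -> str:
        """Left half-site as a positional string (5'->3' outward from the
        crossover, i.e. the bottom strand read right-to-left)."""
        i, _ = self.crossover
        return revcomp(self.sequence[:i + 1])

    def right_half(self) -> str:
        """Right half-site as a positional string (the top strand from the
        crossover outward)."""
        _, j = self.crossover
        return self.sequence[j:]

    def halves(self) -> dict[str, str]:
        return {"left": self.left_half(), "right": self.right_half()}

    @classmethod
    def from_halves(cls, name: str, left: str, right: str) -> "AttSite":
        """Reassemble a site from two positional half-site strings."""
        top = revcomp(left.upper()) + right.upper()
        return cls(name, top, (len(left) - 1, len(left)))


def load_att_sites(path=None) -> dict[str, "AttSite"]:
    """Attachment sites from a FASTA whose record descriptions carry a
    ``crossover=i,j`` tag (0-based indices of the crossover dinucleotide).

    With no path, the packaged synthetic reference sites are loaded.
    """
    from Bio import SeqIO

    if path is None:
        from importlib.resources import files

        path = str(files("attarch.data") / "att_sites.fasta")
    sites = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        tag = [w for w in rec.description.split() if w.startswith("crossover=")]
        if not tag:
            raise ValueError(f"record {rec.id}: no crossover=i,j tag in description")
        i, j = (int(x) for x in tag[0].split("=", 1)[1].split(","))
        sites[rec.id] = AttSite(rec.id, str(rec.seq), (i, j))
    if not sites:
        raise ValueError(f"no FASTA records in {path}")
    return sites


@dataclass(frozen=True)
class MotifHit:
    half: str        # left | right (or the sequence name for bare strings)
    register: int    # crossover-distance of the motif's first base
    strand: str      # + | -
    mismatches: int
    window: str      # positional-string window at the hit


def _scan_one(half_name: str, positional: str, motif: str,
              max_mismatch: int) -> list[MotifHit]:
    k = len(motif)
    rc = revcomp(motif)
    hits = []
    for s in range(len(positional) - k + 1):
        window = positional[s:s + k]
        mm_plus = sum(a != b for a, b in zip(window, motif))
        if mm_plus <= max_mismatch:
            hits.append(MotifHit(half_name, s, "+", mm_plus, window))
        mm_minus = sum(a != b for a, b in zip(window, rc))
        if mm_minus <= max_mismatch:
            hits.append(MotifHit(half_name, s, "-", mm_minus, window))
    return hits


def scan_zd_motif(site: AttSite | str, motif: str = ZD_MOTIF,
                  max_mismatch: int = 0) -> list[MotifHit]:
    """All motif hits on both strands of a site's half-sites (or of one bare
    positional string), sorted by (mismatches, register).

    A '-'-strand hit at register ``r`` means the motif is read on the strand
    complementary to the outward positional strand, i.e. pointing back toward
    the crossover with its last base ``r`` steps out.
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"invalid motif {motif!r}")
    if isinstance(site, str):
        halves = {"seq": site.upper()}
    else:
        halves = site.halves()
    hits: list[MotifHit] = []
    for half_name, positional in halves.items():
        hits.extend(_scan_one(half_name, positional, motif, max_mismatch))
    return sorted(hits, key=lambda h: (h.mismatches, h.register, h.half, h.strand))


def best_motif_register(site: AttSite, motif: str = ZD_MOTIF,
                        max_mismatch: int = 0, half: Optional[str] = None) -> MotifHit:
    """The best (fewest-mismatch, then most crossover-proximal) motif hit."""
    hits = scan_zd_motif(site, motif, max_mismatch)
    if half is not None:
        hits = [h for h in hits if h.half == half]
    if not hits:
        raise ValueError(f"no {motif} hit within {max_mismatch} mismatches "
                         f"in {site.name if isinstance(site, AttSite) else site!r}")
    return hits[0]


def register_shift(site_a: AttSite, site_b: AttSite, motif: str = ZD_MOTIF,
                   max_mismatch: int = 0, half: str = "left") -> int:
    """Difference (a minus b) between the best motif registers of two sites.

    A positive value means the motif — hence the bound zinc-ribbon domain —
    sits further from the crossover on ``site_a`` than on ``site_b``.
    Comparing a site with itself is rejected: a zero shift measured that way
    carries no information.
    """
    if site_a.name == site_b.name and site_a.sequence == site_b.sequence:
        raise ValueError("register shift of a site against itself is not meaningful")
    ra = best_motif_register(site_a, motif, max_mismatch, half).register
    rb = best_motif_register(site_b, motif, max_mismatch, half).register
    return ra - rb


def half_site_symmetry(site: AttSite) -> dict:
    """Positional agreement of the two half-sites of one site.

    Compares the left and right positional strings over their common length;
    perfect agreement means the site is an exact inverted repeat around the
    crossover.
    """
    left, right = site.left_half(), site.right_half()
    n = min(len(left), len(right))
    matches = sum(left[p] == right[p] for p in range(n))
    return {
        "compared": n,
        "matches": matches,
        "identity": matches / n if n else float("nan"),
        "mismatch_positions": [p for p in range(n) if left[p] != right[p]],
    }


def conservation_profile(sequences: Sequence[str], pseudocount: float = 0.01) -> np.ndarray:
    """Per-column information content (bits) of equal-length sequences.

    Columns carry 2 bits when a single base is fully conserved and 0 bits at
    uniform composition; ``pseudocount`` regularizes small samples.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("sequences must be equal length")
    bases = "ACGT"
    info = np.zeros(n)
    for col in range(n):
        counts = np.array([sum(s[col] == b for s in seqs) for b in bases], dtype=float)
        counts += pseudocount
        p = counts / counts.sum()
        entropy = -sum(pi * log2(pi) for pi in p if pi > 0)
        info[col] = 2.0 - entropy
    return info


def pairwise_identity(seq_a: str, seq_b: str) -> dict:
    """Global pairwise identity of two sequences (protein or DNA).

    Alignment: Needleman-Wunsch with match +1, mismatch 0, gap open -5,
    gap extend -1 (identity-style scoring).  Returns the identity over
    aligned columns and the difference count (mismatches plus gap columns).
    """
    from Bio import Align

    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    col_a, col_b = (str(s) for s in (aln[0], aln[1]))
    matches = sum(x == y and x != "-" for x, y in zip(col_a, col_b))
    gaps = sum(x == "-" or y == "-" for x, y in zip(col_a, col_b))
    mismatches = len(col_a) - matches - gaps
    return {
        "aligned_columns": len(col_a),
        "matches": matches,
        "mismatches": mismatches,
        "gap_columns": gaps,
        "identity": matches / len(col_a),
        "differences": mismatches + gaps,
    }
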