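# Methods

## Coarse-grained representation

Each att half-site is one integrase CTD copy bound to a ~25-bp arm duplex.
The duplex is ideal B-DNA (twist 34.3°/bp, rise 3.38 Å) with three coarse
atoms per nucleotide (C1′, N9, P; 5′-terminal nucleotides lack P), numbered
in site coordinates with the crossover dinucleotide at position 0 so arms
from different sites align by construction.  The protein is a CA-only trace
with two rigid bodies:

- **RD block** (residues < 265) — recombinase-domain trace following bp
  0–12 plus a contact cluster, rigid with the duplex;
- **ZD block** (residues ≥ 265) — zinc-ribbon-domain trace following bp
  13–24, the four zinc cysteines (274/277/302/314), the single-residue
  anchor Ala338 placed at radius 30 Å over its anchor bp, and the coiled
  coil ending at Tyr374 with a fixed anchor→tip span of 54 Å.

Domain definitions (RD 133–264, ZD 265–452, CC 342–416 carved out of the ZD)
live in `src/attarch/data/li_domains.yaml`.

## Model building

1. **attP** — two copies of the half-site are placed on a bent dimer
   scaffold by Kabsch superposition of duplex bp 1–5 onto each scaffold
   segment (fit RMSD 0 by construction; crossover backbone gap 10.4 Å).
2. **attB** — each subunit's ZD block is moved by the *exact helical screw*
   that carries duplex register 16–24 onto 11–19 (a 5-bp slide toward the
   crossover); RD and DNA are untouched.  Steric clashes are counted with a
   2.5 Å cutoff (0 for the shipped geometry), and the protein–DNA footprint
   contracts from 50 bp (attP) to 40 bp (attB).
3. **attL/attR** — hybrids of one P-derived and one B-derived half
   (attL = P + B′, attR = B + P′).
4. **Synapses** — two full sites on a tetramer scaffold (two parallel duplex
   planes 95 Å apart), with facing pairs given by the scaffold and an
   alignment choice (parallel/antiparallel).

## Reach model and verdicts

With CC length 54 Å, two CC arms can pair when their ZD anchors are between
d_min = 50 Å and d_max = 2×54 = 108 Å apart.  Rules, in order: an attL/attR
intramolecular distance ≤ d_max ⇒ **autoinhibited** (the site's own arms
pair, sequestering the CCs); any facing distance > d_max ⇒ **blocked_far**;
any < d_min ⇒ **blocked_near**; otherwise **competent**.  For the attL × attR
synapse, constituent-site autoinhibition pre-empts the pair verdict
(`combine_verdicts`).

## Calibration (fixed before any test was written)

The dimer scaffold has C2 symmetry: the right arm is the left arm rotated by
180° about the in-plane axis, which adds 180° to the anchor azimuth.  The
free parameters — inter-arm angle and anchor azimuth — were solved by least
squares against the published anchor separations attP 126 / attB 109 /
attL = attR 101 Å, giving the frozen constants arm angle 107°, azimuth 90°.
These reproduce 126.5 / 107.4 / 101.4 Å, and the whole build pipeline agrees
with the generator's closed-form predictions to 1e−6 (a property test sweeps
100 random geometries).

Emergent (not fitted) values: tetramer facing distances attP×attP 154.6 Å,
attB×attB 35.0 Å, attP×attB 96.3 Å with 154.2 Å diagonals.  Known residuals
against published numbers: attP×attB facing 96.3 vs ~77 Å and diagonal 154.2
vs ~142 Å — the coarse scaffold fixes the two duplex planes at a single
separation, so cross-plane distances are systematically long; the qualitative
verdict landscape (only attP×attB within reach) is unaffected.  attP×attP
(~154 Å) and attB×attB (~35 Å) match.

## Sequence analysis

The shipped att sites (attP 50 bp, attB 40 bp, attL/attR 45 bp, crossover
dinucleotide GC) carry the 9-bp ZD motif on the minus strand of each arm at
register 16 (attP) and 11 (attB): a +5 bp register shift, matching the 5-bp
ZD slide in the structural model.  Scanning is exhaustive over both strands
with a mismatch budget and is property-tested against a brute-force
re-implementation.  A synthetic pair of integrase sequences (452 aa, 11
conservative differences, 97.6 % identity, invariant zinc cysteines and
anchors) exercises the alignment utilities.

## Crystal bookkeeping and NCS

The reference crystal form (290.8 Å cubic cell, space group I 2 3, four
320-residue chains + four 26-nt strands + 4 Zn per asymmetric unit) gives a
solvent fraction of 74.8 %.  `make_mock_ncs_copies` scatters jittered copies
(per-atom σ = 0.17 Å, so pairwise fitted RMSD ≈ √6·σ ≈ 0.42 Å) to exercise
NCS superposition.

## Limitations

- CA-only, rigid-body models: no side chains, no DNA deformation, no
  energetics — distances and clash counts are geometric bookkeeping.
- The tetramer scaffold's single plane separation causes the cross-plane
  distance residuals noted above.
- The deposited-structure regression requires externally fetched coordinates
  (`scripts/fetch_deposited.py`) and stays RED offline by design.
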