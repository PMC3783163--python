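# attarch

Geometric and sequence-level models of how a large serine integrase's
C-terminal domains (CTD) recognise attachment (att) sites and why
recombination only proceeds in one direction.

The package builds coarse-grained structural models of one integrase CTD
bound to one att half-site, assembles them into full sites (attP, attB and
the product sites attL/attR) and into synaptic tetramers, and then asks a
single geometric question: can the coiled-coil (CC) arms of two DNA-bound
subunits reach each other?  The answer — measured as zinc-ribbon-domain
anchor separations compared against the CC reach — reproduces the
directionality logic of the system:

| arrangement        | anchor separation | verdict        |
|--------------------|-------------------|----------------|
| attP × attB        | within CC reach   | competent      |
| attP × attP        | too far           | blocked_far    |
| attB × attB        | too close         | blocked_near   |
| attL, attR (intra) | within reach      | autoinhibited  |
| attL × attR        | —                 | autoinhibited  |

A parallel sequence module locates the zinc-ribbon-domain (ZD) recognition
motif on the shipped att-site sequences and measures the +5 bp register shift
between attP and attB arms that drives the structural difference.

## Modules

- `attarch.structio` — PDB/mmCIF reading/writing, chain-role inference,
  residue-range domain annotation (RD 133–264, ZD 265–452 with the CC
  342–416 carved out), and Matthews/solvent-fraction bookkeeping.
- `attarch.superpose` — rigid transforms and Kabsch superposition.
- `attarch.dna` — ideal B-DNA coarse duplex building, crossover-origin bp
  numbering, and exact helical screw transforms between bp registers.
- `attarch.assembly` — half-site complexes, full-site building on bent dimer
  scaffolds, the ZD register shift that converts attP arms into attB arms,
  hybrid (attL/attR) sites, and synaptic tetramers.
- `attarch.architecture` — anchor-distance measurement, the CC reach model
  and the synapsis verdict rules.
- `attarch.attseq` — att-site sequences, ZD motif scanning, register shift,
  half-site symmetry, conservation and pairwise identity.
- `attarch.synthetic` — deterministic synthetic generators (half-site,
  scaffolds, NCS copies, mock sites, reference sequences and crystal form)
  with closed-form expected observables used as test oracles.
- `attarch.cli` — `attarch build | report | scan | fixtures`.

## CLI

```
attarch build --out models/         # write the 12 models + provenance.json
attarch report                      # distance tables + synapsis verdicts
attarch scan                        # ZD motif hits and the +5 bp shift
attarch fixtures --out fx --seed 1  # synthetic PDB/FASTA fixtures
```

## Tests and acceptance

```
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

One test is expected to fail offline:
`test_acceptance.py::test_deposited_structure_regression` needs deposited
coordinates (fetch with `scripts/fetch_deposited.py` on a networked machine);
it reports that unavailability as a failure rather than skipping.  Everything
else runs from the synthetic generators.

See `docs/methods.md` for the geometry, calibration and known residuals.
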