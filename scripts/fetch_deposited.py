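#!/usr/bin/env python
"""Fetch the deposited inputs needed by the deposited-structure regression.

Usage:
    python scripts/fetch_deposited.py [--out data/deposited]

Downloads (network required):
  - 4kis.cif      mmCIF coordinates of the integrase CTD / att-DNA complex
  - 1gdt.pdb      gamma-delta resolvase catalytic-domain dimer (RD reference)
  - 1zr4.pdb      Sin recombinase tetramer (synaptic reference)
  - cac97653.fasta  homologous integrase protein record from ENA

tests/test_acceptance.py::test_deposited_structure_regression stays RED until
these files exist AND the deposit-specific rebuild (chain mapping, residue
numbering and NCS-copy selection of each asymmetric unit) is implemented on a
machine where the files can be inspected.  This script only fetches inputs;
it deliberately implements no analysis.
"""

import argparse
import urllib.request
from pathlib import Path

SOURCES = {
    "4kis.cif": "https://files.rcsb.org/download/4KIS.cif",
    "1gdt.pdb": "https://files.rcsb.org/download/1GDT.pdb",
    "1zr4.pdb": "https://files.rcsb.org/download/1ZR4.pdb",
    "cac97653.fasta":
        "https://www.ebi.ac.uk/ena/browser/api/fasta/CAC97653.1",
}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("data/deposited"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for name, url in SOURCES.items():
        dest = args.out / name
        if dest.exists():
            print(f"{dest} exists, skipping")
            continue
        print(f"fetching {url} -> {dest}")
        with urllib.request.urlopen(url, timeout=60) as resp:
            dest.write_bytes(resp.read())
    print("done")


if __name__ == "__main__":
    main()
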