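"""Consistency checks against deposited crystal structures (needs files).

Requires local copies of PDB entries 8PFE (NRP1-b1 hexavariant with the
KDKPPR peptide) and 1KEX (wild-type NRP1-b1), e.g.:

    curl -O https://files.rcsb.org/download/8PFE.pdb
    curl -O https://files.rcsb.org/download/1KEX.pdb
    python examples/deposited_structure_checks.py 8PFE.pdb 1KEX.pdb

Checks performed:
  * C-alpha superposition of the two independent monomers (chains A and C)
    of 8PFE — expected RMSD about 0.30 A;
  * C-alpha superposition of 8PFE chain A onto 1KEX chain A (hexavariant
    vs wild type) — expected RMSD about 0.51 A;
  * maximum C-alpha RMSTD from the 8PFE B-factors — expected below 0.75 A.
"""

import sys

import numpy as np

from contactzones import kabsch_superpose, read_structure, rmstd_from_b
from contactzones.structure_io import dedupe_altlocs


def calpha_map(model, chain):
    atoms = dedupe_altlocs(model.chain(chain))
    return {a.residue_number: a for a in atoms if a.name == "CA"}


def paired_coords(map_a, map_b):
    common = sorted(set(map_a) & set(map_b))
    xa = np.array([map_a[r].position for r in common])
    xb = np.array([map_b[r].position for r in common])
    return xa, xb, common


def main(path_8pfe, path_1kex=None):
    complex_model = read_structure(path_8pfe)
    ca_a = calpha_map(complex_model, "A")
    ca_c = calpha_map(complex_model, "C")
    xa, xc, common = paired_coords(ca_a, ca_c)
    _, _, rmsd_ac = kabsch_superpose(xa, xc)
    print(f"8PFE chains A vs C: {len(common)} shared C-alpha, "
          f"RMSD = {rmsd_ac:.2f} A (expected ~0.30)")

    max_rmstd = max(
        rmstd_from_b(a.b_factor) for a in list(ca_a.values()) + list(ca_c.values())
    )
    print(f"max C-alpha RMSTD from B-factors: {max_rmstd:.2f} A "
          "(expected < 0.75)")

    if path_1kex:
        wt = read_structure(path_1kex)
        wt_chain = next(iter(wt.chains))
        xa2, xw, common2 = paired_coords(ca_a, calpha_map(wt, wt_chain))
        _, _, rmsd_wt = kabsch_superpose(xa2, xw)
        print(f"8PFE chain A vs 1KEX chain {wt_chain}: {len(common2)} shared "
              f"C-alpha, RMSD = {rmsd_wt:.2f} A (expected ~0.51)")


if __name__ == "__main__":
    if len(sys.argv) < 2:
        sys.exit(__doc__)
    main(*sys.argv[1:3])
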