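"""Pocket extraction and binding-energy assembly.

Writes a toy protein-ligand complex with residues at scripted
distances, extracts the 5 Å binding pocket as a PDB fragment (the input
a quantum-chemistry engine would consume), then assembles binding
energies E_complex - (E_protein + E_ligand) from component energies and
ranks variant preference.
"""

import tempfile
from pathlib import Path

from ensdock import (
    EnergyComponents,
    SynthConfig,
    compare_variants,
    make_complex,
    pocket_residues,
)

tmp = Path(tempfile.mkdtemp())
truth = make_complex(SynthConfig(seed=9, complex_distances=(3.0, 4.9, 5.1, 8.0)),
                     tmp / "complex.pdb")
sel = pocket_residues(tmp / "complex.pdb", "LIG", 5.0, out_pdb=tmp / "pocket.pdb")
print(f"scripted residue distances: {truth}")
print(f"5 A pocket residues       : {sorted(sel.resnums)}  (closed threshold, d <= 5)")

rows = [
    EnergyComponents("T790M-complex", e_complex=-904.45, e_protein=-250.0,
                     e_ligand=-120.0, variant="T790M"),
    EnergyComponents("L858R-complex", e_complex=-869.87, e_protein=-250.0,
                     e_ligand=-120.0, variant="L858R"),
    EnergyComponents("WT-complex", e_complex=-779.33, e_protein=-250.0,
                     e_ligand=-120.0, variant="WT"),
]
report = compare_variants(rows)
print()
print(report.to_tsv())
print("More negative binding energy = more favorable; the preference string")
print("orders variants by their best complex.")
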