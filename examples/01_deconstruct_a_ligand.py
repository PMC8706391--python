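"""Deconstruct one ligand into rule-of-three-compliant sub-ligands.

PU3, a purine-scaffold Hsp90 inhibitor, is cut at every acyclic single bond
touching a ring system (terminal polar substituents stay attached); each
distinct piece keeps a '*' marker per broken bond.
"""

import fragrebuild as fr

pu3 = fr.canonicalize(fr.PU3_SMILES, id="PU3")
print(f"ligand {pu3.id}: {pu3.smiles_canonical} ({pu3.heavy_atom_count} heavy atoms)\n")

for frag in fr.fragment_ligand(pu3):
    body = fr.strip_markers(frag)
    d = fr.compute_descriptors(body.molecule)
    print(
        f"  {frag.smiles_with_markers:30s} markers={frag.n_attach}  "
        f"stripped={body.molecule.smiles_canonical:20s} "
        f"MW={d.mw:6.1f}  cLogP={d.clogp:5.2f}  HBD={d.hbd}  HBA={d.hba}"
    )

# Each line is one sub-ligand: its marker form (reusable as a header), the
# hydrogen-capped body, and the descriptors that kept it under the rule of
# three (MW < 300, cLogP <= 3, HBD <= 3, HBA <= 3).
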