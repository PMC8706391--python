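"""Reference-library statistics and per-group improvement arithmetic.

Loads the 68 packaged Hsp90 inhibitors, summarizes their published binding
energies, and applies the improvement formula
100 * (|BBE_NL| - |BBE_KL|) / |BBE_KL| to the published per-group best
energies of the semi-exhaustive reference runs.
"""

import fragrebuild as fr

records = fr.load_reference_library()
stats = fr.library_stats(records)
print(f"ligands          : {len(records)}")
print(f"best energy      : {stats['min_be']}   (attained by {stats['n_at_min']} ligands)")
print(f"worst energy     : {stats['max_be']}")
print(f"mean energy      : {stats['mean_be']:.2f}\n")

print("group  n_kl  bbe_kl  bbe_nl  improvement")
for g, ref in sorted(fr.load_reference_results().items()):
    imp = fr.improvement_report(ref["bbe_kl"], ref["bbe_nl"])
    print(f"{g:5d} {ref['n_kl']:5d} {ref['bbe_kl']:7.1f} {ref['bbe_nl']:7.1f} {imp.rounded:10d}%")

# Improvement is the relative gain in the magnitude of the best binding
# energy when moving from the known-ligand library to the reconstructed one.
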