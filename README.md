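# fragrebuild

Fragment-based *deconstruction–reconstruction* design of candidate Hsp90
inhibitors, for computational and medicinal chemists who want to generate
novel drug-like ligands from a library of known actives — and for method
developers who need the combinatorial machinery (fragmentation, coupling,
census accounting, annealing search) separated from any particular docking
engine.

## The method

Starting from a set of known ligands **KL** (the package ships the 68
published Hsp90 inhibitors with their docking binding energies and family
labels — resorcinol, hydroxy-indazole, "others" — plus the eight nested
experiment groups):

1. **Deconstruction.** Every acyclic single bond touching a ring system is
   cut simultaneously (terminal polar substituents — OH, NH₂, halogens —
   stay attached). Each distinct piece keeps one `*` attachment marker per
   broken bond and must satisfy the rule of three (MW < 300, cLogP ≤ 3,
   HBD ≤ 3, HBA ≤ 3). This yields N_FL fragments over all ligands.
2. **Duplicity & cleaning.** Fragments are compared pairwise (Tanimoto
   coefficient on Morgan fingerprints, plus canonical-SMILES equality);
   of duplicates only the first survives: N_SL = N_FL − D_F.
3. **Sub-ligand sets.** Surviving fragments with markers form the *header*
   set SL\*; every surviving fragment contributes its hydrogen-capped twin
   to the *body* set SL.
4. **Semi-exhaustive reconstruction.** Each header is coupled with each
   body (the body bonds into the header's first marker); residual markers
   are filled with seeded random body draws. Candidates failing Lipinski's
   rule of five or Veber's rules are rejected (R_NL), survivors are
   deduplicated (D_NL), and the census must satisfy

   &nbsp;&nbsp;&nbsp;&nbsp;**N = generated − R_NL − D_NL**, which is
   **N = (N_FL − D_F)² − R_NL − D_NL** when headers and bodies both number N_SL.

5. **Heuristic search.** A restart simulated annealer explores the same
   space: a solution is one header plus one body per marker; a *change*
   move replaces a body within its Tanimoto neighborhood, an accepted
   improving change is followed by one *swap* move, deteriorations are
   accepted with probability exp(−Δ/T), and T cools geometrically by α.

Scoring is pluggable: a lookup scorer over the published table, a
deterministic descriptor-based surrogate, or an adapter contract for an
external docking engine (grid 45×45×45 at 0.375 Å, 100 runs, population
150, 1 Å RMS clustering) — the search only ever consumes "most negative
pose energy or unavailable".

## Worked example

```python
import fragrebuild as fr

ligands = [fr.canonicalize(r.smiles, id=r.id) for r in fr.build_group(1)]
lib = fr.build_library(ligands)
new_ligands, acc = fr.semi_exhaustive(lib, seed=7)
print(lib.n_fl, lib.n_df, lib.n_sl, acc.generated, acc.rnl, acc.dnl, acc.n)
```

prints `24 5 19 361 25 3 333`: the five group-1 ligands yield 24 fragments,
5 are duplicates, and the 19×19 = 361 candidate unions lose 25 to the
drug-likeness filter and 3 to duplicate removal, leaving 333 new ligands —
satisfying the census identity 361 − 25 − 3 = 333. The scripts in
`examples/` walk each capability (deconstruction, reconstruction,
annealing search, library statistics) and print what the numbers mean; the
same operations are available from the shell via the `fragrebuild` CLI
(`deconstruct`, `reconstruct`, `search`, `evaluate`, `report`, `fixtures`).

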