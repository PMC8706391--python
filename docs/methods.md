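# Methods

This note documents the model, conventions and design choices behind
`fragrebuild`, in the order the pipeline runs.

## Molecular substrate

All structures are SMILES-backed and normalized through RDKit canonical
SMILES; two spellings of one structure always map to one canonical string.
Stereochemistry is preserved through canonicalization but ignored by
fingerprints, so duplicate detection operates at the constitutional level —
appropriate because duplicate removal is defined through fingerprint
identity.

Descriptors:

* **MW** — average-mass molecular weight (implicit hydrogens included).
* **cLogP** — Crippen atomic-contribution estimate, the de-facto open
  implementation of "cLogP".
* **HBD** — count of N/O atoms bearing at least one hydrogen. (This counts
  donor *groups*; water has one donor.)
* **HBA** — count of N/O atoms whose lone pair is plausibly available:
  every oxygen, plus nitrogens that are not pyrrole-type aromatic N (lone
  pair inside the ring π system), not amide/sulfonamide N, and not
  aniline-type amines conjugated to an aromatic ring. Under this
  convention adenine has 3 acceptors and water 1. A plain N+O count was
  rejected because it classifies the aminopurine fragment of the PU3
  worked example as too acceptor-rich for a fragment filter that the
  worked example evidently passes; the conjugation-aware count is the
  chemically defensible convention consistent with that example. The same
  convention is used in the rule-of-three and rule-of-five checks, so the
  filters are internally consistent.
* **Rotatable bonds, TPSA** — the conventional RDKit definitions.

Fingerprints are Morgan (ECFP-like), radius 2, 2048 bits: standard,
deterministic, and dense enough that Tanimoto 1.0 practically implies
constitutional identity at fragment scale. The Tanimoto coefficient of two
empty fingerprints is defined as 0.0 so marker-free stubs are never
vacuously identical.

Filter thresholds (boundary behavior as stated): rule of three — MW
strictly < 300, cLogP ≤ 3, HBD ≤ 3, HBA ≤ 3; rule of five — MW ≤ 500,
cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10; Veber — rotatable bonds ≤ 10, TPSA ≤ 140 Å².
Both checks report the complete set of violated clauses.

## Deconstruction

A bond is *cleavable* when it is a single, acyclic bond between two heavy
atoms with at least one endpoint in a ring system, excluding bonds that
would sever a terminal non-carbon substituent (hydroxyl, amino, halogen):
those polar decorations define fragment pharmacophores and stay attached.
All cleavable bonds are cut **simultaneously** (one-shot multi-cut, not
recursive enumeration); each broken bond leaves a `*` dummy atom on both
pieces. A ligand's fragment set is its *distinct* pieces (repeated
substituents such as three methoxy groups count once), filtered by the
rule of three with markers hydrogen-capped. This rule was calibrated so
that the PU3 worked example yields exactly five sub-ligands (butyl,
aminopurine, methylene, ring core, methoxy); the raw cut of PU3 gives
seven pieces of five distinct structures. A ligand with no cleavable bonds
contributes itself as a single marker-free fragment, usable only as a
body.

Pooled deduplication compares fragments on their marker-stripped
structure; of duplicates the **first seen** survives, keeping its marker
pattern — a deterministic resolution of the otherwise unspecified
which-copy-survives question. The census fields satisfy
`n_sl == n_fl − n_df` by construction and the library constructor enforces
it.

## Reconstruction

Coupling consumes the header's *first* marker — the marker atom with the
lowest RDKit canonical rank, so "first" is a property of the structure,
not of input ordering. The body-side attachment atom is the first
free-valence heavy atom in canonical order by default; a `random` policy
(seeded) is available. A coupling that cannot produce a valence-valid
sanitized molecule raises an infeasibility signal.

The semi-exhaustive pass iterates headers × bodies; residual markers after
the first union are filled by uniform seeded draws from the body pool.
Rejections (`rnl`) pool drug-likeness failures and coupling
infeasibilities (the latter tracked separately in `rnl_coupling` so the
census identity stays exact). Survivor deduplication uses the same
criterion as the fragment stage. Output is sorted by canonical SMILES, so
a fixed seed reproduces the output byte for byte.

Accounting uses the generalized identity `n == generated − rnl − dnl` with
`generated = |headers| · |bodies|`; the square form
`n == (n_fl − df)² − rnl − dnl` is additionally checked whenever
`generated == n_sl²`. The square is the special case in which every
deduplicated fragment appears in both sets; the generalized identity holds
on every run, any seed, any library.

## Simulated annealing

A solution is one header plus an ordered list of bodies, one per marker;
realization couples them in list order and evaluation applies the
Lipinski+Veber feasibility filter before scoring. Infeasible or
unavailable evaluations compare as +∞, so selection logic never crashes on
them.

The annealer restarts `max_tries` times (the restart is what lets the
header change); each restart draws its initial solution as the best of a
`competition_size` tournament of random solutions (retried once if all are
infeasible). Within a restart: a *change* move replaces one uniformly
chosen body with a uniform draw from its Tanimoto neighborhood (similarity
> 0 to the removed body, itself excluded; empty neighborhood falls back to
the whole pool); an equal-or-better change is accepted and followed by
exactly one *swap* move (two distinct positions exchanged; identity on
single-body solutions), kept only when it too is equal-or-better; a
deteriorating change is accepted with probability `exp(−Δ/T)`. The
equal-energy (`≤`) acceptance is kept deliberately: it lets the walk
traverse plateaus.

The Metropolis exponent is implemented as `exp(−Δ/T)` for a deterioration
Δ > 0 under minimization — the standard cooling-schedule form in which
higher temperature accepts more deteriorations; a positive exponent would
accept every deterioration and contradict the cooling narrative.

Temperature cools geometrically (`T ← αT`) each iteration and the loop
stops at `final_temp` or after `stuck_limit` consecutive iterations
without improving the best solution (reset on strict improvement). The
best solution over the whole process is tracked separately, so the
reported best is the minimum over all evaluated feasible solutions and the
best-energy column of the trace is non-increasing.

Defaults — initial temperature 10, final 0.01, α 0.95 (≈ 135 iterations
per restart), 5 restarts, tournament of 5, stuck limit 50 — are sized so a
search over a small fragment library finishes in seconds; all are
configurable. `pos` (pose count) is forwarded to scorers that sample poses
and ignored by the lookup and surrogate scorers. All randomness flows from
one seeded NumPy generator recorded in the trace header.

## Scoring

* **Lookup** scorer returns the packaged binding energy for any canonical
  SMILES present in the reference table, unavailable otherwise. It
  round-trips all 68 packaged records exactly.
* **Surrogate** scorer is the fixed closed form
  `E = −(1.5·ln(1+MW) + 0.4·HBA + 0.8·rings) + 0.05·cLogP²`, with
  molecules above 60 heavy atoms reported unavailable (emulating a ligand
  too large for a docking grid). The weights are fixed constants chosen to
  put energies on a docking-like scale (roughly −10 to −17 for drug-sized
  molecules) and to make formula-level oracle tests exact; they are not
  fitted to anything and carry no physical meaning. What the surrogate
  emulates: determinism, a lower-is-better energy, sensitivity to
  composition, and an unavailability mode. What it does not emulate:
  geometry, pose sampling, or any real affinity — so passing search tests
  show the algorithms optimize *their objective* correctly, not that the
  emitted molecules bind Hsp90.
* **DockingAdapter** documents the external-engine contract (grid
  45×45×45, spacing 0.375 Å, 100 runs, population 150, 1 Å RMS
  clustering; most negative pose energy wins). It validates executable and
  receptor at construction and degrades to unavailable at call time. It is
  never exercised against a real engine in the test suite — a stub engine
  checks the plumbing only.

## Packaged data

`tables/hsp90_ligands.tsv` carries the 68 published inhibitors (id,
SMILES, binding energy, family), `tables/groups.tsv` the eight nested
experiment groups, and `tables/reference_results.tsv` the published
per-group semi-exhaustive summary used as *input* to the improvement
arithmetic. Ids M16, M57 and M70 exist in the numbering but have no
published structure; group loaders warn and skip them (group 8 lists 40
ids and resolves to 39 structures). No structure is ever invented.

The improvement formula is `100 · (|BBE_NL| − |BBE_KL|) / |BBE_KL|`, the
relative gain in best-binding-energy magnitude; it reproduces the
published 40 % (group 1) and 1 % (group 8) after integer rounding.

## Known limitations

* The cleavable-bond rule is a calibrated reconstruction of an unpublished
  procedure; it reproduces the PU3 worked example and sensible cuts on the
  packaged library, but per-group fragment counts need not match the
  original study's.
* Semi-exhaustive runs with multi-marker headers fill residual markers
  with a *single* random draw per pair, so the realized set is a sampled
  subset of all assignments; the annealer can therefore legitimately beat
  the semi-exhaustive best on such libraries. The subset property
  (heuristic ≥ semi-exhaustive best) holds exactly for single-marker
  header sets and is tested there.
* Binding energies from real docking are out of scope by design; all
  search results in tests and examples are on the surrogate scale.
* No synthesizability, tautomer or protonation-state handling.
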