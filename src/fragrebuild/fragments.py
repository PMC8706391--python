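"""Deconstruction: cut ligands into attachment-marked, RO3-compliant fragments.

A known ligand is cleaved at every *cleavable bond* simultaneously.  A bond
is cleavable when it is a single, acyclic bond between two heavy atoms with
at least one endpoint inside a ring system — except bonds whose non-ring
endpoint is a lone non-carbon substituent (hydroxyl, amino, halogen): those
polar decorations stay attached to their ring.  Each broken bond leaves an
attachment marker (``*`` dummy atom) on both pieces.

A ligand's fragment set is its *distinct* pieces (identical pieces such as
repeated methoxy substituents count once), restricted to pieces that pass
the rule-of-three with markers hydrogen-capped.  Fragments that retain at
least one marker can serve as headers during reconstruction; every fragment
contributes its marker-stripped twin as a body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

from rdkit import Chem

from . import chem
from .chem import Molecule, canonicalize, check_ro3, compute_descriptors, fingerprint, tanimoto
from .errors import ContractError

MARKER = "*"


@dataclass(frozen=True)
class FragmentHeader:
    """A sub-ligand carrying attachment markers (one per broken bond).

    ``n_attach`` equals the number of ``*`` atoms in
    ``smiles_with_markers``; ``n_attach == 0`` marks a ligand that had no
    cleavable bond and is usable only as a body.
    """

    smiles_with_markers: str
    n_attach: int
    parent_id: str

    def __post_init__(self):
        m = chem.rdmol(self.smiles_with_markers)
        n_markers = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 0)
        if n_markers != self.n_attach:
            raise ContractError(
                f"marker count {n_markers} != n_attach {self.n_attach} "
                f"in {self.smiles_with_markers!r}"
            )


# a fragment is a header when it has markers, otherwise body-only
Fragment = FragmentHeader


@dataclass(frozen=True)
class FragmentBody:
    """A sub-ligand with markers replaced by hydrogen: no attachment points."""

    molecule: Molecule
    parent_id: str


@dataclass
class FragmentLibrary:
    """Pooled, deduplicated fragment sets with the stage census.

    ``n_fl`` fragments were produced over all ligands, ``n_df`` were removed
    as cross-ligand duplicates, and ``n_sl == n_fl - n_df`` survive.
    ``headers`` holds the surviving fragments that carry markers; ``bodies``
    holds the marker-stripped twin of every surviving fragment.
    """

    headers: List[FragmentHeader]
    bodies: List[FragmentBody]
    n_fl: int
    n_df: int
    n_sl: int
    n_kl: int = 0

    def __post_init__(self):
        if self.n_sl != self.n_fl - self.n_df:
            raise ContractError(f"n_sl {self.n_sl} != n_fl {self.n_fl} - n_df {self.n_df}")


def cleavable_bond_indices(mol: Chem.Mol) -> List[int]:
    """Indices of bonds the deconstruction rule cuts (see module docstring)."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a1, a2 = bond.GetBeginAtom(), bond.GetEndAtom()
        if a1.GetAtomicNum() <= 1 or a2.GetAtomicNum() <= 1:
            continue
        if not (a1.IsInRing() or a2.IsInRing()):
            continue
        # keep terminal polar substituents (OH, NH2, halogens) on their ring
        keeps = False
        for ring_side, sub in ((a1, a2), (a2, a1)):
            if ring_side.IsInRing() and not sub.IsInRing():
                if sub.GetDegree() == 1 and sub.GetAtomicNum() != 6:
                    keeps = True
        if not keeps:
            out.append(bond.GetIdx())
    return out


def cleave(mol: Molecule) -> List[str]:
    """Cut every cleavable bond simultaneously; return raw marker-SMILES pieces.

    Atom-conserving: the heavy atoms of the pieces (markers excluded) are
    exactly the parent's heavy atoms.  A molecule with no cleavable bonds
    returns itself as the single piece.
    """
    m = chem.rdmol(mol)
    bonds = cleavable_bond_indices(m)
    if not bonds:
        return [mol.smiles_canonical if isinstance(mol, Molecule) else Chem.MolToSmiles(m)]
    cut = Chem.FragmentOnBonds(m, bonds, addDummies=True, dummyLabels=[(0, 0)] * len(bonds))
    return [Chem.MolToSmiles(piece) for piece in Chem.GetMolFrags(cut, asMols=True)]


def strip_markers(fragment) -> FragmentBody:
    """Replace every attachment marker by an implicit hydrogen and canonicalize."""
    if isinstance(fragment, FragmentHeader):
        smiles, parent = fragment.smiles_with_markers, fragment.parent_id
    else:
        smiles, parent = fragment, ""
    return FragmentBody(molecule=canonicalize(strip_marker_smiles(smiles)), parent_id=parent)


def strip_marker_smiles(smiles: str) -> str:
    """Canonical SMILES of a marker-bearing SMILES with markers hydrogenated."""
    m = Chem.RWMol(chem.rdmol(smiles))
    for atom in m.GetAtoms():
        if atom.GetAtomicNum() == 0:
            m.ReplaceAtom(atom.GetIdx(), Chem.Atom(1))
    out = m.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(Chem.RemoveHs(out))


def _n_markers(smiles: str) -> int:
    return sum(1 for a in chem.rdmol(smiles).GetAtoms() if a.GetAtomicNum() == 0)


def fragment_ligand(mol: Molecule) -> List[FragmentHeader]:
    """Deconstruct one ligand into its distinct, RO3-compliant sub-ligands.

    Pieces are compared on their marker-stripped structure; of identical
    pieces only the first is kept.  Pieces whose hydrogen-capped form fails
    the rule of three are discarded.  A ligand with no cleavable bonds
    yields itself as a single marker-free fragment (usable only as a body).
    """
    parent = mol.id or mol.smiles_canonical
    pieces = cleave(mol)
    kept: List[FragmentHeader] = []
    seen = set()
    for smi in pieces:
        stripped = strip_marker_smiles(smi)
        if stripped in seen:
            continue
        if not check_ro3(compute_descriptors(stripped)).passed:
            continue
        seen.add(stripped)
        kept.append(FragmentHeader(smiles_with_markers=smi, n_attach=_n_markers(smi), parent_id=parent))
    return kept


def default_duplicate_key(item) -> Tuple[str, "chem.Fingerprint"]:
    """(canonical SMILES, fingerprint) of the marker-stripped structure."""
    if isinstance(item, FragmentHeader):
        smi = strip_marker_smiles(item.smiles_with_markers)
    elif isinstance(item, FragmentBody):
        smi = item.molecule.smiles_canonical
    elif isinstance(item, Molecule):
        smi = item.smiles_canonical
    else:
        smi = canonicalize(str(item)).smiles_canonical
    return smi, fingerprint(smi)


def deduplicate(items: Sequence, key: Optional[Callable] = None) -> Tuple[list, int]:
    """Remove duplicates, keeping the first occurrence in input order.

    Two items are duplicates when their fingerprints have Tanimoto 1.0 or
    their canonical SMILES are equal.  Returns (kept, n_removed).
    """
    key = key or default_duplicate_key
    kept, kept_keys = [], []
    removed = 0
    for item in items:
        smi, fp = key(item)
        dup = False
        for ksmi, kfp in kept_keys:
            if smi == ksmi or tanimoto(fp, kfp) == 1.0:
                dup = True
                break
        if dup:
            removed += 1
        else:
            kept.append(item)
            kept_keys.append((smi, fp))
    return kept, removed


def build_library(ligands: Sequence[Molecule]) -> FragmentLibrary:
    """Compose deconstruction, pooled dedup and the SL*/SL split.

    ``n_fl`` totals each ligand's distinct fragments; cross-ligand dedup
    (on marker-stripped structure, first-seen marker pattern kept) removes
    ``n_df`` of them, leaving ``n_sl`` fragments.
    """
    if not ligands:
        raise ContractError("build_library requires at least one ligand")
    pooled: List[FragmentHeader] = []
    for lig in ligands:
        pooled.extend(fragment_ligand(lig))
    n_fl = len(pooled)
    kept, n_df = deduplicate(pooled)
    headers = [f for f in kept if f.n_attach >= 1]
    bodies = [strip_markers(f) for f in kept]
    if not headers:
        warnings.warn("fragment library has no marker-bearing headers", stacklevel=2)
    return FragmentLibrary(
        headers=headers,
        bodies=bodies,
        n_fl=n_fl,
        n_df=n_df,
        n_sl=n_fl - n_df,
        n_kl=len(ligands),
    )
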