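"""Reconstruction: semi-exhaustive coupling of headers and bodies.

Every header (fragment with attachment markers) is paired with every body.
The body bonds into the header's first marker; any residual markers are
filled with randomly drawn bodies until none remain.  Candidates failing
the Lipinski+Veber drug-likeness filter are rejected, survivors are
deduplicated, and the census must satisfy the accounting identity

    N = generated - RNL - DNL,

which reduces to the square form N = (NFL - DF)^2 - RNL - DNL whenever the
number of headers and bodies both equal NSL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from . import chem
from .chem import Molecule, check_lipinski_veber, compute_descriptors
from .errors import ContractError, CouplingInfeasibleError
from .fragments import FragmentBody, FragmentHeader, FragmentLibrary, deduplicate

ATTACH_FIRST = "first"
ATTACH_RANDOM = "random"


@dataclass(frozen=True)
class NewLigand:
    """A reconstructed, marker-free, drug-like candidate ligand."""

    molecule: Molecule
    header_parent: str
    body_parents: Tuple[str, ...]
    score: Optional[object] = None


@dataclass
class ReconstructionAccounting:
    """Census of one reconstruction run (the Stage 4-5 bookkeeping)."""

    n_kl: int
    n_fl: int
    df: int
    n_sl: int
    generated: int
    rnl: int
    dnl: int
    n: int
    rnl_coupling: int = 0  # portion of rnl due to coupling-infeasible pairs

    @property
    def square_form_applies(self) -> bool:
        return self.generated == self.n_sl**2


@dataclass(frozen=True)
class AccountingCheck:
    passed: bool
    problems: tuple


def verify_accounting(acc: ReconstructionAccounting) -> AccountingCheck:
    """Check non-negativity and the reconstruction accounting identity."""
    problems = []
    for name in ("n_kl", "n_fl", "df", "n_sl", "generated", "rnl", "dnl", "n"):
        if getattr(acc, name) < 0:
            problems.append(f"{name} < 0")
    if acc.n_sl != acc.n_fl - acc.df:
        problems.append("n_sl != n_fl - df")
    if acc.n != acc.generated - acc.rnl - acc.dnl:
        problems.append("n != generated - rnl - dnl")
    if acc.square_form_applies and acc.n != (acc.n_fl - acc.df) ** 2 - acc.rnl - acc.dnl:
        problems.append("n != (n_fl - df)^2 - rnl - dnl")
    return AccountingCheck(passed=not problems, problems=tuple(problems))


def _marker_atoms(mol: Chem.Mol) -> List[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def _first_marker(mol: Chem.Mol) -> int:
    """Marker atom with the lowest canonical rank (deterministic 'first')."""
    ranks = list(Chem.CanonicalRankAtoms(mol))
    markers = _marker_atoms(mol)
    if not markers:
        raise CouplingInfeasibleError("structure has no attachment markers")
    return min(markers, key=lambda i: ranks[i])


def _attachable_atoms(mol: Chem.Mol) -> List[int]:
    """Heavy atoms with a free valence, ordered by canonical rank."""
    ranks = list(Chem.CanonicalRankAtoms(mol))
    atoms = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() > 1 and a.GetTotalNumHs() >= 1
    ]
    return sorted(atoms, key=lambda i: ranks[i])


def couple(
    header,
    body,
    attach_atom: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    attach_policy: str = ATTACH_FIRST,
) -> str:
    """Bond a body into the header's first attachment marker.

    Returns the product's SMILES, which still carries any residual markers.
    The header may be a :class:`FragmentHeader` or a marker SMILES; the body
    a :class:`FragmentBody`, :class:`Molecule` or SMILES.  The marker is
    consumed by forming a single bond between its neighbor and the chosen
    body atom (first free-valence heavy atom in canonical order by default;
    a seeded uniform draw under the ``random`` policy).

    Raises :class:`CouplingInfeasibleError` when no body atom can accept an
    extra single bond or the product fails valence sanitization.
    """
    header_smiles = header.smiles_with_markers if isinstance(header, FragmentHeader) else str(header)
    if isinstance(body, FragmentBody):
        body_smiles = body.molecule.smiles_canonical
    elif isinstance(body, Molecule):
        body_smiles = body.smiles_canonical
    else:
        body_smiles = str(body)

    hmol = chem.rdmol(header_smiles)
    bmol = chem.rdmol(body_smiles)

    marker = _first_marker(hmol)
    neighbor = hmol.GetAtomWithIdx(marker).GetNeighbors()
    if len(neighbor) != 1:
        raise CouplingInfeasibleError(f"marker with {len(neighbor)} neighbors in {header_smiles!r}")
    neighbor = neighbor[0].GetIdx()

    candidates = _attachable_atoms(bmol)
    if not candidates:
        raise CouplingInfeasibleError(f"no attachable atom in body {body_smiles!r}")
    if attach_atom is not None:
        if attach_atom not in candidates:
            raise CouplingInfeasibleError(f"body atom {attach_atom} cannot accept a bond")
        attach = attach_atom
    elif attach_policy == ATTACH_RANDOM:
        if rng is None:
            raise ContractError("random attach policy requires an rng")
        attach = candidates[int(rng.integers(len(candidates)))]
    else:
        attach = candidates[0]

    combo = Chem.RWMol(Chem.CombineMols(hmol, bmol))
    offset = hmol.GetNumAtoms()
    target = combo.GetAtomWithIdx(offset + attach)
    if target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    combo.AddBond(neighbor, offset + attach, Chem.BondType.SINGLE)
    combo.RemoveAtom(marker)
    product = combo.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # valence or aromaticity failure
        raise CouplingInfeasibleError(
            f"coupling {header_smiles!r} + {body_smiles!r} failed sanitization: {exc}"
        ) from exc
    return Chem.MolToSmiles(product)


def _n_markers(smiles: str) -> int:
    return sum(1 for a in chem.rdmol(smiles).GetAtoms() if a.GetAtomicNum() == 0)


def fill_remaining(
    partial: str,
    bodies: Sequence[FragmentBody],
    rng: np.random.Generator,
    attach_policy: str = ATTACH_FIRST,
    _used: Optional[list] = None,
) -> Molecule:
    """Couple uniformly drawn bodies into the remaining markers until none are left.

    Deterministic under a fixed seed.  Coupling failures propagate.
    """
    if not bodies and _n_markers(partial) > 0:
        raise ContractError("cannot fill markers from an empty body pool")
    smiles = partial
    while _n_markers(smiles) > 0:
        body = bodies[int(rng.integers(len(bodies)))]
        smiles = couple(smiles, body, rng=rng, attach_policy=attach_policy)
        if _used is not None:
            _used.append(body.parent_id)
    return chem.canonicalize(smiles)


def semi_exhaustive(
    lib: FragmentLibrary,
    rng=None,
    seed: Optional[int] = None,
    dedup: bool = True,
    attach_policy: str = ATTACH_FIRST,
) -> Tuple[List[NewLigand], ReconstructionAccounting]:
    """Enumerate every header x body union, fill residual markers, filter, dedup.

    Pairs that cannot couple and products failing Lipinski+Veber are both
    counted in ``rnl`` (coupling failures additionally in
    ``rnl_coupling``); duplicates among survivors count in ``dnl``.  Output
    is sorted by canonical SMILES so runs with the same seed are
    byte-identical.
    """
    if not lib.headers:
        raise ContractError("fragment library has no headers to reconstruct from")
    if rng is None:
        rng = np.random.default_rng(seed)

    candidates: List[NewLigand] = []
    rnl = 0
    rnl_coupling = 0
    generated = len(lib.headers) * len(lib.bodies)
    for header in lib.headers:
        for body in lib.bodies:
            used = [body.parent_id]
            try:
                partial = couple(header, body, rng=rng, attach_policy=attach_policy)
                mol = fill_remaining(partial, lib.bodies, rng, attach_policy, _used=used)
            except CouplingInfeasibleError:
                rnl += 1
                rnl_coupling += 1
                continue
            if not check_lipinski_veber(compute_descriptors(mol)).passed:
                rnl += 1
                continue
            candidates.append(
                NewLigand(molecule=mol, header_parent=header.parent_id, body_parents=tuple(used))
            )

    if dedup:
        kept, dnl = deduplicate(candidates, key=lambda nl: (
            nl.molecule.smiles_canonical,
            chem.fingerprint(nl.molecule),
        ))
    else:
        kept, dnl = list(candidates), 0
    kept.sort(key=lambda nl: nl.molecule.smiles_canonical)

    acc = ReconstructionAccounting(
        n_kl=lib.n_kl,
        n_fl=lib.n_fl,
        df=lib.n_df,
        n_sl=lib.n_sl,
        generated=generated,
        rnl=rnl,
        dnl=dnl,
        n=len(kept),
        rnl_coupling=rnl_coupling,
    )
    return kept, acc
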