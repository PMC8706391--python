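"""Molecular substrate: canonical SMILES, descriptors, fingerprints, filters.

Every other stage of the pipeline works on :class:`Molecule` objects —
canonicalized, SMILES-backed structures — and on the physicochemical
descriptors and circular fingerprints computed here.  Filter predicates for
fragment-likeness (rule of three) and drug-likeness (Lipinski's rule of
five plus Veber's rules) operate on a plain :class:`DescriptorSet` so they
are pure, trivially testable functions.

Conventions
-----------
* Canonical SMILES preserve stereochemistry; fingerprints ignore it, so
  duplicate detection works at the constitutional level.
* ``clogp`` is the Crippen atomic-contribution estimate.
* ``hbd`` is the Lipinski donor count (O–H and N–H groups).
* ``hba`` is an N+O count that excludes nitrogens whose lone pair is not
  actually available for accepting: pyrrole-type aromatic N (the lone pair
  is part of the ring pi system), amide/sulfonamide N, and aniline-type
  amines conjugated into an aromatic ring.  Under this convention adenine
  has 3 acceptors and water has 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .errors import ContractError, SmilesParseError

# RDKit writes parse failures to its own log; we raise exceptions instead.
RDLogger.DisableLog("rdApp.error")

FP_RADIUS = 2
FP_NBITS = 2048

_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_NBITS)


@dataclass(frozen=True)
class Molecule:
    """A canonicalized, marker-free molecular structure.

    Invariants: ``smiles_canonical`` parses to a valence-valid structure,
    re-canonicalizing it returns it unchanged, and ``heavy_atom_count >= 1``.
    """

    smiles_canonical: str
    heavy_atom_count: int
    id: Optional[str] = None


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptors used by the fragment and drug filters."""

    mw: float
    clogp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    tpsa: float


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length circular (Morgan, radius 2) fingerprint."""

    on_bits: frozenset
    n_bits: int = FP_NBITS

    def popcount(self) -> int:
        return len(self.on_bits)


@dataclass(frozen=True)
class RuleCheck:
    """Outcome of a rule filter: overall verdict plus every violated clause."""

    passed: bool
    violations: tuple


@lru_cache(maxsize=100_000)
def _rdmol(smiles: str) -> Chem.Mol:
    """Parse a SMILES (markers allowed) into a sanitized RDKit mol."""
    if not smiles:
        raise SmilesParseError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def rdmol(mol) -> Chem.Mol:
    """RDKit view of a Molecule, a Fragment-like object, or a SMILES string."""
    if isinstance(mol, Molecule):
        return _rdmol(mol.smiles_canonical)
    if isinstance(mol, str):
        return _rdmol(mol)
    return _rdmol(mol.smiles_with_markers)


def canonicalize(smiles: str, id: Optional[str] = None) -> Molecule:
    """Normalize a SMILES string into a :class:`Molecule`.

    Two spellings of the same structure map to an identical canonical
    SMILES; stereochemistry annotations are preserved.  Raises
    :class:`SmilesParseError` (naming the offending input) on unparseable
    or valence-violating SMILES.
    """
    m = _rdmol(smiles)
    canonical = Chem.MolToSmiles(m)
    heavy = m.GetNumHeavyAtoms()
    if heavy < 1:
        raise SmilesParseError(smiles, "no heavy atoms")
    return Molecule(smiles_canonical=canonical, heavy_atom_count=heavy, id=id)


def _is_pyrrole_type(atom: Chem.Atom) -> bool:
    # aromatic N donating its lone pair into the ring pi system
    return atom.GetIsAromatic() and (atom.GetTotalNumHs() > 0 or atom.GetDegree() == 3)


def _is_amide_type(atom: Chem.Atom) -> bool:
    for nb in atom.GetNeighbors():
        if nb.GetAtomicNum() in (6, 16):
            for b in nb.GetBonds():
                if b.GetBondType() == Chem.BondType.DOUBLE and b.GetOtherAtom(nb).GetAtomicNum() == 8:
                    return True
    return False


def _is_aniline_type(atom: Chem.Atom) -> bool:
    return not atom.GetIsAromatic() and any(nb.GetIsAromatic() for nb in atom.GetNeighbors())


def hbond_donors(mol: Chem.Mol) -> int:
    """Count H-bond donor groups: N or O atoms bearing at least one hydrogen."""
    return sum(
        1
        for atom in mol.GetAtoms()
        if atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs() >= 1
    )


def hbond_acceptors(mol: Chem.Mol) -> int:
    """Count H-bond acceptors: all O, plus N with an available lone pair."""
    n = 0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 8:
            n += 1
        elif z == 7:
            if _is_pyrrole_type(atom) or _is_amide_type(atom) or _is_aniline_type(atom):
                continue
            n += 1
    return n


def compute_descriptors(mol) -> DescriptorSet:
    """Descriptor set of a molecule (accepts Molecule or SMILES)."""
    m = rdmol(mol)
    return DescriptorSet(
        mw=Descriptors.MolWt(m),
        clogp=Crippen.MolLogP(m),
        hbd=hbond_donors(m),
        hba=hbond_acceptors(m),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(m),
        tpsa=rdMolDescriptors.CalcTPSA(m),
    )


def ring_count(mol) -> int:
    return rdMolDescriptors.CalcNumRings(rdmol(mol))


@lru_cache(maxsize=100_000)
def _fingerprint_of_smiles(smiles: str) -> Fingerprint:
    fp = _morgan.GetFingerprint(_rdmol(smiles))
    return Fingerprint(on_bits=frozenset(fp.GetOnBits()), n_bits=FP_NBITS)


def fingerprint(mol) -> Fingerprint:
    """Deterministic Morgan fingerprint; identical molecules yield identical bits."""
    if isinstance(mol, Molecule):
        return _fingerprint_of_smiles(mol.smiles_canonical)
    if isinstance(mol, str):
        return _fingerprint_of_smiles(canonicalize(mol).smiles_canonical)
    return _fingerprint_of_smiles(mol.smiles_with_markers)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a & b| / |a | b| on bit sets.

    Two empty fingerprints compare as 0.0 (never vacuously identical).
    """
    if a.n_bits != b.n_bits:
        raise ContractError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 0.0
    return len(a.on_bits & b.on_bits) / union


# --- rule filters -----------------------------------------------------------

RO3 = {"mw": 300.0, "clogp": 3.0, "hbd": 3, "hba": 3}
LIPINSKI = {"mw": 500.0, "clogp": 5.0, "hbd": 5, "hba": 10}
VEBER = {"rotatable_bonds": 10, "tpsa": 140.0}


def check_ro3(d: DescriptorSet) -> RuleCheck:
    """Rule-of-three fragment filter: MW < 300 (strict), cLogP <= 3,
    HBD <= 3, HBA <= 3.  Reports every violated clause."""
    violations = []
    if not d.mw < RO3["mw"]:
        violations.append("mw")
    if not d.clogp <= RO3["clogp"]:
        violations.append("clogp")
    if not d.hbd <= RO3["hbd"]:
        violations.append("hbd")
    if not d.hba <= RO3["hba"]:
        violations.append("hba")
    return RuleCheck(passed=not violations, violations=tuple(violations))


def check_lipinski_veber(d: DescriptorSet) -> RuleCheck:
    """Drug-likeness filter: Lipinski rule of five (MW <= 500, cLogP <= 5,
    HBD <= 5, HBA <= 10) plus Veber's rules (<= 10 rotatable bonds,
    TPSA <= 140 A^2); all boundaries inclusive."""
    violations = []
    if not d.mw <= LIPINSKI["mw"]:
        violations.append("mw")
    if not d.clogp <= LIPINSKI["clogp"]:
        violations.append("clogp")
    if not d.hbd <= LIPINSKI["hbd"]:
        violations.append("hbd")
    if not d.hba <= LIPINSKI["hba"]:
        violations.append("hba")
    if not d.rotatable_bonds <= VEBER["rotatable_bonds"]:
        violations.append("rotatable_bonds")
    if not d.tpsa <= VEBER["tpsa"]:
        violations.append("tpsa")
    return RuleCheck(passed=not violations, violations=tuple(violations))
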