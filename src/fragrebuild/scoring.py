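"""Pluggable ligand scoring.

Search and reporting only ever consume a single number per ligand — a
binding-energy-scale value where lower is better — or an *unavailable*
sentinel for ligands that cannot be evaluated (e.g. too large for the
docking grid).  Three scorers implement that contract:

* :class:`LookupScorer` — serves tabulated binding energies by canonical
  SMILES (the packaged Hsp90 reference library in practice).
* :class:`SurrogateScorer` — a deterministic closed-form stand-in used for
  desk-scale experiments and oracle tests.
* :class:`DockingAdapter` — the contract for driving an external docking
  engine; optional, never used by default.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple

from . import chem
from .chem import Molecule, compute_descriptors, ring_count
from .errors import ContractError


@dataclass(frozen=True)
class ScoreResult:
    """Either a finite energy (lower is better) or an unavailable sentinel."""

    energy: Optional[float] = None
    unavailable_reason: Optional[str] = None

    def __post_init__(self):
        if (self.energy is None) == (self.unavailable_reason is None):
            raise ContractError("exactly one of energy/unavailable_reason must be set")

    @property
    def unavailable(self) -> bool:
        return self.energy is None

    @classmethod
    def of(cls, energy: float) -> "ScoreResult":
        return cls(energy=float(energy))

    @classmethod
    def not_available(cls, reason: str) -> "ScoreResult":
        return cls(unavailable_reason=reason)


def _canonical(mol) -> str:
    if isinstance(mol, Molecule):
        return mol.smiles_canonical
    return chem.canonicalize(str(mol)).smiles_canonical


class LookupScorer:
    """Score by table lookup on canonical SMILES; unknowns are unavailable."""

    def __init__(self, table: Dict[str, Tuple[str, float]]):
        """``table`` maps id -> (smiles, binding_energy)."""
        self._by_smiles = {
            _canonical(smiles): float(be) for smiles, be in table.values()
        }

    @classmethod
    def from_records(cls, records: Iterable) -> "LookupScorer":
        return cls({r.id: (r.smiles, r.be) for r in records})

    def __call__(self, mol) -> ScoreResult:
        be = self._by_smiles.get(_canonical(mol))
        if be is None:
            return ScoreResult.not_available("not in lookup table")
        return ScoreResult.of(be)


#: default surrogate weights (w_mw, w_hba, w_rings, w_clogp); fixed, not fitted
SURROGATE_WEIGHTS = (1.5, 0.4, 0.8, 0.05)
SURROGATE_SIZE_CAP = 60


def surrogate_energy(
    mw: float, hba: int, rings: int, clogp: float, weights=SURROGATE_WEIGHTS
) -> float:
    """Closed-form surrogate: -(w1*ln(1+mw) + w2*hba + w3*rings) + w4*clogp^2."""
    w1, w2, w3, w4 = weights
    return -(w1 * math.log1p(mw) + w2 * hba + w3 * rings) + w4 * clogp**2


class SurrogateScorer:
    """Deterministic descriptor-based energy; emulates a docking-style scale.

    Rewards mass, acceptor count and ring systems, penalizes extreme
    lipophilicity.  Molecules above ``size_cap`` heavy atoms are reported
    unavailable, mirroring a ligand too large for a docking grid.
    """

    def __init__(self, weights=SURROGATE_WEIGHTS, size_cap: int = SURROGATE_SIZE_CAP):
        self.weights = tuple(weights)
        self.size_cap = size_cap

    def __call__(self, mol) -> ScoreResult:
        m = mol if isinstance(mol, Molecule) else chem.canonicalize(str(mol))
        if m.heavy_atom_count > self.size_cap:
            return ScoreResult.not_available(
                f"{m.heavy_atom_count} heavy atoms exceeds grid size cap {self.size_cap}"
            )
        d = compute_descriptors(m)
        return ScoreResult.of(
            surrogate_energy(d.mw, d.hba, ring_count(m), d.clogp, self.weights)
        )


class DockingAdapter:
    """Adapter contract for an external docking engine (AutoDock/Vina-style).

    The constructor validates the engine executable and the prepared
    receptor up front so a missing installation can never fail mid-search.
    Calls write the ligand SMILES to a temp file, invoke the engine, and
    parse the most negative pose energy from stdout lines of the form
    ``RESULT <float>`` (or Vina-style leading-rank table rows).  Engine
    failures and grid overflows come back as unavailable, never exceptions.
    """

    #: protocol defaults: grid points, spacing (A), runs, GA population, RMS cluster (A)
    GRID_POINTS = (45, 45, 45)
    GRID_SPACING = 0.375
    N_RUNS = 100
    POPULATION = 150
    RMS_CLUSTER = 1.0

    def __init__(
        self,
        engine: str,
        receptor: str,
        grid_points=GRID_POINTS,
        grid_spacing: float = GRID_SPACING,
        n_runs: int = N_RUNS,
        population: int = POPULATION,
        rms_cluster: float = RMS_CLUSTER,
        timeout: float = 600.0,
    ):
        resolved = shutil.which(engine) or (engine if Path(engine).is_file() else None)
        if resolved is None:
            raise ContractError(f"docking engine not found: {engine!r}")
        if not Path(receptor).is_file():
            raise ContractError(f"receptor file not found: {receptor!r}")
        self.engine = resolved
        self.receptor = str(receptor)
        self.grid_points = tuple(grid_points)
        self.grid_spacing = grid_spacing
        self.n_runs = n_runs
        self.population = population
        self.rms_cluster = rms_cluster
        self.timeout = timeout

    def command(self, ligand_path: str) -> list:
        gx, gy, gz = self.grid_points
        return [
            self.engine,
            "--receptor", self.receptor,
            "--ligand", ligand_path,
            "--grid", f"{gx}x{gy}x{gz}",
            "--spacing", str(self.grid_spacing),
            "--runs", str(self.n_runs),
            "--population", str(self.population),
            "--rms-cluster", str(self.rms_cluster),
        ]

    @staticmethod
    def parse_energies(stdout: str) -> list:
        energies = []
        for line in stdout.splitlines():
            parts = line.split()
            if len(parts) >= 2 and parts[0] in ("RESULT", "RESULT:"):
                try:
                    energies.append(float(parts[1]))
                except ValueError:
                    continue
            elif len(parts) >= 2 and parts[0].isdigit():
                try:
                    energies.append(float(parts[1]))
                except ValueError:
                    continue
        return energies

    def __call__(self, mol) -> ScoreResult:
        smiles = _canonical(mol)
        with tempfile.NamedTemporaryFile("w", suffix=".smi", delete=False) as fh:
            fh.write(smiles + "\n")
            ligand_path = fh.name
        try:
            proc = subprocess.run(
                self.command(ligand_path),
                capture_output=True,
                text=True,
                timeout=self.timeout,
            )
        except (subprocess.TimeoutExpired, OSError) as exc:
            return ScoreResult.not_available(f"engine failure: {exc}")
        finally:
            Path(ligand_path).unlink(missing_ok=True)
        if proc.returncode != 0:
            return ScoreResult.not_available(f"engine exited {proc.returncode}")
        energies = self.parse_energies(proc.stdout)
        if not energies:
            return ScoreResult.not_available("no pose energies in engine output")
        return ScoreResult.of(min(energies))
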