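"""Packaged Hsp90 reference library, experiment groups, statistics and reports.

The package ships the 68 published Hsp90 inhibitors (with docking binding
energies and family labels: resorcinol, hydroxy-indazole, "others") and the
eight nested known-ligand groups used in the study design.  Three ids (M16,
M57, M70) exist in the numbering but have no published structure; group
definitions referencing M70 warn and skip it rather than inventing a
structure.
"""

from __future__ import annotations

import statistics
import time
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

from . import chem
from .annealing import SAConfig, anneal
from .errors import ContractError
from .fragments import build_library
from .rebuild import semi_exhaustive, verify_accounting

FAMILIES = ("resorcinol", "hydroxy-indazole", "others")

#: PU3, 9-butyl-8-(3,4,5-trimethoxybenzyl)-9H-purin-6-amine — the canonical
#: purine-scaffold Hsp90 inhibitor used as the deconstruction worked example.
PU3_SMILES = "CCCCn1c(Cc2cc(OC)c(OC)c(OC)c2)nc2c(N)ncnc21"


class MissingStructureWarning(UserWarning):
    """A group references a ligand id with no published structure."""


@dataclass(frozen=True)
class LigandRecord:
    id: str
    smiles: str
    be: float
    family: str


@dataclass(frozen=True)
class GroupSpec:
    group_number: int
    ligand_ids: Tuple[str, ...]


def _data_text(name: str) -> str:
    return resources.files("fragrebuild").joinpath("tables", name).read_text()


def load_reference_library() -> List[LigandRecord]:
    """All 68 packaged inhibitor records; every SMILES canonicalizes."""
    records = []
    seen = set()
    for line in _data_text("hsp90_ligands.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        lid, smiles, be, family = line.split("\t")
        if lid in seen:
            raise ContractError(f"duplicate ligand id {lid} in packaged data")
        seen.add(lid)
        chem.canonicalize(smiles)  # raises on corrupt data
        records.append(LigandRecord(id=lid, smiles=smiles, be=float(be), family=family))
    if not records:
        raise ContractError("packaged ligand table is empty")
    return records


def load_group_specs() -> Dict[int, GroupSpec]:
    specs = {}
    for line in _data_text("groups.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        g, ids = line.split("\t")
        specs[int(g)] = GroupSpec(group_number=int(g), ligand_ids=tuple(ids.split(",")))
    return specs


def load_reference_results() -> Dict[int, dict]:
    """Published per-group semi-exhaustive summary (inputs for comparisons)."""
    out = {}
    for line in _data_text("reference_results.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        g, n_kl, bbe_kl, n_sl, n_nl, bbe_nl = line.split("\t")
        out[int(g)] = {
            "n_kl": int(n_kl),
            "bbe_kl": float(bbe_kl),
            "n_sl": int(n_sl),
            "n_nl": int(n_nl),
            "bbe_nl": float(bbe_nl),
        }
    return out


def build_group(n: int) -> List[LigandRecord]:
    """Records of experiment group ``n`` (1-8), in published order.

    Ids without a published structure are skipped with a
    :class:`MissingStructureWarning`.
    """
    specs = load_group_specs()
    if n not in specs:
        raise ContractError(f"group number must be 1-8, got {n}")
    by_id = {r.id: r for r in load_reference_library()}
    out = []
    for lid in specs[n].ligand_ids:
        rec = by_id.get(lid)
        if rec is None:
            warnings.warn(
                f"group {n}: ligand {lid} has no published structure; skipped",
                MissingStructureWarning,
                stacklevel=2,
            )
            continue
        out.append(rec)
    return out


def library_stats(records: Sequence[LigandRecord]) -> dict:
    """min/max/mean binding energy and the count of ligands at the minimum."""
    if not records:
        raise ContractError("library_stats requires a non-empty record list")
    energies = [r.be for r in records]
    min_be = min(energies)
    return {
        "min_be": min_be,
        "max_be": max(energies),
        "mean_be": statistics.fmean(energies),
        "n_at_min": sum(1 for e in energies if e == min_be),
    }


@dataclass(frozen=True)
class Improvement:
    raw: float
    rounded: int


def improvement_report(bbe_kl: float, bbe_nl: float) -> Improvement:
    """Percent improvement of the best new-ligand energy over the best known.

    Defined as 100 * (|bbe_nl| - |bbe_kl|) / |bbe_kl| on the binding-energy
    scale (both energies negative; more negative is better).
    """
    if bbe_kl == 0:
        raise ContractError("bbe_kl must be non-zero")
    if bbe_kl > 0:
        raise ContractError("bbe_kl must be negative (binding-energy scale)")
    raw = 100.0 * (abs(bbe_nl) - abs(bbe_kl)) / abs(bbe_kl)
    return Improvement(raw=raw, rounded=round(raw))


def _best_available(scorer, molecules) -> Optional[float]:
    energies = [r.energy for r in map(scorer, molecules) if not r.unavailable]
    return min(energies) if energies else None


def run_experiment(
    group: int,
    mode: str,
    scorer,
    seed: int,
    sa_config: Optional[SAConfig] = None,
) -> dict:
    """End-to-end pipeline for one group: deconstruct, search, score, report.

    ``mode`` is ``semi_exhaustive`` or ``heuristic``.  The report carries the
    full accounting (semi-exhaustive) or the search trace summary
    (heuristic), the best energies of known and new ligands under ``scorer``,
    and the percent improvement.  Wall time is informational only.
    """
    if mode not in ("semi_exhaustive", "heuristic"):
        raise ContractError(f"unknown mode {mode!r}")
    t0 = time.perf_counter()
    records = build_group(group)
    ligands = [chem.canonicalize(r.smiles, id=r.id) for r in records]
    lib = build_library(ligands)
    bbe_kl = _best_available(scorer, ligands)

    report = {
        "group": group,
        "mode": mode,
        "seed": seed,
        "n_kl": len(records),
        "n_sl": lib.n_sl,
        "bbe_kl": bbe_kl,
    }
    if mode == "semi_exhaustive":
        new_ligands, acc = semi_exhaustive(lib, seed=seed)
        check = verify_accounting(acc)
        bbe_nl = _best_available(scorer, (nl.molecule for nl in new_ligands))
        report.update(
            n_nl=acc.n,
            accounting=acc,
            accounting_ok=check.passed,
            bbe_nl=bbe_nl,
            best_smiles=(
                min(
                    (nl.molecule.smiles_canonical for nl in new_ligands
                     if not scorer(nl.molecule).unavailable),
                    key=lambda s: scorer(chem.canonicalize(s)).energy,
                )
                if bbe_nl is not None
                else None
            ),
        )
    else:
        cfg = sa_config or SAConfig(seed=seed)
        if cfg.seed != seed:
            cfg = SAConfig(**{**cfg.__dict__, "seed": seed})
        trace = anneal(lib, scorer, cfg)
        report.update(
            bbe_nl=trace.best_energy if trace.best_solution is not None else None,
            n_iterations=len(trace.records),
            trace=trace,
        )
    if report["bbe_kl"] is not None and report["bbe_nl"] is not None and report["bbe_kl"] < 0:
        report["improvement"] = improvement_report(report["bbe_kl"], report["bbe_nl"])
    report["wall_time_s"] = time.perf_counter() - t0
    return report
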