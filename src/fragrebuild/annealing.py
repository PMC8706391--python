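"""Simulated-annealing search over header + bodies solutions.

A solution is one header fragment plus an ordered list of bodies, one per
attachment marker.  The annealer restarts ``max_tries`` times from a fresh
tournament-selected solution, proposes a *change* move each iteration
(replace one body by a Tanimoto-neighborhood body), follows an accepted
improving change with a single *swap* move (exchange two body positions,
kept only if it improves), accepts deteriorations with the Metropolis
probability exp(-delta/T), and cools geometrically by ``alpha`` until the
final temperature or a stuck counter is reached.

Equal-or-better moves are accepted (the ``<=`` tie-break), so plateaus are
traversable; the best solution over the whole process is tracked
separately and its energy sequence is non-increasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import chem
from .chem import Molecule, check_lipinski_veber, compute_descriptors, fingerprint, tanimoto
from .errors import ContractError, CouplingInfeasibleError, InfeasibleSolutionError, InfeasibleStartError
from .fragments import FragmentBody, FragmentHeader, FragmentLibrary
from .rebuild import couple
from .scoring import ScoreResult

INFEASIBLE = math.inf


@dataclass(frozen=True)
class Solution:
    """One header plus exactly one body per attachment marker."""

    header: FragmentHeader
    bodies: Tuple[FragmentBody, ...]

    def __post_init__(self):
        if len(self.bodies) != self.header.n_attach:
            raise ContractError(
                f"solution needs {self.header.n_attach} bodies, got {len(self.bodies)}"
            )


@dataclass(frozen=True)
class SAConfig:
    """Annealing parameters.

    Defaults are sized so a search over a small fragment library finishes
    in seconds; every field is configurable.  ``pos`` (number of docking
    poses) is forwarded to scorers that use it and ignored otherwise.
    """

    initial_temp: float = 10.0
    final_temp: float = 0.01
    alpha: float = 0.95
    max_tries: int = 5
    stuck_limit: int = 50
    competition_size: int = 5
    seed: int = 0
    pos: int = 10

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ContractError("alpha must lie strictly inside (0, 1)")
        if not (0.0 < self.final_temp < self.initial_temp):
            raise ContractError("need 0 < final_temp < initial_temp")
        for name in ("max_tries", "stuck_limit", "competition_size", "pos"):
            if getattr(self, name) < 1:
                raise ContractError(f"{name} must be >= 1")


@dataclass(frozen=True)
class TraceRecord:
    try_idx: int
    iteration: int
    temperature: float
    move: str
    current_energy: float
    best_energy: float
    accepted: bool


@dataclass
class SearchTrace:
    """Per-iteration log plus the best solution found over the whole run."""

    records: List[TraceRecord] = field(default_factory=list)
    best_solution: Optional[Solution] = None
    best_energy: float = INFEASIBLE
    seed: Optional[int] = None

    def to_tsv(self) -> str:
        lines = [f"# seed={self.seed}\ttry\titeration\ttemperature\tmove\tcurrent_energy\tbest_energy\taccepted"]
        for r in self.records:
            lines.append(
                f"{r.try_idx}\t{r.iteration}\t{r.temperature:.6g}\t{r.move}"
                f"\t{r.current_energy:.6g}\t{r.best_energy:.6g}\t{int(r.accepted)}"
            )
        return "\n".join(lines) + "\n"


def realize(sol: Solution) -> Molecule:
    """Assemble the molecule: couple bodies into the header's markers in order."""
    smiles = sol.header.smiles_with_markers
    try:
        for body in sol.bodies:
            smiles = couple(smiles, body)
    except CouplingInfeasibleError as exc:
        raise InfeasibleSolutionError(str(exc)) from exc
    return chem.canonicalize(smiles)


def evaluate(sol: Solution, scorer) -> float:
    """Energy of a solution; ``INFEASIBLE`` (+inf) when it cannot be realized,
    fails drug-likeness, or the scorer reports it unavailable."""
    try:
        mol = realize(sol)
    except InfeasibleSolutionError:
        return INFEASIBLE
    if not check_lipinski_veber(compute_descriptors(mol)).passed:
        return INFEASIBLE
    result: ScoreResult = scorer(mol)
    if result.unavailable:
        return INFEASIBLE
    return result.energy


def _random_solution(lib: FragmentLibrary, rng: np.random.Generator) -> Solution:
    header = lib.headers[int(rng.integers(len(lib.headers)))]
    bodies = tuple(
        lib.bodies[int(rng.integers(len(lib.bodies)))] for _ in range(header.n_attach)
    )
    return Solution(header=header, bodies=bodies)


def generate_initial_ligand(
    lib: FragmentLibrary, k: int, rng: np.random.Generator, scorer
) -> Solution:
    """Tournament of ``k`` random solutions; the best-evaluated wins.

    If every candidate is infeasible the tournament is retried once, after
    which :class:`InfeasibleStartError` is raised.
    """
    if not lib.headers:
        raise ContractError("library has no headers")
    if k < 1:
        raise ContractError("competition size must be >= 1")
    for _attempt in range(2):
        best, best_e = None, INFEASIBLE
        for _ in range(k):
            cand = _random_solution(lib, rng)
            e = evaluate(cand, scorer)
            if e < best_e or best is None:
                best, best_e = cand, e
        if best_e < INFEASIBLE:
            return best
    raise InfeasibleStartError("no feasible initial solution in two tournaments")


def change(sol: Solution, lib: FragmentLibrary, rng: np.random.Generator) -> Solution:
    """Replace one uniformly chosen body by a Tanimoto-neighborhood body.

    The neighborhood is every pool body with Tanimoto similarity > 0 to the
    removed body (the removed body itself excluded); when empty, the draw
    falls back to the whole pool.  The input solution is not modified.
    """
    if not sol.bodies:
        return sol
    pos = int(rng.integers(len(sol.bodies)))
    removed = sol.bodies[pos]
    removed_fp = fingerprint(removed.molecule)
    removed_smi = removed.molecule.smiles_canonical
    neighborhood = [
        b
        for b in lib.bodies
        if b.molecule.smiles_canonical != removed_smi
        and tanimoto(fingerprint(b.molecule), removed_fp) > 0.0
    ]
    pool = neighborhood if neighborhood else list(lib.bodies)
    replacement = pool[int(rng.integers(len(pool)))]
    bodies = list(sol.bodies)
    bodies[pos] = replacement
    return Solution(header=sol.header, bodies=tuple(bodies))


def swap(sol: Solution, rng: np.random.Generator) -> Solution:
    """Exchange two distinct body positions; identity on single-body solutions."""
    if len(sol.bodies) < 2:
        return sol
    i, j = rng.choice(len(sol.bodies), size=2, replace=False)
    bodies = list(sol.bodies)
    bodies[int(i)], bodies[int(j)] = bodies[int(j)], bodies[int(i)]
    return Solution(header=sol.header, bodies=tuple(bodies))


def acceptance_probability(delta: float, temperature: float) -> float:
    """Metropolis probability of accepting a deterioration of size ``delta``."""
    if delta <= 0:
        return 1.0
    if not math.isfinite(delta):
        return 0.0
    return math.exp(-delta / temperature)


def anneal(lib: FragmentLibrary, scorer, cfg: SAConfig) -> SearchTrace:
    """Run the restart simulated-annealing search; returns the full trace.

    If no feasible solution is ever found the trace comes back with
    ``best_solution is None`` and ``best_energy == INFEASIBLE``.
    """
    rng = np.random.default_rng(cfg.seed)
    trace = SearchTrace(seed=cfg.seed)
    best: Optional[Solution] = None
    best_e = INFEASIBLE

    for try_idx in range(cfg.max_tries):
        temp = cfg.initial_temp
        try:
            current = generate_initial_ligand(lib, cfg.competition_size, rng, scorer)
        except InfeasibleStartError:
            continue
        cur_e = evaluate(current, scorer)
        if cur_e <= best_e:
            best, best_e = current, cur_e
        stuck = 0
        iteration = 0
        while temp > cfg.final_temp and stuck < cfg.stuck_limit:
            improved = False
            new = change(current, lib, rng)
            new_e = evaluate(new, scorer)
            improving_change = new_e <= cur_e
            if improving_change:
                current, cur_e = new, new_e
                change_accepted = True
            else:
                change_accepted = rng.random() < acceptance_probability(new_e - cur_e, temp)
                if change_accepted:
                    current, cur_e = new, new_e
            improved |= cur_e < best_e
            if cur_e <= best_e:
                best, best_e = current, cur_e
            trace.records.append(
                TraceRecord(try_idx, iteration, temp, "change", cur_e, best_e, change_accepted)
            )
            # exactly one swap per accepted improving change, kept only if improving
            if improving_change and len(current.bodies) >= 2:
                swapped = swap(current, rng)
                sw_e = evaluate(swapped, scorer)
                sw_ok = sw_e <= cur_e
                if sw_ok:
                    current, cur_e = swapped, sw_e
                improved |= cur_e < best_e
                if cur_e <= best_e:
                    best, best_e = current, cur_e
                trace.records.append(
                    TraceRecord(try_idx, iteration, temp, "swap", cur_e, best_e, sw_ok)
                )
            stuck = 0 if improved else stuck + 1
            temp *= cfg.alpha
            iteration += 1

    trace.best_solution = best
    trace.best_energy = best_e
    return trace
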