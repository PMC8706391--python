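"""Simulated annealing: moves, evaluation, Algorithm-level behavior."""

import math

import numpy as np
import pytest

import fragrebuild as fr
from conftest import enumerate_solutions


def make_solution(header_smiles, body_smiles, parent="h"):
    n = header_smiles.count("*")
    header = fr.FragmentHeader(header_smiles, n, parent)
    bodies = tuple(
        fr.FragmentBody(molecule=fr.canonicalize(s), parent_id=s) for s in body_smiles
    )
    return fr.Solution(header=header, bodies=bodies)


class ConstantScorer:
    def __init__(self, value=-5.0):
        self.value = value

    def __call__(self, mol):
        return fr.ScoreResult.of(self.value)


class TestRealize:
    def test_single_body(self):
        sol = make_solution("*c1ccccc1", ["C"])
        assert fr.realize(sol).smiles_canonical == fr.canonicalize("Cc1ccccc1").smiles_canonical

    def test_two_bodies_both_attached(self):
        sol = make_solution("*c1ccc(*)cc1", ["C", "CCO"])
        mol = fr.realize(sol)
        assert "*" not in mol.smiles_canonical
        assert mol.heavy_atom_count == 6 + 1 + 3

    def test_deterministic(self):
        sol = make_solution("*c1ccc(*)cc1", ["CCO", "C"])
        assert fr.realize(sol).smiles_canonical == fr.realize(sol).smiles_canonical

    def test_body_count_must_match_markers(self):
        with pytest.raises(fr.ContractError):
            make_solution("*c1ccc(*)cc1", ["C"])


class TestEvaluate:
    def test_druglikeness_violation_is_infeasible(self):
        # a grossly lipophilic realization fails Lipinski and is filtered
        sol = make_solution("*C", ["C" * 40])
        assert fr.evaluate(sol, ConstantScorer()) == fr.INFEASIBLE

    def test_constant_scorer_energy(self):
        sol = make_solution("*c1ccccc1", ["C"])
        assert fr.evaluate(sol, ConstantScorer(-5.0)) == -5.0

    def test_lookup_scorer_reproduces_published_energy(self, reference_records):
        by_id = {r.id: r for r in reference_records}
        m37 = by_id["M37"]
        scorer = fr.LookupScorer.from_records(reference_records)
        assert scorer(fr.canonicalize(m37.smiles)).energy == -11.3

    def test_unavailable_score_is_infeasible(self):
        sol = make_solution("*c1ccccc1", ["C"])
        scorer = lambda mol: fr.ScoreResult.not_available("stubbed")
        assert fr.evaluate(sol, scorer) == fr.INFEASIBLE


class TestInitialSolution:
    def test_k1_returns_the_single_sample(self, tiny_library, surrogate):
        rng = np.random.default_rng(5)
        sol = fr.generate_initial_ligand(tiny_library, 1, rng, surrogate)
        replay = np.random.default_rng(5)
        header = tiny_library.headers[int(replay.integers(len(tiny_library.headers)))]
        assert sol.header == header

    def test_tournament_selects_best_of_k(self, tiny_library, surrogate):
        rng = np.random.default_rng(9)
        sol = fr.generate_initial_ligand(tiny_library, 5, rng, surrogate)
        # oracle: replay the same 5 seeded samples and evaluate each
        replay = np.random.default_rng(9)
        best_e = fr.INFEASIBLE
        for _ in range(5):
            header = tiny_library.headers[int(replay.integers(len(tiny_library.headers)))]
            bodies = tuple(
                tiny_library.bodies[int(replay.integers(len(tiny_library.bodies)))]
                for _ in range(header.n_attach)
            )
            cand = fr.Solution(header=header, bodies=bodies)
            best_e = min(best_e, fr.evaluate(cand, surrogate))
        assert fr.evaluate(sol, surrogate) == best_e

    def test_fixed_seed_reproducible(self, tiny_library, surrogate):
        a = fr.generate_initial_ligand(tiny_library, 5, np.random.default_rng(1), surrogate)
        b = fr.generate_initial_ligand(tiny_library, 5, np.random.default_rng(1), surrogate)
        assert a == b

    def test_all_infeasible_raises_after_retry(self, tiny_library):
        hopeless = lambda mol: fr.ScoreResult.not_available("never")
        with pytest.raises(fr.InfeasibleStartError):
            fr.generate_initial_ligand(tiny_library, 3, np.random.default_rng(0), hopeless)


class TestChangeMove:
    def test_forced_replacement_in_pool_of_two(self, tiny_library):
        # single-body solution; neighborhood draws must give a different body
        sol = make_solution("*c1ccccc1", ["CCO"])
        lib = fr.FragmentLibrary(
            headers=tiny_library.headers,
            bodies=[
                fr.FragmentBody(molecule=fr.canonicalize("CCO"), parent_id="a"),
                fr.FragmentBody(molecule=fr.canonicalize("CCCO"), parent_id="b"),
            ],
            n_fl=2, n_df=0, n_sl=2,
        )
        new = fr.change(sol, lib, np.random.default_rng(0))
        assert new.bodies[0].molecule.smiles_canonical == "CCCO"
        assert sol.bodies[0].molecule.smiles_canonical == "CCO"  # input unmodified

    def test_empty_neighborhood_falls_back_to_pool(self):
        sol = make_solution("*c1ccccc1", ["C"])  # methane shares no bits with pool
        lib = fr.FragmentLibrary(
            headers=[fr.FragmentHeader("*c1ccccc1", 1, "h")],
            bodies=[fr.FragmentBody(molecule=fr.canonicalize("O=S=O"), parent_id="s")],
            n_fl=1, n_df=0, n_sl=1,
        )
        assert fr.tanimoto(
            fr.fingerprint(fr.canonicalize("C")), fr.fingerprint(fr.canonicalize("O=S=O"))
        ) == 0.0
        new = fr.change(sol, lib, np.random.default_rng(0))
        assert new.bodies[0].molecule.smiles_canonical == fr.canonicalize("O=S=O").smiles_canonical

    def test_seeded_replay(self, tiny_library):
        sol = make_solution("*c1ccc(*)cc1", ["CCO", "c1ccncc1"])
        new = fr.change(sol, tiny_library, np.random.default_rng(17))
        # replay: one uniform position draw, then one uniform pool draw
        replay = np.random.default_rng(17)
        pos = int(replay.integers(2))
        removed = sol.bodies[pos]
        fp = fr.fingerprint(removed.molecule)
        pool = [
            b for b in tiny_library.bodies
            if b.molecule.smiles_canonical != removed.molecule.smiles_canonical
            and fr.tanimoto(fr.fingerprint(b.molecule), fp) > 0.0
        ] or list(tiny_library.bodies)
        expected = pool[int(replay.integers(len(pool)))]
        assert new.bodies[pos] == expected


class TestSwapMove:
    def test_single_body_identity(self):
        sol = make_solution("*c1ccccc1", ["C"])
        assert fr.swap(sol, np.random.default_rng(0)) is sol

    def test_two_bodies_exchange(self):
        sol = make_solution("*c1ccc(*)cc1", ["C", "CCO"])
        new = fr.swap(sol, np.random.default_rng(0))
        assert new.bodies == (sol.bodies[1], sol.bodies[0])

    def test_three_bodies_seeded_replay(self):
        sol = make_solution("*c1cc(*)cc(*)c1", ["C", "CC", "CCO"])
        new = fr.swap(sol, np.random.default_rng(3))
        i, j = np.random.default_rng(3).choice(3, size=2, replace=False)
        expected = list(sol.bodies)
        expected[int(i)], expected[int(j)] = expected[int(j)], expected[int(i)]
        assert new.bodies == tuple(expected)


class TestAcceptanceProbability:
    def test_monotone_in_temperature(self):
        delta = 1.0
        assert fr.acceptance_probability(delta, 10.0) > fr.acceptance_probability(delta, 1.0)

    def test_improvements_always_accepted(self):
        assert fr.acceptance_probability(-0.5, 0.01) == 1.0
        assert fr.acceptance_probability(0.0, 0.01) == 1.0

    def test_infinite_deterioration_never_accepted(self):
        assert fr.acceptance_probability(math.inf, 100.0) == 0.0


class TestAnneal:
    def test_trace_best_energy_non_increasing(self, tiny_library, surrogate):
        trace = fr.anneal(tiny_library, surrogate, fr.SAConfig(seed=2))
        bests = [r.best_energy for r in trace.records]
        assert all(b1 >= b2 for b1, b2 in zip(bests, bests[1:]) if b1 is not None)
        assert trace.best_energy == min(bests)

    def test_temperature_strictly_geometric(self, tiny_library, surrogate):
        cfg = fr.SAConfig(seed=4, alpha=0.9, stuck_limit=1000)
        trace = fr.anneal(tiny_library, surrogate, cfg)
        for try_idx in {r.try_idx for r in trace.records}:
            temps = [r.temperature for r in trace.records
                     if r.try_idx == try_idx and r.move == "change"]
            for t1, t2 in zip(temps, temps[1:]):
                assert t2 == pytest.approx(t1 * cfg.alpha)
                assert t2 < t1
            assert all(t > cfg.final_temp for t in temps)

    def test_constant_scorer_runs_and_returns_first_energy(self, tiny_library):
        trace = fr.anneal(tiny_library, ConstantScorer(-3.0), fr.SAConfig(seed=1))
        assert trace.best_energy == -3.0
        assert trace.best_solution is not None

    def test_never_beats_brute_force_and_usually_matches(self, tiny_library, surrogate):
        optimum = min(fr.evaluate(s, surrogate) for s in enumerate_solutions(tiny_library))
        hits = 0
        for seed in range(5):
            trace = fr.anneal(tiny_library, surrogate, fr.SAConfig(seed=seed))
            assert trace.best_energy >= optimum - 1e-12
            hits += trace.best_energy == pytest.approx(optimum)
        assert hits >= 4

    def test_fixed_seed_identical_trace(self, tiny_library, surrogate):
        cfg = fr.SAConfig(seed=8)
        t1 = fr.anneal(tiny_library, surrogate, cfg)
        t2 = fr.anneal(tiny_library, surrogate, cfg)
        assert t1.to_tsv() == t2.to_tsv()
        assert t1.best_energy == t2.best_energy

    def test_cold_annealer_is_greedy(self, tiny_library, surrogate):
        # at vanishing temperature only improving changes are ever accepted
        cfg = fr.SAConfig(initial_temp=1e-8, final_temp=1e-12, alpha=0.9, seed=6)
        trace = fr.anneal(tiny_library, surrogate, cfg)
        for try_idx in {r.try_idx for r in trace.records}:
            energies = [r.current_energy for r in trace.records
                        if r.try_idx == try_idx and r.accepted]
            assert all(e1 >= e2 for e1, e2 in zip(energies, energies[1:]))

    def test_no_feasible_solution_yields_empty_best(self, tiny_library):
        hopeless = lambda mol: fr.ScoreResult.not_available("never")
        trace = fr.anneal(tiny_library, hopeless, fr.SAConfig(seed=0))
        assert trace.best_solution is None
        assert trace.best_energy == fr.INFEASIBLE

    def test_config_validation(self):
        with pytest.raises(fr.ContractError):
            fr.SAConfig(alpha=1.0)
        with pytest.raises(fr.ContractError):
            fr.SAConfig(initial_temp=1.0, final_temp=2.0)
        with pytest.raises(fr.ContractError):
            fr.SAConfig(max_tries=0)
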