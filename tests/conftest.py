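import pytest
from hypothesis import HealthCheck, settings

import fragrebuild as fr

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_records():
    return fr.load_reference_library()


@pytest.fixture(scope="session")
def group1_library():
    ligands = [fr.canonicalize(r.smiles, id=r.id) for r in fr.build_group(1)]
    return fr.build_library(ligands)


@pytest.fixture(scope="session")
def tiny_library():
    """Handcrafted 2-header x 3-body library, small enough to enumerate."""
    headers = [
        fr.FragmentHeader(smiles_with_markers="*c1ccccc1", n_attach=1, parent_id="h1"),
        fr.FragmentHeader(smiles_with_markers="*c1ccc(*)cc1", n_attach=2, parent_id="h2"),
    ]
    bodies = [
        fr.FragmentBody(molecule=fr.canonicalize("C"), parent_id="b1"),
        fr.FragmentBody(molecule=fr.canonicalize("CCO"), parent_id="b2"),
        fr.FragmentBody(molecule=fr.canonicalize("c1ccncc1"), parent_id="b3"),
    ]
    return fr.FragmentLibrary(
        headers=headers, bodies=bodies, n_fl=5, n_df=0, n_sl=5, n_kl=0
    )


@pytest.fixture(scope="session")
def surrogate():
    return fr.SurrogateScorer()


def enumerate_solutions(lib):
    """Brute-force oracle: every ordered header/body assignment."""
    from itertools import product

    for header in lib.headers:
        for combo in product(lib.bodies, repeat=header.n_attach):
            yield fr.Solution(header=header, bodies=tuple(combo))
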