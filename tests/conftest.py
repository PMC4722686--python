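import numpy as np
import pytest

from hierpred import ontology as onto
from hierpred import synthetic as syn


@pytest.fixture
def chain_dag():
    """R <- A <- B."""
    return onto.OntologyDAG({"R": [], "A": ["R"], "B": ["A"]})


@pytest.fixture
def diamond_dag():
    """R <- {A, B} <- C (C has two parents)."""
    return onto.OntologyDAG({"R": [], "A": ["R"], "B": ["R"], "C": ["A", "B"]})


@pytest.fixture
def three_branch_dag():
    """Root with three branches of three terms each."""
    parents = {"R": []}
    for b in (1, 2, 3):
        parents[f"B{b}"] = ["R"]
        parents[f"B{b}x"] = [f"B{b}"]
        parents[f"B{b}y"] = [f"B{b}x"]
    return onto.OntologyDAG(parents)


def random_dag(n_terms: int, seed: int, max_parents: int = 3) -> onto.OntologyDAG:
    rng = np.random.default_rng(seed)
    parents = {"T0": []}
    for i in range(1, n_terms):
        k = min(int(rng.integers(1, max_parents + 1)), i)
        parents[f"T{i}"] = [f"T{int(j)}" for j in rng.choice(i, size=k, replace=False)]
    return onto.OntologyDAG(parents)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A 60-gene high-signal fixture shared by loader/pipeline tests."""
    out = tmp_path_factory.mktemp("fixture") / "fx"
    syn.write_fixture(
        str(out),
        syn.SimConfig(n_genes=60, n_terms=25, noise=0.0, seed=11),
    )
    return str(out)
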