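import numpy as np
import pytest
from hypothesis import settings

from nemablate import Connectome, make_motif

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def random_connectome(rng: np.random.Generator, max_neurons: int = 8, max_muscles: int = 4):
    """Random small wiring diagram plus an input set (<= 12 states)."""
    n_n = int(rng.integers(2, max_neurons + 1))
    n_m = int(rng.integers(1, max_muscles + 1))
    neurons = [f"N{i:02d}" for i in range(n_n)]
    muscles = [f"MU{j:02d}" for j in range(n_m)]
    records = []
    for pre in neurons:
        for post in neurons:
            if pre != post and rng.random() < 0.25:
                records.append((pre, post, "chemical", 1))
        for m in muscles:
            if rng.random() < 0.35:
                records.append((pre, m, "nmj", 1))
    for i in range(n_n):
        for j in range(i + 1, n_n):
            if rng.random() < 0.08:
                records.append((neurons[i], neurons[j], "gap", 1))
    kinds = {n: "neuron" for n in neurons} | {m: "muscle" for m in muscles}
    c = Connectome.from_records(records, cell_kinds=kinds, use_name_rule=False)
    k = int(rng.integers(1, min(3, n_n) + 1))
    inputs = sorted(rng.choice(neurons, size=k, replace=False).tolist())
    return c, inputs


@pytest.fixture(scope="session")
def group1():
    return make_motif("group1")


@pytest.fixture(scope="session")
def group2():
    return make_motif("group2")


@pytest.fixture(scope="session")
def va_pair():
    return make_motif("va_pair_subnetwork")


@pytest.fixture
def toy_chain():
    """a -> b -> m1 with input a."""
    return Connectome.from_records(
        [("a", "b", "chemical", 1), ("b", "m1", "nmj", 1)],
        cell_kinds={"a": "neuron", "b": "neuron", "m1": "muscle"},
        use_name_rule=False,
    )
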