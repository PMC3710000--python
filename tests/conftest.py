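import pytest

from signetmotif import GeneratorSpec, Motif, SignedDigraph, random_network


@pytest.fixture
def chain():
    """A -> B -> C, activation then inhibition."""
    return SignedDigraph([("A", "B", 1), ("B", "C", -1)])


@pytest.fixture
def negative_loop():
    return SignedDigraph([("A", "B", 1), ("B", "A", -1)])


@pytest.fixture
def positive_cycle():
    return SignedDigraph([("A", "B", 1), ("B", "C", 1), ("C", "A", 1)])


@pytest.fixture
def negative_loop_motif(negative_loop):
    return Motif("neg2", "oscillation", negative_loop)


def make_random(n, m, seed, negative_fraction=0.3):
    return random_network(GeneratorSpec(n=n, m=m, negative_fraction=negative_fraction,
                                        seed=seed))


@pytest.fixture
def small_random_graphs():
    """A corpus of small random signed digraphs at varied densities."""
    out = []
    for seed in range(6):
        n = 5 + seed
        m = min(2 * n, n * (n - 1))
        out.append(make_random(n, m, seed))
    return out
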