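import numpy as np
import pytest

from trophicstab import FoodWeb, Link, Node, sjg_like_scenario_pair


@pytest.fixture
def chain3():
    """A eats B eats C; C basal."""
    return FoodWeb(
        [Node(i) for i in "ABC"], [Link("A", "B"), Link("B", "C")], name="chain3"
    )


@pytest.fixture
def diamond():
    """A eats B (0.5) and C (0.5); B eats C; C basal."""
    return FoodWeb(
        [Node(i) for i in "ABC"],
        [Link("A", "B", 0.5), Link("A", "C", 0.5), Link("B", "C")],
        name="diamond",
    )


@pytest.fixture
def omnivore5():
    """A eats B and C (B at TL 2, C basal); D eats E; E basal."""
    return FoodWeb(
        [Node(i) for i in "ABCDE"],
        [
            Link("A", "B", 0.5),
            Link("A", "C", 0.5),
            Link("B", "C"),
            Link("D", "E"),
        ],
        name="omnivore5",
    )


@pytest.fixture
def two_cycles():
    """Two disjoint directed 3-cycles; abstract graph (no basal)."""
    return FoodWeb(
        [Node(i) for i in "ABCDEF"],
        [
            Link("A", "B"), Link("B", "C"), Link("C", "A"),
            Link("D", "E"), Link("E", "F"), Link("F", "D"),
        ],
        name="two-cycles",
        require_basal=False,
    )


@pytest.fixture(scope="session")
def scenario_pair():
    """One fixed synthetic non-fishing / fishing pair (expensive; shared)."""
    return sjg_like_scenario_pair(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
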