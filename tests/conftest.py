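import pytest

from kappmax.model_io import MetabolicNetwork, Reaction


@pytest.fixture
def diamond_network() -> MetabolicNetwork:
    """source -> A; A -> B via r1 (e1) or via r2, r3 chain (e2, e3); B -> sink
    fixed at 1.0."""
    net = MetabolicNetwork(
        model_id="diamond",
        metabolites=[("A", "c"), ("M", "c"), ("B", "c")],
        reactions=[
            Reaction("src", {"A": 1.0}, 0.0, 10.0),
            Reaction("r1", {"A": -1.0, "B": 1.0}, 0.0, 10.0, gpr="e1"),
            Reaction("r2", {"A": -1.0, "M": 1.0}, 0.0, 10.0, gpr="e2"),
            Reaction("r3", {"M": -1.0, "B": 1.0}, 0.0, 10.0, gpr="e3"),
            Reaction("sink", {"B": -1.0}, 1.0, 1.0),
        ],
        genes=["e1", "e2", "e3"],
        biomass_reaction_id="sink",
    )
    net.validate()
    return net


@pytest.fixture
def diamond_enzyme_map() -> dict[str, set[str]]:
    return {"e1": {"r1"}, "e2": {"r2"}, "e3": {"r3"}}


@pytest.fixture
def linear_pathway() -> MetabolicNetwork:
    """EX -> a; r1: a -> 2 b (gene g1); biomass consumes b."""
    net = MetabolicNetwork(
        model_id="single_pathway",
        metabolites=[("a", "c"), ("b", "c")],
        reactions=[
            Reaction("EX", {"a": 1.0}, 0.0, 1000.0),
            Reaction(
                "r1", {"a": -1.0, "b": 2.0}, 0.0, 1000.0,
                gpr="g1", ec_numbers=["1.1.1.1"],
            ),
            Reaction("BIOMASS", {"b": -1.0}, 0.0, 1000.0),
        ],
        genes=["g1"],
        biomass_reaction_id="BIOMASS",
    )
    net.validate()
    return net
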