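import pytest

from phenomass.model_io import (
    GPRRule,
    MediaCondition,
    MetaboliteRecord,
    MetabolicNetwork,
    ReactionRecord,
)


def _met(mid, comp="c"):
    return MetaboliteRecord(id=mid, name=mid, compartment=comp)


def _rxn(rid, stoich, lb=0.0, ub=1000.0, gene="", is_exchange=False):
    return ReactionRecord(
        id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
        gpr=GPRRule(gene), is_exchange=is_exchange,
    )


def linear_chain_network():
    """A_ex <-> (exchange); A_ex -> A [g1]; A -> B [g2]; B -> C [g3]."""
    return MetabolicNetwork(
        metabolites=[_met("A_ex", "e"), _met("A"), _met("B"), _met("C")],
        reactions=[
            _rxn("EX_A", {"A_ex": -1.0}, lb=-1000.0, is_exchange=True),
            _rxn("T_A", {"A_ex": -1.0, "A": 1.0}, gene="g1"),
            _rxn("R1", {"A": -1.0, "B": 1.0}, gene="g2"),
            _rxn("R2", {"B": -1.0, "C": 1.0}, gene="g3"),
        ],
        genes={"g1", "g2", "g3"},
        id="lin3",
    )


def closed_cycle_network():
    """X -> Y -> X with no external source of either."""
    return MetabolicNetwork(
        metabolites=[_met("X"), _met("Y")],
        reactions=[
            _rxn("R1", {"X": -1.0, "Y": 1.0}),
            _rxn("R2", {"Y": -1.0, "X": 1.0}),
        ],
        id="cycle2",
    )


def diamond_network():
    """Two parallel 2-step routes from A to C."""
    return MetabolicNetwork(
        metabolites=[_met("A_ex", "e"), _met("A"), _met("u1"), _met("u2"), _met("C")],
        reactions=[
            _rxn("EX_A", {"A_ex": -1.0}, lb=-1000.0, is_exchange=True),
            _rxn("T_A", {"A_ex": -1.0, "A": 1.0}, gene="gT"),
            _rxn("B1a", {"A": -1.0, "u1": 1.0}, gene="g1a"),
            _rxn("B1b", {"u1": -1.0, "C": 1.0}, gene="g1b"),
            _rxn("B2a", {"A": -1.0, "u2": 1.0}, gene="g2a"),
            _rxn("B2b", {"u2": -1.0, "C": 1.0}, gene="g2b"),
        ],
        genes={"gT", "g1a", "g1b", "g2a", "g2b"},
        id="diamond",
    )


def byproduct_network(with_consumer=False, with_two_disposals=False):
    """A + X -> P + Q; Q is a dead end unless a disposal route exists."""
    mets = [_met("A"), _met("X"), _met("P"), _met("Q")]
    rxns = [
        _rxn("EX_A", {"A": -1.0}, lb=-1000.0, is_exchange=True),
        _rxn("EX_X", {"X": -1.0}, lb=-1000.0, is_exchange=True),
        _rxn("SYN", {"A": -1.0, "X": -1.0, "P": 1.0, "Q": 1.0}, gene="gS"),
    ]
    if with_consumer:
        rxns.append(_rxn("EX_Q", {"Q": -1.0}, lb=0.0, is_exchange=True))
    if with_two_disposals:
        mets.append(_met("D1"))
        rxns.append(_rxn("QD", {"Q": -1.0, "D1": 1.0}, gene="gD"))
    return MetabolicNetwork(
        metabolites=mets, reactions=rxns,
        genes={"gS"} | ({"gD"} if with_two_disposals else set()),
        id="byproduct",
    )


@pytest.fixture
def lin3():
    return linear_chain_network()


@pytest.fixture
def lin3_media():
    return MediaCondition(id="mA", allowed_uptakes={"EX_A": 10.0})


@pytest.fixture
def cycle_net():
    return closed_cycle_network()


@pytest.fixture
def diamond():
    return diamond_network()
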