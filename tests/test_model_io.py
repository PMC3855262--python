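import logging

import pytest

from phenomass.errors import ConfigurationError, IntegrityError
from phenomass.model_io import (
    GPRRule,
    MediaCondition,
    MetaboliteRecord,
    MetabolicNetwork,
    ReactionRecord,
    apply_knockout,
    apply_media,
    prepare_for_blocking,
    read_model,
    sink_id,
    union_media,
    write_model,
)
from phenomass.synthetic_fixtures import illustrative_example

from conftest import linear_chain_network


def _signature(net):
    return {
        (r.id, tuple(sorted(r.stoichiometry.items())), r.lower_bound,
         r.upper_bound, r.gpr.to_string(), r.is_exchange)
        for r in net.reactions
    }


@pytest.mark.parametrize("dialect", ["cobra-json", "sbml"])
def test_round_trip_preserves_structure(tmp_path, dialect):
    net, _, _, _ = illustrative_example()
    suffix = "json" if dialect == "cobra-json" else "xml"
    path = tmp_path / f"model.{suffix}"
    write_model(net, path, dialect=dialect)
    back = read_model(path, dialect=dialect)
    assert _signature(back) == _signature(net)
    assert back.genes == net.genes
    assert back.biomass_reaction_ids == net.biomass_reaction_ids
    assert back.mu == net.mu


def test_cross_dialect_round_trip_identical(tmp_path):
    net = linear_chain_network()
    write_model(net, tmp_path / "m.json", dialect="cobra-json")
    write_model(net, tmp_path / "m.xml", dialect="sbml")
    from_json = read_model(tmp_path / "m.json", dialect="cobra-json")
    from_sbml = read_model(tmp_path / "m.xml", dialect="sbml")
    assert _signature(from_json) == _signature(from_sbml)
    assert from_json.genes == from_sbml.genes


def test_undeclared_metabolite_is_integrity_error():
    with pytest.raises(IntegrityError, match="X"):
        MetabolicNetwork(
            metabolites=[MetaboliteRecord(id="A")],
            reactions=[
                ReactionRecord(id="R", stoichiometry={"A": -1.0, "X": 1.0},
                               lower_bound=0.0, upper_bound=10.0)
            ],
        )


def test_gpr_semantics():
    assert GPRRule("g1 or g2").evaluate({"g1"})
    assert not GPRRule("g1 and g2").evaluate({"g1"})
    assert GPRRule("").evaluate({"anything"})  # non-gene-associated


def test_apply_media_opens_only_listed_uptakes(lin3, lin3_media):
    out = apply_media(lin3, lin3_media)
    assert out.reaction("EX_A").lower_bound == -10.0
    assert out.reaction("EX_A").upper_bound == 1000.0  # secretion untouched


def test_apply_media_empty_closes_all_uptakes(lin3):
    out = apply_media(lin3, MediaCondition(id="none", allowed_uptakes={}))
    for r in out.exchange_reactions:
        assert r.lower_bound == 0.0


def test_apply_media_union_opens_all_conditions(diamond):
    m1 = MediaCondition(id="m1", allowed_uptakes={"EX_A": 5.0})
    m2 = MediaCondition(id="m2", allowed_uptakes={"EX_A": 10.0})
    robust = union_media([m1, m2])
    out = apply_media(diamond, robust)
    assert out.reaction("EX_A").lower_bound == -10.0


def test_apply_media_unknown_exchange_rejected(lin3):
    with pytest.raises(ConfigurationError):
        apply_media(lin3, MediaCondition(id="bad", allowed_uptakes={"EX_ZZ": 1.0}))


def test_knockout_isozyme_vs_complex():
    net = MetabolicNetwork(
        metabolites=[MetaboliteRecord(id="A"), MetaboliteRecord(id="B")],
        reactions=[
            ReactionRecord(id="ISO", stoichiometry={"A": -1.0, "B": 1.0},
                           lower_bound=0.0, upper_bound=10.0,
                           gpr=GPRRule("g1 or g2")),
            ReactionRecord(id="CPLX", stoichiometry={"B": -1.0, "A": 1.0},
                           lower_bound=0.0, upper_bound=10.0,
                           gpr=GPRRule("g1 and g2")),
        ],
        genes={"g1", "g2"},
    )
    out = apply_knockout(net, {"g1"})
    assert out.reaction("ISO").upper_bound == 10.0  # isozyme compensates
    assert out.reaction("CPLX").lower_bound == 0.0
    assert out.reaction("CPLX").upper_bound == 0.0


def test_knockout_empty_set_is_identity(lin3):
    out = apply_knockout(lin3, set())
    assert _signature(out) == _signature(lin3)


def test_knockout_unknown_gene_warns_and_is_ignored(lin3, caplog):
    with caplog.at_level(logging.WARNING):
        out = apply_knockout(lin3, {"not_a_gene"})
    assert "not_a_gene" in caplog.text
    assert _signature(out) == _signature(lin3)


def test_knockout_monotone_in_gene_set(lin3):
    def disabled(net):
        return {r.id for r in net.reactions
                if r.lower_bound == 0.0 and r.upper_bound == 0.0}

    small = disabled(apply_knockout(lin3, {"g2"}))
    large = disabled(apply_knockout(lin3, {"g2", "g3"}))
    assert small <= large


def test_prepare_for_blocking_counts_and_idempotency(lin3):
    net, _, _, _ = illustrative_example()
    prepared = prepare_for_blocking(net)
    assert not any(r.id in net.biomass_reaction_ids for r in prepared.reactions)
    assert len(prepared.reactions) == len(net.reactions) - 1 + len(net.metabolites)
    again = prepare_for_blocking(prepared)
    assert len(again.reactions) == len(prepared.reactions)
    # original reactions keep their stoichiometry
    originals = {r.id for r in net.reactions} - set(net.biomass_reaction_ids)
    for rid in originals:
        assert prepared.reaction(rid).stoichiometry == net.reaction(rid).stoichiometry


def test_prepare_for_blocking_without_biomass_only_adds_sinks(lin3):
    prepared = prepare_for_blocking(lin3)
    assert len(prepared.reactions) == len(lin3.reactions) + len(lin3.metabolites)
    sink = prepared.reaction(sink_id("B"))
    assert sink.stoichiometry == {"B": -1.0}
    assert sink.lower_bound == 0.0 and sink.upper_bound == 1000.0
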