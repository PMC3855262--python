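import pytest

from phenomass.blocked_core import (
    BlockingConfig,
    ProducibilityResult,
    candidate_blocked,
    producible_oracle,
    producible_set_milp,
)
from phenomass.errors import UsageError
from phenomass.model_io import (
    MediaCondition,
    apply_knockout,
    apply_media,
    prepare_for_blocking,
)
from phenomass.synthetic_fixtures import (
    FixtureSpec,
    fixture_media,
    make_random_network,
)

from conftest import closed_cycle_network, linear_chain_network

CFG = BlockingConfig()


def _staged(net, media, genes=()):
    staged = apply_media(prepare_for_blocking(net), media)
    return apply_knockout(staged, set(genes))


def forward_reachable(net, media):
    """Graph lower bound: metabolites reachable from open uptakes through
    irreversible forward reactions whose substrates are all reachable."""
    staged = apply_media(net, media)
    reachable = set()
    for r in staged.exchange_reactions:
        if r.lower_bound < 0:
            reachable |= set(r.stoichiometry)
    changed = True
    while changed:
        changed = False
        for r in staged.reactions:
            if r.upper_bound <= 0 or r.is_exchange:
                continue
            subs = {m for m, c in r.stoichiometry.items() if c < 0}
            prods = {m for m, c in r.stoichiometry.items() if c > 0}
            if subs <= reachable and not prods <= reachable:
                reachable |= prods
                changed = True
    return reachable


def test_linear_chain_wild_type_nothing_blocked(lin3, lin3_media):
    staged = _staged(lin3, lin3_media)
    for solve in (producible_set_milp, producible_oracle):
        res = solve(staged, CFG)
        assert res.blocked == frozenset()
        assert res.producible == {"A_ex", "A", "B", "C"}


def test_milp_witnesses_meet_threshold(lin3, lin3_media):
    res = producible_set_milp(_staged(lin3, lin3_media), CFG)
    from phenomass.model_io import sink_id

    for m in res.producible:
        assert res.witness_fluxes[sink_id(m)] >= CFG.v_min - 1e-9


def test_closed_cycle_members_blocked_despite_internal_flux(cycle_net):
    # internal circulation X->Y->X is feasible, but mass balance with sinks
    # forces x_X + x_Y = 0, so neither can be net-produced
    staged = prepare_for_blocking(cycle_net)
    for solve in (producible_set_milp, producible_oracle):
        res = solve(staged, CFG)
        assert res.blocked == {"X", "Y"}


def test_every_metabolite_exchanged_means_nothing_blocked(diamond):
    from phenomass.model_io import ReactionRecord

    open_all = diamond.replace_reactions(
        list(diamond.reactions)
        + [
            ReactionRecord(id=f"EX_{m.id}_all", stoichiometry={m.id: -1.0},
                           lower_bound=-1000.0, upper_bound=1000.0,
                           is_exchange=True)
            for m in diamond.metabolites if m.id != "A_ex"
        ]
    )
    media = MediaCondition(
        id="all",
        allowed_uptakes={r.id: 10.0 for r in open_all.exchange_reactions},
    )
    res = producible_set_milp(_staged(open_all, media), CFG)
    assert res.blocked == frozenset()


def test_oracle_knockout_blocks_downstream(lin3, lin3_media):
    res = producible_oracle(_staged(lin3, lin3_media, {"g2"}), CFG)
    assert res.blocked == {"B", "C"}


def test_isolated_metabolite_blocked():
    net = closed_cycle_network()
    # Y unreachable once its producer is removed entirely
    lone = net.replace_reactions([net.reaction("R1")])
    res = producible_oracle(prepare_for_blocking(lone), CFG)
    assert "X" in res.blocked  # no producer of X at all


def test_candidate_blocked_set_difference():
    wt = ProducibilityResult(strain="wt", media_id="m",
                             producible=frozenset({"C"}),
                             blocked=frozenset({"I_ex", "I"}))
    mut = ProducibilityResult(strain="mut", media_id="m",
                              producible=frozenset(),
                              blocked=frozenset({"I_ex", "I", "C"}))
    assert candidate_blocked(wt, mut) == {"C"}
    assert candidate_blocked(wt, wt) == set()


def test_candidate_blocked_rejects_media_mismatch():
    a = ProducibilityResult(strain="wt", media_id="m1",
                            producible=frozenset({"A"}), blocked=frozenset())
    b = ProducibilityResult(strain="mut", media_id="m2",
                            producible=frozenset({"A"}), blocked=frozenset())
    with pytest.raises(UsageError):
        candidate_blocked(a, b)


@pytest.mark.parametrize("seed", range(12))
def test_milp_matches_oracle_on_random_fixtures(seed):
    spec = FixtureSpec(
        n_linear_pathways=3 + seed % 4,
        pathway_length=(2, 5),
        n_isozyme_pairs=seed % 3,
        n_parallel_routes=1 + seed % 2,
        n_closed_cycles=seed % 2,
        n_byproduct_couplings=1,
        seed=seed,
    )
    net = make_random_network(spec)
    staged = _staged(net, fixture_media(spec))
    assert producible_set_milp(staged, CFG).blocked == \
        producible_oracle(staged, CFG).blocked


@pytest.mark.parametrize("seed", [0, 7])
def test_blocking_monotone_under_nested_knockouts(seed):
    spec = FixtureSpec(seed=seed)
    net = make_random_network(spec)
    media = fixture_media(spec)
    genes = sorted(net.genes)[:4]
    prev = frozenset()
    for k in range(len(genes) + 1):
        res = producible_oracle(_staged(net, media, genes[:k]), CFG)
        assert prev <= res.blocked
        prev = res.blocked


@pytest.mark.parametrize("seed", [1, 4])
def test_forward_reachable_metabolites_are_producible(seed):
    spec = FixtureSpec(seed=seed)
    net = make_random_network(spec)
    media = fixture_media(spec)
    res = producible_oracle(_staged(net, media), CFG)
    assert forward_reachable(net, media) <= set(res.producible)
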