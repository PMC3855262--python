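from itertools import chain, combinations

import numpy as np
import pytest

from phenomass.biomass_select import (
    WeightScheme,
    max_agreement,
    modify_biomass,
    select_de_novo,
)
from phenomass.errors import UsageError
from phenomass.phenotype_lists import IncludeExcludeLists


def _lists(include=None, exclude=None, weights=None):
    return IncludeExcludeLists(
        include=include or {}, exclude=exclude or {}, weights=weights or {}
    )


def _subsets(universe):
    u = sorted(universe)
    return chain.from_iterable(combinations(u, k) for k in range(len(u) + 1))


def brute_force_agreement(lists, components, em=()):
    components = set(components)
    total = 0.0
    for e, mets in lists.include.items():
        if components & mets:
            total += lists.weight(e)
    for m in em:
        if m in components:
            total += 1.0
    for e, mets in lists.exclude.items():
        if not components & mets:
            total += lists.weight(e)
    return total


def brute_force_optimum(lists, em=()):
    universe = set(lists.universe) | set(em)
    best, best_sets = -1.0, []
    for sub in _subsets(universe):
        val = brute_force_agreement(lists, sub, em)
        if val > best:
            best, best_sets = val, [frozenset(sub)]
        elif val == best:
            best_sets.append(frozenset(sub))
    return best, best_sets


def test_two_experiment_example_enumerated():
    lists = _lists(include={"e1": {"B", "C"}}, exclude={"e2": {"C"}})
    fix, witness = max_agreement(lists)
    expected, optima = brute_force_optimum(lists)
    assert fix == expected == 2.0
    assert witness in optima
    assert "B" in witness and "C" not in witness


def test_unfixable_ng_experiment_scores_zero():
    lists = _lists(include={"e1": set()}, exclude={})
    fix, _ = max_agreement(lists)
    assert fix == 0.0


def test_conflicting_evidence_scores_one_either_way():
    # metabolite f is the sole blocked metabolite of one growing and one
    # non-growing mutant: at most one of the two can ever be matched
    lists = _lists(include={"eNG": {"f"}}, exclude={"eG": {"f"}})
    fix, _ = max_agreement(lists)
    assert fix == 1.0
    assert brute_force_optimum(lists)[0] == 1.0


def test_minimal_mode_prefers_fewer_components():
    lists = _lists(include={"e1": {"B", "C"}}, exclude={"e2": {"C"}})
    prop = select_de_novo(lists, scheme=WeightScheme(mode="minimal"))
    assert prop.components == {"B"}
    assert prop.agreement == 2.0


def test_weighted_mode_prefers_listed_metabolite():
    lists = _lists(include={"e1": {"B", "C"}})
    scheme = WeightScheme(preferred=frozenset({"C"}), mode="weighted")
    prop = select_de_novo(lists, scheme=scheme)
    assert prop.components == {"C"}


def test_empty_lists_give_empty_proposal():
    prop = select_de_novo(_lists())
    assert prop.components == frozenset()
    assert prop.agreement == 0.0


def test_stale_fix_obj_rejected():
    lists = _lists(include={"e1": {"B"}})
    with pytest.raises(UsageError):
        select_de_novo(lists, fix_obj=5.0)


def test_em_pseudo_experiments_are_soft():
    # phenotype data contradicts the measurement: one growing mutant whose
    # only blocked metabolite is the measured one, plus two supporting NG
    lists = _lists(
        include={"e1": {"m"}, "e2": {"m"}},
        exclude={"e3": {"m"}},
    )
    fix, _ = max_agreement(lists, em=["m"])
    # include m: e1 + e2 + EM = 3; exclude m: e3 = 1 -> include wins
    assert fix == 3.0
    prop = select_de_novo(lists, em=["m"], fix_obj=fix)
    assert "m" in prop.components
    # now outweigh the measurement with conflicting growth experiments
    lists2 = _lists(
        include={"e1": {"m"}},
        exclude={"e3": {"m"}, "e4": {"m"}, "e5": {"m"}},
    )
    fix2, _ = max_agreement(lists2, em=["m"])
    assert fix2 == 3.0
    prop2 = select_de_novo(lists2, em=["m"], fix_obj=fix2)
    assert "m" not in prop2.components


@pytest.mark.parametrize("seed", range(12))
def test_fixobj_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    universe = [f"m{k}" for k in range(int(rng.integers(4, 9)))]
    include, exclude = {}, {}
    for e in range(int(rng.integers(2, 7))):
        mets = set(rng.choice(universe, size=int(rng.integers(1, 4)), replace=False))
        if rng.random() < 0.5:
            include[f"ng{e}"] = mets
        else:
            exclude[f"g{e}"] = mets
    lists = _lists(include=include, exclude=exclude)
    fix, witness = max_agreement(lists)
    expected, optima = brute_force_optimum(lists)
    assert fix == expected
    assert brute_force_agreement(lists, witness) == expected

    prop = select_de_novo(lists, fix_obj=fix, scheme=WeightScheme(mode="minimal"))
    min_card = min(len(s) for s in optima)
    assert len(prop.components) == min_card
    assert brute_force_agreement(lists, prop.components) == expected


def test_select_never_degrades_agreement():
    lists = _lists(
        include={"e1": {"a", "b"}, "e2": {"b", "c"}},
        exclude={"e3": {"c"}, "e4": {"a"}},
    )
    fix, _ = max_agreement(lists)
    prop = select_de_novo(lists, fix_obj=fix)
    assert prop.agreement == fix
    assert brute_force_agreement(lists, prop.components) == fix


def test_new_supporting_ng_experiment_cannot_lower_fixobj():
    lists = _lists(include={"e1": {"a"}}, exclude={"e2": {"b"}})
    fix, _ = max_agreement(lists)
    prop = select_de_novo(lists, fix_obj=fix)
    richer = _lists(
        include={"e1": {"a"}, "e_new": set(prop.components)},
        exclude={"e2": {"b"}},
    )
    fix2, _ = max_agreement(richer)
    assert fix2 >= fix + 1.0  # the new experiment is matched by construction


def test_weighted_experiments_shift_the_optimum():
    lists = _lists(
        include={"eNG": {"f"}},
        exclude={"eG": {"f"}},
        weights={"eNG": 3.0, "eG": 1.0},
    )
    fix, _ = max_agreement(lists)
    assert fix == 3.0
    prop = select_de_novo(lists, fix_obj=fix)
    assert "f" in prop.components


def test_modify_adds_and_removes_per_evidence():
    lists = _lists(include={"e1": {"C"}}, exclude={"e2": {"F"}})
    prop = modify_biomass(lists, mu={"F", "H"})
    assert prop.added == {"C"}
    assert prop.removed == {"F"}
    assert prop.unmodified == {"H"}
    assert prop.final_components == {"C", "H"}


def test_modify_is_noop_when_data_consistent():
    lists = _lists(include={"e1": {"F"}}, exclude={"e2": {"Z"}})
    prop = modify_biomass(lists, mu={"F", "H"})
    assert prop.added == frozenset()
    assert prop.removed == frozenset()
    assert prop.unmodified == {"F", "H"}


def test_modify_with_empty_lists_returns_mu_unchanged():
    prop = modify_biomass(_lists(), mu={"F", "H"})
    assert prop.final_components == {"F", "H"}
    assert prop.added == frozenset() and prop.removed == frozenset()


def test_modify_swaps_macromolecule_proxy_for_constituents():
    # a proxy metabolite is the sole blocked metabolite of a viable mutant,
    # while its amino-acid constituents cover all the no-growth lists
    lists = _lists(
        include={"e1": {"proxy", "ala"}, "e2": {"proxy", "gly"}},
        exclude={"e3": {"proxy"}},
    )
    prop = modify_biomass(lists, mu={"proxy"})
    assert prop.removed == {"proxy"}
    assert prop.added == {"ala", "gly"}
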