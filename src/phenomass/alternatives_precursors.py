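"""Alternative components, essential precursors, component categorization.

An *alternative* of a proposed component is any metabolite that can replace
it without lowering the maximal agreement. An *essential precursor* of a
biomass set is an upstream metabolite whose removal from the network (all
reactions consuming it are disabled in the consuming direction) makes
simultaneous production of every biomass component infeasible under the
robust media (the union of all tested conditions). Together these relations
let a de-novo proposal be compared against a predefined biomass: each
proposed component is a direct match, an alternative of a predefined one,
downstream or upstream of one, or unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

import numpy as np
import scipy.sparse as sp

from phenomass import _solver
from phenomass.biomass_select import BiomassProposal, SelectionIP
from phenomass.blocked_core import BlockingConfig
from phenomass.errors import UsageError
from phenomass.model_io import (
    MediaCondition,
    MetabolicNetwork,
    apply_media,
    is_sink,
    prepare_for_blocking,
    sink_id,
)
from phenomass.phenotype_lists import IncludeExcludeLists

logger = logging.getLogger(__name__)

CATEGORY_ORDER = (
    "direct_match",
    "alternative_of_predefined",
    "downstream_of_predefined",
    "upstream_of_predefined",
    "unique",
)


def enumerate_alternatives(
    proposal: BiomassProposal,
    lists: IncludeExcludeLists,
    target: str,
    em: Iterable[str] = (),
    em_weight: float = 1.0,
    max_alternatives: int = 50,
) -> Set[str]:
    """All metabolites that can stand in for ``target`` at unchanged agreement.

    Every other proposed component is pinned to 1 and the target to 0; the
    selection IP is re-solved with uniform costs at agreement fixed to the
    proposal's value. Each feasible solve yields replacement metabolites,
    which are then pinned to 0 in turn, until the problem is infeasible
    (or no new metabolite appears).
    """
    if target not in proposal.components:
        raise UsageError(f"{target!r} is not a component of the proposal")
    ip = SelectionIP(lists, em, em_weight)
    agree_c = ip.agreement_vector()
    extra = [ip.fix_value_constraint(agree_c, proposal.agreement)]
    cost_c = ip.membership_cost_vector(lambda m: 1.0)

    fixed: Dict[str, int] = {m: 1 for m in proposal.components if m != target}
    fixed[target] = 0
    known = set(proposal.components)
    alternatives: Set[str] = set()
    while len(alternatives) < max_alternatives:
        res = ip.solve(cost_c, maximize=False, fixed=fixed, extra=extra)
        if not res.feasible:
            break
        new = set(ip.components_from(res.x)) - known - alternatives
        if not new:
            break
        for m in sorted(new):
            alternatives.add(m)
            fixed[m] = 0
    return alternatives


def _decoupled_system(net: MetabolicNetwork):
    """Split fluxes into non-negative forward/reverse parts.

    Returns ``(S_split, rxn_ids, lb, ub)`` where columns come in pairs
    ``[v_for, v_rev]`` per reaction and ``S_split = [S, -S]`` interleaved.
    A zero upper (lower) bound zeroes the forward (reverse) direction.
    """
    S, met_ids, rxn_ids = net.stoichiometric_matrix()
    lb_v, ub_v = net.flux_bounds(rxn_ids)
    ub_for = np.maximum(ub_v, 0.0)
    ub_rev = np.maximum(-lb_v, 0.0)
    S_split = sp.hstack([S, -S]).tocsr()
    lb = np.zeros(2 * len(rxn_ids))
    ub = np.concatenate([ub_for, ub_rev])
    return S_split, met_ids, rxn_ids, lb, ub


def essential_precursors(
    net: MetabolicNetwork,
    biomass: Iterable[str],
    robust_media: MediaCondition,
    cfg: BlockingConfig = BlockingConfig(),
    candidates: Optional[Iterable[str]] = None,
    simultaneous: bool = True,
) -> Set[str]:
    """Metabolites whose removal blocks production of the biomass set.

    The sink-augmented network under the robust media must support sink flux
    of at least ``v_min`` for every biomass component simultaneously (a
    single flux vector). For each candidate metabolite ``k`` outside the
    biomass, all reaction directions consuming ``k`` are disabled (forward
    direction where ``k`` has a negative coefficient, reverse direction
    where positive), including ``k``'s own sink and exchange; if the biomass
    demand then becomes infeasible, ``k`` is an essential precursor.

    ``simultaneous=False`` tests each biomass component separately instead
    (a diagnostic mode).
    """
    biomass = sorted(set(biomass))
    if not biomass:
        raise UsageError("biomass set must be nonempty")
    prepared = apply_media(prepare_for_blocking(net), robust_media)
    S_split, met_ids, rxn_ids, lb, ub = _decoupled_system(prepared)
    n2 = len(rxn_ids)
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rxn_pos = {r: j for j, r in enumerate(rxn_ids)}

    def feasible(kill: Optional[str]) -> bool:
        lo, hi = lb.copy(), ub.copy()
        for m in biomass:
            j = rxn_pos[sink_id(m)]
            lo[j] = max(lo[j], cfg.v_min)  # forward part of the sink
        if kill is not None:
            krow = S_split.getrow(met_pos[kill]).tocoo()
            for col, coef in zip(krow.col, krow.data):
                if coef < 0:  # this direction consumes k
                    hi[col] = 0.0
                    lo[col] = min(lo[col], 0.0)
            # the killed metabolite's own sink and exchange must not mask it
            for rid in (sink_id(kill),):
                j = rxn_pos.get(rid)
                if j is not None:
                    hi[j] = 0.0
                    lo[j] = 0.0
            for rid in rxn_ids:
                rec = prepared.reaction(rid)
                if rec.is_exchange and kill in rec.stoichiometry:
                    j = rxn_pos[rid]
                    hi[j] = hi[j + n2] = 0.0
                    lo[j] = lo[j + n2] = 0.0
        res = _solver.solve_lp(
            np.zeros(2 * n2), S_split, np.zeros(len(met_ids)), lo, hi
        )
        return res.feasible

    def feasible_any(kill: Optional[str]) -> bool:
        if simultaneous:
            return feasible(kill)
        # sequential variant: every component must be producible on its own
        nonlocal biomass
        full = list(biomass)
        ok = True
        for comp in full:
            biomass = [comp]
            ok &= feasible(kill)
        biomass = full
        return ok

    if not feasible_any(None):
        raise UsageError(
            "biomass set is not simultaneously producible under the robust "
            "media; the proposal violates the precursor-analysis precondition"
        )
    pool = sorted(set(candidates) if candidates is not None else set(met_ids))
    essential = set()
    for k in pool:
        if k in biomass or k not in met_pos:
            continue
        if not feasible_any(k):
            essential.add(k)
    return essential


def categorize_components(
    de_novo: Iterable[str],
    predefined: Iterable[str],
    net: MetabolicNetwork,
    robust_media: MediaCondition,
    lists: IncludeExcludeLists,
    proposal: Optional[BiomassProposal] = None,
    cfg: BlockingConfig = BlockingConfig(),
    em: Iterable[str] = (),
) -> Dict[str, str]:
    """Classify each de-novo component against the predefined biomass.

    Precedence: direct_match > alternative_of_predefined >
    downstream_of_predefined > upstream_of_predefined > unique.
    """
    de_novo = sorted(set(de_novo))
    predefined = frozenset(predefined)
    known = {m.id for m in net.metabolites}
    missing = (set(de_novo) | predefined) - known
    if missing:
        raise UsageError(f"components outside network universe: {sorted(missing)}")

    categories: Dict[str, str] = {}
    upstream_cache: Dict[str, Set[str]] = {}
    for c in de_novo:
        if c in predefined:
            categories[c] = "direct_match"
            continue
        if proposal is not None and c in proposal.components:
            alts = enumerate_alternatives(proposal, lists, c, em=em)
            if alts & predefined:
                categories[c] = "alternative_of_predefined"
                continue
        # downstream: some predefined metabolite is an essential precursor of c
        try:
            pre_of_c = essential_precursors(
                net, {c}, robust_media, cfg, candidates=predefined
            )
        except UsageError:
            pre_of_c = set()
        if pre_of_c:
            categories[c] = "downstream_of_predefined"
            continue
        # upstream: c is an essential precursor of some predefined component
        upstream = False
        for p in sorted(predefined):
            if p not in upstream_cache:
                try:
                    upstream_cache[p] = essential_precursors(
                        net, {p}, robust_media, cfg, candidates=set(de_novo)
                    )
                except UsageError:
                    # predefined component itself unproducible: no relation
                    upstream_cache[p] = set()
            if c in upstream_cache[p]:
                upstream = True
                break
        categories[c] = "upstream_of_predefined" if upstream else "unique"
    return categories


def write_category_tsv(categories: Dict[str, str], path) -> None:
    import pandas as pd

    rows = sorted(categories.items())
    pd.DataFrame(rows, columns=["component_id", "category"]).to_csv(
        path, sep="\t", index=False
    )


def write_precursor_tsv(precursors: Dict[str, Set[str]], path) -> None:
    """``precursors`` maps biomass component -> its essential precursors."""
    import pandas as pd

    rows = [
        (comp, pre)
        for comp in sorted(precursors)
        for pre in sorted(precursors[comp])
    ]
    pd.DataFrame(rows, columns=["biomass_component", "precursor_id"]).to_csv(
        path, sep="\t", index=False
    )
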