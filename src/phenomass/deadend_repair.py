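"""Dead-end by-product detection and biomass augmentation.

The blocking analysis adds sinks for every metabolite, so a biomass selected
from it can demand components whose synthesis co-produces species with no
consuming route. Without sinks, flux balance then predicts no growth for
experiments the selection IP matched as growing. This module finds, per
growth experiment, the minimal set of sinks that must stay active for the
biomass to carry flux — those are the dead-end by-products — and augments
the biomass so it consumes them itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint

from phenomass import _solver
from phenomass.biomass_select import BiomassProposal
from phenomass.errors import PhenomassError, UsageError
from phenomass.growth_prediction import build_biomass_reaction
from phenomass.model_io import (
    MediaCondition,
    MetabolicNetwork,
    U_SINK,
    apply_knockout,
    apply_media,
    prepare_for_blocking,
    sink_id,
)
from phenomass.phenotype_lists import ExperimentRecord

logger = logging.getLogger(__name__)

#: Minimum biomass flux forced during by-product detection.
DEFAULT_EPS = 0.001

BIOMASS_RXN_ID = "BIOMASS_proposed"


@dataclass
class DeadEndReport:
    experiment_id: str
    eps: float
    active_sinks: FrozenSet[str]
    alternates: List[FrozenSet[str]] = field(default_factory=list)
    fixable: bool = True

    def __post_init__(self):
        if self.eps <= 0:
            raise UsageError("biomass flux threshold eps must be positive")


def _experiment_network(
    net: MetabolicNetwork,
    media: MediaCondition,
    experiment: ExperimentRecord,
    biomass_components: Iterable[str],
    coefficient: float = 1.0,
) -> MetabolicNetwork:
    """Experiment state: predefined biomass removed, media and knockout
    applied, candidate biomass reaction installed, sinks for all metabolites.

    Detection uses a unit biomass coefficient: qualitative growth calls are
    invariant to scaling it, and unit coefficients keep the forced by-product
    fluxes at eps scale, well above solver feasibility tolerances (at the
    reporting coefficient 0.0002 they would be ~2e-7 and below tolerance).
    """
    prepared = prepare_for_blocking(net)  # also removes predefined biomass
    staged = apply_knockout(apply_media(prepared, media), experiment.deleted_genes)
    biomass_rxn = build_biomass_reaction(
        set(biomass_components), coefficient=coefficient, reaction_id=BIOMASS_RXN_ID
    )
    reactions = list(staged.reactions) + [biomass_rxn]
    return staged.replace_reactions(reactions, biomass_reaction_ids=[BIOMASS_RXN_ID])


def deadend_byproducts(
    net: MetabolicNetwork,
    biomass_components: Iterable[str],
    experiment: ExperimentRecord,
    media: MediaCondition,
    eps: float = DEFAULT_EPS,
    big_M: float = U_SINK,
    n_alternates: int = 0,
) -> DeadEndReport:
    """Minimal set of sinks that must be active for biomass flux >= eps.

    Solves a MILP over the experiment's network: binary ``s_i`` activates
    sink ``x_i`` via ``x_i <= big_M * s_i``; the objective minimizes
    ``sum s_i`` subject to mass balance and ``v_biomass >= eps``. Nonzero
    sinks at optimum are dead-end by-products of the required components.
    Alternates are found by pinning one reported sink to zero and re-solving.
    """
    work = _experiment_network(net, media, experiment, biomass_components)
    S, met_ids, rxn_ids = work.stoichiometric_matrix()
    n_r, n_m = len(rxn_ids), len(met_ids)
    rxn_pos = {r: j for j, r in enumerate(rxn_ids)}
    sink_cols = np.array([rxn_pos[sink_id(m)] for m in met_ids])

    lb_v, ub_v = work.flux_bounds(rxn_ids)
    lb_v[rxn_pos[BIOMASS_RXN_ID]] = eps
    lb = np.concatenate([lb_v, np.zeros(n_m)])
    ub = np.concatenate([ub_v, np.ones(n_m)])
    integrality = np.concatenate([np.zeros(n_r), np.ones(n_m)])

    mass_balance = LinearConstraint(
        sp.hstack([S, sp.csr_matrix((n_m, n_m))]).tocsr(), 0.0, 0.0
    )
    pick_x = sp.csr_matrix((np.ones(n_m), (np.arange(n_m), sink_cols)), shape=(n_m, n_r))
    link = LinearConstraint(
        sp.hstack([pick_x, -big_M * sp.identity(n_m, format="csr")]).tocsr(),
        -np.inf, 0.0,
    )
    constraints = [mass_balance, link] + _solver.coupling_constraints(
        work, rxn_ids, n_extra=n_m
    )
    c = np.concatenate([np.zeros(n_r), np.ones(n_m)])

    def solve(forced_zero: Set[str]):
        lo, hi = lb.copy(), ub.copy()
        for m in forced_zero:
            hi[n_r + met_ids.index(m)] = 0.0
        res = _solver.solve_milp(c, constraints, integrality, lo, hi, maximize=False)
        if not res.feasible:
            return None
        active = frozenset(
            m for k, m in enumerate(met_ids) if res.x[n_r + k] > 0.5
            and res.x[sink_cols[k]] > 1e-9
        )
        return active

    primary = solve(set())
    if primary is None:
        logger.warning(
            "experiment %s: growth unattainable even with all sinks open",
            experiment.id,
        )
        return DeadEndReport(
            experiment_id=experiment.id, eps=eps,
            active_sinks=frozenset(), fixable=False,
        )
    alternates: List[FrozenSet[str]] = []
    for m in sorted(primary)[: n_alternates]:
        alt = solve({m})
        if alt is not None and alt != primary and alt not in alternates:
            alternates.append(alt)
    return DeadEndReport(
        experiment_id=experiment.id, eps=eps,
        active_sinks=primary, alternates=alternates,
    )


def augment_biomass(
    proposal: BiomassProposal,
    experiments: Sequence[ExperimentRecord],
    net: MetabolicNetwork,
    media_defs: Mapping[str, MediaCondition],
    eps: float = DEFAULT_EPS,
    max_rounds: int = 10,
) -> Tuple[BiomassProposal, Dict[str, FrozenSet[str]]]:
    """Add dead-end by-products to the biomass until every matched growth
    experiment supports biomass flux without auxiliary sinks.

    Only experiments the selection IP matched as growing are repaired
    (unmatched ones are accepted mispredictions). Returns the augmented
    proposal and an audit trail mapping experiment id -> metabolites added
    on its account.
    """
    matched = {e for e in proposal.matched_g}
    growth_experiments = sorted(
        (rec for rec in experiments if rec.id in matched), key=lambda r: r.id
    )
    components = set(proposal.components)
    audit: Dict[str, FrozenSet[str]] = {}
    for round_no in range(max_rounds):
        new: Set[str] = set()
        for rec in growth_experiments:
            report = deadend_byproducts(
                net, components, rec, media_defs[rec.media_id], eps=eps
            )
            if report.active_sinks:
                audit[rec.id] = report.active_sinks
                new |= set(report.active_sinks)
        if not new:
            break
        components |= new
    else:
        residual = sorted(audit)
        raise PhenomassError(
            f"dead-end repair did not converge in {max_rounds} rounds; "
            f"residual experiments: {residual}"
        )
    augmented = BiomassProposal(
        components=frozenset(components),
        agreement=proposal.agreement,
        matched_ng=proposal.matched_ng,
        matched_g=proposal.matched_g,
        secondary_objective=proposal.secondary_objective,
        em_pseudo_experiments=proposal.em_pseudo_experiments,
    )
    return augmented, audit


def write_deadend_tsv(reports: Sequence[DeadEndReport], path) -> None:
    import pandas as pd

    rows = []
    for rep in reports:
        for m in sorted(rep.active_sinks):
            rows.append((rep.experiment_id, m, "byproduct", 0))
        for idx, alt in enumerate(rep.alternates, start=1):
            for m in sorted(alt):
                rows.append((rep.experiment_id, m, "byproduct", idx))
    pd.DataFrame(
        rows,
        columns=["experiment_id", "metabolite_id", "role", "alternate_set_index"],
    ).to_csv(path, sep="\t", index=False)
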