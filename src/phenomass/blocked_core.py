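"""Net-production-blocked metabolite detection.

A metabolite is *net-production blocked* in a strain/condition when no
steady-state flux distribution can push a minimum amount of it out of the
system through its dedicated sink — even if internal flux through the
metabolite (e.g. around a closed cycle) is feasible. Because sinks actively
remove mass, cycle members without an external supply route are blocked:
mass balance over the cycle forces the sum of their sink fluxes to zero.

Two equivalent routes are provided:

* :func:`producible_set_milp` — a single MILP maximizing the number of
  producible indicators, in the spirit of gap-finding formulations;
* :func:`producible_oracle` — one LP per metabolite maximizing its sink
  flux. This is the defining brute-force criterion and the reference
  the MILP is validated against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint

from phenomass import _solver
from phenomass.errors import ConfigurationError, SolverError, UsageError
from phenomass.model_io import MetabolicNetwork, sink_id

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockingConfig:
    """Thresholds for producibility decisions.

    ``v_min`` is the minimum net production (sink flux) a metabolite must
    sustain to count as producible; ``big_M`` links the sink flux to its
    binary indicator and must dominate any attainable sink flux.
    """

    v_min: float = 0.0005
    big_M: float = 1000.0
    lp_tolerance: float = 1e-9
    integrality_tolerance: float = 1e-7

    def __post_init__(self):
        if not (0 < self.v_min < self.big_M):
            raise ConfigurationError("require 0 < v_min < big_M")
        if self.lp_tolerance >= self.v_min / 10:
            raise ConfigurationError("LP tolerance must be below v_min/10")
        if self.v_min / self.integrality_tolerance < 50:
            raise ConfigurationError("v_min must exceed 50x integrality tolerance")


@dataclass(frozen=True)
class ProducibilityResult:
    """Partition of a network's metabolites into producible and blocked."""

    strain: str
    media_id: str
    producible: FrozenSet[str]
    blocked: FrozenSet[str]
    witness_fluxes: Optional[Dict[str, float]] = field(default=None, compare=False)

    def __post_init__(self):
        if self.producible & self.blocked:
            raise UsageError("producible and blocked sets overlap")

    @property
    def universe(self) -> FrozenSet[str]:
        return self.producible | self.blocked


def _sink_columns(net: MetabolicNetwork, met_ids, rxn_ids):
    rxn_pos = {r: j for j, r in enumerate(rxn_ids)}
    cols = []
    for m in met_ids:
        sid = sink_id(m)
        if sid not in rxn_pos:
            raise UsageError(
                f"network lacks sink for {m!r}; call prepare_for_blocking first"
            )
        cols.append(rxn_pos[sid])
    return np.array(cols)


def producible_set_milp(
    net: MetabolicNetwork,
    cfg: BlockingConfig = BlockingConfig(),
    strain: str = "wild-type",
    media_id: str = "",
) -> ProducibilityResult:
    """Solve the producibility MILP: maximize the number of metabolites whose
    sinks carry at least ``v_min`` flux simultaneously.

    Variables are fluxes ``v`` (one per reaction, sinks included) and binary
    indicators ``z`` (one per metabolite); constraints are steady state
    ``S v = 0``, flux bounds, any network coupling constraints, and the
    linking pair ``v_min * z_i <= x_i <= big_M * z_i`` where ``x_i`` is the
    sink flux of metabolite ``i``.
    """
    S, met_ids, rxn_ids = net.stoichiometric_matrix()
    n_r, n_m = len(rxn_ids), len(met_ids)
    sink_cols = _sink_columns(net, met_ids, rxn_ids)

    lb_v, ub_v = net.flux_bounds(rxn_ids)
    lb = np.concatenate([lb_v, np.zeros(n_m)])
    ub = np.concatenate([ub_v, np.ones(n_m)])
    integrality = np.concatenate([np.zeros(n_r), np.ones(n_m)])

    mass_balance = LinearConstraint(
        sp.hstack([S, sp.csr_matrix((n_m, n_m))]).tocsr(), 0.0, 0.0
    )
    # x_i - v_min z_i >= 0 and x_i - big_M z_i <= 0
    pick_x = sp.csr_matrix(
        (np.ones(n_m), (np.arange(n_m), sink_cols)), shape=(n_m, n_r)
    )
    eye = sp.identity(n_m, format="csr")
    lower_link = LinearConstraint(
        sp.hstack([pick_x, -cfg.v_min * eye]).tocsr(), 0.0, np.inf
    )
    upper_link = LinearConstraint(
        sp.hstack([pick_x, -cfg.big_M * eye]).tocsr(), -np.inf, 0.0
    )
    constraints = [mass_balance, lower_link, upper_link]
    constraints += _solver.coupling_constraints(net, rxn_ids, n_extra=n_m)

    c = np.concatenate([np.zeros(n_r), np.ones(n_m)])
    res = _solver.solve_milp(c, constraints, integrality, lb, ub, maximize=True)
    if not res.feasible:
        raise SolverError(
            "producibility MILP infeasible; the all-zero flux vector should "
            "always be feasible — check coupling constraints"
        )
    z = res.x[n_r:]
    producible = frozenset(m for m, zi in zip(met_ids, z) if zi > 0.5)
    blocked = frozenset(met_ids) - producible
    witnesses = {r: float(res.x[j]) for j, r in enumerate(rxn_ids)}
    return ProducibilityResult(
        strain=strain,
        media_id=media_id,
        producible=producible,
        blocked=blocked,
        witness_fluxes=witnesses,
    )


def producible_oracle(
    net: MetabolicNetwork,
    cfg: BlockingConfig = BlockingConfig(),
    strain: str = "wild-type",
    media_id: str = "",
) -> ProducibilityResult:
    """Per-metabolite LP oracle: metabolite ``i`` is producible iff
    ``max x_i`` over the steady-state polytope reaches ``v_min``."""
    S, met_ids, rxn_ids = net.stoichiometric_matrix()
    n_r, n_m = len(rxn_ids), len(met_ids)
    sink_cols = _sink_columns(net, met_ids, rxn_ids)
    lb, ub = net.flux_bounds(rxn_ids)
    coupling = _solver.coupling_constraints(net, rxn_ids)
    A_ub = b_ub = None
    A_eq_extra = []
    b_lo, b_hi = [], []
    for lc in coupling:
        A_eq_extra.append(lc.A)
        b_lo.append(np.atleast_1d(lc.lb))
        b_hi.append(np.atleast_1d(lc.ub))

    producible = set()
    zero = np.zeros(n_m)
    for i, m in enumerate(met_ids):
        c = np.zeros(n_r)
        c[sink_cols[i]] = 1.0
        A_eq, b_eq = S, zero
        if A_eq_extra:
            # fold equality couplings in; inequality couplings become A_ub rows
            rows_eq, rhs_eq = [S], [zero]
            rows_ub, lo_ub, hi_ub = [], [], []
            for A, lo, hi in zip(A_eq_extra, b_lo, b_hi):
                if np.all(lo == hi):
                    rows_eq.append(A)
                    rhs_eq.append(lo)
                else:
                    rows_ub.append(A)
                    lo_ub.append(lo)
                    hi_ub.append(hi)
            A_eq = sp.vstack(rows_eq).tocsr()
            b_eq = np.concatenate(rhs_eq)
            if rows_ub:
                blocks, rhs = [], []
                for A, lo, hi in zip(rows_ub, lo_ub, hi_ub):
                    if np.all(np.isfinite(hi)):
                        blocks.append(A)
                        rhs.append(hi)
                    if np.all(np.isfinite(lo)):
                        blocks.append(-A)
                        rhs.append(-lo)
                A_ub = sp.vstack(blocks).tocsr()
                b_ub = np.concatenate(rhs)
        res = _solver.solve_lp(c, A_eq, b_eq, lb, ub, A_ub=A_ub, b_ub=b_ub,
                               maximize=True)
        if res.feasible and res.objective >= cfg.v_min - cfg.lp_tolerance:
            producible.add(m)
    blocked = frozenset(met_ids) - producible
    return ProducibilityResult(
        strain=strain, media_id=media_id,
        producible=frozenset(producible), blocked=blocked,
    )


def producibility(
    net: MetabolicNetwork,
    cfg: BlockingConfig = BlockingConfig(),
    strain: str = "wild-type",
    media_id: str = "",
    method: str = "milp",
    cross_check: bool = False,
) -> ProducibilityResult:
    """Compute the producibility partition by the requested method.

    With ``cross_check=True`` the MILP result is compared against the LP
    oracle; on disagreement the oracle partition is returned (the oracle
    defines correctness) and the discrepancy is logged.
    """
    if method == "oracle":
        return producible_oracle(net, cfg, strain, media_id)
    result = producible_set_milp(net, cfg, strain, media_id)
    if cross_check:
        ref = producible_oracle(net, cfg, strain, media_id)
        if ref.blocked != result.blocked:
            logger.error(
                "MILP/oracle producibility disagreement (strain=%s media=%s); "
                "falling back to oracle: milp-only blocked=%s oracle-only blocked=%s",
                strain, media_id,
                sorted(result.blocked - ref.blocked),
                sorted(ref.blocked - result.blocked),
            )
            return ref
    return result


def candidate_blocked(wt: ProducibilityResult, mut: ProducibilityResult) -> set:
    """Mutant-specific blocked metabolites: blocked in the mutant but not in
    the wild type. These are the candidate biomass components (or
    counter-evidence) for the mutant's growth phenotype."""
    if wt.media_id != mut.media_id:
        raise UsageError(
            f"media mismatch: wild type {wt.media_id!r} vs mutant {mut.media_id!r}"
        )
    if wt.universe != mut.universe:
        raise UsageError("wild type and mutant cover different metabolite universes")
    return set(mut.blocked - wt.blocked)


def write_producibility_tsv(results, path) -> None:
    """Serialize partitions as TSV (metabolite_id, strain, media, status)."""
    import pandas as pd

    rows = []
    for res in results:
        for m in sorted(res.producible):
            rows.append((m, res.strain, res.media_id, "producible"))
        for m in sorted(res.blocked):
            rows.append((m, res.strain, res.media_id, "blocked"))
    pd.DataFrame(rows, columns=["metabolite_id", "strain", "media", "status"]).to_csv(
        path, sep="\t", index=False
    )
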