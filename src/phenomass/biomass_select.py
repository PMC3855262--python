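"""Integer programs selecting biomass components from phenotype evidence.

The de-novo problem: choose a set of component indicators ``w_i`` maximizing
the weighted number of experiments the resulting biomass agrees with. A
no-growth experiment ``e`` is matched (``n_e = 1``) when at least one of its
include-list metabolites is a component; a growth experiment is matched
(``g_e = 1``) when none of its exclude-list metabolites is. Once the maximal
agreement ``FixObj`` is known, a secondary selection at fixed agreement
either minimizes component count (minimal mode) or minimizes a weighted sum
that prefers field-typical components such as amino acids and currency
metabolites (weighted mode).

The modification problem starts from a predefined component set μ and, at
maximal agreement, removes as few μ members as possible, then adds as few
new components as possible.

Analytically measured components (the EM set) enter as soft pseudo
no-growth experiments whose include list is the single metabolite, so the
phenotype data can still overrule a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint

from phenomass import _solver
from phenomass.errors import UsageError
from phenomass.phenotype_lists import IncludeExcludeLists

EM_PREFIX = "EM::"

#: slack used when fixing an integral objective value in a follow-up solve
_OBJ_TOL = 1e-6


@dataclass(frozen=True)
class WeightScheme:
    """Secondary-objective weights over candidate components.

    In weighted mode, metabolites in ``preferred`` receive a negative weight
    so they are pulled into the biomass when interchangeable alternatives
    exist; all others cost ``default_weight``. Minimal mode ignores
    ``preferred`` and charges every component equally, yielding a
    minimum-cardinality biomass.
    """

    preferred: FrozenSet[str] = frozenset()
    preferred_weight: float = -1.0
    default_weight: float = 1.0
    mode: str = "minimal"

    def __post_init__(self):
        if self.mode not in ("weighted", "minimal"):
            raise UsageError(f"unknown weight mode {self.mode!r}")
        if self.mode == "weighted" and not (
            self.preferred_weight < 0 < self.default_weight
        ):
            raise UsageError("weighted mode requires preferred_weight < 0 < default_weight")

    def cost(self, metabolite_id: str) -> float:
        if self.mode == "weighted" and metabolite_id in self.preferred:
            return self.preferred_weight
        return self.default_weight


@dataclass(frozen=True)
class BiomassProposal:
    components: FrozenSet[str]
    agreement: float
    matched_ng: FrozenSet[str]
    matched_g: FrozenSet[str]
    secondary_objective: Optional[float] = None
    em_pseudo_experiments: Tuple[str, ...] = ()


@dataclass(frozen=True)
class ModificationProposal:
    added: FrozenSet[str]
    removed: FrozenSet[str]
    unmodified: FrozenSet[str]
    agreement: float
    matched_ng: FrozenSet[str]
    matched_g: FrozenSet[str]

    @property
    def final_components(self) -> FrozenSet[str]:
        return self.unmodified | self.added


class SelectionIP:
    """Shared MILP skeleton over membership indicators and agreement vars.

    Variable layout: ``[m (binary, one per candidate metabolite),
    n (one per NG experiment), g (one per G experiment)]``. The agreement
    variables may be declared continuous in [0, 1]: with binary membership
    the maximization drives them to integral values.
    """

    def __init__(
        self,
        lists: IncludeExcludeLists,
        em: Iterable[str] = (),
        em_weight: float = 1.0,
        extra_candidates: Iterable[str] = (),
    ):
        em = sorted(set(em))
        self.em_ids = [EM_PREFIX + m for m in em]
        self.universe: List[str] = sorted(
            set(lists.universe) | set(em) | set(extra_candidates)
        )
        self.met_pos = {m: i for i, m in enumerate(self.universe)}
        self.ng: List[Tuple[str, Set[str], float]] = [
            (e, set(lists.include[e]), lists.weight(e)) for e in sorted(lists.include)
        ] + [(EM_PREFIX + m, {m}, em_weight) for m in em]
        self.g: List[Tuple[str, Set[str], float]] = [
            (e, set(lists.exclude[e]), lists.weight(e)) for e in sorted(lists.exclude)
        ]
        self.n_m = len(self.universe)
        self.n_ng = len(self.ng)
        self.n_g = len(self.g)
        self.n_vars = self.n_m + self.n_ng + self.n_g
        self._base_constraints = self._build_constraints()

    # -- construction ------------------------------------------------------

    def _build_constraints(self) -> List[LinearConstraint]:
        cons = []
        if self.n_ng:
            rows, cols, vals = [], [], []
            for k, (_, include, _) in enumerate(self.ng):
                rows.append(k)
                cols.append(self.n_m + k)
                vals.append(1.0)
                for m in include:
                    rows.append(k)
                    cols.append(self.met_pos[m])
                    vals.append(-1.0)
            A = sp.csr_matrix((vals, (rows, cols)), shape=(self.n_ng, self.n_vars))
            cons.append(LinearConstraint(A, -np.inf, 0.0))  # n_e <= sum w_i
        pair_rows = []
        for k, (_, exclude, _) in enumerate(self.g):
            for m in sorted(exclude):
                pair_rows.append((k, self.met_pos[m]))
        if pair_rows:
            rows, cols, vals = [], [], []
            for r, (k, mpos) in enumerate(pair_rows):
                rows += [r, r]
                cols += [self.n_m + self.n_ng + k, mpos]
                vals += [1.0, 1.0]
            A = sp.csr_matrix((vals, (rows, cols)), shape=(len(pair_rows), self.n_vars))
            cons.append(LinearConstraint(A, -np.inf, 1.0))  # g_e + w_i <= 1
        return cons

    def agreement_vector(self) -> np.ndarray:
        c = np.zeros(self.n_vars)
        for k, (_, _, wgt) in enumerate(self.ng):
            c[self.n_m + k] = wgt
        for k, (_, _, wgt) in enumerate(self.g):
            c[self.n_m + self.n_ng + k] = wgt
        return c

    def membership_cost_vector(self, cost) -> np.ndarray:
        c = np.zeros(self.n_vars)
        for m, i in self.met_pos.items():
            c[i] = cost(m)
        return c

    # -- solving -----------------------------------------------------------

    def solve(
        self,
        c: np.ndarray,
        maximize: bool,
        fixed: Optional[Mapping[str, int]] = None,
        extra: Sequence[LinearConstraint] = (),
    ) -> _solver.SolveResult:
        lb = np.zeros(self.n_vars)
        ub = np.ones(self.n_vars)
        if fixed:
            for m, val in fixed.items():
                lb[self.met_pos[m]] = ub[self.met_pos[m]] = float(val)
        integrality = np.concatenate(
            [np.ones(self.n_m), np.zeros(self.n_ng + self.n_g)]
        )
        return _solver.solve_milp(
            c,
            list(self._base_constraints) + list(extra),
            integrality,
            lb,
            ub,
            maximize=maximize,
        )

    def fix_value_constraint(self, c: np.ndarray, value: float) -> LinearConstraint:
        return LinearConstraint(
            sp.csr_matrix(c.reshape(1, -1)), value - _OBJ_TOL, value + _OBJ_TOL
        )

    def components_from(self, x: np.ndarray) -> FrozenSet[str]:
        return frozenset(
            m for m, i in self.met_pos.items() if x[i] > 0.5
        )

    # -- evaluation --------------------------------------------------------

    def evaluate(self, components: Set[str]) -> Tuple[float, FrozenSet[str], FrozenSet[str]]:
        """Weighted agreement of a concrete component set, with the matched
        NG / G experiment ids."""
        matched_ng, matched_g, total = set(), set(), 0.0
        for e, include, wgt in self.ng:
            if components & include:
                matched_ng.add(e)
                total += wgt
        for e, exclude, wgt in self.g:
            if not (components & exclude):
                matched_g.add(e)
                total += wgt
        return total, frozenset(matched_ng), frozenset(matched_g)


def _lexicographic_fix(
    ip: SelectionIP,
    extra: List[LinearConstraint],
    candidates: Sequence[str],
    start: np.ndarray,
    prefixed: Optional[Dict[str, int]] = None,
) -> FrozenSet[str]:
    """Deterministic tie-break: walk candidate metabolites in sorted id
    order, keeping each in the set whenever some optimal solution (under the
    already-fixed objectives in ``extra``) contains it. Yields the
    lexicographically smallest optimal component set."""
    fixed: Dict[str, int] = dict(prefixed or {})
    current = ip.components_from(start)
    zero = np.zeros(ip.n_vars)
    for m in sorted(candidates):
        if m in fixed:
            continue
        if m in current:
            fixed[m] = 1
            continue
        trial = dict(fixed)
        trial[m] = 1
        res = ip.solve(zero, maximize=False, fixed=trial, extra=extra)
        if res.feasible:
            fixed[m] = 1
            current = ip.components_from(res.x)
        else:
            fixed[m] = 0
    return frozenset(m for m, v in fixed.items() if v == 1)


def max_agreement(
    lists: IncludeExcludeLists,
    em: Iterable[str] = (),
    em_weight: float = 1.0,
) -> Tuple[float, FrozenSet[str]]:
    """Maximal achievable weighted agreement and one optimal component set.

    Returns ``(FixObj, witness)``; the witness is an arbitrary optimum, use
    :func:`select_de_novo` for a canonical one.
    """
    ip = SelectionIP(lists, em, em_weight)
    if ip.n_vars == 0 or (ip.n_ng == 0 and ip.n_g == 0):
        return 0.0, frozenset()
    res = ip.solve(ip.agreement_vector(), maximize=True)
    return float(round(res.objective, 9)), ip.components_from(res.x)


def select_de_novo(
    lists: IncludeExcludeLists,
    em: Iterable[str] = (),
    fix_obj: Optional[float] = None,
    scheme: WeightScheme = WeightScheme(),
    em_weight: float = 1.0,
    tie_break: bool = True,
) -> BiomassProposal:
    """Propose a biomass de novo: at agreement fixed to ``fix_obj``, minimize
    the scheme's component cost; ties broken to the lexicographically
    smallest component set."""
    ip = SelectionIP(lists, em, em_weight)
    if ip.n_m == 0:
        return BiomassProposal(
            components=frozenset(), agreement=0.0,
            matched_ng=frozenset(), matched_g=frozenset(),
            secondary_objective=0.0,
        )
    agree_c = ip.agreement_vector()
    if fix_obj is None:
        fix_obj, _ = max_agreement(lists, em, em_weight)
    extra = [ip.fix_value_constraint(agree_c, fix_obj)]
    cost_c = ip.membership_cost_vector(scheme.cost)
    res = ip.solve(cost_c, maximize=False, extra=extra)
    if not res.feasible:
        raise UsageError(f"agreement value {fix_obj} is not attainable (stale FixObj?)")
    secondary = float(round(res.objective, 9))
    components = ip.components_from(res.x)
    if tie_break:
        extra2 = extra + [ip.fix_value_constraint(cost_c, secondary)]
        components = _lexicographic_fix(ip, extra2, ip.universe, res.x)
    agreement, matched_ng, matched_g = ip.evaluate(set(components))
    return BiomassProposal(
        components=components,
        agreement=agreement,
        matched_ng=matched_ng,
        matched_g=matched_g,
        secondary_objective=secondary,
        em_pseudo_experiments=tuple(ip.em_ids),
    )


def modify_biomass(
    lists: IncludeExcludeLists,
    mu: Iterable[str],
    em: Iterable[str] = (),
    scheme: WeightScheme = WeightScheme(),
    em_weight: float = 1.0,
    tie_break: bool = True,
) -> ModificationProposal:
    """Modify a predefined component set μ against the evidence.

    Lexicographic objective: (1) maximize weighted agreement; (2) at that
    agreement remove as few μ members as possible; (3) additionally add as
    few non-μ members as possible. Membership of i ∈ μ is ``1 - y_i``
    (``y_i`` the removal indicator); membership of i ∉ μ is the addition
    indicator ``w_i``.
    """
    mu = frozenset(mu)
    if not mu:
        raise UsageError("modify_biomass requires a nonempty predefined set")
    ip = SelectionIP(lists, em, em_weight, extra_candidates=mu)
    agree_c = ip.agreement_vector()
    res1 = ip.solve(agree_c, maximize=True)
    fix_obj = float(round(res1.objective, 9))
    extra = [ip.fix_value_constraint(agree_c, fix_obj)]

    keep_c = ip.membership_cost_vector(lambda m: 1.0 if m in mu else 0.0)
    res2 = ip.solve(keep_c, maximize=True, extra=extra)  # max kept = min removed
    kept = float(round(res2.objective, 9))
    extra.append(ip.fix_value_constraint(keep_c, kept))

    add_c = ip.membership_cost_vector(lambda m: 0.0 if m in mu else scheme.cost(m))
    res3 = ip.solve(add_c, maximize=False, extra=extra)
    additions_cost = float(round(res3.objective, 9))
    members = ip.components_from(res3.x)
    if tie_break:
        extra2 = extra + [ip.fix_value_constraint(add_c, additions_cost)]
        members = _lexicographic_fix(ip, extra2, ip.universe, res3.x)

    added = frozenset(members - mu)
    unmodified = frozenset(members & mu)
    removed = frozenset(mu - members)
    agreement, matched_ng, matched_g = ip.evaluate(set(members))
    return ModificationProposal(
        added=added,
        removed=removed,
        unmodified=unmodified,
        agreement=agreement,
        matched_ng=matched_ng,
        matched_g=matched_g,
    )
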