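"""Qualitative growth prediction by flux balance analysis.

A proposed component set becomes a biomass pseudo-reaction draining each
component at a small uniform coefficient (default 0.0002 — the composition
is qualitative, so only blockedness matters, not yield). Growth is called
when the FBA maximum of that reaction's flux exceeds a threshold chosen far
below any flux a truly open pathway can carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from phenomass import _solver
from phenomass.errors import DataError, UsageError
from phenomass.model_io import (
    MediaCondition,
    MetabolicNetwork,
    ReactionRecord,
    apply_knockout,
    apply_media,
)
from phenomass.phenotype_lists import ExperimentRecord, GROWTH, NO_GROWTH

DEFAULT_BIOMASS_COEFFICIENT = 0.0002
DEFAULT_GROWTH_FLUX_THRESHOLD = 1e-6


def build_biomass_reaction(
    components: Set[str],
    coefficient: float = DEFAULT_BIOMASS_COEFFICIENT,
    reaction_id: str = "BIOMASS_proposed",
    sink_role: Iterable[str] = (),
) -> ReactionRecord:
    """Irreversible drain consuming each component at ``|coefficient|``.

    ``sink_role`` tags metabolites that entered as dead-end by-products
    rather than proposed components (same stoichiometry, distinct semantics
    kept for reporting).
    """
    if not components:
        raise UsageError("cannot build a biomass reaction from zero components")
    stoich = {m: -abs(coefficient) for m in sorted(components)}
    name = "proposed biomass"
    extra = sorted(set(sink_role) & set(components))
    if extra:
        name += f" (sink_role: {','.join(extra)})"
    return ReactionRecord(
        id=reaction_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name=name,
    )


def predict_growth(
    net: MetabolicNetwork,
    biomass_rxn: ReactionRecord,
    experiment: ExperimentRecord,
    media: MediaCondition,
    growth_flux_threshold: float = DEFAULT_GROWTH_FLUX_THRESHOLD,
) -> str:
    """FBA growth call for one experiment.

    Removes any predefined biomass reactions, applies media and knockout,
    installs the candidate biomass reaction (no sinks) and maximizes its
    flux; growth iff the optimum exceeds the threshold.
    """
    biomass_ids = set(net.biomass_reaction_ids)
    stripped = net.replace_reactions(
        [r for r in net.reactions if r.id not in biomass_ids],
        biomass_reaction_ids=[],
    )
    staged = apply_knockout(apply_media(stripped, media), experiment.deleted_genes)
    reactions = list(staged.reactions) + [biomass_rxn]
    work = staged.replace_reactions(reactions, biomass_reaction_ids=[biomass_rxn.id])

    S, met_ids, rxn_ids = work.stoichiometric_matrix()
    lb, ub = work.flux_bounds(rxn_ids)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(biomass_rxn.id)] = 1.0
    coupling = _solver.coupling_constraints(work, rxn_ids)
    A_ub = b_ub = None
    A_eq, b_eq = S, np.zeros(len(met_ids))
    if coupling:
        import scipy.sparse as sp

        eq_rows, eq_rhs, ub_rows, ub_rhs = [S], [b_eq], [], []
        for lc in coupling:
            lo, hi = np.atleast_1d(lc.lb), np.atleast_1d(lc.ub)
            if np.all(lo == hi):
                eq_rows.append(lc.A)
                eq_rhs.append(lo)
            else:
                if np.all(np.isfinite(hi)):
                    ub_rows.append(lc.A)
                    ub_rhs.append(hi)
                if np.all(np.isfinite(lo)):
                    ub_rows.append(-lc.A)
                    ub_rhs.append(-lo)
        A_eq = sp.vstack(eq_rows).tocsr()
        b_eq = np.concatenate(eq_rhs)
        if ub_rows:
            A_ub = sp.vstack(ub_rows).tocsr()
            b_ub = np.concatenate(ub_rhs)
    res = _solver.solve_lp(c, A_eq, b_eq, lb, ub, A_ub=A_ub, b_ub=b_ub, maximize=True)
    if not res.feasible:
        return NO_GROWTH
    return GROWTH if res.objective > growth_flux_threshold else NO_GROWTH


@dataclass
class AgreementReport:
    """Correct-call tabulation per (media condition x phenotype class)."""

    per_category: Dict[Tuple[str, str], Tuple[int, int]]  # (media, class) -> (n, correct)
    records: List[dict] = field(default_factory=list)

    @property
    def n_experiments(self) -> int:
        return sum(n for n, _ in self.per_category.values())

    @property
    def n_correct(self) -> int:
        return sum(c for _, c in self.per_category.values())

    @property
    def percent_agreement(self) -> float:
        n = self.n_experiments
        return 100.0 * self.n_correct / n if n else float("nan")

    def percent(self, media_id: str, phenotype: str) -> float:
        n, c = self.per_category.get((media_id, phenotype), (0, 0))
        return 100.0 * c / n if n else float("nan")

    def as_dataframe(self):
        import pandas as pd

        rows = [
            (media, cls, n, c, 100.0 * c / n if n else float("nan"))
            for (media, cls), (n, c) in sorted(self.per_category.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["media", "phenotype", "n_experiments", "n_correct", "percent"],
        )


def agreement_report(
    predictions: Mapping[str, str],
    experiments: Sequence[ExperimentRecord],
    alternate_predictions: Optional[Mapping[str, str]] = None,
) -> AgreementReport:
    """Tabulate qualitative agreement of predictions with observations.

    With ``alternate_predictions`` supplied (e.g. the predefined biomass next
    to the de-novo one), each record carries both calls and a concordance
    class, enabling the which-variant-mispredicted breakdown.
    """
    per_category: Dict[Tuple[str, str], List[int]] = {}
    records = []
    for rec in sorted(experiments, key=lambda r: r.id):
        if rec.id not in predictions:
            raise DataError(f"missing prediction for experiment {rec.id!r}")
        observed = rec.observed
        predicted = predictions[rec.id]
        key = (rec.media_id, observed)
        per_category.setdefault(key, [0, 0])
        per_category[key][0] += 1
        correct = predicted == observed
        per_category[key][1] += int(correct)
        row = {
            "experiment_id": rec.id,
            "media": rec.media_id,
            "observed": observed,
            "predicted": predicted,
            "concordance": _concordance(observed, predicted),
        }
        if alternate_predictions is not None:
            alt = alternate_predictions.get(rec.id)
            row["predicted_alternate"] = alt
            row["mispredicted_by"] = _mispredicted_by(observed, predicted, alt)
        records.append(row)
    return AgreementReport(
        per_category={k: (n, c) for k, (n, c) in per_category.items()},
        records=records,
    )


def _concordance(observed: str, predicted: str) -> str:
    if observed == GROWTH:
        return "TP" if predicted == GROWTH else "FN"
    return "TN" if predicted == NO_GROWTH else "FP"


def _mispredicted_by(observed: str, primary: str, alternate: Optional[str]) -> str:
    wrong_primary = primary != observed
    wrong_alt = alternate is not None and alternate != observed
    if wrong_primary and wrong_alt:
        return "both"
    if wrong_primary:
        return "primary_only"
    if wrong_alt:
        return "alternate_only"
    return "neither"
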