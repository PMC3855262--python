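"""Include/exclude metabolite lists and evidence-frequency statistics.

Each knockout experiment contributes its mutant-specific blocked metabolites
to an *include* list (no-growth mutants: positive evidence for essentiality)
or an *exclude* list (growing mutants: negative evidence). Mutants with
implausibly large blocked sets (default >100) are filtered out as
uninformative — they usually reflect the loss of an early essential step
such as a carbon transporter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set

from phenomass.blocked_core import (
    BlockingConfig,
    ProducibilityResult,
    candidate_blocked,
    producibility,
)
from phenomass.errors import ConfigurationError, DataError
from phenomass.model_io import (
    MediaCondition,
    MetabolicNetwork,
    apply_knockout,
    apply_media,
    prepare_for_blocking,
)

logger = logging.getLogger(__name__)

GROWTH = "G"
NO_GROWTH = "NG"

#: Fitness score below which a mutant is called no-growth.
DEFAULT_FITNESS_THRESHOLD = -1.0

#: Experiments with more candidate blocked metabolites than this are dropped.
DEFAULT_FILTER_MAX = 100


@dataclass(frozen=True)
class ExperimentRecord:
    """One knockout growth experiment."""

    id: str
    deleted_genes: FrozenSet[str]
    media_id: str
    observed: Optional[str] = None  # "G" or "NG"
    fitness: Optional[float] = None
    weight: float = 1.0

    def __post_init__(self):
        if self.weight <= 0:
            raise DataError(f"experiment {self.id!r}: weight must be positive")
        if self.observed is not None and self.observed not in (GROWTH, NO_GROWTH):
            raise DataError(
                f"experiment {self.id!r}: observed must be 'G' or 'NG', "
                f"got {self.observed!r}"
            )


def classify_phenotype(
    rec: ExperimentRecord, fitness_threshold: float = DEFAULT_FITNESS_THRESHOLD
) -> str:
    """Qualitative growth call: fitness below the threshold means no growth.

    An explicit observed phenotype overrides the fitness score. A fitness
    exactly at the threshold is called growth (the strict-inequality
    convention leaves the tie undefined; ties are logged).
    """
    if rec.observed is not None:
        return rec.observed
    if rec.fitness is None:
        raise DataError(f"experiment {rec.id!r} has neither phenotype nor fitness")
    if rec.fitness == fitness_threshold:
        logger.warning(
            "experiment %s: fitness exactly at threshold %s, calling growth",
            rec.id, fitness_threshold,
        )
        return GROWTH
    return NO_GROWTH if rec.fitness < fitness_threshold else GROWTH


@dataclass
class IncludeExcludeLists:
    """Per-experiment candidate blocked sets split by observed phenotype."""

    include: Dict[str, Set[str]]  # experiment id -> metabolites (NG experiments)
    exclude: Dict[str, Set[str]]  # experiment id -> metabolites (G experiments)
    filtered_out: Set[str] = field(default_factory=set)
    weights: Dict[str, float] = field(default_factory=dict)
    wild_type_blocked: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.include) & set(self.exclude)
        if overlap:
            raise DataError(f"experiments in both include and exclude: {sorted(overlap)}")

    @property
    def universe(self) -> Set[str]:
        u: Set[str] = set()
        for mets in self.include.values():
            u |= mets
        for mets in self.exclude.values():
            u |= mets
        return u

    def weight(self, experiment_id: str) -> float:
        return self.weights.get(experiment_id, 1.0)


def merge_replicates(experiments: Sequence[ExperimentRecord]) -> List[ExperimentRecord]:
    """Merge records with identical knockouts, media and phenotype into one
    record with summed weight."""
    merged: Dict[tuple, ExperimentRecord] = {}
    for rec in experiments:
        key = (rec.deleted_genes, rec.media_id, rec.observed)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(prev, weight=prev.weight + rec.weight)
        else:
            merged[key] = rec
    return [merged[k] for k in sorted(merged, key=lambda k: merged[k].id)]


def keio_essential_records(
    gene_ids: Sequence[str], media_id: str, id_prefix: str = "essential"
) -> List[ExperimentRecord]:
    """Build no-growth records for a genome-wide essential-gene list (each
    gene a single-knockout NG experiment under the given condition)."""
    return [
        ExperimentRecord(
            id=f"{id_prefix}_{g}",
            deleted_genes=frozenset([g]),
            media_id=media_id,
            observed=NO_GROWTH,
        )
        for g in sorted(set(gene_ids))
    ]


def build_lists(
    experiments: Sequence[ExperimentRecord],
    net: MetabolicNetwork,
    media_defs: Mapping[str, MediaCondition],
    cfg: BlockingConfig = BlockingConfig(),
    filter_max: int = DEFAULT_FILTER_MAX,
    fitness_threshold: float = DEFAULT_FITNESS_THRESHOLD,
    method: str = "milp",
    merge: bool = True,
) -> IncludeExcludeLists:
    """Compute per-experiment candidate blocked sets and organize them into
    include (NG) and exclude (G) lists.

    Wild-type producibility is computed once per distinct media. Experiments
    whose candidate set exceeds ``filter_max`` are set aside as uninformative.
    NG experiments with empty candidate sets are retained (they are
    unfixable mispredictions and still count against agreement).
    """
    records = []
    for rec in experiments:
        observed = classify_phenotype(rec, fitness_threshold)
        records.append(replace(rec, observed=observed))
    if merge:
        records = merge_replicates(records)

    prepared = prepare_for_blocking(net)
    wt_cache: Dict[str, ProducibilityResult] = {}
    lists = IncludeExcludeLists(include={}, exclude={})
    for rec in sorted(records, key=lambda r: r.id):
        if rec.media_id not in media_defs:
            raise ConfigurationError(
                f"experiment {rec.id!r}: unknown media {rec.media_id!r}"
            )
        if rec.media_id not in wt_cache:
            wt_net = apply_media(prepared, media_defs[rec.media_id])
            wt_cache[rec.media_id] = producibility(
                wt_net, cfg, strain="wild-type", media_id=rec.media_id, method=method
            )
            lists.wild_type_blocked[rec.media_id] = wt_cache[rec.media_id].blocked
        wt = wt_cache[rec.media_id]
        mut_net = apply_knockout(
            apply_media(prepared, media_defs[rec.media_id]), rec.deleted_genes
        )
        mut = producibility(
            mut_net, cfg, strain=rec.id, media_id=rec.media_id, method=method
        )
        candidates = candidate_blocked(wt, mut)
        if len(candidates) > filter_max:
            lists.filtered_out.add(rec.id)
            continue
        lists.weights[rec.id] = rec.weight
        if rec.observed == NO_GROWTH:
            lists.include[rec.id] = candidates
        else:
            if candidates:
                lists.exclude[rec.id] = candidates
            else:
                # a growing mutant with no candidates is already correctly
                # predicted by any biomass; keep it out of the IP
                lists.exclude[rec.id] = set()
    return lists


@dataclass
class FrequencyTable:
    """Evidence counts per metabolite across include and exclude lists."""

    rows: List[tuple]  # (metabolite_id, include_count, exclude_count, difference)

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows,
            columns=["metabolite_id", "include_count", "exclude_count", "difference"],
        )

    def counts(self, metabolite_id: str):
        for m, inc, exc, diff in self.rows:
            if m == metabolite_id:
                return inc, exc, diff
        return 0, 0, 0


def frequency_table(
    lists: IncludeExcludeLists, focus: Optional[Set[str]] = None
) -> FrequencyTable:
    """Count how many experiments support (include) or refute (exclude) each
    metabolite's essentiality; sorted by difference descending, ties by id.

    Metabolites in ``focus`` with zero counts are reported explicitly: they
    have no direct supporting or refuting experimental evidence.
    """
    inc_count: Dict[str, int] = {}
    exc_count: Dict[str, int] = {}
    for mets in lists.include.values():
        for m in mets:
            inc_count[m] = inc_count.get(m, 0) + 1
    for mets in lists.exclude.values():
        for m in mets:
            exc_count[m] = exc_count.get(m, 0) + 1
    universe = set(inc_count) | set(exc_count)
    if focus is not None:
        universe = set(focus)
    rows = []
    for m in universe:
        inc, exc = inc_count.get(m, 0), exc_count.get(m, 0)
        rows.append((m, inc, exc, inc - exc))
    rows.sort(key=lambda r: (-r[3], r[0]))
    return FrequencyTable(rows=rows)


def lists_to_dict(lists: IncludeExcludeLists) -> dict:
    return {
        "include": {e: sorted(v) for e, v in sorted(lists.include.items())},
        "exclude": {e: sorted(v) for e, v in sorted(lists.exclude.items())},
        "filtered_out": sorted(lists.filtered_out),
        "weights": {e: w for e, w in sorted(lists.weights.items())},
        "wild_type_blocked": {
            m: sorted(v) for m, v in sorted(lists.wild_type_blocked.items())
        },
    }


def lists_from_dict(raw: Mapping) -> IncludeExcludeLists:
    return IncludeExcludeLists(
        include={e: set(v) for e, v in raw.get("include", {}).items()},
        exclude={e: set(v) for e, v in raw.get("exclude", {}).items()},
        filtered_out=set(raw.get("filtered_out", [])),
        weights={e: float(w) for e, w in raw.get("weights", {}).items()},
        wild_type_blocked={
            m: frozenset(v) for m, v in raw.get("wild_type_blocked", {}).items()
        },
    )


def write_lists_tsv(lists: IncludeExcludeLists, path) -> None:
    """Serialize lists as TSV (experiment_id, phenotype, metabolite_id)."""
    import pandas as pd

    rows = []
    for e in sorted(lists.include):
        for m in sorted(lists.include[e]):
            rows.append((e, NO_GROWTH, m))
        if not lists.include[e]:
            rows.append((e, NO_GROWTH, ""))
    for e in sorted(lists.exclude):
        for m in sorted(lists.exclude[e]):
            rows.append((e, GROWTH, m))
    pd.DataFrame(rows, columns=["experiment_id", "phenotype", "metabolite_id"]).to_csv(
        path, sep="\t", index=False
    )
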