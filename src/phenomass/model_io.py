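"""Metabolic-network containers and I/O.

The in-memory model is a lightweight, immutable-by-convention set of records
(metabolites, reactions with gene-protein-reaction rules, optional linear
coupling constraints). SBML and COBRA-style JSON files are read and written
through cobrapy; GPR boolean trees are cobrapy ``GPR`` objects, so their
evaluation semantics (AND = enzyme complex, OR = isozymes, empty rule =
always active) match the rest of the COBRA ecosystem.

Conventions enforced here and relied on downstream:

* an exchange reaction has exactly one metabolite in its stoichiometry;
  negative flux through it is uptake, positive flux is secretion;
* sink reactions added by :func:`prepare_for_blocking` are named
  ``SINK_<metabolite id>``, consume one unit of their metabolite and are
  irreversible with bounds ``[0, U_SINK]``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import scipy.sparse as sp
from cobra.core.gene import GPR

from phenomass.errors import ConfigurationError, FormatError, IntegrityError

logger = logging.getLogger(__name__)

#: Upper bound of every added sink reaction, in flux units. Far above any
#: production threshold used for blocking decisions (v_min defaults to 5e-4).
U_SINK = 1000.0

SINK_PREFIX = "SINK_"


def sink_id(metabolite_id: str) -> str:
    """Deterministic sink-reaction id for a metabolite."""
    return SINK_PREFIX + metabolite_id


@dataclass(frozen=True)
class MetaboliteRecord:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self):
        if not self.id:
            raise IntegrityError("metabolite id must be non-empty")


class GPRRule:
    """Boolean gene-presence rule controlling reaction availability.

    Wraps a cobrapy ``GPR`` expression tree. An empty rule means the reaction
    is not gene-associated and is never disabled by knockouts.
    """

    __slots__ = ("_gpr",)

    def __init__(self, rule: str = ""):
        self._gpr = GPR.from_string(rule or "")

    @property
    def genes(self) -> Set[str]:
        return set(self._gpr.genes)

    @property
    def is_empty(self) -> bool:
        return len(self._gpr.genes) == 0 and not str(self._gpr.to_string()).strip()

    def evaluate(self, deleted_genes: Set[str]) -> bool:
        """True iff the reaction remains catalyzed when ``deleted_genes``
        are absent."""
        return bool(self._gpr.eval(knockouts=deleted_genes))

    def to_string(self) -> str:
        return self._gpr.to_string()

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"GPRRule({self.to_string()!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, GPRRule) and self.to_string() == other.to_string()


@dataclass(frozen=True)
class ReactionRecord:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GPRRule = field(default_factory=GPRRule)
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise IntegrityError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise IntegrityError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    def with_bounds(self, lower: float, upper: float) -> "ReactionRecord":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass(frozen=True)
class LinearCouplingConstraint:
    """Network-specific linear constraint over reaction fluxes
    (e.g. a fixed P/O ratio), of the form ``sum(coef_j * v_j) rel rhs``."""

    coefficients: Mapping[str, float]
    relation: str  # "=", "<=", ">="
    rhs: float

    def __post_init__(self):
        if self.relation not in ("=", "<=", ">="):
            raise ConfigurationError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class MediaCondition:
    """Allowed uptakes for one growth condition.

    ``allowed_uptakes`` maps exchange-reaction ids to maximum uptake
    magnitudes (non-negative; uptake itself is negative flux)."""

    id: str
    allowed_uptakes: Mapping[str, float]
    label: str = ""

    def __post_init__(self):
        for ex_id, mag in self.allowed_uptakes.items():
            if mag < 0:
                raise ConfigurationError(
                    f"media {self.id!r}: uptake magnitude for {ex_id!r} is negative"
                )


def union_media(media: Sequence[MediaCondition], media_id: str = "robust") -> MediaCondition:
    """Union of several conditions: every uptake open at its maximum
    magnitude across the inputs (the 'robust media' used for precursor
    analysis)."""
    merged: Dict[str, float] = {}
    for m in media:
        for ex_id, mag in m.allowed_uptakes.items():
            merged[ex_id] = max(merged.get(ex_id, 0.0), mag)
    return MediaCondition(id=media_id, allowed_uptakes=merged,
                          label=" + ".join(m.id for m in media))


@dataclass
class MetabolicNetwork:
    metabolites: List[MetaboliteRecord]
    reactions: List[ReactionRecord]
    genes: Set[str] = field(default_factory=set)
    coupling: List[LinearCouplingConstraint] = field(default_factory=list)
    biomass_reaction_ids: List[str] = field(default_factory=list)
    id: str = "model"

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------

    @property
    def metabolite_ids(self) -> List[str]:
        return sorted(m.id for m in self.metabolites)

    @property
    def reaction_ids(self) -> List[str]:
        return sorted(r.id for r in self.reactions)

    def reaction(self, reaction_id: str) -> ReactionRecord:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise KeyError(f"no reaction {reaction_id!r} in network {self.id!r}")

    def has_reaction(self, reaction_id: str) -> bool:
        return reaction_id in self._rxn_index

    @property
    def exchange_reactions(self) -> List[ReactionRecord]:
        return [r for r in sorted(self.reactions, key=lambda r: r.id) if r.is_exchange]

    @property
    def mu(self) -> Set[str]:
        """Predefined biomass components: metabolites consumed (negative
        coefficient) by the primary (first-listed) biomass reaction."""
        if not self.biomass_reaction_ids:
            return set()
        rxn = self.reaction(self.biomass_reaction_ids[0])
        return {m for m, c in rxn.stoichiometry.items() if c < 0}

    # -- structure -------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise IntegrityError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise IntegrityError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in known:
                    raise IntegrityError(
                        f"reaction {r.id!r} references undeclared metabolite {m!r}"
                    )
        known_rxns = set(rxn_ids)
        for b in self.biomass_reaction_ids:
            if b not in known_rxns:
                raise IntegrityError(f"biomass reaction {b!r} not in network")
        for c in self.coupling:
            for rid in c.coefficients:
                if rid not in known_rxns:
                    raise IntegrityError(
                        f"coupling constraint references unknown reaction {rid!r}"
                    )
        self._rxn_index = {r.id: r for r in self.reactions}

    def copy(self) -> "MetabolicNetwork":
        # records are frozen dataclasses; shallow list copies suffice
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            genes=set(self.genes),
            coupling=list(self.coupling),
            biomass_reaction_ids=list(self.biomass_reaction_ids),
            id=self.id,
        )

    def replace_reactions(self, reactions: List[ReactionRecord],
                          biomass_reaction_ids: Optional[List[str]] = None
                          ) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=reactions,
            genes=set(self.genes),
            coupling=list(self.coupling),
            biomass_reaction_ids=(list(self.biomass_reaction_ids)
                                  if biomass_reaction_ids is None
                                  else biomass_reaction_ids),
            id=self.id,
        )

    def stoichiometric_matrix(self):
        """Sparse stoichiometric matrix with deterministically sorted axes.

        Returns ``(S, met_ids, rxn_ids)`` where ``S[i, j]`` is the
        coefficient of metabolite ``met_ids[i]`` in reaction ``rxn_ids[j]``.
        """
        met_ids = self.metabolite_ids
        rxn_ids = self.reaction_ids
        met_pos = {m: i for i, m in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(rxn_ids):
            for m, coef in self.reaction(rid).stoichiometry.items():
                rows.append(met_pos[m])
                cols.append(j)
                vals.append(float(coef))
        S = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids

    def flux_bounds(self, rxn_ids: Sequence[str]):
        lb = np.array([self.reaction(r).lower_bound for r in rxn_ids])
        ub = np.array([self.reaction(r).upper_bound for r in rxn_ids])
        return lb, ub


# ---------------------------------------------------------------------------
# cobra conversion and file I/O
# ---------------------------------------------------------------------------


def _is_exchange_stoich(stoich: Mapping[str, float]) -> bool:
    return len(stoich) == 1


def _from_cobra(model) -> MetabolicNetwork:
    metabolites = [
        MetaboliteRecord(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in model.metabolites
    ]
    reactions = []
    for r in model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        if not stoich:
            logger.warning("skipping reaction %s with empty stoichiometry", r.id)
            continue
        reactions.append(
            ReactionRecord(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=GPRRule(r.gene_reaction_rule),
                is_exchange=_is_exchange_stoich(stoich),
                name=r.name or "",
            )
        )
    biomass_ids = []
    for r in model.reactions:
        obj = getattr(r, "objective_coefficient", 0.0) or 0.0
        if obj != 0.0 or "biomass" in r.id.lower():
            biomass_ids.append(r.id)
    genes = {g.id for g in model.genes}
    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction_ids=biomass_ids,
        id=model.id or "model",
    )


def _to_cobra(net: MetabolicNetwork):
    import cobra

    model = cobra.Model(net.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in net.metabolites
    }
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in sorted(net.reactions, key=lambda r: r.id):
        rxn = cobra.Reaction(r.id, name=r.name,
                             lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(rxn)
    model.add_reactions(rxns)
    for r in sorted(net.reactions, key=lambda r: r.id):
        rxn = model.reactions.get_by_id(r.id)
        rxn.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        rule = r.gpr.to_string()
        if rule:
            rxn.gene_reaction_rule = rule
    if net.biomass_reaction_ids:
        model.objective = net.biomass_reaction_ids[0]
    return model


def read_model(path, dialect: str = "cobra-json") -> MetabolicNetwork:
    """Read a metabolic network from SBML or COBRA-style JSON.

    Exchange reactions are identified structurally (single-metabolite
    stoichiometry); biomass reactions by objective coefficient or an id
    containing ``biomass``.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    try:
        if dialect == "cobra-json":
            model = cobra.io.load_json_model(str(path))
        elif dialect == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise ConfigurationError(f"unknown dialect {dialect!r}")
    except ConfigurationError:
        raise
    except Exception as exc:  # cobra raises heterogeneous parse errors
        raise FormatError(f"failed to parse {path} as {dialect}: {exc}") from exc
    return _from_cobra(model)


def write_model(net: MetabolicNetwork, path, dialect: str = "cobra-json") -> None:
    """Write a network as COBRA-style JSON or SBML."""
    import cobra.io

    model = _to_cobra(net)
    if dialect == "cobra-json":
        cobra.io.save_json_model(model, str(path))
    elif dialect == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# media, knockouts, sink augmentation
# ---------------------------------------------------------------------------


def apply_media(net: MetabolicNetwork, media: MediaCondition) -> MetabolicNetwork:
    """Close every exchange uptake except those the media allows.

    The uptake (lower) bound of each exchange reaction is set to
    ``-magnitude`` when listed and ``0`` otherwise; secretion (upper) bounds
    are untouched.
    """
    exchange_ids = {r.id for r in net.reactions if r.is_exchange}
    unknown = set(media.allowed_uptakes) - exchange_ids
    if unknown:
        raise ConfigurationError(
            f"media {media.id!r} references unknown exchange reactions: "
            f"{sorted(unknown)}"
        )
    new_reactions = []
    for r in net.reactions:
        if r.is_exchange:
            mag = media.allowed_uptakes.get(r.id, 0.0)
            new_reactions.append(r.with_bounds(-abs(mag), r.upper_bound))
        else:
            new_reactions.append(r)
    return net.replace_reactions(new_reactions)


def apply_knockout(net: MetabolicNetwork, deleted_genes: Iterable[str]) -> MetabolicNetwork:
    """Disable every reaction whose GPR evaluates false without the genes.

    Genes absent from the network are logged and ignored: phenotype datasets
    routinely span the whole genome while the model covers a subset.
    """
    deleted = set(deleted_genes)
    unknown = deleted - net.genes
    if unknown:
        logger.warning("knockout genes not in model, ignored: %s", sorted(unknown))
    deleted &= net.genes
    if not deleted:
        return net.copy()
    new_reactions = []
    for r in net.reactions:
        if not r.gpr.is_empty and not r.gpr.evaluate(deleted):
            new_reactions.append(r.with_bounds(0.0, 0.0))
        else:
            new_reactions.append(r)
    return net.replace_reactions(new_reactions)


def prepare_for_blocking(net: MetabolicNetwork) -> MetabolicNetwork:
    """Remove all biomass reactions and add a sink for every metabolite.

    Sinks consume one unit of their metabolite, are irreversible with bounds
    ``[0, U_SINK]`` and named ``SINK_<metabolite id>``. Idempotent: existing
    sinks are not duplicated.
    """
    biomass = set(net.biomass_reaction_ids)
    reactions = [r for r in net.reactions if r.id not in biomass]
    present = {r.id for r in reactions}
    for m in net.metabolite_ids:
        sid = sink_id(m)
        if sid not in present:
            reactions.append(
                ReactionRecord(
                    id=sid,
                    stoichiometry={m: -1.0},
                    lower_bound=0.0,
                    upper_bound=U_SINK,
                    is_exchange=False,
                )
            )
    return net.replace_reactions(reactions, biomass_reaction_ids=[])


def is_sink(reaction_id: str) -> bool:
    return reaction_id.startswith(SINK_PREFIX)


# ---------------------------------------------------------------------------
# tables on disk
# ---------------------------------------------------------------------------


def read_media_definitions(path) -> Dict[str, MediaCondition]:
    """Read media definitions from JSON ({media_id: {exchange_id: uptake}})
    or TSV (columns media_id, exchange_id, max_uptake)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return {
            mid: MediaCondition(id=mid, allowed_uptakes={k: float(v) for k, v in up.items()})
            for mid, up in raw.items()
        }
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"media_id", "exchange_id", "max_uptake"}
    if not required <= set(df.columns):
        raise FormatError(f"media table must have columns {sorted(required)}")
    media = {}
    for mid, grp in df.groupby("media_id"):
        media[str(mid)] = MediaCondition(
            id=str(mid),
            allowed_uptakes={
                str(row.exchange_id): float(row.max_uptake) for row in grp.itertuples()
            },
        )
    return media


def read_phenotype_table(path, fitness_threshold: float = -1.0):
    """Read a phenotype table (TSV: experiment_id, deleted_genes
    [semicolon-separated], media_id, phenotype (G/NG) or fitness)."""
    import pandas as pd

    from phenomass.phenotype_lists import ExperimentRecord, classify_phenotype

    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples():
        genes = frozenset(
            g for g in str(getattr(row, "deleted_genes", "") or "").split(";") if g
        )
        fitness = getattr(row, "fitness", None)
        fitness = float(fitness) if fitness not in (None, "", "nan") else None
        observed = getattr(row, "phenotype", None)
        observed = str(observed) if observed not in (None, "", "nan") else None
        rec = ExperimentRecord(
            id=str(row.experiment_id),
            deleted_genes=genes,
            media_id=str(row.media_id),
            observed=observed,
            fitness=fitness,
        )
        if rec.observed is None:
            rec = replace(rec, observed=classify_phenotype(rec, fitness_threshold))
        records.append(rec)
    return records
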