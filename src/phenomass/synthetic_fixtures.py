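"""Synthetic networks and planted phenotypes for end-to-end testing.

The generator assembles small mass-balanced networks from the structural
motifs that drive biomass-inference behavior in real reconstructions:
linear biosynthetic pathways, isozyme pairs (duplicate reactions under
distinct genes), parallel alternate routes, closed cycles with no external
supply (their members are net-production blocked despite feasible internal
flux), and by-product couplings (a co-product with no consumer). A planted
biomass set then induces ground-truth knockout phenotypes: a mutant is
no-growth exactly when some planted component becomes blocked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from phenomass.blocked_core import BlockingConfig, producible_oracle
from phenomass.errors import ConfigurationError, UsageError
from phenomass.model_io import (
    GPRRule,
    MediaCondition,
    MetaboliteRecord,
    MetabolicNetwork,
    ReactionRecord,
    apply_knockout,
    apply_media,
    prepare_for_blocking,
)
from phenomass.phenotype_lists import ExperimentRecord, GROWTH, NO_GROWTH


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one random fixture network."""

    n_linear_pathways: int = 4
    pathway_length: Tuple[int, int] = (3, 6)
    n_isozyme_pairs: int = 1
    n_parallel_routes: int = 1
    n_closed_cycles: int = 1
    n_byproduct_couplings: int = 1
    planted_biomass_size: int = 3
    media_metabolites: Tuple[str, ...] = ("nut1",)
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_linear_pathways, self.n_isozyme_pairs, self.n_parallel_routes,
            self.n_closed_cycles, self.n_byproduct_couplings,
            self.planted_biomass_size,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("fixture counts must be non-negative")
        if self.pathway_length[0] < 1 or self.pathway_length[0] > self.pathway_length[1]:
            raise ConfigurationError("invalid pathway length range")
        if not self.media_metabolites:
            raise ConfigurationError("at least one media metabolite is required")


def _gene_for(rxn_id: str) -> str:
    return "g_" + rxn_id


class _Builder:
    def __init__(self):
        self.mets: Dict[str, MetaboliteRecord] = {}
        self.rxns: List[ReactionRecord] = []
        self.genes: Set[str] = set()
        self.producible: List[str] = []  # internal metabolites fed by the media

    def met(self, mid: str, compartment: str = "c") -> str:
        if mid not in self.mets:
            self.mets[mid] = MetaboliteRecord(id=mid, name=mid, compartment=compartment)
        return mid

    def rxn(self, rid: str, stoich: Dict[str, float], lb: float, ub: float,
            gene: Optional[str] = None, is_exchange: bool = False):
        gpr = GPRRule(gene or "")
        if gene:
            self.genes.add(gene)
        self.rxns.append(
            ReactionRecord(id=rid, stoichiometry=stoich, lower_bound=lb,
                           upper_bound=ub, gpr=gpr, is_exchange=is_exchange)
        )

    def build(self, model_id: str) -> MetabolicNetwork:
        return MetabolicNetwork(
            metabolites=[self.mets[k] for k in sorted(self.mets)],
            reactions=self.rxns,
            genes=self.genes,
            id=model_id,
        )


def make_random_network(spec: FixtureSpec) -> MetabolicNetwork:
    """Deterministically generate a fixture network from the requested motifs."""
    rng = np.random.default_rng(spec.seed)
    b = _Builder()

    for nut in spec.media_metabolites:
        ext = b.met(f"{nut}_e", "e")
        inn = b.met(nut)
        b.rxn(f"EX_{nut}", {ext: -1.0}, -1000.0, 1000.0, is_exchange=True)
        rid = f"T_{nut}"
        b.rxn(rid, {ext: -1.0, inn: 1.0}, 0.0, 1000.0, gene=_gene_for(rid))
        b.producible.append(inn)

    pathway_rxns: List[str] = []
    for p in range(spec.n_linear_pathways):
        length = int(rng.integers(spec.pathway_length[0], spec.pathway_length[1] + 1))
        anchor = b.producible[int(rng.integers(len(b.producible)))]
        prev = anchor
        for step in range(length):
            nxt = b.met(f"p{p}m{step}")
            rid = f"P{p}R{step}"
            b.rxn(rid, {prev: -1.0, nxt: 1.0}, 0.0, 1000.0, gene=_gene_for(rid))
            pathway_rxns.append(rid)
            b.producible.append(nxt)
            prev = nxt

    for k in range(spec.n_isozyme_pairs):
        if not pathway_rxns:
            break
        rid = pathway_rxns[int(rng.integers(len(pathway_rxns)))]
        twin_id = f"{rid}_iso{k}"
        base = next(r for r in b.rxns if r.id == rid)
        b.rxn(twin_id, dict(base.stoichiometry), base.lower_bound,
              base.upper_bound, gene=_gene_for(twin_id))

    for k in range(spec.n_parallel_routes):
        src = b.producible[int(rng.integers(len(b.producible)))]
        mid1 = b.met(f"alt{k}a")
        mid2 = b.met(f"alt{k}b")
        dst = b.met(f"alt{k}z")
        for suffix, mid in (("a", mid1), ("b", mid2)):
            r1 = f"ALT{k}{suffix}1"
            r2 = f"ALT{k}{suffix}2"
            b.rxn(r1, {src: -1.0, mid: 1.0}, 0.0, 1000.0, gene=_gene_for(r1))
            b.rxn(r2, {mid: -1.0, dst: 1.0}, 0.0, 1000.0, gene=_gene_for(r2))
        b.producible.extend([mid1, mid2, dst])

    for k in range(spec.n_closed_cycles):
        members = [b.met(f"cyc{k}m{j}") for j in range(3)]
        for j in range(3):
            rid = f"CYC{k}R{j}"
            b.rxn(
                rid,
                {members[j]: -1.0, members[(j + 1) % 3]: 1.0},
                0.0, 1000.0, gene=_gene_for(rid),
            )

    for k in range(spec.n_byproduct_couplings):
        src = b.producible[int(rng.integers(len(b.producible)))]
        main = b.met(f"bp{k}main")
        waste = b.met(f"bp{k}waste")
        rid = f"BP{k}"
        b.rxn(rid, {src: -1.0, main: 1.0, waste: 1.0}, 0.0, 1000.0,
              gene=_gene_for(rid))
        b.producible.append(main)

    net = b.build(f"fixture_seed{spec.seed}")
    if spec.planted_biomass_size > len(net.metabolites):
        raise ConfigurationError("planted biomass larger than metabolite count")
    return net


def cycle_members(spec: FixtureSpec) -> Set[str]:
    return {f"cyc{k}m{j}" for k in range(spec.n_closed_cycles) for j in range(3)}


def fixture_media(spec: FixtureSpec, uptake: float = 10.0) -> MediaCondition:
    return MediaCondition(
        id="fixture_media",
        allowed_uptakes={f"EX_{nut}": uptake for nut in spec.media_metabolites},
        label="all fixture nutrients",
    )


def planted_biomass(net: MetabolicNetwork, spec: FixtureSpec) -> FrozenSet[str]:
    """Deterministic planted component set: drawn from pathway interior
    metabolites (always producible in the wild type under fixture media)."""
    import re

    rng = np.random.default_rng(spec.seed + 1)
    pool = sorted(
        m.id for m in net.metabolites if re.fullmatch(r"p\d+m\d+", m.id)
    )
    if len(pool) < spec.planted_biomass_size:
        raise ConfigurationError("not enough pathway metabolites to plant biomass")
    idx = rng.choice(len(pool), size=spec.planted_biomass_size, replace=False)
    return frozenset(pool[i] for i in sorted(idx))


def plant_phenotypes(
    net: MetabolicNetwork,
    planted: Set[str],
    knockouts: Sequence[Set[str]],
    media: MediaCondition,
    noise_rate: float = 0.0,
    seed: int = 0,
    cfg: BlockingConfig = BlockingConfig(),
) -> List[ExperimentRecord]:
    """Simulate knockout phenotypes from a planted biomass.

    A mutant is no-growth exactly when some planted component is
    net-production blocked (per the per-metabolite LP oracle); labels are
    then flipped independently with probability ``noise_rate``.
    """
    prepared = apply_media(prepare_for_blocking(net), media)
    wt = producible_oracle(prepared, cfg, strain="wild-type", media_id=media.id)
    unproducible = set(planted) & set(wt.blocked)
    if unproducible:
        raise UsageError(
            f"planted components blocked in the wild type: {sorted(unproducible)}"
        )
    rng = np.random.default_rng(seed)
    records = []
    for idx, genes in enumerate(knockouts):
        genes = frozenset(genes)
        mut_net = apply_knockout(prepared, genes)
        mut = _oracle_on_subset(mut_net, planted, cfg)
        label = NO_GROWTH if set(planted) & mut else GROWTH
        if noise_rate > 0 and rng.random() < noise_rate:
            label = GROWTH if label == NO_GROWTH else NO_GROWTH
        records.append(
            ExperimentRecord(
                id=f"ko{idx:04d}_{'_'.join(sorted(genes))}",
                deleted_genes=genes,
                media_id=media.id,
                observed=label,
            )
        )
    return records


def _oracle_on_subset(net, subset: Set[str], cfg: BlockingConfig) -> Set[str]:
    """Blocked members of ``subset`` by the per-metabolite LP criterion
    (identical to producible_oracle restricted to those metabolites)."""
    import scipy.sparse as sp

    from phenomass import _solver
    from phenomass.model_io import sink_id

    S, met_ids, rxn_ids = net.stoichiometric_matrix()
    lb, ub = net.flux_bounds(rxn_ids)
    rxn_pos = {r: j for j, r in enumerate(rxn_ids)}
    blocked = set()
    zero = np.zeros(len(met_ids))
    for m in sorted(subset):
        c = np.zeros(len(rxn_ids))
        c[rxn_pos[sink_id(m)]] = 1.0
        res = _solver.solve_lp(c, S, zero, lb, ub, maximize=True)
        if not (res.feasible and res.objective >= cfg.v_min - cfg.lp_tolerance):
            blocked.add(m)
    return blocked


def single_knockout_panel(
    net: MetabolicNetwork, n: int, seed: int = 0
) -> List[Set[str]]:
    """``n`` single-gene knockouts drawn uniformly (with replacement when
    ``n`` exceeds the gene count) from the network's genes."""
    genes = sorted(net.genes)
    rng = np.random.default_rng(seed)
    if n <= len(genes):
        idx = rng.choice(len(genes), size=n, replace=False)
    else:
        idx = rng.integers(0, len(genes), size=n)
    return [{genes[i]} for i in idx]


def illustrative_example():
    """Hand-built pedagogical fixture (an homage to the classic worked
    example of this method family; the topology is this package's own).

    Returns ``(network, media, experiments, mu)`` where:

    * metabolites I_ex and I are blocked in the wild type (no supply route
      under the media) and hence excluded from candidacy;
    * the experiment set drives modification of the predefined biomass
      ``mu = {F, H}`` to add C and remove F;
    * no experiment provides evidence about H, so the de-novo proposal
      omits it while modification leaves it untouched.
    """
    b = _Builder()
    for m in "ABCDEFGHI":
        b.met(m)
    b.met("I_ex", "e")
    b.rxn("EX_A", {"A": -1.0}, -1000.0, 1000.0, is_exchange=True)
    b.rxn("EX_G", {"G": -1.0}, -1000.0, 1000.0, is_exchange=True)
    b.rxn("EX_I", {"I_ex": -1.0}, -1000.0, 1000.0, is_exchange=True)
    b.rxn("T_I", {"I_ex": -1.0, "I": 1.0}, 0.0, 1000.0, gene="g_TI")
    b.rxn("R_AB", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, gene="g_AB")
    b.rxn("R_BC", {"B": -1.0, "C": 1.0}, 0.0, 1000.0, gene="g_BC")
    b.rxn("R_CD", {"C": -1.0, "D": 1.0}, 0.0, 1000.0, gene="g_CD")
    b.rxn("R_AE", {"A": -1.0, "E": 1.0}, 0.0, 1000.0, gene="g_AE")
    b.rxn("R_EF", {"E": -1.0, "F": 1.0}, 0.0, 1000.0, gene="g_EF")
    b.rxn("R_GH", {"G": -1.0, "H": 1.0}, 0.0, 1000.0, gene="g_GH")
    b.rxn(
        "BIOMASS_predefined",
        {"F": -0.0002, "H": -0.0002},
        0.0, 1000.0,
    )
    net = MetabolicNetwork(
        metabolites=[b.mets[k] for k in sorted(b.mets)],
        reactions=b.rxns,
        genes=b.genes,
        biomass_reaction_ids=["BIOMASS_predefined"],
        id="illustrative",
    )
    media = MediaCondition(
        id="AG", allowed_uptakes={"EX_A": 10.0, "EX_G": 10.0}, label="A and G"
    )
    experiments = [
        ExperimentRecord(id="e1_dBC", deleted_genes=frozenset(["g_BC"]),
                         media_id="AG", observed=NO_GROWTH),
        ExperimentRecord(id="e2_dEF", deleted_genes=frozenset(["g_EF"]),
                         media_id="AG", observed=GROWTH),
        ExperimentRecord(id="e3_dCD", deleted_genes=frozenset(["g_CD"]),
                         media_id="AG", observed=GROWTH),
    ]
    return net, media, experiments, frozenset({"F", "H"})
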