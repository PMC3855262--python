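# Methods

## Model and assumptions

The package operates on ordinary constraint-based metabolic models: a
stoichiometric matrix `S` over metabolites × reactions, flux bounds
`LBⱼ ≤ vⱼ ≤ UBⱼ`, boolean gene–protein–reaction (GPR) rules, and optional
network-specific linear coupling constraints (e.g. fixed P/O ratios). A
knockout disables every reaction whose GPR evaluates false without the
deleted genes; reactions without a GPR are never disabled. Media are
expressed purely through exchange bounds: an exchange reaction has exactly
one metabolite in its stoichiometry, uptake is negative flux, and applying
a media condition closes every uptake not explicitly allowed while leaving
secretion bounds untouched.

The central assumption inherited from the qualitative-biomass viewpoint is
that growth requires net production of every biomass component and nothing
more: stoichiometric proportions are irrelevant to a growth/no-growth call,
which is why biomass reactions are built with a uniform arbitrary
coefficient and all conclusions are qualitative.

### Net-production blockedness

With the biomass removed and a sink `xᵢ ∈ [0, 1000]` added per metabolite,
metabolite `i` is producible iff some steady-state flux vector achieves
`xᵢ ≥ v_min`. The single-MILP formulation (maximize `Σ zᵢ` with
`v_min·zᵢ ≤ xᵢ ≤ M·zᵢ`) and the per-metabolite LP (`max xᵢ`) agree whenever
flux bounds are not binding across summed witnesses, which holds by a
convex-scaling argument at the magnitudes used here (bounds ±1000,
`v_min = 5·10⁻⁴`); the pipeline exposes a `cross_check` mode that falls
back to the LP oracle and logs any discrepancy, since the oracle is the
definition. Sinks remove mass, so members of a cycle with no external
supply are blocked even though circulating flux through them is feasible —
this is deliberate and distinguishes net-production blockedness from
flux-carrying ability.

### Selection integer programs

Candidate metabolites are those blocked in some mutant but not in the wild
type; wild-type-blocked metabolites never enter the candidate universe.
The de-novo IP and the modification IP share one skeleton (membership
binaries `mᵢ`, agreement indicators per experiment, constraints
`n_e ≤ Σ_{i∈In(e)} mᵢ` and `g_e + mᵢ ≤ 1` for `i ∈ Ex(e)`); agreement
indicators are declared continuous in [0, 1] because maximization makes
them integral once membership is binary, which keeps the MILPs small. All
solves demand proven optimality (zero MIP gap; the objectives are integral
under unit weights).

Experimentally measured components (the EM set) are soft evidence: each
contributes a pseudo no-growth experiment whose include list is that single
metabolite, at a configurable weight defaulting to 1. Hard constraints were
rejected because phenotype data must be able to overrule a measurement.

The modification objective is lexicographic — maximal agreement, then
fewest removals from the predefined set μ, then fewest additions —
implemented as three sequential solves, each fixing the previous objective
value with a ±10⁻⁶ band. A single weighted objective would trade removals
against additions at an arbitrary exchange rate; the lexicographic order
encodes the curatorial intent (keep the predefined biomass unless the data
demand otherwise) without a tunable penalty.

### Determinism and tie-breaking

Optimal component sets are usually non-unique. After the secondary solve,
the implementation probes metabolites in sorted-id order, fixing each to 1
whenever some optimum consistent with the earlier fixes contains it; this
returns the lexicographically smallest optimal set and makes every run
reproducible (variable order is sorted everywhere; HiGHS is deterministic
single-threaded). The probing costs one small MILP per candidate metabolite
and can be disabled (`tie_break=False`) when only the objective value
matters.

### Alternatives, precursors, categorization

An alternative of component `k` is found by pinning all other components to
1, `k` to 0, re-solving at fixed agreement with uniform costs, and
repeating with each discovered replacement pinned to 0 until infeasible
(capped at 50 per component). Essential-precursor analysis decouples every
flux into `v = v_for − v_rev` (both ≥ 0; a zero upper/lower bound zeroes
the corresponding direction), requires sink flux ≥ `v_min` simultaneously
for all biomass components under the robust media (the union of all tested
conditions), and for each candidate `k` disables every direction consuming
`k` — including `k`'s own sink and exchange, which could otherwise mask the
removal — declaring `k` essential when the demand becomes infeasible. These
are pure LP feasibility tests. Categorization applies the precedence
direct match → alternative → downstream (a predefined metabolite is an
essential precursor of the component) → upstream → unique.

A per-component sequential variant of the precursor test is available
behind `simultaneous=False` for diagnosis; the simultaneous single-flux-
vector form is the default and the one used in reports.

### Dead-end by-products

Because blocking analysis grants every metabolite a sink, a selected
biomass may depend on reactions whose co-products have no consumer; plain
FBA would then predict no growth for experiments the IP matched as growing.
Detection solves, per matched growth experiment, a MILP minimizing the
number of active sinks subject to biomass flux ≥ ε (default 10⁻³) —
minimizing the count gives the most parsimonious repair; minimizing total
sink flux would conflate magnitude with necessity. Alternate repairs are
enumerated by pinning a reported sink to zero. Augmentation unions the
reported by-products into the biomass and iterates to a fixed point
(default cap 10 rounds). Detection uses a unit biomass coefficient:
growth calls are invariant to that scaling, and unit coefficients keep the
forced by-product fluxes at ε scale, comfortably above solver feasibility
tolerances (at the reporting coefficient 2·10⁻⁴ they would sit near 10⁻⁷).

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `v_min` | 5·10⁻⁴ flux units | minimum sink flux for "producible" |
| `big_M` / sink bound | 1000 | linking constant; exceeds `v_min` by >6 orders |
| `filter_max` | 100 | blocked-set size above which a mutant is uninformative |
| `fitness_threshold` | −1 | fitness below ⇒ no growth; exactly at ⇒ growth (logged) |
| ε (dead-end) | 10⁻³ | biomass flux forced during by-product detection |
| biomass coefficient | 2·10⁻⁴ | uniform drain per component in evaluation |
| growth flux threshold | 10⁻⁶ | FBA optimum above ⇒ growth call |
| EM weight | 1 | weight of a measured-component pseudo-experiment |
| integrality tol | 10⁻⁷ | enforced ≥ 50× below `v_min` |

The fitness tie (exactly at threshold) is called growth because the
convention only defines the strict inequalities; tied records are logged so
they can be audited. Replicate experiments (same knockout, media and
phenotype) are merged with summed weights. Filtering is applied to the
candidate set after the wild-type set difference; a flag could move it
before, but post-difference filtering is the stricter reading of
"uninformative mutant".

## What the synthetic generator emulates — and what it does not

`synthetic_fixtures` assembles networks from the motifs that actually
drive biomass-inference behavior: linear biosynthetic chains, isozyme
pairs (duplicate reactions under distinct genes), parallel alternate
routes, closed unreplenished cycles, and by-product couplings. One gene
per reaction (beyond declared isozyme pairs) keeps GPR evaluation
exercised without combinatorial blowup. Phenotypes are planted from a
chosen biomass set — no-growth exactly when a planted component is blocked
per the LP oracle — with optional independent label noise.

These fixtures do not attempt genome-scale realism: no compartments beyond
a cytosol/extracellular split, no cofactor coupling across pathways, no
correlated measurement error, no GPR complexes spanning pathways, and far
smaller blocked sets than a real reconstruction produces. Passing the
planted-recovery study therefore demonstrates correctness of the machinery
(detection, list building, IP optimality, repair, FBA closure) under the
model's own assumptions — not predictive accuracy on a real organism, which
depends on reconstruction quality and dataset coverage. The worked example
(`illustrative_example`) is an homage to the classic pedagogical network of
this method family: only its qualitative facts are asserted, its topology
is this package's own.

Problem sizes used by the test suite and the acceptance script — 100
random networks of 20–60 reactions for oracle equivalence, 50 enumerated
instances of ≤12 candidates for IP optimality, one 200-experiment planted
study — were chosen as the smallest sizes that exercise every motif
combination and keep exhaustive enumeration tractable as an oracle.

## Numerical choices

* scipy's HiGHS backends (`linprog`, `milp`) solve every LP/MILP; zero MIP
  gap requested, default feasibility tolerances (~10⁻⁷).
* Oracle producibility uses `optimum ≥ v_min − 10⁻⁹`.
* Objective-fixing constraints in sequential solves carry a ±10⁻⁶ band —
  far below the unit granularity of the integral objectives.
* Degenerate inputs: empty evidence yields an empty de-novo proposal and a
  no-op modification; a no-growth experiment with an empty candidate set is
  retained as an unfixable misprediction; an experiment unfixable by any
  sink set is reported, not raised.

## Known limitations

* Consumption-blocked analysis is out of scope; only dead-end by-products
  of the proposed biomass are repaired, and proposing new consuming
  reactions (the alternative remedy) is reported as out of scope rather
  than attempted.
* No thermodynamic/loopless constraints; internal cycles may carry flux in
  FBA evaluations.
* Stoichiometric coefficients of proposed biomasses are arbitrary; the
  output is not suitable for quantitative yield predictions.
* Linear coupling constraints are honored in all solves but are not
  serialized to SBML/JSON (no standard encoding); they must be attached
  programmatically.
* With very large candidate universes the deterministic tie-break's
  one-MILP-per-metabolite probing dominates runtime; disable it if only
  agreement values are needed.
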