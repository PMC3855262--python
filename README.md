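# phenomass

Infer — or minimally revise — the biomass composition of a constraint-based
metabolic model directly from gene-knockout growth phenotypes.

Flux-balance analysis (FBA) predicts whether a mutant grows by maximizing
flux through a biomass pseudo-reaction, so every qualitative growth
prediction stands or falls with the list of metabolites that reaction
drains. Curated biomass equations are usually borrowed from related
organisms or assembled by hand, and large parts of them are never tested
against data. `phenomass` treats the component list itself as the unknown:
given a genome-scale network (SBML or COBRA-style JSON) and a table of
knockout growth/no-growth calls (or fitness scores), it finds the component
set that makes the model agree with as many experiments as possible. It is
aimed at model curators and systems biologists with high-throughput
knockout phenotype or fitness datasets in hand.

## Method

1. **Blocked-metabolite detection.** The biomass reaction is removed and an
   irreversible sink is added for every metabolite. For strain/condition
   pair, a MILP maximizes `Σᵢ zᵢ` subject to steady state `S·v = 0` (sinks
   included), flux bounds, and the linking constraints
   `v_min·zᵢ ≤ xᵢ ≤ M·zᵢ`, where `xᵢ` is the sink flux of metabolite `i`
   and `v_min = 5·10⁻⁴`. Metabolites with `zᵢ = 0` are *net-production
   blocked*: no steady-state flux can export them, even if internal cycle
   flux through them is feasible (an unreplenished cycle can circulate but
   never be drained without violating mass conservation). A per-metabolite
   LP (`max xᵢ`) serves as the defining oracle the MILP is validated
   against.

2. **Evidence lists.** For each experiment the mutant-specific blocked set
   (mutant blocked minus wild-type blocked) goes into an *include* list if
   the mutant did not grow — those metabolites, if essential, would explain
   the death — or an *exclude* list if it grew. Mutants with more than 100
   blocked metabolites are set aside as uninformative.

3. **Selection IPs.** Binary indicators `wᵢ` mark biomass membership. A
   no-growth experiment `e` is matched when `Σ_{i∈In(e)} wᵢ ≥ n_e`, a growth
   experiment when `g_e ≤ 1 − wᵢ` for all `i ∈ Ex(e)`; the IP maximizes the
   weighted number of matched experiments (`FixObj`), then a second solve at
   fixed agreement picks a minimum-cardinality set or preferentially weights
   field-typical components (amino acids, currency metabolites).
   Analytically measured components enter as soft pseudo-experiments.
   Modification of a predefined set μ solves lexicographically: maximal
   agreement, then fewest removals from μ, then fewest additions.

4. **Interpretation and repair.** Alternatives (interchangeable components),
   essential precursors under a robust media (union of all tested
   conditions), categorization of de-novo components against a predefined
   biomass, and detection of dead-end by-products whose accumulation would
   otherwise turn matched growth experiments into FBA false negatives.

5. **Evaluation.** The proposed set becomes a biomass reaction (uniform
   coefficient 0.0002) and plain FBA tabulates percent agreement per media
   condition and phenotype class, side by side with the predefined biomass.

## Worked example

The built-in worked example is a ten-metabolite network fed by metabolites
A and G, with predefined biomass μ = {F, H} and three knockout experiments:

```python
import phenomass as pm

net, media, experiments, mu = pm.illustrative_example()
lists = pm.build_lists(experiments, net, {media.id: media})
print({e: sorted(v) for e, v in lists.include.items()})
print({e: sorted(v) for e, v in lists.exclude.items()})

fix, _ = pm.max_agreement(lists)
de_novo = pm.select_de_novo(lists, fix_obj=fix)
print(fix, sorted(de_novo.components))

mod = pm.modify_biomass(lists, mu)
print(sorted(mod.added), sorted(mod.removed), sorted(mod.unmodified))
```

prints

```
{'e1_dBC': ['C', 'D']}
{'e2_dEF': ['F'], 'e3_dCD': ['D']}
3.0 ['C']
['C'] ['F'] ['H']
```

The no-growth mutant e1 blocks C and D, so one of them must be a biomass
component; the growing mutants e2 and e3 block F and D respectively, ruling
both out. All three experiments can be matched (`FixObj = 3`), and the
minimal de-novo biomass is {C}. Modification of μ = {F, H} adds C, removes
F (contradicted by e2), and keeps H — no experiment bears on H, so the
conservative modification retains it while the evidence-only de-novo
proposal omits it. The wild type cannot produce I_ex or I under this media,
so neither is ever considered a candidate.

The same pipeline runs from the shell on simulated data:

```bash
phenomass simulate --seed 1 --out run/
phenomass lists --model run/model.json --phenotypes run/phenotypes.tsv \
    --media run/media.json --out run/
phenomass denovo --lists run/lists.json --out run/
phenomass evaluate --model run/model.json --proposal run/proposal.json \
    --phenotypes run/phenotypes.tsv --media run/media.json --out run/
```

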