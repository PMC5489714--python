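# strongcoupling

Deciding the feasibility of **strongly growth-coupled metabolite production**
in constraint-based metabolic models, by computing and verifying
**constrained minimal cut sets (cMCS)** — reaction or gene knockouts — with a
duality-based MILP, plus a batch screen that classifies every
substrate-producible organic metabolite as coupleable, provably not
coupleable, or undecided at given minimum-yield levels.

## The problem

A production strain is *strongly* growth-coupled when **every** feasible
steady-state flux distribution — not just the growth-optimal one — attains at
least a demanded product yield, so that synthesis is enforced even at zero
growth (the non-growth-associated maintenance demand keeps the cell
metabolically active). Given a stoichiometric matrix **N** with flux bounds
α ≤ r ≤ β, substrate uptake rate r_S, product export r_P and growth rate μ,
the *undesired* flux region collects everything with too low a yield,

    T r ≤ t :   r_P − Y_min^P · r_S ≤ 0,

and the *desired* region demands both a product and a biomass yield,

    D r ≤ d :   −r_P + Y_min^P · r_S ≤ 0,   −μ + Y_min^BM · r_S ≤ 0.

A cMCS is an inclusion-minimal knockout set that empties the undesired region
while the desired one stays nonempty. The MILP searches for such a set by
pairing a **Farkas certificate** of infeasibility of the (knockout-relaxed)
undesired system with a primal witness of the desired system; binary
indicators `zp_i`/`zn_i` gate the per-reaction knockout duals `vp_i`/`vn_i`
and simultaneously force the desired-region flux of cut reactions to zero.
Reactions that are not enzyme-catalysed (exchanges, transport and pseudo
reactions, spontaneous or gene-less reactions) are *irrepressible*: their
indicators are fixed to zero. Every candidate the solver returns is
re-verified with plain LPs on the uncompressed network and reduced to a true
cMCS; MILP infeasibility is a proof that no coupling knockout set exists.

## Worked example

The bundled toy network TOY3 feeds a substrate A into two catabolic routes —
CAT1 (→ ATP + product P) and CAT2 (→ ATP + waste W) — an anabolic reaction
ANA (A + ATP → biomass precursor), a maintenance demand on ATP with lower
bound 1, and export reactions. Cutting CAT2 forces all ATP synthesis through
the product route, so r_P − 0.5·r_S = 0.5·MAINT ≥ 0.5 for every surviving
flux: production is coupled to being alive.

```python
from strongcoupling import synthetic, intervention, milp

fix = synthetic.make_toy("TOY3")
problem = intervention.build_coupling_problem(fix.network, fix.config, "EX_P", 0.5)
verdict = milp.find_cmcs(problem, fix.config)
print(verdict.status, sorted(verdict.cutset))
```

prints

```
FEASIBLE ['CAT2']
```

i.e. a single knockout enforces at least 50 % of the maximum product yield
(which is 1 mol P per mol substrate here). The same search on TOY1 — where
maintenance drains the substrate pool directly, so an ATP-free zero-production
flux always survives — returns `INFEASIBLE` at every yield level, with the
MILP's infeasibility serving as the proof.

The batch screen does this for every candidate metabolite and level:

```sh
strongcoupling toy --name TOY3 --out toy3.json
strongcoupling screen --model toy3.json --config config.yaml \
    --levels 0.1,0.3,0.5 --out results.tsv
```

and reports, per level, the percentage of substrate-producible organic
metabolites that are coupleable / provably not coupleable / undecided,
together with cut-set size statistics. `strongcoupling cmcs`, `verify` and
`gpr-extend` cover single-product searches, LP verification of externally
proposed cut sets, and gene-level network extension. SBML (Level 3 / FBC)
models are read directly: `--model model.xml` with a YAML configuration
naming the substrate exchange, uptake limit, maintenance demand, open organic
outflows, oxygen condition and solver budgets.

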