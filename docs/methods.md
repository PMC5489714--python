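# Methods

## Model and regions

A metabolic network with m internal metabolites and n reactions is
represented by its stoichiometric matrix **N** (boundary species dropped),
flux bounds α ≤ r ≤ β (mmol·gDW⁻¹·h⁻¹; ±∞ allowed) and the steady-state
condition **N**r = 0. The substrate uptake rate r_S is a nonnegative rate:
internally it is σ·(substrate exchange flux), where the orientation σ is
declared in the configuration (`negative-exchange` for BiGG-style models
that encode uptake as negative exchange flux, `positive-uptake` for
networks written with an import-positive substrate exchange).

For a product export r_P, a demanded minimum product yield Y_min^P and a
minimum biomass yield Y_min^BM, the *undesired* region is
{r : **N**r = 0, bounds, r_P − Y_min^P·r_S ≤ 0} and the *desired* region
additionally demands both yields (two rows; see README). Y_min^P is a
fraction (default levels 10/30/50 %) of the maximum product yield, which is
computed by maximizing the product export LP and dividing by the substrate
uptake realized at that optimum; to make the quotient deterministic when the
uptake limit does not bind, the uptake is minimized in a second LP at the
fixed product optimum. Y_min^BM defaults to 0.01 gDW·mmol⁻¹ substrate (for
photon-limited autotrophs a value of 10⁻⁴ gDW per mmol photons is the
appropriate order).

Strong coupling is decidable only if the zero flux vector lies outside the
undesired region — both yield rows are homogeneous, so something
inhomogeneous must exclude it. A maintenance pseudo-reaction with positive
lower bound (present in most curated models) does this naturally. When no
such reaction exists the undesired region receives an explicit minimum
uptake row r_S ≥ ε with ε = 0.001 × uptake limit; the choice of ε is
reported in the problem object and configurable.

## Configuration and repressibility

`apply_config` sets the substrate uptake limit and the maintenance lower
bound, closes all organic-metabolite exchanges except the configured
standard outflows (minimal medium; inorganic exchanges stay unlimited),
applies the oxygen condition (aerobic, removal of the oxygen exchange, or
removal of a named respiratory reaction), and derives each reaction's
repressibility. Irrepressible are: an explicit id list, exchanges,
transport reactions (participants spanning ≥ 2 compartments), pseudo
reactions (biomass, maintenance, keyword match), spontaneous reactions
(annotation keyword list, e.g. the conventional gene token `s0001`), and —
in models that carry gene associations at all — reactions without one.
"Organic" means the formula contains carbon and the compartment-stripped id
is not in the inorganic-carbon list (CO2, CO, carbonate, bicarbonate by
default; bicarbonate contains carbon, hence the explicit list).

## Compression

Before the MILP the network is reduced losslessly: linearly dependent rows
of **N** (conserved moieties) are dropped via QR with pivoting (tolerance
1e-9 relative), reactions whose kernel row vanishes (blocked at every
steady state, bounds ignored) are pruned, and fully coupled sets — reactions
with proportional kernel rows — are merged with exact scaling factors.
Merged bounds are the intersection of member bounds after scaling; a merged
reaction is repressible iff at least one member is, and a cut of a merged
reaction expands to its first repressible member, with the other repressible
members reported as interchangeable alternatives. Kernel-based coupling
deliberately ignores bounds: bound-aware coupling is condition-dependent and
could change verdicts. Compression is idempotent and verdict-preserving;
both properties are tested, and the MILP can be run without compression.

## The cMCS MILP

Infeasibility of the knockout-constrained undesired system is encoded by a
Farkas certificate (free metabolite duals u, nonnegative bound duals
lam_lb/lam_ub, nonnegative undesired-row duals w, knockout duals vp/vn)
with stationarity per reaction column and the certificate row
βᵀlam_ub − αᵀlam_lb + tᵀw ≤ −1 (any negative constant is equivalent by
scaling). vp_i > 0 certifies infeasibility of the relaxation {r_i ≤ 0},
vn_i > 0 (reversible columns only) of {r_i ≥ 0}; each contains {r_i = 0},
so either sign is a sound knockout dual, and since the dual of an equality
is one free number, one of the two always suffices — the encoding loses no
cut sets. Binary indicators zp/zn gate the duals through big-M rows
(M = 10 × max(1, largest |FVA bound|)), satisfy zp_i + zn_i ≤ 1, are fixed
to zero for irrepressible reactions, and force the desired-region flux of a
cut reaction to zero via α̂_i(1−z) ≤ r_des,i ≤ β̂_i(1−z) with original bounds
(capped where infinite). The objective minimizes Σ(zp+zn). All LPs and
MILPs run on HiGHS (scipy); the solver stops at a 98 % relative gap — the
search wants *a* cut set quickly, not the smallest — or at the configured
time limit (default 60 s per attempt, 10 attempts).

HiGHS exposes no random-seed option through scipy, so the per-attempt
"different solver seed" is realized by a seed-derived permutation of the
reaction order in the assembled MILP, which changes the branch-and-bound
exploration in the same spirit.

The flux bounds entering the dual come from an FVA over the region with the
minimum-biomass-yield row added (unbounded results capped at ±2,000
mmol·gDW⁻¹·h⁻¹); if that FVA is infeasible, coupling is impossible and the
verdict is INFEASIBLE outright. These tightened bounds can, however, let the
solver certify emptiness of a region *smaller* than the true undesired one,
producing candidates that fail verification. Every candidate is therefore
checked with two plain LPs on the original, uncompressed network with its
original (possibly infinite) bounds — valid iff the undesired region is
infeasible and the desired region feasible — and, after the first
verification failure, the remaining attempts rebuild the MILP with FVA
bounds computed *without* the biomass row, which are valid inequalities for
the undesired region itself and make the certificate genuine. INFEASIBLE
verdicts are sound under either bound set (a valid cut set would give the
MILP a feasible point), FEASIBLE verdicts are sound because verification is
big-M-free, and the whole trichotomy is checked against exhaustive
enumeration (below). Verified cut sets are reduced to true cMCS by
iteratively testing the necessity of each knockout with the
undesired-infeasibility LP (descending reaction index; different orders may
give different, equally valid minima), and `shrink_cmcs` can spend an extra
budget re-minimizing with the gap closed.

## Gene-level cut sets

Gene associations (and/or trees, `and` binding tighter) are converted to
DNF with a 64-term cap per reaction (beyond it the reaction stays
gene-irrepressible, with a warning-style error naming it). Each repressible
catalysed reaction consumes a dedicated auxiliary metabolite produced by one
enzyme pseudo-reaction per DNF term; enzymes consume gene-product
metabolites made by translation pseudo-reactions from nothing. Reversible
catalysed reactions are split into irreversible halves sharing one
auxiliary metabolite (otherwise the reverse direction would produce it).
Only translation reactions are repressible, and a translation reaction is
itself irrepressible when its gene occurs in the association of any
reaction that is irrepressible at reaction level (the conservative reading
of "affects"). Gene verdicts are mapped back to the implied reaction
disablement pattern and re-verified at reaction level.

## Screening driver

Candidates are the organic, substrate-producible internal metabolites,
excluding every compartmental instance of the substrate compound and, for
compounds with an open standard outflow, all instances except the excreted
one. Producibility is decided by the maximum-yield LP (zero ⇒ not
producible; unbounded ⇒ not limited by the substrate ⇒ excluded). A
temporary export-only exchange is added (or a closed one opened) per
candidate. Levels are processed ascending; a cut set found at a lower level
is re-verified at the next level and reused without a new MILP when valid;
after all levels, a smaller higher-level set replaces a larger lower-level
record (statistics only). The summary reports, per level, the percentages
of FEASIBLE / INFEASIBLE / UNDECIDED over the candidate count plus cMCS
size statistics. Increasing budgets can only move UNDECIDED rows to a
decided status; INFEASIBLE is certificate-backed and budget-independent.

## Synthetic fixtures and the oracle

The fixture module is first-class code: named toys (TOY1, TOY3, TOY3-G,
TOY3-G-ISO; see README and the module docstring for the hand algebra) and a
seeded generator of small networks (≈ 8–16 reactions, ≤ 6 repressible,
integer stoichiometries in {1, 2}) that always contain a limited uptake
(10 mmol·gDW⁻¹·h⁻¹), a maintenance demand with lower bound 1, a biomass
sink and at least one producible organic product. The generator mixes two
archetypes — maintenance on a catabolic co-product (coupling often
feasible) versus directly on the substrate pool (provably infeasible) — so
a seed census contains both ground truths in quantity. The exhaustive
oracle enumerates all subsets of repressible reactions with two plain LPs
each and returns the full family of inclusion-minimal valid cut sets; it
shares no code path with the MILP (original network, true bounds, no
big-M). What the fixtures do *not* emulate: genome-scale size, cofactor
redundancy, compartmentalization beyond a token case, and thermodynamic
loops — so passing tests demonstrate algorithmic correctness, not biological
performance on genome-scale models, whose runs remain hours-to-days of
solver time and are out of the test suite's scope.

## Numerical choices and limitations

* Feasibility/zero tolerance 1e-6 on the natural flux scale everywhere
  (COBRA practice); kernel/rank tolerances 1e-9.
* Problem sizes in the test suite and the acceptance script (100 and 60
  random fixtures, toy networks) were chosen so the whole suite runs in
  about a minute on one CPU while still covering both verdict classes in
  quantity.
* Big-M linking means an extremely ill-scaled model could in principle hide
  a certificate beyond M; verification prevents unsound FEASIBLE verdicts,
  and the oracle-equivalence tests bound the risk at desk scale. Solver
  indicator constraints would remove the issue where available.
* The ±2,000 flux cap makes FVA bounds finite for the dual; models with
  genuine fluxes beyond the cap would need it raised in the configuration.
* Co-utilized substrates, weak coupling (yield demanded only at maximal
  growth) and enumeration of *all* smallest cMCS are out of scope.
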