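"""Verification and minimization of candidate cut sets with plain LPs.

Verification always runs on the original network with its original
(possibly infinite) bounds — it is big-M-free and independent of the FVA
tightening used inside the MILP, so it is the soundness gate for every
candidate the solver returns.
"""

from __future__ import annotations

from . import lp_core
from .intervention import CouplingProblem


def verify_cutset(problem: CouplingProblem, cutset) -> dict:
    """Two LP feasibility checks: valid iff the undesired region becomes
    infeasible and the desired region stays feasible under the knockouts."""
    cutset = frozenset(cutset)
    bad = cutset - problem.repressible
    if bad:
        raise ValueError(f"cut set contains irrepressible reactions: {sorted(bad)}")
    undesired = lp_core.check_region_feasible(problem.undesired_region(cutset)).feasible
    desired = lp_core.check_region_feasible(problem.desired_region(cutset)).feasible
    return {"valid": (not undesired) and desired,
            "undesired_feasible": undesired, "desired_feasible": desired}


def reduce_to_cmcs(problem: CouplingProblem, cutset) -> frozenset:
    """Iteratively drop unnecessary knockouts until the set is a true cMCS.

    Removal only needs the undesired-infeasibility LP (desired feasibility is
    monotone under removing cuts); knockouts are visited in descending
    reaction index — different orders may yield different, equally valid,
    minimal sets. A final full verification guards the result.
    """
    cutset = frozenset(cutset)
    if not verify_cutset(problem, cutset)["valid"]:
        raise ValueError("reduce_to_cmcs requires a valid cut set")
    ridx = problem.network.reaction_index
    current = set(cutset)
    for rid in sorted(cutset, key=lambda r: -ridx[r]):
        trial = current - {rid}
        if not lp_core.check_region_feasible(problem.undesired_region(frozenset(trial))).feasible:
            current = trial
    result = frozenset(current)
    assert verify_cutset(problem, result)["valid"]
    return result


def applicable_at(problem: CouplingProblem, cutset) -> bool:
    """Whether a cut set found at a lower yield level still verifies here
    (the screening driver reuses it and skips the MILP when it does)."""
    return verify_cutset(problem, cutset)["valid"]


def shrink_cmcs(problem: CouplingProblem, cutset, budget_s: float,
                config=None):
    """Attempt to find a smaller cMCS within a time budget by re-running the
    minimization MILP with the gap closed. Returns (cut set, proven_optimal);
    proven_optimal is True only when the solver certifies optimality."""
    from . import compression, milp  # deferred: milp imports this module
    from .network_io import ModelConfig

    cutset = frozenset(cutset)
    if budget_s <= 0:
        return cutset, False
    if config is None:
        config = ModelConfig(substrate_exchange_id=problem.substrate_id,
                             biomass_reaction_id=problem.biomass_id)
    cnet, cmap = compression.compress(problem.network)
    cproblem = milp._translate_problem(problem, cnet, cmap)
    biomass_row = lp_core.LinearConstraintSet([cproblem.desired.rows[1]])
    table = lp_core.fva(lp_core.FluxRegion(cnet, extra=biomass_row), config.flux_cap)
    if table == lp_core.FVA_INFEASIBLE:
        return cutset, False
    struct = milp.assemble_cmcs_milp(cproblem, table)
    kind, cand, proven_optimal = milp.solve_cmcs_once(struct, budget_s, config.rng_seed, gap=0.0)
    if kind != "cutset":
        return cutset, False
    cand_orig, _ = compression.expand_cutset(cmap, cand)
    if not verify_cutset(problem, cand_orig)["valid"]:
        return cutset, False
    cand_min = reduce_to_cmcs(problem, cand_orig)
    best = cand_min if len(cand_min) < len(cutset) else cutset
    return best, proven_optimal


def cutsets_to_tsv(rows, path) -> None:
    """rows: iterable of (metabolite, level, cutset, alternatives dict)."""
    with open(path, "w") as fh:
        fh.write("metabolite\tlevel\tsize\treactions\talternatives\n")
        for met, level, cut, alts in rows:
            alt_txt = "|".join(f"{rid}:{','.join(alts.get(rid, [rid]))}" for rid in sorted(cut))
            fh.write(f"{met}\t{level}\t{len(cut)}\t{';'.join(sorted(cut))}\t{alt_txt}\n")
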