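"""The cMCS MILP: find a knockout set whose Farkas certificate proves the
undesired flux region empty while a primal desired flux survives.

For the undesired system {N r = 0, alpha <= r <= beta, T r <= t, r_i = 0 for
cut i} (all bounds finite, from FVA), infeasibility is equivalent to the
existence of a Farkas certificate

    N^T u + lam_ub - lam_lb + T^T w + vp - vn = 0        (per reaction column)
    beta^T lam_ub - alpha^T lam_lb + t^T w <= -1         (certificate row)

with u free, lam_lb, lam_ub, w, vp, vn >= 0; vn exists only for reversible
columns. vp_i > 0 (or vn_i > 0) certifies infeasibility of the relaxation
{r_i <= 0} (resp. {r_i >= 0}), each of which contains {r_i = 0}, so either
sign is a sound knockout dual; a free dual is one-signed, so one of the two
always suffices. Binary indicators zp_i, zn_i gate the knockout duals via
big-M rows (vp_i <= M zp_i, vn_i <= M zn_i, zp_i + zn_i <= 1) and force the
corresponding desired-flux variable to zero; indicators of irrepressible
reactions are fixed to zero. The objective minimizes the number of cuts.

Because the FVA bounds entering the dual are tightened by the minimum
biomass yield, a returned assignment may certify only the tightened region;
every candidate cut set is therefore re-verified with plain LPs on the
original network before a FEASIBLE verdict is issued. MILP infeasibility
remains a sound proof that coupling is impossible: a valid cut set would
yield both a certificate for the (smaller) tightened region and a desired
flux, i.e. a feasible MILP point.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp as scipy_milp

from . import compression, cutset_tools, intervention, lp_core
from .network_io import INF, MetabolicNetwork, ModelConfig

STATUS_FEASIBLE = "FEASIBLE"
STATUS_INFEASIBLE = "INFEASIBLE"
STATUS_UNDECIDED = "UNDECIDED"


@dataclass
class Verdict:
    status: str
    cutset: frozenset | None = None
    attempts: list = field(default_factory=list)
    proven_minimal: bool = False
    alternatives: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status == STATUS_FEASIBLE:
            assert self.cutset is not None


@dataclass
class MilpStructure:
    """Symbolic cMCS MILP: matrices are materialized per solver seed (the seed
    permutes the reaction order, changing the branch-and-bound exploration)."""

    problem: intervention.CouplingProblem
    finite_bounds: dict[str, tuple[float, float]]
    M: float

    @property
    def network(self) -> MetabolicNetwork:
        return self.problem.network

    def counts(self) -> dict[str, int]:
        net = self.network
        rev = [r for r in net.reactions if r.reversible]
        free_binaries = sum(1 for r in net.reactions if r.id in self.problem.repressible)
        free_binaries += sum(1 for r in rev if r.id in self.problem.repressible)
        return {
            "u": len(net.internal_metabolites),
            "vp": len(net.reactions),
            "vn": len(rev),
            "free_binaries": free_binaries,
        }


def assemble_cmcs_milp(problem: intervention.CouplingProblem,
                       finite_bounds: dict[str, tuple[float, float]],
                       M: float | None = None) -> MilpStructure:
    """Build the MILP structure; every reaction must carry finite FVA bounds."""
    for r in problem.network.reactions:
        if r.id not in finite_bounds:
            raise ValueError(f"no FVA bounds for reaction {r.id}; run FVA first")
        lo, hi = finite_bounds[r.id]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"non-finite FVA bound for {r.id}; run FVA with a flux cap first")
    if M is None:
        bmax = max((max(abs(lo), abs(hi)) for lo, hi in finite_bounds.values()), default=1.0)
        M = 10.0 * max(1.0, bmax)
    return MilpStructure(problem, dict(finite_bounds), M)


def _normalized_undesired_rows(problem: intervention.CouplingProblem):
    rows = []
    for coeffs, sense, rhs in problem.undesired:
        if sense == "<=":
            rows.append((coeffs, rhs))
        elif sense == ">=":
            rows.append(({k: -v for k, v in coeffs.items()}, -rhs))
        else:  # equality as two inequalities
            rows.append((coeffs, rhs))
            rows.append(({k: -v for k, v in coeffs.items()}, -rhs))
    return rows


def _materialize(struct: MilpStructure, rng: np.random.Generator):
    """Build (c, integrality, bounds, constraints, decode) with a seed-permuted
    reaction order."""
    net = struct.network
    prob = struct.problem
    n = len(net.reactions)
    perm = rng.permutation(n)
    rxns = [net.reactions[i] for i in perm]
    rid_pos = {r.id: j for j, r in enumerate(rxns)}
    m_index = {m.id: i for i, m in enumerate(net.internal_metabolites)}
    m = len(m_index)
    rev_pos = [j for j, r in enumerate(rxns) if r.reversible]
    rev_of = {j: k for k, j in enumerate(rev_pos)}
    n_rev = len(rev_pos)
    t_rows = _normalized_undesired_rows(prob)
    nT = len(t_rows)
    rep = [r.id in prob.repressible for r in rxns]

    # variable layout
    off_u = 0
    off_llb = off_u + m
    off_lub = off_llb + n
    off_w = off_lub + n
    off_vp = off_w + nT
    off_vn = off_vp + n
    off_zp = off_vn + n_rev
    off_zn = off_zp + n
    off_r = off_zn + n_rev
    nvar = off_r + n

    lo = np.full(nvar, -np.inf)
    hi = np.full(nvar, np.inf)
    lo[off_llb:off_r] = 0.0  # all blocks after u are nonnegative / binary
    hi[off_vp:off_vp + n] = [struct.M if rep[j] else 0.0 for j in range(n)]
    hi[off_vn:off_vn + n_rev] = [struct.M if rep[j] else 0.0 for j in rev_pos]
    hi[off_zp:off_zp + n] = [1.0 if rep[j] else 0.0 for j in range(n)]
    hi[off_zn:off_zn + n_rev] = [1.0 if rep[j] else 0.0 for j in rev_pos]
    alpha = np.array([struct.finite_bounds[r.id][0] for r in rxns])
    beta = np.array([struct.finite_bounds[r.id][1] for r in rxns])
    cap = max(struct.M / 10.0, 1.0)
    a_des = np.array([max(r.lb, -cap) if r.lb != -INF else -cap for r in rxns])
    b_des = np.array([min(r.ub, cap) if r.ub != INF else cap for r in rxns])
    lo[off_r:off_r + n] = a_des
    hi[off_r:off_r + n] = b_des

    integrality = np.zeros(nvar)
    integrality[off_zp:off_r] = 1

    c = np.zeros(nvar)
    c[off_zp:off_r] = 1.0

    rows_i, cols_i, vals, con_lo, con_hi = [], [], [], [], []
    row = 0

    def add(entries, lb_, ub_):
        nonlocal row
        for col, val in entries:
            rows_i.append(row)
            cols_i.append(col)
            vals.append(val)
        con_lo.append(lb_)
        con_hi.append(ub_)
        row += 1

    # (a) stationarity per reaction column
    for j, r in enumerate(rxns):
        entries = [(off_u + m_index[mid], coef) for mid, coef in r.stoich.items()
                   if mid in m_index]
        entries.append((off_lub + j, 1.0))
        entries.append((off_llb + j, -1.0))
        for ti, (coeffs, _) in enumerate(t_rows):
            if r.id in coeffs:
                entries.append((off_w + ti, coeffs[r.id]))
        entries.append((off_vp + j, 1.0))
        if j in rev_of:
            entries.append((off_vn + rev_of[j], -1.0))
        add(entries, 0.0, 0.0)

    # certificate row: beta^T lam_ub - alpha^T lam_lb + t^T w <= -1
    entries = [(off_lub + j, beta[j]) for j in range(n)]
    entries += [(off_llb + j, -alpha[j]) for j in range(n)]
    entries += [(off_w + ti, rhs) for ti, (_, rhs) in enumerate(t_rows)]
    add(entries, -np.inf, -1.0)

    # (c) big-M links and zp+zn<=1, repressible reactions only
    for j in range(n):
        if not rep[j]:
            continue
        add([(off_vp + j, 1.0), (off_zp + j, -struct.M)], -np.inf, 0.0)
        if j in rev_of:
            k = rev_of[j]
            add([(off_vn + k, 1.0), (off_zn + k, -struct.M)], -np.inf, 0.0)
            add([(off_zp + j, 1.0), (off_zn + k, 1.0)], -np.inf, 1.0)

    # (b) desired primal: N r = 0
    met_rows: dict[int, list[tuple[int, float]]] = {i: [] for i in range(m)}
    for j, r in enumerate(rxns):
        for mid, coef in r.stoich.items():
            if mid in m_index:
                met_rows[m_index[mid]].append((off_r + j, coef))
    for i in range(m):
        add(met_rows[i], 0.0, 0.0)
    # D r <= d
    for coeffs, sense, rhs in prob.desired:
        entries = [(off_r + rid_pos[rid], coef) for rid, coef in coeffs.items()]
        if sense == "<=":
            add(entries, -np.inf, rhs)
        elif sense == ">=":
            add(entries, rhs, np.inf)
        else:
            add(entries, rhs, rhs)
    # knockout linking: a(1 - z) <= r_des <= b(1 - z)
    for j in range(n):
        if not rep[j]:
            continue
        zcols = [(off_zp + j, 1.0)]
        if j in rev_of:
            zcols.append((off_zn + rev_of[j], 1.0))
        add([(off_r + j, 1.0)] + [(col, b_des[j] * v) for col, v in zcols], -np.inf, b_des[j])
        add([(off_r + j, -1.0)] + [(col, -a_des[j] * v) for col, v in zcols], -np.inf, -a_des[j])

    A = sparse.csc_matrix((vals, (rows_i, cols_i)), shape=(row, nvar))
    constraint = LinearConstraint(A, np.array(con_lo), np.array(con_hi))

    def decode(x: np.ndarray) -> frozenset:
        cut = set()
        for j, r in enumerate(rxns):
            z = x[off_zp + j]
            if j in rev_of:
                z = max(z, x[off_zn + rev_of[j]])
            if rep[j] and z > 0.5:
                cut.add(r.id)
        return frozenset(cut)

    return c, integrality, Bounds(lo, hi), constraint, decode


def solve_cmcs_once(struct: MilpStructure, time_limit_s: float, seed: int,
                    gap: float):
    """One MILP attempt. Returns ("cutset", frozenset, proven_optimal),
    ("infeasible", None, False) or ("timeout", None, False); the cut set is
    the z-support (possibly non-minimal, possibly suboptimal — the solver
    stops at the configured relative gap)."""
    rng = np.random.default_rng(seed)
    try:
        c, integrality, bounds, constraint, decode = _materialize(struct, rng)
        res = scipy_milp(c=c, constraints=constraint, integrality=integrality,
                         bounds=bounds,
                         options={"time_limit": float(time_limit_s),
                                  "mip_rel_gap": float(gap)})
    except Exception:  # noqa: BLE001 - solver crash counts as a failed attempt
        return "timeout", None, False
    if res.status == 2:
        return "infeasible", None, False
    if res.x is not None:
        return "cutset", decode(res.x), res.status == 0 and gap == 0.0
    return "timeout", None, False


def find_cmcs(problem: intervention.CouplingProblem, config: ModelConfig,
              use_compression: bool = True) -> Verdict:
    """Full pipeline for one product/yield level: wild-type guards, network
    compression, FVA flux bounding, time-limited MILP with seed retries, LP
    verification on the original network, and reduction to a true cMCS."""
    attempts: list[tuple] = []
    sanity = intervention.wildtype_sanity(problem)
    if not sanity["desired_feasible"]:
        return Verdict(STATUS_INFEASIBLE, attempts=[("wildtype", 0.0, "desired infeasible")])
    if not sanity["undesired_feasible"]:
        return Verdict(STATUS_FEASIBLE, cutset=frozenset(), proven_minimal=True,
                       attempts=[("wildtype", 0.0, "already coupled")])

    if use_compression:
        # the problem's repressible set is authoritative (it may be narrower
        # than the network's flags, e.g. for what-if analyses)
        net = problem.network.copy()
        for r in net.reactions:
            r.repressible = r.id in problem.repressible
        cnet, cmap = compression.compress(net)
        cproblem = _translate_problem(problem, cnet, cmap)
    else:
        cnet, cmap = problem.network, None
        cproblem = problem

    # FVA with the minimum-biomass-yield row; infeasible => coupling impossible
    biomass_row = lp_core.LinearConstraintSet([cproblem.desired.rows[1]])
    table = lp_core.fva(lp_core.FluxRegion(cnet, extra=biomass_row), config.flux_cap)
    if table == lp_core.FVA_INFEASIBLE:
        return Verdict(STATUS_INFEASIBLE, attempts=[("fva", 0.0, "biomass-yield FVA infeasible")])

    struct = assemble_cmcs_milp(cproblem, table)
    sound_bounds = False
    for attempt in range(config.milp_retries):
        seed = (config.rng_seed + attempt) % (2**31)
        t0 = time.perf_counter()
        kind, cut, _ = solve_cmcs_once(struct, config.milp_time_limit_s, seed, config.milp_gap)
        dt = time.perf_counter() - t0
        if kind == "infeasible":
            attempts.append((seed, dt, "proven-infeasible"))
            return Verdict(STATUS_INFEASIBLE, attempts=attempts)
        if kind == "timeout":
            attempts.append((seed, dt, "timeout"))
            continue
        if cmap is not None:
            cut_orig, alts = compression.expand_cutset(cmap, cut)
        else:
            cut_orig, alts = frozenset(cut), {rid: [rid] for rid in cut}
        check = cutset_tools.verify_cutset(problem, cut_orig)
        if not check["valid"]:
            attempts.append((seed, dt, "candidate failed verification"))
            if not sound_bounds:
                # the biomass-yield-tightened FVA bounds can certify emptiness
                # of a region smaller than the true undesired one; switch the
                # remaining attempts to bounds valid for the undesired region
                table2 = lp_core.fva(lp_core.FluxRegion(cnet), config.flux_cap)
                if table2 != lp_core.FVA_INFEASIBLE:
                    struct = assemble_cmcs_milp(cproblem, table2)
                sound_bounds = True
            continue
        reduced = cutset_tools.reduce_to_cmcs(problem, cut_orig)
        attempts.append((seed, dt, f"cutset size {len(reduced)}"))
        alts = {rid: alts.get(rid, [rid]) for rid in reduced}
        return Verdict(STATUS_FEASIBLE, cutset=reduced, attempts=attempts,
                       proven_minimal=True, alternatives=alts)
    return Verdict(STATUS_UNDECIDED, attempts=attempts)


def _translate_problem(problem: intervention.CouplingProblem,
                       cnet: MetabolicNetwork,
                       cmap: compression.CompressionMap) -> intervention.CouplingProblem:
    m2g = cmap.member_to_group
    und = lp_core.LinearConstraintSet(
        compression.translate_constraints(problem.undesired, cmap, cnet))
    des = lp_core.LinearConstraintSet(
        compression.translate_constraints(problem.desired, cmap, cnet))
    repressible = frozenset(r.id for r in cnet.reactions if r.repressible)

    def role(rid: str) -> str:
        if rid in m2g:
            return m2g[rid][0]
        return rid  # blocked role reaction: leave id (degenerate, caught by LPs)

    return intervention.CouplingProblem(
        cnet, role(problem.substrate_id), problem.substrate_sign,
        role(problem.product_id), role(problem.biomass_id),
        problem.y_min_product, problem.y_min_biomass,
        und, des, repressible, problem.zero_exclusion)
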