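"""Linear-programming primitives: feasibility, FBA-style maximization, FVA,
operative-reaction detection and maximum product yield.

All LPs run on scipy's HiGHS backend. The feasibility/zero tolerance is 1e-6
on the natural flux scale (mmol·gDW⁻¹·h⁻¹), standard COBRA practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .network_io import INF, MetabolicNetwork, ModelConfig

TOL = 1e-6

FVA_INFEASIBLE = "INFEASIBLE"


@dataclass
class LinearConstraintSet:
    """Rows of (coefficient map reaction-id -> real, sense, rhs).

    Houses the undesired (T, t) and desired (D, d) region descriptions as
    well as ad-hoc rows (minimum biomass yield for FVA, etc.).
    """

    rows: list[tuple[dict[str, float], str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for coeffs, sense, rhs in self.rows:
            if sense not in ("<=", ">=", "="):
                raise ValueError(f"unknown sense {sense!r}")
            if not np.isfinite(rhs):
                raise ValueError("constraint rhs must be finite")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class FluxRegion:
    """{r : N r = 0, lb <= r <= ub, extra rows hold, r_i = 0 for knocked out}."""

    network: MetabolicNetwork
    extra: LinearConstraintSet | None = None
    knocked_out: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.knocked_out = frozenset(self.knocked_out)
        ridx = self.network.reaction_index
        unknown = [rid for rid in self.knocked_out if rid not in ridx]
        if self.extra is not None:
            unknown += [rid for coeffs, _, _ in self.extra for rid in coeffs if rid not in ridx]
        if unknown:
            raise ValueError(f"constraints reference unknown reactions: {sorted(set(unknown))}")


@dataclass
class FeasibilityResult:
    feasible: bool
    witness: dict[str, float] | None = None


def _build_lp(region: FluxRegion):
    net = region.network
    n = len(net.reactions)
    ridx = net.reaction_index
    N = net.stoichiometric_matrix()
    A_eq_rows = [N]
    b_eq = [np.zeros(N.shape[0])]
    A_ub_rows, b_ub = [], []
    if region.extra is not None:
        for coeffs, sense, rhs in region.extra:
            row = np.zeros(n)
            for rid, c in coeffs.items():
                row[ridx[rid]] += c
            if sense == "=":
                A_eq_rows.append(sparse.csr_matrix(row))
                b_eq.append(np.array([rhs]))
            elif sense == "<=":
                A_ub_rows.append(row)
                b_ub.append(rhs)
            else:  # >=
                A_ub_rows.append(-row)
                b_ub.append(-rhs)
    A_eq = sparse.vstack(A_eq_rows, format="csr")
    b_eq = np.concatenate(b_eq)
    A_ub = np.array(A_ub_rows) if A_ub_rows else None
    b_ub = np.array(b_ub) if b_ub else None
    bounds = []
    for r in net.reactions:
        if r.id in region.knocked_out:
            bounds.append((0.0, 0.0))
        else:
            bounds.append((None if r.lb == -INF else r.lb, None if r.ub == INF else r.ub))
    return A_eq, b_eq, A_ub, b_ub, bounds


def _solve(region: FluxRegion, c: np.ndarray):
    A_eq, b_eq, A_ub, b_ub, bounds = _build_lp(region)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 4:  # numerical trouble: retry without presolve, then rescaled
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs", options={"presolve": False})
    if res.status == 4:
        scale = max(1.0, float(abs(c).max()) if np.any(c) else 1.0)
        res = linprog(c / scale, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        if res.status == 4:
            raise RuntimeError(f"LP solver failure: {res.message}")
        res.fun = res.fun * scale if res.fun is not None else None
    return res


def check_region_feasible(region: FluxRegion) -> FeasibilityResult:
    """LP feasibility of a flux region, with a witness flux vector when feasible."""
    res = _solve(region, np.zeros(len(region.network.reactions)))
    if res.status == 0 or res.status == 3:  # unbounded with c=0 cannot occur, but be safe
        witness = {r.id: float(x) for r, x in zip(region.network.reactions, res.x)}
        return FeasibilityResult(True, witness)
    return FeasibilityResult(False, None)


def maximize(region: FluxRegion, objective: Mapping[str, float]):
    """Maximize a linear flux objective. Returns (status, value) with status in
    {"optimal", "unbounded", "infeasible"}; value is None unless optimal."""
    net = region.network
    c = np.zeros(len(net.reactions))
    ridx = net.reaction_index
    for rid, coef in objective.items():
        c[ridx[rid]] += coef
    res = _solve(region, -c)
    if res.status == 0:
        return "optimal", float(-res.fun)
    if res.status == 3:
        return "unbounded", None
    return "infeasible", None


@dataclass
class YieldResult:
    status: str  # "yield" | "zero" | "unbounded" | "infeasible"
    value: float | None = None
    uptake: float | None = None


def max_product_yield(network: MetabolicNetwork, product_exchange: str,
                      config: ModelConfig) -> YieldResult:
    """Maximum product flux divided by the substrate uptake realized at the optimum.

    The product flux is maximized first; the uptake is then minimized at the
    fixed product optimum so the reported yield is deterministic when the
    uptake limit does not bind.
    """
    region = FluxRegion(network)
    status, pmax = maximize(region, {product_exchange: 1.0})
    if status == "unbounded":
        return YieldResult("unbounded")
    if status == "infeasible":
        return YieldResult("infeasible")
    if pmax <= TOL:
        return YieldResult("zero", 0.0)
    sigma = config.substrate_orientation
    fixed = LinearConstraintSet([({product_exchange: 1.0}, ">=", pmax * (1 - 1e-9))])
    status2, up = maximize(FluxRegion(network, extra=fixed),
                           {config.substrate_exchange_id: -sigma})
    uptake = -up if status2 == "optimal" else None
    if uptake is None or uptake <= TOL:
        # producible without consuming the limited substrate -> not substrate-bounded
        return YieldResult("unbounded")
    return YieldResult("yield", pmax / uptake, uptake)


def fva(region: FluxRegion, flux_cap: float,
        reactions: Sequence[str] | None = None):
    """Per-reaction [min, max] over the region; unbounded results are capped
    at ±flux_cap. Returns FVA_INFEASIBLE if the region itself is infeasible."""
    net = region.network
    if not check_region_feasible(region).feasible:
        return FVA_INFEASIBLE
    ids = list(reactions) if reactions is not None else [r.id for r in net.reactions]
    table: dict[str, tuple[float, float]] = {}
    for rid in ids:
        lo_status, lo = maximize(region, {rid: -1.0})
        lo = -lo if lo_status == "optimal" else -flux_cap
        hi_status, hi = maximize(region, {rid: 1.0})
        if hi_status == "optimal":
            hi_val = hi
        else:
            hi_val = flux_cap
        lo = max(lo, -flux_cap)
        hi_val = min(hi_val, flux_cap)
        table[rid] = (min(lo, hi_val), hi_val)
    return table


def fva_to_tsv(table: Mapping[str, tuple[float, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tmin\tmax\n")
        for rid, (lo, hi) in table.items():
            fh.write(f"{rid}\t{lo:.9g}\t{hi:.9g}\n")


def operative_reactions(network: MetabolicNetwork, config: ModelConfig) -> set[str]:
    """Reactions that can carry flux under the configured medium (FVA max |flux| > tol)."""
    table = fva(FluxRegion(network), config.flux_cap)
    if table == FVA_INFEASIBLE:
        return set()
    return {rid for rid, (lo, hi) in table.items() if max(abs(lo), abs(hi)) > TOL}
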