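"""Per-metabolite driver and whole-model batch screen.

For every substrate-producible organic metabolite and every demanded minimum
yield level, the screen decides whether strong growth coupling is FEASIBLE
(with a verified cMCS), provably INFEASIBLE, or UNDECIDED within the solver
budget, and summarizes the three fractions per level.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import pandas as pd

from . import cutset_tools, intervention, lp_core, milp
from .network_io import INF, MetabolicNetwork, ModelConfig, Reaction, is_organic

logger = logging.getLogger(__name__)

TMP_EXCHANGE_PREFIX = "EXPORT__"


@dataclass
class ScreeningResult:
    table: pd.DataFrame
    summary: pd.DataFrame
    candidates: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def ensure_export_exchange(network: MetabolicNetwork, met_id: str):
    """Return (network', exchange id, added flag): an export-only exchange for
    the metabolite, added when absent and opened for export when closed."""
    for rxn in network.exchanges:
        met = network.exchange_metabolite(rxn)
        if met is not None and met.id == met_id:
            if rxn.ub <= 0:  # exists but closed: open export only, temporarily
                net = network.copy()
                r = net.reaction(rxn.id)
                r.lb, r.ub = 0.0, INF
                return net, rxn.id, True
            return network, rxn.id, False
    net = network.copy()
    rid = TMP_EXCHANGE_PREFIX + met_id
    net.reactions.append(Reaction(rid, {met_id: -1.0}, f"temporary export of {met_id}",
                                  0.0, INF, repressible=False, is_exchange=True))
    return net, rid, True


def enumerate_candidates(network: MetabolicNetwork, config: ModelConfig) -> list[str]:
    """Organic, substrate-producible metabolites eligible for coupling.

    Every compartmental instance of the substrate compound is excluded; for a
    compound with an open standard outflow only the excreted (extracellular)
    instance is a candidate. Metabolites whose maximum yield is zero or not
    bounded by the limited substrate are dropped.
    """
    sub_rxn = network.reaction(config.substrate_exchange_id)
    sub_met = network.exchange_metabolite(sub_rxn)
    sub_key = sub_met.compound_key if sub_met is not None else None

    outflow_keys: dict[str, str] = {}  # compound key -> excreted metabolite id
    for rid in config.open_outflow_ids:
        met = network.exchange_metabolite(network.reaction(rid))
        if met is not None:
            outflow_keys[met.compound_key] = met.id

    candidates = []
    for met in network.internal_metabolites:
        if not is_organic(met, config):
            continue
        if sub_key is not None and met.compound_key == sub_key:
            continue
        if met.compound_key in outflow_keys and met.id != outflow_keys[met.compound_key]:
            continue
        net2, ex_id, _ = ensure_export_exchange(network, met.id)
        yres = lp_core.max_product_yield(net2, ex_id, config)
        if yres.status == "yield":
            candidates.append(met.id)
    return candidates


@dataclass
class LevelVerdict:
    level: float
    verdict: milp.Verdict
    reused: bool = False
    wall_time_s: float = 0.0


def screen_metabolite(network: MetabolicNetwork, config: ModelConfig, met_id: str,
                      levels=None) -> list[LevelVerdict]:
    """Steps of the per-metabolite procedure: temporary export exchange,
    ascending yield levels with cut-set reuse, MILP search with verification,
    and the cross-level replacement of larger lower-level cut sets."""
    levels = sorted(levels if levels is not None else config.yield_levels)
    net, ex_id, _added = ensure_export_exchange(network, met_id)
    out: list[LevelVerdict] = []
    prev_cut: frozenset | None = None
    for level in levels:
        t0 = time.perf_counter()
        try:
            problem = intervention.build_coupling_problem(net, config, ex_id, level)
        except ValueError:
            out.append(LevelVerdict(level, milp.Verdict(
                milp.STATUS_INFEASIBLE, attempts=[("candidate", 0.0, "not producible")]),
                wall_time_s=time.perf_counter() - t0))
            continue
        if prev_cut is not None and cutset_tools.applicable_at(problem, prev_cut):
            # step-5 reuse: the lower-level cut set verifies here; skip the MILP
            verdict = milp.Verdict(milp.STATUS_FEASIBLE, cutset=prev_cut,
                                   proven_minimal=False,
                                   attempts=[("reuse", 0.0, "lower-level cut set reused")])
            out.append(LevelVerdict(level, verdict, reused=True,
                                    wall_time_s=time.perf_counter() - t0))
            continue
        verdict = milp.find_cmcs(problem, config)
        if verdict.status == milp.STATUS_FEASIBLE:
            prev_cut = verdict.cutset
        out.append(LevelVerdict(level, verdict, wall_time_s=time.perf_counter() - t0))

    # cross-level replacement: a smaller higher-level set replaces a larger
    # lower-level record (statistics only; validity is monotone downward)
    best: frozenset | None = None
    for lv in reversed(out):
        if lv.verdict.status != milp.STATUS_FEASIBLE:
            continue
        if best is not None and len(best) < len(lv.verdict.cutset):
            lv.verdict = replace(lv.verdict, cutset=best, proven_minimal=False)
        else:
            best = lv.verdict.cutset
    return out


def screen_model(network: MetabolicNetwork, config: ModelConfig,
                 levels=None) -> ScreeningResult:
    """Batch screen: every candidate metabolite x every yield level."""
    levels = sorted(levels if levels is not None else config.yield_levels)
    candidates = enumerate_candidates(network, config)
    rows = []
    for met_id in candidates:
        try:
            per_level = screen_metabolite(network, config, met_id, levels)
        except Exception as exc:  # noqa: BLE001 - isolate per-metabolite failures
            logger.error("screening %s failed: %s", met_id, exc)
            per_level = [LevelVerdict(lvl, milp.Verdict(
                milp.STATUS_UNDECIDED, attempts=[("error", 0.0, str(exc))]))
                for lvl in levels]
        for lv in per_level:
            cut = lv.verdict.cutset
            rows.append({
                "metabolite": met_id,
                "level": lv.level,
                "status": lv.verdict.status,
                "cutset_size": len(cut) if cut is not None else pd.NA,
                "cutset": ";".join(sorted(cut)) if cut else "",
                "reused": lv.reused,
                "attempts": len(lv.verdict.attempts),
                "wall_time_s": round(lv.wall_time_s, 4),
            })
    table = pd.DataFrame(rows, columns=["metabolite", "level", "status", "cutset_size",
                                        "cutset", "reused", "attempts", "wall_time_s"])
    summary = _summarize(table, levels, len(candidates))
    return ScreeningResult(table, summary, candidates)


def _summarize(table: pd.DataFrame, levels, n_candidates: int) -> pd.DataFrame:
    rows = []
    for level in levels:
        sub = table[table["level"] == level]
        n = len(sub)
        counts = sub["status"].value_counts()
        feas = int(counts.get(milp.STATUS_FEASIBLE, 0))
        infeas = int(counts.get(milp.STATUS_INFEASIBLE, 0))
        undec = int(counts.get(milp.STATUS_UNDECIDED, 0))
        sizes = sub.loc[sub["status"] == milp.STATUS_FEASIBLE, "cutset_size"].dropna()
        rows.append({
            "level": level,
            "n_candidates": n_candidates,
            "percent_feasible": 100.0 * feas / n if n else 0.0,
            "percent_infeasible": 100.0 * infeas / n if n else 0.0,
            "percent_undecided": 100.0 * undec / n if n else 0.0,
            "mean_cmcs_size": float(sizes.mean()) if len(sizes) else float("nan"),
            "max_cmcs_size": int(sizes.max()) if len(sizes) else 0,
        })
    return pd.DataFrame(rows)
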