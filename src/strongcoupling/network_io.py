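"""Metabolic network representation, model IO and medium/repressibility configuration.

The internal representation is deliberately small: a :class:`MetabolicNetwork`
is an ordered list of metabolites and reactions from which the m x n
stoichiometric matrix ``N`` (internal metabolites only) is derived on demand.
Fluxes are in mmol·gDW⁻¹·h⁻¹ throughout; exchange reactions are written
export-positive except that the substrate exchange's orientation is declared
in :class:`ModelConfig` (BiGG models encode uptake as negative exchange flux).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import sparse

logger = logging.getLogger(__name__)

INF = math.inf

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str | None) -> dict[str, int] | None:
    """Parse a Hill-notation chemical formula into an element-count map."""
    if text is None or text == "":
        return None
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            return None  # unparseable (e.g. polymer 'R' groups with parens)
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        return None
    return counts


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: dict[str, int] | None = None
    is_boundary: bool = False

    @property
    def compound_key(self) -> str:
        """Metabolite id with its compartment suffix stripped.

        BiGG-style ids append ``_<compartment>``; instances of the same
        compound in different compartments share the key.
        """
        suffix = "_" + self.compartment
        if self.compartment and self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float] = field(default_factory=dict)
    name: str = ""
    lb: float = 0.0
    ub: float = INF
    repressible: bool = False
    gpr: str | None = None
    is_exchange: bool = False

    @property
    def reversible(self) -> bool:
        # the stored bound is authoritative: reversible == negative flux allowed
        return self.lb < 0

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoich), self.name, self.lb, self.ub,
                        self.repressible, self.gpr, self.is_exchange)


class MetabolicNetwork:
    """Ordered metabolites + reactions with the implied stoichiometric matrix."""

    def __init__(self, metabolites: Iterable[Metabolite], reactions: Iterable[Reaction]):
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self._check_unique_ids()

    def _check_unique_ids(self) -> None:
        for kind, items in (("metabolite", self.metabolites), ("reaction", self.reactions)):
            seen: set[str] = set()
            dups = [x.id for x in items if x.id in seen or seen.add(x.id)]
            if dups:
                raise ValueError(f"duplicate {kind} ids: {sorted(set(dups))}")

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self.metabolite_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.reaction_index[rid]]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_boundary]

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """m x n matrix over internal metabolites; boundary species are dropped."""
        internal = {m.id: i for i, m in enumerate(self.internal_metabolites)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoich.items():
                if mid not in internal:
                    if mid not in self.metabolite_index:
                        raise ValueError(f"reaction {rxn.id} references unknown metabolite {mid}")
                    continue  # boundary species
                rows.append(internal[mid])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix((vals, (rows, cols)),
                                 shape=(len(internal), len(self.reactions)))

    def validate(self) -> None:
        N = self.stoichiometric_matrix()
        col_nnz = np.diff(sparse.csc_matrix(N).indptr)
        empty = [self.reactions[j].id for j in np.where(col_nnz == 0)[0]]
        if empty:
            raise ValueError(f"reactions with no internal-metabolite coefficients: {empty}")
        for r in self.reactions:
            if r.lb > r.ub:
                raise ValueError(f"reaction {r.id}: lb {r.lb} > ub {r.ub}")

    def copy(self) -> "MetabolicNetwork":
        mets = [Metabolite(m.id, m.name, m.compartment,
                           dict(m.formula) if m.formula else None, m.is_boundary)
                for m in self.metabolites]
        return MetabolicNetwork(mets, [r.copy() for r in self.reactions])

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_metabolite(self, rxn: Reaction) -> Metabolite | None:
        """The single internal metabolite an exchange reaction moves."""
        internal = [mid for mid in rxn.stoich if not self.metabolite(mid).is_boundary]
        if len(internal) == 1:
            return self.metabolite(internal[0])
        return None


# ---------------------------------------------------------------------------
# configuration

DEFAULT_INORGANIC_CARBON = ("co2", "co", "hco3", "co3", "h2co3")


@dataclass
class ModelConfig:
    """Medium, role reactions and solver budgets for a coupling screen."""

    substrate_exchange_id: str = ""
    substrate_uptake_limit: float = 10.0
    uptake_sign: str = "negative-exchange"  # or "positive-uptake"
    maintenance_reaction_id: str | None = None
    maintenance_lb: float = 0.0
    open_outflow_ids: list[str] = field(default_factory=list)
    oxygen_mode: str = "aerobic"  # aerobic | anaerobic-remove-exchange | anaerobic-remove-reaction:<id>
    oxygen_exchange_id: str | None = None
    irrepressible_ids: list[str] = field(default_factory=list)
    irrepressible_rules: dict[str, bool] = field(default_factory=lambda: {
        "exchanges": True, "transporters": True, "pseudo_reactions": True,
        "spontaneous": True, "no_gene": True})
    spontaneous_keywords: list[str] = field(default_factory=lambda: ["spontaneous", "s0001"])
    inorganic_carbon_ids: list[str] = field(default_factory=lambda: list(DEFAULT_INORGANIC_CARBON))
    yield_levels: list[float] = field(default_factory=lambda: [0.1, 0.3, 0.5])
    min_biomass_yield: float = 0.01
    biomass_reaction_id: str = ""
    flux_cap: float = 2000.0
    milp_time_limit_s: float = 60.0
    milp_retries: int = 10
    milp_gap: float = 0.98
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 < y <= 1.0 for y in self.yield_levels):
            raise ValueError("yield_levels must lie in (0, 1]")
        if self.substrate_uptake_limit <= 0:
            raise ValueError("substrate_uptake_limit must be positive")
        if self.flux_cap <= 0:
            raise ValueError("flux_cap must be positive")
        if self.milp_retries < 1:
            raise ValueError("milp_retries must be >= 1")
        if self.uptake_sign not in ("negative-exchange", "positive-uptake"):
            raise ValueError(f"unknown uptake_sign {self.uptake_sign!r}")

    @property
    def substrate_orientation(self) -> float:
        """sigma such that the uptake rate r_S = sigma * (substrate exchange flux)."""
        return -1.0 if self.uptake_sign == "negative-exchange" else 1.0


def read_config(path) -> ModelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {f.name for f in ModelConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return ModelConfig(**data)


def write_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def is_organic(met: Metabolite, config: ModelConfig) -> bool:
    """Organic = carbon-containing formula, excluding the inorganic carbon list.

    Bicarbonate etc. contain carbon, hence the explicit exclusion list
    (matched against the compartment-stripped compound key).
    """
    if met.formula is None or met.formula.get("C", 0) < 1:
        return False
    return met.compound_key.lower() not in {c.lower() for c in config.inorganic_carbon_ids}


def _is_transport(network: MetabolicNetwork, rxn: Reaction) -> bool:
    comps = {network.metabolite(mid).compartment for mid in rxn.stoich}
    return len(comps) >= 2


_PSEUDO_KEYWORDS = ("biomass", "growth", "maintenance", "atpm")


def _is_pseudo(rxn: Reaction, config: ModelConfig) -> bool:
    if rxn.id in (config.biomass_reaction_id, config.maintenance_reaction_id):
        return True
    blob = (rxn.id + " " + rxn.name).lower()
    return any(k in blob for k in _PSEUDO_KEYWORDS)


def _is_spontaneous(rxn: Reaction, config: ModelConfig) -> bool:
    blob = ((rxn.gpr or "") + " " + rxn.name).lower()
    return any(k.lower() in blob for k in config.spontaneous_keywords if k)


def apply_config(network: MetabolicNetwork, config: ModelConfig) -> MetabolicNetwork:
    """Return a configured copy: medium bounds, oxygen condition, repressibility.

    Organic-metabolite exchanges other than the substrate and the configured
    open outflows are closed (minimal medium: no organic uptake, no
    non-standard organic excretion); inorganic exchanges are untouched.
    """
    net = network.copy()
    ridx = net.reaction_index

    def _get(rid: str, what: str) -> Reaction:
        if rid not in ridx:
            raise ValueError(f"{what} id {rid!r} not in network")
        return net.reactions[ridx[rid]]

    sub = _get(config.substrate_exchange_id, "substrate exchange")
    if config.uptake_sign == "negative-exchange":
        sub.lb = -config.substrate_uptake_limit
        sub.ub = max(sub.ub, 0.0)
    else:
        sub.lb = max(sub.lb, 0.0)
        sub.ub = config.substrate_uptake_limit

    if config.maintenance_reaction_id:
        maint = _get(config.maintenance_reaction_id, "maintenance reaction")
        maint.lb = config.maintenance_lb
        if maint.ub < maint.lb:
            maint.ub = INF
    if config.biomass_reaction_id:
        _get(config.biomass_reaction_id, "biomass reaction")
    for rid in config.open_outflow_ids:
        _get(rid, "open outflow")

    open_ids = set(config.open_outflow_ids) | {sub.id}
    for rxn in net.reactions:
        if not rxn.is_exchange or rxn.id in open_ids:
            continue
        met = net.exchange_metabolite(rxn)
        if met is not None and is_organic(met, config):
            rxn.lb = 0.0
            rxn.ub = 0.0
    for rid in config.open_outflow_ids:
        rxn = net.reactions[ridx[rid]]
        rxn.lb = max(rxn.lb, 0.0)  # export only

    # oxygen condition
    if config.oxygen_mode == "anaerobic-remove-exchange":
        o2 = _find_oxygen_exchange(net, config)
        o2.lb = 0.0
        o2.ub = 0.0
    elif config.oxygen_mode.startswith("anaerobic-remove-reaction:"):
        rid = config.oxygen_mode.split(":", 1)[1]
        rxn = _get(rid, "anaerobic removal target")
        rxn.lb = 0.0
        rxn.ub = 0.0
    elif config.oxygen_mode != "aerobic":
        raise ValueError(f"unknown oxygen_mode {config.oxygen_mode!r}")

    _apply_repressibility(net, config)
    _warn_if_growth_impossible(net, config)
    return net


def _find_oxygen_exchange(net: MetabolicNetwork, config: ModelConfig) -> Reaction:
    if config.oxygen_exchange_id:
        if config.oxygen_exchange_id not in net.reaction_index:
            raise ValueError(f"oxygen exchange id {config.oxygen_exchange_id!r} not in network")
        return net.reaction(config.oxygen_exchange_id)
    for rxn in net.exchanges:
        met = net.exchange_metabolite(rxn)
        if met is not None and (met.formula == {"O": 2} or met.compound_key.lower() == "o2"):
            return rxn
    raise ValueError("no oxygen exchange found; set oxygen_exchange_id")


def _apply_repressibility(net: MetabolicNetwork, config: ModelConfig) -> None:
    rules = config.irrepressible_rules
    explicit = set(config.irrepressible_ids)
    any_gpr = any(r.gpr for r in net.reactions)
    for rxn in net.reactions:
        irrepressible = (
            rxn.id in explicit
            or (rules.get("exchanges", True) and rxn.is_exchange)
            or (rules.get("transporters", True) and _is_transport(net, rxn))
            or (rules.get("pseudo_reactions", True) and _is_pseudo(rxn, config))
            or (rules.get("spontaneous", True) and _is_spontaneous(rxn, config))
            or (rules.get("no_gene", True) and any_gpr and not rxn.gpr)
        )
        rxn.repressible = not irrepressible


def _warn_if_growth_impossible(net: MetabolicNetwork, config: ModelConfig) -> None:
    if not config.biomass_reaction_id:
        return
    from . import lp_core  # deferred: lp_core imports this module's types

    region = lp_core.FluxRegion(net, extra=lp_core.LinearConstraintSet(
        [({config.biomass_reaction_id: 1.0}, ">=", 1e-6)]))
    if not lp_core.check_region_feasible(region).feasible:
        logger.warning("configured medium admits no growth (biomass LP infeasible)")


# ---------------------------------------------------------------------------
# SBML reading (via cobrapy / libsbml)

def read_sbml(path) -> MetabolicNetwork:
    """Read an SBML L3/FBC model into the internal representation.

    Bounds, reversibilities and gene-association texts mirror the file;
    species flagged as boundary are dropped from the stoichiometric matrix.
    Missing bounds default to (-inf, inf) for reversible and (0, inf) for
    irreversible reactions (logged).
    """
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"could not parse SBML file {path}: {exc}") from exc

    mets = [Metabolite(m.id, m.name or "", m.compartment or "",
                       dict(m.elements) if m.formula else None, False)
            for m in model.metabolites]
    exchange_ids = {r.id for r in model.exchanges} | {r.id for r in model.boundary}
    rxns = []
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if lb is None or ub is None:
            lb = -INF if r.reversibility else 0.0
            ub = INF
            logger.warning("reaction %s missing bounds; defaulted to (%s, %s)", r.id, lb, ub)
        rxns.append(Reaction(r.id, {m.id: c for m, c in r.metabolites.items()},
                             r.name or "", float(lb), float(ub),
                             repressible=True, gpr=r.gene_reaction_rule or None,
                             is_exchange=r.id in exchange_ids))
    return MetabolicNetwork(mets, rxns)


# ---------------------------------------------------------------------------
# native JSON format

def _num_to_json(x: float):
    if x == INF:
        return "inf"
    if x == -INF:
        return "-inf"
    return x


def _num_from_json(x) -> float:
    if isinstance(x, str):
        return float(x)
    return float(x)


def write_native(network: MetabolicNetwork, path) -> None:
    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "formula": m.formula, "is_boundary": m.is_boundary}
            for m in network.metabolites
        ],
        "reactions": [
            {"id": r.id, "name": r.name, "stoich": r.stoich,
             "lb": _num_to_json(r.lb), "ub": _num_to_json(r.ub),
             "repressible": r.repressible, "gpr": r.gpr, "is_exchange": r.is_exchange}
            for r in network.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_native(path) -> MetabolicNetwork:
    with open(path) as fh:
        doc = json.load(fh)
    mets = [Metabolite(d["id"], d.get("name", ""), d.get("compartment", ""),
                       d.get("formula"), d.get("is_boundary", False))
            for d in doc.get("metabolites", [])]
    rxns = []
    for d in doc.get("reactions", []):
        lb = _num_from_json(d.get("lb", 0.0))
        ub = _num_from_json(d.get("ub", "inf"))
        if lb > ub:
            raise ValueError(f"reaction {d['id']}: lb {lb} > ub {ub}")
        rxns.append(Reaction(d["id"], {k: float(v) for k, v in d.get("stoich", {}).items()},
                             d.get("name", ""), lb, ub, d.get("repressible", False),
                             d.get("gpr"), d.get("is_exchange", False)))
    return MetabolicNetwork(mets, rxns)


def native_io(path, network: MetabolicNetwork | None = None):
    """Read (``network is None``) or write the native JSON dialect."""
    if network is None:
        return read_native(path)
    write_native(network, path)
    return None
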