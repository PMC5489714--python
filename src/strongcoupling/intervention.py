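"""Construction of the undesired / desired flux regions for a product and
yield level — the mathematical core of strong growth coupling.

With substrate uptake rate r_S (a nonnegative rate, sigma * exchange flux),
product export r_P and growth rate mu, the *undesired* region is every
steady-state flux whose product yield falls below the demanded minimum,

    T r <= t :   r_P - Y_min^P * r_S <= 0          (one row)

while the *desired* region demands both yields,

    D r <= d :  -r_P + Y_min^P * r_S <= 0
                -mu  + Y_min^BM * r_S <= 0         (two rows)

A knockout set that empties the undesired region while the desired one stays
nonempty induces strong coupling: production is forced at every feasible
flux, even at zero growth. The zero flux vector must lie outside the
undesired region for any such set to exist; a maintenance demand with
positive lower bound does this, and models without one get an explicit
minimum-uptake row r_S >= eps instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from . import lp_core
from .lp_core import FluxRegion, LinearConstraintSet
from .network_io import MetabolicNetwork, ModelConfig

EPS_UPTAKE_FRACTION = 0.001  # eps = 0.001 * uptake limit when no maintenance exists


@dataclass
class CouplingProblem:
    network: MetabolicNetwork
    substrate_id: str
    substrate_sign: float  # r_S = substrate_sign * flux(substrate exchange)
    product_id: str
    biomass_id: str
    y_min_product: float
    y_min_biomass: float
    undesired: LinearConstraintSet
    desired: LinearConstraintSet
    repressible: frozenset
    zero_exclusion: str  # "maintenance" | "min-uptake"

    def undesired_region(self, knocked=frozenset()) -> FluxRegion:
        return FluxRegion(self.network, extra=self.undesired, knocked_out=knocked)

    def desired_region(self, knocked=frozenset()) -> FluxRegion:
        return FluxRegion(self.network, extra=self.desired, knocked_out=knocked)

    def at_level(self, y_min_product: float) -> "CouplingProblem":
        """The same problem at a different minimum product yield."""
        und, des = _build_rows(self.substrate_id, self.substrate_sign, self.product_id,
                               self.biomass_id, y_min_product, self.y_min_biomass)
        if self.zero_exclusion == "min-uptake":
            und.rows.append(self.undesired.rows[-1])
        return replace(self, y_min_product=y_min_product, undesired=und, desired=des)

    def to_json(self, path) -> None:
        doc = {
            "substrate_id": self.substrate_id, "substrate_sign": self.substrate_sign,
            "product_id": self.product_id, "biomass_id": self.biomass_id,
            "y_min_product": self.y_min_product, "y_min_biomass": self.y_min_biomass,
            "undesired": self.undesired.rows, "desired": self.desired.rows,
            "repressible": sorted(self.repressible), "zero_exclusion": self.zero_exclusion,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _build_rows(sub: str, sigma: float, prod: str, bio: str,
                ymin_p: float, ymin_bm: float):
    undesired = LinearConstraintSet([
        ({prod: 1.0, sub: -ymin_p * sigma}, "<=", 0.0),
    ])
    desired = LinearConstraintSet([
        ({prod: -1.0, sub: ymin_p * sigma}, "<=", 0.0),
        ({bio: -1.0, sub: ymin_bm * sigma}, "<=", 0.0),
    ])
    return undesired, desired


def build_coupling_problem(network: MetabolicNetwork, config: ModelConfig,
                           product_exchange: str, yield_fraction: float) -> CouplingProblem:
    """Y_min^P = yield_fraction x (maximum product yield); errors out when the
    metabolite cannot be produced or its production is not substrate-bounded."""
    yres = lp_core.max_product_yield(network, product_exchange, config)
    if yres.status != "yield":
        raise ValueError(
            f"{product_exchange}: max product yield is {yres.status}; not a coupling candidate")
    ymin_p = yield_fraction * yres.value
    sigma = config.substrate_orientation
    undesired, desired = _build_rows(config.substrate_exchange_id, sigma,
                                     product_exchange, config.biomass_reaction_id,
                                     ymin_p, config.min_biomass_yield)
    maint_ok = (config.maintenance_reaction_id is not None
                and config.maintenance_reaction_id in network.reaction_index
                and network.reaction(config.maintenance_reaction_id).lb > 0)
    if maint_ok:
        zero_exclusion = "maintenance"
    else:
        zero_exclusion = "min-uptake"
        eps = EPS_UPTAKE_FRACTION * config.substrate_uptake_limit
        undesired.rows.append(({config.substrate_exchange_id: -sigma}, "<=", -eps))
    repressible = frozenset(r.id for r in network.reactions if r.repressible)
    return CouplingProblem(network, config.substrate_exchange_id, sigma,
                           product_exchange, config.biomass_reaction_id,
                           ymin_p, config.min_biomass_yield,
                           undesired, desired, repressible, zero_exclusion)


def wildtype_sanity(problem: CouplingProblem) -> dict[str, bool]:
    """Feasibility of both regions on the unmodified network.

    A wild type whose desired region is already empty can never be coupled;
    a wild type whose undesired region is empty is already coupled."""
    return {
        "undesired_feasible": lp_core.check_region_feasible(problem.undesired_region()).feasible,
        "desired_feasible": lp_core.check_region_feasible(problem.desired_region()).feasible,
    }
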