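"""Fixture networks with known coupling structure and the exhaustive
brute-force oracle that defines ground truth for the MILP path.

The toys emulate the structure of genome-scale models at desk scale: a
limited substrate uptake, a maintenance demand with positive lower bound
(which keeps the zero flux vector out of the undesired region), a biomass
sink, and product/waste branches whose repressibility decides whether
coupling is achievable.

TOY1 ("uncoupled branches"): the maintenance demand drains the substrate
pool directly, so a zero-production flux always exists no matter which of
the three branches is cut — coupling is provably infeasible.

TOY3 ("coupled catabolism"): maintenance runs on ATP, which is only made by
the two catabolic branches CAT1 (-> product P) and CAT2 (-> waste W).
Cutting CAT2 forces all ATP synthesis — hence at least the maintenance flux
— through the product branch: r_P - 0.5 r_S = 0.5 * MAINT >= 0.5 > 0, so
every surviving flux exceeds the 50% yield threshold. {CAT2} is the unique
cMCS for P (and {CAT1} for W, by symmetry).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import cutset_tools, lp_core
from .intervention import CouplingProblem, build_coupling_problem
from .milp import STATUS_FEASIBLE, STATUS_INFEASIBLE, Verdict
from .network_io import INF, MetabolicNetwork, Metabolite, ModelConfig, Reaction

TOY_NAMES = ("TOY1", "TOY3", "TOY3-G", "TOY3-G-ISO")


@dataclass
class ToyFixture:
    name: str
    network: MetabolicNetwork  # already configured
    config: ModelConfig
    products: list[str] = field(default_factory=list)  # candidate product exchange ids
    ground_truth: dict = field(default_factory=dict)  # (product, level) -> (status, (cutsets,))


def _toy_config(**overrides) -> ModelConfig:
    base = dict(substrate_exchange_id="EX_S", substrate_uptake_limit=10.0,
                uptake_sign="positive-uptake", maintenance_reaction_id="MAINT",
                maintenance_lb=1.0, open_outflow_ids=["EX_P", "EX_W"],
                biomass_reaction_id="BIO", min_biomass_yield=0.01,
                yield_levels=[0.1, 0.3, 0.5], milp_time_limit_s=10.0,
                milp_retries=3, rng_seed=0)
    base.update(overrides)
    return ModelConfig(**base)


def _mets_common() -> list[Metabolite]:
    return [
        Metabolite("A", "substrate", "c", {"C": 6, "H": 12, "O": 6}),
        Metabolite("B", "biomass precursor", "c", None),
        Metabolite("P", "product", "c", {"C": 3, "H": 6, "O": 3}),
        Metabolite("W", "waste", "c", {"C": 2, "H": 4, "O": 2}),
    ]


def _finish(name, mets, rxns, config, products, truth) -> ToyFixture:
    net = MetabolicNetwork(mets, rxns)
    for r in net.reactions:  # fixtures are built pre-configured
        r.repressible = r.id in ("R_B", "R_P", "R_W", "CAT1", "CAT2", "ANA")
    net.validate()
    return ToyFixture(name, net, config, products, truth)


def make_toy(name: str) -> ToyFixture:
    """Build a named fixture; ground truth is regenerable via the oracle."""
    if name == "TOY1":
        mets = _mets_common()
        rxns = [
            Reaction("EX_S", {"A": 1.0}, "substrate uptake", 0.0, 10.0, is_exchange=True),
            Reaction("MAINT", {"A": -1.0}, "maintenance", 1.0, 2000.0),
            Reaction("R_B", {"A": -1.0, "B": 1.0}, "anabolic branch"),
            Reaction("R_P", {"A": -1.0, "P": 1.0}, "product branch"),
            Reaction("R_W", {"A": -1.0, "W": 1.0}, "waste branch"),
            Reaction("BIO", {"B": -1.0}, "biomass", 0.0, INF),
            Reaction("EX_P", {"P": -1.0}, "", 0.0, INF, is_exchange=True),
            Reaction("EX_W", {"W": -1.0}, "", 0.0, INF, is_exchange=True),
        ]
        truth = {("EX_P", lvl): (STATUS_INFEASIBLE, ()) for lvl in (0.1, 0.3, 0.5)}
        return _finish(name, mets, rxns, _toy_config(), ["EX_P", "EX_W"], truth)

    if name in ("TOY3", "TOY3-G", "TOY3-G-ISO"):
        mets = _mets_common() + [Metabolite("ATP", "energy carrier", "c", None)]
        rxns = [
            Reaction("EX_S", {"A": 1.0}, "substrate uptake", 0.0, 10.0, is_exchange=True),
            Reaction("CAT1", {"A": -1.0, "ATP": 1.0, "P": 1.0}, "catabolism to product"),
            Reaction("CAT2", {"A": -1.0, "ATP": 1.0, "W": 1.0}, "catabolism to waste"),
            Reaction("ANA", {"A": -1.0, "ATP": -1.0, "B": 1.0}, "anabolism"),
            Reaction("MAINT", {"ATP": -1.0}, "maintenance", 1.0, 2000.0),
            Reaction("BIO", {"B": -1.0}, "biomass", 0.0, INF),
            Reaction("EX_P", {"P": -1.0}, "", 0.0, INF, is_exchange=True),
            Reaction("EX_W", {"W": -1.0}, "", 0.0, INF, is_exchange=True),
        ]
        if name == "TOY3-G":
            gprs = {"CAT1": "gA", "CAT2": "gB", "ANA": "gC"}
        elif name == "TOY3-G-ISO":
            gprs = {"CAT1": "gA", "CAT2": "gB or gD", "ANA": "gC"}
        else:
            gprs = {}
        for r in rxns:
            r.gpr = gprs.get(r.id)
        truth = {}
        for lvl in (0.1, 0.3, 0.5):
            truth[("EX_P", lvl)] = (STATUS_FEASIBLE, (frozenset({"CAT2"}),))
            truth[("EX_W", lvl)] = (STATUS_FEASIBLE, (frozenset({"CAT1"}),))
        return _finish(name, mets, rxns, _toy_config(), ["EX_P", "EX_W"], truth)

    raise ValueError(f"unknown toy fixture {name!r}; known: {TOY_NAMES}")


# ---------------------------------------------------------------------------
# seeded random fixtures

def random_network(seed: int, max_reactions: int = 12,
                   max_repressible: int = 6) -> ToyFixture:
    """Seed-deterministic small network with substrate uptake, positive
    maintenance demand, biomass sink and >= 1 candidate product.

    Two archetypes are mixed: maintenance drawn from a catabolic co-product
    (ATP; coupling often feasible) or directly from the substrate pool
    (coupling provably infeasible), with random extra branches, chain
    lengths, stoichiometric coefficients in {1, 2} and occasional reversible
    shuttles. Integer stoichiometry keeps the fixtures hand-checkable.
    Draws whose products all turn out non-producible are redrawn
    deterministically until at least one candidate product remains.
    """
    for attempt in range(32):
        fix = _random_network_once(np.random.default_rng((seed, attempt)),
                                   seed, max_repressible)
        fix.products = [p for p in fix.products
                        if lp_core.max_product_yield(fix.network, p, fix.config).status == "yield"]
        if fix.products:
            return fix
    raise RuntimeError(f"could not generate a fixture with a producible product (seed {seed})")


def _random_network_once(rng: np.random.Generator, seed: int,
                         max_repressible: int) -> ToyFixture:
    coupled_style = bool(rng.integers(0, 2))
    n_products = int(rng.integers(1, 3))
    n_waste = int(rng.integers(1, 3))

    mets = [Metabolite("A", "substrate", "c", {"C": 6, "H": 12, "O": 6}),
            Metabolite("B", "biomass precursor", "c", None)]
    rxns = [Reaction("EX_S", {"A": 1.0}, "uptake", 0.0, 10.0, is_exchange=True),
            Reaction("BIO", {"B": -1.0}, "biomass", 0.0, INF)]
    repressible: list[str] = []

    if coupled_style:
        mets.append(Metabolite("ATP", "energy", "c", None))
        rxns.append(Reaction("MAINT", {"ATP": -1.0}, "maintenance", 1.0, 2000.0))
        ana_stoich = {"A": -1.0, "B": 1.0}
        if rng.random() < 0.8:
            ana_stoich["ATP"] = -float(rng.integers(1, 3))
        rxns.append(Reaction("ANA", ana_stoich, "anabolism"))
        repressible.append("ANA")
    else:
        rxns.append(Reaction("MAINT", {"A": -1.0}, "maintenance", 1.0, 2000.0))
        rxns.append(Reaction("ANA", {"A": -1.0, "B": 1.0}, "anabolism"))
        repressible.append("ANA")

    def add_branch(tag: str, organic: bool) -> None:
        mid = tag
        formula = {"C": int(rng.integers(1, 4)), "H": 4, "O": 2} if organic else None
        mets.append(Metabolite(mid, "", "c", formula))
        stoich = {"A": -1.0, mid: float(rng.integers(1, 3))}
        if coupled_style and rng.random() < 0.85:
            stoich["ATP"] = float(rng.integers(1, 3))
        rid = f"R_{tag}"
        rxns.append(Reaction(rid, stoich, "branch"))
        repressible.append(rid)
        rxns.append(Reaction(f"EX_{tag}", {mid: -1.0}, "", 0.0, INF, is_exchange=True))

    products = []
    for k in range(n_products):
        add_branch(f"P{k}", organic=True)
        products.append(f"EX_P{k}")
    for k in range(n_waste):
        add_branch(f"W{k}", organic=True)

    # occasional reversible shuttle A <-> C feeding the first product pool
    if rng.random() < 0.3 and len(rxns) + 2 <= 16:
        mets.append(Metabolite("C", "", "c", None))
        rxns.append(Reaction("SHUTTLE", {"A": -1.0, "C": 1.0}, "", -50.0, 50.0))
        rxns.append(Reaction("DRAIN_C", {"C": -1.0, "P0": 1.0}, "drain"))
        repressible += ["SHUTTLE", "DRAIN_C"]

    rng.shuffle(repressible)
    repressible = repressible[:max_repressible]
    net = MetabolicNetwork(mets, rxns)
    for r in net.reactions:
        r.repressible = r.id in repressible
    net.validate()
    open_outflows = [r.id for r in net.reactions if r.is_exchange and r.id != "EX_S"]
    config = _toy_config(open_outflow_ids=open_outflows, rng_seed=seed % (2**31))
    return ToyFixture(f"RANDOM-{seed}", net, config, products, {})


# ---------------------------------------------------------------------------
# exhaustive oracle

@dataclass
class OracleResult:
    status: str
    minimal_cutsets: tuple = ()
    n_subsets_checked: int = 0

    def accepts(self, cutset: frozenset | None) -> bool:
        """Whether a cut set is valid and inclusion-minimal per the oracle."""
        if cutset is None:
            return False
        return cutset in set(self.minimal_cutsets)


def oracle_is_valid(problem: CouplingProblem, cutset: frozenset) -> bool:
    """Two plain LPs on the original network with true bounds — no FVA
    shrinkage, no big-M. The soundness reference for the MILP path."""
    und = lp_core.check_region_feasible(problem.undesired_region(cutset)).feasible
    des = lp_core.check_region_feasible(problem.desired_region(cutset)).feasible
    return (not und) and des


def brute_force_verdict(problem: CouplingProblem, max_size: int | None = None) -> OracleResult:
    """Enumerate all subsets of repressible reactions (ascending size) and
    return all inclusion-minimal valid cut sets; INFEASIBLE iff none exists."""
    rep = sorted(problem.repressible)
    if max_size is None:
        max_size = len(rep)
    minimal: list[frozenset] = []
    checked = 0
    for size in range(0, max_size + 1):
        for combo in itertools.combinations(rep, size):
            K = frozenset(combo)
            if any(mset <= K for mset in minimal):
                continue  # superset of a known minimal set
            checked += 1
            if oracle_is_valid(problem, K):
                minimal.append(K)
    if minimal:
        return OracleResult(STATUS_FEASIBLE, tuple(minimal), checked)
    return OracleResult(STATUS_INFEASIBLE, (), checked)


def fixture_problem(fix: ToyFixture, product: str, level: float) -> CouplingProblem:
    return build_coupling_problem(fix.network, fix.config, product, level)
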