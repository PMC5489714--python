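import json

import pytest
from hypothesis import given, settings, strategies as st

from strongcoupling import network_io, synthetic
from strongcoupling.network_io import (INF, MetabolicNetwork, Metabolite, ModelConfig,
                                       Reaction, apply_config, is_organic,
                                       read_native, write_native)


def networks_equal(a: MetabolicNetwork, b: MetabolicNetwork) -> bool:
    if [m.id for m in a.metabolites] != [m.id for m in b.metabolites]:
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if (ra.id, ra.stoich, ra.lb, ra.ub, ra.repressible, ra.gpr, ra.is_exchange) != \
           (rb.id, rb.stoich, rb.lb, rb.ub, rb.repressible, rb.gpr, rb.is_exchange):
            return False
    return True


class TestNativeRoundTrip:
    @pytest.mark.parametrize("name", ["TOY1", "TOY3", "TOY3-G"])
    def test_toys(self, name, tmp_path):
        net = synthetic.make_toy(name).network
        p = tmp_path / "net.json"
        write_native(net, p)
        assert networks_equal(net, read_native(p))

    def test_infinite_bounds_round_trip(self, tmp_path):
        net = synthetic.make_toy("TOY3").network.copy()
        net.reaction("CAT1").lb = -INF
        net.reaction("CAT1").ub = INF
        p = tmp_path / "net.json"
        write_native(net, p)
        back = read_native(p)
        assert back.reaction("CAT1").lb == -INF and back.reaction("CAT1").ub == INF
        with open(p) as fh:
            raw = json.load(fh)
        cat1 = next(r for r in raw["reactions"] if r["id"] == "CAT1")
        assert cat1["lb"] == "-inf" and cat1["ub"] == "inf"

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=300))
    def test_generated_networks(self, seed, tmp_path_factory):
        net = synthetic.random_network(seed).network
        p = tmp_path_factory.mktemp("rt") / "net.json"
        write_native(net, p)
        assert networks_equal(net, read_native(p))

    def test_lb_above_ub_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"metabolites": [{"id": "A"}],
                                 "reactions": [{"id": "R", "stoich": {"A": 1}, "lb": 5, "ub": 1}]}))
        with pytest.raises(ValueError, match="lb"):
            read_native(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.json"
        p.write_text(json.dumps({"metabolites": [{"id": "A"}],
                                 "reactions": [{"id": "R", "stoich": {"A": 1}},
                                               {"id": "R", "stoich": {"A": -1}}]}))
        with pytest.raises(ValueError, match="duplicate.*R"):
            read_native(p)


class TestSbml:
    def _cobra_toy(self):
        import cobra

        model = cobra.Model("toy")
        a = cobra.Metabolite("a_c", formula="C6H12O6", compartment="c")
        b = cobra.Metabolite("b_c", formula="C3H6O3", compartment="c")
        r1 = cobra.Reaction("R1", lower_bound=-10, upper_bound=10)
        r1.add_metabolites({a: -1, b: 1})
        r1.gene_reaction_rule = "g1 or g2"
        ex = cobra.Reaction("EX_a", lower_bound=-5, upper_bound=1000)
        ex.add_metabolites({a: -1})
        model.add_reactions([r1, ex])
        return model

    def test_read_sbml_mirrors_model(self, tmp_path):
        import cobra.io

        model = self._cobra_toy()
        p = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(model, str(p))
        net = network_io.read_sbml(p)
        assert len(net.metabolites) == 2 and len(net.reactions) == 2
        r1 = net.reaction("R1")
        assert (r1.lb, r1.ub) == (-10, 10) and r1.reversible
        assert r1.gpr == "g1 or g2"
        assert net.reaction("EX_a").is_exchange
        assert net.metabolite("a_c").formula == {"C": 6, "H": 12, "O": 6}

    def test_empty_model(self, tmp_path):
        import cobra.io

        p = tmp_path / "empty.xml"
        cobra.io.write_sbml_model(cobra.Model("empty"), str(p))
        net = network_io.read_sbml(p)
        assert net.reactions == [] and net.metabolites == []

    def test_malformed_file(self, tmp_path):
        p = tmp_path / "garbage.xml"
        p.write_text("<not-sbml>")
        with pytest.raises(ValueError, match="parse"):
            network_io.read_sbml(p)


class TestApplyConfig:
    def test_substrate_and_maintenance_bounds(self, toy3):
        net = apply_config(toy3.network, toy3.config)
        assert (net.reaction("EX_S").lb, net.reaction("EX_S").ub) == (0.0, 10.0)
        assert net.reaction("MAINT").lb == 1.0

    def test_anaerobic_removes_oxygen_exchange(self, toy3):
        net = toy3.network.copy()
        net.metabolites.append(Metabolite("o2", "oxygen", "e", {"O": 2}))
        net.reactions.append(Reaction("EX_o2", {"o2": -1.0}, lb=-INF, ub=INF, is_exchange=True))
        net.reactions.append(Reaction("RESP", {"o2": 1.0, "ATP": 1.0}, lb=0, ub=INF))
        cfg = ModelConfig(**{**_cfg_dict(toy3.config), "oxygen_mode": "anaerobic-remove-exchange"})
        out = apply_config(net, cfg)
        assert (out.reaction("EX_o2").lb, out.reaction("EX_o2").ub) == (0.0, 0.0)

    def test_anaerobic_remove_named_reaction(self, toy3):
        cfg = ModelConfig(**{**_cfg_dict(toy3.config),
                             "oxygen_mode": "anaerobic-remove-reaction:CAT2"})
        out = apply_config(toy3.network, cfg)
        assert (out.reaction("CAT2").lb, out.reaction("CAT2").ub) == (0.0, 0.0)

    def test_closes_organic_exchanges_not_in_open_list(self, toy3):
        cfg = ModelConfig(**{**_cfg_dict(toy3.config), "open_outflow_ids": ["EX_P"]})
        out = apply_config(toy3.network, cfg)
        assert (out.reaction("EX_W").lb, out.reaction("EX_W").ub) == (0.0, 0.0)
        assert out.reaction("EX_P").ub > 0

    def test_repressibility_partition_and_protected_roles(self, toy3):
        out = apply_config(toy3.network, toy3.config)
        for rxn in out.reactions:
            assert isinstance(rxn.repressible, bool)
        for rid in ("EX_S", "EX_P", "EX_W", "BIO", "MAINT"):
            assert not out.reaction(rid).repressible
        assert {r.id for r in out.reactions if r.repressible} == {"CAT1", "CAT2", "ANA"}

    def test_unknown_id_raises(self, toy3):
        cfg = ModelConfig(**{**_cfg_dict(toy3.config), "substrate_exchange_id": "EX_missing"})
        with pytest.raises(ValueError, match="EX_missing"):
            apply_config(toy3.network, cfg)

    def test_no_gene_rule_applies_only_when_gprs_exist(self, toy3g):
        out = apply_config(toy3g.network, toy3g.config)
        # CAT1/CAT2/ANA carry genes and stay repressible; nothing else has genes
        assert {r.id for r in out.reactions if r.repressible} == {"CAT1", "CAT2", "ANA"}


class TestOrganicRule:
    def test_carbon_required_and_inorganic_excluded(self, toy3):
        cfg = toy3.config
        assert is_organic(Metabolite("x", formula={"C": 2, "H": 6}), cfg)
        assert not is_organic(Metabolite("x", formula={"N": 2}), cfg)
        assert not is_organic(Metabolite("x", formula=None), cfg)
        assert not is_organic(Metabolite("hco3_c", compartment="c",
                                         formula={"C": 1, "H": 1, "O": 3}), cfg)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            ModelConfig(substrate_exchange_id="EX", yield_levels=[0.0, 0.5])
        with pytest.raises(ValueError):
            ModelConfig(substrate_exchange_id="EX", substrate_uptake_limit=-1)
        with pytest.raises(ValueError):
            ModelConfig(substrate_exchange_id="EX", milp_retries=0)


def _cfg_dict(config) -> dict:
    from dataclasses import asdict

    return asdict(config)
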