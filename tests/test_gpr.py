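import pytest
from hypothesis import given, settings, strategies as st

from strongcoupling import gpr, lp_core, milp, synthetic
from strongcoupling.gpr import (GprParseError, eval_gpr, extend_with_genes, gene_cutsets,
                                parse_gpr, to_dnf, unparse_gpr)
from tests.conftest import problem_for


class TestParser:
    def test_plain_conjunction(self):
        assert parse_gpr("g1 and g2") == ("and", ["g1", "g2"])

    def test_or_with_nested_and(self):
        assert parse_gpr("g1 or (g2 and g3)") == ("or", ["g1", ("and", ["g2", "g3"])])

    def test_and_binds_tighter_than_or(self):
        assert parse_gpr("g1 or g2 and g3") == ("or", ["g1", ("and", ["g2", "g3"])])

    def test_distribution_to_dnf(self):
        terms = to_dnf(parse_gpr("(g1 or g2) and g3"))
        assert set(terms) == {frozenset({"g1", "g3"}), frozenset({"g2", "g3"})}

    def test_redundant_terms_are_minimized(self):
        terms = to_dnf(parse_gpr("g1 or (g1 and g2)"))
        assert set(terms) == {frozenset({"g1"})}

    @pytest.mark.parametrize("bad", ["", "g1 and", "and g1", "(g1 or g2", "g1 ) g2"])
    def test_malformed_text_reports_position(self, bad):
        with pytest.raises(GprParseError, match="position"):
            parse_gpr(bad)

    def test_dnf_term_cap(self):
        # 2^7 = 128 conjunctions > 64-term cap
        text = " and ".join(f"(a{i} or b{i})" for i in range(7))
        with pytest.raises(ValueError, match="64"):
            to_dnf(parse_gpr(text))

    gene = st.text(alphabet="abcdefg", min_size=1, max_size=3).map(lambda s: "g_" + s)

    @st.composite
    @staticmethod
    def trees(draw, depth=3):
        if depth == 0 or draw(st.booleans()):
            return draw(TestParser.gene)
        op = draw(st.sampled_from(["and", "or"]))
        kids = draw(st.lists(TestParser.trees(depth=depth - 1), min_size=2, max_size=3))
        return (op, kids)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(tree=trees())
    def test_unparse_parse_round_trip_preserves_semantics(self, tree):
        back = parse_gpr(unparse_gpr(tree))
        genes = sorted(gpr.gpr_genes(tree))
        # semantic equivalence over all single- and two-gene knockouts
        probes = [set()] + [{g} for g in genes] + \
            [{a, b} for a in genes for b in genes if a < b][:20]
        for knocked in probes:
            assert eval_gpr(back, knocked) == eval_gpr(tree, knocked)


class TestExtension:
    def test_isozymes_keep_reaction_alive_after_single_cut(self, toy3g_iso):
        extended, ext = extend_with_genes(toy3g_iso.network)
        # cut gB: CAT2 still usable through gD's enzyme
        region = lp_core.FluxRegion(extended, knocked_out=frozenset({"TR__gB"}))
        status, value = lp_core.maximize(region, {"EX_W": 1.0})
        assert status == "optimal" and value > 1.0
        # cut both isozyme genes: waste route dead
        region2 = lp_core.FluxRegion(extended, knocked_out=frozenset({"TR__gB", "TR__gD"}))
        _, value2 = lp_core.maximize(region2, {"EX_W": 1.0})
        assert value2 == pytest.approx(0.0, abs=1e-6)

    def test_enzyme_complex_dies_with_either_subunit(self, toy3):
        net = toy3.network.copy()
        net.reaction("CAT2").gpr = "gB and gD"
        extended, ext = extend_with_genes(net)
        for gene in ("gB", "gD"):
            region = lp_core.FluxRegion(extended, knocked_out=frozenset({"TR__" + gene}))
            _, value = lp_core.maximize(region, {"EX_W": 1.0})
            assert value == pytest.approx(0.0, abs=1e-6)

    def test_network_without_gprs_extends_to_identity(self, toy3):
        extended, ext = extend_with_genes(toy3.network)
        assert len(extended.reactions) == len(toy3.network.reactions)
        assert not any(r.repressible for r in extended.reactions)

    def test_only_translation_reactions_repressible(self, toy3g):
        extended, ext = extend_with_genes(toy3g.network)
        rep = {r.id for r in extended.reactions if r.repressible}
        assert rep == {"TR__gA", "TR__gB", "TR__gC"}

    def test_flux_projection_matches_reaction_knockouts(self, toy3g):
        """Gene knockouts restrict the original columns exactly like knocking
        out the GPR-disabled reactions."""
        extended, ext = extend_with_genes(toy3g.network)
        for genes, disabled in ((set(), set()), ({"gA"}, {"CAT1"}),
                                ({"gB"}, {"CAT2"}), ({"gA", "gC"}, {"CAT1", "ANA"})):
            assert ext.disabled_reactions(genes) == frozenset(disabled)
            tr = frozenset("TR__" + g for g in genes)
            for objective in ({"EX_P": 1.0}, {"EX_W": 1.0}, {"BIO": 1.0}):
                _, v_gene = lp_core.maximize(
                    lp_core.FluxRegion(extended, knocked_out=tr), objective)
                _, v_rxn = lp_core.maximize(
                    lp_core.FluxRegion(toy3g.network, knocked_out=frozenset(disabled)),
                    objective)
                if v_gene is None or v_rxn is None:
                    assert v_gene == v_rxn
                else:
                    assert v_gene == pytest.approx(v_rxn, abs=1e-6)


class TestGeneCutsets:
    def test_dedicated_genes_reproduce_reaction_verdict(self, toy3g):
        prob = problem_for(toy3g, level=0.5)
        extended, ext = extend_with_genes(toy3g.network)
        verdict = gene_cutsets(prob, extended, ext, toy3g.config)
        assert verdict.status == milp.STATUS_FEASIBLE
        assert verdict.cutset == frozenset({"gB"})

    def test_isozyme_pair_needs_both_genes(self, toy3g_iso):
        prob = problem_for(toy3g_iso, level=0.5)
        extended, ext = extend_with_genes(toy3g_iso.network)
        verdict = gene_cutsets(prob, extended, ext, toy3g_iso.config)
        assert verdict.status == milp.STATUS_FEASIBLE
        assert verdict.cutset == frozenset({"gB", "gD"})

    def test_gene_shared_with_irrepressible_reaction_is_protected(self, toy3g):
        net = toy3g.network.copy()
        net.reaction("MAINT").gpr = "gB"  # waste-route gene also runs maintenance
        extended, ext = extend_with_genes(net)
        assert "gB" in ext.irrepressible_genes
        assert not extended.reaction("TR__gB").repressible
        prob = problem_for(toy3g, level=0.5)
        verdict = gene_cutsets(prob, extended, ext, toy3g.config)
        # without cutting gB the waste route cannot be closed
        assert verdict.status == milp.STATUS_INFEASIBLE
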