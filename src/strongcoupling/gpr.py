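"""Gene–protein–reaction logic integrated into the network structure.

Each catalysed, repressible reaction gets an auxiliary "catalysis" metabolite
X_R that the reaction consumes at unit stoichiometry; X_R is produced by one
enzyme pseudo-reaction per DNF term of the reaction's gene association, each
consuming the gene-product metabolites G_g of its genes; every gene product
is made by a translation pseudo-reaction from nothing. Knocking out a
translation reaction then disables exactly the reactions whose associations
evaluate to false — so cut sets can be computed at the gene level with the
unchanged cMCS machinery, where only translation reactions are repressible.

Reversible catalysed reactions are split into irreversible forward/backward
halves that share one X_R; without the split the backward direction would
*produce* the auxiliary metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import milp
from .intervention import CouplingProblem
from .network_io import INF, MetabolicNetwork, Metabolite, ModelConfig, Reaction

DNF_TERM_CAP = 64

AND = "and"
OR = "or"


# ---------------------------------------------------------------------------
# parsing: standard and/or grammar, 'and' binds tighter than 'or'

class GprParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


def _tokenize(text: str):
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append((ch, i))
            i += 1
        else:
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "()":
                j += 1
            word = text[i:j]
            kind = word.lower() if word.lower() in (AND, OR) else "gene"
            tokens.append((word if kind == "gene" else kind, i))
            i = j
    return tokens


def parse_gpr(text: str):
    """Parse a gene association into a tree of ('and'|'or', children) tuples
    with bare gene ids as leaves; 'and' binds tighter than 'or'."""
    tokens = _tokenize(text)
    if not tokens:
        raise GprParseError("empty gene association", 0)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(text))

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek()[0] == OR:
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else (OR, terms)

    def parse_and():
        nonlocal pos
        factors = [parse_atom()]
        while peek()[0] == AND:
            pos += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else (AND, factors)

    def parse_atom():
        nonlocal pos
        tok, at = peek()
        if tok == "(":
            pos += 1
            node = parse_or()
            tok2, at2 = peek()
            if tok2 != ")":
                raise GprParseError("expected ')'", at2)
            pos += 1
            return node
        if tok in (None, ")", AND, OR):
            raise GprParseError(f"expected gene identifier, got {tok!r}", at)
        pos += 1
        return tok

    tree = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"unexpected token {tokens[pos][0]!r}", tokens[pos][1])
    return tree


def unparse_gpr(tree) -> str:
    if isinstance(tree, str):
        return tree
    op, children = tree
    sep = f" {op} "
    parts = []
    for ch in children:
        txt = unparse_gpr(ch)
        if not isinstance(ch, str) and ch[0] != op:
            txt = f"({txt})"
        parts.append(txt)
    return sep.join(parts)


def gpr_genes(tree) -> set[str]:
    if isinstance(tree, str):
        return {tree}
    out: set[str] = set()
    for ch in tree[1]:
        out |= gpr_genes(ch)
    return out


def to_dnf(tree, cap: int = DNF_TERM_CAP) -> list[frozenset]:
    """Disjunctive normal form as a list of gene-id conjunctions (each a
    frozenset = one isoenzyme); raises if distribution exceeds ``cap`` terms."""
    if isinstance(tree, str):
        return [frozenset([tree])]
    op, children = tree
    child_dnfs = [to_dnf(ch, cap) for ch in children]
    if op == OR:
        terms = [t for d in child_dnfs for t in d]
    else:  # AND: cartesian product of terms
        terms = [frozenset()]
        for d in child_dnfs:
            terms = [a | b for a in terms for b in d]
            if len(terms) > cap:
                raise ValueError(f"DNF exceeds {cap} terms")
    # drop non-minimal (superset) terms
    minimal = [t for t in terms if not any(o < t for o in terms)]
    seen, out = set(), []
    for t in minimal:
        if t not in seen:
            seen.add(t)
            out.append(t)
    if len(out) > cap:
        raise ValueError(f"DNF exceeds {cap} terms")
    return out


def eval_gpr(tree, knocked: set[str]) -> bool:
    """Whether the association still evaluates true with ``knocked`` genes gone."""
    if isinstance(tree, str):
        return tree not in knocked
    op, children = tree
    results = (eval_gpr(ch, knocked) for ch in children)
    return any(results) if op == OR else all(results)


# ---------------------------------------------------------------------------
# network extension

AUX_PREFIX = "X__"
GENE_MET_PREFIX = "G__"
ENZ_PREFIX = "ENZ__"
TRANS_PREFIX = "TR__"


@dataclass
class GeneExtension:
    gene_to_translation: dict[str, str] = field(default_factory=dict)
    reaction_genes: dict[str, object] = field(default_factory=dict)  # reaction id -> gpr tree
    split_reactions: dict[str, tuple[str, str]] = field(default_factory=dict)
    irrepressible_genes: set[str] = field(default_factory=set)

    def translation_to_gene(self, rid: str) -> str:
        return rid[len(TRANS_PREFIX):] if rid.startswith(TRANS_PREFIX) else rid

    def disabled_reactions(self, knocked_genes) -> frozenset:
        knocked = set(knocked_genes)
        return frozenset(rid for rid, tree in self.reaction_genes.items()
                         if not eval_gpr(tree, knocked))


def extend_with_genes(network: MetabolicNetwork, dnf_cap: int = DNF_TERM_CAP):
    """Return (extended network, GeneExtension).

    Only reactions that are repressible at reaction level and carry a gene
    association are extended. In the extended network nothing but gene
    translation reactions is repressible, and a translation reaction is
    itself irrepressible when its gene occurs in the association of any
    reaction-level-irrepressible reaction.
    """
    net = network.copy()
    ext = GeneExtension()
    genes_seen: set[str] = set()

    for rxn in network.reactions:
        if rxn.gpr:
            try:
                tree = parse_gpr(rxn.gpr)
            except GprParseError:
                continue
            if not rxn.repressible:
                ext.irrepressible_genes |= gpr_genes(tree)

    new_mets: list[Metabolite] = []
    new_rxns: list[Reaction] = []
    for rxn in net.reactions:
        rxn.repressible = False  # only translation reactions may be cut
        src = network.reaction(rxn.id)
        if not src.gpr or not src.repressible:
            continue
        try:
            tree = parse_gpr(src.gpr)
        except GprParseError:
            continue  # unparseable association: left untouched, gene-irrepressible
        try:
            terms = to_dnf(tree, dnf_cap)
        except ValueError as exc:
            raise ValueError(f"reaction {src.id}: {exc}") from exc
        ext.reaction_genes[src.id] = tree
        genes_seen |= gpr_genes(tree)
        aux = AUX_PREFIX + src.id
        new_mets.append(Metabolite(aux, name=f"catalysis of {src.id}"))
        if src.reversible:
            fwd = Reaction(src.id + "__fwd", dict(src.stoich), src.name,
                           0.0, src.ub, False, src.gpr, src.is_exchange)
            bwd = Reaction(src.id + "__bwd", {k: -v for k, v in src.stoich.items()},
                           src.name, 0.0, -src.lb, False, src.gpr, src.is_exchange)
            fwd.stoich[aux] = fwd.stoich.get(aux, 0.0) - 1.0
            bwd.stoich[aux] = bwd.stoich.get(aux, 0.0) - 1.0
            rxn.lb, rxn.ub = 0.0, 0.0  # replaced by the two halves
            new_rxns += [fwd, bwd]
            ext.split_reactions[src.id] = (fwd.id, bwd.id)
        else:
            net.reaction(rxn.id).stoich[aux] = rxn.stoich.get(aux, 0.0) - 1.0
        for k, term in enumerate(terms):
            enz = Reaction(f"{ENZ_PREFIX}{src.id}__{k}",
                           {aux: 1.0, **{GENE_MET_PREFIX + g: -1.0 for g in sorted(term)}},
                           lb=0.0, ub=INF, repressible=False)
            new_rxns.append(enz)

    for g in sorted(genes_seen):
        gm = GENE_MET_PREFIX + g
        new_mets.append(Metabolite(gm, name=f"gene product {g}"))
        tr = Reaction(TRANS_PREFIX + g, {gm: 1.0}, name=f"translation of {g}",
                      lb=0.0, ub=INF,
                      repressible=g not in ext.irrepressible_genes)
        ext.gene_to_translation[g] = tr.id
        new_rxns.append(tr)

    extended = MetabolicNetwork(net.metabolites + new_mets, net.reactions + new_rxns)
    return extended, ext


def gene_problem(problem: CouplingProblem, extended: MetabolicNetwork,
                 ext: GeneExtension) -> CouplingProblem:
    """Rebuild a coupling problem on the gene-extended network.

    Yield rows referencing a split reversible reaction are rewritten onto its
    forward/backward halves (net flux = fwd - bwd)."""
    from dataclasses import replace
    from .lp_core import LinearConstraintSet

    def translate(rows):
        out = []
        for coeffs, sense, rhs in rows:
            row: dict[str, float] = {}
            for rid, a in coeffs.items():
                if rid in ext.split_reactions:
                    f, b = ext.split_reactions[rid]
                    row[f] = row.get(f, 0.0) + a
                    row[b] = row.get(b, 0.0) - a
                else:
                    row[rid] = row.get(rid, 0.0) + a
            out.append((row, sense, rhs))
        return out

    repressible = frozenset(r.id for r in extended.reactions if r.repressible)
    return replace(problem, network=extended,
                   undesired=LinearConstraintSet(translate(problem.undesired)),
                   desired=LinearConstraintSet(translate(problem.desired)),
                   repressible=repressible)


def gene_cutsets(problem: CouplingProblem, extended: MetabolicNetwork,
                 ext: GeneExtension, config: ModelConfig) -> milp.Verdict:
    """Run the cMCS search on the gene-extended network; the verdict's cut
    set is reported as gene ids, and the implied reaction disablement pattern
    is re-verified on the reaction-level problem."""
    from . import cutset_tools

    gprob = gene_problem(problem, extended, ext)
    verdict = milp.find_cmcs(gprob, config)
    if verdict.status != milp.STATUS_FEASIBLE:
        return verdict
    genes = frozenset(ext.translation_to_gene(rid) for rid in verdict.cutset)
    disabled = ext.disabled_reactions(genes)
    check = cutset_tools.verify_cutset(problem, disabled & problem.repressible)
    if not check["valid"]:
        return milp.Verdict(milp.STATUS_UNDECIDED,
                            attempts=verdict.attempts + [("gene-map", 0.0,
                                                          "mapped pattern failed verification")])
    return milp.Verdict(milp.STATUS_FEASIBLE, cutset=genes, attempts=verdict.attempts,
                        proven_minimal=verdict.proven_minimal)


def genes_to_tsv(verdict: milp.Verdict, ext: GeneExtension, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdisabled_reactions\n")
        if verdict.cutset:
            for g in sorted(verdict.cutset):
                dis = ext.disabled_reactions({g})
                fh.write(f"{g}\t{';'.join(sorted(dis))}\n")
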