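"""Lossless network reduction before the MILP: drop conservation relations
(linearly dependent rows of N), prune blocked reactions and merge fully
coupled reaction sets, with an exact mapping back to the original network.

Full coupling is detected from a kernel basis of N (proportional kernel
rows), ignoring bounds: bound-aware coupling is condition-dependent, the
kernel criterion is the safe lossless one. Blocked reactions (identically
zero in every steady state) are pruned first — they cannot affect any
verdict and cutting them is a no-op.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .network_io import INF, MetabolicNetwork, Metabolite, Reaction

logger = logging.getLogger(__name__)

RANK_TOL = 1e-9
COUPLING_TOL = 1e-9


@dataclass
class CompressionMap:
    """Exact mapping between original and compressed reaction spaces.

    ``merged_groups`` maps each compressed reaction to its ordered members
    with scaling factors c_k such that member_flux = c_k * compressed_flux.
    Blocked reactions (zero flux in every steady state) are listed separately;
    they form their own implicit singleton groups and never appear in cuts.
    """

    merged_groups: list[tuple[str, list[tuple[str, float]]]] = field(default_factory=list)
    dropped_metabolites: list[str] = field(default_factory=list)
    blocked_reactions: list[str] = field(default_factory=list)
    repressible_members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def member_to_group(self) -> dict[str, tuple[str, float]]:
        out = {}
        for gid, members in self.merged_groups:
            for rid, scale in members:
                out[rid] = (gid, scale)
        return out

    def to_tsv(self, path) -> None:
        lookup = {gid: members for gid, members in self.merged_groups}
        with open(path, "w") as fh:
            fh.write("group_id\tmember_id\tscale\trepressible\n")
            for gid, members in self.merged_groups:
                reps = set(self.repressible_members.get(gid, []))
                for rid, scale in members:
                    fh.write(f"{gid}\t{rid}\t{scale:.9g}\t{int(rid in reps)}\n")


def remove_conservation_relations(network: MetabolicNetwork):
    """Drop linearly dependent rows of N (conserved moieties).

    The flux solution set {r : N r = 0, bounds} is unchanged; returns the
    reduced network and the list of dropped metabolite ids.
    """
    N = network.stoichiometric_matrix().toarray()
    if N.shape[0] == 0:
        return network.copy(), []
    # QR with column pivoting on N^T selects a maximal independent row set of N
    _, R, piv = linalg.qr(N.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = RANK_TOL * max(1.0, diag.max() if diag.size else 1.0)
    rank = int((diag > thresh).sum())
    keep = sorted(piv[:rank])
    internal = network.internal_metabolites
    dropped = [internal[i].id for i in sorted(set(range(len(internal))) - set(keep))]
    if not dropped:
        return network.copy(), []
    keep_ids = {internal[i].id for i in keep}
    mets = [m for m in network.metabolites if m.is_boundary or m.id in keep_ids]
    rxns = []
    for r in network.reactions:
        r2 = r.copy()
        r2.stoich = {mid: c for mid, c in r.stoich.items() if mid in keep_ids
                     or network.metabolite(mid).is_boundary}
        rxns.append(r2)
    return MetabolicNetwork(mets, rxns), dropped


def _kernel(network: MetabolicNetwork) -> np.ndarray:
    N = network.stoichiometric_matrix().toarray()
    if N.shape[1] == 0:
        return np.zeros((0, 0))
    if N.shape[0] == 0:
        return np.eye(N.shape[1])
    return linalg.null_space(N)


def fully_coupled_sets(network: MetabolicNetwork) -> list[list[str]]:
    """Partition reactions into ratio-locked groups.

    i and j share a group iff r_i = c * r_j with fixed nonzero c over the
    whole kernel of N; blocked reactions each form their own group.
    """
    K = _kernel(network)
    n = len(network.reactions)
    if K.size == 0:
        return [[r.id] for r in network.reactions]
    norms = np.linalg.norm(K, axis=1)
    scale = max(1.0, norms.max() if norms.size else 1.0)
    groups: list[list[int]] = []
    reps: list[np.ndarray] = []
    for i in range(n):
        if norms[i] <= COUPLING_TOL * scale:
            groups.append([i])  # blocked: singleton
            reps.append(None)
            continue
        placed = False
        for g, rep in zip(groups, reps):
            if rep is None:
                continue
            # proportional iff cross-products vanish
            if np.max(np.abs(np.outer(K[i], rep) - np.outer(rep, K[i]))) <= COUPLING_TOL * scale * scale:
                g.append(i)
                placed = True
                break
        if not placed:
            groups.append([i])
            reps.append(K[i])
    return [[network.reactions[i].id for i in g] for g in groups]


def _coupling_ratio(K: np.ndarray, i: int, rep: int) -> float:
    j = int(np.argmax(np.abs(K[rep])))
    return float(K[i, j] / K[rep, j])


def compress(network: MetabolicNetwork):
    """Compress: remove conservation relations, prune blocked reactions and
    merge fully coupled sets. Returns (compressed network, CompressionMap)."""
    reduced, dropped_mets = remove_conservation_relations(network)
    K = _kernel(reduced)
    n = len(reduced.reactions)
    norms = np.linalg.norm(K, axis=1) if K.size else np.zeros(n)
    scale = max(1.0, norms.max() if norms.size else 1.0)
    blocked = [reduced.reactions[i].id for i in range(n) if norms[i] <= COUPLING_TOL * scale]
    if blocked:
        logger.info("pruning %d blocked reactions before coupling detection", len(blocked))

    groups_ids = [g for g in fully_coupled_sets(reduced) if g[0] not in set(blocked)]
    ridx = reduced.reaction_index

    cmap = CompressionMap(dropped_metabolites=dropped_mets, blocked_reactions=blocked)
    new_rxns: list[Reaction] = []
    used_mets: set[str] = set()
    for g in groups_ids:
        members = [reduced.reactions[ridx[rid]] for rid in g]
        rep_i = ridx[g[0]]
        scales = [(_coupling_ratio(K, ridx[rid], rep_i) if len(g) > 1 else 1.0) for rid in g]
        gid = g[0] if len(g) == 1 else "*".join(g)
        stoich: dict[str, float] = {}
        lb, ub = -INF, INF
        for rxn, c in zip(members, scales):
            for mid, coef in rxn.stoich.items():
                stoich[mid] = stoich.get(mid, 0.0) + c * coef
            # member bound lb_k <= c*v <= ub_k  =>  v in [lb/c, ub/c] (swapped if c<0)
            mlo, mhi = rxn.lb / c, rxn.ub / c
            if c < 0:
                mlo, mhi = mhi, mlo
            lb, ub = max(lb, mlo), min(ub, mhi)
        stoich = {mid: c for mid, c in stoich.items() if abs(c) > 1e-10}
        used_mets.update(stoich)
        repressible_members = [r.id for r in members if r.repressible]
        merged = Reaction(gid, stoich, name="+".join(r.name for r in members if r.name),
                          lb=lb, ub=ub, repressible=bool(repressible_members),
                          gpr=None, is_exchange=any(r.is_exchange for r in members))
        new_rxns.append(merged)
        cmap.merged_groups.append((gid, list(zip(g, scales))))
        cmap.repressible_members[gid] = repressible_members

    mets = [m for m in reduced.metabolites if m.id in used_mets]
    compressed = MetabolicNetwork(mets, new_rxns)
    return compressed, cmap


def expand_cutset(cmap: CompressionMap, compressed_cut) -> tuple[frozenset, dict[str, list[str]]]:
    """Map a compressed cut set back to original reactions.

    Each cut group is replaced by its canonical (first) repressible member;
    the full list of interchangeable repressible members is returned per
    group so callers can report alternatives.
    """
    cut: set[str] = set()
    alternatives: dict[str, list[str]] = {}
    for gid in compressed_cut:
        members = cmap.repressible_members.get(gid)
        assert members, f"cut group {gid} has no repressible member"
        cut.add(members[0])
        alternatives[members[0]] = list(members)
    return frozenset(cut), alternatives


def translate_constraints(rows, cmap: CompressionMap, compressed: MetabolicNetwork):
    """Rewrite constraint rows from original reaction ids to compressed ids.

    A coefficient a on original reaction r with r = c * v_group becomes a*c on
    the group variable; coefficients on blocked reactions (flux identically 0)
    drop out.
    """
    m2g = cmap.member_to_group
    blocked = set(cmap.blocked_reactions)
    out = []
    for coeffs, sense, rhs in rows:
        row: dict[str, float] = {}
        for rid, a in coeffs.items():
            if rid in blocked:
                continue
            gid, c = m2g[rid]
            row[gid] = row.get(gid, 0.0) + a * c
        out.append((row, sense, rhs))
    return out
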