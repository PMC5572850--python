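"""Maximal-biclique module extraction.

A synergistic competing module is a complete bipartite subgraph of the
network: a set of lncRNAs every one of which is linked to every member of a
partner set.  Modules are found by exact enumeration of maximal bicliques.

The network need not be strictly bipartite: lncRNA–lncRNA competing edges
are allowed.  To keep the biclique definition bipartite, every lncRNA that
occurs as a competing partner is mirrored onto the partner side as a tagged
copy; tags are removed from the reported modules.  A consequence is that a
module built around lncRNA partners can also appear in mirrored form with
the roles exchanged; both are genuine maximal bicliques of the mirrored
bipartite graph and both are reported.

Enumeration uses Close-by-One over the lncRNA side: every maximal biclique
(A, B) satisfies A = {l : adj(l) ⊇ B} and B = ∩_{l∈A} adj(l), i.e. it is a
closed concept of the bipartite adjacency, and CbO visits each closed
concept exactly once via a canonicity test.  This is exact, with cost
proportional to the number of concepts — small for the sparse, star-like
networks this stage receives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .containers import LNCRNA
from .errors import ConsistencyError, UsageError
from .netanalysis import CeRNANetwork

_PARTNER_TAG = ("partner",)  # nodes on the mirrored side are ("partner", id)


@dataclass(frozen=True)
class BicliqueModule:
    """A maximal complete-bipartite module of the network."""

    lnc_side: frozenset[str]
    partner_side: frozenset[str]

    def __post_init__(self) -> None:
        if self.lnc_side & self.partner_side:
            raise ConsistencyError(
                f"module sides overlap: {sorted(self.lnc_side & self.partner_side)}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.lnc_side) + len(self.partner_side)

    @property
    def members(self) -> frozenset[str]:
        return self.lnc_side | self.partner_side

    def sort_key(self) -> tuple:
        return (-self.n_genes, tuple(sorted(self.members)))


def _bipartite_adjacency(net: CeRNANetwork) -> dict[str, frozenset]:
    """lncRNA → partner-side neighbor sets; lncRNA partners are tagged."""
    g = net.graph
    adj: dict[str, set] = {}
    for u, v in g.edges:
        cu = g.nodes[u]["node_class"]
        cv = g.nodes[v]["node_class"]
        if cu == LNCRNA and cv == LNCRNA:
            adj.setdefault(u, set()).add(("partner", v))
            adj.setdefault(v, set()).add(("partner", u))
        elif cu == LNCRNA:
            adj.setdefault(u, set()).add(v)
        elif cv == LNCRNA:
            adj.setdefault(v, set()).add(u)
        else:
            raise ConsistencyError(f"edge ({u}, {v}) joins two non-lncRNA nodes")
    return {l: frozenset(s) for l, s in adj.items()}


def _closed_concepts(adj: dict[str, frozenset]) -> Iterator[tuple[frozenset, frozenset]]:
    """Close-by-One enumeration of all closed (lnc-set, partner-set) pairs."""
    lncs = sorted(adj)
    index = {l: i for i, l in enumerate(lncs)}
    all_partners = frozenset().union(*adj.values()) if adj else frozenset()

    def extent(B: frozenset) -> frozenset:
        return frozenset(l for l in lncs if B <= adj[l])

    def recurse(A: frozenset, B: frozenset, y: int) -> Iterator[tuple[frozenset, frozenset]]:
        yield A, B
        for j in range(y + 1, len(lncs)):
            l = lncs[j]
            if l in A:
                continue
            B2 = B & adj[l]
            A2 = extent(B2)
            # canonicity: no generator with a smaller index may be new
            if any(index[h] < j and h not in A for h in A2):
                continue
            yield from recurse(A2, B2, j)

    if not lncs:
        return
    A0 = extent(all_partners)
    yield from recurse(A0, all_partners, -1)


def _untag(partner_side: frozenset) -> frozenset[str]:
    return frozenset(p[1] if isinstance(p, tuple) else p for p in partner_side)


def enumerate_maximal_bicliques(
    net: CeRNANetwork, min_lnc: int = 2, min_partner: int = 2
) -> list[BicliqueModule]:
    """All maximal bicliques with side sizes >= (min_lnc, min_partner).

    Output is sorted by decreasing gene count, ties broken by the sorted
    member tuple, so results are stable across runs.  Every returned module
    is checked for completeness and maximality against the network.
    """
    if min_lnc < 1 or min_partner < 1:
        raise UsageError("minimum side sizes must be >= 1")
    adj = _bipartite_adjacency(net)
    modules = []
    for A, B in _closed_concepts(adj):
        if len(A) >= min_lnc and len(B) >= min_partner:
            modules.append(BicliqueModule(frozenset(A), _untag(B)))
    modules.sort(key=BicliqueModule.sort_key)
    for m in modules:
        verify_module(net, m)
    return modules


def verify_module(net: CeRNANetwork, module: BicliqueModule) -> None:
    """Assert completeness and maximality of a module; raise if violated."""
    g = net.graph
    for l in module.lnc_side:
        for p in module.partner_side:
            if not g.has_edge(l, p):
                raise ConsistencyError(f"module incomplete: missing edge ({l}, {p})")
    adj = _bipartite_adjacency(net)
    # partner p is tagged in the mirrored bipartite graph iff it is a lncRNA
    tagged = frozenset(
        ("partner", p) if g.nodes[p]["node_class"] == LNCRNA else p
        for p in module.partner_side
    )
    common = frozenset.intersection(*(adj[l] for l in module.lnc_side))
    if common != tagged:
        raise ConsistencyError(
            f"module partner side not maximal for lnc side {sorted(module.lnc_side)}"
        )
    closed = frozenset(l for l in adj if tagged <= adj[l])
    if closed != module.lnc_side:
        raise ConsistencyError(
            f"module lnc side not maximal for partner side {sorted(module.partner_side)}"
        )


def select_modules(modules: Sequence[BicliqueModule], top_k: int) -> list[BicliqueModule]:
    """The ``top_k`` largest modules under the deterministic size ordering."""
    if top_k <= 0:
        raise UsageError(f"top_k must be positive, got {top_k}")
    return sorted(modules, key=BicliqueModule.sort_key)[:top_k]
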