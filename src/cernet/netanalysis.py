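"""Topological characterization of the competing-endogenous-RNA network.

The filtered edge set is assembled into an undirected simple graph whose
nodes carry lncRNA/mRNA class labels.  Characterization follows the usual
interactome playbook: degree, shortest-path betweenness and closeness
centralities, hub calling at a degree threshold, a log-log least-squares
fit of the degree distribution (scale-free check), and a Welch t-test
comparing centrality between the two node classes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import LNCRNA, MRNA
from .coexpr import WeightedEdge
from .errors import ConsistencyError, InsufficientDataError, UsageError

CENTRALITY_METRICS = ("degree", "betweenness", "closeness")


@dataclass
class CeRNANetwork:
    """Weighted undirected ceRNA network.

    Thin wrapper over a :class:`networkx.Graph` whose nodes carry a
    ``node_class`` attribute and whose edges carry ``weight`` plus the
    detection provenance (Y, p, q and the three correlations).
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, node: str) -> str:
        return self.graph.nodes[node]["node_class"]

    def nodes_of_class(self, cls: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["node_class"] == cls)

    @property
    def lncRNAs(self) -> list[str]:
        return self.nodes_of_class(LNCRNA)

    @property
    def mRNAs(self) -> list[str]:
        return self.nodes_of_class(MRNA)


def build_network(edges: Sequence[WeightedEdge]) -> CeRNANetwork:
    """Assemble weighted edges into a simple undirected network.

    Duplicate edges with identical weights are collapsed; a duplicate with
    a conflicting weight raises :class:`ConsistencyError`.
    """
    if not edges:
        raise UsageError("cannot build a network from an empty edge list")
    g = nx.Graph()
    for e in sorted(edges, key=lambda e: (e.lnc_id, e.partner_id)):
        u, v = e.lnc_id, e.partner_id
        if u == v:
            raise ConsistencyError(f"self-loop on {u!r}")
        g.add_node(u, node_class=LNCRNA)
        if v not in g:
            g.add_node(v, node_class=e.pair.partner_class)
        elif g.nodes[v]["node_class"] != e.pair.partner_class:
            raise ConsistencyError(f"node {v!r} assigned two classes")
        if g.has_edge(u, v):
            if not math.isclose(g[u][v]["weight"], e.weight, rel_tol=0, abs_tol=1e-12):
                raise ConsistencyError(
                    f"duplicate edge ({u}, {v}) with conflicting weights "
                    f"{g[u][v]['weight']} vs {e.weight}"
                )
            continue
        g.add_edge(
            u, v,
            weight=float(e.weight),
            Y=e.pair.Y, p=e.pair.p_raw, q=e.pair.q_fdr,
            M=e.pair.M, N=e.pair.N, K=e.pair.K,
            partner_class=e.pair.partner_class,
            pcc_pooled=e.pcc_pooled, pcc_tumor=e.pcc_tumor, pcc_normal=e.pcc_normal,
            mode=e.mode,
        )
    return CeRNANetwork(g)


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    node_class: str
    degree: int
    betweenness: float
    closeness: float
    is_hub: bool


def centralities(
    net: CeRNANetwork, hub_threshold: int = 60, normalized_betweenness: bool = False
) -> list[CentralityRecord]:
    """Per-node degree, betweenness and closeness with hub flags.

    Betweenness is Freeman shortest-path betweenness over unweighted paths,
    each unordered pair counted once; ``normalized_betweenness`` divides by
    (n-1)(n-2)/2.  Closeness is component-restricted:
    (reachable nodes) / (sum of distances to them), 0 for isolates.  Hubs
    are nodes with degree strictly above ``hub_threshold``.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise UsageError("empty network")
    btw = nx.betweenness_centrality(g, normalized=normalized_betweenness)
    clo = nx.closeness_centrality(g, wf_improved=False)
    return [
        CentralityRecord(
            node=n,
            node_class=g.nodes[n]["node_class"],
            degree=int(g.degree[n]),
            betweenness=float(btw[n]),
            closeness=float(clo[n]),
            is_hub=g.degree[n] > hub_threshold,
        )
        for n in sorted(g.nodes)
    ]


def centrality_frame(records: Iterable[CentralityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.node, r.node_class, r.degree, r.betweenness, r.closeness, r.is_hub)
            for r in records
        ],
        columns=["node", "node_class", "degree", "betweenness", "closeness", "is_hub"],
    )


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(frequency) on log10(degree)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fit_degree_loglog(degrees: Iterable[int]) -> PowerLawFit:
    """Fit the degree-frequency histogram on log-log axes.

    Degrees of zero are excluded (log undefined); at least 3 distinct
    positive degree values are required.
    """
    counts = Counter(int(d) for d in degrees if int(d) > 0)
    if len(counts) < 3:
        raise InsufficientDataError(
            f"power-law fit needs >= 3 distinct degree values, got {len(counts)}"
        )
    ks = np.array(sorted(counts), dtype=float)
    freqs = np.array([counts[int(k)] for k in ks], dtype=float)
    res = sps.linregress(np.log10(ks), np.log10(freqs))
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(ks),
    )


def fit_power_law(net: CeRNANetwork) -> PowerLawFit:
    """Power-law check of a network's degree distribution."""
    return fit_degree_loglog(d for _, d in net.graph.degree)


@dataclass(frozen=True)
class ClassComparison:
    """Welch t-test of a centrality metric between lncRNAs and mRNAs."""

    metric: str
    mean_lnc: float
    mean_mrna: float
    n_lnc: int
    n_mrna: int
    t_stat: float
    p_value: float


def compare_classes(records: Sequence[CentralityRecord], metric: str) -> ClassComparison:
    """Welch (unequal-variance) two-sample t-test of lncRNA vs mRNA values."""
    if metric not in CENTRALITY_METRICS:
        raise UsageError(f"unknown metric {metric!r}; expected one of {CENTRALITY_METRICS}")
    lnc = np.array([getattr(r, metric) for r in records if r.node_class == LNCRNA], dtype=float)
    mrna = np.array([getattr(r, metric) for r in records if r.node_class == MRNA], dtype=float)
    for name, vals in ((LNCRNA, lnc), (MRNA, mrna)):
        if vals.size < 2:
            raise UsageError(f"class {name!r} has fewer than 2 records")
    if lnc.std(ddof=1) == 0.0 and mrna.std(ddof=1) == 0.0:
        # degenerate: no within-class variation
        if lnc.mean() == mrna.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if lnc.mean() > mrna.mean() else -math.inf, 0.0
    else:
        t, p = sps.ttest_ind(lnc, mrna, equal_var=False)
    return ClassComparison(
        metric=metric,
        mean_lnc=float(lnc.mean()),
        mean_mrna=float(mrna.mean()),
        n_lnc=int(lnc.size),
        n_mrna=int(mrna.size),
        t_stat=float(t),
        p_value=float(p),
    )
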