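"""Shared fixtures: tiny catalogs, expression matrices and networks built
programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cernet import (
    CompetingPairResult,
    ExpressionMatrix,
    InteractionCatalog,
    WeightedEdge,
    build_network,
)
from cernet.containers import LNCRNA, MRNA, NORMAL, TUMOR

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_pair(lnc, partner, partner_class=MRNA, M=5, N=5, Y=3, K=100,
              p=1e-4, q=1e-3) -> CompetingPairResult:
    return CompetingPairResult(lnc, partner, partner_class, M, N, Y, K, p, q)


def make_edge(lnc, partner, weight=0.9, partner_class=MRNA,
              mode="group_difference", pcc_pooled=0.5, pcc_tumor=0.9,
              pcc_normal=0.0) -> WeightedEdge:
    return WeightedEdge(make_pair(lnc, partner, partner_class), pcc_pooled,
                        pcc_tumor, pcc_normal, weight, mode)


def network_from_edgelist(pairs, lnc_prefix="L"):
    """Build a CeRNANetwork from (lnc, partner) tuples; partners starting
    with the lnc prefix are classed lncRNA."""
    edges = [
        make_edge(u, v, partner_class=LNCRNA if v.startswith(lnc_prefix) else MRNA)
        for u, v in pairs
    ]
    return build_network(edges)


@pytest.fixture
def toy_catalog() -> InteractionCatalog:
    """4 lncRNAs x 5 mRNAs over a 30-miRNA universe, overlaps by hand."""
    mir = [f"m{i:02d}" for i in range(30)]
    lnc = {
        "L1": frozenset(mir[0:6]),
        "L2": frozenset(mir[4:10]),
        "L3": frozenset(mir[10:14]),
        "L4": frozenset(mir[20:25]),
    }
    mrna = {
        "G1": frozenset(mir[0:5]),
        "G2": frozenset(mir[3:8]),
        "G3": frozenset(mir[9:13]),
        "G4": frozenset(mir[12:18]),
        "G5": frozenset(mir[25:30]),
    }
    return InteractionCatalog.from_maps(lnc, mrna, mir)


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    """6 genes x 8 samples (4 per group), seeded Gaussian noise."""
    rng = np.random.default_rng(42)
    genes = ["L1", "L2", "G1", "G2", "G3", "G4"]
    samples = [f"N{i}" for i in range(4)] + [f"T{i}" for i in range(4)]
    values = pd.DataFrame(rng.normal(size=(6, 8)), index=genes, columns=samples)
    group = pd.Series([NORMAL] * 4 + [TUMOR] * 4, index=samples)
    return ExpressionMatrix(values, group)
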