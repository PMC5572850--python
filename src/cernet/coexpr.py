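"""Co-expression weighting of candidate ceRNA pairs.

Each FDR-passing pair is annotated with three Pearson correlations of its
members' expression vectors — pooled over all samples, within the tumor
group and within the normal group — and assigned a weight under one of two
definitions:

``pooled_abs``
    |pooled PCC|, in [0, 1].
``group_difference``
    |PCC(tumor) − PCC(normal)|, in [0, 2].  Only this definition can exceed
    1, which happens when the two groups correlate with opposite signs —
    pairs whose coupling is rewired between conditions.

Edges with weight strictly above the cutoff (default 0.8) form the highly
competitive network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import NORMAL, TUMOR, ExpressionMatrix
from .detect import CompetingPairResult
from .errors import UsageError

log = logging.getLogger(__name__)

WEIGHT_MODES = ("pooled_abs", "group_difference")


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors.

    Requires length >= 3 and nonzero variance on both sides.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(f"vectors must be 1-D and equal length, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.dot(x - x.mean(), y - y.mean()) / (x.size * sx * sy))
    return min(1.0, max(-1.0, r))


@dataclass(frozen=True)
class WeightedEdge:
    """A competing pair with its co-expression weight."""

    pair: CompetingPairResult
    pcc_pooled: float
    pcc_tumor: float
    pcc_normal: float
    weight: float
    mode: str

    @property
    def lnc_id(self) -> str:
        return self.pair.lnc_id

    @property
    def partner_id(self) -> str:
        return self.pair.partner_id


def edge_weight(pcc_pooled: float, pcc_tumor: float, pcc_normal: float, mode: str) -> float:
    if mode == "pooled_abs":
        return abs(pcc_pooled)
    if mode == "group_difference":
        return abs(pcc_tumor - pcc_normal)
    raise UsageError(f"unknown weight mode {mode!r}; expected one of {WEIGHT_MODES}")


def weight_edges(
    pairs: Sequence[CompetingPairResult],
    expr: ExpressionMatrix,
    mode: str = "group_difference",
    cutoff: float = 0.8,
) -> list[WeightedEdge]:
    """Correlate every pair's expression and keep edges with weight > cutoff.

    Pairs whose members are absent from the matrix are dropped with a
    warning.  The retained edges are sorted by (lnc id, partner id).
    """
    if mode not in WEIGHT_MODES:
        raise UsageError(f"unknown weight mode {mode!r}; expected one of {WEIGHT_MODES}")
    if cutoff < 0.0:
        raise UsageError(f"cutoff must be non-negative, got {cutoff}")
    present = set(expr.gene_ids)
    edges: list[WeightedEdge] = []
    for pair in pairs:
        missing = [g for g in (pair.lnc_id, pair.partner_id) if g not in present]
        if missing:
            log.warning(
                "dropping pair (%s, %s): not in expression matrix: %s",
                pair.lnc_id, pair.partner_id, missing,
            )
            continue
        a_all = expr.vector(pair.lnc_id)
        b_all = expr.vector(pair.partner_id)
        pcc_pooled = pearson(a_all, b_all)
        pcc_tumor = pearson(expr.vector(pair.lnc_id, TUMOR), expr.vector(pair.partner_id, TUMOR))
        pcc_normal = pearson(
            expr.vector(pair.lnc_id, NORMAL), expr.vector(pair.partner_id, NORMAL)
        )
        w = edge_weight(pcc_pooled, pcc_tumor, pcc_normal, mode)
        if w > cutoff:
            edges.append(WeightedEdge(pair, pcc_pooled, pcc_tumor, pcc_normal, w, mode))
    edges.sort(key=lambda e: (e.lnc_id, e.partner_id))
    return edges
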