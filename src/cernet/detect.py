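"""Detection of candidate ceRNA pairs by the shared-miRNA hypergeometric test.

Two transcripts that bind many of the same miRNAs are candidate competing
endogenous RNAs.  For each lncRNA–mRNA pair (optionally also lncRNA–lncRNA)
the overlap of their miRNA sets is scored against the hypergeometric null of
independent draws from the miRNA universe; p-values are adjusted jointly by
Benjamini–Hochberg and pairs passing the FDR cutoff form the "original"
competing-interaction network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import LNCRNA, MRNA, InteractionCatalog
from .errors import UsageError
from .stats import bh_adjust, hypergeom_pvalue

log = logging.getLogger(__name__)

__all__ = ["CompetingPairResult", "detect_competing_pairs", "hypergeom_pvalue", "bh_adjust"]


@dataclass(frozen=True)
class CompetingPairResult:
    """One tested lncRNA–partner pair.

    ``M`` is the partner's miRNA-set size, ``N`` the lncRNA's, ``Y`` the
    shared count and ``K`` the universe size used for the test.
    """

    lnc_id: str
    partner_id: str
    partner_class: str  # LNCRNA or MRNA
    M: int
    N: int
    Y: int
    K: int
    p_raw: float
    q_fdr: float

    def __post_init__(self) -> None:
        if not (0 <= self.Y <= min(self.M, self.N) <= self.K):
            raise ValueError(
                f"invalid counts for pair ({self.lnc_id}, {self.partner_id}): "
                f"Y={self.Y} M={self.M} N={self.N} K={self.K}"
            )


def _candidate_pairs(
    catalog: InteractionCatalog, include_lnc_lnc: bool
) -> list[tuple[str, str, str, int, int, int]]:
    """All (lnc, partner, class, M, N, Y) tuples, Y computed by indicator
    matrix products over the miRNA universe."""
    mir_index = {m: i for i, m in enumerate(sorted(catalog.mirna_universe))}
    lncs = sorted(catalog.lnc_to_mir)
    mrnas = sorted(catalog.mrna_to_mir)

    def indicator(genes: list[str], mapping) -> np.ndarray:
        mat = np.zeros((len(genes), len(mir_index)), dtype=np.uint8)
        for i, g in enumerate(genes):
            for m in mapping[g]:
                mat[i, mir_index[m]] = 1
        return mat

    out: list[tuple[str, str, str, int, int, int]] = []
    L = indicator(lncs, catalog.lnc_to_mir)
    if mrnas:
        R = indicator(mrnas, catalog.mrna_to_mir)
        overlap = L.astype(np.int64) @ R.T.astype(np.int64)
        n_sizes = L.sum(axis=1)
        m_sizes = R.sum(axis=1)
        for i, lnc in enumerate(lncs):
            for j, mrna in enumerate(mrnas):
                out.append((lnc, mrna, MRNA, int(m_sizes[j]), int(n_sizes[i]), int(overlap[i, j])))
    if include_lnc_lnc:
        overlap_ll = L.astype(np.int64) @ L.T.astype(np.int64)
        sizes = L.sum(axis=1)
        for i in range(len(lncs)):
            for j in range(i + 1, len(lncs)):
                out.append(
                    (lncs[i], lncs[j], LNCRNA, int(sizes[j]), int(sizes[i]), int(overlap_ll[i, j]))
                )
    return out


def detect_competing_pairs(
    catalog: InteractionCatalog,
    fdr_cutoff: float | None = 0.01,
    include_lnc_lnc: bool = False,
    min_shared: int = 1,
    tail: str = "inclusive",
    universe_size: int | None = None,
) -> list[CompetingPairResult]:
    """Test every candidate pair and return those passing the FDR cutoff.

    Parameters
    ----------
    catalog : interaction catalog supplying the miRNA sets and universe.
    fdr_cutoff : retain pairs with adjusted q strictly below this value;
        ``None`` returns every tested pair.
    include_lnc_lnc : also test lncRNA–lncRNA pairs (off by default; the
        partner in each such pair is the lexicographically larger id).
    min_shared : only pairs sharing at least this many miRNAs are tested
        (and enter the BH correction).
    tail : ``"inclusive"`` (default) or ``"strict"``; see
        :func:`cernet.stats.hypergeom_pvalue`.
    universe_size : override for K; defaults to the catalog's universe size.

    Results are sorted by (q, lnc id, partner id).
    """
    if not catalog.lnc_to_mir or not catalog.mrna_to_mir:
        if not include_lnc_lnc or not catalog.lnc_to_mir:
            log.warning("catalog has an empty regulator class; nothing to test")
            return []
    if min_shared < 0:
        raise UsageError(f"min_shared must be >= 0, got {min_shared}")
    if fdr_cutoff is not None and not (0.0 < fdr_cutoff <= 1.0):
        raise UsageError(f"fdr_cutoff must lie in (0, 1], got {fdr_cutoff}")
    K = catalog.universe_size if universe_size is None else int(universe_size)
    max_set = max(
        (len(s) for s in (*catalog.lnc_to_mir.values(), *catalog.mrna_to_mir.values())),
        default=0,
    )
    if K < max_set:
        raise UsageError(f"universe size K={K} smaller than the largest miRNA set ({max_set})")

    candidates = [c for c in _candidate_pairs(catalog, include_lnc_lnc) if c[5] >= min_shared]
    if not candidates:
        log.warning("no candidate pairs with shared miRNAs >= %d", min_shared)
        return []
    pvals = [hypergeom_pvalue(K, M, N, Y, tail=tail) for (_, _, _, M, N, Y) in candidates]
    qvals = bh_adjust(pvals)
    results = [
        CompetingPairResult(lnc, partner, cls, M, N, Y, K, float(p), float(q))
        for (lnc, partner, cls, M, N, Y), p, q in zip(candidates, pvals, qvals)
    ]
    if fdr_cutoff is not None:
        results = [r for r in results if r.q_fdr < fdr_cutoff]
    results.sort(key=lambda r: (r.q_fdr, r.lnc_id, r.partner_id))
    return results
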