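"""Gene-set enrichment for network mRNAs and qRT-PCR fold-change arithmetic.

Enrichment is the one-sided Fisher exact test (hypergeometric upper tail,
shared with the ceRNA-pair test) of a query gene list against user-supplied
annotation collections in GMT format, BH-adjusted within a collection.
Conventionally GO-style collections are filtered at FDR < 0.01 and pathway
collections at FDR < 0.05.

Fold change follows the relative-quantification ΔΔCt convention:
ΔΔCt = (Ct_target − Ct_reference)_case − (Ct_target − Ct_reference)_control
and fold change = 2^(−ΔΔCt), so positive ΔΔCt (down-regulation in the case
group) gives fold change < 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import UsageError
from .stats import bh_adjust, hypergeom_pvalue

GO_FDR_DEFAULT = 0.01
PATHWAY_FDR_DEFAULT = 0.05


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k_overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_raw: float
    q_fdr: float


def enrich(
    query: Iterable[str],
    gene_sets: Mapping[str, GeneSet] | Iterable[GeneSet],
    background: Iterable[str],
    fdr_cutoff: float | None = PATHWAY_FDR_DEFAULT,
) -> list[EnrichmentResult]:
    """Test one annotation collection for over-representation in a query.

    Every annotation is intersected with the background before testing; the
    query must be a subset of the background.  Terms with empty background
    intersection are skipped; all remaining terms enter one BH correction.
    ``fdr_cutoff=None`` returns all tested terms.  Results sorted by
    (q, p, term id).
    """
    query_set = frozenset(query)
    bg = frozenset(background)
    if not query_set or not bg:
        raise UsageError("query and background must both be nonempty")
    if not query_set <= bg:
        stray = sorted(query_set - bg)
        raise UsageError(f"query genes missing from background: {stray[:10]}")
    if isinstance(gene_sets, Mapping):
        sets = list(gene_sets.values())
    else:
        sets = list(gene_sets)
    K = len(bg)
    N = len(query_set)
    tested: list[tuple[GeneSet, int, int, float]] = []
    for gs in sets:
        members = gs.genes & bg
        if not members:
            continue
        M = len(members)
        Y = len(members & query_set)
        p = hypergeom_pvalue(K, M, N, Y, tail="inclusive")
        tested.append((gs, M, Y, p))
    if not tested:
        return []
    qvals = bh_adjust([p for (_, _, _, p) in tested])
    results = [
        EnrichmentResult(
            term_id=gs.name,
            term_name=gs.description,
            k_overlap=Y,
            set_size=M,
            query_size=N,
            background_size=K,
            p_raw=float(p),
            q_fdr=float(q),
        )
        for (gs, M, Y, p), q in zip(tested, qvals)
    ]
    if fdr_cutoff is not None:
        results = [r for r in results if r.q_fdr < fdr_cutoff]
    results.sort(key=lambda r: (r.q_fdr, r.p_raw, r.term_id))
    return results


@dataclass(frozen=True)
class FoldChangeRecord:
    gene_id: str
    delta_delta_ct: float
    fold_change: float


def fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
    gene_id: str = "",
) -> FoldChangeRecord:
    """Relative expression by the ΔΔCt method (fold change = 2^-ΔΔCt)."""
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    for v in cts:
        if not (float("-inf") < float(v) < float("inf")):
            raise ValueError(f"non-finite Ct value: {v!r}")
    ddct = (float(ct_target_case) - float(ct_ref_case)) - (
        float(ct_target_ctrl) - float(ct_ref_ctrl)
    )
    return FoldChangeRecord(gene_id=gene_id, delta_delta_ct=ddct, fold_change=2.0 ** (-ddct))
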