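"""Shared statistical primitives: hypergeometric tail probabilities and
Benjamini–Hochberg adjustment.

The hypergeometric upper tail is the significance test for the number of
miRNAs shared by a candidate ceRNA pair: with ``K`` miRNAs in the universe,
``M`` bound by one transcript, ``N`` by the other and ``Y`` shared, the
p-value is the probability that a hypergeometric draw shows at least (or,
in ``strict`` mode, more than) ``Y`` common miRNAs.  The same tail doubles
as the one-sided Fisher exact test used for gene-set enrichment.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

#: Tail modes.  ``inclusive`` is the conventional P(X >= Y); ``strict`` is
#: P(X > Y), which excludes the observed count (some typeset forms of the
#: test, written 1 - sum_{t=0}^{Y}, correspond to this strict tail).
TAIL_MODES = ("inclusive", "strict")

# Below this universe size the tail is summed in exact integer arithmetic;
# above it, in log space via scipy.  2000 keeps big-int cost negligible.
_EXACT_K_MAX = 2000


def hypergeom_pvalue(K: int, M: int, N: int, Y: int, tail: str = "inclusive") -> float:
    """Upper-tail hypergeometric p-value for a shared-miRNA count.

    Parameters
    ----------
    K : size of the miRNA universe.
    M : miRNAs bound by the partner transcript (mRNA side).
    N : miRNAs bound by the lncRNA.
    Y : observed shared-miRNA count.
    tail : ``"inclusive"`` for P(X >= Y) or ``"strict"`` for P(X > Y).

    Returns
    -------
    float in [0, 1].
    """
    for name, v in (("K", K), ("M", M), ("N", N), ("Y", Y)):
        if not isinstance(v, (int, np.integer)):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if K < 0 or M < 0 or N < 0 or Y < 0:
        raise ValueError(f"negative hypergeometric argument: K={K} M={M} N={N} Y={Y}")
    if M > K or N > K:
        raise ValueError(f"set size exceeds universe: K={K} M={M} N={N}")
    if Y > min(M, N):
        raise ValueError(f"shared count Y={Y} exceeds min(M, N)={min(M, N)}")
    if tail not in TAIL_MODES:
        raise ValueError(f"unknown tail mode {tail!r}; expected one of {TAIL_MODES}")
    threshold = Y if tail == "inclusive" else Y + 1
    return _upper_tail(int(K), int(M), int(N), threshold)


def _upper_tail(K: int, M: int, N: int, threshold: int) -> float:
    """P(X >= threshold) for X ~ Hypergeometric(K, M, N)."""
    lo = max(0, M + N - K)  # smallest achievable overlap
    hi = min(M, N)
    if threshold <= lo:
        return 1.0
    if threshold > hi:
        return 0.0
    if K <= _EXACT_K_MAX:
        num = 0
        for t in range(threshold, hi + 1):
            num += math.comb(M, t) * math.comb(K - M, N - t)
        # Fraction -> float is correctly rounded, so the result is exact to
        # full double precision.
        return float(Fraction(num, math.comb(K, N)))
    p = float(hypergeom.sf(threshold - 1, K, M, N))
    return min(1.0, max(0.0, p))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Returns the adjusted values in the original input order, clipped at 1.
    Raises ``ValueError`` for inputs outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(np.isnan(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        bad = p[(np.isnan(p)) | (p < 0.0) | (p > 1.0)]
        raise ValueError(f"p-values outside [0, 1]: {bad[:5]!r}")
    return multipletests(p, method="fdr_bh")[1]
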