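"""Core in-memory containers: the miRNA-interaction catalog and the
group-labelled expression matrix.

An :class:`InteractionCatalog` holds, for every lncRNA and every mRNA, the
set of miRNAs experimentally reported to bind it, together with the miRNA
universe those sets live in.  These three pieces supply the K, M, N counts
of the shared-miRNA hypergeometric test.

An :class:`ExpressionMatrix` is a genes-by-samples table with a two-group
(normal vs tumor) sample annotation; it supplies the expression vectors
whose Pearson correlation weights candidate ceRNA edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DataFormatError, UsageError

log = logging.getLogger(__name__)

LNCRNA = "lncRNA"
MRNA = "mRNA"
NORMAL = "normal"
TUMOR = "tumor"
GROUPS = (NORMAL, TUMOR)


def normalize_mirna(mirna: str) -> str:
    """Canonical miRNA identifier: whitespace-trimmed, lower-cased."""
    return str(mirna).strip().lower()


@dataclass(frozen=True)
class InteractionCatalog:
    """Regulator → miRNA-set maps for lncRNAs and mRNAs.

    Invariants enforced at construction: the two identifier namespaces are
    disjoint, every retained regulator binds at least one miRNA, and every
    miRNA referenced by a target set belongs to ``mirna_universe``.
    """

    lnc_to_mir: Mapping[str, frozenset[str]]
    mrna_to_mir: Mapping[str, frozenset[str]]
    mirna_universe: frozenset[str]

    def __post_init__(self) -> None:
        lnc = {str(g): frozenset(normalize_mirna(m) for m in s) for g, s in self.lnc_to_mir.items()}
        mrna = {str(g): frozenset(normalize_mirna(m) for m in s) for g, s in self.mrna_to_mir.items()}
        both = set(lnc) & set(mrna)
        if both:
            raise ConsistencyError(
                f"identifiers listed as both lncRNA and mRNA: {sorted(both)[:10]}"
            )
        for name, mapping in (("lncRNA", lnc), ("mRNA", mrna)):
            empty = [g for g, s in mapping.items() if not s]
            if empty:
                raise ConsistencyError(f"{name} entries with empty miRNA sets: {empty[:10]}")
        universe = frozenset(normalize_mirna(m) for m in self.mirna_universe)
        used = frozenset().union(*lnc.values(), *mrna.values(), frozenset())
        stray = used - universe
        if stray:
            raise ConsistencyError(f"miRNAs outside the declared universe: {sorted(stray)[:10]}")
        object.__setattr__(self, "lnc_to_mir", lnc)
        object.__setattr__(self, "mrna_to_mir", mrna)
        object.__setattr__(self, "mirna_universe", universe)

    @classmethod
    def from_maps(
        cls,
        lnc_to_mir: Mapping[str, Iterable[str]],
        mrna_to_mir: Mapping[str, Iterable[str]],
        mirna_universe: Iterable[str] | None = None,
    ) -> "InteractionCatalog":
        """Build a catalog; the universe defaults to the union of all sets."""
        lnc = {g: frozenset(s) for g, s in lnc_to_mir.items()}
        mrna = {g: frozenset(s) for g, s in mrna_to_mir.items()}
        if mirna_universe is None:
            universe: frozenset[str] = frozenset().union(
                *lnc.values(), *mrna.values(), frozenset()
            )
        else:
            universe = frozenset(mirna_universe)
        return cls(lnc, mrna, universe)

    @property
    def universe_size(self) -> int:
        return len(self.mirna_universe)

    def gene_class(self, gene: str) -> str:
        if gene in self.lnc_to_mir:
            return LNCRNA
        if gene in self.mrna_to_mir:
            return MRNA
        raise KeyError(gene)

    def classes(self) -> dict[str, str]:
        out = {g: LNCRNA for g in self.lnc_to_mir}
        out.update({g: MRNA for g in self.mrna_to_mir})
        return out


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with a two-group sample annotation.

    ``values`` is a pandas DataFrame indexed by gene id with sample-id
    columns; ``group`` maps every sample id to ``"normal"`` or ``"tumor"``.
    Rows that are constant within either group (undefined within-group
    correlation) are dropped at construction with a logged warning.
    """

    values: pd.DataFrame
    group: pd.Series
    gene_class: Mapping[str, str] | None = None
    _group_cols: dict[str, list[str]] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.group = pd.Series(self.group, dtype=object)
        unknown = set(self.group.unique()) - set(GROUPS)
        if unknown:
            raise DataFormatError(f"unknown sample group labels: {sorted(unknown)}")
        missing = [s for s in self.values.columns if s not in self.group.index]
        if missing:
            raise DataFormatError(f"samples missing from the group file: {missing[:10]}")
        self.group = self.group.loc[list(self.values.columns)]
        if not np.issubdtype(np.asarray(self.values.dtypes).dtype, np.object_):
            pass
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise DataFormatError(f"non-numeric expression values: {exc}") from exc
        if self.values.isna().any().any():
            r, c = np.argwhere(self.values.isna().to_numpy())[0]
            raise DataFormatError(
                f"missing value at gene {self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        for g in GROUPS:
            cols = [s for s in self.values.columns if self.group[s] == g]
            if len(cols) < 3:
                raise DataFormatError(
                    f"group {g!r} has {len(cols)} samples; at least 3 are required"
                )
            self._group_cols[g] = cols
        # drop rows constant within either group
        keep = np.ones(len(self.values), dtype=bool)
        for g in GROUPS:
            sub = self.values[self._group_cols[g]].to_numpy()
            keep &= sub.std(axis=1) > 0.0
        if not keep.all():
            dropped = list(self.values.index[~keep])
            log.warning(
                "dropping %d gene(s) constant within a sample group: %s",
                len(dropped), dropped[:10],
            )
            self.values = self.values.loc[keep]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples(self, group: str | None = None) -> list[str]:
        if group is None:
            return self.sample_ids
        if group not in GROUPS:
            raise UsageError(f"unknown group {group!r}")
        return list(self._group_cols[group])

    def vector(self, gene: str, group: str | None = None) -> np.ndarray:
        """Expression vector of one gene, optionally restricted to a group."""
        if gene not in self.values.index:
            raise KeyError(gene)
        return self.values.loc[gene, self.samples(group)].to_numpy(dtype=float)

    def with_classes(self, catalog: InteractionCatalog) -> "ExpressionMatrix":
        """Return a copy annotated with lncRNA/mRNA classes from a catalog."""
        classes = catalog.classes()
        known = {g: classes[g] for g in self.gene_ids if g in classes}
        return ExpressionMatrix(self.values.copy(), self.group.copy(), known)
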