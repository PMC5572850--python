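"""Readers and writers for all external formats.

Formats handled:

* miRNA–target interaction tables — TSV with ``miRNA`` and ``target``
  columns (extra columns ignored), one table per target class.
* expression matrix — TSV, first column gene id, remaining columns sample
  ids; sample groups in a two-column ``sample``/``group`` TSV.
* competing-pair and weighted-edge tables — TSV at full float precision.
* network exports — SIF and GraphML for downstream visualization (e.g.
  Cytoscape), plus a lossless edge-TSV round-trip format.
* gene-set collections — GMT.

All writers emit rows in a deterministic sorted order so repeated runs
produce byte-identical files.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .containers import LNCRNA, MRNA, ExpressionMatrix, InteractionCatalog, normalize_mirna
from .coexpr import WeightedEdge
from .detect import CompetingPairResult
from .enrich import EnrichmentResult, GeneSet
from .errors import DataFormatError, UsageError
from .netanalysis import CeRNANetwork, build_network

log = logging.getLogger(__name__)

TARGET_CLASSES = (LNCRNA, MRNA)
NETWORK_FORMATS = ("sif", "graphml", "edge-tsv")

PAIR_COLUMNS = ["lnc", "partner", "partner_class", "M", "N", "Y", "K", "p", "q"]
EDGE_COLUMNS = PAIR_COLUMNS + ["pcc_pooled", "pcc_tumor", "pcc_normal", "weight", "mode"]


# ---------------------------------------------------------------- interactions

def read_interactions(path: str | Path, target_class: str) -> dict[str, frozenset[str]]:
    """Parse one interaction table into a target → miRNA-set map.

    Rows are deduplicated and row order is irrelevant.  miRNA ids are
    trimmed and lower-cased; target ids are trimmed only.
    """
    if target_class not in TARGET_CLASSES:
        raise UsageError(f"target_class must be one of {TARGET_CLASSES}, got {target_class!r}")
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: empty interaction file") from None
    for col in ("miRNA", "target"):
        if col not in table.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    if len(table) == 0:
        raise DataFormatError(f"{path}: interaction file has no data rows")
    out: dict[str, set[str]] = {}
    for mirna, target in zip(table["miRNA"], table["target"]):
        if pd.isna(mirna) or pd.isna(target):
            raise DataFormatError(f"{path}: blank miRNA or target field")
        out.setdefault(str(target).strip(), set()).add(normalize_mirna(mirna))
    return {g: frozenset(s) for g, s in out.items()}


def load_catalog(lnc_path: str | Path, mrna_path: str | Path) -> InteractionCatalog:
    """Read the lncRNA–miRNA and mRNA–miRNA tables into one catalog.

    Class membership comes from which file a target appears in; an id
    present in both files is an error.
    """
    lnc = read_interactions(lnc_path, LNCRNA)
    mrna = read_interactions(mrna_path, MRNA)
    return InteractionCatalog.from_maps(lnc, mrna)


def write_interactions(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["miRNA", "target"])
        for target in sorted(mapping):
            for mirna in sorted(mapping[target]):
                w.writerow([mirna, target])


def write_catalog(
    catalog: InteractionCatalog, lnc_path: str | Path, mrna_path: str | Path
) -> None:
    write_interactions(catalog.lnc_to_mir, lnc_path)
    write_interactions(catalog.mrna_to_mir, mrna_path)


# ----------------------------------------------------------------- expression

def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix and its sample-group file.

    Every sample column in the matrix must appear in the groups file
    (offenders are listed in the error); extra samples in the groups file
    are ignored.  Non-numeric cells raise with their row and column.
    """
    matrix_path = Path(matrix_path)
    try:
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{matrix_path}: empty expression file") from None
    numeric = mat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~mat.isna()
    if bad.any().any():
        import numpy as np

        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"{matrix_path}: non-numeric value {mat.iat[r, c]!r} at "
            f"gene {mat.index[r]!r}, sample {mat.columns[c]!r}"
        )
    groups = read_groups(groups_path)
    missing = [s for s in mat.columns if s not in groups.index]
    if missing:
        raise DataFormatError(
            f"{matrix_path}: samples absent from group file: {missing[:10]}"
        )
    return ExpressionMatrix(numeric, groups.loc[list(mat.columns)])


def read_groups(groups_path: str | Path) -> pd.Series:
    groups_path = Path(groups_path)
    try:
        table = pd.read_csv(groups_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{groups_path}: empty group file") from None
    for col in ("sample", "group"):
        if col not in table.columns:
            raise DataFormatError(f"{groups_path}: missing required column {col!r}")
    if table["sample"].duplicated().any():
        dupes = sorted(table["sample"][table["sample"].duplicated()])
        raise DataFormatError(f"{groups_path}: duplicated samples: {dupes[:10]}")
    return pd.Series(table["group"].to_numpy(), index=table["sample"].to_numpy())


def write_expression(
    expr: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path
) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene", lineterminator="\n", float_format="%.17g")
    with open(groups_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "group"])
        for sample in expr.sample_ids:
            w.writerow([sample, expr.group[sample]])


# ------------------------------------------------------- pairs / edges / nets

def pairs_frame(pairs: Iterable[CompetingPairResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.lnc_id, p.partner_id, p.partner_class, p.M, p.N, p.Y, p.K, p.p_raw, p.q_fdr)
         for p in pairs],
        columns=PAIR_COLUMNS,
    )


def write_pairs(pairs: Iterable[CompetingPairResult], path: str | Path) -> None:
    frame = pairs_frame(pairs).sort_values(["q", "lnc", "partner"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.17g")


def read_pairs(path: str | Path) -> list[CompetingPairResult]:
    table = _read_table(path, PAIR_COLUMNS)
    return [
        CompetingPairResult(
            str(row.lnc), str(row.partner), str(row.partner_class),
            int(row.M), int(row.N), int(row.Y), int(row.K),
            float(row.p), float(row.q),
        )
        for row in table.itertuples(index=False)
    ]


def edges_frame(edges: Iterable[WeightedEdge]) -> pd.DataFrame:
    rows = []
    for e in edges:
        p = e.pair
        rows.append(
            (p.lnc_id, p.partner_id, p.partner_class, p.M, p.N, p.Y, p.K, p.p_raw, p.q_fdr,
             e.pcc_pooled, e.pcc_tumor, e.pcc_normal, e.weight, e.mode)
        )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def write_edges(edges: Iterable[WeightedEdge], path: str | Path) -> None:
    frame = edges_frame(edges).sort_values(["lnc", "partner"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.17g")


def read_edges(path: str | Path) -> list[WeightedEdge]:
    table = _read_table(path, EDGE_COLUMNS)
    edges = []
    for row in table.itertuples(index=False):
        pair = CompetingPairResult(
            str(row.lnc), str(row.partner), str(row.partner_class),
            int(row.M), int(row.N), int(row.Y), int(row.K),
            float(row.p), float(row.q),
        )
        edges.append(
            WeightedEdge(pair, float(row.pcc_pooled), float(row.pcc_tumor),
                         float(row.pcc_normal), float(row.weight), str(row.mode))
        )
    return edges


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: empty table") from None
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required columns {missing}")
    return table


def write_network(net: CeRNANetwork, path: str | Path, fmt: str = "edge-tsv") -> None:
    """Export a network as SIF, GraphML or the lossless edge-TSV.

    SIF lines are ``source cerna target`` sorted by (source, target).
    """
    if fmt not in NETWORK_FORMATS:
        raise UsageError(f"unknown network format {fmt!r}; expected one of {NETWORK_FORMATS}")
    if net.n_edges == 0:
        raise UsageError("refusing to export an empty network")
    g = net.graph
    if fmt == "sif":
        with open(path, "w", newline="") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in g.edges):
                fh.write(f"{u}\tcerna\t{v}\n")
        return
    if fmt == "graphml":
        out = nx.Graph()
        for n in sorted(g.nodes):
            out.add_node(n, node_class=g.nodes[n]["node_class"])
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            out.add_edge(u, v, **{k: _graphml_scalar(v2) for k, v2 in g.get_edge_data(u, v).items()})
        nx.write_graphml(out, path)
        return
    write_edges(network_edges(net), path)


def _graphml_scalar(value):
    return value if isinstance(value, (str, int, float, bool)) else str(value)


def network_edges(net: CeRNANetwork) -> list[WeightedEdge]:
    """Recover the WeightedEdge list from a network's edge attributes."""
    g = net.graph
    edges = []
    for u, v, d in g.edges(data=True):
        lnc, partner = (u, v)
        if g.nodes[u]["node_class"] != LNCRNA or (
            g.nodes[v]["node_class"] == LNCRNA and v < u
        ):
            lnc, partner = (v, u)
        pair = CompetingPairResult(
            lnc, partner, d["partner_class"], d["M"], d["N"], d["Y"], d["K"], d["p"], d["q"]
        )
        edges.append(
            WeightedEdge(pair, d["pcc_pooled"], d["pcc_tumor"], d["pcc_normal"],
                         d["weight"], d["mode"])
        )
    edges.sort(key=lambda e: (e.lnc_id, e.partner_id))
    return edges


def read_network(path: str | Path) -> CeRNANetwork:
    """Rebuild a network from an edge-TSV export."""
    return build_network(read_edges(path))


# ------------------------------------------------------------------------ GMT

def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT gene-set collection: name, description, then genes."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise DataFormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise DataFormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = GeneSet(name, desc, genes)
    if not sets:
        raise DataFormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for name in sorted(sets):
            gs = sets[name]
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def write_enrichment(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.term_id, r.term_name, r.k_overlap, r.set_size, r.query_size,
          r.background_size, r.p_raw, r.q_fdr) for r in results],
        columns=["term", "name", "k_overlap", "set_size", "query_size",
                 "background_size", "p", "q"],
    ).sort_values(["q", "p", "term"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.17g")
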