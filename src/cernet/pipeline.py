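"""One-shot pipeline driver: detect → weight → network → modules → enrich.

Every stage writes its product to a file another stage (or an external
tool) can consume, and a manifest records the configuration, its hash and
the row counts of every product.  Identical configuration and inputs yield
byte-identical products.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .bicliques import enumerate_maximal_bicliques, select_modules
from .coexpr import weight_edges
from .detect import detect_competing_pairs
from .enrich import enrich
from .errors import InsufficientDataError, UsageError
from .io import (
    load_catalog,
    read_expression,
    read_gmt,
    write_edges,
    write_enrichment,
    write_network,
    write_pairs,
)
from .netanalysis import (
    build_network,
    centralities,
    centrality_frame,
    compare_classes,
    fit_power_law,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run."""

    lnc_interactions: str = ""
    mrna_interactions: str = ""
    expression: str = ""
    groups: str = ""
    gmt: str | None = None
    fdr_cutoff: float = 0.01
    weight_cutoff: float = 0.8
    weight_mode: str = "group_difference"
    tail: str = "inclusive"
    min_shared: int = 1
    include_lnc_lnc: bool = False
    universe_size: int | None = None
    hub_threshold: int = 60
    min_lnc: int = 2
    min_partner: int = 2
    top_k: int = 2
    enrich_fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_cutoff <= 1.0):
            raise UsageError(f"fdr_cutoff must be in (0, 1], got {self.fdr_cutoff}")
        if self.weight_cutoff < 0.0:
            raise UsageError(f"weight_cutoff must be >= 0, got {self.weight_cutoff}")
        if not (0.0 < self.enrich_fdr <= 1.0):
            raise UsageError(f"enrich_fdr must be in (0, 1], got {self.enrich_fdr}")
        if self.hub_threshold < 0:
            raise UsageError(f"hub_threshold must be >= 0, got {self.hub_threshold}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def sha256(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and return the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    products: dict[str, int] = {}
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "products": products,
    }

    log.info("[detect] loading interaction catalog")
    catalog = load_catalog(config.lnc_interactions, config.mrna_interactions)
    pairs = detect_competing_pairs(
        catalog,
        fdr_cutoff=config.fdr_cutoff,
        include_lnc_lnc=config.include_lnc_lnc,
        min_shared=config.min_shared,
        tail=config.tail,
        universe_size=config.universe_size,
    )
    write_pairs(pairs, outdir / "pairs.tsv")
    products["pairs.tsv"] = len(pairs)
    log.info("[detect] %d FDR-passing pairs", len(pairs))

    log.info("[weight] loading expression matrix")
    expr = read_expression(config.expression, config.groups)
    edges = weight_edges(pairs, expr, mode=config.weight_mode, cutoff=config.weight_cutoff)
    write_edges(edges, outdir / "edges.tsv")
    products["edges.tsv"] = len(edges)
    log.info("[weight] %d edges above weight cutoff", len(edges))

    if not edges:
        log.warning("[network] no edges pass both filters; stopping after edges.tsv")
        _write_manifest(manifest, outdir)
        return manifest

    net = build_network(edges)
    write_network(net, outdir / "network.sif", "sif")
    write_network(net, outdir / "network.graphml", "graphml")
    products["network.sif"] = net.n_edges
    log.info("[network] %d nodes, %d edges", net.n_nodes, net.n_edges)

    records = centralities(net, hub_threshold=config.hub_threshold)
    centrality_frame(records).to_csv(
        outdir / "centralities.tsv", sep="\t", index=False, lineterminator="\n"
    )
    products["centralities.tsv"] = len(records)

    try:
        fit = fit_power_law(net)
        fit_payload = dataclasses.asdict(fit)
    except InsufficientDataError as exc:
        log.warning("[network] power-law fit skipped: %s", exc)
        fit_payload = {"skipped": str(exc)}
    (outdir / "powerlaw.json").write_text(
        json.dumps(fit_payload, sort_keys=True, indent=2) + "\n"
    )
    products["powerlaw.json"] = 1

    try:
        comparisons = {
            metric: dataclasses.asdict(compare_classes(records, metric))
            for metric in ("degree", "betweenness", "closeness")
        }
    except UsageError as exc:
        log.warning("[network] class comparison skipped: %s", exc)
        comparisons = {"skipped": str(exc)}
    (outdir / "class_comparison.json").write_text(
        json.dumps(comparisons, sort_keys=True, indent=2) + "\n"
    )
    products["class_comparison.json"] = 1

    log.info("[modules] enumerating maximal bicliques")
    modules = enumerate_maximal_bicliques(
        net, min_lnc=config.min_lnc, min_partner=config.min_partner
    )
    top = select_modules(modules, config.top_k) if modules else []
    rows = []
    for i, mod in enumerate(top, start=1):
        for gene in sorted(mod.lnc_side):
            rows.append((i, "lnc", gene))
        for gene in sorted(mod.partner_side):
            rows.append((i, "partner", gene))
    with open(outdir / "modules.tsv", "w", newline="") as fh:
        fh.write("module\tside\tgene\n")
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\n")
    (outdir / "modules.json").write_text(
        json.dumps(
            {
                "n_maximal_bicliques": len(modules),
                "n_selected": len(top),
                "selected": [
                    {
                        "lnc_side": sorted(m.lnc_side),
                        "partner_side": sorted(m.partner_side),
                        "n_genes": m.n_genes,
                    }
                    for m in top
                ],
            },
            sort_keys=True,
            indent=2,
        )
        + "\n"
    )
    products["modules.tsv"] = len(rows)
    products["modules.json"] = len(top)
    log.info("[modules] %d maximal bicliques, %d selected", len(modules), len(top))

    if config.gmt:
        log.info("[enrich] testing gene sets")
        gene_sets = read_gmt(config.gmt)
        background = sorted(g for g in expr.gene_ids if g in catalog.mrna_to_mir)
        query = sorted(net.mRNAs)
        query = [g for g in query if g in set(background)]
        results = enrich(query, gene_sets, background, fdr_cutoff=config.enrich_fdr)
        write_enrichment(results, outdir / "enrichment.tsv")
        products["enrichment.tsv"] = len(results)
        log.info("[enrich] %d significant terms", len(results))

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
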