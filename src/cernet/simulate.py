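"""Synthetic interaction catalogs and expression matrices with known truth.

The generator emulates the statistical structure the pipeline assumes:

* a miRNA universe shared by lncRNAs and mRNAs, with background miRNA sets
  drawn uniformly (so a null pair's shared-miRNA count is hypergeometric
  with expectation M·N/K) and planted pairs constructed to share an exact
  number of miRNAs;
* group-structured expression in which each planted pair follows a
  per-group latent-factor model x = √ρ·z + √(1−ρ)·ε, giving within-group
  Pearson correlation ρ (tumor and normal ρ set independently, so the
  group-difference weight is controllable), while unplanted genes are
  independent Gaussian noise;
* planted complete-bipartite modules whose members share a common miRNA
  core and load a common per-group factor, so every cross pair passes both
  the FDR and the weight filter and downstream biclique extraction has an
  exact target.

One integer seed drives everything; per-stage generators are derived from
it by fixed offsets, so identical scenarios are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .containers import LNCRNA, MRNA, NORMAL, TUMOR, ExpressionMatrix, InteractionCatalog
from .errors import ScenarioError

_SEED_MOD = 2**31
_CATALOG_OFFSET = 0
_EXPRESSION_OFFSET = 1
_MODULE_OFFSET = 2


class PlantedPair(NamedTuple):
    """A lncRNA–mRNA pair with controlled miRNA overlap and correlations."""

    lnc: str
    mrna: str
    shared: int
    rho_tumor: float
    rho_normal: float


class PlantedModule(NamedTuple):
    """A complete-bipartite module: lncRNA side × partner side."""

    lnc_side: tuple[str, ...]
    partner_side: tuple[str, ...]


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of one synthetic dataset.

    Defaults mirror the study design the pipeline targets: 20 samples per
    group, a few-hundred-miRNA universe, background miRNA-set sizes of
    5–15 (null overlap expectation M·N/K ≈ 0.2, well below one shared
    miRNA).  Module planting uses a shared core of 8 miRNAs and a strong
    tumor-group factor (ρ = 0.99 vs 0 in normal).
    """

    n_mirna: int = 500
    n_lnc: int = 20
    n_mrna: int = 100
    planted_pairs: tuple[PlantedPair, ...] = ()
    background_set_size: tuple[int, int] = (5, 15)
    planted_modules: tuple[PlantedModule, ...] = ()
    n_samples_per_group: int = 20
    noise_sd: float = 1.0
    seed: int = 0
    module_shared_mirnas: int = 8
    module_rho_tumor: float = 0.99
    module_rho_normal: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.background_set_size
        if not (1 <= lo <= hi <= self.n_mirna):
            raise ScenarioError(
                f"invalid background_set_size {self.background_set_size} for K={self.n_mirna}"
            )
        if self.n_lnc < 1 or self.n_mrna < 1 or self.n_mirna < 1:
            raise ScenarioError("n_mirna, n_lnc and n_mrna must all be positive")
        if self.noise_sd <= 0:
            raise ScenarioError(f"noise_sd must be positive, got {self.noise_sd}")
        pairs = tuple(PlantedPair(*p) for p in self.planted_pairs)
        object.__setattr__(self, "planted_pairs", pairs)
        modules = tuple(
            PlantedModule(tuple(m[0]), tuple(m[1])) for m in self.planted_modules
        )
        object.__setattr__(self, "planted_modules", modules)
        for p in pairs:
            for rho in (p.rho_tumor, p.rho_normal):
                if not abs(rho) < 1:
                    raise ScenarioError(f"|rho| must be < 1 for pair ({p.lnc}, {p.mrna})")
            if p.shared < 1:
                raise ScenarioError(f"pair ({p.lnc}, {p.mrna}): shared count must be >= 1")
            if p.shared > hi:
                raise ScenarioError(
                    f"pair ({p.lnc}, {p.mrna}): shared={p.shared} exceeds the "
                    f"maximum background set size {hi}"
                )
        seen: set[str] = set()
        for p in pairs:
            for g in (p.lnc, p.mrna):
                if g in seen:
                    raise ScenarioError(f"gene {g!r} appears in more than one planted pair")
                seen.add(g)
        module_genes: set[str] = set()
        for mod in modules:
            genes = set(mod.lnc_side) | set(mod.partner_side)
            if len(genes) != len(mod.lnc_side) + len(mod.partner_side):
                raise ScenarioError(f"module sides overlap: {mod}")
            clash = genes & (module_genes | seen)
            if clash:
                raise ScenarioError(
                    f"genes shared between planted structures: {sorted(clash)[:10]}"
                )
            module_genes |= genes
        if not (0 <= abs(self.module_rho_tumor) < 1 and 0 <= abs(self.module_rho_normal) < 1):
            raise ScenarioError("module correlations must satisfy |rho| < 1")

    # -- identifiers ---------------------------------------------------------
    def lnc_ids(self) -> list[str]:
        return [f"LNC{i:04d}" for i in range(1, self.n_lnc + 1)]

    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i:04d}" for i in range(1, self.n_mrna + 1)]

    def mirna_ids(self) -> list[str]:
        return [f"mir{i:04d}" for i in range(1, self.n_mirna + 1)]

    def stage_seed(self, offset: int) -> int:
        return (int(self.seed) + offset) % _SEED_MOD

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_mirna": self.n_mirna,
            "n_lnc": self.n_lnc,
            "n_mrna": self.n_mrna,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "background_set_size": list(self.background_set_size),
            "planted_modules": [[list(m.lnc_side), list(m.partner_side)]
                                for m in self.planted_modules],
            "n_samples_per_group": self.n_samples_per_group,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "module_shared_mirnas": self.module_shared_mirnas,
            "module_rho_tumor": self.module_rho_tumor,
            "module_rho_normal": self.module_rho_normal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        d = dict(d)
        if "background_set_size" in d:
            d["background_set_size"] = tuple(d["background_set_size"])
        if "planted_pairs" in d:
            d["planted_pairs"] = tuple(PlantedPair(*p) for p in d["planted_pairs"])
        if "planted_modules" in d:
            d["planted_modules"] = tuple(
                PlantedModule(tuple(m[0]), tuple(m[1])) for m in d["planted_modules"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------- catalog

def simulate_catalog(scn: SimulationScenario) -> InteractionCatalog:
    """Draw background miRNA sets and install planted exact overlaps."""
    rng = np.random.default_rng(scn.stage_seed(_CATALOG_OFFSET))
    mirnas = np.array(scn.mirna_ids())
    lo, hi = scn.background_set_size
    lnc_ids = scn.lnc_ids()
    mrna_ids = scn.mrna_ids()
    for p in scn.planted_pairs:
        if p.lnc not in lnc_ids or p.mrna not in mrna_ids:
            raise ScenarioError(f"planted pair ({p.lnc}, {p.mrna}) references unknown genes")

    def draw_set(size: int) -> frozenset[str]:
        return frozenset(rng.choice(mirnas, size=size, replace=False))

    lnc_map = {g: draw_set(int(rng.integers(lo, hi + 1))) for g in lnc_ids}
    mrna_map = {g: draw_set(int(rng.integers(lo, hi + 1))) for g in mrna_ids}

    for p in scn.planted_pairs:
        # set sizes stay within the background range but accommodate the core
        n_size = int(rng.integers(max(lo, p.shared), hi + 1))
        m_size = int(rng.integers(max(lo, p.shared), hi + 1))
        need = p.shared + (n_size - p.shared) + (m_size - p.shared)
        if need > scn.n_mirna:
            raise ScenarioError(
                f"pair ({p.lnc}, {p.mrna}): overlap {p.shared} with set sizes "
                f"({n_size}, {m_size}) needs {need} distinct miRNAs but K={scn.n_mirna}"
            )
        pool = rng.choice(mirnas, size=need, replace=False)
        core = frozenset(pool[: p.shared])
        lnc_map[p.lnc] = core | frozenset(pool[p.shared: n_size])
        mrna_map[p.mrna] = core | frozenset(pool[n_size: n_size + (m_size - p.shared)])
        assert len(lnc_map[p.lnc] & mrna_map[p.mrna]) == p.shared
    return InteractionCatalog(lnc_map, mrna_map, frozenset(mirnas))


# ------------------------------------------------------------- expression

def _latent_pair(rng: np.random.Generator, n: int, rho: float, sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Two length-n vectors with population correlation rho (sign honored)."""
    z = rng.normal(size=n)
    a = np.sqrt(abs(rho)) * z + np.sqrt(1 - abs(rho)) * rng.normal(size=n)
    b = np.sign(rho) * np.sqrt(abs(rho)) * z + np.sqrt(1 - abs(rho)) * rng.normal(size=n)
    if rho == 0:
        b = rng.normal(size=n)
    return sd * a, sd * b


def simulate_expression(
    scn: SimulationScenario, catalog: InteractionCatalog
) -> ExpressionMatrix:
    """Gaussian expression with planted per-group correlations.

    Samples are ``Normal_01..`` then ``Tumor_01..``; genes are the catalog's
    lncRNAs followed by its mRNAs, both sorted.
    """
    if scn.n_samples_per_group < 3:
        raise ScenarioError(
            f"n_samples_per_group must be >= 3, got {scn.n_samples_per_group}"
        )
    rng = np.random.default_rng(scn.stage_seed(_EXPRESSION_OFFSET))
    genes = sorted(catalog.lnc_to_mir) + sorted(catalog.mrna_to_mir)
    n = scn.n_samples_per_group
    samples = [f"Normal_{i:03d}" for i in range(1, n + 1)] + [
        f"Tumor_{i:03d}" for i in range(1, n + 1)
    ]
    values = rng.normal(0.0, scn.noise_sd, size=(len(genes), 2 * n))
    frame = pd.DataFrame(values, index=genes, columns=samples)
    group_slices = {NORMAL: slice(0, n), TUMOR: slice(n, 2 * n)}
    for p in scn.planted_pairs:
        for grp, rho in ((NORMAL, p.rho_normal), (TUMOR, p.rho_tumor)):
            a, b = _latent_pair(rng, n, rho, scn.noise_sd)
            frame.iloc[frame.index.get_loc(p.lnc), group_slices[grp]] = a
            frame.iloc[frame.index.get_loc(p.mrna), group_slices[grp]] = b
    group = pd.Series(
        [NORMAL] * n + [TUMOR] * n, index=samples, dtype=object
    )
    return ExpressionMatrix(frame, group, catalog.classes())


# ---------------------------------------------------------------- modules

def plant_modules(
    scn: SimulationScenario,
    catalog: InteractionCatalog,
    matrix: ExpressionMatrix,
) -> tuple[InteractionCatalog, ExpressionMatrix, pd.DataFrame]:
    """Install planted complete-bipartite modules into catalog and matrix.

    Every member of a module receives the module's miRNA core plus private
    background miRNAs (so each cross pair shares exactly the core), and all
    members load a common per-group latent factor at the module
    correlations.  Returns updated copies and a truth table of all planted
    edges (pairs and module cross edges).
    """
    rng = np.random.default_rng(scn.stage_seed(_MODULE_OFFSET))
    mirnas = np.array(scn.mirna_ids())
    lo, hi = scn.background_set_size
    core_size = scn.module_shared_mirnas
    if core_size > hi:
        raise ScenarioError(
            f"module_shared_mirnas={core_size} exceeds maximum set size {hi}"
        )
    lnc_map = dict(catalog.lnc_to_mir)
    mrna_map = dict(catalog.mrna_to_mir)
    frame = matrix.values.copy()
    n = scn.n_samples_per_group
    group_slices = {NORMAL: slice(0, n), TUMOR: slice(n, 2 * n)}

    truth_rows: list[tuple[str, str, str, str]] = []
    for p in scn.planted_pairs:
        truth_rows.append((p.lnc, p.mrna, MRNA, "pair"))

    for idx, mod in enumerate(scn.planted_modules, start=1):
        members = list(mod.lnc_side) + list(mod.partner_side)
        for g in members:
            if g not in lnc_map and g not in mrna_map:
                raise ScenarioError(f"module {idx}: unknown gene {g!r}")
        extras = [
            int(rng.integers(max(lo, core_size), hi + 1)) - core_size for _ in members
        ]
        need = core_size + sum(extras)
        if need > scn.n_mirna:
            raise ScenarioError(
                f"module {idx}: needs {need} distinct miRNAs but K={scn.n_mirna}"
            )
        pool = rng.choice(mirnas, size=need, replace=False)
        core = frozenset(pool[:core_size])
        cursor = core_size
        for g, extra in zip(members, extras):
            private = frozenset(pool[cursor: cursor + extra])
            cursor += extra
            target = lnc_map if g in lnc_map else mrna_map
            target[g] = core | private
        for grp, rho in ((NORMAL, scn.module_rho_normal), (TUMOR, scn.module_rho_tumor)):
            if abs(rho) == 0:
                continue  # keep the independent background noise
            factor = rng.normal(size=n)
            for g in members:
                row = np.sqrt(abs(rho)) * factor + np.sqrt(1 - abs(rho)) * rng.normal(size=n)
                frame.iloc[frame.index.get_loc(g), group_slices[grp]] = scn.noise_sd * row
        for l in mod.lnc_side:
            for partner in mod.partner_side:
                cls = LNCRNA if partner in lnc_map else MRNA
                truth_rows.append((l, partner, cls, f"module{idx}"))

    new_catalog = InteractionCatalog(lnc_map, mrna_map, catalog.mirna_universe)
    new_matrix = ExpressionMatrix(frame, matrix.group.copy(), new_catalog.classes())
    truth = pd.DataFrame(truth_rows, columns=["lnc", "partner", "partner_class", "source"])
    return new_catalog, new_matrix, truth


def simulate_dataset(
    scn: SimulationScenario,
) -> tuple[InteractionCatalog, ExpressionMatrix, pd.DataFrame]:
    """Full generator: catalog, expression and the planted-edge truth table."""
    catalog = simulate_catalog(scn)
    matrix = simulate_expression(scn, catalog)
    return plant_modules(scn, catalog, matrix)


def default_module_scenario(seed: int = 0) -> SimulationScenario:
    """A strong-settings scenario with two disjoint planted modules
    (4 lncRNAs × 12 mRNAs and 5 lncRNAs × 11 mRNAs)."""
    scn = SimulationScenario(seed=seed)
    lncs = scn.lnc_ids()
    mrnas = scn.mrna_ids()
    return replace(
        scn,
        planted_modules=(
            PlantedModule(tuple(lncs[:4]), tuple(mrnas[:12])),
            PlantedModule(tuple(lncs[4:9]), tuple(mrnas[12:23])),
        ),
        n_samples_per_group=500,
    )
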