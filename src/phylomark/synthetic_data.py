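"""Synthetic study generator with planted ground truth.

Emulates the shape of a multi-tissue bulk RNA-Seq compendium (FPKM scale,
2-5 biological replicates per tissue) together with the evolutionary side
of the analysis: a time-calibrated focal lineage, a taxonomy tree around it,
and ortholog groups engineered so that each gene's LCA lands on a planted
lineage clade.  Planted gene classes:

* house-keeping (HK): FPKM >= 1 in every sample, high stable baseline;
* tissue-enriched (TE): FPKM >= 1 in at least one replicate of at most
  three tissues, < 1 elsewhere;
* background: expressed in none or in >= 4 tissues at intermediate levels;
* coexpression modules: groups of background-class genes sharing a latent
  per-tissue profile (broadcast to replicates, so replicates correlate)
  perturbed by log2-scale Gaussian noise.

Everything is driven by one seed; identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .phylostrata import Lineage, OrthologGroup, StageScheme, TaxonomyTree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "generate_lineage",
    "generate_taxonomy",
    "generate_truth",
    "generate_ortholog_groups",
    "generate_expression",
    "simulate",
]

_HK_LOG2_MEAN = 5.0   # log2 FPKM baseline of house-keeping genes
_TE_LOG2_MEAN = 3.0   # log2 FPKM in the expressed tissues of TE genes
_BG_LOG2_MEAN = 3.5   # log2 FPKM in the expressed tissues of background genes
_OFF_FPKM_MAX = 0.5   # off-tissue FPKM ~ Uniform[0, 0.5)


@dataclass
class SimulationConfig:
    """Study design for one synthetic run.

    Defaults mirror a down-scaled tissue compendium: 10 tissues with 3
    replicates each, 2,000 genes, five planted coexpression modules of 20
    genes, and log2-scale noise of 0.25.
    """

    n_tissues: int = 10
    replicates_per_tissue: list[int] = field(default_factory=lambda: [3] * 10)
    n_genes: int = 2000
    frac_hk: float = 0.2
    frac_te: float = 0.12
    n_modules: int = 5
    module_size: int = 20
    module_age_stage: list[int] = field(default_factory=lambda: [1, 2, 5, 7, 8])
    noise_sd: float = 0.25
    seed: int = 1
    n_clades: int = 31
    root_age: float = 4000.0
    species_per_clade: int = 2
    n_stages: int = 8

    def __post_init__(self) -> None:
        if len(self.replicates_per_tissue) != self.n_tissues:
            raise ValueError("replicates_per_tissue length must equal n_tissues")
        if any(r < 1 for r in self.replicates_per_tissue):
            raise ValueError("every tissue needs at least one replicate")
        if min(self.n_tissues, self.n_genes, self.module_size) < 1:
            raise ValueError("counts must be >= 1")
        if self.frac_hk < 0 or self.frac_te < 0 or self.frac_hk + self.frac_te > 1:
            raise ValueError("frac_hk + frac_te must lie in [0, 1]")
        if len(self.module_age_stage) != self.n_modules:
            raise ValueError("one planted stage per module required")
        if any(not 1 <= s <= self.n_stages for s in self.module_age_stage):
            raise ValueError(f"module stages must lie in 1..{self.n_stages}")
        if self.n_modules * self.module_size > self.n_genes * (1 - self.frac_hk - self.frac_te):
            raise ValueError("not enough background genes to host the planted modules")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted per-gene labels: class, lineage clade index, optional module."""

    table: pd.DataFrame  # index gene_id; columns: class_label, clade_index, module_id

    def __post_init__(self) -> None:
        need = {"class_label", "clade_index", "module_id"}
        if not need <= set(self.table.columns):
            raise ValueError(f"truth table lacks columns {need - set(self.table.columns)}")
        in_module = self.table["module_id"] >= 0
        if (self.table.loc[in_module, "module_id"] < 0).any():
            raise ValueError("planted module genes must carry a module id")

    def genes_of_class(self, label: str) -> set[str]:
        return set(self.table.index[self.table["class_label"] == label])

    def module_members(self, module_id: int) -> list[str]:
        return list(self.table.index[self.table["module_id"] == module_id])

    @property
    def n_modules(self) -> int:
        ids = self.table["module_id"]
        return int((ids[ids >= 0].nunique()))

    def clade_map(self) -> pd.Series:
        return self.table["clade_index"]

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent named substream per generation stage
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_lineage(n_clades: int, root_age: float, seed: int) -> Lineage:
    """Random time-calibrated lineage: ages strictly decrease from
    ``root_age`` at the root-most clade to 0 at the focal species."""
    if n_clades < 2:
        raise ValueError("a lineage needs at least 2 clades (root and focal)")
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    rng = _rng(seed, 0)
    # Dirichlet spacings keep ages strictly decreasing and deterministic
    spacings = rng.dirichlet(np.ones(n_clades - 1)) * root_age
    ages = np.concatenate([[root_age], root_age - np.cumsum(spacings)])
    ages[-1] = 0.0
    names = [f"clade_{i:02d}" for i in range(1, n_clades)] + ["focal_species"]
    node_ids = list(range(1, n_clades + 1))
    return Lineage(names=names, node_ids=node_ids, ages=[float(a) for a in ages])


def generate_taxonomy(lineage: Lineage, species_per_clade: int, seed: int) -> TaxonomyTree:
    """Embed the lineage in a taxonomy: each non-focal clade gets
    ``species_per_clade`` off-path leaf species; the focal species is the
    lineage's last node and is a leaf."""
    if species_per_clade < 1:
        raise ValueError("species_per_clade must be >= 1")
    parent: dict[int, int | None] = {lineage.node_ids[0]: None}
    names: dict[int, str] = {lineage.node_ids[0]: lineage.names[0]}
    for prev, cur, name in zip(lineage.node_ids, lineage.node_ids[1:], lineage.names[1:]):
        parent[cur] = prev
        names[cur] = name
    next_id = max(lineage.node_ids) + 1
    for i, clade in enumerate(lineage.node_ids[:-1], start=1):
        for j in range(1, species_per_clade + 1):
            parent[next_id] = clade
            names[next_id] = f"sp_c{i:02d}_{j}"
            next_id += 1
    return TaxonomyTree(parent, names)


def species_by_clade(lineage: Lineage, tree: TaxonomyTree) -> dict[int, list[int]]:
    """Off-path leaf species attached at each 1-based lineage clade index."""
    on_path = set(lineage.node_ids)
    out: dict[int, list[int]] = {}
    for idx, clade in enumerate(lineage.node_ids, start=1):
        out[idx] = sorted(
            c for c in tree.children(clade) if c not in on_path and tree.is_leaf(c)
        )
    return out


def generate_truth(config: SimulationConfig, scheme: StageScheme, seed: int | None = None) -> GroundTruth:
    """Assign planted classes, lineage clades and module membership.

    HK genes are biased toward early stages and TE genes toward late stages
    (so the synthetic cumulative-emergence curves separate the way real HK/TE
    profiles do); background genes draw stages uniformly; module genes draw
    their clade inside the module's planted stage.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 1)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(1, n + 1)]
    n_hk = int(round(config.frac_hk * n))
    n_te = int(round(config.frac_te * n))
    labels = np.array(["HK"] * n_hk + ["TE"] * n_te + ["background"] * (n - n_hk - n_te))

    n_stages = scheme.n_stages
    early = np.arange(n_stages, 0, -1, dtype=float) ** 2
    late = np.arange(1, n_stages + 1, dtype=float) ** 2
    flat = np.ones(n_stages)

    def draw_stage(count: int, weights: np.ndarray) -> np.ndarray:
        p = weights / weights.sum()
        return rng.choice(np.arange(1, n_stages + 1), size=count, p=p)

    stages = np.empty(n, dtype=int)
    stages[labels == "HK"] = draw_stage(n_hk, early)
    stages[labels == "TE"] = draw_stage(n_te, late)
    stages[labels == "background"] = draw_stage(n - n_hk - n_te, flat)

    module_id = np.full(n, -1, dtype=int)
    bg_idx = np.flatnonzero(labels == "background")
    chosen = rng.choice(bg_idx, size=config.n_modules * config.module_size, replace=False)
    for m in range(config.n_modules):
        members = chosen[m * config.module_size:(m + 1) * config.module_size]
        module_id[members] = m
        stages[members] = config.module_age_stage[m]

    clade = np.empty(n, dtype=int)
    stage_labels = scheme.stage_order
    for s in range(1, n_stages + 1):
        mask = stages == s
        clades = scheme.clades_of(stage_labels[s - 1])
        clade[mask] = rng.choice(clades, size=int(mask.sum()))

    table = pd.DataFrame(
        {"class_label": labels, "clade_index": clade, "module_id": module_id},
        index=pd.Index(genes, name="gene_id"),
    )
    return GroundTruth(table)


def generate_ortholog_groups(
    taxonomy: TaxonomyTree,
    truth: GroundTruth,
    lineage: Lineage,
    seed: int,
) -> list[OrthologGroup]:
    """Plant each gene's ortholog group so its LCA is the planted clade.

    The group holds the focal species, at least one species attached at the
    planted clade (fixing the LCA there), and a random sprinkle of species
    attached strictly below it (which cannot raise the LCA).  A gene planted
    at the focal clade gets the degenerate group {focal species}.
    """
    rng = _rng(seed, 2)
    pool = species_by_clade(lineage, taxonomy)
    focal = lineage.focal_node
    n_clades = len(lineage)
    groups: list[OrthologGroup] = []
    for gene, k in truth.clade_map().items():
        k = int(k)
        if k == n_clades:
            members = {focal}
        else:
            if not pool.get(k):
                raise ValueError(f"no off-path species attached at clade {k}: cannot plant")
            members = {focal, int(rng.choice(pool[k]))}
            # extra members strictly below the planted clade keep the LCA fixed
            for below in range(k + 1, n_clades):
                for sp in pool.get(below, []):
                    if rng.random() < 0.25:
                        members.add(sp)
        groups.append(OrthologGroup(f"OG{len(groups) + 1:05d}", str(gene), frozenset(members)))
    return groups


def _sample_layout(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in range(config.n_tissues):
        tissue = f"tissue{t + 1:02d}"
        for r in range(config.replicates_per_tissue[t]):
            rows.append({"sample_id": f"{tissue}_r{r + 1}", "tissue": tissue, "replicate": r + 1})
    return pd.DataFrame(rows)


def generate_expression(config: SimulationConfig, truth: GroundTruth,
                        seed: int | None = None) -> ExpressionMatrix:
    """Draw the FPKM matrix realizing the planted classes and modules.

    Values are generated in log2 space (log-normal FPKM) and mapped back via
    FPKM = 2^x - 1; hard guarantees (HK >= 1 everywhere, TE >= 1 in its
    expressed tissues, off-tissue < 1) are enforced by construction.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 3)
    design = _sample_layout(config)
    tissues = list(pd.unique(design["tissue"]))
    tissue_of_col = design["tissue"].to_numpy()
    n_samples = len(design)
    n = config.n_genes
    genes = list(truth.table.index)
    values = np.zeros((n, n_samples))

    labels = truth.table["class_label"].to_numpy()
    module_id = truth.table["module_id"].to_numpy()

    # latent per-tissue profiles, one per module, broadcast to replicates.
    # A permuted evenly spaced ladder fixes the cross-tissue variance, which
    # guarantees the module contract (pairwise Spearman > threshold in
    # expectation) for every module rather than only on average draws.
    ladder = np.linspace(1.0, 7.0, len(tissues))
    module_profiles = np.stack(
        [rng.permutation(ladder) for _ in range(max(config.n_modules, 1))]
    )
    tissue_index = {t: i for i, t in enumerate(tissues)}
    col_tissue_idx = np.array([tissue_index[t] for t in tissue_of_col])

    for i in range(n):
        noise = rng.normal(0.0, config.noise_sd, size=n_samples)
        if module_id[i] >= 0:
            x = module_profiles[module_id[i], col_tissue_idx] + noise
            values[i] = np.maximum(np.exp2(x) - 1.0, 0.0)
            continue
        if labels[i] == "HK":
            base = rng.normal(_HK_LOG2_MEAN, 1.0)
            values[i] = np.maximum(np.exp2(base + noise) - 1.0, 1.0)
            continue
        off = rng.uniform(0.0, _OFF_FPKM_MAX, size=n_samples)
        if labels[i] == "TE":
            n_expr = rng.integers(1, 4)
            expr_tissues = rng.choice(len(tissues), size=n_expr, replace=False)
            base = rng.normal(_TE_LOG2_MEAN, 1.0)
            on = np.isin(col_tissue_idx, expr_tissues)
            values[i] = np.where(on, np.maximum(np.exp2(base + noise) - 1.0, 1.0), off)
        else:  # background: silent, or expressed in >= 4 tissues
            lo = min(4, len(tissues))
            n_expr = int(rng.integers(lo, len(tissues) + 1))
            if rng.random() < 0.15:
                n_expr = 0
            if n_expr == 0:
                values[i] = off
            else:
                expr_tissues = rng.choice(len(tissues), size=n_expr, replace=False)
                per_tissue = rng.normal(_BG_LOG2_MEAN, 1.5, size=len(tissues))
                x = per_tissue[col_tissue_idx] + noise
                on = np.isin(col_tissue_idx, expr_tissues)
                values[i] = np.where(on, np.maximum(np.exp2(x) - 1.0, 1.0), off)

    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                      columns=design["sample_id"])
    return ExpressionMatrix(df, design, log_scale=False)


@dataclass
class SimulationResult:
    """All artefacts of one synthetic study."""

    config: SimulationConfig
    lineage: Lineage
    scheme: StageScheme
    taxonomy: TaxonomyTree
    truth: GroundTruth
    groups: list[OrthologGroup]
    matrix: ExpressionMatrix

    def hk_reference(self) -> set[str]:
        return self.truth.genes_of_class("HK")

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artefact as plain text; returns the path map."""
        from .phylostrata import write_ortholog_groups
        from .gene_classes import write_gene_list

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": out / "expression.tsv",
            "design": out / "design.tsv",
            "taxonomy": out / "taxonomy.tsv",
            "taxonomy_newick": out / "taxonomy.nwk",
            "lineage": out / "lineage.yaml",
            "groups": out / "ortholog_groups.tsv",
            "truth": out / "truth.tsv",
            "hk_reference": out / "hk_reference.txt",
            "config": out / "sim_config.yaml",
        }
        self.matrix.write(paths["matrix"], paths["design"])
        self.taxonomy.to_table(paths["taxonomy"])
        paths["taxonomy_newick"].write_text(self.taxonomy.to_newick() + "\n")
        self.lineage.to_yaml(paths["lineage"])
        write_ortholog_groups(self.groups, paths["groups"])
        self.truth.write(paths["truth"])
        write_gene_list(self.hk_reference(), paths["hk_reference"])
        self.config.to_yaml(paths["config"])
        return paths


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator off one seed."""
    lineage = generate_lineage(config.n_clades, config.root_age, config.seed)
    scheme = StageScheme.contiguous(config.n_clades, config.n_stages)
    taxonomy = generate_taxonomy(lineage, config.species_per_clade, config.seed)
    truth = generate_truth(config, scheme)
    groups = generate_ortholog_groups(taxonomy, truth, lineage, config.seed)
    matrix = generate_expression(config, truth)
    return SimulationResult(config, lineage, scheme, taxonomy, truth, groups, matrix)
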