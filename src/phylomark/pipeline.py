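"""End-to-end orchestration: simulate -> expression -> classes -> ages ->
coexpression -> enrichment, with a machine-readable summary and manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import (
    ExpressionMatrix,
    cluster_samples,
    detect_expressed,
    filter_expressed_genes,
    log_transform,
    sample_distance,
)
from .gene_classes import (
    classify_housekeeping,
    classify_tissue_enriched,
    compare_class_expression,
    overlap_odds_ratio,
    read_gene_list,
)
from .phylostrata import (
    Lineage,
    StageScheme,
    TaxonomyTree,
    assign_gene_ages,
    read_ortholog_groups,
    stage_profile,
    time_axis,
)
from .coexpression import (
    age_homogeneity_test,
    build_network,
    candidate_edges,
    filter_min_group,
    mcode_modules,
    module_age_composition,
    resample_validate,
    validated_edges,
    write_edges,
    write_graphml,
)
from .enrichment import AnnotationMap, hypergeom_enrich
from .synthetic_data import SimulationConfig, simulate

log = logging.getLogger("phylomark")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (usually loaded from YAML).

    Either ``simulate`` holds a synthetic-study configuration, or the input
    paths (matrix/design/taxonomy/lineage/groups/hk_reference) point at
    existing files.  All randomness flows from ``seed``.
    """

    outdir: str = "phylomark_run"
    seed: int = 1
    fpkm_threshold: float = 1.0
    r_min: float = 0.85
    n_iter: int = 100
    reps_per_tissue: int = 2
    max_te_tissues: int = 3
    min_group: int = 5
    linkage: str = "complete"
    filter_rule: str = "any_tissue"
    n_stages: int = 8
    stage_scheme: str = "contiguous"  # or "human"
    simulate: dict | None = None
    matrix: str | None = None
    design: str | None = None
    taxonomy: str | None = None
    lineage: str | None = None
    groups: str | None = None
    hk_reference: str | None = None
    annotations: str | None = None  # optional TSV; default: stage-derived terms
    _raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= 1:
            raise ValueError("r_min must lie in (0, 1]")
        if self.n_iter < 1 or self.min_group < 1 or self.max_te_tissues < 1:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        cfg._raw = doc
        return cfg


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"pipeline input missing from config: {what}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write per-stage outputs under ``config.outdir``,
    and return (and write) the summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    t_start = time.time()

    # -- stage 0: inputs (synthetic or on disk) ---------------------------
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**{**config.simulate, "seed": config.seed})
        sim = simulate(sim_cfg)
        paths = sim.write(out / "sim")
        matrix, lineage, taxonomy = sim.matrix, sim.lineage, sim.taxonomy
        groups, hk_ref = sim.groups, sim.hk_reference()
        scheme = sim.scheme
        summary["simulated"] = True
        log.info("simulated %d genes x %d samples", sim_cfg.n_genes, len(matrix.sample_ids))
    else:
        matrix = ExpressionMatrix.read(
            _require(config.matrix, "expression matrix"),
            _require(config.design, "design table"),
        )
        taxonomy = TaxonomyTree.from_table(_require(config.taxonomy, "taxonomy table"))
        lineage = Lineage.from_yaml(_require(config.lineage, "lineage calibration"))
        groups = read_ortholog_groups(_require(config.groups, "ortholog groups"))
        hk_ref = read_gene_list(_require(config.hk_reference, "HK reference list"))
        if config.stage_scheme == "human":
            scheme = StageScheme.human(lineage)
        else:
            scheme = StageScheme.contiguous(len(lineage), config.n_stages)
        summary["simulated"] = False

    # -- stage 1: expression ----------------------------------------------
    t0 = time.time()
    filtered = filter_expressed_genes(matrix, config.fpkm_threshold, config.filter_rule)
    calls = detect_expressed(filtered, config.fpkm_threshold)
    logm = log_transform(filtered)
    dist = sample_distance(logm)
    dend = cluster_samples(dist, config.linkage)
    calls.write(out / "expression_calls.tsv")
    dist.to_csv(out / "sample_distances.tsv", sep="\t")
    (out / "sample_dendrogram.nwk").write_text(dend.to_newick() + "\n")
    summary["n_genes_input"] = len(matrix.gene_ids)
    summary["n_genes_expressed"] = len(filtered.gene_ids)
    summary["n_samples"] = len(matrix.sample_ids)
    summary["n_tissues"] = len(matrix.tissues)
    log.info("expression stage done in %.1fs", time.time() - t0)

    # -- stage 2: gene classes --------------------------------------------
    t0 = time.time()
    hk = classify_housekeeping(calls, hk_ref)
    te = classify_tissue_enriched(calls, config.max_te_tissues)
    universe = set(filtered.gene_ids)
    overlap = overlap_odds_ratio(universe, calls.expressed_in_all_samples(), hk_ref & universe)
    contrast = compare_class_expression(logm, hk, te) if hk and te else None
    cls_table = pd.DataFrame(
        {"gene_id": sorted(universe)}
    )
    cls_table["class_label"] = [
        "HK" if g in hk else ("TE" if g in te else "background") for g in cls_table["gene_id"]
    ]
    cls_table.to_csv(out / "gene_classes.tsv", sep="\t", index=False)
    overlap.write(out / "hk_overlap.json")
    summary["n_hk"] = len(hk)
    summary["n_te"] = len(te)
    summary["n_expressed_in_all_samples"] = len(calls.expressed_in_all_samples())
    summary["hk_overlap_or"] = overlap.odds_ratio
    if contrast is not None:
        summary["hk_te_mean_log2_diff"] = contrast.mean_diff
    log.info("gene-class stage done in %.1fs", time.time() - t0)

    # -- stage 3: gene ages -----------------------------------------------
    t0 = time.time()
    assignment = assign_gene_ages(groups, taxonomy, lineage, scheme)
    mapped = assignment.loc[assignment.index.intersection(filtered.gene_ids)]
    profiles = {"all": stage_profile(mapped, scheme, label="all")}
    for name, genes in (("HK", hk), ("TE", te)):
        sub = set(genes) & set(mapped.index)
        if sub:
            profiles[name] = stage_profile(mapped, scheme, subset=sub, label=name)
    assignment_out = assignment.copy()
    assignment_out.index.name = "gene_id"
    assignment_out.to_csv(out / "gene_ages.tsv", sep="\t")
    for name, prof in profiles.items():
        prof.to_frame().to_csv(out / f"stage_profile_{name}.tsv", sep="\t")
    time_axis(lineage, profiles["all"]).to_csv(out / "time_axis_all.tsv", sep="\t", index=False)
    summary["n_genes_dated"] = int(len(mapped))
    summary["n_unmapped"] = int(len(universe) - len(mapped))
    summary["stage_counts"] = {k: v.stage_counts.to_dict() for k, v in profiles.items()}
    log.info("age stage done in %.1fs", time.time() - t0)

    # -- stage 4: coexpression network ------------------------------------
    t0 = time.time()
    cand = candidate_edges(logm, config.r_min)
    validated = resample_validate(
        logm, cand, n_iter=config.n_iter, reps_per_tissue=config.reps_per_tissue,
        r_min=config.r_min, seed=config.seed, on_small="use_all",
    )
    edges = validated_edges(validated, config.n_iter)
    network = build_network(edges)
    core_net = filter_min_group(network, config.min_group)
    modules = mcode_modules(core_net)
    write_edges(validated, out / "candidate_edges.tsv")
    write_edges(edges, out / "validated_edges.tsv")
    write_graphml(core_net, out / "network.graphml")
    mod_rows = []
    for i, mod in enumerate(modules):
        comp = module_age_composition(mod, mapped, scheme.stage_order) \
            if set(map(str, mod.nodes)) & set(mapped.index) else None
        for node in mod.nodes:
            mod_rows.append({"module": i, "gene_id": node, "score": mod.score,
                             "dominant_stage": comp.dominant_stage if comp else ""})
    pd.DataFrame(mod_rows, columns=["module", "gene_id", "score", "dominant_stage"]).to_csv(
        out / "modules.tsv", sep="\t", index=False
    )
    if modules and len(mapped):
        homog = age_homogeneity_test(modules, mapped, n_perm=500, seed=config.seed)
        homog.to_csv(out / "module_age_homogeneity.tsv", sep="\t", index=False)
    summary["n_candidate_edges"] = int(len(cand))
    summary["n_validated_edges"] = int(len(edges))
    summary["network_nodes"] = int(core_net.number_of_nodes())
    summary["network_edges"] = int(core_net.number_of_edges())
    summary["n_modules"] = len(modules)
    log.info("coexpression stage done in %.1fs", time.time() - t0)

    # -- stage 5: enrichment ----------------------------------------------
    t0 = time.time()
    if config.annotations is not None:
        ann = AnnotationMap.from_tsv(_require(config.annotations, "annotations"))
    else:
        # stage-derived terms: a self-contained annotation built from the ages
        ann = AnnotationMap(
            {f"stage:{s}": set(mapped.index[mapped["stage"] == s]) for s in scheme.stage_order},
            {f"stage:{s}": f"genes dated to {s}" for s in scheme.stage_order},
        )
    enr_frames = []
    uni = set(mapped.index)
    for i, mod in enumerate(modules):
        query = {str(v) for v in mod.nodes} & uni
        if not query:
            continue
        res = hypergeom_enrich(query, uni, ann)
        res.insert(0, "module", i)
        enr_frames.append(res)
    if enr_frames:
        pd.concat(enr_frames, ignore_index=True).to_csv(
            out / "module_enrichment.tsv", sep="\t", index=False
        )
    log.info("enrichment stage done in %.1fs", time.time() - t0)

    # -- summary + manifest -----------------------------------------------
    summary["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    raw = yaml.safe_dump(config._raw or config.__dict__, sort_keys=True, default_flow_style=True)
    manifest = {
        "config_sha256": hashlib.sha256(raw.encode()).hexdigest(),
        "seed": config.seed,
        "phylomark_version": __version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
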