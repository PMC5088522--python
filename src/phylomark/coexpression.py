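"""Resampling-validated Spearman coexpression networks and dense modules.

Pipeline: (1) candidate gene pairs with all-sample Spearman r above a hard
threshold (default 0.85); (2) cross-validation by repeatedly recomputing r
on random subsamples of two replicates per tissue, keeping only pairs that
pass the threshold in every one of the (default 100) repetitions; (3) graph
construction, small-component filtering; (4) dense-module detection with
the MCODE algorithm (vertex weight = highest-k-core number of the closed
neighborhood times the density of that core; seeded expansion; 2-core
filter; haircut); (5) per-module evolutionary-age composition and a
permutation test of age homogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix
from .enrichment import bh_adjust

__all__ = [
    "Module",
    "candidate_edges",
    "resample_validate",
    "validated_edges",
    "build_network",
    "filter_min_group",
    "mcode_modules",
    "module_age_composition",
    "age_homogeneity_test",
    "write_edges",
    "read_edges",
    "write_graphml",
]

EDGE_COLUMNS = ["gene_a", "gene_b", "r", "n_validated"]


def _spearman_candidates(arr: np.ndarray, r_min: float, block: int = 512):
    """Upper-triangle scan of the gene-gene Spearman matrix in row blocks
    (memory stays O(block * n) instead of O(n^2))."""
    n = arr.shape[0]
    ranks = np.apply_along_axis(rankdata, 1, arr)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    ranks = ranks / norms[:, None]
    hits_i, hits_j, hits_r = [], [], []
    for start in range(0, n, block):
        stop = min(start + block, n)
        corr = ranks[start:stop] @ ranks.T  # (block, n)
        for row in range(start, stop):
            cols = np.flatnonzero(corr[row - start, row + 1:] >= r_min) + row + 1
            if cols.size:
                hits_i.extend([row] * cols.size)
                hits_j.extend(cols.tolist())
                hits_r.extend(corr[row - start, cols].tolist())
    return np.array(hits_i, dtype=int), np.array(hits_j, dtype=int), np.array(hits_r)


def candidate_edges(matrix: ExpressionMatrix, r_min: float = 0.85) -> pd.DataFrame:
    """All unordered gene pairs with full-sample Spearman r >= ``r_min``.

    Genes with zero variance across samples have undefined rank correlation;
    they are excluded and reported via a warning and ``df.attrs["n_zero_variance"]``.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    arr = matrix.values.to_numpy(dtype=float)
    var = arr.var(axis=1)
    keep = var > 0
    n_zero = int((~keep).sum())
    if n_zero:
        warnings.warn(f"excluded {n_zero} zero-variance genes from the correlation scan")
    genes = np.array(matrix.gene_ids)[keep]
    i, j, r = _spearman_candidates(arr[keep], r_min)
    df = pd.DataFrame(
        {"gene_a": genes[i], "gene_b": genes[j], "r": r, "n_validated": 0}
    )
    df.attrs["n_zero_variance"] = n_zero
    return df


def _draw_subsample(design: pd.DataFrame, reps_per_tissue: int,
                    rng: np.random.Generator, on_small: str) -> list[str]:
    cols: list[str] = []
    for tissue, grp in design.groupby("tissue", sort=True):
        ids = list(grp["sample_id"])
        if len(ids) < reps_per_tissue:
            if on_small == "use_all":
                cols.extend(ids)
                continue
            raise ValueError(
                f"tissue {tissue!r} has {len(ids)} replicates < {reps_per_tissue}; "
                "pass on_small='use_all' to keep them all"
            )
        if len(ids) == reps_per_tissue:
            cols.extend(ids)  # sampling k of k is deterministic
        else:
            picked = rng.choice(len(ids), size=reps_per_tissue, replace=False)
            cols.extend(ids[p] for p in sorted(picked))
    return cols


def resample_validate(
    matrix: ExpressionMatrix,
    candidates: pd.DataFrame,
    n_iter: int = 100,
    reps_per_tissue: int = 2,
    r_min: float = 0.85,
    seed: int = 0,
    on_small: str = "error",
) -> pd.DataFrame:
    """Count, per candidate pair, the subsample iterations with r >= ``r_min``.

    Each iteration draws ``reps_per_tissue`` random replicates from every
    tissue (tissues with exactly that many contribute all of them) and
    recomputes Spearman r for the candidate pairs only.  Deterministic given
    the seed; iteration i draws all tissues before iteration i+1.
    """
    rng = np.random.default_rng(seed)
    cand = candidates.reset_index(drop=True).copy()
    involved = sorted(set(cand["gene_a"]) | set(cand["gene_b"]))
    pos = {g: k for k, g in enumerate(involved)}
    ia = cand["gene_a"].map(pos).to_numpy()
    ib = cand["gene_b"].map(pos).to_numpy()
    sub_values = matrix.values.loc[involved]
    n_validated = np.zeros(len(cand), dtype=int)
    for _ in range(n_iter):
        cols = _draw_subsample(matrix.design, reps_per_tissue, rng, on_small)
        arr = sub_values[cols].to_numpy(dtype=float)
        ranks = np.apply_along_axis(rankdata, 1, arr)
        ranks = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(ranks, axis=1)
        norms[norms == 0] = np.inf  # degenerate gene in this subsample: r := 0
        ranks = ranks / norms[:, None]
        r = np.einsum("ij,ij->i", ranks[ia], ranks[ib])
        n_validated += r >= r_min
    cand["n_validated"] = n_validated
    cand.attrs["n_iter"] = n_iter
    return cand


def validated_edges(candidates: pd.DataFrame, n_iter: int | None = None) -> pd.DataFrame:
    """Pairs validated in every iteration (the final edge selection)."""
    n_iter = n_iter if n_iter is not None else candidates.attrs.get("n_iter", int(candidates["n_validated"].max()))
    return candidates[candidates["n_validated"] >= n_iter].reset_index(drop=True)


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Simple undirected graph over all edge endpoints."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, r=float(row.r),
                   n_validated=int(row.n_validated))
    return g


def filter_min_group(network: nx.Graph, min_size: int = 5) -> nx.Graph:
    """Keep connected components with at least ``min_size`` nodes."""
    keep: set = set()
    for comp in nx.connected_components(network):
        if len(comp) >= min_size:
            keep |= comp
    return network.subgraph(keep).copy()


@dataclass
class Module:
    """A densely connected region: members, its seed, and density x size score."""

    nodes: list
    seed: object
    density: float
    score: float

    def __len__(self) -> int:
        return len(self.nodes)


def _vertex_weights(g: nx.Graph) -> dict:
    """MCODE vertex weighting: highest-k-core number of the closed
    neighborhood times the density of that core."""
    w = {}
    for v in g.nodes:
        nbhd = g.subgraph(set(g[v]) | {v})
        core_nums = nx.core_number(nbhd)
        k = max(core_nums.values())
        core = nbhd.subgraph([u for u, c in core_nums.items() if c >= k])
        w[v] = k * nx.density(core) if core.number_of_nodes() > 1 else 0.0
    return w


def mcode_modules(
    network: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
) -> list[Module]:
    """MCODE dense-module detection with the published defaults.

    Vertices below ``degree_cutoff`` get weight 0.  Modules grow outward from
    the highest-weight unvisited seed, admitting unvisited neighbors whose
    weight is >= (1 - node_score_cutoff) * seed weight, to at most
    ``max_depth`` hops.  Modules without a ``k_core``-core are discarded;
    haircut iteratively strips singly-connected members.  Each node belongs
    to at most one module (fluff off); modules are ranked by density x size.
    """
    g = nx.Graph(network)
    g.remove_edges_from(nx.selfloop_edges(g))
    weights = _vertex_weights(g)
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
    visited: set = set()
    modules: list[Module] = []
    for seed in sorted(g.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [(seed, 0)]
        visited.add(seed)
        while frontier:
            v, depth = frontier.pop(0)
            if depth >= max_depth:
                continue
            for u in g[v]:
                if u in visited or u in members:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    visited.add(u)
                    frontier.append((u, depth + 1))
        sub = g.subgraph(members).copy()
        core = nx.k_core(sub, k_core)
        if core.number_of_nodes() == 0:
            continue
        if haircut:
            while True:
                ones = [v for v in sub.nodes if sub.degree(v) < 2]
                if not ones or sub.number_of_nodes() - len(ones) < 2:
                    break
                sub.remove_nodes_from(ones)
        if sub.number_of_nodes() < 2:
            continue
        density = nx.density(sub)
        modules.append(
            Module(
                nodes=sorted(sub.nodes, key=str),
                seed=seed,
                density=density,
                score=density * sub.number_of_nodes(),
            )
        )
    modules.sort(key=lambda m: (-m.score, str(m.seed)))
    return modules


@dataclass
class AgeComposition:
    """Stage makeup of one module's members."""

    proportions: pd.Series  # index = stage labels, sums to 1 over assigned members
    n_assigned: int
    n_unassigned: int

    @property
    def dominant_stage(self) -> str:
        return str(self.proportions.idxmax())


def module_age_composition(module: Module, assignment: pd.DataFrame,
                           stage_order: Sequence[str] | None = None) -> AgeComposition:
    """Per-stage proportions of a module's age-assigned members."""
    if "stage" not in assignment.columns:
        raise ValueError("age assignment lacks a 'stage' column")
    members = [str(v) for v in module.nodes]
    assigned = [m for m in members if m in assignment.index]
    if not assigned:
        raise ValueError("no module member has an age assignment")
    stages = assignment.loc[assigned, "stage"]
    counts = stages.value_counts()
    if stage_order is not None:
        counts = counts.reindex(list(stage_order), fill_value=0)
    props = counts / counts.sum()
    return AgeComposition(props, n_assigned=len(assigned),
                          n_unassigned=len(members) - len(assigned))


def age_homogeneity_test(
    modules: Iterable[Module],
    assignment: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    p_mode: str = "conservative",
) -> pd.DataFrame:
    """Permutation test of within-module age homogeneity.

    Statistic: the dominant-stage proportion among a module's age-assigned
    members.  Null: stage labels permuted across all assigned nodes of the
    network.  p_mode="conservative" gives (1 + #{perm >= obs}) / (n_perm + 1);
    p_mode="randomized" breaks ties uniformly, which makes the null p exactly
    uniform for these discrete statistics.  q is the BH adjustment across
    modules.
    """
    modules = list(modules)
    if "stage" not in assignment.columns:
        raise ValueError("age assignment lacks a 'stage' column")
    net_genes = sorted({str(v) for m in modules for v in m.nodes} & set(assignment.index))
    stages = assignment.loc[net_genes, "stage"]
    codes, uniques = pd.factorize(stages, sort=True)
    if len(uniques) < 2:
        # no contrast possible: every p is 1 by definition
        rows = [{"module": i, "stat": 1.0, "p": 1.0} for i in range(len(modules))]
        out = pd.DataFrame(rows)
        out["q"] = 1.0
        return out
    pos = {g: k for k, g in enumerate(net_genes)}
    member_idx = [
        np.array([pos[str(v)] for v in m.nodes if str(v) in pos], dtype=int)
        for m in modules
    ]
    n_stages = len(uniques)

    def stat(perm_codes: np.ndarray, idx: np.ndarray) -> float:
        c = np.bincount(perm_codes[idx], minlength=n_stages)
        return c.max() / idx.size

    obs = np.array([stat(codes, idx) for idx in member_idx])
    rng = np.random.default_rng(seed)
    ge = np.zeros(len(modules))
    gt = np.zeros(len(modules))
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        for k, idx in enumerate(member_idx):
            s = stat(perm, idx)
            ge[k] += s >= obs[k]
            gt[k] += s > obs[k]
    if p_mode == "conservative":
        p = (1.0 + ge) / (n_perm + 1.0)
    elif p_mode == "randomized":
        u = rng.uniform(size=len(modules))
        p = (gt + u * (ge - gt + 1.0)) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    out = pd.DataFrame({"module": range(len(modules)), "stat": obs, "p": p})
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# -- I/O -------------------------------------------------------------------

def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))
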