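"""Shared fixtures: synthetic studies are generated once per session."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from phylomark.expression import ExpressionMatrix, filter_expressed_genes, log_transform
from phylomark.coexpression import (
    build_network,
    candidate_edges,
    filter_min_group,
    mcode_modules,
    resample_validate,
    validated_edges,
)
from phylomark.phylostrata import assign_gene_ages
from phylomark.synthetic_data import SimulationConfig, simulate


def matrix_from_array(arr, tissue_of_col, genes=None, log_scale=False) -> ExpressionMatrix:
    """Tiny ExpressionMatrix builder for hand-made examples."""
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    reps: dict[str, int] = {}
    sample_ids, rows = [], []
    for t in tissue_of_col:
        reps[t] = reps.get(t, 0) + 1
        sid = f"{t}_r{reps[t]}"
        sample_ids.append(sid)
        rows.append({"sample_id": sid, "tissue": t, "replicate": reps[t]})
    values = pd.DataFrame(arr, index=genes, columns=sample_ids)
    return ExpressionMatrix(values, pd.DataFrame(rows), log_scale=log_scale)


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study: 2,000 genes, 10 tissues x 3 replicates,
    5 planted modules of 20, noise_sd 0.25, seed 1."""
    return simulate(SimulationConfig())


@pytest.fixture(scope="session")
def default_network(default_sim):
    """Candidate + validated edges, network and modules of the default study."""
    sim = default_sim
    logm = log_transform(filter_expressed_genes(sim.matrix))
    cand = candidate_edges(logm)
    val = resample_validate(logm, cand, n_iter=100, reps_per_tissue=2, seed=1)
    edges = validated_edges(val, 100)
    net = filter_min_group(build_network(edges), 5)
    modules = mcode_modules(net)
    assignment = assign_gene_ages(sim.groups, sim.taxonomy, sim.lineage, sim.scheme)
    within = set()
    for mid in range(sim.config.n_modules):
        members = sorted(sim.truth.module_members(mid))
        within |= {tuple(sorted(p)) for p in itertools.combinations(members, 2)}
    return {
        "logm": logm,
        "candidates": cand,
        "validated": val,
        "edges": edges,
        "network": net,
        "modules": modules,
        "assignment": assignment,
        "within_pairs": within,
    }


@pytest.fixture(scope="session")
def null_sim():
    """A study with no planted modules (null calibration)."""
    cfg = SimulationConfig(n_modules=0, module_age_stage=[], seed=3)
    return simulate(cfg)
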