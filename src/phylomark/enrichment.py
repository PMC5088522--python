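"""Hypergeometric term enrichment with Benjamini-Hochberg correction.

Over-representation testing of a query gene set against term annotations
restricted to a declared universe: p = P[X >= k] for
X ~ Hypergeometric(N, K, n) (the observed overlap is included in the tail),
followed by the BH step-up adjustment across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["AnnotationMap", "hypergeom_enrich", "bh_adjust"]


@dataclass
class AnnotationMap:
    """term id -> gene set, with optional readable names."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def restrict(self, universe: set[str]) -> "AnnotationMap":
        return AnnotationMap(
            {t: g & universe for t, g in self.terms.items()}, dict(self.names)
        )

    @classmethod
    def from_tsv(cls, path: str | Path, names_path: str | Path | None = None) -> "AnnotationMap":
        """Two-column TSV (term_id, gene_id); optional term-name TSV."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        tcol, gcol = df.columns[:2]
        terms: dict[str, set[str]] = {}
        for term, grp in df.groupby(tcol):
            terms[str(term)] = set(grp[gcol].astype(str))
        names = {}
        if names_path is not None:
            nd = pd.read_csv(names_path, sep="\t", dtype=str)
            names = dict(zip(nd.iloc[:, 0], nd.iloc[:, 1]))
        return cls(terms, names)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "AnnotationMap":
        terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            term, desc, genes = parts[0], parts[1], parts[2:]
            terms[term] = set(g for g in genes if g)
            if desc:
                names[term] = desc
        return cls(terms, names)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    query: Iterable[str],
    universe: Iterable[str],
    annotations: AnnotationMap,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` within ``universe``.

    Returns a DataFrame with term, name, k (hits), K (term size), n (query
    size), N (universe size), p and BH-adjusted q, sorted by (q, p, term).
    """
    query = set(query)
    universe = set(universe)
    offenders = query - universe
    if offenders:
        raise ValueError(
            f"{len(offenders)} query genes outside the universe, e.g. "
            f"{sorted(offenders)[:5]}"
        )
    ann = annotations.restrict(universe)
    N, n = len(universe), len(query)
    rows = []
    for term, genes in sorted(ann.terms.items()):
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & query)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P[X >= k]
        rows.append(
            {"term": term, "name": ann.names.get(term, ""), "k": k, "K": K,
             "n": n, "N": N, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["q", "p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df
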