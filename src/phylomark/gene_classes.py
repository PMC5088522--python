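"""House-keeping vs tissue-enriched gene classes and their statistics.

House-keeping genes (HKg) are expressed (FPKM >= threshold) in every sample
of every tissue *and* appear in a curated reference list (e.g. the Eisenberg
& Levanon compilation).  Tissue-enriched genes (TEg) are expressed in at most
three tissues.  The overlap between the all-sample-expressed set and the
reference is summarised as a 2x2 table over the expressed-gene universe with
an odds ratio: either the conditional maximum-likelihood estimator of the
noncentral hypergeometric model (the estimator reported by Fisher's exact
test, the default) or the plain cross-product ratio with a Woolf interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .expression import ExpressionCalls, ExpressionMatrix

__all__ = [
    "OverlapStats",
    "ClassContrast",
    "classify_housekeeping",
    "classify_tissue_enriched",
    "overlap_odds_ratio",
    "overlap_stats_from_counts",
    "compare_class_expression",
    "read_gene_list",
    "write_gene_list",
]


@dataclass
class OverlapStats:
    """2x2 overlap of two gene sets in a universe, with OR, CI and Fisher p.

    table = (a, b, c, d): a in both, b in A only, c in B only, d in neither.
    overlap_pct = 100 * a / (a + c), the fraction of B recovered in A.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    overlap_pct: float
    method: str

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("odds ratio must lie inside its confidence interval")

    @property
    def universe(self) -> int:
        return self.a + self.b + self.c + self.d

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class ClassContrast:
    """Expression contrast between two gene classes on the log2 scale."""

    mean_diff: float
    t_p: float
    wilcoxon_p: float
    n_a: int
    n_b: int


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def classify_housekeeping(calls: ExpressionCalls, reference: set[str]) -> set[str]:
    """Genes expressed in every sample intersected with the reference list."""
    if not reference:
        raise ValueError("house-keeping reference list is empty")
    hk = calls.expressed_in_all_samples() & reference
    if not hk:
        warnings.warn("no overlap between all-sample-expressed genes and the reference")
    return hk


def classify_tissue_enriched(calls: ExpressionCalls, max_tissues: int = 3) -> set[str]:
    """Genes expressed in at least one and at most ``max_tissues`` tissues."""
    t = calls.table["tissues_expressed_in"]
    return set(t.index[(t >= 1) & (t <= max_tissues)])


def overlap_stats_from_counts(a: int, b: int, c: int, d: int,
                              method: str = "cmle") -> OverlapStats:
    """Overlap statistics straight from 2x2 counts.

    method="cmle": conditional-MLE OR under the noncentral hypergeometric
    model with the exact (fisher.test-style) confidence interval; handles
    zero cells natively.  method="sample": cross-product ratio ad/bc with the
    Woolf log-normal interval; zero cells get the Haldane 0.5 correction.
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    p_value = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "cmle":
        res = _scipy_odds_ratio(table, kind="conditional")
        ci = res.confidence_interval(confidence_level=0.95)
        or_, lo, hi = float(res.statistic), float(ci.low), float(ci.high)
    elif method == "sample":
        aa, bb, cc, dd = (float(x) for x in (a, b, c, d))
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = aa + 0.5, bb + 0.5, cc + 0.5, dd + 0.5
        or_ = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        lo = float(np.exp(np.log(or_) - 1.959963984540054 * se))
        hi = float(np.exp(np.log(or_) + 1.959963984540054 * se))
    else:
        raise ValueError(f"unknown method {method!r}")
    overlap_pct = 100.0 * a / (a + c) if (a + c) else float("nan")
    return OverlapStats(a, b, c, d, or_, lo, hi, p_value, overlap_pct, method)


def overlap_odds_ratio(universe: int | set[str], set_a: set[str], set_b: set[str],
                       method: str = "cmle") -> OverlapStats:
    """Tabulate two gene sets against a universe and compute overlap statistics.

    When ``universe`` is a gene set, members of A or B outside it are dropped
    before tabulation (the universe defines the population at risk).
    """
    if isinstance(universe, (set, frozenset)):
        uni = set(universe)
        set_a, set_b = set_a & uni, set_b & uni
        n = len(uni)
    else:
        n = int(universe)
        if len(set_a | set_b) > n:
            raise ValueError("universe smaller than the union of the two sets")
    a = len(set_a & set_b)
    b = len(set_a) - a
    c = len(set_b) - a
    d = n - a - b - c
    return overlap_stats_from_counts(a, b, c, d, method=method)


def compare_class_expression(matrix: ExpressionMatrix, hk: set[str],
                             te: set[str]) -> ClassContrast:
    """Contrast HK vs TE expression over all gene x sample log2 values.

    mean_diff = mean(HK) - mean(TE); two-sided Welch t and Wilcoxon rank-sum
    tests.  Singleton classes skip the tests (p = NaN) with a warning.
    """
    if not matrix.log_scale:
        raise ValueError("compare_class_expression expects log2-scale values")
    if not hk or not te:
        raise ValueError("both gene classes must be nonempty")
    va = matrix.values.loc[sorted(hk & set(matrix.gene_ids))].to_numpy().ravel()
    vb = matrix.values.loc[sorted(te & set(matrix.gene_ids))].to_numpy().ravel()
    mean_diff = float(va.mean() - vb.mean())
    if len(va) < 2 or len(vb) < 2:
        warnings.warn("singleton class: significance tests skipped")
        return ClassContrast(mean_diff, float("nan"), float("nan"), len(va), len(vb))
    t_p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
    w_p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
    return ClassContrast(mean_diff, t_p, w_p, len(va), len(vb))
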