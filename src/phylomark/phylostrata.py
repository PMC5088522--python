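"""Gene-age dating on a time-calibrated taxonomy lineage (phylostratigraphy).

Each protein-coding gene of a focal species is dated by the lowest common
ancestor (LCA) of the species present in its ortholog group.  Because the
focal species is always a member of its own group, the LCA lies on the
root-to-focal path of the taxonomy, so every gene maps to exactly one clade
of the focal lineage.  Clades carry divergence ages (Mya, TimeTree-style
calibration) and are binned into a small number of contiguous "hallmark"
stages; cumulative gene-emergence profiles over clades or stages summarise
when the gene complement of the genome arose.

The human lineage used by default has 31 consecutive clades from
*cellular organisms* to *Homo sapiens* and an eight-stage hallmark scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaxonomyTree",
    "Lineage",
    "OrthologGroup",
    "StageScheme",
    "StageProfile",
    "assign_gene_ages",
    "stage_profile",
    "collapse_to_common_strata",
    "time_axis",
    "read_ortholog_groups",
    "write_ortholog_groups",
]

DEFAULT_STAGE_LABELS = tuple(f"st{i}" for i in range(1, 9))


class TaxonomyTree:
    """A rooted taxonomy given by parent pointers (NCBI node-table dialect).

    Parameters
    ----------
    parent
        Mapping of node id -> parent id.  The root may point to itself,
        to ``None``, or be absent from the mapping's value side.
    names
        Optional mapping of node id -> human-readable name.
    """

    def __init__(self, parent: Mapping[int, int | None], names: Mapping[int, str] | None = None):
        self.parent: dict[int, int | None] = {}
        roots = []
        for node, par in parent.items():
            if par is None or par == node:
                self.parent[node] = None
                roots.append(node)
            else:
                self.parent[node] = par
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root: int = roots[0]
        missing = {p for p in self.parent.values() if p is not None and p not in self.parent}
        if missing:
            raise ValueError(f"parent ids missing from node set: {sorted(missing)[:5]}")
        self.names: dict[int, str] = dict(names or {})
        self._children: dict[int, list[int]] = {n: [] for n in self.parent}
        for node, par in self.parent.items():
            if par is not None:
                self._children[par].append(node)
        self._depth: dict[int, int] = {self.root: 0}
        # cycle check + depth fill via iterative walk
        for node in self.parent:
            self._resolve_depth(node)

    def _resolve_depth(self, node: int) -> int:
        stack = []
        n = node
        while n not in self._depth:
            stack.append(n)
            n = self.parent[n]  # type: ignore[index]
            if len(stack) > len(self.parent):
                raise ValueError("taxonomy contains a cycle")
        d = self._depth[n]
        for m in reversed(stack):
            d += 1
            self._depth[m] = d
        return self._depth[node]

    # -- basic queries ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.parent)

    def __contains__(self, node: int) -> bool:
        return node in self.parent

    def children(self, node: int) -> list[int]:
        return list(self._children[node])

    def is_leaf(self, node: int) -> bool:
        return not self._children[node]

    def leaves(self) -> list[int]:
        return [n for n in self.parent if self.is_leaf(n)]

    def depth(self, node: int) -> int:
        return self._depth[node]

    def path_to_root(self, node: int) -> list[int]:
        """Ancestor chain from ``node`` (inclusive) up to the root."""
        if node not in self.parent:
            raise KeyError(f"unknown taxon id: {node}")
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])  # type: ignore[arg-type]
        return path

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a nonempty set of node ids.

        The deepest node that is an ancestor-or-self of every taxon.
        Runs in O(sum of depths) via pairwise depth-aligned walks.
        """
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        for t in taxa:
            if t not in self.parent:
                raise KeyError(f"unknown taxon id: {t}")
        anc = taxa[0]
        for t in taxa[1:]:
            anc = self._lca2(anc, t)
            if anc == self.root:
                break
        return anc

    def _lca2(self, a: int, b: int) -> int:
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self.parent[a]  # type: ignore[assignment]
            da -= 1
        while db > da:
            b = self.parent[b]  # type: ignore[assignment]
            db -= 1
        while a != b:
            a = self.parent[a]  # type: ignore[assignment]
            b = self.parent[b]  # type: ignore[assignment]
        return a

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_table(cls, path: str | Path) -> "TaxonomyTree":
        """Read a node-table TSV with columns node_id, parent_id, name.

        An empty/self/0 parent marks the root.
        """
        df = pd.read_csv(path, sep="\t", dtype={"node_id": int, "name": str}, keep_default_na=False)
        parent: dict[int, int | None] = {}
        names: dict[int, str] = {}
        for row in df.itertuples(index=False):
            node = int(row.node_id)
            raw = str(row.parent_id).strip()
            par: int | None
            par = None if raw in ("", "0", "NA") else int(float(raw))
            if par == node:
                par = None
            parent[node] = par
            if getattr(row, "name", ""):
                names[node] = str(row.name)
        return cls(parent, names)

    def to_table(self, path: str | Path) -> None:
        rows = [
            {
                "node_id": n,
                "parent_id": "" if p is None else p,
                "name": self.names.get(n, ""),
            }
            for n, p in sorted(self.parent.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def to_newick(self) -> str:
        """Newick string with node ids as labels (names ignored; ids are unique)."""

        def render(node: int) -> str:
            kids = self._children[node]
            if not kids:
                return str(node)
            return "(" + ",".join(render(k) for k in sorted(kids)) + ")" + str(node)

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, path_or_str: str | Path) -> "TaxonomyTree":
        import skbio

        text = str(path_or_str)
        if "(" not in text and Path(text).exists():
            tree = skbio.TreeNode.read(str(path_or_str))
        else:
            import io

            tree = skbio.TreeNode.read(io.StringIO(text))
        parent: dict[int, int | None] = {}
        counter = [0]

        def node_id(node) -> int:
            if node.name is not None:
                try:
                    return int(node.name)
                except ValueError:
                    pass
            counter[0] -= 1  # synthesize negative ids for unlabeled nodes
            return counter[0]

        ids: dict[int, int] = {}
        for node in tree.traverse(include_self=True):
            ids[id(node)] = node_id(node)
        for node in tree.traverse(include_self=True):
            par = node.parent
            parent[ids[id(node)]] = ids[id(par)] if par is not None else None
        return cls(parent)


@dataclass
class Lineage:
    """Ordered root-to-focal clade chain with divergence ages.

    ``clade index`` is 1-based: index 1 is the root-most clade, index
    ``len(self)`` is the focal species (age 0 Mya).
    """

    names: list[str]
    node_ids: list[int]
    ages: list[float]

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.node_ids) == len(self.ages) == n):
            raise ValueError("names, node_ids and ages must have equal length")
        if n < 2:
            raise ValueError("a lineage needs at least a root clade and the focal species")
        diffs = np.diff(self.ages)
        if not np.all(diffs < 0):
            raise ValueError("clade ages must be strictly decreasing from root to focal")
        if self.ages[-1] != 0:
            raise ValueError("the focal clade must have age 0")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def focal_node(self) -> int:
        return self.node_ids[-1]

    def index_of_node(self) -> dict[int, int]:
        """node id -> 1-based clade index."""
        return {nid: i + 1 for i, nid in enumerate(self.node_ids)}

    def validate_against(self, tree: TaxonomyTree) -> None:
        """Check that consecutive clades are ancestor/descendant in ``tree``."""
        path = set(tree.path_to_root(self.focal_node))
        off = [name for name, nid in zip(self.names, self.node_ids) if nid not in path]
        if off:
            raise ValueError(f"lineage clades not on the focal root-path: {off}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Lineage":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        clades = doc["clades"]
        return cls(
            names=[str(c["name"]) for c in clades],
            node_ids=[int(c["node_id"]) for c in clades],
            ages=[float(c["age_mya"]) for c in clades],
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "clades": [
                {"name": n, "node_id": i, "age_mya": a}
                for n, i, a in zip(self.names, self.node_ids, self.ages)
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def human(cls) -> "Lineage":
        """The 31-clade human lineage shipped with the package."""
        from importlib.resources import files

        return cls.from_yaml(str(files("phylomark.data") / "human_lineage.yaml"))


@dataclass(frozen=True)
class OrthologGroup:
    """An ortholog group: the focal gene plus the species where orthologs occur."""

    group_id: str
    gene_id: str
    members: frozenset[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"ortholog group {self.group_id} has no members")


@dataclass
class StageScheme:
    """Ordered, disjoint, exhaustive binning of lineage clade indices into stages.

    ``labels[k]`` is the stage of 1-based clade index ``k+1``; labels must be
    contiguous blocks in lineage order.
    """

    labels: list[str]
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for lab in self.labels:
            if not seen or seen[-1] != lab:
                if lab in seen:
                    raise ValueError(f"stage {lab!r} is not a contiguous clade block")
                seen.append(lab)
        if not self.stage_order:
            self.stage_order = seen
        elif self.stage_order != seen:
            raise ValueError("stage_order inconsistent with labels")

    def __len__(self) -> int:
        return len(self.labels)

    def stage_of(self, clade_index: int) -> str:
        if not 1 <= clade_index <= len(self.labels):
            raise IndexError(f"clade index {clade_index} outside [1, {len(self.labels)}]")
        return self.labels[clade_index - 1]

    @property
    def n_stages(self) -> int:
        return len(self.stage_order)

    def clades_of(self, stage: str) -> list[int]:
        return [i + 1 for i, lab in enumerate(self.labels) if lab == stage]

    @classmethod
    def contiguous(cls, n_clades: int, n_stages: int = 8,
                   stage_labels: Sequence[str] | None = None) -> "StageScheme":
        """Split ``n_clades`` into ``n_stages`` near-equal contiguous blocks."""
        if n_clades < n_stages:
            raise ValueError("cannot define more stages than lineage clades")
        stage_labels = list(stage_labels or [f"st{i}" for i in range(1, n_stages + 1)])
        bounds = np.linspace(0, n_clades, n_stages + 1).round().astype(int)
        labels = []
        for s in range(n_stages):
            labels.extend([stage_labels[s]] * (bounds[s + 1] - bounds[s]))
        return cls(labels)

    @classmethod
    def from_boundaries(cls, lineage: Lineage, last_clade_names: Sequence[str],
                        stage_labels: Sequence[str] | None = None) -> "StageScheme":
        """Build a scheme from the name of the last clade of each stage.

        The final stage implicitly ends at the focal species and need not be
        listed.
        """
        stage_labels = list(stage_labels or [f"st{i}" for i in range(1, len(last_clade_names) + 2)])
        cuts = []
        for name in last_clade_names:
            if name not in lineage.names:
                raise ValueError(f"boundary clade {name!r} not in lineage")
            cuts.append(lineage.names.index(name) + 1)
        if cuts != sorted(cuts):
            raise ValueError("boundary clades must appear in lineage order")
        cuts.append(len(lineage))
        labels, start = [], 0
        for lab, end in zip(stage_labels, cuts):
            labels.extend([lab] * (end - start))
            start = end
        return cls(labels)

    @classmethod
    def human(cls, lineage: Lineage | None = None) -> "StageScheme":
        """The eight-hallmark human scheme (st1 Prokaryota ... st8 Primates->Homo).

        Stage boundaries: cellular organisms | Eukaryota | Metazoa |
        Vertebrata | Euteleostomi | Mammalia | Primates | Homo sapiens.
        """
        lineage = lineage or Lineage.human()
        return cls.from_boundaries(
            lineage,
            ["cellular organisms", "Eukaryota", "Metazoa", "Vertebrata",
             "Euteleostomi", "Mammalia", "Primates"],
        )


@dataclass
class StageProfile:
    """Per-clade and per-stage gene counts with percentages for a gene class."""

    label: str
    total: int
    stage_counts: pd.Series  # index = ordered stage labels
    clade_counts: pd.Series | None = None  # index = 1-based clade index

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("stage profile requires a positive gene total")
        if int(self.stage_counts.sum()) != self.total:
            raise ValueError("stage counts must sum to the total")

    @property
    def pct_of_total(self) -> pd.Series:
        return 100.0 * self.stage_counts / self.total

    @property
    def cumulative_pct(self) -> pd.Series:
        return self.pct_of_total.cumsum()

    @classmethod
    def from_stage_counts(cls, counts: Sequence[int],
                          stage_labels: Sequence[str] = DEFAULT_STAGE_LABELS,
                          label: str = "all") -> "StageProfile":
        counts = [int(c) for c in counts]
        if len(counts) != len(stage_labels):
            raise ValueError("one count per stage label required")
        s = pd.Series(counts, index=list(stage_labels), dtype=int)
        return cls(label=label, total=int(s.sum()), stage_counts=s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.stage_counts,
                "pct_of_total": self.pct_of_total,
                "cumulative_pct": self.cumulative_pct,
            }
        )


def assign_gene_ages(
    groups: Iterable[OrthologGroup],
    tree: TaxonomyTree,
    lineage: Lineage,
    scheme: StageScheme | None = None,
) -> pd.DataFrame:
    """Date genes by ortholog-group LCA, projected onto the focal lineage.

    Returns a DataFrame indexed by gene id with columns ``clade_index``
    (1-based), ``clade_name``, ``age_mya`` and, when a scheme is given,
    ``stage``.  Groups lacking the focal species are skipped with a warning;
    the number skipped is stored in ``df.attrs["n_skipped"]``.
    """
    idx_of = lineage.index_of_node()
    focal = lineage.focal_node
    rows: dict[str, tuple[int, str, float]] = {}
    n_skipped = 0
    for grp in groups:
        if focal not in grp.members:
            n_skipped += 1
            continue
        node = tree.lca(grp.members)
        # the LCA is an ancestor of the focal species, hence on the root-path;
        # lift to the nearest lineage clade at-or-above it
        while node not in idx_of:
            par = tree.parent[node]
            if par is None:
                raise ValueError(
                    f"LCA {node} of group {grp.group_id} is not under any lineage clade"
                )
            node = par
        k = idx_of[node]
        if grp.gene_id in rows:  # first mapping wins, duplicates logged
            warnings.warn(f"duplicate mapping for gene {grp.gene_id}; keeping the first")
            continue
        rows[grp.gene_id] = (k, lineage.names[k - 1], lineage.ages[k - 1])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} ortholog groups lacking the focal species")
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["clade_index", "clade_name", "age_mya"]
    )
    df.index.name = "gene_id"
    if scheme is not None:
        df["stage"] = [scheme.stage_of(int(k)) for k in df["clade_index"]]
    df.attrs["n_skipped"] = n_skipped
    return df


def stage_profile(
    assignment: pd.DataFrame,
    scheme: StageScheme,
    subset: Iterable[str] | None = None,
    label: str = "all",
) -> StageProfile:
    """Bin an age assignment into stages for a gene class (all / HK / TE)."""
    if subset is not None:
        subset = set(subset)
        missing = subset - set(assignment.index)
        if missing:
            raise ValueError(f"{len(missing)} subset genes have no age assignment")
        assignment = assignment.loc[sorted(subset)]
    if len(assignment) == 0:
        raise ValueError("empty gene subset: no profile to compute")
    clade_counts = (
        assignment["clade_index"].value_counts().reindex(range(1, len(scheme) + 1), fill_value=0)
    )
    stage_counts = pd.Series(
        {s: int(clade_counts.loc[scheme.clades_of(s)].sum()) for s in scheme.stage_order},
        dtype=int,
    ).reindex(scheme.stage_order)
    return StageProfile(
        label=label,
        total=int(len(assignment)),
        stage_counts=stage_counts,
        clade_counts=clade_counts.astype(int),
    )


def collapse_to_common_strata(
    a: pd.DataFrame,
    scheme_a: StageScheme,
    b: pd.DataFrame,
    scheme_b: StageScheme,
) -> pd.DataFrame:
    """Collapse two age assignments onto a shared stratum scheme for comparison.

    Both schemes must use the same ordered stratum labels (each mapping its own
    lineage's clades onto them); returns per-stratum counts and within-dataset
    fractions for each assignment.
    """
    if scheme_a.stage_order != scheme_b.stage_order:
        raise ValueError("stage schemes do not share an ordered common stratum set")
    pa = stage_profile(a, scheme_a, label="a")
    pb = stage_profile(b, scheme_b, label="b")
    return pd.DataFrame(
        {
            "count_a": pa.stage_counts,
            "count_b": pb.stage_counts,
            "frac_a": pa.stage_counts / pa.total,
            "frac_b": pb.stage_counts / pb.total,
        }
    )


def time_axis(lineage: Lineage, profile: StageProfile) -> pd.DataFrame:
    """Cumulative emergence curve: one (age Mya, cumulative %) point per clade."""
    if profile.clade_counts is None:
        raise ValueError("profile has no per-clade counts (built from stage totals only)")
    if len(profile.clade_counts) != len(lineage):
        raise ValueError("profile and lineage disagree on the number of clades")
    cum = 100.0 * profile.clade_counts.cumsum() / profile.total
    return pd.DataFrame(
        {
            "clade_index": range(1, len(lineage) + 1),
            "clade_name": lineage.names,
            "age_mya": lineage.ages,
            "cumulative_pct": cum.to_numpy(),
        }
    )


# -- ortholog group I/O ----------------------------------------------------

def read_ortholog_groups(path: str | Path) -> list[OrthologGroup]:
    """Read OMA-style group TSV: group_id, gene_id, comma-separated species ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        members = frozenset(int(x) for x in str(row.species).split(",") if x)
        out.append(OrthologGroup(str(row.group_id), str(row.gene_id), members))
    return out


def write_ortholog_groups(groups: Iterable[OrthologGroup], path: str | Path) -> None:
    rows = [
        {
            "group_id": g.group_id,
            "gene_id": g.gene_id,
            "species": ",".join(str(m) for m in sorted(g.members)),
        }
        for g in groups
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
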