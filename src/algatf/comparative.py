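"""Comparative layer: count/proportion tables, presence/absence
dendrogram, proportion-based family clustering and SHAQKYF ratios.

The substrate is a species x family count table (pandas DataFrame with
species as rows). A published seven-microalga table ships with the
package (:func:`algal_counts`) so the comparative operations have a
worked example without re-running the identification pipeline.

Family grouping convention: count-table columns are subfamily-level row
labels; for presence/absence and family counting, subfamily rows that
share a family (the two AP2/ERF rows) collapse into one family column,
while MYB classes, NF-Y subunits and the Homeobox/C2C2/GARP rows count
as separate families. This is the convention under which the published
per-species family counts are recovered.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .benchmark import round_half_up
from .records import Assignment
from .rules import RuleSet

SPECIES = [
    "T. lutea",
    "Pavlova sp.",
    "E. huxleyi",
    "P. tricornutum",
    "N. gaditana",
    "P. purpureum",
    "C. reinhardtii",
]


# ---------------------------------------------------------------------------
# count and proportion tables


def count_table(
    assignments_by_species: Mapping[str, Sequence[Assignment]],
    ruleset: RuleSet,
) -> pd.DataFrame:
    """Species x family count table from per-species assignments.

    Unclassified records are excluded; a family label unknown to the
    ruleset is an error.
    """
    species = list(assignments_by_species)
    table = pd.DataFrame(
        0, index=species, columns=ruleset.labels, dtype=int
    )
    for sp, assignments in assignments_by_species.items():
        for a in assignments:
            if not a.is_classified:
                continue
            if a.label not in ruleset:
                raise ValueError(
                    f"assignment family {a.label!r} not in the rule set"
                )
            table.loc[sp, a.label] += 1
    return table


def totals(table: pd.DataFrame) -> pd.Series:
    return table.sum(axis=1)


def proportions(
    table: pd.DataFrame, species_totals: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Per-species percentages (100 * count / species total).

    Raw (unrounded) values are returned; use :func:`display_proportions`
    for rounded display. ``species_totals`` overrides the row sums —
    needed when reproducing a published table whose stated total differs
    from the sum of the broken-out rows. A species with zero total is an
    error.
    """
    tot = totals(table) if species_totals is None else species_totals
    zero = tot[tot == 0]
    if len(zero):
        raise ValueError(f"zero TF total for species: {list(zero.index)}")
    return 100.0 * table.div(tot, axis=0)


def display_proportions(
    table: pd.DataFrame,
    decimals: int = 2,
    species_totals: Optional[pd.Series] = None,
) -> pd.DataFrame:
    props = proportions(table, species_totals=species_totals)
    return props.map(lambda x: round_half_up(x, decimals))


def combined_percentage(
    table: pd.DataFrame, species: str, family_group: Iterable[str]
) -> float:
    """Percentage of a species' TFs in a group of families (summed counts)."""
    group = list(family_group)
    if not group:
        raise ValueError("empty family group")
    missing = [f for f in group if f not in table.columns]
    if missing:
        raise ValueError(f"unknown families: {missing}")
    return 100.0 * table.loc[species, group].sum() / table.loc[species].sum()


def shaqkyf_ratio(table: pd.DataFrame, species: str) -> Optional[float]:
    """Percentage of MYB-SHAQKYF among MYB-related TFs.

    Union denominator: 100 * SHAQKYF / (SHAQKYF + MYB-rel). None when
    both counts are zero.
    """
    s = int(table.loc[species, "MYB-SHAQKYF"])
    r = int(table.loc[species, "MYB-rel"])
    if s + r == 0:
        return None
    return 100.0 * s / (s + r)


# ---------------------------------------------------------------------------
# presence/absence


def presence_absence(
    table: pd.DataFrame, ruleset: Optional[RuleSet] = None
) -> pd.DataFrame:
    """Binary species x family matrix (1 iff any count > 0).

    With a ruleset, subfamily columns sharing a family collapse to one
    family-level column (present iff any subfamily is present).
    """
    if ruleset is not None:
        groups: dict[str, list[str]] = {}
        order: list[str] = []
        for label in table.columns:
            fam = ruleset.family_of_label(label) if label in ruleset else label
            if fam not in groups:
                groups[fam] = []
                order.append(fam)
            groups[fam].append(label)
        data = {
            fam: (table[cols].sum(axis=1) > 0).astype(int)
            for fam, cols in groups.items()
        }
        return pd.DataFrame(data)[order]
    return (table > 0).astype(int)


def n_families(table: pd.DataFrame, ruleset: Optional[RuleSet] = None) -> pd.Series:
    """Number of distinct families present per species."""
    return presence_absence(table, ruleset).sum(axis=1)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class DendrogramNode:
    """Recursive dendrogram: leaf (name) or internal node with a height."""

    name: Optional[str] = None
    children: tuple["DendrogramNode", ...] = ()
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def to_newick(self) -> str:
        return self._newick_inner(parent_height=self.height) + ";"

    def _newick_inner(self, parent_height: float) -> str:
        blen = max(parent_height - self.height, 0.0)
        if self.is_leaf:
            return f"{_quote(self.name)}:{blen:.6g}"
        inner = ",".join(c._newick_inner(self.height) for c in self.children)
        return f"({inner}):{blen:.6g}"


def _quote(name: str | None) -> str:
    name = name or ""
    if any(ch in name for ch in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _tree_from_linkage(Z: np.ndarray, labels: Sequence[str]) -> DendrogramNode:
    n = len(labels)
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(name=labels[i]) for i in range(n)
    }
    for i, (a, b, height, _) in enumerate(Z):
        nodes[n + i] = DendrogramNode(
            children=(nodes[int(a)], nodes[int(b)]), height=float(height)
        )
    return nodes[n + len(Z) - 1]


def dendrogram(
    presence: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
) -> tuple[DendrogramNode, str]:
    """Agglomerative clustering of species rows; returns (tree, newick).

    Defaults mirror the conventional R hclust defaults (Euclidean
    distance, complete linkage) on the 0/1 rows; both are configurable
    because the choice is a convention, not part of the data.
    """
    if len(presence) < 2:
        raise ValueError("dendrogram needs at least 2 species")
    dist = pdist(presence.to_numpy(dtype=float), metric=metric)
    Z = linkage(dist, method=method)
    tree = _tree_from_linkage(Z, list(presence.index))
    return tree, tree.to_newick()


def family_clusters(
    proportion_table: pd.DataFrame,
    k: int = 4,
    metric: str = "euclidean",
    method: str = "complete",
    scale_rows: bool = False,
) -> dict[str, int]:
    """Cluster family columns by their proportion profiles; cut at k.

    Operates on the family rows (transpose of the species x family
    proportion table). Deterministic given inputs.
    """
    rows = proportion_table.T
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(rows):
        raise ValueError(f"k={k} exceeds number of families ({len(rows)})")
    X = rows.to_numpy(dtype=float)
    if scale_rows:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    Z = linkage(pdist(X, metric=metric), method=method)
    ids = fcluster(Z, t=k, criterion="maxclust")
    return {fam: int(c) for fam, c in zip(rows.index, ids)}


# ---------------------------------------------------------------------------
# bundled published table


def load_count_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a family x species count TSV into the species x family layout."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    table = df.T
    table.index.name = None
    table.columns.name = None
    return table.astype(int)


def algal_counts() -> pd.DataFrame:
    """The published seven-microalga TF count table (species x family)."""
    ref = resources.files("algatf") / "data" / "algal_tf_counts.tsv"
    with resources.as_file(ref) as path:
        return load_count_table(path)


def algal_totals() -> pd.Series:
    """Published per-species TF totals for the bundled table.

    These are the totals the source publication states and normalizes by.
    For P. purpureum the published total (199) exceeds the sum of the
    broken-out family rows by one — an inconsistency in the source table
    itself; all published percentages for that species use 199.
    """
    return pd.Series(
        [155, 128, 478, 196, 93, 199, 212], index=SPECIES, dtype=int
    )
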