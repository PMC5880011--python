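"""Presence/absence profiling of a reference gene set across species.

A reference gene is called present in a species when at least one homology
hit passes both thresholds (e-value <= 1e-5 and query coverage strictly
> 30% by default); the recorded cell value is the highest percent identity
among passing hits.  Profiles are clustered with Euclidean distance and
complete linkage, and per-gene absence patterns are reconciled on the
species tree under Dollo parsimony to date the losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .dollo_parsimony import per_branch_losses, reconstruct
from .formats_io import HitTable, ReferenceError_, SpeciesTree

__all__ = [
    "PresenceMatrix",
    "call_presence",
    "cluster_profiles",
    "reconcile_losses",
]


@dataclass
class PresenceMatrix:
    """Reference genes x species; cells are best-hit percent identity,
    NaN marks absence."""

    identities: pd.DataFrame
    e_value_max: float
    min_query_coverage: float

    def binary(self) -> pd.DataFrame:
        return self.identities.notna().astype(int)


def call_presence(hits: dict[str, HitTable], e_value_max: float = 1e-5,
                  min_query_coverage: float = 0.30) -> PresenceMatrix:
    """Best-identity presence calls per (reference gene, species).

    ``hits`` maps species id to that species' hit table (shared query set).
    A hit passes iff e-value <= ``e_value_max`` and query coverage is
    strictly greater than ``min_query_coverage``.
    """
    if not hits:
        raise ValueError("no hit tables supplied")
    queries: set[str] = set()
    for table in hits.values():
        queries |= set(table.query_lengths)
        extra = set(table.rows["query_id"]) - set(table.query_lengths)
        if extra:
            raise ReferenceError_(f"queries without length: {sorted(extra)}")
    index = sorted(queries)
    cols = sorted(hits)
    mat = pd.DataFrame(np.nan, index=index, columns=cols)
    for sp in cols:
        rows = hits[sp].rows
        if not len(rows):
            continue
        passing = rows[(rows["e_value"] <= e_value_max)
                       & (rows["query_coverage"] > min_query_coverage)]
        if not len(passing):
            continue
        best = passing.groupby("query_id")["pct_identity"].max()
        mat.loc[best.index, sp] = best.to_numpy()
    return PresenceMatrix(identities=mat, e_value_max=e_value_max,
                          min_query_coverage=min_query_coverage)


def _linkage_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node, root: bool = False) -> str:
        if node.is_leaf():
            s = labels[node.id]
        else:
            s = f"({render(node.left)},{render(node.right)})"
        return s if root else f"{s}:{node.dist:g}"

    return render(tree, root=True) + ";"


def cluster_profiles(matrix: PresenceMatrix) -> dict[str, object]:
    """Complete-linkage Euclidean clustering of gene and species profiles.

    Absent cells are imputed as identity 0.  Rows and columns are pre-sorted
    lexicographically so merge order is deterministic under distance ties.
    Returns linkage matrices and Newick renderings of both dendrograms.
    """
    filled = matrix.identities.fillna(0.0)
    if filled.shape[0] < 2 or filled.shape[1] < 2:
        raise ValueError("need >= 2 genes and >= 2 species to cluster")
    filled = filled.sort_index(axis=0).sort_index(axis=1)
    gene_linkage = hierarchy.linkage(filled.to_numpy(), method="complete",
                                     metric="euclidean")
    species_linkage = hierarchy.linkage(filled.to_numpy().T, method="complete",
                                        metric="euclidean")
    return {
        "gene_linkage": gene_linkage,
        "species_linkage": species_linkage,
        "gene_newick": _linkage_newick(gene_linkage, list(filled.index)),
        "species_newick": _linkage_newick(species_linkage, list(filled.columns)),
        "gene_order": list(filled.index),
        "species_order": list(filled.columns),
    }


def reconcile_losses(matrix: PresenceMatrix, tree: SpeciesTree
                     ) -> tuple[pd.Series, pd.DataFrame]:
    """Dollo gain/loss reconciliation of every reference gene on the tree.

    Returns per-branch loss totals (branches keyed by child node) and a
    per-gene table of gain node and loss count.  Genes absent from every
    species carry no signal and are skipped.
    """
    extra = sorted(set(matrix.identities.columns) - set(tree.leaves()))
    if extra:
        raise ReferenceError_(f"species not in tree: {extra}")
    binary = matrix.binary()
    results = []
    per_gene = []
    for gene, row in binary.iterrows():
        pattern = {leaf: int(row.get(leaf, 0)) for leaf in tree.leaves()}
        if sum(pattern.values()) == 0:
            per_gene.append({"gene_id": gene, "gain_node": None, "loss_count": None})
            continue
        rec = reconstruct(pattern, tree, character_id=str(gene))
        results.append(rec)
        per_gene.append({"gene_id": gene, "gain_node": rec.gain_node,
                         "loss_count": rec.loss_count})
    totals = per_branch_losses(results, tree)
    return (pd.Series(totals, name="losses").sort_index(),
            pd.DataFrame(per_gene))
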