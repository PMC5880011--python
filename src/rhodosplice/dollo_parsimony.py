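"""Dollo parsimony for binary characters on a rooted species tree.

Under Dollo parsimony a character (a gene family, or an intron position) is
gained exactly once and can only be lost thereafter.  For a binary
presence/absence pattern over the leaves, the minimal-loss reconstruction is
unique: the gain sits on the branch above the most recent common ancestor of
all present leaves, every node inside the gain clade whose subtree retains at
least one present leaf is ancestrally present, and one loss is charged to
each maximal subtree of the gain clade containing no present leaf.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .formats_io import ReferenceError_, SpeciesTree

__all__ = [
    "DolloReconstruction",
    "reconstruct",
    "reconstruct_matrix",
    "ancestral_inventory",
    "per_branch_losses",
    "read_character_matrix",
    "write_character_matrix",
]


@dataclass
class DolloReconstruction:
    """Single-character result: where gained, where lost, ancestral states."""

    character_id: str
    gain_node: str
    loss_branches: frozenset[str]
    states: dict[str, int]  # every node (leaves included) -> 0/1

    @property
    def loss_count(self) -> int:
        return len(self.loss_branches)


def reconstruct(pattern: dict[str, int], tree: SpeciesTree,
                character_id: str = "char") -> DolloReconstruction:
    """Minimal-loss single-gain reconstruction of one leaf pattern.

    ``pattern`` maps every leaf id to 0/1; at least one leaf must be 1
    (an all-zero character is unobserved and carries no signal).
    """
    leaves = tree.leaves()
    missing = [l for l in leaves if l not in pattern]
    if missing:
        raise ReferenceError_(f"pattern missing leaves: {missing}")
    bad = sorted(v for v in set(pattern.values()) if v not in (0, 1))
    if bad:
        raise ValueError(f"non-binary states: {bad}")
    ones = [l for l in leaves if pattern[l] == 1]
    if not ones:
        raise ValueError(f"character {character_id}: all-zero pattern")

    gain = tree.mrca(ones)
    has_one: dict[str, bool] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            has_one[nid] = pattern[nid] == 1
        else:
            has_one[nid] = any(has_one[c] for c in node.children)

    in_gain_clade: dict[str, bool] = {}
    for nid in tree.preorder():
        parent = tree.parent(nid)
        in_gain_clade[nid] = nid == gain or (
            parent is not None and in_gain_clade.get(parent, False))

    states = {nid: int(in_gain_clade[nid] and has_one[nid]) for nid in tree.postorder()}
    losses = frozenset(
        nid for nid in tree.branches()
        if states.get(tree.parent(nid), 0) == 1 and not has_one[nid]
    )
    return DolloReconstruction(character_id, gain, losses, states)


def reconstruct_matrix(matrix: pd.DataFrame, tree: SpeciesTree) -> list[DolloReconstruction]:
    """Reconstruct every row of a characters x leaves binary matrix."""
    extra = sorted(set(matrix.columns) - set(tree.leaves()))
    if extra:
        raise ReferenceError_(f"matrix species not in tree: {extra}")
    out = []
    for char_id, row in matrix.iterrows():
        out.append(reconstruct({l: int(row[l]) for l in matrix.columns}, tree,
                               character_id=str(char_id)))
    return out


def ancestral_inventory(results: list[DolloReconstruction], node: str,
                        tree: SpeciesTree) -> int:
    """Number of characters ancestrally present at ``node``."""
    if node not in tree.nodes:
        raise ReferenceError_(f"unknown node {node!r}")
    return sum(r.states[node] for r in results)


def per_branch_losses(results: list[DolloReconstruction],
                      tree: SpeciesTree) -> dict[str, int]:
    """Additive per-branch loss tally over all characters."""
    tally: Counter[str] = Counter()
    for r in results:
        tally.update(r.loss_branches)
    return {b: tally.get(b, 0) for b in tree.branches()}


def read_character_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_character_matrix(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="character_id")


def results_to_frame(results: list[DolloReconstruction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "character_id": [r.character_id for r in results],
            "gain_node": [r.gain_node for r in results],
            "loss_branches": [",".join(sorted(r.loss_branches)) for r in results],
            "loss_count": [r.loss_count for r in results],
        }
    )
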