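#!/usr/bin/env python
"""Spliceosomal-gene presence profiling and Dollo loss dating.

Calls presence/absence of the reference gene set in every species from the
homology hit tables (e-value <= 1e-5, query coverage > 30%), clusters the
identity profiles (Euclidean distance, complete linkage), reconciles each
gene's absence pattern on the species tree under Dollo parsimony, and
reports the ancestral gene inventory and per-branch loss counts.
"""

import os

import pandas as pd

from rhodosplice.formats_io import read_hit_table, read_newick
from rhodosplice.presence_profile import (call_presence, cluster_profiles,
                                          reconcile_losses)

COHORT_DIR = "scratch/cohort"
RESULTS = "results"


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    tree = read_newick(os.path.join(COHORT_DIR, "tree.nwk"))
    qlen = pd.read_csv(os.path.join(COHORT_DIR, "query_lengths.tsv"),
                       sep="\t", index_col=0)["length"].to_dict()
    hits = {sp: read_hit_table(
        os.path.join(COHORT_DIR, "hits", f"{sp}.hits.tsv"), qlen)
        for sp in tree.leaves()}
    matrix = call_presence(hits)
    matrix.identities.to_csv(os.path.join(RESULTS, "presence_matrix.tsv"),
                             sep="\t")
    clustering = cluster_profiles(matrix)
    for which in ("gene", "species"):
        with open(os.path.join(RESULTS, f"{which}_dendrogram.nwk"), "w") as fh:
            fh.write(clustering[f"{which}_newick"] + "\n")
    branch_losses, per_gene = reconcile_losses(matrix, tree)
    branch_losses.rename_axis("branch").reset_index().to_csv(
        os.path.join(RESULTS, "branch_losses.tsv"), sep="\t", index=False)
    per_gene.to_csv(os.path.join(RESULTS, "gene_dollo.tsv"),
                    sep="\t", index=False)

    n_root = int(per_gene["gain_node"].eq(tree.root).sum())
    per_species = matrix.binary().sum(axis=0)
    print(f"{n_root} of {len(per_gene)} reference genes were present in the "
          f"common ancestor (gain at the root)")
    print("genes retained per species:")
    print(per_species.to_string())
    print("\nlosses per branch (branch = child node):")
    print(branch_losses[branch_losses > 0].to_string())


if __name__ == "__main__":
    main()
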