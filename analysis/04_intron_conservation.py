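#!/usr/bin/env python
"""Cross-species intron-position conservation and intron gain/loss history.

Projects every focal-species intron into protein-alignment column space
against each other species, calls positional conservation (same column,
same phase), labels introns lineage-specific vs shared, clusters intron
positions into characters, and reconstructs intron gain/loss on the tree
under Dollo parsimony -- including the estimated ancestral intron count.
"""

import os
from dataclasses import replace

import pandas as pd

from rhodosplice import dollo_parsimony, intron_homology
from rhodosplice.formats_io import GenomeSet, read_fasta, read_gff3, read_newick
from rhodosplice.intron_catalog import extract_introns

COHORT_DIR = "scratch/cohort"
RESULTS = "results"
FOCAL = "gsu"


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    tree = read_newick(os.path.join(COHORT_DIR, "tree.nwk"))
    catalogs, proteins = {}, {}
    for sp in tree.leaves():
        genome = GenomeSet(sp, read_fasta(
            os.path.join(COHORT_DIR, f"{sp}.genome.fasta")))
        models = read_gff3(os.path.join(COHORT_DIR, f"{sp}.gff3"), genome)
        catalogs[sp] = [replace(r, gene_id=f"{sp}|{r.gene_id}")
                        for r in extract_introns(models, genome)]
        proteins[sp] = {f"{sp}|{m.gene_id}": m.protein for m in models}

    # conservation between every pair of species, so intron positions merge
    # into cohort-wide characters
    import itertools
    all_calls = []
    focal_calls = []
    for sp_a, sp_b in itertools.combinations(tree.leaves(), 2):
        shared = sorted({g.split("|")[1] for g in proteins[sp_a]}
                        & {g.split("|")[1] for g in proteins[sp_b]})
        alignments, pairs = {}, []
        for g in shared:
            key = (f"{sp_a}|{g}", f"{sp_b}|{g}")
            aln = intron_homology.align_proteins_global(
                proteins[sp_a][key[0]], proteins[sp_b][key[1]])
            alignments[key] = intron_homology.ProteinAlignment(
                ids=key, gapped=aln.gapped)
            pairs.append(key)
        calls = intron_homology.call_conservation(
            catalogs[sp_a], catalogs[sp_b], alignments, pairs)
        all_calls.extend(calls)
        if FOCAL in (sp_a, sp_b):
            focal_calls.extend(calls)

    labels = intron_homology.classify_lineage_specificity(
        focal_calls, tree, FOCAL, set(), catalogs[FOCAL])
    labels_df = pd.DataFrame(sorted(labels.items()), columns=["intron", "label"])
    labels_df.to_csv(os.path.join(RESULTS, "lineage_labels.tsv"),
                     sep="\t", index=False)
    frac = labels_df["label"].value_counts(normalize=True)
    print("focal intron positions by conservation label:")
    print((100 * frac).round(1).to_string())

    matrix = intron_homology.build_intron_character_matrix(all_calls, catalogs)
    results = dollo_parsimony.reconstruct_matrix(matrix, tree)
    dollo_parsimony.results_to_frame(results).to_csv(
        os.path.join(RESULTS, "intron_dollo.tsv"), sep="\t", index=False)
    inventory = {n: dollo_parsimony.ancestral_inventory(results, n, tree)
                 for n in tree.postorder()}
    losses = dollo_parsimony.per_branch_losses(results, tree)
    pd.DataFrame({"node": list(inventory), "inventory": list(inventory.values()),
                  "losses_on_branch": [losses.get(n, 0) for n in inventory]}
                 ).to_csv(os.path.join(RESULTS, "intron_dollo_summary.tsv"),
                          sep="\t", index=False)
    print(f"\nestimated intron positions in the common ancestor: "
          f"{inventory[tree.root]} (of {len(matrix)} characters)")


if __name__ == "__main__":
    main()
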