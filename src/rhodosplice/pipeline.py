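"""End-to-end orchestration: simulate -> catalog -> presence -> dollo ->
conservation -> retention -> diffsplice, with one config, deterministic
execution, and a manifest of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import dollo_parsimony, intron_homology
from .formats_io import read_fasta, read_gff3, read_hit_table, read_newick, GenomeSet
from .intron_catalog import (catalog_to_frame, compute_genome_stats,
                             extract_introns, stats_to_frame)
from .presence_profile import call_presence, cluster_profiles, reconcile_losses
from .retention_effects import classify_retention, summarize_consequences
from .splice_divergence import (SplicingCountTable, call_de_genes,
                                calls_to_frame, filter_junctions,
                                test_differential)
from .synthetic_cohort import (CohortParams, CountSimParams, simulate_cohort,
                               simulate_counts, write_cohort)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

_ALL_STAGES = ("catalog", "presence", "conservation", "retention", "diffsplice")


@dataclass
class RunConfig:
    """Paths, thresholds (defaults are the published analysis values), seed
    and stage toggles for a full run."""

    cohort_dir: str = "cohort"
    out_dir: str = "results"
    seed: int = 0
    simulate: bool = False
    focal_species: str = "gsu"
    outgroup_species: list[str] = field(default_factory=list)
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))
    # presence thresholds
    e_value_max: float = 1e-5
    min_query_coverage: float = 0.30
    # intron similarity screen
    similarity_min_coverage: float = 0.5
    similarity_min_score: float = 40.0
    # retention
    ptc_scope: str = "intron_only"
    # differential splicing
    mean_cov_min: float = 10.0
    min_detected_samples: int = 4
    exon_cov_min: float = 16.0
    intron_cov_min: float = 8.0
    stat_threshold: float = 0.25
    fdr: float = 0.01
    n_null: int = 10000
    fold_change_min: float = 2.5
    # generator conditions (used with simulate=True)
    cohort: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, outputs: list[str], **kw) -> None:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
    outputs.append(path)


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report (also written
    as ``manifest.json`` in the output directory)."""
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: list[str] = []
    report: dict = {"stages": [], "seed": config.seed}

    if config.simulate:
        params = CohortParams(**{"seed": config.seed, **config.cohort})
        cohort = simulate_cohort(params)
        write_cohort(cohort, config.cohort_dir)
        cparams = CountSimParams(**{"seed": config.seed, **config.counts})
        table, planted = simulate_counts(cohort.truth, config.focal_species, cparams)
        table.to_frame().to_csv(os.path.join(config.cohort_dir, "counts.tsv"),
                                sep="\t", index=False)
        pd.Series(planted, name="intron_id").to_csv(
            os.path.join(config.cohort_dir, "truth", "planted_differential.tsv"),
            sep="\t", index=False)
        report["stages"].append("simulate")

    tree = read_newick(os.path.join(config.cohort_dir, "tree.nwk"))
    species = tree.leaves()
    genomes: dict[str, GenomeSet] = {}
    models: dict = {}
    catalogs: dict = {}
    for sp in species:
        genomes[sp] = GenomeSet(sp, read_fasta(
            os.path.join(config.cohort_dir, f"{sp}.genome.fasta")))
        models[sp] = read_gff3(os.path.join(config.cohort_dir, f"{sp}.gff3"),
                               genomes[sp])
        catalogs[sp] = extract_introns(models[sp], genomes[sp])

    if "catalog" in config.stages:
        frames = [catalog_to_frame(catalogs[sp]) for sp in species]
        _write_tsv(pd.concat(frames, ignore_index=True),
                   os.path.join(config.out_dir, "introns.tsv"), outputs)
        stats = [compute_genome_stats(catalogs[sp], models[sp], genomes[sp])
                 for sp in species]
        _write_tsv(stats_to_frame(stats),
                   os.path.join(config.out_dir, "genome_stats.tsv"), outputs)
        report["stages"].append("catalog")

    if "presence" in config.stages:
        qlen = pd.read_csv(os.path.join(config.cohort_dir, "query_lengths.tsv"),
                           sep="\t", index_col=0)["length"].to_dict()
        hits = {sp: read_hit_table(
            os.path.join(config.cohort_dir, "hits", f"{sp}.hits.tsv"), qlen)
            for sp in species}
        matrix = call_presence(hits, e_value_max=config.e_value_max,
                               min_query_coverage=config.min_query_coverage)
        _write_tsv(matrix.identities,
                   os.path.join(config.out_dir, "presence_matrix.tsv"),
                   outputs, index=True)
        clustering = cluster_profiles(matrix)
        for which in ("gene", "species"):
            path = os.path.join(config.out_dir, f"{which}_dendrogram.nwk")
            with open(path, "w") as fh:
                fh.write(clustering[f"{which}_newick"] + "\n")
            outputs.append(path)
        branch_losses, per_gene = reconcile_losses(matrix, tree)
        _write_tsv(branch_losses.rename_axis("branch").reset_index(),
                   os.path.join(config.out_dir, "branch_losses.tsv"), outputs)
        _write_tsv(per_gene, os.path.join(config.out_dir, "gene_dollo.tsv"),
                   outputs)
        report["stages"].append("presence")
        report["sm_genes_at_root"] = int(
            per_gene["gain_node"].eq(tree.root).sum())

    if "conservation" in config.stages:
        focal = config.focal_species
        all_calls = []
        proteins = {sp: {m.gene_id: m.protein for m in models[sp]}
                    for sp in species}
        for other in species:
            if other == focal:
                continue
            shared = sorted(set(proteins[focal]) & set(proteins[other]))
            alignments = {}
            for gid in shared:
                aln = intron_homology.align_proteins_global(
                    proteins[focal][gid], proteins[other][gid],
                    id_a=gid, id_b=gid)
                # sequence ids collide (same gene id); store with explicit ids
                alignments[(gid, gid)] = intron_homology.ProteinAlignment(
                    ids=(f"{focal}|{gid}", f"{other}|{gid}"), gapped=aln.gapped)
            calls = intron_homology.call_conservation(
                _with_prefixed_ids(catalogs[focal], focal),
                _with_prefixed_ids(catalogs[other], other),
                {(f"{focal}|{a}", f"{other}|{b}"): aln
                 for (a, b), aln in alignments.items()},
                [(f"{focal}|{g}", f"{other}|{g}") for g in shared])
            all_calls.extend(calls)
        calls_df = pd.DataFrame([{
            "intron_a": c.intron_a, "intron_b": c.intron_b,
            "species_a": c.species_a, "species_b": c.species_b,
            "column_a": c.column_a, "column_b": c.column_b,
            "phase_a": c.phase_a, "phase_b": c.phase_b,
            "conserved": c.conserved} for c in all_calls])
        _write_tsv(calls_df, os.path.join(config.out_dir, "homology_calls.tsv"),
                   outputs)
        labels = intron_homology.classify_lineage_specificity(
            all_calls, tree, focal, set(config.outgroup_species),
            _with_prefixed_ids(catalogs[focal], focal))
        labels_df = pd.DataFrame(sorted(labels.items()),
                                 columns=["intron", "label"])
        _write_tsv(labels_df, os.path.join(config.out_dir, "lineage_labels.tsv"),
                   outputs)
        report["lineage_specific_fraction"] = (
            float(labels_df["label"].eq("lineage_specific").mean())
            if len(labels_df) else float("nan"))
        report["stages"].append("conservation")

    if "retention" in config.stages:
        focal = config.focal_species
        model_by_gene = {m.gene_id: m for m in models[focal]}
        consequences = [classify_retention(r, model_by_gene[r.gene_id],
                                           ptc_scope=config.ptc_scope)
                        for r in catalogs[focal]]
        cons_df = pd.DataFrame([{
            "intron": c.intron_key, "causes_frameshift": c.causes_frameshift,
            "introduces_ptc": c.introduces_ptc, "category": c.category,
            "first_stop_offset": c.first_stop_offset} for c in consequences])
        _write_tsv(cons_df, os.path.join(config.out_dir, "consequences.tsv"),
                   outputs)
        if consequences:
            summary = summarize_consequences(consequences)
            _write_tsv(pd.DataFrame([summary]),
                       os.path.join(config.out_dir, "retention_summary.tsv"),
                       outputs)
            report["retention_summary"] = summary
        report["stages"].append("retention")

    if "diffsplice" in config.stages:
        long = pd.read_csv(os.path.join(config.cohort_dir, "counts.tsv"), sep="\t")
        table = SplicingCountTable.from_frame(long)
        filtered = filter_junctions(
            table, mean_cov_min=config.mean_cov_min,
            min_detected_samples=config.min_detected_samples,
            exon_cov_min=config.exon_cov_min,
            intron_cov_min=config.intron_cov_min)
        calls = test_differential(filtered, stat_threshold=config.stat_threshold,
                                  fdr=config.fdr, n_null=config.n_null,
                                  seed=config.seed)
        _write_tsv(calls_to_frame(calls),
                   os.path.join(config.out_dir, "differential_introns.tsv"),
                   outputs)
        report["n_differential"] = int(sum(c.significant for c in calls))
        # gene-level expression proxy: summed junction totals per gene
        truth_in = pd.read_csv(os.path.join(config.cohort_dir, "truth",
                                            "intron_characters.tsv"), sep="\t")
        gene_of = dict(zip(truth_in["char_id"], truth_in["gene"]))
        totals = table.spliced + table.retained
        totals["gene"] = [gene_of.get(i, i) for i in totals.index]
        gene_counts = totals.groupby("gene").sum()
        de = call_de_genes(gene_counts, table.conditions,
                           fold_change_min=config.fold_change_min)
        _write_tsv(de, os.path.join(config.out_dir, "de_genes.tsv"), outputs)
        report["n_de_genes"] = int(de["called"].sum())
        report["stages"].append("diffsplice")

    config_record = asdict(config)
    # record path basenames so identical runs in different directories
    # produce byte-identical manifests (hash-stability contract)
    for key in ("cohort_dir", "out_dir"):
        config_record[key] = os.path.basename(config_record[key].rstrip("/"))
    manifest = {
        "config": config_record,
        "outputs": {os.path.relpath(p, config.out_dir): _sha256(p)
                    for p in sorted(outputs)},
        "report": {k: v for k, v in report.items() if k != "stages"},
        "stages_run": report["stages"],
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return report


def _with_prefixed_ids(catalog, species: str):
    """Copies of intron records whose gene ids carry a species prefix, so
    identically named orthologs from different species stay distinct in
    alignment/e call keying."""
    from dataclasses import replace
    return [replace(r, gene_id=f"{species}|{r.gene_id}") for r in catalog]
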