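"""End-to-end comparative pipeline.

Stages (each independently re-runnable through the CLI):

1. tetranucleotide signature matrix + signature dendrogram
2. proteome clustering, presence/absence matrix, Jaccard proteome tree
3. pangenome partitions (cluster universe and annotation-label universe)
4. per-family variability table + conserved/variable core classification
5. endolysin-holin architecture calls
6. endolysin gene tree + UniFrac and parsimony permutation tests against
   host and architecture labels

Outputs are pure functions of (inputs, thresholds, seed); a rerun with the
same configuration reproduces every artifact byte for byte.  The manifest
additionally records versions and stage timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .align import center_star_msa, filter_columns
from .clustering import (
    classify_core,
    family_variability,
    greedy_cluster,
    pangenome_partition,
    presence_absence,
    proteome_tree,
)
from .context import classify_lysis_architecture, is_endolysin, write_architecture_calls
from .errors import PipelineError
from .phylo import (
    neighbor_joining,
    p_distance_matrix,
    permutation_test,
    read_trait_table,
    write_newick,
)
from .seqio import read_fasta, read_feature_table
from .signatures import signature_matrix, signature_tree, tetra_zscores
from .synth import Community, SyntheticConfig, generate_community

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: Path
    seed: int
    synth: SyntheticConfig | None = None
    genomes_fasta: Path | None = None
    proteins_fasta: Path | None = None
    feature_tables: list[Path] = field(default_factory=list)
    host_traits: Path | None = None
    cluster_threshold: float = 0.40
    conserved_cutoff_pct: float = 92.0
    column_filter: float = 0.10
    linkage: str = "complete"
    n_perm: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.cluster_threshold <= 1:
            raise ValueError("cluster_threshold must be in (0, 1]")
        if not 0 <= self.conserved_cutoff_pct <= 100:
            raise ValueError("conserved_cutoff_pct must be in [0, 100]")
        if not 0 <= self.column_filter < 1:
            raise ValueError("column_filter must be in [0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.synth is None and (
            self.genomes_fasta is None
            or self.proteins_fasta is None
            or not self.feature_tables
        ):
            raise ValueError(
                "either a synthetic config or genomes+proteins+features paths required"
            )


def _load_inputs(config: RunConfig):
    if config.synth is not None:
        community = generate_community(config.synth)
        host_labels = dict(community.truth.genome_to_group)
        return (
            community.genomes,
            community.proteins,
            community.annotations,
            host_labels,
        )
    genomes = read_fasta(config.genomes_fasta, alphabet="nucleotide")
    proteins = read_fasta(config.proteins_fasta, alphabet="protein")
    annotations = {}
    for p in config.feature_tables:
        ann = read_feature_table(p)
        annotations[ann.genome_id] = ann
    host_labels = read_trait_table(config.host_traits) if config.host_traits else None
    return genomes, proteins, annotations, host_labels


def _write_matrix_tsv(ids, matrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(ids)) + "\n")
        for name, row in zip(ids, matrix):
            fh.write("\t".join([name] + [f"{v:.6g}" for v in row]) + "\n")


class _Stage:
    """Context manager: logs timing, converts failures to PipelineError,
    and marks half-written artifacts with a .partial suffix."""

    def __init__(self, name: str, timings: dict, outdir: Path):
        self.name = name
        self.timings = timings
        self.outdir = outdir
        self.artifacts: list[Path] = []

    def emit(self, path: Path) -> Path:
        self.artifacts.append(path)
        return path

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc is None:
            self.timings[self.name] = elapsed
            logger.info("stage %s: done in %.2fs", self.name, elapsed)
            return False
        for artifact in self.artifacts:
            if artifact.exists():
                artifact.rename(artifact.with_suffix(artifact.suffix + ".partial"))
        raise PipelineError(self.name, exc) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return artifact paths plus headline results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    results: dict = {}

    genomes, proteins, annotations, host_labels = _load_inputs(config)
    gene_to_genome = {
        f.gene_id: gid for gid, ann in annotations.items() for f in ann.features
    }
    protein_seqs = {p.id: p.residues for p in proteins}

    with _Stage("signatures", timings, outdir) as stage:
        sigs = [tetra_zscores(g.residues, genome_id=g.id) for g in genomes]
        mat = signature_matrix(sigs)
        path = stage.emit(outdir / "signature_correlations.tsv")
        _write_matrix_tsv(mat.ids, mat.r, path)
        artifacts["signature_matrix"] = path.name
        tree = signature_tree(sigs, linkage=config.linkage)
        path = stage.emit(outdir / "signature_tree.nwk")
        path.write_text(write_newick(tree))
        artifacts["signature_tree"] = path.name
        results["signature_tree"] = write_newick(tree).strip()

    with _Stage("clustering", timings, outdir) as stage:
        clusters = greedy_cluster(proteins, threshold=config.cluster_threshold)
        path = stage.emit(outdir / "clusters.tsv")
        with open(path, "w") as fh:
            fh.write("cluster_id\trepresentative\tmember\tgenome\n")
            for idx, cluster in enumerate(clusters.clusters):
                for member in cluster.members:
                    fh.write(
                        f"C{idx + 1:04d}\t{cluster.representative}\t{member}\t"
                        f"{gene_to_genome[member]}\n"
                    )
        artifacts["clusters"] = path.name
        pa = presence_absence(clusters, gene_to_genome)
        path = stage.emit(outdir / "presence_absence.tsv")
        pa.table.astype(int).to_csv(path, sep="\t")
        artifacts["presence_absence"] = path.name
        ptree = proteome_tree(pa, linkage=config.linkage)
        path = stage.emit(outdir / "proteome_tree.nwk")
        path.write_text(write_newick(ptree))
        artifacts["proteome_tree"] = path.name
        results["n_clusters"] = len(clusters)
        results["proteome_tree"] = write_newick(ptree).strip()

    with _Stage("pangenome", timings, outdir) as stage:
        cluster_universe = {
            c.representative: {gene_to_genome[m] for m in c.members}
            for c in clusters.clusters
        }
        label_universe: dict[str, set] = {}
        for gid, ann in annotations.items():
            for f in ann.features:
                for lab in f.family_labels:
                    label_universe.setdefault(lab, set()).add(gid)
        report = {}
        for name, universe in (
            ("clusters", cluster_universe),
            ("family_labels", label_universe),
        ):
            if not universe:
                continue
            part = pangenome_partition(universe, ids=sorted(annotations))
            report[name] = {
                "counts": part.counts(),
                "core": part.core,
                "cells": {
                    "+".join(sorted(cell)): fams for cell, fams in part.cells.items()
                },
            }
        path = stage.emit(outdir / "pangenome.json")
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        artifacts["pangenome"] = path.name
        results["core_clusters"] = len(report["clusters"]["core"])

    with _Stage("variability", timings, outdir) as stage:
        family_members: dict[str, list] = {}
        for gid, ann in annotations.items():
            for f in ann.features:
                for lab in f.family_labels:
                    seq = protein_seqs.get(f.gene_id)
                    if seq is not None:
                        family_members.setdefault(lab, []).append(
                            (f.gene_id, gid, seq)
                        )
        profiles = [
            family_variability(fam, members)
            for fam, members in sorted(family_members.items())
            if len(members) >= 2
        ]
        classify_core(
            profiles,
            genome_count=len(annotations),
            conserved_cutoff_pct=config.conserved_cutoff_pct,
        )
        path = stage.emit(outdir / "family_variability.tsv")
        with open(path, "w") as fh:
            fh.write("family\tn_members\tn_genomes\tmin_identity_pct\tclass\n")
            for pr in profiles:
                fh.write(
                    f"{pr.family_id}\t{len(pr.gene_ids)}\t{len(pr.genomes)}\t"
                    f"{pr.min_identity_pct:.2f}\t{pr.cls}\n"
                )
        artifacts["family_variability"] = path.name
        path = stage.emit(outdir / "pairwise_identities.tsv")
        with open(path, "w") as fh:
            fh.write("family\tidentity_pct\n")
            for pr in profiles:
                for v in pr.pairwise_identity_pct:
                    fh.write(f"{pr.family_id}\t{v:.2f}\n")
        artifacts["pairwise_identities"] = path.name
        results["core_classes"] = {pr.family_id: pr.cls for pr in profiles}

    with _Stage("architecture", timings, outdir) as stage:
        calls = [
            classify_lysis_architecture(annotations[gid])
            for gid in sorted(annotations)
        ]
        path = stage.emit(outdir / "architecture_calls.tsv")
        write_architecture_calls(calls, path)
        artifacts["architecture_calls"] = path.name
        arch_labels = {c.genome_id: c.label for c in calls}
        results["architecture"] = arch_labels

    with _Stage("phylostats", timings, outdir) as stage:
        endo_ids, endo_seqs = [], []
        for gid in sorted(annotations):
            for f in annotations[gid].features:
                if is_endolysin(f) and f.gene_id in protein_seqs:
                    endo_ids.append(gid)
                    endo_seqs.append(protein_seqs[f.gene_id])
        if len(endo_ids) < 3:
            raise ValueError("need >= 3 endolysin sequences for a gene tree")
        msa = center_star_msa(endo_seqs, ids=endo_ids)
        filtered = filter_columns(msa, min_conservation=config.column_filter)
        tree = neighbor_joining(p_distance_matrix(filtered))
        path = stage.emit(outdir / "endolysin_tree.nwk")
        path.write_text(write_newick(tree))
        artifacts["endolysin_tree"] = path.name
        tests = {}
        label_sets = {"architecture": arch_labels}
        if host_labels is not None:
            label_sets["host"] = host_labels
        for label_name, labels in sorted(label_sets.items()):
            if len({labels[g] for g in endo_ids}) < 2:
                logger.warning(
                    "skipping %s tests: fewer than 2 distinct labels", label_name
                )
                continue
            for statistic in ("unifrac", "fitch"):
                res = permutation_test(
                    tree,
                    {g: labels[g] for g in endo_ids},
                    statistic=statistic,
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
                tests[f"{label_name}_{statistic}"] = res.to_dict()
        path = stage.emit(outdir / "association_tests.json")
        path.write_text(json.dumps(tests, indent=2, sort_keys=True))
        artifacts["association_tests"] = path.name
        results["association_tests"] = tests

    manifest = {
        "package": "phagecompare",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "thresholds": {
            "cluster_threshold": config.cluster_threshold,
            "conserved_cutoff_pct": config.conserved_cutoff_pct,
            "column_filter": config.column_filter,
        },
        "linkage": config.linkage,
        "n_perm": config.n_perm,
        "artifacts": artifacts,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["artifacts"] = {k: str(outdir / v) for k, v in artifacts.items()}
    results["manifest"] = str(outdir / "manifest.json")
    return results
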