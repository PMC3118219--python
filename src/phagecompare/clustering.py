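"""Proteome clustering, pangenome partitions, and core-genome classification.

Greedy incremental clustering in the style of CD-HIT: sequences are sorted
by decreasing length (ties broken by id) and each sequence joins the first
existing cluster whose representative it matches at or above the identity
threshold, computed over the shorter sequence's length; otherwise it founds
a new cluster.  Representatives are therefore always the longest member.

Presence/absence of clusters across genomes feeds a Jaccard-distance
proteome dendrogram; gene families present in every genome form the core
genome, split into a conserved core (minimum pairwise identity at or above
the cutoff, default 92% = a maximum pairwise difference of 8%) and a
variable core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import global_align, identity_over_shorter
from .errors import AlignmentError, FormatError
from .seqio import SequenceRecord

DEFAULT_CLUSTER_THRESHOLD = 0.40
DEFAULT_CONSERVED_CUTOFF_PCT = 92.0


@dataclass
class Cluster:
    representative: str
    members: list[str]


@dataclass
class ClusterSet:
    threshold: float
    clusters: list[Cluster]
    gene_to_cluster: dict[str, int]

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class PresenceAbsenceMatrix:
    """Boolean genome x cluster occupancy table."""

    table: pd.DataFrame  # index: genome ids, columns: cluster ids (representatives)

    @property
    def genomes(self) -> list[str]:
        return list(self.table.index)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.table.columns)

    def present(self, genome: str) -> set[str]:
        row = self.table.loc[genome]
        return set(row.index[row])


@dataclass
class PangenomePartition:
    """Each family assigned to the exact subset of genomes/groups holding it."""

    ids: list[str]  # genomes or groups
    cells: dict[frozenset, list[str]]

    @property
    def core(self) -> list[str]:
        return self.cells.get(frozenset(self.ids), [])

    def counts(self) -> dict[str, int]:
        return {
            "+".join(sorted(cell)): len(fams) for cell, fams in self.cells.items()
        }


@dataclass
class FamilyVariabilityProfile:
    family_id: str
    gene_ids: list[str]
    genomes: set[str]
    pairwise_identity_pct: list[float]
    min_identity_pct: float
    cls: str | None = None  # conserved_core | variable_core | accessory


def greedy_cluster(
    proteins: Sequence[SequenceRecord],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    **align_kwargs,
) -> ClusterSet:
    """Greedy incremental identity clustering of a proteome.

    Deterministic for a given input set: the sort order (length descending,
    id ascending) fixes both the founding order of clusters and the
    first-qualifying-representative assignment rule.
    """
    if not proteins:
        raise FormatError("cannot cluster an empty protein set")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate protein ids in clustering input")
    ordered = sorted(proteins, key=lambda p: (-len(p.residues), p.id))
    clusters: list[Cluster] = []
    reps: list[str] = []  # representative sequences
    gene_to_cluster: dict[str, int] = {}
    for rec in ordered:
        assigned = False
        for idx, rep_seq in enumerate(reps):
            if rec.residues == rep_seq:
                identity = 100.0
            else:
                identity = identity_over_shorter(
                    global_align(rep_seq, rec.residues, **align_kwargs)
                )
            if identity >= threshold * 100.0:
                clusters[idx].members.append(rec.id)
                gene_to_cluster[rec.id] = idx
                assigned = True
                break
        if not assigned:
            clusters.append(Cluster(representative=rec.id, members=[rec.id]))
            reps.append(rec.residues)
            gene_to_cluster[rec.id] = len(clusters) - 1
    return ClusterSet(
        threshold=threshold, clusters=clusters, gene_to_cluster=gene_to_cluster
    )


def presence_absence(
    clusters: ClusterSet, gene_to_genome: Mapping[str, str]
) -> PresenceAbsenceMatrix:
    """Genome x cluster boolean occupancy from cluster membership."""
    for cluster in clusters.clusters:
        for gene in cluster.members:
            if gene not in gene_to_genome:
                raise FormatError(f"gene {gene!r} has no genome mapping")
    genomes = sorted(set(gene_to_genome[g] for c in clusters.clusters for g in c.members))
    data = {}
    for cluster in clusters.clusters:
        present = {gene_to_genome[g] for g in cluster.members}
        data[cluster.representative] = [g in present for g in genomes]
    table = pd.DataFrame(data, index=genomes, dtype=bool)
    return PresenceAbsenceMatrix(table=table)


def jaccard_distance(pa: PresenceAbsenceMatrix, genome_a: str, genome_b: str) -> float:
    """1 - |A n B| / |A u B| over the two genomes' cluster sets."""
    a, b = pa.present(genome_a), pa.present(genome_b)
    union = a | b
    if not union:
        raise FormatError(
            f"genomes {genome_a!r} and {genome_b!r} both have empty cluster sets"
        )
    return 1.0 - len(a & b) / len(union)


def proteome_tree(pa: PresenceAbsenceMatrix, linkage: str = "complete"):
    """Agglomerative genome dendrogram on pairwise Jaccard distances."""
    from skbio import DistanceMatrix

    from .phylo import hierarchical_tree

    genomes = pa.genomes
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes for a proteome tree")
    n = len(genomes)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = jaccard_distance(pa, genomes[i], genomes[j])
    return hierarchical_tree(DistanceMatrix(d, ids=genomes), linkage=linkage)


def pangenome_partition(
    family_to_members: Mapping[str, Iterable[str]],
    ids: Sequence[str] | None = None,
) -> PangenomePartition:
    """Partition families by the exact subset of genomes (or groups) holding them.

    ``family_to_members`` maps each family to the genomes/groups it occurs
    in.  Families land in exactly one Venn cell; the "core" cell is the one
    containing every id.
    """
    if not family_to_members:
        raise FormatError("empty family universe")
    occupancy = {f: frozenset(m) for f, m in family_to_members.items()}
    all_ids = sorted(set().union(*occupancy.values())) if ids is None else list(ids)
    if len(all_ids) < 2:
        raise ValueError("a pangenome partition needs at least 2 sets")
    cells: dict[frozenset, list[str]] = {}
    for fam in sorted(occupancy):
        subset = occupancy[fam]
        if not subset:
            raise FormatError(f"family {fam!r} occurs in no genome")
        cells.setdefault(subset, []).append(fam)
    return PangenomePartition(ids=all_ids, cells=cells)


def family_variability(
    family_id: str,
    members: Sequence[tuple[str, str, str]],
    **align_kwargs,
) -> FamilyVariabilityProfile:
    """All pairwise identities within one family.

    ``members`` is a sequence of (gene_id, genome_id, protein_sequence).
    Identity follows the pairwise-alignment convention (alignment columns,
    terminal gaps excluded), matching full-length protein comparisons.
    """
    if len(members) < 2:
        raise AlignmentError(
            f"family {family_id!r} needs >= 2 members for variability analysis"
        )
    identities: list[float] = []
    for (_, _, seq_a), (_, _, seq_b) in combinations(members, 2):
        if seq_a == seq_b:
            identities.append(100.0)
        else:
            identities.append(global_align(seq_a, seq_b, **align_kwargs).identity_pct)
    return FamilyVariabilityProfile(
        family_id=family_id,
        gene_ids=[m[0] for m in members],
        genomes={m[1] for m in members},
        pairwise_identity_pct=identities,
        min_identity_pct=min(identities),
    )


def classify_core(
    profiles: Sequence[FamilyVariabilityProfile],
    genome_count: int,
    conserved_cutoff_pct: float = DEFAULT_CONSERVED_CUTOFF_PCT,
) -> list[FamilyVariabilityProfile]:
    """Label families conserved_core / variable_core / accessory.

    A family is core only if present in all ``genome_count`` genomes; core
    families with minimum pairwise identity at or above the cutoff are the
    conserved core, the rest the variable core.
    """
    for profile in profiles:
        if len(profile.genomes) < genome_count:
            profile.cls = "accessory"
        elif profile.min_identity_pct >= conserved_cutoff_pct:
            profile.cls = "conserved_core"
        else:
            profile.cls = "variable_core"
    return list(profiles)
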