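"""Synthetic phage communities with known ground truth.

The generator emulates the statistical structure a comparative phage
analysis assumes, so every downstream stage can be exercised offline:

* host groups with distinct genome composition, via group-specific order-2
  Markov background models and group-specific codon choice when coding
  sequences are back-translated;
* a conserved core of near-identical protein families, including an
  invariant holin (per-site substitution rate 0);
* a variable core whose families each carry two very distinct sequence
  types ("genotypes"); the endolysin's two genotypes diverge mostly within
  a hypervariable N-terminal block (the enzymatically active domain), and
  the endolysin's genotype assignment deliberately crosses host groups
  while the other variable families follow them;
* accessory families homed to one host group and present in its genomes
  with a Bernoulli probability;
* an endolysin-holin gene pair placed adjacently with a per-group
  arrangement (holin upstream = typical, holin downstream = reversed).

All randomness flows through one seeded generator in a fixed order, so a
community is byte-reproducible from its configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .errors import GeneratorError
from .seqio import (
    FeatureRecord,
    GenomeAnnotation,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_feature_table,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

ENDOLYSIN_FAMILY = "PF01520"
HOLIN_FAMILY = "PF04531"

_VARIABLE_PRODUCTS = [
    "tail tape measure protein",
    "thymidylate synthase",
    "P22 coat protein",
    "hypothetical protein",
]

# codon back-table for translation table 11, stops excluded
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE11.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic community."""

    seed: int
    n_host_groups: int = 2
    genomes_per_group: int = 3
    genome_length: int = 40_000
    markov_order: int = 2
    group_bias: float = 0.10
    n_conserved_core: int = 12
    conserved_divergence: float = 0.015
    n_variable_core: int = 5
    n_genotypes_per_variable_family: int = 2
    ead_fraction: float = 0.45
    ead_rate: float = 0.40
    cbd_rate: float = 0.05
    n_accessory: int = 20
    accessory_presence_prob: float = 0.80
    architectures: list[str] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise GeneratorError("a seed is mandatory")
        if self.markov_order != 2:
            raise GeneratorError("only order-2 background models are supported")
        for name in (
            "group_bias",
            "conserved_divergence",
            "ead_rate",
            "cbd_rate",
            "ead_fraction",
            "accessory_presence_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorError(f"{name}={v} outside [0, 1]")
        if self.genome_length <= 0 or self.genomes_per_group <= 0:
            raise GeneratorError("lengths and counts must be positive")
        if self.n_host_groups < 1:
            raise GeneratorError("need at least one host group")
        if self.architectures is None:
            self.architectures = ["holin_downstream"] + ["holin_upstream"] * (
                self.n_host_groups - 1
            )
        if len(self.architectures) != self.n_host_groups:
            raise GeneratorError("one architecture label per host group required")


@dataclass
class SyntheticTruth:
    genome_to_group: dict[str, str]
    family_class: dict[str, str]
    genotype: dict[str, dict[str, int]]
    architecture: dict[str, str]


@dataclass
class Community:
    config: SyntheticConfig
    genomes: list[SequenceRecord]
    proteins: list[SequenceRecord]
    annotations: dict[str, GenomeAnnotation]
    truth: SyntheticTruth
    gene_to_genome: dict[str, str] = field(default_factory=dict)
    gene_to_family: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_markov_genome(model: np.ndarray, length: int, seed) -> str:
    """Sample a nucleotide sequence from an order-2 Markov model.

    ``model`` is a (16, 4) row-stochastic table: row 4*i + j gives the
    distribution of the next base after context (base_i, base_j).
    """
    model = np.asarray(model, dtype=float)
    if model.shape != (16, 4):
        raise GeneratorError("order-2 model must have shape (16, 4)")
    if not np.allclose(model.sum(axis=1), 1.0, atol=1e-9):
        raise GeneratorError("transition table rows must sum to 1")
    if (model < 0).any():
        raise GeneratorError("transition probabilities must be non-negative")
    if length < 3:
        raise GeneratorError("length must be at least 3")
    rng = _as_rng(seed)
    cum = np.cumsum(model, axis=1)
    uniforms = rng.random(length)
    bases = np.empty(length, dtype=np.int64)
    bases[0] = int(uniforms[0] * 4)
    bases[1] = int(uniforms[1] * 4)
    ctx = bases[0] * 4 + bases[1]
    for i in range(2, length):
        nxt = int(np.searchsorted(cum[ctx], uniforms[i], side="right"))
        nxt = min(nxt, 3)
        bases[i] = nxt
        ctx = (ctx * 4 + nxt) % 16
    return "".join("ACGT"[b] for b in bases)


def random_protein(length: int, seed) -> str:
    rng = _as_rng(seed)
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def evolve_family(
    ancestor: str,
    per_site_rate: float,
    n_copies: int,
    region_rates: Sequence[tuple[tuple[int, int], float]] | None = None,
    seed=None,
) -> list[str]:
    """Independently mutated copies of an ancestral protein.

    Each copy receives i.i.d. substitutions to a uniformly chosen different
    residue at ``per_site_rate`` per site; ``region_rates`` overrides the
    rate inside 1-based inclusive blocks.  Two copies are expected to agree
    at a site with probability (1-r)^2 + r^2/19.
    """
    if not 0.0 <= per_site_rate < 1.0:
        raise GeneratorError("per_site_rate must be in [0, 1)")
    rng = _as_rng(seed)
    length = len(ancestor)
    rates = np.full(length, per_site_rate)
    for (start, end), rate in region_rates or []:
        if not (1 <= start <= end <= length):
            raise GeneratorError(
                f"region ({start}, {end}) outside sequence of length {length}"
            )
        if not 0.0 <= rate < 1.0:
            raise GeneratorError("region rate must be in [0, 1)")
        rates[start - 1 : end] = rate
    copies = []
    anc = np.frombuffer(ancestor.encode("ascii"), dtype=np.uint8).copy()
    for _ in range(n_copies):
        copy = anc.copy()
        mutate = rng.random(length) < rates
        for pos in np.nonzero(mutate)[0]:
            choices = [aa for aa in AA20 if ord(aa) != copy[pos]]
            copy[pos] = ord(choices[rng.integers(0, len(choices))])
        copies.append(copy.tobytes().decode("ascii"))
    return copies


def _group_models(n_groups: int, bias: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-group order-2 models: uniform background mixed with a
    group-specific Dirichlet tilt at weight ``bias``."""
    models = []
    for _ in range(n_groups):
        tilt = rng.dirichlet(np.ones(4), size=16)
        models.append((1.0 - bias) * np.full((16, 4), 0.25) + bias * tilt)
    return models


def _codon_table(model: np.ndarray) -> dict[str, str]:
    """Most-probable codon per amino acid under the model's base marginals.

    Back-translating with group-preferred codons keeps coding regions
    carrying the group's composition signature.
    """
    q = np.asarray(model).mean(axis=0)
    base_index = {b: i for i, b in enumerate("ACGT")}

    def score(codon: str) -> float:
        return float(np.prod([q[base_index[c]] for c in codon]))

    return {aa: max(codons, key=score) for aa, codons in _CODONS_BY_AA.items()}


def back_translate(protein: str, codon_table: dict[str, str]) -> str:
    try:
        return "".join(codon_table[aa] for aa in protein)
    except KeyError as exc:
        raise GeneratorError(f"cannot back-translate residue {exc}") from exc


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------

@dataclass
class _Family:
    family_id: str
    product: str
    cls: str  # conserved_core | variable_core | accessory
    members: dict[str, str]  # genome_id -> protein sequence
    genotypes: dict[str, int] | None = None


def _conserved_families(config: SyntheticConfig, genome_ids, rng) -> list[_Family]:
    families = []
    for i in range(config.n_conserved_core):
        if i == 0:
            family_id, product, length, rate = HOLIN_FAMILY, "holin", 130, 0.0
        else:
            family_id = f"PFC{i + 1:03d}"
            product = "conserved phage protein"
            length = int(rng.integers(150, 401))
            rate = config.conserved_divergence
        ancestor = random_protein(length, rng)
        copies = evolve_family(ancestor, rate, len(genome_ids), seed=rng)
        families.append(
            _Family(family_id, product, "conserved_core", dict(zip(genome_ids, copies)))
        )
    return families


def _variable_families(
    config: SyntheticConfig, genome_ids, genome_group: dict[str, int], rng
) -> list[_Family]:
    families = []
    k = config.n_genotypes_per_variable_family
    for i in range(config.n_variable_core):
        members: dict[str, str] = {}
        genotypes: dict[str, int] = {}
        if i == 0:
            # the endolysin: two genotypes diverged mostly within the
            # N-terminal enzymatically-active block, host-discordant
            family_id, product = ENDOLYSIN_FAMILY, (
                "endolysin, N-acetylmuramoyl-L-alanine amidase"
            )
            length = 350
            ead_end = max(1, round(config.ead_fraction * length))
            ancestor = random_protein(length, rng)
            founders = [
                evolve_family(
                    ancestor,
                    config.cbd_rate,
                    1,
                    region_rates=[((1, ead_end), config.ead_rate)],
                    seed=rng,
                )[0]
                for _ in range(k)
            ]
            within_group_index: dict[int, int] = {}
            for gid in genome_ids:
                g = genome_group[gid]
                j = within_group_index.get(g, 0)
                within_group_index[g] = j + 1
                genotypes[gid] = 0 if j == 0 else 1 % k
        else:
            family_id = f"PFV{i + 1:03d}"
            product = _VARIABLE_PRODUCTS[(i - 1) % len(_VARIABLE_PRODUCTS)]
            length = int(rng.integers(200, 401))
            founders = [random_protein(length, rng) for _ in range(k)]
            for gid in genome_ids:
                genotypes[gid] = genome_group[gid] % k
        for gid in genome_ids:
            members[gid] = evolve_family(
                founders[genotypes[gid]], config.conserved_divergence, 1, seed=rng
            )[0]
        families.append(
            _Family(family_id, product, "variable_core", members, genotypes)
        )
    return families


def _accessory_families(
    config: SyntheticConfig, genome_ids, genome_group: dict[str, int], rng
) -> list[_Family]:
    families = []
    for i in range(config.n_accessory):
        family_id = f"PFA{i + 1:03d}"
        home = i % config.n_host_groups
        ancestor = random_protein(int(rng.integers(100, 301)), rng)
        home_genomes = [g for g in genome_ids if genome_group[g] == home]
        flags = rng.random(len(home_genomes)) < config.accessory_presence_prob
        present = [g for g, keep in zip(home_genomes, flags) if keep]
        if not present:
            present = [home_genomes[0]]
        copies = evolve_family(
            ancestor, config.conserved_divergence, len(present), seed=rng
        )
        families.append(
            _Family(family_id, "accessory protein", "accessory", dict(zip(present, copies)))
        )
    return families


def generate_community(config: SyntheticConfig) -> Community:
    """Generate genomes, proteomes, feature tables, and ground truth."""
    rng = np.random.default_rng(config.seed)
    n_groups = config.n_host_groups
    group_names = [chr(ord("A") + g) for g in range(n_groups)]
    genome_ids = [
        f"phage{group_names[g]}{j + 1}"
        for g in range(n_groups)
        for j in range(config.genomes_per_group)
    ]
    genome_group = {
        gid: g
        for g in range(n_groups)
        for gid in genome_ids[
            g * config.genomes_per_group : (g + 1) * config.genomes_per_group
        ]
    }

    models = _group_models(n_groups, config.group_bias, rng)
    codon_tables = [_codon_table(m) for m in models]

    conserved = _conserved_families(config, genome_ids, rng)
    variable = _variable_families(config, genome_ids, genome_group, rng)
    accessory = _accessory_families(config, genome_ids, genome_group, rng)
    holin, other_conserved = conserved[0], conserved[1:]
    endolysin, other_variable = variable[0], variable[1:]

    # per-genome accessory strand choices and intergenic gaps are drawn in a
    # fixed genome order to keep the community reproducible
    genomes: list[SequenceRecord] = []
    proteins: list[SequenceRecord] = []
    annotations: dict[str, GenomeAnnotation] = {}
    gene_to_genome: dict[str, str] = {}
    gene_to_family: dict[str, str] = {}

    for gid in genome_ids:
        g = genome_group[gid]
        arch = config.architectures[g]
        if arch == "holin_downstream":
            lysis_pair = [endolysin, holin]
        elif arch == "holin_upstream":
            lysis_pair = [holin, endolysin]
        else:
            raise GeneratorError(f"unknown architecture {arch!r}")
        ordered = (
            other_conserved
            + lysis_pair
            + other_variable
            + [f for f in accessory if gid in f.members]
        )
        background = generate_markov_genome(models[g], config.genome_length, rng)
        genome_chars = list(background)
        features: list[FeatureRecord] = []
        pos = 1 + int(rng.integers(100, 400))
        for fam in ordered:
            protein = fam.members[gid]
            if fam.cls == "accessory":
                strand = "-" if rng.random() < 0.3 else "+"
            else:
                strand = "+"
            cds = back_translate(protein, codon_tables[g]) + "TAA"
            start, end = pos, pos + len(cds) - 1
            if end > config.genome_length:
                raise GeneratorError(
                    f"genes exceed genome length {config.genome_length} in {gid}; "
                    "increase genome_length"
                )
            placed = cds if strand == "+" else reverse_complement(cds)
            genome_chars[start - 1 : end] = list(placed)
            gene_id = f"{gid}_{fam.family_id}"
            features.append(
                FeatureRecord(
                    genome_id=gid,
                    gene_id=gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=fam.product,
                    family_labels=[fam.family_id],
                )
            )
            proteins.append(
                SequenceRecord(
                    gene_id, protein, description=fam.product, alphabet="protein"
                )
            )
            gene_to_genome[gene_id] = gid
            gene_to_family[gene_id] = fam.family_id
            pos = end + 1 + int(rng.integers(30, 200))
        genomes.append(
            SequenceRecord(gid, "".join(genome_chars), alphabet="nucleotide")
        )
        annotations[gid] = GenomeAnnotation(genome_id=gid, features=features)

    truth = SyntheticTruth(
        genome_to_group={gid: group_names[genome_group[gid]] for gid in genome_ids},
        family_class={
            f.family_id: f.cls for f in conserved + variable + accessory
        },
        genotype={
            f.family_id: dict(f.genotypes) for f in variable if f.genotypes is not None
        },
        architecture={
            gid: config.architectures[genome_group[gid]] for gid in genome_ids
        },
    )
    return Community(
        config=config,
        genomes=genomes,
        proteins=proteins,
        annotations=annotations,
        truth=truth,
        gene_to_genome=gene_to_genome,
        gene_to_family=gene_to_family,
    )


def write_community(community: Community, outdir: str | Path) -> dict[str, Path]:
    """Write genomes/proteins FASTA, per-genome GFF3 subset, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": outdir / "genomes.fasta",
        "proteins": outdir / "proteins.fasta",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    write_fasta(community.genomes, paths["genomes"])
    write_fasta(community.proteins, paths["proteins"])
    for gid, annotation in community.annotations.items():
        p = outdir / f"{gid}.gff3"
        write_feature_table(annotation, p)
        paths[f"features:{gid}"] = p
    paths["truth"].write_text(json.dumps(asdict(community.truth), indent=2, sort_keys=True))
    paths["config"].write_text(json.dumps(asdict(community.config), indent=2, sort_keys=True))
    return paths
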