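# Methods

`phagecompare` implements a comparative-genomics workflow for small
communities of related bacteriophage genomes: whole-genome composition
signatures, proteome-content dendrograms, core/accessory genome
designation, gene trees with permutation tests of trait association, and
lysis-module (endolysin-holin) architecture calling.  A seeded synthetic
community generator provides inputs with known ground truth so every stage
can be validated offline.  This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Tetranucleotide signatures

A genome's signature is the vector of z-scores of its 256 tetranucleotide
counts against a maximal-order Markov null.  For w = N1N2N3N4 with n(.)
observed counts of embedded shorter words:

    E(w)   = n(N1N2N3) n(N2N3N4) / n(N2N3)
    var(w) = E(w) (n(N2N3) - n(N1N2N3)) (n(N2N3) - n(N2N3N4)) / n(N2N3)^2
    z(w)   = (obs(w) - E(w)) / sqrt(var(w))

Because the null conditions on the genome's own di- and trinucleotide
composition, z-scores are insensitive to base composition per se and pick
up fourth-order structure: shared sequence, codon-usage idiosyncrasies,
repeats.  Both strands are counted by default (sequence and reverse
complement, counted separately, never across the junction), which makes
dual-mode signatures exactly invariant under reverse complementation; a
single-strand mode is retained for testing.  Windows containing `N` are
skipped; only `N` is accepted as an ambiguity code, other IUPAC codes are
rejected loudly.  Words with undefined or zero variance (absent subwords,
degenerate inputs) get z = 0 with a logged diagnostic rather than an
exception, keeping signatures finite on short inputs.

Genome relatedness is the Pearson correlation r over the 256 paired
z-scores (two-sided p from a t test with 254 df).  Dendrograms use the
simplest monotone transform d = 1 - r and agglomerative clustering
(complete linkage by default; average and single exposed).  Tie-breaking
among equidistant merge candidates follows scipy's deterministic order.

## Alignment and conservation

Pairwise alignment is global Needleman-Wunsch under BLOSUM62 with affine
gaps (open 10, extend 1; a gap run of length L costs 10 + (L-1)).  Two
identity denominators are used deliberately:

* **family variability** — alignment columns with terminal-gap columns
  excluded, softening length heterogeneity between full-length members;
* **greedy clustering** — the shorter sequence's length, the convention of
  greedy incremental clustering tools.

Among co-optimal alignments the first in Biopython's deterministic
enumeration is taken; the score is tie-invariant and identity differences
between co-optimal tracebacks are negligible for the divergences involved.
Published percent-identity values from other tools use unstated
denominators, so small discrepancies against such numbers are expected.

The multiple aligner is a documented center-star construction: the center
minimizes summed pairwise distance (d = 1 - identity/100) and other
sequences are merged against it under "once a gap, always a gap".
Downstream consumers (conservation profiles, p-distances, neighbor
joining) need consistent columns, not any particular heuristic aligner's
output.  Per-column conservation is the modal-residue fraction among
non-gap residues (all-gap columns score 0), and hypervariable columns are
removed by keeping columns with conservation strictly above 10% (the
strict inequality is configurable).

## Clustering and the pangenome

Proteomes are clustered greedily: sequences sorted by decreasing length
(ties by id) each join the first cluster whose representative matches at
>= 40% identity over the shorter sequence, else found a new cluster —
deterministic and input-order-invariant.  Presence/absence of clusters
across genomes gives Jaccard distances d = 1 - |A n B| / |A u B| and a
proteome dendrogram.  Pangenome Venn partitions are computed for both the
cluster universe and the annotation-label universe (family labels are
opaque tokens; database annotation is out of scope).

Core families (present in every genome) are split at a minimum pairwise
identity of 92% — i.e. a maximum pairwise difference of 8% — into a
conserved core and a variable core.  Both the 40% clustering threshold and
the 92% cutoff are exposed in configuration.

## Trees and permutation tests

Gene trees are neighbor joining (Saitou-Nei, Studier-Keppler Q criterion,
negative branch estimates clamped to 0) on p-distances with pairwise gap
deletion, computed on conservation-filtered alignment columns.  Maximum
likelihood is deliberately out of scope: NJ output is the tree of record.

The unweighted UniFrac statistic is the fraction of total branch length
(root branch excluded) on branches whose descendant tips carry exactly one
trait label.  For two labels this is the classic unique-vs-shared
branch-length fraction; the k-label generalization lets one test span many
host genera and recovers the pairwise definition at k = 2.  The parsimony
P-test uses the Fitch score (minimum label changes; multifurcations are
resolved arbitrarily with zero-length branches first, exact for binary
trees).  Significance comes from permuting tip labels preserving the label
multiset: UniFrac large-is-extreme, Fitch small-is-extreme.  Sampled mode
uses p = (1 + b) / (1 + n_perm), which cannot report p = 0; exhaustive
mode enumerates distinct label assignments and reports the exact fraction.
The permutation count is configurable (default 1000; no canonical value
exists), and results are bit-reproducible given (seed, n_perm).

## Architecture calls

The endolysin is located by family label (PF01520/COG0860) or product
regex; holins by PF04531 or product regex.  The immediate neighbor in the
transcription direction of the endolysin (annotated strand; minus-strand
genes read toward decreasing coordinates) determines the call:
`holin_downstream` (the reversed arrangement), `holin_upstream` (typical),
or `not_adjacent`.  Adjacency ignores intergenic distance by default
because "immediately adjacent" carries no bp cutoff in practice; an
optional `max_gap` imposes one.  Opposite-strand neighbors still count but
are flagged strand-discordant.  Calls are invariant under
reverse-complementing the whole genome.

## Synthetic communities

The generator emulates the features the analysis relies on; defaults are
the study conditions used by the test suite:

| parameter | default | why |
|---|---|---|
| host groups x genomes | 2 x 3 | smallest community exercising every stage |
| genome length | 40 kb | typical tailed-phage genome scale |
| group_bias | 0.10 | mixing weight of a group-specific Dirichlet tilt on an order-2 uniform background; >= 0.08 at 20 kb renders groups monophyletic |
| conserved core | 12 families | incl. an invariant holin (rate 0) |
| conserved_divergence | 0.015/site/copy | pairwise difference is ~2x the per-copy rate, so min pairwise identity lands ~95-96%, inside the conserved-core band and >= 2 points clear of the 92% cutoff |
| variable core | 5 families, 2 genotypes | genotypes from independent deep ancestors ("two very distinct sequence types") |
| endolysin | 350 aa, EAD = N-terminal 45% | genotype founders diverge at 0.40/site in the EAD vs 0.05 in the CBD, reproducing N-terminal hypervariability |
| accessory | 20 families, Bernoulli 0.8 | homed to one host group (see below) |

Design choices worth recording:

* **Back-translation** uses each group's preferred codon per amino acid
  (highest marginal base probability under the group's Markov model), so
  coding regions carry the group signature: conserved proteins are
  identical in amino acids across groups yet differ synonymously between
  them.  This is what makes the signature tree group-structured — an
  order-2 Markov background alone is exactly what the z-score null
  removes.
* **Accessory families are group-homed**: present only in their home
  group's genomes, each independently with probability 0.8 (at least one
  forced carrier).  Purely unstructured accessory content would leave the
  Jaccard tree with no host signal at all, since core families occupy
  every genome.
* **Genotype assignment**: non-endolysin variable families follow the host
  group; the endolysin's genotype deliberately crosses groups (first
  genome of each group carries genotype 0).  Variable-family gene trees
  therefore cluster by genotype, and the endolysin tree is discordant with
  the host grouping — the discordance pattern the pipeline is meant to
  expose.

What the generator does **not** emulate: realistic phage gene order beyond
the lysis module, recombination, indel evolution (substitutions only), and
annotation noise (family labels are exact).  Passing recovery tests
therefore shows the pipeline's inferences are correct when its modeling
assumptions hold, not that they are robust to misannotation or
rearrangement in real genomes.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive throughout (GFF3 convention).
* Signature correlation on a zero-variance signature raises rather than
  returning NaN.
* Hierarchical-tree branch lengths place children at half the merge
  height, so tips first joined at height h are at path distance h;
  ultrametric inputs are reproduced exactly under average linkage.
* Newick inputs without branch lengths parse with lengths defaulted to 0
  and a logged warning; tree statistics that need lengths raise.
* The type-I-error check uses the UniFrac statistic on random 20-tip trees
  with continuous branch lengths; the Fitch statistic is integer-valued
  and its permutation p-values are conservative by discreteness, which is
  expected behavior, not an error.

## Problem sizes

The validation suite runs communities of 4-6 genomes of 22-40 kb,
30-tip gene trees with 2000 permutations, and 200-replicate calibration
runs at 399 permutations each — sizes chosen so the full suite completes
in a few minutes on one CPU while every stage is exercised end to end.
Counts printed for any particular real dataset (numbers of shared
clusters, family-class tallies) depend on the genomes and annotation
database used and are recovered here structurally, on synthetic data, not
numerically.

## Known limitations

* Center-star MSA is O(n^2) pairwise alignments and has no refinement
  pass; for hundreds of sequences a dedicated aligner is preferable.
* Greedy clustering aligns every sequence against cluster representatives
  without k-mer prefiltering; fine for phage-scale proteomes, slow for
  large ones.
* The k-label UniFrac generalization and the zero-length multifurcation
  resolution before Fitch are approximations documented above, not
  published standards.
* Gene prediction, HMM annotation, ML tree inference, and structural
  modeling are explicitly out of scope; family labels and gene coordinates
  are taken as input.
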