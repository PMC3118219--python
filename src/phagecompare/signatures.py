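"""Tetranucleotide z-score genome signatures.

A genome's signature is the 256-vector of standardized deviations of its
observed tetranucleotide counts from a maximal-order (order-2) Markov
expectation.  For a word w = N1N2N3N4, with n(.) the observed counts of the
embedded shorter words,

    E(w)   = n(N1N2N3) * n(N2N3N4) / n(N2N3)
    var(w) = E(w) * (n(N2N3) - n(N1N2N3)) * (n(N2N3) - n(N2N3N4)) / n(N2N3)^2
    z(w)   = (obs(w) - E(w)) / sqrt(var(w))

Because the expectation conditions on the genome's own di-/trinucleotide
composition, z-scores capture genuine fourth-order structure (shared genes,
codon-usage idiosyncrasies) rather than raw base composition.  By default
both strands are counted (the sequence and its reverse complement,
separately, never across the junction), which makes signatures invariant
under reverse complementation of the input.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import AlignmentError, FormatError
from .seqio import reverse_complement

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: The 256 tetranucleotides in lexicographic order AAAA..TTTT.
TETRANUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=4)]


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3; N (the only allowed ambiguity) becomes -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    bad = (out == -1) & (arr != ord("N"))
    if bad.any():
        raise FormatError(
            f"non-nucleotide character {chr(arr[bad.argmax()])!r} in sequence"
        )
    return out


def _count_array(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts of all 4^k overlapping words; windows containing N are skipped."""
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(4 ** k, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    word_codes = windows[valid] @ powers
    return np.bincount(word_codes, minlength=4 ** k).astype(np.int64)


def count_words(seq: str, k: int) -> Counter:
    """Overlapping k-mer counts (k in {2, 3, 4}) as a Counter of words.

    Windows containing ``N`` are skipped, so the counts sum to the number of
    valid windows (``L - k + 1`` for an N-free sequence of length L).
    """
    if k not in (2, 3, 4):
        raise ValueError("k must be 2, 3 or 4")
    seq = seq.upper()
    if len(seq) < k:
        raise FormatError(f"sequence of length {len(seq)} is shorter than k={k}")
    counts = _count_array(_encode(seq), k)
    words = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    return Counter({w: int(c) for w, c in zip(words, counts) if c})


@dataclass
class TetraSignature:
    """256 tetranucleotide z-scores for one genome."""

    genome_id: str
    zscores: np.ndarray
    strand_mode: str = "dual"
    total_windows: int = 0

    def __post_init__(self) -> None:
        self.zscores = np.asarray(self.zscores, dtype=float)
        if self.zscores.shape != (256,):
            raise ValueError("a tetranucleotide signature has exactly 256 entries")
        if not np.isfinite(self.zscores).all():
            raise ValueError("signature z-scores must be finite")


@dataclass
class SignatureMatrix:
    """Pairwise Pearson correlations (and p-values) between signatures."""

    ids: list[str]
    r: np.ndarray
    p: np.ndarray | None = None


def tetra_zscores(
    seq: str, strand_mode: str = "dual", genome_id: str = ""
) -> TetraSignature:
    """Compute the tetranucleotide z-score signature of a genome.

    ``strand_mode="dual"`` (default) sums the counts of the sequence and its
    reverse complement, each counted separately.  Words whose expectation or
    variance is undefined or zero get z = 0; this is logged, not raised, so
    short or degenerate inputs still yield a finite signature.
    """
    if strand_mode not in ("single", "dual"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    seq = seq.upper()
    if len(seq.replace("N", "")) < 4:
        raise FormatError("sequence must contain at least 4 non-N bases")
    strands = [seq] if strand_mode == "single" else [seq, reverse_complement(seq)]
    n2 = np.zeros(16, dtype=np.int64)
    n3 = np.zeros(64, dtype=np.int64)
    n4 = np.zeros(256, dtype=np.int64)
    for s in strands:
        codes = _encode(s)
        n2 += _count_array(codes, 2)
        n3 += _count_array(codes, 3)
        n4 += _count_array(codes, 4)

    w = np.arange(256)
    prefix3 = w // 4        # N1N2N3
    suffix3 = w % 64        # N2N3N4
    mid2 = prefix3 % 16     # N2N3
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n2[mid2].astype(float)
        expected = n3[prefix3] * n3[suffix3] / denom
        var = (
            expected
            * (n2[mid2] - n3[prefix3])
            * (n2[mid2] - n3[suffix3])
            / denom ** 2
        )
        z = (n4 - expected) / np.sqrt(var)
    degenerate = ~np.isfinite(z)
    if degenerate.any():
        logger.debug(
            "%s: %d/256 words with undefined or zero variance set to z=0",
            genome_id or "<anonymous>",
            int(degenerate.sum()),
        )
        z[degenerate] = 0.0
    return TetraSignature(
        genome_id=genome_id,
        zscores=z,
        strand_mode=strand_mode,
        total_windows=int(n4.sum()),
    )


def signature_correlation(
    a: TetraSignature, b: TetraSignature
) -> tuple[float, float]:
    """Pearson r (and two-sided p, 254 df) between two 256-entry signatures."""
    if a.zscores.std() == 0 or b.zscores.std() == 0:
        raise AlignmentError(
            "correlation undefined: a signature has zero variance"
        )
    r, p = stats.pearsonr(a.zscores, b.zscores)
    return float(r), float(p)


def signature_matrix(sigs: Sequence[TetraSignature]) -> SignatureMatrix:
    """All pairwise signature correlations as a symmetric matrix."""
    n = len(sigs)
    r = np.eye(n)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rij, pij = signature_correlation(sigs[i], sigs[j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return SignatureMatrix(ids=[s.genome_id for s in sigs], r=r, p=p)


def signature_tree(sigs: Sequence[TetraSignature], linkage: str = "complete"):
    """Agglomerative dendrogram of genomes from signature dissimilarities.

    The correlation matrix is transformed to dissimilarities d = 1 - r and
    clustered hierarchically; leaves carry genome ids.
    """
    from skbio import DistanceMatrix

    from .phylo import hierarchical_tree

    if len(sigs) < 2:
        raise ValueError("need at least 2 signatures to build a tree")
    mat = signature_matrix(sigs)
    d = 1.0 - mat.r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # guard against float asymmetry
    return hierarchical_tree(DistanceMatrix(d, ids=mat.ids), linkage=linkage)
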