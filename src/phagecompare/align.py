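"""Pairwise and multiple protein alignment and per-column conservation.

Pairwise alignment is global Needleman-Wunsch under BLOSUM62 with affine
gaps (open 10, extend 1): a gap run of length L costs ``open + (L-1)*extend``.
Percent identity is computed over alignment columns with terminal-gap
columns excluded from the denominator, which softens length heterogeneity
between full-length family members.

The multiple aligner is a center-star construction: the center sequence is
the one minimizing the summed pairwise distance (d = 1 - identity/100) to
all others, and the remaining sequences are merged against it under the
"once a gap, always a gap" rule.  Downstream consumers (conservation
profiles, p-distances, neighbor joining) need consistent columns, not any
particular heuristic aligner's output.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlignmentError

GAP = "-"


@dataclass
class PairwiseAlignment:
    """Two equal-length gapped rows plus score and percent identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned rows must have equal length")


@dataclass
class MultipleAlignment:
    """Ordered gapped rows; every row degaps to its source sequence."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows must correspond")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("all alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    return aligner


def _identity_pct(row_a: str, row_b: str) -> float:
    """Identical columns / columns, terminal-gap columns excluded."""
    both = [i for i in range(len(row_a)) if row_a[i] != GAP and row_b[i] != GAP]
    if not both:
        return 0.0
    start, end = both[0], both[-1]
    span = end - start + 1
    identical = sum(
        1
        for i in range(start, end + 1)
        if row_a[i] == row_b[i] and row_a[i] != GAP
    )
    return 100.0 * identical / span


def identity_over_shorter(aln: PairwiseAlignment) -> float:
    """Identical columns as a percentage of the shorter sequence's length.

    The denominator convention of greedy incremental clustering tools.
    """
    identical = sum(
        1
        for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x == y and x != GAP
    )
    shorter = min(
        len(aln.aligned_a.replace(GAP, "")), len(aln.aligned_b.replace(GAP, ""))
    )
    return 100.0 * identical / shorter


def global_align(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Returns the first optimal alignment in Biopython's deterministic
    enumeration order; the score is invariant across co-optimal tracebacks.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    row_a, row_b = alignment[0], alignment[1]
    return PairwiseAlignment(
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(alignment.score),
        identity_pct=_identity_pct(row_a, row_b),
    )


def _merge_into_master(
    master_rows: list[list[str]], center_aln: str, new_aln: str
) -> list[str]:
    """Merge one pairwise (center, new) alignment into the master alignment.

    ``master_rows[0]`` is the gapped center as accumulated so far.  Gaps
    already present are never removed ("once a gap, always a gap").
    Returns the new row; mutates master_rows in place.
    """
    out_rows: list[list[str]] = [[] for _ in master_rows]
    new_row: list[str] = []
    i = j = 0
    master_center = master_rows[0]
    n_master, n_pair = len(master_center), len(center_aln)
    while i < n_master or j < n_pair:
        master_gap = i < n_master and master_center[i] == GAP
        pair_gap = j < n_pair and center_aln[j] == GAP
        if i < n_master and master_gap:
            # column already inserted by an earlier sequence
            for row, out in zip(master_rows, out_rows):
                out.append(row[i])
            new_row.append(GAP)
            i += 1
        elif j < n_pair and pair_gap:
            # new sequence inserts a column relative to the center
            for out in out_rows:
                out.append(GAP)
            new_row.append(new_aln[j])
            j += 1
        else:
            for row, out in zip(master_rows, out_rows):
                out.append(row[i])
            new_row.append(new_aln[j])
            i += 1
            j += 1
    for row, out in zip(master_rows, out_rows):
        row[:] = out
    return "".join(new_row)


def center_star_msa(
    seqs: Sequence[str], ids: Sequence[str] | None = None, **align_kwargs
) -> MultipleAlignment:
    """Center-star multiple alignment of >= 2 protein sequences."""
    n = len(seqs)
    if n < 2:
        raise AlignmentError("need at least 2 sequences for a multiple alignment")
    if ids is None:
        ids = [f"seq{i+1}" for i in range(n)]
    pairwise: dict[tuple[int, int], PairwiseAlignment] = {}
    dist_sum = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], **align_kwargs)
            pairwise[(i, j)] = aln
            d = 1.0 - aln.identity_pct / 100.0
            dist_sum[i] += d
            dist_sum[j] += d
    center = int(np.argmin(dist_sum))

    master_rows: list[list[str]] = [list(seqs[center])]
    order = [center]
    for j in range(n):
        if j == center:
            continue
        if (center, j) in pairwise or (j, center) in pairwise:
            if center < j:
                aln = pairwise[(center, j)]
                c_row, s_row = aln.aligned_a, aln.aligned_b
            else:
                aln = pairwise[(j, center)]
                c_row, s_row = aln.aligned_b, aln.aligned_a
        new_row = _merge_into_master(master_rows, c_row, s_row)
        master_rows.append(list(new_row))
        order.append(j)

    # restore input order
    rows_by_input = {k: "".join(r) for k, r in zip(order, master_rows)}
    return MultipleAlignment(
        ids=list(ids), rows=[rows_by_input[i] for i in range(n)]
    )


def column_conservation(msa: MultipleAlignment) -> np.ndarray:
    """Per-column fraction of non-gap residues matching the modal residue.

    Gaps are excluded from both numerator and denominator; a column that is
    all gaps scores 0.
    """
    if len(msa.rows) < 2:
        raise AlignmentError("conservation needs at least 2 rows")
    out = np.zeros(msa.n_columns)
    for i in range(msa.n_columns):
        residues = [c for c in msa.column(i) if c != GAP]
        if residues:
            out[i] = max(residues.count(r) for r in set(residues)) / len(residues)
    return out


def filter_columns(
    msa: MultipleAlignment, min_conservation: float = 0.10, strict: bool = True
) -> MultipleAlignment:
    """Drop hypervariable columns, keeping those with conservation above
    ``min_conservation`` (strictly by default), in their original order."""
    cons = column_conservation(msa)
    if strict:
        keep = [i for i, c in enumerate(cons) if c > min_conservation]
    else:
        keep = [i for i, c in enumerate(cons) if c >= min_conservation]
    if not keep:
        raise AlignmentError(
            "no columns survive the conservation filter; lower min_conservation"
        )
    return MultipleAlignment(
        ids=list(msa.ids),
        rows=["".join(row[i] for i in keep) for row in msa.rows],
    )
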