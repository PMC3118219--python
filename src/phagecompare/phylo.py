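"""Trees and tree statistics: Newick I/O, hierarchical clustering, neighbor
joining, Fitch parsimony, unweighted UniFrac, and Monte Carlo permutation
tests of trait-phylogeny association.

The unweighted UniFrac statistic used here is the fraction of total branch
length (root branch excluded) carried by branches whose descendant tips all
share a single trait label.  For two labels this is the classic unique
versus shared branch-length fraction; it generalizes directly to k labels,
which lets one test run across many host genera.  Significance comes from
permuting labels across tips while preserving the label multiset: large
UniFrac values are extreme (more label-exclusive branch length than
chance), small Fitch parsimony scores are extreme (fewer label changes than
chance).  Sampled-mode p-values use the (1 + b) / (1 + n) estimator, which
can never report p = 0.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj
from sympy.utilities.iterables import multiset_permutations

from .align import MultipleAlignment, global_align
from .errors import FormatError, TreeError

logger = logging.getLogger(__name__)

#: The tree container used throughout the package.
PhyloTree = TreeNode

#: tip id -> categorical label (host genus, architecture class, genotype, ...)
TraitLabeling = dict


# ---------------------------------------------------------------------------
# Newick I/O and trait tables
# ---------------------------------------------------------------------------

def read_newick(text: str) -> TreeNode:
    """Parse a Newick string; missing branch lengths default to 0 (logged)."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"Newick parse error: {exc}") from exc
    missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            missing += 1
    if missing:
        logger.warning("Newick input lacked %d branch lengths; defaulted to 0", missing)
    return tree


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def read_trait_table(path: str | Path) -> TraitLabeling:
    """Two-column TSV (tip_id, label) -> labeling dict."""
    labels: TraitLabeling = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"trait table line {line!r} is not 2-column TSV")
        labels[fields[0]] = fields[1]
    if not labels:
        raise FormatError(f"no trait rows found in {path}")
    return labels


def write_trait_table(labels: TraitLabeling, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tip in sorted(labels):
            fh.write(f"{tip}\t{labels[tip]}\n")


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def hierarchical_tree(d: DistanceMatrix, linkage: str = "complete") -> TreeNode:
    """Agglomerative clustering of a distance matrix into a rooted tree.

    Branch lengths are assigned so the path between two tips first joined
    at merge height h has length h (children hang at half the merge height,
    the dendrogram convention).
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    data = np.asarray(d.data, dtype=float)
    if np.isnan(data).any():
        raise TreeError("distance matrix contains NaN")
    ids = list(d.ids)
    n = len(ids)
    if n < 2:
        raise TreeError("need at least 2 items to cluster")
    Z = hierarchy.linkage(squareform(data, checks=False), method=linkage)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    heights: list[float] = [0.0] * n
    for left, right, height, _count in Z:
        left, right = int(left), int(right)
        for child in (left, right):
            nodes[child].length = max(height - heights[child], 0.0) / 2.0
        parent = TreeNode(children=[nodes[left], nodes[right]])
        nodes.append(parent)
        heights.append(float(height))
    root = nodes[-1]
    root.length = None
    return root


def p_distance_matrix(
    alignment: MultipleAlignment | Sequence[tuple[str, str]],
) -> DistanceMatrix:
    """Pairwise p-distances (1 - identical/compared).

    From an MSA, gap columns are deleted pairwise; supply the output of
    ``align.filter_columns`` to mirror the conservation-restricted analysis.
    Alternatively a list of (id, ungapped_sequence) pairs may be given, in
    which case each pair is globally aligned first.
    """
    if isinstance(alignment, MultipleAlignment):
        ids, rows = alignment.ids, alignment.rows
        n = len(rows)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                compared = matches = 0
                for a, b in zip(rows[i], rows[j]):
                    if a != "-" and b != "-":
                        compared += 1
                        if a == b:
                            matches += 1
                if compared == 0:
                    raise TreeError(
                        f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                    )
                d[i, j] = d[j, i] = 1.0 - matches / compared
    else:
        ids = [name for name, _ in alignment]
        seqs = [seq for _, seq in alignment]
        n = len(seqs)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pct = 100.0 if seqs[i] == seqs[j] else global_align(
                    seqs[i], seqs[j]
                ).identity_pct
                d[i, j] = d[j, i] = 1.0 - pct / 100.0
    return DistanceMatrix(d, ids=ids)


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining (Studier-Keppler Q criterion).

    Negative estimated branch lengths are clamped to 0.  The returned tree
    is unrooted; it is serialized with an arbitrary root at the final join.
    """
    if len(d.ids) < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    data = np.asarray(d.data)
    if not np.allclose(data, data.T):
        raise TreeError("distance matrix must be symmetric")
    return _skbio_nj(d)


# ---------------------------------------------------------------------------
# Tree statistics
# ---------------------------------------------------------------------------

def _resolved_binary_copy(tree: TreeNode) -> TreeNode:
    """Copy of the tree with multifurcations resolved into zero-length
    binary joins (arbitrary left-leaning resolution)."""
    tree = tree.copy()
    multis = [
        node for node in tree.traverse(include_self=True) if len(node.children) > 2
    ]
    if multis:
        logger.debug("resolving %d multifurcations with zero-length branches", len(multis))
    for node in multis:
        while len(node.children) > 2:
            a = node.children[0]
            b = node.children[1]
            node.remove(a)
            node.remove(b)
            joined = TreeNode(children=[a, b], length=0.0)
            node.append(joined)
    return tree


def _check_labels(tree: TreeNode, labels: Mapping[str, str]) -> list[str]:
    tips = [t.name for t in tree.tips()]
    missing = [t for t in tips if t not in labels]
    if missing:
        raise TreeError(f"unlabeled tips: {missing}")
    return tips


def fitch_score(tree: TreeNode, labels: Mapping[str, str]) -> int:
    """Minimum number of label changes on the tree (Fitch parsimony).

    Multifurcations are resolved arbitrarily with zero-length branches
    before the bottom-up pass, so the score is exact for binary trees and
    an upper-bound heuristic otherwise.
    """
    _check_labels(tree, labels)
    work = _resolved_binary_copy(tree)
    changes = 0
    sets: dict[int, frozenset] = {}
    for node in work.postorder(include_self=True):
        if node.is_tip():
            sets[id(node)] = frozenset([labels[node.name]])
        else:
            child_sets = [sets[id(c)] for c in node.children]
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[id(node)] = inter
            else:
                sets[id(node)] = frozenset.union(*child_sets)
                changes += 1
    return changes


def unifrac_statistic(tree: TreeNode, labels: Mapping[str, str]) -> float:
    """Fraction of branch length leading exclusively to a single label.

    Root branch excluded.  Raises if branch lengths are missing, the total
    branch length is 0, or fewer than 2 distinct labels occur at the tips.
    """
    tips = _check_labels(tree, labels)
    if len({labels[t] for t in tips}) < 2:
        raise TreeError("unifrac needs at least 2 distinct tip labels")
    total = unique = 0.0
    label_sets: dict[int, set] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            label_sets[id(node)] = {labels[node.name]}
        else:
            label_sets[id(node)] = set().union(
                *(label_sets[id(c)] for c in node.children)
            )
        if node.is_root():
            continue
        if node.length is None:
            raise TreeError(f"branch above {node.name!r} lacks a length")
        total += node.length
        if len(label_sets[id(node)]) == 1:
            unique += node.length
    if total <= 0:
        raise TreeError("total branch length is 0; unifrac undefined")
    return unique / total


def is_monophyletic(tree: TreeNode, labels: Mapping[str, str], target: str) -> bool:
    """True if the tips carrying ``target`` form a clade of the rooted tree."""
    tips = _check_labels(tree, labels)
    wanted = {t for t in tips if labels[t] == target}
    if not wanted:
        raise TreeError(f"no tips carry label {target!r}")
    for node in tree.traverse(include_self=True):
        node_tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if node_tips == wanted:
            return True
    return False


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    statistic: str
    observed: float
    null_samples: list[float]
    n_perm: int
    seed: int | None
    p_value: float
    mode: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "mode": self.mode,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _branch_incidence(tree: TreeNode, tips: list[str]):
    """(lengths, incidence) for all non-root branches: incidence[b, t] is
    True when tip t descends through branch b."""
    tip_index = {name: i for i, name in enumerate(tips)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(tips), dtype=bool)
            vec[tip_index[node.name]] = True
        else:
            vec = np.zeros(len(tips), dtype=bool)
            for c in node.children:
                vec |= below[id(c)]
        below[id(node)] = vec
        if not node.is_root():
            if node.length is None:
                raise TreeError(f"branch above {node.name!r} lacks a length")
            lengths.append(node.length)
            rows.append(vec)
    return np.array(lengths, dtype=float), np.vstack(rows)


def _unifrac_from_codes(
    lengths: np.ndarray, incidence: np.ndarray, codes: np.ndarray, k: int
) -> float:
    counts = np.stack([incidence @ (codes == j) for j in range(k)], axis=1)
    single = (counts > 0).sum(axis=1) == 1
    return float(lengths[single].sum() / lengths.sum())


def _fitch_structure(tree: TreeNode, tips: list[str]):
    """Postorder (left, right) child indices of the resolved binary tree,
    with tips numbered by their position in ``tips``."""
    work = _resolved_binary_copy(tree)
    tip_index = {name: i for i, name in enumerate(tips)}
    node_ids: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    next_id = len(tips)
    for node in work.postorder(include_self=True):
        if node.is_tip():
            node_ids[id(node)] = tip_index[node.name]
        else:
            children = [node_ids[id(c)] for c in node.children]
            # zero-length resolution guarantees exactly 2 children here
            pairs.append((children[0], children[1]))
            node_ids[id(node)] = next_id
            next_id += 1
    return pairs


def _fitch_from_codes(pairs: list[tuple[int, int]], codes: np.ndarray) -> int:
    masks = [1 << int(c) for c in codes] + [0] * len(pairs)
    n_tips = len(codes)
    changes = 0
    for idx, (a, b) in enumerate(pairs):
        inter = masks[a] & masks[b]
        if inter:
            masks[n_tips + idx] = inter
        else:
            masks[n_tips + idx] = masks[a] | masks[b]
            changes += 1
    return changes


def permutation_test(
    tree: TreeNode,
    labels: Mapping[str, str],
    statistic: str = "unifrac",
    n_perm: int = 1000,
    seed: int | None = 0,
    mode: str = "sampled",
) -> PermutationTestResult:
    """Monte Carlo (or exhaustive) label-permutation test on a tree.

    Labels are shuffled across tips preserving the label multiset.  For
    ``unifrac`` large values are extreme, for ``fitch`` small values are.
    Sampled mode reports p = (1 + b) / (1 + n_perm) where b counts null
    samples at least as extreme as the observation; exhaustive mode reports
    the exact fraction over all distinct label assignments.
    """
    if statistic not in ("unifrac", "fitch"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if mode not in ("sampled", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    tips = _check_labels(tree, labels)
    distinct = sorted({labels[t] for t in tips})
    if len(distinct) < 2:
        raise TreeError("permutation test needs at least 2 distinct labels")
    code_of = {lab: i for i, lab in enumerate(distinct)}
    codes = np.array([code_of[labels[t]] for t in tips])
    k = len(distinct)

    if statistic == "unifrac":
        lengths, incidence = _branch_incidence(tree, tips)
        if lengths.sum() <= 0:
            raise TreeError("total branch length is 0; unifrac undefined")

        def evaluate(c: np.ndarray) -> float:
            return _unifrac_from_codes(lengths, incidence, c, k)

        def is_extreme(null: float, obs: float) -> bool:
            return null >= obs - 1e-12
    else:
        pairs = _fitch_structure(tree, tips)

        def evaluate(c: np.ndarray) -> float:
            return float(_fitch_from_codes(pairs, c))

        def is_extreme(null: float, obs: float) -> bool:
            return null <= obs + 1e-12

    observed = evaluate(codes)

    if mode == "exhaustive":
        total = extreme = 0
        for assignment in multiset_permutations(sorted(codes.tolist())):
            total += 1
            if is_extreme(evaluate(np.array(assignment)), observed):
                extreme += 1
        null = []  # not stored for exhaustive enumeration
        p = extreme / total
        n_used = total
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        null = [evaluate(rng.permutation(codes)) for _ in range(n_perm)]
        b = sum(1 for v in null if is_extreme(v, observed))
        p = (1 + b) / (1 + n_perm)
        n_used = n_perm

    return PermutationTestResult(
        statistic=statistic,
        observed=observed,
        null_samples=null,
        n_perm=n_used,
        seed=seed if mode == "sampled" else None,
        p_value=p,
        mode=mode,
    )
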