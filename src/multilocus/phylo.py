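"""Distances, neighbor-joining trees and incongruence comparison.

Distances use *pairwise deletion*: for each sequence pair only columns where
both rows carry a determinate nucleotide/residue are compared.  Implemented
models:

* ``raw-count`` — number of mismatching compared sites (Hamming count);
* ``p`` — mismatch proportion (Hamming/p-distance), the default;
* ``jc69`` — d = -(3/4) ln(1 - 4p/3), the one-parameter correction for
  multiple substitutions;
* ``k80`` — d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q), with P and Q the
  transition and transversion proportions over compared sites.

A pair with zero compared sites is *undefined*; a pair whose log argument is
non-positive is *saturated*.  Both are stored as NaN with a flag and poison
tree building (explicit error rather than silent imputation).

Trees are unrooted (trifurcating root node).  Neighbor joining follows the
classical Q-criterion agglomeration with the Studier–Keppler update and a
deterministic lowest-index tie-break; branch lengths may come out negative
and are clamped to zero by :func:`build_trees` (the default workflow), not
redistributed.  Incongruence between gene trees is quantified by the
Robinson–Foulds symmetric difference of non-trivial bipartitions over the
shared leaf set.
"""

from __future__ import annotations

import io as _pyio
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio.tree import TreeNode

from .core import (
    GAP,
    NUC_STATES,
    NUCLEOTIDE,
    LocusAlignment,
    MultiLocusContainer,
    concatenate_loci,
    resolve_selector,
)
from .errors import (
    AlphabetError,
    ComparisonError,
    IncompleteDistanceError,
    NewickParseError,
    SelectorError,
)

MODELS = ("raw-count", "p", "jc69", "k80")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class DistanceMatrix:
    """Symmetric labelled distances with undefined/saturated pair flags.

    ``values`` is square, symmetric, zero-diagonal; undefined or saturated
    entries hold NaN and are flagged in the corresponding boolean matrices.
    """

    labels: list[str]
    values: np.ndarray
    model: str = "p"
    undefined: np.ndarray = None
    saturated: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix")
        if self.undefined is None:
            self.undefined = np.zeros((n, n), dtype=bool)
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def __getitem__(self, pair) -> float:
        a, b = pair
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def to_tsv(self) -> str:
        """Square tab-separated text with a label header row/column."""
        lines = ["\t" + "\t".join(self.labels)]
        for label, row in zip(self.labels, self.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            lines.append(label + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def _encode(a: LocusAlignment) -> np.ndarray:
    """Integer-encode rows: A/C/G/T -> 0..3, anything else -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for k, ch in enumerate(NUC_STATES):
        lut[ord(ch)] = k
    raw = np.frombuffer(
        "".join(a.sequences.values()).encode("ascii"), dtype=np.uint8
    ).reshape(len(a), a.n_cols)
    return lut[raw]


def _encode_generic(a: LocusAlignment) -> np.ndarray:
    """Amino-acid encoding: determinate residues get codes, gaps/'?'/X -> -1."""
    lut = np.full(256, -1, dtype=np.int16)
    from .core import AA_STATES

    for k, ch in enumerate(AA_STATES):
        lut[ord(ch)] = k
    raw = np.frombuffer(
        "".join(a.sequences.values()).encode("ascii"), dtype=np.uint8
    ).reshape(len(a), a.n_cols)
    return lut[raw]


def pairwise_distance(a: LocusAlignment, model: str = "p") -> DistanceMatrix:
    """All-pairs distance under ``model`` with pairwise deletion.

    jc69/k80 require nucleotide data; raw-count and p also work on amino
    acids (determinate residues compared, X/'?'/gaps deleted pairwise).
    """
    if model not in MODELS:
        raise SelectorError(f"unknown distance model {model!r}; use {MODELS}")
    if model in ("jc69", "k80") and a.alphabet != NUCLEOTIDE:
        raise AlphabetError(f"model {model!r} requires nucleotide data")
    if len(a) < 2:
        raise SelectorError("need at least 2 sequences for distances")
    enc = _encode(a) if a.alphabet == NUCLEOTIDE else _encode_generic(a)
    n = len(a)
    values = np.zeros((n, n))
    undefined = np.zeros((n, n), dtype=bool)
    saturated = np.zeros((n, n), dtype=bool)
    is_purine = np.isin(enc, (0, 2))  # A, G
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] >= 0) & (enc[j] >= 0)
            L = int(both.sum())
            if L == 0:
                values[i, j] = values[j, i] = np.nan
                undefined[i, j] = undefined[j, i] = True
                continue
            diff = both & (enc[i] != enc[j])
            mism = int(diff.sum())
            if model == "raw-count":
                d = float(mism)
            elif model == "p":
                d = mism / L
            elif model == "jc69":
                p = mism / L
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0:
                    values[i, j] = values[j, i] = np.nan
                    saturated[i, j] = saturated[j, i] = True
                    continue
                d = -0.75 * math.log(arg)
            else:  # k80
                ts = int((diff & (is_purine[i] == is_purine[j])).sum())
                P = ts / L
                Q = (mism - ts) / L
                arg1 = 1.0 - 2.0 * P - Q
                arg2 = 1.0 - 2.0 * Q
                if arg1 <= 0 or arg2 <= 0:
                    values[i, j] = values[j, i] = np.nan
                    saturated[i, j] = saturated[j, i] = True
                    continue
                d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(a.labels, values, model, undefined, saturated)


def dist_multilocus(
    c: MultiLocusContainer, pool: bool = False, model: str = "p"
):
    """Distances per locus (``pool=False``) or on the supermatrix.

    Per-locus matrices cover the full canonical label set, so gap-only
    padding rows yield undefined pairs; drop them first (or use
    :func:`build_trees`) if complete matrices are needed.
    """
    if pool:
        return pairwise_distance(concatenate_loci(c), model)
    return {
        loc.name: pairwise_distance(loc, model) for loc in c.loci
    }


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """(Un)rooted tree with branch lengths, Newick-serializable.

    Thin wrapper around a :class:`skbio.tree.TreeNode`; an unrooted tree is
    represented with a trifurcating root.  Use :func:`nj_tree`,
    :func:`build_trees` or :meth:`from_newick` to construct.
    """

    def __init__(self, node: TreeNode, rooted: bool = False):
        self._tree = node
        self.rooted = rooted

    @property
    def skbio_tree(self) -> TreeNode:
        return self._tree

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self._tree.tips()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def branch_lengths(self) -> list[float]:
        return [
            nd.length
            for nd in self._tree.traverse(include_self=False)
            if nd.length is not None
        ]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.copy(), self.rooted)

    def clamped(self) -> "PhyloTree":
        """Negative branch lengths set to zero; everything else untouched."""
        t = self._tree.copy()
        for nd in t.traverse(include_self=False):
            if nd.length is not None and nd.length < 0:
                nd.length = 0.0
        return PhyloTree(t, self.rooted)

    def to_newick(self) -> str:
        return _emit_newick(self._tree) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            node = TreeNode.read(_pyio.StringIO(text))
        except Exception as exc:
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        root_children = len(node.children)
        return cls(node, rooted=(root_children == 2))

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonical frozensets of leaf names.

        Each internal edge splits the leaves in two; the side not containing
        the lexicographically smallest leaf is the canonical representative.
        """
        leaves = set(self.leaf_names)
        ref = min(leaves)
        splits = set()
        for nd in self._tree.non_tips(include_self=False):
            side = frozenset(t.name for t in nd.tips())
            if ref in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= len(leaves) - 2:
                splits.add(side)
        return splits

    def restricted_to(self, names: Sequence[str]) -> "PhyloTree":
        """Induced subtree over the given leaves (degree-2 nodes collapsed)."""
        missing = set(names) - set(self.leaf_names)
        if missing:
            raise SelectorError(f"unknown leaves: {sorted(missing)}")
        return PhyloTree(self._tree.copy().shear(list(names)), self.rooted)

    def __str__(self) -> str:
        return self.to_newick()

    def __repr__(self) -> str:
        return f"<PhyloTree: {self.n_leaves} leaves>"


def _quote_label(name: str) -> str:
    if any(ch in name for ch in " \t()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _emit_newick(node: TreeNode) -> str:
    if node.is_tip():
        out = _quote_label(node.name or "")
    else:
        out = "(" + ",".join(_emit_newick(ch) for ch in node.children) + ")"
        if node.name:
            out += _quote_label(node.name)
    if node.length is not None:
        out += ":" + f"{node.length:.6g}"
    return out


def write_newick(t: PhyloTree) -> str:
    """Serialize with 6-significant-digit branch lengths and trailing ';'."""
    return t.to_newick()


def read_newick(text: str) -> PhyloTree:
    return PhyloTree.from_newick(text)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Classical neighbor joining (Saitou–Nei with Studier–Keppler update).

    Requires a complete matrix; undefined or saturated pairs raise
    :class:`IncompleteDistanceError`.  Output is unrooted (trifurcating
    root); branch lengths are as computed and may be negative — see
    :meth:`PhyloTree.clamped`.  Ties on the Q criterion resolve to the
    lowest (row-major) active index pair.
    """
    if not d.is_complete():
        bad = int(np.isnan(d.values).sum() // 2)
        raise IncompleteDistanceError(
            f"{bad} undefined/saturated pair(s); cannot build a tree"
        )
    n = d.n
    if n < 2:
        raise SelectorError("need at least 2 labels")
    nodes = [TreeNode(name=label) for label in d.labels]
    if n == 2:
        half = float(d.values[0, 1]) / 2.0
        for nd in nodes:
            nd.length = half
        return PhyloTree(TreeNode(children=nodes), rooted=False)
    D = d.values.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin on the row-major flattened matrix
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # Studier–Keppler: distance from the new node to every other node
        new_row = np.zeros(D.shape[0])
        for ak in active:
            if ak not in (i, j):
                new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    x, y, z = active
    nodes[x].length = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    nodes[y].length = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    nodes[z].length = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return PhyloTree(root, rooted=False)


def ladderize(t: PhyloTree) -> PhyloTree:
    """Children of every internal node ordered by descending clade size,
    ties broken by the smallest leaf label; topology and lengths unchanged."""
    out = t.copy()

    def key(nd: TreeNode):
        tips = [x.name for x in nd.tips()] if not nd.is_tip() else [nd.name]
        return (-len(tips), min(tips))

    for nd in out._tree.traverse(include_self=True):
        if nd.children:
            nd.children.sort(key=key)
    # in-place child sort invalidates skbio's lookup caches
    out._tree.clear_caches()
    return out


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson–Foulds symmetric difference over the shared leaf set.

    Both trees are restricted to their common leaves (at least 4 required);
    the count is the number of non-trivial bipartitions present in exactly
    one of the two induced subtrees.
    """
    common = sorted(set(t1.leaf_names) & set(t2.leaf_names))
    if len(common) < 4:
        raise ComparisonError(
            f"only {len(common)} shared leaves; need at least 4"
        )
    s1 = t1.restricted_to(common).bipartitions()
    s2 = t2.restricted_to(common).bipartitions()
    return len(s1 ^ s2)


def build_trees(
    c: MultiLocusContainer,
    pool: bool = False,
    model: str = "p",
    clamp: bool = True,
    ladderize_trees: bool = True,
):
    """The default tree workflow: NJ on pairwise-deletion distances.

    Per locus (``pool=False``), gap-only padding rows are dropped before the
    distance computation, a locus left with fewer than 3 sequences is
    skipped with a warning, and each remaining locus yields one tree.  With
    ``pool=True`` a single tree is built on the concatenation of all loci,
    keeping every individual.  Negative NJ branch lengths are clamped to
    zero (``clamp``) and trees are ladderized (``ladderize_trees``) by
    default.
    """

    def finish(t: PhyloTree) -> PhyloTree:
        if clamp:
            t = t.clamped()
        if ladderize_trees:
            t = ladderize(t)
        return t

    if pool:
        return finish(nj_tree(pairwise_distance(concatenate_loci(c), model)))
    out: dict[str, PhyloTree] = {}
    for loc in c.loci:
        gap = set(loc.gap_only_labels())
        keep = [l for l in loc.labels if l not in gap]
        if len(keep) < 3:
            warnings.warn(
                f"locus {loc.name!r}: only {len(keep)} non-gap-only "
                "sequences; skipped",
                stacklevel=2,
            )
            continue
        sub = loc.reordered(keep)
        out[loc.name] = finish(nj_tree(pairwise_distance(sub, model)))
    return out


def tree_distance_matrix(t: PhyloTree) -> DistanceMatrix:
    """Patristic (path-length) leaf-to-leaf distances of a tree."""
    dm = t.skbio_tree.tip_tip_distances()
    labels = list(dm.ids)
    return DistanceMatrix(labels, np.asarray(dm.data, dtype=float), model="p")
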