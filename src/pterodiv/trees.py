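"""Chronogram data model and branch-scaling transforms.

A chronogram is a rooted, time-calibrated (ultrametric) phylogeny with branch
lengths in millions of years (my). This module provides Newick I/O (parsing
delegated to dendropy), node-age and branching-time utilities, the most recent
common ancestor (MRCA) query, the phylogenetic trait covariance implied by
shared path lengths, and the two Pagel branch/covariance transforms used by
the trait-evolution stage:

* the delta transform raises node depths-from-root ``x`` to ``x**delta``
  and renormalizes by ``T**(1 - delta)`` so that the total depth ``T`` is
  preserved (delta > 1 concentrates change near the present);
* the lambda transform multiplies the off-diagonal entries of the
  phylogenetic covariance by ``lambda`` (lambda = 0 is a star phylogeny).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # dendropy is the Newick parser of record
    import dendropy
except ImportError:  # pragma: no cover
    dendropy = None

__all__ = [
    "Chronogram",
    "PhyloCovariance",
    "NewickError",
    "UltrametricityError",
    "parse_newick",
    "lambda_transform",
]

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate or missing labels...)."""


class UltrametricityError(ValueError):
    """Tip depths deviate from a common root-to-tip depth beyond tolerance."""


@dataclass
class PhyloCovariance:
    """Shared-path-length matrix between tip pairs (my), with tip ordering.

    diagonal = tip depths; off-diagonal[i, j] = depth of MRCA(i, j).
    """

    matrix: np.ndarray
    tip_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.T, rtol=0, atol=1e-9):
            raise ValueError("covariance must be symmetric")


class Chronogram:
    """Rooted tree stored as parallel arrays over nodes.

    Nodes are indexed 0..n_nodes-1 with tips first (0..n_tips-1, in the order
    of ``tip_labels``). ``parent[root] == -1`` and ``lengths[root] == 0`` unless
    the source Newick carried a root edge.
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        tip_labels: list[str],
        internal_labels: dict[int, str] | None = None,
        check_ultrametric: bool = True,
        ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_labels = list(tip_labels)
        self.internal_labels = dict(internal_labels or {})
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        if self.n_tips < 2:
            raise ValueError("a chronogram needs at least 2 tips")
        if len(set(self.tip_labels)) != self.n_tips:
            dups = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise NewickError(f"duplicate tip labels: {', '.join(dups)}")
        if np.any(self.lengths < 0):
            raise ValueError("negative branch lengths")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        for i in range(self.n_tips):
            if self.children[i]:
                raise ValueError("tips must come first in node order")
        self._postorder = self._compute_postorder()
        self._depths = self._compute_depths()
        if check_ultrametric:
            self.assert_ultrametric(ultrametric_rtol)

    # -- construction -----------------------------------------------------

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return order

    def _compute_depths(self) -> np.ndarray:
        depths = np.zeros(self.n_nodes)
        for node in reversed(self._postorder):  # preorder
            p = self.parent[node]
            if p >= 0:
                depths[node] = depths[p] + self.lengths[node]
        return depths

    # -- basic queries -----------------------------------------------------

    @property
    def postorder(self) -> list[int]:
        return list(self._postorder)

    @property
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (my)."""
        return self._depths.copy()

    @property
    def crown_age(self) -> float:
        return float(self._depths[: self.n_tips].max())

    def is_binary(self) -> bool:
        return all(len(self.children[i]) in (0, 2) for i in range(self.n_nodes))

    def assert_ultrametric(self, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> None:
        tip_depths = self._depths[: self.n_tips]
        T = tip_depths.max()
        dev = float(np.abs(tip_depths - T).max())
        if T > 0 and dev > rtol * T:
            raise UltrametricityError(
                f"tree is not ultrametric: max tip-depth deviation {dev:.6g} "
                f"exceeds rtol {rtol:g} of depth {T:.6g}"
            )

    def node_ages(self, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> np.ndarray:
        """Ages in my before present; tips snapped to 0 after validation."""
        self.assert_ultrametric(rtol)
        ages = self.crown_age - self._depths
        ages[: self.n_tips] = 0.0
        return ages

    def branching_times(self) -> np.ndarray:
        """Internal-node ages, descending; first element is the crown age."""
        if not self.is_binary():
            raise ValueError("branching_times requires a fully binary tree")
        ages = self.node_ages()
        bt = np.sort(ages[self.n_tips :])[::-1]
        return bt

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"{label!r} not in tree") from None

    def mrca(self, labels) -> int:
        """Node index of the most recent common ancestor of the given tips."""
        labels = list(labels)
        missing = [x for x in labels if x not in self.tip_labels]
        if missing:
            raise KeyError(f"labels not in tree: {', '.join(map(str, missing))}")
        if len(labels) < 1:
            raise ValueError("need at least one label")
        anc_sets = []
        for lab in labels:
            node = self.tip_index(lab)
            path = []
            while node >= 0:
                path.append(node)
                node = self.parent[node]
            anc_sets.append(path)
        common = set(anc_sets[0])
        for path in anc_sets[1:]:
            common &= set(path)
        # deepest common ancestor = max depth
        return max(common, key=lambda n: self._depths[n])

    def mrca_clade(self, labels) -> dict:
        """MRCA handle with crown and stem ages; stem is None at the root."""
        node = self.mrca(labels)
        ages = self.node_ages()
        parent = int(self.parent[node])
        return {
            "node": int(node),
            "crown_age": float(ages[node]),
            "stem_age": float(ages[parent]) if parent >= 0 else None,
            "stem_defined": parent >= 0,
            "tip_set": frozenset(self.clade_tips(node)),
        }

    def clade_tips(self, node: int) -> list[str]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(self.tip_labels[v])
            else:
                stack.extend(self.children[v])
        return out

    # -- transforms --------------------------------------------------------

    def delta_transform(self, delta: float) -> "Chronogram":
        """Pagel's delta: node depth x -> x**delta * T**(1-delta); T preserved."""
        if delta <= 0:
            raise ValueError("delta must be > 0")
        T = self.crown_age
        if T <= 0:
            raise ValueError("degenerate tree of zero depth")
        new_depths = (self._depths / T) ** delta * T
        new_lengths = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                new_lengths[i] = new_depths[i] - new_depths[p]
        return Chronogram(
            self.parent.copy(),
            new_lengths,
            self.tip_labels,
            self.internal_labels,
            check_ultrametric=False,
        )

    def covariance(self) -> PhyloCovariance:
        """Tip-pair shared path lengths: C[i, j] = depth of MRCA(i, j)."""
        n = self.n_tips
        C = np.zeros((n, n))
        tipsets: dict[int, list[int]] = {}
        for node in self._postorder:
            if node < n:
                tipsets[node] = [node]
                C[node, node] = self._depths[node]
            else:
                kids = self.children[node]
                sets = [tipsets.pop(c) for c in kids]
                d = self._depths[node]
                for a in range(len(sets)):
                    for b in range(a + 1, len(sets)):
                        for i in sets[a]:
                            for j in sets[b]:
                                C[i, j] = C[j, i] = d
                merged = [i for s in sets for i in s]
                tipsets[node] = merged
        return PhyloCovariance(C, list(self.tip_labels))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        text: str,
        check_ultrametric: bool = True,
        ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
    ) -> "Chronogram":
        return parse_newick(text, check_ultrametric=check_ultrametric,
                            ultrametric_rtol=ultrametric_rtol)

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if node < self.n_tips:
                core = _quote_label(self.tip_labels[node])
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
                if node in self.internal_labels:
                    core += _quote_label(self.internal_labels[node])
            if self.parent[node] >= 0:
                core += f":{self.lengths[node]:.17g}"
            return core

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return fmt(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}:;,= \t\n'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(
    text: str,
    check_ultrametric: bool = True,
    ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
) -> Chronogram:
    """Parse a Newick string into a :class:`Chronogram`.

    Branch lengths are mandatory except on the root edge; quoted labels are
    supported; internal-node labels are preserved but unused.
    """
    if dendropy is None:  # pragma: no cover
        raise ImportError("dendropy is required for Newick parsing")
    if not text.strip():
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=False,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickError(f"Newick parse error: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    tips = [nd for nd in dnodes if nd.is_leaf()]
    if len(tips) < 2:
        raise NewickError("fewer than 2 tips")
    labels = []
    for nd in tips:
        lab = nd.taxon.label if nd.taxon is not None else nd.label
        if lab is None or lab == "":
            raise NewickError("tip without a label")
        labels.append(str(lab))
    if len(set(labels)) != len(labels):
        dups = sorted({t for t in labels if labels.count(t) > 1})
        raise NewickError(f"duplicate tip labels: {', '.join(dups)}")

    index: dict[int, int] = {}
    for i, nd in enumerate(tips):
        index[id(nd)] = i
    nxt = len(tips)
    for nd in dnodes:
        if not nd.is_leaf():
            index[id(nd)] = nxt
            nxt += 1

    parent = np.full(nxt, -1, dtype=int)
    lengths = np.zeros(nxt)
    internal_labels: dict[int, str] = {}
    for nd in dnodes:
        i = index[id(nd)]
        if not nd.is_leaf() and nd.label:
            internal_labels[i] = str(nd.label)
        if nd.parent_node is None:
            lengths[i] = float(nd.edge.length or 0.0)
            parent[i] = -1
        else:
            if nd.edge.length is None:
                who = labels[i] if i < len(tips) else f"internal node #{i}"
                raise NewickError(f"missing branch length on edge to {who}")
            lengths[i] = float(nd.edge.length)
            parent[i] = index[id(nd.parent_node)]

    return Chronogram(
        parent,
        lengths,
        labels,
        internal_labels,
        check_ultrametric=check_ultrametric,
        ultrametric_rtol=ultrametric_rtol,
    )


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda: multiply off-diagonal covariance entries by lam in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    m = cov.matrix.copy()
    d = np.diag(m).copy()
    m *= lam
    np.fill_diagonal(m, d)
    return PhyloCovariance(m, list(cov.tip_labels))
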