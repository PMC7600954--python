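"""Rooted, binary, time-calibrated trees.

``TimeTree`` stores a fixed topology in flat arrays (tips ``0..n-1``,
internal nodes ``n..2n-2``) with node heights in relative time (tips at
height 0) and an optional substitution rate on the branch above each
non-root node.  This layout keeps MCMC state updates and per-sample
clade summaries cheap; conversion to and from dendropy handles all
Newick/NEXUS parsing and writing.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidCladeError, TreeFormatError

_RATE_COMMENT = re.compile(r"&?rate\s*=\s*([0-9eE+.\-]+)")


@dataclass
class TimeTree:
    labels: list[str]                 # tip labels, tip id = index
    parent: np.ndarray                # (2n-1,) int; -1 at root
    children: np.ndarray              # (2n-1, 2) int; -1 rows for tips
    heights: np.ndarray               # (2n-1,) float; tips 0
    rates: np.ndarray = field(default=None)  # type: ignore[assignment]
    clades: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.children = np.asarray(self.children, dtype=np.int64)
        self.heights = np.asarray(self.heights, dtype=float)
        n_nodes = self.parent.size
        if n_nodes != 2 * self.n_tips - 1:
            raise TreeFormatError("node arrays inconsistent with a binary tree")
        if self.rates is None:
            self.rates = np.full(n_nodes, np.nan)
        self.rates = np.asarray(self.rates, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeFormatError("tree must have exactly one root")
        self._root = int(roots[0])
        self._postorder: np.ndarray | None = None
        self._leafsets: list[frozenset[int]] | None = None

    # -- basic structure -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self._root

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def postorder_internal(self) -> np.ndarray:
        """Internal node ids, children-before-parents."""
        if self._postorder is None:
            order: list[int] = []
            stack = [(self._root, False)]
            while stack:
                node, done = stack.pop()
                if node < self.n_tips:
                    continue
                if done:
                    order.append(node)
                else:
                    stack.append((node, True))
                    stack.extend((int(c), False) for c in self.children[node])
            self._postorder = np.asarray(order, dtype=np.int64)
        return self._postorder

    def durations(self) -> np.ndarray:
        """Time span of the branch above each node (0 at the root)."""
        d = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        d[mask] = self.heights[self.parent[mask]] - self.heights[mask]
        return d

    def total_time(self) -> float:
        return float(self.durations().sum())

    def branch_ids(self) -> np.ndarray:
        """Ids of nodes that carry a branch (everything but the root)."""
        return np.flatnonzero(self.parent >= 0)

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        return bool(np.all(np.abs(self.heights[: self.n_tips]) <= tol))

    def validate_heights(self) -> bool:
        mask = self.parent >= 0
        return bool(np.all(self.heights[self.parent[mask]] > self.heights[mask] - 1e-15))

    # -- clades ----------------------------------------------------------
    def leaf_sets(self) -> list[frozenset[int]]:
        """Tip-id set below each node."""
        if self._leafsets is None:
            sets: list[frozenset[int] | None] = [None] * self.n_nodes
            for tip in range(self.n_tips):
                sets[tip] = frozenset((tip,))
            for node in self.postorder_internal():
                c1, c2 = self.children[node]
                sets[node] = sets[c1] | sets[c2]  # type: ignore[operator]
            self._leafsets = sets  # type: ignore[assignment]
        return self._leafsets  # type: ignore[return-value]

    def tip_ids(self, tip_labels: Iterable[str]) -> frozenset[int]:
        index = {t: i for i, t in enumerate(self.labels)}
        missing = [t for t in tip_labels if t not in index]
        if missing:
            raise InvalidCladeError(f"clade members not in tree: {missing}")
        return frozenset(index[t] for t in tip_labels)

    def mrca(self, tip_labels: Iterable[str]) -> int:
        want = self.tip_ids(tip_labels)
        best, best_size = self._root, self.n_tips + 1
        for node, ls in enumerate(self.leaf_sets()):
            if want <= ls and len(ls) < best_size:
                best, best_size = node, len(ls)
        return best

    def is_monophyletic(self, tip_labels: Iterable[str]) -> bool:
        want = self.tip_ids(tip_labels)
        return len(self.leaf_sets()[self.mrca(tip_labels)]) == len(want)

    def clade_edges(self, tip_labels: Iterable[str]) -> np.ndarray:
        """Node ids of crown branches strictly inside the clade (stem excluded)."""
        if not self.is_monophyletic(tip_labels):
            raise InvalidCladeError(
                f"tip set is not monophyletic: {sorted(tip_labels)}")
        mrca = self.mrca(tip_labels)
        want = self.leaf_sets()[mrca]
        return np.asarray(
            [n for n, ls in enumerate(self.leaf_sets())
             if n != mrca and ls <= want], dtype=np.int64)

    def named_clades_of_size(self, min_size: int, max_size: int | None = None
                             ) -> dict[str, frozenset[str]]:
        """All monophyletic tip sets within a size range, keyed c0, c1, ..."""
        max_size = max_size or self.n_tips - 1
        out: dict[str, frozenset[str]] = {}
        k = 0
        for node in sorted(self.postorder_internal().tolist()):
            ls = self.leaf_sets()[node]
            if min_size <= len(ls) <= max_size and len(ls) < self.n_tips:
                out[f"c{k}"] = frozenset(self.labels[i] for i in ls)
                k += 1
        return out

    # -- copies ----------------------------------------------------------
    def copy(self) -> "TimeTree":
        return TimeTree(list(self.labels), self.parent.copy(), self.children.copy(),
                        self.heights.copy(), self.rates.copy(), dict(self.clades))

    def with_state(self, heights: np.ndarray, rates: np.ndarray) -> "TimeTree":
        """Same topology with replacement heights/rates (no copy of arrays)."""
        t = TimeTree(self.labels, self.parent, self.children,
                     np.asarray(heights, dtype=float),
                     np.asarray(rates, dtype=float), self.clades)
        return t

    # -- serialization ---------------------------------------------------
    def newick(self, include_rates: bool = False, precision: int = 12) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def rec(node: int) -> str:
            if node < self.n_tips:
                core = self.labels[node]
            else:
                c1, c2 = self.children[node]
                core = f"({rec(int(c1))},{rec(int(c2))})"
            if self.parent[node] < 0:
                return core
            bl = self.heights[self.parent[node]] - self.heights[node]
            ann = ""
            if include_rates and np.isfinite(self.rates[node]):
                ann = f"[&rate={fmt(self.rates[node])}]"
            return f"{core}{ann}:{fmt(bl)}"

        return rec(self._root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "TimeTree":
        import dendropy
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 extract_comment_metadata=False)
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree) -> "TimeTree":
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        for nd in internals:
            if len(nd.child_nodes()) != 2:
                raise TreeFormatError(
                    "tree is polytomous or unrooted; the fixed-topology engine "
                    "requires a fully resolved rooted binary tree")
        labels = []
        for nd in tips:
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise TreeFormatError("tip without a label")
            labels.append(lab)
        if len(set(labels)) != len(labels):
            raise TreeFormatError("duplicate tip labels")
        n = len(labels)
        ids = {}
        for i, nd in enumerate(tips):
            ids[id(nd)] = i
        for j, nd in enumerate(internals):
            ids[id(nd)] = n + j
        n_nodes = 2 * n - 1
        if len(nodes) != n_nodes:
            raise TreeFormatError("tree is not strictly binary")
        parent = np.full(n_nodes, -1, dtype=np.int64)
        children = np.full((n_nodes, 2), -1, dtype=np.int64)
        depth = np.zeros(n_nodes)
        rates = np.full(n_nodes, np.nan)
        for nd in nodes:
            me = ids[id(nd)]
            if nd.parent_node is not None:
                pa = ids[id(nd.parent_node)]
                parent[me] = pa
                depth[me] = depth[pa] + (nd.edge.length or 0.0)
            for k, ch in enumerate(nd.child_nodes()):
                children[me, k] = ids[id(ch)]
            for comment in (nd.comments or []):
                m = _RATE_COMMENT.search(comment)
                if m:
                    rates[me] = float(m.group(1))
        heights = depth.max() - depth
        # snap tiny numerical noise on tip heights to zero
        tipmask = np.arange(n_nodes) < n
        heights[tipmask & (np.abs(heights) < 1e-9)] = 0.0
        return cls(labels, parent, children, heights, rates)


def read_tree(path: str | Path, fmt: str = "newick") -> TimeTree:
    """Read a rooted binary tree from a Newick or NEXUS file."""
    import dendropy
    path = Path(path)
    if not path.exists():
        raise TreeFormatError(f"no such tree file: {path}")
    if fmt not in ("newick", "nexus"):
        raise TreeFormatError(f"unsupported tree format {fmt!r}")
    try:
        tree = dendropy.Tree.get(path=str(path), schema=fmt,
                                 suppress_internal_node_taxa=True,
                                 extract_comment_metadata=False)
    except Exception as exc:
        raise TreeFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    return TimeTree.from_dendropy(tree)


def write_tree(tree: TimeTree, path: str | Path, include_rates: bool = False,
               header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"[{line}]\n")
        fh.write(tree.newick(include_rates=include_rates) + "\n")


def write_nexus_trees(trees: Iterable[tuple[str, TimeTree]], path: str | Path,
                      include_rates: bool = True,
                      header_lines: Sequence[str] = ()) -> None:
    """Write a NEXUS trees block with BEAST-style bracketed rate comments."""
    trees = list(trees)
    if not trees:
        raise TreeFormatError("no trees to write")
    taxa = trees[0][1].labels
    buf = io.StringIO()
    buf.write("#NEXUS\n")
    for line in header_lines:
        buf.write(f"[{line}]\n")
    buf.write("BEGIN TAXA;\n")
    buf.write(f"    DIMENSIONS NTAX={len(taxa)};\n    TAXLABELS\n")
    for t in taxa:
        buf.write(f"        {_nexus_token(t)}\n")
    buf.write("    ;\nEND;\nBEGIN TREES;\n")
    for name, tr in trees:
        buf.write(f"    TREE {name} = [&R] "
                  f"{tr.newick(include_rates=include_rates)}\n")
    buf.write("END;\n")
    Path(path).write_text(buf.getvalue())


def _nexus_token(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"
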