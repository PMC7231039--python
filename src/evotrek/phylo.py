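"""Species trees, Newick I/O, Jukes-Cantor distances and neighbor joining.

The tree container used throughout the package is :class:`SpeciesTree`, a
rooted tree with stable integer node ids, optional node names and
non-negative branch lengths (expected substitutions per site).  The Newick
dialect is deliberately small: unquoted labels, optional branch lengths,
optional internal labels, no comments or NHX in input.  Serialization is
canonical (children in stored order, lengths printed with ``%.12g``) so that
``parse -> write -> parse -> write`` is a fixed point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Node",
    "SpeciesTree",
    "NewickError",
    "TreeError",
    "DistanceMatrix",
    "parse_newick",
    "write_newick",
    "jc_distance",
    "neighbor_joining",
    "root_with_outgroup",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class TreeError(ValueError):
    """Structurally invalid tree or invalid tree operation."""


@dataclass
class Node:
    id: int
    name: Optional[str] = None
    length: float = 0.0  # length of the branch above this node (0 for root)
    parent: Optional["Node"] = field(default=None, repr=False)
    children: list["Node"] = field(default_factory=list, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted phylogeny with uniquely named leaves.

    Branch lengths hang on child nodes; the root's length is ignored.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()
        self.validate()

    # -- construction / bookkeeping -------------------------------------

    def _index(self) -> None:
        self.nodes: dict[int, Node] = {}
        for node in self.preorder():
            if node.id in self.nodes:
                raise TreeError(f"duplicate node id {node.id}")
            self.nodes[node.id] = node

    def validate(self) -> None:
        names = [leaf.name for leaf in self.leaves()]
        if any(not n for n in names):
            raise TreeError("every leaf must have a non-empty name")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf names: {dupes}")
        for node in self.preorder():
            if node is not self.root and node.parent is None:
                raise TreeError(f"non-root node {node.id} has no parent")
            if not (node.length >= 0 and math.isfinite(node.length)):
                raise TreeError(
                    f"branch length of node {node.id} must be finite and >= 0"
                )

    # -- traversal ------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        yield from reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]  # type: ignore[misc]

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if node.name == name:
                return node
        raise TreeError(f"no node named {name!r}")

    def depth(self, node: Node) -> int:
        """Number of edges from the root."""
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def subtree_leaves(self, node: Node) -> list[Node]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            stack.extend(n.children)
        return out

    # -- metrics --------------------------------------------------------

    def leaf_path_lengths(self) -> "DistanceMatrix":
        """Patristic (path-length) distances between all leaf pairs."""
        leaves = self.leaves()
        names = [l.name for l in leaves]
        # distance from every node to root, then d(a,b) = da + db - 2*d(lca)
        to_root: dict[int, float] = {self.root.id: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                to_root[node.id] = to_root[node.parent.id] + node.length
        n = len(leaves)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                lca = self._lca(leaves[i], leaves[j])
                d = to_root[leaves[i].id] + to_root[leaves[j].id] - 2 * to_root[lca.id]
                mat[i, j] = mat[j, i] = d
        return DistanceMatrix(names, mat)  # type: ignore[arg-type]

    def _lca(self, a: Node, b: Node) -> Node:
        anc = set()
        n: Optional[Node] = a
        while n is not None:
            anc.add(n.id)
            n = n.parent
        n = b
        while n is not None:
            if n.id in anc:
                return n
            n = n.parent
        raise TreeError("nodes share no ancestor")  # pragma: no cover

    def copy(self) -> "SpeciesTree":
        return parse_newick(write_newick(self))

    # -- serialization --------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({write_newick(self)})"


# ---------------------------------------------------------------------------
# Newick


def _fmt_len(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: SpeciesTree, branch_comments: Optional[dict[int, str]] = None) -> str:
    """Canonical Newick serialization.

    ``branch_comments`` maps node id -> text emitted as a bracketed comment
    after that node's branch length (used by the event report).
    """

    def rec(node: Node) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.name:
                s += node.name
        if node.parent is not None:
            s += f":{_fmt_len(node.length)}"
            if branch_comments and node.id in branch_comments:
                s += f"[{branch_comments[node.id]}]"
        return s

    return rec(tree.root) + ";"


def parse_newick(text: str) -> SpeciesTree:
    """Parse a Newick string into a :class:`SpeciesTree`.

    Unquoted labels only; bracketed comments are rejected.  Raises
    :class:`NewickError` on malformed input and :class:`TreeError` on
    duplicate leaf names.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0
    counter = 0

    def new_node() -> Node:
        nonlocal counter
        node = Node(id=counter)
        counter += 1
        return node

    def parse_clade() -> Node:
        nonlocal pos
        node = new_node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child = parse_clade()
                child.parent = node
                node.children.append(child)
                if pos >= len(s):
                    raise NewickError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {s[pos]!r} at {pos}")
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;[":
            pos += 1
        label = s[start:pos]
        if label:
            node.name = label
        if pos < len(s) and s[pos] == "[":
            raise NewickError("bracketed comments are not accepted in input")
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()[;":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError as exc:
                raise NewickError(f"bad branch length {s[start:pos]!r}") from exc
            if pos < len(s) and s[pos] == "[":
                raise NewickError("bracketed comments are not accepted in input")
        return node

    root = parse_clade()
    if pos != len(s):
        raise NewickError(f"trailing characters after tree: {s[pos:]!r}")
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# Distances


_NUCS = frozenset("ACGT")


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance between two aligned nucleotide sequences.

    Columns with a gap or ambiguity code in either sequence are excluded
    (pairwise deletion).  Returns ``nan`` (an explicitly undefined value)
    when the mismatch fraction p >= 0.75 or no columns are retained;
    otherwise ``d = -(3/4) ln(1 - 4p/3)``.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    kept = 0
    diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _NUCS and y in _NUCS:
            kept += 1
            if x != y:
                diff += 1
    if kept == 0:
        return math.nan
    p = diff / kept
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


class DistanceMatrix:
    """Symmetric non-negative distance matrix over ordered taxa.

    Undefined entries are ``nan`` — explicitly flagged, never silently zero.
    """

    def __init__(self, taxa: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(taxa), len(taxa)):
            raise ValueError("matrix shape does not match taxa")
        with np.errstate(invalid="ignore"):
            if not np.allclose(matrix, matrix.T, equal_nan=True):
                raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(matrix), 0.0):
            raise ValueError("diagonal must be zero")
        defined = ~np.isnan(matrix)
        if np.any(matrix[defined] < 0):
            raise ValueError("distances must be non-negative")
        self.taxa = list(taxa)
        self.matrix = matrix

    def has_undefined(self) -> bool:
        return bool(np.isnan(self.matrix).any())

    @classmethod
    def from_alignment(cls, names: Sequence[str], rows: Sequence[str]) -> "DistanceMatrix":
        n = len(names)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = jc_distance(rows[i], rows[j])
        return cls(names, mat)


def neighbor_joining(dm: DistanceMatrix) -> SpeciesTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Joins the pair minimizing the Q criterion; ties broken by the lowest
    (i, j) index pair in the current working order.  Negative estimated
    branch lengths are clamped to zero with a warning.  Returns the
    standard rooted representation of the unrooted NJ tree: a trifurcation
    at the top for >= 3 taxa.
    """
    if dm.has_undefined():
        raise ValueError("distance matrix contains undefined entries")
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    counter = 0

    def new_node(name: Optional[str] = None) -> Node:
        nonlocal counter
        node = Node(id=counter, name=name)
        counter += 1
        return node

    active: list[Node] = [new_node(t) for t in dm.taxa]
    D = dm.matrix.astype(float).copy()

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(f"negative NJ branch length {x:.3g} clamped to 0")
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = D.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best  # type: ignore[misc]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        u = new_node()
        active[i].length = clamp(li)
        active[j].length = clamp(lj)
        active[i].parent = active[j].parent = u
        u.children = [active[i], active[j]]
        # distances from u to every other active node
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        active = [active[k] for k in keep] + [u]

    a, b = active
    d = D[0, 1]
    # attach the remaining pair; root at an internal node if one exists
    if not b.is_leaf:
        a, b = b, a
    if a.is_leaf:  # both leaves: only possible for n == 2, excluded above
        raise AssertionError("unreachable")
    b.length = clamp(d)
    b.parent = a
    a.children.append(b)
    a.length = 0.0
    a.parent = None
    return SpeciesTree(a)


def root_with_outgroup(tree: SpeciesTree, outgroup: str) -> SpeciesTree:
    """Root (or re-root) a tree on the outgroup's pendant edge.

    The new root is placed at the midpoint of the edge carrying the
    outgroup leaf (edge lengths measured on the unrooted tree, i.e. a
    previous degree-2 root is suppressed first).  Leaf names and pairwise
    path lengths are preserved.
    """
    leaf_names = set(tree.leaf_names())
    if outgroup not in leaf_names:
        raise TreeError(f"outgroup {outgroup!r} is not a leaf of the tree")

    # build an undirected adjacency with edge lengths
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, Optional[str]] = {}
    for node in tree.preorder():
        adj.setdefault(node.id, [])
        names[node.id] = node.name
        if node.parent is not None:
            adj.setdefault(node.parent.id, [])
            adj[node.id].append((node.parent.id, node.length))
            adj[node.parent.id].append((node.id, node.length))
    # suppress the old root if it has degree 2 on the unrooted tree
    rid = tree.root.id
    if len(adj[rid]) == 2:
        (u, lu), (v, lv) = adj[rid]
        adj[u] = [(w, l) for (w, l) in adj[u] if w != rid] + [(v, lu + lv)]
        adj[v] = [(w, l) for (w, l) in adj[v] if w != rid] + [(u, lu + lv)]
        del adj[rid]

    og_id = tree.find(outgroup).id
    (attach, pend_len), = adj[og_id]

    counter = max(adj) + 1
    new_root = Node(id=counter, name=None)
    og_node = Node(id=og_id, name=outgroup, length=pend_len / 2.0, parent=new_root)
    new_root.children.append(og_node)

    def build(nid: int, parent_id: int, length: float, parent_node: Node) -> None:
        node = Node(id=nid, name=names.get(nid), length=length, parent=parent_node)
        parent_node.children.append(node)
        for (w, l) in sorted(adj[nid], key=lambda t: t[0]):
            if w != parent_id:
                build(w, nid, l, node)

    build(attach, og_id, pend_len / 2.0, new_root)
    return SpeciesTree(new_root)
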