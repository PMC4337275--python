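"""Gene trees: Newick ingestion, outgroup rooting, and a neighbor-joining
stand-in builder.

Gene trees analysed here are typically inferred upstream by maximum
likelihood or Bayesian methods and consumed as Newick text with support
values stored as internal-node labels.  Posterior probabilities (0-1) and
bootstrap percentages (0-100) are normalized onto one 0-1 scale so a single
support threshold applies throughout.  The bundled neighbor-joining builder
exists for desk-scale work (fixtures, smoke tests); it is not a replacement
for proper phylogenetic inference.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .records import InputError


class TreeError(InputError):
    """Raised for malformed or inconsistent tree input."""


class Clade:
    """A node of a gene tree.

    ``length`` and ``support`` describe the edge above the node (the root
    carries neither).  Supports are stored on the 0-1 scale.
    """

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name: str | None = name
        self.length: float | None = length
        self.support: float | None = support
        self.children: list[Clade] = []
        self.parent: Clade | None = None
        for child in children or ():
            self.add(child)

    def add(self, child: "Clade") -> "Clade":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Clade"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Clade"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.name if self.is_leaf else f"internal({len(self.children)})"
        return f"<Clade {kind}>"


@dataclass
class GeneTree:
    """A gene tree plus the leaf -> (taxon, lineage) map.

    ``rooted`` is True when the root is a meaningful bifurcation (e.g. after
    :func:`root_on_outgroup`); trees parsed with a basal multifurcation are
    treated as unrooted.
    """

    root: Clade
    meta: dict[str, tuple[str, str]] = field(default_factory=dict)
    rooted: bool = False

    def __post_init__(self) -> None:
        names = self.root.leaf_names()
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")

    def leaves(self) -> list[Clade]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def taxon_of(self, leaf_name: str) -> str:
        return self.meta.get(leaf_name, (leaf_name, "other"))[0]

    def lineage_of(self, leaf_name: str) -> str:
        return self.meta.get(leaf_name, (leaf_name, "other"))[1]

    def copy(self) -> "GeneTree":
        return GeneTree(copy.deepcopy(self.root), dict(self.meta), self.rooted)


def _normalize_support(value: float, where: str) -> float:
    if 0.0 <= value <= 1.0:
        return value
    if 1.0 < value <= 100.0:  # bootstrap percentage convention
        return value / 100.0
    raise TreeError(f"support value {value} out of range at {where}")


def parse_newick(
    text: str,
    metadata: Mapping[str, tuple[str, str]] | None = None,
) -> GeneTree:
    """Parse Newick text into a :class:`GeneTree`.

    Internal-node labels that parse as numbers are taken as support values;
    values above 1 are interpreted as bootstrap percentages and divided by
    100.  Non-numeric internal labels are kept as node names.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> Clade:
        node = Clade()
        node.length = (
            float(dnode.edge.length) if dnode.edge.length is not None else None
        )
        if dnode.is_leaf():
            node.name = dnode.taxon.label if dnode.taxon else dnode.label
            if node.name is None:
                raise TreeError("unlabeled leaf in newick input")
        else:
            label = dnode.label
            if label is not None:
                try:
                    node.support = _normalize_support(
                        float(label), f"internal node {label!r}"
                    )
                except ValueError:
                    node.name = label
            for dchild in dnode.child_nodes():
                node.add(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    rooted = len(root.children) == 2
    return GeneTree(root, dict(metadata or {}), rooted)


def _fmt_length(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: GeneTree | Clade) -> str:
    """Serialize a tree to Newick; supports written as internal labels."""
    root = tree.root if isinstance(tree, GeneTree) else tree

    def render(node: Clade) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = _fmt_length(node.support)
            elif node.name:
                label = node.name
            s = f"({inner}){label}"
        if node.length is not None:
            s += f":{_fmt_length(node.length)}"
        return s

    return render(root) + ";"


def read_leaf_metadata(source: str | Path | io.TextIOBase) -> dict[str, tuple[str, str]]:
    """Read a leaf metadata TSV with columns leaf_id, taxon_name, lineage."""
    frame = pd.read_csv(source, sep="\t", dtype=str)
    required = {"leaf_id", "taxon_name", "lineage"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"leaf metadata TSV missing columns: {sorted(missing)}")
    return {
        row.leaf_id: (row.taxon_name, row.lineage)
        for row in frame.itertuples(index=False)
    }


def write_leaf_metadata(meta: Mapping[str, tuple[str, str]], dest) -> None:
    frame = pd.DataFrame(
        [(k, v[0], v[1]) for k, v in meta.items()],
        columns=["leaf_id", "taxon_name", "lineage"],
    )
    frame.to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# outgroup rooting
# ---------------------------------------------------------------------------

def _half(x: float | None) -> float | None:
    return None if x is None else x / 2.0


def root_on_outgroup(tree: GeneTree, outgroup: Iterable[str]) -> GeneTree:
    """Root the tree on the branch separating ``outgroup`` from the rest.

    The outgroup must form one side of a split of the unrooted topology;
    otherwise an error lists the intruding leaves.  The split branch's
    length is apportioned 50/50 to the two sides of the new root and its
    support is carried by both root children, keeping round trips
    deterministic.
    """
    outgroup = set(outgroup)
    if not outgroup:
        raise TreeError("outgroup must be non-empty")
    all_leaves = set(tree.leaf_names())
    unknown = outgroup - all_leaves
    if unknown:
        raise TreeError(f"outgroup leaves not in tree: {sorted(unknown)}")
    if outgroup == all_leaves:
        raise TreeError("outgroup cannot contain every leaf")

    if len(all_leaves) == 2:
        a, b = copy.deepcopy(tree.root).children
        total = None
        if a.length is not None or b.length is not None:
            total = (a.length or 0.0) + (b.length or 0.0)
        a.length = b.length = _half(total)
        a.parent = b.parent = None
        pair = [a, b] if {a.name} == outgroup else [b, a]
        return GeneTree(Clade(children=pair), dict(tree.meta), rooted=True)

    work = copy.deepcopy(tree.root)

    # Collapse a degree-2 root so the starting point is properly unrooted:
    # the two edges meeting at such a root are one physical branch.
    if len(work.children) == 2 and any(not c.is_leaf for c in work.children):
        a, b = work.children
        keep, fold = (a, b) if not a.is_leaf else (b, a)
        merged_len = None
        if keep.length is not None or fold.length is not None:
            merged_len = (keep.length or 0.0) + (fold.length or 0.0)
        fold.length = merged_len
        fold.support = fold.support if fold.support is not None else keep.support
        keep.add(fold)
        keep.parent = None
        keep.length = None
        keep.support = None
        work = keep

    # locate the edge whose child-side leaf set is the outgroup (or its
    # complement)
    leafsets: dict[int, set[str]] = {}

    def fill(node: Clade) -> set[str]:
        s = {node.name} if node.is_leaf else set()
        for c in node.children:
            s |= fill(c)
        leafsets[id(node)] = s
        return s

    fill(work)
    complement = all_leaves - outgroup
    target: Clade | None = None
    for node in work.preorder():
        if node is work:
            continue
        below = leafsets[id(node)]
        if below == outgroup or below == complement:
            target = node
            break
    if target is None:
        # report intruders under the minimal clade spanning the outgroup
        best = min(
            (n for n in work.preorder() if outgroup <= leafsets[id(n)]),
            key=lambda n: len(leafsets[id(n)]),
        )
        intruders = sorted(leafsets[id(best)] - outgroup)
        raise TreeError(
            f"outgroup is not monophyletic; intruding leaves: {intruders}"
        )

    new_root = _reroot_on_edge(work, target)
    # orient: outgroup child first
    def side_leaves(c: Clade) -> set[str]:
        return set(c.leaf_names())

    if side_leaves(new_root.children[0]) != outgroup:
        new_root.children.reverse()
    return GeneTree(new_root, dict(tree.meta), rooted=True)


def _reroot_on_edge(root: Clade, target: Clade) -> Clade:
    """Place a new root at the midpoint of the edge above ``target``."""
    edge_length = target.length
    edge_support = target.support

    def reversed_side(node: Clade, coming_from: Clade) -> Clade:
        """Rebuild ``node``'s side of the tree with edges oriented away from
        the new root.  The edge between ``node`` and ``coming_from`` has
        already been consumed by the caller."""
        fresh = Clade(name=node.name)
        kids = [c for c in node.children if c is not coming_from]
        up = node.parent
        for c in kids:
            fresh.add(c)
        if up is not None:
            parent_sub = reversed_side(up, node)
            # the reversed edge carries node's own (old) edge attributes
            parent_sub.length = node.length
            parent_sub.support = node.support
            fresh.add(parent_sub)
        return fresh

    upper = reversed_side(target.parent, target)
    upper.length = _half(edge_length)
    upper.support = edge_support

    lower = target
    lower.parent = None
    lower.length = _half(edge_length)
    lower.support = edge_support

    new_root = Clade(children=[lower, upper])
    return new_root


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_build(
    distances: np.ndarray | Sequence[Sequence[float]],
    labels: Sequence[str],
) -> GeneTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou-Nei agglomeration with deterministic tie-breaking
    (lexicographically smallest join).  On an additive matrix the generating
    topology and edge lengths are recovered exactly; negative estimated
    branch lengths (possible on non-additive input) are clamped to zero.
    The result is unrooted (basal trifurcation).
    """
    d = np.asarray(distances, dtype=float)
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise InputError("neighbor joining requires at least 3 taxa")
    if d.shape != (n, n):
        raise InputError(f"distance matrix shape {d.shape} does not match {n} labels")
    if not np.all(np.isfinite(d)):
        raise InputError("distance matrix contains NaN or infinite entries")
    if np.any(d < 0):
        raise InputError("distance matrix contains negative entries")
    if not np.allclose(d, d.T):
        raise InputError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise InputError("distance matrix diagonal must be zero")

    nodes: list[Clade] = [Clade(name=lab) for lab in labels]
    d = d.copy()

    def clamp(x: float) -> float:
        return 0.0 if x < 0 else x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic arg-min: smallest Q, ties to smallest (i, j)
        best = np.unravel_index(np.argmin(q), q.shape)
        i, j = min(best), max(best)
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        joined = Clade()
        a, b = nodes[i], nodes[j]
        a.length = clamp(li)
        b.length = clamp(lj)
        joined.add(a)
        joined.add(b)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = new_d[keep]
        d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [joined]

    # resolve the final 3-star with closed-form pendant lengths
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp((dab + dac - dbc) / 2.0)
    b.length = clamp((dab + dbc - dac) / 2.0)
    c.length = clamp((dac + dbc - dab) / 2.0)
    root = Clade(children=[a, b, c])
    return GeneTree(root, rooted=False)


def splits(tree: GeneTree | Clade) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted topology, each represented
    by the smaller (or lexicographically first) side."""
    root = tree.root if isinstance(tree, GeneTree) else tree
    all_leaves = frozenset(root.leaf_names())
    out: set[frozenset[str]] = set()
    for node in root.preorder():
        if node is root or node.is_leaf:
            continue
        below = frozenset(node.leaf_names())
        other = all_leaves - below
        if not other:
            continue
        canon = min(below, other, key=lambda s: (len(s), sorted(s)))
        if len(canon) >= 2:
            out.add(canon)
    return out


def leaf_distances(tree: GeneTree | Clade) -> tuple[list[str], np.ndarray]:
    """Patristic (path-length) distances between all leaf pairs."""
    root = tree.root if isinstance(tree, GeneTree) else tree
    leaves = root.leaves()
    names = [l.name for l in leaves]
    n = len(leaves)
    dist = np.zeros((n, n))

    def path_to_root(node: Clade) -> list[Clade]:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    paths = [path_to_root(l) for l in leaves]
    for i in range(n):
        anc_i = {id(x): k for k, x in enumerate(paths[i])}
        for j in range(i + 1, n):
            # find lowest common ancestor
            for node in paths[j]:
                if id(node) in anc_i:
                    lca = node
                    break
            total = 0.0
            for node in (leaves[i], leaves[j]):
                cur = node
                while cur is not lca:
                    total += cur.length or 0.0
                    cur = cur.parent
            dist[i, j] = dist[j, i] = total
    return names, dist
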