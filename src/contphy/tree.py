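"""Time-calibrated phylogenies with heterochronous tips and sampled ancestors.

Internal representation: node ages in time-before-present (youngest tip at
age 0 unless explicit tip dates are supplied).  A sampled ancestor is stored
as a flagged tip attached to its host node by a zero-length edge, which is
also the on-disk convention (BEAST-style zero-length terminal edges).

Taxon ordering everywhere (covariance matrices, character matrices) is
lexicographic by tip label.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

from .errors import TaxonLookupError, TreeParseError, ValidationError

__all__ = [
    "Node",
    "TimeTree",
    "CladeConstraint",
    "parse_tree",
    "write_tree",
    "phylo_vcv",
    "shared_path_length",
    "prune_taxa",
    "mcc_tree",
]

_AGE_TOL = 1e-9


class Node:
    """A node in a :class:`TimeTree`."""

    __slots__ = ("id", "label", "age", "parent", "children", "rate", "sampled_ancestor")

    def __init__(
        self,
        id: int,
        label: str | None = None,
        age: float = 0.0,
        rate: float = 1.0,
        sampled_ancestor: bool = False,
    ) -> None:
        self.id = id
        self.label = label
        self.age = float(age)
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.rate = float(rate)  # relative rate of the edge to the parent
        self.sampled_ancestor = sampled_ancestor

    @property
    def is_tip(self) -> bool:
        return not self.children

    def edge_length(self) -> float:
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node(id={self.id}, label={self.label!r}, age={self.age:.6g})"


class TimeTree:
    """Rooted time tree; see module docstring for conventions."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def nodes(self) -> list[Node]:
        return list(self.preorder())

    def tips(self) -> list[Node]:
        """All sampled taxa: ordinary tips plus sampled-ancestor tips."""
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [n for n in self.preorder() if n.children]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    def taxon_labels(self) -> list[str]:
        """Tip labels in the canonical (lexicographic) order."""
        return sorted(n.label for n in self.tips())

    def tip(self, label: str) -> Node:
        for n in self.tips():
            if n.label == label:
                return n
        raise TaxonLookupError(f"no tip labelled {label!r}")

    def n_tips(self) -> int:
        return len(self.tips())

    # -- bookkeeping --------------------------------------------------------

    def reindex(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.id = i

    def copy(self) -> "TimeTree":
        mapping: dict[int, Node] = {}
        for node in self.preorder():
            clone = Node(node.id, node.label, node.age, node.rate, node.sampled_ancestor)
            mapping[id(node)] = clone
            if node.parent is not None:
                mapping[id(node.parent)].add_child(clone)
        return TimeTree(mapping[id(self.root)])

    def validate(self) -> None:
        labels = [n.label for n in self.tips()]
        if any(not lab for lab in labels):
            raise ValidationError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            raise ValidationError("tip labels must be unique")
        for node in self.preorder():
            if node.age < -_AGE_TOL:
                raise ValidationError(f"negative node age at {node!r}")
            if node.rate <= 0:
                raise ValidationError(f"non-positive branch rate at {node!r}")
            if node.parent is not None:
                dt = node.parent.age - node.age
                if dt < -_AGE_TOL:
                    raise ValidationError(f"child older than parent at {node!r}")
                if dt <= _AGE_TOL and node.is_tip and not node.sampled_ancestor:
                    raise ValidationError(
                        f"zero-length terminal edge at {node.label!r} lacks the "
                        "sampled-ancestor flag"
                    )
            if node.sampled_ancestor and not node.is_tip:
                raise ValidationError("sampled-ancestor flag on an internal node")

    # -- queries ------------------------------------------------------------

    def mrca(self, u: str, w: str) -> Node:
        pu = self._root_path(self.tip(u))
        pw = set(id(n) for n in self._root_path(self.tip(w)))
        for node in pu:
            if id(node) in pw:
                return node
        raise ValidationError("disconnected tree")  # pragma: no cover

    def _root_path(self, node: Node) -> list[Node]:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    def count_sampled_ancestors(self) -> int:
        return sum(1 for n in self.tips() if n.sampled_ancestor)

    def total_branch_length(self) -> float:
        return sum(n.edge_length() for n in self.preorder() if n.parent is not None)

    def bipartitions(self) -> set[frozenset[str]]:
        """Clades (as tip-label sets) of all internal nodes below the root."""
        out: set[frozenset[str]] = set()
        clade = _clade_map(self)
        for node in self.internal_nodes(include_root=False):
            out.add(clade[id(node)])
        return out

    def newick(self, include_rates: bool = False) -> str:
        return _to_newick(self, include_rates=include_rates) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree(n_tips={self.n_tips()}, root_age={self.root.age:.6g})"


class CladeConstraint:
    """A set of tip labels required to be monophyletic during tree search."""

    def __init__(self, labels: Iterable[str], fixed_subtopology: bool = False) -> None:
        self.labels = frozenset(labels)
        if not self.labels:
            raise ValidationError("constraint label set must be non-empty")
        self.fixed_subtopology = fixed_subtopology

    def satisfied_by(self, tree: TimeTree) -> bool:
        tips = set(tree.taxon_labels())
        if not self.labels <= tips:
            raise ValidationError("constraint labels not a subset of tree tips")
        if self.labels == tips:
            return True
        return self.labels in tree.bipartitions() or len(self.labels) == 1


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------


def parse_tree(
    text: str,
    dialect: str = "newick",
    tip_ages: dict[str, float] | None = None,
) -> TimeTree:
    """Parse a Newick/NEXUS tree into a :class:`TimeTree`.

    Node ages are recovered from branch lengths; the youngest tip anchors
    age 0 unless explicit ``tip_ages`` (taxon -> age) are supplied.
    Zero-length terminal edges are flagged as sampled ancestors.
    """
    if dialect not in ("newick", "nexus"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=dialect,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeParseError(f"could not parse {dialect} tree: {exc}") from exc

    root = Node(0)
    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    mapping = {id(dtree.seed_node): root}
    for dnode in dtree.preorder_node_iter():
        if dnode is dtree.seed_node:
            continue
        length = dnode.edge.length
        if length is None:
            raise TreeParseError(f"missing branch length above {dnode}")
        if length < 0:
            raise ValidationError(f"negative branch length {length} above {dnode}")
        node = Node(0)
        if dnode.taxon is not None:
            node.label = dnode.taxon.label
        elif dnode.is_leaf():
            node.label = str(dnode.label) if dnode.label else None
        rate = _annotation_value(dnode, "rate")
        if rate is not None:
            node.rate = float(rate)
        mapping[id(dnode.parent_node)].add_child(node)
        mapping[id(dnode)] = node
        depth[id(dnode)] = depth[id(dnode.parent_node)] + length

    # depths -> ages
    tree = TimeTree(root)
    max_depth = max(depth[id(d)] for d in dtree.leaf_node_iter())
    for dnode in dtree.preorder_node_iter():
        mapping[id(dnode)].age = max_depth - depth[id(dnode)]
    if tip_ages:
        offsets = []
        for tip in tree.tips():
            if tip.label in tip_ages:
                offsets.append(tip_ages[tip.label] - tip.age)
        if not offsets:
            raise ValidationError("tip_ages shares no labels with the tree")
        if max(offsets) - min(offsets) > 1e-6:
            raise ValidationError("tip_ages inconsistent with branch lengths")
        off = offsets[0]
        for node in tree.preorder():
            node.age += off
    for node in tree.preorder():
        if abs(node.age) <= _AGE_TOL:
            node.age = abs(node.age)
        if (
            node.is_tip
            and node.parent is not None
            and node.parent.age - node.age <= _AGE_TOL
        ):
            node.sampled_ancestor = True
    tree.reindex()
    tree.validate()
    return tree


def _annotation_value(dnode, key: str):
    try:
        return dnode.annotations.get_value(key)
    except Exception:  # pragma: no cover
        return None


def _to_newick(tree: TimeTree, include_rates: bool = False) -> str:
    def render(node: Node) -> str:
        if node.is_tip:
            core = _quote(node.label)
        else:
            core = "(" + ",".join(render(c) for c in node.children) + ")"
        if node.parent is None:
            return core
        meta = f"[&rate={node.rate:.12g}]" if include_rates and node.rate != 1.0 else ""
        return f"{core}{meta}:{node.edge_length():.12g}"

    return render(tree.root)


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_tree(tree: TimeTree, dialect: str = "newick", include_rates: bool = False) -> str:
    """Serialize a tree; sampled ancestors become zero-length terminal edges."""
    if dialect == "newick":
        return tree.newick(include_rates=include_rates)
    if dialect == "nexus":
        buf = io.StringIO()
        labels = tree.taxon_labels()
        buf.write("#NEXUS\nBegin taxa;\n")
        buf.write(f"    Dimensions ntax={len(labels)};\n    Taxlabels\n")
        for lab in labels:
            buf.write(f"        {_quote(lab)}\n")
        buf.write("        ;\nEnd;\nBegin trees;\n")
        buf.write(f"tree TREE1 = {tree.newick(include_rates=include_rates)}\n")
        buf.write("End;\n")
        return buf.getvalue()
    raise ValidationError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# phylogenetic covariance
# ---------------------------------------------------------------------------


def _root_path_weight(tree: TimeTree, node: Node, c_m: float) -> float:
    total = 0.0
    while node.parent is not None:
        total += c_m * node.rate * node.edge_length()
        node = node.parent
    return total


def phylo_vcv(tree: TimeTree, c_m: float = 1.0) -> np.ndarray:
    """The n x n phylogenetic variance-covariance matrix.

    Entry (u, w) is the rate-weighted length of the path shared between
    root->u and root->w, i.e. the path root->MRCA(u, w); taxa are ordered
    lexicographically by tip label.
    """
    if c_m <= 0:
        raise ValidationError("c_m must be > 0")
    labels = tree.taxon_labels()
    tips = {lab: tree.tip(lab) for lab in labels}
    n = len(labels)

    # accumulate rate-weighted depth from the root for every node
    wdepth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            wdepth[id(node)] = wdepth[id(node.parent)] + c_m * node.rate * node.edge_length()

    paths = {lab: set(id(n_) for n_ in tree._root_path(tips[lab])) for lab in labels}
    T = np.zeros((n, n))
    for i, u in enumerate(labels):
        T[i, i] = wdepth[id(tips[u])]
        pu = tree._root_path(tips[u])
        for j in range(i + 1, n):
            w = labels[j]
            mrca = next(nd for nd in pu if id(nd) in paths[w])
            T[i, j] = T[j, i] = wdepth[id(mrca)]
    return T


def shared_path_length(tree: TimeTree, u: str, w: str) -> float:
    """Length of the root-to-MRCA(u, w) path (all rates taken as 1)."""
    tu, tw = tree.tip(u), tree.tip(w)
    if u == w:
        return sum(n.edge_length() for n in tree._root_path(tu) if n.parent is not None)
    mrca = tree.mrca(u, w)
    return sum(n.edge_length() for n in tree._root_path(mrca) if n.parent is not None)


# ---------------------------------------------------------------------------
# pruning taxa
# ---------------------------------------------------------------------------


def prune_taxa(tree: TimeTree, labels: Iterable[str]) -> TimeTree:
    """Remove the listed tips; suppress resulting degree-2 pass-through nodes.

    Merged edges sum their lengths and carry the length-weighted mean of the
    two relative rates, preserving the rate-weighted path length.
    """
    labels = set(labels)
    out = tree.copy()
    present = set(out.taxon_labels())
    unknown = labels - present
    if unknown:
        raise TaxonLookupError(f"unknown taxa: {sorted(unknown)}")
    if len(present - labels) < 2:
        raise ValidationError("pruning would leave fewer than 2 tips")
    for lab in labels:
        _remove_tip(out, out.tip(lab))
    out.reindex()
    out.validate()
    return out


def _remove_tip(tree: TimeTree, tip: Node) -> None:
    parent = tip.parent
    if parent is None:
        raise ValidationError("cannot remove the root")
    parent.children.remove(tip)
    _suppress_if_passthrough(tree, parent)


def _suppress_if_passthrough(tree: TimeTree, node: Node) -> None:
    if len(node.children) != 1 or node.is_tip:
        return
    child = node.children[0]
    if node.parent is None:
        # root with a single child: make the child the new root unless doing
        # so would orphan a sampled-ancestor attachment structure
        if child.is_tip:
            return
        child.parent = None
        tree.root = child
        return
    # merge the two edges around `node`
    upper, lower = node.edge_length(), child.edge_length()
    total = upper + lower
    merged_rate = (
        (node.rate * upper + child.rate * lower) / total if total > 0 else node.rate
    )
    grand = node.parent
    grand.children[grand.children.index(node)] = child
    child.parent = grand
    child.rate = merged_rate


# ---------------------------------------------------------------------------
# MCC summarization
# ---------------------------------------------------------------------------


def _clade_map(tree: TimeTree) -> dict[int, frozenset[str]]:
    clades: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            clades[id(node)] = frozenset([node.label])
        else:
            clades[id(node)] = frozenset().union(*(clades[id(c)] for c in node.children))
    return clades


def mcc_tree(
    trees: Sequence[TimeTree],
    burnin_fraction: float = 0.1,
    hpd_level: float = 0.95,
):
    """Maximum-clade-credibility summary of a posterior tree sample.

    Returns ``(tree, clade_probs, annotations)`` where ``tree`` is the
    sampled tree maximizing the product of clade posterior frequencies,
    ``clade_probs`` maps each clade (frozenset of labels) to its frequency,
    and ``annotations`` maps each internal clade of the winner to a dict
    with the posterior ``mean`` age, ``hpd`` bounds and ``prob``.
    """
    from .inference.summaries import hpd_interval

    if not 0 <= burnin_fraction < 1:
        raise ValidationError("burnin_fraction must be in [0, 1)")
    start = int(len(trees) * burnin_fraction)
    post = list(trees[start:])
    if not post:
        raise ValidationError("empty post-burnin tree sample")

    counts: dict[frozenset[str], int] = {}
    ages: dict[frozenset[str], list[float]] = {}
    per_tree_clades = []
    for t in post:
        clades = _clade_map(t)
        node_clades = []
        for node in t.internal_nodes():
            cl = clades[id(node)]
            counts[cl] = counts.get(cl, 0) + 1
            ages.setdefault(cl, []).append(node.age)
            node_clades.append(cl)
        per_tree_clades.append(node_clades)

    n = len(post)
    clade_probs = {cl: c / n for cl, c in counts.items()}
    scores = [
        sum(np.log(clade_probs[cl]) for cl in node_clades)
        for node_clades in per_tree_clades
    ]
    best = int(np.argmax(scores))
    winner = post[best].copy()
    annotations = {}
    clades = _clade_map(winner)
    for node in winner.internal_nodes():
        cl = clades[id(node)]
        vals = ages[cl]
        if len(vals) > 1:
            lo, hi = hpd_interval(vals, hpd_level)
        else:
            lo = hi = vals[0]
        annotations[cl] = {
            "mean": float(np.mean(vals)),
            "hpd": (lo, hi),
            "prob": clade_probs[cl],
        }
    return winner, clade_probs, annotations
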