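"""Tree data model, Newick I/O, stratigraphic time-scaling and covariance.

The central object is :class:`DatedTree`, a rooted tree whose branch lengths
are in time units. Ages are measured back from the "present", defined as the
depth of the deepest tip, so extant tips have age 0 and fossil tips positive
ages. All traversals are iterative (no recursion-depth limits on pectinate
trees).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "NewickParseError",
    "StratRange",
    "Node",
    "DatedTree",
    "read_trees",
    "write_trees",
    "timescale_mbl",
    "sample_fossil_tip_ages",
    "prune_to_taxa",
    "rescale_unit_height",
    "phylo_covariance",
]

#: tips whose age exceeds this (in tree time units) are classified extinct
EXTANT_AGE_TOL = 1e-9


class TreeError(ValueError):
    """Invalid tree structure or operation argument."""


class NewickParseError(TreeError):
    """Input could not be parsed into a valid dated tree."""


@dataclass(frozen=True)
class StratRange:
    """Stratigraphic interval of a fossil tip: first/last appearance ages (Ma)."""

    taxon: str
    fad: float
    lad: float

    def __post_init__(self) -> None:
        if not (self.fad >= self.lad >= 0):
            raise TreeError(
                f"StratRange for {self.taxon!r} violates fad >= lad >= 0: "
                f"fad={self.fad}, lad={self.lad}"
            )


class Node:
    """One node of a :class:`DatedTree`. Branch ``length`` leads to the parent."""

    __slots__ = ("parent", "children", "length", "label", "index")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = float(length)
        self.label = label
        self.index = -1  # postorder index, assigned by DatedTree

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "internal"
        return f"<Node {kind} label={self.label!r} length={self.length}>"


def _postorder(root: Node) -> list[Node]:
    out: list[Node] = []
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            out.append(node)
        else:
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))
    return out


class DatedTree:
    """Rooted tree with branch lengths in time, extinct/extant tips, node ages.

    Invariants (checked on construction):

    * every branch length >= 0;
    * ``age(child) + length(child) == age(parent)`` (ages are derived);
    * extant tips (those at maximal depth) have age exactly 0.

    Polytomies are resolved into zero-length binary splits in input order; the
    number of resolved polytomies is recorded in ``resolution_log``.
    """

    def __init__(self, root: Node, resolve_polytomies: bool = True):
        self.resolution_log: list[str] = []
        if resolve_polytomies:
            self._resolve_polytomies(root)
        self.root = root
        self._index()
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _resolve_polytomies(self, root: Node) -> None:
        for node in _postorder(root):
            while len(node.children) > 2:
                # collapse the first two children under a zero-length node
                a, b = node.children[0], node.children[1]
                joint = Node(length=0.0)
                joint.parent = node
                joint.children = [a, b]
                a.parent = b.parent = joint
                node.children = [joint] + node.children[2:]
                self.resolution_log.append(
                    f"resolved polytomy above {a.label or a.index!r} with zero-length split"
                )

    def _index(self) -> None:
        self.nodes: list[Node] = _postorder(self.root)
        for i, node in enumerate(self.nodes):
            node.index = i
        self.tips: list[Node] = [n for n in self.nodes if n.is_tip]
        self.tip_labels: list[str] = [t.label or f"tip{t.index}" for t in self.tips]
        # depths measured from the root (root depth 0)
        depth = np.zeros(len(self.nodes))
        for node in reversed(self.nodes):  # preorder
            if node.parent is not None:
                depth[node.index] = depth[node.parent.index] + node.length
        self.depths = depth
        tip_depths = np.array([depth[t.index] for t in self.tips])
        self.height = float(tip_depths.max()) if len(tip_depths) else 0.0
        self.node_ages = self.height - depth
        # snap float-accumulation dust so extant tips are exactly age 0
        self.node_ages[np.abs(self.node_ages) < EXTANT_AGE_TOL] = 0.0
        self.tip_ages = {t.label: float(self.node_ages[t.index]) for t in self.tips}

    def _validate(self) -> None:
        labels = [t.label for t in self.tips]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for node in self.nodes:
            if node.length < 0:
                raise TreeError(f"negative branch length at {node.label or node.index}")
            if node.parent is not None and node.length > 0:
                if not self.node_ages[node.parent.index] > self.node_ages[node.index]:
                    raise TreeError("parent not older than child on positive branch")

    # -- basic queries --------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def age(self, node: Node) -> float:
        return float(self.node_ages[node.index])

    def is_extinct(self, tip: Node) -> bool:
        return self.node_ages[tip.index] > EXTANT_AGE_TOL

    def extinct_labels(self) -> list[str]:
        return [t.label for t in self.tips if self.is_extinct(t)]

    def extant_labels(self) -> list[str]:
        return [t.label for t in self.tips if not self.is_extinct(t)]

    def tip_depth_vector(self) -> np.ndarray:
        """Root-to-tip path lengths, in tip order."""
        return np.array([self.depths[t.index] for t in self.tips])

    # -- copying and serialization --------------------------------------------

    def copy(self) -> "DatedTree":
        mapping: dict[Node, Node] = {}
        for node in self.nodes:
            clone = Node(label=node.label, length=node.length)
            mapping[node] = clone
            for child in node.children:
                clone_child = mapping[child]
                clone_child.parent = clone
                clone.children.append(clone_child)
        return DatedTree(mapping[self.root], resolve_polytomies=False)

    def to_newick(self, precision: int = 12) -> str:
        parts: dict[int, str] = {}
        for node in self.nodes:
            if node.is_tip:
                s = _quote_label(node.label or "")
            else:
                inner = ",".join(parts.pop(c.index) for c in node.children)
                s = f"({inner})"
            if node.parent is not None:
                s += f":{node.length:.{precision}g}"
            parts[node.index] = s
        return parts[self.root.index] + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        trees = read_trees(io.StringIO(newick))
        if len(trees) != 1:
            raise NewickParseError(f"expected exactly 1 tree, got {len(trees)}")
        return trees[0]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DatedTree n_tips={self.n_tips} height={self.height:.4g}>"


def _quote_label(label: str) -> str:
    if any(c in label for c in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# I/O


def _from_dendropy(dtree: "dendropy.Tree", tree_index: int) -> DatedTree:
    if dtree.is_rooted is False:
        raise NewickParseError(f"tree {tree_index}: tree is explicitly unrooted")

    def convert(dnode, parent_edge_required):
        length = dnode.edge.length
        if length is None:
            if parent_edge_required:
                name = dnode.taxon.label if dnode.taxon else "<internal>"
                raise NewickParseError(
                    f"tree {tree_index}: missing branch length at {name!r}"
                )
            length = 0.0
        label = dnode.taxon.label if dnode.taxon is not None else None
        return Node(label=label, length=length)

    droot = dtree.seed_node
    root = convert(droot, parent_edge_required=False)
    stack = [(droot, root)]
    while stack:
        dnode, node = stack.pop()
        for dchild in dnode.child_nodes():
            child = convert(dchild, parent_edge_required=True)
            node.add_child(child)
            stack.append((dchild, child))
    return DatedTree(root)


def read_trees(path) -> list[DatedTree]:
    """Read one or more rooted Newick trees (with branch lengths) from a file.

    ``path`` may be a filesystem path or a text stream. Node and tip ages are
    computed taking the maximum root-to-tip path as the age-0 reference;
    polytomies are resolved into zero-length binary splits.
    """
    try:
        if hasattr(path, "read"):
            tl = dendropy.TreeList.get(data=path.read(), schema="newick")
        else:
            tl = dendropy.TreeList.get(path=str(path), schema="newick")
    except (OSError, ValueError) as exc:
        raise NewickParseError(f"cannot read Newick input: {exc}") from exc
    except Exception as exc:  # dendropy raises its own error hierarchy
        raise NewickParseError(f"Newick parse failure: {exc}") from exc
    if len(tl) == 0:
        raise NewickParseError("no trees found in input")
    return [_from_dendropy(t, i) for i, t in enumerate(tl)]


def write_trees(trees: Iterable[DatedTree], path) -> None:
    text = "\n".join(t.to_newick() for t in trees) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Time-scaling


def timescale_mbl(
    tree: DatedTree,
    tip_ages: Mapping[str, float] | None = None,
    min_bl: float = 1.0,
) -> DatedTree:
    """Minimum-branch-length stratigraphic fit with fixed internal node ages.

    Tip ages are replaced by ``tip_ages`` where given; internal node ages are
    kept at their input values except where a descendant forces a rootward
    shift, in which case the node (cascading through its ancestors as needed)
    moves to the minimal older age satisfying ``branch >= min_bl``. Shifts are
    recorded on the returned tree's ``mbl_log``.
    """
    if min_bl < 0:
        raise TreeError(f"min_bl must be >= 0, got {min_bl}")
    tip_ages = dict(tip_ages or {})
    unknown = set(tip_ages) - set(tree.tip_labels)
    if unknown:
        raise TreeError(f"tip_ages refer to unknown tips: {sorted(unknown)}")

    new = tree.copy()
    ages = new.node_ages.copy()
    for tip in new.tips:
        if tip.label in tip_ages:
            ages[tip.index] = float(tip_ages[tip.label])
    log: list[str] = []
    for node in new.nodes:  # postorder: children already final
        if node.is_tip:
            continue
        required = max(ages[c.index] + min_bl for c in node.children)
        if ages[node.index] < required - 1e-12:
            log.append(
                f"node {node.index}: age {ages[node.index]:.6g} -> {required:.6g}"
            )
            ages[node.index] = required
    for node in new.nodes:
        if node.parent is not None:
            node.length = float(ages[node.parent.index] - ages[node.index])
    out = DatedTree(new.root, resolve_polytomies=False)
    out.mbl_log = log  # type: ignore[attr-defined]
    return out


def sample_fossil_tip_ages(
    tree: DatedTree,
    ranges: Sequence[StratRange],
    n_trees: int,
    seed: int,
    min_bl: float = 1.0,
) -> list[DatedTree]:
    """Draw fossil tip ages uniformly on [lad, fad], re-apply the MBL fit.

    Produces ``n_trees`` replicates with per-replicate child seeds spawned
    from ``seed``; extant tips are untouched.
    """
    if n_trees < 1:
        raise TreeError("n_trees must be >= 1")
    by_taxon = {r.taxon: r for r in ranges}
    extinct = tree.extinct_labels()
    missing = [t for t in extinct if t not in by_taxon]
    if missing:
        raise TreeError(f"extinct tips without stratigraphic range: {sorted(missing)}")
    out = []
    for child_seq in np.random.SeedSequence(seed).spawn(n_trees):
        rng = np.random.default_rng(child_seq)
        new_ages = {
            t: float(rng.uniform(by_taxon[t].lad, by_taxon[t].fad)) for t in extinct
        }
        out.append(timescale_mbl(tree, tip_ages=new_ages, min_bl=min_bl))
    return out


# ---------------------------------------------------------------------------
# Pruning and rescaling


def prune_to_taxa(tree: DatedTree, taxa: Iterable[str]) -> DatedTree:
    """Induced subtree on ``taxa``; unary nodes suppressed, path lengths kept."""
    keep = set(taxa)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 taxa to prune to")

    retained: dict[int, Node] = {}
    for node in tree.nodes:  # postorder
        if node.is_tip:
            if node.label in keep:
                retained[node.index] = Node(label=node.label, length=node.length)
        else:
            kept_children = [retained[c.index] for c in node.children if c.index in retained]
            if not kept_children:
                continue
            if len(kept_children) == 1:
                # suppress this node: child absorbs the branch
                child = kept_children[0]
                child.length += node.length
                retained[node.index] = child
            else:
                clone = Node(label=node.label, length=node.length)
                for c in kept_children:
                    clone.children.append(c)
                    c.parent = clone
                retained[node.index] = clone
    root = retained[tree.root.index]
    root.length = 0.0  # drop any stem accumulated while suppressing the old root
    root.parent = None
    return DatedTree(root, resolve_polytomies=False)


def rescale_unit_height(tree: DatedTree) -> DatedTree:
    """Divide every branch by the tree height so the new height is 1."""
    if tree.height <= 0:
        raise TreeError("cannot rescale a zero-height tree")
    new = tree.copy()
    h = tree.height
    for node in new.nodes:
        node.length /= h
    return DatedTree(new.root, resolve_polytomies=False)


# ---------------------------------------------------------------------------
# Covariance


def phylo_covariance(tree: DatedTree) -> tuple[np.ndarray, np.ndarray]:
    """Shared-path matrix S and root-to-tip depth vector T, in tip order.

    ``S[i, j]`` is the root-to-MRCA(i, j) path length; ``S[i, i] = T[i]``.
    """
    n = tree.n_tips
    tip_pos = {t.index: k for k, t in enumerate(tree.tips)}
    S = np.zeros((n, n))
    T = tree.tip_depth_vector()
    below: dict[int, np.ndarray] = {}
    for node in tree.nodes:  # postorder
        if node.is_tip:
            below[node.index] = np.array([tip_pos[node.index]])
            continue
        child_sets = [below.pop(c.index) for c in node.children]
        d = tree.depths[node.index]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                S[np.ix_(child_sets[a], child_sets[b])] = d
                S[np.ix_(child_sets[b], child_sets[a])] = d
        below[node.index] = np.concatenate(child_sets)
    np.fill_diagonal(S, T)
    return S, T
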