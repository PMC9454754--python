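"""Rooted clone-tree container shared by the simulator, phylogeny and migration code.

A clone tree is rooted at the normal (all-reference) genotype.  Every other
node is a clone, observed or inferred-ancestral; an edge carries the novel
SNVs acquired on that lineage segment, so integer branch lengths are mutation
counts.  Location leaves (zero-length pendants that pin a clone to an
anatomical site) are marked with a non-None ``site``.
"""
from __future__ import annotations

from typing import Iterator, Optional

import dendropy


class CloneNode:
    """A node of a rooted clone phylogeny."""

    __slots__ = ("name", "parent", "children", "mutations", "losses", "site", "observed")

    def __init__(
        self,
        name: str,
        mutations: Optional[list[str]] = None,
        site: Optional[str] = None,
        observed: bool = True,
        losses: Optional[list[str]] = None,
    ) -> None:
        self.name = name
        self.parent: Optional[CloneNode] = None
        self.children: list[CloneNode] = []
        # novel SNVs gained on the edge above this node
        self.mutations: list[str] = list(mutations) if mutations else []
        # SNVs lost on that edge (empty on perfect-phylogeny trees)
        self.losses: list[str] = list(losses) if losses else []
        self.site = site
        self.observed = observed

    # -- structure ---------------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.mutations) + len(self.losses)

    def add_child(self, node: "CloneNode") -> "CloneNode":
        node.parent = self
        self.children.append(node)
        return node

    def detach(self) -> "CloneNode":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def is_leaf(self) -> bool:
        return not self.children

    def is_location_leaf(self) -> bool:
        return self.site is not None

    def preorder(self) -> Iterator["CloneNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["CloneNode"]:
        out: list[CloneNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> list["CloneNode"]:
        return [n for n in self.preorder() if n.is_leaf()]

    def clone_nodes(self) -> list["CloneNode"]:
        """All non-root, non-location-leaf nodes (the clones)."""
        return [n for n in self.preorder() if n.parent is not None and n.site is None]

    def find(self, name: str) -> Optional["CloneNode"]:
        for node in self.preorder():
            if node.name == name:
                return node
        return None

    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d, node = d + 1, node.parent
        return d

    def ancestors(self) -> list["CloneNode"]:
        out, node = [], self.parent
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def genotype(self) -> frozenset:
        """Set of SNVs carried: edge gains minus losses applied root-to-node."""
        path = [self] + self.ancestors()
        muts: set[str] = set()
        for node in reversed(path):
            muts.update(node.mutations)
            muts.difference_update(node.losses)
        return frozenset(muts)

    def copy(self) -> "CloneNode":
        new = CloneNode(self.name, self.mutations, self.site, self.observed, self.losses)
        for child in self.children:
            new.add_child(child.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CloneNode({self.name!r}, n_children={len(self.children)})"


def lca(nodes: list[CloneNode]) -> CloneNode:
    """Lowest common ancestor of a non-empty list of nodes in one tree."""
    if not nodes:
        raise ValueError("lca of an empty node list is undefined")
    paths = []
    for node in nodes:
        path = [node] + node.ancestors()
        paths.append(list(reversed(path)))
    shortest = min(len(p) for p in paths)
    ancestor = paths[0][0]
    for i in range(shortest):
        level = {id(p[i]) for p in paths}
        if len(level) == 1:
            ancestor = paths[0][i]
        else:
            break
    return ancestor


# -- Newick serialization ---------------------------------------------------


def _quote(label: str) -> str:
    if any(ch in label for ch in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(root: CloneNode) -> str:
    """Newick string with clone labels and integer branch lengths."""

    def render(node: CloneNode) -> str:
        inner = ""
        if node.children:
            inner = "(" + ",".join(render(c) for c in node.children) + ")"
        label = _quote(node.name)
        if node.parent is None:
            return f"{inner}{label}"
        return f"{inner}{label}:{node.length}"

    return render(root) + ";"


def from_newick(text: str) -> CloneNode:
    """Parse a Newick string (labels on all nodes) into a CloneNode tree.

    Branch lengths are not turned back into mutation lists; they are kept as
    anonymous placeholder SNVs so that ``length`` round-trips.
    """
    dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=False)
    counter = [0]

    def convert(dnode) -> CloneNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        if label is None:
            counter[0] += 1
            label = f"node{counter[0]}"
        n_mut = int(dnode.edge.length or 0)
        muts = [f"{label}.m{i}" for i in range(n_mut)]
        node = CloneNode(label, mutations=muts)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.mutations = []
    return root


def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def n_binary_resolutions(n_children: int) -> int:
    """Number of rooted binary trees over ``n_children`` labeled subtrees."""
    if n_children < 3:
        return 1
    return double_factorial(2 * n_children - 3)
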