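"""Maximum-parsimony clone phylogeny, MRCA location, polytomy resolutions.

The clone phylogeny is rooted at the normal (all-reference) genotype.  When
the binary genotypes admit a perfect phylogeny (no pair of SNV characters in
conflict) the tree is built directly from the laminar family of character
carrier sets and is exact.  Otherwise the minimum-length tree under the
Fitch (unordered binary) criterion is found by exhaustive search over
unrooted topologies for up to 8 clones, or stepwise addition with NNI
refinement beyond that.  Branch lengths are integer mutation counts.
"""
from __future__ import annotations

import itertools
import warnings
from typing import Iterator, Optional, Union

import numpy as np
import pandas as pd

from .tree import CloneNode, lca, n_binary_resolutions

EXHAUSTIVE_MAX_CLONES = 8

Topology = Union[int, tuple]  # nested tuples over leaf indices


# -- characters -------------------------------------------------------------


def _genotype_frame(clones) -> pd.DataFrame:
    if isinstance(clones, pd.DataFrame):
        return clones
    return clones.genotypes  # CloneSet


def _characters(genotypes: pd.DataFrame) -> list[tuple[frozenset, list[str]]]:
    """Group SNV columns by identical carrier sets (multiplicity = weight)."""
    by_pattern: dict[frozenset, list[str]] = {}
    values = genotypes.values
    for j, snv in enumerate(genotypes.columns):
        carriers = frozenset(genotypes.index[values[:, j] == 1])
        if not carriers:
            continue
        by_pattern.setdefault(carriers, []).append(snv)
    # deterministic order: big clades first, then by first SNV column order
    col_order = {s: j for j, s in enumerate(genotypes.columns)}
    return sorted(
        by_pattern.items(), key=lambda kv: (-len(kv[0]), col_order[kv[1][0]])
    )


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


# -- perfect phylogeny ------------------------------------------------------


def _perfect_phylogeny(
    genotypes: pd.DataFrame, chars: list[tuple[frozenset, list[str]]]
) -> CloneNode:
    root = CloneNode("Normal", observed=False)
    placed: list[tuple[frozenset, CloneNode]] = []
    node_of_char: dict[int, CloneNode] = {}
    for i, (carriers, snvs) in enumerate(chars):
        parent = root
        best: Optional[tuple[int, int, CloneNode]] = None
        for j, (prev_carriers, prev_node) in enumerate(placed):
            if carriers < prev_carriers:
                key = (len(prev_carriers), -j)
                if best is None or key < best[:2]:
                    best = (*key, prev_node)
        if best is not None:
            parent = best[2]
        node = CloneNode(f"_chr{i}", mutations=snvs, observed=False)
        parent.add_child(node)
        placed.append((carriers, node))
        node_of_char[i] = node

    # attach clones at their minimal character node
    for clone in genotypes.index:
        carried = [
            (len(carriers), i)
            for i, (carriers, _) in enumerate(chars)
            if clone in carriers
        ]
        if not carried:
            root.add_child(CloneNode(clone))  # normal-identical clone
            continue
        _, i = min(carried)
        node = node_of_char[i]
        node.name = clone
        node.observed = True

    # suppress unary unobserved character nodes, merging edge mutations
    changed = True
    while changed:
        changed = False
        for node in list(root.preorder()):
            if node.parent is None or node.observed or len(node.children) != 1:
                continue
            child = node.children[0]
            child.mutations = node.mutations + child.mutations
            parent = node.parent
            idx = parent.children.index(node)
            node.detach()
            child.parent = parent
            parent.children.insert(idx, child)
            changed = True
    # name remaining unobserved internals deterministically
    counter = 0
    for node in root.preorder():
        if node.name.startswith("_chr"):
            node.name = f"A{counter}"
            counter += 1
    return root


# -- general parsimony search ----------------------------------------------


def _attach(t: Topology, leaf: Topology, pos: int):
    """Attach ``leaf`` as sibling of the ``pos``-th node of ``t`` (preorder)."""
    if pos == 0:
        return (t, leaf), None
    if not isinstance(t, tuple):
        return None, 1
    left, right = t
    nl, cl = _attach(left, leaf, pos - 1)
    if cl is None:
        return (nl, right), None
    nr, cr = _attach(right, leaf, pos - 1 - cl)
    if cr is None:
        return (left, nr), None
    return None, 1 + cl + cr


def _n_nodes(t: Topology) -> int:
    if not isinstance(t, tuple):
        return 1
    return 1 + _n_nodes(t[0]) + _n_nodes(t[1])


def attach_at(t: Topology, leaf: Topology, pos: int) -> Topology:
    new, _ = _attach(t, leaf, pos)
    if new is None:
        raise IndexError(f"position {pos} out of range")
    return new


def binary_trees(items: list) -> Iterator[Topology]:
    """All rooted binary trees over ``items`` ((2m-3)!! of them)."""
    if not items:
        return
    if len(items) == 1:
        yield items[0]
        return
    for t in binary_trees(items[:-1]):
        for pos in range(2 * (len(items) - 1) - 1):
            yield attach_at(t, items[-1], pos)


def unrank_binary_tree(items: list, index: int) -> Topology:
    """The ``index``-th tree of the :func:`binary_trees` insertion order."""
    total = n_binary_resolutions(len(items)) if len(items) >= 2 else 1
    if not 0 <= index < max(total, 1):
        raise IndexError(f"index {index} out of range for {len(items)} items")
    # same order as binary_trees: the last item's position varies fastest
    digits = [0] * len(items)
    for k in range(len(items) - 1, 0, -1):
        digits[k] = index % (2 * k - 1)
        index //= 2 * k - 1
    t: Topology = items[0]
    for k in range(1, len(items)):
        t = attach_at(t, items[k], digits[k])
    return t


def _fitch_length(t: Topology, leaf_states: np.ndarray, weights: np.ndarray) -> int:
    """Weighted Fitch parsimony length of rooted topology ``t``.

    ``leaf_states`` is (n_leaves, n_chars) with bitmasks 1 (state 0) or
    2 (state 1).
    """
    total = np.zeros(leaf_states.shape[1], dtype=np.int64)

    def rec(node: Topology) -> np.ndarray:
        if not isinstance(node, tuple):
            return leaf_states[node]
        a, b = rec(node[0]), rec(node[1])
        inter = a & b
        total[...] += (inter == 0) * 1
        return np.where(inter != 0, inter, a | b)

    rec(t)
    return int((total * weights).sum())


def _nni_neighbors(t: Topology) -> Iterator[Topology]:
    """All nearest-neighbor interchanges of a rooted nested-tuple topology."""
    if not isinstance(t, tuple):
        return
    left, right = t
    if isinstance(right, tuple):
        rl, rr = right
        yield (rl, (left, rr))
        yield (rr, (rl, left))
    if isinstance(left, tuple):
        ll, lr = left
        yield ((ll, right), lr)
        yield ((right, lr), ll)
    for nl in _nni_neighbors(left):
        yield (nl, right)
    for nr in _nni_neighbors(right):
        yield (left, nr)


def _search_topology(
    leaf_states: np.ndarray, weights: np.ndarray, n_taxa: int, exhaustive: bool
) -> tuple[Topology, int]:
    items = list(range(1, n_taxa))  # taxon 0 (Normal) joins as outgroup
    if exhaustive:
        best_t, best_len = None, None
        for t in binary_trees(items):
            length = _fitch_length((t, 0), leaf_states, weights)
            if best_len is None or length < best_len:
                best_t, best_len = t, length
        return (best_t, 0), best_len
    # stepwise addition: try every node position (= parent edge) for the new leaf
    t: Topology = items[0]
    for leaf in items[1:]:
        best_pos, best_len = 0, None
        for pos in range(_n_nodes(t)):
            cand = attach_at(t, leaf, pos)
            length = _fitch_length((cand, 0), leaf_states, weights)
            if best_len is None or length < best_len:
                best_pos, best_len = pos, length
        t = attach_at(t, leaf, best_pos)
    length = _fitch_length((t, 0), leaf_states, weights)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(t):
            cand_len = _fitch_length((cand, 0), leaf_states, weights)
            if cand_len < length:
                t, length, improved = cand, cand_len, True
                break
    return (t, 0), length


def _fitch_assign(
    full: Topology, leaf_states: np.ndarray, n_chars: int
) -> tuple[dict[int, np.ndarray], dict]:
    """Fitch state sets (up-pass) and refined states (down-pass, root = 0)."""
    up: dict[int, np.ndarray] = {}
    kids: dict[int, tuple[int, ...]] = {}
    leaf_of: dict[int, int] = {}
    counter = itertools.count()

    def build(node: Topology) -> int:
        nid = next(counter)
        if not isinstance(node, tuple):
            up[nid] = leaf_states[node].copy()
            kids[nid] = ()
            leaf_of[nid] = node
            return nid
        a = build(node[0])
        b = build(node[1])
        inter = up[a] & up[b]
        up[nid] = np.where(inter != 0, inter, up[a] | up[b]).astype(np.uint8)
        kids[nid] = (a, b)
        return nid

    root_id = build(full)
    states: dict[int, np.ndarray] = {
        root_id: np.ones(n_chars, dtype=np.uint8)  # root forced to state 0
    }

    def down_pass(nid: int) -> None:
        parent_state = states[nid]
        for ch in kids[nid]:
            s = up[ch]
            keep = (s & parent_state) != 0
            child_state = np.where(keep, parent_state, s & (~s + 1))  # lowest bit
            states[ch] = child_state.astype(np.uint8)
            down_pass(ch)

    down_pass(root_id)
    return states, {"children": kids, "root": root_id, "leaf_of": leaf_of}


def _tree_from_topology(
    full: Topology,
    genotypes: pd.DataFrame,
    chars: list[tuple[frozenset, list[str]]],
) -> CloneNode:
    taxa = ["Normal"] + list(genotypes.index)
    n_chars = len(chars)
    leaf_states = np.ones((len(taxa), n_chars), dtype=np.uint8)
    for i, taxon in enumerate(taxa[1:], start=1):
        for k, (carriers, _) in enumerate(chars):
            leaf_states[i, k] = 2 if taxon in carriers else 1
    states, meta = _fitch_assign(full, leaf_states, n_chars)
    children, root_id = meta["children"], meta["root"]
    leaf_of = meta["leaf_of"]

    counter = itertools.count()

    def materialize(nid: int, parent_state: np.ndarray) -> CloneNode:
        state = states[nid]
        gains = [s for k in np.flatnonzero((parent_state == 1) & (state == 2)) for s in chars[k][1]]
        losses = [s for k in np.flatnonzero((parent_state == 2) & (state == 1)) for s in chars[k][1]]
        if nid in leaf_of:
            name = taxa[leaf_of[nid]]
            node = CloneNode(name, mutations=gains, losses=losses, observed=True)
        else:
            node = CloneNode(f"A{next(counter)}", mutations=gains, losses=losses, observed=False)
            for ch in children[nid]:
                node.add_child(materialize(ch, state))
        return node

    # root of ``full`` corresponds to the edge joining Normal; find Normal leaf
    a, b = children[root_id]
    if leaf_of.get(a) == 0:
        normal_id, other = a, b
    elif leaf_of.get(b) == 0:
        normal_id, other = b, a
    else:  # Normal is nested deeper; fall back to treating virtual root as Normal
        normal_id, other = None, None
    root = CloneNode("Normal", observed=False)
    if normal_id is not None:
        root.add_child(materialize(other, np.ones(n_chars, dtype=np.uint8)))
    else:
        for ch in children[root_id]:
            root.add_child(materialize(ch, np.ones(n_chars, dtype=np.uint8)))

    # collapse zero-length edges into polytomies (canonical form)
    changed = True
    while changed:
        changed = False
        for node in list(root.preorder()):
            if (
                node.parent is not None
                and not node.observed
                and node.length == 0
                and node.children
            ):
                parent = node.parent
                idx = parent.children.index(node)
                kids = list(node.children)
                node.detach()
                for off, kid in enumerate(kids):
                    kid.parent = parent
                    parent.children.insert(idx + off, kid)
                changed = True
    return root


# -- public operations ------------------------------------------------------


def infer_parsimony_tree(clones) -> CloneNode:
    """Rooted maximum-parsimony clone phylogeny (root = all-zero genotype).

    Accepts a :class:`~metmap.deconvolve.CloneSet` or a binary clone x SNV
    genotype DataFrame.  Perfect-phylogeny inputs are solved exactly;
    conflicting characters trigger exhaustive search (<= 8 clones) or
    stepwise addition plus NNI.
    """
    genotypes = _genotype_frame(clones).copy()
    if genotypes.shape[0] < 1:
        raise ValueError("need at least one clone")
    # merge duplicate genotypes
    dup = genotypes.duplicated(keep="first")
    if dup.any():
        warnings.warn(
            f"merging {int(dup.sum())} duplicate clone genotype(s)", stacklevel=2
        )
        genotypes = genotypes[~dup.values]
    chars = _characters(genotypes)
    if all(
        _compatible(a, b) for (a, _), (b, _) in itertools.combinations(chars, 2)
    ):
        return _perfect_phylogeny(genotypes, chars)
    taxa = ["Normal"] + list(genotypes.index)
    leaf_states = np.ones((len(taxa), len(chars)), dtype=np.uint8)
    for i, taxon in enumerate(taxa[1:], start=1):
        for k, (carriers, _) in enumerate(chars):
            leaf_states[i, k] = 2 if taxon in carriers else 1
    weights = np.array([len(snvs) for _, snvs in chars], dtype=np.int64)
    exhaustive = genotypes.shape[0] <= EXHAUSTIVE_MAX_CLONES
    full, _ = _search_topology(leaf_states, weights, len(taxa), exhaustive)
    return _tree_from_topology(full, genotypes, chars)


def tree_length(root: CloneNode) -> int:
    return sum(n.length for n in root.preorder() if n.parent is not None)


def branch_lengths(root: CloneNode) -> dict[tuple[str, str], int]:
    """Edge -> mutation count (characters changing under Fitch)."""
    return {
        (n.parent.name, n.name): n.length
        for n in root.preorder()
        if n.parent is not None
    }


def _locations_dict(locations) -> dict[str, set[str]]:
    if hasattr(locations, "locations"):
        return locations.locations
    return locations


def find_mrca(
    root: CloneNode, locations, site_classes: dict[str, str]
) -> tuple[CloneNode, str]:
    """MRCA node of all observed clones plus its observed-sites annotation.

    Annotation is ``both`` / ``primary`` / ``metastasis`` / ``unobserved``
    according to where the MRCA clone itself was detected.
    """
    locs = _locations_dict(locations)
    observed_nodes = [
        node
        for node in root.preorder()
        if node.site is None and locs.get(node.name)
    ]
    if not observed_nodes:
        raise ValueError("no observed clones to take an MRCA over")
    mrca = lca(observed_nodes)
    own = locs.get(mrca.name, set())
    classes = {site_classes[s] for s in own}
    if not classes:
        annotation = "unobserved"
    elif classes == {"primary"}:
        annotation = "primary"
    elif classes == {"metastasis"}:
        annotation = "metastasis"
    else:
        annotation = "both"
    return mrca, annotation


def find_meta_mrca(
    root: CloneNode, locations, site_classes: dict[str, str]
) -> Optional[CloneNode]:
    """MRCA of clones found only in metastatic sites; None when none exist."""
    locs = _locations_dict(locations)
    met_only = [
        node
        for node in root.preorder()
        if node.site is None
        and locs.get(node.name)
        and all(site_classes[s] == "metastasis" for s in locs[node.name])
    ]
    if not met_only:
        return None
    return lca(met_only)


# -- polytomy resolutions ---------------------------------------------------


def count_polytomy_resolutions(root: CloneNode) -> int:
    total = 1
    for node in root.preorder():
        if len(node.children) > 2:
            total *= n_binary_resolutions(len(node.children))
    return total


def enumerate_polytomy_resolutions(
    root: CloneNode, max_n: int = 30, seed: int = 0
) -> list[CloneNode]:
    """Distinct full binary resolutions of every polytomy.

    If the total number of resolutions (a product of double factorials) is
    at most ``max_n`` they are enumerated exhaustively; otherwise ``max_n``
    distinct resolutions are sampled uniformly without replacement using
    ``seed``.  A binary tree returns a single-item list with an identical
    copy.
    """
    poly_positions = [
        i for i, node in enumerate(root.preorder()) if len(node.children) > 2
    ]
    radices = [
        n_binary_resolutions(len(node.children))
        for node in root.preorder()
        if len(node.children) > 2
    ]
    total = 1
    for r in radices:
        total *= r
    if total <= max_n:
        tuples = list(itertools.product(*[range(r) for r in radices]))
    else:
        rng = np.random.default_rng(seed)
        seen: set[tuple[int, ...]] = set()
        tuples = []
        while len(tuples) < max_n:
            cand = tuple(int(rng.integers(r)) for r in radices)
            if cand not in seen:
                seen.add(cand)
                tuples.append(cand)

    out = []
    for digits in tuples:
        copy = root.copy()
        nodes = list(copy.preorder())
        res_counter = itertools.count()
        for pos, digit in zip(poly_positions, digits):
            node = nodes[pos]
            kids = list(node.children)
            for kid in kids:
                kid.detach()
            shape = unrank_binary_tree(list(range(len(kids))), digit)

            def build(t) -> CloneNode:
                if not isinstance(t, tuple):
                    return kids[t]
                new = CloneNode(
                    f"{node.name}.r{next(res_counter)}", observed=False
                )
                new.add_child(build(t[0]))
                new.add_child(build(t[1]))
                return new

            # the shape root stands for the polytomy node itself: its two
            # top-level subtrees become the node's new (binary) children
            node.add_child(build(shape[0]))
            node.add_child(build(shape[1]))
        out.append(copy)
    return out
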