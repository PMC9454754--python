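"""Anatomical migration-history inference over a clone phylogeny.

Clone observations become zero-length location leaves on an augmented tree;
ancestral anatomical sites are reconstructed by minimum-migration (Sankoff,
unit cost per site change) labelings with the root fixed to the primary
site.  Near-optimal labelings (within a cost window, pooled across polytomy
resolutions) are weighted by a Boltzmann factor exp(-lambda * cost) to give
each directed site pair a posterior support.  The final migration map keeps
high-support paths (posterior >= 0.5), completes unreached sites from
low-support candidates (posterior > 0.15) with the fewest extra migrations,
and annotates each path with clone-migration and mapped-variant counts.
Patients whose retained paths average below 0.3 support are flagged for
exclusion.
"""
from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .phylogeny import enumerate_polytomy_resolutions, find_mrca, _locations_dict
from .tree import CloneNode

INF = float("inf")
DEFAULT_HI = 0.5
DEFAULT_LO = 0.15
DEFAULT_SUPPORT_MIN = 0.3
DEFAULT_LAMBDA = 1.0
DEFAULT_COST_WINDOW = 2
MAX_STORED_LABELINGS = 10_000
MAX_ENUMERATED_LABELINGS = 200_000


class MigrationInferenceError(ValueError):
    """Raised for inconsistent migration-inference inputs."""


@dataclass(frozen=True)
class Labeling:
    """One ancestral site labeling: its cost and its clone migrations."""

    cost: int
    migrations: tuple[tuple[str, str, int], ...]  # (source, dest, edge mutations)

    @property
    def pair_counts(self) -> Counter:
        return Counter((s, d) for s, d, _ in self.migrations)

    def pairs(self) -> frozenset:
        return frozenset((s, d) for s, d, _ in self.migrations)


@dataclass
class PosteriorResult:
    posteriors: dict[tuple[str, str], float]
    labelings: list[Labeling]
    min_migrations: int
    total_weight: float
    n_labelings: int
    truncated: bool


@dataclass
class MigrationEdge:
    source: str
    dest: str
    path_type: str  # "P->M" | "M->M" | "M->P"
    clone_count: int
    posterior: float
    support_class: str  # "high" | "low"
    variant_count: int


@dataclass
class MigrationMap:
    edges: list[MigrationEdge]
    root_site: str
    site_classes: dict[str, str]
    occupied_sites: set[str]
    overall_support: float
    excluded: bool
    incomplete: bool
    min_migrations: int
    posteriors: dict[tuple[str, str], float] = field(default_factory=dict)

    def pair_counts(self) -> dict[tuple[str, str], int]:
        return {(e.source, e.dest): e.clone_count for e in self.edges}

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for site in sorted(self.occupied_sites):
            g.add_node(site, site_class=self.site_classes.get(site, "metastasis"))
        for e in self.edges:
            g.add_edge(
                e.source,
                e.dest,
                path_type=e.path_type,
                clone_count=e.clone_count,
                posterior=e.posterior,
                support_class=e.support_class,
                variant_count=e.variant_count,
            )
        return g

    def to_dict(self) -> dict:
        return {
            "root_site": self.root_site,
            "nodes": [
                {"site_label": s, "site_class": self.site_classes.get(s, "metastasis")}
                for s in sorted(self.occupied_sites)
            ],
            "edges": [
                {
                    "source": e.source,
                    "dest": e.dest,
                    "path_type": e.path_type,
                    "clone_count": e.clone_count,
                    "posterior": round(e.posterior, 6),
                    "support_class": e.support_class,
                    "variant_count": e.variant_count,
                }
                for e in self.edges
            ],
            "overall_support": None
            if math.isnan(self.overall_support)
            else round(self.overall_support, 6),
            "excluded": self.excluded,
            "incomplete": self.incomplete,
            "min_migrations": self.min_migrations,
        }

    def to_dot(self) -> str:
        lines = ["digraph migration_map {"]
        for s in sorted(self.occupied_sites):
            shape = "box" if self.site_classes.get(s) == "primary" else "ellipse"
            lines.append(f'  "{s}" [shape={shape}];')
        for e in self.edges:
            style = "solid" if e.support_class == "high" else "dashed"
            lines.append(
                f'  "{e.source}" -> "{e.dest}" '
                f'[label="{e.variant_count}", style={style}];'
            )
        lines.append("}")
        return "\n".join(lines)


def path_type_of(source: str, dest: str, site_classes: dict[str, str]) -> str:
    src = "P" if site_classes.get(source) == "primary" else "M"
    dst = "P" if site_classes.get(dest) == "primary" else "M"
    return f"{src}->{dst}"


# -- augmented tree ---------------------------------------------------------


def build_augmented_tree(tree: CloneNode, locations) -> CloneNode:
    """Attach one zero-length location leaf per (clone, site) occurrence."""
    locs = _locations_dict(locations)
    if not any(locs.values()):
        raise MigrationInferenceError("no clone has an observed location")
    aug = tree.copy()
    nodes = {n.name: n for n in aug.preorder()}
    for clone, sites in locs.items():
        if clone not in nodes:
            raise MigrationInferenceError(f"located clone {clone!r} absent from tree")
        for site in sorted(sites):
            nodes[clone].add_child(CloneNode(f"{clone}@{site}", site=site))
    return aug


# -- Sankoff ----------------------------------------------------------------


def _transition_matrix(sites: list[str], forbidden_dest: Optional[str]) -> np.ndarray:
    n = len(sites)
    M = np.ones((n, n)) - np.eye(n)
    if forbidden_dest is not None and forbidden_dest in sites:
        f = sites.index(forbidden_dest)
        M[:, f] = INF
        M[f, f] = 0.0
    return M


def _sankoff_tables(
    root: CloneNode, sites: list[str], M: np.ndarray
) -> dict[int, np.ndarray]:
    idx = {s: i for i, s in enumerate(sites)}
    n = len(sites)
    cost: dict[int, np.ndarray] = {}
    for node in root.postorder():
        if node.site is not None:
            v = np.full(n, INF)
            v[idx[node.site]] = 0.0
        else:
            v = np.zeros(n)
            for child in node.children:
                v = v + np.min(M + cost[id(child)][None, :], axis=1)
        cost[id(node)] = v
    return cost


def _enumerate_labelings(
    root: CloneNode,
    root_site: str,
    sites: list[str],
    M: np.ndarray,
    budget: float,
    emit,
    counter: dict,
) -> None:
    """Stream every site labeling with total cost <= budget through ``emit``.

    ``emit(cost, migrations)`` receives the migration list (source site,
    dest site, edge mutation count) of one labeling.  ``counter`` carries
    the enumeration cap state across calls.
    """
    idx = {s: i for i, s in enumerate(sites)}
    cost = _sankoff_tables(root, sites, M)
    minc = {
        id(node): {
            id(child): np.min(M + cost[id(child)][None, :], axis=1)
            for child in node.children
        }
        for node in root.preorder()
    }

    def options(node: CloneNode, s: int, slack: float):
        """Yield (cost, migrations) for the edges strictly below ``node``."""
        children = node.children

        def go(i: int, slack_i: float):
            if i == len(children):
                yield 0.0, []
                return
            child = children[i]
            lb_rest = sum(
                float(minc[id(node)][id(c)][s]) for c in children[i + 1 :]
            )
            avail = slack_i - lb_rest
            ccost = cost[id(child)]
            for t in range(len(sites)):
                edge = M[s, t]
                if edge + ccost[t] > avail + 1e-9:
                    continue
                mig = (
                    [(sites[s], sites[t], child.length)] if edge else []
                )
                for sub_cost, sub_migs in options(child, t, avail - edge):
                    used = edge + sub_cost
                    for rest_cost, rest_migs in go(i + 1, slack_i - used):
                        yield used + rest_cost, mig + sub_migs + rest_migs

        yield from go(0, slack)

    r = idx[root_site]
    if cost[id(root)][r] > budget + 1e-9:
        return
    for total, migs in options(root, r, budget):
        counter["n"] += 1
        emit(int(round(total)), migs)
        if counter["n"] >= counter["cap"]:
            counter["truncated"] = True
            return


def min_migration_history(
    aug: CloneNode,
    root_site: str,
    sites: Optional[list[str]] = None,
    forbidden_dest: Optional[str] = None,
    max_store: int = MAX_STORED_LABELINGS,
) -> tuple[int, list[Labeling]]:
    """Minimum number of clone migrations and all optimal site labelings.

    Each site change along any edge of the augmented tree is one clone
    migration, directed parent-site -> child-site.  At most ``max_store``
    labelings are returned (enumeration continues for the count).
    """
    if sites is None:
        sites = sorted({n.site for n in aug.preorder() if n.site is not None} | {root_site})
    M = _transition_matrix(sites, forbidden_dest)
    tables = _sankoff_tables(aug, sites, M)
    min_count = tables[id(aug)][sites.index(root_site)]
    if not np.isfinite(min_count):
        raise MigrationInferenceError("no feasible site labeling")
    min_count = int(round(min_count))
    stored: list[Labeling] = []

    def emit(cost: int, migs: list) -> None:
        if len(stored) < max_store:
            stored.append(Labeling(cost, tuple(migs)))

    counter = {"n": 0, "cap": MAX_ENUMERATED_LABELINGS, "truncated": False}
    _enumerate_labelings(aug, root_site, sites, M, float(min_count), emit, counter)
    return min_count, stored


def edge_posteriors(
    tree: CloneNode,
    locations,
    root_site: str,
    lam: float = DEFAULT_LAMBDA,
    cost_window: int = DEFAULT_COST_WINDOW,
    max_resolutions: int = 30,
    seed: int = 0,
    forbidden_dest: Optional[str] = None,
    max_store: int = MAX_STORED_LABELINGS,
) -> PosteriorResult:
    """Posterior support per directed site pair.

    Site labelings with cost within ``cost_window`` of the global minimum
    are pooled across up to ``max_resolutions`` polytomy resolutions; each
    labeling gets weight exp(-lam * (cost - min)).  The posterior of a
    directed migration is the weight fraction of labelings containing it at
    least once.
    """
    locs = _locations_dict(locations)
    sites = sorted({s for ss in locs.values() for s in ss} | {root_site})
    M = _transition_matrix(sites, forbidden_dest)
    resolutions = enumerate_polytomy_resolutions(tree, max_n=max_resolutions, seed=seed)
    augmented = [build_augmented_tree(res, locs) for res in resolutions]

    mins = []
    for aug in augmented:
        tables = _sankoff_tables(aug, sites, M)
        mins.append(tables[id(aug)][sites.index(root_site)])
    finite = [m for m in mins if np.isfinite(m)]
    if not finite:
        raise MigrationInferenceError("no feasible site labeling in any resolution")
    global_min = int(round(min(finite)))
    budget = float(global_min + cost_window)

    total_w = 0.0
    pair_w: dict[tuple[str, str], float] = {}
    stored: list[Labeling] = []
    counter = {"n": 0, "cap": MAX_ENUMERATED_LABELINGS, "truncated": False}

    def emit(cost: int, migs: list) -> None:
        nonlocal total_w
        w = math.exp(-lam * (cost - global_min))
        total_w += w
        for pair in {(s, d) for s, d, _ in migs}:
            pair_w[pair] = pair_w.get(pair, 0.0) + w
        if len(stored) < max_store:
            stored.append(Labeling(cost, tuple(migs)))

    for aug in augmented:
        if counter["truncated"]:
            break
        _enumerate_labelings(aug, root_site, sites, M, budget, emit, counter)

    posteriors = {p: w / total_w for p, w in pair_w.items()}
    return PosteriorResult(
        posteriors=posteriors,
        labelings=stored,
        min_migrations=global_min,
        total_weight=total_w,
        n_labelings=counter["n"],
        truncated=counter["truncated"],
    )


# -- map selection ----------------------------------------------------------


def _labeling_sort_key(l: Labeling):
    return (l.cost, len(l.migrations), tuple(sorted(l.migrations)))


def select_migration_map(
    result: PosteriorResult,
    locations,
    site_classes: dict[str, str],
    root_site: str,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
    support_min: float = DEFAULT_SUPPORT_MIN,
) -> MigrationMap:
    """Threshold posteriors into the final migration map.

    Paths with posterior >= ``hi`` are kept at high support.  If occupied
    sites remain without an incoming migration, candidate paths with
    posterior > ``lo`` are pooled and the completion with the fewest added
    migrations (ties: higher posterior, then lexicographic site order) is
    added at low support.  The map is flagged for exclusion when the mean
    posterior of retained paths is below ``support_min`` (strict).
    """
    locs = _locations_dict(locations)
    occupied = {s for ss in locs.values() for s in ss} | {root_site}
    post = result.posteriors
    selected = {p for p, v in post.items() if v >= hi}
    incomplete = False

    uncovered = sorted(
        s
        for s in occupied
        if s != root_site and not any(d == s for _, d in selected)
    )
    if uncovered:
        cand_by_site = {
            s: sorted(
                (p for p in post if p[1] == s and lo < post[p] < hi),
                key=lambda p: (-post[p], p),
            )
            for s in uncovered
        }
        coverable = [s for s in uncovered if cand_by_site[s]]
        if len(coverable) < len(uncovered):
            incomplete = True
        if coverable:
            pools = [cand_by_site[s] for s in coverable]
            n_combos = 1
            for pool in pools:
                n_combos *= len(pool)
            best_choice, best_key = None, None
            combos = (
                itertools.product(*pools)
                if n_combos <= 20_000
                else [tuple(pool[0] for pool in pools)]
            )
            for combo in combos:
                edges = selected | set(combo)
                reach = _reachable(edges, root_site)
                ok = occupied <= reach | {s for s in uncovered if not cand_by_site[s]}
                key = (
                    not ok,
                    len(set(combo)),
                    -sum(post[p] for p in set(combo)),
                    tuple(sorted(set(combo))),
                )
                if best_key is None or key < best_key:
                    best_choice, best_key = set(combo), key
            if best_choice is not None:
                if best_key[0]:
                    incomplete = True
                selected |= best_choice
        high = {p for p in selected if post[p] >= hi}
    else:
        high = set(selected)

    # representative labeling for clone and variant counts
    rep: Optional[Labeling] = None
    compatible = [l for l in result.labelings if l.pairs() <= selected]
    if compatible:
        rep = min(compatible, key=_labeling_sort_key)

    edges = []
    for pair in sorted(selected):
        source, dest = pair
        counts_from = rep if rep is not None and pair in rep.pairs() else None
        if counts_from is None:
            containing = [l for l in result.labelings if pair in l.pairs()]
            counts_from = min(containing, key=_labeling_sort_key) if containing else None
        if counts_from is not None:
            clone_count = counts_from.pair_counts[pair]
            variant_count = sum(
                ln for s, d, ln in counts_from.migrations if (s, d) == pair
            )
        else:  # only possible under enumeration truncation
            clone_count, variant_count = 1, 0
        edges.append(
            MigrationEdge(
                source=source,
                dest=dest,
                path_type=path_type_of(source, dest, site_classes),
                clone_count=int(clone_count),
                posterior=float(post[pair]),
                support_class="high" if pair in high else "low",
                variant_count=int(variant_count),
            )
        )

    support = float(np.mean([e.posterior for e in edges])) if edges else float("nan")
    excluded = (not edges) or support < support_min
    return MigrationMap(
        edges=edges,
        root_site=root_site,
        site_classes=dict(site_classes),
        occupied_sites=occupied,
        overall_support=support,
        excluded=excluded,
        incomplete=incomplete,
        min_migrations=result.min_migrations,
        posteriors=dict(post),
    )


def _reachable(pairs: set, root_site: str) -> set:
    out = {root_site}
    frontier = [root_site]
    while frontier:
        node = frontier.pop()
        for s, d in pairs:
            if s == node and d not in out:
                out.add(d)
                frontier.append(d)
    return out


def overall_support(mmap: MigrationMap, support_min: float = DEFAULT_SUPPORT_MIN):
    """Mean posterior of retained paths and the exclusion flag (< bound)."""
    if not mmap.edges:
        return float("nan"), True
    support = float(np.mean([e.posterior for e in mmap.edges]))
    return support, support < support_min


# -- missing-primary mode ---------------------------------------------------


def apply_missing_primary_assumption(
    tree: CloneNode,
    locations,
    declared_primary_absent: bool,
    site_classes: dict[str, str],
    pseudo_primary: str = "P*",
) -> tuple[str, dict[str, set[str]], dict[str, str]]:
    """Root-site choice, creating a pseudo-primary when no primary was sampled.

    In missing-primary mode the MRCA clone is assumed present in an
    unsampled primary site which becomes the root; migrations back into it
    are structurally impossible, so no M->P path can be inferred.
    """
    locs = {c: set(s) for c, s in _locations_dict(locations).items()}
    primaries = sorted(s for s, c in site_classes.items() if c == "primary")
    if declared_primary_absent:
        if primaries:
            raise MigrationInferenceError(
                f"primary site {primaries[0]!r} present but dataset declared primary-absent"
            )
        mrca, _ = find_mrca(tree, locs, site_classes)
        locs.setdefault(mrca.name, set()).add(pseudo_primary)
        classes = dict(site_classes)
        classes[pseudo_primary] = "primary"
        return pseudo_primary, locs, classes
    if not primaries:
        raise MigrationInferenceError(
            "no primary site in sample table; set declared_primary_absent"
        )
    return primaries[0], locs, dict(site_classes)


# -- end-to-end convenience -------------------------------------------------


def infer_migration_history(
    tree: CloneNode,
    locations,
    site_classes: dict[str, str],
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
    support_min: float = DEFAULT_SUPPORT_MIN,
    lam: float = DEFAULT_LAMBDA,
    cost_window: int = DEFAULT_COST_WINDOW,
    max_resolutions: int = 30,
    seed: int = 0,
    missing_primary: Optional[bool] = None,
) -> MigrationMap:
    """Full migration inference for one patient phylogeny."""
    if missing_primary is None:
        missing_primary = not any(c == "primary" for c in site_classes.values())
    root_site, locs, classes = apply_missing_primary_assumption(
        tree, locations, missing_primary, site_classes
    )
    forbidden = root_site if missing_primary else None
    result = edge_posteriors(
        tree,
        locs,
        root_site,
        lam=lam,
        cost_window=cost_window,
        max_resolutions=max_resolutions,
        seed=seed,
        forbidden_dest=forbidden,
    )
    return select_migration_map(
        result, locs, classes, root_site, hi=hi, lo=lo, support_min=support_min
    )
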