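"""Progression-model and seeding-model classification.

Progression models describe the *shape* of the clone phylogeny together
with where clones were observed: ``linear`` (a single ancestor-descendant
chain), ``big_bang`` (a star: every observed clone descends directly from
the MRCA), ``parallel`` (the metastasis-restricted clones form a branching
monophyletic clade with no primary clone inside) or ``hybrid`` (a mixture).
Seeding models describe the *shape* of the migration map: every metastasis
seeded straight from the primary; a single linear metastatic cascade; one
metastasis fanning out to the others; or a network where some site receives
clones from more than one source.
"""
from __future__ import annotations

from dataclasses import dataclass

from .migration import MigrationMap
from .phylogeny import _locations_dict
from .tree import CloneNode, lca

PROGRESSION_LABELS = ("parallel", "linear", "big_bang", "hybrid")
SEEDING_LABELS = (
    "primary_seeds_all",
    "metastatic_cascade",
    "metastasis_seeds_metastases",
    "network",
)
NOT_APPLICABLE = "not_applicable"


@dataclass
class ProgressionLabel:
    label: str
    evidence: dict


@dataclass
class SeedingLabel:
    label: str
    evidence: dict


def classify_phylogeny(
    tree: CloneNode, locations, site_classes: dict[str, str]
) -> ProgressionLabel:
    """Assign exactly one progression model to a located clone phylogeny.

    Predicates are evaluated strictest-first (linear, big_bang, parallel,
    hybrid) so overlapping shapes (a two-clone chain is also a trivial
    star) resolve deterministically.  Primary clones nested inside
    metastatic clades additionally raise a self-seeding evidence flag.
    """
    locs = _locations_dict(locations)
    met_sites = {s for s, c in site_classes.items() if c == "metastasis"}
    clone_nodes = [n for n in tree.preorder() if n.parent is not None and n.site is None]
    observed = [n for n in clone_nodes if locs.get(n.name)]
    met_clones = [n for n in observed if locs[n.name] & met_sites]
    if not met_clones:
        return ProgressionLabel(NOT_APPLICABLE, {"reason": "no metastatic clones"})

    chain = all(len(n.children) <= 1 for n in tree.preorder() if n.site is None)

    mrca = lca(observed)
    direct = {id(mrca)} | {id(c) for c in mrca.children}
    star = all(id(n) in direct for n in observed)

    met_only = [
        n for n in observed if locs[n.name] and locs[n.name] <= met_sites
    ]
    monophyletic_met = False
    branching_met = False
    if len(met_only) >= 2:
        clade_root = lca(met_only)
        clade = [n for n in clade_root.preorder() if n.site is None]
        primary_inside = any(
            locs.get(n.name) and (locs[n.name] - met_sites) for n in clade
        )
        monophyletic_met = not primary_inside
        met_only_ids = {id(n) for n in met_only}
        subtrees_with_met = sum(
            1
            for child in clade_root.children
            if any(id(n) in met_only_ids for n in child.preorder())
        ) + (1 if id(clade_root) in met_only_ids else 0)
        branching_met = subtrees_with_met >= 2

    met_only_ids = {id(n) for n in met_only}
    self_seeding = any(
        any(id(a) in met_only_ids for a in n.ancestors())
        for n in observed
        if locs[n.name] - met_sites
    )

    evidence = {
        "chain": chain,
        "star": star,
        "metastatic_monophyly": monophyletic_met,
        "metastatic_branching": branching_met,
        "n_met_only_clones": len(met_only),
        "self_seeding": self_seeding,
    }
    if chain:
        return ProgressionLabel("linear", evidence)
    if star:
        return ProgressionLabel("big_bang", evidence)
    if monophyletic_met and branching_met:
        return ProgressionLabel("parallel", evidence)
    return ProgressionLabel("hybrid", evidence)


def _seeding_from_edges(
    pairs: set[tuple[str, str]], primary_sites: set[str], met_sites: set[str]
) -> SeedingLabel:
    mets = sorted(met_sites)
    if len(mets) < 2:
        return SeedingLabel(NOT_APPLICABLE, {"reason": "fewer than two metastatic sites"})
    sources: dict[str, set[str]] = {}
    for s, d in pairs:
        sources.setdefault(d, set()).add(s)
    evidence = {"n_met_sites": len(mets), "sources": {d: sorted(s) for d, s in sources.items()}}

    if any(len(s) >= 2 for s in sources.values()):
        return SeedingLabel("network", evidence)
    met_sources = {
        d: s for d, s in sources.items() if d in met_sites
    }
    if met_sources and all(s <= primary_sites for s in met_sources.values()) and set(
        met_sources
    ) == set(mets):
        return SeedingLabel("primary_seeds_all", evidence)
    primary_seeded = {
        d for d, s in met_sources.items() if s & primary_sites
    }
    mm_pairs = {(s, d) for s, d in pairs if s in met_sites and d in met_sites}
    if len(primary_seeded) == 1:
        # cascade: metastasis->metastasis edges form one directed path
        # starting at the primary-seeded site and covering all other sites
        out_deg: dict[str, int] = {}
        in_deg: dict[str, int] = {}
        for s, d in mm_pairs:
            out_deg[s] = out_deg.get(s, 0) + 1
            in_deg[d] = in_deg.get(d, 0) + 1
        start = next(iter(primary_seeded))
        is_path = (
            len(mm_pairs) == len(mets) - 1
            and all(v == 1 for v in out_deg.values())
            and all(v == 1 for v in in_deg.values())
            and start not in in_deg
        )
        if is_path:
            node, seen = start, {start}
            nxt = {s: d for s, d in mm_pairs}
            while node in nxt:
                node = nxt[node]
                if node in seen:
                    break
                seen.add(node)
            if seen == set(mets):
                return SeedingLabel("metastatic_cascade", evidence)
    return SeedingLabel("metastasis_seeds_metastases", evidence)


def classify_migration_map(mmap: MigrationMap, high_only: bool = False) -> SeedingLabel:
    """Assign exactly one seeding model to a selected migration map."""
    pairs = {
        (e.source, e.dest)
        for e in mmap.edges
        if not high_only or e.support_class == "high"
    }
    primary_sites = {s for s, c in mmap.site_classes.items() if c == "primary"}
    met_sites = {
        s
        for s in mmap.occupied_sites
        if mmap.site_classes.get(s, "metastasis") == "metastasis"
    }
    return _seeding_from_edges(pairs, primary_sites, met_sites)


def seeding_label_from_events(
    events: list[tuple[str, str, str]], primary_site: str, met_sites: set[str]
) -> SeedingLabel:
    """Seeding model implied by a ground-truth migration event log."""
    pairs = {(s, d) for s, d, _ in events}
    return _seeding_from_edges(pairs, {primary_site}, set(met_sites))
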