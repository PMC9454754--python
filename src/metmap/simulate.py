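"""Synthetic tumor-evolution simulator with known migration ground truth.

Generates, per patient: a rooted clone genealogy under the infinite-sites,
CNA-free, heterozygous-diploid mutation model; an anatomical migration
history over a primary site and a configurable number of metastatic sites;
and bulk read counts (one sample per site) with Dirichlet clone mixing,
Poisson coverage and binomial read sampling.  The ground truth (tree, clone
locations, migration event log, clone frequencies) is kept in a
:class:`TruthBundle` so every downstream inference stage can be scored
against it.

Migration process (one preorder pass, per-clone probabilities, no time
axis): a clone is born at its parent's residence.  A clone born in the
primary migrates with probability ``rate_PM`` to a metastatic site; a clone
born in a metastasis migrates onward with ``rate_MM`` and back to the
primary with ``rate_MP``.  A forward migration relocates the clone (it
persists in the destination while its ancestors mark the source lineage),
whereas a back-seeding to the primary copies the clone so the metastasis
persists; with probability ``polyclonal_prob`` a second clone resident at the
source accompanies the seeding as a copy, ending up observed in both sites.  The
MRCA clone founds the primary and never relocates, so no site is ever left
without clones.  New metastatic sites are founded until ``n_met_sites``
exist; later seedings pick an existing site uniformly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import SnvMatrix, write_sample_info, write_snv_table
from .tree import CloneNode, to_newick

PRIMARY_SITE = "P"
TREE_SHAPES = ("random", "chain", "star", "fork")


class SimulationConfigError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic patient.

    Defaults emulate the cohorts the pipeline targets: about six clones and
    four tumors per patient, mean purity 0.6, exome-like coverage of 150
    reads per SNV, and modest per-clone migration probabilities that yield a
    handful of seeding events per patient.
    """

    n_clones: int = 6
    n_met_sites: int = 3
    has_primary: bool = True
    n_snvs_per_branch_mean: float = 300.0
    rate_PM: float = 0.5
    rate_MM: float = 0.25
    rate_MP: float = 0.05
    coverage_mean: float = 150.0
    purity: float = 0.6
    polyclonal_prob: float = 0.2
    dirichlet_conc: float = 1.0
    tree_shape: str = "random"
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_clones < 1:
            raise SimulationConfigError("n_clones must be >= 1")
        if self.n_met_sites < 0:
            raise SimulationConfigError("n_met_sites must be >= 0")
        for name in ("rate_PM", "rate_MM", "rate_MP", "polyclonal_prob", "purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {v}")
        if self.coverage_mean <= 0:
            raise SimulationConfigError("coverage_mean must be > 0")
        if self.n_snvs_per_branch_mean <= 0:
            raise SimulationConfigError("n_snvs_per_branch_mean must be > 0")
        if self.dirichlet_conc <= 0:
            raise SimulationConfigError("dirichlet_conc must be > 0")
        if self.tree_shape not in TREE_SHAPES:
            raise SimulationConfigError(
                f"tree_shape must be one of {TREE_SHAPES}, got {self.tree_shape!r}"
            )
        return self


@dataclass
class TruthBundle:
    """Simulator ground truth used as the recovery oracle."""

    tree: CloneNode
    clone_locations: dict[str, set[str]]
    migration_events: list[tuple[str, str, str]]  # (source site, dest site, clone)
    primary_site: str
    met_sites: list[str]
    has_primary: bool
    config: SimulationConfig
    clone_frequencies: Optional[pd.DataFrame] = field(default=None)

    @property
    def site_classes(self) -> dict[str, str]:
        classes = {s: "metastasis" for s in self.met_sites}
        classes[self.primary_site] = "primary"
        return classes

    def sampled_sites(self) -> list[str]:
        """Sites that yield a bulk sample (pseudo-primary is unsampled)."""
        sites = list(self.met_sites)
        if self.has_primary:
            sites = [self.primary_site] + sites
        return sites

    def genotypes(self) -> pd.DataFrame:
        """Binary clone x SNV matrix from the true tree."""
        clones = self.tree.clone_nodes()
        snvs = [m for node in self.tree.preorder() for m in node.mutations]
        G = pd.DataFrame(0, index=[c.name for c in clones], columns=snvs, dtype=np.int8)
        for node in clones:
            for snv in node.genotype():
                G.loc[node.name, snv] = 1
        return G

    def snv_branch(self) -> dict[str, str]:
        """Map SNV id -> name of the clone whose edge introduced it."""
        return {m: node.name for node in self.tree.preorder() for m in node.mutations}

    def true_progression_label(self):
        from .classify import classify_phylogeny

        return classify_phylogeny(self.tree, self.clone_locations, self.site_classes)

    def true_seeding_label(self):
        from .classify import seeding_label_from_events

        met = {s for s in self.met_sites}
        return seeding_label_from_events(self.migration_events, self.primary_site, met)


def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


def simulate_clone_tree(config: SimulationConfig) -> CloneNode:
    """Rooted genealogy of ``n_clones`` clones below the normal root.

    Each branch carries a zero-truncated Poisson number of novel SNVs
    (infinite sites: no SNV recurs), so all clone genotypes are distinct.
    """
    config.validate()
    rng = _rng(1, config.seed)
    root = CloneNode("Normal", observed=False)
    counter = [0]

    def draw_mutations() -> list[str]:
        k = 0
        while k < 1:
            k = int(rng.poisson(config.n_snvs_per_branch_mean))
        out = [f"s{counter[0] + i}" for i in range(k)]
        counter[0] += k
        return out

    clones: list[CloneNode] = []
    for i in range(config.n_clones):
        if i == 0:
            parent = root
        elif config.tree_shape == "chain":
            parent = clones[i - 1]
        elif config.tree_shape == "star":
            parent = clones[0]
        elif config.tree_shape == "fork":
            parent = clones[0] if i == 1 else clones[1]
        else:
            parent = clones[int(rng.integers(len(clones)))]
        node = CloneNode(f"C{i}", mutations=draw_mutations())
        parent.add_child(node)
        clones.append(node)
    return root


def simulate_migrations(tree: CloneNode, config: SimulationConfig) -> TruthBundle:
    """One preorder migration pass over the clone tree (see module docstring)."""
    config.validate()
    rng = _rng(2, config.seed)
    clones = tree.clone_nodes()
    locations: dict[str, set[str]] = {}
    residence: dict[str, str] = {}
    events: list[tuple[str, str, str]] = []
    met_sites: list[str] = []

    def pick_met(exclude: Optional[str]) -> Optional[str]:
        if len(met_sites) < config.n_met_sites:
            site = f"M{len(met_sites) + 1}"
            met_sites.append(site)
            return site
        options = [s for s in met_sites if s != exclude]
        if not options:
            return None
        return options[int(rng.integers(len(options)))]

    def maybe_companion(src: str, dest: str, migrant: str) -> None:
        if config.polyclonal_prob <= 0 or rng.random() >= config.polyclonal_prob:
            return
        candidates = sorted(
            c for c, locs in locations.items() if src in locs and c != migrant
        )
        if not candidates:
            return
        companion = candidates[int(rng.integers(len(candidates)))]
        events.append((src, dest, companion))
        locations[companion].add(dest)

    for i, node in enumerate(clones):
        if i == 0:
            residence[node.name] = PRIMARY_SITE
            locations[node.name] = {PRIMARY_SITE}
            continue
        birth = residence[node.parent.name]
        residence[node.name] = birth
        locations[node.name] = {birth}
        current = birth
        if current == PRIMARY_SITE:
            if rng.random() < config.rate_PM:
                dest = pick_met(exclude=None)
                if dest is not None:
                    events.append((current, dest, node.name))
                    locations[node.name] = {dest}
                    residence[node.name] = dest
                    maybe_companion(current, dest, node.name)
        else:
            if rng.random() < config.rate_MM:
                dest = pick_met(exclude=current)
                if dest is not None:
                    events.append((current, dest, node.name))
                    locations[node.name] = {dest}
                    residence[node.name] = dest
                    maybe_companion(current, dest, node.name)
                    current = dest
            if rng.random() < config.rate_MP:
                # self-seeding copies the clone back: the metastasis persists
                events.append((current, PRIMARY_SITE, node.name))
                locations[node.name].add(PRIMARY_SITE)
                maybe_companion(current, PRIMARY_SITE, node.name)

    return TruthBundle(
        tree=tree,
        clone_locations=locations,
        migration_events=events,
        primary_site=PRIMARY_SITE,
        met_sites=met_sites,
        has_primary=config.has_primary,
        config=config,
    )


def simulate_read_counts(
    truth: TruthBundle, config: SimulationConfig
) -> tuple[SnvMatrix, pd.DataFrame]:
    """Bulk read counts, one sample per sampled site.

    Per sample, frequencies of the clones present are drawn from a symmetric
    Dirichlet and scaled by purity; per SNV the expected VAF is half the
    summed frequency of carrying clones (heterozygous diploid), total reads
    are Poisson(coverage_mean) floored at 1 and variant reads binomial.
    The drawn frequencies are recorded in ``truth.clone_frequencies``.
    """
    config.validate()
    rng = _rng(3, config.seed)
    sites = truth.sampled_sites()
    clones = [c.name for c in truth.tree.clone_nodes()]
    F = pd.DataFrame(0.0, index=clones, columns=sites)
    for site in sites:
        present = [c for c in clones if site in truth.clone_locations[c]]
        if present:
            freqs = rng.dirichlet(np.full(len(present), config.dirichlet_conc))
            F.loc[present, site] = freqs * config.purity
    truth.clone_frequencies = F

    G = truth.genotypes()  # clone x snv
    snvs = list(G.columns)
    vaf = 0.5 * (G.values.T @ F.values)  # snv x site
    totals = np.maximum(rng.poisson(config.coverage_mean, size=vaf.shape), 1)
    variants = rng.binomial(totals, np.clip(vaf, 0.0, 1.0))
    matrix = SnvMatrix(snvs, sites, totals, variants)

    classes = truth.site_classes
    sample_info = pd.DataFrame(
        {
            "sample_id": sites,
            "site_label": sites,
            "site_class": [classes[s] for s in sites],
        }
    )
    return matrix, sample_info


def true_vaf_matrix(truth: TruthBundle) -> pd.DataFrame:
    """Analytic (noise-free) VAF matrix from the recorded clone frequencies."""
    if truth.clone_frequencies is None:
        raise ValueError(
            "clone frequencies not drawn yet; run simulate_read_counts first"
        )
    F = truth.clone_frequencies
    G = truth.genotypes().loc[F.index]
    vaf = 0.5 * (G.values.T @ F.values)
    return pd.DataFrame(vaf, index=list(G.columns), columns=list(F.columns))


ARCHETYPES = (
    "primary_seeds_all",
    "metastatic_cascade",
    "metastasis_seeds_metastases",
)


def simulate_archetype(
    kind: str, config: SimulationConfig
) -> tuple[SnvMatrix, pd.DataFrame, TruthBundle]:
    """One patient whose migration history is a pure seeding-model shape.

    Builds the canonical map shapes directly: every metastasis seeded from
    the primary; a single linear metastatic cascade; or one metastasis
    fanning out to all others.  Each seeded site keeps a resident subclone
    besides its founder so the true history is the unique minimum-migration
    reconstruction (a site holding only a pass-through founder makes the
    seeding direction non-identifiable).  Read counts come from the usual
    generator, so the full pipeline can be run end to end.
    """
    if kind not in ARCHETYPES:
        raise SimulationConfigError(f"unknown archetype {kind!r}")
    config.validate()
    if config.n_met_sites < 2:
        raise SimulationConfigError("archetypes need at least two metastatic sites")
    rng = _rng(4, config.seed)
    root = CloneNode("Normal", observed=False)
    counter = [0]

    def draw_mutations() -> list[str]:
        k = 0
        while k < 1:
            k = int(rng.poisson(config.n_snvs_per_branch_mean))
        out = [f"s{counter[0] + i}" for i in range(k)]
        counter[0] += k
        return out

    idx = [0]

    def new_clone(parent: CloneNode) -> CloneNode:
        node = CloneNode(f"C{idx[0]}", mutations=draw_mutations())
        idx[0] += 1
        parent.add_child(node)
        return node

    mets = [f"M{i + 1}" for i in range(config.n_met_sites)]
    locations: dict[str, set[str]] = {}
    events: list[tuple[str, str, str]] = []

    mrca = new_clone(root)
    locations[mrca.name] = {PRIMARY_SITE}

    def seed_site(source_clone: CloneNode, source_site: str, dest: str) -> CloneNode:
        founder = new_clone(source_clone)
        locations[founder.name] = {dest}
        events.append((source_site, dest, founder.name))
        resident = new_clone(founder)  # anchors the site
        locations[resident.name] = {dest}
        return founder

    if kind == "primary_seeds_all":
        for site in mets:
            seed_site(mrca, PRIMARY_SITE, site)
    elif kind == "metastatic_cascade":
        clone, site = mrca, PRIMARY_SITE
        for dest in mets:
            clone = seed_site(clone, site, dest)
            site = dest
    else:  # metastasis_seeds_metastases
        hub = seed_site(mrca, PRIMARY_SITE, mets[0])
        for dest in mets[1:]:
            seed_site(hub, mets[0], dest)

    truth = TruthBundle(
        tree=root,
        clone_locations=locations,
        migration_events=events,
        primary_site=PRIMARY_SITE,
        met_sites=mets,
        has_primary=config.has_primary,
        config=config,
    )
    matrix, sample_info = simulate_read_counts(truth, config)
    return matrix, sample_info, truth


def simulate_patient(
    config: SimulationConfig,
) -> tuple[SnvMatrix, pd.DataFrame, TruthBundle]:
    """Run the three stages for one patient."""
    tree = simulate_clone_tree(config)
    truth = simulate_migrations(tree, config)
    matrix, sample_info = simulate_read_counts(truth, config)
    return matrix, sample_info, truth


def write_patient(out_dir, matrix: SnvMatrix, sample_info: pd.DataFrame, truth: TruthBundle) -> None:
    """Write SNV table, sample metadata and ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_snv_table(matrix, out / "snv_table.tsv")
    write_sample_info(sample_info, out / "samples.tsv")
    cfg = asdict(truth.config)
    payload = {
        "tree_newick": to_newick(truth.tree),
        "clone_locations": {c: sorted(s) for c, s in truth.clone_locations.items()},
        "migration_events": [list(e) for e in truth.migration_events],
        "primary_site": truth.primary_site,
        "met_sites": truth.met_sites,
        "has_primary": truth.has_primary,
        "config": cfg,
        "clone_frequencies": (
            None
            if truth.clone_frequencies is None
            else truth.clone_frequencies.round(10).to_dict(orient="index")
        ),
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
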