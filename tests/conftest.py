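"""Shared fixtures: small trees, maps and simulated patients."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metmap.io import SnvMatrix
from metmap.migration import MigrationEdge, MigrationMap
from metmap.simulate import SimulationConfig
from metmap.tree import CloneNode


@pytest.fixture
def small_matrix() -> SnvMatrix:
    return SnvMatrix(
        ["s0", "s1"],
        ["A", "B", "C"],
        np.array([[100, 80, 60], [120, 90, 70]]),
        np.array([[25, 40, 0], [30, 0, 35]]),
    )


@pytest.fixture
def quick_config() -> SimulationConfig:
    # small branches keep unit tests fast; analyses use the realistic default
    return SimulationConfig(n_snvs_per_branch_mean=10.0, seed=0)


def make_chain(n: int, sites: dict[str, set[str]] | None = None) -> CloneNode:
    """Normal -> C0 -> ... -> C{n-1}, one private SNV per branch."""
    root = CloneNode("Normal", observed=False)
    parent = root
    for i in range(n):
        parent = parent.add_child(CloneNode(f"C{i}", mutations=[f"m{i}"]))
    return root


def make_star(n: int) -> CloneNode:
    """Normal -> C0 -> {C1..C{n-1}}."""
    root = CloneNode("Normal", observed=False)
    c0 = root.add_child(CloneNode("C0", mutations=["m0"]))
    for i in range(1, n):
        c0.add_child(CloneNode(f"C{i}", mutations=[f"m{i}"]))
    return root


def make_map(
    pairs: dict[tuple[str, str], int],
    site_classes: dict[str, str],
    posteriors: dict[tuple[str, str], float] | None = None,
    root_site: str = "P",
) -> MigrationMap:
    posteriors = posteriors or {}
    edges = [
        MigrationEdge(
            source=s,
            dest=d,
            path_type=(
                ("P" if site_classes.get(s) == "primary" else "M")
                + "->"
                + ("P" if site_classes.get(d) == "primary" else "M")
            ),
            clone_count=k,
            posterior=posteriors.get((s, d), 1.0),
            support_class="high",
            variant_count=0,
        )
        for (s, d), k in pairs.items()
    ]
    occupied = {s for pair in pairs for s in pair} | {root_site}
    support = float(np.mean([e.posterior for e in edges])) if edges else float("nan")
    return MigrationMap(
        edges=edges,
        root_site=root_site,
        site_classes=site_classes,
        occupied_sites=occupied,
        overall_support=support,
        excluded=not edges or support < 0.3,
        incomplete=False,
        min_migrations=sum(pairs.values()),
        posteriors={(e.source, e.dest): e.posterior for e in edges},
    )
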