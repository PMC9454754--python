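"""Migration inference: Sankoff labelings, posteriors, map selection."""
import itertools

import numpy as np
import pytest

from conftest import make_chain, make_star
from metmap.migration import (
    Labeling,
    MigrationInferenceError,
    PosteriorResult,
    apply_missing_primary_assumption,
    build_augmented_tree,
    edge_posteriors,
    infer_migration_history,
    min_migration_history,
    overall_support,
    select_migration_map,
)
from metmap.tree import CloneNode


def brute_force_min(aug, root_site, sites):
    nodes = [n for n in aug.preorder() if n.site is None and n.parent is not None]
    best = None
    for combo in itertools.product(sites, repeat=len(nodes)):
        assign = {id(aug): root_site}
        assign.update({id(n): s for n, s in zip(nodes, combo)})
        cost = 0
        for n in aug.preorder():
            if n.parent is None:
                continue
            s = assign[id(n.parent)]
            t = n.site if n.site is not None else assign[id(n)]
            cost += s != t
        best = cost if best is None else min(best, cost)
    return best


class TestAugmentedTree:
    def test_one_leaf_per_location(self):
        root = make_chain(2)
        aug = build_augmented_tree(root, {"C0": {"P"}, "C1": {"P", "Lu", "Li"}})
        leaves = [n for n in aug.preorder() if n.site is not None]
        assert len(leaves) == 4
        c1 = aug.find("C1")
        assert sum(1 for c in c1.children if c.site is not None) == 3

    def test_unknown_clone_rejected(self):
        root = make_chain(2)
        with pytest.raises(MigrationInferenceError, match="absent from tree"):
            build_augmented_tree(root, {"C9": {"P"}})

    def test_empty_locations_rejected(self):
        root = make_chain(2)
        with pytest.raises(MigrationInferenceError):
            build_augmented_tree(root, {"C0": set(), "C1": set()})


class TestMinMigrationHistory:
    def test_all_same_site_zero_migrations(self):
        root = make_chain(3)
        aug = build_augmented_tree(root, {f"C{i}": {"P"} for i in range(3)})
        count, labelings = min_migration_history(aug, "P")
        assert count == 0
        assert labelings and labelings[0].migrations == ()

    def test_two_metastatic_clades_need_two_seedings(self):
        root = make_star(3)
        aug = build_augmented_tree(root, {"C0": {"P"}, "C1": {"M1"}, "C2": {"M2"}})
        count, _ = min_migration_history(aug, "P")
        assert count == 2

    def test_matches_exhaustive_enumeration_on_random_instances(self):
        from metmap.simulate import SimulationConfig, simulate_clone_tree

        rng = np.random.default_rng(13)
        for trial in range(40):
            cfg = SimulationConfig(
                n_clones=int(rng.integers(3, 8)), seed=trial, n_snvs_per_branch_mean=3
            )
            tree = simulate_clone_tree(cfg)
            sites = [f"S{i}" for i in range(int(rng.integers(2, 5)))]
            locs = {
                c.name: set(rng.choice(sites, size=int(rng.integers(1, 3)), replace=False))
                for c in tree.clone_nodes()
            }
            aug = build_augmented_tree(tree, locs)
            all_sites = sorted({s for ss in locs.values() for s in ss} | {sites[0]})
            count, _ = min_migration_history(aug, sites[0], sites=all_sites)
            assert count == brute_force_min(aug, sites[0], all_sites)


class TestEdgePosteriors:
    def test_unique_optimum_all_posteriors_one_at_high_lambda(self):
        root = make_chain(3)
        locs = {"C0": {"P"}, "C1": {"M1"}, "C2": {"M1"}}
        res = edge_posteriors(root, locs, "P", lam=50.0, cost_window=2)
        assert res.posteriors[("P", "M1")] == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_optima_share_posterior_mass(self):
        # C1 observed in both M1 and M2: three equally parsimonious labelings
        # (C1 at P, M1 or M2); shared edges appear in 2/3 of them, private
        # return edges in 1/3
        root = make_chain(2)
        locs = {"C0": {"P"}, "C1": {"M1", "M2"}}
        res = edge_posteriors(root, locs, "P", lam=50.0, cost_window=0)
        assert res.min_migrations == 2
        assert res.posteriors[("P", "M1")] == pytest.approx(2 / 3, abs=1e-9)
        assert res.posteriors[("P", "M2")] == pytest.approx(2 / 3, abs=1e-9)
        assert res.posteriors[("M1", "M2")] == pytest.approx(1 / 3, abs=1e-9)
        assert res.posteriors[("M2", "M1")] == pytest.approx(1 / 3, abs=1e-9)

    def test_lambda_zero_equals_plain_fraction(self):
        from metmap.simulate import SimulationConfig, simulate_clone_tree

        rng = np.random.default_rng(21)
        checked = 0
        for trial in range(30):
            cfg = SimulationConfig(
                n_clones=int(rng.integers(3, 6)), seed=100 + trial, n_snvs_per_branch_mean=3
            )
            tree = simulate_clone_tree(cfg)
            if any(len(n.children) > 2 for n in tree.preorder()):
                continue  # keep a single resolution so pooling is directly comparable
            sites = [f"S{i}" for i in range(int(rng.integers(2, 4)))]
            locs = {
                c.name: {str(rng.choice(sites))} for c in tree.clone_nodes()
            }
            aug = build_augmented_tree(tree, locs)
            all_sites = sorted({s for ss in locs.values() for s in ss} | {sites[0]})
            # brute force: fraction of labelings with cost <= min+2 containing edge
            nodes = [n for n in aug.preorder() if n.site is None and n.parent is not None]
            entries = []
            for combo in itertools.product(all_sites, repeat=len(nodes)):
                assign = {id(aug): all_sites.index(sites[0])}
                assign = {id(aug): sites[0]}
                assign.update({id(n): s for n, s in zip(nodes, combo)})
                cost, migs = 0, set()
                for n in aug.preorder():
                    if n.parent is None:
                        continue
                    s = assign[id(n.parent)]
                    t = n.site if n.site is not None else assign[id(n)]
                    if s != t:
                        cost += 1
                        migs.add((s, t))
                entries.append((cost, frozenset(migs)))
            mn = min(c for c, _ in entries)
            pool = [m for c, m in entries if c <= mn + 2]
            expected = {}
            for migs in pool:
                for p in migs:
                    expected[p] = expected.get(p, 0) + 1
            expected = {p: v / len(pool) for p, v in expected.items()}
            res = edge_posteriors(tree, locs, sites[0], lam=0.0, cost_window=2)
            for p in set(expected) | set(res.posteriors):
                assert abs(expected.get(p, 0.0) - res.posteriors.get(p, 0.0)) < 1e-12
            checked += 1
        assert checked >= 10


class TestSelectMigrationMap:
    classes = {"P": "primary", "Lu": "metastasis", "Sm": "metastasis", "Li": "metastasis"}

    def make_result(self, posteriors, labelings=()):
        return PosteriorResult(
            posteriors=posteriors,
            labelings=list(labelings),
            min_migrations=min((l.cost for l in labelings), default=0),
            total_weight=1.0,
            n_labelings=len(labelings),
            truncated=False,
        )

    def test_high_posterior_edges_cover_everything(self):
        post = {("P", "Lu"): 0.9, ("P", "Sm"): 0.8}
        labeling = Labeling(2, (("P", "Lu", 3), ("P", "Sm", 4)))
        res = self.make_result(post, [labeling])
        locs = {"C0": {"P"}, "C1": {"Lu"}, "C2": {"Sm"}}
        mmap = select_migration_map(res, locs, self.classes, "P")
        assert {(e.source, e.dest) for e in mmap.edges} == set(post)
        assert all(e.support_class == "high" for e in mmap.edges)
        assert not mmap.incomplete

    def test_low_support_completion_prefers_higher_posterior_on_tie(self):
        post = {("P", "Lu"): 0.9, ("P", "Li"): 0.4, ("Lu", "Li"): 0.3}
        labelings = [
            Labeling(2, (("P", "Lu", 3), ("P", "Li", 5))),
            Labeling(2, (("P", "Lu", 3), ("Lu", "Li", 2))),
        ]
        res = self.make_result(post, labelings)
        locs = {"C0": {"P"}, "C1": {"Lu"}, "C2": {"Li"}}
        mmap = select_migration_map(res, locs, self.classes, "P")
        pairs = {(e.source, e.dest): e.support_class for e in mmap.edges}
        assert pairs == {("P", "Lu"): "high", ("P", "Li"): "low"}

    def test_posterior_point_one_never_retained(self):
        post = {("P", "Lu"): 0.9, ("P", "Li"): 0.10}
        res = self.make_result(post, [Labeling(1, (("P", "Lu", 3),))])
        locs = {"C0": {"P"}, "C1": {"Lu"}, "C2": {"Li"}}
        mmap = select_migration_map(res, locs, self.classes, "P")
        assert ("P", "Li") not in {(e.source, e.dest) for e in mmap.edges}
        assert mmap.incomplete

    def test_variant_counts_from_representative_labeling(self):
        post = {("P", "Lu"): 1.0}
        res = self.make_result(post, [Labeling(1, (("P", "Lu", 10),))])
        locs = {"C0": {"P"}, "C1": {"Lu"}}
        mmap = select_migration_map(res, locs, self.classes, "P")
        assert mmap.edges[0].variant_count == 10
        assert mmap.edges[0].clone_count == 1

    def test_shared_identical_clone_counts_zero_variants(self):
        root = make_chain(2)
        locs = {"C0": {"P"}, "C1": {"P", "Lu"}}
        mmap = infer_migration_history(
            root, locs, {"P": "primary", "Lu": "metastasis"}
        )
        edge = next(e for e in mmap.edges if (e.source, e.dest) == ("P", "Lu"))
        assert edge.variant_count == 0


class TestOverallSupport:
    def test_mean_posterior_and_flag(self, small_matrix):
        from conftest import make_map

        classes = {"P": "primary", "Lu": "metastasis", "Li": "metastasis"}
        mmap = make_map(
            {("P", "Lu"): 1, ("P", "Li"): 1},
            classes,
            posteriors={("P", "Lu"): 1.0, ("P", "Li"): 0.6},
        )
        support, flagged = overall_support(mmap)
        assert support == pytest.approx(0.8) and not flagged

    def test_below_bound_flagged(self):
        from conftest import make_map

        classes = {"P": "primary", "Lu": "metastasis", "Li": "metastasis"}
        mmap = make_map(
            {("P", "Lu"): 1, ("P", "Li"): 1},
            classes,
            posteriors={("P", "Lu"): 0.2, ("P", "Li"): 0.25},
        )
        support, flagged = overall_support(mmap)
        assert support == pytest.approx(0.225) and flagged

    def test_exactly_point_three_not_flagged(self):
        from conftest import make_map

        classes = {"P": "primary", "Lu": "metastasis"}
        mmap = make_map({("P", "Lu"): 1}, classes, posteriors={("P", "Lu"): 0.3})
        support, flagged = overall_support(mmap)
        assert support == pytest.approx(0.3) and not flagged


class TestMissingPrimary:
    def test_pseudo_primary_created_and_no_mp_edges(self):
        root = make_chain(3)
        locs = {"C0": {"M1"}, "C1": {"M1"}, "C2": {"M2"}}
        classes = {"M1": "metastasis", "M2": "metastasis"}
        mmap = infer_migration_history(root, locs, classes, missing_primary=True)
        assert mmap.root_site == "P*"
        assert all(e.path_type != "M->P" for e in mmap.edges)

    def test_flag_with_primary_present_is_error(self):
        root = make_chain(2)
        locs = {"C0": {"P"}, "C1": {"M1"}}
        classes = {"P": "primary", "M1": "metastasis"}
        with pytest.raises(MigrationInferenceError, match="declared primary-absent"):
            apply_missing_primary_assumption(root, locs, True, classes)

    def test_primary_present_uses_its_site_label(self):
        root = make_chain(2)
        locs = {"C0": {"P"}, "C1": {"M1"}}
        classes = {"P": "primary", "M1": "metastasis"}
        root_site, _, _ = apply_missing_primary_assumption(root, locs, False, classes)
        assert root_site == "P"
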