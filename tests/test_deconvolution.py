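"""Clone deconvolution: clustering, nesting, frequencies, purity, presence."""
import numpy as np
import pandas as pd
import pytest

from metmap.deconvolve import (
    CloneLocationMap,
    DeconvolutionError,
    build_clone_genotypes,
    clone_presence,
    cluster_prevalences,
    cluster_snvs,
    deconvolve,
    estimate_clone_frequencies,
    estimate_purity,
)
from metmap.simulate import SimulationConfig, simulate_patient, true_vaf_matrix


def vaf_frame(rows, samples=("A", "B")):
    return pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=[f"s{i}" for i in range(len(rows))],
        columns=list(samples),
    )


def sample_info(samples=("A", "B"), sites=None, classes=None):
    sites = sites or list(samples)
    classes = classes or ["primary"] + ["metastasis"] * (len(samples) - 1)
    return pd.DataFrame(
        {"sample_id": list(samples), "site_label": sites, "site_class": classes}
    )


class TestClusterSnvs:
    def test_identical_vaf_vectors_form_one_cluster(self):
        vaf = vaf_frame([[0.4, 0.1]] * 20)
        labels = cluster_snvs(vaf)
        assert set(labels) == {1}

    def test_two_separated_groups_found_by_bic(self):
        rows = [[0.5, 0.0]] * 50 + [[0.25, 0.25]] * 50
        labels = cluster_snvs(vaf_frame(rows))
        assert len(set(labels)) == 2
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1

    def test_all_missing_snv_excluded_with_warning(self):
        vaf = vaf_frame([[0.4, 0.1], [np.nan, np.nan], [0.4, 0.1]])
        with pytest.warns(UserWarning, match="no usable observation"):
            labels = cluster_snvs(vaf)
        assert labels[1] == -1 and labels[0] == labels[2] != -1

    def test_single_sample_rejected(self):
        with pytest.raises(DeconvolutionError):
            cluster_snvs(vaf_frame([[0.4]], samples=("A",)))

    def test_simulated_branches_recovered(self):
        # branches resolvable at this coverage (mutual VAF separation above
        # the binomial noise scale) must be recovered with their SNVs
        from metmap.io import compute_vaf, filter_snvs
        from scipy.optimize import linear_sum_assignment

        checked = 0
        for seed in range(8):
            cfg = SimulationConfig(
                seed=seed, n_clones=5, coverage_mean=500,
                n_snvs_per_branch_mean=200, n_met_sites=3, rate_PM=1.0,
            )
            matrix, samples, truth = simulate_patient(cfg)
            if matrix.n_samples < 3:
                continue
            G, F = truth.genotypes(), truth.clone_frequencies
            prev = {
                n.name: 0.5 * (G[n.mutations[0]].values @ F.values)
                for n in truth.tree.clone_nodes()
            }
            names = list(prev)
            min_sep = min(
                np.abs(prev[a] - prev[b]).max()
                for i, a in enumerate(names)
                for b in names[i + 1 :]
            )
            if min_sep < 0.05:  # unresolvable draw; not the claim under test
                continue
            filtered = filter_snvs(matrix)
            vaf = compute_vaf(filtered)
            cloneset, _ = deconvolve(filtered, samples)
            labels = cloneset.snv_cluster.values
            branch = truth.snv_branch()
            true = pd.Series([branch[s] for s in vaf.index])
            assert len(set(labels)) == true.nunique()
            ct = pd.crosstab(pd.Series(labels), true)
            r, c = linear_sum_assignment(-ct.values)
            assert ct.values[r, c].sum() / len(labels) >= 0.95
            checked += 1
        assert checked >= 2


class TestNesting:
    def test_nested_prevalences_give_chain(self):
        rows = [[0.4, 0.4]] * 5 + [[0.15, 0.0]] * 5  # prevalences (.8,.8), (.3,0)
        vaf = vaf_frame(rows)
        labels = cluster_snvs(vaf)
        G, parent, clone_of = build_clone_genotypes(vaf, labels, tol=0.05)
        roots = [k for k, p in parent.items() if p is None]
        assert len(roots) == 1
        genos = {frozenset(G.columns[G.loc[c].values == 1]) for c in G.index}
        small = frozenset(f"s{i}" for i in range(5))
        assert genos == {small, small | {f"s{i}" for i in range(5, 10)}}

    def test_crossing_prevalences_become_siblings(self):
        rows = [[0.25, 0.0]] * 5 + [[0.0, 0.25]] * 5
        vaf = vaf_frame(rows)
        labels = cluster_snvs(vaf)
        G, parent, _ = build_clone_genotypes(vaf, labels, tol=0.05)
        assert all(p is None for p in parent.values())
        # no clone carries both mutation sets
        for c in G.index:
            carried = set(G.columns[G.loc[c].values == 1])
            assert not (carried & {"s0"} and carried & {"s5"})

    def test_unobserved_cluster_sample_counts_as_zero_prevalence(self):
        vaf = vaf_frame([[0.3, np.nan], [0.3, np.nan]])
        prev = cluster_prevalences(vaf, np.array([1, 1]))
        assert prev.loc[1, "B"] == 0.0


class TestFrequencies:
    def test_single_clone_frequency_is_twice_vaf(self):
        vaf = vaf_frame([[0.3, 0.3]] * 4)
        labels = cluster_snvs(vaf)
        _, parent, clone_of = build_clone_genotypes(vaf, labels)
        freqs = estimate_clone_frequencies(vaf, labels, parent, clone_of)
        assert np.allclose(freqs.values, 0.6)

    def test_all_zero_vaf_gives_zero_frequencies(self):
        vaf = vaf_frame([[0.0, 0.0]] * 4)
        labels = cluster_snvs(vaf)
        _, parent, clone_of = build_clone_genotypes(vaf, labels)
        freqs = estimate_clone_frequencies(vaf, labels, parent, clone_of)
        assert np.allclose(freqs.values, 0.0)

    def test_nested_pair_closed_form(self):
        # cluster VAFs (0.30, 0.10) in one sample -> frequencies (0.40, 0.20)
        rows = [[0.30, 0.30]] * 5 + [[0.10, 0.10]] * 5
        vaf = vaf_frame(rows)
        labels = cluster_snvs(vaf)
        _, parent, clone_of = build_clone_genotypes(vaf, labels)
        freqs = estimate_clone_frequencies(vaf, labels, parent, clone_of)
        assert sorted(np.round(freqs["A"].values, 6)) == [0.2, 0.4]

    def test_frequencies_nonnegative_and_simplex_bounded(self):
        rng = np.random.default_rng(0)
        rows = np.clip(rng.normal(0.2, 0.1, size=(30, 3)), 0, 1)
        vaf = pd.DataFrame(rows, index=[f"s{i}" for i in range(30)], columns=list("ABC"))
        labels = cluster_snvs(vaf)
        _, parent, clone_of = build_clone_genotypes(vaf, labels)
        freqs = estimate_clone_frequencies(vaf, labels, parent, clone_of)
        assert (freqs.values >= -1e-9).all()
        assert (freqs.sum(axis=0) <= 1 + 1e-6).all()


class TestPurityAndPresence:
    def test_purity_is_frequency_sum(self):
        freqs = pd.DataFrame([[0.4, 0.1], [0.2, 0.0]], index=["C0", "C1"], columns=["A", "B"])
        purity = estimate_purity(freqs)
        assert purity["A"] == pytest.approx(0.6) and purity["B"] == pytest.approx(0.1)

    def test_purity_recovered_on_simulated_replicates(self):
        errs = []
        for seed in range(8):
            cfg = SimulationConfig(
                seed=seed, purity=0.6, coverage_mean=500,
                n_snvs_per_branch_mean=100, n_met_sites=3,
            )
            matrix, samples, truth = simulate_patient(cfg)
            if matrix.n_samples < 3:
                continue
            from metmap.io import filter_snvs

            cloneset, _ = deconvolve(filter_snvs(matrix), samples)
            errs.extend(np.abs(estimate_purity(cloneset.frequencies).values - 0.6))
        assert np.mean(errs) < 0.05

    @pytest.mark.parametrize(
        "freq,present", [(0.2, True), (0.0, False), (5e-4, False), (2e-3, True)]
    )
    def test_presence_threshold(self, freq, present):
        freqs = pd.DataFrame([[freq, 0.5]], index=["C0"], columns=["A", "B"])
        locmap = clone_presence(freqs, sample_info())
        assert ("A" in locmap.locations["C0"]) is present

    def test_absent_everywhere_flagged_unobserved(self):
        freqs = pd.DataFrame([[0.0, 0.0], [0.3, 0.3]], index=["C0", "C1"], columns=["A", "B"])
        locmap = clone_presence(freqs, sample_info())
        assert locmap.unobserved == {"C0"}

    def test_samples_aggregate_by_site_label(self):
        freqs = pd.DataFrame([[0.2, 0.0]], index=["C0"], columns=["A", "B"])
        info = sample_info(sites=["Lu", "Lu"], classes=["metastasis", "metastasis"])
        locmap = clone_presence(freqs, info)
        assert locmap.locations["C0"] == {"Lu"}


class TestInvariants:
    def test_relabeling_invariance(self):
        cfg = SimulationConfig(
            seed=5, n_snvs_per_branch_mean=20, n_met_sites=3, rate_PM=1.0,
            tree_shape="star",
        )
        matrix, samples, truth = simulate_patient(cfg)
        vaf = true_vaf_matrix(truth)
        info = sample_info(
            samples=list(vaf.columns),
            sites=list(vaf.columns),
            classes=["primary"] + ["metastasis"] * (vaf.shape[1] - 1),
        )
        cs1, _ = deconvolve(vaf, info, tol=1e-6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(vaf.shape[0])
        cs2, _ = deconvolve(vaf.iloc[perm], info, tol=1e-6)
        g1 = {frozenset(cs1.genotypes.columns[row.values == 1]) for _, row in cs1.genotypes.iterrows()}
        g2 = {frozenset(cs2.genotypes.columns[row.values == 1]) for _, row in cs2.genotypes.iterrows()}
        assert g1 == g2

    def test_assignment_accuracy_degrades_with_coverage(self):
        from metmap.io import compute_vaf, filter_snvs
        from scipy.optimize import linear_sum_assignment

        means = []
        for coverage in (1000, 200, 50):
            accs = []
            for seed in range(6):
                cfg = SimulationConfig(
                    seed=seed, coverage_mean=coverage, n_clones=5,
                    n_snvs_per_branch_mean=60, n_met_sites=3, rate_PM=1.0,
                )
                matrix, samples, truth = simulate_patient(cfg)
                filtered = filter_snvs(matrix)
                if matrix.n_samples < 2 or filtered.n_snvs < 10:
                    accs.append(0.0)
                    continue
                cloneset, _ = deconvolve(filtered, samples)
                lab = cloneset.snv_cluster
                branch = truth.snv_branch()
                true = pd.Series([branch[s] for s in lab.index])
                ct = pd.crosstab(pd.Series(lab.values), true)
                r, c = linear_sum_assignment(-ct.values)
                accs.append(ct.values[r, c].sum() / len(lab))
            means.append(np.mean(accs))
        assert means[0] + 1e-9 >= means[1] >= means[2] - 0.02
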