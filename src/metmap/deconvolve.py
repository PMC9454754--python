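"""Clone deconvolution: genotypes, frequencies, presence and purity from VAFs.

The algorithm is cluster-then-nest.  SNVs are partitioned by their VAF
vectors across samples with a Gaussian mixture on the arcsine-sqrt scale
whose per-cell variance is the known binomial value 1/(4 coverage); the
mixture is fitted by EM from a Ward-linkage initialization and the cluster
count is chosen by BIC.  Each cluster is a candidate branch of the clone tree;
cluster mean VAFs define per-sample prevalences (2 x VAF under the
heterozygous-diploid assumption) that are nested by the pigeonhole rule: a
cluster is ancestral to another iff its prevalence dominates it in every
sample, up to a containment tolerance.  Each nesting-tree node defines one
clone genotype (the union of clusters on its root path); per-sample clone
frequencies then solve the triangular prevalence system under nonnegativity
and a unit-simplex bound, and tumor purity is the per-sample frequency sum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize, nnls
from scipy.special import logsumexp

_VAR_FLOOR = 1e-6


class DeconvolutionError(ValueError):
    """Raised when deconvolution cannot proceed."""


@dataclass
class CloneSet:
    """Binary clone genotypes over SNVs plus clone x sample frequencies."""

    clone_ids: list[str]
    genotypes: pd.DataFrame  # clone x SNV, int8 0/1
    frequencies: pd.DataFrame  # clone x sample, float
    snv_cluster: pd.Series  # SNV -> cluster index (-1: excluded)
    cluster_parent: dict[int, Optional[int]]  # nesting tree over clusters
    clone_of_cluster: dict[int, str]

    def check(self, eps: float = 1e-6) -> None:
        if (self.frequencies.values < -eps).any():
            raise DeconvolutionError("negative clone frequency")
        sums = self.frequencies.sum(axis=0)
        if (sums > 1 + eps).any():
            raise DeconvolutionError("per-sample frequency sum exceeds 1")
        rows = [tuple(r) for r in self.genotypes.values]
        if len(set(rows)) != len(rows):
            raise DeconvolutionError("duplicate clone genotypes")


@dataclass
class CloneLocationMap:
    """Map clone -> set of anatomical site labels where it is present."""

    locations: dict[str, set[str]]
    unobserved: set[str] = field(default_factory=set)

    def observed_clones(self) -> list[str]:
        return [c for c, s in self.locations.items() if s]


# -- clustering -------------------------------------------------------------


def _impute_masked(X: np.ndarray) -> np.ndarray:
    """Zero-impute masked VAF cells for clustering.

    At exome depth a masked cell means the variant sits below the read
    filter, i.e. its VAF is (near) zero, and which cells are masked is
    itself the signal that separates a rootward branch from a nested clade
    with identical VAFs on the jointly observed samples.  The imputation is
    used only for clustering; prevalence and frequency estimation stay on
    the observed cells.
    """
    return np.where(np.isnan(X), 0.0, X)


def _fixed_variance_em(
    Y: np.ndarray,
    W: np.ndarray,
    k: int,
    init_labels: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """EM for a Gaussian mixture with *known* per-cell variance.

    On the arcsine-sqrt scale a binomial VAF estimate has variance
    1/(4 * coverage) whatever its mean, so the component variances are not
    free parameters: ``W`` holds the per-cell precisions (4 * coverage) and
    only the k*d component means and k-1 mixing weights are fitted.  A soft
    mixture is used rather than a hard partition because hard data-optimized
    partitions always overfit an information criterion.
    Returns (log-likelihood, responsibilities).
    """
    n, d = Y.shape
    mus = np.vstack(
        [
            Y[init_labels == c].mean(axis=0) if (init_labels == c).any() else Y.mean(axis=0)
            for c in range(1, k + 1)
        ]
    )
    pis = np.array([(init_labels == c).mean() for c in range(1, k + 1)]).clip(1e-6)
    pis /= pis.sum()
    log_norm_const = 0.5 * np.log(W / (2 * np.pi)).sum(axis=1)  # per point
    prev = -np.inf
    resp = np.ones((n, k)) / k
    for _ in range(max_iter):
        # E-step
        diff = Y[:, None, :] - mus[None, :, :]
        log_pdf = -0.5 * (W[:, None, :] * diff**2).sum(axis=2) + log_norm_const[:, None]
        log_r = np.log(pis)[None, :] + log_pdf
        norm = logsumexp(log_r, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(log_r - norm[:, None])
        # M-step (precision-weighted means)
        wk = resp[:, :, None] * W[:, None, :]  # n x k x d
        mus = (wk * Y[:, None, :]).sum(axis=0) / np.maximum(wk.sum(axis=0), 1e-12)
        pis = resp.mean(axis=0).clip(1e-12)
        pis /= pis.sum()
        if loglik - prev < tol:
            break
        prev = loglik
    return loglik, resp


def cluster_snvs(
    vaf: pd.DataFrame,
    max_clusters: int = 15,
    seed: int = 0,
    subsample: int = 3000,
    raw_vaf: Optional[pd.DataFrame] = None,
    coverage: Optional[pd.DataFrame] = None,
    pseudo_coverage: float = 1e8,
) -> np.ndarray:
    """Partition SNVs into k <= max_clusters clusters of shared VAF pattern.

    Returns an integer label per SNV (1..k); SNVs with no observed cell are
    excluded with label -1 and a warning.  For each candidate k a
    known-variance Gaussian mixture is fitted by EM from a Ward-linkage
    initialization, and k is chosen by BIC.  When ``raw_vaf`` (unmasked
    variant/total, available whenever read counts are) is provided it is
    used for the distance/BIC stage: sub-threshold cells carry pattern
    information even though they are excluded from frequency estimation.
    ``coverage`` (total reads per cell) sets the known binomial noise scale
    of the BIC; without it, cells are treated as ``pseudo_coverage``-deep
    (the default suits analytic, noise-free VAF input; pass the real
    coverage for noisy data).
    """
    X = vaf.values.astype(float)
    R = raw_vaf.values.astype(float) if raw_vaf is not None else None
    C = coverage.values.astype(float) if coverage is not None else None
    if X.shape[0] < 1:
        raise DeconvolutionError("need at least one SNV")
    if X.shape[1] < 2:
        raise DeconvolutionError("need at least two samples")
    valid = ~np.all(np.isnan(X), axis=1)
    if not valid.all():
        warnings.warn(
            f"excluding {int((~valid).sum())} SNV(s) with no usable observation",
            stacklevel=2,
        )
    Xv = X[valid]
    n = Xv.shape[0]
    labels_out = np.full(X.shape[0], -1, dtype=int)
    if n == 0:
        return labels_out
    if n == 1:
        labels_out[valid] = 1
        return labels_out

    base = R[valid] if R is not None else _impute_masked(Xv)
    # variance-stabilize binomial noise: var(asin sqrt p) ~ 1/(4n) regardless
    # of p, so the Gaussian mixture has known per-cell variance
    Yv = np.arcsin(np.sqrt(np.clip(base, 0.0, 1.0)))
    Wv = (
        4.0 * np.maximum(C[valid], 1.0)
        if C is not None
        else np.full_like(Yv, 4.0 * pseudo_coverage)
    )
    d = Yv.shape[1]
    fit_idx = np.arange(n)
    if n > subsample:
        rng = np.random.default_rng(seed)
        fit_idx = np.sort(rng.choice(n, subsample, replace=False))
    Z = linkage(Yv[fit_idx], method="ward", metric="euclidean")

    best_k, best_resp, best_bic = 1, None, np.inf
    for k in range(1, min(max_clusters, n) + 1):
        init = np.ones(n, dtype=int)
        init[fit_idx] = fcluster(Z, t=k, criterion="maxclust")
        loglik, resp = _fixed_variance_em(Yv, Wv, k, init)
        n_params = k * d + (k - 1)
        bic = -2.0 * loglik + n_params * np.log(n)
        if bic < best_bic - 1e-9:
            best_k, best_resp, best_bic = k, resp, bic

    labels_v = best_resp.argmax(axis=1) + 1
    # renumber to drop empty components
    ids = sorted(set(labels_v))
    remap = {c: i + 1 for i, c in enumerate(ids)}
    labels_out[valid] = np.array([remap[c] for c in labels_v])
    return labels_out


def cluster_prevalences(vaf: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per-sample prevalence (2 x mean VAF) of each cluster.

    A sample in which every SNV of a cluster is masked contributes
    prevalence 0: at realistic coverage an entire unobserved cluster means
    the variant fraction sits below the read filter.
    """
    ks = sorted(set(labels[labels > 0]))
    rows = []
    for k in ks:
        member = vaf.values[labels == k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(member, axis=0)
        rows.append(np.where(np.isnan(mean), 0.0, 2.0 * mean))
    return pd.DataFrame(np.clip(rows, 0.0, 2.0), index=ks, columns=vaf.columns)


# -- nesting ----------------------------------------------------------------


def build_clone_genotypes(
    vaf: pd.DataFrame, labels: np.ndarray, tol: float = 0.05
) -> tuple[pd.DataFrame, dict[int, Optional[int]], dict[int, str]]:
    """Nest clusters by prevalence containment and emit clone genotypes.

    Cluster A can be ancestral to B iff its prevalence is >= B's minus
    ``tol`` in every sample.  Clusters are placed in decreasing order of
    total prevalence; each attaches beneath the containing placed cluster of
    smallest total prevalence, or becomes a sibling branch at the root when
    nothing contains it (crossing prevalences).  Clone i's genotype is the
    union of the SNV clusters on cluster i's root path.
    """
    prev = cluster_prevalences(vaf, labels)
    ks = list(prev.index)
    totals = prev.sum(axis=1)
    order = sorted(ks, key=lambda k: (-totals[k], k))
    parent: dict[int, Optional[int]] = {}
    for k in order:
        candidates = []
        for j in parent:  # already placed
            if np.all(prev.loc[j].values >= prev.loc[k].values - tol):
                candidates.append(j)
        if candidates:
            parent[k] = min(candidates, key=lambda j: (totals[j], j))
        else:
            parent[k] = None

    snv_of_cluster = {k: list(vaf.index[labels == k]) for k in ks}
    clone_of_cluster = {k: f"C{i}" for i, k in enumerate(order)}
    geno_rows = []
    for k in order:
        snvs: list[str] = []
        node: Optional[int] = k
        while node is not None:
            snvs.extend(snv_of_cluster[node])
            node = parent[node]
        geno_rows.append((clone_of_cluster[k], set(snvs)))
    genotypes = pd.DataFrame(
        0, index=[name for name, _ in geno_rows], columns=list(vaf.index), dtype=np.int8
    )
    for name, snvs in geno_rows:
        genotypes.loc[name, list(snvs)] = 1
    return genotypes, parent, clone_of_cluster


# -- frequencies ------------------------------------------------------------


def estimate_clone_frequencies(
    vaf: pd.DataFrame,
    labels: np.ndarray,
    cluster_parent: dict[int, Optional[int]],
    clone_of_cluster: dict[int, str],
) -> pd.DataFrame:
    """Per-sample clone frequencies from cluster mean VAFs.

    Solves ``A f = 2 v`` where ``A[k, c] = 1`` iff cluster k lies on clone
    c's root path, subject to ``f >= 0`` and ``sum(f) <= 1``.  The exact
    (triangular) solution is used when feasible; otherwise nonnegative least
    squares, then an SLSQP projection onto the simplex-bounded set.  A
    degenerate fit falls back to a zero vector with a diagnostic warning.
    """
    prev = cluster_prevalences(vaf, labels)
    ks = list(prev.index)
    clones = [clone_of_cluster[k] for k in ks]
    idx = {k: i for i, k in enumerate(ks)}
    # membership: cluster k in clone-of-cluster-c's path iff k is an ancestor
    # (or self) of c in the nesting tree
    A = np.zeros((len(ks), len(ks)))
    for c in ks:
        node: Optional[int] = c
        while node is not None:
            A[idx[node], idx[c]] = 1.0
            node = cluster_parent[node]

    out = np.zeros((len(ks), prev.shape[1]))
    for j, sample in enumerate(prev.columns):
        b = prev[sample].values.astype(float)
        try:
            f = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:  # pragma: no cover - A is unitriangular
            f = np.full(len(ks), np.nan)
        if np.all(f >= -1e-9) and f.sum() <= 1 + 1e-6:
            out[:, j] = np.clip(f, 0.0, None)
            continue
        f, _ = nnls(A, b)
        if f.sum() <= 1 + 1e-6:
            out[:, j] = f
            continue
        res = minimize(
            lambda x: float(np.sum((A @ x - b) ** 2)),
            x0=f / max(f.sum(), 1.0),
            jac=lambda x: 2.0 * A.T @ (A @ x - b),
            bounds=[(0.0, 1.0)] * len(ks),
            constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum()}],
            method="SLSQP",
        )
        if res.success:
            out[:, j] = np.clip(res.x, 0.0, None)
        else:
            warnings.warn(
                f"degenerate frequency fit in sample {sample!r}; returning zeros",
                stacklevel=2,
            )
    freq = pd.DataFrame(out, index=clones, columns=prev.columns)
    order = sorted(clones, key=lambda c: int(c[1:]))
    return freq.loc[order]


def estimate_purity(frequencies: pd.DataFrame) -> pd.Series:
    """Per-sample tumor purity: sum of clone frequencies, clipped to [0, 1]."""
    return frequencies.sum(axis=0).clip(0.0, 1.0)


def clone_presence(
    frequencies: pd.DataFrame,
    sample_info: pd.DataFrame,
    eps: float = 1e-3,
) -> CloneLocationMap:
    """Clone -> sites map: present where inferred frequency exceeds ``eps``.

    Sites aggregate all samples sharing a site label.  A clone present
    nowhere is flagged unobserved-ancestral but kept for the phylogeny.
    """
    site_of = dict(zip(sample_info["sample_id"], sample_info["site_label"]))
    locations: dict[str, set[str]] = {c: set() for c in frequencies.index}
    for sample in frequencies.columns:
        site = site_of[sample]
        for clone in frequencies.index:
            if frequencies.loc[clone, sample] > eps:
                locations[clone].add(site)
    unobserved = {c for c, s in locations.items() if not s}
    return CloneLocationMap(locations=locations, unobserved=unobserved)


def deconvolve(
    data,
    sample_info: pd.DataFrame,
    max_clusters: int = 15,
    tol: float = 0.05,
    eps: float = 1e-3,
    seed: int = 0,
) -> tuple[CloneSet, CloneLocationMap]:
    """Full deconvolution: cluster, nest, solve frequencies, locate clones.

    ``data`` is either a filtered :class:`~metmap.io.SnvMatrix` (clustering
    then also sees the raw sub-threshold VAFs) or a VAF DataFrame.
    """
    from .io import SnvMatrix, compute_vaf

    raw_vaf, coverage = None, None
    if isinstance(data, SnvMatrix):
        vaf = compute_vaf(data)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(
                data.total_reads > 0,
                data.variant_reads / np.maximum(data.total_reads, 1),
                0.0,
            )
        raw_vaf = pd.DataFrame(raw, index=vaf.index, columns=vaf.columns)
        coverage = pd.DataFrame(
            data.total_reads, index=vaf.index, columns=vaf.columns
        )
    else:
        vaf = data
    labels = cluster_snvs(
        vaf,
        max_clusters=max_clusters,
        seed=seed,
        raw_vaf=raw_vaf,
        coverage=coverage,
    )
    genotypes, parent, clone_of_cluster = build_clone_genotypes(vaf, labels, tol=tol)
    frequencies = estimate_clone_frequencies(vaf, labels, parent, clone_of_cluster)
    genotypes = genotypes.loc[frequencies.index]
    cloneset = CloneSet(
        clone_ids=list(frequencies.index),
        genotypes=genotypes,
        frequencies=frequencies,
        snv_cluster=pd.Series(labels, index=vaf.index),
        cluster_parent=parent,
        clone_of_cluster=clone_of_cluster,
    )
    locmap = clone_presence(frequencies, sample_info, eps=eps)
    return cloneset, locmap
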