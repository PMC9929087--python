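"""Quantitative evaluation of ancestry spaces: K-means clustering accuracy
with optimal label matching, KNN classification, Mahalanobis relatedness
diagnostics, NRMSD projection-robustness scores and pairwise t-tests with
Bonferroni correction."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .linear import AncestryScores


@dataclass
class RobustnessResult:
    """Per-axis NRMSD of one perturbation replicate for one method."""

    nrmsd_per_axis: np.ndarray
    mean_nrmsd: float
    replicate: int = 0
    method: str = ""


def kmeans_cluster(
    scores: AncestryScores,
    n_clusters: int,
    restarts: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Best-inertia K-means labelling over ``restarts`` initializations.

    Settings mirror common practice for genotype latent spaces: k-means++
    initialization, 300 iterations max, tolerance 1e-4.
    """
    if n_clusters > scores.values.shape[0]:
        raise ValueError("n_clusters exceeds the number of samples")
    km = KMeans(
        n_clusters=n_clusters, n_init=restarts, max_iter=300, tol=1e-4,
        random_state=seed,
    )
    return km.fit_predict(scores.values)


def clustering_accuracy(truth: Sequence, pred: Sequence) -> float:
    """Maximal fraction of label agreements over all cluster-label
    permutations, solved as an optimal assignment on the contingency table
    (Hungarian algorithm, O(K^3))."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("label vectors differ in length")
    t_codes, _ = pd.factorize(truth)
    p_codes, _ = pd.factorize(pred)
    n_t, n_p = t_codes.max() + 1, p_codes.max() + 1
    size = max(n_t, n_p)
    table = np.zeros((size, size), dtype=np.int64)
    np.add.at(table, (p_codes, t_codes), 1)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / truth.size)


def knn_classify(
    ref_scores: AncestryScores,
    ref_labels: Sequence,
    target_scores: AncestryScores,
    k_neighbors: int = 3,
) -> np.ndarray:
    """Majority label among the k nearest reference points (Euclidean).

    An even vote is broken by the label of the single nearest neighbor.
    """
    ref_labels = np.asarray(ref_labels, dtype=object)
    if ref_labels.size == 0:
        raise ValueError("empty reference")
    if k_neighbors > ref_labels.size:
        raise ValueError("k_neighbors exceeds the reference size")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(ref_scores.values)
    _, idx = nn.kneighbors(target_scores.values)
    out = np.empty(target_scores.values.shape[0], dtype=object)
    for i, neigh in enumerate(idx):
        labs = ref_labels[neigh]
        uniq, counts = np.unique(labs.astype(str), return_counts=True)
        top = counts.max()
        winners = set(uniq[counts == top])
        if len(winners) == 1:
            out[i] = winners.pop()
        else:  # tie: fall back to the closest neighbor among tied labels
            out[i] = next(str(l) for l in labs if str(l) in winners)
    return out


def classification_accuracy(truth: Sequence, pred: Sequence) -> float:
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("label vectors differ in length")
    return float(np.mean(truth.astype(str) == pred.astype(str)))


def mean_mahalanobis(
    scores: AncestryScores,
    cluster_members: Sequence[int],
    probes: Sequence[int],
    ridge: float = 1e-8,
) -> float:
    """Mean Mahalanobis distance of probe samples to a population cluster.

    The cluster's mean and covariance are estimated from ``cluster_members``;
    a small ridge (1e-8 x mean variance) stabilizes near-singular covariance
    when the cluster is small relative to the axis count.
    """
    z = scores.values
    members = np.asarray(cluster_members, dtype=int)
    probes = np.asarray(probes, dtype=int)
    k = z.shape[1]
    if members.size <= k:
        import warnings

        warnings.warn("cluster smaller than the axis count; covariance is singular "
                      "and relies on the ridge")
    mu = z[members].mean(axis=0)
    cov = np.cov(z[members], rowvar=False, ddof=1)
    cov = np.atleast_2d(cov) + ridge * (np.trace(np.atleast_2d(cov)) / k) * np.eye(k)
    centered = z[probes] - mu
    sq = np.einsum("ij,ji->i", centered, np.linalg.solve(cov, centered.T))
    return float(np.mean(np.sqrt(np.maximum(sq, 0.0))))


def nrmsd(
    original: AncestryScores,
    perturbed: AncestryScores,
    axes: int = 2,
    replicate: int = 0,
    method: str = "",
) -> RobustnessResult:
    """Per-axis RMSD between original and perturbed scores, normalized by the
    range of the original scores on that axis; the summary is the mean over
    the first ``axes`` axes."""
    a = original.values
    b = perturbed.values
    if a.shape != b.shape:
        raise ValueError("score shapes differ")
    if a.shape[1] < axes:
        raise ValueError("fewer axes than requested")
    rmsd = np.sqrt(np.mean((a - b) ** 2, axis=0))
    rng_ = a.max(axis=0) - a.min(axis=0)
    if (rng_[:axes] == 0).any():
        raise ValueError("zero score range on a requested axis; NRMSD undefined")
    per_axis = np.divide(rmsd, rng_, out=np.full_like(rmsd, np.nan), where=rng_ != 0)
    return RobustnessResult(
        nrmsd_per_axis=per_axis,
        mean_nrmsd=float(per_axis[:axes].mean()),
        replicate=replicate,
        method=method,
    )


def bonferroni_threshold(n_methods: int, alpha: float = 0.05) -> tuple[int, float]:
    """Number of pairwise comparisons and the adjusted significance level."""
    m = n_methods * (n_methods - 1) // 2
    return m, alpha / m


def compare_methods_ttest(
    results: dict[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise two-sample t-tests on per-replicate robustness scores.

    Returns a tidy table (method_a, method_b, t, p, significant) with the
    Bonferroni threshold alpha/m attached; m = C(n_methods, 2).
    """
    methods = list(results)
    if any(len(results[name]) < 2 for name in methods):
        raise ValueError("need at least 2 replicates per method")
    m, threshold = bonferroni_threshold(len(methods), alpha)
    rows = []
    for a, b in combinations(methods, 2):
        xa = np.asarray(results[a], dtype=float)
        xb = np.asarray(results[b], dtype=float)
        if xa.var() == 0 and xb.var() == 0:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(xa, xb)
        rows.append({
            "method_a": a, "method_b": b, "t": t, "p": p,
            "significant": bool(p < threshold) if np.isfinite(p) else False,
        })
    table = pd.DataFrame(rows)
    table.attrs["n_tests"] = m
    table.attrs["threshold"] = threshold
    return table


def covariance_summary(scores: AncestryScores, center: bool = False) -> np.ndarray:
    """Variance-covariance matrix of the score columns.

    By default the *uncentered* second-moment matrix is returned: for SVD
    scores (PCA, UPCA, SUGIBS, SAE-IBS) the columns are orthogonal, so the
    off-diagonals are exactly zero on this scale — the structure the
    orthogonality checks assert.  With ``center=True`` the conventional
    mean-centered sample covariance is computed instead.
    """
    z = scores.values
    n = z.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    if center:
        z = z - z.mean(axis=0)
    return z.T @ z / (n - 1)


def axis_stability(
    scores_small: AncestryScores,
    scores_large: AncestryScores,
    n_axes: int = 4,
) -> float:
    """Minimum matched |correlation| of the first ``n_axes`` axes of a model
    against the axes of a higher-dimensional refit.

    Axes are matched by optimal assignment on the absolute correlation
    matrix, which gives unordered latent spaces (plain AE) their best
    possible pairing; a value near 1 means the low-dimensional structure is
    preserved when more dimensions are sought.
    """
    a = scores_small.values[:, :n_axes]
    b = scores_large.values
    corr = np.zeros((a.shape[1], b.shape[1]))
    for i in range(a.shape[1]):
        for j in range(b.shape[1]):
            sa, sb = a[:, i].std(), b[:, j].std()
            if sa == 0 or sb == 0:
                continue
            corr[i, j] = abs(np.corrcoef(a[:, i], b[:, j])[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    return float(corr[rows, cols].min())
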