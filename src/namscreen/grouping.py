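"""Unsupervised chemical grouping and Fowlkes-Mallows correspondence testing.

Chemicals are clustered hierarchically from any numeric feature matrix
(bioactivity PODs or ToxPi scores, external assay AC50 vectors, structural
fingerprints).  Agreement between a k-group cut and the reference chemical
classing is quantified with the Fowlkes-Mallows (FM) pair-counting index
B = Tk / sqrt(Pk * Qk), with significance against the null of random label
assignment either from the closed-form moments of Tk under permutation or
from an explicit permutation test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

log = logging.getLogger(__name__)


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterTree:
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge history
    linkage: str
    distance: str
    items: tuple[str, ...]


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - r distances; constant rows get maximal dissimilarity 1."""
    n = x.shape[0]
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning(
            "%d constant feature vector(s) under pearson distance; set to distance 1",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    d = 1.0 - r
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def impute_missing(features: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute missing feature values per column, logging the count."""
    n_missing = int(features.isna().to_numpy().sum())
    if n_missing:
        log.info("mean-imputing %d missing feature values", n_missing)
        features = features.fillna(features.mean())
    return features


def cluster_chemicals(
    features: pd.DataFrame,
    distance: str = "pearson",
    linkage: str = "average",
    k: int = 5,
) -> tuple[pd.Series, ClusterTree]:
    """Agglomerative clustering of chemicals cut into ``k`` groups.

    ``features`` is a chemicals x features frame (no missing values; see
    :func:`impute_missing`).  ``distance`` is ``'pearson'`` (1 - r between
    chemical feature vectors, range [0, 2], not clipped) or ``'euclidean'``;
    ``linkage`` is ``'average'`` or ``'ward'``.  Returns the group labels
    (Series indexed by chemical) and the dendrogram.
    """
    n = features.shape[0]
    if n < 2:
        raise PartitionError("need >= 2 chemicals to cluster")
    if not 2 <= k <= n - 1:
        raise PartitionError(f"k must be in [2, {n - 1}], got {k}")
    if distance not in ("pearson", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("average", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    x = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values; impute first")
    condensed = _pearson_distance(x) if distance == "pearson" else pdist(x, "euclidean")
    z = hierarchy.linkage(condensed, method=linkage)
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    tree = ClusterTree(z, linkage, distance, tuple(features.index))
    return pd.Series(labels, index=features.index, name="cluster"), tree


# ---------------------------------------------------------------------------
# Fowlkes-Mallows index


@dataclass(frozen=True)
class FMResult:
    b: float  # FM index in [0, 1]
    tk: float
    pk: float
    qk: float
    n: int
    labels_a: tuple
    labels_b: tuple
    expected_b: float | None = None
    z: float | None = None
    p: float | None = None
    null_mode: str | None = None
    n_permutations: int | None = None


def _aligned_labels(partition_a, partition_b) -> tuple[np.ndarray, np.ndarray]:
    a = pd.Series(partition_a)
    b = pd.Series(partition_b)
    if set(a.index) != set(b.index):
        raise PartitionError("partitions cover different item sets")
    b = b.reindex(a.index)
    return a.to_numpy(), b.to_numpy()


def fm_index(partition_a, partition_b) -> FMResult:
    """Fowlkes-Mallows index between two partitions of the same items.

    With contingency counts m_ij: Tk = sum m_ij^2 - n, Pk = sum(row sums^2) - n,
    Qk = sum(col sums^2) - n, and B = Tk / sqrt(Pk * Qk).  B = 1 iff the
    partitions are identical up to relabeling; B = 0 when no pair of items is
    co-clustered in both.  All-singleton partitions make B undefined.
    """
    a, b = _aligned_labels(partition_a, partition_b)
    n = a.size
    m = pd.crosstab(a, b).to_numpy(dtype=float)
    tk = float((m**2).sum() - n)
    pk = float((m.sum(axis=1) ** 2).sum() - n)
    qk = float((m.sum(axis=0) ** 2).sum() - n)
    if pk == 0 or qk == 0:
        raise PartitionError("FM index undefined: a partition is all singletons")
    bval = tk / math.sqrt(pk * qk)
    return FMResult(b=bval, tk=tk, pk=pk, qk=qk, n=n, labels_a=tuple(a), labels_b=tuple(b))


def _tk_moments(pk: float, qk: float, pk_p: float, qk_p: float, n: int) -> tuple[float, float]:
    """Mean and variance of Tk under uniformly random relabeling of one
    partition (Fowlkes & Mallows, 1983), with
    Pk' = sum n_i (n_i - 1)(n_i - 2) over cluster sizes."""
    # Tk counts ordered item pairs co-clustered in both partitions; splitting
    # E[Tk^2] over identical / one-shared-item / disjoint pair-pairs gives
    e_tk = pk * qk / (n * (n - 1))
    var_tk = (
        2.0 * pk * qk / (n * (n - 1))
        + 4.0 * pk_p * qk_p / (n * (n - 1) * (n - 2))
        + (pk**2 - 2.0 * pk - 4.0 * pk_p)
        * (qk**2 - 2.0 * qk - 4.0 * qk_p)
        / (n * (n - 1) * (n - 2) * (n - 3))
        - e_tk**2
    )
    return e_tk, var_tk


def _prime(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    c = counts.astype(float)
    return float((c * (c - 1) * (c - 2)).sum())


def fm_significance(
    result: FMResult,
    mode: str = "analytic",
    n_perm: int = 999,
    seed: int | None = None,
) -> FMResult:
    """Complete an :class:`FMResult` with null expectation, z, and one-sided p.

    Analytic mode uses the closed-form permutation moments of Tk; permutation
    mode relabels one partition uniformly at random ``n_perm`` times, takes z
    from the empirical moments and p = (1 + #{B_perm >= B_obs}) / (n_perm + 1).
    Small n (<= 3) or a degenerate analytic variance forces permutation mode.
    """
    if mode not in ("analytic", "permutation"):
        raise ValueError(f"unknown mode {mode!r}")
    a = np.asarray(result.labels_a)
    b = np.asarray(result.labels_b)
    n = result.n

    if mode == "analytic":
        pk_p = _prime(a)
        qk_p = _prime(b)
        if n <= 3:
            log.info("n <= 3: falling back to permutation null")
            return fm_significance(result, "permutation", n_perm, seed)
        e_tk, var_tk = _tk_moments(result.pk, result.qk, pk_p, qk_p, n)
        if var_tk <= 0:
            log.info("degenerate analytic variance: falling back to permutation null")
            return fm_significance(result, "permutation", n_perm, seed)
        denom = math.sqrt(result.pk * result.qk)
        expected_b = e_tk / denom
        z = (result.tk - e_tk) / math.sqrt(var_tk)
        p = float(norm.sf(z))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        return replace(result, expected_b=expected_b, z=z, p=p, null_mode="analytic")

    if n_perm < 999:
        raise ValueError("permutation mode requires n_perm >= 999")
    rng = np.random.default_rng(seed)
    denom = math.sqrt(result.pk * result.qk)
    _, a_codes = np.unique(a, return_inverse=True)
    nb, b_codes = np.unique(b, return_inverse=True)
    nb = nb.size
    bs = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(b_codes)
        counts = np.bincount(a_codes * nb + perm)
        bs[i] = (float((counts.astype(float) ** 2).sum()) - n) / denom
    mean, sd = float(bs.mean()), float(bs.std(ddof=1))
    z = (result.b - mean) / sd if sd > 0 else math.inf
    p = (1.0 + float((bs >= result.b).sum())) / (n_perm + 1.0)
    return replace(
        result,
        expected_b=mean,
        z=z,
        p=p,
        null_mode="permutation",
        n_permutations=n_perm,
    )
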