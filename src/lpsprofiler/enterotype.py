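"""Functional enterotyping: JSD distances, PAM clustering, cluster-number
selection and class-driven ordinations.

Samples are clustered on their relative-abundance functional profiles with
the classic community-typing recipe: pairwise Jensen-Shannon divergence
(its square root, a true metric bounded by sqrt(ln 2)), partitioning around
medoids (PAM), and the Calinski-Harabasz (CH) index to pick the number of
clusters.  Because JSD space has no coordinates, within- and between-cluster
dispersions for CH are computed from pairwise distances alone via the
Huygens identity  sum_i ||x_i - c||^2 = (1/n) sum_{i<j} ||x_i - x_j||^2.

Between-class analysis (an ordination with the cluster assignment as
instrumental variable) and classical PCoA support visualisation of the
separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb as _comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix as _SkbioDM
from skbio.stats.ordination import pcoa as _skbio_pcoa

MAX_SQRT_JSD = float(np.sqrt(np.log(2.0)))

#: pam_cluster solves exactly when C(n, k) is at most this many medoid sets
_EXACT_PAM_LIMIT = 5000


@dataclass
class EnterotypeFit:
    """Result of PAM clustering with CH-based model selection."""

    k: int
    assignments: pd.Series  # sample -> cluster label (1-based)
    medoids: dict[int, str]  # cluster label -> medoid sample id
    ch_scores: dict[int, float]  # k -> Calinski-Harabasz score
    objective: float  # total distance of samples to their medoids


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    inertia: np.ndarray  # eigenvalue / explained-inertia per axis
    method: str
    between_total_ratio: float | None = None


# ---------------------------------------------------------------------------
# distances


def jsd_distance(profiles: pd.DataFrame, sqrt: bool = True) -> pd.DataFrame:
    """Pairwise Jensen-Shannon distances between sample profiles.

    Rows are renormalized to probability vectors.  With ``sqrt=True`` (the
    default) the metric form sqrt(JSD) is returned, with
    JSD(a, b) = KL(a||m)/2 + KL(b||m)/2, m = (a+b)/2, natural log; zero
    probability features contribute nothing to their own KL terms.  Entries
    are bounded by sqrt(ln 2).
    """
    arr = profiles.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("profiles contain negative entries")
    sums = arr.sum(axis=1)
    if (sums <= 0).any():
        bad = list(profiles.index[sums <= 0])
        raise ValueError(f"zero-sum profile row(s): {bad}")
    arr = arr / sums[:, None]
    # scipy's jensenshannon is sqrt(JSD) with natural log by default
    d = pdist(arr, metric="jensenshannon")
    d = np.nan_to_num(d, nan=0.0)  # identical rows can produce 0/0
    if not sqrt:
        d = d**2
    out = pd.DataFrame(squareform(d), index=profiles.index, columns=profiles.index)
    return out


def _check_distance(dist: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(dist, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (np.diag(arr) != 0).any():
        raise ValueError("distance matrix must have a zero diagonal")
    if (arr < 0).any():
        raise ValueError("distance matrix must be non-negative")
    return arr


# ---------------------------------------------------------------------------
# PAM (k-medoids, BUILD + SWAP) — deterministic, no seed


def pam_cluster(
    dist: pd.DataFrame, k: int
) -> tuple[pd.Series, dict[int, str], float]:
    """Partitioning around medoids on a precomputed distance matrix.

    Small instances (at most 5,000 candidate medoid sets) are solved exactly
    by enumeration; larger ones by the classical BUILD (greedy medoid
    seeding) + SWAP (steepest improving medoid/non-medoid exchange until
    none improves the total distance of samples to their nearest medoid)
    local search.  Deterministic either way: ties are broken by lowest
    sample index / lexicographically smallest medoid set.

    Returns (assignments as 1-based cluster labels ordered by medoid index,
    medoid map, objective).
    """
    d = _check_distance(dist)
    n = d.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples ({n}), got {k}")

    if _comb(n, k) <= _EXACT_PAM_LIMIT:
        medoids, current = _pam_exact(d, k)
        return _pam_result(dist, d, medoids, current)

    # BUILD: first medoid minimizes total distance; then greedily add the
    # point giving the largest reduction.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(nearest - d[:, j], 0.0).sum()
            if gain > best_gain + 1e-15:
                best_gain, best_j = gain, j
        medoids.append(best_j)

    def objective(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    current = objective(medoids)
    improved = True
    while improved:
        improved = False
        best = (current, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                val = objective(cand)
                if val < best[0] - 1e-12:
                    best = (val, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            current = best[0]
            improved = True

    return _pam_result(dist, d, medoids, current)


def _pam_exact(d: np.ndarray, k: int) -> tuple[list[int], float]:
    """Exhaustive k-medoids minimizer (lexicographically first on ties)."""
    n = d.shape[0]
    best_obj, best_set = np.inf, None
    for cand in combinations(range(n), k):
        val = d[:, cand].min(axis=1).sum()
        if val < best_obj - 1e-12:
            best_obj, best_set = val, cand
    return list(best_set), float(best_obj)


def _pam_result(
    dist: pd.DataFrame, d: np.ndarray, medoids: list[int], objective: float
) -> tuple[pd.Series, dict[int, str], float]:
    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    assignments = pd.Series(labels + 1, index=dist.index, name="cluster")
    medoid_map = {c + 1: str(dist.index[m]) for c, m in enumerate(medoids)}
    return assignments, medoid_map, objective


def calinski_harabasz(dist: pd.DataFrame, assignments: pd.Series) -> float:
    """Distance-based Calinski-Harabasz score CH = (B/(k-1)) / (W/(n-k)).

    Within-cluster dispersion W is computed from pairwise distances via the
    Huygens identity (no centroids needed); between-cluster dispersion is
    B = T - W with T the total dispersion.
    """
    d2 = _check_distance(dist) ** 2
    n = d2.shape[0]
    labels = assignments.reindex(dist.index).to_numpy()
    ks = np.unique(labels)
    k = len(ks)
    if k < 2:
        raise ValueError("need at least two clusters")
    total = d2.sum() / (2.0 * n)
    within = 0.0
    for c in ks:
        mask = labels == c
        nc = mask.sum()
        within += d2[np.ix_(mask, mask)].sum() / (2.0 * nc)
    between = total - within
    if within <= 0:
        raise ValueError("degenerate clustering: zero within-cluster dispersion")
    return float((between / (k - 1)) / (within / (n - k)))


def select_k(dist: pd.DataFrame, k_range: range = range(2, 7)) -> EnterotypeFit:
    """Fit PAM for each candidate k and keep the CH-maximal fit.

    Ties in CH go to the smaller k.  Raises on non-informative (all-equal)
    distances.
    """
    arr = _check_distance(dist)
    n = arr.shape[0]
    off = arr[~np.eye(n, dtype=bool)]
    if off.size and np.allclose(off, off[0], atol=1e-12):
        raise ValueError("non-informative distances: all pairs are equidistant")
    if max(k_range) >= n:
        raise ValueError(f"max k ({max(k_range)}) must be < n_samples ({n})")

    best: EnterotypeFit | None = None
    ch_scores: dict[int, float] = {}
    for k in k_range:
        assignments, medoids, obj = pam_cluster(dist, k)
        ch = calinski_harabasz(dist, assignments)
        ch_scores[k] = ch
        if best is None or ch > ch_scores[best.k] + 1e-12:
            best = EnterotypeFit(k, assignments, medoids, {}, obj)
    assert best is not None
    best.ch_scores = ch_scores
    return best


# ---------------------------------------------------------------------------
# ordinations


def between_class_analysis(
    profiles: pd.DataFrame, classes: pd.Series
) -> OrdinationResult:
    """Ordination maximizing separation between predefined classes.

    Profiles are centred per feature (covariance-based, no per-feature
    scaling).  The axes are the principal directions of the class centroids
    weighted by class sizes; samples are projected onto them.  At most
    (number of classes - 1) axes.  The ratio of between-class to total
    inertia is reported together with its axis-wise decomposition.
    """
    classes = classes.reindex(profiles.index)
    if classes.isna().any():
        raise ValueError("every sample needs a class label")
    levels = classes.unique()
    if len(levels) < 2:
        raise ValueError("between-class analysis needs at least two classes")

    X = profiles.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    total_inertia = float((Xc**2).sum()) / n
    if total_inertia <= 0:
        raise ValueError("profiles have zero variance")

    centroids, weights = [], []
    for lv in levels:
        mask = (classes == lv).to_numpy()
        centroids.append(Xc[mask].mean(axis=0))
        weights.append(mask.sum() / n)
    G = np.array(centroids) * np.sqrt(np.array(weights))[:, None]
    # eigen-analysis of the weighted between-class covariance via SVD of G
    _, svals, vt = np.linalg.svd(G, full_matrices=False)
    n_axes = min(len(levels) - 1, vt.shape[0])
    axes = vt[:n_axes]
    eig = svals[:n_axes] ** 2  # between-class inertia per axis
    coords = Xc @ axes.T
    between = float((np.array(centroids) ** 2
                     * np.array(weights)[:, None]).sum())
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=profiles.index,
            columns=[f"BCA{i + 1}" for i in range(n_axes)],
        ),
        inertia=eig,
        method="bca",
        between_total_ratio=between / total_inertia,
    )


def bca_permutation_pvalue(
    profiles: pd.DataFrame,
    classes: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation test of the between/total inertia ratio.

    Returns (p value, null distribution of the ratio)."""
    observed = between_class_analysis(profiles, classes).between_total_ratio
    rng = np.random.default_rng(seed)
    labels = classes.reindex(profiles.index).to_numpy()
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = pd.Series(rng.permutation(labels), index=profiles.index)
        null[i] = between_class_analysis(profiles, perm).between_total_ratio
    p = (1 + (null >= observed).sum()) / (1 + n_permutations)
    return float(p), null


def pcoa(dist: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Classical principal coordinate analysis of a distance matrix.

    Double-centres the squared distances and eigendecomposes; axes are
    ordered by decreasing eigenvalue and axes with non-positive eigenvalues
    are dropped (their count is recoverable from ``inertia``'s length versus
    the requested number).  Euclidean inputs are reconstructed exactly.
    """
    _check_distance(dist)
    import warnings as _w

    with _w.catch_warnings():
        # full eigendecomposition is intended: negative eigenvalues must be
        # detectable, so silence skbio's all-dimensions performance note
        _w.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(
            _SkbioDM(dist.to_numpy(dtype=float), ids=[str(i) for i in dist.index]),
            method="eigh",
        )
    eig = res.eigvals.to_numpy()
    keep = np.flatnonzero(eig > 1e-12)
    if n_axes is not None:
        keep = keep[:n_axes]
    coords = res.samples.to_numpy()[:, keep]
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=dist.index,
            columns=[f"PCo{i + 1}" for i in range(len(keep))],
        ),
        inertia=eig[keep],
        method="pcoa",
    )
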