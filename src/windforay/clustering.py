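"""Partitioning Around Medoids over standardized track metrics.

Complete excursion tracks are clustered on six features: z-scored median
step length, maximum distance, duration and straightness, plus the
median direction encoded as ``(sin, cos)/sqrt(2)`` so the circular
variable contributes comparable Euclidean scale without a seam at
0/360 degrees.

PAM is the exact k-medoids algorithm: greedy BUILD initialisation
followed by SWAP passes that accept any single medoid/non-medoid
exchange reducing the total dissimilarity cost, until no exchange
improves.  Ties are broken toward the lower index, making the result
deterministic for a given row order.  Cluster-count diagnostics
(average silhouette, elbow/total-cost curve, and the Tibshirani gap
statistic with uniform-over-range reference sets) support the choice of
k; the pipeline default is k = 2, splitting extra-home-range tracks
into medium-range (MRM) and long-range (LRM) movements, the latter
being the longer-duration cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

FEATURE_COLUMNS = ("median_step_km", "max_distance_km", "duration_h", "straightness")


@dataclass
class FeatureMatrix:
    """Standardized feature rows for the clustered tracks."""

    values: np.ndarray          # (n_tracks, 6)
    track_ids: np.ndarray
    means: np.ndarray           # per z-scored column, for inverse transform
    sds: np.ndarray
    columns: tuple[str, ...]


@dataclass
class PamResult:
    k: int
    medoids: np.ndarray         # indices of medoid rows
    assignment: np.ndarray      # medoid position (0..k-1) per row
    cost: float
    iterations: int
    silhouette_values: np.ndarray | None = None
    silhouette_mean: float | None = None


def build_features(tracks: pd.DataFrame) -> FeatureMatrix:
    """Z-score the four linear metrics and encode direction as (sin, cos).

    Only rows that are both ``complete`` and ``metric_complete`` are
    used.  Zero-variance columns are left centred (SD treated as 1).
    """
    ok = tracks["complete"] & tracks["metric_complete"]
    sub = tracks.loc[ok]
    if sub.empty:
        raise ValueError("no complete tracks to cluster")
    lin = sub[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    means = lin.mean(axis=0)
    sds = lin.std(axis=0, ddof=0)
    sds_safe = np.where(sds > 0, sds, 1.0)
    z = (lin - means) / sds_safe
    ang = np.radians(sub["median_direction_deg"].to_numpy(dtype=float))
    circ = np.column_stack([np.sin(ang), np.cos(ang)]) / np.sqrt(2.0)
    values = np.column_stack([z, circ])
    cols = FEATURE_COLUMNS + ("dir_sin", "dir_cos")
    return FeatureMatrix(values, sub["track_id"].to_numpy(), means, sds_safe, cols)


def _swap_descent(dist: np.ndarray, med: np.ndarray, cost: float):
    """Steepest-descent SWAP: best single exchange until no improvement."""
    n = dist.shape[0]
    k = len(med)
    iterations = 0
    while iterations < 500:
        iterations += 1
        best_cost, best_swap = cost, None
        for mi in range(k):
            others = np.delete(med, mi)
            d_excl = (dist[others].min(axis=0) if len(others)
                      else np.full(n, np.inf))
            cand_costs = np.minimum(d_excl[None, :], dist).sum(axis=1)
            cand_costs[med] = np.inf
            h = int(np.argmin(cand_costs))
            if cand_costs[h] < best_cost - 1e-12:
                best_cost, best_swap = float(cand_costs[h]), (mi, h)
        if best_swap is None:
            break
        med = med.copy()
        med[best_swap[0]] = best_swap[1]
        med = np.sort(med)
        cost = best_cost
    return med, cost, iterations


def _pam_core(dist: np.ndarray, k: int) -> tuple[np.ndarray, float, int]:
    """BUILD + SWAP with deterministic perturbation restarts.

    BUILD greedily adds the medoid giving the largest cost reduction,
    then steepest-descent SWAP runs to a local optimum.  Because plain
    BUILD+SWAP can stall on small unstructured instances, the descent is
    restarted from the single-swap neighbourhood of the incumbent (all
    neighbours for small n, the cost-ordered best few otherwise) and,
    for very small problems, from pair-swap neighbours as well, keeping
    the best solution found.  Everything is deterministic given the row
    order; candidate ties resolve to the lowest index.
    """
    import itertools as _it

    n = dist.shape[0]
    medoids: list[int] = []
    nearest = np.full(n, np.inf)
    for _ in range(k):
        costs = np.minimum(nearest[None, :], dist).sum(axis=1)
        if medoids:
            costs[np.array(medoids)] = np.inf
        best_i = int(np.argmin(costs))
        medoids.append(best_i)
        nearest = np.minimum(nearest, dist[best_i])
    med = np.array(sorted(medoids))
    med, cost, iterations = _swap_descent(dist, med, float(dist[med].min(axis=0).sum()))

    width = n if n <= 40 else 4
    pair_depth = n <= 14
    for _ in range(10):
        improved = False
        for mi in range(k):
            cand_h = np.setdiff1d(np.arange(n), med)
            if width < len(cand_h):
                others = np.delete(med, mi)
                d_excl = (dist[others].min(axis=0) if len(others)
                          else np.full(n, np.inf))
                cc = np.minimum(d_excl[None, :], dist).sum(axis=1)
                cand_h = cand_h[np.argsort(cc[cand_h], kind="stable")][:width]
            for h in cand_h:
                med2 = med.copy()
                med2[mi] = h
                med2 = np.sort(med2)
                m3, c3, it3 = _swap_descent(dist, med2,
                                            float(dist[med2].min(axis=0).sum()))
                iterations += it3
                if c3 < cost - 1e-12:
                    med, cost = m3, c3
                    improved = True
        if pair_depth and k >= 2:
            non_med = np.setdiff1d(np.arange(n), med)
            for mi, mj in _it.combinations(range(k), 2):
                for h1, h2 in _it.combinations(non_med, 2):
                    med2 = med.copy()
                    med2[mi], med2[mj] = h1, h2
                    med2 = np.sort(med2)
                    m3, c3, it3 = _swap_descent(dist, med2,
                                                float(dist[med2].min(axis=0).sum()))
                    iterations += it3
                    if c3 < cost - 1e-12:
                        med, cost = m3, c3
                        improved = True
        if not improved:
            break
    return med, cost, iterations


def pam(features: np.ndarray | FeatureMatrix, k: int) -> PamResult:
    """Exact k-medoids (PAM) with Euclidean dissimilarity."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 rows")
    if k >= n:
        raise ValueError("k must be smaller than the number of rows")
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = cdist(X, X)
    med, cost, iters = _pam_core(dist, k)
    assignment = np.argmin(dist[med], axis=0)
    res = PamResult(k=k, medoids=med, assignment=assignment, cost=cost, iterations=iters)
    if k >= 2:
        s = silhouette(X, assignment, dist=dist)
        res.silhouette_values = s
        res.silhouette_mean = float(s.mean())
    return res


def silhouette(
    features: np.ndarray,
    assignment: np.ndarray,
    dist: np.ndarray | None = None,
) -> np.ndarray:
    """Per-point silhouette widths ``(b - a) / max(a, b)``.

    ``a`` is the mean dissimilarity to the point's own cluster (excluding
    itself), ``b`` the smallest mean dissimilarity to any other cluster.
    Points in singleton clusters score 0 by convention.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    assignment = np.asarray(assignment)
    clusters = np.unique(assignment)
    if clusters.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if dist is None:
        dist = cdist(X, X)
    n = len(X)
    s = np.zeros(n)
    for i in range(n):
        own = assignment == assignment[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, assignment == c].mean() for c in clusters if c != assignment[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def elbow_curve(features: np.ndarray | FeatureMatrix, k_range=range(1, 9)) -> pd.DataFrame:
    """PAM total cost per k (non-increasing in k)."""
    rows = [{"k": int(k), "cost": pam(features, int(k)).cost} for k in k_range]
    return pd.DataFrame(rows)


def gap_statistic(
    features: np.ndarray | FeatureMatrix,
    k_range=range(1, 9),
    B: int = 50,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Tibshirani gap statistic with uniform-over-range reference sets.

    ``Gap(k) = mean_b log W*_kb - log W_k`` where W is the PAM total
    within-cluster cost; the standard error includes the usual
    ``sqrt(1 + 1/B)`` factor.  The selection rule picks the smallest k
    with ``Gap(k) >= Gap(k+1) - SE(k+1)``.
    """
    if B < 10:
        raise ValueError("need at least 10 reference sets")
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = [int(k) for k in k_range]
    log_w = {k: np.log(max(pam(X, k).cost, 1e-300)) for k in ks}
    ref_log_w = {k: np.empty(B) for k in ks}
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for k in ks:
            ref_log_w[k][b] = np.log(max(pam(ref, k).cost, 1e-300))
    rows = []
    for k in ks:
        mean_ref = ref_log_w[k].mean()
        sd_ref = ref_log_w[k].std(ddof=0)
        rows.append(
            {
                "k": k,
                "log_w": log_w[k],
                "gap": mean_ref - log_w[k],
                "gap_se": sd_ref * np.sqrt(1.0 + 1.0 / B),
            }
        )
    return pd.DataFrame(rows)


def select_k_gap(gap_table: pd.DataFrame) -> int:
    """Smallest k with Gap(k) >= Gap(k+1) - SE(k+1)."""
    g = gap_table.sort_values("k").reset_index(drop=True)
    for i in range(len(g) - 1):
        if g["gap"][i] >= g["gap"][i + 1] - g["gap_se"][i + 1]:
            return int(g["k"][i])
    return int(g["k"].iloc[-1])


def assign_movement_labels(
    result: PamResult,
    tracks: pd.DataFrame,
    feature_matrix: FeatureMatrix,
) -> dict[int, str]:
    """Map PAM clusters to movement-type labels.

    The cluster with the larger median (unstandardised) duration is LRM;
    ties break on median maximum distance.  With k > 2 the longest-
    duration cluster is LRM and the others MRM1..MRM(k-1).
    """
    import warnings

    sub = tracks.set_index("track_id").loc[feature_matrix.track_ids]
    durations = sub["duration_h"].to_numpy(dtype=float)
    dmax = sub["max_distance_km"].to_numpy(dtype=float)
    k = result.k
    med_dur = np.array([np.median(durations[result.assignment == c]) for c in range(k)])
    med_dist = np.array([np.median(dmax[result.assignment == c]) for c in range(k)])
    order = np.lexsort((med_dist, med_dur))  # ascending; last = LRM
    lrm_cluster = int(order[-1])
    if k == 2:
        return {lrm_cluster: "LRM", int(order[0]): "MRM"}
    warnings.warn(f"k={k} != 2: labelling longest-duration cluster LRM, rest MRM1..")
    mapping = {lrm_cluster: "LRM"}
    for rank, c in enumerate(order[:-1], start=1):
        mapping[int(c)] = f"MRM{rank}"
    return mapping


def apply_cluster_labels(
    tracks: pd.DataFrame,
    feature_matrix: FeatureMatrix,
    result: PamResult,
    mapping: dict[int, str],
) -> pd.DataFrame:
    """Merge cluster indices and movement labels back into the track table."""
    out = tracks.copy()
    lab = pd.Series(
        [mapping[int(c)] if int(c) in mapping else str(c) for c in result.assignment],
        index=feature_matrix.track_ids,
    )
    clu = pd.Series(result.assignment, index=feature_matrix.track_ids)
    out["cluster"] = out["track_id"].map(clu).fillna(-1).astype(int)
    out["label"] = out["track_id"].map(lab).fillna("")
    return out
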