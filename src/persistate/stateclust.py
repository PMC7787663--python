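"""Repeated, condition-balanced k-means clustering of behavior frames.

Frames are sampled in equal numbers from every condition (with
replacement), z-scored per repeat over the sampled frames, and k-means
clustered; the procedure is repeated many times with fresh samples.
Cluster labels are arbitrary per repeat, so clusters are matched to a
reference repeat by minimum mean-squared error between centroids (optimal
one-to-one assignment). Reported outputs are per-cluster occupancy
probabilities by condition and the fraction of frames covered by the
largest clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class ClusterConfig:
    """Protocol parameters. Defaults follow the full-scale analysis:
    k = 20 clusters, 500 iterations, 30 repeats, sampling with
    replacement, equal frame counts per condition."""

    k: int = 20
    max_iter: int = 500
    n_repeats: int = 30
    params: Optional[List[str]] = None      # feature subset, e.g. the 8 significant
    frames_per_condition: int = 100_000
    sample_with_replacement: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1 or self.frames_per_condition < 1:
            raise ValueError("counts must be positive")


@dataclass
class ClusterRepeat:
    centroids: np.ndarray          # (k, n_params), z-scored space
    assignments: np.ndarray        # (n_frames,)
    conditions: np.ndarray         # (n_frames,) condition of each sampled frame
    sizes: np.ndarray              # (k,)
    z_mean: np.ndarray
    z_sd: np.ndarray
    frame_indices: np.ndarray      # indices into the source table


def sample_balanced_frames(
    conditions: np.ndarray,
    frames_per_condition: int,
    rng: np.random.Generator,
    with_replacement: bool = True,
) -> np.ndarray:
    """Indices of an equal-sized sample from every condition."""
    out = []
    for c in np.unique(conditions):
        idx = np.where(np.asarray(conditions) == c)[0]
        if len(idx) == 0:
            raise ValueError(f"condition {c!r} has no frames")
        if not with_replacement and frames_per_condition > len(idx):
            raise ValueError(
                f"condition {c!r}: {frames_per_condition} frames requested "
                f"without replacement but only {len(idx)} available")
        out.append(rng.choice(idx, size=frames_per_condition,
                              replace=with_replacement))
    return np.concatenate(out)


def run_clustering_repeats(
    features: pd.DataFrame,
    conditions: np.ndarray,
    cfg: ClusterConfig,
) -> List[ClusterRepeat]:
    """Run the sample -> z-score -> k-means cycle ``n_repeats`` times.

    z-scoring statistics are recomputed per repeat over that repeat's own
    sampled frames. k-means uses k-means++ initialization with a per-repeat
    seed derived from the master seed.
    """
    from sklearn.cluster import KMeans

    params = cfg.params or list(features.columns)
    x_all = features[params].to_numpy(dtype=float)
    conditions = np.asarray(conditions)
    master = np.random.SeedSequence(cfg.seed)
    repeats = []
    for child in master.spawn(cfg.n_repeats):
        rng = np.random.default_rng(child)
        idx = sample_balanced_frames(conditions, cfg.frames_per_condition,
                                     rng, cfg.sample_with_replacement)
        x = x_all[idx]
        mu, sd = x.mean(axis=0), x.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("degenerate (constant) parameter in sample")
        xz = (x - mu) / sd
        if len(np.unique(xz, axis=0)) < cfg.k:
            raise ValueError("fewer distinct points than clusters")
        km = KMeans(n_clusters=cfg.k, init="k-means++", n_init=1,
                    max_iter=cfg.max_iter,
                    random_state=int(rng.integers(2**31))).fit(xz)
        sizes = np.bincount(km.labels_, minlength=cfg.k)
        repeats.append(ClusterRepeat(
            centroids=km.cluster_centers_, assignments=km.labels_,
            conditions=conditions[idx], sizes=sizes,
            z_mean=mu, z_sd=sd, frame_indices=idx))
    return repeats


def match_clusters(
    reference: ClusterRepeat | np.ndarray,
    other: ClusterRepeat | np.ndarray,
    method: str = "optimal",
) -> Tuple[np.ndarray, np.ndarray]:
    """Map each cluster of ``other`` onto a reference cluster.

    The cost of pairing clusters is the mean squared error between their
    centroid vectors. ``optimal`` solves the one-to-one assignment that
    minimizes total MSE (Hungarian); ``greedy`` repeatedly takes the
    globally smallest remaining pair. Returns (mapping, per-pair MSE)
    where ``mapping[j]`` is the reference cluster for other-cluster j.
    """
    ref = reference.centroids if isinstance(reference, ClusterRepeat) else np.asarray(reference)
    oth = other.centroids if isinstance(other, ClusterRepeat) else np.asarray(other)
    if ref.shape != oth.shape:
        raise ValueError("cluster sets must have equal k and dimensionality")
    k = len(ref)
    cost = ((oth[:, None, :] - ref[None, :, :]) ** 2).mean(axis=2)
    mapping = np.empty(k, dtype=int)
    if method == "optimal":
        rows, cols = linear_sum_assignment(cost)
        mapping[rows] = cols
    elif method == "greedy":
        c = cost.copy()
        for _ in range(k):
            j, r = np.unravel_index(np.argmin(c), c.shape)
            mapping[j] = r
            c[j, :] = np.inf
            c[:, r] = np.inf
    else:
        raise ValueError("method must be 'optimal' or 'greedy'")
    return mapping, cost[np.arange(k), mapping]


def brute_force_match(ref: np.ndarray, oth: np.ndarray) -> Tuple[np.ndarray, float]:
    """Exhaustive assignment over all k! mappings (oracle; k <= 8)."""
    k = len(ref)
    if k > 8:
        raise ValueError("brute force limited to k <= 8")
    cost = ((oth[:, None, :] - ref[None, :, :]) ** 2).mean(axis=2)
    best, best_total = None, np.inf
    for perm in permutations(range(k)):
        total = cost[np.arange(k), perm].sum()
        if total < best_total:
            best, best_total = np.array(perm), total
    return best, best_total


@dataclass
class MatchedClusters:
    reference: int
    mappings: List[np.ndarray]             # per repeat: cluster -> ref cluster
    occupancy: pd.DataFrame                # repeat, cluster, condition, probability
    coverage: float                        # mean top-n coverage across repeats
    top_n: int


def occupancy_and_coverage(
    repeats: Sequence[ClusterRepeat],
    top_n: int = 7,
    reference: int = 0,
    method: str = "optimal",
) -> MatchedClusters:
    """Match all repeats to a reference and tabulate cluster usage.

    Occupancy is, per repeat and condition, the fraction of that
    condition's frames assigned to each (reference-relabeled) cluster —
    so occupancies sum to 1 within each (repeat, condition). Coverage is
    the fraction of frames in the ``top_n`` largest clusters of each
    repeat (by its own cluster sizes), averaged across repeats.
    """
    if not repeats:
        raise ValueError("no repeats")
    k = len(repeats[reference].centroids)
    top_n = min(top_n, k)
    mappings, occ_rows, coverages = [], [], []
    for r, rep in enumerate(repeats):
        if r == reference:
            mapping = np.arange(k)
        else:
            mapping, _ = match_clusters(repeats[reference], rep, method)
        mappings.append(mapping)
        relabeled = mapping[rep.assignments]
        for cond in np.unique(rep.conditions):
            sel = rep.conditions == cond
            counts = np.bincount(relabeled[sel], minlength=k)
            probs = counts / counts.sum()
            for c in range(k):
                occ_rows.append({"repeat": r, "cluster": c,
                                 "condition": cond, "probability": probs[c]})
        sizes_sorted = np.sort(rep.sizes)[::-1]
        coverages.append(sizes_sorted[:top_n].sum() / rep.sizes.sum())
    return MatchedClusters(
        reference=reference, mappings=mappings,
        occupancy=pd.DataFrame(occ_rows),
        coverage=float(np.mean(coverages)), top_n=top_n)
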