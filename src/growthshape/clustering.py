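"""k-means over trajectories with a shape-respecting distance.

Cluster centroids are smoothed mean trajectories (LOWESS over the pooled
member points) evaluated on a fixed age grid, so that members with
different visit schedules or missing visits contribute without imputation.
Assignment uses the generalized discrete Fréchet distance between each
child's observed points and the centroid polyline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import silhouette_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .frechet import ShapeDistanceConfig, frechet_distance, distance_matrix

PATTERN_NAMES_K3 = ("High", "Middle", "Low")


def default_grid(max_age_months: float = 132.0) -> np.ndarray:
    """40-point age grid, denser before 24 months where growth is fastest."""
    early = np.linspace(0.0, 24.0, 24)
    late = np.linspace(24.0, max_age_months, 17)[1:]
    return np.concatenate([early, late])


def mean_pattern(
    members: Sequence,
    grid: np.ndarray,
    span: float = 0.5,
    robust_iters: int = 1,
) -> np.ndarray:
    """LOWESS mean trajectory of a set of members, evaluated on ``grid``.

    All (age, z) points of all members are pooled and smoothed with
    tricube-weighted local linear regression (fraction ``span`` of the
    points per window), then linearly interpolated onto the grid.
    """
    if len(members) == 0:
        raise ValueError("empty cluster has no mean pattern")
    ts, zs = [], []
    for t, z in members:
        t = np.asarray(t, float)
        z = np.asarray(z, float)
        keep = np.isfinite(t) & np.isfinite(z)
        ts.append(t[keep])
        zs.append(z[keep])
    t = np.concatenate(ts)
    z = np.concatenate(zs)
    if t.size == 0:
        raise ValueError("cluster has no observed points")
    if t.size == 1:
        return np.full(len(grid), z[0])
    delta = 0.01 * (t.max() - t.min())
    sm = lowess(z, t, frac=span, it=robust_iters, delta=delta, return_sorted=True)
    return np.interp(grid, sm[:, 0], sm[:, 1])


@dataclass
class ClusterResult:
    k: int
    labels: dict[str, int]
    mean_patterns: np.ndarray  # (k, len(grid))
    grid: np.ndarray
    iterations: int
    converged: bool
    seed: int
    inertia_history: list[float] = field(default_factory=list)
    pattern_names: list[str] | None = None

    @property
    def inertia(self) -> float:
        return self.inertia_history[-1] if self.inertia_history else float("nan")

    def named_labels(self) -> dict[str, str]:
        if self.pattern_names is None:
            raise ValueError("call label_patterns first")
        return {cid: self.pattern_names[c] for cid, c in self.labels.items()}


def _init_centroid_indices(
    trajs, k: int, rng: np.random.Generator, cfg: ShapeDistanceConfig, method: str
) -> list[int]:
    n = len(trajs)
    if method == "random":
        return list(rng.choice(n, size=k, replace=False))
    # "maximin": deterministic farthest-point; "kmeans++": D^2 sampling.
    # Both beat uniform sampling when class frequencies are unbalanced.
    chosen = [int(rng.integers(n))]
    d_min = np.array([frechet_distance(t, trajs[chosen[0]], cfg) for t in trajs])
    while len(chosen) < k:
        if method == "maximin":
            nxt = int(np.argmax(d_min))
        else:
            w = d_min**2
            total = w.sum()
            if total <= 0:
                nxt = int(rng.integers(n))
            else:
                nxt = int(rng.choice(n, p=w / total))
        chosen.append(nxt)
        d_new = np.array([frechet_distance(t, trajs[nxt], cfg) for t in trajs])
        d_min = np.minimum(d_min, d_new)
    return chosen


def kmeans_shape(
    trajs: Sequence,
    k: int,
    cfg: ShapeDistanceConfig = ShapeDistanceConfig(),
    seed: int = 0,
    max_iter: int = 100,
    ids: Sequence[str] | None = None,
    grid: np.ndarray | None = None,
    span: float = 0.5,
    init: str = "kmeans++",
    n_init: int = 5,
    init_indices: Sequence[int] | None = None,
) -> ClusterResult:
    """Lloyd-style k-means with Fréchet assignment and LOWESS centroids.

    Iterates (assign to nearest centroid, recompute centroid as the smoothed
    mean pattern of its members) until no label changes or ``max_iter``.
    An emptied cluster is reseeded with the trajectory farthest from its
    current centroid. ``n_init`` restarts with different seeded
    initializations are run and the solution with the lowest total
    within-cluster distance kept (a single run when ``init_indices`` pins
    the starting centroids). Deterministic given ``seed``.
    """
    n = len(trajs)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of trajectories n={n}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    if grid is None:
        grid = default_grid()

    if init_indices is not None and len(init_indices) != k:
        raise ValueError("init_indices must have length k")
    restarts = 1 if init_indices is not None else max(1, n_init)
    best = None
    for run, sub_seed in enumerate(
        np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
    ):
        rng = np.random.default_rng(int(sub_seed))
        res = _kmeans_single(
            trajs, k, cfg, rng, max_iter, ids, grid, span, init, init_indices, seed
        )
        if best is None or res.inertia < best.inertia:
            best = res
    return best


def _kmeans_single(
    trajs, k, cfg, rng, max_iter, ids, grid, span, init, init_indices, seed
) -> ClusterResult:
    n = len(trajs)
    if init_indices is not None:
        chosen = list(init_indices)
    else:
        chosen = _init_centroid_indices(trajs, k, rng, cfg, init)
    centroids = [mean_pattern([trajs[i]], grid, span=span) for i in chosen]

    labels = np.full(n, -1, dtype=int)
    inertia_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # assignment
        dist = np.empty((n, k))
        for i, t in enumerate(trajs):
            for c in range(k):
                dist[i, c] = frechet_distance(t, (grid, centroids[c]), cfg)
        new_labels = np.argmin(dist, axis=1)
        # reseed empty clusters with the worst-fitting trajectory
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(np.argmax(dist[np.arange(n), new_labels]))
                new_labels[worst] = c
        inertia_history.append(float(dist[np.arange(n), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        # update
        for c in range(k):
            members = [trajs[i] for i in np.flatnonzero(labels == c)]
            centroids[c] = mean_pattern(members, grid, span=span)

    return ClusterResult(
        k=k,
        labels={ids[i]: int(labels[i]) for i in range(n)},
        mean_patterns=np.vstack(centroids),
        grid=np.asarray(grid, float),
        iterations=it,
        converged=converged,
        seed=seed,
        inertia_history=inertia_history,
    )


def label_patterns(result: ClusterResult) -> ClusterResult:
    """Name clusters by the time-average level of their mean pattern.

    With k = 3 the descending order is High / Middle / Low; otherwise rank
    strings C1 (highest) … Ck. Exact level ties are broken by the mean
    slope of the pattern, larger slope ranking higher.
    """
    means = result.mean_patterns.mean(axis=1)
    slopes = np.array(
        [np.polyfit(result.grid, p, 1)[0] for p in result.mean_patterns]
    )
    order = sorted(range(result.k), key=lambda c: (-means[c], -slopes[c]))
    rank_of = {c: r for r, c in enumerate(order)}
    if result.k == 3:
        names = [PATTERN_NAMES_K3[rank_of[c]] for c in range(result.k)]
    else:
        names = [f"C{rank_of[c] + 1}" for c in range(result.k)]
    result.pattern_names = names
    return result


@dataclass
class KSelection:
    table: "pd.DataFrame"  # per-k quality indices
    recommended_k: int


def select_k(
    trajs: Sequence,
    cfg: ShapeDistanceConfig = ShapeDistanceConfig(),
    k_range: Sequence[int] = range(2, 7),
    seed: int = 0,
    **kmeans_kwargs,
) -> KSelection:
    """Per-k quality indices and a majority-vote recommendation.

    Indices: mean silhouette width on the Fréchet distance matrix, a
    Calinski–Harabasz analogue built from centroid distances, and the total
    within-cluster distance (elbow via the largest curvature). Each index
    votes for one k; ties go to the smaller k. The recommendation is
    advisory — a caller may prefer a different k (e.g. to keep an
    interpretable intermediate pattern).
    """
    import pandas as pd

    n = len(trajs)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range empty after clipping to [2, n-1]")
    D = distance_matrix(trajs, cfg)
    if not np.any(D > 0):
        raise ValueError("all trajectories identical; quality indices undefined")
    grid = kmeans_kwargs.pop("grid", None)

    rows = []
    results = {}
    for k in k_range:
        res = kmeans_shape(trajs, k, cfg, seed=seed, grid=grid, **kmeans_kwargs)
        results[k] = res
        lab = np.fromiter(res.labels.values(), dtype=int)  # insertion order == input order
        sil = float(silhouette_score(D, lab, metric="precomputed"))
        within = res.inertia
        # CH analogue: centroid-to-global-centroid distances vs within distances
        global_centroid = mean_pattern(trajs, res.grid)
        between = 0.0
        within_sq = 0.0
        for c in range(k):
            members = np.flatnonzero(lab == c)
            d_cg = frechet_distance(
                (res.grid, res.mean_patterns[c]), (res.grid, global_centroid), cfg
            )
            between += len(members) * d_cg**2
            for i in members:
                within_sq += frechet_distance(
                    trajs[i], (res.grid, res.mean_patterns[c]), cfg
                ) ** 2
        ch = (
            (between / (k - 1)) / (within_sq / (n - k))
            if k > 1 and within_sq > 0
            else float("inf")
        )
        rows.append({"k": k, "silhouette": sil, "calinski_harabasz": ch, "within": within})

    table = pd.DataFrame(rows)
    votes = [
        int(table.loc[table["silhouette"].idxmax(), "k"]),
        int(table.loc[table["calinski_harabasz"].idxmax(), "k"]),
        _elbow_k(table["k"].to_numpy(), table["within"].to_numpy()),
    ]
    counts = {k: votes.count(k) for k in set(votes)}
    best = max(counts.values())
    recommended = min(k for k, c in counts.items() if c == best)
    table.attrs["votes"] = votes
    return KSelection(table=table, recommended_k=recommended)


def _elbow_k(ks: np.ndarray, within: np.ndarray) -> int:
    """k with the largest positive curvature of the within-distance curve;
    for fewer than 3 candidate ks, the k with the smallest within distance."""
    if len(ks) < 3:
        return int(ks[np.argmin(within)])
    curvature = within[:-2] - 2 * within[1:-1] + within[2:]
    return int(ks[1:-1][np.argmax(curvature)])
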