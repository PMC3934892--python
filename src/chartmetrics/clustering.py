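"""Matched-restart k-means and the cluster hierarchy over chart counts.

Clustering runs in the de-correlated feature space (see
:mod:`chartmetrics.decorrelation`) but is generic over any vector set.
Because k-means with random initialization is stochastic, every solution
here is the best of ``restarts`` independent runs, and a *stability*
score reports the fraction of restarts that found the same centroid set —
matched up by an optimal (Hungarian) assignment, since cluster labels are
arbitrary.  Sweeping k produces a hierarchy: centroids at consecutive k
are matched by optimal partial assignment, giving persistence chains that
expose whether clusters stay put as k grows or split and re-merge (the
pathology that motivates de-correlating before clustering).

Display always happens in the original response space: cluster-sum charts
add up the untransformed member charts, rendered on the Munsell layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .chart_space import ACHROMATIC_ROWS, ChipGrid, N_HUE_COLUMNS
from .wcs_io import Chart

__all__ = [
    "ClusterResult",
    "PersistenceLink",
    "HierarchyResult",
    "kmeans_restarts",
    "match_centroids",
    "cluster_hierarchy",
    "cluster_sum_charts",
    "render_chart_grid",
]

#: Two matched centroids count as "the same" when their distance is below
#: this relative tolerance; restarts agree when every matched pair does.
CENTROID_MATCH_RTOL = 1e-6


@dataclass(frozen=True)
class ClusterResult:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    stability: float
    seed: int
    restarts: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.assignments, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("reported solution must have no empty clusters")
        if not 0.0 <= self.stability <= 1.0:
            raise ValueError("stability must lie in [0, 1]")


def match_centroids(
    runA: np.ndarray, runB: np.ndarray
) -> tuple[np.ndarray, float]:
    """Minimum-total-Euclidean-cost bijection between two centroid sets.

    Returns ``(perm, cost)`` where ``runB[perm[i]]`` is the partner of
    ``runA[i]`` and cost is the summed Euclidean distance of the pairing.
    """
    A = np.atleast_2d(runA)
    B = np.atleast_2d(runB)
    if A.shape != B.shape:
        raise ValueError(f"centroid sets differ in shape: {A.shape} vs {B.shape}")
    cost = cdist(A, B)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm, float(cost[rows, cols].sum())


def _sets_coincide(A: np.ndarray, B: np.ndarray, perm: np.ndarray) -> bool:
    diffs = np.linalg.norm(A - B[perm], axis=1)
    scale = 1.0 + np.linalg.norm(B[perm], axis=1)
    return bool(np.all(diffs <= CENTROID_MATCH_RTOL * scale))


def _init_centers(
    X: np.ndarray, k: int, rng: np.random.Generator, init: str
) -> np.ndarray:
    n = X.shape[0]
    if init == "random":
        return X[rng.choice(n, size=k, replace=False)].copy()
    if init == "k-means++":
        centers = np.empty((k, X.shape[1]))
        centers[0] = X[rng.integers(n)]
        d2 = cdist(X, centers[:1], "sqeuclidean").ravel()
        for c in range(1, k):
            total = d2.sum()
            if total <= 0:  # all points already on a center
                centers[c] = X[rng.integers(n)]
                continue
            centers[c] = X[rng.choice(n, p=d2 / total)]
            d2 = np.minimum(d2, cdist(X, centers[c:c + 1], "sqeuclidean").ravel())
        return centers
    raise ValueError(f"unknown init {init!r}")


def _lloyd(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    init: str = "random",
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-means run.  An empty cluster is re-seeded at the data point
    currently farthest from its assigned centroid (repeatedly, if several
    clusters empty out), which also resolves stalls on duplicate points."""
    centers = _init_centers(X, k, rng, init)
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        new_labels = d2.argmin(axis=1)
        own = d2[np.arange(len(X)), new_labels]
        for c in range(k):
            if not np.any(new_labels == c):
                # only steal from clusters that keep at least one member
                counts = np.bincount(new_labels, minlength=k)
                donors = np.flatnonzero(counts[new_labels] > 1)
                far = int(donors[np.argmax(own[donors])])
                centers[c] = X[far]
                new_labels[far] = c
                own[far] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centers[c] = X[labels == c].mean(axis=0)
    d2 = cdist(X, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    return centers, labels, inertia


def kmeans_restarts(
    X: np.ndarray,
    k: int,
    restarts: int = 100,
    seed: int = 0,
    init: str = "random",
) -> ClusterResult:
    """Best-of-restarts k-means with a restart-agreement stability report.

    Each restart draws its initial centers as ``k`` distinct observations
    chosen uniformly at random (``init="random"``; ``"k-means++"`` also
    accepted).  The reported solution is the restart with the lowest
    inertia; stability is the fraction of restarts whose centroid set,
    after optimal matching, coincides with the winner's within a relative
    L2 tolerance of ``1e-6`` per centroid.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in 1..{n} (number of vectors)")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    runs = [_lloyd(X, k, rng, init=init) for _ in range(restarts)]
    best_centers, best_labels, best_inertia = min(runs, key=lambda r: r[2])
    agree = 0
    for centers, _, _ in runs:
        perm, _ = match_centroids(centers, best_centers)
        if _sets_coincide(centers, best_centers, perm):
            agree += 1
    return ClusterResult(
        k=k,
        centroids=best_centers.copy(),
        assignments=best_labels.copy(),
        inertia=best_inertia,
        stability=agree / restarts,
        seed=seed,
        restarts=restarts,
    )


@dataclass(frozen=True)
class PersistenceLink:
    """Match of centroid ``parent`` at level k to ``child`` at level k+1."""

    k: int
    parent: int
    child: int
    distance: float


@dataclass(frozen=True)
class HierarchyResult:
    results: tuple[ClusterResult, ...]
    links: tuple[PersistenceLink, ...]
    split_remerge_events: tuple[tuple, ...] = field(default=())
    tolerance: float = float("nan")

    def result_for(self, k: int) -> ClusterResult:
        for r in self.results:
            if r.k == k:
                return r
        raise KeyError(f"no result for k={k}")


def _chain_positions(
    results: Sequence[ClusterResult], links: Sequence[PersistenceLink]
) -> list[list[tuple[int, np.ndarray]]]:
    """Follow persistence links into per-chain centroid trajectories."""
    succ = {(l.k, l.parent): l.child for l in links}
    ks = [r.k for r in results]
    by_k = {r.k: r for r in results}
    chains: list[list[tuple[int, np.ndarray]]] = []
    # a chain starts at any centroid with no incoming link
    has_parent = {(l.k + 1, l.child) for l in links}
    for k in ks:
        for c in range(by_k[k].k):
            if (k, c) in has_parent:
                continue
            chain = []
            kk, cc = k, c
            while True:
                chain.append((kk, by_k[kk].centroids[cc]))
                if (kk, cc) not in succ:
                    break
                cc = succ[(kk, cc)]
                kk += 1
            chains.append(chain)
    return chains


def cluster_hierarchy(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int = 11,
    restarts: int = 100,
    seed: int = 0,
    init: str = "random",
    tolerance: float | None = None,
) -> HierarchyResult:
    """Independent matched-restart solutions for each k, plus persistence.

    Consecutive levels are linked by matching the k centroids of level k
    into the k+1 centroids of level k+1 (optimal partial assignment); the
    unmatched new centroid is the level's "newborn" cluster.  A
    split-and-re-merge event is flagged when a chain's centroid leaves its
    earlier position by more than ``tolerance`` and a later level returns
    within tolerance of that abandoned position — i.e. a cluster dissolved
    and came back.  By default the tolerance is a tenth of the median
    pairwise centroid distance at the deepest level.
    """
    X = np.asarray(X, dtype=float)
    if not 1 <= k_min <= k_max <= X.shape[0]:
        raise ValueError("need 1 <= k_min <= k_max <= n")
    ss = np.random.SeedSequence(seed)
    level_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in
                   ss.spawn(k_max - k_min + 1)]
    results = [
        kmeans_restarts(X, k, restarts=restarts, seed=s, init=init)
        for k, s in zip(range(k_min, k_max + 1), level_seeds)
    ]
    links: list[PersistenceLink] = []
    for lo, hi in zip(results[:-1], results[1:]):
        cost = cdist(lo.centroids, hi.centroids)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            links.append(PersistenceLink(k=lo.k, parent=int(r), child=int(c),
                                         distance=float(cost[r, c])))
    if tolerance is None:
        final = results[-1].centroids
        if len(final) > 1:
            pw = cdist(final, final)
            tolerance = 0.1 * float(np.median(pw[np.triu_indices(len(final), 1)]))
        else:
            tolerance = 0.0
    events: list[tuple] = []
    for chain in _chain_positions(results, links):
        for i1 in range(len(chain)):
            k1, p1 = chain[i1]
            left = None
            for i2 in range(i1 + 1, len(chain)):
                k2, p2 = chain[i2]
                d = float(np.linalg.norm(p2 - p1))
                if left is None and d > tolerance:
                    left = k2
                elif left is not None and d <= tolerance:
                    events.append((k1, left, k2))
                    break
    return HierarchyResult(
        results=tuple(results),
        links=tuple(links),
        split_remerge_events=tuple(events),
        tolerance=float(tolerance),
    )


def cluster_sum_charts(
    charts: Sequence[Chart], assignments: np.ndarray
) -> list[Chart]:
    """Entrywise sum of the original (untransformed) charts per cluster."""
    assignments = np.asarray(assignments)
    if len(assignments) != len(charts):
        raise ValueError("assignments must cover all charts")
    k = int(assignments.max()) + 1
    if np.any(assignments < 0):
        raise IndexError("negative cluster index")
    out = []
    for c in range(k):
        idx = np.flatnonzero(assignments == c)
        if len(idx) == 0:
            continue
        total = np.sum([charts[i].values for i in idx], axis=0)
        out.append(Chart(values=total, language="cluster", term=str(c),
                         level="language"))
    return out


def render_chart_grid(
    chart, grid: ChipGrid, path, cell_px: int = 10
) -> np.ndarray:
    """Render a chart as a grayscale Munsell-chart raster (PNG).

    Rows A-J top to bottom, columns 0-40 left to right; darker cells carry
    more response mass (a zero chart is uniformly light); positions with
    no chip (A and J beyond column 0) are white.  Returns the pixel array
    that was written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = chart.values if hasattr(chart, "values") else np.asarray(chart, float)
    if len(values) != len(grid):
        raise ValueError("chart length does not match grid")
    img = np.ones((len(ACHROMATIC_ROWS), N_HUE_COLUMNS + 1))
    row_index = {r: i for i, r in enumerate(ACHROMATIC_ROWS)}
    vmax = values.max()
    for chip, v in zip(grid.chips, values):
        # light gray 0.9 for zero response, down to 0.1 at the maximum
        shade = 0.9 if vmax == 0 else 0.9 - 0.8 * (v / vmax)
        img[row_index[chip.row], chip.column] = shade
    pixels = np.kron(img, np.ones((cell_px, cell_px)))
    plt.imsave(path, pixels, cmap="gray", vmin=0.0, vmax=1.0)
    return pixels
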