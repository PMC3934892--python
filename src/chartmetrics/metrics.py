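"""Chart-to-chart dissimilarities.

Two families are implemented side by side:

* **Permutation-invariant baselines.**  Euclidean distance and the Pearson
  correlation over chip entries treat chips as exchangeable coordinates:
  re-ordering the chips changes nothing, so all perceptual structure of
  the chart is discarded.  They are provided as the comparison point, not
  as a recommendation — once two charts have disjoint support these
  measures cannot tell perceptually near pairs from far ones.

* **Ground-metric-aware distances.**  The Earth Mover's Distance (EMD)
  treats charts as piles of mass over the chips and returns the minimum
  work (mass times dE moved) to turn one into the other, found by a linear
  program over flows.  The Quadratic chi-square distance (Pele & Werman)
  instead normalizes entry differences by similarity-weighted totals via a
  chip similarity matrix A.

Both aware distances accept arbitrary ground geometry, so EMD extends to
charts on *different* grids through a rectangular dE cost matrix
(``cross_support_emd``) — distributions from different elicitation
instruments become directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .chart_space import GroundDistanceMatrix, SimilarityMatrix
from .decorrelation import DecorrelationOperator, apply_decorrelation
from .wcs_io import Chart

__all__ = [
    "FlowPlan",
    "DistanceMatrix",
    "MetricSpec",
    "EmdComputationError",
    "euclidean_distance",
    "pearson_similarity",
    "emd",
    "emd_with_flow",
    "cross_support_emd",
    "quadratic_chi",
    "pairwise_distance_matrix",
    "rank_by_distance",
]

METRIC_NAMES = ("euclidean", "pearson", "emd", "qchi2", "decorrelated")


class EmdComputationError(RuntimeError):
    """The transport linear program failed to solve."""


@dataclass(frozen=True)
class FlowPlan:
    """Optimal transport plan: ``f[i, j]`` is mass moved from source chip i
    to target chip j (full source-grid x target-grid shape)."""

    f: np.ndarray
    source_mass: np.ndarray
    target_mass: np.ndarray

    @property
    def total_flow(self) -> float:
        return float(self.f.sum())

    def to_triplets(self) -> pd.DataFrame:
        """Sparse (i, j, flow) triplet view, 1-based chip indices."""
        i, j = np.nonzero(self.f)
        return pd.DataFrame({"i": i + 1, "j": j + 1, "flow": self.f[i, j]})


def _as_values(P) -> np.ndarray:
    return P.values if isinstance(P, Chart) else np.asarray(P, dtype=float)


def _check_same_length(p: np.ndarray, q: np.ndarray) -> None:
    if p.shape != q.shape:
        raise ValueError(f"chart length mismatch: {p.shape} vs {q.shape}")


def euclidean_distance(P, Q) -> float:
    """Plain L2 distance between chart entry vectors."""
    p, q = _as_values(P), _as_values(Q)
    _check_same_length(p, q)
    return float(np.linalg.norm(p - q))


def pearson_similarity(P, Q) -> float:
    """Sample Pearson correlation of the two charts' chip entries.

    Undefined (raises) when either chart is constant across chips.
    """
    p, q = _as_values(P), _as_values(Q)
    _check_same_length(p, q)
    sp, sq = p.std(), q.std()
    if sp == 0 or sq == 0:
        raise ValueError("Pearson correlation undefined for a constant chart")
    r = float(np.mean((p - p.mean()) * (q - q.mean())) / (sp * sq))
    return max(-1.0, min(1.0, r))


def _solve_transport(
    p: np.ndarray, q: np.ndarray, cost: np.ndarray
) -> tuple[float, np.ndarray]:
    """Minimum-work flow between mass vectors p, q with given cost matrix.

    Solves  min sum_ij f_ij c_ij  s.t.  f >= 0, row sums <= p,
    column sums <= q, total flow = min(sum p, sum q).  Restricting the LP
    to nonzero-mass bins keeps it desk-scale even on the 330-chip grid.
    Returns (work per unit flow, full dense flow matrix).
    """
    si = np.flatnonzero(p)
    tj = np.flatnonzero(q)
    if len(si) == 0 or len(tj) == 0:
        raise ValueError("EMD requires nonzero mass in both charts")
    ps, qt = p[si], q[tj]
    C = cost[np.ix_(si, tj)]
    ns, nt = len(si), len(tj)
    total = min(ps.sum(), qt.sum())

    nvar = ns * nt
    # row-sum and column-sum inequality constraints, sparse
    rows_i = np.repeat(np.arange(ns), nt)
    cols_j = np.tile(np.arange(nt), ns)
    var = np.arange(nvar)
    A_ub = sparse.vstack(
        [
            sparse.coo_matrix((np.ones(nvar), (rows_i, var)), shape=(ns, nvar)),
            sparse.coo_matrix((np.ones(nvar), (cols_j, var)), shape=(nt, nvar)),
        ]
    ).tocsr()
    b_ub = np.concatenate([ps, qt])
    A_eq = sparse.csr_matrix(np.ones((1, nvar)))
    res = linprog(
        C.ravel(),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=[total],
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise EmdComputationError(
            f"transport LP failed: {res.message} (status {res.status})"
        )
    f_small = res.x.reshape(ns, nt)
    f = np.zeros_like(cost)
    f[np.ix_(si, tj)] = f_small
    return float(res.fun) / total, f


def emd(P, Q, D: GroundDistanceMatrix, normalize: bool = True) -> float:
    """Earth Mover's Distance between two charts over ground metric D."""
    value, _ = emd_with_flow(P, Q, D, normalize=normalize)
    return value


def emd_with_flow(
    P, Q, D: GroundDistanceMatrix, normalize: bool = True
) -> tuple[float, FlowPlan]:
    """EMD plus the optimal flow plan realizing it.

    With ``normalize`` (default) both charts are scaled to unit mass, so
    the value is the mean dE a unit of naming mass must travel.  Without
    it, unequal totals give a partial match moving min(total P, total Q).
    """
    p, q = _as_values(P), _as_values(Q)
    _check_same_length(p, q)
    if D.n != len(p):
        raise ValueError("ground distance matrix does not match chart length")
    if normalize:
        if p.sum() <= 0 or q.sum() <= 0:
            raise ValueError("cannot normalize a zero-mass chart")
        p = p / p.sum()
        q = q / q.sum()
    value, f = _solve_transport(p, q, D.D)
    return value, FlowPlan(f=f, source_mass=p, target_mass=q)


def cross_support_emd(P, Q, D12: np.ndarray) -> float:
    """EMD between charts on two different grids via a rectangular dE cost.

    ``D12[i, j]`` is the dE between chip i of P's grid and chip j of Q's
    grid.  Unit-mass normalization is always applied (the grids need not
    even have comparable response totals).
    """
    p, q = _as_values(P), _as_values(Q)
    D12 = np.asarray(D12, dtype=float)
    if D12.shape != (len(p), len(q)):
        raise ValueError(
            f"cost shape {D12.shape} does not match charts ({len(p)}, {len(q)})"
        )
    if np.any(D12 < 0):
        raise ValueError("cost matrix must be nonnegative")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("cannot normalize a zero-mass chart")
    value, _ = _solve_transport(p / p.sum(), q / q.sum(), D12)
    return value


def quadratic_chi(
    P, Q, A: SimilarityMatrix, m: float = 0.9, normalize: bool = True
) -> float:
    """Quadratic chi-square distance of Pele & Werman.

    Entry differences are normalized by similarity-weighted totals
    ``Z_i = (sum_c (P_c + Q_c) A_ci)**m`` (with 0/0 := 0) and then
    contracted through the similarity matrix::

        QC(P, Q) = sqrt( sum_ij (d_i / Z_i)(d_j / Z_j) A_ij ),  d = P - Q

    ``m`` in [0, 1) controls how strongly large totals are discounted;
    m = 0 with A = I recovers the plain Euclidean distance.
    """
    p, q = _as_values(P), _as_values(Q)
    _check_same_length(p, q)
    K = A.K
    if K.shape[0] != len(p):
        raise ValueError("similarity matrix does not match chart length")
    if not 0 <= m < 1:
        raise ValueError("need 0 <= m < 1")
    if normalize:
        if p.sum() <= 0 or q.sum() <= 0:
            raise ValueError("cannot normalize a zero-mass chart")
        p = p / p.sum()
        q = q / q.sum()
    d = p - q
    Z = np.power((p + q) @ K, m)
    ratio = np.divide(d, Z, out=np.zeros_like(d), where=Z != 0)
    radicand = float(ratio @ K @ ratio)
    if radicand < 0:
        if radicand >= -1e-12:
            radicand = 0.0
        else:
            raise ValueError(
                f"negative Quadratic chi-square radicand {radicand:.3e}: "
                "similarity matrix is not positive semidefinite"
            )
    return float(np.sqrt(radicand))


@dataclass(frozen=True)
class MetricSpec:
    """A named dissimilarity plus the auxiliary structures it needs.

    ``name`` is one of euclidean, pearson, emd, qchi2, decorrelated.
    ``ground`` is required for emd, ``similarity`` for qchi2, ``operator``
    for decorrelated (Euclidean distance after the de-correlation map).
    Pearson is a similarity; ``dissimilarity`` converts it as 1 - r.
    """

    name: str
    ground: GroundDistanceMatrix | None = None
    similarity: SimilarityMatrix | None = None
    operator: DecorrelationOperator | None = None
    m: float = 0.9
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.name not in METRIC_NAMES:
            raise ValueError(
                f"unknown metric {self.name!r}; choose from {METRIC_NAMES}"
            )
        if self.name == "emd" and self.ground is None:
            raise ValueError("emd needs a ground distance matrix")
        if self.name == "qchi2" and self.similarity is None:
            raise ValueError("qchi2 needs a similarity matrix")
        if self.name == "decorrelated" and self.operator is None:
            raise ValueError("decorrelated needs a decorrelation operator")

    @property
    def is_similarity(self) -> bool:
        return self.name == "pearson"

    def _maybe_normalize(self, v: np.ndarray) -> np.ndarray:
        if self.normalize and self.name in ("euclidean", "decorrelated"):
            return v / v.sum()
        return v

    def value(self, P, Q) -> float:
        """Raw metric value (similarity for pearson, distance otherwise)."""
        p, q = _as_values(P), _as_values(Q)
        if self.name == "euclidean":
            return euclidean_distance(self._maybe_normalize(p), self._maybe_normalize(q))
        if self.name == "pearson":
            return pearson_similarity(p, q)
        if self.name == "emd":
            return emd(p, q, self.ground, normalize=self.normalize)
        if self.name == "qchi2":
            return quadratic_chi(p, q, self.similarity, m=self.m,
                                 normalize=self.normalize)
        # decorrelated: Euclidean in the kernel feature space
        tp, tq = apply_decorrelation(
            self.operator, [self._maybe_normalize(p), self._maybe_normalize(q)]
        )
        return float(np.linalg.norm(tp - tq))

    def dissimilarity(self, P, Q) -> float:
        v = self.value(P, Q)
        return 1.0 - v if self.is_similarity else v

    @property
    def params(self) -> dict:
        out: dict = {"normalize": self.normalize}
        if self.name == "qchi2":
            out["m"] = self.m
            out["sigma"] = self.similarity.sigma
        if self.name == "decorrelated":
            out["sigma"] = self.operator.sigma
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise chart dissimilarity matrix with labels and provenance."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    metric_name: str
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def pairwise_distance_matrix(
    charts: Sequence[Chart], spec: MetricSpec
) -> DistanceMatrix:
    """Full symmetric matrix of pairwise metric values, one solve per
    unordered pair."""
    if len(charts) < 2:
        raise ValueError("need at least two charts")
    n = len(charts)
    M = np.zeros((n, n))
    labels = tuple(c.label for c in charts)
    for i in range(n):
        if spec.is_similarity:
            M[i, i] = spec.value(charts[i], charts[i])
        for j in range(i + 1, n):
            try:
                v = spec.value(charts[i], charts[j])
            except Exception as exc:
                raise type(exc)(
                    f"metric {spec.name} failed for pair "
                    f"({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            M[i, j] = M[j, i] = v
    return DistanceMatrix(matrix=M, labels=labels, metric_name=spec.name,
                          params=spec.params)


def rank_by_distance(
    reference: Chart, charts: Sequence[Chart], spec: MetricSpec
) -> list[tuple[str, float]]:
    """Order charts by ascending dissimilarity to a reference chart.

    Similarities (Pearson) are converted to 1 - r first; ties break
    lexicographically by chart label.
    """
    scored = []
    for c in charts:
        try:
            v = spec.dissimilarity(reference, c)
        except Exception as exc:
            raise type(exc)(
                f"metric {spec.name} failed ranking {c.label!r} against "
                f"{reference.label!r}: {exc}"
            ) from exc
        scored.append((c.label, float(v)))
    return sorted(scored, key=lambda t: (t[1], t[0]))
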