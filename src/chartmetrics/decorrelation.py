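"""Kernel de-correlation of response charts.

Perceptually close chips elicit correlated responses; classical methods
(Euclidean distance, PCA, k-means) assume no such systematic dependence.
The fix: treat the chip similarity kernel K as a bilinear form and find a
linear map under which it becomes the canonical inner product.  Since K is
positive semidefinite, the Cholesky factorization K = R'R supplies one:
after x -> R x, plain dot products compute x'Ky, so any Euclidean method
run on transformed charts is implicitly perception-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, LinAlgError

from .chart_space import SimilarityMatrix

__all__ = ["DecorrelationOperator", "NotPositiveSemidefiniteError",
           "factor_similarity", "apply_decorrelation",
           "write_operator", "load_operator"]


class NotPositiveSemidefiniteError(np.linalg.LinAlgError):
    """The similarity matrix could not be Cholesky-factored even with jitter."""


@dataclass(frozen=True)
class DecorrelationOperator:
    """Upper-triangular factor R with R'R = K, plus kernel provenance."""

    R: np.ndarray
    sigma: float
    grid_fingerprint: str = ""

    @property
    def n(self) -> int:
        return self.R.shape[0]


def factor_similarity(
    K: SimilarityMatrix, jitter: float = 1e-10
) -> DecorrelationOperator:
    """Cholesky-factor a similarity kernel into a de-correlation operator.

    The exponential kernel is PSD in exact arithmetic but can fail strict
    positive-definiteness numerically; one retry with ``jitter * I`` added
    covers that. A failure after the retry reports the smallest eigenvalue.
    """
    A = np.asarray(K.K, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    try:
        R = cholesky(A, lower=False)
    except LinAlgError:
        try:
            R = cholesky(A + jitter * np.eye(A.shape[0]), lower=False)
        except LinAlgError as exc:
            min_eig = float(np.linalg.eigvalsh(A)[0])
            raise NotPositiveSemidefiniteError(
                f"similarity matrix is not positive semidefinite even with "
                f"jitter {jitter:g}: smallest eigenvalue {min_eig:.3e}"
            ) from exc
    fingerprint = f"n={A.shape[0]}"
    return DecorrelationOperator(R=R, sigma=K.sigma, grid_fingerprint=fingerprint)


def apply_decorrelation(
    op: DecorrelationOperator, charts: Sequence
) -> list[np.ndarray]:
    """Map each chart x to R x, making x'Ky the plain dot product."""
    out = []
    for c in charts:
        x = c.values if hasattr(c, "values") else np.asarray(c, dtype=float)
        if x.shape != (op.n,):
            raise ValueError(
                f"chart length {x.shape} does not match operator size {op.n}"
            )
        out.append(op.R @ x)
    return out


def write_operator(op: DecorrelationOperator, path) -> None:
    """Persist the factor as TSV with a one-line provenance header."""
    header = f"# sigma={op.sigma!r} grid={op.grid_fingerprint}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, op.R, delimiter="\t")


def load_operator(path) -> DecorrelationOperator:
    with open(path) as fh:
        header = fh.readline().strip()
        R = np.loadtxt(fh, delimiter="\t")
    sigma = float("nan")
    fingerprint = ""
    if header.startswith("#"):
        for token in header[1:].split():
            if token.startswith("sigma="):
                sigma = float(token[len("sigma="):])
            elif token.startswith("grid="):
                fingerprint = token[len("grid="):]
    return DecorrelationOperator(R=R, sigma=sigma, grid_fingerprint=fingerprint)
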