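"""Stimulus chart geometry and its perceptual embedding.

The World Color Survey (WCS) elicitation chart is a 330-cell Munsell-style
grid: 10 achromatic grey-scale chips (rows A-J, column 0) and 320 maximally
saturated chromatic chips (rows B-I by lightness, columns 1-40 by hue).
This module constructs that grid, assigns CIE L*a*b* coordinates to each
chip (either synthetic or loaded from a table), and derives the two square
matrices every downstream computation rests on:

* the ground distance matrix ``D`` of pairwise CIELAB-76 ``dE`` values, and
* the similarity kernel ``K = exp(-D / sigma)``.

``dE`` (delta-E) is the Euclidean distance in L*a*b* space, standardized so
that equal distances approximate equal perceptual dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Chip",
    "ChipGrid",
    "LabTable",
    "GroundDistanceMatrix",
    "SimilarityMatrix",
    "ACHROMATIC_ROWS",
    "CHROMATIC_ROWS",
    "N_HUE_COLUMNS",
    "DEFAULT_SIGMA",
    "build_wcs_grid",
    "synthetic_lab_coordinates",
    "load_lab_table",
    "write_lab_table",
    "ground_distance_matrix",
    "similarity_matrix",
]

#: Rows carrying the 10-step grey scale (column 0).
ACHROMATIC_ROWS = "ABCDEFGHIJ"
#: Rows carrying chromatic chips (columns 1-40); A and J exist only at column 0.
CHROMATIC_ROWS = "BCDEFGHI"
#: Number of hue columns on the chromatic part of the chart.
N_HUE_COLUMNS = 40

#: Default kernel bandwidth in CIELAB units.  Chosen so that off-diagonal
#: similarities span a wide range of values (roughly 0.04-0.81 on the
#: synthetic 330-chip table).
DEFAULT_SIGMA = 30.0


class GridStructureError(ValueError):
    """The chip grid violates the expected WCS chart structure."""


class LabTableError(ValueError):
    """A L*a*b* coordinate table could not be parsed or is inconsistent."""


@dataclass(frozen=True)
class Chip:
    """One stimulus cell: 1-based id, row letter, hue column, chromatic flag."""

    chip_id: int
    row: str
    column: int
    is_achromatic: bool


@dataclass(frozen=True)
class ChipGrid:
    """Ordered collection of chips; internal array index is ``chip_id - 1``."""

    chips: tuple[Chip, ...]

    def __post_init__(self) -> None:
        ids = [c.chip_id for c in self.chips]
        if ids != list(range(1, len(ids) + 1)):
            raise GridStructureError("chip_ids must be contiguous 1..N in order")
        for c in self.chips:
            if c.is_achromatic != (c.column == 0):
                raise GridStructureError(
                    f"chip {c.chip_id}: achromatic flag inconsistent with column"
                )

    def __len__(self) -> int:
        return len(self.chips)

    @property
    def n_chips(self) -> int:
        return len(self.chips)

    @property
    def achromatic_mask(self) -> np.ndarray:
        """Boolean mask over internal indices, True for grey-scale chips."""
        return np.array([c.is_achromatic for c in self.chips], dtype=bool)

    @property
    def chip_ids(self) -> np.ndarray:
        return np.arange(1, len(self.chips) + 1)

    def index_of(self, chip_id: int) -> int:
        if not 1 <= chip_id <= len(self.chips):
            raise KeyError(f"chip_id {chip_id} not on this {len(self.chips)}-chip grid")
        return chip_id - 1


def build_wcs_grid() -> ChipGrid:
    """Construct the standard 330-chip WCS chart.

    Ordering is deterministic: the 10 achromatic chips A0..J0 first
    (chip_ids 1-10), then the chromatic rows B..I scanned left to right
    (chip_ids 11-330).  External files use the 1-based chip_id; array code
    uses chip_id - 1.
    """
    chips: list[Chip] = []
    cid = 1
    for row in ACHROMATIC_ROWS:
        chips.append(Chip(cid, row, 0, True))
        cid += 1
    for row in CHROMATIC_ROWS:
        for col in range(1, N_HUE_COLUMNS + 1):
            chips.append(Chip(cid, row, col, False))
            cid += 1
    return ChipGrid(tuple(chips))


@dataclass(frozen=True)
class LabTable:
    """CIE L*a*b* coordinates per chip, aligned with a grid's internal order.

    ``coords`` has shape (N, 3) with columns L, a, b.
    """

    chip_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.chip_ids), 3):
            raise LabTableError("coords must be (n_chips, 3)")
        L = self.coords[:, 0]
        if np.any(L < 0) or np.any(L > 100):
            raise LabTableError("L* must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.chip_ids)

    @property
    def L(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def a(self) -> np.ndarray:
        return self.coords[:, 1]

    @property
    def b(self) -> np.ndarray:
        return self.coords[:, 2]


def synthetic_lab_coordinates(
    grid: ChipGrid,
    chroma: float = 40.0,
    l_min: float = 20.0,
    l_max: float = 90.0,
) -> LabTable:
    """Place chips in L*a*b* on a lightness-graded hue cylinder.

    A stand-in for the measured WCS chip coordinates: lightness L* is
    assigned linearly by row (A lightest .. J darkest) and chromatic chips
    sit on a hue circle of radius ``chroma`` with hue angle
    ``2*pi*(column-1)/40``; achromatic chips get a = b = 0.  The resulting
    geometry preserves the chart's qualitative structure: constant dE
    between neighbouring hue columns within a row, antipodal hues opposite,
    grey scale orthogonal to hue.
    """
    if chroma <= 0:
        raise ValueError("chroma must be positive")
    if not 0 <= l_min < l_max <= 100:
        raise ValueError("need 0 <= l_min < l_max <= 100")
    rows = ACHROMATIC_ROWS
    levels = np.linspace(l_max, l_min, len(rows))
    l_of_row = dict(zip(rows, levels))
    coords = np.zeros((len(grid), 3))
    for i, chip in enumerate(grid.chips):
        if chip.row not in l_of_row:
            raise GridStructureError(f"unknown row letter {chip.row!r}")
        coords[i, 0] = l_of_row[chip.row]
        if not chip.is_achromatic:
            theta = 2.0 * np.pi * (chip.column - 1) / N_HUE_COLUMNS
            coords[i, 1] = chroma * np.cos(theta)
            coords[i, 2] = chroma * np.sin(theta)
    return LabTable(grid.chip_ids, coords)


def write_lab_table(lab: LabTable, path) -> None:
    """Write a Lab table as TSV with columns chip_id, L, a, b."""
    df = pd.DataFrame(
        {"chip_id": lab.chip_ids, "L": lab.L, "a": lab.a, "b": lab.b}
    )
    df.to_csv(path, sep="\t", index=False)


def load_lab_table(path, grid: ChipGrid | None = None) -> LabTable:
    """Load a TSV Lab table (columns chip_id, L, a, b; header required).

    Rows may appear in any order; they are sorted by chip_id.  Duplicated
    chip ids, non-numeric coordinates and (when ``grid`` is given) missing
    chips are rejected with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["chip_id", "L", "a", "b"]
    if list(df.columns[:4]) != required:
        raise LabTableError(f"{path}: expected header {required}, got {list(df.columns)}")
    try:
        ids = df["chip_id"].astype(int)
        coords = df[["L", "a", "b"]].astype(float)
    except ValueError as exc:
        bad = df[~df[["L", "a", "b"]].apply(
            lambda col: col.str.match(r"^-?\d+(\.\d+)?([eE][+-]?\d+)?$")
        ).all(axis=1)]
        line = int(bad.index[0]) + 2 if len(bad) else "?"
        raise LabTableError(f"{path}: non-numeric coordinate at line {line}") from exc
    dup = ids[ids.duplicated()]
    if len(dup):
        line = int(dup.index[0]) + 2
        raise LabTableError(
            f"{path}: duplicate chip_id {dup.iloc[0]} at line {line}"
        )
    order = np.argsort(ids.to_numpy())
    ids_sorted = ids.to_numpy()[order]
    coords_sorted = coords.to_numpy()[order]
    if grid is not None and not np.array_equal(ids_sorted, grid.chip_ids):
        missing = sorted(set(grid.chip_ids.tolist()) - set(ids_sorted.tolist()))
        raise LabTableError(f"{path}: missing chips {missing[:5]}... for grid")
    return LabTable(ids_sorted, coords_sorted)


@dataclass(frozen=True)
class GroundDistanceMatrix:
    """Pairwise CIELAB-76 dE distances between chips (symmetric, metric)."""

    D: np.ndarray

    def __post_init__(self) -> None:
        D = self.D
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        if np.any(D < 0) or np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("D must be nonnegative with zero diagonal")

    @property
    def n(self) -> int:
        return self.D.shape[0]


def ground_distance_matrix(lab: LabTable) -> GroundDistanceMatrix:
    """CIELAB-76 dE: plain Euclidean distance over (L, a, b) triples."""
    D = squareform(pdist(lab.coords, metric="euclidean"))
    return GroundDistanceMatrix(D)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Exponential similarity kernel ``K_ij = exp(-D_ij / sigma)``.

    The kernel is symmetric with unit diagonal and, because dE is a
    Euclidean metric, positive semidefinite; ``min_eigenvalue`` records the
    numerically smallest eigenvalue as a diagnostic.
    """

    K: np.ndarray
    sigma: float
    min_eigenvalue: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")

    @property
    def n(self) -> int:
        return self.K.shape[0]


def similarity_matrix(
    D: GroundDistanceMatrix, sigma: float = DEFAULT_SIGMA
) -> SimilarityMatrix:
    """Build ``K = exp(-D / sigma)`` from a ground distance matrix.

    ``sigma`` (CIELAB units) controls how fast similarity decays with
    perceptual distance; larger sigma couples more distant chips.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    K = np.exp(-D.D / float(sigma))
    min_eig = float(np.linalg.eigvalsh(K)[0])
    return SimilarityMatrix(K=K, sigma=float(sigma), min_eigenvalue=min_eig)
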