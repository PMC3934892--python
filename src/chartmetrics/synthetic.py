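"""Synthetic WCS-shaped color-naming data with known ground truth.

Emulates the full-chart elicitation task: every speaker names every chip
with exactly one term.  Terms are organized around *focal points* — chips
acting as perceptual prototypes — and a speaker's term for a chip is drawn
with probability proportional to ``exp(-dE(chip, focal)^2 / T^2)``, where
``T`` (the *temperature*, in CIELAB units) softens term boundaries.  At
T = 0 naming is deterministic: each chip goes to its nearest focal, i.e.
the dE-Voronoi partition of the chart.

The ``ring`` focal mode places focals at equally spaced hue columns on a
middle-lightness row, so hue-adjacent and antipodal term pairs exist by
construction — the geometry needed to probe whether a chart metric
respects perceptual proximity.

Defaults (8 terms, 20 speakers, T = 10) model a mid-sized color lexicon
with boundary disagreement confined to chips near term borders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .chart_space import (
    CHROMATIC_ROWS,
    ChipGrid,
    GroundDistanceMatrix,
    LabTable,
    N_HUE_COLUMNS,
    ground_distance_matrix,
)
from .wcs_io import ResponseRecord, ResponseTable, make_table

__all__ = [
    "SimulationConfig",
    "generate_focal_points",
    "voronoi_labels",
    "simulate_responses",
    "write_ground_truth",
]

#: Middle-lightness chromatic row hosting ring-mode focal points.
RING_ROW = "E"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic naming task.

    ``temperature`` is in CIELAB units: 0 gives deterministic
    nearest-focal naming; around 10, chips within roughly one focal
    half-spacing of a boundary flip terms occasionally while term cores
    stay unanimous.
    """

    n_terms: int = 8
    n_speakers: int = 20
    temperature: float = 10.0
    seed: int = 0
    focal_mode: str = "ring"
    language: str = "synth"

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("need at least two terms")
        if self.temperature < 0:
            raise ValueError("temperature must be nonnegative")
        if self.focal_mode not in ("ring", "random"):
            raise ValueError("focal_mode must be 'ring' or 'random'")


def term_name(t: int) -> str:
    return f"t{t:02d}"


def generate_focal_points(
    grid: ChipGrid, lab: LabTable, cfg: SimulationConfig
) -> list[int]:
    """Choose one focal chip per term.

    Ring mode: equally spaced hue columns (spacing 40 / n_terms, rounded)
    on the middle-lightness row, so consecutive terms are hue neighbours
    and terms half a ring apart are antipodal.  Random mode: distinct
    chromatic chips drawn uniformly with the config seed.
    """
    chromatic = [c for c in grid.chips if not c.is_achromatic]
    if cfg.n_terms > len(chromatic):
        raise ValueError("more terms than chromatic chips")
    if cfg.focal_mode == "random":
        rng = np.random.default_rng(cfg.seed)
        picks = rng.choice(len(chromatic), size=cfg.n_terms, replace=False)
        return [chromatic[i].chip_id for i in sorted(picks)]
    if RING_ROW not in CHROMATIC_ROWS:
        raise ValueError(f"ring row {RING_ROW!r} is not chromatic")
    columns = [1 + round(t * N_HUE_COLUMNS / cfg.n_terms) % N_HUE_COLUMNS
               for t in range(cfg.n_terms)]
    if len(set(columns)) != cfg.n_terms:
        raise ValueError("n_terms too large for distinct ring columns")
    by_pos = {(c.row, c.column): c.chip_id for c in grid.chips}
    return [by_pos[(RING_ROW, col)] for col in columns]


def voronoi_labels(
    lab: LabTable, focals: list[int], D: GroundDistanceMatrix | None = None
) -> np.ndarray:
    """Per-chip index of the nearest focal (ties to the lowest term index)."""
    if D is None:
        D = ground_distance_matrix(lab)
    focal_idx = [f - 1 for f in focals]
    return np.argmin(D.D[:, focal_idx], axis=1)


def simulate_responses(
    grid: ChipGrid,
    lab: LabTable,
    focals: list[int],
    cfg: SimulationConfig,
) -> ResponseTable:
    """Draw a full naming table: every speaker names every chip once.

    Term probabilities for a chip follow a Gaussian-like kernel in dE to
    each focal, ``p(t) ∝ exp(-dE(chip, focal_t)^2 / T^2)``; T = 0
    degenerates to the Voronoi partition.  Deterministic given the seed.
    """
    if len(set(focals)) != len(focals):
        raise ValueError("focal chips must be distinct")
    D = ground_distance_matrix(lab)
    focal_idx = [f - 1 for f in focals]
    dists = D.D[:, focal_idx]  # (n_chips, n_terms)
    rng = np.random.default_rng(cfg.seed)
    n_chips, n_terms = dists.shape
    if cfg.temperature == 0:
        hard = np.argmin(dists, axis=1)
        probs = None
    else:
        logits = -((dists / cfg.temperature) ** 2)
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
    records = []
    for s in range(cfg.n_speakers):
        speaker = f"s{s:03d}"
        if probs is None:
            choice = hard
        else:
            u = rng.random((n_chips, 1))
            choice = (probs.cumsum(axis=1) > u).argmax(axis=1)
        for chip in range(n_chips):
            records.append(
                ResponseRecord(
                    language=cfg.language,
                    speaker=speaker,
                    chip_id=chip + 1,
                    term=term_name(int(choice[chip])),
                )
            )
    return make_table(records, grid)


def write_ground_truth(
    path, focals: list[int], lab: LabTable, cfg: SimulationConfig
) -> None:
    """Dump focals, the per-chip Voronoi labels and the config as JSON."""
    labels = voronoi_labels(lab, focals)
    payload = {
        "config": asdict(cfg),
        "focals": list(map(int, focals)),
        "voronoi_labels": [int(x) for x in labels],
        "terms": [term_name(t) for t in range(cfg.n_terms)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
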