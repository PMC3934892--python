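"""WCS-style response data: parsing and the three standard representations.

A response record says that one speaker of one language used one term for
one chip.  From a table of such records this module builds:

* **speaker response vectors** — per (language, speaker, term), a 0/1
  vector over the chart with 1 exactly at the chips that speaker named
  with that term;
* **language response vectors** — the entrywise sum of a term's speaker
  vectors across the language's speakers (nonnegative counts);
* **centroid representatives** — the single chip nearest (in dE) to the
  speaker-mean-then-language-mean L*a*b* average of a term's responses.

Any of these distributions over the chart is called a *chart*.  The
achromatic exclusion filter removes every chart whose support touches the
grey-scale column, mirroring the restriction some clustering studies apply.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chart_space import ChipGrid, LabTable

__all__ = [
    "ResponseRecord",
    "ResponseTable",
    "Chart",
    "ResponseFormatError",
    "read_responses",
    "write_responses",
    "speaker_response_vectors",
    "language_response_vectors",
    "filter_achromatic",
    "centroid_representative",
    "write_charts",
    "read_charts",
]

RESPONSE_COLUMNS = ["language", "speaker", "chip", "term"]


class ResponseFormatError(ValueError):
    """A response file or table violates the expected dialect."""


@dataclass(frozen=True)
class ResponseRecord:
    language: str
    speaker: str
    chip_id: int
    term: str


@dataclass(frozen=True)
class ResponseTable:
    """Validated naming records; at most one term per (language, speaker, chip)."""

    records: tuple[ResponseRecord, ...]
    grid: ChipGrid

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.language, r.speaker, r.chip_id, r.term) for r in self.records],
            columns=RESPONSE_COLUMNS,
        )


@dataclass(frozen=True)
class Chart:
    """A response distribution over the chips of a grid.

    ``level`` is ``"speaker"`` (0/1 values) or ``"language"`` (summed
    nonnegative counts).  ``label`` renders as language:term or
    language:term:speaker.
    """

    values: np.ndarray
    language: str
    term: str
    level: str
    speaker: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.level not in ("speaker", "language"):
            raise ValueError(f"unknown chart level {self.level!r}")
        if np.any(v < 0):
            raise ValueError("chart values must be nonnegative")
        if not np.any(v > 0):
            raise ValueError("chart must have at least one nonzero entry")
        if self.level == "speaker" and not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError("speaker-level charts must be 0/1 valued")

    @property
    def label(self) -> str:
        if self.speaker is not None:
            return f"{self.language}:{self.term}:{self.speaker}"
        return f"{self.language}:{self.term}"

    @property
    def support(self) -> np.ndarray:
        """Internal indices of chips with nonzero mass."""
        return np.flatnonzero(self.values)

    @property
    def total(self) -> float:
        return float(self.values.sum())


def make_table(records: Iterable[ResponseRecord], grid: ChipGrid) -> ResponseTable:
    """Validate records against the grid and the one-term-per-chip rule."""
    recs = tuple(records)
    seen: dict[tuple[str, str, int], str] = {}
    for r in recs:
        if not 1 <= r.chip_id <= len(grid):
            raise ResponseFormatError(
                f"chip_id {r.chip_id} not on the {len(grid)}-chip grid"
            )
        key = (r.language, r.speaker, r.chip_id)
        if key in seen and seen[key] != r.term:
            raise ResponseFormatError(
                f"conflicting terms {seen[key]!r} and {r.term!r} for "
                f"(language={r.language}, speaker={r.speaker}, chip={r.chip_id})"
            )
        seen[key] = r.term
    return ResponseTable(recs, grid)


def read_responses(path, grid: ChipGrid) -> ResponseTable:
    """Read a 4-column TSV (language, speaker, chip, term) with header.

    The WCS archive's ``term.txt`` uses the same four fields (language
    number, speaker number, chip number, term abbreviation) and needs only
    a header line to load here.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns[:4]) != RESPONSE_COLUMNS:
        raise ResponseFormatError(
            f"{path}: expected header {RESPONSE_COLUMNS}, got {list(df.columns)}"
        )
    try:
        chips = df["chip"].astype(int)
    except ValueError as exc:
        raise ResponseFormatError(f"{path}: non-integer chip id") from exc
    records = [
        ResponseRecord(str(l), str(s), int(c), str(t))
        for l, s, c, t in zip(df["language"], df["speaker"], chips, df["term"])
    ]
    return make_table(records, grid)


def write_responses(rt: ResponseTable, path) -> None:
    rt.to_frame().to_csv(path, sep="\t", index=False)


def speaker_response_vectors(rt: ResponseTable) -> list[Chart]:
    """One 0/1 chart per (language, speaker, term) triple, in sorted order."""
    n = len(rt.grid)
    grouped: dict[tuple[str, str, str], np.ndarray] = {}
    for r in rt.records:
        key = (r.language, r.speaker, r.term)
        vec = grouped.setdefault(key, np.zeros(n))
        vec[r.chip_id - 1] = 1.0
    return [
        Chart(values=grouped[k], language=k[0], speaker=k[1], term=k[2],
              level="speaker")
        for k in sorted(grouped)
    ]


def language_response_vectors(charts: Sequence[Chart]) -> list[Chart]:
    """Sum speaker vectors by (language, term) into language count charts."""
    if any(c.level != "speaker" for c in charts):
        raise ValueError("language_response_vectors expects speaker-level charts")
    grouped: dict[tuple[str, str], np.ndarray] = {}
    for c in charts:
        key = (c.language, c.term)
        if key in grouped:
            grouped[key] = grouped[key] + c.values
        else:
            grouped[key] = c.values.copy()
    return [
        Chart(values=grouped[k], language=k[0], term=k[1], level="language")
        for k in sorted(grouped)
    ]


def filter_achromatic(charts: Sequence[Chart], grid: ChipGrid) -> list[Chart]:
    """Keep only charts whose support avoids all 10 achromatic chips.

    Matches the restriction to naming patterns wholly contained in the 320
    chromatic chips; idempotent by construction.
    """
    achromatic = grid.achromatic_mask
    return [c for c in charts if not np.any(c.values[achromatic] > 0)]


def centroid_representative(charts: Sequence[Chart], lab: LabTable) -> int:
    """Project a term's responses to its closest single chip.

    Averaging is hierarchical: the mean L*a*b* coordinate over each
    speaker's supported chips is taken first, then the mean of those
    speaker means — so a prolific speaker does not dominate the language
    average.  Returns the chip_id minimizing dE to that average; ties go to
    the lowest chip_id.
    """
    if not charts:
        raise ValueError("centroid_representative needs at least one chart")
    if any(c.level != "speaker" for c in charts):
        raise ValueError("centroid_representative expects speaker-level charts")
    speaker_means = []
    for c in charts:
        idx = c.support
        speaker_means.append(lab.coords[idx].mean(axis=0))
    language_mean = np.mean(speaker_means, axis=0)
    d = np.linalg.norm(lab.coords - language_mean, axis=1)
    # argmin returns the first (lowest-index, hence lowest chip_id) minimum
    return int(lab.chip_ids[int(np.argmin(d))])


# ---------------------------------------------------------------------------
# Chart matrix serialization — the exchange format between pipeline stages.
# Rows are charts, columns are chips (header = chip_ids); three leading
# metadata columns identify each chart.

_META_COLUMNS = ["language", "term", "speaker"]


def write_charts(charts: Sequence[Chart], path) -> None:
    if not charts:
        raise ValueError("no charts to write")
    n = len(charts[0].values)
    rows = []
    for c in charts:
        if len(c.values) != n:
            raise ValueError("charts must share a grid")
        rows.append(
            [c.language, c.term, c.speaker if c.speaker is not None else ""]
            + list(c.values)
        )
    df = pd.DataFrame(rows, columns=_META_COLUMNS + [str(i + 1) for i in range(n)])
    df.to_csv(path, sep="\t", index=False)


def read_charts(path) -> list[Chart]:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _META_COLUMNS},
                     comment="#")
    if list(df.columns[:3]) != _META_COLUMNS:
        raise ResponseFormatError(
            f"{path}: expected leading columns {_META_COLUMNS}"
        )
    charts = []
    values = df[df.columns[3:]].to_numpy(dtype=float)
    speakers = df["speaker"].fillna("")
    for i in range(len(df)):
        spk = str(speakers.iloc[i])
        charts.append(
            Chart(
                values=values[i],
                language=str(df["language"].iloc[i]),
                term=str(df["term"].iloc[i]),
                speaker=spk if spk else None,
                level="speaker" if spk else "language",
            )
        )
    return charts
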