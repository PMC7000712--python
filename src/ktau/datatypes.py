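"""Core data containers: raw plate-reader traces and normalized time courses.

Times are minutes everywhere inside the package; plate files store seconds
(plate readers report seconds) and the io layer converts on read/write.
Concentrations are molar throughout; displays use nM/uM at the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

Direction = Literal["upward", "downward"]

#: minimum points for a fittable time course
MIN_POINTS = 8
#: minimum pre-addition baseline points for a raw trace
MIN_BASELINE_POINTS = 5


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D array")
    return arr


@dataclass(frozen=True)
class RawTrace:
    """One well's raw fluorescence recording, baseline segment included.

    Parameters
    ----------
    times : array-like
        Read times in minutes, strictly increasing, spanning the pre-addition
        baseline and the post-addition response.
    raw_fluorescence : array-like
        Raw fluorescence intensity in arbitrary plate-reader units.
    addition_time : float
        Nominal ligand-addition time in minutes. At least ``MIN_BASELINE_POINTS``
        reads must precede it (the baseline used for DeltaF/F normalization).
    """

    times: np.ndarray
    raw_fluorescence: np.ndarray
    addition_time: float
    well: str = ""
    ligand: str = ""
    conc: float = 0.0
    replicate: int = 0
    channel: str = "green"
    direction: Direction = "downward"

    def __post_init__(self):
        object.__setattr__(self, "times", _as_float_array(self.times))
        object.__setattr__(
            self, "raw_fluorescence", _as_float_array(self.raw_fluorescence)
        )
        if self.times.shape != self.raw_fluorescence.shape:
            raise ValueError("times and raw_fluorescence must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must be strictly increasing (well {self.well!r})")
        if self.conc < 0:
            raise ValueError("conc must be non-negative (molar)")
        n_baseline = int(np.sum(self.times < self.addition_time))
        if n_baseline < MIN_BASELINE_POINTS:
            raise ValueError(
                f"need >= {MIN_BASELINE_POINTS} pre-addition baseline points, "
                f"got {n_baseline} (well {self.well!r})"
            )

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.times < self.addition_time


@dataclass(frozen=True)
class TimeCourse:
    """A baseline-normalized (DeltaF/F) fluorescence time course for one well.

    ``direction`` records whether the underlying sensor responds with an
    increase ("upward") or decrease ("downward") in fluorescence; downward
    traces are inverted (1 - DeltaF/F) before fitting stimulation models.
    """

    times: np.ndarray
    values: np.ndarray
    direction: Direction = "upward"
    ligand: str = ""
    conc: float = 0.0
    replicate: int = 0
    channel: str = "green"
    well: str = ""
    addition_time: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", _as_float_array(self.times))
        object.__setattr__(self, "values", _as_float_array(self.values))
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) < MIN_POINTS:
            raise ValueError(f"need >= {MIN_POINTS} points, got {len(self.times)}")
        if self.conc < 0:
            raise ValueError("conc must be non-negative (molar)")
        if self.direction not in ("upward", "downward"):
            raise ValueError("direction must be 'upward' or 'downward'")

    def with_values(self, values, direction: Direction | None = None) -> "TimeCourse":
        return replace(
            self,
            values=_as_float_array(values),
            direction=self.direction if direction is None else direction,
        )
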