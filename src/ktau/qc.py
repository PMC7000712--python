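"""Trace preprocessing and plate-level quality control.

Preprocessing follows the standard fluorescent-biosensor convention: each
well's fluorescence is divided by the mean of its own pre-addition baseline
reads (DeltaF/F), and downward sensors are inverted (1 - DeltaF/F) so that
stimulation is always fit as an upward response.

QC covers replicate robustness (percent CV per time point), the
screening-window statistic Z' per time point, and endpoint (single-time-point)
dose-response analysis read from the fitted curves rather than raw wells, so
that per-well differences in addition time do not smear the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import RawTrace, TimeCourse
from .fitting import ExpFitResults, HillCurve, SigmoidResults

__all__ = [
    "delta_f_over_f",
    "preprocess",
    "invert_downward",
    "percent_cv",
    "z_prime",
    "EndpointDR",
    "endpoint_dose_response",
]

#: Z' sentinel when the control means do not separate ("no window")
NO_WINDOW = -np.inf


def delta_f_over_f(trace: RawTrace) -> TimeCourse:
    """Baseline-normalize a raw trace: divide by the mean pre-addition value.

    The pre-addition segment is retained (it normalizes to ~1), so the fitted
    onset time x0 stays meaningful.  Refuses traces whose baseline mean is
    zero or negative.
    """
    baseline = trace.raw_fluorescence[trace.baseline_mask]
    if baseline.size == 0:
        raise ValueError("empty baseline window")
    mean = float(np.mean(baseline))
    if mean <= 0:
        raise ValueError(f"non-positive baseline mean ({mean:g}): cannot normalize")
    return TimeCourse(
        times=trace.times,
        values=trace.raw_fluorescence / mean,
        direction=trace.direction,
        ligand=trace.ligand,
        conc=trace.conc,
        replicate=trace.replicate,
        channel=trace.channel,
        well=trace.well,
        addition_time=trace.addition_time,
    )


def preprocess(trace: RawTrace) -> TimeCourse:
    """DeltaF/F normalization followed by inversion for downward sensors.

    The standard route from a raw well to a fit-ready (upward) time course.
    """
    tc = delta_f_over_f(trace)
    return invert_downward(tc) if tc.direction == "downward" else tc


def invert_downward(tc: TimeCourse) -> TimeCourse:
    """Invert a DeltaF/F trace as 1 - DeltaF/F and flip its direction label.

    Applying it twice is the identity.
    """
    new_dir = "upward" if tc.direction == "downward" else "downward"
    return tc.with_values(1.0 - tc.values, direction=new_dir)


def _stack_aligned(traces: Sequence[TimeCourse]) -> tuple[np.ndarray, np.ndarray]:
    times = traces[0].times
    for tc in traces[1:]:
        if tc.times.shape != times.shape or not np.allclose(tc.times, times):
            raise ValueError("replicate traces must share the same time grid")
    return times, np.vstack([tc.values for tc in traces])


def percent_cv(traces: Sequence[TimeCourse]) -> pd.Series:
    """Percent coefficient of variation across replicates at each time point.

    100 * sd / mean with the sample (n-1) standard deviation, indexed by time
    (minutes).  Requires >= 2 replicates on a shared grid.
    """
    if len(traces) < 2:
        raise ValueError("need >= 2 replicate traces")
    times, mat = _stack_aligned(traces)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    return pd.Series(cv, index=pd.Index(times, name="time_min"), name="percent_cv")


def z_prime(
    positive: Sequence[TimeCourse], negative: Sequence[TimeCourse]
) -> pd.Series:
    """Screening-window statistic per time point.

    Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|, with sample (n-1)
    standard deviations.  Z' <= 1 always; 1 at zero variance, 0 when the
    3-sigma bands just touch, and the ``NO_WINDOW`` sentinel (-inf) where the
    control means coincide.
    """
    if len(positive) < 2 or len(negative) < 2:
        raise ValueError("need >= 2 wells in each control group")
    times, pos = _stack_aligned(list(positive))
    times_n, neg = _stack_aligned(list(negative))
    if not np.allclose(times, times_n):
        raise ValueError("positive and negative wells must share the time grid")
    sep = np.abs(pos.mean(axis=0) - neg.mean(axis=0))
    spread = 3.0 * (pos.std(axis=0, ddof=1) + neg.std(axis=0, ddof=1))
    z = np.where(sep > 0, 1.0 - spread / np.where(sep > 0, sep, 1.0), NO_WINDOW)
    return pd.Series(z, index=pd.Index(times, name="time_min"), name="z_prime")


@dataclass(frozen=True)
class EndpointDR:
    """Single-time-point dose-response summary for one ligand."""

    time_point: float
    ec50: float
    e_max: float
    hill: float
    ligand: str = ""
    fit: SigmoidResults | None = None

    def __post_init__(self):
        if not self.ec50 > 0:
            raise ValueError("ec50 must be > 0")


def endpoint_dose_response(
    fits: Sequence[ExpFitResults],
    time_point: float,
    concs: Sequence[float] | None = None,
    ligand: str = "",
) -> EndpointDR:
    """Endpoint dose-response at ``time_point`` minutes after ligand addition.

    The response for each concentration is read from its fitted time-course
    curve at onset + time_point, minus the fitted baseline y0 -- not from raw
    wells, so well-to-well addition-time offsets cancel.  The responses are
    then fit to the variable-slope sigmoid (bottom fixed at 0) for EC50,
    Emax and Hill slope.
    """
    fits = list(fits)
    if concs is None:
        concs = [f.conc for f in fits]
        if any(c is None for c in concs):
            raise ValueError("fits carry no concentration metadata; pass concs")
    responses = np.array(
        [
            float(f.predict(np.array([f.params["x0"] + time_point]))[0])
            - f.params["y0"]
            for f in fits
        ]
    )
    res = HillCurve(np.asarray(concs, float), responses, fix_bottom_at_zero=True).fit()
    return EndpointDR(
        time_point=float(time_point),
        ec50=res.l50,
        e_max=float(res.params["top"]),
        hill=float(res.params["hill"]),
        ligand=ligand or fits[0].ligand,
        fit=res,
    )
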