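"""Session-level AROM reduction and accuracy metrics.

A measurement session is ~30 frames of one movement; the active range of
motion (AROM) reported for the session is the maximum of the
median-smoothed angle series. The running median (default window 5,
shrinking at the edges) suppresses single-frame depth-sensor artefacts
("flying pixels") without biasing a sustained hold; window 1 disables
smoothing. The session mean and sample SD (n-1) are reported alongside
so that either max or mean can be compared against goniometry.

Accuracy against a goniometer-set reference angle is expressed as the
absolute error (degrees, half-up to 3 decimals) and the relative error
(percent of the reference, truncated to 2 decimals — the convention of
the printed validation tables this module reproduces).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .angles import AngleMeasurement, AngleSeries
from .errors import DomainError, EmptyStreamError


@dataclass(frozen=True)
class AromResult:
    """AROM summary of one measurement session."""

    movement: str
    side: str
    arom: float        # degrees: max of the smoothed series
    mean: float        # degrees: mean of the smoothed series
    sd: float          # degrees: sample SD (n-1); NaN for a 1-frame session
    n_used: int
    n_excluded: int


@dataclass(frozen=True)
class ReferenceMeasurement:
    """A goniometer-set reference angle (the validation ground truth)."""

    reference_angle: float
    instrument: str = "goniometer"

    def __post_init__(self):
        if not (0.0 <= self.reference_angle <= 180.0):
            raise DomainError(f"reference angle {self.reference_angle} outside [0, 180]")


@dataclass(frozen=True)
class AccuracyRow:
    reference: float
    measured_mean: float
    absolute_error: float   # degrees, half-up to 3 decimals
    relative_error: float   # percent of reference, truncated to 2 decimals


def smooth_series(series: AngleSeries, window: int = 5) -> AngleSeries:
    """Centred running median; the window shrinks at the series edges.

    Window must be odd (>= 1); window 1 is the identity. Exclusion
    bookkeeping is carried through unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise DomainError(f"window must be odd and >= 1, got {window}")
    if window == 1 or len(series) <= 1:
        return series
    smoothed = (
        pd.Series(series.thetas)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    measurements = [replace(m, theta=float(v))
                    for m, v in zip(series.measurements, smoothed)]
    return AngleSeries(series.movement, series.side, measurements,
                       list(series.excluded_frames))


def extract_arom(series: AngleSeries, window: int = 5) -> AromResult:
    """Reduce one session's angle series to its AROM summary."""
    if len(series) == 0:
        raise EmptyStreamError("cannot extract AROM from an empty series")
    sm = smooth_series(series, window)
    thetas = sm.thetas
    sd = float(np.std(thetas, ddof=1)) if len(thetas) > 1 else float("nan")
    return AromResult(
        movement=series.movement, side=series.side,
        arom=float(np.max(thetas)), mean=float(np.mean(thetas)), sd=sd,
        n_used=len(thetas), n_excluded=len(series.excluded_frames))


def accuracy_row(measured_mean: float, reference: ReferenceMeasurement) -> AccuracyRow:
    """Error of a session mean against a goniometer reference.

    Decimal arithmetic keeps the printed-table conventions exact:
    e.g. a mean of 30.549 at reference 30 gives absolute error 0.549
    and relative error 1.83 %.
    """
    ref = reference.reference_angle
    if ref <= 0:
        raise DomainError("relative error undefined for reference angle 0")
    m = Decimal(repr(float(measured_mean)))
    r = Decimal(repr(float(ref)))
    abs_exact = abs(m - r)
    abs_err = abs_exact.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    rel_err = (abs_exact / r * 100).quantize(Decimal("0.01"), rounding=ROUND_DOWN)
    return AccuracyRow(float(ref), float(measured_mean), float(abs_err), float(rel_err))


def accuracy_table(rows: list[tuple[float, float]]) -> pd.DataFrame:
    """Accuracy rows for (reference, measured_mean) pairs as a DataFrame."""
    recs = [accuracy_row(m, ReferenceMeasurement(r)) for r, m in rows]
    return pd.DataFrame(
        {"reference_deg": [r.reference for r in recs],
         "measured_mean_deg": [r.measured_mean for r in recs],
         "absolute_error_deg": [r.absolute_error for r in recs],
         "relative_error_pct": [r.relative_error for r in recs]})


def series_from_values(values, movement: str = "shoulder_abduction",
                       side: str = "right") -> AngleSeries:
    """Convenience: wrap raw angle values (one per frame) as an AngleSeries."""
    ms = [AngleMeasurement(float(v), movement, side, i) for i, v in enumerate(values)]
    return AngleSeries(movement, side, ms)


def summarize_rounded(result: AromResult, decimals: int = 2) -> dict:
    """AROM summary with table-style half-up rounding applied."""
    return {
        "movement": result.movement, "side": result.side,
        "arom_deg": round_half_up(result.arom, decimals),
        "mean_deg": round_half_up(result.mean, decimals),
        "sd_deg": (round_half_up(result.sd, decimals)
                   if np.isfinite(result.sd) else None),
        "n_used": result.n_used, "n_excluded": result.n_excluded,
    }
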