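"""Linear calibration curves relating concentration to stereoisomer peak area.

For a single astaxanthin source injected alone, the peak area ``y`` it
produces on one stereoisomer channel is linear in its concentration ``x``:

    y = a * x + b

with slope ``a`` (mAU·s per µg/mL) and intercept ``b`` (mAU·s).  One source
populates only the channels present in its stereoisomer fingerprint, so a
source is described by up to three such curves (a :class:`SourceProfile`).
Fits are ordinary least squares; the fit quality is the squared Pearson
correlation of area against concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .channels import canonical_channel
from .errors import (
    CalibrationQualityWarning,
    CalibrationRangeWarning,
    DegenerateDesignError,
    ConfigurationError,
    InputError,
)

#: Default QC threshold on r²; fits below it raise a warning, never an error.
DEFAULT_R2_THRESHOLD = 0.999


@dataclass(frozen=True)
class CalibrationPoint:
    """One standard injection: concentration (µg/mL) and peak area (mAU·s)."""

    concentration: float
    peak_area: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or not math.isfinite(self.peak_area):
            raise InputError("calibration point values must be finite")
        if self.concentration < 0:
            raise InputError(
                f"concentration must be non-negative, got {self.concentration}"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted line y = slope_a·x + intercept_b for one (source, channel).

    ``r_squared`` is ``None`` when the response was constant across
    standards (zero variance in area), in which case the correlation is
    undefined; this is an explicit flag, never a NaN.
    ``valid_range`` is the concentration span of the standards the curve
    was fitted on (µg/mL).
    """

    source_id: str
    channel_id: str
    slope_a: float
    intercept_b: float
    r_squared: float | None
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_id", canonical_channel(self.channel_id))
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InputError(f"r_squared must lie in [0, 1], got {self.r_squared}")
        lo, hi = self.valid_range
        if not lo < hi:
            raise InputError(f"valid_range must satisfy low < high, got {self.valid_range}")

    @property
    def constant_response(self) -> bool:
        """True when the standards showed no area variation (r² undefined)."""
        return self.r_squared is None


@dataclass(frozen=True)
class SourceProfile:
    """A named astaxanthin source with its calibrated stereoisomer channels.

    The set of channels a source populates, together with the relative
    slopes, is the source's quantitative fingerprint.
    """

    source_id: str
    curves: tuple[CalibrationCurve, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", tuple(self.curves))
        seen: set[str] = set()
        for c in self.curves:
            if c.source_id != self.source_id:
                raise ConfigurationError(
                    f"curve for source {c.source_id!r} placed in profile {self.source_id!r}"
                )
            if c.channel_id in seen:
                raise ConfigurationError(
                    f"duplicate calibration curve for ({self.source_id!r}, {c.channel_id!r})"
                )
            seen.add(c.channel_id)

    def curve_for(self, channel_id: str) -> CalibrationCurve | None:
        channel_id = canonical_channel(channel_id)
        for c in self.curves:
            if c.channel_id == channel_id:
                return c
        return None


def fit_line(
    points: Iterable[CalibrationPoint],
    *,
    source_id: str = "",
    channel_id: str = "3S,3'S",
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> CalibrationCurve:
    """Fit an unweighted ordinary-least-squares calibration line.

    Parameters
    ----------
    points
        Standard injections; at least two distinct concentrations required.
    source_id, channel_id
        Labels stamped onto the returned curve.
    r2_threshold
        QC floor on r².  A fit below it emits a
        :class:`~astamix.errors.CalibrationQualityWarning` (the curve is
        still returned: calibration quality gates are advisory).

    Raises
    ------
    DegenerateDesignError
        Fewer than two points, or all points at one concentration.
    """
    pts = list(points)
    if len(pts) < 2:
        raise DegenerateDesignError("calibration requires at least 2 points")
    x = np.array([p.concentration for p in pts], dtype=float)
    y = np.array([p.peak_area for p in pts], dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateDesignError(
            "calibration requires at least 2 distinct concentrations"
        )

    # OLS via lstsq on the design [x, 1].
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)

    ss_y = float(np.sum((y - y.mean()) ** 2))
    if ss_y == 0.0:
        r2: float | None = None  # constant response: correlation undefined
    else:
        resid = y - (slope * x + intercept)
        r2 = float(min(1.0, max(0.0, 1.0 - np.sum(resid**2) / ss_y)))
        if r2 < r2_threshold:
            warnings.warn(
                f"calibration r²={r2:.6f} below QC threshold {r2_threshold}"
                f" for ({source_id!r}, {channel_id!r})",
                CalibrationQualityWarning,
                stacklevel=2,
            )

    return CalibrationCurve(
        source_id=source_id,
        channel_id=channel_id,
        slope_a=float(slope),
        intercept_b=float(intercept),
        r_squared=r2,
        valid_range=(float(x.min()), float(x.max())),
    )


def predict_area(curve: CalibrationCurve, concentration: float) -> float:
    """Predicted peak area a·x + b (mAU·s) at ``concentration`` µg/mL.

    Emits a :class:`~astamix.errors.CalibrationRangeWarning` when the
    concentration falls outside the curve's fitted range; extrapolation is
    reported, not forbidden.
    """
    if not math.isfinite(concentration):
        raise InputError("concentration must be finite")
    if concentration < 0:
        raise InputError(f"concentration must be non-negative, got {concentration}")
    lo, hi = curve.valid_range
    if not lo <= concentration <= hi:
        warnings.warn(
            f"concentration {concentration} µg/mL outside calibrated range"
            f" [{lo}, {hi}] for ({curve.source_id!r}, {curve.channel_id!r})",
            CalibrationRangeWarning,
            stacklevel=2,
        )
    return curve.slope_a * concentration + curve.intercept_b


def fit_profiles(
    grouped_points: dict[tuple[str, str], Sequence[CalibrationPoint]],
    *,
    source_order: Sequence[str] | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[SourceProfile]:
    """Fit every (source, channel) group and bundle curves into profiles.

    ``source_order`` fixes the order of the returned profiles (hence of
    the unknowns in the assembled mixture model); by default sources
    appear in first-seen order of the input mapping.
    """
    if source_order is None:
        source_order = list(dict.fromkeys(src for src, _ in grouped_points))
    curves_by_source: dict[str, list[CalibrationCurve]] = {s: [] for s in source_order}
    for (src, chan), pts in grouped_points.items():
        if src not in curves_by_source:
            raise ConfigurationError(f"source {src!r} not in source_order")
        curves_by_source[src].append(
            fit_line(pts, source_id=src, channel_id=chan, r2_threshold=r2_threshold)
        )
    return [SourceProfile(s, tuple(curves_by_source[s])) for s in source_order]
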