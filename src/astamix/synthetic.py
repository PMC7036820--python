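"""Synthetic standards, mixtures and chromatograms.

No public instrument dataset accompanies the three-source astaxanthin
model, so every pipeline stage is exercised on simulated data with the
statistical structure the analysis assumes:

* standards follow the calibration line with multiplicative Gaussian
  area noise (a coefficient of variation on the mean area), truncated at
  zero since integrated areas cannot be negative;
* mixture channel totals are the forward-model prediction A·x + k plus
  the same style of channel-wise noise, replicated like triplicate
  injections;
* chromatogram traces place one Gaussian peak per stereoisomer at its
  retention time, with the analytic peak area equal to the requested
  channel area (mAU·s; the time axis is minutes).

All randomness flows through ``numpy.random.default_rng`` seeded from the
:class:`NoiseSpec`, so every simulation is bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, CalibrationPoint
from .channels import CHANNELS, RETENTION_TIMES_MIN
from .errors import InputError, ResolutionWarning
from .unmix import (
    MixtureModel,
    PeakObservation,
    predict_channel_areas,
    solve_concentrations,
)

#: Default Gaussian peak width (standard deviation), minutes.  Adjacent
#: stereoisomer peaks are ≥1.58 min apart, so this keeps them baseline
#: resolved.
DEFAULT_PEAK_WIDTH_MIN = 0.15

#: Default trace sampling rate, Hz.
DEFAULT_SAMPLING_HZ = 10.0


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate noise model: per-channel CV of peak areas, plus the seed.

    ``area_cv`` may be a single CV applied to every channel or a mapping
    of channel label to CV.  CV 0 gives exact, noise-free areas.
    """

    area_cv: float | Mapping[str, float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        cvs = (
            self.area_cv.values()
            if isinstance(self.area_cv, Mapping)
            else [self.area_cv]
        )
        for cv in cvs:
            if not math.isfinite(cv) or cv < 0:
                raise InputError(f"area_cv must be finite and ≥ 0, got {cv}")

    def cv_for(self, channel_id: str) -> float:
        if isinstance(self.area_cv, Mapping):
            return float(self.area_cv.get(channel_id, 0.0))
        return float(self.area_cv)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ChromTrace:
    """A simulated detector trace: time in minutes, absorbance in mAU."""

    time_min: np.ndarray
    absorbance_mau: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        y = np.asarray(self.absorbance_mau, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise InputError("time and absorbance must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise InputError("time axis must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise InputError("absorbance must be finite")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "absorbance_mau", y)


def simulate_standards(
    curve: CalibrationCurve,
    concentrations: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
) -> list[CalibrationPoint]:
    """Simulate standard injections from a known calibration line.

    Each area is a·x + b plus Gaussian noise with standard deviation
    cv·|a·x + b|, truncated at zero.
    """
    if len(concentrations) == 0:
        raise InputError("at least one standard concentration required")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise InputError("standard concentrations must be non-negative")
    mean = curve.slope_a * conc + curve.intercept_b
    cv = noise.cv_for(curve.channel_id)
    if cv > 0:
        rng = noise.rng()
        areas = mean + rng.normal(0.0, cv * np.abs(mean))
        areas = np.maximum(areas, 0.0)
    else:
        areas = mean
    return [CalibrationPoint(float(x), float(y)) for x, y in zip(conc, areas)]


def simulate_mixture(
    model: MixtureModel,
    x: Mapping[str, float] | Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
    replicates: int = 3,
    *,
    mixture_id: str = "",
) -> PeakObservation:
    """Simulate replicate injections of a mixture at true concentrations x.

    Per replicate, each channel total is the forward prediction plus
    Gaussian noise of SD cv·|prediction|, truncated at zero; the returned
    observation carries the replicate mean (and SD for ≥2 replicates).
    """
    if replicates < 1:
        raise InputError(f"replicates must be ≥ 1, got {replicates}")
    clean = predict_channel_areas(model, x)
    rng = noise.rng()
    reps = []
    for _ in range(replicates):
        rep = {}
        for chan, mean in clean.items():
            sd = noise.cv_for(chan) * abs(mean)
            # truncation applies to the noise, never to the clean prediction
            rep[chan] = max(mean + rng.normal(0.0, sd), 0.0) if sd > 0 else mean
        reps.append(rep)
    return PeakObservation.from_replicates(reps, mixture_id=mixture_id)


def simulate_chromatogram(
    channel_areas: Mapping[str, float],
    retention_times: Mapping[str, float] = RETENTION_TIMES_MIN,
    peak_widths: float | Mapping[str, float] = DEFAULT_PEAK_WIDTH_MIN,
    sampling_rate_hz: float = DEFAULT_SAMPLING_HZ,
    baseline_noise_mau: float = 0.0,
    seed: int = 0,
    time_window_min: tuple[float, float] | None = None,
) -> ChromTrace:
    """Render channel areas as Gaussian peaks on a detector trace.

    Each channel contributes a Gaussian at its retention time whose
    analytic area (in mAU·s, accounting for the minute→second conversion)
    equals the requested channel area:  height = area / (60·σ·√(2π)).
    A :class:`~astamix.errors.ResolutionWarning` is emitted when two peaks
    sit closer than three combined widths.
    """

    def width_of(chan: str) -> float:
        w = peak_widths.get(chan, DEFAULT_PEAK_WIDTH_MIN) if isinstance(
            peak_widths, Mapping
        ) else peak_widths
        if w <= 0:
            raise InputError(f"peak width must be positive, got {w}")
        return float(w)

    chans = [c for c in CHANNELS if c in channel_areas]
    if time_window_min is None:
        rts = [retention_times[c] for c in chans] or list(retention_times.values())
        pad = 10 * max((width_of(c) for c in chans), default=DEFAULT_PEAK_WIDTH_MIN)
        time_window_min = (min(rts) - pad, max(rts) + pad)
    t0, t1 = time_window_min
    if not t0 < t1:
        raise InputError("time window must satisfy start < end")

    n = int(round((t1 - t0) * 60.0 * sampling_rate_hz)) + 1
    t = t0 + np.arange(n) / (60.0 * sampling_rate_hz)
    y = np.zeros_like(t)

    for i, ci in enumerate(chans):
        for cj in chans[i + 1 :]:
            gap = abs(retention_times[ci] - retention_times[cj])
            if gap < 3.0 * (width_of(ci) + width_of(cj)):
                warnings.warn(
                    f"peaks {ci!r} and {cj!r} are {gap:.2f} min apart;"
                    " resolution loss likely",
                    ResolutionWarning,
                    stacklevel=2,
                )

    for chan in chans:
        area = float(channel_areas[chan])
        if area < 0:
            raise InputError(f"channel area must be non-negative, got {area}")
        if area == 0:
            continue
        rt = retention_times[chan]
        if not t0 <= rt <= t1:
            raise InputError(
                f"retention time {rt} min for {chan!r} outside trace window {time_window_min}"
            )
        sigma = width_of(chan)
        height = area / (60.0 * sigma * math.sqrt(2.0 * math.pi))
        y += height * np.exp(-0.5 * ((t - rt) / sigma) ** 2)

    if baseline_noise_mau > 0:
        y = y + np.random.default_rng(seed).normal(0.0, baseline_noise_mau, size=y.shape)
    return ChromTrace(time_min=t, absorbance_mau=y)


def default_integration_windows(
    retention_times: Mapping[str, float] = RETENTION_TIMES_MIN,
    peak_width_min: float = DEFAULT_PEAK_WIDTH_MIN,
    half_width_sigmas: float = 4.0,
) -> dict[str, tuple[float, float]]:
    """±kσ integration windows centred on the retention times."""
    half = half_width_sigmas * peak_width_min
    return {c: (rt - half, rt + half) for c, rt in retention_times.items()}


def integrate_peaks(
    trace: ChromTrace, windows: Mapping[str, tuple[float, float]]
) -> dict[str, float]:
    """Baseline-subtracted trapezoidal peak areas per channel (mAU·s).

    The baseline under each window is the straight line joining the trace
    at the window endpoints.  Windows must be disjoint and lie within the
    trace span; times are minutes, areas converted to mAU·s.
    """
    t, y = trace.time_min, trace.absorbance_mau
    spans = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (c1, (a1, b1)), (c2, (a2, _)) in zip(spans, spans[1:]):
        if a2 < b1:
            raise InputError(f"integration windows {c1!r} and {c2!r} overlap")
    areas: dict[str, float] = {}
    for chan, (w0, w1) in windows.items():
        if not w0 < w1:
            raise InputError(f"window for {chan!r} must satisfy start < end")
        if w0 < t[0] or w1 > t[-1]:
            raise InputError(f"window {w0, w1} for {chan!r} outside trace span")
        mask = (t >= w0) & (t <= w1)
        tw, yw = t[mask], y[mask]
        if tw.size < 2:
            areas[chan] = 0.0
            continue
        baseline = np.interp(tw, [tw[0], tw[-1]], [yw[0], yw[-1]])
        areas[chan] = float(np.trapezoid(yw - baseline, tw) * 60.0)
    return areas


def parameter_recovery_experiment(
    model: MixtureModel,
    x_grid: Sequence[Sequence[float]],
    noise_levels: Sequence[float | Mapping[str, float]],
    replicates: int = 100,
    seed: int = 0,
    *,
    method: str = "exact",
) -> pd.DataFrame:
    """Monte-Carlo bias/RMSE of the unmixing solve over a truth × noise grid.

    For every (true concentration vector, noise CV) cell, ``replicates``
    single-injection mixtures are simulated, solved, and summarized as the
    per-source mean estimate, bias, RMSE and mean recovery.  Fully
    deterministic for a given ``seed``.
    """
    if len(x_grid) == 0:
        raise InputError("x_grid must be non-empty")
    seeds = np.random.SeedSequence(seed).spawn(len(x_grid) * len(noise_levels))
    rows = []
    cell = 0
    for xi, x in enumerate(x_grid):
        truth = dict(zip(model.source_order, map(float, x)))
        for cv in noise_levels:
            child = seeds[cell]
            cell += 1
            ests = np.empty((replicates, model.n_sources))
            for r, s in enumerate(child.spawn(replicates)):
                obs = simulate_mixture(
                    model, truth, NoiseSpec(area_cv=cv, seed=s), replicates=1
                )
                res = solve_concentrations(model, obs, method=method)
                ests[r] = [res.concentrations[src] for src in model.source_order]
            true_vec = np.array([truth[s] for s in model.source_order])
            bias = ests.mean(axis=0) - true_vec
            rmse = np.sqrt(np.mean((ests - true_vec) ** 2, axis=0))
            cv_label = (
                float(np.mean(list(cv.values()))) if isinstance(cv, Mapping) else float(cv)
            )
            for j, src in enumerate(model.source_order):
                rows.append(
                    {
                        "x_index": xi,
                        "source_id": src,
                        "true_ug_per_ml": true_vec[j],
                        "area_cv": cv_label,
                        "mean_estimate": ests[:, j].mean(),
                        "bias": bias[j],
                        "rmse": rmse[j],
                        "mean_recovery_pct": (
                            100.0 * ests[:, j].mean() / true_vec[j]
                            if true_vec[j] > 0
                            else np.nan
                        ),
                    }
                )
    return pd.DataFrame(rows)
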