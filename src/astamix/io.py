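"""CSV/JSON input and output.

Conventions: comma-separated, UTF-8, dot decimal, one header row.  Units
are embedded in column names (``concentration_ug_per_ml``,
``peak_area_mau_s``) so files cannot silently change units.  Channel
labels contain commas and are therefore quoted by the writers; readers
accept any spelling :func:`astamix.channels.canonical_channel` does.

Fitted models are serialized as JSON, which round-trips slopes and
intercepts bit-exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .calibration import CalibrationCurve, CalibrationPoint, SourceProfile
from .channels import (
    ANALYTICAL_RANGE_UG_PER_ML,
    CHANNELS,
    RETENTION_TIMES_MIN,
    canonical_channel,
)
from .errors import InputError, ParseError
from .unmix import (
    DEFAULT_PRESENCE_THRESHOLD,
    MixtureModel,
    PeakObservation,
    RecoveryReport,
    UnmixResult,
    assemble_model,
)

CALIBRATION_COLUMNS = (
    "source_id",
    "channel_id",
    "concentration_ug_per_ml",
    "peak_area_mau_s",
)
OBSERVATION_COLUMNS = ("channel_id", "replicate", "peak_area_mau_s")
ACTUAL_COLUMNS = ("source_id", "concentration_ug_per_ml")


@dataclass(frozen=True)
class RunConfig:
    """Run-level settings for the command-line workflow."""

    channel_order: tuple[str, ...] = CHANNELS
    retention_windows_min: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            c: (rt - 0.6, rt + 0.6) for c, rt in RETENTION_TIMES_MIN.items()
        }
    )
    presence_threshold_ug_per_ml: float = DEFAULT_PRESENCE_THRESHOLD
    analytical_range_ug_per_ml: tuple[float, float] = ANALYTICAL_RANGE_UG_PER_ML
    solver_method: str = "exact"
    output_decimals: int = 2

    def __post_init__(self) -> None:
        if self.presence_threshold_ug_per_ml < 0:
            raise InputError("presence threshold must be ≥ 0")
        windows = sorted(
            (self.retention_windows_min[c] for c in self.channel_order
             if c in self.retention_windows_min),
        )
        for (lo1, hi1), (lo2, _) in zip(windows, windows[1:]):
            if lo1 >= hi1 or lo2 < hi1:
                raise InputError("retention windows must be ordered and non-overlapping")


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON config file mapping onto :class:`RunConfig` fields."""
    raw = json.loads(Path(path).read_text())
    kwargs = {}
    if "channel_order" in raw:
        kwargs["channel_order"] = tuple(canonical_channel(c) for c in raw["channel_order"])
    if "retention_windows_min" in raw:
        kwargs["retention_windows_min"] = {
            canonical_channel(c): tuple(w) for c, w in raw["retention_windows_min"].items()
        }
    for key in ("presence_threshold_ug_per_ml", "solver_method", "output_decimals"):
        if key in raw:
            kwargs[key] = raw[key]
    if "analytical_range_ug_per_ml" in raw:
        kwargs["analytical_range_ug_per_ml"] = tuple(raw["analytical_range_ug_per_ml"])
    return RunConfig(**kwargs)


def _open_rows(path: str | Path, required: Sequence[str]) -> list[tuple[int, dict]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError("file is empty (no header row)", path=str(path))
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ParseError(
                f"missing required column(s) {missing}; found {reader.fieldnames}",
                path=str(path),
                line=1,
            )
        rows = [(reader.line_num, row) for row in reader]
    if not rows:
        raise ParseError("file contains a header but no data rows", path=str(path))
    return rows


def _parse_float(value: str, column: str, path: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric value {value!r} in column {column!r}", path=path, line=line
        ) from None


def read_calibration_table(
    path: str | Path,
) -> dict[tuple[str, str], list[CalibrationPoint]]:
    """Read standard injections grouped by (source, channel).

    Repeated (source, channel, concentration) rows are replicate
    standards and are kept.  Unknown channel labels are rejected with the
    offending line number.
    """
    groups: dict[tuple[str, str], list[CalibrationPoint]] = {}
    for line, row in _open_rows(path, CALIBRATION_COLUMNS):
        src = (row["source_id"] or "").strip()
        if not src:
            raise ParseError("empty source_id", path=str(path), line=line)
        try:
            chan = canonical_channel(row["channel_id"])
        except InputError as exc:
            raise ParseError(str(exc), path=str(path), line=line) from None
        conc = _parse_float(row["concentration_ug_per_ml"],
                            "concentration_ug_per_ml", str(path), line)
        area = _parse_float(row["peak_area_mau_s"], "peak_area_mau_s", str(path), line)
        try:
            point = CalibrationPoint(conc, area)
        except InputError as exc:
            raise ParseError(str(exc), path=str(path), line=line) from None
        groups.setdefault((src, chan), []).append(point)
    return groups


def write_calibration_table(
    groups: Mapping[tuple[str, str], Sequence[CalibrationPoint]], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CALIBRATION_COLUMNS)
        for (src, chan), pts in groups.items():
            for p in pts:
                writer.writerow([src, chan, repr(p.concentration), repr(p.peak_area)])


def read_observations(path: str | Path) -> list[PeakObservation]:
    """Read observed channel areas, grouped by mixture and replicate.

    Columns ``channel_id``, ``replicate`` and ``peak_area_mau_s`` are
    required; an optional ``mixture_id`` column separates several
    mixtures in one file (a single unnamed mixture otherwise).
    """
    per_mixture: dict[str, dict[str, dict[str, float]]] = {}
    order: list[str] = []
    for line, row in _open_rows(path, OBSERVATION_COLUMNS):
        mid = (row.get("mixture_id") or "").strip()
        rep = (row["replicate"] or "").strip() or "1"
        try:
            chan = canonical_channel(row["channel_id"])
        except InputError as exc:
            raise ParseError(str(exc), path=str(path), line=line) from None
        area = _parse_float(row["peak_area_mau_s"], "peak_area_mau_s", str(path), line)
        if mid not in per_mixture:
            per_mixture[mid] = {}
            order.append(mid)
        if chan in per_mixture[mid].setdefault(rep, {}):
            raise ParseError(
                f"duplicate area for channel {chan!r}, replicate {rep!r}",
                path=str(path),
                line=line,
            )
        per_mixture[mid][rep][chan] = area
    return [
        PeakObservation.from_replicates(
            [per_mixture[mid][rep] for rep in sorted(per_mixture[mid])],
            mixture_id=mid,
        )
        for mid in order
    ]


def write_observations(obs: Iterable[PeakObservation], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(("mixture_id",) + OBSERVATION_COLUMNS)
        for o in obs:
            reps = o.replicate_areas or (o.channel_totals,)
            for r, rep in enumerate(reps, start=1):
                for chan in CHANNELS:
                    if chan in rep:
                        writer.writerow([o.mixture_id, chan, r, repr(rep[chan])])


def read_actuals(path: str | Path) -> dict[str, dict[str, float]]:
    """Read known spiked concentrations: mixture_id → source → µg/mL."""
    out: dict[str, dict[str, float]] = {}
    for line, row in _open_rows(path, ACTUAL_COLUMNS):
        mid = (row.get("mixture_id") or "").strip()
        src = (row["source_id"] or "").strip()
        if not src:
            raise ParseError("empty source_id", path=str(path), line=line)
        conc = _parse_float(row["concentration_ug_per_ml"],
                            "concentration_ug_per_ml", str(path), line)
        out.setdefault(mid, {})[src] = conc
    return out


# ---------------------------------------------------------------------------
# Model (de)serialization


def model_to_dict(model: MixtureModel, profiles: Sequence[SourceProfile]) -> dict:
    return {
        "format": "astamix-model",
        "version": 1,
        "analytical_range_ug_per_ml": list(model.analytical_range),
        "sources": [
            {
                "source_id": p.source_id,
                "curves": [
                    {
                        "channel_id": c.channel_id,
                        "slope_a": c.slope_a,
                        "intercept_b": c.intercept_b,
                        "r_squared": c.r_squared,
                        "valid_range_ug_per_ml": list(c.valid_range),
                    }
                    for c in p.curves
                ],
            }
            for p in profiles
        ],
    }


def write_model(
    profiles: Sequence[SourceProfile],
    path: str | Path,
    *,
    analytical_range: tuple[float, float] = ANALYTICAL_RANGE_UG_PER_ML,
) -> MixtureModel:
    """Assemble and serialize a model; returns the assembled model."""
    model = assemble_model(profiles, analytical_range=analytical_range)
    Path(path).write_text(json.dumps(model_to_dict(model, profiles), indent=2) + "\n")
    return model


def read_model(path: str | Path) -> tuple[MixtureModel, list[SourceProfile]]:
    """Read a serialized model file back into profiles and the assembled model."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}", path=str(path)) from None
    if raw.get("format") != "astamix-model":
        raise ParseError("not an astamix model file", path=str(path))
    profiles = []
    for src in raw["sources"]:
        curves = tuple(
            CalibrationCurve(
                source_id=src["source_id"],
                channel_id=c["channel_id"],
                slope_a=float(c["slope_a"]),
                intercept_b=float(c["intercept_b"]),
                r_squared=None if c["r_squared"] is None else float(c["r_squared"]),
                valid_range=tuple(c["valid_range_ug_per_ml"]),
            )
            for c in src["curves"]
        )
        profiles.append(SourceProfile(src["source_id"], curves))
    rng = tuple(raw.get("analytical_range_ug_per_ml", ANALYTICAL_RANGE_UG_PER_ML))
    return assemble_model(profiles, analytical_range=rng), profiles


# ---------------------------------------------------------------------------
# Verification report


def _fmt_actual(actual: Mapping[str, float], sources: Sequence[str]) -> str:
    return " + ".join(f"{actual.get(s, 0.0):g}·{s}" for s in sources)


def write_verification_report(
    results: Sequence[UnmixResult],
    actuals: Sequence[Mapping[str, float]],
    path: str | Path,
    *,
    recovery_source: str | None = None,
) -> None:
    """Write a human-readable validation table plus a full-precision sidecar.

    One row per mixture: actual composition, observed channel totals
    S1–S3, calculated concentrations (2 decimals) and the recovery rate
    (1 decimal, percent) of ``recovery_source`` (the first source by
    default); ``--`` where the recovery is undefined because that source
    was not spiked.  Full-precision values go to ``<path>.json``.
    """
    from .unmix import recovery_rates  # local import to avoid cycle at module load

    if len(results) != len(actuals):
        raise InputError(
            f"{len(results)} results but {len(actuals)} actual compositions"
        )
    path = Path(path)
    lines = [
        "actual_concentration_ug_per_ml\tS1_mau_s\tS2_mau_s\tS3_mau_s"
        "\tcalculated_concentration_ug_per_ml\trecovery_pct"
    ]
    sidecar: list[dict] = []
    for res, actual in zip(results, actuals):
        sources = list(res.concentrations)
        rsource = recovery_source or sources[0]
        report: RecoveryReport = recovery_rates(res, actual)
        obs = res.observation
        s_vals = (
            [obs.channel_totals.get(c, float("nan")) for c in CHANNELS]
            if obs is not None
            else [float("nan")] * 3
        )
        calc = " + ".join(
            f"{res.concentrations[s]:.2f}·{s}" for s in sources
        )
        rec = report.recovery_pct.get(rsource)
        lines.append(
            "\t".join(
                [
                    _fmt_actual(actual, sources),
                    *(f"{v:.2f}" for v in s_vals),
                    calc,
                    "--" if rec is None else f"{rec:.1f}",
                ]
            )
        )
        sidecar.append(
            {
                "mixture_id": obs.mixture_id if obs is not None else "",
                "actual_ug_per_ml": dict(actual),
                "observed_mau_s": dict(obs.channel_totals) if obs is not None else {},
                "calculated_ug_per_ml": dict(res.concentrations),
                "recovery_pct": {
                    s: report.recovery_pct[s] for s in res.concentrations
                },
                "max_deviation_ug_per_ml": report.max_deviation,
                "residuals_mau_s": dict(res.residuals),
                "condition_number": res.condition_number,
                "method": res.method,
            }
        )
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )
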