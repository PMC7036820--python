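"""Assembly and solution of the linear mixture model.

Peak areas are additive: in a mixture, the total area S_m observed on
stereoisomer channel m is the sum of the areas each source contributes
there.  Substituting each source's calibration line y_mi = a_mi·x_i + b_mi
gives, for n sources on the three channels,

    S_m = Σ_i a_mi·x_i + k_m,      k_m = Σ_i b_mi   (m = 1, 2, 3)

where the intercept sum k_m runs only over sources that actually populate
channel m.  Writing A for the 3×n slope matrix, observed channel totals S
determine the per-source concentrations x by solving

    A·x = S − k.

With three channels at most three sources are resolvable.  The exact
method solves the square system directly (or by unconstrained least
squares when n < 3); the ``nnls`` method imposes x ≥ 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.optimize

from .calibration import SourceProfile
from .channels import ANALYTICAL_RANGE_UG_PER_ML, CHANNELS, canonical_channel
from .errors import ConfigurationError, IdentifiabilityError, InputError

#: Relative singular-value cutoff below which the slope matrix is treated
#: as rank deficient.
RANK_TOLERANCE = 1e-10

#: Default concentration above which a source is declared present, µg/mL.
#: Equals the lower end of the analytical range.
DEFAULT_PRESENCE_THRESHOLD = 5.0


@dataclass(frozen=True)
class MixtureModel:
    """The assembled linear system for a set of calibrated sources.

    ``slope_matrix`` has one row per channel (elution order) and one
    column per source (declaration order); an entry is zero exactly when
    that source has no calibrated curve on that channel.
    ``intercept_vector`` holds the per-channel intercept sums k_m.
    """

    source_order: tuple[str, ...]
    channel_order: tuple[str, str, str]
    slope_matrix: np.ndarray  # (3, n) mAU·s per µg/mL
    intercept_vector: np.ndarray  # (3,) mAU·s
    analytical_range: tuple[float, float] = ANALYTICAL_RANGE_UG_PER_ML

    def __post_init__(self) -> None:
        A = np.asarray(self.slope_matrix, dtype=float)
        k = np.asarray(self.intercept_vector, dtype=float)
        if A.shape != (len(self.channel_order), len(self.source_order)):
            raise ConfigurationError(
                f"slope matrix shape {A.shape} inconsistent with"
                f" {len(self.channel_order)} channels × {len(self.source_order)} sources"
            )
        if k.shape != (len(self.channel_order),):
            raise ConfigurationError("intercept vector length must match channels")
        A.flags.writeable = False
        k.flags.writeable = False
        object.__setattr__(self, "slope_matrix", A)
        object.__setattr__(self, "intercept_vector", k)

    @property
    def n_sources(self) -> int:
        return len(self.source_order)

    def column_fingerprint(self, source_id: str) -> dict[str, float]:
        """Slope column of one source normalized to sum 1.

        When all intercepts are zero this equals the source's area
        fingerprint fractions, bridging the fingerprint and model views.
        """
        j = self.source_order.index(source_id)
        col = self.slope_matrix[:, j]
        total = col.sum()
        if total <= 0:
            raise InputError(f"source {source_id!r} has no positive slopes")
        return dict(zip(self.channel_order, (col / total).tolist()))


@dataclass(frozen=True)
class PeakObservation:
    """Observed total peak area per stereoisomer channel for one mixture.

    ``channel_totals`` is the mean over replicate injections; ``sd`` and
    ``replicate_areas`` are kept when replicates are available.
    """

    channel_totals: Mapping[str, float]
    replicate_areas: tuple[Mapping[str, float], ...] | None = None
    sd: Mapping[str, float] | None = None
    mixture_id: str = ""

    def __post_init__(self) -> None:
        totals = {canonical_channel(c): float(v) for c, v in self.channel_totals.items()}
        object.__setattr__(self, "channel_totals", totals)
        if self.replicate_areas is not None:
            reps = tuple(
                {canonical_channel(c): float(v) for c, v in r.items()}
                for r in self.replicate_areas
            )
            if len(reps) < 1:
                raise InputError("replicate_areas, when given, must be non-empty")
            object.__setattr__(self, "replicate_areas", reps)
        if self.sd is not None:
            object.__setattr__(
                self, "sd", {canonical_channel(c): float(v) for c, v in self.sd.items()}
            )

    @classmethod
    def from_replicates(
        cls, replicates: Sequence[Mapping[str, float]], *, mixture_id: str = ""
    ) -> "PeakObservation":
        """Aggregate per-replicate channel areas into mean ± SD totals."""
        if len(replicates) < 1:
            raise InputError("at least one replicate required")
        reps = [
            {canonical_channel(c): float(v) for c, v in r.items()} for r in replicates
        ]
        chans = sorted({c for r in reps for c in r}, key=CHANNELS.index)
        arr = np.array([[r.get(c, 0.0) for c in chans] for r in reps], dtype=float)
        mean = dict(zip(chans, arr.mean(axis=0).tolist()))
        sd = (
            dict(zip(chans, arr.std(axis=0, ddof=1).tolist()))
            if len(reps) > 1
            else None
        )
        return cls(channel_totals=mean, replicate_areas=tuple(reps), sd=sd,
                   mixture_id=mixture_id)


@dataclass(frozen=True)
class UnmixResult:
    """Solved per-source concentrations with diagnostics."""

    concentrations: Mapping[str, float]  # µg/mL
    residuals: Mapping[str, float]  # mAU·s, observed − reconstructed
    presence: Mapping[str, bool]
    condition_number: float
    method: str
    negative_sources: tuple[str, ...] = ()
    observation: PeakObservation | None = None


@dataclass(frozen=True)
class RangeFlag:
    """One out-of-range finding for a solved source."""

    source_id: str
    value: float  # µg/mL
    kind: str  # "below", "above" or "negative"

    def __str__(self) -> str:
        lo, hi = ANALYTICAL_RANGE_UG_PER_ML
        desc = {
            "below": f"below the analytical range (≥{lo} µg/mL)",
            "above": f"above the analytical range (≤{hi} µg/mL)",
            "negative": "negative (physically impossible; model misfit)",
        }[self.kind]
        return f"{self.source_id}: {self.value:.2f} µg/mL is {desc}"


@dataclass(frozen=True)
class RecoveryReport:
    """Recovery-rate validation of a solved mixture against known truth."""

    recovery_pct: Mapping[str, float | None]  # None where actual == 0
    deviations: Mapping[str, float]  # |calculated − actual|, µg/mL
    max_deviation: float
    undefined_sources: tuple[str, ...] = ()


def assemble_model(
    profiles: Iterable[SourceProfile],
    *,
    analytical_range: tuple[float, float] = ANALYTICAL_RANGE_UG_PER_ML,
) -> MixtureModel:
    """Build the slope matrix A and intercept sums k from calibrated profiles.

    Sources appear as columns in declaration order; channels as rows in
    elution order.  A source contributes its intercept to k_m only on
    channels where it has a calibrated curve.
    """
    profiles = list(profiles)
    if not profiles:
        raise ConfigurationError("at least one source profile required")
    seen_sources: set[str] = set()
    for p in profiles:
        if p.source_id in seen_sources:
            raise ConfigurationError(f"duplicate source profile {p.source_id!r}")
        seen_sources.add(p.source_id)

    n = len(profiles)
    A = np.zeros((3, n))
    k = np.zeros(3)
    for j, prof in enumerate(profiles):
        for curve in prof.curves:
            m = CHANNELS.index(curve.channel_id)
            A[m, j] = curve.slope_a
            k[m] += curve.intercept_b
    return MixtureModel(
        source_order=tuple(p.source_id for p in profiles),
        channel_order=CHANNELS,
        slope_matrix=A,
        intercept_vector=k,
        analytical_range=analytical_range,
    )


def _concentration_vector(model: MixtureModel, x: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    if isinstance(x, Mapping):
        missing = set(model.source_order) - set(x)
        if missing:
            raise InputError(f"missing concentrations for sources {sorted(missing)}")
        vec = np.array([float(x[s]) for s in model.source_order])
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape != (model.n_sources,):
            raise InputError(
                f"expected {model.n_sources} concentrations, got shape {vec.shape}"
            )
    if not np.all(np.isfinite(vec)):
        raise InputError("concentrations must be finite")
    if np.any(vec < 0):
        raise InputError("concentrations must be non-negative")
    return vec


def predict_channel_areas(
    model: MixtureModel, x: Mapping[str, float] | Sequence[float]
) -> dict[str, float]:
    """Forward model: total area A·x + k per channel (mAU·s)."""
    vec = _concentration_vector(model, x)
    totals = model.slope_matrix @ vec + model.intercept_vector
    return dict(zip(model.channel_order, totals.tolist()))


def _observation_vector(model: MixtureModel, obs: PeakObservation) -> np.ndarray:
    missing = [c for c in model.channel_order if c not in obs.channel_totals]
    if missing:
        raise InputError(f"observation missing channels {missing}")
    return np.array([obs.channel_totals[c] for c in model.channel_order])


def _check_rank(model: MixtureModel) -> float:
    """Return cond(A); raise IdentifiabilityError naming colinear sources."""
    A = model.slope_matrix
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[0] == 0 or sv[-1] < RANK_TOLERANCE * sv[0]:
        # The right null-space vector flags which columns are involved.
        _, _, vt = np.linalg.svd(A)
        null = np.abs(vt[-1])
        involved = tuple(
            s for s, w in zip(model.source_order, null) if w > 1e-6
        )
        raise IdentifiabilityError(
            "mixture model is rank deficient: sources "
            + ", ".join(repr(s) for s in involved)
            + " have colinear stereoisomer responses and cannot be separated",
            colinear_sources=involved,
        )
    return float(sv[0] / sv[-1])


def solve_concentrations(
    model: MixtureModel,
    obs: PeakObservation,
    *,
    method: str = "exact",
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> UnmixResult:
    """Solve A·x = S − k for the per-source concentrations.

    Parameters
    ----------
    method
        ``"exact"`` — direct linear solve for n = 3 (unconstrained least
        squares for n < 3); negative solutions are reported and flagged,
        never clamped.  ``"nnls"`` — non-negative least squares, for
        observations inconsistent with an exact non-negative solution.
    presence_threshold
        Concentration (µg/mL) at or above which a source is declared
        present.

    Raises
    ------
    InputError
        More than three sources (only three stereoisomer channels exist).
    IdentifiabilityError
        Rank-deficient slope matrix (colinear source fingerprints).
    """
    if model.n_sources > 3:
        raise InputError(
            "at most 3 sources are resolvable from 3 stereoisomer channels,"
            f" got {model.n_sources}"
        )
    if method not in ("exact", "nnls"):
        raise InputError(f"unknown method {method!r}; expected 'exact' or 'nnls'")

    cond = _check_rank(model)
    A = model.slope_matrix
    S = _observation_vector(model, obs)
    rhs = S - model.intercept_vector

    if method == "exact":
        if model.n_sources == 3:
            x = np.linalg.solve(A, rhs)
        else:
            x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    else:
        x, _ = scipy.optimize.nnls(A, rhs)

    reconstructed = A @ x + model.intercept_vector
    residuals = dict(zip(model.channel_order, (S - reconstructed).tolist()))
    conc = dict(zip(model.source_order, x.tolist()))
    negative = tuple(s for s, v in conc.items() if v < 0)
    presence = {s: v >= presence_threshold for s, v in conc.items()}
    return UnmixResult(
        concentrations=conc,
        residuals=residuals,
        presence=presence,
        condition_number=cond,
        method=method,
        negative_sources=negative,
        observation=obs,
    )


def solve_per_replicate(
    model: MixtureModel,
    obs: PeakObservation,
    *,
    method: str = "exact",
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> tuple[dict[str, float], dict[str, float] | None, list[UnmixResult]]:
    """Solve each replicate separately; return mean, SD and per-replicate results.

    The default workflow solves on mean areas; this is the opt-in
    alternative when replicate-level spread in the concentrations is
    wanted.  SD is ``None`` with a single replicate.
    """
    if obs.replicate_areas is None:
        raise InputError("observation carries no replicate-level areas")
    results = [
        solve_concentrations(
            model,
            PeakObservation(channel_totals=rep, mixture_id=obs.mixture_id),
            method=method,
            presence_threshold=presence_threshold,
        )
        for rep in obs.replicate_areas
    ]
    arr = np.array(
        [[r.concentrations[s] for s in model.source_order] for r in results]
    )
    mean = dict(zip(model.source_order, arr.mean(axis=0).tolist()))
    sd = (
        dict(zip(model.source_order, arr.std(axis=0, ddof=1).tolist()))
        if len(results) > 1
        else None
    )
    return mean, sd, results


def recovery_rates(
    result: UnmixResult, actual: Mapping[str, float]
) -> RecoveryReport:
    """Validate a solve against known spiked concentrations.

    recovery_i = 100 · x_i / actual_i (percent); sources spiked at zero
    get an undefined-recovery flag rather than a division by zero.
    """
    recov: dict[str, float | None] = {}
    dev: dict[str, float] = {}
    undefined: list[str] = []
    for s, x in result.concentrations.items():
        a = float(actual.get(s, 0.0))
        dev[s] = abs(x - a)
        if a > 0:
            recov[s] = 100.0 * x / a
        else:
            recov[s] = None
            undefined.append(s)
    return RecoveryReport(
        recovery_pct=recov,
        deviations=dev,
        max_deviation=max(dev.values()) if dev else 0.0,
        undefined_sources=tuple(undefined),
    )


def detect_sources(
    result: UnmixResult, threshold: float = DEFAULT_PRESENCE_THRESHOLD
) -> dict[str, bool]:
    """Presence call per source: solved concentration ≥ threshold (µg/mL)."""
    if threshold < 0 or not math.isfinite(threshold):
        raise InputError("presence threshold must be finite and non-negative")
    return {s: v >= threshold for s, v in result.concentrations.items()}


def check_range(
    result: UnmixResult,
    analytical_range: tuple[float, float] = ANALYTICAL_RANGE_UG_PER_ML,
) -> list[RangeFlag]:
    """Flag solved concentrations outside the analytical range.

    Solutions are still reported; flags are advisory.  Negative estimates
    get an additional ``"negative"`` flag since they indicate model
    misfit, not just extrapolation.
    """
    lo, hi = analytical_range
    flags: list[RangeFlag] = []
    for s, v in result.concentrations.items():
        if v < 0:
            flags.append(RangeFlag(s, v, "below"))
            flags.append(RangeFlag(s, v, "negative"))
        elif v < lo:
            flags.append(RangeFlag(s, v, "below"))
        elif v > hi:
            flags.append(RangeFlag(s, v, "above"))
    return flags
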