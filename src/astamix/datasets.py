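"""Packaged reference data for the three commercial astaxanthin sources.

Ships the published chiral-HPLC characterization of astaxanthin from
*Phaffia rhodozyma* (yeast), *Haematococcus pluvialis* (alga) and chemical
synthesis measured on a CHIRALPAK IC column at 476 nm:

* single-source stereoisomer peak areas (the fingerprints),
* the seven fitted calibration curves (slope/intercept per source and
  channel; the per-curve r² values were reported only as exceeding 0.999,
  so they are stored as unreported), and
* seven verification mixtures with known spiked concentrations and
  observed mean ± SD channel areas over triplicate injections.

Everything here is data; the model itself is assembled through the same
:func:`astamix.unmix.assemble_model` path user calibrations take.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .calibration import CalibrationCurve, SourceProfile
from .channels import ANALYTICAL_RANGE_UG_PER_ML, CHANNEL_RR, CHANNEL_SR, CHANNEL_SS
from .fingerprint import IsomerFingerprint, normalize_fingerprint
from .unmix import MixtureModel, PeakObservation, assemble_model

SOURCE_PHAFFIA = "P. rhodozyma"
SOURCE_HAEMATOCOCCUS = "H. pluvialis"
SOURCE_SYNTHETIC = "synthetic"
REFERENCE_SOURCES = (SOURCE_PHAFFIA, SOURCE_HAEMATOCOCCUS, SOURCE_SYNTHETIC)

# Single-source reference peak areas (mAU·s) per stereoisomer channel.
_FINGERPRINT_AREAS: dict[str, dict[str, float]] = {
    SOURCE_PHAFFIA: {CHANNEL_SR: 55.87, CHANNEL_RR: 789.90},
    SOURCE_HAEMATOCOCCUS: {CHANNEL_SS: 640.53, CHANNEL_SR: 222.55},
    SOURCE_SYNTHETIC: {CHANNEL_SS: 405.19, CHANNEL_SR: 828.27, CHANNEL_RR: 415.65},
}

# The seven calibration curves: (source, channel) -> (slope a, intercept b).
_CURVE_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    (SOURCE_PHAFFIA, CHANNEL_SR): (2.3151, -0.4045),
    (SOURCE_PHAFFIA, CHANNEL_RR): (32.543, -7.7618),
    (SOURCE_HAEMATOCOCCUS, CHANNEL_SS): (26.12, -5.6712),
    (SOURCE_HAEMATOCOCCUS, CHANNEL_SR): (9.4757, -1.489),
    (SOURCE_SYNTHETIC, CHANNEL_SS): (16.595, 1.6309),
    (SOURCE_SYNTHETIC, CHANNEL_SR): (34.198, -0.4557),
    (SOURCE_SYNTHETIC, CHANNEL_RR): (17.259, -2.9307),
}

# Verification mixtures: spiked concentrations (µg/mL) per source, then
# observed mean and SD channel areas (mAU·s) in elution order, n = 3.
_VERIFICATION_ROWS: list[tuple[tuple[float, float, float],
                               tuple[float, float, float],
                               tuple[float, float, float]]] = [
    ((25, 5, 5), (215.80, 272.68, 861.04), (11.16, 9.21, 69.41)),
    ((25, 25, 25), (1084.81, 1189.62, 1211.06), (12.72, 32.78, 41.44)),
    ((25, 75, 100), (3706.90, 4376.76, 2641.15), (111.08, 11.01, 110.07)),
    ((10, 25, 10), (804.46, 601.49, 472.68), (16.58, 15.88, 15.82)),
    ((30, 25, 15), (879.53, 818.29, 1174.93), (15.09, 15.26, 43.63)),
    ((50, 75, 25), (2429.42, 1825.07, 2179.89), (49.13, 7.79, 19.12)),
    ((100, 50, 25), (1846.67, 1787.07, 3829.39), (29.74, 5.19, 18.43)),
]


@dataclass(frozen=True)
class VerificationMixture:
    """One spiked validation mixture: known truth plus observed areas."""

    mixture_id: str
    actual: Mapping[str, float]  # µg/mL per source
    observation: PeakObservation


def reference_curves() -> list[CalibrationCurve]:
    """The seven packaged calibration curves, in source then elution order."""
    curves = []
    for src in REFERENCE_SOURCES:
        for (s, chan), (a, b) in _CURVE_PARAMS.items():
            if s == src:
                curves.append(
                    CalibrationCurve(
                        source_id=src,
                        channel_id=chan,
                        slope_a=a,
                        intercept_b=b,
                        r_squared=None,  # reported only as > 0.999
                        valid_range=ANALYTICAL_RANGE_UG_PER_ML,
                    )
                )
    return curves


def reference_profiles() -> list[SourceProfile]:
    curves = reference_curves()
    return [
        SourceProfile(src, tuple(c for c in curves if c.source_id == src))
        for src in REFERENCE_SOURCES
    ]


def reference_model() -> MixtureModel:
    """The fully parameterized three-source mixture model."""
    return assemble_model(reference_profiles())


def reference_fingerprints() -> dict[str, IsomerFingerprint]:
    """Normalized stereoisomer fingerprints of the three sources."""
    return {
        src: normalize_fingerprint(areas, source_id=src)
        for src, areas in _FINGERPRINT_AREAS.items()
    }


def reference_verification_mixtures() -> list[VerificationMixture]:
    """The seven spiked mixtures used to validate the model."""
    out = []
    for idx, (actual, means, sds) in enumerate(_VERIFICATION_ROWS, start=1):
        chans = reference_model().channel_order
        out.append(
            VerificationMixture(
                mixture_id=f"mix{idx}",
                actual=dict(zip(REFERENCE_SOURCES, map(float, actual))),
                observation=PeakObservation(
                    channel_totals=dict(zip(chans, means)),
                    sd=dict(zip(chans, sds)),
                    mixture_id=f"mix{idx}",
                ),
            )
        )
    return out


def reference_noise_cv() -> dict[str, float]:
    """Per-channel replicate coefficient of variation of the packaged
    verification table (mean of SD/mean over the seven mixtures).

    These are the noise magnitudes the synthetic module uses by default,
    so simulations match the replicate scatter of the real validation
    experiment (roughly 1–8% of the mean area per channel).
    """
    mixtures = reference_verification_mixtures()
    chans = mixtures[0].observation.channel_totals.keys()
    cv: dict[str, float] = {}
    for c in chans:
        ratios = [
            m.observation.sd[c] / m.observation.channel_totals[c] for m in mixtures
        ]
        cv[c] = float(np.mean(ratios))
    return cv
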