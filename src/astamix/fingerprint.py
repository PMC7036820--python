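"""Stereoisomer fingerprints of single astaxanthin sources.

Each source distributes its total peak area over the three stereoisomer
channels in a fixed ratio — e.g. yeast (*Phaffia rhodozyma*) astaxanthin is
dominated by (3R,3'R) with a small (3S,3'R) fraction (~14:1), algal
(*Haematococcus pluvialis*) astaxanthin by (3S,3'S) over (3S,3'R) (~3:1),
and chemical synthesis produces (3S,3'S):(3S,3'R):(3R,3'R) near 1:2:1.
These fingerprints are what makes source apportionment possible: channels
overlap between sources, but the ratios per source are constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .channels import CHANNELS, canonical_channel
from .errors import InputError, UndefinedRatioError


@dataclass(frozen=True)
class IsomerFingerprint:
    """A source's stereoisomer composition.

    ``channel_areas`` holds the raw single-source reference peak areas
    (mAU·s) on each of the three channels (0 where the source produces no
    peak); ``normalized_ratio`` holds the same composition as fractions
    summing to one.
    """

    source_id: str
    channel_areas: Mapping[str, float]
    normalized_ratio: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.normalized_ratio.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"normalized ratios must sum to 1, got {total}")


def normalize_fingerprint(
    channel_areas: Mapping[str, float], *, source_id: str = ""
) -> IsomerFingerprint:
    """Build a fingerprint from raw channel areas.

    Channels missing from the mapping are taken as zero; at least one
    area must be positive.
    """
    areas = {c: 0.0 for c in CHANNELS}
    for label, area in channel_areas.items():
        area = float(area)
        if not math.isfinite(area) or area < 0:
            raise InputError(f"peak area must be finite and non-negative, got {area}")
        areas[canonical_channel(label)] = area
    total = sum(areas.values())
    if total <= 0:
        raise InputError("fingerprint requires at least one positive channel area")
    fractions = {c: a / total for c, a in areas.items()}
    return IsomerFingerprint(source_id=source_id, channel_areas=areas,
                             normalized_ratio=fractions)


def area_ratio(
    fingerprint: IsomerFingerprint, channel_num: str, channel_den: str
) -> float:
    """Ratio of raw peak areas between two channels of one source.

    This is the continuous analogue of the "15:1" / "3:1" / "1:2:1" style
    composition statements used to describe sources.
    """
    num = fingerprint.channel_areas.get(canonical_channel(channel_num), 0.0)
    den = fingerprint.channel_areas.get(canonical_channel(channel_den), 0.0)
    if den <= 0:
        raise UndefinedRatioError(
            f"denominator channel {channel_den!r} has zero area for source"
            f" {fingerprint.source_id!r}"
        )
    return num / den
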