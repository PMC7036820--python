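"""Stereoisomer channel identities and chromatographic metadata.

Astaxanthin carries stereogenic carbons at C3 and C3', giving two
enantiomers, (3S,3'S) and (3R,3'R), plus the meso (3S,3'R) form.  On the
chiral column used throughout this package the three configurations elute
as three baseline-resolved peaks, in the fixed order

    (3S,3'S)  <  (3S,3'R)  <  (3R,3'R)

at roughly 10.23, 11.81 and 13.64 minutes.  Every module orders channels
by this elution order; :data:`CHANNELS` is the single authority.
"""

from __future__ import annotations

from .errors import InputError

#: Canonical channel labels in elution order.
CHANNEL_SS = "3S,3'S"
CHANNEL_SR = "3S,3'R"
CHANNEL_RR = "3R,3'R"
CHANNELS: tuple[str, str, str] = (CHANNEL_SS, CHANNEL_SR, CHANNEL_RR)

#: Retention time of each stereoisomer peak on the chiral column, minutes.
RETENTION_TIMES_MIN: dict[str, float] = {
    CHANNEL_SS: 10.23,
    CHANNEL_SR: 11.81,
    CHANNEL_RR: 13.64,
}

#: Concentration interval over which the calibrated model is declared
#: valid, µg/mL.
ANALYTICAL_RANGE_UG_PER_ML: tuple[float, float] = (5.0, 100.0)

#: VWD detection wavelength, nm (provenance metadata only).
DETECTION_WAVELENGTH_NM = 476.0

# Accepted spellings for each channel.  Unicode primes, parentheses and
# whitespace are stripped before lookup.
_ALIASES: dict[str, str] = {
    "3S,3'S": CHANNEL_SS,
    "3S3'S": CHANNEL_SS,
    "SS": CHANNEL_SS,
    "S,S": CHANNEL_SS,
    "LEVO": CHANNEL_SS,
    "3S,3'R": CHANNEL_SR,
    "3S3'R": CHANNEL_SR,
    "SR": CHANNEL_SR,
    "S,R": CHANNEL_SR,
    "MESO": CHANNEL_SR,
    "3R,3'R": CHANNEL_RR,
    "3R3'R": CHANNEL_RR,
    "RR": CHANNEL_RR,
    "R,R": CHANNEL_RR,
    "DEXTRO": CHANNEL_RR,
}


def canonical_channel(label: str) -> str:
    """Map a user-supplied stereoisomer label to its canonical form.

    Raises
    ------
    InputError
        If the label does not name one of the three channels.
    """
    cleaned = (
        str(label)
        .strip()
        .replace("′", "'")  # prime -> apostrophe
        .replace("(", "")
        .replace(")", "")
        .replace(" ", "")
        .upper()
    )
    try:
        return _ALIASES[cleaned]
    except KeyError:
        raise InputError(
            f"unknown stereoisomer channel {label!r}; expected one of {CHANNELS}"
        ) from None
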