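"""10–20 montage and QEEG band definitions.

Channel order follows the Mitsar/WinEEG convention, in which the occipital
electrodes precede the lateral frontal/temporal chain.  This ordering is what
gives the numeric feature names their meaning: feature ``"15d"`` is the
fifteenth electrode (T5) in the delta band, ``"2a"`` is FP2 in alpha, and so
on.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical 19-channel 10–20 montage (1-based positions name the features).
CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "FZ", "CZ", "PZ",
)


@dataclass(frozen=True)
class Band:
    """A frequency band with its one-letter (or two-letter) name code."""

    name: str
    low: float   # Hz, inclusive
    high: float  # Hz, inclusive
    code: str

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges {self.low}–{self.high} Hz")


#: The five QEEG bands used throughout: delta, theta, alpha, beta, high beta.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 3.5, "d"),
    Band("theta", 4.0, 7.5, "t"),
    Band("alpha", 8.0, 12.0, "a"),
    Band("beta", 12.5, 25.0, "b"),
    Band("high_beta", 25.5, 30.0, "hb"),
)

_BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}
_BAND_BY_CODE = {b.code: b for b in DEFAULT_BANDS}


def band_by_name(name: str) -> Band:
    try:
        return _BAND_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; known: {sorted(_BAND_BY_NAME)}") from None


def channel_index(label: str, channels: tuple[str, ...] = CHANNELS) -> int:
    """0-based index of a channel label (case-insensitive)."""
    try:
        return [c.upper() for c in channels].index(label.upper())
    except ValueError:
        raise KeyError(f"unknown channel {label!r}") from None


def feature_id(channel: str, band: Band, channels: tuple[str, ...] = CHANNELS) -> str:
    """Numeric feature name, e.g. ``("T5", delta) -> "15d"``."""
    return f"{channel_index(channel, channels) + 1}{band.code}"


def parse_feature_id(fid: str, channels: tuple[str, ...] = CHANNELS) -> tuple[str, Band]:
    """Invert :func:`feature_id`: ``"15d" -> ("T5", delta)``."""
    i = 0
    while i < len(fid) and fid[i].isdigit():
        i += 1
    num, code = fid[:i], fid[i:]
    if not num or code not in _BAND_BY_CODE:
        raise ValueError(f"malformed feature id {fid!r}")
    pos = int(num)
    if not 1 <= pos <= len(channels):
        raise ValueError(f"feature id {fid!r}: channel number out of range")
    return channels[pos - 1], _BAND_BY_CODE[code]
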