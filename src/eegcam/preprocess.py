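"""Band-pass filtering, amplitude screening, and epoch extraction.

The analysis band is 1–30 Hz, applied as a zero-phase (forward-backward)
Butterworth band-pass of order 2 per pass — a 12 dB/octave roll-off per pass,
24 dB/octave effective.  Amplitude screening rejects epochs whose slow-wave
(< 8 Hz) peak exceeds 50 µV or whose fast-wave (>= 8 Hz) peak exceeds 30 µV,
thresholds based on normal alpha/beta amplitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal

from .synth import EEGSession, TurnEvent

logger = logging.getLogger(__name__)


@dataclass
class Epoch:
    """A fixed-length labeled segment of multichannel EEG around a turn event."""

    data: np.ndarray                 # (n_channels, n_samples), µV
    fs: float
    label: str                       # "LEFT" | "RIGHT"
    event: TurnEvent | None = None
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("epoch data must be a non-empty channels × samples matrix")
        if self.label not in ("LEFT", "RIGHT"):
            raise ValueError(f"label must be LEFT or RIGHT, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def bandpass(
    session: EEGSession,
    low: float = 1.0,
    high: float = 30.0,
    order: int = 2,
    zero_phase: bool = True,
) -> EEGSession:
    """Butterworth band-pass per channel; zero-phase via forward-backward pass.

    ``order`` is the per-pass filter order (2 -> 12 dB/octave per pass).
    Events and metadata are preserved.
    """
    if not 0 < low < high < session.fs / 2:
        raise ValueError(f"band edges {low}-{high} Hz invalid for fs={session.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", output="sos",
                        fs=session.fs)
    out = session.copy()
    if zero_phase:
        out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    else:
        out.data = signal.sosfilt(sos, out.data, axis=1)
    return out


def _split_slow_fast(data: np.ndarray, fs: float, split: float,
                     order: int = 4) -> tuple[np.ndarray, np.ndarray]:
    sos_lo = signal.butter(order, split, btype="lowpass", output="sos", fs=fs)
    sos_hi = signal.butter(order, split, btype="highpass", output="sos", fs=fs)
    slow = signal.sosfiltfilt(sos_lo, data, axis=1)
    fast = signal.sosfiltfilt(sos_hi, data, axis=1)
    return slow, fast


def amplitude_screen(
    epoch: Epoch,
    slow_max: float = 50.0,
    fast_max: float = 30.0,
    split: float = 8.0,
) -> bool:
    """True = keep.  Reject when any channel's slow (< split Hz) peak exceeds
    ``slow_max`` µV or its fast (>= split Hz) peak exceeds ``fast_max`` µV."""
    if slow_max <= 0 or fast_max <= 0:
        raise ValueError("thresholds must be positive")
    if epoch.n_samples < 10:
        raise ValueError("epoch too short to screen")
    slow, fast = _split_slow_fast(epoch.data, epoch.fs, split)
    return bool(np.abs(slow).max() <= slow_max and np.abs(fast).max() <= fast_max)


def extract_epochs(
    session: EEGSession,
    window: tuple[float, float] = (0.0, 5.0),
) -> list[Epoch]:
    """One labeled epoch per turn event, spanning [onset - pre, onset + post).

    Events whose window exceeds the recording bounds are skipped with a log
    message.  Raises when the session has no events at all.
    """
    if not session.events:
        raise ValueError("session has no turn events")
    pre_s, post_s = window
    pre = int(round(pre_s * session.fs))
    post = int(round(post_s * session.fs))
    if pre + post <= 0:
        raise ValueError("window must span at least one sample")
    epochs = []
    for ev in session.events:
        i0, i1 = ev.onset_sample - pre, ev.onset_sample + post
        if i0 < 0 or i1 > session.n_samples:
            logger.warning("skipping %s event at sample %d: window [%d, %d) "
                           "outside recording", ev.direction, ev.onset_sample, i0, i1)
            continue
        epochs.append(Epoch(session.data[:, i0:i1], session.fs, ev.direction,
                            event=ev, channel_labels=session.channel_labels))
    return epochs


def screen_epochs(
    epochs: list[Epoch],
    slow_max: float = 50.0,
    fast_max: float = 30.0,
    split: float = 8.0,
) -> tuple[list[Epoch], int]:
    """Apply :func:`amplitude_screen` to a list; returns (kept, n_rejected)."""
    kept = [e for e in epochs if amplitude_screen(e, slow_max, fast_max, split)]
    n_rej = len(epochs) - len(kept)
    if n_rej:
        logger.info("amplitude screening rejected %d of %d epochs", n_rej, len(epochs))
    return kept, n_rej


def ica_hook(
    session: EEGSession,
    transform: Callable[[EEGSession], EEGSession] | None = None,
) -> EEGSession:
    """Pass-through slot for an external artifact-removal step.

    Synthetic sessions are generated clean (or with transients that amplitude
    screening removes), so the default is the identity; a caller may supply
    any session -> session callable.
    """
    return session if transform is None else transform(session)
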