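"""QEEG feature extraction: FFT absolute band power and time-domain means.

The basic feature is the *absolute power* of a channel within a frequency
band, estimated from a single rectangular-window periodogram of the whole
epoch.  The periodogram is normalized so that the sum over all frequency bins
equals the mean square of the (mean-removed) signal — Parseval's identity
holds exactly, which the test-suite exploits as an oracle.  Units are µV².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Band, DEFAULT_BANDS, feature_id
from .preprocess import Epoch
from .synth import EEGSession


def band_power(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] | Band,
    window: str = "boxcar",
) -> float:
    """Absolute power (µV²) of ``x`` in ``band`` = [low, high] Hz, inclusive.

    The signal mean is removed first (DC lies outside every band).  A bin
    belongs to the band when its center frequency lies in the closed interval
    [low, high].  With the default rectangular window the one-sided
    periodogram sums to ``mean((x - mean(x))**2)`` to machine precision.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("band_power expects a 1-D signal of length >= 2")
    low, high = (band.low, band.high) if isinstance(band, Band) else band
    if not 0 <= low < high < fs / 2:
        raise ValueError(f"band {low}-{high} Hz outside (0, Nyquist={fs / 2}) range")
    n = x.size
    if window == "boxcar":
        xw = x - x.mean()
        norm = n * n
    elif window == "hann":
        w = np.hanning(n)
        xw = (x - x.mean()) * w
        norm = np.sum(w**2) * n  # asymptotically unbiased power normalization
    else:
        raise ValueError(f"unknown window {window!r}")
    spec = np.abs(np.fft.rfft(xw)) ** 2 / norm
    # one-sided doubling; DC and (for even n) Nyquist appear once
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)
    return float(spec[mask].sum())


@dataclass
class FeatureMatrix:
    """Epochs × (channel, band) absolute-power table with class labels."""

    values: np.ndarray                  # (n_epochs, n_features), µV²
    feature_ids: list[str]              # numeric names, e.g. "15d"
    labels: np.ndarray                  # per-epoch "LEFT" / "RIGHT"
    channels: tuple[str, ...] = field(default_factory=tuple)
    bands: tuple[Band, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (epochs × features)")
        if self.values.shape[0] != self.labels.size:
            raise ValueError("one label per epoch required")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("one feature id per column required")
        if (self.values < 0).any():
            raise ValueError("absolute powers must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def columns(self, ids: list[str]) -> np.ndarray:
        idx = [self.feature_ids.index(f) for f in ids]
        return self.values[:, idx]

    def restrict(self, ids: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.columns(ids), list(ids), self.labels,
                             self.channels, self.bands)

    def band_feature_ids(self, band_name: str) -> list[str]:
        code = {b.name: b.code for b in self.bands}[band_name]
        return [f for f in self.feature_ids if f.lstrip("0123456789") == code]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        labels = df["label"].to_numpy()
        vals = df.drop(columns=["label"])
        return cls(vals.to_numpy(dtype=float), list(vals.columns), labels)


def build_feature_matrix(
    epochs: list[Epoch],
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    window: str = "boxcar",
) -> FeatureMatrix:
    """One row per epoch, one column per (channel, band), channel-major order.

    With the full 19-channel montage and the five default bands this yields
    the 95-column candidate feature set.
    """
    if not epochs:
        raise ValueError("no epochs given")
    lengths = {e.data.shape for e in epochs}
    if len(lengths) != 1:
        raise ValueError(f"ragged epochs: shapes {sorted(lengths)}")
    channels = epochs[0].channel_labels
    ids = [feature_id(ch, b, channels) for ch in channels for b in bands]
    rows = np.empty((len(epochs), len(ids)))
    for r, ep in enumerate(epochs):
        k = 0
        for c in range(len(channels)):
            for b in bands:
                rows[r, k] = band_power(ep.data[c], ep.fs, b, window=window)
                k += 1
    labels = np.array([e.label for e in epochs])
    return FeatureMatrix(rows, ids, labels, channels, bands)


def time_domain_means(
    session: EEGSession,
    per_class_duration: float = 50.0,
    epoch_window: tuple[float, float] = (0.0, 5.0),
) -> dict[str, np.ndarray]:
    """Per-class per-electrode mean over ``per_class_duration`` s of signal.

    Concatenates the turn-locked signal of each class (in event order) and
    averages the first ``per_class_duration`` seconds per electrode.  At
    500 Hz and 50 s the averaged segment is 19 × 25000.
    """
    from .preprocess import extract_epochs  # local import avoids cycle at import time

    need = int(round(per_class_duration * session.fs))
    pools = class_signal_pools(session, epoch_window)
    out: dict[str, np.ndarray] = {}
    for label, pool in pools.items():
        if pool.shape[1] < need:
            raise ValueError(
                f"class {label}: only {pool.shape[1] / session.fs:.1f} s of labeled "
                f"signal, need {per_class_duration} s"
            )
        out[label] = pool[:, :need].mean(axis=1)
    return out


def class_signal_pools(
    session: EEGSession,
    epoch_window: tuple[float, float] = (0.0, 5.0),
) -> dict[str, np.ndarray]:
    """Concatenate each class's turn-locked samples into one channels × n block."""
    from .preprocess import extract_epochs

    epochs = extract_epochs(session, epoch_window)
    out: dict[str, np.ndarray] = {}
    for label in ("LEFT", "RIGHT"):
        segs = [e.data for e in epochs if e.label == label]
        if not segs:
            raise ValueError(f"no {label} epochs in session")
        out[label] = np.concatenate(segs, axis=1)
    return out
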