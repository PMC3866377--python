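"""Seeded synthetic driving-EEG sessions.

The study conditions these sessions emulate: a 5-minute simulator drive at
500 Hz on the 19-channel 10–20 montage, four laps each containing four left
and four right turns (32 turn events, 16 per direction), and three behavioral
groups of subjects whose band-power signatures differ.  A subject's group
determines which (channel, band) powers are elevated during left- versus
right-turn maneuvers; the generator plants those effects as narrowband bursts
on top of broadband noise so that every downstream stage — filtering, band
power, t-ranking, Hopfield classification — has a recoverable ground truth.

Everything is deterministic given ``(config, subject_id, seed)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import CHANNELS, Band, DEFAULT_BANDS, band_by_name, channel_index

LEFT = "LEFT"
RIGHT = "RIGHT"
DIRECTIONS = (LEFT, RIGHT)

#: Default behavioral-group signatures: (group, direction, channel, band,
#: power multiplier).  During a turn of the stated direction, the stated
#: channel's band power is raised to ``multiplier`` times its baseline.
#: Group 1 elevates FP2/O1 delta when turning right; group 2 elevates F7
#: delta right and P3 delta left; group 3 elevates FP2/P3/T4 delta left.
DEFAULT_SIGNATURES: tuple[tuple[str, str, str, str, float], ...] = (
    ("G1", RIGHT, "FP2", "delta", 5.0),
    ("G1", RIGHT, "O1", "delta", 5.0),
    ("G2", RIGHT, "F7", "delta", 5.0),
    ("G2", LEFT, "P3", "delta", 5.0),
    ("G3", LEFT, "FP2", "delta", 5.0),
    ("G3", LEFT, "P3", "delta", 5.0),
    ("G3", LEFT, "T4", "delta", 5.0),
)

#: Default ten-subject cohort: five in group 1, two in group 2, three in
#: group 3 (the observed cohort composition).
DEFAULT_GROUPS: dict[str, str] = {
    "s01": "G1", "s02": "G1", "s05": "G1", "s08": "G1", "s10": "G1",
    "s03": "G2", "s06": "G2",
    "s04": "G3", "s07": "G3", "s09": "G3",
}


class SchedulingError(ValueError):
    """The session is too short to space the requested turn events."""


@dataclass(frozen=True)
class TurnEvent:
    onset_sample: int
    direction: str
    lap: int

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be LEFT or RIGHT, got {self.direction!r}")
        if self.onset_sample < 0:
            raise ValueError("onset_sample must be non-negative")


@dataclass
class EEGSession:
    """Multichannel µV time series with sampling rate, labels and turn events."""

    data: np.ndarray                    # (n_channels, n_samples), µV
    fs: float
    channel_labels: tuple[str, ...]
    events: list[TurnEvent] = field(default_factory=list)
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} labels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for ev in self.events:
            if not 0 <= ev.onset_sample < self.n_samples:
                raise ValueError(f"event onset {ev.onset_sample} outside session")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGSession":
        return EEGSession(self.data.copy(), self.fs, self.channel_labels,
                          list(self.events), self.subject_id, self.group)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults reproduce the study layout."""

    n_subjects: int = 10
    group_assignment: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    laps: int = 4
    turns_per_direction_per_lap: int = 4
    fs: float = 500.0
    channel_labels: tuple[str, ...] = CHANNELS
    session_duration: float = 300.0
    band_signatures: tuple[tuple[str, str, str, str, float], ...] = DEFAULT_SIGNATURES
    noise_sd: float = 10.0              # µV, broadband background
    pink_noise: bool = False            # 1/f amplitude shaping toggle
    artifact_rate: float = 0.0          # large-transient events per minute
    epoch_length: float = 5.0           # s, turn-maneuver window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.laps < 0 or self.turns_per_direction_per_lap < 0:
            raise ValueError("laps and turns per lap must be >= 0")
        if self.fs <= 0 or self.session_duration <= 0 or self.epoch_length <= 0:
            raise ValueError("fs, session_duration and epoch_length must be positive")
        if self.noise_sd < 0 or self.artifact_rate < 0:
            raise ValueError("noise_sd and artifact_rate must be >= 0")
        labels = {c.upper() for c in self.channel_labels}
        bands = {b.name for b in DEFAULT_BANDS}
        for group, direction, channel, band, mult in self.band_signatures:
            if direction not in DIRECTIONS:
                raise ValueError(f"signature direction {direction!r} invalid")
            if channel.upper() not in labels:
                raise ValueError(f"signature channel {channel!r} not in montage")
            if band not in bands:
                raise ValueError(f"signature band {band!r} unknown")
            if mult <= 0:
                raise ValueError("signature multipliers must be > 0")

    def subjects(self) -> list[str]:
        return sorted(self.group_assignment)[: self.n_subjects]


def event_schedule(
    laps: int,
    turns_per_direction_per_lap: int,
    session_duration: float,
    fs: float,
    min_slot: float = 1.0,
) -> list[TurnEvent]:
    """Evenly spaced, direction-alternating turn schedule.

    The session is divided into ``laps × 2 × turns_per_direction_per_lap``
    equal slots; each slot holds one turn onset at one quarter of the slot,
    alternating LEFT/RIGHT so every lap is balanced.  Raises
    :class:`SchedulingError` when slots would be shorter than ``min_slot``
    seconds.
    """
    if laps < 0 or turns_per_direction_per_lap < 0:
        raise ValueError("laps and turns per lap must be >= 0")
    n_events = laps * 2 * turns_per_direction_per_lap
    if n_events == 0:
        return []
    slot = session_duration / n_events
    if slot < min_slot:
        raise SchedulingError(
            f"{n_events} events do not fit in {session_duration} s "
            f"(slot {slot:.2f} s < {min_slot} s)"
        )
    events = []
    per_lap = 2 * turns_per_direction_per_lap
    for k in range(n_events):
        onset = int(round((k + 0.25) * slot * fs))
        direction = DIRECTIONS[k % 2]
        events.append(TurnEvent(onset, direction, lap=k // per_lap))
    return events


def inject_band_burst(
    session: EEGSession,
    channel: str,
    center_freq: float,
    window: tuple[float, float],
    amplitude: float,
    phase: float = 0.0,
) -> EEGSession:
    """Add a sinusoidal burst on one channel inside ``window`` = (start_s, end_s).

    Returns a new session; every sample outside the named channel/window is
    bit-identical to the input.  A burst of amplitude A contributes A²/2 to
    the matching band's absolute power over the window.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    start_s, end_s = window
    if not 0 <= start_s < end_s <= session.duration + 1e-9:
        raise ValueError(f"window {window} outside session of {session.duration} s")
    ci = channel_index(channel, session.channel_labels)
    out = session.copy()
    i0 = int(round(start_s * session.fs))
    i1 = min(int(round(end_s * session.fs)), session.n_samples)
    t = np.arange(i1 - i0) / session.fs
    out.data[ci, i0:i1] += amplitude * np.sin(2 * np.pi * center_freq * t + phase)
    return out


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(subject_id.encode("utf8"))])
    )


def _background(rng: np.random.Generator, n_ch: int, n: int, sd: float,
                pink: bool) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, size=(n_ch, n))
    if pink and n > 2:
        spec = np.fft.rfft(noise, axis=1)
        f = np.fft.rfftfreq(n)
        shaping = np.ones_like(f)
        nz = f > 0
        shaping[nz] = 1.0 / np.sqrt(f[nz] / f[nz].min())
        spec *= shaping
        noise = np.fft.irfft(spec, n=n, axis=1)
        noise /= noise.std(axis=1, keepdims=True)
    return sd * noise


def generate_session(
    cfg: GeneratorConfig,
    subject_id: str,
    seed: int | None = None,
) -> EEGSession:
    """Simulate one subject's session; deterministic in (cfg, subject_id, seed).

    Background noise is i.i.d. Gaussian per channel/sample (optionally 1/f
    shaped); each turn event receives the subject's group signatures as
    band-center sinusoidal bursts over ``[onset, onset + epoch_length]``,
    with burst amplitude chosen so the window's band power is the signature's
    multiplier times the measured pre-burst baseline.
    """
    from .features import band_power  # deferred: features imports this module

    seed = cfg.seed if seed is None else seed
    try:
        group = cfg.group_assignment[subject_id]
    except KeyError:
        raise KeyError(f"subject {subject_id!r} has no group assignment") from None
    rng = _subject_rng(seed, subject_id)
    n = int(round(cfg.session_duration * cfg.fs))
    n_ch = len(cfg.channel_labels)

    data = (np.zeros((n_ch, n)) if cfg.noise_sd == 0
            else _background(rng, n_ch, n, cfg.noise_sd, cfg.pink_noise))

    base = event_schedule(cfg.laps, cfg.turns_per_direction_per_lap,
                          cfg.session_duration, cfg.fs)
    n_events = len(base)
    events: list[TurnEvent] = []
    if n_events:
        slot = cfg.session_duration / n_events
        jitter_max = max(int(0.1 * slot * cfg.fs), 0)
        max_onset = n - int(cfg.epoch_length * cfg.fs) - 1
        for ev in base:
            j = int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max else 0
            onset = int(np.clip(ev.onset_sample + j, 0, max_onset))
            events.append(TurnEvent(onset, ev.direction, ev.lap))

    session = EEGSession(data, cfg.fs, cfg.channel_labels, events,
                         subject_id=subject_id, group=group)

    # Burst amplitude targets multiplier × the channel's *baseline* band power,
    # with the baseline measured once over the whole pre-burst session (so the
    # planted oscillation has a fixed amplitude per event instead of tracking
    # the local noise power of each 5 s window).
    sigs = [s for s in cfg.band_signatures if s[0] == group]
    baselines: dict[tuple[int, str], float] = {}
    for _, _, channel, band_name, _ in sigs:
        ci = channel_index(channel, cfg.channel_labels)
        if (ci, band_name) not in baselines and n >= 2:
            baselines[(ci, band_name)] = band_power(
                session.data[ci], cfg.fs, band_by_name(band_name))
    for ev in events:
        start_s = ev.onset_sample / cfg.fs
        end_s = min(start_s + cfg.epoch_length, cfg.session_duration)
        for _, direction, channel, band_name, mult in sigs:
            if direction != ev.direction or mult == 1.0:
                continue
            band = band_by_name(band_name)
            ci = channel_index(channel, cfg.channel_labels)
            baseline = baselines.get((ci, band_name), 0.0)
            amplitude = float(np.sqrt(2.0 * max(mult - 1.0, 0.0) * baseline))
            if amplitude == 0.0:
                continue
            session = inject_band_burst(
                session, channel, (band.low + band.high) / 2.0,
                (start_s, end_s), amplitude,
                phase=float(rng.uniform(0, 2 * np.pi)),
            )

    if cfg.artifact_rate > 0:
        n_art = rng.poisson(cfg.artifact_rate * cfg.session_duration / 60.0)
        for _ in range(n_art):
            t0 = float(rng.uniform(0, cfg.session_duration - 0.5))
            ch = cfg.channel_labels[int(rng.integers(0, n_ch))]
            session = inject_band_burst(session, ch, 2.0, (t0, t0 + 0.5), 120.0)

    return session


def generate_cohort(cfg: GeneratorConfig, seed: int | None = None) -> list[EEGSession]:
    """One session per configured subject, each independently seeded."""
    return [generate_session(cfg, sid, seed) for sid in cfg.subjects()]
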