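"""Scalar feature selection and bipolar binarization.

Features are ranked by the absolute value of a two-sample t statistic between
the LEFT and RIGHT epoch groups (Welch form; the p-value is reported
descriptively, no multiple-testing correction — ranking, not testing).  A
two-stage variant ranks channels and bands separately by aggregated |t| and
keeps the cross product, e.g. 7 channels × 2 bands = 14 of 95 features.

Binarization centers every selected feature on its cross-epoch mean and maps
the sign to ±1 (sign(0) -> +1, the one global tie rule).  Class prototypes
are class-mean feature vectors binarized against the same means, and
positions where the two prototypes agree carry no class information — they
are pruned, leaving the "effective neurons".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import FeatureMatrix


class NoDiscriminativeFeaturesError(ValueError):
    """Both class prototypes are identical: nothing to classify with."""


@dataclass(frozen=True)
class RankedFeature:
    feature_id: str
    t_abs: float
    p_value: float
    rank: int  # 1-based, by |t| descending


@dataclass
class BipolarPattern:
    """Fixed-length ±1 vector, optionally class-labeled."""

    bits: np.ndarray
    label: str | None = None
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.ndim != 1:
            raise ValueError("bits must be a vector")
        if not np.isin(self.bits, (-1, 1)).all():
            raise ValueError("pattern entries must be -1 or +1")
        if self.feature_ids and len(self.feature_ids) != self.bits.size:
            raise ValueError("feature_ids must align with bits")

    def __len__(self) -> int:
        return self.bits.size

    def hamming(self, other: "BipolarPattern") -> int:
        return int(np.sum(self.bits != other.bits))


def sign_pm1(x: np.ndarray) -> np.ndarray:
    """Elementwise sign with sign(0) -> +1."""
    return np.where(np.asarray(x) >= 0, 1, -1)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Welch t statistic and p-value; degenerate cases -> t = 0."""
    with warnings.catch_warnings():
        # near-constant features trip scipy's precision warning; they are
        # handled below by the t = 0 convention
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(t):
        return 0.0, 1.0
    return float(t), float(p)


def rank_features(fm: FeatureMatrix) -> list[RankedFeature]:
    """Rank every feature by |t| between the two classes, descending.

    Ties (and all ordering) are broken stably by column position.
    """
    classes = np.unique(fm.labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    a = fm.values[fm.labels == classes[0]]
    b = fm.values[fm.labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 epochs per class for a t statistic")
    scored = []
    for j, fid in enumerate(fm.feature_ids):
        t, p = welch_t(a[:, j], b[:, j])
        scored.append((abs(t), p, j, fid))
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][0], scored[i][2]))
    return [
        RankedFeature(scored[i][3], scored[i][0], scored[i][1], rank=r + 1)
        for r, i in enumerate(order)
    ]


def _aggregate(ranked: list[RankedFeature], key_of, agg: str) -> dict[str, float]:
    groups: dict[str, list[float]] = {}
    for rf in ranked:
        groups.setdefault(key_of(rf.feature_id), []).append(rf.t_abs)
    f = np.mean if agg == "mean" else np.max
    return {k: float(f(v)) for k, v in groups.items()}


def two_stage_select(
    ranked: list[RankedFeature],
    n_channels: int = 7,
    n_bands: int = 2,
    agg: str = "mean",
) -> list[str]:
    """Pick channels and bands separately by aggregated |t|; keep the cross product.

    Channels are scored by ``agg`` of |t| over their bands and bands over
    their channels ("mean" or "max"); the returned ids are ordered
    channel-major, both dimensions by score descending (ties by first
    appearance).  The result has exactly ``n_channels × n_bands`` ids.
    """
    if not ranked:
        raise ValueError("empty ranking")
    if agg not in ("mean", "max"):
        raise ValueError("agg must be 'mean' or 'max'")

    def chan(fid: str) -> str:
        return "".join(c for c in fid if c.isdigit())

    def band(fid: str) -> str:
        return fid.lstrip("0123456789")

    first_seen: dict[str, int] = {}
    for i, rf in enumerate(ranked):
        for k in (chan(rf.feature_id), band(rf.feature_id)):
            first_seen.setdefault(k, i)
    chan_scores = _aggregate(ranked, chan, agg)
    band_scores = _aggregate(ranked, band, agg)
    if n_channels > len(chan_scores) or n_bands > len(band_scores):
        raise ValueError("cannot select more channels/bands than exist")
    top = lambda scores, n: sorted(scores, key=lambda k: (-scores[k], first_seen[k]))[:n]
    channels = top(chan_scores, n_channels)
    bands = top(band_scores, n_bands)
    available = {rf.feature_id for rf in ranked}
    ids = [f"{c}{b}" for c in channels for b in bands]
    missing = [f for f in ids if f not in available]
    if missing:
        raise ValueError(f"selected ids absent from ranking: {missing}")
    return ids


def scalar_select(
    ranked: list[RankedFeature],
    alpha: float = 1e-3,
    n_min: int = 2,
    n_max: int | None = None,
) -> list[str]:
    """Keep features whose t-test p-value clears ``alpha``; reject the rest.

    The direct scalar rule — high-|t| features are chosen, others rejected —
    with guard rails: at least ``n_min`` features (topped up by rank when the
    threshold passes fewer, e.g. on a signal-free subject) and at most
    ``n_max``.
    """
    if not ranked:
        raise ValueError("empty ranking")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    chosen = [rf.feature_id for rf in ranked if rf.p_value <= alpha]
    if len(chosen) < n_min:
        chosen = [rf.feature_id for rf in ranked[:n_min]]
    if n_max is not None:
        chosen = chosen[:n_max]
    return chosen


@dataclass
class Binarizer:
    """Centering-then-sign binarization fit on one (training) feature matrix.

    Stores per-feature means so held-out epochs are binarized with training
    statistics only.
    """

    feature_ids: list[str]
    means: np.ndarray
    prototypes: dict[str, BipolarPattern]

    @classmethod
    def fit(cls, fm: FeatureMatrix, selected: list[str]) -> "Binarizer":
        if not selected:
            raise ValueError("empty feature selection")
        vals = fm.columns(selected)
        means = vals.mean(axis=0)
        protos = {}
        for label in np.unique(fm.labels):
            class_mean = vals[fm.labels == label].mean(axis=0)
            protos[str(label)] = BipolarPattern(
                sign_pm1(class_mean - means), label=str(label),
                feature_ids=list(selected),
            )
        return cls(list(selected), means, protos)

    def transform(self, fm: FeatureMatrix) -> list[BipolarPattern]:
        vals = fm.columns(self.feature_ids)
        return [
            BipolarPattern(sign_pm1(row - self.means), label=str(lbl),
                           feature_ids=self.feature_ids)
            for row, lbl in zip(vals, fm.labels)
        ]


def binarize(
    fm: FeatureMatrix, selected: list[str]
) -> tuple[list[BipolarPattern], dict[str, BipolarPattern]]:
    """Per-epoch ±1 patterns plus per-class prototypes over ``selected``."""
    bz = Binarizer.fit(fm, selected)
    return bz.transform(fm), bz.prototypes


def prune_constant(
    proto_a: BipolarPattern, proto_b: BipolarPattern
) -> tuple[np.ndarray, list[str]]:
    """Positions (and ids, when present) where the two class prototypes differ.

    These are the effective neurons; positions with the same value in both
    states are redundant.  Raises when the prototypes are identical.
    """
    if len(proto_a) != len(proto_b):
        raise ValueError("prototypes must have equal length")
    keep = np.nonzero(proto_a.bits != proto_b.bits)[0]
    if keep.size == 0:
        raise NoDiscriminativeFeaturesError(
            "class prototypes are identical at every position"
        )
    ids = [proto_a.feature_ids[i] for i in keep] if proto_a.feature_ids else []
    return keep, ids


def restrict_pattern(p: BipolarPattern, keep: np.ndarray) -> BipolarPattern:
    ids = [p.feature_ids[i] for i in keep] if p.feature_ids else []
    return BipolarPattern(p.bits[keep], label=p.label, feature_ids=ids)
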