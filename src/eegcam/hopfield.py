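"""Hopfield content-addressable memory over bipolar patterns.

Hebbian outer-product training builds a symmetric, zero-diagonal integer
weight matrix W with w_ij = Σ_p x_i^(p) x_j^(p); neuron thresholds T default
to zero.  A neuron's update is sign(Σ_j w_ij x_j − T_i) with sign(0) -> +1.
Two schedules are provided: asynchronous (seeded random order, one neuron at
a time — every update is non-increasing in the energy
E = −½ Σ_{i≠j} w_ij x_i x_j + Σ_i T_i x_i) and synchronous (all neurons at
once, the matrix form sign(Wx − T), which can enter 2-cycles).  Recall
iterates full sweeps until stable or a 40-sweep cap; classification reads
out the stored label nearest the final state in Hamming distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .report import PerformanceReport
from .selection import BipolarPattern, sign_pm1

INDETERMINATE = None


@dataclass
class HopfieldNetwork:
    W: np.ndarray                         # (n, n) int, symmetric, zero diagonal
    T: np.ndarray                         # (n,) thresholds
    stored: list[BipolarPattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        self.T = np.asarray(self.T, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if not np.array_equal(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal")
        if self.T.shape != (self.W.shape[0],):
            raise ValueError("T must have one threshold per neuron")
        for p in self.stored:
            if len(p) != self.n:
                raise ValueError("stored pattern length must equal neuron count")

    @property
    def n(self) -> int:
        return self.W.shape[0]


def train(patterns: list[BipolarPattern]) -> HopfieldNetwork:
    """Hebbian outer-product rule; weights are exact integer sums."""
    if not patterns:
        raise ValueError("need at least one pattern")
    n = len(patterns[0])
    if any(len(p) != n for p in patterns):
        raise ValueError("all patterns must have the same length")
    W = np.zeros((n, n), dtype=int)
    for p in patterns:
        W += np.outer(p.bits, p.bits)
    np.fill_diagonal(W, 0)
    return HopfieldNetwork(W, np.zeros(n), stored=list(patterns))


def _as_bits(state: BipolarPattern | np.ndarray, n: int) -> np.ndarray:
    bits = state.bits if isinstance(state, BipolarPattern) else np.asarray(state, int)
    if bits.shape != (n,):
        raise ValueError(f"state length {bits.size} != network size {n}")
    return bits.copy()


def update_state(
    net: HopfieldNetwork,
    state: BipolarPattern | np.ndarray,
    schedule: str = "async",
    rng: np.random.Generator | int | None = None,
) -> BipolarPattern:
    """One full update step: a synchronous step or one asynchronous sweep."""
    x = _as_bits(state, net.n)
    if schedule == "sync":
        x = sign_pm1(net.W @ x - net.T)
    elif schedule == "async":
        rng = np.random.default_rng(rng)
        for i in rng.permutation(net.n):
            x[i] = 1 if net.W[i] @ x - net.T[i] >= 0 else -1
    else:
        raise ValueError("schedule must be 'sync' or 'async'")
    return BipolarPattern(x)


def energy(net: HopfieldNetwork, state: BipolarPattern | np.ndarray) -> float:
    """E = −½ Σ_{i≠j} w_ij x_i x_j + Σ_i T_i x_i (diagonal is zero)."""
    x = _as_bits(state, net.n)
    return float(-0.5 * x @ net.W @ x + net.T @ x)


@dataclass
class RecallResult:
    final_state: BipolarPattern
    converged: bool
    n_iterations: int
    energy_trace: list[float]


def recall(
    net: HopfieldNetwork,
    probe: BipolarPattern | np.ndarray,
    max_iter: int = 40,
    schedule: str = "async",
    rng: np.random.Generator | int | None = None,
) -> RecallResult:
    """Iterate update sweeps until a sweep changes nothing or ``max_iter``.

    The energy trace holds E before the first sweep and after each sweep;
    under the asynchronous schedule it is non-increasing.
    """
    rng = np.random.default_rng(rng)
    x = _as_bits(probe, net.n)
    trace = [energy(net, x)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nxt = update_state(net, x, schedule=schedule, rng=rng).bits
        trace.append(energy(net, nxt))
        if np.array_equal(nxt, x):
            converged = True
            break
        x = nxt
    return RecallResult(BipolarPattern(x), converged, it, trace)


def classify(
    net: HopfieldNetwork,
    probe: BipolarPattern | np.ndarray,
    max_iter: int = 40,
    schedule: str = "async",
    rng: np.random.Generator | int | None = None,
) -> str | None:
    """Recall, then return the label of the nearest stored pattern.

    An exact Hamming-distance tie between differently labeled stored
    patterns is indeterminate (returns ``None``).
    """
    if not net.stored:
        raise ValueError("network has no stored patterns to read out")
    final = recall(net, probe, max_iter=max_iter, schedule=schedule, rng=rng).final_state
    dists = np.array([final.hamming(p) for p in net.stored])
    best = np.nonzero(dists == dists.min())[0]
    labels = {net.stored[i].label for i in best}
    return net.stored[best[0]].label if len(labels) == 1 else INDETERMINATE


def distort(
    pattern: BipolarPattern,
    fraction: float,
    rng: np.random.Generator | int | None = None,
) -> BipolarPattern:
    """Flip exactly ``rint(fraction·n)`` distinct, uniformly chosen positions.

    Rounding is to the nearest integer, ties to even (so 15% of 6 bits flips
    round(0.9) = 1 bit).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    n = len(pattern)
    k = int(np.rint(fraction * n))
    bits = pattern.bits.copy()
    if k:
        idx = rng.choice(n, size=k, replace=False)
        bits[idx] *= -1
    return BipolarPattern(bits, label=pattern.label, feature_ids=list(pattern.feature_ids))


def distortion_experiment(
    net: HopfieldNetwork,
    fraction: float,
    n_trials: int = 20,
    seed: int | None = None,
    schedule: str = "sync",
    max_iter: int = 40,
) -> PerformanceReport:
    """Distort every stored pattern, recall, and score, ``n_trials`` times.

    Per probe two scores are kept: pattern-level (the recalled state is
    strictly nearest its own source pattern) and bit-level (fraction of
    final-state bits matching the source).  ``accuracy`` reports the former,
    ``bit_accuracy`` the latter; the mean error is 1 − bit_accuracy.  The
    default schedule is the synchronous matrix-form update used in the
    distortion-recall benchmark; significance is an exact binomial test of
    the total matched bits against chance 0.5.
    """
    if not net.stored:
        raise ValueError("network has no stored patterns")
    rng = np.random.default_rng(seed)
    per_trial_bits: list[float] = []
    pattern_hits = 0
    bit_hits = 0
    n_bits = 0
    for _ in range(n_trials):
        trial_bits = []
        for p in net.stored:
            probe = distort(p, fraction, rng)
            final = recall(net, probe, max_iter=max_iter, schedule=schedule,
                           rng=rng).final_state
            match = np.mean(final.bits == p.bits)
            trial_bits.append(match)
            bit_hits += int(np.sum(final.bits == p.bits))
            n_bits += len(p)
            dists = np.array([final.hamming(q) for q in net.stored])
            d_self = final.hamming(p)
            if d_self == dists.min() and (dists == d_self).sum() == 1:
                pattern_hits += 1
        per_trial_bits.append(float(np.mean(trial_bits)))
    n_probes = n_trials * len(net.stored)
    p_binom = float(stats.binomtest(bit_hits, n_bits, 0.5,
                                    alternative="greater").pvalue)
    return PerformanceReport(
        accuracy=pattern_hits / n_probes,
        bit_accuracy=bit_hits / n_bits,
        per_repeat=per_trial_bits,
        n_train=len(net.stored),
        n_test=n_probes,
        seed=seed,
        significance=p_binom,
        notes={"fraction": fraction, "schedule": schedule, "max_iter": max_iter},
    )
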