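"""The four experiments: time-domain baseline, band-wise classification,
group-pattern network, and per-subject Monte-Carlo cross-validation.

Each experiment builds a two-stable-point (or six, for the group network)
Hebbian Hopfield net from class prototypes, prunes the neurons that carry the
same value in both states, and reads test patterns out through recall +
nearest-Hamming labeling.  Selection, binarization statistics and pruning are
always fit on training data only.  Significance is reported from an exact
binomial test against chance 0.5 (optionally a label-permutation test)
rather than a parametric ANOVA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
from scipy import stats

from .features import FeatureMatrix, build_feature_matrix, class_signal_pools
from .hopfield import HopfieldNetwork, classify, train
from .preprocess import bandpass, extract_epochs, screen_epochs
from .report import PerformanceReport
from .selection import (
    Binarizer,
    BipolarPattern,
    prune_constant,
    rank_features,
    restrict_pattern,
    scalar_select,
    sign_pm1,
    two_stage_select,
)
from .synth import EEGSession, GeneratorConfig, generate_session

logger = logging.getLogger(__name__)


def _binomial_p(hits: int, n: int) -> float:
    return float(stats.binomtest(hits, n, 0.5, alternative="greater").pvalue)


def _classify_patterns(
    net: HopfieldNetwork,
    probes: list[BipolarPattern],
    rng: np.random.Generator,
) -> tuple[int, list[str | None]]:
    """Count probes whose read-out label matches their own; ties count as misses."""
    hits = 0
    out = []
    for p in probes:
        label = classify(net, p, rng=rng)
        out.append(label)
        hits += int(label == p.label)
    return hits, out


def _prototype_net(
    prototypes: dict[str, BipolarPattern]
) -> tuple[HopfieldNetwork, np.ndarray]:
    labels = sorted(prototypes)
    if len(labels) != 2:
        raise ValueError(f"expected two class prototypes, got {labels}")
    keep, _ = prune_constant(prototypes[labels[0]], prototypes[labels[1]])
    pruned = [restrict_pattern(prototypes[l], keep) for l in labels]
    return train(pruned), keep


def time_domain_baseline(
    session: EEGSession,
    seed: int | None = None,
    per_class_duration: float = 50.0,
    n_test_per_class: int = 10,
    test_segment: float = 5.0,
    epoch_window: tuple[float, float] = (0.0, 5.0),
) -> PerformanceReport:
    """Classify raw per-electrode mean amplitudes with a 2-prototype net.

    For each class, ``per_class_duration`` seconds of turn-locked signal are
    averaged per electrode (19 × 25000 samples at the defaults), the two
    19×1 class means are centered on their joint mean and binarized to ±1,
    constant positions are pruned, and a Hebbian net with two stable points
    is trained.  Test probes are ``n_test_per_class`` seeded sub-segment
    means per class, binarized with the same centers.
    """
    rng = np.random.default_rng(seed)
    pools = class_signal_pools(session, epoch_window)
    labels = sorted(pools)
    need = int(round(per_class_duration * session.fs))
    for l in labels:
        if pools[l].shape[1] < need:
            raise ValueError(f"class {l}: need {per_class_duration} s of signal")
    class_means = {l: pools[l][:, :need].mean(axis=1) for l in labels}
    center = np.mean([class_means[l] for l in labels], axis=0)
    prototypes = {
        l: BipolarPattern(sign_pm1(class_means[l] - center), label=l)
        for l in labels
    }
    net, keep = _prototype_net(prototypes)

    seg = int(round(test_segment * session.fs))
    probes = []
    for l in labels:
        pool = pools[l]
        starts = rng.integers(0, pool.shape[1] - seg + 1, size=n_test_per_class)
        for s in starts:
            v = pool[:, s:s + seg].mean(axis=1)
            probes.append(BipolarPattern(sign_pm1(v - center)[keep], label=l))
    hits, _ = _classify_patterns(net, probes, rng)
    n = len(probes)
    return PerformanceReport(
        accuracy=hits / n, n_train=2, n_test=n, seed=seed,
        significance=_binomial_p(hits, n),
        notes={"experiment": "time_domain", "effective_neurons": int(keep.size)},
    )


def bandwise_classification(
    fm: FeatureMatrix,
    band: str,
    seed: int | None = None,
) -> PerformanceReport:
    """Two-prototype classification restricted to a single band's channels.

    Mirrors the band-by-band table: the report notes the band, the number of
    effective neurons after pruning, and the accuracy over all epoch
    patterns.
    """
    ids = fm.band_feature_ids(band)
    if not ids:
        raise KeyError(f"band {band!r} has no features in this matrix")
    rng = np.random.default_rng(seed)
    sub = fm.restrict(ids)
    bz = Binarizer.fit(sub, ids)
    net, keep = _prototype_net(bz.prototypes)
    probes = [restrict_pattern(p, keep) for p in bz.transform(sub)]
    hits, _ = _classify_patterns(net, probes, rng)
    n = len(probes)
    return PerformanceReport(
        accuracy=hits / n, n_train=2, n_test=n, seed=seed,
        significance=_binomial_p(hits, n),
        notes={"experiment": "bandwise", "band": band,
               "effective_neurons": int(keep.size)},
    )


def selected_classification(
    fm: FeatureMatrix,
    seed: int | None = None,
    n_select_channels: int = 7,
    n_select_bands: int = 2,
) -> PerformanceReport:
    """Two-prototype classification on the two-stage-selected feature subset.

    Same in-sample protocol as :func:`bandwise_classification` (prototypes
    and test patterns from the same epochs) so the two rungs of the
    experiment ladder are directly comparable; the default selection is the
    7 channels × 2 bands = 14-feature set.
    """
    rng = np.random.default_rng(seed)
    selected = two_stage_select(rank_features(fm), n_select_channels, n_select_bands)
    bz = Binarizer.fit(fm, selected)
    net, keep = _prototype_net(bz.prototypes)
    probes = [restrict_pattern(p, keep) for p in bz.transform(fm)]
    hits, _ = _classify_patterns(net, probes, rng)
    n = len(probes)
    return PerformanceReport(
        accuracy=hits / n, n_train=2, n_test=n, seed=seed,
        significance=_binomial_p(hits, n),
        notes={"experiment": "selected", "selected_features": selected,
               "effective_neurons": int(keep.size)},
    )


def group_patterns(
    subject_prototypes: list[tuple[str, str, BipolarPattern]],
) -> list[BipolarPattern]:
    """Majority-vote the per-subject prototypes into 3 × 2 labeled patterns.

    ``subject_prototypes`` holds (group, direction, pattern) triples over a
    common feature set.  Every (group, direction) cell must be populated;
    ties follow sign(0) -> +1.  Duplicate stable points across cells raise a
    warning — they cannot be told apart at read-out.
    """
    cells: dict[tuple[str, str], list[np.ndarray]] = {}
    ids: list[str] = []
    for group, direction, p in subject_prototypes:
        cells.setdefault((group, direction), []).append(p.bits)
        ids = ids or list(p.feature_ids)
    groups = sorted({g for g, _ in cells})
    directions = sorted({d for _, d in cells})
    if len(groups) != 3 or len(directions) != 2:
        raise ValueError(f"need 3 groups × 2 directions, got {groups} × {directions}")
    out = []
    for g in groups:
        for d in directions:
            if (g, d) not in cells:
                raise ValueError(f"missing prototypes for cell ({g}, {d})")
            vote = np.sum(cells[(g, d)], axis=0)
            out.append(BipolarPattern(sign_pm1(vote), label=f"{g}-{d}",
                                      feature_ids=list(ids)))
    seen: dict[bytes, str] = {}
    for p in out:
        key = p.bits.tobytes()
        if key in seen:
            warnings.warn(f"duplicate stable point: {p.label} equals {seen[key]}",
                          stacklevel=2)
        else:
            seen[key] = p.label
    return out


def monte_carlo_cv(
    fm: FeatureMatrix,
    train_frac: float = 0.7,
    n_repeats: int = 10,
    n_select_channels: int = 7,
    n_select_bands: int = 2,
    seed: int | None = None,
    max_redraws: int = 20,
    selection: str = "two_stage",
    alpha: float = 1e-3,
) -> PerformanceReport:
    """Random sub-sampling cross-validation of the selection + Hopfield flow.

    Per repeat: a seeded stratified ``train_frac`` split; t-ranking,
    selection, binarization and pruning fit on the training split only; the
    test epochs are binarized with training statistics and read out through
    the two-prototype net.  ``selection`` is either ``"two_stage"``
    (``n_select_channels × n_select_bands`` cross product) or ``"scalar"``
    (every feature with p ≤ ``alpha``).  Splits that would leave a class
    empty are re-drawn (logged).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.unique(fm.labels)
    if labels.size != 2:
        raise ValueError("need exactly two classes")
    per_repeat = []
    total_hits = 0
    total_tests = 0
    selected_per_repeat: list[list[str]] = []
    train_indices: list[list[int]] = []
    for _ in range(n_repeats):
        for attempt in range(max_redraws):
            train_idx, test_idx = [], []
            for l in labels:
                idx = np.nonzero(fm.labels == l)[0]
                idx = rng.permutation(idx)
                k = int(round(train_frac * idx.size))
                train_idx.extend(idx[:k])
                test_idx.extend(idx[k:])
            if (len(test_idx) >= 2 and len(train_idx) >= 4
                    and all((fm.labels[train_idx] == l).sum() >= 2 for l in labels)
                    and all((fm.labels[test_idx] == l).any() for l in labels)):
                break
            logger.info("re-drawing split (attempt %d): a class was empty", attempt + 1)
        else:
            raise ValueError("could not draw a split with both classes present")
        train_fm = FeatureMatrix(fm.values[train_idx], fm.feature_ids,
                                 fm.labels[train_idx], fm.channels, fm.bands)
        test_fm = FeatureMatrix(fm.values[test_idx], fm.feature_ids,
                                fm.labels[test_idx], fm.channels, fm.bands)
        ranked = rank_features(train_fm)
        if selection == "two_stage":
            selected = two_stage_select(ranked, n_select_channels, n_select_bands)
        elif selection == "scalar":
            selected = scalar_select(ranked, alpha=alpha)
        else:
            raise ValueError("selection must be 'two_stage' or 'scalar'")
        selected_per_repeat.append(selected)
        train_indices.append(sorted(int(i) for i in train_idx))
        bz = Binarizer.fit(train_fm, selected)
        net, keep = _prototype_net(bz.prototypes)
        probes = [restrict_pattern(p, keep) for p in bz.transform(test_fm)]
        hits, _ = _classify_patterns(net, probes, rng)
        per_repeat.append(hits / len(probes))
        total_hits += hits
        total_tests += len(probes)
    return PerformanceReport(
        accuracy=float(np.mean(per_repeat)),
        per_repeat=per_repeat,
        n_train=len(train_idx), n_test=len(test_idx), seed=seed,
        significance=_binomial_p(total_hits, total_tests),
        notes={"experiment": "monte_carlo_cv",
               "selected_features": selected_per_repeat,
               "train_indices": train_indices},
    )


def subject_pipeline(
    session: EEGSession,
    seed: int | None = None,
    low: float = 1.0,
    high: float = 30.0,
    epoch_window: tuple[float, float] = (0.0, 5.0),
    n_per_class: int = 10,
    train_frac: float = 0.7,
    n_repeats: int = 10,
    selection: str = "scalar",
    alpha: float = 1e-3,
    n_select_channels: int = 7,
    n_select_bands: int = 2,
    slow_max: float = 50.0,
    fast_max: float = 30.0,
) -> PerformanceReport:
    """Full per-subject flow: filter, epoch, screen, features, Monte-Carlo CV.

    After amplitude screening the first ``n_per_class`` surviving epochs per
    class are taken (deterministically, in event order), mirroring the
    10 + 10 artifact-free turnings per subject.  Per-subject selection
    defaults to the scalar p ≤ ``alpha`` rule: individual turn responses are
    sparse (a few channels in one band), and a lean selection keeps noise
    bits out of the bipolar code.
    """
    filtered = bandpass(session, low, high)
    epochs = extract_epochs(filtered, epoch_window)
    kept, n_rej = screen_epochs(epochs, slow_max, fast_max)
    chosen = []
    for label in ("LEFT", "RIGHT"):
        cls = [e for e in kept if e.label == label]
        if len(cls) < n_per_class:
            raise ValueError(
                f"subject {session.subject_id}: only {len(cls)} {label} epochs "
                f"survive screening, need {n_per_class}"
            )
        chosen.extend(cls[:n_per_class])
    fm = build_feature_matrix(chosen)
    rep = monte_carlo_cv(fm, train_frac, n_repeats, n_select_channels,
                         n_select_bands, seed=seed, selection=selection,
                         alpha=alpha)
    rep.notes.update(subject_id=session.subject_id, group=session.group,
                     epochs_rejected=n_rej)
    return rep


def permutation_significance(
    fm: FeatureMatrix,
    observed_accuracy: float,
    n_permutations: int = 50,
    seed: int | None = None,
    **cv_kwargs,
) -> float:
    """Label-permutation null for a Monte-Carlo CV accuracy."""
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_permutations):
        perm = FeatureMatrix(fm.values, fm.feature_ids,
                             rng.permutation(fm.labels), fm.channels, fm.bands)
        null.append(monte_carlo_cv(perm, seed=int(rng.integers(2**31)),
                                   **cv_kwargs).accuracy)
    null = np.asarray(null)
    return float((1 + np.sum(null >= observed_accuracy)) / (1 + null.size))


def study_progression(
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
    subjects: list[str] | None = None,
) -> dict[str, float]:
    """Run the experiment ladder on one synthetic cohort.

    Returns mean accuracies for the time-domain baseline, the best single
    band on pooled features, pooled feature-selected CV, and the per-subject
    pipeline — the progression the study reports from worst to best.
    """
    cfg = cfg or GeneratorConfig()
    subjects = subjects or cfg.subjects()
    sessions = [generate_session(cfg, sid, seed) for sid in subjects]
    filtered = [bandpass(s) for s in sessions]
    window = (0.0, cfg.epoch_length)
    fms = [build_feature_matrix(extract_epochs(s, window)) for s in filtered]
    pooled = FeatureMatrix(
        np.vstack([f.values for f in fms]), fms[0].feature_ids,
        np.concatenate([f.labels for f in fms]), fms[0].channels, fms[0].bands,
    )
    td = float(np.mean([
        time_domain_baseline(s, seed=seed + i).accuracy
        for i, s in enumerate(filtered)
    ]))
    band_accs = {b.name: bandwise_classification(pooled, b.name, seed=seed).accuracy
                 for b in pooled.bands}
    pooled_sel = selected_classification(pooled, seed=seed).accuracy
    per_subject = float(np.mean([
        subject_pipeline(s, seed=seed + i).accuracy
        for i, s in enumerate(sessions)
    ]))
    return {
        "time_domain": td,
        "best_band": max(band_accs.values()),
        "band_accuracies": band_accs,
        "selected_pooled": pooled_sel,
        "per_subject": per_subject,
    }
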