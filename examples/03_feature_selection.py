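"""Rank features by |t|, select, binarize to bipolar codes, prune.

The scalar criterion ranks every (channel, band) power by the absolute
two-sample t statistic between left- and right-turn epochs.  The two-stage
variant picks top channels and top bands separately and keeps the cross
product (7 x 2 = 14 of 95); binarization centers each kept feature and maps
signs to +/-1, and positions equal in both class prototypes are pruned.
"""

from eegcam import (
    GeneratorConfig,
    bandpass,
    binarize,
    build_feature_matrix,
    extract_epochs,
    generate_session,
    prune_constant,
    rank_features,
    two_stage_select,
)

cfg = GeneratorConfig()
session = generate_session(cfg, "s01", seed=1)
fm = build_feature_matrix(extract_epochs(bandpass(session), (0.0, 5.0)))

ranked = rank_features(fm)
print("top five features by |t|:")
for r in ranked[:5]:
    print(f"  rank {r.rank}: {r.feature_id:>4s}  |t| = {r.t_abs:5.2f}  "
          f"p = {r.p_value:.2e}")

selected = two_stage_select(ranked, n_channels=7, n_bands=2)
print(f"two-stage selection (7 channels x 2 bands): {len(selected)} features")
print("  " + " ".join(selected))

patterns, prototypes = binarize(fm, selected)
keep, kept_ids = prune_constant(prototypes["LEFT"], prototypes["RIGHT"])
print(f"LEFT  prototype: {prototypes['LEFT'].bits}")
print(f"RIGHT prototype: {prototypes['RIGHT'].bits}")
print(f"effective neurons after pruning: {len(keep)} ({' '.join(kept_ids)})")
print("only positions that differ between the prototypes carry class information")
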