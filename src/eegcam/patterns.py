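"""Synthetic six-pattern group/direction fixture.

The group-level distortion benchmark stores one bipolar pattern per
(behavioral group, turn direction) cell — six stable points over six
selected features.  The original bit values are not available, so the
patterns here are a *synthetic reconstruction* from the described group
behaviors over the delta-band features of the seven selected channels:

========  =======  ====================================================
feature   channel  elevated (+1) in
========  =======  ====================================================
2d        FP2      G1-RIGHT, G3-LEFT
15d       T5       (no direction effect described; tie rule gives +1)
7d        P3       G2-LEFT, G3-LEFT
9d        O1       G1-RIGHT
14d       T4       G3-LEFT
11d       F7       G2-RIGHT
========  =======  ====================================================

A bit is +1 where the cell's band power is elevated above the pooled mean,
−1 otherwise; ties follow the global sign(0) -> +1 rule.
"""

from __future__ import annotations

import numpy as np

from .selection import BipolarPattern

GROUP_FEATURE_IDS: list[str] = ["2d", "15d", "7d", "9d", "14d", "11d"]

_BITS: dict[tuple[str, str], list[int]] = {
    ("G1", "LEFT"):  [-1, +1, -1, -1, -1, -1],
    ("G1", "RIGHT"): [+1, +1, -1, +1, -1, -1],
    ("G2", "LEFT"):  [-1, +1, +1, -1, -1, -1],
    ("G2", "RIGHT"): [-1, +1, -1, -1, -1, +1],
    ("G3", "LEFT"):  [+1, +1, +1, -1, +1, -1],
    ("G3", "RIGHT"): [-1, +1, -1, -1, -1, -1],
}


def synthetic_group_prototypes() -> list[BipolarPattern]:
    """The six labeled group/direction patterns (synthetic reconstruction)."""
    return [
        BipolarPattern(np.array(bits), label=f"{g}-{d}",
                       feature_ids=list(GROUP_FEATURE_IDS))
        for (g, d), bits in _BITS.items()
    ]
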