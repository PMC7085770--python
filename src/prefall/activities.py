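"""Canonical activity vocabulary: 14 ADLs and 6 fall types.

ADLs marked highly dynamic are those whose peak raw acceleration SVM
exceeds 2 g; the remainder are less-dynamic.  Forward-facing falls are
excluded by design (the hip does not strike the ground), so every fall
type is backward or lateral.
"""

from __future__ import annotations

ADL_ACTIVITIES: tuple[str, ...] = (
    "walking",
    "jogging",
    "squatting",
    "waist_bending",
    "lying_down",
    "running_in_place",
    "jumping",
    "stairs",
    "slow_sit_stool",
    "quick_sit_chair",
    "collapse_chair",
    "stumble_walking",
    "slow_sit_mattress",
    "quick_sit_mattress",
)

FALL_ACTIVITIES: tuple[str, ...] = (
    "slip_backward_fall",
    "sitdown_backward_fall",
    "sit_backward_fall",
    "backward_fall",
    "lateral_fall",
    "twist_fall",
)

#: ADLs whose peak raw acceleration SVM exceeds 2 g
HIGHLY_DYNAMIC: frozenset[str] = frozenset(
    {
        "jogging",
        "running_in_place",
        "jumping",
        "quick_sit_chair",
        "collapse_chair",
        "stumble_walking",
        "quick_sit_mattress",
    }
)

ALL_ACTIVITIES: tuple[str, ...] = ADL_ACTIVITIES + FALL_ACTIVITIES
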