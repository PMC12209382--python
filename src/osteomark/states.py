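"""Health states and fracture sites.

The model tracks eight health states: well, four acute fracture states
(hip, vertebral, wrist, other), two post-fracture states (post-hip,
post-vertebral) and dead.  Fracture sites are ordered by a severity
hierarchy (impact on quality of life and cost): hip > vertebral >
wrist > other.
"""

from __future__ import annotations

from enum import IntEnum


class FractureSite(IntEnum):
    """Osteoporotic fracture sites, ordered by severity (lower = more severe)."""

    HIP = 0
    VERTEBRAL = 1
    WRIST = 2
    OTHER = 3

    @property
    def label(self) -> str:
        return SITES[self.value]


#: Canonical site order used for all per-site arrays (severity order).
SITES = ("hip", "vertebral", "wrist", "other")
SITE_INDEX = {name: i for i, name in enumerate(SITES)}


class HealthState(IntEnum):
    """Markov health states.  DEAD is absorbing and tracked as cumulative mass."""

    WELL = 0
    HIP_FX = 1
    VERT_FX = 2
    WRIST_FX = 3
    OTHER_FX = 4
    POST_HIP = 5
    POST_VERT = 6
    DEAD = 7


#: Alive states carried in the occupancy array.
N_ALIVE_STATES = 7

#: States implying a fracture history (prior-fracture relative risk applies).
FRACTURE_HISTORY_STATES = (
    HealthState.HIP_FX,
    HealthState.VERT_FX,
    HealthState.WRIST_FX,
    HealthState.OTHER_FX,
    HealthState.POST_HIP,
    HealthState.POST_VERT,
)

#: Prior-vertebral-fracture flag values for the occupancy array.
VF_NONE = 0       # no vertebral fracture history
VF_PREVALENT = 1  # vertebral fracture present at model entry
VF_INCIDENT = 2   # vertebral fracture sustained during the simulation
N_VF_FLAGS = 3
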