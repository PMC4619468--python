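"""Joint numbering and connection map of the 20-joint skeleton model.

The depth-sensor skeleton tracker reports 20 named joints per frame.  All
indices are 1-based throughout the public API (files, logs, errors) so that
they can be compared directly with the standard joint table.  "Left/right"
follow the image convention of the sensor, not the subject's body; no
mirroring is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

N_JOINTS = 20

#: 1-based joint index by name.
JOINT_INDEX = MappingProxyType({
    "hip centre": 1,
    "spine": 2,
    "shoulder centre": 3,
    "head": 4,
    "shoulder left": 5,
    "elbow left": 6,
    "wrist left": 7,
    "hand left": 8,
    "shoulder right": 9,
    "elbow right": 10,
    "wrist right": 11,
    "hand right": 12,
    "hip left": 13,
    "knee left": 14,
    "ankle left": 15,
    "foot left": 16,
    "hip right": 17,
    "knee right": 18,
    "ankle right": 19,
    "foot right": 20,
})

#: Connection vectors (pairs of 1-based joint indices) grouped by body part.
CONNECTIONS = MappingProxyType({
    "spine": ((1, 2), (2, 3), (3, 4)),
    "left hand": ((3, 5), (5, 6), (6, 7), (7, 8)),
    "right hand": ((3, 9), (9, 10), (10, 11), (11, 12)),
    "left leg": ((1, 13), (13, 14), (14, 15), (15, 16)),
    "right leg": ((1, 17), (17, 18), (18, 19), (19, 20)),
})

# Joint pairs used for leg-length estimation (thigh and shank per side).
LEFT_THIGH = (13, 14)
LEFT_SHANK = (14, 15)
RIGHT_THIGH = (17, 18)
RIGHT_SHANK = (18, 19)

# Joints averaged into each "leg centre" for the inter-foot distance.
LEFT_FOOT_JOINTS = (15, 16)
RIGHT_FOOT_JOINTS = (19, 20)

# Torso joints averaged into the per-frame centre of mass.
COM_JOINTS = (1, 2, 3)


@dataclass(frozen=True)
class JointMap:
    """Bijective name<->index map plus the grouped connection vectors."""

    index: MappingProxyType
    connections: MappingProxyType

    def __post_init__(self) -> None:
        idx = sorted(self.index.values())
        if idx != list(range(1, N_JOINTS + 1)):
            raise ValueError("joint indices must be a permutation of 1..20")
        for group, pairs in self.connections.items():
            for a, b in pairs:
                if not (1 <= a <= N_JOINTS and 1 <= b <= N_JOINTS):
                    raise ValueError(
                        f"connection ({a},{b}) in group {group!r} "
                        "references an invalid joint index"
                    )

    def name_of(self, index: int) -> str:
        for name, i in self.index.items():
            if i == index:
                return name
        raise KeyError(index)

    def __getitem__(self, name: str) -> int:
        return self.index[name]


def joint_map() -> JointMap:
    """Return the fixed 20-joint map and connection vectors."""
    return JointMap(index=JOINT_INDEX, connections=CONNECTIONS)
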