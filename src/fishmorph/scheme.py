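"""Landmark schemes: which anatomical points a configuration contains.

A scheme fixes the number, order and names of the landmarks, which of them
form bilateral (left/right) pairs, and which internal coordinate axis plays
which anatomical role.  Internally every configuration is stored with

* axis 0 = anteroposterior (length),
* axis 1 = dorsoventral (depth),
* axis 2 = mediolateral (width),

so that per-axis variance sums decompose body-shape disparity directly into
length/depth/width components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ANTEROPOSTERIOR = "anteroposterior"
DORSOVENTRAL = "dorsoventral"
MEDIOLATERAL = "mediolateral"

#: the three anatomical axis roles, in internal axis order
AXIS_ROLES = (ANTEROPOSTERIOR, DORSOVENTRAL, MEDIOLATERAL)


@dataclass(frozen=True)
class LandmarkScheme:
    """An ordered set of named 3D landmarks.

    Parameters
    ----------
    landmark_names
        Ordered landmark names; configuration rows follow this order.
    landmark_numbers
        Integer labels conventionally attached to each landmark
        (placement-protocol numbering, not row order).
    bilateral_pairs
        ``(left_index, right_index)`` row-index pairs of landmarks that
        mirror each other across the midsagittal plane.
    axis_roles
        Mapping of internal axis index (0, 1, 2) to anatomical role; must
        be a bijection onto :data:`AXIS_ROLES`.
    """

    landmark_names: tuple[str, ...]
    landmark_numbers: tuple[int, ...]
    bilateral_pairs: tuple[tuple[int, int], ...] = ()
    axis_roles: dict[int, str] = field(
        default_factory=lambda: {0: ANTEROPOSTERIOR, 1: DORSOVENTRAL, 2: MEDIOLATERAL}
    )

    def __post_init__(self) -> None:
        p = len(self.landmark_names)
        if p < 3:
            raise ValueError(f"a scheme needs at least 3 landmarks, got {p}")
        if len(set(self.landmark_names)) != p:
            raise ValueError("landmark names must be unique")
        if len(self.landmark_numbers) != p:
            raise ValueError("landmark_numbers length must match landmark_names")
        for left, right in self.bilateral_pairs:
            if left == right or not (0 <= left < p and 0 <= right < p):
                raise ValueError(f"invalid bilateral pair ({left}, {right})")
        if sorted(self.axis_roles) != [0, 1, 2] or set(self.axis_roles.values()) != set(
            AXIS_ROLES
        ):
            raise ValueError("axis_roles must map axes 0,1,2 bijectively onto the roles")

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_names)

    def index_of(self, name: str) -> int:
        """Row index of a landmark name (exact match)."""
        try:
            return self.landmark_names.index(name)
        except ValueError:
            raise KeyError(f"landmark {name!r} not in scheme") from None

    def axis_for_role(self, role: str) -> int:
        """Internal axis index carrying an anatomical role."""
        for axis, r in self.axis_roles.items():
            if r == role:
                return axis
        raise KeyError(f"unknown axis role {role!r}")


def default_scheme() -> LandmarkScheme:
    """The 11-landmark fish body-shape scheme.

    Landmarks sit on major skeletal discontinuities — tip of snout, eyes,
    pectoral (P1) and pelvic (P2) fin insertions, dorsal-fin (DF) and
    anal-fin (AF) anterior insertions, and the posterior hypural margins —
    digitized on both sides of the body where paired.
    """
    names = (
        "Tip snout",
        "Left eye",
        "Left P1",
        "Left P2",
        "AF anterior insertion",
        "Left Hypural",
        "DF anterior insertion",
        "Right eye",
        "Right P1",
        "Right P2",
        "Right Hypural",
    )
    numbers = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)
    pairs = ((1, 7), (2, 8), (3, 9), (5, 10))
    return LandmarkScheme(names, numbers, pairs)
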