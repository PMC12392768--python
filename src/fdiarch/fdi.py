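"""FDI two-digit tooth notation: validation, mirroring and arch sequences.

The FDI (Fédération Dentaire Internationale) system codes each permanent
tooth as a two-digit integer: the first digit is the quadrant (1 upper
right, 2 upper left, 3 lower left, 4 lower right, from the patient's point
of view), the second the position from the midline (1 central incisor ...
8 third molar).  Everything downstream — the crop augmentation, the offset
prior and the dynamic program — works on the canonical left-to-right arch
sequences defined here.

Orientation convention used throughout the package: in the standardized
frame, +x is the patient-left side of the image (quadrants 2 and 3) and
-x the patient-right side (quadrants 1 and 4); anterior teeth sit toward
-y and the occlusal surfaces face +z.  Any consistent convention works
because pair offsets are learned in the same frame they are applied in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .errors import ValidationError

UPPER = "upper"
LOWER = "lower"

#: canonical left-to-right traversal of the upper arch (quadrant 1 then 2)
UPPER_SEQUENCE: Tuple[int, ...] = (
    18, 17, 16, 15, 14, 13, 12, 11, 21, 22, 23, 24, 25, 26, 27, 28,
)
#: canonical left-to-right traversal of the lower arch (quadrant 4 then 3)
LOWER_SEQUENCE: Tuple[int, ...] = (
    48, 47, 46, 45, 44, 43, 42, 41, 31, 32, 33, 34, 35, 36, 37, 38,
)

#: fixed 32-class label order used for logit vectors everywhere
ALL_LABELS: Tuple[int, ...] = UPPER_SEQUENCE + LOWER_SEQUENCE

_VALID = frozenset(ALL_LABELS)


def is_valid_fdi(value: int) -> bool:
    """True if ``value`` is a permanent-dentition FDI code (11-48)."""
    return value in _VALID


def validate_fdi(value: int) -> int:
    if value not in _VALID:
        raise ValidationError(
            f"{value!r} is not a valid FDI code (quadrant 1-4, position 1-8)"
        )
    return int(value)


def quadrant_position(label: int) -> Tuple[int, int]:
    """Decompose an FDI code into (quadrant, position)."""
    validate_fdi(label)
    return label // 10, label % 10


def mirror_fdi(label: int) -> int:
    """Reflect a label across the midline: quadrant 1<->2, 3<->4.

    The position digit is preserved, so e.g. 21 -> 11 and 16 -> 26.
    """
    quadrant, position = quadrant_position(label)
    mirrored_quadrant = {1: 2, 2: 1, 3: 4, 4: 3}[quadrant]
    return mirrored_quadrant * 10 + position


def arch_of(label: int) -> str:
    """Arch membership: quadrants 1, 2 -> upper; 3, 4 -> lower."""
    quadrant, _ = quadrant_position(label)
    return UPPER if quadrant in (1, 2) else LOWER


@dataclass(frozen=True)
class ArchSequence:
    """The 16 labels of one arch in spatial order along the dental arch.

    ``direction`` is "left-to-right" for the canonical traversal (quadrant
    1 -> 2 upper, 4 -> 3 lower) or "right-to-left" for its reversal.
    """

    arch: str
    labels: Tuple[int, ...]
    direction: str = "left-to-right"

    def __post_init__(self) -> None:
        if self.arch not in (UPPER, LOWER):
            raise ValidationError(f"unknown arch {self.arch!r}")
        if len(self.labels) != 16 or len(set(self.labels)) != 16:
            raise ValidationError("an arch sequence holds 16 distinct labels")
        for label in self.labels:
            if arch_of(label) != self.arch:
                raise ValidationError(f"label {label} not in {self.arch} arch")

    def index(self, label: int) -> int:
        return self.labels.index(label)

    def reversed(self) -> "ArchSequence":
        flipped = ("right-to-left" if self.direction == "left-to-right"
                   else "left-to-right")
        return ArchSequence(self.arch, tuple(reversed(self.labels)), flipped)


def arch_sequence(arch: str, reverse: bool = False) -> ArchSequence:
    """Canonical spatially continuous traversal of one arch.

    Upper: 18..11, 21..28.  Lower: 48..41, 31..38.  ``reverse=True``
    returns the right-to-left traversal.
    """
    if arch == UPPER:
        seq = ArchSequence(UPPER, UPPER_SEQUENCE)
    elif arch == LOWER:
        seq = ArchSequence(LOWER, LOWER_SEQUENCE)
    else:
        raise ValidationError(f"unknown arch {arch!r}")
    return seq.reversed() if reverse else seq
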