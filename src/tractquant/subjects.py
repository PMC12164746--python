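"""Study participants.

A :class:`SubjectRecord` carries everything the statistical layer needs to
know about one participant: diagnostic group, whether they were operated,
the side of the ictal onset zone (IOZ), the 1-year Engel outcome class and
basic demographics.  Engel class I is read as seizure freedom, classes
II-IV as seizure recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import ENGEL_CLASSES, GROUPS
from .errors import DataError


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str                     # control | FLE | TLE
    operated: bool = False
    ioz_side: str = "none"         # left | right | none
    engel_class: str = "none"      # I..IV | none
    age: float = float("nan")
    sex: str = "unknown"           # F | M | unknown
    epilepsy_duration: float = float("nan")
    timepoints_present: frozenset[str] = field(
        default_factory=lambda: frozenset({"pre"}))

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.group == "control":
            if (self.ioz_side != "none" or self.engel_class != "none"
                    or self.operated):
                raise DataError(
                    f"{self.subject_id}: controls must have ioz_side=none, "
                    "engel_class=none and operated=False")
        else:
            if self.ioz_side not in ("left", "right"):
                raise DataError(
                    f"{self.subject_id}: patient ioz_side must be left/right")
            if self.engel_class not in ENGEL_CLASSES + ("none",):
                raise DataError(
                    f"{self.subject_id}: bad engel_class {self.engel_class!r}")
            if self.engel_class != "none" and not self.operated:
                raise DataError(
                    f"{self.subject_id}: an Engel class implies surgery")

    @property
    def is_patient(self) -> bool:
        return self.group != "control"

    @property
    def seizure_free(self) -> bool:
        """Engel class I one year after surgery."""
        return self.engel_class == "I"

    @property
    def seizure_recurrence(self) -> bool:
        """Operated with Engel class II-IV."""
        return self.engel_class in ("II", "III", "IV")
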