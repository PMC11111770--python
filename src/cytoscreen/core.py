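"""Domain vocabulary for cervical cytology grading (TBS 2014).

Patch-level and slide-level grade enumerations, the patch→slide grouping
map, nested risk strata used for screening decisions, and slide metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union


class PatchGrade(str, Enum):
    """The six abnormal-cell categories annotated at the patch level."""

    ASC_US = "ASC-US"
    LSIL = "LSIL"
    ASC_H = "ASC-H"
    HSIL = "HSIL"
    SCC = "SCC"
    AGC = "AGC"

    @classmethod
    def from_label(cls, label: Union[str, "PatchGrade"]) -> "PatchGrade":
        if isinstance(label, cls):
            return label
        try:
            return cls(label)
        except ValueError:
            raise ValueError(f"unknown patch grade label: {label!r}") from None

    def __str__(self) -> str:  # serialize as the canonical label
        return self.value


class SlideGrade(str, Enum):
    """The five slide-level (WSI) report categories."""

    NILM = "NILM"
    ASC_US = "ASC-US"
    LSIL = "LSIL"
    HSIL_PLUS = "HSIL+"
    AGC = "AGC"

    @classmethod
    def from_label(cls, label: Union[str, "SlideGrade"]) -> "SlideGrade":
        if isinstance(label, cls):
            return label
        try:
            return cls(label)
        except ValueError:
            raise ValueError(f"unknown slide grade label: {label!r}") from None

    def __str__(self) -> str:
        return self.value


#: Severity rank used ONLY for deterministic reporting sorts and
#: argmax tie-breaking (more severe wins). AGC sits between LSIL and
#: HSIL+ by convention; stratum membership never uses this order.
SEVERITY_ORDER: dict[SlideGrade, int] = {
    SlideGrade.NILM: 0,
    SlideGrade.ASC_US: 1,
    SlideGrade.LSIL: 2,
    SlideGrade.AGC: 3,
    SlideGrade.HSIL_PLUS: 4,
}

_PATCH_TO_SLIDE: dict[PatchGrade, SlideGrade] = {
    PatchGrade.ASC_US: SlideGrade.ASC_US,
    PatchGrade.LSIL: SlideGrade.LSIL,
    PatchGrade.ASC_H: SlideGrade.HSIL_PLUS,
    PatchGrade.HSIL: SlideGrade.HSIL_PLUS,
    PatchGrade.SCC: SlideGrade.HSIL_PLUS,
    PatchGrade.AGC: SlideGrade.AGC,
}


def patch_to_slide_category(grade: Union[str, PatchGrade]) -> SlideGrade:
    """Map a patch-level grade to its slide-level report category.

    ASC-H, HSIL and SCC collapse into the slide category HSIL+; ASC-US,
    LSIL and AGC map to their identically named slide categories.
    """
    return _PATCH_TO_SLIDE[PatchGrade.from_label(grade)]


class RiskStratum(Enum):
    """Nested grade-or-worse binarizations used for screening decisions.

    The squamous strata are defined by their patch-grade constituents:
    ASC-US+ = {ASC-US, LSIL, ASC-H, HSIL, SCC}, LSIL+ = {LSIL, ASC-H,
    HSIL, SCC}, HSIL+ = {ASC-H, HSIL, SCC}. AGC belongs to none of the
    squamous strata and only to ALL_ABNORMAL (every non-NILM grade).
    """

    ASC_US_PLUS = "ASC-US+"
    LSIL_PLUS = "LSIL+"
    HSIL_PLUS = "HSIL+"
    ALL_ABNORMAL = "ALL_ABNORMAL"

    @property
    def patch_members(self) -> frozenset[PatchGrade]:
        return _STRATUM_PATCH_MEMBERS[self]

    @property
    def slide_members(self) -> frozenset[SlideGrade]:
        """Slide-level grades whose patch constituents fall in the stratum."""
        return _STRATUM_SLIDE_MEMBERS[self]

    def __str__(self) -> str:
        return self.value


_STRATUM_PATCH_MEMBERS: dict[RiskStratum, frozenset[PatchGrade]] = {
    RiskStratum.ASC_US_PLUS: frozenset(
        {PatchGrade.ASC_US, PatchGrade.LSIL, PatchGrade.ASC_H, PatchGrade.HSIL, PatchGrade.SCC}
    ),
    RiskStratum.LSIL_PLUS: frozenset(
        {PatchGrade.LSIL, PatchGrade.ASC_H, PatchGrade.HSIL, PatchGrade.SCC}
    ),
    RiskStratum.HSIL_PLUS: frozenset({PatchGrade.ASC_H, PatchGrade.HSIL, PatchGrade.SCC}),
    RiskStratum.ALL_ABNORMAL: frozenset(PatchGrade),
}

_STRATUM_SLIDE_MEMBERS: dict[RiskStratum, frozenset[SlideGrade]] = {
    RiskStratum.ASC_US_PLUS: frozenset(
        {SlideGrade.ASC_US, SlideGrade.LSIL, SlideGrade.HSIL_PLUS}
    ),
    RiskStratum.LSIL_PLUS: frozenset({SlideGrade.LSIL, SlideGrade.HSIL_PLUS}),
    RiskStratum.HSIL_PLUS: frozenset({SlideGrade.HSIL_PLUS}),
    RiskStratum.ALL_ABNORMAL: frozenset(g for g in SlideGrade if g is not SlideGrade.NILM),
}


def stratum_membership(grade: Union[str, SlideGrade], stratum: RiskStratum) -> bool:
    """True iff a slide grade counts as positive for the given risk stratum."""
    return SlideGrade.from_label(grade) in stratum.slide_members


@dataclass(frozen=True)
class SlideRecord:
    """Metadata for one whole-slide image.

    pixel_size_um is the specimen-level pixel pitch in micrometres per
    pixel (40x scanners in routine use sit around 0.25 um/px).
    """

    slide_id: str
    width_px: int
    height_px: int
    pixel_size_um: float = 0.2529
    true_grade: Optional[SlideGrade] = None

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("slide dimensions must be >= 1 px")
        if not (0.1 < self.pixel_size_um < 1.0):
            raise ValueError(
                f"pixel_size_um must lie in (0.1, 1.0), got {self.pixel_size_um}"
            )
        if self.true_grade is not None:
            object.__setattr__(self, "true_grade", SlideGrade.from_label(self.true_grade))
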