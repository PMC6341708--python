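"""Domain types for checklist-based facility quality assessment.

The assessment instrument is a weighted checklist: every indicator belongs
to one of nine scoring sections (six quality dimensions, with QD3 split
into four sub-dimensions), carries an importance weight from 1 (least
important) to 5 (most important), and is answered yes/no/not-applicable —
or on a graded scale in [0, 1] for the medicine-availability items.
Facilities sit at one of three levels of care with different service
mandates, so some indicators are inapplicable at lower levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import pandas as pd


class Section(str, Enum):
    """One of the nine scoring sections."""

    QD1 = "QD1"
    QD2 = "QD2"
    QD3A = "QD3A"
    QD3B = "QD3B"
    QD3C = "QD3C"
    QD3D = "QD3D"
    QD4 = "QD4"
    QD5 = "QD5"
    QD6 = "QD6"


#: The six quality dimensions that contribute equally to the overall score.
QDS = ("QD1", "QD2", "QD3", "QD4", "QD5", "QD6")

#: Section -> parent quality dimension (QD3A..D pool into QD3).
SECTION_TO_QD = {
    "QD1": "QD1",
    "QD2": "QD2",
    "QD3A": "QD3",
    "QD3B": "QD3",
    "QD3C": "QD3",
    "QD3D": "QD3",
    "QD4": "QD4",
    "QD5": "QD5",
    "QD6": "QD6",
}

SECTIONS = tuple(SECTION_TO_QD)

LEVELS = ("dispensary", "health_center", "hospital")
OWNERS = ("public", "private_not_for_profit", "private_for_profit", "parastatal")

INDICATOR_TYPES = ("structure", "process", "outcome")
RESPONSE_KINDS = ("binary", "graded")


@dataclass(frozen=True)
class IndicatorSpec:
    """A single checklist item.

    Parameters
    ----------
    id : str
        Indicator identifier, unique within a catalog.
    section : str
        One of the nine sections (``QD1`` .. ``QD6``, with ``QD3A``–``QD3D``).
    weight : int
        Importance weight in 1..5.
    itype : str
        Donabedian category: ``structure``, ``process`` or ``outcome``.
    applicable_levels : frozenset of str
        Facility levels whose mandate includes this indicator.
    response_kind : str
        ``binary`` (yes/no/na) or ``graded`` (values in [0, 1]).
    """

    id: str
    section: str
    weight: int
    itype: str = "process"
    applicable_levels: frozenset = field(
        default_factory=lambda: frozenset(LEVELS)
    )
    response_kind: str = "binary"

    def __post_init__(self):
        if self.section not in SECTIONS:
            raise ValueError(f"unknown section {self.section!r}")
        if self.weight not in (1, 2, 3, 4, 5):
            raise ValueError(f"weight must be in 1..5, got {self.weight}")
        if self.itype not in INDICATOR_TYPES:
            raise ValueError(f"unknown indicator type {self.itype!r}")
        if not self.applicable_levels:
            raise ValueError("applicable_levels must be nonempty")
        if not set(self.applicable_levels) <= set(LEVELS):
            raise ValueError(f"unknown levels in {set(self.applicable_levels)}")
        if self.response_kind not in RESPONSE_KINDS:
            raise ValueError(f"unknown response kind {self.response_kind!r}")


@dataclass(frozen=True)
class FacilityProfile:
    """A health facility: level of care, owner category, council."""

    id: str
    level: str
    owner: str
    council: str

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.owner not in OWNERS:
            raise ValueError(f"unknown owner {self.owner!r}")


def catalog_frame(indicators: Iterable[IndicatorSpec]) -> pd.DataFrame:
    """Build a catalog DataFrame from :class:`IndicatorSpec` records."""
    rows = [
        {
            "id": i.id,
            "section": i.section,
            "weight": i.weight,
            "itype": i.itype,
            "applicable_levels": ";".join(
                sorted(i.applicable_levels, key=LEVELS.index)
            ),
            "response_kind": i.response_kind,
        }
        for i in indicators
    ]
    df = pd.DataFrame(
        rows,
        columns=["id", "section", "weight", "itype", "applicable_levels", "response_kind"],
    )
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate indicator ids: {dups}")
    return df


def roster_frame(facilities: Iterable[FacilityProfile]) -> pd.DataFrame:
    """Build a roster DataFrame from :class:`FacilityProfile` records."""
    rows = [
        {"facility": f.id, "level": f.level, "owner": f.owner, "council": f.council}
        for f in facilities
    ]
    df = pd.DataFrame(rows, columns=["facility", "level", "owner", "council"])
    if df["facility"].duplicated().any():
        raise ValueError("duplicate facility ids in roster")
    return df


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Validate a catalog DataFrame in place; returns it for chaining."""
    required = {"id", "section", "weight", "applicable_levels", "response_kind"}
    missing = required - set(catalog.columns)
    if missing:
        raise ValueError(f"catalog missing columns {sorted(missing)}")
    bad = set(catalog["section"]) - set(SECTIONS)
    if bad:
        raise ValueError(f"unknown sections {sorted(bad)}")
    w = catalog["weight"].astype(int)
    if not w.isin([1, 2, 3, 4, 5]).all():
        raise ValueError("weights outside 1..5")
    if catalog["id"].duplicated().any():
        raise ValueError("duplicate indicator ids")
    return catalog
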