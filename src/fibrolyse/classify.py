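"""Rule-based fibrinolysis classification.

Two complementary schemes grade fibrinolysis in a subject:

* the **viscoelastometric scheme** uses the EXTEM lysis index at 60 min
  (LI60) together with plasma fibrinogen: LI60 above the laboratory
  reference interval is hypofibrinolysis, within it basal fibrinolysis;
  LI60 below it is increased fibrinolysis when fibrinogen > 100 mg/dL and
  hyperfibrinolysis when fibrinogen <= 100 mg/dL (low fibrinogen marking
  heightened bleeding risk).  Within increased/hyper, the time course of
  total clot breakdown distinguishes fulminant (within 30 min),
  intermediate (30-60 min) and late (after 60 min / never within the run)
  lysis patterns.

* the **standard-test scheme** uses semiquantitative fibrin(ogen)
  degradation products (FDPs), quantitative D-dimer and fibrinogen.
  Normal FDPs and D-dimer is hypo/basal fibrinolysis (this scheme cannot
  separate the two); any elevation is increased fibrinolysis
  (fibrinogen > 100) or hyperfibrinolysis (fibrinogen <= 100), further
  typed as primary (FDPs up, D-dimer normal: plasmin without concomitant
  thrombin generation) or secondary (D-dimer up: lysis of cross-linked
  fibrin from ongoing coagulation).

All classifiers are total and deterministic on valid panels.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FDPS_CATEGORIES",
    "FIBRINOGEN_DETECTION_FLOOR",
    "ReferenceIntervals",
    "CoagulationPanel",
    "RotemGrade",
    "LysisPattern",
    "StandardGrade",
    "StandardType",
    "grade_by_rotem",
    "pattern_by_rotem",
    "grade_by_standard",
    "type_by_standard",
    "clinically_relevant_bleeding",
    "classify_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Ordered levels of the semiquantitative FDPs latex-agglutination assay (ug/mL).
FDPS_CATEGORIES = ("<5", "5-20", ">20")

#: Fibrinogen assay detection limit is 60 mg/dL; sub-limit values are
#: recorded as 59 mg/dL by laboratory convention.
FIBRINOGEN_DETECTION_FLOOR = 59.0


@dataclass(frozen=True)
class ReferenceIntervals:
    """Laboratory reference intervals and decision cut-offs.

    Defaults are the internal canine reference values of the laboratory
    whose classification rules this module implements (LI60 86-98 %,
    A5 29-44 mm, ML 19-38 %, fibrinogen 152-284 mg/dL, FDPs < 5 ug/mL,
    D-dimer 0.01-0.34 ug/mL, HCT 39.0-59.2 %) plus the 100 mg/dL
    fibrinogen cut-off marking increased bleeding risk.
    """

    li60: tuple[float, float] = (86.0, 98.0)
    a5: tuple[float, float] = (29.0, 44.0)
    ml: tuple[float, float] = (19.0, 38.0)
    fibrinogen: tuple[float, float] = (152.0, 284.0)
    fdps_upper: float = 5.0
    ddimer: tuple[float, float] = (0.01, 0.34)
    hct: tuple[float, float] = (39.0, 59.2)
    fibrinogen_bleeding_cutoff: float = 100.0

    def __post_init__(self) -> None:
        for name in ("li60", "a5", "ml", "fibrinogen", "ddimer", "hct"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: interval lower bound must be < upper")
        if self.fdps_upper <= 0 or self.fibrinogen_bleeding_cutoff <= 0:
            raise ValueError("cut-offs must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceIntervals":
        """Load reference intervals from a key-value YAML config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, (list, tuple)) else float(v)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            f.name: list(v) if isinstance(v := getattr(self, f.name), tuple) else v
            for f in fields(self)
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


class RotemGrade(str, enum.Enum):
    """Fibrinolysis severity by the viscoelastometric scheme, ordered."""

    HYPOFIBRINOLYSIS = "hypofibrinolysis"
    BASAL = "basal"
    INCREASED = "increased"
    HYPERFIBRINOLYSIS = "hyperfibrinolysis"

    @property
    def rank(self) -> int:
        return _ROTEM_ORDER.index(self)


_ROTEM_ORDER = [
    RotemGrade.HYPOFIBRINOLYSIS,
    RotemGrade.BASAL,
    RotemGrade.INCREASED,
    RotemGrade.HYPERFIBRINOLYSIS,
]


class LysisPattern(str, enum.Enum):
    """Time-course pattern of clot breakdown (only for increased/hyper grades)."""

    NONE = "none"
    LATE = "late"
    INTERMEDIATE = "intermediate"
    FULMINANT = "fulminant"


class StandardGrade(str, enum.Enum):
    """Fibrinolysis severity by the standard-test scheme.

    Hypofibrinolysis cannot be separated from basal fibrinolysis with
    FDPs/D-dimer alone, so the lowest level is merged by construction.
    """

    HYPO_BASAL = "hypo_basal"
    INCREASED = "increased"
    HYPERFIBRINOLYSIS = "hyperfibrinolysis"


class StandardType(str, enum.Enum):
    """Fibrinolysis type by the standard-test scheme."""

    HYPO_BASAL = "hypo_basal"
    PRIMARY_FIBRINOLYSIS = "primary_fibrinolysis"
    SECONDARY_FIBRINOLYSIS = "secondary_fibrinolysis"
    PRIMARY_HYPERFIBRINOLYSIS = "primary_hyperfibrinolysis"
    SECONDARY_HYPERFIBRINOLYSIS = "secondary_hyperfibrinolysis"


#: Collapse a type onto its severity grade (coarsening used by the
#: severity comparison, which groups primary with secondary).
TYPE_TO_GRADE = {
    StandardType.HYPO_BASAL: StandardGrade.HYPO_BASAL,
    StandardType.PRIMARY_FIBRINOLYSIS: StandardGrade.INCREASED,
    StandardType.SECONDARY_FIBRINOLYSIS: StandardGrade.INCREASED,
    StandardType.PRIMARY_HYPERFIBRINOLYSIS: StandardGrade.HYPERFIBRINOLYSIS,
    StandardType.SECONDARY_HYPERFIBRINOLYSIS: StandardGrade.HYPERFIBRINOLYSIS,
}


@dataclass(frozen=True)
class CoagulationPanel:
    """Per-subject coagulation work-up feeding both classification schemes."""

    subject_id: str
    group: str
    li60: float  # percent
    fibrinogen: float  # mg/dL, >= 59 (detection-floor convention)
    fdps_category: str  # one of FDPS_CATEGORIES
    ddimer: float  # ug/mL
    hct: float  # percent
    bleeding_event: bool = False
    a5: Optional[float] = None  # mm
    ml: Optional[float] = None  # percent
    breakdown_time: Optional[float] = None  # minutes after CT

    def __post_init__(self) -> None:
        if self.fdps_category not in FDPS_CATEGORIES:
            raise ValueError(f"fdps_category must be one of {FDPS_CATEGORIES}")
        if self.fibrinogen < FIBRINOGEN_DETECTION_FLOOR:
            raise ValueError(
                f"fibrinogen below the {FIBRINOGEN_DETECTION_FLOOR} mg/dL "
                "detection-floor encoding"
            )
        if self.ddimer < 0:
            raise ValueError("ddimer must be >= 0")
        if not 0 <= self.hct <= 100:
            raise ValueError("hct must be a percentage")
        if not 0 <= self.li60 <= 100:
            raise ValueError("li60 must lie in [0, 100]")


def grade_by_rotem(
    li60: float, fibrinogen: float, ri: ReferenceIntervals = ReferenceIntervals()
) -> RotemGrade:
    """Severity grade from LI60 and fibrinogen.

    LI60 above the reference interval -> hypofibrinolysis; within it ->
    basal; below it -> increased (fibrinogen > 100 mg/dL) or
    hyperfibrinolysis (fibrinogen <= 100 mg/dL, boundary inclusive).
    """
    lo, hi = ri.li60
    if li60 > hi:
        return RotemGrade.HYPOFIBRINOLYSIS
    if li60 >= lo:
        return RotemGrade.BASAL
    if fibrinogen <= ri.fibrinogen_bleeding_cutoff:
        return RotemGrade.HYPERFIBRINOLYSIS
    return RotemGrade.INCREASED


def pattern_by_rotem(
    grade: RotemGrade,
    breakdown_time: Optional[float],
    fulminant_le: float = 30.0,
    intermediate_le: float = 60.0,
) -> LysisPattern:
    """Breakdown-time pattern for increased/hyperfibrinolytic traces.

    Total breakdown within 30 min is fulminant, between 30 and 60 min
    intermediate (boundaries read as half-open (30, 60]), later or never
    within the run is late.  Hypofibrinolytic/basal traces have no pattern.
    The boundary values are configurable since either tie side is
    defensible.
    """
    if grade in (RotemGrade.HYPOFIBRINOLYSIS, RotemGrade.BASAL):
        return LysisPattern.NONE
    if breakdown_time is None or breakdown_time > intermediate_le:
        return LysisPattern.LATE
    if breakdown_time <= fulminant_le:
        return LysisPattern.FULMINANT
    return LysisPattern.INTERMEDIATE


def _fdps_elevated(fdps_category: str, ri: ReferenceIntervals) -> bool:
    # semiquantitative assay: any category at or above 5 ug/mL is elevated
    return FDPS_CATEGORIES.index(fdps_category) >= 1


def _ddimer_elevated(ddimer: float, ri: ReferenceIntervals) -> bool:
    # strictly above the reference-interval upper bound; sub-RI values are
    # treated as normal (the scheme defines no hypofibrinolysis)
    return ddimer > ri.ddimer[1]


def type_by_standard(
    fdps_category: str,
    ddimer: float,
    fibrinogen: float,
    ri: ReferenceIntervals = ReferenceIntervals(),
) -> StandardType:
    """Fibrinolysis type from FDPs, D-dimer and fibrinogen.

    Elevated D-dimer marks secondary (reactive) fibrinolysis, whatever the
    FDPs level; elevated FDPs with normal D-dimer marks primary
    fibrinolysis; fibrinogen <= 100 mg/dL upgrades either to the
    hyperfibrinolytic form.
    """
    if fdps_category not in FDPS_CATEGORIES:
        raise ValueError(f"fdps_category must be one of {FDPS_CATEGORIES}")
    fdps_up = _fdps_elevated(fdps_category, ri)
    dd_up = _ddimer_elevated(ddimer, ri)
    if not fdps_up and not dd_up:
        return StandardType.HYPO_BASAL
    hyper = fibrinogen <= ri.fibrinogen_bleeding_cutoff
    if dd_up:
        return (
            StandardType.SECONDARY_HYPERFIBRINOLYSIS
            if hyper
            else StandardType.SECONDARY_FIBRINOLYSIS
        )
    return (
        StandardType.PRIMARY_HYPERFIBRINOLYSIS
        if hyper
        else StandardType.PRIMARY_FIBRINOLYSIS
    )


def grade_by_standard(
    fdps_category: str,
    ddimer: float,
    fibrinogen: float,
    ri: ReferenceIntervals = ReferenceIntervals(),
) -> StandardGrade:
    """Severity grade from FDPs, D-dimer and fibrinogen (type, coarsened)."""
    return TYPE_TO_GRADE[type_by_standard(fdps_category, ddimer, fibrinogen, ri)]


def clinically_relevant_bleeding(
    hct: float, bleeding_event: bool, ri: ReferenceIntervals = ReferenceIntervals()
) -> bool:
    """Bleeding severe enough to cause anemia (HCT below the reference interval).

    Both conditions are required: a recorded bleeding event AND
    HCT < 39.0 %.  Anemia without bleeding is not relevant bleeding.
    """
    return bool(bleeding_event) and hct < ri.hct[0]


#: Classification output columns appended to a cohort table.
LABEL_COLUMNS = ["rotem_grade", "rotem_pattern", "std_grade", "std_type", "relevant_bleeding"]


def classify_cohort(
    panels: Sequence[CoagulationPanel],
    ri: ReferenceIntervals = ReferenceIntervals(),
    pattern_boundaries: tuple[float, float] = (30.0, 60.0),
) -> pd.DataFrame:
    """Apply both schemes to every panel; one label per scheme per subject.

    Returns a DataFrame with one row per subject (id, group, raw values,
    and the five label columns).  Panels with missing required fields are
    excluded with a log entry, never silently dropped.
    """
    rows = []
    for p in panels:
        try:
            rg = grade_by_rotem(p.li60, p.fibrinogen, ri)
            rows.append(
                {
                    "id": p.subject_id,
                    "group": p.group,
                    "a5_mm": p.a5,
                    "li60_pct": p.li60,
                    "ml2h_pct": p.ml,
                    "breakdown_min": p.breakdown_time,
                    "fibrinogen_mgdl": p.fibrinogen,
                    "fdps_cat": p.fdps_category,
                    "ddimer_ugml": p.ddimer,
                    "hct_pct": p.hct,
                    "bleeding_event": p.bleeding_event,
                    "rotem_grade": rg.value,
                    "rotem_pattern": pattern_by_rotem(
                        rg, p.breakdown_time, *pattern_boundaries
                    ).value,
                    "std_grade": grade_by_standard(
                        p.fdps_category, p.ddimer, p.fibrinogen, ri
                    ).value,
                    "std_type": type_by_standard(
                        p.fdps_category, p.ddimer, p.fibrinogen, ri
                    ).value,
                    "relevant_bleeding": clinically_relevant_bleeding(
                        p.hct, p.bleeding_event, ri
                    ),
                }
            )
        except (TypeError, ValueError) as exc:
            logger.warning("subject %s excluded: %s", p.subject_id, exc)
    return pd.DataFrame(rows)


_COHORT_COLUMNS = [
    "id", "group", "a5_mm", "li60_pct", "ml2h_pct", "breakdown_min",
    "fibrinogen_mgdl", "fdps_cat", "ddimer_ugml", "hct_pct", "bleeding_event",
]


def read_cohort_csv(path: str | Path) -> list[CoagulationPanel]:
    """Read a cohort CSV (one row per subject, schema of ``_COHORT_COLUMNS``)."""
    df = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    panels = []
    for _, r in df.iterrows():
        panels.append(
            CoagulationPanel(
                subject_id=str(r["id"]),
                group=str(r["group"]),
                li60=float(r["li60_pct"]),
                fibrinogen=float(r["fibrinogen_mgdl"]),
                fdps_category=str(r["fdps_cat"]),
                ddimer=float(r["ddimer_ugml"]),
                hct=float(r["hct_pct"]),
                bleeding_event=bool(r["bleeding_event"]),
                a5=None if pd.isna(r["a5_mm"]) else float(r["a5_mm"]),
                ml=None if pd.isna(r["ml2h_pct"]) else float(r["ml2h_pct"]),
                breakdown_time=(
                    None if pd.isna(r["breakdown_min"]) else float(r["breakdown_min"])
                ),
            )
        )
    return panels


def write_cohort_csv(panels: Sequence[CoagulationPanel], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "id": p.subject_id,
                "group": p.group,
                "a5_mm": p.a5,
                "li60_pct": p.li60,
                "ml2h_pct": p.ml,
                "breakdown_min": p.breakdown_time,
                "fibrinogen_mgdl": p.fibrinogen,
                "fdps_cat": p.fdps_category,
                "ddimer_ugml": p.ddimer,
                "hct_pct": p.hct,
                "bleeding_event": p.bleeding_event,
            }
            for p in panels
        ],
        columns=_COHORT_COLUMNS,
    )
    df.to_csv(path, index=False)
    return df
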