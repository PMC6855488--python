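"""Reference canine effusion cohort: published counts and a matching fixture.

The reference analysis surface is a two-arm case-control cohort of 64
dogs — 32 with intracavitary (abdominal and/or pleural) effusion and 32
matched effusion-free sick controls — classified for fibrinolysis by both
the viscoelastometric and the standard-test scheme.  This module holds

* the published group-level count tables and summary statistics of that
  cohort (transcribed constants; per-subject raw data are not public), and
* :func:`fixture_cohort_from_tables`, a deterministic synthetic 64-subject
  panel set whose values, pushed through the *real* classifiers, reproduce
  every published cross-tabulation exactly: severity grades and lysis
  patterns per arm, standard-test types per arm, the 3 x 3 cross-scheme
  agreement table, the FDPs category counts, the bleeding counts, and all
  of these restricted to the subjects without clinically relevant bleeding.

The continuous values in the fixture are representative points inside each
category's defining region (e.g. LI60 = 92 for basal fibrinolysis); they
are synthetic stand-ins, arbitrary within the classification constraints.
The joint allocation of subjects to (standard grade x ROTEM grade x
pattern x bleeding x FDPs) cells is one consistent solution; the published
margins do not determine it uniquely.
"""

from __future__ import annotations

import numpy as np

from .classify import CoagulationPanel
from .stats import ContingencyTable

__all__ = [
    "GROUPS",
    "ROTEM_GRADE_LEVELS",
    "PATTERN_LEVELS",
    "STANDARD_TYPE_LEVELS",
    "GRADE3_LEVELS",
    "rotem_grade_counts",
    "pattern_counts",
    "standard_type_counts",
    "fdps_counts",
    "agreement_counts",
    "bleeding_counts",
    "sexual_status_counts",
    "A5_SUMMARY",
    "BODY_WEIGHT_SUMMARY",
    "AGE_SUMMARY",
    "grouped_rotem_grade_table",
    "grouped_pattern_table",
    "grouped_standard_grade_table",
    "standard_type_table",
    "fixture_cohort_from_tables",
]

GROUPS = ("effusion", "control")

ROTEM_GRADE_LEVELS = ("hypofibrinolysis", "basal", "increased", "hyperfibrinolysis")
PATTERN_LEVELS = ("hypofibrinolysis", "basal", "late", "intermediate", "fulminant")
STANDARD_TYPE_LEVELS = (
    "hypo_basal",
    "primary_fibrinolysis",
    "secondary_fibrinolysis",
    "primary_hyperfibrinolysis",
    "secondary_hyperfibrinolysis",
)
#: Severity after grouping hypofibrinolysis with basal (how every severity
#: comparison and the agreement analysis treat the scale).
GRADE3_LEVELS = ("hypo_basal", "increased", "hyperfibrinolysis")

# -- published counts; "_nb" rows restrict to subjects without clinically
#    relevant bleeding (19 effusion, 28 control) -----------------------------

_ROTEM_GRADE = {
    "effusion": (12, 9, 5, 6),
    "control": (17, 12, 2, 1),
    "effusion_nb": (5, 5, 4, 5),
    "control_nb": (15, 10, 2, 1),
}

_PATTERN = {  # hypo, basal, late, intermediate, fulminant
    "effusion": (12, 9, 6, 4, 1),
    "control": (17, 12, 3, 0, 0),
    "effusion_nb": (5, 5, 5, 3, 1),
    "control_nb": (15, 10, 3, 0, 0),
}

_STANDARD_TYPE = {  # hypo_basal, PF, SF, PHF, SHF
    "effusion": (8, 15, 2, 5, 2),
    "control": (12, 10, 10, 0, 0),
    "effusion_nb": (6, 8, 0, 4, 1),
    "control_nb": (11, 9, 8, 0, 0),
}

_FDPS = {  # <5, 5-20, >20 ug/mL
    "effusion": (9, 11, 12),
    "control": (16, 8, 8),
    "effusion_nb": (7, 8, 4),
    "control_nb": (14, 8, 6),
}

#: Cross-scheme agreement over all 64 dogs: rows = standard-test grade,
#: columns = viscoelastometric grade, both on the grouped 3-level scale.
_AGREEMENT = ((14, 3, 3), (33, 4, 0), (3, 0, 4))

#: Clinically relevant bleeding by arm (columns: bleeding, no bleeding).
_BLEEDING = ((13, 19), (4, 28))

#: Sexual status by arm (intact male, neutered male, intact female, spayed female).
_SEX_STATUS = ((16, 1, 3, 12), (7, 7, 5, 13))

#: (mean, sd, n) per arm.
A5_SUMMARY = {"effusion": (34.88, 16.23, 32), "control": (53.41, 16.24, 32)}
BODY_WEIGHT_SUMMARY = {"effusion": (26.7, 15.1, 32), "control": (22.1, 14.7, 32)}
AGE_SUMMARY = {"effusion": (107.0, 40.0, 32), "control": (108.0, 47.0, 32)}


def rotem_grade_counts(subset: str = "") -> dict[str, tuple[int, ...]]:
    sfx = "_nb" if subset == "no_bleeding" else ""
    return {g: _ROTEM_GRADE[g + sfx] for g in GROUPS}


def pattern_counts(subset: str = "") -> dict[str, tuple[int, ...]]:
    sfx = "_nb" if subset == "no_bleeding" else ""
    return {g: _PATTERN[g + sfx] for g in GROUPS}


def standard_type_counts(subset: str = "") -> dict[str, tuple[int, ...]]:
    sfx = "_nb" if subset == "no_bleeding" else ""
    return {g: _STANDARD_TYPE[g + sfx] for g in GROUPS}


def fdps_counts(subset: str = "") -> dict[str, tuple[int, ...]]:
    sfx = "_nb" if subset == "no_bleeding" else ""
    return {g: _FDPS[g + sfx] for g in GROUPS}


def agreement_counts() -> ContingencyTable:
    return ContingencyTable(np.array(_AGREEMENT), GRADE3_LEVELS, GRADE3_LEVELS)


def bleeding_counts() -> ContingencyTable:
    return ContingencyTable(np.array(_BLEEDING), GROUPS, ("bleeding", "no_bleeding"))


def sexual_status_counts() -> ContingencyTable:
    return ContingencyTable(
        np.array(_SEX_STATUS),
        GROUPS,
        ("male_intact", "male_neutered", "female_intact", "female_spayed"),
    )


# -- the comparison tables exactly as the severity/pattern/type tests use them


def _two_group(counts: dict[str, tuple[int, ...]], labels) -> ContingencyTable:
    return ContingencyTable(
        np.array([counts["effusion"], counts["control"]]), GROUPS, labels
    )


def grouped_rotem_grade_table(subset: str = "") -> ContingencyTable:
    """ROTEM severity per arm with hypofibrinolysis + basal grouped (2 x 3)."""
    c = rotem_grade_counts(subset)
    grouped = {g: (v[0] + v[1], v[2], v[3]) for g, v in c.items()}
    return _two_group(grouped, GRADE3_LEVELS)


def grouped_pattern_table(subset: str = "") -> ContingencyTable:
    """Lysis pattern per arm with hypofibrinolysis + basal grouped (2 x 4)."""
    c = pattern_counts(subset)
    grouped = {g: (v[0] + v[1], v[2], v[3], v[4]) for g, v in c.items()}
    return _two_group(grouped, ("hypo_basal", "late", "intermediate", "fulminant"))


def grouped_standard_grade_table(subset: str = "") -> ContingencyTable:
    """Standard-test severity per arm, types coarsened to grades (2 x 3)."""
    c = standard_type_counts(subset)
    grouped = {g: (v[0], v[1] + v[2], v[3] + v[4]) for g, v in c.items()}
    return _two_group(grouped, GRADE3_LEVELS)


def standard_type_table(subset: str = "") -> ContingencyTable:
    """Standard-test type per arm, all five categories (2 x 5)."""
    return _two_group(standard_type_counts(subset), STANDARD_TYPE_LEVELS)


# ---------------------------------------------------------------------------
# Fixture cohort
#
# Each block: (count, rotem level, pattern, standard type, bleeding, FDPs).
# Continuous panel values are then chosen inside the block's defining
# region, so the real classifiers regenerate the labels.  The blocks below
# are one integer solution to the joint constraints posed by all the
# published margins at once (incl. their bleeding-excluded versions).

_BLOCKS = {
    "effusion": [
        # --- no clinically relevant bleeding (n = 19) ---
        (2, "hypo", None, "hb", False, "<5"),
        (1, "basal", None, "hb", False, "<5"),
        (2, "hypo", None, "pf", False, "5-20"),
        (3, "basal", None, "pf", False, "5-20"),
        (1, "hypo", None, "phf", False, ">20"),
        (1, "basal", None, "shf", False, "<5"),
        (1, "inc", "intermediate", "hb", False, "<5"),
        (2, "inc", "intermediate", "pf", False, "5-20"),
        (1, "inc", "late", "pf", False, "5-20"),
        (2, "hyper", "late", "hb", False, "<5"),
        (2, "hyper", "late", "phf", False, ">20"),
        (1, "hyper", "fulminant", "phf", False, ">20"),
        # --- clinically relevant bleeding (n = 13) ---
        (1, "hypo", None, "hb", True, "<5"),
        (1, "basal", None, "hb", True, "<5"),
        (4, "hypo", None, "pf", True, ">20"),
        (2, "basal", None, "pf", True, "5-20"),
        (1, "hypo", None, "pf", True, "5-20"),
        (1, "hypo", None, "sf", True, ">20"),
        (1, "basal", None, "shf", True, ">20"),
        (1, "inc", "intermediate", "sf", True, ">20"),
        (1, "hyper", "late", "phf", True, ">20"),
    ],
    "control": [
        # --- no clinically relevant bleeding (n = 28) ---
        (5, "hypo", None, "hb", False, "<5"),
        (3, "basal", None, "hb", False, "<5"),
        (6, "hypo", None, "pf", False, "5-20"),
        (3, "basal", None, "pf", False, ">20"),
        (3, "hypo", None, "sf", False, "<5"),
        (1, "hypo", None, "sf", False, "5-20"),
        (1, "basal", None, "sf", False, "5-20"),
        (3, "basal", None, "sf", False, ">20"),
        (2, "inc", "late", "hb", False, "<5"),
        (1, "hyper", "late", "hb", False, "<5"),
        # --- clinically relevant bleeding (n = 4) ---
        (1, "hypo", None, "hb", True, "<5"),
        (1, "hypo", None, "pf", True, ">20"),
        (1, "basal", None, "sf", True, "<5"),
        (1, "basal", None, "sf", True, ">20"),
    ],
}

# Representative continuous values inside each category's defining region.
_LI60 = {"hypo": 99.0, "basal": 92.0, "late": 80.0, "intermediate": 40.0, "fulminant": 3.0}
_ML = {"hypo": 2.0, "basal": 8.0, "late": 35.0, "intermediate": 85.0, "fulminant": 100.0}
_BREAKDOWN = {"late": None, "intermediate": 45.0, "fulminant": 25.0}
_DDIMER = {"hb": 0.10, "pf": 0.15, "phf": 0.15, "sf": 0.60, "shf": 0.60}
_STD_NAME = {
    "hb": "hypo_basal",
    "pf": "primary_fibrinolysis",
    "sf": "secondary_fibrinolysis",
    "phf": "primary_hyperfibrinolysis",
    "shf": "secondary_hyperfibrinolysis",
}
_A5 = {"effusion": 35.0, "control": 53.0}


def _fibrinogen_for(rotem: str, std: str) -> float:
    # the fibrinogen cut-off is shared by both schemes, so the value must
    # satisfy the subject's cell in the cross-classification
    if rotem == "inc":
        return 177.0  # > 100 required by the viscoelastometric grade
    if rotem == "hyper":
        return 80.0  # <= 100 required
    # hypo/basal traces leave fibrinogen free for the standard scheme
    if std in ("phf", "shf"):
        return 85.0
    if std in ("pf", "sf"):
        return 250.0
    return 300.0


def fixture_cohort_from_tables() -> list[CoagulationPanel]:
    """Deterministic 64-subject synthetic cohort realizing the published tables.

    Classification of these panels (and cross-tabulation of the two
    severity labels) regenerates every published count table exactly; no
    label is hand-assigned, everything flows through the classifiers.
    """
    panels: list[CoagulationPanel] = []
    for group, blocks in _BLOCKS.items():
        i = 0
        for count, rotem, pattern, std, bleeding, fdps in blocks:
            key = pattern if rotem in ("inc", "hyper") else rotem
            for _ in range(count):
                i += 1
                panels.append(
                    CoagulationPanel(
                        subject_id=f"{group}-{i:02d}",
                        group=group,
                        li60=_LI60[key],
                        fibrinogen=_fibrinogen_for(rotem, std),
                        fdps_category=fdps,
                        ddimer=_DDIMER[std],
                        hct=31.0 if bleeding else 46.0,
                        bleeding_event=bleeding,
                        a5=_A5[group],
                        ml=_ML[key],
                        breakdown_time=(
                            _BREAKDOWN[key] if rotem in ("inc", "hyper") else None
                        ),
                    )
                )
    return panels
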