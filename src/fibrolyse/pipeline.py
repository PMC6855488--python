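"""End-to-end cohort analysis: classify, cross-tabulate, compare, agree.

``run_analysis`` reproduces the reference study's analysis plan on any
two-arm cohort of coagulation panels:

1. per-arm summaries of the viscoelastometric and standard-test measures;
2. classification of every subject by both fibrinolysis schemes;
3. between-arm comparisons — chi-square for the FDPs categories and for
   clinically relevant bleeding (with Yates correction on the 2 x 2),
   pooled t for A5, Mann-Whitney for LI60/ML/fibrinogen/D-dimer, and the
   Fisher-Freeman-Halton exact test for severity grade, lysis pattern and
   fibrinolysis type (hypofibrinolysis and basal fibrinolysis always
   grouped; primary/secondary types grouped only for the severity test);
4. cross-scheme agreement: observed and per-category conditional
   concordance and weighted Cohen's kappa with its 95% CI;
5. optionally, the fibrinolysis comparisons repeated after excluding
   subjects with clinically relevant bleeding (which changes membership
   only, never a label).

All comparisons are two-sided at alpha = 0.05 with no multiplicity
correction, matching the reference analysis.  Structural zero categories
are retained in the tables; the exact test handles them natively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import (
    FDPS_CATEGORIES,
    CoagulationPanel,
    ReferenceIntervals,
    classify_cohort,
)
from .stats import (
    AgreementResult,
    ContingencyTable,
    TestResult,
    chi_square,
    cohen_kappa,
    conditional_concordance,
    crosstab,
    fisher_exact_rxc,
    mann_whitney,
    t_from_summary,
)

__all__ = ["AnalysisReport", "run_analysis", "report_to_files"]

GRADE3 = ("hypo_basal", "increased", "hyperfibrinolysis")
PATTERN4 = ("hypo_basal", "late", "intermediate", "fulminant")
TYPE5 = (
    "hypo_basal",
    "primary_fibrinolysis",
    "secondary_fibrinolysis",
    "primary_hyperfibrinolysis",
    "secondary_hyperfibrinolysis",
)


@dataclass
class AnalysisReport:
    """Everything the analysis produces, ready for serialization."""

    groups: tuple[str, str]
    cohort: pd.DataFrame
    group_summaries: pd.DataFrame
    tables: dict[str, ContingencyTable]
    tests: dict[str, TestResult]
    agreement: AgreementResult
    conditional_concordance: dict[str, float]
    options: dict
    no_bleeding: Optional["AnalysisReport"] = None

    def to_dict(self) -> dict:
        """Plain-dict view (JSON-serializable, deterministic key order)."""
        out = {
            "groups": list(self.groups),
            "n": int(len(self.cohort)),
            "group_summaries": _df_records(self.group_summaries),
            "tables": {
                name: {
                    "rows": list(t.row_labels),
                    "cols": list(t.col_labels),
                    "counts": t.counts.tolist(),
                }
                for name, t in sorted(self.tables.items())
            },
            "tests": {
                name: {
                    "statistic": r.statistic,
                    "p": r.p_value,
                    "method": r.method,
                    **({"df": r.df} if r.df is not None else {}),
                }
                for name, r in sorted(self.tests.items())
            },
            "agreement": {
                "kappa": self.agreement.kappa,
                "se": self.agreement.se,
                "ci95": list(self.agreement.ci95),
                "observed_concordance_pct": self.agreement.observed_concordance,
                "weighting": self.agreement.weighting,
                "conditional_concordance_pct": dict(
                    sorted(self.conditional_concordance.items())
                ),
            },
            "options": dict(sorted(self.options.items())),
        }
        if self.no_bleeding is not None:
            out["no_bleeding"] = self.no_bleeding.to_dict()
        return out


def _df_records(df: pd.DataFrame) -> list[dict]:
    recs = df.reset_index().to_dict(orient="records")
    return [
        {k: (v.item() if isinstance(v, np.generic) else v) for k, v in r.items()}
        for r in recs
    ]


def _median_iqr(x: pd.Series) -> tuple[float, float, float]:
    x = x.dropna()
    return (
        float(x.median()),
        float(x.quantile(0.25)),
        float(x.quantile(0.75)),
    )


def _summaries(df: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    rows = {}
    for g in groups:
        sub = df[df["group"] == g]
        med = {
            name: _median_iqr(sub[col])
            for name, col in [
                ("li60", "li60_pct"),
                ("ml2h", "ml2h_pct"),
                ("fibrinogen", "fibrinogen_mgdl"),
                ("ddimer", "ddimer_ugml"),
            ]
        }
        a5 = sub["a5_mm"].dropna()
        rows[g] = {
            "n": len(sub),
            "a5_mean": float(a5.mean()) if len(a5) else np.nan,
            "a5_sd": float(a5.std(ddof=1)) if len(a5) > 1 else np.nan,
            **{
                f"{name}_{stat}": val
                for name, (m, lo, hi) in med.items()
                for stat, val in [("median", m), ("q1", lo), ("q3", hi)]
            },
            "relevant_bleeding_n": int(sub["relevant_bleeding"].sum()),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    return out


def _group_counts(
    df: pd.DataFrame, column: str, levels: Sequence[str], groups: Sequence[str]
) -> ContingencyTable:
    counts = np.array(
        [[int((df.loc[df["group"] == g, column] == lv).sum()) for lv in levels] for g in groups]
    )
    return ContingencyTable(counts, tuple(groups), tuple(levels))


def _grade3(series: pd.Series) -> pd.Series:
    return series.replace({"hypofibrinolysis": "hypo_basal", "basal": "hypo_basal"})


def _pattern4(df: pd.DataFrame) -> pd.Series:
    return np.where(df["rotem_pattern"] == "none", "hypo_basal", df["rotem_pattern"])


def _fibrinolysis_block(
    df: pd.DataFrame, groups: Sequence[str], fisher_variant: str
) -> tuple[dict[str, ContingencyTable], dict[str, TestResult]]:
    """Tables and exact tests for severity, pattern and type (plus FDPs)."""
    work = df.copy()
    work["rotem_grade3"] = _grade3(work["rotem_grade"])
    work["pattern4"] = _pattern4(work)
    work["std_grade"] = work["std_grade"].astype(str)
    tables = {
        "fdps_by_group": _group_counts(work, "fdps_cat", FDPS_CATEGORIES, groups),
        "rotem_grade_by_group": _group_counts(
            work, "rotem_grade3", GRADE3, groups
        ),
        "rotem_pattern_by_group": _group_counts(work, "pattern4", PATTERN4, groups),
        "standard_grade_by_group": _group_counts(work, "std_grade", GRADE3, groups),
        "standard_type_by_group": _group_counts(work, "std_type", TYPE5, groups),
    }
    tests = {"fdps_chi2": chi_square(tables["fdps_by_group"])}
    for name, key in [
        ("rotem_grade_fisher", "rotem_grade_by_group"),
        ("rotem_pattern_fisher", "rotem_pattern_by_group"),
        ("standard_grade_fisher", "standard_grade_by_group"),
        ("standard_type_fisher", "standard_type_by_group"),
    ]:
        # structural zeros are kept in the reported tables but cannot enter
        # the exact test; a table collapsing below 2 x 2 has no comparison
        reduced = tables[key].drop_empty()
        if reduced.counts.shape[0] >= 2 and reduced.counts.shape[1] >= 2:
            tests[name] = fisher_exact_rxc(reduced, fisher_variant)
    return tables, tests


def _continuous_tests(df: pd.DataFrame, groups: Sequence[str]) -> dict[str, TestResult]:
    tests: dict[str, TestResult] = {}
    g1 = df[df["group"] == groups[0]]
    g2 = df[df["group"] == groups[1]]
    a5_1, a5_2 = g1["a5_mm"].dropna(), g2["a5_mm"].dropna()
    if len(a5_1) >= 2 and len(a5_2) >= 2 and a5_1.std() > 0 and a5_2.std() > 0:
        tests["a5_t"] = t_from_summary(
            a5_1.mean(), a5_1.std(ddof=1), len(a5_1),
            a5_2.mean(), a5_2.std(ddof=1), len(a5_2),
        )
    for name, col in [
        ("li60_mw", "li60_pct"),
        ("ml2h_mw", "ml2h_pct"),
        ("fibrinogen_mw", "fibrinogen_mgdl"),
        ("ddimer_mw", "ddimer_ugml"),
    ]:
        x, y = g1[col].dropna(), g2[col].dropna()
        if len(x) and len(y):
            tests[name] = mann_whitney(x, y)
    return tests


def run_analysis(
    panels: Sequence[CoagulationPanel],
    ri: ReferenceIntervals = ReferenceIntervals(),
    kappa_weighting: str = "linear",
    fisher_variant: str = "midp",
    pattern_boundaries: tuple[float, float] = (30.0, 60.0),
    exclude_bleeding_repeat: bool = True,
    demographics: Optional[dict] = None,
) -> AnalysisReport:
    """Run the full two-arm fibrinolysis analysis.

    ``demographics``, when given, may carry a ``"sexual_status"``
    :class:`ContingencyTable` (compared by plain chi-square) and
    ``"age"`` / ``"body_weight"`` dicts of per-group ``(mean, sd, n)``
    summaries (compared by pooled t), for cohorts where those covariates
    are available.

    Raises on single-group input.  Bleeding exclusion never alters any
    label, only membership.
    """
    df = classify_cohort(panels, ri, pattern_boundaries)
    if df.empty:
        raise ValueError("empty cohort")
    groups = tuple(pd.unique(df["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {list(groups)}")

    tables, tests = _fibrinolysis_block(df, groups, fisher_variant)
    bleeding_tab = ContingencyTable(
        np.array(
            [
                [
                    int(df[(df["group"] == g)]["relevant_bleeding"].sum()),
                    int((~df[df["group"] == g]["relevant_bleeding"]).sum()),
                ]
                for g in groups
            ]
        ),
        tuple(groups),
        ("bleeding", "no_bleeding"),
    )
    tables["bleeding_by_group"] = bleeding_tab
    tests["bleeding_chi2_yates"] = chi_square(bleeding_tab, yates=True)
    tests.update(_continuous_tests(df, groups))

    if demographics:
        if "sexual_status" in demographics:
            tests["sexual_status_chi2"] = chi_square(demographics["sexual_status"])
        for key in ("age", "body_weight"):
            if key in demographics:
                (m1, s1, n1), (m2, s2, n2) = (
                    demographics[key][g] for g in groups
                )
                tests[f"{key}_t"] = t_from_summary(m1, s1, n1, m2, s2, n2)

    agree_tab = crosstab(
        _grade3(df["std_grade"]).tolist(),
        _grade3(df["rotem_grade"]).tolist(),
        categories=GRADE3,
    )
    tables["grade_agreement"] = agree_tab
    agreement = cohen_kappa(agree_tab, weighting=kappa_weighting)
    cond = {}
    for cat in GRADE3:
        try:
            cond[cat] = conditional_concordance(agree_tab, cat)
        except ValueError:
            pass

    options = {
        "kappa_weighting": kappa_weighting,
        "fisher_variant": fisher_variant,
        "pattern_boundaries": list(pattern_boundaries),
        "exclude_bleeding_repeat": exclude_bleeding_repeat,
    }

    report = AnalysisReport(
        groups=groups,
        cohort=df,
        group_summaries=_summaries(df, groups),
        tables=tables,
        tests=tests,
        agreement=agreement,
        conditional_concordance=cond,
        options=options,
    )

    if exclude_bleeding_repeat:
        keep = [p for p, excl in zip(panels, df["relevant_bleeding"]) if not excl]
        if keep:
            sub_df = df[~df["relevant_bleeding"]]
            if sub_df["group"].nunique() == 2:
                sub_tables, sub_tests = _fibrinolysis_block(
                    sub_df, groups, fisher_variant
                )
                sub_tests.update(_continuous_tests(sub_df, groups))
                sub_agree = crosstab(
                    _grade3(sub_df["std_grade"]).tolist(),
                    _grade3(sub_df["rotem_grade"]).tolist(),
                    categories=GRADE3,
                )
                sub_tables["grade_agreement"] = sub_agree
                sub_cond = {}
                for cat in GRADE3:
                    try:
                        sub_cond[cat] = conditional_concordance(sub_agree, cat)
                    except ValueError:
                        pass
                report.no_bleeding = AnalysisReport(
                    groups=groups,
                    cohort=sub_df,
                    group_summaries=_summaries(sub_df, groups),
                    tables=sub_tables,
                    tests=sub_tests,
                    agreement=cohen_kappa(sub_agree, weighting=kappa_weighting),
                    conditional_concordance=sub_cond,
                    options={**options, "subset": "no_relevant_bleeding"},
                )
    return report


#: Table files written by :func:`report_to_files` (one CSV each).
REPORT_TABLES = (
    "fdps_by_group",
    "rotem_grade_by_group",
    "rotem_pattern_by_group",
    "standard_type_by_group",
    "bleeding_by_group",
    "grade_agreement",
)


def report_to_files(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write the report: one CSV per headline table, a JSON summary and a
    human-readable text summary.  Deterministic: same report, same bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in REPORT_TABLES:
        path = out / f"{name}.csv"
        report.tables[name].to_frame().to_csv(path)
        written.append(path)
    jpath = out / "report.json"
    with open(jpath, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=False)
        fh.write("\n")
    written.append(jpath)
    tpath = out / "summary.txt"
    with open(tpath, "w") as fh:
        fh.write(_text_summary(report))
    written.append(tpath)
    return written


def _text_summary(report: AnalysisReport) -> str:
    lines = [
        f"Two-arm fibrinolysis analysis: {report.groups[0]} (n = "
        f"{int((report.cohort['group'] == report.groups[0]).sum())}) vs "
        f"{report.groups[1]} (n = "
        f"{int((report.cohort['group'] == report.groups[1]).sum())})",
        "",
        "Between-arm tests (two-sided):",
    ]
    for name, r in sorted(report.tests.items()):
        lines.append(f"  {name:28s} stat = {r.statistic:10.4g}   p = {r.p_value:.4g}")
    a = report.agreement
    lines += [
        "",
        "Cross-scheme agreement (severity, hypo+basal grouped):",
        f"  observed concordance = {a.observed_concordance:.1f}%",
        f"  Cohen's kappa ({a.weighting}) = {a.kappa:.2f} "
        f"(95% CI {a.ci95[0]:.2f} to {a.ci95[1]:.2f})",
    ]
    for cat, v in sorted(report.conditional_concordance.items()):
        lines.append(f"  conditional concordance [{cat}] = {v:.1f}%")
    if report.no_bleeding is not None:
        nb = report.no_bleeding
        lines += [
            "",
            f"Excluding clinically relevant bleeding (n = {len(nb.cohort)}):",
        ]
        for name, r in sorted(nb.tests.items()):
            lines.append(
                f"  {name:28s} stat = {r.statistic:10.4g}   p = {r.p_value:.4g}"
            )
    return "\n".join(lines) + "\n"
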