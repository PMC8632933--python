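"""Group-comparison statistics and tabular cohort reports.

Continuous variables are compared across the five phenotype groups with
the Kruskal-Wallis rank test; when the omnibus test is significant at
0.05, pairwise Dunn post-hoc comparisons (tie-corrected, Bonferroni
adjusted) are attached.  Categorical variables use the chi-square test,
falling back to Fisher's exact test for 2x2 tables with any expected
cell below 5.  Subgroup mortality associations are univariate Cox fits
per factor with instability flags for zero-event levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CSVD_TYPES
from .survival import CoxModelSpec, CoxMortalityModel

POSTHOC_ALPHA = 0.05


@dataclass
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p_value: float
    posthoc: list = field(default_factory=list)  # [(("a","b"), adjusted_p), ...]


def _dunn_posthoc(values_by_group: dict) -> list:
    """Pairwise Dunn z-tests on pooled ranks, Bonferroni-adjusted."""
    labels = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        k = len(values_by_group[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k

    pairs = list(combinations(labels, 2))
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * len(pairs))
        out.append(((a, b), float(p)))
    return out


def compare_groups_continuous(
    values_by_group: dict, variable: str = ""
) -> GroupComparison:
    """Kruskal-Wallis omnibus test with Dunn/Bonferroni post-hoc.

    ``values_by_group`` maps group label to a sequence of values.
    Post-hoc comparisons are attached only when the omnibus p < 0.05.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # scipy raises on all-identical input
        return GroupComparison(variable, "kruskal_wallis", 0.0, 1.0)
    stat, p = stats.kruskal(*arrays)
    comp = GroupComparison(variable, "kruskal_wallis", float(stat), float(p))
    if p < POSTHOC_ALPHA:
        comp.posthoc = _dunn_posthoc(values_by_group)
    return comp


def compare_groups_categorical(table, variable: str = "") -> GroupComparison:
    """Chi-square test of independence on a contingency table.

    For 2x2 tables with any expected count below 5, Fisher's exact test
    is used instead (and the switch is recorded in the ``test`` field).
    """
    tab = np.asarray(table, dtype=float)
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("contingency table must hold non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    expected = stats.contingency.expected_freq(tab)
    if tab.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(tab.astype(int))
        return GroupComparison(variable, "fisher_exact", float(odds), float(p))
    stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return GroupComparison(variable, "chi_square", float(stat), float(p))


_TABLE1_CONTINUOUS = [
    ("age_years", "Age, years"),
    ("followup_years", "Follow-up time, years"),
    ("sbp_mmhg", "Systolic BP, mmHg"),
    ("ldl_mg_dl", "LDL, mg/dl"),
    ("hba1c_pct", "HgbA1c, %"),
]
_TABLE1_BINARY = [
    ("hypertension", "Hypertension"),
    ("diabetes", "Diabetes"),
    ("dyslipidemia", "Dyslipidemia"),
    ("smoking", "Cigarette smoking"),
]


def table1_report(cohort: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Demographics-and-markers table by phenotype group with test p-values.

    One row per variable; per-group cells show ``n (%)`` for discrete and
    ``mean (sd)`` for continuous variables, plus the omnibus p-value.
    """
    df = cohort.merge(
        phenotypes[["subject_id", "severe_wmh", "wmh_ratio", "csvd_type", "csvd_score"]],
        on="subject_id",
    )
    groups = [g for g in CSVD_TYPES if (df["csvd_type"] == g).any()]
    rows = []

    def cells_continuous(col):
        return {
            g: f"{df.loc[df.csvd_type == g, col].mean():.1f} "
            f"({df.loc[df.csvd_type == g, col].std(ddof=1):.1f})"
            for g in groups
        }

    def cells_binary(col):
        out = {}
        for g in groups:
            sub = df[df.csvd_type == g]
            k = int(sub[col].sum())
            out[g] = f"{k} ({100.0 * k / len(sub):.1f}%)"
        return out

    counts = {g: int((df.csvd_type == g).sum()) for g in groups}
    rows.append(
        {"variable": "Number", **{g: f"{counts[g]} ({100.0 * counts[g] / len(df):.1f}%)" for g in groups}, "p_value": np.nan}
    )
    for col, label in _TABLE1_CONTINUOUS:
        if df[col].isna().all():
            continue
        comp = compare_groups_continuous(
            {g: df.loc[(df.csvd_type == g) & df[col].notna(), col] for g in groups}, label
        )
        rows.append({"variable": label, **cells_continuous(col), "p_value": comp.p_value})
    male = (df["sex"] == "male").astype(int)
    df = df.assign(_male=male)
    comp = compare_groups_categorical(
        [[int(df.loc[df.csvd_type == g, "_male"].sum()),
          int((df.csvd_type == g).sum()) - int(df.loc[df.csvd_type == g, "_male"].sum())]
         for g in groups],
        "Sex, men",
    )
    rows.append({"variable": "Sex, men", **cells_binary("_male"), "p_value": comp.p_value})
    for col, label in _TABLE1_BINARY:
        comp = compare_groups_categorical(
            [[int(df.loc[df.csvd_type == g, col].sum()),
              int((df.csvd_type == g).sum()) - int(df.loc[df.csvd_type == g, col].sum())]
             for g in groups],
            label,
        )
        rows.append({"variable": label, **cells_binary(col), "p_value": comp.p_value})
    # marker summaries
    rows.append(
        {
            "variable": "Severe WMH",
            **cells_binary("severe_wmh"),
            "p_value": np.nan,
        }
    )
    comp = compare_groups_continuous(
        {g: df.loc[df.csvd_type == g, "csvd_score"] for g in groups}, "CSVD score"
    )
    rows.append(
        {
            "variable": "CSVD score, mean (SD)",
            **{
                g: f"{df.loc[df.csvd_type == g, 'csvd_score'].mean():.1f} "
                f"({df.loc[df.csvd_type == g, 'csvd_score'].std(ddof=1):.1f})"
                for g in groups
            },
            "p_value": comp.p_value,
        }
    )
    return pd.DataFrame(rows)


#: Factors examined in the within-type subgroup mortality analysis.
SUBGROUP_FACTORS = [
    "age_above_median",
    "sex_female",
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "smoking",
    "severe_wmh",
    "lacune_present",
    "cmb_ge2",
    "score2_vs1",
    "score3_vs1",
]


def subgroup_hazards(
    cohort: pd.DataFrame,
    phenotypes: pd.DataFrame,
    csvd_type: str = "type4",
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Univariate mortality hazard ratios within one phenotype subgroup.

    Each factor is fitted alone in a Cox model (age dichotomized at the
    subgroup median, burden-score categories contrasted against score 1).
    Estimates from levels with zero events are flagged unstable rather
    than suppressed, matching how sparse subgroup tables behave.
    """
    factors = factors or SUBGROUP_FACTORS
    df = cohort.merge(
        phenotypes[["subject_id", "severe_wmh", "csvd_type", "csvd_score"]],
        on="subject_id",
    )
    sub = df[df["csvd_type"] == csvd_type].copy()
    if len(sub) == 0 or sub["died"].sum() < 1:
        raise ValueError(f"subgroup {csvd_type!r} is empty or has no events")

    age_median = sub["age_years"].median()
    sub["age_above_median"] = (sub["age_years"] > age_median).astype(int)
    sub["sex_female"] = (sub["sex"] == "female").astype(int)
    sub["lacune_present"] = (sub["lacune_count"] >= 1).astype(int)
    total_cmb = sub[["cmb_lobar", "cmb_deep", "cmb_infratentorial"]].sum(axis=1)
    sub["cmb_ge2"] = (total_cmb >= 2).astype(int)
    sub["severe_wmh"] = sub["severe_wmh"].astype(int)
    sub["score2_vs1"] = (sub["csvd_score"] == 2).astype(int)
    sub["score3_vs1"] = (sub["csvd_score"] == 3).astype(int)

    rows = []
    for factor in factors:
        x = sub[factor]
        if x.nunique() < 2:
            raise ValueError(f"factor {factor!r} has no contrast in subgroup")
        if factor.startswith("score"):
            frame = sub[(sub["csvd_score"] == 1) | (x == 1)]
        else:
            frame = sub
        events_by_level = frame.groupby(x.loc[frame.index])["died"].sum()
        unstable = bool((events_by_level == 0).any())
        if unstable:
            warnings.warn(
                f"factor {factor!r}: a level has zero events; estimate unstable",
                stacklevel=2,
            )
        frame = frame.assign(_factor=frame[factor])
        model = CoxMortalityModel(
            exposure="_factor", reference_level=0, covariates=()
        )
        try:
            model.fit(frame)
            term = model.summary_.iloc[0]
            rows.append(
                {
                    "factor": factor,
                    "hazard_ratio": term["hazard_ratio"],
                    "ci95_low": term["ci95_low"],
                    "ci95_high": term["ci95_high"],
                    "p_value": term["p_value"],
                    "n": int(len(frame)),
                    "events": int(frame["died"].sum()),
                    "unstable": unstable,
                }
            )
        except RuntimeError:
            rows.append(
                {
                    "factor": factor,
                    "hazard_ratio": np.nan,
                    "ci95_low": np.nan,
                    "ci95_high": np.nan,
                    "p_value": np.nan,
                    "n": int(len(frame)),
                    "events": int(frame["died"].sum()),
                    "unstable": True,
                }
            )
    return pd.DataFrame(rows)
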