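"""All-cause-mortality survival analysis by CSVD phenotype or burden score.

Person-year incidence rates, Kaplan-Meier curves with the log-rank test,
and crude/adjusted Cox proportional-hazards models with exposure encoded
as indicator contrasts against a reference group (the control group by
default).  A proportional-hazards check tests the exposure x log(time)
interaction on an episode-split dataset.  Controls can optionally be
restricted to an age-matched subset (1:1 nearest-neighbour matching
without replacement within a caliper).

Follow-up time is the outcome timescale; including it as a covariate is
statistically degenerate but offered as an explicit opt-in because some
reports adjust for it.  Enabling it emits a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .schema import CSVD_TYPES

RISK_FACTORS = ["hypertension", "diabetes", "dyslipidemia", "smoking"]
DEFAULT_COVARIATES = ("age", "sex", "hypertension", "diabetes", "dyslipidemia", "smoking")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for incidence rates)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class CoxModelSpec:
    """Configuration of one Cox regression.

    exposure
        ``csvd_type`` or ``csvd_score`` (indicator contrasts against
        ``reference_level``), or ``None`` for a covariates-only model.
    covariates
        Subset of age, sex and the four vascular risk factors; optionally
        follow-up time via ``include_followup_covariate``.
    ties_method
        Partial-likelihood tie handling: ``efron`` (default) or ``breslow``.
    control_set
        ``all`` uses every control subject; ``age_matched`` restricts the
        reference group to controls age-matched 1:1 to the exposed.
    """

    exposure: str | None = "csvd_type"
    reference_level: str | int = "control"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    ties_method: str = "efron"
    control_set: str = "all"
    include_followup_covariate: bool = False
    caliper_years: float = 2.0
    match_seed: int = 0

    def __post_init__(self) -> None:
        if self.ties_method not in ("efron", "breslow"):
            raise ValueError(f"unknown ties_method: {self.ties_method!r}")
        if self.control_set not in ("all", "age_matched"):
            raise ValueError(f"unknown control_set: {self.control_set!r}")


def person_year_rates(
    cohort: pd.DataFrame, phenotypes: pd.DataFrame, grouping: str = "csvd_type"
) -> pd.DataFrame:
    """Per-group event counts, person-years and mortality rate per 100 PY.

    ``grouping`` is ``csvd_type`` or ``csvd_score``.  ``rate_per_100py``
    is the exact ratio; ``rate_display`` rounds half-away-from-zero to one
    decimal for tabulation.
    """
    if grouping not in ("csvd_type", "csvd_score"):
        raise ValueError(f"unknown grouping: {grouping!r}")
    df = cohort.merge(phenotypes[["subject_id", grouping]], on="subject_id")
    if (df["followup_years"] <= 0).any():
        raise ValueError("followup_years must be positive for all subjects")
    levels = CSVD_TYPES if grouping == "csvd_type" else sorted(df[grouping].unique())
    rows = []
    for level in levels:
        sub = df[df[grouping] == level]
        if len(sub) == 0:
            continue
        events = int(sub["died"].sum())
        py = float(sub["followup_years"].sum())
        rate = 100.0 * events / py
        rows.append(
            {
                "group": level,
                "n": int(len(sub)),
                "events": events,
                "person_years": py,
                "rate_per_100py": rate,
                "rate_display": round_half_away(rate, 1),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
            }
        )


def km_curve(times, events, group: str = "") -> KMCurve:
    """Kaplan-Meier estimate; subjects with ``event`` false are right-censored."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    return KMCurve(
        group=group,
        times=kmf.survival_function_.index.to_numpy(),
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(),
    )


def logrank(groups: list[tuple]) -> tuple[float, int, float]:
    """k-group log-rank test.

    ``groups`` is a list of ``(times, events)`` pairs.  Returns the
    chi-square statistic, its degrees of freedom (k - 1), and the p-value.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    durations, flags, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {i} is empty")
        durations.append(t)
        flags.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(
        np.concatenate(durations), np.concatenate(labels), np.concatenate(flags)
    )
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def _design_matrix(
    df: pd.DataFrame, spec: CoxModelSpec
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.exposure is not None:
        levels = [lv for lv in _exposure_levels(df, spec) if lv != spec.reference_level]
        for lv in levels:
            cols.append((df[spec.exposure] == lv).to_numpy(dtype=float))
            names.append(f"{spec.exposure}[{lv}]")
    for cov in spec.covariates:
        if cov == "age":
            cols.append(df["age_years"].to_numpy(dtype=float))
            names.append("age")
        elif cov == "sex":
            cols.append((df["sex"] == "male").to_numpy(dtype=float))
            names.append("sex[male]")
        elif cov in RISK_FACTORS:
            cols.append(df[cov].to_numpy(dtype=float))
            names.append(cov)
        else:
            raise ValueError(f"unknown covariate: {cov!r}")
    if spec.include_followup_covariate:
        warnings.warn(
            "follow-up time is the outcome timescale; including it as a "
            "covariate is statistically degenerate",
            stacklevel=3,
        )
        cols.append(df["followup_years"].to_numpy(dtype=float))
        names.append("followup_time")
    if not cols:
        raise ValueError("model has no terms")
    return np.column_stack(cols), names


def _exposure_levels(df: pd.DataFrame, spec: CoxModelSpec) -> list:
    present = df[spec.exposure].unique()
    if spec.exposure == "csvd_type":
        order = [lv for lv in CSVD_TYPES if lv in present]
    else:
        order = sorted(present)
    if spec.reference_level not in order:
        raise ValueError(
            f"reference level {spec.reference_level!r} absent from {spec.exposure}"
        )
    if len(order) < 2:
        raise ValueError("exposure must have at least two levels present")
    return order


def _merge(cohort: pd.DataFrame, phenotypes: pd.DataFrame | None) -> pd.DataFrame:
    if phenotypes is None:
        return cohort.copy()
    keep = [c for c in ("csvd_type", "csvd_score") if c in phenotypes.columns]
    return cohort.merge(phenotypes[["subject_id", *keep]], on="subject_id")


class CoxMortalityModel:
    """Cox proportional-hazards model for group mortality contrasts.

    A thin estimator over :class:`statsmodels.duration.hazard_regression.PHReg`
    (chosen for its support of both Efron and Breslow tie handling) that
    encodes the CSVD exposure as indicator contrasts against a reference
    group and reports per-term hazard ratios with Wald 95% CIs.

    Parameters mirror :class:`CoxModelSpec`.  Fitted attributes:

    ``summary_``
        DataFrame with coef, se, hazard_ratio, ci95_low, ci95_high,
        p_value per term.
    ``n_``, ``events_``
        Subjects and deaths used in the fit.
    ``match_table_``
        Age-matching audit table when ``control_set="age_matched"``.
    """

    def __init__(
        self,
        exposure: str | None = "csvd_type",
        reference_level: str | int = "control",
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        ties_method: str = "efron",
        control_set: str = "all",
        include_followup_covariate: bool = False,
        caliper_years: float = 2.0,
        match_seed: int = 0,
    ) -> None:
        self.exposure = exposure
        self.reference_level = reference_level
        self.covariates = covariates
        self.ties_method = ties_method
        self.control_set = control_set
        self.include_followup_covariate = include_followup_covariate
        self.caliper_years = caliper_years
        self.match_seed = match_seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "exposure": self.exposure,
            "reference_level": self.reference_level,
            "covariates": self.covariates,
            "ties_method": self.ties_method,
            "control_set": self.control_set,
            "include_followup_covariate": self.include_followup_covariate,
            "caliper_years": self.caliper_years,
            "match_seed": self.match_seed,
        }

    def set_params(self, **params) -> "CoxMortalityModel":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _spec(self) -> CoxModelSpec:
        return CoxModelSpec(**self.get_params())

    def fit(
        self, cohort: pd.DataFrame, phenotypes: pd.DataFrame | None = None
    ) -> "CoxMortalityModel":
        spec = self._spec()
        df = _merge(cohort, phenotypes)
        self.match_table_ = None
        if spec.control_set == "age_matched":
            if spec.exposure is None:
                raise ValueError("age-matched control set requires an exposure")
            controls = df[df[spec.exposure] == spec.reference_level]
            exposed = df[df[spec.exposure] != spec.reference_level]
            matched, table = age_match_controls(
                controls, exposed, seed=spec.match_seed, caliper=spec.caliper_years
            )
            df = pd.concat([matched, exposed], ignore_index=True)
            self.match_table_ = table

        if int(df["died"].sum()) < 1:
            raise ValueError("no events in the analysis set")
        used = [c for c in spec.covariates if c in RISK_FACTORS] + (
            ["age_years"] if "age" in spec.covariates else []
        )
        if df[used].isna().any().any():
            raise ValueError("missing covariate values in the analysis set")

        X, names = _design_matrix(df, spec)
        model = PHReg(
            df["followup_years"].to_numpy(dtype=float),
            X,
            status=df["died"].to_numpy(dtype=int),
            ties=spec.ties_method,
        )
        try:
            res = model.fit(disp=False)
        except Exception as err:  # non-convergence surfaces with diagnostics
            raise RuntimeError(f"Cox partial-likelihood fit failed: {err}") from err
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise RuntimeError("Cox fit did not converge: non-finite coefficients")
        se = np.asarray(res.bse, dtype=float)
        if spec.exposure is not None:
            self._warn_sparse_levels(df, spec)
        z = np.divide(params, se, out=np.zeros_like(params), where=se > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        with np.errstate(over="ignore"):  # separation inflates CIs to inf
            self.summary_ = pd.DataFrame(
                {
                    "term": names,
                    "coef": params,
                    "se": se,
                    "hazard_ratio": np.exp(params),
                    "ci95_low": np.exp(params - 1.96 * se),
                    "ci95_high": np.exp(params + 1.96 * se),
                    "p_value": pvals,
                }
            ).set_index("term")
        self.n_ = int(len(df))
        self.events_ = int(df["died"].sum())
        self._fit_frame = df
        self._result = res
        return self

    def _warn_sparse_levels(self, df: pd.DataFrame, spec: CoxModelSpec) -> None:
        for lv, sub in df.groupby(spec.exposure):
            if lv != spec.reference_level and sub["died"].sum() == 0:
                warnings.warn(
                    f"exposure level {lv!r} has zero events (n={len(sub)}); "
                    "its hazard-ratio estimate is unstable",
                    stacklevel=3,
                )

    def hazard_ratios(self) -> pd.Series:
        self._check_fitted()
        return self.summary_["hazard_ratio"]

    def ph_check(self) -> float:
        """p-value of the exposure x log(time) interaction (PH assumption)."""
        self._check_fitted()
        spec = self._spec()
        if spec.exposure is None:
            raise ValueError("PH check requires an exposure")
        return ph_check(self._fit_frame, None, spec)

    def _check_fitted(self) -> None:
        if not hasattr(self, "summary_"):
            raise AttributeError("model is not fitted; call fit first")


def cox_fit(
    cohort: pd.DataFrame,
    phenotypes: pd.DataFrame | None = None,
    spec: CoxModelSpec | None = None,
) -> CoxMortalityModel:
    """Fit a Cox model per ``spec`` (default: type exposure, full adjustment)."""
    spec = spec or CoxModelSpec()
    model = CoxMortalityModel(**spec.__dict__)
    return model.fit(cohort, phenotypes)


def ph_check(
    cohort: pd.DataFrame,
    phenotypes: pd.DataFrame | None = None,
    spec: CoxModelSpec | None = None,
) -> float:
    """Proportional-hazards check: Wald test of exposure x log(time).

    Each subject's follow-up is episode-split at the distinct event times;
    the exposure indicators enter once as fixed covariates and once
    multiplied by log(time), and the test is a joint Wald chi-square on
    the interaction block.  p > 0.05 is read as no evidence against
    proportionality.
    """
    spec = spec or CoxModelSpec()
    if spec.exposure is None:
        raise ValueError("PH check requires an exposure")
    df = _merge(cohort, phenotypes)
    levels = _exposure_levels(df, spec)  # raises on a single-level exposure

    time = df["followup_years"].to_numpy(dtype=float)
    status = df["died"].to_numpy(dtype=int)
    event_times = np.unique(time[status == 1])
    if event_times.size < 2:
        raise ValueError("too few distinct event times for a PH check")

    X, names = _design_matrix(df, spec)
    n_exp = len(levels) - 1

    # Episode-split: one row per subject per event time <= its exit time.
    rows_start, rows_stop, rows_status, rows_idx = [], [], [], []
    for i in range(len(df)):
        cuts = event_times[event_times < time[i]]
        starts = np.concatenate(([0.0], cuts))
        stops = np.concatenate((cuts, [time[i]]))
        st = np.zeros(stops.size, dtype=int)
        st[-1] = status[i]
        rows_start.append(starts)
        rows_stop.append(stops)
        rows_status.append(st)
        rows_idx.append(np.full(stops.size, i))
    start = np.concatenate(rows_start)
    stop = np.concatenate(rows_stop)
    st = np.concatenate(rows_status)
    idx = np.concatenate(rows_idx)

    Xe = X[idx]
    inter = Xe[:, :n_exp] * np.log(stop)[:, None]
    design = np.column_stack([Xe, inter])
    model = PHReg(stop, design, status=st, entry=start, ties=spec.ties_method)
    res = model.fit(disp=False)
    k = design.shape[1]
    sel = np.arange(k - n_exp, k)
    beta = np.asarray(res.params)[sel]
    cov = np.asarray(res.cov_params())[np.ix_(sel, sel)]
    wald = float(beta @ np.linalg.solve(cov, beta))
    return float(stats.chi2.sf(wald, n_exp))


def plot_km_curves(curves: list[KMCurve], path: str | None = None):
    """Step plot of one or more Kaplan-Meier curves; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.step(curve.times, curve.survival, where="post", label=curve.group or None)
    ax.set_xlabel("years of follow-up")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0.0, 1.02)
    if any(c.group for c in curves):
        ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def age_match_controls(
    controls: pd.DataFrame,
    exposed: pd.DataFrame,
    seed: int,
    caliper: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """1:1 nearest-neighbour age matching of controls to exposed subjects.

    Greedy matching without replacement: exposed subjects are visited in a
    seeded random order and each takes the closest still-available control
    by age, provided the difference is within ``caliper`` years (ties
    broken by the same seeded order).  Exposed subjects with no control in
    the caliper are left unmatched and recorded in the match table.

    Returns ``(matched_controls, match_table)``; the table has one row per
    exposed subject with the matched control id and the signed age
    difference (NaN when unmatched).
    """
    if len(controls) == 0 or len(exposed) == 0:
        raise ValueError("both control and exposed sets must be non-empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(exposed))
    ctrl_ages = controls["age_years"].to_numpy(dtype=float)
    ctrl_ids = controls["subject_id"].to_numpy()
    # seeded shuffle so that equidistant controls are taken in random order
    ctrl_perm = rng.permutation(len(controls))
    available = np.ones(len(controls), dtype=bool)

    rows = []
    matched_pos = []
    for i in order:
        age = float(exposed["age_years"].iloc[i])
        diffs = np.abs(ctrl_ages - age)
        diffs[~available] = np.inf
        best = min(ctrl_perm, key=lambda j: (diffs[j], 0))
        if diffs[best] <= caliper:
            available[best] = False
            matched_pos.append(best)
            rows.append(
                {
                    "exposed_id": exposed["subject_id"].iloc[i],
                    "control_id": ctrl_ids[best],
                    "exposed_age": age,
                    "control_age": ctrl_ages[best],
                    "age_diff": age - ctrl_ages[best],
                }
            )
        else:
            rows.append(
                {
                    "exposed_id": exposed["subject_id"].iloc[i],
                    "control_id": None,
                    "exposed_age": age,
                    "control_age": np.nan,
                    "age_diff": np.nan,
                }
            )
    table = pd.DataFrame(rows)
    matched = controls.iloc[sorted(matched_pos)].copy()
    return matched, table


def survival_report(
    cohort: pd.DataFrame,
    phenotypes: pd.DataFrame,
    grouping: str = "csvd_type",
    ties_method: str = "efron",
    match_seed: int = 0,
) -> dict:
    """Mortality-table bundle for one grouping: rates, crude and adjusted HRs.

    Returns a dict with ``rates`` (person-year table), ``crude`` and
    ``adjusted`` Cox summaries, plus age-matched variants when grouping by
    CSVD type.  Mirrors the layout of a rates-and-hazard-ratios table.
    """
    ref = "control" if grouping == "csvd_type" else 0
    bundle: dict = {"rates": person_year_rates(cohort, phenotypes, grouping)}
    base = dict(exposure=grouping, reference_level=ref, ties_method=ties_method)
    bundle["crude"] = cox_fit(
        cohort, phenotypes, CoxModelSpec(covariates=(), **base)
    ).summary_
    bundle["age_sex_adjusted"] = cox_fit(
        cohort, phenotypes, CoxModelSpec(covariates=("age", "sex"), **base)
    ).summary_
    bundle["adjusted"] = cox_fit(
        cohort, phenotypes, CoxModelSpec(covariates=DEFAULT_COVARIATES, **base)
    ).summary_
    if grouping == "csvd_type":
        for key, covs in [
            ("age_matched_age_sex_adjusted", ("age", "sex")),
            ("age_matched_adjusted", DEFAULT_COVARIATES),
        ]:
            model = cox_fit(
                cohort,
                phenotypes,
                CoxModelSpec(
                    covariates=covs,
                    control_set="age_matched",
                    match_seed=match_seed,
                    **base,
                ),
            )
            bundle[key] = model.summary_
    return bundle
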