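"""Synthetic CSVD cohorts: a configurable generator and a deterministic fixture.

The generator works group-first: each subject is assigned a phenotype
(control or CSVD type 1-4) and the MRI markers are then drawn so that the
classifier recovers the assigned group exactly under the fixed severity
threshold (marker rules invert the classification scheme).  Demographics,
risk-factor prevalences and marker frequencies default to the published
group profiles; death times follow an exponential (optionally Weibull)
hazard with log-linear covariate effects, right-censored at a drawn
follow-up time.

``build_table1_fixture`` returns a fixed 735-subject cohort whose
classification reproduces the published marginal tables (group counts,
score-category counts, per-group event counts and person-year totals).
The source tables are internally inconsistent in two places — the type-1
person-year total and the type-4 lacune marginal — so the fixture
reproduces the self-consistent majority and the deviations are documented
in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log

import numpy as np
import pandas as pd
from scipy import stats

from .schema import COLUMNS, CSVD_TYPES, validate_cohort

#: Fixed WMH/TIV severity threshold used by the generator and fixture (0.07%).
SEVERE_THRESHOLD = 0.0007

_GROUPS = CSVD_TYPES  # control, type1..type4 order used throughout

#: Published per-group profile: n, age mean/sd, male fraction, risk-factor
#: prevalences, continuous covariate means/sds, follow-up mean/sd.
GROUP_PROFILE = pd.DataFrame(
    {
        "n": [335, 249, 52, 61, 38],
        "age_mean": [57.9, 65.6, 67.8, 67.1, 64.3],
        "age_sd": [5.9, 8.1, 9.2, 10.3, 9.0],
        "male_n": [132, 120, 26, 31, 17],
        "hypertension_n": [77, 106, 28, 25, 9],
        "diabetes_n": [22, 46, 14, 11, 8],
        "dyslipidemia_n": [15, 14, 2, 7, 3],
        "smoking_n": [67, 75, 18, 17, 9],
        "sbp_mean": [124.3, 132.0, 134.7, 132.6, 129.2],
        "sbp_sd": [14.7, 16.3, 19.3, 18.0, 21.3],
        "ldl_mean": [120.1, 117.3, 114.0, 113.6, 112.5],
        "ldl_sd": [33.6, 31.2, 27.8, 29.7, 27.4],
        "hba1c_mean": [5.8, 6.0, 6.6, 6.1, 6.0],
        "hba1c_sd": [0.6, 0.8, 1.4, 1.0, 0.8],
    },
    index=_GROUPS,
)

#: Published mortality table by CSVD type: events and person-years.
GROUP_EVENTS = {"control": 18, "type1": 18, "type2": 10, "type3": 9, "type4": 7}
GROUP_PERSON_YEARS = {"control": 1925.0, "type1": 914.0, "type2": 294.0,
                      "type3": 337.0, "type4": 215.0}
#: Published mortality table by burden score.
SCORE_EVENTS = {0: 18, 1: 20, 2: 21, 3: 3}
SCORE_PERSON_YEARS = {0: 1925.0, 1: 1559.0, 2: 544.0, 3: 157.0}


def _default_log_hr() -> dict:
    # Group effects from the published adjusted contrasts; covariate effects
    # are typical all-cause-mortality gradients (see docs/methods.md).
    return {
        "type1": log(1.0),
        "type2": log(2.4),
        "type3": log(1.6),
        "type4": log(5.0),
        "age_per_year": log(1.09),
        "male": log(1.5),
        "hypertension": log(1.3),
        "diabetes": log(1.5),
        "dyslipidemia": 0.0,
        "smoking": log(1.5),
    }


@dataclass
class SimConfig:
    """Everything that controls a synthetic cohort draw.

    ``baseline_hazard`` is the yearly death hazard of the reference
    subject (control group, age ``age_center``, female, no risk factors);
    ``log_hr`` maps group levels and covariates to log hazard ratios.
    ``weibull_shape`` = 1 gives the default exponential (proportional)
    hazard; other values allow PH-violation experiments.
    """

    n: int = 735
    seed: int = 0
    group_probs: tuple = (335 / 735, 249 / 735, 52 / 735, 61 / 735, 38 / 735)
    severe_threshold: float = SEVERE_THRESHOLD
    type3_severe_p: float = 0.803
    type3_lacune_p: float = 0.426
    type4_severe_p: float = 0.579
    type4_lacune_p: float = 0.132
    baseline_hazard: float = 0.0074
    weibull_shape: float = 1.0
    age_center: float = 60.0
    followup_mean: float = 5.7
    followup_sd: float = 0.7
    followup_bounds: tuple = (0.5, 8.0)
    log_hr: dict = field(default_factory=_default_log_hr)

    def __post_init__(self) -> None:
        probs = np.asarray(self.group_probs, dtype=float)
        if probs.size != 5 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("group_probs must be 5 non-negative values summing to 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_probs"] = list(self.group_probs)
        d["followup_bounds"] = list(self.followup_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "group_probs" in d:
            d["group_probs"] = tuple(d["group_probs"])
        if "followup_bounds" in d:
            d["followup_bounds"] = tuple(d["followup_bounds"])
        if "log_hr" in d:
            merged = _default_log_hr()
            merged.update(d["log_hr"])
            d["log_hr"] = merged
        return cls(**d)


def _trunc_lognormal(rng, n, mu, sigma, lo, hi):
    """Log-normal draws truncated to (lo, hi) via inverse-CDF sampling."""
    a = stats.norm.cdf((np.log(lo) - mu) / sigma)
    b = stats.norm.cdf((np.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _zt_poisson(rng, n, lam):
    """Zero-truncated Poisson draws (resampling rejection)."""
    out = rng.poisson(lam, size=n)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, size=int(zero.sum()))


def simulate_cohort(config: SimConfig | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort; reproducible given ``config.seed``."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    thr = cfg.severe_threshold
    group_idx = rng.choice(5, size=n, p=np.asarray(cfg.group_probs, dtype=float))
    group = np.asarray(_GROUPS, dtype=object)[group_idx]

    prof = GROUP_PROFILE
    age = rng.normal(
        prof["age_mean"].to_numpy()[group_idx], prof["age_sd"].to_numpy()[group_idx]
    ).clip(50.0, 95.0)
    male = rng.random(n) < (prof["male_n"] / prof["n"]).to_numpy()[group_idx]
    rf = {}
    for factor in ["hypertension", "diabetes", "dyslipidemia", "smoking"]:
        p = (prof[f"{factor}_n"] / prof["n"]).to_numpy()[group_idx]
        rf[factor] = (rng.random(n) < p).astype(int)
    sbp = rng.normal(prof["sbp_mean"].to_numpy()[group_idx],
                     prof["sbp_sd"].to_numpy()[group_idx])
    ldl = rng.normal(prof["ldl_mean"].to_numpy()[group_idx],
                     prof["ldl_sd"].to_numpy()[group_idx])
    hba1c = rng.normal(prof["hba1c_mean"].to_numpy()[group_idx],
                       prof["hba1c_sd"].to_numpy()[group_idx])

    # --- markers, drawn to invert the classifier exactly ---
    severe = np.zeros(n, dtype=bool)
    severe[group == "type1"] = True
    severe[group == "type2"] = True
    m3, m4 = group == "type3", group == "type4"
    severe[m3] = rng.random(int(m3.sum())) < cfg.type3_severe_p
    severe[m4] = rng.random(int(m4.sum())) < cfg.type4_severe_p

    ratio = np.empty(n)
    ns, sv = ~severe, severe
    # non-severe stratum: median well below threshold; severe: above it
    ratio[ns] = _trunc_lognormal(rng, int(ns.sum()), np.log(3e-4), 0.5,
                                 2e-5, thr * 0.99)
    ratio[sv] = _trunc_lognormal(rng, int(sv.sum()), np.log(2.5e-3), 0.7,
                                 thr * 1.01, 5e-2)

    lacune = np.zeros(n, dtype=int)
    m2 = group == "type2"
    lacune[m2] = _zt_poisson(rng, int(m2.sum()), 0.87)  # mean ~1.5
    has3 = m3 & (rng.random(n) < cfg.type3_lacune_p)
    lacune[has3] = _zt_poisson(rng, int(has3.sum()), 1.75)  # mean ~2.1
    has4 = m4 & (rng.random(n) < cfg.type4_lacune_p)
    lacune[has4] = _zt_poisson(rng, int(has4.sum()), 0.9)

    cmb_lobar = np.zeros(n, dtype=int)
    cmb_deep = np.zeros(n, dtype=int)
    cmb_infra = np.zeros(n, dtype=int)
    n3 = int(m3.sum())
    if n3:
        total = _zt_poisson(rng, n3, 2.5)  # mean ~2.7
        deep = rng.binomial(total, 0.45)
        infra = rng.binomial(total - deep, 0.25)
        lobar = total - deep - infra
        none_deep = (deep + infra) == 0  # mixed topography requires one
        deep[none_deep] += 1
        lobar[none_deep] -= 1
        cmb_deep[m3], cmb_infra[m3], cmb_lobar[m3] = deep, infra, lobar
    n4 = int(m4.sum())
    if n4:
        cmb_lobar[m4] = _zt_poisson(rng, n4, 0.44)  # mean ~1.2

    tiv = rng.normal(1450.0, 120.0, size=n).clip(1100.0, 1900.0)
    wmh = ratio * tiv

    # --- survival ---
    lh = cfg.log_hr
    beta_group = np.array([0.0, lh["type1"], lh["type2"], lh["type3"], lh["type4"]])
    lp = (
        beta_group[group_idx]
        + lh["age_per_year"] * (age - cfg.age_center)
        + lh["male"] * male.astype(float)
        + lh["hypertension"] * rf["hypertension"]
        + lh["diabetes"] * rf["diabetes"]
        + lh["dyslipidemia"] * rf["dyslipidemia"]
        + lh["smoking"] * rf["smoking"]
    )
    hazard = cfg.baseline_hazard * np.exp(lp)
    u = rng.uniform(size=n)
    death_time = (-np.log(u) / hazard) ** (1.0 / cfg.weibull_shape)
    censor = rng.normal(cfg.followup_mean, cfg.followup_sd, size=n).clip(
        *cfg.followup_bounds
    )
    died = death_time <= censor
    followup = np.where(died, death_time, censor)

    df = pd.DataFrame(
        {
            "subject_id": [f"P{i:06d}" for i in range(n)],
            "age_years": age,
            "sex": np.where(male, "male", "female"),
            "hypertension": rf["hypertension"],
            "diabetes": rf["diabetes"],
            "dyslipidemia": rf["dyslipidemia"],
            "smoking": rf["smoking"],
            "sbp_mmhg": sbp,
            "ldl_mg_dl": ldl,
            "hba1c_pct": hba1c,
            "wmh_volume_ml": wmh,
            "tiv_ml": tiv,
            "lacune_count": lacune,
            "cmb_lobar": cmb_lobar,
            "cmb_deep": cmb_deep,
            "cmb_infratentorial": cmb_infra,
            "followup_years": followup,
            "died": died.astype(int),
        },
        columns=COLUMNS,
    )
    out = validate_cohort(df)
    out.attrs["true_group"] = group
    return out


# ---------------------------------------------------------------------------
# Deterministic fixture
# ---------------------------------------------------------------------------

# Cells of the fixture: (csvd_type, score) -> n, events, person-years, and the
# marker pattern (severe, lacune count).  Score-2 cells of the bleeding groups
# split into severe-only and lacune-only sub-cells to hit the published severe
# and lacune marginals (type 3: severe 49, lacune 26; type 4: severe 22).
# Person-years per type match the published table exactly; per score they
# match for scores 0, 2, 3 (the score-1 total is irreconcilable with the
# type-1 row; see module docstring).
_FIXTURE_CELLS = [
    # type,   n,  events, person_years, severe, lacune_n
    ("control", 335, 18, 1925.0, False, 0),
    ("type1", 249, 18, 914.0, True, 0),
    ("type2", 52, 10, 294.0, True, 2),  # lacune counts alternate 1/2 -> mean 1.5
    ("type3", 10, 1, 56.0, False, 0),    # score 1
    ("type3", 25, 5, 135.0, True, 0),    # score 2, severe only
    ("type3", 2, 1, 11.0, False, 2),     # score 2, lacune only
    ("type3", 24, 2, 135.0, True, 2),    # score 3
    ("type4", 16, 1, 89.0, False, 0),    # score 1
    ("type4", 18, 5, 104.0, True, 0),    # score 2, severe only
    ("type4", 4, 1, 22.0, True, 1),      # score 3
]

_FIXTURE_SEED = 20211130  # fixed: the fixture is deterministic by construction


def _spread(mean: float, sd: float, n: int) -> np.ndarray:
    """Deterministic normal-quantile spread with the given mean and scale."""
    if n == 1:
        return np.array([mean])
    q = stats.norm.ppf((np.arange(n) + 0.5) / n)
    return mean + sd * q


def build_table1_fixture() -> pd.DataFrame:
    """Deterministic 735-subject cohort reproducing the published marginals.

    Classification under the fixed 0.07% threshold yields group counts
    335/249/52/61/38, burden-score counts 335/275/97/28 and 62 deaths;
    per-type event counts and person-year totals equal the published
    mortality table.  Follow-up times are spread evenly within each cell
    so that they sum exactly to the cell's person-years, with deaths
    assigned to the earliest (shortest-follow-up) subjects.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    thr = SEVERE_THRESHOLD
    frames = []
    for ci, (gtype, n, events, py, severe, lacune_n) in enumerate(_FIXTURE_CELLS):
        mean_fu = py / n
        # wide symmetric spread: keeps the exact person-year sum while the
        # groups' observation windows overlap (disjoint windows would make
        # group contrasts inestimable in a Cox model)
        half = min(2.0, mean_fu - 0.5)
        fu = np.linspace(mean_fu - half, mean_fu + half, n) if n > 1 else np.array([mean_fu])
        died = np.zeros(n, dtype=int)
        died[:events] = 1  # earliest follow-ups are the deaths
        if severe:
            lo, hi = thr * 1.05, 8.5e-3
        else:
            lo, hi = 0.05e-3, thr * 0.92
        ratio = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
        lacune = np.full(n, lacune_n, dtype=int)
        if gtype == "type2":
            lacune = 1 + (np.arange(n) % 2)  # counts 1/2, mean 1.5
        lobar = np.zeros(n, dtype=int)
        deep = np.zeros(n, dtype=int)
        if gtype == "type3":
            deep[:] = 1
            lobar[:] = np.resize([0, 1, 2, 4], n)  # mean total CMB ~2.7
        elif gtype == "type4":
            lobar[:] = 1 + (np.arange(n) % 5 == 0)  # mean ~1.2
        frames.append(
            pd.DataFrame(
                {
                    "cell": ci,
                    "csvd_type": gtype,
                    "followup_years": fu,
                    "died": died,
                    "ratio": ratio,
                    "lacune_count": lacune,
                    "cmb_lobar": lobar,
                    "cmb_deep": deep,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)

    # demographics drawn per group from the published profile, permuted so
    # they are not aligned with follow-up order within cells
    prof = GROUP_PROFILE
    for col in ["age_years", "sex", "hypertension", "diabetes", "dyslipidemia",
                "smoking", "sbp_mmhg", "ldl_mg_dl", "hba1c_pct"]:
        df[col] = 0.0 if col != "sex" else ""
    for gtype in _GROUPS:
        mask = (df["csvd_type"] == gtype).to_numpy()
        n = int(mask.sum())
        row = prof.loc[gtype]
        ages = _spread(row["age_mean"], row["age_sd"], n)
        df.loc[mask, "age_years"] = rng.permutation(ages)
        sex = np.array(["male"] * int(row["male_n"]) + ["female"] * (n - int(row["male_n"])))
        df.loc[mask, "sex"] = rng.permutation(sex)
        for factor in ["hypertension", "diabetes", "dyslipidemia", "smoking"]:
            k = int(row[f"{factor}_n"])
            flags = np.array([1] * k + [0] * (n - k))
            df.loc[mask, factor] = rng.permutation(flags)
        for cont in ["sbp", "ldl", "hba1c"]:
            vals = _spread(row[f"{cont}_mean"], row[f"{cont}_sd"], n)
            col = {"sbp": "sbp_mmhg", "ldl": "ldl_mg_dl", "hba1c": "hba1c_pct"}[cont]
            df.loc[mask, col] = rng.permutation(vals)

    tiv = 1400.0
    out = pd.DataFrame(
        {
            "subject_id": [f"F{i:04d}" for i in range(len(df))],
            "age_years": df["age_years"].round(1),
            "sex": df["sex"],
            "hypertension": df["hypertension"].astype(int),
            "diabetes": df["diabetes"].astype(int),
            "dyslipidemia": df["dyslipidemia"].astype(int),
            "smoking": df["smoking"].astype(int),
            "sbp_mmhg": df["sbp_mmhg"].round(1),
            "ldl_mg_dl": df["ldl_mg_dl"].round(1),
            "hba1c_pct": df["hba1c_pct"].round(2),
            "wmh_volume_ml": df["ratio"] * tiv,
            "tiv_ml": tiv,
            "lacune_count": df["lacune_count"],
            "cmb_lobar": df["cmb_lobar"],
            "cmb_deep": df["cmb_deep"],
            "cmb_infratentorial": 0,
            "followup_years": df["followup_years"],
            "died": df["died"],
        },
        columns=COLUMNS,
    )
    return validate_cohort(out)
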