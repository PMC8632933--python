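"""MRI-marker-based CSVD phenotype classification and burden scoring.

The stratification scheme assigns each subject one of five labels using
three MRI markers in a fixed decision order:

1. **Cerebral microbleeds (CMB) present?**  If yes, the subject has a
   bleeding phenotype and the CMB topography decides the subtype:
   *mixed* (any deep and/or infratentorial CMB, with or without lobar
   ones, suggesting arteriosclerosis/lipohyalinosis) → **type 3**;
   *strictly lobar* (CMB exclusively in lobar regions, suggesting
   cerebral amyloid angiopathy) → **type 4**.
2. **Severe white-matter hyperintensity (WMH) burden?**  Severity is a
   WMH/TIV volume ratio strictly above a threshold — either the cohort's
   50th percentile or a fixed fraction (0.0007 in the original cohort).
   Severe WMH without CMB → **type 1** if no lacune, **type 2** with at
   least one lacune.
3. Neither CMB nor severe WMH → **control**.  A control subject with a
   lacune is flagged (``lacune_only_flag``): the scheme assigns such
   subjects nowhere else and they are tallied separately in reports.

The simple CSVD burden score (0–3) awards one point each for the presence
of any lacune, severe WMH, and any CMB.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import CSVD_TYPES, RESULT_COLUMNS, CohortValidationError, validate_cohort

#: WMH/TIV severity threshold of the original cohort (0.07%).
DEFAULT_FIXED_THRESHOLD = 0.0007

SCORE_LEVELS = [0, 1, 2, 3]


@dataclass(frozen=True)
class ClassificationConfig:
    """Threshold provenance for severe-WMH determination.

    threshold_mode
        ``"cohort_median"`` recomputes the 50th percentile of the WMH/TIV
        ratio from the cohort at hand; ``"fixed"`` uses
        ``fixed_threshold`` (a fraction, e.g. 0.0007 for 0.07%).
    """

    threshold_mode: str = "cohort_median"
    fixed_threshold: float = DEFAULT_FIXED_THRESHOLD

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("cohort_median", "fixed"):
            raise ValueError(f"unknown threshold_mode: {self.threshold_mode!r}")
        if not 0.0 < self.fixed_threshold < 1.0:
            raise ValueError("fixed_threshold must lie in (0, 1)")


def compute_wmh_ratio(wmh_volume_ml: float, tiv_ml: float) -> float:
    """WMH volume as a fraction of total intracranial volume."""
    if tiv_ml <= 0:
        raise ValueError("tiv_ml must be positive")
    if wmh_volume_ml < 0:
        raise ValueError("wmh_volume_ml must be non-negative")
    if wmh_volume_ml > tiv_ml:
        raise ValueError("wmh_volume_ml cannot exceed tiv_ml")
    return wmh_volume_ml / tiv_ml


def compute_severe_threshold(
    ratios: Iterable[float], config: ClassificationConfig
) -> float:
    """Severity cut-point for the WMH/TIV ratio.

    In ``cohort_median`` mode this is the sample median (linear
    interpolation for even n); in ``fixed`` mode it is the configured
    fraction regardless of the data.
    """
    if config.threshold_mode == "fixed":
        return config.fixed_threshold
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take the cohort median of an empty ratio list")
    return float(np.median(arr))


def classify_cmb_topography(
    cmb_lobar: int, cmb_deep: int, cmb_infratentorial: int
) -> str:
    """Topographic CMB class: ``none``, ``strictly_lobar`` or ``mixed``.

    Any deep and/or infratentorial microbleed makes the pattern mixed,
    with or without lobar ones; lobar-only is strictly lobar.
    """
    if min(cmb_lobar, cmb_deep, cmb_infratentorial) < 0:
        raise ValueError("CMB counts must be non-negative")
    if cmb_deep > 0 or cmb_infratentorial > 0:
        return "mixed"
    if cmb_lobar > 0:
        return "strictly_lobar"
    return "none"


def classify_csvd_type(record: Mapping, threshold: float) -> dict:
    """Classify a single subject; returns the per-subject phenotype result.

    ``record`` needs the MRI marker fields of the cohort schema.  The
    severity comparison is strict: a ratio exactly equal to the threshold
    is not severe.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    ratio = compute_wmh_ratio(record["wmh_volume_ml"], record["tiv_ml"])
    severe = ratio > threshold
    lacune = int(record["lacune_count"]) >= 1
    topography = classify_cmb_topography(
        int(record["cmb_lobar"]),
        int(record["cmb_deep"]),
        int(record["cmb_infratentorial"]),
    )
    if topography == "mixed":
        csvd_type = "type3"
    elif topography == "strictly_lobar":
        csvd_type = "type4"
    elif severe:
        csvd_type = "type2" if lacune else "type1"
    else:
        csvd_type = "control"
    score = int(lacune) + int(severe) + int(topography != "none")
    return {
        "subject_id": str(record.get("subject_id", "")),
        "wmh_ratio": ratio,
        "severe_wmh": bool(severe),
        "cmb_topography": topography,
        "csvd_type": csvd_type,
        "csvd_score": score,
        "lacune_only_flag": bool(csvd_type == "control" and lacune),
    }


def compute_csvd_score(record: Mapping, threshold: float) -> int:
    """Simple CSVD burden score: one point each for any lacune, severe WMH, any CMB."""
    return classify_csvd_type(record, threshold)["csvd_score"]


class CSVDPhenotypeClassifier(BaseEstimator, TransformerMixin):
    """Rule-based CSVD phenotype classifier with a learned severity threshold.

    ``fit`` determines the severe-WMH threshold (the cohort median of the
    WMH/TIV ratio, or a fixed fraction); ``predict`` returns the five-level
    CSVD type per subject and ``transform`` the full per-subject result
    table (ratio, severity flag, CMB topography, type, burden score,
    lacune-only flag).  Input is a cohort DataFrame following the schema in
    :mod:`csvdstrat.schema`.

    Parameters
    ----------
    threshold_mode : {"cohort_median", "fixed"}, default "cohort_median"
        Provenance of the severity threshold.
    fixed_threshold : float, default 0.0007
        Threshold used in ``fixed`` mode (WMH/TIV fraction).

    Attributes
    ----------
    threshold_ : float
        Severity cut-point applied by ``predict``/``transform``.
    """

    def __init__(
        self,
        threshold_mode: str = "cohort_median",
        fixed_threshold: float = DEFAULT_FIXED_THRESHOLD,
    ) -> None:
        self.threshold_mode = threshold_mode
        self.fixed_threshold = fixed_threshold

    def _config(self) -> ClassificationConfig:
        return ClassificationConfig(
            threshold_mode=self.threshold_mode, fixed_threshold=self.fixed_threshold
        )

    def fit(self, X: pd.DataFrame, y=None) -> "CSVDPhenotypeClassifier":
        cohort = validate_cohort(X)
        ratios = cohort["wmh_volume_ml"].to_numpy() / cohort["tiv_ml"].to_numpy()
        self.threshold_ = compute_severe_threshold(ratios, self._config())
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-subject phenotype results in cohort row order."""
        if not hasattr(self, "threshold_"):
            raise AttributeError("classifier is not fitted; call fit first")
        cohort = validate_cohort(X)
        ratio = cohort["wmh_volume_ml"].to_numpy() / cohort["tiv_ml"].to_numpy()
        severe = ratio > self.threshold_
        lacune = cohort["lacune_count"].to_numpy() >= 1
        deep_or_infra = (
            cohort["cmb_deep"].to_numpy() + cohort["cmb_infratentorial"].to_numpy()
        ) > 0
        lobar = cohort["cmb_lobar"].to_numpy() > 0
        topography = np.where(
            deep_or_infra, "mixed", np.where(lobar, "strictly_lobar", "none")
        )
        csvd_type = np.where(
            deep_or_infra,
            "type3",
            np.where(
                lobar,
                "type4",
                np.where(severe, np.where(lacune, "type2", "type1"), "control"),
            ),
        )
        score = severe.astype(int) + lacune.astype(int) + (topography != "none").astype(int)
        return pd.DataFrame(
            {
                "subject_id": cohort["subject_id"],
                "wmh_ratio": ratio,
                "severe_wmh": severe,
                "cmb_topography": topography,
                "csvd_type": csvd_type,
                "csvd_score": score,
                "lacune_only_flag": (csvd_type == "control") & lacune,
            },
            columns=RESULT_COLUMNS,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """CSVD type labels (control/type1..type4) per subject."""
        return self.transform(X)["csvd_type"].to_numpy()


def classify_cohort(
    cohort: pd.DataFrame, config: ClassificationConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Classify a whole cohort; returns (result table, group-count summary).

    The summary reports counts by CSVD type, by burden-score category, and
    the number of lacune-only control subjects.
    """
    config = config or ClassificationConfig()
    clf = CSVDPhenotypeClassifier(
        threshold_mode=config.threshold_mode, fixed_threshold=config.fixed_threshold
    ).fit(cohort)
    results = clf.transform(cohort)
    type_counts = results["csvd_type"].value_counts()
    score_counts = results["csvd_score"].value_counts()
    summary = {
        "threshold": clf.threshold_,
        "n": int(len(results)),
        "type_counts": {t: int(type_counts.get(t, 0)) for t in CSVD_TYPES},
        "score_counts": {s: int(score_counts.get(s, 0)) for s in SCORE_LEVELS},
        "lacune_only": int(results["lacune_only_flag"].sum()),
    }
    return results, summary
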