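"""End-to-end orchestration: cohort -> classification -> survival -> reports.

``run_pipeline`` takes a cohort source (CSV path, the built-in fixture, or
a simulation request), classifies it, and writes the phenotype table, the
group-comparison table, the mortality-rate/hazard-ratio tables for both
groupings, the type-4 subgroup table, Kaplan-Meier coordinate tables and
a run manifest with a content digest per artifact.  Identical inputs and
seed produce an identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .descriptives import subgroup_hazards, table1_report
from .phenotype import ClassificationConfig, classify_cohort
from .schema import load_cohort_csv, write_cohort_csv
from .simulate import SimConfig, build_table1_fixture, simulate_cohort
from .survival import km_curve, logrank, survival_report

log = logging.getLogger("csvdstrat")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_cohort(source: str, sim_config: SimConfig | None = None) -> pd.DataFrame:
    """Resolve a cohort source: ``fixture``, ``simulate`` or a CSV path."""
    if source == "fixture":
        return build_table1_fixture()
    if source == "simulate":
        return simulate_cohort(sim_config or SimConfig())
    return load_cohort_csv(source)


def run_pipeline(
    source: str,
    out_dir: str | Path,
    classification: ClassificationConfig | None = None,
    sim_config: SimConfig | None = None,
    seed: int = 0,
) -> dict:
    """Run the full analysis and write the report bundle; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classification = classification or ClassificationConfig(
        threshold_mode="fixed"
    )
    cohort = load_cohort(source, sim_config)
    log.info("cohort loaded: %d subjects", len(cohort))

    results, summary = classify_cohort(cohort, classification)
    log.info("classified with threshold %.6f: %s", summary["threshold"], summary["type_counts"])

    artifacts: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        artifacts[name] = path

    write_cohort_csv(cohort, out / "cohort.csv")
    artifacts["cohort.csv"] = out / "cohort.csv"
    results.to_csv(out / "phenotypes.csv", index=False)
    artifacts["phenotypes.csv"] = out / "phenotypes.csv"

    save("table1.csv", table1_report(cohort, results))
    for grouping in ["csvd_type", "csvd_score"]:
        bundle = survival_report(cohort, results, grouping, match_seed=seed)
        tag = "type" if grouping == "csvd_type" else "score"
        save(f"table2_{tag}_rates.csv", bundle["rates"])
        for key, frame in bundle.items():
            if key == "rates":
                continue
            save(f"cox_{tag}_{key}.csv", frame.reset_index())
    try:
        save("table3_type4.csv", subgroup_hazards(cohort, results, "type4"))
    except ValueError as err:
        log.warning("type-4 subgroup table skipped: %s", err)

    # KM coordinates and log-rank by type
    merged = cohort.merge(results[["subject_id", "csvd_type"]], on="subject_id")
    curves = []
    groups = []
    for gname, sub in merged.groupby("csvd_type"):
        curves.append(
            km_curve(sub["followup_years"], sub["died"].astype(bool), group=gname).as_frame()
        )
        groups.append((sub["followup_years"].to_numpy(), sub["died"].to_numpy(dtype=bool)))
    save("km_curves.csv", pd.concat(curves, ignore_index=True))
    lr_stat, lr_df, lr_p = logrank(groups)

    manifest = {
        "package_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "source": source,
        "seed": seed,
        "classification": {
            "threshold_mode": classification.threshold_mode,
            "fixed_threshold": classification.fixed_threshold,
            "threshold_used": summary["threshold"],
        },
        "sim_config": sim_config.to_dict() if sim_config else None,
        "summary": summary,
        "logrank_by_type": {"statistic": lr_stat, "df": lr_df, "p_value": lr_p},
        "artifacts": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("bundle written to %s (%d artifacts)", out, len(artifacts))
    return manifest
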