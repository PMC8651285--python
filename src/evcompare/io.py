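"""CSV/JSON/YAML readers and writers for the pipeline's external formats.

All CSVs are comma-separated UTF-8 with a mandatory header and '.' decimal
separator; malformed rows fail loudly rather than being skipped.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .assay import CalibrationStandard, ConcentrationEstimate
from .compare import (
    MethodMeasurement,
    PurityResult,
    RankingReport,
    RecoveryResult,
    average_day_replicates,
    correct_input_volume,
)
from .errors import ConfigurationError

__all__ = [
    "read_calibration_csv",
    "read_plate_csv",
    "read_measurement_csv",
    "measurements_from_table",
    "write_estimates_csv",
    "build_report",
    "write_report_json",
    "render_report_table",
    "load_run_config",
    "config_hash",
]

CALIBRATION_COLUMNS = ["marker", "concentration_pM", "replicate", "aeb"]
PLATE_COLUMNS = ["sample_id", "marker", "replicate", "n_on", "n_total"]
MEASUREMENT_COLUMNS = [
    "biofluid",
    "method",
    "marker",
    "replicate_day",
    "value_pM",
    "input_volume_ml",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{what}: missing columns {missing}")


def read_calibration_csv(path: str | Path) -> dict[str, list[CalibrationStandard]]:
    """Calibration standards grouped by marker."""
    df = pd.read_csv(path)
    _require_columns(df, CALIBRATION_COLUMNS, "calibration CSV")
    if df["aeb"].isna().any() or df["concentration_pM"].isna().any():
        raise ConfigurationError("calibration CSV: missing values")
    out: dict[str, list[CalibrationStandard]] = {}
    for (marker, conc), grp in df.groupby(["marker", "concentration_pM"], sort=True):
        out.setdefault(str(marker), []).append(
            CalibrationStandard(
                marker=str(marker),
                concentration_pM=float(conc),
                signal_replicates=tuple(float(a) for a in grp["aeb"]),
            )
        )
    return out


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Well-array counts; rejects saturated rows (all wells on) by number."""
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS, "plate CSV")
    bad = df.index[(df["n_on"] >= df["n_total"]) | (df["n_on"] < 0) | (df["n_total"] <= 0)]
    if len(bad):
        # +2: header line plus 1-based indexing
        raise ConfigurationError(
            f"plate CSV: saturated or invalid counts at rows {[int(i) + 2 for i in bad]}"
        )
    return df


def read_measurement_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, MEASUREMENT_COLUMNS, "measurement CSV")
    if df["value_pM"].isna().any():
        raise ConfigurationError("measurement CSV: missing values")
    return df


def measurements_from_table(
    table: pd.DataFrame, standard_volume_ml: float = 0.5
) -> dict[str, list[MethodMeasurement]]:
    """Long-format replicate rows -> averaged measurements per biofluid.

    Each replicate is volume-corrected to ``standard_volume_ml`` before
    day-replicate averaging, mirroring the analysis convention for
    conditions run from reduced sample volumes.
    """
    out: dict[str, list[MethodMeasurement]] = {}
    for (biofluid, method), grp in table.groupby(["biofluid", "method"], sort=True):
        replicates = []
        for _, rep in grp.groupby("replicate_day", sort=True):
            volumes = rep["input_volume_ml"].unique()
            if len(volumes) != 1:
                raise ConfigurationError(
                    f"{method}: inconsistent input volume within a replicate"
                )
            m = MethodMeasurement(
                biofluid=str(biofluid),
                method=str(method),
                marker_values_pM={
                    str(r["marker"]): float(r["value_pM"]) for _, r in rep.iterrows()
                },
                input_volume_ml=float(volumes[0]),
            )
            replicates.append(correct_input_volume(m, standard_volume_ml))
        out.setdefault(str(biofluid), []).append(average_day_replicates(replicates))
    return out


def write_estimates_csv(
    estimates: list[tuple[str, ConcentrationEstimate]], path: str | Path
) -> None:
    rows = [
        dict(
            sample_id=sid,
            marker=e.marker,
            value_pM=e.value_pM,
            cv=e.cv,
            n_replicates=e.n_replicates,
            flags=";".join(sorted(e.flags)),
        )
        for sid, e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def build_report(
    biofluid: str,
    recoveries: Sequence[RecoveryResult],
    purities: Sequence[PurityResult],
    ranking: RankingReport,
    reference: str,
    seed: int | None = None,
) -> dict[str, Any]:
    """Machine-readable comparison report for one biofluid.

    Concentrations are compared as measured in each condition's final
    eluate/pool; pools of different volume are not renormalised, matching
    the study convention this pipeline follows (noted in the report).
    """
    ref_rec = next(r for r in recoveries if r.method == reference)
    fold_changes = {
        r.method: dict(
            recovery_vs_reference=r.combined_recovery / ref_rec.combined_recovery,
            albumin_vs_reference=next(p for p in purities if p.method == r.method).albumin_pM
            / next(p for p in purities if p.method == reference).albumin_pM,
        )
        for r in recoveries
    }
    return dict(
        biofluid=biofluid,
        reference=reference,
        note=(
            "concentrations are per final eluate/pool without correction for "
            "pool-volume differences between methods"
        ),
        seed=seed,
        recoveries={
            r.method: dict(
                per_marker_ratio=dict(r.per_marker_ratio),
                combined_recovery=r.combined_recovery,
            )
            for r in recoveries
        },
        purities={
            p.method: dict(
                tetraspanin_sum_pM=p.tetraspanin_sum_pM,
                albumin_pM=p.albumin_pM,
                purity=p.purity,
            )
            for p in purities
        },
        fold_changes=fold_changes,
        winners=dict(
            high_yield=ranking.high_yield,
            high_purity=ranking.high_purity,
            yield_ties=list(ranking.yield_ties),
            purity_ties=list(ranking.purity_ties),
        ),
    )


def write_report_json(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def render_report_table(report: dict[str, Any]) -> str:
    """Human-readable summary table of one biofluid's report."""
    lines = [
        f"biofluid: {report['biofluid']}   reference: {report['reference']}",
        f"{'method':<18}{'recovery':>10}{'purity':>14}{'albumin pM':>16}",
    ]
    for method in sorted(report["recoveries"]):
        rec = report["recoveries"][method]["combined_recovery"]
        pur = report["purities"][method]["purity"]
        alb = report["purities"][method]["albumin_pM"]
        lines.append(f"{method:<18}{rec:>10.3f}{pur:>14.4g}{alb:>16.4g}")
    w = report["winners"]
    lines.append(f"high yield: {w['high_yield']}   high purity: {w['high_purity']}")
    return "\n".join(lines)


def load_run_config(path: str | Path, allowed_keys: set[str]) -> dict[str, Any]:
    """YAML run configuration; unknown keys are rejected."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigurationError("run config must be a mapping")
    unknown = set(raw) - allowed_keys
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return raw


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
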