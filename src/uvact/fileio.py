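"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 CSV with a header row and "." decimal separator; every
CSV report has a JSON mirror for machine use.  Readers validate row by row
and report the offending data row number (header = row 1).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .dosimetry import GateReport, IrradianceField, LedSpec
from .kinetics import COUNT_COLUMNS
from .wavelength_sensitivity import GfTable

__all__ = [
    "read_counts",
    "write_counts",
    "read_irradiance_grid",
    "read_led_config",
    "read_gf_table",
    "write_report",
]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate-count CSV.

    Required columns: condition_id, wavelength_nm, dose_mj_cm2, replicate,
    dilution_factor, plated_volume_ml, colony_count.  Every (condition,
    wavelength) group must contain dose-0 control rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")

    def _bad(mask: pd.Series, field: str, rule: str) -> None:
        if mask.any():
            row = int(df.index[mask][0]) + 2  # header is line 1
            raise ValueError(f"{path}: row {row}: {field} {rule}")

    for col in ("wavelength_nm", "dose_mj_cm2", "dilution_factor",
                "plated_volume_ml", "colony_count"):
        _bad(pd.to_numeric(df[col], errors="coerce").isna(), col, "is not numeric")
    _bad(df["colony_count"] < 0, "colony_count", "must be >= 0")
    _bad(df["dilution_factor"] < 1, "dilution_factor", "must be >= 1")
    _bad(df["plated_volume_ml"] <= 0, "plated_volume_ml", "must be > 0")
    _bad(df["dose_mj_cm2"] < 0, "dose_mj_cm2", "must be >= 0")

    for (cond, wl), grp in df.groupby(["condition_id", "wavelength_nm"]):
        if not (grp["dose_mj_cm2"] == 0).any():
            raise ValueError(
                f"{path}: no unirradiated control (dose-0 rows) for "
                f"condition {cond!r} at {wl} nm"
            )
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=False, columns=list(COUNT_COLUMNS))


def read_irradiance_grid(
    path: str | Path, dish_diameter_mm: float = 35.0
) -> IrradianceField:
    """Read an irradiance-grid CSV (x_mm, y_mm, irradiance_mw_cm2)."""
    df = pd.read_csv(path)
    for col in ("x_mm", "y_mm", "irradiance_mw_cm2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    neg = df["irradiance_mw_cm2"] < 0
    if neg.any():
        row = int(df.index[neg][0]) + 2
        raise ValueError(f"{path}: row {row}: irradiance_mw_cm2 must be >= 0")
    return IrradianceField.from_grid(
        df["x_mm"].to_numpy(),
        df["y_mm"].to_numpy(),
        df["irradiance_mw_cm2"].to_numpy(),
        dish_diameter_mm=dish_diameter_mm,
    )


def read_led_config(path: str | Path) -> LedSpec:
    """Read one LED descriptor from a YAML file.

    Fields: rank_label, peak_wavelength_nm, fwhm_nm,
    irradiance_setpoint_mw_cm2, drive_current_a, time_lag (constant seconds
    or a [[current_a, lag_s], ...] table), overshoot_fraction.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    lag = raw.get("time_lag", 0.0)
    if isinstance(lag, list):
        lag = [tuple(pair) for pair in lag]
    return LedSpec(
        rank_label=raw["rank_label"],
        peak_wavelength_nm=float(raw["peak_wavelength_nm"]),
        fwhm_nm=float(raw.get("fwhm_nm", 10.0)),
        irradiance_setpoint_mw_cm2=float(raw.get("irradiance_setpoint_mw_cm2", 1.0)),
        drive_current_a=float(raw.get("drive_current_a", 2.4)),
        time_lag_s=lag,
        overshoot_fraction=float(raw.get("overshoot_fraction", 0.0)),
    )


def _config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_gf_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(
    results: Mapping[str, Any],
    out_dir: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write the pipeline outputs under ``out_dir``.

    Recognized keys in ``results``: ``gf_table`` (GfTable), ``gates``
    (GateReport), ``fits`` (mapping of wavelength -> fit summary dict).
    Every file embeds the config hash and seed so reruns are attributable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = dict(config or {})
    meta = {"config_hash": _config_hash(config), "seed": seed}
    written: list[Path] = []

    table = results.get("gf_table")
    if table is not None:
        if not isinstance(table, GfTable):
            raise TypeError("gf_table must be a GfTable")
        frame = table.to_frame()
        csv_path = out / "gf_table.csv"
        with open(csv_path, "w") as fh:
            fh.write(f"# config_hash={meta['config_hash']} seed={meta['seed']}\n")
            frame.to_csv(fh, index=False)
        json_path = out / "gf_table.json"
        json_path.write_text(
            json.dumps(
                {
                    **meta,
                    "reference_wavelength_nm": table.reference_wavelength_nm,
                    "d0_mj_cm2": table.d0_mj_cm2,
                    "rows": frame.to_dict(orient="records"),
                },
                indent=2,
            )
        )
        written += [csv_path, json_path]

    gates = results.get("gates")
    if gates is not None:
        if not isinstance(gates, GateReport):
            raise TypeError("gates must be a GateReport")
        txt = out / "correction_factors.txt"
        lines = [f"# config_hash={meta['config_hash']} seed={meta['seed']}"]
        lines += gates.lines()
        txt.write_text("\n".join(lines) + "\n")
        jsn = out / "correction_factors.json"
        jsn.write_text(
            json.dumps(
                {
                    **meta,
                    "wf": gates.factors.wf,
                    "df": gates.factors.df,
                    "pf_center": gates.factors.pf_center,
                    "pf_max": gates.factors.pf_max,
                    "rf": gates.factors.rf,
                    "cv_percent": gates.factors.cv_percent,
                    "wf_pass": gates.wf_pass,
                    "df_pass": gates.df_pass,
                    "cv_pass": gates.cv_pass,
                    "all_pass": gates.all_pass,
                },
                indent=2,
            )
        )
        written += [txt, jsn]

    fits = results.get("fits")
    if fits is not None:
        path = out / "fit_summary.json"
        path.write_text(json.dumps({**meta, "fits": fits}, indent=2))
        written.append(path)

    return written
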