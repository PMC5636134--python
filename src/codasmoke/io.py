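"""File formats and provenance sidecars.

Conventions: prevalence is stored everywhere as a proportion in [0, 1]
(percent appears only in plots); every output file gets a JSON provenance
sidecar (``<file>.meta.json``) echoing the configuration and seed that
produced it, sufficient to regenerate the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .calibrate import CohortData, N_ANNUAL, results_table
from .simulate import PrevalenceSeries

__all__ = [
    "read_cohorts_csv",
    "write_cohorts_csv",
    "write_series_csv",
    "write_calibration_csv",
    "write_calibration_json",
    "write_sweep_csv",
    "write_provenance",
    "read_provenance",
    "load_run_config",
]


def sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_provenance(path, payload: dict) -> Path:
    """Write the JSON provenance sidecar for ``path``."""
    out = sidecar_path(path)
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return out


def read_provenance(path) -> dict:
    return json.loads(sidecar_path(path).read_text())


# -- cohort observations ------------------------------------------------------


def write_cohorts_csv(cohorts, path) -> Path:
    """Long format: cohort_id, start_year, year_index (1-6), prevalence."""
    rows = []
    for c in cohorts:
        for i, v in enumerate(c.annual_prevalence, start=1):
            rows.append(
                {
                    "cohort_id": c.cohort_id,
                    "start_year": c.start_year,
                    "year_index": i,
                    "prevalence": v,
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_cohorts_csv(path) -> list[CohortData]:
    """Read cohort observations, accepting ``year_index`` (1-6) or ``age``
    (12-17) as the within-cohort ordering column."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"cohort_id", "prevalence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "year_index" in df.columns:
        order_col, offset = "year_index", 0
    elif "age" in df.columns:
        order_col, offset = "age", 11  # age 12 -> year_index 1
    else:
        raise ValueError(f"{path}: need a 'year_index' or 'age' column")

    bad = pd.to_numeric(df["prevalence"], errors="coerce").isna() & df["prevalence"].notna()
    if bad.any() or df["prevalence"].isna().any():
        row = int(df.index[bad | df["prevalence"].isna()][0])
        raise ValueError(
            f"{path}: non-numeric or missing prevalence in data row {row + 1} "
            f"(value {df['prevalence'].iloc[row]!r})"
        )
    df["prevalence"] = df["prevalence"].astype(float)

    cohorts = []
    for cohort_id, g in df.groupby("cohort_id", sort=False):
        g = g.sort_values(order_col)
        idx = (g[order_col].astype(int) - offset).tolist()
        if idx != list(range(1, N_ANNUAL + 1)):
            raise ValueError(
                f"{path}: cohort {cohort_id!r} must have {order_col} values covering "
                f"all {N_ANNUAL} years exactly once, got {idx}"
            )
        start_year = int(g["start_year"].iloc[0]) if "start_year" in g.columns else 0
        cohorts.append(
            CohortData(
                cohort_id=str(cohort_id),
                annual_prevalence=tuple(g["prevalence"]),
                start_year=start_year,
            )
        )
    if not cohorts:
        raise ValueError(f"{path}: no cohorts found")
    return cohorts


# -- simulation / sweep / calibration outputs ---------------------------------


def write_series_csv(series, path) -> Path:
    """One or many PrevalenceSeries as cohort_id, month, prevalence rows."""
    if isinstance(series, PrevalenceSeries):
        series = [series]
    path = Path(path)
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)
    return path


def write_calibration_csv(results, path) -> Path:
    """The published-table-shaped wide CSV (mean column + one per cohort)."""
    path = Path(path)
    results_table(results).to_csv(path)
    return path


def write_calibration_json(results, path, extra: dict | None = None) -> Path:
    """Full-precision per-cohort results with provenance fields."""
    payload = {
        "results": [
            {
                "cohort_id": r.cohort_id,
                "alpha": r.alpha,
                "beta": r.beta,
                "p0": r.p0,
                "alpha_plus_beta": r.likelihood_sum,
                "sse": r.sse,
                "pseudo_r2": r.pseudo_r2,
                "regime": r.regime.value,
                "n_reps": r.n_reps,
                "grid_spec": r.grid_spec,
            }
            for r in results
        ]
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def write_sweep_csv(result, path) -> Path:
    """Long-format sweep fan: parameter, value, month, prevalence."""
    path = Path(path)
    result.to_frame().to_csv(path, index=False)
    return path


# -- run configuration --------------------------------------------------------


def load_run_config(path, allowed_keys) -> dict:
    """Load a YAML or JSON run configuration; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - set(allowed_keys)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return data
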