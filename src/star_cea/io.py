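"""Report writers, panel CSV dialect, and run manifests.

Numbers are written unrounded (full precision) in JSON outputs and rounded
only in the human-readable CSV reports: 2 decimals for money and QALY totals,
3 for probabilities.
"""

from __future__ import annotations

import datetime
import json
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .markov_engine import ArmResult, CohortTrace
from .parameters import STATES

__all__ = [
    "PANEL_COLUMNS",
    "read_panel",
    "write_panel",
    "write_manifest",
    "trace_frame",
    "arm_result_frame",
    "round_report",
]

PANEL_COLUMNS = [
    "patient_id",
    "arm",
    "time_months",
    "oks_ps",
    "utility",
    "cost_prescriptions",
    "cost_consultations",
    "cost_hospital",
]

_MONEY_QALY_COLS = ("qalys", "costs", "delta", "inmb", "icer")


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a patient panel CSV, checking the dialect and value ranges."""
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"panel {path}: missing required columns {missing}")
    for col in PANEL_COLUMNS[4:]:
        if col not in df.columns:
            df[col] = np.nan
    bad = df[~df["oks_ps"].between(0, 28) & df["oks_ps"].notna()]
    if not bad.empty:
        row = bad.index[0]
        raise ValueError(
            f"panel {path}: row {row}: column oks_ps value {bad.loc[row, 'oks_ps']} outside [0, 28]"
        )
    dup = df.duplicated(subset=["patient_id", "time_months"])
    if dup.any():
        raise ValueError(f"panel {path}: duplicate (patient_id, time_months) at row {int(np.flatnonzero(dup)[0])}")
    return df[PANEL_COLUMNS]


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


def trace_frame(trace: CohortTrace, arm: str) -> pd.DataFrame:
    """Tidy per-cycle state memberships: columns arm, year, state, membership."""
    rows = [
        {"arm": arm, "year": year, "state": s.value, "membership": trace.fraction(year, s)}
        for year in range(1, trace.horizon + 1)
        for s in STATES
    ]
    return pd.DataFrame(rows)


def arm_result_frame(result: ArmResult, arm: str) -> pd.DataFrame:
    """Tidy per-cycle discounted QALYs and costs for one arm."""
    years = np.arange(1, len(result.per_cycle_qalys) + 1)
    return pd.DataFrame({
        "arm": arm,
        "year": years,
        "qalys_disc": result.per_cycle_qalys,
        "costs_disc": result.per_cycle_costs,
        "qalys_undisc": result.per_cycle_qalys_undiscounted,
        "costs_undisc": result.per_cycle_costs_undiscounted,
    })


def round_report(df: pd.DataFrame) -> pd.DataFrame:
    """Report-boundary rounding: 2 dp for money/QALYs, 3 dp for probabilities."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        if "probability" in col or "membership" in col or col == "delta_qalys":
            out[col] = out[col].round(3)
        elif any(key in col for key in _MONEY_QALY_COLS):
            out[col] = out[col].round(2)
    return out


def write_manifest(out_dir: str | Path, command: str, outputs: list[str], **info) -> Path:
    """Write the run manifest JSON next to the outputs; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("star-cea")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "command": command,
        "package_version": version,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": outputs,
        **info,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
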