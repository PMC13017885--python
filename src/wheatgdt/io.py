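"""Trajectory serialization: tidy long-format CSV and run-level JSON summary.

The CSV has one row per (day, organ, variable); plant-level series (pool
stocks, totals, aggregate fluxes) appear under the pseudo-organ
``plant``.  The initial snapshot is exported with day = -1.  The audit
can be re-run from a written CSV alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .state import DayRecord, OrganKind, Trajectory

_PLANT = "plant"
_PLANT_VARS = (
    "pool_c",
    "pool_n",
    "s_plant_mean",
    "s_plant_max",
    "total_c",
    "total_n",
    "assimilation_c",
    "respiration_c",
    "n_uptake_total",
)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy long-format frame: columns day, organ, variable, value."""
    rows: list[dict] = []

    def emit(rec: DayRecord, day: int) -> None:
        for var in _PLANT_VARS:
            rows.append(
                {"day": day, "organ": _PLANT, "variable": var, "value": getattr(rec, var)}
            )
        rows.append({"day": day, "organ": _PLANT, "variable": "stage", "value": rec.stage})
        for kind, orec in rec.organs.items():
            for f in dataclasses.fields(orec):
                value = getattr(orec, f.name)
                if isinstance(value, bool):
                    value = float(value)
                rows.append(
                    {"day": day, "organ": kind.value, "variable": f.name, "value": value}
                )

    emit(traj.initial, -1)
    for rec in traj.records:
        emit(rec, rec.day)
    return pd.DataFrame(rows, columns=["day", "organ", "variable", "value"])


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False, float_format="%.17g")


def summarize(traj: Trajectory) -> dict:
    """Run-level summary: final masses, cumulative fluxes, audit residuals."""
    from .simulation import audit_mass_balance

    last = traj.records[-1] if traj.records else traj.initial
    audit = audit_mass_balance(traj)
    return {
        "days_simulated": len(traj.records),
        "final_structural_mass": {
            kind.value: last.organs[kind].mass for kind in OrganKind
        },
        "final_total_structural_mass": traj.final_total_mass(),
        "final_defense_pool": {
            kind.value: last.organs[kind].defense_pool for kind in OrganKind
        },
        "final_pool": {"carbon": last.pool_c, "nitrogen": last.pool_n},
        "cumulative": {
            "assimilation_c": sum(r.assimilation_c for r in traj.records),
            "respiration_c": sum(r.respiration_c for r in traj.records),
            "n_uptake": sum(r.n_uptake_total for r in traj.records),
            "defense_synthesis_c": sum(
                o.defense_synthesis_c for r in traj.records for o in r.organs.values()
            ),
            "maintenance_deficit_days": sum(
                1 for r in traj.records for o in r.organs.values() if o.maintenance_deficit
            ),
        },
        "audit": {
            "max_c_residual": float(audit["c_residual"].max()) if len(audit) else 0.0,
            "max_n_residual": float(audit["n_residual"].max()) if len(audit) else 0.0,
            "flagged_days": int(audit["flagged"].sum()) if len(audit) else 0,
        },
    }


def write_summary_json(traj: Trajectory, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summarize(traj), indent=2, sort_keys=True))


def audit_frame(df: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Re-run the mass-balance audit from a written trajectory CSV frame."""
    plant = df[df["organ"] == _PLANT]
    wide = plant.pivot(index="day", columns="variable", values="value").sort_index()
    needed = {"total_c", "total_n", "assimilation_c", "respiration_c", "n_uptake_total"}
    missing = needed - set(wide.columns)
    if missing:
        raise ValueError(f"trajectory frame missing audit fields: {sorted(missing)}")
    wide = wide.astype({c: float for c in needed})
    rows = []
    days = list(wide.index)
    for prev_day, day in zip(days[:-1], days[1:]):
        dc = wide.loc[day, "total_c"] - wide.loc[prev_day, "total_c"]
        dn = wide.loc[day, "total_n"] - wide.loc[prev_day, "total_n"]
        assim = wide.loc[day, "assimilation_c"]
        resp = wide.loc[day, "respiration_c"]
        upt = wide.loc[day, "n_uptake_total"]
        c_resid = abs(dc - (assim - resp)) / max(abs(assim) + abs(resp) + abs(dc), 1e-6)
        n_resid = abs(dn - upt) / max(abs(upt) + abs(dn), 1e-6)
        rows.append(
            {
                "day": day,
                "c_residual": c_resid,
                "n_residual": n_resid,
                "flagged": bool(c_resid > tol or n_resid > tol),
            }
        )
    return pd.DataFrame(rows, columns=["day", "c_residual", "n_residual", "flagged"])
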