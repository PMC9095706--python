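"""Plain-text I/O for assay traces, force curves and result tables.

Traces travel as a CSV with columns ``time_s`` and ``fluorescence`` plus a
JSON sidecar (same stem, ``.json`` extension) holding the dithionite
addition time and any condition labels (Ca2+, lipid composition, batch id).
Force curves use ``indentation_m``/``force_N`` columns with tip geometry in
the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import ScramblingFit
from .kinetics import FluorescenceTrace
from .mechanics import ForceCurve

__all__ = [
    "read_trace",
    "write_trace",
    "read_force_curve",
    "write_force_curve",
    "fits_to_table",
    "write_fit_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: FluorescenceTrace, path: str | Path) -> None:
    """Write a trace as CSV plus JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.time, "fluorescence": trace.fluorescence}
    ).to_csv(path, index=False)
    meta = {
        "dithionite_time_s": trace.dithionite_time,
        "normalized": trace.normalized,
    }
    meta.update({k: v for k, v in trace.meta.items() if _json_safe(v)})
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace(path: str | Path) -> FluorescenceTrace:
    """Read a trace CSV and its JSON sidecar."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"time_s", "fluorescence"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, fluorescence")
    meta = json.loads(_sidecar(path).read_text())
    dith = float(meta.pop("dithionite_time_s"))
    normalized = bool(meta.pop("normalized", False))
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(float),
        fluorescence=df["fluorescence"].to_numpy(float),
        dithionite_time=dith,
        normalized=normalized,
        meta=meta,
    )


def write_force_curve(curve: ForceCurve, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"indentation_m": curve.indentation, "force_N": curve.force}
    ).to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps(
            {
                "tip_half_angle_deg": float(np.degrees(curve.tip_half_angle)),
                "nu": curve.nu,
            },
            indent=1,
        )
    )


def read_force_curve(path: str | Path) -> ForceCurve:
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"indentation_m", "force_N"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns indentation_m, force_N")
    meta = json.loads(_sidecar(path).read_text())
    return ForceCurve(
        indentation=df["indentation_m"].to_numpy(float),
        force=df["force_N"].to_numpy(float),
        tip_half_angle=float(np.radians(meta["tip_half_angle_deg"])),
        nu=float(meta.get("nu", 0.5)),
    )


def fits_to_table(fits: dict[str, ScramblingFit], batch_ids: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabulate per-trace fits: one row per trace id."""
    rows = []
    for trace_id, fit in fits.items():
        e = fit.estimates
        rows.append(
            {
                "trace_id": trace_id,
                "alpha": e.alpha,
                "alpha_se": fit.standard_errors.get("alpha"),
                "beta": e.beta,
                "beta_se": fit.standard_errors.get("beta"),
                "f0": e.f0,
                "f0_se": fit.standard_errors.get("f0"),
                "rss": fit.residual_norm,
                "converged": fit.converged,
                "batch_id": (batch_ids or {}).get(trace_id, ""),
            }
        )
    return pd.DataFrame(rows)


def write_fit_table(fits: dict[str, ScramblingFit], path: str | Path, batch_ids=None) -> None:
    fits_to_table(fits, batch_ids).to_csv(Path(path), index=False)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except (TypeError, ValueError):
        return False
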