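"""Trial file formats.

A trial directory holds ``markers.csv`` (``time_s, SACR_x, SACR_y, SACR_z,
LASI_x, ...`` in mm), ``grf.csv`` (``time_s, fz_N``) and a sidecar
``meta.json`` documenting units, sampling rate and the axis convention
(x = AP, +forward; y = ML, +left; z = VT, +up).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gaittube.signal_prep import PELVIS_MARKERS, ForceSignal, MarkerFrameSeries

__all__ = ["write_trial", "read_trial", "ingest_external_trial"]

_AXIS_SUFFIXES = ("x", "y", "z")


def write_trial(directory: str | Path, markers: MarkerFrameSeries, vgrf: ForceSignal,
                metadata: dict | None = None) -> Path:
    """Write a trial to ``directory`` in the canonical CSV format."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = markers.n_frames
    t = np.arange(n) / markers.rate
    cols: dict[str, np.ndarray] = {"time_s": t}
    for name in PELVIS_MARKERS:
        for a, suf in enumerate(_AXIS_SUFFIXES):
            cols[f"{name}_{suf}"] = markers.positions[name][:, a]
    pd.DataFrame(cols).to_csv(directory / "markers.csv", index=False, float_format="%.6f")
    tg = np.arange(vgrf.fz.shape[0]) / vgrf.rate
    pd.DataFrame({"time_s": tg, "fz_N": vgrf.fz}).to_csv(
        directory / "grf.csv", index=False, float_format="%.6f"
    )
    meta = {
        "units": {"position": "mm", "force": "N", "time": "s"},
        "marker_rate_hz": markers.rate,
        "grf_rate_hz": vgrf.rate,
        "axis_convention": markers.axis_convention,
        "axes": {"x": "AP (+forward)", "y": "ML (+left)", "z": "VT (+up)"},
    }
    if metadata:
        meta.update(metadata)
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def _rate_from_time(t: np.ndarray, label: str) -> float:
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{label}: time column is not uniformly sampled")
    return float(1.0 / dt[0])


def read_trial(directory: str | Path) -> tuple[MarkerFrameSeries, ForceSignal, dict]:
    """Read a trial directory written by :func:`write_trial`."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    mk = pd.read_csv(directory / "markers.csv")
    gr = pd.read_csv(directory / "grf.csv")
    missing = [
        m for m in PELVIS_MARKERS
        if any(f"{m}_{s}" not in mk.columns for s in _AXIS_SUFFIXES)
    ]
    if missing:
        raise ValueError(f"markers.csv is missing pelvis marker(s): {', '.join(missing)}")
    if "fz_N" not in gr.columns:
        raise ValueError("grf.csv is missing the vertical GRF channel 'fz_N'")
    rate = meta.get("marker_rate_hz") or _rate_from_time(mk["time_s"].to_numpy(), "markers.csv")
    grate = meta.get("grf_rate_hz") or _rate_from_time(gr["time_s"].to_numpy(), "grf.csv")
    positions = {
        m: mk[[f"{m}_{s}" for s in _AXIS_SUFFIXES]].to_numpy(dtype=float)
        for m in PELVIS_MARKERS
    }
    markers = MarkerFrameSeries(
        rate=float(rate), positions=positions,
        axis_convention=meta.get("axis_convention", "AP-ML-VT"),
    )
    return markers, ForceSignal(rate=float(grate), fz=gr["fz_N"].to_numpy(dtype=float)), meta


def ingest_external_trial(
    path: str | Path, format: str = "csv", units: str | None = None
) -> tuple[MarkerFrameSeries, ForceSignal]:
    """Load and validate an external trial in the canonical axis convention.

    ``units`` may be ``"mm"`` or ``"m"`` to override auto-detection; positions
    declared (or detected) to be in meters are converted to mm.  Auto-detection
    flags meters when the largest absolute coordinate is below 10, far below
    any plausible pelvis-marker coordinate expressed in mm.
    """
    if format != "csv":
        raise ValueError(f"unsupported trial format {format!r}; only 'csv' is supported")
    markers, vgrf, meta = read_trial(path)
    declared = units or meta.get("units", {}).get("position")
    if declared is None:
        peak = max(np.nanmax(np.abs(p)) for p in markers.positions.values())
        declared = "m" if peak < 10.0 else "mm"
    if declared == "m":
        markers = MarkerFrameSeries(
            rate=markers.rate,
            positions={k: v * 1000.0 for k, v in markers.positions.items()},
            axis_convention=markers.axis_convention,
        )
    elif declared != "mm":
        raise ValueError(f"unsupported position unit {declared!r}; expected 'mm' or 'm'")
    return markers, vgrf
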