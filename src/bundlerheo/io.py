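"""Plain-text serialization: kymograph CSV, fit/profile files, parameter
files.

All intermediates are human-readable (CSV/JSON, `key = value` parameter
text) so every pipeline stage can be inspected and re-run independently;
only the image frames themselves use TIFF.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .models import DriveProtocol, Kymograph, RodModel

_PARAM_UNITS = {
    "rod.kappa": "J*m (bending stiffness)",
    "rod.contour_length": "m",
    "rod.diameter": "m",
    "rod.medium_viscosity": "Pa*s",
    "rod.temperature": "K",
    "rod.background_velocity": "m/s",
    "drive.amplitude": "m",
    "drive.frequency_hz": "Hz",
    "drive.drive_point": "end|middle",
    "drive.n_periods": "count",
    "drive.frame_interval": "s",
    "drive.exposure": "s",
}


def kymograph_to_dataframe(kymo: Kymograph) -> pd.DataFrame:
    """Long-format table: one row per (time, x) sample."""
    nt, nx = kymo.y.shape
    t = np.repeat(kymo.times, nx)
    x = np.tile(kymo.x_positions, nt)
    return pd.DataFrame(
        {
            "time": t,
            "x": x,
            "y": kymo.y.ravel(),
            "quality": kymo.quality.ravel(),
            "excluded": np.tile(kymo.excluded_columns, nt).astype(int),
        }
    )


def dataframe_to_kymograph(df: pd.DataFrame) -> Kymograph:
    times = np.unique(df["time"].to_numpy())
    xs = np.unique(df["x"].to_numpy())
    piv = df.pivot_table(index="time", columns="x", values="y", dropna=False)
    qual = df.pivot_table(index="time", columns="x", values="quality", dropna=False)
    excl = (
        df.groupby("x")["excluded"].max().reindex(piv.columns).to_numpy().astype(bool)
    )
    return Kymograph(
        y=piv.to_numpy(),
        x_positions=piv.columns.to_numpy(dtype=float),
        times=piv.index.to_numpy(dtype=float),
        quality=qual.to_numpy(),
        excluded_columns=excl,
    )


def write_kymograph_csv(kymo: Kymograph, path) -> Path:
    path = Path(path)
    kymograph_to_dataframe(kymo).to_csv(path, index=False, float_format="%.17g")
    return path


def read_kymograph_csv(path) -> Kymograph:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing kymograph file {path}")
    return dataframe_to_kymograph(pd.read_csv(path))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "value"):  # enums
        return obj.value
    return obj


def write_json(obj, path) -> Path:
    """Write a dataclass (fit result, scaling model, config) as JSON."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, default=str))
    return path


def read_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing JSON file {path}")
    return json.loads(path.read_text())


def save_params(path, rod: Optional[RodModel] = None, drive: Optional[DriveProtocol] = None) -> Path:
    """Write physical parameters as a plain-text `key = value` file.

    Each key is commented with its SI unit; the format round-trips through
    :func:`load_params`.
    """
    lines = ["# bundlerheo parameter file (SI units)"]
    sections = {}
    if rod is not None:
        sections["rod"] = {
            "kappa": rod.kappa,
            "contour_length": rod.contour_length,
            "diameter": rod.diameter,
            "medium_viscosity": rod.medium_viscosity,
            "temperature": rod.temperature,
            "background_velocity": rod.background_velocity,
        }
    if drive is not None:
        sections["drive"] = {
            "amplitude": drive.amplitude,
            "frequency_hz": drive.frequency_hz,
            "drive_point": drive.drive_point.value,
            "n_periods": drive.n_periods,
            "frame_interval": drive.frame_interval,
            "exposure": drive.exposure,
        }
    for sec, entries in sections.items():
        for key, val in entries.items():
            full = f"{sec}.{key}"
            unit = _PARAM_UNITS.get(full, "")
            comment = f"  # {unit}" if unit else ""
            if isinstance(val, float):
                lines.append(f"{full} = {val!r}{comment}")
            else:
                lines.append(f"{full} = {val}{comment}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def load_params(path) -> dict:
    """Parse a `key = value` parameter file into nested dicts.

    Returns ``{"rod": RodModel | None, "drive": DriveProtocol | None}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing parameter file {path}")
    sections: dict = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected `key = value`, got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if "." not in key:
            raise ValueError(f"{path}:{ln}: key must be `section.name`, got {key!r}")
        sec, name = key.split(".", 1)
        try:
            parsed = json.loads(val)
        except json.JSONDecodeError:
            parsed = val
        sections.setdefault(sec, {})[name] = parsed
    out = {"rod": None, "drive": None}
    if "rod" in sections:
        out["rod"] = RodModel.from_dict(sections["rod"])
    if "drive" in sections:
        out["drive"] = DriveProtocol.from_dict(sections["drive"])
    return out
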