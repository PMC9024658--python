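"""On-disk formats, configuration loading and logging.

Canonical on-disk units are SI (tesla, meter, ampere, volt); conversion to
nT/mm/degrees happens only in report output.  Tables are CSV with a
``# units: ...`` header line; models and sensor parameters are JSON.  Every
reader validates its schema and raises :class:`SchemaError` with a message
naming the offending column or field.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import SensorParameters
from .fieldmodel import CoilModelSet, FieldMeasurementSet
from .vsh import VSHModel

__all__ = [
    "SchemaError",
    "write_measurement_table",
    "read_measurement_table",
    "write_model_set",
    "read_model_set",
    "write_sensor_parameters",
    "read_sensor_parameters",
    "write_currents",
    "read_currents",
    "load_config",
    "setup_logging",
]

log = logging.getLogger("coilcal")

_TRIAXIAL_COLS = ["coil_id", "x", "y", "z", "Bx", "By", "Bz", "current"]
_PROJECTED_COLS = ["coil_id", "x", "y", "z", "value", "nx", "ny", "nz", "current"]
_UNITS_HEADER = "# units: x,y,z [m]; B,value [T]; current [A]\n"


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def setup_logging(level: int = logging.INFO) -> logging.Logger:
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)
    return log


def _version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

def write_measurement_table(path, measurements: list[FieldMeasurementSet]) -> None:
    """CSV with one row per mapped point (triaxial) or per projected sample.

    Values are written back in raw units (per-unit-current values times the
    recorded current) so that write -> read is the identity.
    """
    frames = []
    for m in measurements:
        if m.is_triaxial:
            df = pd.DataFrame(m.positions, columns=["x", "y", "z"])
            df[["Bx", "By", "Bz"]] = m.values * m.current
        else:
            df = pd.DataFrame(m.positions, columns=["x", "y", "z"])
            df["value"] = m.values * m.current
            df[["nx", "ny", "nz"]] = m.projections
        df.insert(0, "coil_id", m.coil_id)
        df["current"] = m.current
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER)
        table.to_csv(fh, index=False)


def read_measurement_table(path) -> list[FieldMeasurementSet]:
    """Parse a mapping CSV into one FieldMeasurementSet per coil id."""
    with open(path) as fh:
        text = fh.read()
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    df = pd.read_csv(_io.StringIO(body))
    triaxial = set(_TRIAXIAL_COLS).issubset(df.columns)
    projected = set(_PROJECTED_COLS).issubset(df.columns)
    if not (triaxial or projected):
        missing = sorted(set(_TRIAXIAL_COLS) - set(df.columns))
        raise SchemaError(f"measurement table missing required columns: {missing}")
    numeric = [c for c in df.columns if c != "coil_id"]
    if not np.all(np.isfinite(df[numeric].to_numpy(dtype=float))):
        raise SchemaError("measurement table contains non-finite values")
    out = []
    for coil_id, grp in df.groupby("coil_id", sort=False):
        current = float(grp["current"].iloc[0])
        if not np.allclose(grp["current"], current):
            raise SchemaError(f"coil {coil_id!r}: current column must be constant per coil")
        if triaxial:
            out.append(
                FieldMeasurementSet(
                    coil_id=str(coil_id),
                    positions=grp[["x", "y", "z"]].to_numpy(),
                    values=grp[["Bx", "By", "Bz"]].to_numpy(),
                    current=current,
                )
            )
        else:
            out.append(
                FieldMeasurementSet(
                    coil_id=str(coil_id),
                    positions=grp[["x", "y", "z"]].to_numpy(),
                    values=grp["value"].to_numpy(),
                    projections=grp[["nx", "ny", "nz"]].to_numpy(),
                    current=current,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Models, parameters, currents
# ---------------------------------------------------------------------------

def write_model_set(path, models: CoilModelSet) -> None:
    payload = {
        "format": "coilcal-model-set",
        "version": _version(),
        "models": [m.to_dict() for m in models],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model_set(path) -> CoilModelSet:
    payload = json.loads(Path(path).read_text())
    if "models" not in payload:
        raise SchemaError("model-set JSON missing the 'models' field")
    return CoilModelSet([VSHModel.from_dict(d) for d in payload["models"]])


def write_sensor_parameters(path, params: dict[str, SensorParameters], extra=None) -> None:
    payload = {
        "format": "coilcal-sensor-parameters",
        "version": _version(),
        "units": {"gain": "V/T", "position": "m"},
        "channels": {name: p.to_dict() for name, p in params.items()},
    }
    if extra:
        payload["report"] = extra
    Path(path).write_text(json.dumps(payload, indent=1))


def read_sensor_parameters(path) -> dict[str, SensorParameters]:
    payload = json.loads(Path(path).read_text())
    if "channels" not in payload:
        raise SchemaError("sensor-parameter JSON missing the 'channels' field")
    return {k: SensorParameters.from_dict(v) for k, v in payload["channels"].items()}


def write_currents(path, names: list[str], currents: np.ndarray, coil_ids: list[str]) -> None:
    df = pd.DataFrame(np.atleast_2d(currents), index=names, columns=coil_ids)
    df.index.name = "excitation"
    with open(path, "w") as fh:
        fh.write("# units: currents [A]\n")
        df.to_csv(fh)


def read_currents(path) -> pd.DataFrame:
    with open(path) as fh:
        body = "\n".join(ln for ln in fh.read().splitlines() if not ln.startswith("#"))
    df = pd.read_csv(_io.StringIO(body), index_col=0)
    if df.empty:
        raise SchemaError("currents table is empty")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise SchemaError("currents table contains non-finite values")
    return df


def load_config(path) -> dict:
    """YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError("configuration must be a mapping")
    return cfg
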