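"""Readers/writers and run configuration.

Delimited text is comma-separated, UTF-8, "." decimal. NIfTI volumes are
read and written with nibabel and treated as already co-registered; no
resampling or reorientation is performed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .etco2 import CapnoTrace
from .paradigm import AcquisitionSpec, ParadigmSpec
from .simulate import BreathModel


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a pipeline run. Every field has a default;
    unknown keys in a config file are rejected."""

    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    breath: BreathModel = field(default_factory=BreathModel)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    slope_tolerance: float = 0.02  # mmHg/s, steady-state QC
    baseline_tolerance: float = 2.0  # mmHg, baseline-return QC
    drift_order: int = 1
    delay_mode: str = "none"  # "none" | "xcorr"
    max_delay: float = 15.0  # s
    mad_k: float = 6.0
    wmh_log_base: float = math.e
    sex_reference: str = "F"
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.delay_mode not in ("none", "xcorr"):
            raise ValueError("delay_mode must be 'none' or 'xcorr'")
        if self.drift_order not in (0, 1, 2):
            raise ValueError("drift_order must be 0, 1 or 2")
        if self.mad_k <= 0:
            raise ValueError("mad_k must be positive")


_NESTED = {
    "paradigm": ParadigmSpec,
    "breath": BreathModel,
    "acquisition": AcquisitionSpec,
}


def _build_nested(cls, payload, key):
    if not isinstance(payload, dict):
        raise ValueError(f"config key {key!r} must be a mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown config key {key}.{sorted(unknown)[0]}")
    if cls is ParadigmSpec and "blocks" in payload:
        payload = dict(payload)
        payload["blocks"] = tuple(
            (str(state), float(dur)) for state, dur in payload["blocks"]
        )
    if cls is AcquisitionSpec and "grid_shape" in payload:
        payload = dict(payload)
        payload["grid_shape"] = tuple(int(v) for v in payload["grid_shape"])
    try:
        return cls(**payload)
    except TypeError as exc:
        raise ValueError(f"invalid value in config section {key!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing keys fall back to defaults."""
    text = Path(path).read_text(encoding="utf-8")
    payload = yaml.safe_load(text)
    if payload is None:
        return RunConfig()
    if not isinstance(payload, dict):
        raise ValueError("config file must contain a mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown config key {sorted(unknown)[0]!r}")
    kwargs = {}
    for key, value in payload.items():
        if key in _NESTED:
            kwargs[key] = _build_nested(_NESTED[key], value, key)
        else:
            default = RunConfig.__dataclass_fields__[key].default
            if isinstance(default, bool):
                kwargs[key] = bool(value)
            elif isinstance(default, int) and not isinstance(default, bool):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = type(default)(value) if default is not None else value
    return RunConfig(**kwargs)


def config_summary(config: RunConfig) -> str:
    """Human-readable echo of the full effective configuration."""
    return yaml.safe_dump(
        dataclasses.asdict(config), default_flow_style=False, sort_keys=True
    )


# --------------------------------------------------------------------------
# Capnometry traces


def read_capno_csv(path) -> CapnoTrace:
    """Read a 2-column (time_s, co2_mmHg) delimited trace.

    Time must be strictly increasing; the sampling rate is the reciprocal of
    the median time step (small jitter in the stamps is tolerated).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("capnometry file needs two columns: time_s, co2_mmHg")
    time_col, co2_col = df.columns[:2]
    for col in (time_col, co2_col):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ValueError(f"non-numeric value in column {col!r} at line {row}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna())[0]) + 2
            raise ValueError(f"missing value in column {col!r} at line {row}")
        df[col] = numeric
    t = df[time_col].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    step = float(np.median(np.diff(t)))
    return CapnoTrace(sampling_rate=1.0 / step, values=df[co2_col].to_numpy(dtype=float))


def write_capno_csv(trace: CapnoTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "co2_mmHg": trace.values}
    ).to_csv(path, index=False, float_format="%.17g")


def write_table(df: pd.DataFrame, path) -> None:
    """Write a delimited table at full double precision."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# --------------------------------------------------------------------------
# NIfTI


def write_nifti(volume: np.ndarray, path, affine: Optional[np.ndarray] = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def read_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(dtype=np.float64))


def read_mask(path, like: Optional[np.ndarray] = None) -> np.ndarray:
    """Read a binary mask; optionally check its grid against another volume."""
    data = read_nifti(path)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("mask is not binary (values other than 0/1)")
    if like is not None and data.shape != np.asarray(like).shape[: data.ndim]:
        raise ValueError("mask grid does not match the map grid")
    return data.astype(bool)
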