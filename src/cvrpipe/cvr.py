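"""CVR estimation: GLM fit of the EtCO2 regressor to BOLD, unit conversion,
ROI extraction, and MAD outlier flagging.

CVR is quantified as the percent BOLD signal change per mmHg change in raw
end-tidal CO2 (%BOLD/mmHg). Because the regressor is normalized by the
maximum end-tidal value, one unit of the regressor corresponds to
``trace_max`` mmHg, so the conversion from the fitted coefficient is
``beta / trace_max`` on percent-signal-change data, or
``100 * beta / (intercept * trace_max)`` on raw-signal data (the intercept
estimates the drift-free baseline signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import statsmodels.api as sm

from .etco2 import EtCO2Series, Regressor


@dataclass
class BoldSeries:
    """BOLD signal samples on the acquisition grid.

    ``units`` is ``"raw"`` (scanner units) or ``"percent"``
    (percent signal change).
    """

    sample_times: np.ndarray
    values: np.ndarray
    units: str = "raw"

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_times.shape != self.values.shape:
            raise ValueError("sample_times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")
        if self.units not in ("raw", "percent"):
            raise ValueError("units must be 'raw' or 'percent'")


@dataclass
class GlmFit:
    """One GLM fit of BOLD on (intercept, EtCO2 regressor, drift terms)."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    residuals: np.ndarray
    design_names: Tuple[str, ...]
    response_units: str

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def beta(self) -> float:
        """Coefficient of the normalized EtCO2 regressor."""
        return float(self.params[1])

    @property
    def beta_se(self) -> float:
        return float(self.bse[1])

    @property
    def beta_t(self) -> float:
        return float(self.tvalues[1])


@dataclass
class RoiMask:
    """Binary region-of-interest indicator over a voxel grid."""

    data: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if not self.data.any():
            raise ValueError(f"ROI mask {self.name!r} has no voxels")


@dataclass
class CVRMap:
    """Per-voxel CVR values in %BOLD/mmHg; NaN outside the fitted mask."""

    values: np.ndarray
    mask: np.ndarray
    delta_etco2: float
    provenance: str = ""


def to_percent_change(bold: BoldSeries, baseline_window: Tuple[float, float]) -> BoldSeries:
    """Express a raw BOLD series as percent signal change about the baseline
    window mean."""
    if bold.units == "percent":
        raise ValueError("series is already in percent-signal-change units")
    lo, hi = baseline_window
    sel = (bold.sample_times >= lo) & (bold.sample_times <= hi)
    if not np.any(sel):
        raise ValueError("baseline window contains no BOLD samples")
    base = float(np.mean(bold.values[sel]))
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return BoldSeries(
        sample_times=bold.sample_times,
        values=100.0 * (bold.values - base) / base,
        units="percent",
    )


def fit_cvr_glm(bold: BoldSeries, reg: Regressor, drift_order: int = 1) -> GlmFit:
    """Ordinary least squares of BOLD on the normalized EtCO2 regressor.

    The design is (intercept, regressor, t, ..., t^drift_order); polynomial
    drift terms absorb slow scanner trends. No prewhitening is applied: with
    drift modeled, AR(1) noise affects efficiency but not unbiasedness of the
    point estimate.
    """
    if drift_order not in (0, 1, 2):
        raise ValueError("drift_order must be 0, 1 or 2")
    y = bold.values
    t = bold.sample_times
    if reg.normalized_values.shape != y.shape:
        raise ValueError("regressor and BOLD series must have equal length")
    cols = [np.ones_like(t), reg.normalized_values]
    names = ["intercept", "etco2"]
    for k in range(1, drift_order + 1):
        cols.append(t**k)
        names.append(f"drift_t{k}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, X).fit()
    return GlmFit(
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        tvalues=np.asarray(res.tvalues, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
        design_names=tuple(names),
        response_units=bold.units,
    )


def cvr_from_fit(fit: GlmFit, et: EtCO2Series) -> float:
    """Convert the fitted regressor coefficient to CVR in %BOLD/mmHg."""
    if et.trace_max <= 0:
        raise ValueError("trace_max must be positive")
    if fit.response_units == "percent":
        return fit.beta / et.trace_max
    if fit.intercept <= 0:
        raise ValueError("non-positive baseline (intercept) in raw-unit fit")
    return 100.0 * fit.beta / (fit.intercept * et.trace_max)


def estimate_cvr(
    bold: BoldSeries,
    reg: Regressor,
    et: EtCO2Series,
    drift_order: int = 1,
    percent_mode: str = "intercept",
    baseline_window: Optional[Tuple[float, float]] = None,
) -> Tuple[float, GlmFit]:
    """End-to-end CVR estimate from one BOLD series.

    ``percent_mode`` selects the %BOLD reference: ``"intercept"`` (default)
    fits the raw signal and scales by the GLM intercept, which is immune to
    additive drift; ``"baseline"`` first converts to percent change about the
    baseline-window mean.
    """
    if percent_mode not in ("intercept", "baseline"):
        raise ValueError("percent_mode must be 'intercept' or 'baseline'")
    series = bold
    if percent_mode == "baseline":
        window = baseline_window if baseline_window is not None else et.baseline_window
        if series.units == "raw":
            series = to_percent_change(series, window)
    fit = fit_cvr_glm(series, reg, drift_order=drift_order)
    return cvr_from_fit(fit, et), fit


def fit_cvr_map(
    volume: np.ndarray,
    reg: Regressor,
    et: EtCO2Series,
    mask: RoiMask,
    drift_order: int = 1,
    percent_mode: str = "intercept",
) -> CVRMap:
    """Massively univariate CVR fit over the voxels of a mask.

    ``volume`` is a 4-D array (x, y, z, t); voxels are fitted independently.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, t)")
    if mask.data.shape != volume.shape[:3]:
        raise ValueError("mask grid does not match the volume grid")
    values = np.full(volume.shape[:3], np.nan)
    times = reg.sample_times
    if volume.shape[3] != times.size:
        raise ValueError("volume time axis does not match the regressor grid")
    for idx in np.argwhere(mask.data):
        series = BoldSeries(sample_times=times, values=volume[tuple(idx)], units="raw")
        cvr, _ = estimate_cvr(
            series, reg, et, drift_order=drift_order, percent_mode=percent_mode
        )
        values[tuple(idx)] = cvr
    return CVRMap(
        values=values,
        mask=mask.data.copy(),
        delta_etco2=reg.delta_etco2,
        provenance=f"glm drift_order={drift_order} percent_mode={percent_mode}",
    )


def roi_mean(cvr_map: CVRMap, mask: RoiMask) -> float:
    """Unweighted mean CVR over the voxels of an ROI mask."""
    if mask.data.shape != cvr_map.values.shape:
        raise ValueError("ROI mask grid does not match the CVR map grid")
    vals = cvr_map.values[mask.data]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"ROI {mask.name!r} contains no fitted voxels")
    return float(np.mean(vals))


def hippocampal_average(left: float, right: float) -> float:
    """Hippocampal CVR: simple mean of the left and right ROI means."""
    return 0.5 * (left + right)


def mad_outliers(values, k: float = 6.0) -> np.ndarray:
    """Flag values with |value - median| > k * MAD (raw MAD, no consistency
    constant). Strict inequality: an all-equal sample flags nothing."""
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 3:
        raise ValueError("need at least 3 values for the MAD rule")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    return np.abs(vals - med) > k * mad
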