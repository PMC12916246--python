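"""End-tidal CO2 processing: breath detection, regressor building, QC.

Turns a raw capnometry trace (CO2 partial pressure sampled at the face-mask
line) into a breath-wise end-tidal series, a normalized regressor on the
BOLD sampling grid, the hypercapnic EtCO2 increase (delta EtCO2), and a
steady-state / baseline-return quality-control report.

The end-tidal value of a breath is the maximum CO2 concentration at the end
of the exhalation; normalization subtracts the normocapnic baseline mean and
divides by the maximum end-tidal value, so that one unit of the normalized
regressor corresponds to ``trace_max`` mmHg of raw EtCO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .paradigm import AcquisitionSpec, ParadigmSpec


@dataclass
class CapnoTrace:
    """Raw CO2 partial-pressure time series (mmHg) at a fixed sampling rate."""

    sampling_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("CO2 partial pressure cannot be negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate


@dataclass
class EtCO2Series:
    """Breath-wise end-tidal values with the baseline summary used downstream.

    ``baseline_mean`` is the mean end-tidal value over breaths inside
    ``baseline_window``; ``trace_max`` is the maximum end-tidal value over the
    whole series (the divisor of the normalization).
    """

    breath_times: np.ndarray
    etco2_values: np.ndarray
    baseline_window: Tuple[float, float]
    baseline_mean: float = field(init=False)
    trace_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.breath_times = np.asarray(self.breath_times, dtype=float)
        self.etco2_values = np.asarray(self.etco2_values, dtype=float)
        if self.breath_times.shape != self.etco2_values.shape:
            raise ValueError("breath_times and etco2_values must match")
        if self.breath_times.size < 1:
            raise ValueError("series must contain at least one breath")
        if np.any(np.diff(self.breath_times) <= 0):
            raise ValueError("breath times must be strictly increasing")
        lo, hi = self.baseline_window
        in_base = (self.breath_times >= lo) & (self.breath_times <= hi)
        if not np.any(in_base):
            raise ValueError(
                f"no breaths inside baseline window ({lo:g}, {hi:g}) s"
            )
        self.baseline_mean = float(np.mean(self.etco2_values[in_base]))
        self.trace_max = float(np.max(self.etco2_values))

    @property
    def n_breaths(self) -> int:
        return int(self.breath_times.size)

    def breaths_in(self, start: float, end: float, closed_left: bool = True) -> np.ndarray:
        """Indices of breaths with time in ``[start, end]`` or ``(start, end]``."""
        if closed_left:
            sel = (self.breath_times >= start) & (self.breath_times <= end)
        else:
            sel = (self.breath_times > start) & (self.breath_times <= end)
        return np.flatnonzero(sel)


@dataclass
class Regressor:
    """Normalized EtCO2 model regressor resampled onto the BOLD grid."""

    sample_times: np.ndarray
    normalized_values: np.ndarray
    bulk_delay: float
    delta_etco2: float
    raw_values: np.ndarray  # pre-normalization interpolant, mmHg
    trace_max: float
    baseline_mean: float


@dataclass
class QCReport:
    """Per-block steady-state and baseline-return checks on an EtCO2 series."""

    steady_state_ok: list
    steady_state_slopes: list  # mmHg/s, one per CO2 block
    baseline_return_ok: list
    baseline_deviations: list  # mmHg, one per post-CO2 air block
    slope_tolerance: float
    baseline_tolerance: float

    @property
    def overall_pass(self) -> bool:
        return all(self.steady_state_ok) and all(self.baseline_return_ok)


def extract_end_tidal(
    trace: CapnoTrace,
    min_breath_period: float = 2.0,
    prominence_fraction: float = 0.25,
    baseline_window: Tuple[float, float] = (0.0, 60.0),
) -> EtCO2Series:
    """Detect breaths and return one end-tidal value per breath.

    Breaths are local maxima of the trace separated by at least
    ``min_breath_period`` seconds, with prominence at least
    ``prominence_fraction`` of the trace range. Flat end-tidal plateaus are
    reported at their midpoint with the plateau value.
    """
    if not min_breath_period > 0:
        raise ValueError("min_breath_period must be positive")
    if trace.duration < 2 * min_breath_period:
        raise ValueError("trace must span at least two breaths")
    values = trace.values
    span = float(values.max() - values.min())
    if span <= 0:
        raise ValueError("no breaths detected: trace is constant")
    distance = max(1, int(round(min_breath_period * trace.sampling_rate)))
    peaks, _ = find_peaks(values, distance=distance, prominence=prominence_fraction * span)
    if peaks.size == 0:
        raise ValueError("no breaths detected in the capnometry trace")
    return EtCO2Series(
        breath_times=peaks / trace.sampling_rate,
        etco2_values=values[peaks],
        baseline_window=baseline_window,
    )


def normalize_etco2(
    values: Sequence[float],
    times: Sequence[float],
    baseline_window: Tuple[float, float],
    divisor: Optional[float] = None,
) -> np.ndarray:
    """Normalize a raw EtCO2 interpolant: subtract baseline mean, divide by max.

    ``divisor`` overrides the default maximum-over-all-samples, for use when
    the true maximum of the underlying envelope is known exactly.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    lo, hi = baseline_window
    in_base = (t >= lo) & (t <= hi)
    if not np.any(in_base):
        raise ValueError("baseline window contains no samples")
    m = float(np.max(x)) if divisor is None else float(divisor)
    if m <= 0:
        raise ValueError("maximum EtCO2 must be positive to normalize")
    return (x - float(np.mean(x[in_base]))) / m


def build_regressor(
    et: EtCO2Series,
    acq: AcquisitionSpec,
    paradigm: Optional[ParadigmSpec] = None,
    bold_for_alignment=None,
    max_delay: float = 15.0,
    delay_step: float = 0.5,
) -> Regressor:
    """Resample the breath-wise envelope onto the BOLD grid and normalize.

    The envelope is piecewise-linear across end-tidal values. When a BOLD
    series is supplied, a bulk haemodynamic delay is estimated as the argmax
    of the Pearson correlation over a discrete delay grid in
    ``[0, max_delay]`` (the regressor is shifted later in time by the delay);
    otherwise the delay is zero.
    """
    if paradigm is None:
        paradigm = ParadigmSpec()
    sample_times = acq.sample_times
    # Coverage: allow extrapolation-by-clamping up to one median breath interval
    margin = (
        float(np.median(np.diff(et.breath_times))) if et.n_breaths > 1 else 0.0
    )
    if sample_times[-1] > et.breath_times[-1] + margin or sample_times[0] < et.breath_times[0] - margin:
        raise ValueError(
            "acquisition window extends beyond the end-tidal series support"
        )

    def raw_at(delay: float) -> np.ndarray:
        return np.interp(sample_times - delay, et.breath_times, et.etco2_values)

    bulk_delay = 0.0
    if bold_for_alignment is not None:
        bold_vals = np.asarray(getattr(bold_for_alignment, "values", bold_for_alignment), dtype=float)
        if bold_vals.shape != sample_times.shape:
            raise ValueError("alignment BOLD series must match the acquisition grid")
        delays = np.arange(0.0, max_delay + 0.5 * delay_step, delay_step)
        scores = np.full(delays.size, -np.inf)
        b = bold_vals - bold_vals.mean()
        bn = np.linalg.norm(b)
        for i, d in enumerate(delays):
            r = raw_at(d)
            r = r - r.mean()
            denom = np.linalg.norm(r) * bn
            if denom > 0:
                scores[i] = float(r @ b) / denom
        bulk_delay = float(delays[int(np.argmax(scores))])

    raw = raw_at(bulk_delay)
    if et.trace_max <= 0:
        raise ValueError("maximum EtCO2 must be positive to normalize")
    # Baseline referenced to the breath-wise baseline mean so the regressor
    # is exactly (raw - baseline_mean)/trace_max regardless of the BOLD grid.
    normalized = (raw - et.baseline_mean) / et.trace_max
    try:
        delta = compute_delta_etco2(et, paradigm)
    except ValueError:
        # series does not span the paradigm's blocks (e.g. a short excerpt)
        delta = float("nan")
    return Regressor(
        sample_times=sample_times,
        normalized_values=normalized,
        bulk_delay=bulk_delay,
        delta_etco2=delta,
        raw_values=raw,
        trace_max=et.trace_max,
        baseline_mean=et.baseline_mean,
    )


def compute_delta_etco2(et: EtCO2Series, paradigm: ParadigmSpec) -> float:
    """Hypercapnic EtCO2 increase in mmHg.

    Mean end-tidal value over breaths in the second half (half-open interval
    ``(midpoint, end]``) of every CO2 block, minus the mean over breaths in
    the initial normocapnic air block.
    """
    co2 = paradigm.co2_intervals()
    if not co2:
        raise ValueError("paradigm contains no CO2 block")
    b_lo, b_hi = paradigm.baseline_window
    base_idx = et.breaths_in(b_lo, b_hi)
    if base_idx.size == 0:
        raise ValueError("no breaths in the initial normocapnic block")
    block_means = []
    for i, (start, end) in enumerate(co2):
        mid = 0.5 * (start + end)
        idx = et.breaths_in(mid, end, closed_left=False)
        if idx.size == 0:
            raise ValueError(f"no breaths in the second half of CO2 block {i + 1}")
        block_means.append(float(np.mean(et.etco2_values[idx])))
    return float(np.mean(block_means) - np.mean(et.etco2_values[base_idx]))


def qc_trace(
    et: EtCO2Series,
    paradigm: ParadigmSpec,
    slope_tolerance: float = 0.02,
    baseline_tolerance: float = 2.0,
) -> QCReport:
    """Codified steady-state and baseline-return checks.

    A CO2 block passes if the least-squares slope of its second-half breath
    values is within ``slope_tolerance`` mmHg/s of zero; a post-block air
    period passes if its breath mean is within ``baseline_tolerance`` mmHg of
    the initial baseline mean.
    """
    b_lo, b_hi = paradigm.baseline_window
    base_idx = et.breaths_in(b_lo, b_hi)
    if base_idx.size == 0:
        raise ValueError("no breaths in the initial normocapnic block")
    base_mean = float(np.mean(et.etco2_values[base_idx]))

    ss_ok, slopes = [], []
    for i, (start, end) in enumerate(paradigm.co2_intervals()):
        mid = 0.5 * (start + end)
        idx = et.breaths_in(mid, end, closed_left=False)
        if idx.size < 2:
            raise ValueError(
                f"fewer than two breaths in the second half of CO2 block {i + 1}"
            )
        slope = float(
            np.polyfit(et.breath_times[idx], et.etco2_values[idx], 1)[0]
        )
        slopes.append(slope)
        ss_ok.append(abs(slope) <= slope_tolerance)

    ret_ok, devs = [], []
    for i, (start, end) in enumerate(paradigm.air_intervals_after_co2()):
        # Skip the wash-out at the start of the period: use the second half,
        # where EtCO2 has had time to return toward baseline.
        mid = 0.5 * (start + end)
        idx = et.breaths_in(mid, end, closed_left=False)
        if idx.size == 0:
            raise ValueError(f"no breaths in post-CO2 air period {i + 1}")
        dev = float(np.mean(et.etco2_values[idx]) - base_mean)
        devs.append(dev)
        ret_ok.append(abs(dev) <= baseline_tolerance)

    return QCReport(
        steady_state_ok=ss_ok,
        steady_state_slopes=slopes,
        baseline_return_ok=ret_ok,
        baseline_deviations=devs,
        slope_tolerance=slope_tolerance,
        baseline_tolerance=baseline_tolerance,
    )
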