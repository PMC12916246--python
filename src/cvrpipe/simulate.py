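"""Synthetic capnometry, BOLD, and two-wave cohort generation.

Everything downstream of this module is testable against planted ground
truth: the capnometry simulator produces a breath-by-breath CO2 trace with
known end-tidal plateaus; the BOLD simulator inverts the CVR definition
(percent signal change per mmHg of EtCO2) as a forward model with polynomial
drift and AR(1) noise; the cohort simulator draws a two-wave sample with
planted CVR-structure effects and per-wave affine scanner effects.

Default cohort parameters emulate an older-adult sample of 154 participants
(26% female, age ~68 y at wave 1, 8.7 +/- 1.2 y between waves) with
hippocampal CVR around 0.2 %/mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .etco2 import CapnoTrace, EtCO2Series
from .paradigm import GAS_CO2, AcquisitionSpec, ParadigmSpec


# --------------------------------------------------------------------------
# Capnometry


@dataclass(frozen=True)
class BreathModel:
    """Breath-by-breath capnogram parameters.

    ``baseline_etco2`` and ``hypercapnic_boost`` are the normocapnic end-tidal
    plateau and its increase under 5% CO2, both in mmHg. Block transitions
    approach the new plateau target with first-order time constant
    ``transition_time_constant`` (seconds). Each breath rises from
    ``inspiratory_floor`` to its plateau, holds it for ``plateau_fraction`` of
    the breath, and falls back. ``plateau_jitter_sd`` adds breath-to-breath
    end-tidal variability; ``baseline_drift`` (mmHg/s) tilts the whole
    envelope, for generating QC-failing traces.
    """

    breathing_rate: float = 12.0  # breaths/min
    baseline_etco2: float = 40.0  # mmHg
    hypercapnic_boost: float = 8.0  # mmHg
    transition_time_constant: float = 10.0  # s
    inspiratory_floor: float = 4.0  # mmHg
    sampling_rate: float = 20.0  # Hz
    plateau_fraction: float = 0.3
    plateau_jitter_sd: float = 0.0  # mmHg
    baseline_drift: float = 0.0  # mmHg/s

    def __post_init__(self) -> None:
        if not 0 <= self.inspiratory_floor < self.baseline_etco2:
            raise ValueError("need baseline_etco2 > inspiratory_floor >= 0")
        if self.hypercapnic_boost < 0:
            raise ValueError("hypercapnic_boost must be non-negative")
        if not 0 < self.plateau_fraction < 1:
            raise ValueError("plateau_fraction must lie in (0, 1)")
        if self.breathing_rate <= 0:
            raise ValueError("breathing_rate must be positive")
        if self.transition_time_constant < 0:
            raise ValueError("transition_time_constant must be non-negative")
        if self.plateau_jitter_sd < 0:
            raise ValueError("plateau_jitter_sd must be non-negative")
        min_rate = 4.0 * self.breathing_rate / 60.0
        if self.sampling_rate < min_rate:
            raise ValueError(
                "sampling_rate too low to resolve breaths: need at least "
                f"{min_rate:g} Hz (4 samples per breath)"
            )

    @property
    def breath_period(self) -> float:
        return 60.0 / self.breathing_rate


def _plateau_envelope(
    paradigm: ParadigmSpec, breath: BreathModel, times: np.ndarray
) -> np.ndarray:
    """First-order wash-in/wash-out envelope of the end-tidal target.

    Solves dp/dt = (target(t) - p)/tau piecewise analytically; tau -> 0 gives
    the instantaneous block target.
    """
    tau = breath.transition_time_constant
    target = {False: breath.baseline_etco2, True: breath.baseline_etco2 + breath.hypercapnic_boost}
    out = np.empty_like(times)
    p_start = breath.baseline_etco2  # start at the normocapnic plateau
    for gas, start, end in paradigm.intervals():
        g = target[gas == GAS_CO2]
        sel = (times >= start) & (times < end)
        if tau <= 1e-12:
            out[sel] = g
            p_end = g
        else:
            out[sel] = g + (p_start - g) * np.exp(-(times[sel] - start) / tau)
            p_end = g + (p_start - g) * math.exp(-(end - start) / tau)
        p_start = p_end
    sel = times >= paradigm.total_duration
    out[sel] = p_start
    return out


def simulate_capnometry(
    paradigm: ParadigmSpec,
    breath: BreathModel,
    seed: int,
) -> Tuple[CapnoTrace, EtCO2Series]:
    """Generate a capnometry trace and its ground-truth end-tidal series.

    Each breath occupies one breath period and consists of a raised-cosine
    rise from the inspiratory floor, a flat end-tidal plateau occupying
    ``plateau_fraction`` of the breath, and a raised-cosine fall; breath
    boundaries sit at the floor, so the per-breath maximum is the plateau.
    The returned series lists each breath's plateau midpoint time and true
    plateau value.
    """
    rng = np.random.default_rng(seed)
    fs = breath.sampling_rate
    total = paradigm.total_duration
    period = breath.breath_period
    n_breaths = int(math.floor(total / period + 1e-9))
    if n_breaths < 2:
        raise ValueError("paradigm too short for two breaths")

    pf = breath.plateau_fraction
    a = (1.0 - pf) / 2.0  # rise (and fall) fraction
    plateau_start = np.arange(n_breaths) * period + a * period
    plateau_mid = plateau_start + 0.5 * pf * period

    plateaus = _plateau_envelope(paradigm, breath, plateau_start)
    plateaus = plateaus + breath.baseline_drift * plateau_start
    if breath.plateau_jitter_sd > 0:
        plateaus = plateaus + rng.normal(0.0, breath.plateau_jitter_sd, n_breaths)
    plateaus = np.maximum(plateaus, breath.inspiratory_floor)

    times = np.arange(int(round(total * fs))) / fs
    k = np.minimum((times / period).astype(int), n_breaths - 1)
    u = times / period - k
    p = plateaus[k]
    floor = breath.inspiratory_floor
    values = np.empty_like(times)
    rise = u < a
    fall = u >= a + pf
    flat = ~rise & ~fall
    values[rise] = floor + (p[rise] - floor) * 0.5 * (1 - np.cos(np.pi * u[rise] / a))
    values[flat] = p[flat]
    values[fall] = floor + (p[fall] - floor) * 0.5 * (
        1 + np.cos(np.pi * np.minimum(u[fall] - a - pf, 1 - a - pf) / (1 - a - pf))
    )
    # trailing partial breath (period not dividing the paradigm): hold the floor
    values[times >= n_breaths * period] = floor

    trace = CapnoTrace(sampling_rate=fs, values=values)
    truth = EtCO2Series(
        breath_times=plateau_mid,
        etco2_values=plateaus,
        baseline_window=paradigm.baseline_window,
    )
    return trace, truth


# --------------------------------------------------------------------------
# BOLD


@dataclass(frozen=True)
class VoxelModel:
    """Forward signal model of one voxel (or ROI mean).

    signal(t) = s0 * (1 + true_cvr * (etco2(t) - baseline_mean) / 100)
                + drift_linear * t + drift_quadratic * t^2 + AR(1) noise,
    with ``true_cvr`` in %BOLD per mmHg and ``noise_sd`` the stationary
    (marginal) standard deviation of the AR(1) noise.
    """

    s0: float = 1000.0
    true_cvr: float = 0.2  # %BOLD per mmHg
    drift_linear: float = 0.0  # units/s
    drift_quadratic: float = 0.0  # units/s^2
    noise_sd: float = 0.0
    ar1_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ValueError("s0 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")


def ar1_noise(n: int, phi: float, marginal_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with lag-1 coefficient ``phi``."""
    if marginal_sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * math.sqrt(1.0 - phi * phi)
    w = rng.normal(0.0, innov_sd, n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, marginal_sd)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + w[i]
    return x


def simulate_bold(
    truth: EtCO2Series,
    vox: VoxelModel,
    acq: AcquisitionSpec,
    seed: int,
):
    """Simulate an ROI-mean BOLD series from a ground-truth EtCO2 envelope."""
    from .cvr import BoldSeries  # local import to avoid a module cycle

    rng = np.random.default_rng(seed)
    t = acq.sample_times
    margin = (
        float(np.median(np.diff(truth.breath_times))) if truth.n_breaths > 1 else 0.0
    )
    if t[-1] > truth.breath_times[-1] + margin:
        raise ValueError("acquisition window is longer than the EtCO2 trace")
    e = np.interp(t, truth.breath_times, truth.etco2_values)
    signal = vox.s0 * (1.0 + vox.true_cvr * (e - truth.baseline_mean) / 100.0)
    signal = signal + vox.drift_linear * t + vox.drift_quadratic * t**2
    signal = signal + ar1_noise(t.size, vox.ar1_coefficient, vox.noise_sd, rng)
    return BoldSeries(sample_times=t, values=signal, units="raw")


def simulate_bold_volume(
    truth: EtCO2Series,
    vox: VoxelModel,
    acq: AcquisitionSpec,
    seed: int,
    cvr_grid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Simulate a small 4-D volume of independent voxels.

    ``cvr_grid`` (shape ``acq.grid_shape``) gives per-voxel true CVR values;
    if omitted, every voxel uses ``vox.true_cvr``. Noise is independent
    across voxels; seeds are derived per voxel from ``seed``.
    """
    shape = acq.grid_shape
    if cvr_grid is None:
        cvr_grid = np.full(shape, vox.true_cvr)
    cvr_grid = np.asarray(cvr_grid, dtype=float)
    if cvr_grid.shape != tuple(shape):
        raise ValueError("cvr_grid shape must equal acq.grid_shape")
    out = np.empty(tuple(shape) + (acq.n_volumes,))
    seeds = np.random.SeedSequence(seed).spawn(cvr_grid.size)
    for flat_i, idx in enumerate(np.ndindex(*shape)):
        v = replace(vox, true_cvr=float(cvr_grid[idx]))
        voxel_seed = int(seeds[flat_i].generate_state(1)[0] % (2**31))
        series = simulate_bold(truth, v, acq, voxel_seed)
        out[idx] = series.values
    return out


# --------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class ScannerAffine:
    """Per-wave affine scanner effect: observed = scale * latent + offset."""

    scale: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scanner scale must be positive")


@dataclass(frozen=True)
class MetricSpec:
    """Latent model of one structural metric across the two waves.

    latent wave 1  ~ Normal(wave1_mean, wave1_sd)
    annual change  = annual_change_mean + longitudinal_effect * CVR
                     + Normal(0, annual_change_sd)
    latent wave 2  = wave 1 + annual change * interval
                     + cross_sectional_effect * CVR
    observed value = scanner scale * latent + offset
                     + Normal(0, measurement_noise_sd)   (per wave)

    Effects are in outcome units per (%/mmHg) of CVR; ``family`` groups tract
    metrics for FDR correction and decline orientation.
    """

    wave1_mean: float
    wave1_sd: float
    annual_change_mean: float = 0.0
    annual_change_sd: float = 0.0
    measurement_noise_sd: float = 0.0
    cross_sectional_effect: float = 0.0
    longitudinal_effect: float = 0.0
    family: str = "other"


def _default_metrics() -> Dict[str, MetricSpec]:
    """Structural metrics of an older-adult cohort (hippocampal and whole-brain
    grey-matter volumes in cm^3, tract diffusion metrics in native units,
    WMH as log-percent of total brain volume), with gentle age-typical
    annual drifts."""
    tracts = ("corpus_callosum", "cingulum_bundle", "internal_capsule", "fornix")
    fa_mean = dict(zip(tracts, (0.72, 0.60, 0.64, 0.50)))
    fa_sd = dict(zip(tracts, (0.03, 0.03, 0.02, 0.04)))
    md_mean = dict(zip(tracts, (6.94e-4, 6.56e-4, 6.28e-4, 8.47e-4)))
    md_sd = dict(zip(tracts, (4.18e-5, 2.93e-5, 2.59e-5, 6.62e-5)))
    rd_mean = dict(zip(tracts, (3.11e-4, 3.85e-4, 3.45e-4, 6.03e-4)))
    rd_sd = dict(zip(tracts, (4.51e-5, 3.31e-5, 2.79e-5, 8.38e-5)))
    l1_mean = dict(zip(tracts, (1.46e-3, 1.20e-3, 1.19e-3, 1.33e-3)))
    l1_sd = dict(zip(tracts, (4.81e-5, 4.17e-5, 3.68e-5, 4.99e-5)))

    metrics: Dict[str, MetricSpec] = {
        "gmv_left_hippocampus": MetricSpec(3.05, 0.44, -0.015, 0.006, 0.09, family="gmv"),
        "gmv_right_hippocampus": MetricSpec(3.20, 0.40, -0.015, 0.006, 0.08, family="gmv"),
        "gmv_total": MetricSpec(549.0, 45.39, -2.0, 0.6, 9.0, family="gmv"),
        "log_wmh_pct": MetricSpec(1.55 - 0.6, 0.49, 0.07, 0.02, 0.10, family="wmh"),
    }
    for t in tracts:
        metrics[f"fa_{t}"] = MetricSpec(
            fa_mean[t] + 0.01, fa_sd[t], -0.0012, 0.0006, 0.2 * fa_sd[t], family="fa"
        )
        metrics[f"md_{t}"] = MetricSpec(
            md_mean[t] - 2e-5, md_sd[t], 2.5e-6, 1.0e-6, 0.2 * md_sd[t], family="md"
        )
        metrics[f"rd_{t}"] = MetricSpec(
            rd_mean[t] - 2e-5, rd_sd[t], 2.5e-6, 1.2e-6, 0.2 * rd_sd[t], family="rd"
        )
        metrics[f"l1_{t}"] = MetricSpec(
            l1_mean[t] - 1e-5, l1_sd[t], 1.5e-6, 1.0e-6, 0.2 * l1_sd[t], family="l1"
        )
    return metrics


@dataclass(frozen=True)
class CohortSpec:
    """Two-wave cohort structure with planted CVR-structure effects."""

    n_participants: int = 154
    female_fraction: float = 40.0 / 154.0
    age_mean: float = 68.2  # years at wave 1
    age_sd: float = 4.4
    interval_mean: float = 8.7  # years between waves
    interval_sd: float = 1.2
    cvr_mean: float = 0.205  # %/mmHg, hippocampal average
    cvr_sd: float = 0.07
    metrics: Dict[str, MetricSpec] = field(default_factory=_default_metrics)
    scanner_wave1: ScannerAffine = ScannerAffine()
    scanner_wave2: ScannerAffine = ScannerAffine(scale=1.04, offset=0.0)

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValueError("need at least 3 participants")
        for name in ("age_sd", "interval_sd", "cvr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")

    def with_effect(
        self,
        metric: str,
        cross_sectional: Optional[float] = None,
        longitudinal: Optional[float] = None,
    ) -> "CohortSpec":
        """Return a copy with a planted effect on one metric."""
        ms = self.metrics[metric]
        updates = {}
        if cross_sectional is not None:
            updates["cross_sectional_effect"] = cross_sectional
        if longitudinal is not None:
            updates["longitudinal_effect"] = longitudinal
        new_metrics = dict(self.metrics)
        new_metrics[metric] = replace(ms, **updates)
        return replace(self, metrics=new_metrics)


def _truncated_positive_normal(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection sampling of Normal(mean, sd) truncated to (0, inf)."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate truncated normal with non-positive mean")
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, 2 * (n - filled) + 8)
        draw = draw[draw > 0]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def simulate_cohort(spec: CohortSpec, seed: int) -> Tuple[pd.DataFrame, dict]:
    """Draw a two-wave cohort table plus its ground truth.

    Returns ``(table, truth)``. The table has one row per participant with
    demographic columns, CVR columns (``cvr_left_hipp``, ``cvr_right_hipp``,
    ``cvr_hipp``, ``cvr_whole_brain``) and, for every metric, observed
    ``<metric>_w1`` / ``<metric>_w2`` columns. ``truth`` records the planted
    effects and the latent (scanner-free) values.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_participants

    sex = np.where(rng.random(n) < spec.female_fraction, "F", "M")
    age_w1 = rng.normal(spec.age_mean, spec.age_sd, n)
    interval = np.clip(rng.normal(spec.interval_mean, spec.interval_sd, n), 0.5, None)
    age_w2 = age_w1 + interval

    cvr_hipp = _truncated_positive_normal(spec.cvr_mean, spec.cvr_sd, n, rng)
    lateral = rng.normal(0.0, 0.015, n) if spec.cvr_sd > 0 else np.zeros(n)
    cvr_left = np.maximum(cvr_hipp + 0.005 + lateral, 1e-3)
    cvr_right = np.maximum(cvr_hipp - 0.005 - lateral, 1e-3)
    wb_noise = rng.normal(0.0, 0.05, n) if spec.cvr_sd > 0 else np.zeros(n)
    cvr_wb = np.maximum(0.28 + 0.7 * (cvr_hipp - spec.cvr_mean) + wb_noise, 1e-3)

    data = {
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "sex": sex,
        "age_w1": age_w1,
        "age_w2": age_w2,
        "interval_years": interval,
        "cvr_left_hipp": cvr_left,
        "cvr_right_hipp": cvr_right,
        "cvr_hipp": cvr_hipp,
        "cvr_whole_brain": cvr_wb,
    }
    latent = {}
    for name, ms in spec.metrics.items():
        w1 = rng.normal(ms.wave1_mean, ms.wave1_sd, n) if ms.wave1_sd > 0 else np.full(n, ms.wave1_mean)
        change = ms.annual_change_mean + ms.longitudinal_effect * cvr_hipp
        if ms.annual_change_sd > 0:
            change = change + rng.normal(0.0, ms.annual_change_sd, n)
        w2 = w1 + change * interval + ms.cross_sectional_effect * cvr_hipp
        for wave, lat, aff in (
            ("w1", w1, spec.scanner_wave1),
            ("w2", w2, spec.scanner_wave2),
        ):
            obs = aff.scale * lat + aff.offset
            if ms.measurement_noise_sd > 0:
                obs = obs + rng.normal(0.0, ms.measurement_noise_sd, n)
            data[f"{name}_{wave}"] = obs
        latent[name] = {"w1": w1, "w2": w2}

    table = pd.DataFrame(data)
    truth = {
        "effects": {
            name: {
                "cross_sectional": ms.cross_sectional_effect,
                "longitudinal": ms.longitudinal_effect,
            }
            for name, ms in spec.metrics.items()
        },
        "latent": latent,
        "spec": spec,
    }
    return table, truth
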