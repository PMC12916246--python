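"""Cross-scanner standardized change scores and the WMH log transform.

Waves 1 and 2 of the cohort were scanned on different machines, so raw
volumes and diffusion metrics are not directly comparable across waves.
Values are therefore z-scored within each wave (sample SD, n-1 denominator)
and longitudinal change is the difference of z-scores,
``delta = z_wave2 - z_wave1`` — a relative measure that is exactly invariant
to any positive-scale affine scanner effect applied uniformly within a wave.

White-matter hyperintensity volume is handled separately: it is expressed as
a percentage of total brain volume (grey + white + CSF), log-transformed,
and its change is the plain difference of log-percent values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: Decline orientation per metric family: for GMV and FA a more negative
#: delta means more decline; for the diffusivities (MD, RD, L1) a more
#: positive delta means more decline.
DECLINE_ORIENTATION = {
    "gmv": "negative",
    "fa": "negative",
    "md": "positive",
    "rd": "positive",
    "l1": "positive",
}


def metric_family(metric: str) -> str:
    """Metric family inferred from the name prefix (e.g. ``fa_fornix`` -> ``fa``)."""
    prefix = metric.split("_", 1)[0].lower()
    if prefix in DECLINE_ORIENTATION:
        return prefix
    if metric.lower().startswith("log_wmh") or prefix == "wmh":
        return "wmh"
    return "other"


def zscore_wave(values) -> np.ndarray:
    """Standardize metric values within one wave: (x - mean) / sample SD."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 participants to z-score a wave")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero variance within wave: cannot z-score")
    return (x - float(np.mean(x))) / sd


@dataclass
class ChangeScores:
    """Per-participant standardized change for one metric."""

    participants: np.ndarray
    metric: str
    z_wave1: np.ndarray
    z_wave2: np.ndarray
    delta: np.ndarray
    decline_orientation: str


def change_scores(z1: pd.Series, z2: pd.Series, metric: str = "") -> ChangeScores:
    """Difference of within-wave z-scores, wave 2 minus wave 1.

    ``z1`` and ``z2`` are indexed by participant id; the participant sets
    must match exactly (completers-only analysis).
    """
    ids1, ids2 = set(z1.index), set(z2.index)
    if ids1 != ids2:
        missing = sorted(ids1 ^ ids2)
        raise ValueError(f"unmatched participants across waves: {missing}")
    z2 = z2.reindex(z1.index)
    return ChangeScores(
        participants=np.asarray(z1.index),
        metric=metric,
        z_wave1=z1.to_numpy(dtype=float),
        z_wave2=z2.to_numpy(dtype=float),
        delta=(z2 - z1).to_numpy(dtype=float),
        decline_orientation=DECLINE_ORIENTATION.get(metric_family(metric), "negative"),
    )


def build_change_table(long_table: pd.DataFrame) -> pd.DataFrame:
    """Change scores for every metric of a long-format two-wave table.

    ``long_table`` has columns (participant_id, wave, metric, value) with
    wave labels 1 and 2. Participants missing either wave of a metric are
    excluded listwise for that metric; the output is a wide table indexed by
    participant with one ``delta_<metric>`` column per metric.
    """
    required = {"participant_id", "wave", "metric", "value"}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = {}
    for metric, grp in long_table.groupby("metric"):
        wide = grp.pivot_table(
            index="participant_id", columns="wave", values="value", aggfunc="first"
        )
        if not {1, 2} <= set(wide.columns):
            raise ValueError(f"metric {metric!r} lacks one of the waves")
        complete = wide.dropna(subset=[1, 2])
        z1 = pd.Series(zscore_wave(complete[1].to_numpy()), index=complete.index)
        z2 = pd.Series(zscore_wave(complete[2].to_numpy()), index=complete.index)
        out[f"delta_{metric}"] = z2 - z1
    return pd.DataFrame(out)


@dataclass(frozen=True)
class WmhRecord:
    """WMH volume as log-percent of total brain volume."""

    wmh: float
    grey: float
    white: float
    csf: float
    percent_wmh: float
    log_wmh: float
    log_base: float


def wmh_percent_log(
    wmh: float,
    grey: float,
    white: float,
    csf: float,
    base: float = math.e,
) -> WmhRecord:
    """Express WMH volume as a percentage of total brain volume, then take
    the log (natural log by default; the base is configurable)."""
    for name, v in (("wmh", wmh), ("grey", grey), ("white", white), ("csf", csf)):
        if not v > 0:
            raise ValueError(f"{name} volume must be positive")
    if not base > 0 or base == 1:
        raise ValueError("log base must be positive and not 1")
    percent = 100.0 * wmh / (grey + white + csf)
    return WmhRecord(
        wmh=wmh,
        grey=grey,
        white=white,
        csf=csf,
        percent_wmh=percent,
        log_wmh=math.log(percent) / math.log(base),
        log_base=base,
    )


def wmh_change(record1: WmhRecord, record2: WmhRecord) -> float:
    """Longitudinal WMH change: wave-2 minus wave-1 log-percent values
    (positive = WMH increase)."""
    if record1.log_base != record2.log_base:
        raise ValueError("records use different log bases")
    return record2.log_wmh - record1.log_wmh
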