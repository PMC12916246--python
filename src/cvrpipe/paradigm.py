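"""Gas-challenge paradigm and acquisition specifications.

The default paradigm is the block design used for hypercapnic CVR mapping in
older cohorts: one minute of medical air to establish the normocapnic
baseline, then two 75-s blocks of 5% CO2 in air, each followed by a 75-s
air washout block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Tuple

GAS_AIR = "air"
GAS_CO2 = "co2"

_DEFAULT_BLOCKS: Tuple[Tuple[str, float], ...] = (
    (GAS_AIR, 60.0),
    (GAS_CO2, 75.0),
    (GAS_AIR, 75.0),
    (GAS_CO2, 75.0),
    (GAS_AIR, 75.0),
)


@dataclass(frozen=True)
class ParadigmSpec:
    """Ordered gas blocks of a CO2-inhalation paradigm.

    Each block is a ``(gas_state, duration_s)`` pair with ``gas_state`` one of
    ``"air"`` or ``"co2"``. The first block must be air: it defines the
    normocapnic baseline window used for EtCO2 normalization and for the
    percent-signal-change reference.
    """

    blocks: Tuple[Tuple[str, float], ...] = _DEFAULT_BLOCKS

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("paradigm must contain at least one block")
        for state, duration in self.blocks:
            if state not in (GAS_AIR, GAS_CO2):
                raise ValueError(f"unknown gas state {state!r}")
            if not duration > 0:
                raise ValueError("block durations must be positive")
        if self.blocks[0][0] != GAS_AIR:
            raise ValueError("first block must be air (normocapnic baseline)")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.blocks))

    def intervals(self) -> Iterator[Tuple[str, float, float]]:
        """Yield ``(gas_state, start_s, end_s)`` for each block in order."""
        t = 0.0
        for state, duration in self.blocks:
            yield state, t, t + duration
            t += duration

    @property
    def baseline_window(self) -> Tuple[float, float]:
        """Initial normocapnic window ``(0, first air-block end)`` in seconds."""
        return 0.0, self.blocks[0][1]

    def co2_intervals(self) -> list[Tuple[float, float]]:
        return [(s, e) for g, s, e in self.intervals() if g == GAS_CO2]

    def air_intervals_after_co2(self) -> list[Tuple[float, float]]:
        """Air blocks that follow a CO2 block (baseline-return QC windows)."""
        out = []
        prev = None
        for g, s, e in self.intervals():
            if g == GAS_AIR and prev == GAS_CO2:
                out.append((s, e))
            prev = g
        return out


@dataclass(frozen=True)
class AcquisitionSpec:
    """BOLD sampling grid: repetition time, volume count, spatial grid.

    ``grid_shape`` of ``(1, 1, 1)`` denotes ROI-series mode (a single mean
    time course rather than a volume).
    """

    repetition_time: float = 2.0
    n_volumes: int = 180
    grid_shape: Tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if not self.repetition_time > 0:
            raise ValueError("repetition_time must be positive")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be at least 2")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")

    @property
    def sample_times(self):
        import numpy as np

        return np.arange(self.n_volumes) * self.repetition_time

    @property
    def duration(self) -> float:
        return self.n_volumes * self.repetition_time
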