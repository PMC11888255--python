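"""Intermittent theta-burst stimulation (iTBS) pulse-train generation.

The iTBS600 protocol packs 600 magnetic pulses into 3-pulse bursts at 50 Hz,
bursts repeating at 5 Hz (every 200 ms), with 10 bursts per 2-s duty cycle and
an 8-s silent interval before the next cycle, for 20 cycles in total.  This
module generates the pulse timestamps for any protocol of that family and can
re-segment a timestamp train back into its cycle/burst structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ProtocolConfigError(ValueError):
    """Raised when a stimulation-protocol configuration violates an invariant."""


@dataclass(frozen=True)
class StimProtocolConfig:
    """Timing parameters of an intermittent burst-stimulation protocol.

    Parameters
    ----------
    n_cycles : int
        Number of duty cycles (default 20).
    bursts_per_cycle : int
        Bursts delivered within each duty cycle (default 10).
    pulses_per_burst : int
        Pulses per burst (default 3).
    intra_burst_rate : float
        Pulse rate within a burst, Hz (default 50).
    burst_rate : float
        Burst repetition rate within a cycle, Hz (default 5).
    inter_cycle_gap : float
        Silent interval between the end of one cycle's burst train and the
        first pulse of the next cycle, seconds (default 8).  With the default
        numbers one duty cycle spans bursts_per_cycle/burst_rate +
        inter_cycle_gap = 2 s + 8 s = 10 s.
    """

    n_cycles: int = 20
    bursts_per_cycle: int = 10
    pulses_per_burst: int = 3
    intra_burst_rate: float = 50.0
    burst_rate: float = 5.0
    inter_cycle_gap: float = 8.0

    def __post_init__(self) -> None:
        for name in ("n_cycles", "bursts_per_cycle", "pulses_per_burst"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ProtocolConfigError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("intra_burst_rate", "burst_rate"):
            v = getattr(self, name)
            if not v > 0:
                raise ProtocolConfigError(f"{name} must be > 0, got {v!r}")
        if not self.intra_burst_rate > self.burst_rate:
            raise ProtocolConfigError(
                "intra_burst_rate must exceed burst_rate "
                f"({self.intra_burst_rate} <= {self.burst_rate})"
            )
        if self.inter_cycle_gap < 0:
            raise ProtocolConfigError(
                f"inter_cycle_gap must be >= 0, got {self.inter_cycle_gap!r}"
            )

    @property
    def n_pulses(self) -> int:
        return self.n_cycles * self.bursts_per_cycle * self.pulses_per_burst

    @property
    def cycle_period(self) -> float:
        """Start-to-start spacing of consecutive duty cycles, seconds."""
        return self.bursts_per_cycle / self.burst_rate + self.inter_cycle_gap


@dataclass(frozen=True)
class PulseTrain:
    """Strictly increasing pulse timestamps (s), first pulse at t = 0."""

    timestamps: np.ndarray
    config: StimProtocolConfig

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.size != self.config.n_pulses:
            raise ValueError(
                f"expected {self.config.n_pulses} timestamps, got {ts.size}"
            )
        if ts.size and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.timestamps.size)


def generate_pulse_train(cfg: StimProtocolConfig | None = None) -> PulseTrain:
    """Generate the pulse timestamps of a burst-stimulation protocol.

    Pulse i of burst j of cycle k fires at
    ``k * cycle_period + j / burst_rate + i / intra_burst_rate``
    with the first pulse at t = 0.  The default configuration yields the
    iTBS600 train: 600 pulses over 20 cycles, ending at 191.84 s.
    """
    if cfg is None:
        cfg = StimProtocolConfig()
    k = np.arange(cfg.n_cycles)[:, None, None] * cfg.cycle_period
    j = np.arange(cfg.bursts_per_cycle)[None, :, None] / cfg.burst_rate
    i = np.arange(cfg.pulses_per_burst)[None, None, :] / cfg.intra_burst_rate
    ts = (k + j + i).ravel()
    return PulseTrain(timestamps=ts, config=cfg)


def segment_train(
    timestamps: np.ndarray | PulseTrain,
    burst_gap: float = 0.1,
    cycle_gap: float = 1.0,
) -> list[list[list[int]]]:
    """Segment pulse timestamps into cycles -> bursts -> pulse indices.

    A new burst starts whenever the inter-pulse gap exceeds ``burst_gap``;
    a new cycle whenever it exceeds ``cycle_gap``.  The defaults (0.1 s, 1 s)
    sit between the default protocol's intra-burst (0.02 s), inter-burst
    (0.2 s) and inter-cycle (8 s) spacings.  Every pulse is assigned to
    exactly one burst of exactly one cycle.
    """
    if not 0 < burst_gap < cycle_gap:
        raise ValueError(f"need 0 < burst_gap < cycle_gap, got {burst_gap}, {cycle_gap}")
    ts = timestamps.timestamps if isinstance(timestamps, PulseTrain) else np.asarray(
        timestamps, dtype=float
    )
    if ts.size == 0:
        return []
    cycles: list[list[list[int]]] = [[[0]]]
    for idx in range(1, ts.size):
        gap = ts[idx] - ts[idx - 1]
        if gap > cycle_gap:
            cycles.append([[idx]])
        elif gap > burst_gap:
            cycles[-1].append([idx])
        else:
            cycles[-1][-1].append(idx)
    return cycles


# Default 11-point imaging schedule of the time-lapse spine experiment:
# daily scans on days 0-4, stimulation ~1 h after the day-4 scan, hourly
# scans for 5 h post-stimulation, and a final scan 24 h post-stimulation.
SCHEDULE_STIM_TIME_H = 97.0


@dataclass(frozen=True)
class ImagingSchedule:
    """Labeled scan times (hours from the first scan) of the spine experiment."""

    labels: tuple[str, ...] = (
        "day0", "day1", "day2", "day3", "day4",
        "+1h", "+2h", "+3h", "+4h", "+5h", "+24h",
    )
    times_h: tuple[float, ...] = (
        0.0, 24.0, 48.0, 72.0, 96.0,
        SCHEDULE_STIM_TIME_H + 1, SCHEDULE_STIM_TIME_H + 2, SCHEDULE_STIM_TIME_H + 3,
        SCHEDULE_STIM_TIME_H + 4, SCHEDULE_STIM_TIME_H + 5, SCHEDULE_STIM_TIME_H + 24,
    )
    stim_time_h: float = SCHEDULE_STIM_TIME_H
    baseline_label: str = "day4"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.times_h):
            raise ValueError("labels and times_h must have equal length")
        if len(self.labels) != 11:
            raise ValueError(f"schedule must have 11 scan labels, got {len(self.labels)}")
        if not all(b > a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("scan times must be strictly increasing")
        if self.baseline_label not in self.labels:
            raise ValueError(f"baseline label {self.baseline_label!r} not in schedule")

    @property
    def post_stim_labels(self) -> tuple[str, ...]:
        """Labels of scans acquired after the stimulation marker."""
        return tuple(
            lab for lab, t in zip(self.labels, self.times_h) if t > self.stim_time_h
        )

    @property
    def window_24h_labels(self) -> tuple[str, ...]:
        """Baseline-through-+24h labels used for trajectory correlations."""
        i0 = self.labels.index(self.baseline_label)
        return self.labels[i0:]

    def time_of(self, label: str) -> float:
        return self.times_h[self.labels.index(label)]


DEFAULT_SCHEDULE = ImagingSchedule()
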