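"""In-memory containers shared by the simulator and the signal pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FLAG_OK",
    "FLAG_DEGAS",
    "FLAG_SPIKE",
    "FLAG_GAP",
    "PressureTrace",
    "Event",
    "EventLog",
    "DegassingEvent",
    "CumulativeVolumeTrace",
    "ProductionRate",
    "GroundTruth",
]

FLAG_OK = "ok"
FLAG_DEGAS = "degas"
FLAG_SPIKE = "spike"
FLAG_GAP = "gap"


@dataclass
class PressureTrace:
    """Uniformly sampled absolute-pressure series for one reactor.

    ``flags`` carries per-sample quality markers (``ok``, ``degas``,
    ``spike``, ``gap``).  ``validate`` enforces strictly increasing, uniform
    timestamps (within 1 %) and physically admissible pressures.
    """

    time_s: np.ndarray
    pressure_bar: np.ndarray
    reactor_id: str = "R1"
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_bar = np.asarray(self.pressure_bar, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.time_s.shape, FLAG_OK, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def sampling_interval_s(self) -> float:
        return float(np.median(np.diff(self.time_s))) if len(self) > 1 else np.nan

    def validate(self) -> None:
        if len(self.time_s) != len(self.pressure_bar):
            raise ValueError("time_s and pressure_bar lengths differ")
        dt = np.diff(self.time_s)
        if len(dt) and not np.all(dt > 0):
            k = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"time not strictly increasing at row {k}")
        if len(dt):
            med = np.median(dt)
            if np.any(np.abs(dt - med) > 0.01 * med):
                k = int(np.argmax(np.abs(dt - med) > 0.01 * med)) + 1
                raise ValueError(f"non-uniform sampling interval at row {k}")
        bad = ~((self.pressure_bar > 0) & (self.pressure_bar <= 3.4))
        if np.any(bad):
            k = int(np.argmax(bad))
            raise ValueError(
                f"pressure {self.pressure_bar[k]!r} at row {k} outside (0, 3.4] bar"
            )

    def copy(self) -> "PressureTrace":
        return PressureTrace(
            self.time_s.copy(),
            self.pressure_bar.copy(),
            self.reactor_id,
            self.flags.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "reactor_id": self.reactor_id,
                "pressure_bar": self.pressure_bar,
                "flag": self.flags,
            }
        )


class Event(NamedTuple):
    time_s: float
    reactor_id: str
    event_type: str  # degas_start | degas_end | feed | waste | sample
    value: float


EVENT_TYPES = frozenset({"degas_start", "degas_end", "feed", "waste", "sample"})


class EventLog:
    """Timestamped controller/actuator events for one or more reactors."""

    def __init__(self, events=()):
        self.events: list[Event] = [Event(*e) for e in events]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def append(self, time_s, reactor_id, event_type, value=0.0) -> None:
        if event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {event_type!r}")
        self.events.append(Event(float(time_s), reactor_id, event_type, float(value)))

    def extend(self, other: "EventLog") -> None:
        self.events.extend(other.events)

    def sort(self) -> "EventLog":
        self.events.sort(key=lambda e: e.time_s)
        return self

    def of_type(self, *event_types: str) -> list[Event]:
        return [e for e in self.events if e.event_type in event_types]

    def total_volume(self, event_type: str) -> float:
        return sum(e.value for e in self.of_type(event_type))

    def validate(self) -> None:
        times = [e.time_s for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be nondecreasing")
        open_count = 0
        for e in self.events:
            if e.event_type == "degas_start":
                open_count += 1
            elif e.event_type == "degas_end":
                open_count -= 1
                if open_count < 0:
                    raise ValueError(f"degas_end at t={e.time_s} without degas_start")
        if open_count != 0:
            raise ValueError("unmatched degas_start (no later degas_end)")

    def degas_windows(self) -> list[tuple[float, float]]:
        """Paired (start, end) times of degassing intervals."""
        self.validate()
        starts = [e.time_s for e in self.of_type("degas_start")]
        ends = [e.time_s for e in self.of_type("degas_end")]
        return list(zip(starts, ends))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=Event._fields)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventLog":
        return cls(
            Event(float(r.time_s), str(r.reactor_id), str(r.event_type), float(r.value))
            for r in frame.itertuples()
        )


@dataclass
class DegassingEvent:
    """One automatic pump-out: pressure drop from ~p_high back to ~p_low."""

    start_time_s: float
    end_time_s: float
    pressure_before_bar: float
    pressure_after_bar: float

    def __post_init__(self) -> None:
        if not self.start_time_s < self.end_time_s:
            raise ValueError("degassing event needs start < end")
        if self.drop_bar <= 0:
            raise ValueError("degassing event needs a positive pressure drop")

    @property
    def drop_bar(self) -> float:
        return self.pressure_before_bar - self.pressure_after_bar


@dataclass
class CumulativeVolumeTrace:
    """Stitched, spike-filtered, STP-normalised cumulative biogas volume."""

    time_d: np.ndarray
    volume_mL_STP: np.ndarray
    reactor_id: str = "R1"
    flags: np.ndarray | None = None
    n_spikes_removed: int = 0
    n_degas_events: int = 0

    def __post_init__(self) -> None:
        self.time_d = np.asarray(self.time_d, dtype=float)
        self.volume_mL_STP = np.asarray(self.volume_mL_STP, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.time_d.shape, FLAG_OK, dtype=object)
        if len(self.volume_mL_STP) and self.volume_mL_STP[0] != 0.0:
            raise ValueError("cumulative volume must start at 0")
        if self.n_spikes_removed < 0 or self.n_degas_events < 0:
            raise ValueError("counts must be >= 0")

    def __len__(self) -> int:
        return len(self.time_d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_d": self.time_d,
                "volume_mL_STP": self.volume_mL_STP,
                "flag": self.flags,
            }
        )


@dataclass
class ProductionRate:
    """OLS estimate of the biogas production rate (slope over time in days)."""

    slope_mL_d: float
    r2: float
    se_slope_mL_d: float
    n_points: int
    intercept_mL: float = 0.0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("rate estimate needs at least 3 points")
        if self.se_slope_mL_d < 0:
            raise ValueError("standard error must be >= 0")

    def interval(self, k: float = 3.0) -> tuple[float, float]:
        """Slope ± k standard errors."""
        return (
            self.slope_mL_d - k * self.se_slope_mL_d,
            self.slope_mL_d + k * self.se_slope_mL_d,
        )


@dataclass
class GroundTruth:
    """Per-sample true state of a simulated reactor, for pipeline validation.

    All gas quantities are in mL STP-equivalent.  ``produced``, ``degassed``
    are cumulative; ``headspace`` is the instantaneous headspace inventory;
    ``dissolved`` the dissolved pool.
    """

    time_s: np.ndarray
    pressure_bar: np.ndarray
    produced_mL_STP: np.ndarray
    degassed_mL_STP: np.ndarray
    headspace_mL_STP: np.ndarray
    dissolved_mL_STP: np.ndarray
    overpressure: bool = False

    def mass_balance_error(self) -> float:
        """Relative closure error of produced = ΔG + degassed + ΔD.

        Absolute error when nothing was produced.
        """
        produced = self.produced_mL_STP[-1]
        accounted = (
            (self.headspace_mL_STP[-1] - self.headspace_mL_STP[0])
            + self.degassed_mL_STP[-1]
            + (self.dissolved_mL_STP[-1] - self.dissolved_mL_STP[0])
        )
        err = abs(produced - accounted)
        return err / produced if produced > 0 else err

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "pressure_bar": self.pressure_bar,
                "produced_mL_STP": self.produced_mL_STP,
                "degassed_mL_STP": self.degassed_mL_STP,
                "headspace_mL_STP": self.headspace_mL_STP,
                "dissolved_mL_STP": self.dissolved_mL_STP,
            }
        )
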