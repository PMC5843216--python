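"""Reactor, production-profile and artifact configuration.

A :class:`ReactorConfig` describes one quasi-continuous anaerobic chemostat:
vessel geometry, temperature, the hysteresis degassing thresholds, the sensor
model, pulse feed/waste schedules and the organic loading rate.  A
:class:`ProductionProfile` prescribes the exogenous biogas production kinetics
(the package does not model microbial growth), and an :class:`ArtifactSpec`
describes measurement artifacts — transient spikes, persistent baseline steps
(e.g. liquid sampling) and slow leaks — to inject into a sensor trace.

All three can be loaded from a single TOML file via :func:`load_config`.
"""

from __future__ import annotations

import math
import tomllib
import warnings
from dataclasses import dataclass, field, fields, asdict
from typing import Sequence

__all__ = [
    "P_STD_BAR",
    "T_STD_K",
    "VESSEL_MAX_BAR",
    "SENSOR_MAX_BAR",
    "ReactorConfig",
    "ProductionProfile",
    "ArtifactSpec",
    "ConfigBundle",
    "ConfigError",
    "load_config",
]

#: Standard (normalisation) pressure for biogas volumes, bar.
P_STD_BAR = 1.013
#: Standard (normalisation) temperature for biogas volumes, K.
T_STD_K = 293.15
#: Pressure rating of the reactor vessel, bar absolute.
VESSEL_MAX_BAR = 1.5
#: Accepted maximum pressure of the sensor, bar absolute.
SENSOR_MAX_BAR = 3.4

#: Working-volume range the bench hardware accommodates, mL.
WORKING_VOLUME_RANGE_ML = (50.0, 200.0)


class ConfigError(ValueError):
    """A configuration value violates an invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class ReactorConfig:
    """Static description of one reactor.

    Parameters
    ----------
    working_volume_mL
        Liquid volume.  The hardware accepts 50–200 mL; values outside that
        range raise a warning, not an error.
    headspace_volume_mL
        Effective gas-phase volume (vessel headspace plus sensor/tubing dead
        volume).  It must be supplied, not derived from the bottle size.
    temperature_K
        Reactor temperature (constant; mesophilic default 310.15 K = 37 °C).
    p_high_bar, p_low_bar
        Hysteresis degassing thresholds: pump-out starts at ``p_high_bar``
        and stops at ``p_low_bar`` (defaults 1.2 / 1.05 bar absolute).
    p_init_bar
        Pressure at t = 0 (default: the lower threshold).
    sampling_interval_s
        Sensor logging period (default 20 s).
    sensor_resolution_bar
        Quantization step of the pressure sensor (default 0.0015 bar).
    sensor_noise_sd_bar
        SD of additive Gaussian sensor noise (default half a quantization
        step).
    degas_pump_rate_mL_min
        Volumetric gas removal rate at reactor conditions while degassing.
    feed_pulses_per_day, feed_pulse_volume_mL
        Pulse feeding schedule (default 24 × 0.5 mL).
    waste_pulses_per_day, waste_pulse_volume_mL
        Pulse wasting schedule (default 24 × 0.5 mL = 12 mL/d).
    olr_gCOD_L_d
        Organic loading rate as chemical oxygen demand (default 1.33).
    henry_capacity_mL_per_bar
        Capacity of the dissolved-gas pool, mL STP per bar of headspace
        pressure.  0 disables gas–liquid re-equilibration.
    reequil_rate_per_h
        First-order rate at which the dissolved pool relaxes toward its
        pressure-dependent equilibrium.
    """

    working_volume_mL: float = 150.0
    headspace_volume_mL: float = 50.0
    temperature_K: float = 310.15
    p_high_bar: float = 1.2
    p_low_bar: float = 1.05
    p_init_bar: float = 1.05
    sampling_interval_s: float = 20.0
    sensor_resolution_bar: float = 0.0015
    sensor_noise_sd_bar: float = 0.00075
    degas_pump_rate_mL_min: float = 20.0
    feed_pulses_per_day: int = 24
    feed_pulse_volume_mL: float = 0.5
    waste_pulses_per_day: int = 24
    waste_pulse_volume_mL: float = 0.5
    olr_gCOD_L_d: float = 1.33
    henry_capacity_mL_per_bar: float = 0.0
    reequil_rate_per_h: float = 2.0
    reactor_id: str = "R1"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self
        _require(
            0 < c.p_low_bar < c.p_high_bar,
            f"need 0 < p_low_bar < p_high_bar, got p_low_bar={c.p_low_bar}, "
            f"p_high_bar={c.p_high_bar}",
        )
        _require(
            c.p_high_bar <= VESSEL_MAX_BAR,
            f"p_high_bar={c.p_high_bar} exceeds vessel rating {VESSEL_MAX_BAR} bar",
        )
        _require(
            c.p_high_bar < SENSOR_MAX_BAR,
            f"p_high_bar={c.p_high_bar} exceeds sensor maximum {SENSOR_MAX_BAR} bar",
        )
        _require(c.p_init_bar > 0, f"p_init_bar={c.p_init_bar} must be > 0")
        for name in (
            "working_volume_mL",
            "headspace_volume_mL",
            "temperature_K",
            "sampling_interval_s",
            "sensor_resolution_bar",
            "degas_pump_rate_mL_min",
        ):
            v = getattr(c, name)
            _require(v > 0, f"{name}={v} must be > 0")
        for name in (
            "sensor_noise_sd_bar",
            "feed_pulses_per_day",
            "feed_pulse_volume_mL",
            "waste_pulses_per_day",
            "waste_pulse_volume_mL",
            "olr_gCOD_L_d",
            "henry_capacity_mL_per_bar",
            "reequil_rate_per_h",
        ):
            v = getattr(c, name)
            _require(v >= 0, f"{name}={v} must be >= 0")
        lo, hi = WORKING_VOLUME_RANGE_ML
        if not lo <= c.working_volume_mL <= hi:
            warnings.warn(
                f"working_volume_mL={c.working_volume_mL} outside the "
                f"supported range [{lo}, {hi}] mL",
                stacklevel=3,
            )

    @property
    def daily_cod_g(self) -> float:
        """Daily COD load, g/d (= OLR × working volume in L)."""
        return self.olr_gCOD_L_d * self.working_volume_mL / 1000.0

    @property
    def hydraulic_retention_time_d(self) -> float:
        """HRT = liquid volume / daily wasting throughflow, days.

        Reported from the configured schedule (V/Q), not asserted against any
        nominal value.  Infinite in fed-batch mode (zero wasting).
        """
        q = self.waste_pulses_per_day * self.waste_pulse_volume_mL
        return math.inf if q == 0 else self.working_volume_mL / q

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProductionProfile:
    """Exogenous biogas production kinetics, in mL STP per day.

    ``kind`` selects constant, piecewise-constant (rates between successive
    ``breakpoints_d``) or first-order (``rate * exp(-k t)``) kinetics.
    """

    kind: str = "constant"
    rate_mL_STP_d: float | Sequence[float] = 8.0
    breakpoints_d: Sequence[float] = field(default_factory=tuple)
    k_per_d: float = 0.0

    def __post_init__(self) -> None:
        _require(
            self.kind in ("constant", "piecewise_constant", "first_order"),
            f"unknown profile kind {self.kind!r}",
        )
        rates = self._rates()
        _require(all(r >= 0 for r in rates), f"rates must be >= 0, got {rates}")
        bp = tuple(self.breakpoints_d)
        _require(
            all(b1 < b2 for b1, b2 in zip(bp, bp[1:])),
            f"breakpoints_d must be strictly increasing, got {bp}",
        )
        if self.kind == "piecewise_constant":
            _require(
                len(rates) == len(bp) + 1,
                f"piecewise profile needs len(rates) == len(breakpoints)+1, "
                f"got {len(rates)} rates and {len(bp)} breakpoints",
            )
        if self.kind == "first_order":
            _require(self.k_per_d >= 0, f"k_per_d={self.k_per_d} must be >= 0")

    def _rates(self) -> tuple[float, ...]:
        r = self.rate_mL_STP_d
        return tuple(r) if isinstance(r, (list, tuple)) else (float(r),)

    def rate_at(self, t_d: float) -> float:
        """Instantaneous production rate at time ``t_d`` (days), mL STP/d."""
        rates = self._rates()
        if self.kind == "constant":
            return rates[0]
        if self.kind == "piecewise_constant":
            i = sum(1 for b in self.breakpoints_d if t_d >= b)
            return rates[i]
        return rates[0] * math.exp(-self.k_per_d * t_d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["breakpoints_d"] = list(self.breakpoints_d)
        return d


@dataclass
class ArtifactSpec:
    """Measurement artifacts to superimpose on a sensor trace.

    spike_events
        ``(time_d, magnitude_mbar, duration_samples)``: transient excursions
        that add ``magnitude`` for ``duration`` samples and then revert
        (sensor glitches).
    step_events
        ``(time_d, magnitude_mbar)``: persistent baseline shifts, as caused
        by manual liquid sampling (headspace expands, pressure drops and
        stays down).
    leak_events
        ``(start_d, end_d, rate_mbar_min)``: sustained declines accumulating
        over the window; the accumulated deficit persists afterwards.
    spikes_per_day / steps_per_day
        Random-placement alternative to explicit times; positions are drawn
        reproducibly from ``seed``.
    """

    spike_events: Sequence[tuple] = field(default_factory=tuple)
    step_events: Sequence[tuple] = field(default_factory=tuple)
    leak_events: Sequence[tuple] = field(default_factory=tuple)
    spikes_per_day: float = 0.0
    spike_magnitude_mbar: float = 15.0
    spike_duration_samples: int = 1
    steps_per_day: float = 0.0
    step_magnitude_mbar: float = -15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for ev in self.spike_events:
            _require(len(ev) == 3, f"spike event needs (time_d, mbar, n), got {ev}")
            _require(int(ev[2]) >= 1, f"spike duration must be >= 1 sample: {ev}")
        for ev in self.step_events:
            _require(len(ev) == 2, f"step event needs (time_d, mbar), got {ev}")
        for ev in self.leak_events:
            _require(len(ev) == 3, f"leak event needs (start_d, end_d, rate), got {ev}")
            _require(ev[0] < ev[1], f"leak window must have start < end: {ev}")
        _require(self.spikes_per_day >= 0, "spikes_per_day must be >= 0")
        _require(self.steps_per_day >= 0, "steps_per_day must be >= 0")

    @property
    def empty(self) -> bool:
        return not (
            self.spike_events
            or self.step_events
            or self.leak_events
            or self.spikes_per_day
            or self.steps_per_day
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("spike_events", "step_events", "leak_events"):
            d[k] = [list(ev) for ev in d[k]]
        return d


@dataclass
class ConfigBundle:
    """Everything a simulation run needs: reactor, kinetics, artifacts, seed."""

    reactor: ReactorConfig
    profile: ProductionProfile
    artifacts: ArtifactSpec
    seed: int | None = None
    duration_d: float | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "duration_d": self.duration_d,
            "reactor": self.reactor.to_dict(),
            "profile": self.profile.to_dict(),
            "artifacts": self.artifacts.to_dict(),
        }


def _build(cls, table: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(table) - known
    for key in sorted(unknown):
        warnings.warn(f"unknown key {key!r} in [{section}] ignored", stacklevel=3)
    kwargs = {k: v for k, v in table.items() if k in known}
    # tuples survive TOML as lists of lists
    for k in ("spike_events", "step_events", "leak_events"):
        if k in kwargs:
            kwargs[k] = [tuple(ev) for ev in kwargs[k]]
    return cls(**kwargs)


def load_config(path) -> ConfigBundle:
    """Load and validate a TOML configuration file.

    Top-level keys ``seed`` and ``duration_d`` plus ``[reactor]``,
    ``[profile]`` and ``[artifacts]`` tables; every field of the three
    dataclasses is addressable.  Unknown keys warn; invariant violations
    raise :class:`ConfigError` naming the field and bound.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known_top = {"seed", "duration_d", "reactor", "profile", "artifacts"}
    for key in sorted(set(raw) - known_top):
        warnings.warn(f"unknown top-level key {key!r} in {path} ignored", stacklevel=2)
    try:
        reactor = _build(ReactorConfig, raw.get("reactor", {}), "reactor")
        profile = _build(ProductionProfile, raw.get("profile", {}), "profile")
        artifacts = _build(ArtifactSpec, raw.get("artifacts", {}), "artifacts")
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    return ConfigBundle(
        reactor=reactor,
        profile=profile,
        artifacts=artifacts,
        seed=raw.get("seed"),
        duration_d=raw.get("duration_d"),
    )
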