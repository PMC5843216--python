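"""Digital twin of one pressure-monitored anaerobic chemostat.

The reactor is a sealed vessel whose headspace pressure rises as biogas is
produced and falls when a hysteresis-controlled pump degasses it: pump-out
starts when the pressure reaches ``p_high_bar`` (1.2 bar by default) and
stops once it has fallen to ``p_low_bar`` (1.05 bar), producing the
characteristic sawtooth trace.

State variables, all in mL of gas at standard conditions (293.15 K,
1.013 bar):

* ``G`` — headspace gas inventory.  Ideal-gas law links it to pressure:
  ``P = G * P_N * T / (V_head * T_N)``.
* ``D`` — dissolved CO2/CH4 pool, relaxing first-order toward its
  pressure-dependent equilibrium ``D* = henry_capacity * P``.  After each
  degassing drop the pool outgasses back into the headspace, producing the
  small post-degassing re-equilibration bumps seen on real traces.

Production is an exogenous :class:`~manostat.config.ProductionProfile`; no
microbial kinetics are modelled.  Integration is explicit Euler with one
step per sensor sample (signals change on timescales of hours, so 20-s
steps are far inside the stable/accurate regime, and it keeps simulator
state aligned with the logged samples).  Gas bookkeeping is exact by
construction: every mL produced is added to ``G`` or ``D`` and every mL
pumped out is tallied, so the mass balance closes to floating-point
round-off for every configuration.

The sensor model quantizes the true pressure plus Gaussian noise to integer
multiples of the sensor resolution.  The degassing controller acts on the
true pressure; the sensor model only affects the logged trace, which keeps
ground-truth event timing deterministic for a given seed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .config import (
    P_STD_BAR,
    T_STD_K,
    VESSEL_MAX_BAR,
    ArtifactSpec,
    ProductionProfile,
    ReactorConfig,
)
from .containers import EventLog, GroundTruth, PressureTrace

__all__ = [
    "step_controller",
    "schedule_pulses",
    "simulate",
    "inject_artifacts",
]

IDLE = "idle"
DEGASSING = "degassing"


def step_controller(pressure_bar: float, mode: str, config: ReactorConfig) -> str:
    """Advance the hysteresis degassing controller by one observation.

    ``idle`` switches to ``degassing`` when the pressure reaches
    ``p_high_bar``; ``degassing`` switches back to ``idle`` once the
    pressure has fallen to ``p_low_bar``; otherwise the mode is unchanged.
    """
    if not math.isfinite(pressure_bar) or pressure_bar <= 0:
        raise ValueError(f"invalid sensor reading: {pressure_bar!r}")
    if mode not in (IDLE, DEGASSING):
        raise ValueError(f"unknown controller mode {mode!r}")
    if mode == IDLE and pressure_bar >= config.p_high_bar:
        return DEGASSING
    if mode == DEGASSING and pressure_bar <= config.p_low_bar:
        return IDLE
    return mode


def schedule_pulses(
    pulses_per_day: int,
    pulse_volume_mL: float,
    duration_d: float,
    event_type: str = "waste",
    reactor_id: str = "R1",
) -> EventLog:
    """Evenly spaced pump pulses over ``duration_d`` days.

    Total volume moved per day is ``pulses_per_day * pulse_volume_mL``
    (e.g. the default wasting schedule, 24 x 0.5 mL = 12 mL/d).
    """
    if pulses_per_day < 0 or duration_d < 0:
        raise ValueError("pulses_per_day and duration_d must be >= 0")
    if pulse_volume_mL < 0:
        raise ValueError(f"pulse_volume_mL={pulse_volume_mL} must be >= 0")
    log = EventLog()
    if pulses_per_day == 0 or duration_d == 0:
        return log
    interval_s = 86400.0 / pulses_per_day
    n = int(round(pulses_per_day * duration_d))
    for k in range(n):
        log.append((k + 1) * interval_s, reactor_id, event_type, pulse_volume_mL)
    return log


def _resolve_random_events(spec: ArtifactSpec, duration_d: float, seed) -> ArtifactSpec:
    """Materialise counts-per-day artifact requests into explicit events."""
    if spec.spikes_per_day == 0 and spec.steps_per_day == 0:
        return spec
    if seed is None:
        seed = spec.seed
    if seed is None:
        raise ValueError("random artifact placement requires a seed")
    rng = np.random.default_rng(seed)
    spikes = list(spec.spike_events)
    steps = list(spec.step_events)
    n_spikes = int(round(spec.spikes_per_day * duration_d))
    n_steps = int(round(spec.steps_per_day * duration_d))
    for t in np.sort(rng.uniform(0, duration_d, n_spikes)):
        sign = rng.choice([-1.0, 1.0])
        spikes.append(
            (float(t), sign * spec.spike_magnitude_mbar, spec.spike_duration_samples)
        )
    for t in np.sort(rng.uniform(0, duration_d, n_steps)):
        steps.append((float(t), spec.step_magnitude_mbar))
    return ArtifactSpec(
        spike_events=spikes,
        step_events=steps,
        leak_events=spec.leak_events,
    )


def inject_artifacts(
    trace: PressureTrace, spec: ArtifactSpec, seed: int | None = None
) -> PressureTrace:
    """Superimpose spikes, steps and leaks on a pressure trace.

    Spikes add their magnitude over the stated number of samples and then
    revert; steps shift the baseline permanently from their time onward;
    leaks subtract an accumulating deficit over their window (frozen at the
    window total afterwards).  Samples not reached by any event are
    bit-identical to the input.  Events outside the trace span are errors.
    """
    out = trace.copy()
    if spec.empty:
        return out
    t = out.time_s
    duration_d = t[-1] / 86400.0
    spec = _resolve_random_events(spec, duration_d, seed)
    n = len(t)

    def index_of(time_d: float) -> int:
        idx = int(np.searchsorted(t, time_d * 86400.0, side="left"))
        if not 0 <= idx < n:
            raise ValueError(f"artifact at t={time_d} d outside trace span")
        return idx

    for time_d, mag_mbar, dur in spec.spike_events:
        i = index_of(time_d)
        j = i + int(dur)
        if j > n:
            raise ValueError(f"spike at t={time_d} d extends past trace end")
        out.pressure_bar[i:j] += mag_mbar / 1000.0
    for time_d, mag_mbar in spec.step_events:
        i = index_of(time_d)
        out.pressure_bar[i:] += mag_mbar / 1000.0
    for start_d, end_d, rate_mbar_min in spec.leak_events:
        i, j = index_of(start_d), index_of(end_d)
        elapsed_min = np.minimum(t[i:] - t[i], t[j] - t[i]) / 60.0
        out.pressure_bar[i:] -= rate_mbar_min / 1000.0 * elapsed_min
    return out


def simulate(
    config: ReactorConfig,
    profile: ProductionProfile,
    duration_d: float,
    artifacts: ArtifactSpec | None = None,
    seed: int = 0,
) -> tuple[PressureTrace, EventLog, GroundTruth]:
    """Simulate one reactor and return sensor trace, event log, ground truth.

    The returned :class:`PressureTrace` is the quantized, noisy sensor
    reading at ``sampling_interval_s`` (artifacts applied); the
    :class:`EventLog` holds the true degas/feed/waste events; the
    :class:`GroundTruth` holds the noise-free state series.  Identical
    arguments and seed give bit-identical output.
    """
    if duration_d <= 0:
        raise ValueError(f"duration_d={duration_d} must be > 0")
    dt = config.sampling_interval_s
    n = int(round(duration_d * 86400.0 / dt)) + 1
    times = np.arange(n) * dt
    rng = np.random.default_rng(seed)

    # bar of headspace pressure per mL STP of gas inventory
    bar_per_mL = (P_STD_BAR * config.temperature_K) / (
        config.headspace_volume_mL * T_STD_K
    )
    G = config.p_init_bar / bar_per_mL
    D = config.henry_capacity_mL_per_bar * config.p_init_bar  # start at equilibrium
    produced = 0.0
    degassed = 0.0
    mode = IDLE

    p_true = np.empty(n)
    g_arr = np.empty(n)
    d_arr = np.empty(n)
    prod_arr = np.empty(n)
    degas_arr = np.empty(n)

    events = EventLog()
    pump_mL_per_step = config.degas_pump_rate_mL_min * dt / 60.0
    relax = config.reequil_rate_per_h * dt / 3600.0
    overpressure = False

    for i in range(n):
        p = G * bar_per_mL
        p_true[i] = p
        g_arr[i] = G
        d_arr[i] = D
        prod_arr[i] = produced
        degas_arr[i] = degassed
        if p > VESSEL_MAX_BAR:
            overpressure = True
        new_mode = step_controller(p, mode, config)
        if new_mode != mode:
            kind = "degas_start" if new_mode == DEGASSING else "degas_end"
            events.append(times[i], config.reactor_id, kind, p)
            mode = new_mode
        if i == n - 1:
            break
        # advance one sampling interval
        prod = profile.rate_at(times[i] / 86400.0) * dt / 86400.0
        flux = relax * (config.henry_capacity_mL_per_bar * p - D)
        G += prod - flux
        D += flux
        produced += prod
        if mode == DEGASSING:
            p_now = G * bar_per_mL
            # pump removes gas at reactor conditions; never past p_low within
            # a step (pump + release threshold act continuously inside it).
            # the target sits a hair below p_low so the release comparison is
            # not decided by round-off
            target = config.p_low_bar * (1.0 - 1e-12) / bar_per_mL
            out = pump_mL_per_step * p_now / P_STD_BAR * T_STD_K / config.temperature_K
            out = min(out, max(G - target, 0.0))
            G -= out
            degassed += out

    if mode == DEGASSING:  # close the trailing window for log validity
        events.append(times[-1], config.reactor_id, "degas_end", p_true[-1])

    if overpressure:
        warnings.warn(
            f"simulated pressure exceeded the {VESSEL_MAX_BAR} bar vessel "
            "rating (degassing pump too slow for the production rate)",
            stacklevel=2,
        )

    for kind, pulses, vol in (
        ("feed", config.feed_pulses_per_day, config.feed_pulse_volume_mL),
        ("waste", config.waste_pulses_per_day, config.waste_pulse_volume_mL),
    ):
        events.extend(
            schedule_pulses(pulses, vol, duration_d, kind, config.reactor_id)
        )
    events.sort()

    noise = rng.normal(0.0, config.sensor_noise_sd_bar, n)
    reading = (
        np.round((p_true + noise) / config.sensor_resolution_bar)
        * config.sensor_resolution_bar
    )
    trace = PressureTrace(times, reading, config.reactor_id)
    if artifacts is not None and not artifacts.empty:
        art_seed = artifacts.seed if artifacts.seed is not None else seed + 1
        trace = inject_artifacts(trace, artifacts, seed=art_seed)

    truth = GroundTruth(
        time_s=times,
        pressure_bar=p_true,
        produced_mL_STP=prod_arr,
        degassed_mL_STP=degas_arr,
        headspace_mL_STP=g_arr,
        dissolved_mL_STP=d_arr,
        overpressure=overpressure,
    )
    return trace, events, truth
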