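"""Raw pressure log → normalized cumulative biogas volume → production rate.

The conversion follows three signal-processing steps:

1. **Degassing removal** (:func:`detect_degassing` + :func:`stitch_cumulative`)
   — the sawtooth drops caused by automatic pump-out (≈1.2 → 1.05 bar) are
   detected and removed, yielding a monotone "cumulated absolute pressure"
   curve in which each drop is replaced by a running offset.
2. **Spike rejection** (:func:`filter_spikes`) — per-sample increments
   beyond the ±10 mbar spike allowance for one measurement are zeroed so
   that technical excursions (gas leaks, liquid sampling) do not contribute
   to the accumulated signal.  The stricter per-minute reading of the limit
   (±10 mbar·min⁻¹, i.e. ≈3.33 mbar per 20-s sample) is also available.
3. **STP normalisation** (:func:`to_volume`) — the cumulated pressure gain is
   converted to the biogas volume it represents at standard conditions
   (293.15 K, 1.013 bar) via the ideal-gas law and the headspace volume.

:func:`fit_rate` then estimates the production rate as the ordinary
least-squares slope of cumulative volume over time (days), reporting slope,
r², the slope's standard error and the point count.  :func:`run_pipeline`
composes all five stages.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .config import P_STD_BAR, T_STD_K, ReactorConfig
from .containers import (
    FLAG_DEGAS,
    FLAG_SPIKE,
    CumulativeVolumeTrace,
    DegassingEvent,
    EventLog,
    PressureTrace,
    ProductionRate,
)

__all__ = [
    "detect_degassing",
    "stitch_cumulative",
    "filter_spikes",
    "to_volume",
    "fit_rate",
    "run_pipeline",
]


def _nearest_index(time_s: np.ndarray, t: float, what: str) -> int:
    if t < time_s[0] or t > time_s[-1]:
        raise ValueError(f"{what} at t={t} s outside trace span")
    return int(np.argmin(np.abs(time_s - t)))


def detect_degassing(
    trace: PressureTrace,
    events: EventLog | None = None,
    *,
    p_high_bar: float = 1.2,
    p_low_bar: float = 1.05,
    drop_threshold_bar: float = 0.05,
    tol_bar: float = 0.02,
) -> list[DegassingEvent]:
    """Locate automatic degassing drops in a pressure trace.

    If an event log is given, its ``degas_start``/``degas_end`` pairs are
    authoritative and are mapped onto the nearest samples.  Otherwise the
    drops are found from the trace signature alone: a maximal run of
    consecutive negative steps counts as a degassing event when its total
    drop is at least ``drop_threshold_bar``, it starts from a pressure
    within ``tol_bar`` of (or above) ``p_high_bar`` and ends within
    ``tol_bar`` of (or below) ``p_low_bar``.
    """
    t, p = trace.time_s, trace.pressure_bar
    out: list[DegassingEvent] = []
    if events is not None:
        for start, end in events.degas_windows():
            i = _nearest_index(t, start, "degas_start")
            j = _nearest_index(t, end, "degas_end")
            if j <= i:
                j = min(i + 1, len(t) - 1)
            out.append(DegassingEvent(t[i], t[j], p[i], p[j]))
        return out

    steps = np.diff(p)
    k = 0
    while k < len(steps):
        if steps[k] >= 0:
            k += 1
            continue
        j = k
        while j + 1 < len(steps) and steps[j + 1] < 0:
            j += 1
        i_start, i_end = k, j + 1  # sample indices bracketing the run
        drop = p[i_start] - p[i_end]
        if (
            drop >= drop_threshold_bar
            and p[i_start] >= p_high_bar - tol_bar
            and p[i_end] <= p_low_bar + tol_bar
        ):
            out.append(DegassingEvent(t[i_start], t[i_end], p[i_start], p[i_end]))
        k = j + 1
    return out


def stitch_cumulative(
    trace: PressureTrace, events: list[DegassingEvent]
) -> PressureTrace:
    """Remove degassing drops, producing the cumulated absolute pressure.

    Every sample inside an event window is flagged ``degas`` and bridged by
    carrying the pre-event cumulated value forward (no signal is invented
    while the pump runs); after each event the running offset grows by the
    event's pressure drop, so the final cumulated pressure equals the final
    raw pressure plus the sum of all drops, exactly.
    """
    t = trace.time_s
    order = sorted(events, key=lambda e: e.start_time_s)
    for e1, e2 in zip(order, order[1:]):
        if e2.start_time_s < e1.end_time_s:
            raise ValueError(
                f"overlapping degassing events at t={e2.start_time_s} s"
            )
    out = trace.copy()
    inc = np.diff(out.pressure_bar)
    for ev in order:
        i = _nearest_index(t, ev.start_time_s, "event start")
        j = _nearest_index(t, ev.end_time_s, "event end")
        inc[i:j] = 0.0  # bridge: carry the value at the event start forward
        out.flags[i + 1 : j + 1] = FLAG_DEGAS
    out.pressure_bar = np.concatenate(
        ([out.pressure_bar[0]], out.pressure_bar[0] + np.cumsum(inc))
    )
    return out


def filter_spikes(
    cumulated: PressureTrace,
    rate_limit: float = 10.0,
    *,
    per_minute: bool = False,
) -> PressureTrace:
    """Zero increments exceeding the ±``rate_limit`` spike allowance.

    Applied to the cumulated (degassing-free) curve in one forward pass:
    any per-sample increment beyond the limit is set to zero — the sample
    is flagged ``spike`` and does not contribute to the accumulated signal.
    Idempotent: surviving increments are all below the limit.

    By default ``rate_limit`` is the allowance in mbar for one measurement
    (±10 mbar per sample), scaled proportionally across data gaps.  This
    reading leaves the quantized sensor staircase untouched: with a 1.5
    mbar resolution an occasional multi-quantum noise excursion stays below
    the limit and reverts by itself, whereas zeroing it would strand the
    reversion as a permanent offset and visibly bias low production rates.
    With ``per_minute=True`` the limit is instead a rate in mbar·min⁻¹, so
    a 20-s sample may move at most ≈3.33 mbar.
    """
    if rate_limit <= 0:
        raise ValueError(f"rate_limit={rate_limit} must be > 0")
    out = cumulated.copy()
    if len(out) < 2:
        return out
    inc = np.diff(out.pressure_bar)
    dt = np.diff(out.time_s)
    if per_minute:
        limit = rate_limit / 1000.0 * dt / 60.0
    else:
        limit = rate_limit / 1000.0 * dt / np.median(dt)
    bad = np.abs(inc) > limit
    inc[bad] = 0.0
    out.pressure_bar = np.concatenate(
        ([out.pressure_bar[0]], out.pressure_bar[0] + np.cumsum(inc))
    )
    spike_idx = np.flatnonzero(bad) + 1
    out.flags[spike_idx] = FLAG_SPIKE
    return out


def to_volume(
    cumulated: PressureTrace,
    headspace_volume_mL: float,
    reactor_T_K: float,
) -> CumulativeVolumeTrace:
    """Convert cumulated pressure gain into biogas volume at STP.

    ``V(t) = ΔP_cum(t) · V_head / 1.013 bar · 293.15 K / T_reactor`` in mL;
    time is re-expressed in days since the first sample.
    """
    if headspace_volume_mL <= 0 or reactor_T_K <= 0:
        raise ValueError("headspace volume and temperature must be > 0")
    dp = cumulated.pressure_bar - cumulated.pressure_bar[0]
    volume = dp * headspace_volume_mL / P_STD_BAR * T_STD_K / reactor_T_K
    flags = cumulated.flags.copy()
    return CumulativeVolumeTrace(
        time_d=(cumulated.time_s - cumulated.time_s[0]) / 86400.0,
        volume_mL_STP=volume,
        reactor_id=cumulated.reactor_id,
        flags=flags,
        n_spikes_removed=int(np.sum(flags == FLAG_SPIKE)),
        n_degas_events=0,
    )


def fit_rate(
    volume: CumulativeVolumeTrace,
    window_d: tuple[float, float] | None = None,
) -> ProductionRate:
    """OLS production rate from cumulative volume over time (days).

    Returns the slope (mL/d), r², the slope's standard error
    ``sqrt(Σê²/(n−2) / Σ(t−t̄)²)`` and the number of points used.
    """
    t, v = volume.time_d, volume.volume_mL_STP
    if window_d is not None:
        lo, hi = window_d
        mask = (t >= lo) & (t <= hi)
        t, v = t[mask], v[mask]
    if len(t) < 3:
        raise ValueError(f"need >= 3 points for a rate estimate, got {len(t)}")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance in regression window")
    res = sps.linregress(t, v)
    return ProductionRate(
        slope_mL_d=float(res.slope),
        r2=float(res.rvalue**2),
        se_slope_mL_d=float(res.stderr),
        n_points=len(t),
        intercept_mL=float(res.intercept),
    )


def run_pipeline(
    trace: PressureTrace,
    events: EventLog | None = None,
    config: ReactorConfig | None = None,
    *,
    headspace_volume_mL: float | None = None,
    temperature_K: float | None = None,
    rate_limit: float = 10.0,
    per_minute: bool = False,
    window_d: tuple[float, float] | None = None,
    drop_threshold_bar: float = 0.05,
    tol_bar: float = 0.02,
) -> tuple[CumulativeVolumeTrace, ProductionRate]:
    """Full conversion: detect → stitch → filter → normalise → regress.

    Geometry and thresholds come from ``config`` when given; headspace and
    temperature can also be passed explicitly.  All intermediate quality
    flags are retained on the returned volume trace.
    """
    if config is not None:
        headspace_volume_mL = headspace_volume_mL or config.headspace_volume_mL
        temperature_K = temperature_K or config.temperature_K
        p_high, p_low = config.p_high_bar, config.p_low_bar
    else:
        p_high, p_low = 1.2, 1.05
    if headspace_volume_mL is None or temperature_K is None:
        raise ValueError("need a ReactorConfig or explicit headspace and temperature")

    degas = detect_degassing(
        trace,
        events,
        p_high_bar=p_high,
        p_low_bar=p_low,
        drop_threshold_bar=drop_threshold_bar,
        tol_bar=tol_bar,
    )
    cumulated = stitch_cumulative(trace, degas)
    filtered = filter_spikes(cumulated, rate_limit, per_minute=per_minute)
    volume = to_volume(filtered, headspace_volume_mL, temperature_K)
    volume.n_degas_events = len(degas)
    rate = fit_rate(volume, window_d)
    return volume, rate
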