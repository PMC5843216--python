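"""Reactor digital twin: controller, schedulers, physics, artifacts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from manostat import (
    ArtifactSpec,
    ProductionProfile,
    ReactorConfig,
    inject_artifacts,
    schedule_pulses,
    simulate,
    step_controller,
)
from manostat.config import P_STD_BAR, T_STD_K


class TestController:
    @pytest.mark.parametrize(
        "pressure,mode,expected",
        [
            (1.19, "idle", "idle"),
            (1.20, "idle", "degassing"),  # trigger threshold inclusive
            (1.25, "idle", "degassing"),
            (1.10, "degassing", "degassing"),
            (1.05, "degassing", "idle"),  # release threshold inclusive
            (1.00, "degassing", "idle"),
            (1.10, "idle", "idle"),  # hysteresis: mid-band keeps mode
        ],
    )
    def test_hysteresis_band(self, pressure, mode, expected, default_config):
        assert step_controller(pressure, mode, default_config) == expected

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -1.0, 0.0])
    def test_invalid_reading_rejected(self, bad, default_config):
        with pytest.raises(ValueError):
            step_controller(bad, "idle", default_config)

    @given(
        p=st.floats(0.5, 1.4),
        mode=st.sampled_from(["idle", "degassing"]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_mode_changes_only_at_thresholds(self, p, mode):
        cfg = ReactorConfig(headspace_volume_mL=50.0)
        new = step_controller(p, mode, cfg)
        if new != mode:
            assert (mode == "idle" and p >= cfg.p_high_bar) or (
                mode == "degassing" and p <= cfg.p_low_bar
            )


class TestSchedulePulses:
    @pytest.mark.parametrize(
        "pulses_per_day,volume,duration,n_events,total",
        [
            (24, 0.5, 1.0, 24, 12.0),  # the wasting schedule: 12 mL/d
            (24, 0.0, 1.0, 24, 0.0),
            (3, 2.0, 2.0, 6, 12.0),
            (0, 1.0, 5.0, 0, 0.0),
        ],
    )
    def test_count_and_volume(self, pulses_per_day, volume, duration, n_events, total):
        log = schedule_pulses(pulses_per_day, volume, duration)
        assert len(log) == n_events
        assert log.total_volume("waste") == pytest.approx(total)

    def test_evenly_spaced(self):
        log = schedule_pulses(24, 0.5, 1.0)
        times = [e.time_s for e in log]
        assert np.allclose(np.diff(times), 3600.0)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            schedule_pulses(24, -0.5, 1.0)


class TestSimulate:
    def test_zero_production_stays_at_p_init(self, noisefree_config):
        trace, events, truth = simulate(
            noisefree_config, ProductionProfile(rate_mL_STP_d=0.0), 1.0, seed=0
        )
        assert np.allclose(trace.pressure_bar, noisefree_config.p_init_bar, atol=1e-8)
        assert len(events.of_type("degas_start")) == 0

    def test_degassing_frequency_matches_ideal_gas_arithmetic(self, noisefree_config):
        # each 0.15 bar cycle holds 50 * (0.15/1.013) * (293.15/310.15)
        # ≈ 7.0 mL STP, so 63.8 mL/d empties ≈ 9.1 cycles/day
        trace, events, truth = simulate(
            noisefree_config, ProductionProfile(rate_mL_STP_d=63.8), 5.0, seed=0
        )
        cycle_mL = (
            50.0 * (0.15 / P_STD_BAR) * (T_STD_K / noisefree_config.temperature_K)
        )
        expected_per_day = 63.8 / cycle_mL
        observed_per_day = len(events.of_type("degas_start")) / 5.0
        assert observed_per_day == pytest.approx(expected_per_day, abs=0.25)
        assert cycle_mL == pytest.approx(6.998, abs=0.01)

    @pytest.mark.parametrize("rate,henry", [(8.0, 0.0), (63.8, 0.0), (20.0, 40.0)])
    def test_mass_balance_closes(self, rate, henry):
        cfg = ReactorConfig(
            headspace_volume_mL=50.0,
            henry_capacity_mL_per_bar=henry,
        )
        _, _, truth = simulate(cfg, ProductionProfile(rate_mL_STP_d=rate), 3.0, seed=4)
        assert truth.mass_balance_error() < 1e-9

    def test_pressure_never_exceeds_trigger_plus_one_step(self, noisefree_config):
        cfg = noisefree_config
        rate = 63.8
        _, _, truth = simulate(cfg, ProductionProfile(rate_mL_STP_d=rate), 3.0, seed=0)
        step_bar = (
            rate / 86400 * cfg.sampling_interval_s
            * P_STD_BAR * cfg.temperature_K / (cfg.headspace_volume_mL * T_STD_K)
        )
        assert truth.pressure_bar.max() <= cfg.p_high_bar + step_bar + 1e-12

    def test_sensor_readings_are_quantized(self, five_day_run):
        trace, _, _ = five_day_run
        res = 0.0015
        remainder = np.abs(trace.pressure_bar / res - np.round(trace.pressure_bar / res))
        assert remainder.max() < 1e-9

    def test_same_seed_bit_identical(self, default_config):
        prof = ProductionProfile(rate_mL_STP_d=8.0)
        art = ArtifactSpec(spikes_per_day=2.0, seed=7)
        a = simulate(default_config, prof, 1.0, art, seed=3)
        b = simulate(default_config, prof, 1.0, art, seed=3)
        assert np.array_equal(a[0].pressure_bar, b[0].pressure_bar)
        assert a[1].to_frame().equals(b[1].to_frame())

    def test_doubling_headspace_halves_degassing_frequency(self):
        prof = ProductionProfile(rate_mL_STP_d=40.0)
        counts = []
        for v_head in (50.0, 100.0):
            cfg = ReactorConfig(
                headspace_volume_mL=v_head,
                sensor_noise_sd_bar=0.0,
                sensor_resolution_bar=1e-9,
                degas_pump_rate_mL_min=40.0,
            )
            _, events, _ = simulate(cfg, prof, 10.0, seed=0)
            counts.append(len(events.of_type("degas_start")))
        assert abs(counts[0] - 2 * counts[1]) <= 1

    def test_overpressure_flagged_not_silent(self):
        cfg = ReactorConfig(
            headspace_volume_mL=50.0,
            degas_pump_rate_mL_min=0.001,  # pump far too slow
            sensor_noise_sd_bar=0.0,
        )
        with pytest.warns(UserWarning, match="vessel rating"):
            _, _, truth = simulate(
                cfg, ProductionProfile(rate_mL_STP_d=300.0), 2.0, seed=0
            )
        assert truth.overpressure

    def test_event_log_is_valid(self, five_day_run):
        _, events, _ = five_day_run
        events.validate()  # nondecreasing, degas pairs matched

    def test_piecewise_profile_changes_rate(self, noisefree_config):
        prof = ProductionProfile(
            kind="piecewise_constant", rate_mL_STP_d=[5.0, 50.0], breakpoints_d=[1.0]
        )
        _, events, truth = simulate(noisefree_config, prof, 2.0, seed=0)
        produced = truth.produced_mL_STP
        n_half = (len(produced) - 1) // 2
        assert produced[n_half] == pytest.approx(5.0, rel=1e-6)
        assert produced[-1] == pytest.approx(55.0, rel=1e-6)

    def test_reequilibration_bumps_after_degassing(self):
        """With a dissolved pool, pressure rebounds faster right after a drop."""
        cfg = ReactorConfig(
            headspace_volume_mL=50.0,
            henry_capacity_mL_per_bar=40.0,
            reequil_rate_per_h=2.0,
            sensor_noise_sd_bar=0.0,
            sensor_resolution_bar=1e-9,
        )
        _, events, truth = simulate(
            cfg, ProductionProfile(rate_mL_STP_d=30.0), 5.0, seed=0
        )
        windows = events.degas_windows()
        assert windows
        end = windows[0][1]
        i = int(np.searchsorted(truth.time_s, end))
        # slope just after the drop exceeds the steady production slope
        post = np.diff(truth.pressure_bar[i + 1 : i + 10]).mean()
        steady = np.diff(truth.pressure_bar[i + 200 : i + 250]).mean()
        assert post > steady


class TestInjectArtifacts:
    def test_empty_spec_is_identity(self, five_day_run):
        trace, _, _ = five_day_run
        out = inject_artifacts(trace, ArtifactSpec())
        assert np.array_equal(out.pressure_bar, trace.pressure_bar)

    def test_single_spike_touches_one_sample(self, five_day_run):
        trace, _, _ = five_day_run
        out = inject_artifacts(trace, ArtifactSpec(spike_events=[(2.0, 15.0, 1)]))
        diff = out.pressure_bar - trace.pressure_bar
        idx = np.flatnonzero(diff)
        assert len(idx) == 1
        assert diff[idx[0]] == pytest.approx(0.015)

    def test_step_is_persistent(self, five_day_run):
        trace, _, _ = five_day_run
        out = inject_artifacts(trace, ArtifactSpec(step_events=[(2.0, -15.0)]))
        diff = out.pressure_bar - trace.pressure_bar
        i = np.flatnonzero(diff)[0]
        assert np.allclose(diff[i:], -0.015)
        assert np.all(diff[:i] == 0)

    def test_leak_accumulates_then_freezes(self, five_day_run):
        trace, _, _ = five_day_run
        out = inject_artifacts(
            trace, ArtifactSpec(leak_events=[(1.0, 1.0 + 1200 / 86400, 10.0)])
        )
        deficit = trace.pressure_bar - out.pressure_bar
        assert deficit.min() >= 0
        # 20-min window at 10 mbar/min -> 200 mbar total, frozen afterwards
        assert deficit[-1] == pytest.approx(0.200, rel=1e-6)
        assert np.all(np.diff(deficit) >= -1e-12)

    def test_same_seed_same_random_placement(self, five_day_run):
        trace, _, _ = five_day_run
        spec = ArtifactSpec(spikes_per_day=3.0, seed=5)
        a = inject_artifacts(trace, spec)
        b = inject_artifacts(trace, spec)
        assert np.array_equal(a.pressure_bar, b.pressure_bar)

    def test_event_outside_span_rejected(self, five_day_run):
        trace, _, _ = five_day_run
        with pytest.raises(ValueError, match="outside"):
            inject_artifacts(trace, ArtifactSpec(spike_events=[(99.0, 15.0, 1)]))
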