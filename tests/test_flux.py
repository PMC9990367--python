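import numpy as np
import pytest

from fretflux.cohort import _trace_from_series
from fretflux.flux import (
    AnalysisConfig,
    FluxModel,
    anchor_normalize,
    estimate_amplitude,
    estimate_basal,
    estimate_slope,
    invert_to_concentration,
)
from fretflux.kinetics import (
    KineticParams,
    baseline_steady_state,
    simulate_concentrations,
)
from fretflux.pipeline import RatioTrace
from fretflux.protocols import get_protocol
from fretflux.sensors import LACONIC, SensorModel


def make_trace(r, frame_rate=1.0, window=1, meta=None):
    r = np.asarray(r, dtype=float)
    return RatioTrace(
        t=np.arange(len(r)) / frame_rate,
        r=r,
        frame_rate=frame_rate,
        smoothing_window=window,
        meta=meta or {},
    )


def sensor_trace(params, protocol, *, frame_rate=2.0, sensor=LACONIC):
    """Noise-free trace of a simulated protocol through a sensor."""
    series = simulate_concentrations(params, protocol, dt=0.5)
    return _trace_from_series(
        series, None, 1.0, sensor, frame_rate, 1, 0.0,
        np.random.default_rng(0), meta={},
    )


class TestAnchorNormalize:
    def test_anchor_window_mean_is_zero(self, params):
        prot = get_protocol("trans_acceleration")
        trace = sensor_trace(params, prot)
        nt = anchor_normalize(trace, prot, "end_zero")
        t0, t1 = nt.anchor_window
        sel = (nt.t >= t0) & (nt.t <= t1)
        assert nt.dr[sel].mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_trace_normalizes_to_zero_both_kinds(self, mct_block):
        trace = make_trace(np.full(500, 1.2))
        for kind in ("end_zero", "baseline"):
            nt = anchor_normalize(trace, mct_block, kind)
            assert np.allclose(nt.dr, 0.0)

    def test_idempotent_with_same_window(self, mct_block):
        rng = np.random.default_rng(0)
        trace = make_trace(1.1 + 0.01 * rng.random(500))
        nt1 = anchor_normalize(trace, mct_block, "baseline")
        renorm = make_trace(nt1.dr + 1.0)  # re-wrap (ratios must be > 0)
        nt2 = anchor_normalize(renorm, mct_block, "baseline")
        assert np.allclose(nt2.dr, nt1.dr, atol=1e-12)

    def test_trans_acceleration_initial_dr_matches_simulator_truth(self, params):
        """After end-anchoring, the t=0 level equals the ratio gap
        between the basal and floor lactate concentrations."""
        prot = get_protocol("trans_acceleration")
        series = simulate_concentrations(params, prot, dt=0.5)
        trace = sensor_trace(params, prot)
        nt = anchor_normalize(trace, prot, "end_zero")
        basal_lac, _ = baseline_steady_state(params)
        floor_lac = series.lac_in[-1]
        expected = LACONIC.forward(basal_lac) - LACONIC.forward(floor_lac)
        assert nt.dr[0] == pytest.approx(expected, abs=1e-4)

    def test_unknown_kind_rejected(self, mct_block):
        with pytest.raises(ValueError):
            anchor_normalize(make_trace(np.ones(500)), mct_block, "divisive")


class TestEstimateBasal:
    def test_constructed_flat_baseline(self):
        prot = get_protocol("trans_acceleration")
        r = np.full(1201, 1.0)
        r[:241] = 1.20  # 0.20 above the terminal floor until the onset at 120 s
        trace = make_trace(r, frame_rate=2.0)
        nt = anchor_normalize(trace, prot, "end_zero")
        est = estimate_basal(nt)
        assert est.value == pytest.approx(0.20, abs=1e-12)
        assert est.flags == []

    def test_requires_end_zero_anchoring(self, mct_block):
        trace = make_trace(np.ones(900))
        nt = anchor_normalize(trace, mct_block, "baseline")
        with pytest.raises(ValueError, match="end_zero"):
            estimate_basal(nt)

    def test_drifting_baseline_is_flagged(self):
        prot = get_protocol("trans_acceleration")
        t = np.arange(1201) / 2.0
        r = np.full_like(t, 1.0)
        drift = 0.05 / 60.0  # ratio/s == 0.05 per min, above the 0.01 default
        base = (t >= 0) & (t <= 120)
        r[base] += 0.2 + drift * (t[base] - 60.0)
        trace = make_trace(r, frame_rate=2.0)
        nt = anchor_normalize(trace, prot, "end_zero")
        est = estimate_basal(nt)
        assert "unstable_baseline" in est.flags


class TestEstimateAmplitude:
    def test_constructed_step_plateau(self, mct_block):
        t = np.arange(841) / 2.0
        r = np.where(t <= mct_block.first_intervention().onset, 1.0, 1.5)
        trace = make_trace(r, frame_rate=2.0)
        nt = anchor_normalize(trace, mct_block, "baseline")
        est = estimate_amplitude(nt, mct_block)
        assert est.value == pytest.approx(0.5, abs=1e-12)

    def test_simulator_truth_in_linear_range(self):
        """In the sensor's quasi-linear range the amplitude equals gain
        times the accumulated lactate, within 5%."""
        sensor = SensorModel(analyte="lactate", kd=50.0, hill=1.0, r_min=1.0, r_max=2.0)
        prot = get_protocol("mct_block")
        p = KineticParams()
        series = simulate_concentrations(p, prot, dt=0.5)
        trace = sensor_trace(p, prot, sensor=sensor)
        nt = anchor_normalize(trace, prot, "baseline")
        est = estimate_amplitude(nt, prot, sensor=sensor)
        basal, _ = baseline_steady_state(p)
        cfg = AnalysisConfig()
        plateau_sel = series.t >= prot.duration - cfg.plateau_window
        true_gain = sensor.gain(basal)
        expected = true_gain * (series.lac_in[plateau_sel].mean() - basal)
        assert est.value == pytest.approx(expected, rel=0.05)

    def test_saturation_flagged(self, mct_block):
        t = np.arange(841) / 2.0
        r = np.where(t < 120.0, 1.02, 1.29)  # plateau at 97% of the range
        trace = make_trace(r, frame_rate=2.0)
        nt = anchor_normalize(trace, mct_block, "baseline")
        est = estimate_amplitude(nt, mct_block, sensor=LACONIC)
        assert "saturation" in est.flags


class TestEstimateSlope:
    def test_exact_line_recovered(self, mct_block):
        t = np.arange(841) / 2.0
        r = 1.0 + 0.01 * t  # 0.01 ratio/s everywhere
        trace = make_trace(r, frame_rate=2.0)
        nt = anchor_normalize(trace, mct_block, "baseline")
        est = estimate_slope(nt, mct_block)
        assert est.value == pytest.approx(0.6, rel=1e-9)  # 0.01/s -> 0.6/min
        assert est.r2 == pytest.approx(1.0)

    def test_exponential_initial_slope_within_5pct(self):
        """dr = A(1 - e^{-t/tau}) sampled over a window of tau/10 has an
        OLS slope within 5% of the initial rate A/tau."""
        tau, A = 100.0, 0.5
        prot = get_protocol("mct_block", onset=60.0, duration=300.0)
        t = np.arange(601) / 2.0
        onset = 60.0
        dr = np.where(t < onset, 0.0, A * (1.0 - np.exp(-(t - onset) / tau)))
        trace = make_trace(dr + 1.0, frame_rate=2.0)
        cfg = AnalysisConfig(slope_delay=0.0, slope_duration=10.0)
        nt = anchor_normalize(trace, prot, "baseline", cfg)
        est = estimate_slope(nt, prot, cfg)
        assert est.value == pytest.approx(A / tau * 60.0, rel=0.05)

    def test_too_few_frames_rejected(self, mct_block):
        trace = make_trace(np.ones(841) + np.arange(841) * 1e-4, frame_rate=2.0)
        nt = anchor_normalize(trace, mct_block, "baseline")
        cfg = AnalysisConfig(slope_duration=1.0)
        with pytest.raises(ValueError, match="5 frames"):
            estimate_slope(nt, mct_block, cfg)

    def test_window_beyond_trace_rejected(self, mct_block):
        trace = make_trace(np.ones(300), frame_rate=2.0)  # ends at 150 s
        nt = anchor_normalize(
            trace, mct_block, "baseline", AnalysisConfig(baseline_window=60.0)
        )
        with pytest.raises(ValueError, match="exceeds"):
            estimate_slope(nt, mct_block)


class TestInvertToConcentration:
    def test_midpoint_ratio_maps_to_kd(self, mct_block):
        prot = get_protocol("trans_acceleration")
        t = np.arange(1201) / 2.0
        mid = (LACONIC.r_min + LACONIC.r_max) / 2
        r = np.where(t <= 120.0, mid, LACONIC.r_min)
        nt = anchor_normalize(make_trace(r, frame_rate=2.0), prot, "end_zero")
        est = estimate_basal(nt)
        inv = invert_to_concentration(est, nt.anchor_value, LACONIC)
        assert inv.value == pytest.approx(LACONIC.kd, rel=1e-9)
        assert inv.units == "mM"

    def test_noiseless_simulator_round_trip_within_2pct(self, params):
        prot = get_protocol("trans_acceleration")
        trace = sensor_trace(params, prot)
        res = FluxModel(trace, prot, sensor=LACONIC).fit()
        basal_mM = res.in_mM()["basal"].value
        true_basal, _ = baseline_steady_state(params)
        # the anchor floor is near but not exactly zero lactate
        floor = simulate_concentrations(params, prot, dt=0.5).lac_in[-1]
        assert basal_mM == pytest.approx(true_basal - floor, rel=0.02)

    def test_ratio_above_sensor_range_rejected(self, mct_block):
        t = np.arange(841) / 2.0
        r = np.where(t < 120.0, 1.0, 1.5)  # plateau beyond r_max = 1.3
        nt = anchor_normalize(make_trace(r, frame_rate=2.0), mct_block, "baseline")
        est = estimate_amplitude(nt, mct_block)
        with pytest.raises(ValueError, match="out of sensor range"):
            invert_to_concentration(est, nt.anchor_value, LACONIC)


class TestLinearityAndModel:
    def test_scaling_dr_scales_all_readouts(self, params, mct_block):
        trace = sensor_trace(params, mct_block)
        nt = anchor_normalize(trace, mct_block, "baseline")
        amp1 = estimate_amplitude(nt, mct_block).value
        slope1 = estimate_slope(nt, mct_block).value
        scaled = make_trace(3.0 * nt.dr + 1.0, frame_rate=trace.frame_rate)
        nts = anchor_normalize(scaled, mct_block, "baseline")
        assert estimate_amplitude(nts, mct_block).value == pytest.approx(3.0 * amp1, rel=1e-9)
        assert estimate_slope(nts, mct_block).value == pytest.approx(3.0 * slope1, rel=1e-9)

    def test_model_readouts_follow_protocol(self, params):
        prot_ta = get_protocol("trans_acceleration")
        res = FluxModel(sensor_trace(params, prot_ta), prot_ta, sensor=LACONIC).fit()
        assert res.basal is not None
        assert res.slope is None and res.amplitude is None

        prot_mb = get_protocol("mct_block")
        res2 = FluxModel(sensor_trace(params, prot_mb), prot_mb, sensor=LACONIC).fit()
        assert res2.basal is None
        assert res2.slope is not None and res2.amplitude is not None
        assert "slope" in res2.summary() and "mct_block" in res2.summary()

    def test_consumption_rate_is_magnitude_of_negative_slope(self, params):
        from fretflux.sensors import FLIIP

        prot = get_protocol("glut_block_then_aglycemia")
        res = FluxModel(sensor_trace(params, prot, sensor=FLIIP), prot, sensor=FLIIP).fit()
        assert res.slope < 0
        assert res.consumption_rate == pytest.approx(-res.slope)
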