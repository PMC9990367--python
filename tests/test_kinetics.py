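import numpy as np
import pytest

from fretflux.kinetics import (
    KineticParams,
    baseline_steady_state,
    simulate_concentrations,
    simulate_concentrations_batch,
)
from fretflux.protocols import get_protocol


class TestConservationAndValidation:
    def test_zero_fluxes_conserve_pools_exactly(self, mct_block):
        p = KineticParams(j_hk_vmax=0.0, glut_vmax=0.0, mct_vmax=0.0)
        s = simulate_concentrations(p, mct_block, dt=1.0, initial=(1.0, 2.0))
        assert np.all(s.lac_in == 1.0)
        assert np.all(s.glc_in == 2.0)

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(mct_vmax=-0.1)
        with pytest.raises(ValueError):
            KineticParams(mct4_frac=1.5)
        with pytest.raises(ValueError):
            KineticParams(lac_prod_frac=2.5)

    def test_bad_dt_rejected(self, params, mct_block):
        with pytest.raises(ValueError):
            simulate_concentrations(params, mct_block, dt=0.0)
        with pytest.raises(ValueError):
            simulate_concentrations(params, mct_block, dt=mct_block.duration + 1)

    def test_baseline_is_flat_at_steady_state(self, params, mct_block):
        s = simulate_concentrations(params, mct_block, dt=1.0)
        onset = int(mct_block.first_intervention().onset)
        assert np.ptp(s.lac_in[:onset]) < 1e-6
        assert np.ptp(s.glc_in[:onset]) < 1e-6


class TestLinearRegime:
    def test_linearized_steady_state_matches_closed_form(self):
        """Constant production p with linearized efflux k*L settles at p/k.

        Far below Km the carrier is linear: J = (vmax/km) * L, so the
        ODE dL/dt = p - k L has the closed form p/k; the integrator must
        land within 1% after 10/k seconds.
        """
        # production: saturated hexokinase (G >> k_hk), lactate well below mct_km
        p = KineticParams(
            j_hk_vmax=1e-4, k_hk_km=1e-4, glut_vmax=0.05, glut_km=5.0,
            mct_vmax=10.0, mct_km=1000.0, lac_prod_frac=1.0,
        )
        k = p.mct_vmax / p.mct_km  # 0.01 / s in the linear limit
        prod = p.lac_prod_frac * p.j_hk_vmax
        protocol = get_protocol("mct_block", onset=10.0 / k, duration=10.0 / k + 60.0)
        s = simulate_concentrations(p, protocol, dt=1.0, initial=(0.0, 6.0))
        i_end = int(10.0 / k)
        assert s.lac_in[i_end] == pytest.approx(prod / k, rel=0.01)

    def test_full_linear_solution_at_all_grid_points(self):
        """With L << Km the trajectory matches L(t) = (p/k)(1 - e^{-kt})."""
        p = KineticParams(
            j_hk_vmax=1e-4, k_hk_km=1e-4, glut_vmax=0.05,
            mct_vmax=10.0, mct_km=1000.0,
        )
        k = p.mct_vmax / p.mct_km
        prod = p.j_hk_vmax
        protocol = get_protocol("aglycemia_only", onset=400.0, duration=401.0)
        s = simulate_concentrations(p, protocol, dt=1.0, initial=(0.0, 6.0))
        t = s.t[s.t <= 400.0]
        expected = (prod / k) * (1.0 - np.exp(-k * t))
        assert np.allclose(s.lac_in[: len(t)], expected, rtol=0.01, atol=1e-6)


class TestProtocolBehaviours:
    def test_full_mct_block_gives_production_ramp(self, params, mct_block):
        """With no blocker-insensitive transport, lactate ramps at the
        net production rate after the block."""
        s = simulate_concentrations(params, mct_block, dt=1.0)
        onset = int(mct_block.first_intervention().onset)
        _, g0 = baseline_steady_state(params)
        prod = params.lac_prod_frac * params.j_hk_vmax * g0 / (params.k_hk_km + g0)
        # glucose (hence production) is nearly constant over the first 60 s
        slope = np.polyfit(s.t[onset + 1 : onset + 61], s.lac_in[onset + 1 : onset + 61], 1)[0]
        assert slope == pytest.approx(prod, rel=0.01)

    def test_oxamate_floor_matches_aglycemia_floor(self, params):
        """Trans-accelerated depletion and glucose starvation drive
        lactate to nearly the same floor (both near zero)."""
        ox = simulate_concentrations(params, get_protocol("trans_acceleration"), dt=1.0)
        ag = simulate_concentrations(params, get_protocol("aglycemia_only"), dt=1.0)
        basal, _ = baseline_steady_state(params)
        assert abs(ox.lac_in[-1] - ag.lac_in[-1]) < 0.05 * basal

    def test_mct4_escape_reduces_ramp_slope_monotonically(self, mct_block):
        slopes = []
        for frac in (0.0, 0.2, 0.4):
            p = KineticParams(mct4_frac=frac)
            s = simulate_concentrations(p, mct_block, dt=1.0)
            sel = (s.t >= 130) & (s.t <= 190)
            slopes.append(np.polyfit(s.t[sel], s.lac_in[sel], 1)[0])
        assert slopes[0] > slopes[1] > slopes[2]

    def test_basal_lactate_monotone_in_production_fraction(self):
        basals = [
            baseline_steady_state(KineticParams(lac_prod_frac=f))[0]
            for f in (0.5, 1.0, 1.5)
        ]
        assert basals[0] < basals[1] < basals[2]

    def test_concentrations_never_negative(self, params):
        for name in ("trans_acceleration", "mct_block", "glut_block_then_aglycemia",
                     "aglycemia_only"):
            s = simulate_concentrations(params, get_protocol(name), dt=1.0)
            assert np.all(s.lac_in >= 0)
            assert np.all(s.glc_in >= 0)


class TestBatchIntegrator:
    def test_batch_agrees_with_adaptive_integrator(self, mct_block):
        ps = [
            KineticParams(),
            KineticParams(lac_prod_frac=1.5, mct_vmax=0.075),
            KineticParams(mct4_frac=0.3),
        ]
        t, lac, glc = simulate_concentrations_batch(ps, mct_block, dt=0.5)
        for i, p in enumerate(ps):
            s = simulate_concentrations(p, mct_block, dt=0.5)
            assert np.allclose(lac[i], s.lac_in, atol=1e-5)
            assert np.allclose(glc[i], s.glc_in, atol=1e-5)

    def test_batch_rejects_empty_and_bad_dt(self, mct_block):
        with pytest.raises(ValueError):
            simulate_concentrations_batch([], mct_block, dt=1.0)
        with pytest.raises(ValueError):
            simulate_concentrations_batch([KineticParams()], mct_block, dt=-1.0)


def test_no_steady_state_when_production_exceeds_export():
    p = KineticParams(lac_prod_frac=2.0, mct_vmax=0.005)
    with pytest.raises(ValueError, match="export capacity"):
        baseline_steady_state(p)
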