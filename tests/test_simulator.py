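"""Unit tests for the reduced ionic-model simulator: the stochastic Euler
update, drug-block schemes, cycle-length detection, membrane resistance,
and the calibrated morphology contract."""

import numpy as np
import pytest

from aptrans import simulator as sim
from aptrans.preprocess import morphology_features
from aptrans.simulator import (
    DrugSpec,
    NoiseSpec,
    PacingProtocol,
    SimulationError,
    apply_simple_block,
    detect_cycle_length,
    detect_upstrokes,
    euler_noise_step,
    membrane_resistance_series,
    simulate_ap,
    simulate_trace,
    state_dependent_gkr_factor,
)


# ---------------------------------------------------------------------------
# Eq.-style stochastic Euler update
# ---------------------------------------------------------------------------

class TestEulerNoiseStep:
    def test_zero_drift_zero_noise_leaves_voltage_unchanged(self):
        spec = NoiseSpec(xi=0.0, dt=1.0)
        assert euler_noise_step(-80.0, 0.0, spec, n=1.7) == -80.0

    @pytest.mark.parametrize("dt,expected_std", [(1.0, 0.3), (0.25, 0.15)])
    def test_additive_term_std_matches_xi_sqrt_dt(self, dt, expected_std):
        # Monte Carlo over 1e6 seeded draws; closed form is xi * sqrt(dt)
        rng = np.random.default_rng(42)
        n = rng.standard_normal(1_000_000)
        spec = NoiseSpec(xi=0.3, dt=dt)
        increments = euler_noise_step(0.0, 0.0, spec, n)
        s = increments.std()
        assert abs(s - expected_std) / expected_std < 0.01
        # mean is zero within 3 sigma / sqrt(N)
        assert abs(increments.mean()) < 3 * expected_std / 1000.0

    def test_deterministic_drift_term(self):
        spec = NoiseSpec(xi=0.0, dt=0.5)
        # V - I*dt/Cm with I=2, dt=0.5, Cm=2 -> V - 0.5
        assert euler_noise_step(-10.0, 2.0, spec, n=0.0, Cm=2.0) == -10.5

    def test_non_finite_inputs_rejected_with_name(self):
        spec = NoiseSpec(xi=0.3, dt=1.0)
        with pytest.raises(SimulationError, match="V_t"):
            euler_noise_step(float("nan"), 0.0, spec, 0.0)
        with pytest.raises(SimulationError, match="I_total"):
            euler_noise_step(-80.0, float("inf"), spec, 0.0)


# ---------------------------------------------------------------------------
# drug schemes
# ---------------------------------------------------------------------------

class TestSimpleBlock:
    def test_zero_fraction_is_identity(self):
        p = sim.immature_params()
        assert apply_simple_block(p, 0.0) == p

    @pytest.mark.parametrize("fraction,scale", [(0.01, 0.99), (0.5, 0.50)])
    def test_gkr_scaling_range(self, fraction, scale):
        p = sim.adult_params()
        blocked = apply_simple_block(p, fraction)
        assert blocked.G_Kr == pytest.approx(p.G_Kr * scale)
        # everything else untouched
        assert {k: v for k, v in vars(blocked).items() if k != "G_Kr"} == \
               {k: v for k, v in vars(p).items() if k != "G_Kr"}

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_simple_block(sim.adult_params(), 1.2)
        with pytest.raises(ValueError):
            apply_simple_block(sim.adult_params(), -0.1)


class TestStateDependentBlock:
    def test_no_drug_keeps_multiplier_one(self):
        drug = DrugSpec(mode="state_dependent", concentration=0.0,
                        k_on=1e-3, k_off=1e-3)
        b = 0.0
        for _ in range(100):
            mult, b = state_dependent_gkr_factor(0.8, b, drug, dt=1.0)
        assert b == 0.0 and mult == 1.0

    def test_irreversible_binding_saturates(self):
        drug = DrugSpec(mode="state_dependent", concentration=1.0,
                        k_on=1e-2, k_off=0.0)
        b = 0.0
        for _ in range(5000):
            mult, b = state_dependent_gkr_factor(1.0, b, drug, dt=1.0)
        assert b == pytest.approx(1.0, abs=1e-6)
        assert mult == pytest.approx(0.0, abs=1e-6)

    def test_steady_state_matches_closed_form(self):
        # k_on*[D] = 0.01/ms, k_off = 0.005/ms, p_open = 1:
        # b_ss = 0.01 / 0.015 = 2/3, multiplier 1/3
        drug = DrugSpec(mode="state_dependent", concentration=2.0,
                        k_on=5e-3, k_off=5e-3)
        b = 0.0
        for _ in range(20000):
            mult, b = state_dependent_gkr_factor(1.0, b, drug, dt=0.1)
        assert b == pytest.approx(2.0 / 3.0, rel=1e-2)
        assert mult == pytest.approx(1.0 / 3.0, rel=1e-2)

    def test_invalid_inputs_rejected(self):
        drug = DrugSpec(mode="state_dependent", concentration=1.0,
                        k_on=1e-3, k_off=1e-3)
        with pytest.raises(ValueError):
            state_dependent_gkr_factor(1.5, 0.0, drug, 1.0)
        with pytest.raises(ValueError):
            state_dependent_gkr_factor(0.5, -0.1, drug, 1.0)
        with pytest.raises(ValueError):
            state_dependent_gkr_factor(0.5, 0.0, DrugSpec(), 1.0)


# ---------------------------------------------------------------------------
# cycle-length detection
# ---------------------------------------------------------------------------

def _pulse_train(upstroke_times, n=2200):
    """Synthetic trace with sharp upstrokes at given times (ms)."""
    v = np.full(n, -80.0)
    for t in upstroke_times:
        v[t:t + 200] = 20.0
    return v


class TestDetectCycleLength:
    def test_matched_cycle_length_worked_value(self):
        tr = sim.APTrace(voltage=_pulse_train([10, 992]))
        assert detect_cycle_length(tr) == pytest.approx(982.0)

    def test_periodic_train(self):
        tr = sim.APTrace(voltage=_pulse_train([100, 1100, 2100], n=2400))
        assert detect_cycle_length(tr) == pytest.approx(1000.0)

    def test_single_beat_is_an_error(self):
        tr = sim.APTrace(voltage=_pulse_train([100]))
        with pytest.raises(SimulationError, match="upstroke"):
            detect_cycle_length(tr)

    def test_refractory_suppresses_noise_recrossings(self):
        v = _pulse_train([100, 1100], n=2400)
        v[105] += 30.0  # extra fast deflection inside the AP
        ups = detect_upstrokes(v)
        assert len(ups) == 2


# ---------------------------------------------------------------------------
# membrane resistance
# ---------------------------------------------------------------------------

class TestMembraneResistance:
    @pytest.mark.parametrize("g,expected", [(0.1, 10.0), (1.0, 1.0)])
    def test_ohmic_membrane_equals_one_over_g(self, g, expected):
        t = np.linspace(0, 100, 101)
        v = -80 + 60 * np.sin(t / 18.0)
        i = g * (v - (-85.0))
        r, capped = membrane_resistance_series(v, i)
        assert not capped.any()
        assert np.allclose(r, expected, rtol=1e-9)

    def test_constant_current_plateau_is_capped_and_flagged(self):
        v = np.linspace(0, 10, 50)
        i = np.full(50, 3.0)
        r, capped = membrane_resistance_series(v, i, cap=1e4)
        assert capped.all()
        assert np.all(np.abs(r) == 1e4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            membrane_resistance_series(np.zeros(5), np.zeros(6))


# ---------------------------------------------------------------------------
# whole-cell simulation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def short_protocol():
    return PacingProtocol(stim_amplitude=0.0, cycle_length_ms=982.0,
                          conditioning_beats=8, noisy_beats=4)


@pytest.fixture(scope="module")
def imm_baseline(short_protocol):
    return simulate_trace(sim.immature_params(), short_protocol,
                          record_current=True)


class TestSimulateAP:
    def test_deterministic_given_seed(self, short_protocol):
        a = simulate_trace(sim.immature_params(), short_protocol,
                           noise=NoiseSpec(xi=0.3), seed=5)
        b = simulate_trace(sim.immature_params(), short_protocol,
                           noise=NoiseSpec(xi=0.3), seed=5)
        assert np.array_equal(a.voltage, b.voltage)

    def test_noise_free_run_is_deterministic(self, short_protocol):
        a = simulate_trace(sim.immature_params(), short_protocol, seed=1)
        b = simulate_trace(sim.immature_params(), short_protocol, seed=2)
        assert np.array_equal(a.voltage, b.voltage)

    def test_window_shape_and_validity(self, short_protocol):
        tr = simulate_ap(sim.immature_params(), short_protocol,
                         noise=NoiseSpec(xi=0.3), seed=3)
        assert len(tr) == sim.NETWORK_WINDOW
        assert tr.is_valid_ap()
        assert np.isfinite(tr.cycle_length_ms)

    def test_quiescent_cell_fails_to_beat(self, short_protocol):
        p = sim.immature_params()
        p.G_f = 0.0
        p.G_bg = 0.0
        with pytest.raises(SimulationError, match="spontaneous"):
            simulate_ap(p, short_protocol)

    def test_voltage_blowup_names_the_beat(self):
        p = sim.adult_params()
        prot = PacingProtocol(stim_amplitude=5e4, cycle_length_ms=500.0,
                              conditioning_beats=0, noisy_beats=1)
        with pytest.raises(SimulationError, match="blow-up"):
            simulate_trace(p, prot)

    def test_internal_step_contract(self, short_protocol):
        with pytest.raises(ValueError):
            simulate_trace(sim.immature_params(), short_protocol,
                           dt_internal=0.02)


class TestMorphologyContract:
    """Calibration contract of the packaged default parameter sets."""

    def test_immature_beats_spontaneously_near_982ms(self, imm_baseline):
        cl = detect_cycle_length(imm_baseline)
        assert abs(cl - 982.0) / 982.0 < 0.10

    def test_immature_mdp_in_range(self, imm_baseline):
        ups = detect_upstrokes(imm_baseline.voltage)
        mdp = imm_baseline.voltage[ups[-2]:ups[-1]].min()
        assert -80.0 <= mdp <= -70.0

    def test_adult_quiescent_and_resting_potential(self):
        prot = PacingProtocol(stim_amplitude=0.0, cycle_length_ms=1000.0,
                              conditioning_beats=2, noisy_beats=2)
        tr = simulate_trace(sim.adult_params(), prot)
        assert tr.voltage.max() - tr.voltage.min() < 1.0  # no spontaneous APs
        assert -92.0 <= tr.voltage.min() <= -84.0

    def test_adult_paces_one_to_one(self):
        prot = PacingProtocol(cycle_length_ms=982.0, conditioning_beats=8,
                              noisy_beats=4)
        tr = simulate_trace(sim.adult_params(), prot)
        assert len(detect_upstrokes(tr.voltage)) == 4

    def test_phenotype_ordering_vmax_and_apd(self, imm_baseline):
        cl = detect_cycle_length(imm_baseline)
        prot = PacingProtocol(cycle_length_ms=cl, conditioning_beats=8,
                              noisy_beats=4)
        adult = simulate_ap(sim.adult_params(), prot)
        imm_win = simulate_ap(sim.immature_params(),
                              PacingProtocol(stim_amplitude=0.0,
                                             cycle_length_ms=982.0,
                                             conditioning_beats=8,
                                             noisy_beats=4))
        f_ad = morphology_features(adult.voltage)
        f_im = morphology_features(imm_win.voltage)
        assert f_ad.vmax_mv_per_ms > f_im.vmax_mv_per_ms
        assert f_ad.apd90_ms < f_im.apd90_ms

    def test_adult_apd_nondecreasing_in_block(self):
        prot = PacingProtocol(cycle_length_ms=982.0, conditioning_beats=8,
                              noisy_beats=2)
        apds = []
        for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            drug = (DrugSpec() if frac == 0 else
                    DrugSpec(mode="simple_block", block_fraction=frac))
            tr = simulate_ap(sim.adult_params(), prot, drug=drug)
            apds.append(morphology_features(tr.voltage).apd90_ms)
        assert all(b >= a for a, b in zip(apds, apds[1:]))
        assert apds[-1] > apds[0]  # 50 % block strictly prolongs

    def test_high_resistance_phase_in_late_plateau(self, imm_baseline):
        from aptrans.ablation import locate_high_resistance_window
        ups = detect_upstrokes(imm_baseline.voltage)
        u = ups[-2]
        v = imm_baseline.voltage[u - 5:u - 5 + 701]
        i = imm_baseline.current[u - 5:u - 5 + 701]
        win = locate_high_resistance_window(v, i)
        apd = morphology_features(v).apd90_ms
        # the high-resistance phase sits in the plateau, before full
        # repolarization
        assert win[0] < apd + 100
        assert win[1] > 100
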