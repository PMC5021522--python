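"""Synthetic-data generator: statistical structure and contracts."""

import numpy as np
import pytest
from scipy import stats

from mechanobfp.kinetics import predict_unfold_probability
from mechanobfp.params import MSD_UNFOLD_RATE_25PN, lifetime_params
from mechanobfp.simulate import (
    CalciumCoupling,
    SimParams,
    simulate_cycle,
    simulate_outcomes,
    simulate_session,
)


class TestParams:
    def test_ramp_rate_is_spring_times_speed(self):
        p = SimParams(spring_constant=0.3, retraction_speed=3.3)
        assert p.ramp_rate == pytest.approx(990.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimParams(adhesion_probability=1.2)
        with pytest.raises(ValueError):
            SimParams(spring_constant=0.0)
        with pytest.raises(ValueError):
            SimParams(lifetime_lrrd_minus={"w1": 0.5, "k1": -1.0, "k2": 0.2})


class TestCycle:
    def test_no_adhesion_means_no_bond_and_flat_tension(self):
        params = SimParams(adhesion_probability=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            trace, truth = simulate_cycle(params, rng)
            assert not truth.bond_formed and truth.outcome == "no_bond"
            tensile = trace.force[trace.segments["retract"]:]
            assert tensile.max() < 5 * params.noise_sd

    def test_infinite_unfold_rate_gives_immediate_event(self):
        params = SimParams(adhesion_probability=1.0, msd_unfold_rate=1e6,
                           lrrd_probability=0.0, msd_ramp_probability=0.0,
                           ramp_rupture_probability=0.0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            _, truth = simulate_cycle(params, rng)
            if truth.outcome == "lifetime":
                ev = [e for e in truth.events if e.phase == "clamped"]
                assert len(ev) == 1 and ev[0].time < 1e-3

    def test_force_is_spring_constant_times_deflection(self):
        rng = np.random.default_rng(2)
        trace, _ = simulate_cycle(SimParams(adhesion_probability=1.0), rng)
        assert np.allclose(trace.force, trace.spring_constant * trace.probe_nm)

    def test_time_grid_uniform_and_increasing(self):
        rng = np.random.default_rng(3)
        trace, _ = simulate_cycle(SimParams(), rng)
        dt = np.diff(trace.time)
        assert np.allclose(dt, dt[0])


class TestStatisticalStructure:
    def test_adhesion_fraction_within_binomial_error(self):
        outs = simulate_outcomes(4000, SimParams(adhesion_probability=0.15), 4)
        pa = np.mean([o.bond_formed for o in outs])
        assert abs(pa - 0.15) < 3 * np.sqrt(0.15 * 0.85 / 4000)

    def test_lifetime_survival_matches_dual_exponential(self):
        params = SimParams(adhesion_probability=1.0, lrrd_probability=0.0,
                           msd_ramp_probability=0.0, msd_unfold_rate=0.0,
                           ramp_rupture_probability=0.0)
        outs = simulate_outcomes(20000, params, 5)
        t = np.array([o.lifetime for o in outs if o.outcome == "lifetime"])
        lt = lifetime_params("A1WT", 25.0, False)

        def cdf(x):
            return (lt["w1"] * (1 - np.exp(-lt["k1"] * x))
                    + (1 - lt["w1"]) * (1 - np.exp(-lt["k2"] * x)))

        ks = stats.ks_1samp(t, cdf)
        assert ks.pvalue > 0.01

    def test_mean_time_to_unfold_matches_rate(self):
        params = SimParams(adhesion_probability=1.0, lrrd_probability=0.0,
                           msd_ramp_probability=0.0, ramp_rupture_probability=0.0)
        outs = simulate_outcomes(30000, params, 6)
        t_u = np.array([e.time for o in outs for e in o.events if e.phase == "clamped"])
        # observed t_u are censored at t_b; compare against the conditional
        # mean of the joint model instead of 1/k_u
        ku = MSD_UNFOLD_RATE_25PN
        lt = lifetime_params("A1WT", 25.0, False)
        # E[t_u | t_u < t_b] for the independence model
        num = (lt["w1"] * ku / (ku + lt["k1"]) ** 2
               + (1 - lt["w1"]) * ku / (ku + lt["k2"]) ** 2)
        pu = predict_unfold_probability(ku, lt)
        cond_mean = num / pu
        sem = t_u.std(ddof=1) / np.sqrt(t_u.size)
        assert t_u.mean() == pytest.approx(cond_mean, abs=3 * sem)

    def test_clamped_unfolding_frequency_matches_closed_form(self):
        params = SimParams(adhesion_probability=1.0, lrrd_probability=0.0,
                           msd_ramp_probability=0.0, ramp_rupture_probability=0.0)
        outs = simulate_outcomes(10000, params, 7)
        life = [o for o in outs if o.outcome == "lifetime"]
        freq = np.mean([o.msd_clamped_unfolded for o in life])
        pu = predict_unfold_probability(MSD_UNFOLD_RATE_25PN,
                                        lifetime_params("A1WT", 25.0, False))
        assert abs(freq - pu) < 3 * np.sqrt(pu * (1 - pu) / len(life))


class TestSession:
    def test_fixed_seed_reproduces_bytes(self):
        params = SimParams()
        a_cycles, a_cal = simulate_session(10, params, CalciumCoupling(), seed=9)
        b_cycles, b_cal = simulate_session(10, params, CalciumCoupling(), seed=9)
        for (ta, _), (tb, _) in zip(a_cycles, b_cycles):
            assert np.array_equal(ta.force, tb.force)
            assert np.array_equal(ta.target_nm, tb.target_nm)
        assert np.array_equal(a_cal.intensity, b_cal.intensity)

    def test_coupling_disabled_gives_null_trace(self):
        coupling = CalciumCoupling(enabled=False)
        _, cal = simulate_session(30, SimParams(), coupling, seed=10,
                                  render_traces=False)
        assert cal.ca_type == "null"
        assert cal.delta_i_max < 0.05

    def test_long_lifetime_with_unfolding_triggers_alpha_spike(self):
        params = SimParams(adhesion_probability=1.0, msd_unfold_rate=5.0,
                           ramp_rupture_probability=0.0,
                           lifetime_lrrd_minus={"w1": 0.0, "k1": 1.0, "k2": 0.2})
        cycles, cal = simulate_session(10, params, CalciumCoupling(), seed=11,
                                       render_traces=False)
        assert any(t.lifetime and t.lifetime > 2 for _, t in cycles)
        assert cal.ca_type == "alpha"
        assert cal.delta_i_max > 0.5

    def test_session_spans_roughly_two_hundred_seconds(self):
        cycles, cal = simulate_session(60, SimParams(), CalciumCoupling(),
                                       seed=12, render_traces=False)
        span = cal.time[-1]
        assert 120 < span < 400
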