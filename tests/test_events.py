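"""Cycle classification, lifetime measurement and unfolding detection."""

import numpy as np
import pytest

from conftest import match_events
from mechanobfp.events import (
    NotALifetimeError,
    analyze_cycle,
    classify_cycle,
    detect_clamped_unfolding,
    detect_ramped_unfolding,
    force_extension_curve,
    measure_lifetime,
    ramped_unfolding_length,
)
from mechanobfp.simulate import ForceTrace, SimParams, simulate_cycle
from mechanobfp.wlc import WLCParams, fit_contour_length, wlc_extension


def make_trace(force, spring_constant=0.3, sample_rate=1000.0, clamp_force=25.0,
               target=None):
    force = np.asarray(force, dtype=float)
    t = np.arange(force.size) / sample_rate
    probe = force / spring_constant
    if target is None:
        target = np.cumsum(np.full(force.size, 3.3))
    return ForceTrace(time=t, force=force, probe_nm=probe, target_nm=target,
                      mode="clamp", spring_constant=spring_constant,
                      sample_rate=sample_rate, clamp_force=clamp_force,
                      segments={"retract": 0})


class TestClassification:
    def test_flat_trace_is_no_bond(self):
        rng = np.random.default_rng(0)
        tr = make_trace(rng.normal(0, 1, 800))
        assert classify_cycle(tr) == "no_bond"

    def test_plateau_trace_is_lifetime_and_tb_measured(self):
        # steep ramp reaches 25 pN at t=1.0 s, collapse at t=4.2 s -> 3.2 s
        f = np.concatenate([
            np.zeros(900),
            np.linspace(0, 25, 100),
            np.full(3200, 25.0),
            np.zeros(200),
        ])
        tr = make_trace(f)
        assert classify_cycle(tr) == "lifetime"
        assert measure_lifetime(tr) == pytest.approx(3.2, abs=0.03)

    def test_immediate_collapse_gives_near_zero_lifetime(self):
        f = np.concatenate([np.zeros(900), np.linspace(0, 25, 100),
                            np.full(8, 25.0), np.zeros(500)])
        tr = make_trace(f)
        assert measure_lifetime(tr) == pytest.approx(0.0, abs=0.03)

    def test_ramp_that_never_reaches_clamp_is_rupture(self):
        f = np.concatenate([np.zeros(300), np.linspace(0, 18, 500), np.zeros(400)])
        tr = make_trace(f)
        assert classify_cycle(tr) == "rupture"
        with pytest.raises(NotALifetimeError):
            measure_lifetime(tr)

    def test_simulated_outcomes_recovered(self, labeled_cycles):
        _, data = labeled_cycles
        agree = 0
        total = 0
        for trace, truth in data[:150]:
            total += 1
            got = classify_cycle(trace)
            agree += got == truth.outcome
        assert agree / total > 0.97

    def test_simulated_lifetimes_match_truth(self, labeled_cycles):
        params, data = labeled_cycles
        errs = []
        for trace, truth in data:
            if truth.outcome == "lifetime" and classify_cycle(trace) == "lifetime":
                errs.append(abs(measure_lifetime(trace)
                                - min(truth.lifetime, params.max_lifetime_s)))
        assert len(errs) > 400
        assert np.median(errs) < 0.02


class TestClampedDetection:
    def test_drop_of_six_piconewton_gives_twenty_nm(self):
        f = np.concatenate([
            np.zeros(200), np.linspace(0, 25, 100), np.full(1000, 25.0),
            np.full(30, 19.0), np.linspace(19, 25, 50), np.full(1000, 25.0),
            np.zeros(100),
        ])
        tr = make_trace(f)
        events = detect_clamped_unfolding(tr)
        assert len(events) == 1
        assert events[0].length == pytest.approx(6.0 / 0.3, abs=1.0)
        # drop onset 1.0 s after the clamp level is reached
        assert events[0].t_u == pytest.approx(1.0, abs=0.05)

    def test_collapse_to_zero_is_not_unfolding(self):
        f = np.concatenate([np.zeros(200), np.linspace(0, 25, 700),
                            np.full(1500, 25.0), np.zeros(300)])
        tr = make_trace(f)
        assert detect_clamped_unfolding(tr) == []

    def test_simulated_t_u_measured_to_sampling_resolution(self, labeled_cycles):
        _, data = labeled_cycles
        errs = []
        for trace, truth in data:
            te = [e for e in truth.events if e.phase == "clamped"]
            de = (detect_clamped_unfolding(trace)
                  if classify_cycle(trace) == "lifetime" else [])
            pairs, _, _ = match_events(te, de, "clamped")
            errs.extend(abs(d.t_u - t.time) for t, d in pairs)
        assert len(errs) > 50
        assert np.median(errs) < 0.01

    def test_t_u_below_lifetime_invariant(self, labeled_cycles):
        _, data = labeled_cycles
        for trace, truth in data:
            if truth.outcome != "lifetime" or classify_cycle(trace) != "lifetime":
                continue
            t_b = measure_lifetime(trace)
            for ev in detect_clamped_unfolding(trace):
                assert ev.t_u <= t_b + 0.05


class TestRampedDetection:
    def test_pure_ramp_has_no_events(self):
        rng = np.random.default_rng(1)
        params = SimParams(adhesion_probability=1.0, lrrd_probability=0.0,
                           msd_ramp_probability=0.0, msd_unfold_rate=0.0,
                           ramp_rupture_probability=0.0)
        n_events = 0
        n = 300
        for _ in range(n):
            trace, _ = simulate_cycle(params, rng)
            n_events += len(detect_ramped_unfolding(trace))
            if classify_cycle(trace) == "lifetime":
                n_events += len(detect_clamped_unfolding(trace))
        # false-positive budget on event-free traces
        assert n_events / n <= 0.01

    def test_lrrd_kink_detected_in_reported_force_range(self):
        rng = np.random.default_rng(2)
        params = SimParams(adhesion_probability=1.0, lrrd_probability=1.0,
                           msd_ramp_probability=0.0, msd_unfold_rate=0.0,
                           ramp_rupture_probability=0.0)
        found = 0
        for _ in range(20):
            trace, truth = simulate_cycle(params, rng)
            events = detect_ramped_unfolding(trace)
            if events:
                found += 1
                assert 5.0 <= events[0].force <= 22.0
        assert found >= 18

    def test_detector_recall_precision_and_lengths(self, labeled_cycles):
        _, data = labeled_cycles
        tp = fp = fn = 0
        len_errs = []
        for trace, truth in data:
            res = analyze_cycle(trace)
            for phase in ("ramped", "clamped"):
                te = [e for e in truth.events if e.phase == phase]
                de = [e for e in res.events if e.phase == phase]
                pairs, missed, extra = match_events(te, de, phase)
                tp += sum(1 for t, _ in pairs if t.observable)
                fn += sum(1 for t in missed if t.observable)
                fp += len(extra)
                for t, d in pairs:
                    covers = sum(1 for t2 in te
                                 if abs((d.time if phase == "ramped" else d.t_u)
                                        - t2.time) < 0.05)
                    if covers == 1:
                        len_errs.append(abs(d.length - t.length))
        n_det = tp + fp
        assert tp / (tp + fn) > 0.95        # recall on observable events
        assert tp / n_det > 0.95            # precision
        assert np.median(len_errs) < 2.0    # nm


class TestForceExtension:
    def test_rigid_tether_gives_vertical_line(self):
        # target motion fully absorbed by the spring: zero molecular extension
        f = np.concatenate([np.zeros(200), np.linspace(0, 20, 500)])
        probe = f / 0.3
        target = probe.copy()
        tr = ForceTrace(time=np.arange(f.size) / 1000.0, force=f, probe_nm=probe,
                        target_nm=target, mode="clamp", spring_constant=0.3,
                        sample_rate=1000.0, clamp_force=25.0,
                        segments={"retract": 0})
        ext, force = force_extension_curve(tr)
        assert np.ptp(ext) < 1e-9
        assert np.ptp(force) > 10

    def test_recovers_generating_wlc(self):
        # the extension origin is only known to a few nm, which biases an
        # offset-free WLC fit low; the recovered contour must still match
        # the generating tether within that origin uncertainty
        rng = np.random.default_rng(3)
        params = SimParams(adhesion_probability=1.0, lrrd_probability=0.0,
                           msd_ramp_probability=0.0, msd_unfold_rate=0.0,
                           ramp_rupture_probability=0.0, noise_sd=0.0)
        trace, _ = simulate_cycle(params, rng)
        ext, f = force_extension_curve(trace)
        sel = f > 2.0
        res = fit_contour_length(ext[sel], f[sel])
        assert res.contour_length == pytest.approx(params.tether_contour_nm, rel=0.08)


def two_branch_curve(lc1, lc2, f_event, noise_sd=0.0, seed=0, n=60):
    rng = np.random.default_rng(seed)
    f_pre = np.linspace(2.0, f_event, n)
    f_post = np.linspace(f_event * 0.6, f_event + 10.0, n)
    x = np.concatenate([
        [wlc_extension(f, WLCParams(lc1)) for f in f_pre],
        [wlc_extension(f, WLCParams(lc2)) for f in f_post],
    ])
    f = np.concatenate([f_pre, f_post]) + rng.normal(0, noise_sd, 2 * n)
    return x, np.clip(f, 0.1, None), n


class TestRampedLength:
    def test_delta_lc_reproduces_two_branch_contour_difference(self):
        x, f, i = two_branch_curve(279.3, 318.6, 30.0)
        dlc = ramped_unfolding_length(x, f, i, method="delta_Lc", units="contour")
        assert dlc == pytest.approx(318.6 - 279.3, abs=0.5)

    def test_zero_jump_curve_gives_zero_both_methods(self):
        x, f, i = two_branch_curve(100.0, 100.0, 20.0)
        for method in ("jump", "delta_Lc"):
            val = ramped_unfolding_length(x, f, i, method=method, units="contour")
            assert abs(val) < 1.5

    def test_methods_agree_on_noisy_ensembles(self):
        diffs = []
        rng = np.random.default_rng(4)
        for k in range(100):
            lc1 = rng.uniform(50, 90)
            dlc = 25.99 if k % 2 else 70.29
            f_e = rng.uniform(10, 25)
            x, f, i = two_branch_curve(lc1, lc1 + dlc, f_e, noise_sd=1.0, seed=k)
            a = ramped_unfolding_length(x, f, i, method="jump", units="contour")
            b = ramped_unfolding_length(x, f, i, method="delta_Lc", units="contour")
            diffs.append(abs(a - b))
        assert np.median(diffs) < 3.0

    def test_extension_and_contour_units_related_by_z(self):
        x, f, i = two_branch_curve(60.0, 86.0, 15.0)
        ext = ramped_unfolding_length(x, f, i, method="jump", units="extension")
        con = ramped_unfolding_length(x, f, i, method="jump", units="contour")
        assert 0 < ext < con
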