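"""Calcium-trace normalization, typing, pre-onset statistics, ROC."""

import numpy as np
import pytest

from mechanobfp import calcium as ca
from mechanobfp.simulate import CalciumCoupling, SimParams, simulate_session


def synth_trace(kind, n=400, rate=2.0, onset=60.0, amp=0.8, rise=3.0, seed=0,
                noise=0.01, scale=1.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    base = 1.0 + rng.normal(0, noise, n)
    if kind != "null":
        s = np.clip(t - onset, 0, None) / rise
        base = base + amp * s * np.exp(1 - s)
    return t, base * scale


class TestNormalization:
    def test_constant_trace_has_no_peak_or_onset(self):
        t, raw = synth_trace("null")
        an = ca.normalize_and_peak(t, raw)
        assert an.delta_i_max < 0.05
        assert an.onset_time is None

    def test_doubling_trace_gives_unit_increase(self):
        t = np.arange(100) / 2.0
        raw = np.concatenate([np.full(50, 3.0), np.full(50, 6.0)])
        an = ca.normalize_and_peak(t, raw)
        assert an.delta_i_max == pytest.approx(1.0, abs=0.01)

    def test_onset_located_within_one_frame(self):
        t, raw = synth_trace("alpha", onset=60.0, amp=0.9)
        an = ca.normalize_and_peak(t, raw)
        assert an.onset_time == pytest.approx(60.0, abs=1.5)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            ca.normalize_and_peak(np.arange(20), np.full(20, -1.0))


class TestClassification:
    def test_flat_low_amplitude_is_null(self):
        t, raw = synth_trace("null", seed=1)
        assert ca.classify_calcium(ca.normalize_and_peak(t, raw)) == "null"

    def test_latency_spike_fast_decay_is_alpha(self):
        t, raw = synth_trace("alpha", amp=0.8, rise=3.0, seed=2)
        assert ca.classify_calcium(ca.normalize_and_peak(t, raw)) == "alpha"

    def test_gradual_intermediate_rise_is_beta(self):
        t, raw = synth_trace("beta", amp=0.3, rise=30.0, seed=3)
        assert ca.classify_calcium(ca.normalize_and_peak(t, raw)) == "beta"

    def test_scale_invariance_of_typing(self):
        for scale in (0.1, 1.0, 250.0):
            t, raw = synth_trace("alpha", amp=0.8, seed=4, scale=scale)
            assert ca.classify_calcium(ca.normalize_and_peak(t, raw)) == "alpha"


class TestPreCaStats:
    def test_single_lifetime(self):
        st = ca.pre_ca_stats([3.0], [10.0], onset_time=50.0)
        assert st.t_max == st.sum_t == st.mean_t == 3.0

    def test_arithmetic_on_three_lifetimes(self):
        st = ca.pre_ca_stats([0.3, 0.5, 4.0], [10.0, 20.0, 30.0], onset_time=40.0)
        assert st.t_max == 4.0
        assert st.sum_t == pytest.approx(4.8)
        assert st.mean_t == pytest.approx(1.6)

    def test_post_onset_lifetimes_excluded(self):
        st = ca.pre_ca_stats([1.0, 9.0], [10.0, 60.0], onset_time=30.0)
        assert st.n_lifetimes == 1 and st.t_max == 1.0

    def test_onset_before_first_contact_flagged(self):
        with pytest.raises(ValueError):
            ca.pre_ca_stats([1.0], [10.0], onset_time=5.0)

    def test_cumulative_dominated_by_longest_in_simulation(self):
        dominant = 0
        total = 0
        for s in range(25):
            cycles, cal = simulate_session(60, SimParams(), CalciumCoupling(),
                                           seed=200 + s, render_traces=False)
            tb = [t.lifetime for _, t in cycles if t.outcome == "lifetime"]
            ends = [t.start_time + t.lifetime for _, t in cycles
                    if t.outcome == "lifetime"]
            if not tb or cal.onset_time is None:
                continue
            try:
                st = ca.pre_ca_stats(tb, ends, cal.onset_time)
            except ValueError:
                continue
            total += 1
            dominant += st.t_max > 0.5 * st.sum_t
        assert total >= 10
        assert dominant / total > 0.6


class TestCorrelation:
    def test_exact_linear_relationship(self):
        x = np.arange(10.0)
        r = ca.correlate(2 * x, x)
        assert r["r"] == pytest.approx(1.0)
        assert r["slope"] == pytest.approx(2.0)
        assert r["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_permutation_destroys_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2, 1, 200)
        y = 0.3 * x + rng.normal(0, 0.1, 200)
        r1 = ca.correlate(y, x)["r"]
        r2 = ca.correlate(y, rng.permutation(x))["r"]
        assert r1 > 0.8
        assert abs(r2) < 0.25

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ca.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestROC:
    def test_separable_classes_perfect_threshold(self):
        t_max = np.array([0.5, 1.0, 1.5, 3.0, 4.0, 5.0])
        labels = np.array([False, False, False, True, True, True])
        roc = ca.roc_threshold(t_max, labels)
        assert roc["sensitivity"] == 1.0
        assert roc["specificity"] == 1.0
        assert 1.5 <= roc["t0"] < 3.0
        assert roc["auc"] == pytest.approx(1.0)

    def test_reported_operating_point_reproduced(self):
        # 12 of 17 alpha above 2 s; 17 of 21 beta at or below 2 s.  The four
        # long-lived beta responders sit above every alpha so no threshold
        # beats the 2 s operating point.
        alpha = np.concatenate([np.linspace(2.5, 6.0, 12), np.linspace(0.3, 1.8, 5)])
        beta = np.concatenate([np.linspace(0.2, 1.9, 16), [2.0],
                               np.array([7.0, 7.5, 8.0, 9.0])])
        t_max = np.concatenate([alpha, beta])
        labels = np.concatenate([np.ones(17, bool), np.zeros(21, bool)])
        roc = ca.roc_threshold(t_max, labels)
        assert roc["sensitivity"] == pytest.approx(0.7059, abs=1e-4)
        assert roc["specificity"] == pytest.approx(0.8095, abs=1e-4)
        assert roc["t0"] == pytest.approx(2.0, abs=1e-9)

    def test_label_reversal_maps_auc(self):
        rng = np.random.default_rng(7)
        t_max = rng.uniform(0, 5, 60)
        labels = t_max + rng.normal(0, 1, 60) > 2.5
        a1 = ca.roc_threshold(t_max, labels)["auc"]
        a2 = ca.roc_threshold(-t_max, labels)["auc"]
        assert a1 + a2 == pytest.approx(1.0, abs=0.05)
        assert 0 <= a1 <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ca.roc_threshold([1.0, 2.0], [True, True])

    def test_random_labels_accuracy_near_prior(self):
        rng = np.random.default_rng(8)
        t_max = rng.uniform(0, 5, 300)
        labels = rng.random(300) < 0.5
        roc = ca.roc_threshold(t_max, labels)
        n_pos, n_neg = labels.sum(), (~labels).sum()
        best_acc = (roc["sensitivity"] * n_pos + roc["specificity"] * n_neg) / 300
        assert best_acc < 0.62

    def test_recovers_generating_threshold_on_simulated_sessions(self):
        t_max, labels = [], []
        params = SimParams()
        for s in range(50):
            cycles, cal = simulate_session(60, params, CalciumCoupling(),
                                           seed=500 + s, render_traces=False)
            if cal.ca_type == "null":
                continue
            tb = [t.lifetime for _, t in cycles if t.outcome == "lifetime"]
            ends = [t.start_time + t.lifetime for _, t in cycles
                    if t.outcome == "lifetime"]
            try:
                st = ca.pre_ca_stats(tb, ends, cal.onset_time)
            except ValueError:
                continue
            t_max.append(st.t_max)
            labels.append(cal.ca_type == "alpha")
        t_max, labels = np.array(t_max), np.array(labels)
        assert labels.sum() >= 5 and (~labels).sum() >= 5
        roc = ca.roc_threshold(t_max, labels)
        # generating rule: alpha requires a pre-onset lifetime > 2 s, so the
        # optimal decision band (t0, next value above t0] must contain 2 s
        next_above = t_max[t_max > roc["t0"]].min()
        assert roc["t0"] < 2.0 <= next_above + 0.2

    def test_segregation_by_unfolding_groups(self):
        recs = [
            {"lrrd": True, "msd": True, "delta_i_max": 0.9, "t_max": 5.0},
            {"lrrd": True, "msd": True, "delta_i_max": 0.8, "t_max": 4.0},
            {"lrrd": False, "msd": True, "delta_i_max": 0.6, "t_max": 3.0},
            {"lrrd": False, "msd": False, "delta_i_max": 0.1, "t_max": 0.5},
        ]
        groups = ca.segregate_by_unfolding(recs)
        fracs = [g["fraction"] for g in groups.values()]
        assert sum(fracs) == pytest.approx(1.0)
        assert groups[("LRRD+", "MSD+")]["mean_delta_i_max"] == max(
            g["mean_delta_i_max"] for g in groups.values())
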