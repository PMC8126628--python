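import numpy as np
import pytest
from hypothesis import given, strategies as st

from flysleep.circadian_drive import (CircadianParams, CircadianState,
                                      DelayHistory, circadian_period,
                                      circadian_rhs, classify_epoch,
                                      dclock_free, external_current,
                                      hill_terms, integrate_circadian)

CP = CircadianParams()


class TestDclockFree:
    @pytest.mark.parametrize("d, p, expected", [
        (1.0, 0.3, 0.7),
        (0.3, 1.0, 0.0),
        (0.42, 0.42, 0.0),
        (0.0, 0.0, 0.0),
    ])
    def test_clamped_difference(self, d, p, expected):
        assert dclock_free(d, p) == pytest.approx(expected)

    @given(d=st.floats(0, 10), p=st.floats(0, 10))
    def test_never_negative(self, d, p):
        assert dclock_free(d, p) >= 0.0


class TestHillTerms:
    def test_limits_at_zero(self):
        r_sc, r_sp = hill_terms(0.0, 0.0, CP)
        assert r_sc == 1.0 and r_sp == 0.0

    def test_half_saturation(self):
        r_sc, _ = hill_terms(CP.K2, 0.0, CP)
        _, r_sp = hill_terms(0.0, CP.K1, CP)
        assert r_sc == pytest.approx(0.5)
        assert r_sp == pytest.approx(0.5)

    @given(x1=st.floats(0, 100), x2=st.floats(0, 100))
    def test_ranges(self, x1, x2):
        r_sc, r_sp = hill_terms(x2, x1, CP)
        assert 0.0 < r_sc <= 1.0
        assert 0.0 <= r_sp < 1.0


class TestCircadianRhs:
    def test_balance_point(self):
        # constant history at x0 freezes R_sc; dclock at v_sc R_sc / k_dc
        x0 = 0.2
        hist = DelayHistory(0.0, 0.01, 25.0, x0)
        r_sc, r_sp = hill_terms(x0, x0, CP)
        state = CircadianState(dclock=CP.v_sc * r_sc / CP.k_dc,
                               per=CP.v_sp * r_sp / CP.k_dp, history=hist)
        dd, dp = circadian_rhs(state, 0.0, CP)
        assert dd == pytest.approx(0.0, abs=1e-12)
        assert dp == pytest.approx(0.0, abs=1e-12)

    def test_per_flat_when_history_empty_of_free_dclock(self):
        hist = DelayHistory(0.0, 0.01, 25.0, 0.0)
        state = CircadianState(dclock=0.3, per=0.0, history=hist)
        _, dp = circadian_rhs(state, 0.0, CP)
        assert dp == 0.0

    def test_missing_history_raises(self):
        with pytest.raises(ValueError):
            circadian_rhs(CircadianState(dclock=0.1, per=0.1), 0.0, CP)


class TestExternalCurrent:
    def test_zero_during_sleep(self):
        assert external_current(-60.0, 0.2, 0.5, CP) == 0.0
        assert external_current(-60.0, 0.2, 0.2, CP) == 0.0

    def test_zero_driving_force(self):
        assert external_current(CP.E_syn, 1.0, 0.0, CP) == 0.0

    def test_hand_value(self):
        # g [dCLOCK] (E_syn - V) = 0.05 * 1 * 110
        assert external_current(-60.0, 1.0, 0.0, CP) == pytest.approx(5.5)


class TestClassifyEpoch:
    def test_examples(self):
        assert classify_epoch(0.5, 0.5) == "sleep"
        assert classify_epoch(0.5, 0.4999) == "wake"
        assert classify_epoch(1e-5, 0.0, eps=1e-6) == "wake"

    def test_trace_partitions_into_one_pair_per_cycle(self):
        """After the transient, sleep and wake alternate with exactly one
        sleep episode per oscillator period (brute-force epoch counting)."""
        t, d, p = integrate_circadian(CP, duration=240.0, dt=0.01)
        keep = t >= 48.0
        sleep = classify_epoch(d[keep], p[keep]) == "sleep"
        n_onsets = np.count_nonzero(~sleep[:-1] & sleep[1:])
        span = t[keep][-1] - t[keep][0]
        period = circadian_period(CP)
        assert n_onsets == pytest.approx(span / period, abs=1.0)


class TestIntegration:
    def test_nonnegative_and_bounded(self):
        t, d, p = integrate_circadian(CP, duration=200.0, dt=0.02,
                                      dclock0=1.7, per0=2.9)
        assert np.all(d >= 0) and np.all(p >= 0)
        late = t >= 100.0
        assert np.all(d[late] <= CP.v_sc / CP.k_dc + 1e-6)
        assert np.all(p[late] <= CP.v_sp / CP.k_dp + 1e-6)

    def test_sustained_oscillation_not_fixed_point(self):
        t, d, p = integrate_circadian(CP, duration=200.0, dt=0.01)
        late = t >= 150.0
        assert p[late].max() - p[late].min() > 0.2
        assert d[late].max() - d[late].min() > 0.2

    def test_ring_buffer_matches_dense_storage_oracle(self):
        """Brute-force DDE integration with full dense storage of the
        delayed variable must agree with the ring-buffer integrator."""
        dt, duration = 0.02, 60.0
        n = int(round(duration / dt))
        t = np.arange(n + 1) * dt
        d = np.empty(n + 1); p = np.empty(n + 1)
        d[0], p[0] = 0.5, 0.1
        xs = [max(d[0] - p[0], 0.0)]  # dense history from t=0 backwards const

        def lookup(tq):
            if tq <= 0:
                return xs[0]
            pos = tq / dt
            k = min(int(pos), len(xs) - 1)
            frac = pos - k
            if k + 1 < len(xs):
                return (1 - frac) * xs[k] + frac * xs[k + 1]
            return xs[k]

        def rhs(ti, dd, pp):
            x1 = lookup(ti - CP.tau1)
            x2 = lookup(ti - CP.tau2)
            return (CP.v_sc * CP.K2 / (CP.K2 + x2) - CP.k_dc * dd,
                    CP.v_sp * x1 / (CP.K1 + x1) - CP.k_dp * pp)

        for i in range(n):
            ti = t[i]
            k1 = rhs(ti, d[i], p[i])
            k2 = rhs(ti + dt / 2, d[i] + dt / 2 * k1[0], p[i] + dt / 2 * k1[1])
            k3 = rhs(ti + dt / 2, d[i] + dt / 2 * k2[0], p[i] + dt / 2 * k2[1])
            k4 = rhs(ti + dt, d[i] + dt * k3[0], p[i] + dt * k3[1])
            d[i + 1] = d[i] + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            p[i + 1] = p[i] + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            xs.append(max(d[i + 1] - p[i + 1], 0.0))

        t2, d2, p2 = integrate_circadian(CP, duration=duration, dt=dt)
        assert np.allclose(d, d2, atol=1e-9)
        assert np.allclose(p, p2, atol=1e-9)

    def test_period_stable_under_dt_refinement(self):
        p1 = circadian_period(CP, duration=200.0, dt=0.02)
        p2 = circadian_period(CP, duration=200.0, dt=0.005)
        assert p1 == pytest.approx(p2, abs=0.05)

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            integrate_circadian(CP, duration=10.0, dt=0.0)
        with pytest.raises(ValueError):
            integrate_circadian(CP, duration=10.0, dt=11.0)


class TestDelayHistory:
    def test_underflow_raises(self):
        hist = DelayHistory(0.0, 0.1, 1.0, 0.5)
        for _ in range(30):
            hist.push(1.0)
        with pytest.raises(ValueError):
            hist.lookup(hist.t_latest - 10.0)

    def test_linear_interpolation_between_samples(self):
        hist = DelayHistory(0.0, 1.0, 5.0, 0.0)
        for v in (1.0, 2.0, 3.0):
            hist.push(v)
        assert hist.lookup(2.5) == pytest.approx(2.5)
        assert hist.lookup(0.5) == pytest.approx(0.5)
        assert hist.lookup(3.0) == pytest.approx(3.0)
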