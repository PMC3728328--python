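"""Washout inversion and Kalman separation of resting vs activity components."""

import dataclasses

import numpy as np
import pytest

from metacage import (
    GasTrace,
    bin_trace,
    derive_components,
    kalman_decompose,
    washout_correct,
)
from metacage.decomposition import decompose_trace
from metacage.parameters import weir_ee
from metacage.synthetic import generate_latent_session, generate_session

from conftest import window_mean


def _trace(vo2, vco2=None, activity=None, dt=5.0, t0=0.0, missing=None):
    vo2 = np.asarray(vo2, dtype=float)
    t = t0 + dt * np.arange(len(vo2))
    return GasTrace(
        time_s=t,
        vo2=vo2,
        vco2=vo2 * 0.8 if vco2 is None else np.asarray(vco2, float),
        activity=np.zeros_like(vo2) if activity is None else np.asarray(activity, float),
        missing=missing,
    )


TAU = 420.0


class TestWashout:
    def test_constant_trace_unchanged(self):
        trace = _trace(np.full(600, 5.0))
        out = washout_correct(trace, TAU)
        np.testing.assert_allclose(out.vo2, 5.0, rtol=1e-9)

    def test_step_inversion_recovers_step(self):
        """Noise-free s*(1-exp(-t/tau)) must invert to the step s."""
        dt = 5.0
        t = np.arange(-1800.0, 3600.0, dt)
        s = 4.0
        resp = np.where(t >= 0, s * (1.0 - np.exp(-t / TAU)), 0.0) + 1.0
        out = washout_correct(_trace(resp, vco2=resp * 0.8, t0=t[0]), TAU)
        interior = t > 120.0  # away from the step edge and boundaries
        assert np.max(np.abs(out.vo2[interior] - (1.0 + s))) < 0.01 * (1.0 + s)

    def test_roundtrip_against_generator_truth(self, quiet_config):
        """Correcting the chamber output recovers the latent production."""
        lat, trace = generate_session(None, quiet_config)
        out = washout_correct(trace, quiet_config.tau_s)
        mid = (trace.time_s > -6000) & (trace.time_s < -600)  # steady fasted segment
        assert np.allclose(out.vo2[mid], lat.true_rest_vo2[mid], rtol=2e-3)

    def test_gap_guard_band_propagates(self, short_config):
        _, trace = generate_session(None, short_config)
        out = washout_correct(trace, short_config.tau_s)
        assert out.missing.sum() > trace.missing.sum() > 0
        gap_idx = np.flatnonzero(trace.missing)
        assert out.missing[gap_idx.min() - 1] and out.missing[gap_idx.max() + 1]

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="smoothing window"):
            washout_correct(_trace(np.full(5, 5.0)), TAU)


def _piecewise_session(rest=5.0, cost=0.03, act_level=20.0, noise=0.0, n=2400, seed=0):
    """Alternating 10-min activity blocks with constant rest and cost."""
    rng = np.random.default_rng(seed)
    act = np.zeros(n)
    block = 120  # 10 min at 5 s
    for start in range(block, n, 2 * block):
        act[start : start + block] = act_level
    vo2 = rest + cost * act + rng.normal(0, noise, n)
    vco2 = 0.8 * rest + 0.9 * cost * act + rng.normal(0, noise, n)
    return _trace(vo2, vco2=vco2, activity=act), rest, cost


class TestKalman:
    def test_rest_tracks_mean_when_no_activity(self, rng):
        y = 5.0 + rng.normal(0, 0.05, 1200)
        with pytest.warns(RuntimeWarning, match="not identifiable"):
            dec = kalman_decompose(_trace(y))
        assert not dec.cost_identifiable
        mid = slice(200, 1000)
        assert np.mean(dec.rest_vo2[mid]) == pytest.approx(np.mean(y), abs=0.02)

    def test_known_cost_recovered_within_5pct(self):
        trace, rest, cost = _piecewise_session(noise=0.02)
        dec = kalman_decompose(trace)
        active = trace.activity > 0
        assert np.median(dec.cost_vo2[active]) == pytest.approx(cost, rel=0.05)
        assert np.median(dec.rest_vo2) == pytest.approx(rest, rel=0.05)

    def test_windowed_ols_oracle_agreement_noise_free(self):
        """On noise-free piecewise-constant data the filter must agree with a
        sliding-window least-squares fit of gas on activity to within 1%."""
        trace, rest, cost = _piecewise_session(noise=0.0)
        dec = kalman_decompose(trace, obs_noise_vo2=0.01, obs_noise_vco2=0.01)
        window = 120  # 10 min
        mids, intercepts, slopes = [], [], []
        for start in range(0, len(trace) - window, window // 2):
            sl = slice(start, start + window)
            a = trace.activity[sl]
            if a.std() == 0:
                continue
            X = np.column_stack([np.ones(window), a])
            beta, *_ = np.linalg.lstsq(X, trace.vo2[sl], rcond=None)
            mids.append(start + window // 2)
            intercepts.append(beta[0])
            slopes.append(beta[1])
        assert len(mids) > 5
        rest_err = np.abs(dec.rest_vo2[mids] - np.array(intercepts)) / rest
        cost_err = np.abs(dec.cost_vo2[mids] - np.array(slopes)) / cost
        assert np.median(rest_err) < 0.01
        assert np.median(cost_err) < 0.01

    def test_global_ols_oracle_agreement_low_noise(self):
        # OLS of vo2 on activity over the whole session (both activity
        # levels) as an independent estimate of rest and cost
        trace, rest, cost = _piecewise_session(noise=0.01, seed=3)
        dec = kalman_decompose(trace)
        X = np.column_stack([np.ones(len(trace)), trace.activity])
        beta, *_ = np.linalg.lstsq(X, trace.vo2, rcond=None)
        active = trace.activity > 0
        assert np.median(dec.cost_vo2[active]) == pytest.approx(beta[1], rel=0.10)
        assert np.median(dec.rest_vo2) == pytest.approx(beta[0], rel=0.10)

    def test_all_missing_rejected(self):
        y = np.full(100, np.nan)
        with pytest.raises(ValueError, match="no valid samples"):
            kalman_decompose(_trace(y, vco2=y, missing=np.ones(100, bool)))

    def test_filter_only_mode_is_causal_and_bounded(self):
        trace, rest, cost = _piecewise_session(noise=0.05, seed=9)
        dec = kalman_decompose(trace, smooth=False)
        assert np.isfinite(dec.rest_vo2).all()
        assert (dec.rest_vo2 > 0).all()  # floored, never negative

    def test_missing_gap_inflates_variance(self, short_config):
        _, trace = generate_session(None, short_config)
        dec = kalman_decompose(trace, smooth=False)
        gap = np.flatnonzero(trace.missing)
        assert dec.rest_vo2_var[gap[-1]] > dec.rest_vo2_var[gap[0] - 1]


class TestDerivedComponents:
    def test_weir_point_values_on_states(self):
        trace, *_ = _piecewise_session(noise=0.0)
        dec = kalman_decompose(trace)
        dec.rest_vo2 = np.full_like(dec.rest_vo2, 10.0)
        dec.rest_vco2 = np.full_like(dec.rest_vco2, 8.0)
        out = derive_components(dec)
        np.testing.assert_allclose(out.rest_rq, 0.8, rtol=1e-12)
        np.testing.assert_allclose(out.ree_w, 3.326, rtol=1e-12)

    def test_act_rq_unity_when_cost_components_equal(self):
        trace, *_ = _piecewise_session(noise=0.0)
        dec = kalman_decompose(trace)
        dec.cost_vo2 = np.full_like(dec.cost_vo2, 0.03)
        dec.cost_vco2 = np.full_like(dec.cost_vco2, 0.03)
        out = derive_components(dec)
        active = out.act_rq[~np.isnan(out.act_rq)]
        assert len(active) > 0
        np.testing.assert_allclose(active, 1.0, rtol=1e-12)

    def test_act_rq_fully_masked_without_activity(self, rng):
        y = 5.0 + rng.normal(0, 0.02, 600)
        with pytest.warns(RuntimeWarning):
            dec = kalman_decompose(_trace(y))
        out = derive_components(dec)
        assert np.isnan(out.act_rq).all()

    def test_weir_linearity_of_decomposition(self):
        """Weir(rest) + Weir(cost*activity) == Weir(total) exactly."""
        trace, *_ = _piecewise_session(noise=0.01, seed=4)
        out = derive_components(kalman_decompose(trace))
        total = weir_ee(
            out.rest_vo2 + np.maximum(out.cost_vo2, 0) * trace.activity,
            out.rest_vco2 + np.maximum(out.cost_vco2, 0) * trace.activity,
        )
        np.testing.assert_allclose(out.ree_w + out.act_ee_w, total, rtol=1e-12)

    def test_rest_rq_physiological_range_on_generator_output(self, decomposed_session):
        *_, dec, binned = decomposed_session
        clean = binned.loc[~binned.flagged, "rest_rq"]
        assert clean.between(0.6, 1.1).all()


class TestBinning:
    def test_constant_series_bins_to_constant(self):
        trace, *_ = _piecewise_session(noise=0.0)
        out = derive_components(kalman_decompose(trace, obs_noise_vo2=0.01, obs_noise_vco2=0.01))
        binned = bin_trace(out, 15.0)
        complete = binned[binned.n_samples == 180]
        assert complete.rest_vo2.std() < 0.01

    def test_complete_bin_has_180_samples(self, decomposed_session):
        *_, binned = decomposed_session
        assert binned.n_samples.max() == 180

    def test_bins_align_to_meal(self, decomposed_session):
        *_, binned = decomposed_session
        assert (binned.bin_start_min % 15 == 0).all()
        assert (binned.bin_start_min == 0).any()

    def test_gap_bin_flagged_neighbors_clean(self):
        # constructed fixture: a 10-min gap inside one 15-min bin (>50%
        # missing) must flag that bin and leave its neighbors clean
        n = 3 * 180
        vo2 = np.full(n, 5.0)
        missing = np.zeros(n, bool)
        missing[180 + 30 : 180 + 150] = True  # 10 min of the middle bin
        vo2c = vo2.copy()
        vo2c[missing] = np.nan
        trace = _trace(vo2c, vco2=vo2c * 0.8, missing=missing)
        dec = derive_components(
            kalman_decompose(trace, obs_noise_vo2=0.05, obs_noise_vco2=0.05)
        )
        binned = bin_trace(dec, 15.0)
        assert binned.flagged.tolist() == [False, True, False]
        assert binned.loc[~binned.flagged, "rest_vo2"].notna().all()

    def test_bad_width_rejected(self, decomposed_session):
        dec = decomposed_session[3]
        with pytest.raises(ValueError, match="multiple"):
            bin_trace(dec, 0.13)


class TestPipelineRecovery:
    def test_rest_rq_recovery_across_sessions(self):
        """Median |error| of pre-meal Rest-RQ <= 0.02 across seeded sessions."""
        from metacage import SessionConfig

        errs = []
        for seed in range(8):
            cfg = SessionConfig(
                seed=seed, meal_type="HF",
                session_start="07:30", meal_time="10:00", session_end="15:00",
            )
            lat, trace = generate_session({"adchg": 2.0}, cfg)
            dec, binned = decompose_trace(trace, tau_s=cfg.tau_s)
            est = window_mean(binned, "rest_rq", -120, 0)
            truth = lat.true_rest_rq[(lat.time_s >= -7200) & (lat.time_s < 0)].mean()
            errs.append(abs(est - truth))
        assert np.median(errs) <= 0.02
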