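"""Cohort and session generators: calibration, determinism, chamber physics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from metacage import (
    CohortConfig,
    SessionConfig,
    apply_chamber_mixing,
    generate_cohort,
    generate_latent_session,
    generate_session,
)
from metacage.inference import pearson_correlation
from metacage.parameters import weir_ee
from metacage.synthetic import LatentSession, adiposity_gains


class TestCohort:
    def test_seeded_generation_is_reproducible(self, default_cohort_config):
        a = generate_cohort(default_cohort_config)
        b = generate_cohort(dataclasses.replace(default_cohort_config))
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_rats=5),
            dict(n_rats=2),
            dict(gain_correlation=1.5),
            dict(bw_adiposity_coupling_hfd=-1.2),
            dict(hcd_gain_sd=-0.1),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(**bad))

    def test_schema_and_composition_identity(self, default_cohort_config):
        cohort = generate_cohort(default_cohort_config)
        mri = cohort.dropna(subset=["mri_session"])
        # FFM = BW - FM at every imaging day; depots never exceed total fat
        np.testing.assert_allclose(mri.ffm_g, mri.bw_g - mri.fm_g)
        assert ((mri.fm_visc_g + mri.fm_subc_g) <= mri.fm_g + 1e-9).all()
        ad = mri.fm_g / mri.bw_g * 100
        assert ((ad > 0) & (ad < 100)).all()
        assert mri.groupby("rat_id").size().eq(3).all()

    def test_zero_correlation_gains_are_independent(self):
        rs = []
        for seed in range(60):
            cfg = CohortConfig(seed=seed, gain_correlation=0.0)
            g = adiposity_gains(generate_cohort(cfg))
            rs.append(pearson_correlation(g.hcd_gain_pct, g.hfd_gain_pct)[0])
        # SE of mean r at n=24 over 60 cohorts is ~0.027
        assert abs(np.mean(rs)) < 0.08

    def test_cohort_moments_converge(self):
        """Sample moments across many cohorts match the configured moments."""
        cfg = CohortConfig()
        hcd, hfd, rs = [], [], []
        n_cohorts = 300
        for seed in range(n_cohorts):
            g = adiposity_gains(generate_cohort(dataclasses.replace(cfg, seed=seed)))
            hcd.append(g.hcd_gain_pct.mean())
            hfd.append(g.hfd_gain_pct.mean())
            rs.append(pearson_correlation(g.hcd_gain_pct, g.hfd_gain_pct)[0])
        se_mean = cfg.hcd_gain_sd / np.sqrt(24 * n_cohorts)
        assert abs(np.mean(hcd) - cfg.hcd_gain_mean) < 3 * se_mean
        se_mean = cfg.hfd_gain_sd / np.sqrt(24 * n_cohorts)
        assert abs(np.mean(hfd) - cfg.hfd_gain_mean) < 3 * se_mean
        # sample r is slightly biased toward 0; allow bias + 3 SE
        assert abs(np.mean(rs) - cfg.gain_correlation) < 0.01 + 3 * np.std(rs) / np.sqrt(n_cohorts)

    def test_visceral_subcutaneous_median_after_hcd(self):
        meds = []
        for seed in range(100):
            cohort = generate_cohort(CohortConfig(seed=seed))
            mri2 = cohort[cohort.mri_session == 2]
            meds.append(np.median(mri2.fm_visc_g / mri2.fm_subc_g))
        assert np.mean(meds) == pytest.approx(1.82, abs=0.05)

    def test_extreme_selection_inflates_start_adiposity_spread(self):
        plain = generate_cohort(CohortConfig(seed=3, select_extremes=False))
        sel = generate_cohort(CohortConfig(seed=3, select_extremes=True))

        def start_sd(cohort):
            m1 = cohort[cohort.mri_session == 1]
            return (m1.fm_g / m1.bw_g * 100).std()

        assert start_sd(sel) > start_sd(plain)


class TestLatentSession:
    def test_quiet_session_is_constant(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, tef_fraction=0.0, rq_excursion=0.0)
        lat = generate_latent_session(None, cfg)
        assert np.allclose(lat.activity, 0.0)
        assert np.ptp(lat.true_rest_vo2) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(lat.true_rest_rq) == pytest.approx(0.0, abs=1e-12)

    def test_sensitive_rat_hc_meal_peaks_above_hcd_food_quotient(self, short_config):
        cfg = dataclasses.replace(short_config, meal_type="HC")
        lat = generate_latent_session({"adchg": 3.0}, cfg)  # upper-half gainer
        assert lat.true_rest_rq.max() > 0.946

    def test_resistant_rat_hc_meal_stays_below_food_quotient(self, short_config):
        cfg = dataclasses.replace(short_config, meal_type="HC", rq_walk_sd=0.0)
        lat = generate_latent_session({"adchg": -1.0}, cfg)  # low gainer
        assert lat.true_rest_rq.max() < 0.946

    def test_hf_meal_mean_rq_rise(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, meal_type="HF")
        lat = generate_latent_session(None, cfg)
        pre = lat.true_rest_rq[(lat.time_s >= -7200) & (lat.time_s < 0)].mean()
        post = lat.true_rest_rq[(lat.time_s > 0) & (lat.time_s <= 18000)].mean()
        assert post - pre == pytest.approx(0.035, abs=1e-3)

    def test_energy_conservation_of_tef_bump(self, quiet_config):
        """Post-meal latent EE minus basal integrates to tef_fraction * meal."""
        lat = generate_latent_session(None, quiet_config)
        dt = quiet_config.sampling_interval
        post = (lat.time_s > 0) & (lat.time_s <= 300 * 60)
        ee = weir_ee(lat.true_rest_vo2, lat.true_rest_vco2)
        excess_kj = np.sum(ee[post] - lat.basal_ee_w) * dt / 1000.0
        truth = quiet_config.tef_fraction * quiet_config.meal_energy
        assert excess_kj == pytest.approx(truth, rel=1e-3)

    def test_weir_inversion_is_exact(self, short_config):
        lat = generate_latent_session(None, short_config)
        np.testing.assert_allclose(
            weir_ee(lat.true_rest_vo2, lat.true_rest_vco2), lat.true_rest_ee_w, rtol=1e-12
        )

    def test_latent_positivity_enforced(self, short_config):
        lat = generate_latent_session(None, short_config)
        assert (lat.true_rest_vo2 > 0).all() and (lat.true_rest_vco2 > 0).all()
        assert (lat.activity >= 0).all()
        with pytest.raises(ValueError):
            LatentSession(
                time_s=np.array([0.0, 5.0]),
                true_rest_vo2=np.array([1.0, -1.0]),
                true_rest_vco2=np.array([1.0, 1.0]),
                true_act_cost_vo2=np.zeros(2),
                true_act_cost_vco2=np.zeros(2),
                activity=np.zeros(2),
            )

    def test_metabolic_mass_scales_basal_rate(self, quiet_config):
        small = generate_latent_session({"ffm_g": 200.0, "fm_g": 20.0}, quiet_config)
        large = generate_latent_session({"ffm_g": 350.0, "fm_g": 80.0}, quiet_config)
        assert large.basal_ee_w > small.basal_ee_w


class TestChamberMixing:
    def test_time_constant_is_seven_minutes(self):
        assert SessionConfig().tau_s == pytest.approx(7 * 60.0)

    def _latent_step(self, cfg, base=5.0, step=5.0):
        t = np.arange(-3600.0, 3600.0, cfg.sampling_interval)
        vo2 = np.where(t >= 0, base + step, base)
        return LatentSession(
            time_s=t,
            true_rest_vo2=vo2,
            true_rest_vco2=0.8 * vo2,
            true_act_cost_vo2=np.zeros_like(t),
            true_act_cost_vco2=np.zeros_like(t),
            activity=np.zeros_like(t),
            config=cfg,
        )

    def test_step_response_matches_first_order_closed_form(self, quiet_config):
        cfg = quiet_config
        lat = self._latent_step(cfg)
        trace = apply_chamber_mixing(lat, cfg)
        t = trace.time_s
        pos = t > 0
        expected = 5.0 + 5.0 * (1.0 - np.exp(-t[pos] / cfg.tau_s))
        assert np.max(np.abs(trace.vo2[pos] - expected)) < 0.05  # ZOH discretization

    def test_steady_state_reached_within_five_tau(self, quiet_config):
        cfg = quiet_config
        trace = apply_chamber_mixing(self._latent_step(cfg), cfg)
        tail = trace.time_s > 5 * cfg.tau_s
        assert np.all(np.abs(trace.vo2[tail] - 10.0) / 10.0 < 0.01)

    def test_nonuniform_grid_rejected(self, quiet_config):
        lat = self._latent_step(quiet_config)
        lat.time_s[10] += 1.0
        with pytest.raises(ValueError, match="uniform"):
            apply_chamber_mixing(lat, quiet_config)

    def test_freeze_gap_is_missing_not_zero(self, short_config):
        _, trace = generate_session(None, short_config)
        gap = (trace.time_s >= 0) & (trace.time_s < short_config.freeze_gap)
        assert trace.missing[gap].all()
        assert np.isnan(trace.vo2[gap]).all()
        assert not trace.missing[~gap].any()

    def test_session_generation_is_reproducible(self, short_config):
        _, a = generate_session({"adchg": 1.0}, short_config)
        _, b = generate_session({"adchg": 1.0}, dataclasses.replace(short_config))
        np.testing.assert_array_equal(a.vo2, b.vo2)
        np.testing.assert_array_equal(a.activity, b.activity)
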