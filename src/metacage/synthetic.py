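"""Synthetic cohorts and calorimetry sessions with known ground truth.

The generator emulates a fasting-refeeding indirect-calorimetry study in
male Wistar rats: a 24-rat cohort fed a high-carbohydrate diet (HCD) for
three weeks and then a high-fat diet (HFD) for three weeks, with body
composition imaged at the start, after HCD and after HFD, and two overnight
calorimetry sessions per rat (one high-carbohydrate and one high-fat 60 kJ
test meal) during the HCD period.

Cohort level: per-rat adiposity gains under HCD and HFD are drawn from a
bivariate normal with a configurable, deliberately loose inter-diet
correlation (default 0.482); body-weight gains are coupled to the adiposity
gains at configurable Pearson strengths (defaults 0.911 under HFD, 0.525
under HCD). Visceral:subcutaneous fat ratios are lognormal around stated
medians (1.44 at start, 1.82 after HCD, 1.53 after HFD).

Session level: rats enter the chamber at 18:00 without food; the test meal
arrives at 10:00 and recording ends at 17:00. The latent resting state is an
overnight-fasted metabolism (Rest-RQ ~= 0.80) with slow random-walk drift,
a post-meal thermic-effect bump (gamma-kernel rise-decay carrying a
configurable fraction of meal energy over 300 min) and an RQ excursion
toward the diet's food quotient whose amplitude scales with the rat's
carbohydrate sensitivity. Activity is a marked point process of bursts with
a per-unit energy cost. The chamber's first-order mixing (10.5 L practical
dilution volume ventilated at 1.5 L/min, time constant 7 min) low-passes the
latent production before observation noise is added; acquisition freezes for
a configurable gap while the meal is introduced (missing records, never
zeros).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import GasTrace
from .parameters import HCD, HFD, weir_ee

__all__ = [
    "CohortConfig",
    "SessionConfig",
    "LatentSession",
    "generate_cohort",
    "generate_latent_session",
    "apply_chamber_mixing",
    "generate_session",
    "adiposity_gains",
]

_WEIR_O2 = 16.3
_WEIR_CO2 = 4.57


def _parse_clock(s: str) -> float:
    """'HH:MM' -> hours as float."""
    hh, mm = s.split(":")
    return int(hh) + int(mm) / 60.0


@dataclass
class CohortConfig:
    """Stated world of the synthetic cohort.

    Adiposity is (fat mass / body weight) * 100; gains are differences in
    percentage points between consecutive imaging sessions. Starting body
    weight matches the study cohort (303.3 g with SEM 5.0 at n=24, i.e. SD
    24.5 g). Start adiposity and the gain means/SDs are not stated by the
    source study and are set to values typical of young male Wistar rats on
    3-week diet blocks (see docs/methods.md).
    """

    n_rats: int = 24
    seed: int = 0
    start_bw_mean: float = 303.3  # g
    start_bw_sd: float = 24.5  # g  (SEM 5.0 * sqrt(24))
    start_adiposity_mean: float = 10.0  # %
    start_adiposity_sd: float = 2.5  # %
    hcd_gain_mean: float = 2.0  # percentage points of adiposity
    hcd_gain_sd: float = 1.5
    hfd_gain_mean: float = 6.0
    hfd_gain_sd: float = 2.0
    gain_correlation: float = 0.482  # HCD gain vs HFD gain
    bw_adiposity_coupling_hfd: float = 0.911  # Pearson r, BW gain vs adiposity gain
    bw_adiposity_coupling_hcd: float = 0.525
    bw_gain_hcd_mean: float = 84.0  # g over the 3-week HCD block (~4 g/day)
    bw_gain_hcd_sd: float = 15.0
    bw_gain_hfd_mean: float = 100.0
    bw_gain_hfd_sd: float = 20.0
    visc_subc_ratio_start: float = 1.44  # medians of visceral:subcutaneous fat
    visc_subc_ratio_post_hcd: float = 1.82
    visc_subc_ratio_post_hfd: float = 1.53
    visc_subc_ratio_log_sd: float = 0.22
    depot_fat_fraction: float = 0.7  # share of FM sitting in the two depots
    bw_noise_sd: float = 1.5  # g, day-to-day weighing fluctuation
    mri1_day: int = 0
    mri2_day: int = 21
    final_day: int = 42
    weigh_every_days: int = 2
    select_extremes: bool = False  # arrival screen: keep 2 leanest + 2 fattest of 8

    def validate(self) -> None:
        if self.n_rats < 4 or self.n_rats % 2:
            raise ValueError("n_rats must be even and >= 4")
        for name in (
            "start_bw_sd",
            "start_adiposity_sd",
            "hcd_gain_sd",
            "hfd_gain_sd",
            "bw_gain_hcd_sd",
            "bw_gain_hfd_sd",
            "visc_subc_ratio_log_sd",
            "bw_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "gain_correlation",
            "bw_adiposity_coupling_hfd",
            "bw_adiposity_coupling_hcd",
        ):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if not self.mri1_day < self.mri2_day < self.final_day:
            raise ValueError("imaging days must be strictly increasing")


def _coupled(rng, target: np.ndarray, r: float, mean: float, sd: float) -> np.ndarray:
    """Draw values with Pearson correlation r to ``target`` (in expectation)."""
    z = (target - target.mean()) / target.std(ddof=0)
    e = rng.standard_normal(len(target))
    e = (e - e.mean()) / e.std(ddof=0)
    # orthogonalize the noise against z so the sample r is close to target r
    e = e - z * (z @ e) / (z @ z)
    e = e / e.std(ddof=0)
    return mean + sd * (r * z + math.sqrt(max(1.0 - r * r, 0.0)) * e)


def _split_depots(fm: np.ndarray, ratio: np.ndarray, depot_frac: float):
    depot = depot_frac * fm
    visc = depot * ratio / (1.0 + ratio)
    subc = depot / (1.0 + ratio)
    return visc, subc


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a cohort table: one row per rat per day with a measurement.

    Columns: rat_id, day, bw_g, ffm_g, fm_g, fm_visc_g, fm_subc_g,
    mri_session. Composition columns are NaN on plain weighing days;
    mri_session is 1/2/3 on imaging days (3 = final composition, which in
    practice may come from dissection) and NaN otherwise. Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_rats

    if config.select_extremes:
        # arrival screen: per incoming group of 8, keep the 2 leanest and
        # 2 fattest by starting adiposity, inflating starting variability
        n_groups = n // 4
        start_ad = []
        for _ in range(n_groups):
            grp = rng.normal(config.start_adiposity_mean, config.start_adiposity_sd, 8)
            grp.sort()
            start_ad.extend([*grp[:2], *grp[-2:]])
        start_ad = np.asarray(start_ad)
    else:
        start_ad = rng.normal(config.start_adiposity_mean, config.start_adiposity_sd, n)
    start_ad = np.clip(start_ad, 1.0, 60.0)
    start_bw = np.clip(rng.normal(config.start_bw_mean, config.start_bw_sd, n), 150, None)

    rho = config.gain_correlation
    cov = np.array(
        [
            [config.hcd_gain_sd**2, rho * config.hcd_gain_sd * config.hfd_gain_sd],
            [rho * config.hcd_gain_sd * config.hfd_gain_sd, config.hfd_gain_sd**2],
        ]
    )
    try:
        np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate
        raise ValueError("gain covariance matrix is not positive definite") from exc
    gains = rng.multivariate_normal(
        [config.hcd_gain_mean, config.hfd_gain_mean], cov, size=n, method="cholesky"
    )
    hcd_gain, hfd_gain = gains[:, 0], gains[:, 1]

    bw_gain_hcd = _coupled(
        rng, hcd_gain, config.bw_adiposity_coupling_hcd,
        config.bw_gain_hcd_mean, config.bw_gain_hcd_sd,
    )
    bw_gain_hfd = _coupled(
        rng, hfd_gain, config.bw_adiposity_coupling_hfd,
        config.bw_gain_hfd_mean, config.bw_gain_hfd_sd,
    )
    bw_gain_hcd = np.clip(bw_gain_hcd, 5.0, None)
    bw_gain_hfd = np.clip(bw_gain_hfd, 5.0, None)

    bw = np.column_stack([start_bw, start_bw + bw_gain_hcd, start_bw + bw_gain_hcd + bw_gain_hfd])
    ad = np.column_stack([start_ad, start_ad + hcd_gain, start_ad + hcd_gain + hfd_gain])
    ad = np.clip(ad, 0.5, 99.0)
    fm = ad / 100.0 * bw
    ffm = bw - fm

    medians = [
        config.visc_subc_ratio_start,
        config.visc_subc_ratio_post_hcd,
        config.visc_subc_ratio_post_hfd,
    ]
    ratios = np.exp(
        np.log(medians)[None, :]
        + config.visc_subc_ratio_log_sd * rng.standard_normal((n, 3))
    )

    mri_days = [config.mri1_day, config.mri2_day, config.final_day]
    rat_ids = [f"R{i+1:02d}" for i in range(n)]
    rows = []
    for i in range(n):
        for j, day in enumerate(mri_days):
            visc, subc = _split_depots(fm[i, j], ratios[i, j], config.depot_fat_fraction)
            rows.append(
                dict(
                    rat_id=rat_ids[i],
                    day=day,
                    bw_g=bw[i, j],
                    ffm_g=ffm[i, j],
                    fm_g=fm[i, j],
                    fm_visc_g=visc,
                    fm_subc_g=subc,
                    mri_session=j + 1,
                )
            )
        # plain weighings: linear trajectory between anchors + scale noise
        for day in range(0, config.final_day + 1, config.weigh_every_days):
            if day in mri_days:
                continue
            bw_day = np.interp(day, mri_days, bw[i]) + rng.normal(0, config.bw_noise_sd)
            rows.append(
                dict(
                    rat_id=rat_ids[i],
                    day=day,
                    bw_g=bw_day,
                    ffm_g=np.nan,
                    fm_g=np.nan,
                    fm_visc_g=np.nan,
                    fm_subc_g=np.nan,
                    mri_session=np.nan,
                )
            )
    df = pd.DataFrame(rows).sort_values(["rat_id", "day"]).reset_index(drop=True)
    return df


def adiposity_gains(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-rat adiposity (and BW) gains between consecutive imaging sessions.

    Returns a frame indexed by rat_id with columns hcd_gain_pct, hfd_gain_pct
    (percentage-point changes in adiposity between MRI1->MRI2 and
    MRI2->final), bw_gain_hcd_g and bw_gain_hfd_g. ``relative=True`` is
    deliberately not offered here; see body-composition utilities for the
    relative-change variant.
    """
    mri = cohort.dropna(subset=["mri_session"]).copy()
    mri["adiposity"] = mri["fm_g"] / mri["bw_g"] * 100.0
    wide_ad = mri.pivot(index="rat_id", columns="mri_session", values="adiposity")
    wide_bw = mri.pivot(index="rat_id", columns="mri_session", values="bw_g")
    out = pd.DataFrame(
        {
            "hcd_gain_pct": wide_ad[2] - wide_ad[1],
            "hfd_gain_pct": wide_ad[3] - wide_ad[2],
            "bw_gain_hcd_g": wide_bw[2] - wide_bw[1],
            "bw_gain_hfd_g": wide_bw[3] - wide_bw[2],
        }
    )
    out.index.name = "rat_id"
    return out


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------


@dataclass
class SessionConfig:
    """Stated world of one overnight fasting-refeeding calorimetry session.

    ``rq_excursion`` is the mean Rest-RQ rise over the 0..300 min post-meal
    window for a rat of zero adiposity change; ``rq_adchg_slope`` adds to it
    per percentage point of HCD adiposity gain (the carbohydrate-sensitivity
    mechanism: defaults 0.06 + 0.0086/pp for HC meals, so sensitive rats
    peak above the HCD food quotient of 0.946, and a flat 0.035 for HF
    meals). ``tef_fraction`` of the meal energy is dissipated as a
    gamma-kernel (shape 2) rise-decay over the post-meal window.
    """

    seed: int = 0
    sampling_interval: float = 5.0  # s
    dilution_volume: float = 10.5  # L
    flow: float = 1.5  # L/min
    session_start: str = "18:00"
    meal_time: str = "10:00"
    session_end: str = "17:00"
    meal_energy: float = 60.0  # kJ
    meal_type: str = "HC"
    basal_rq: float = 0.80
    basal_ee_w_per_300g: float = 1.5  # resting EE scale at 300 g metabolic mass
    rq_excursion: float | None = None  # default by meal type
    rq_adchg_slope: float | None = None
    tef_fraction: float = 0.1
    tef_window_min: float = 300.0
    tef_kernel_shape: float = 2.0
    tef_kernel_scale_min: float = 60.0
    activity_burst_rate: float = 12.0  # events/h
    act_cost: float = 0.010  # W per arbitrary activity unit
    act_cost_postmeal_factor: float = 1.25
    act_rq_offset: float = 0.02
    burst_magnitude_median: float = 15.0  # AU, lognormal
    burst_magnitude_log_sd: float = 0.5
    burst_duration_mean_s: float = 60.0
    noise_sd_vo2: float = 0.05  # mL/min
    noise_sd_vco2: float = 0.05
    freeze_gap: float = 300.0  # s of missing data around meal delivery
    rest_ee_walk_sd: float = 2e-4  # per-sample sd of log resting EE
    rq_walk_sd: float = 5e-5  # per-sample sd of resting RQ

    def validate(self) -> None:
        if not 0.65 <= self.basal_rq <= 1.0:
            raise ValueError("basal_rq must lie in [0.65, 1.0]")
        if self.dilution_volume <= 0 or self.flow <= 0:
            raise ValueError("dilution volume and flow must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.meal_type not in ("HC", "HF"):
            raise ValueError("meal_type must be 'HC' or 'HF'")
        start, meal, end = map(
            _parse_clock, (self.session_start, self.meal_time, self.session_end)
        )
        if self.start_rel_s >= 0 or self.end_rel_s <= 0:
            raise ValueError("meal time must fall strictly inside the session")

    @property
    def tau_s(self) -> float:
        """Chamber washout time constant, seconds (V/F; 7 min at defaults)."""
        return self.dilution_volume / self.flow * 60.0

    @property
    def start_rel_s(self) -> float:
        start = _parse_clock(self.session_start)
        meal = _parse_clock(self.meal_time)
        rel_h = start - meal
        if rel_h >= 0:  # session starts the previous evening
            rel_h -= 24.0
        return rel_h * 3600.0

    @property
    def end_rel_s(self) -> float:
        return (_parse_clock(self.session_end) - _parse_clock(self.meal_time)) * 3600.0

    @property
    def diet(self):
        return HCD if self.meal_type == "HC" else HFD

    def effective_rq_rise(self, adchg: float = 0.0) -> float:
        base = self.rq_excursion
        slope = self.rq_adchg_slope
        if base is None:
            base = 0.06 if self.meal_type == "HC" else 0.035
        if slope is None:
            slope = 0.0086 if self.meal_type == "HC" else 0.0
        return base + slope * adchg


@dataclass
class LatentSession:
    """Ground-truth components on the sampling grid (time relative to meal)."""

    time_s: np.ndarray
    true_rest_vo2: np.ndarray
    true_rest_vco2: np.ndarray
    true_act_cost_vo2: np.ndarray  # mL/min per AU
    true_act_cost_vco2: np.ndarray
    activity: np.ndarray
    config: SessionConfig = field(repr=False, default=None)
    true_rest_rq: np.ndarray | None = None
    true_rest_ee_w: np.ndarray | None = None
    basal_ee_w: float = np.nan

    def __post_init__(self):
        if np.any(self.true_rest_vo2 <= 0) or np.any(self.true_rest_vco2 <= 0):
            raise ValueError("latent gas series must be strictly positive")
        if np.any(self.activity < 0):
            raise ValueError("latent activity must be non-negative")

    @property
    def total_vo2(self) -> np.ndarray:
        return self.true_rest_vo2 + self.true_act_cost_vo2 * self.activity

    @property
    def total_vco2(self) -> np.ndarray:
        return self.true_rest_vco2 + self.true_act_cost_vco2 * self.activity


def _gamma_kernel(t_s: np.ndarray, shape: float, scale_s: float) -> np.ndarray:
    """Unnormalized gamma rise-decay kernel on t >= 0 (zero before)."""
    g = np.zeros_like(t_s)
    pos = t_s > 0
    g[pos] = t_s[pos] ** (shape - 1.0) * np.exp(-t_s[pos] / scale_s)
    return g


def generate_latent_session(
    rat: dict | None, config: SessionConfig
) -> LatentSession:
    """Ground-truth resting/activity components for one session.

    ``rat`` may carry ``adchg`` (HCD adiposity gain, percentage points: the
    carbohydrate-sensitivity covariate scaling the HC-meal RQ excursion) and
    ``ffm_g``/``fm_g`` for Kleiber-type scaling of the basal rate; ``None``
    uses a reference 300 g metabolic-mass rat with adchg 0.

    The thermic-effect kernel is normalized so that its time integral over
    the 0..tef_window equals ``tef_fraction * meal_energy`` exactly (discrete
    quadrature), and the RQ kernel so that its mean over the same window is
    the configured rise. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_interval
    t = np.arange(config.start_rel_s, config.end_rel_s + 0.5 * dt, dt)
    n = len(t)

    rat = rat or {}
    adchg = float(rat.get("adchg", 0.0))
    ffm = rat.get("ffm_g")
    fm = rat.get("fm_g")
    if ffm is not None and fm is not None:
        mm = ffm + 0.2 * fm
        basal_ee = config.basal_ee_w_per_300g * (mm / 300.0) ** 0.75
    else:
        basal_ee = config.basal_ee_w_per_300g

    # slowly drifting resting state: random walks on log-EE and RQ
    log_ee = math.log(basal_ee) + np.cumsum(
        rng.normal(0.0, config.rest_ee_walk_sd, n)
    )
    rq = config.basal_rq + np.cumsum(rng.normal(0.0, config.rq_walk_sd, n))

    # post-meal thermic effect: gamma-kernel bump carrying tef_fraction of
    # the meal energy within the post-meal window
    window_s = config.tef_window_min * 60.0
    kernel = _gamma_kernel(t, config.tef_kernel_shape, config.tef_kernel_scale_min * 60.0)
    in_window = (t > 0) & (t <= window_s)
    tef_bump = np.zeros(n)
    if config.tef_fraction > 0 and in_window.any():
        mass = np.sum(kernel[in_window]) * dt  # discrete integral over window
        tef_bump = kernel * (config.tef_fraction * config.meal_energy * 1000.0 / mass)
    ee = np.exp(log_ee) + tef_bump

    # post-meal RQ excursion toward/above the diet food quotient, mean rise
    # over the window set by meal type and carbohydrate sensitivity
    rq_exc = np.zeros(n)
    rise = config.effective_rq_rise(adchg)
    if rise != 0 and in_window.any():
        rq_exc = kernel * (rise / np.mean(kernel[in_window]))
    rq = np.clip(rq + rq_exc, 0.65, 1.0)

    # invert the Weir form so that Weir(vo2, vco2) == ee exactly
    rest_vo2 = 60.0 * ee / (_WEIR_O2 + _WEIR_CO2 * rq)
    rest_vco2 = rq * rest_vo2

    # activity: marked point process of bursts (exponential inter-event
    # times, lognormal magnitudes, exponential durations)
    activity = np.zeros(n)
    if config.activity_burst_rate > 0:
        duration_h = (t[-1] - t[0]) / 3600.0
        n_events = rng.poisson(config.activity_burst_rate * duration_h)
        starts = rng.uniform(t[0], t[-1], n_events)
        durations = rng.exponential(config.burst_duration_mean_s, n_events)
        magnitudes = config.burst_magnitude_median * np.exp(
            rng.normal(0.0, config.burst_magnitude_log_sd, n_events)
        )
        for s0, d, m in zip(starts, durations, magnitudes):
            i0 = int(np.searchsorted(t, s0))
            i1 = int(np.searchsorted(t, s0 + d))
            activity[i0:i1] += m

    # energy cost of activity; muscles burn a mix close to (slightly above)
    # the resting mix, and the cost rises after feeding
    act_rq = np.clip(rq + config.act_rq_offset, 0.65, 1.0)
    cost_w = np.where(t > 0, config.act_cost * config.act_cost_postmeal_factor, config.act_cost)
    cost_vo2 = 60.0 * cost_w / (_WEIR_O2 + _WEIR_CO2 * act_rq)
    cost_vco2 = act_rq * cost_vo2

    return LatentSession(
        time_s=t,
        true_rest_vo2=rest_vo2,
        true_rest_vco2=rest_vco2,
        true_act_cost_vo2=cost_vo2,
        true_act_cost_vco2=cost_vco2,
        activity=activity,
        config=config,
        true_rest_rq=rq,
        true_rest_ee_w=ee,
        basal_ee_w=basal_ee,
    )


def apply_chamber_mixing(latent: LatentSession, config: SessionConfig) -> GasTrace:
    """Pass latent gas production through the chamber and the analyzers.

    The measured series is the first-order low-pass response of total latent
    production (rest + cost * activity) with time constant tau = dilution
    volume / flow, discretized exactly under a zero-order hold, plus additive
    Gaussian analyzer noise. Samples within ``freeze_gap`` seconds after meal
    delivery are marked missing (the acquisition freeze while the meal is
    introduced).
    """
    t = latent.time_s
    dt = np.diff(t)
    if len(dt) and not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
        raise ValueError("sampling grid is not uniform")
    step = float(dt[0]) if len(dt) else config.sampling_interval
    decay = math.exp(-step / config.tau_s)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    out = {}
    for name, u, sd in (
        ("vo2", latent.total_vo2, config.noise_sd_vo2),
        ("vco2", latent.total_vco2, config.noise_sd_vco2),
    ):
        m = np.empty_like(u)
        m[0] = u[0]  # chamber equilibrated at entry
        for k in range(1, len(u)):
            m[k] = u[k - 1] + (m[k - 1] - u[k - 1]) * decay
        if sd > 0:
            m = m + rng.normal(0.0, sd, len(m))
        out[name] = m

    missing = np.zeros(len(t), dtype=bool)
    if config.freeze_gap > 0:
        missing = (t >= 0) & (t < config.freeze_gap)
    vo2 = out["vo2"].copy()
    vco2 = out["vco2"].copy()
    vo2[missing] = np.nan
    vco2[missing] = np.nan
    return GasTrace(time_s=t, vo2=vo2, vco2=vco2, activity=latent.activity, missing=missing)


def generate_session(rat: dict | None, config: SessionConfig) -> tuple[LatentSession, GasTrace]:
    """Convenience: latent ground truth plus its measured trace."""
    latent = generate_latent_session(rat, config)
    return latent, apply_chamber_mixing(latent, config)
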