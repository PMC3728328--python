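"""Decomposition of metabolic-cage gas-exchange traces into resting and
activity-specific components.

Two stages. First, washout correction inverts the first-order mixing of the
respirometry chamber (time constant tau = dilution volume / flow) so that the
corrected trace tracks the animal's instantaneous gas production rather than
the analyzer's lagged view of it. Second, a linear-Gaussian state-space model
separates the corrected VO2/VCO2 into a slowly drifting resting component and
a per-activity-unit cost component:

    state   x(k) = [rest(k), cost(k)]           (random walk)
    obs     y(k) = rest(k) + cost(k) * a(k) + e(k)

where a(k) is the measured spontaneous activity. The VO2 and VCO2 channels
share the activity regressor but are otherwise independent, so the four-state
problem factorizes into two two-state filters. A forward Kalman pass followed
by fixed-interval (RTS) smoothing is the default; a causal filter-only mode
is available. Resting RQ, activity RQ, resting energy expenditure and the
energy cost of activity are then derived per sample, and the series are
reduced to meal-anchored time bins for statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import substrate_oxidation, weir_ee

__all__ = [
    "GasTrace",
    "DecomposedTrace",
    "washout_correct",
    "kalman_decompose",
    "derive_components",
    "bin_trace",
    "decompose_trace",
]

# numerical floors applied after smoothing: resting gas rates must stay
# physically positive; cost states may sit at zero when no activity occurs
_REST_FLOOR = 1e-3  # mL/min
_COST_FLOOR = 0.0


@dataclass
class GasTrace:
    """Uniformly sampled gas-exchange record from one calorimetry session.

    ``time_s`` is relative to meal delivery (negative = fasted, pre-meal).
    Missing samples (e.g. the acquisition freeze while the test meal is
    introduced) carry NaN gas values and ``missing=True`` — never zeros.
    """

    time_s: np.ndarray
    vo2: np.ndarray  # mL/min
    vco2: np.ndarray  # mL/min
    activity: np.ndarray  # arbitrary units, >= 0
    missing: np.ndarray = field(default=None)  # bool

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.missing is None:
            self.missing = np.isnan(self.vo2) | np.isnan(self.vco2)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = len(self.time_s)
        for name in ("vo2", "vco2", "activity", "missing"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time axis")
        if n >= 2:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
                raise ValueError("sampling grid is not uniform")
        if np.any(self.activity[~np.isnan(self.activity)] < 0):
            raise ValueError("activity must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class DecomposedTrace:
    """Per-sample resting and activity-specific components with uncertainty."""

    time_s: np.ndarray
    rest_vo2: np.ndarray
    rest_vco2: np.ndarray
    cost_vo2: np.ndarray  # mL/min per activity unit
    cost_vco2: np.ndarray
    rest_vo2_var: np.ndarray
    rest_vco2_var: np.ndarray
    cost_vo2_var: np.ndarray
    cost_vco2_var: np.ndarray
    activity: np.ndarray
    missing: np.ndarray
    cost_identifiable: bool = True
    # derived series, filled by derive_components
    rest_rq: np.ndarray | None = None
    act_rq: np.ndarray | None = None
    ree_w: np.ndarray | None = None
    act_ee_w: np.ndarray | None = None
    act_cost_w_per_au: np.ndarray | None = None
    rest_gox_w: np.ndarray | None = None
    rest_lox_w: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time_s": self.time_s,
            "rest_vo2": self.rest_vo2,
            "rest_vco2": self.rest_vco2,
            "cost_vo2": self.cost_vo2,
            "cost_vco2": self.cost_vco2,
            "activity_au": self.activity,
            "missing_flag": self.missing.astype(int),
        }
        for name in (
            "rest_rq",
            "act_rq",
            "ree_w",
            "act_ee_w",
            "act_cost_w_per_au",
            "rest_gox_w",
            "rest_lox_w",
        ):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# washout correction
# ---------------------------------------------------------------------------


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    # nearest-edge padding keeps constant traces exactly constant at the ends
    return uniform_filter1d(y, size=width, mode="nearest")


def washout_correct(trace: GasTrace, tau_s: float, smooth_s: float = 30.0) -> GasTrace:
    """Invert the chamber's first-order mixing: returns m(t) + tau * dm/dt.

    The derivative is taken on a ``smooth_s`` moving-average copy to keep the
    amplified sample noise bounded. Samples within one smoothing width of a
    missing gap are also marked missing (guard band), because the smoothed
    derivative there mixes in interpolated values.
    """
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    dt = trace.dt
    width = max(int(round(smooth_s / dt)), 1)
    if len(trace) < 2 * width:
        raise ValueError("trace shorter than the smoothing window")

    t = trace.time_s
    missing = trace.missing.copy()
    out = {}
    for name in ("vo2", "vco2"):
        y = getattr(trace, name).astype(float).copy()
        valid = ~missing & ~np.isnan(y)
        if valid.sum() < 2:
            raise ValueError("not enough valid samples to correct")
        # interpolate through gaps for the smoothing/derivative only
        y_filled = np.interp(t, t[valid], y[valid])
        y_smooth = _moving_average(y_filled, width)
        dy = np.gradient(y_smooth, dt)
        out[name] = y_filled + tau_s * dy

    # guard band: one smoothing width on each side of any missing sample
    if missing.any():
        idx = np.flatnonzero(missing)
        guard = np.zeros(len(t), dtype=bool)
        for i in idx:
            guard[max(0, i - width) : i + width + 1] = True
        missing = missing | guard
    for name in ("vo2", "vco2"):
        out[name][missing] = np.nan

    return GasTrace(
        time_s=t,
        vo2=out["vo2"],
        vco2=out["vco2"],
        activity=trace.activity.copy(),
        missing=missing,
    )


# ---------------------------------------------------------------------------
# Kalman filter / RTS smoother (2-state, scalar observation)
# ---------------------------------------------------------------------------


def _kf_forward(y, a, valid, q1, q2, r, m1_0, m2_0, p1_0, p2_0):
    n = len(y)
    m = np.empty((n, 2))
    P = np.empty((n, 3))  # P11, P12, P22
    m1, m2 = m1_0, m2_0
    p11, p12, p22 = p1_0, 0.0, p2_0
    for k in range(n):
        # predict (F = I)
        p11 += q1
        p22 += q2
        if valid[k]:
            ak = a[k]
            s = p11 + 2.0 * ak * p12 + ak * ak * p22 + r
            k1 = (p11 + ak * p12) / s
            k2 = (p12 + ak * p22) / s
            resid = y[k] - (m1 + ak * m2)
            m1 += k1 * resid
            m2 += k2 * resid
            h1 = p11 + ak * p12
            h2 = p12 + ak * p22
            p11 -= k1 * h1
            p12 -= k1 * h2
            p22 -= k2 * h2
        m[k, 0] = m1
        m[k, 1] = m2
        P[k, 0] = p11
        P[k, 1] = p12
        P[k, 2] = p22
    return m, P


def _rts_backward(m_f, P_f, q1, q2):
    n = m_f.shape[0]
    m_s = m_f.copy()
    P_s = P_f.copy()
    for k in range(n - 2, -1, -1):
        p11, p12, p22 = P_f[k, 0], P_f[k, 1], P_f[k, 2]
        # predicted covariance at k+1 (F = I): P_f[k] + Q
        a11 = p11 + q1
        a12 = p12
        a22 = p22 + q2
        det = a11 * a22 - a12 * a12
        if det <= 0:
            continue
        # C = P_f[k] @ inv(P_pred)
        c11 = (p11 * a22 - p12 * a12) / det
        c12 = (-p11 * a12 + p12 * a11) / det
        c21 = (p12 * a22 - p22 * a12) / det
        c22 = (-p12 * a12 + p22 * a11) / det
        dm1 = m_s[k + 1, 0] - m_f[k, 0]
        dm2 = m_s[k + 1, 1] - m_f[k, 1]
        m_s[k, 0] = m_f[k, 0] + c11 * dm1 + c12 * dm2
        m_s[k, 1] = m_f[k, 1] + c21 * dm1 + c22 * dm2
        # P_s[k] = P_f[k] + C (P_s[k+1] - P_pred) C'
        d11 = P_s[k + 1, 0] - a11
        d12 = P_s[k + 1, 1] - a12
        d22 = P_s[k + 1, 2] - a22
        e11 = c11 * d11 + c12 * d12
        e12 = c11 * d12 + c12 * d22
        e21 = c21 * d11 + c22 * d12
        e22 = c21 * d12 + c22 * d22
        P_s[k, 0] = p11 + e11 * c11 + e12 * c12
        P_s[k, 1] = p12 + e11 * c21 + e12 * c22
        P_s[k, 2] = p22 + e21 * c21 + e22 * c22
    return m_s, P_s


try:  # pragma: no cover - jit is a speed-up, not behavior
    from numba import njit

    _kf_forward = njit(cache=False)(_kf_forward)
    _rts_backward = njit(cache=False)(_rts_backward)
except Exception:  # pragma: no cover
    pass


def _estimate_obs_noise(y: np.ndarray, valid: np.ndarray, dt: float) -> float:
    """Robust observation-noise scale from the first 10 valid minutes.

    Residuals against a 30-s moving average, scaled by 1.4826 * MAD.
    """
    n10 = int(round(600.0 / dt))
    yy = y[valid][:n10]
    if len(yy) < 10:
        raise ValueError("not enough valid samples to estimate noise")
    width = max(int(round(30.0 / dt)), 1)
    resid = yy - _moving_average(yy, width)
    # trim convolution edges
    resid = resid[width:-width] if len(resid) > 2 * width else resid
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    return max(float(sigma), 1e-4)


def kalman_decompose(
    trace: GasTrace,
    q_rest: float = 0.01,
    q_cost: float = 0.001,
    obs_noise_vo2: float | None = None,
    obs_noise_vco2: float | None = None,
    smooth: bool = True,
) -> DecomposedTrace:
    """Estimate resting and per-activity-unit gas-exchange components.

    ``q_rest`` / ``q_cost`` are random-walk standard deviations per sample
    (mL/min and mL/min/AU): the resting level drifts slowly, the activity
    cost is near-constant on the session timescale. Observation noise is
    estimated per channel from the first 10 valid minutes (robust MAD of
    residuals) unless given. Rest states initialize at the median of the
    first 10 minutes, cost states at zero with a wide prior. Missing samples
    are predicted through without update, so their variance inflates.

    With ``smooth=True`` (default) a fixed-interval RTS pass follows the
    forward filter; ``smooth=False`` gives the causal filter-only estimate.
    """
    valid = ~trace.missing & ~np.isnan(trace.vo2) & ~np.isnan(trace.vco2)
    if not valid.any():
        raise ValueError("trace has no valid samples")
    a = np.where(np.isnan(trace.activity), 0.0, trace.activity)
    act_seen = a[valid]
    identifiable = bool(np.any(act_seen > 0))
    if not identifiable:
        warnings.warn(
            "activity is identically zero: activity-cost states are not "
            "identifiable and remain at their prior",
            RuntimeWarning,
            stacklevel=2,
        )

    dt = trace.dt
    n10 = int(round(600.0 / dt))
    results = {}
    for name, noise in (("vo2", obs_noise_vo2), ("vco2", obs_noise_vco2)):
        y = np.where(valid, getattr(trace, name), 0.0)
        sigma = noise if noise is not None else _estimate_obs_noise(
            getattr(trace, name), valid, dt
        )
        m0 = float(np.median(getattr(trace, name)[valid][:n10]))
        m_f, P_f = _kf_forward(
            y.astype(float),
            a.astype(float),
            valid,
            q_rest**2,
            q_cost**2,
            sigma**2,
            m0,
            0.0,
            4.0,  # (2 mL/min)^2 prior on rest
            1.0,  # wide prior on cost
        )
        if smooth:
            m_f, P_f = _rts_backward(m_f, P_f, q_rest**2, q_cost**2)
        rest = np.maximum(m_f[:, 0], _REST_FLOOR)
        cost = np.maximum(m_f[:, 1], _COST_FLOOR)
        results[name] = (rest, cost, P_f[:, 0], P_f[:, 2])

    return DecomposedTrace(
        time_s=trace.time_s.copy(),
        rest_vo2=results["vo2"][0],
        rest_vco2=results["vco2"][0],
        cost_vo2=results["vo2"][1],
        cost_vco2=results["vco2"][1],
        rest_vo2_var=results["vo2"][2],
        rest_vco2_var=results["vco2"][2],
        cost_vo2_var=results["vo2"][3],
        cost_vco2_var=results["vco2"][3],
        activity=trace.activity.copy(),
        missing=trace.missing.copy(),
        cost_identifiable=identifiable,
    )


def derive_components(
    dt: DecomposedTrace, activity_threshold: float | None = None
) -> DecomposedTrace:
    """Fill the derived series: RQs, resting EE, activity EE and cost.

    rest_rq = rest_vco2/rest_vo2 and ree_w = Weir(rest components);
    act_cost_w_per_au = Weir(cost components), act_ee_w = Weir(cost *
    activity). Act-RQ is the ratio of the cost components and is masked
    (NaN) wherever activity falls below the threshold — by default the 5th
    percentile of nonzero activity — where the ratio is numerically
    meaningless. Resting glucose/lipid oxidation are filled alongside.
    """
    out = replace(dt)
    out.rest_rq = dt.rest_vco2 / dt.rest_vo2
    out.ree_w = weir_ee(dt.rest_vo2, dt.rest_vco2)
    cost_vo2 = np.maximum(dt.cost_vo2, 0.0)
    cost_vco2 = np.maximum(dt.cost_vco2, 0.0)
    out.act_cost_w_per_au = weir_ee(cost_vo2, cost_vco2)
    act = np.where(np.isnan(dt.activity), 0.0, dt.activity)
    out.act_ee_w = weir_ee(cost_vo2 * act, cost_vco2 * act)

    if activity_threshold is None:
        nz = act[act > 0]
        activity_threshold = float(np.percentile(nz, 5)) if len(nz) else np.inf
    act_rq = np.full(len(dt.time_s), np.nan)
    mask = (act >= activity_threshold) & (cost_vo2 > 1e-9)
    if dt.cost_identifiable:
        act_rq[mask] = cost_vco2[mask] / cost_vo2[mask]
    out.act_rq = act_rq

    gox, lox = substrate_oxidation(dt.rest_vo2, dt.rest_vco2)
    out.rest_gox_w = gox
    out.rest_lox_w = lox
    return out


def bin_trace(dt: DecomposedTrace, width_min: float = 15.0) -> pd.DataFrame:
    """Reduce a decomposed trace to meal-anchored time bins.

    Bin edges sit at multiples of ``width_min`` relative to meal delivery
    (..., -15, 0, 15, ... for the default 15-min bins). Each bin carries the
    mean of every derived series over its non-missing samples; bins with more
    than 50% missing samples are flagged.
    """
    width_s = width_min * 60.0
    if not np.isclose(width_s % dt.dt, 0.0) and not np.isclose(
        width_s % dt.dt, dt.dt
    ):
        raise ValueError("bin width must be a multiple of the sampling interval")
    frame = dt.to_frame()
    idx = np.floor(frame["time_s"] / width_s).astype(int)
    frame = frame.assign(_bin=idx)

    rows = []
    value_cols = [
        c for c in frame.columns if c not in ("time_s", "missing_flag", "_bin")
    ]
    for b, grp in frame.groupby("_bin", sort=True):
        miss_frac = float(grp["missing_flag"].mean())
        clean = grp.loc[grp["missing_flag"] == 0]
        row = {
            "bin_start_min": b * width_min,
            "bin_end_min": (b + 1) * width_min,
            "bin_mid_min": (b + 0.5) * width_min,
            "n_samples": len(grp),
            "frac_missing": miss_frac,
            "flagged": miss_frac > 0.5,
        }
        for c in value_cols:
            row[c] = float(clean[c].mean()) if len(clean) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def decompose_trace(
    trace: GasTrace,
    tau_s: float,
    bin_min: float = 15.0,
    smooth: bool = True,
    **kalman_kwargs,
) -> tuple[DecomposedTrace, pd.DataFrame]:
    """Full chain: washout correction -> Kalman -> derived series -> bins."""
    corrected = washout_correct(trace, tau_s)
    dec = kalman_decompose(corrected, smooth=smooth, **kalman_kwargs)
    dec = derive_components(dec)
    return dec, bin_trace(dec, bin_min)
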