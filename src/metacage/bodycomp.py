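"""Body-composition bookkeeping: adiposity trajectories, sensitivity
classification and fat-distribution statistics.

Composition enters as tabular per-rat values (fat mass, fat-free mass and
the visceral/subcutaneous split) at up to three imaging sessions; only the
MRI volume-to-mass conversion (0.9 g/cm3 adipose density) is implemented
here, not any image processing. Because calorimetry sessions fall between
imaging days, FFM and FM are linearly interpolated to the session day, and
the interpolation is validated by regressing predicted body weight
(FFM + FM) on the weight actually measured on those days.

Rats are classified carbohydrate-resistant/sensitive (CR/CS) and
fat-resistant/sensitive (FR/FS) by independent median splits of their
adiposity gains under the high-carbohydrate and high-fat diet blocks;
the labels are descriptive, the underlying gains stay continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ADIPOSE_DENSITY_G_CM3",
    "fm_from_volume",
    "adiposity_pct",
    "interpolate_composition",
    "validate_interpolation",
    "InterpolationValidation",
    "classify_cohort",
    "classification_table",
    "fat_distribution_stats",
]

ADIPOSE_DENSITY_G_CM3 = 0.9


def fm_from_volume(volume_cm3):
    """Fat mass (g) from segmented adipose volume (cm3) at 0.9 g/cm3."""
    v = np.asarray(volume_cm3, dtype=float)
    if np.any(v < 0):
        raise ValueError("adipose volume must be non-negative")
    out = ADIPOSE_DENSITY_G_CM3 * v
    return float(out) if out.ndim == 0 else out


def adiposity_pct(fm_g, bw_g):
    """Adiposity = (body fat / body weight) * 100."""
    return np.asarray(fm_g, dtype=float) / np.asarray(bw_g, dtype=float) * 100.0


def _imaging_rows(cohort: pd.DataFrame, rat_id: str) -> pd.DataFrame:
    rows = cohort.loc[
        (cohort["rat_id"] == rat_id) & cohort["mri_session"].notna()
    ].sort_values("day")
    if len(rows) < 2:
        raise ValueError(f"rat {rat_id} has fewer than two imaging sessions")
    return rows


def interpolate_composition(
    cohort: pd.DataFrame, rat_id: str, day: float
) -> tuple[float, float]:
    """Linearly interpolate (FFM, FM) to ``day`` between MRI1 and MRI2.

    FFM and FM are interpolated independently on the assumption that both
    evolve linearly over the short MRI1-MRI2 interval. Days outside
    [MRI1, MRI2] raise: composition is never extrapolated past MRI2.
    """
    rows = _imaging_rows(cohort, rat_id)
    d1, d2 = float(rows["day"].iloc[0]), float(rows["day"].iloc[1])
    if not d1 <= day <= d2:
        raise ValueError(f"day {day} outside the MRI1-MRI2 bracket [{d1}, {d2}]")
    w = 0.0 if d2 == d1 else (day - d1) / (d2 - d1)
    ffm = (1 - w) * rows["ffm_g"].iloc[0] + w * rows["ffm_g"].iloc[1]
    fm = (1 - w) * rows["fm_g"].iloc[0] + w * rows["fm_g"].iloc[1]
    return float(ffm), float(fm)


@dataclass(frozen=True)
class InterpolationValidation:
    slope: float
    slope_se: float
    r_squared: float
    n: int


def validate_interpolation(
    cohort: pd.DataFrame, calorimetry_days: dict[str, list[float]]
) -> InterpolationValidation:
    """Regress interpolated body weight on measured body weight.

    For every rat-day in ``calorimetry_days``, predicted BW = interpolated
    FFM + FM; measured BW is the weighing recorded on (or nearest to) that
    day. Returns the OLS slope with its SE and the R squared; a slope near 1
    with R2 near 1 certifies the linear-evolution assumption.
    """
    predicted, measured = [], []
    for rat_id, days in calorimetry_days.items():
        rat_rows = cohort.loc[cohort["rat_id"] == rat_id]
        for day in days:
            ffm, fm = interpolate_composition(cohort, rat_id, day)
            predicted.append(ffm + fm)
            exact = rat_rows.loc[rat_rows["day"] == day, "bw_g"]
            if len(exact):
                measured.append(float(exact.iloc[0]))
            else:
                nearest = rat_rows.iloc[(rat_rows["day"] - day).abs().argsort()]
                measured.append(float(nearest["bw_g"].iloc[0]))
    if len(predicted) < 3:
        raise ValueError("need at least 3 rat-days to validate interpolation")
    res = stats.linregress(measured, predicted)
    return InterpolationValidation(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n=len(predicted),
    )


def classify_cohort(gains: pd.Series, labels: tuple[str, str] = ("resistant", "sensitive")) -> pd.Series:
    """Median-split a per-rat gain series into exactly n/2 + n/2 classes.

    The lower half of gainers is labelled ``labels[0]`` (resistant), the
    upper half ``labels[1]`` (sensitive). The cohort size must be even. Ties
    straddling the median are broken by stable input order with a warning.
    The split is invariant under any strictly increasing transform of the
    gains.
    """
    n = len(gains)
    if n % 2:
        raise ValueError("cohort size must be even for a median split")
    order = np.argsort(gains.to_numpy(), kind="stable")
    half = n // 2
    vals = gains.to_numpy()[order]
    if half > 0 and vals[half - 1] == vals[half]:
        warnings.warn(
            "gains tie across the median; split resolved by stable input order",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.empty(n, dtype=object)
    out[order[:half]] = labels[0]
    out[order[half:]] = labels[1]
    return pd.Series(out, index=gains.index, name="class")


def classification_table(gains: pd.DataFrame) -> pd.DataFrame:
    """CR/CS and FR/FS labels from per-rat HCD and HFD adiposity gains.

    ``gains`` is the frame from :func:`metacage.synthetic.adiposity_gains`
    (columns hcd_gain_pct, hfd_gain_pct, indexed by rat_id). The two splits
    are independent, so the four cross-classes need not be balanced.
    """
    out = gains[["hcd_gain_pct", "hfd_gain_pct"]].copy()
    out["class_hcd"] = classify_cohort(gains["hcd_gain_pct"], ("CR", "CS"))
    out["class_hfd"] = classify_cohort(gains["hfd_gain_pct"], ("FR", "FS"))
    return out


def fat_distribution_stats(cohort: pd.DataFrame) -> dict:
    """Visceral:subcutaneous ratio summaries and paired shift tests.

    Per imaging session: the median ratio and half the interquartile range
    (quartiles by linear interpolation). Between every pair of sessions with
    complete pairing: a two-sided Wilcoxon signed-rank test. Identical paired
    samples give p = 1 (no shift). Unpaired records raise.
    """
    mri = cohort.dropna(subset=["mri_session"]).copy()
    mri["ratio"] = mri["fm_visc_g"] / mri["fm_subc_g"]
    wide = mri.pivot(index="rat_id", columns="mri_session", values="ratio")
    sessions = sorted(wide.columns)
    if len(sessions) < 2:
        raise ValueError("need paired ratios at >= 2 imaging sessions")
    if wide[sessions].isna().any().any():
        raise ValueError("visceral:subcutaneous ratios are not fully paired")

    summary = {}
    for s in sessions:
        vals = wide[s].to_numpy()
        q1, q3 = np.percentile(vals, [25, 75])  # linear-interp quartiles
        summary[int(s)] = {
            "median": float(np.median(vals)),
            "half_iqr": float((q3 - q1) / 2.0),
            "n": len(vals),
        }

    tests = {}
    for i, s1 in enumerate(sessions):
        for s2 in sessions[i + 1 :]:
            d = wide[s2].to_numpy() - wide[s1].to_numpy()
            if np.allclose(d, 0.0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(d, alternative="two-sided").pvalue)
            tests[(int(s1), int(s2))] = p
    return {"summary": summary, "wilcoxon_p": tests}
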