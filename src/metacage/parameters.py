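"""Session-level metabolic parameters from decomposed, binned gas-exchange traces.

Converts resting/activity gas-exchange components into the physiological
quantities of a fasting-refeeding protocol: energy expenditure by the Weir
equation, whole-body glucose and lipid oxidation, basal metabolic rate from
the pre-meal window, the thermic effect of feeding (TEF) as the post-meal
area under the resting-metabolic-rate curve above basal, metabolic-mass
normalization, and diet energetics (energy density, food quotient, test-meal
mass).

Units: gas rates in mL/min, energy rates in Watts, energies in kJ, masses in
g, times in minutes relative to meal delivery unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "weir_ee",
    "substrate_oxidation",
    "compute_bmr",
    "compute_tef",
    "normalize_to_metabolic_mass",
    "DietSpec",
    "diet_metrics",
    "SessionSummary",
    "summarize_session",
    "HCD",
    "HFD",
    "HCD_LABEL_ENERGY_DENSITY_KJ_G",
    "HFD_LABEL_ENERGY_DENSITY_KJ_G",
    "PRE_MEAL_WINDOW_MIN",
    "POST_MEAL_WINDOW_MIN",
]

# Analysis windows, minutes relative to meal delivery.
PRE_MEAL_WINDOW_MIN = (-120.0, 0.0)
POST_MEAL_WINDOW_MIN = (0.0, 300.0)

# Weir coefficients for VO2/VCO2 in mL/min -> Watts.
_WEIR_O2 = 16.3
_WEIR_CO2 = 4.57

# Metabolizable energy densities, kJ/g.
_KJ_PER_G_CARB = 16.7
_KJ_PER_G_PROTEIN = 16.7
_KJ_PER_G_FAT = 37.7

# Food-quotient weights per macronutrient energy fraction.
_FQ_CARB = 1.0
_FQ_PROTEIN = 0.825
_FQ_FAT = 0.7

# Energy densities as printed on the diet labels (kJ/g). These differ in the
# third significant figure from the values recomputed from the g/kg recipe
# (15.92 / 19.80) and are retained for meal-mass bookkeeping so that a 60 kJ
# high-fat test meal weighs the nominal 3.0 g.
HCD_LABEL_ENERGY_DENSITY_KJ_G = 15.95
HFD_LABEL_ENERGY_DENSITY_KJ_G = 19.82


def weir_ee(vo2, vco2):
    """Energy expenditure in Watts from the abbreviated Weir equation.

    ``EE = (16.3 * VO2 + 4.57 * VCO2) / 60`` with gas rates in mL/min.
    Accepts scalars or arrays; raises on negative inputs.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas exchange rates must be non-negative")
    out = (_WEIR_O2 * vo2 + _WEIR_CO2 * vco2) / 60.0
    return float(out) if out.ndim == 0 else out


def substrate_oxidation(rest_vo2, rest_vco2):
    """Whole-body glucose and lipid oxidation rates (Watts) from resting gases.

    Gox = ((4.57*VCO2 - 3.23*VO2) * 15.6) / 60
    Lox = ((1.69*VO2 - 1.69*VCO2) * 39.5) / 60

    with VO2/VCO2 in mL/min; 15.6 and 39.5 kJ/g are the energy densities of
    glucose and lipid. Values may be negative when the resting RQ leaves the
    pure-oxidation range; they are returned as-is (net rates).
    """
    vo2 = np.asarray(rest_vo2, dtype=float)
    vco2 = np.asarray(rest_vco2, dtype=float)
    gox = (4.57 * vco2 - 3.23 * vo2) * 15.6 / 60.0
    lox = (1.69 * vo2 - 1.69 * vco2) * 39.5 / 60.0
    if gox.ndim == 0:
        return float(gox), float(lox)
    return gox, lox


def _window_bins(binned: pd.DataFrame, window: tuple[float, float]) -> pd.DataFrame:
    lo, hi = window
    sel = (binned["bin_start_min"] >= lo) & (binned["bin_end_min"] <= hi)
    return binned.loc[sel]


def compute_bmr(
    binned: pd.DataFrame,
    column: str = "ree_w",
    window: tuple[float, float] = PRE_MEAL_WINDOW_MIN,
    min_bins: int = 4,
) -> float:
    """Basal metabolic rate: mean of clean-bin RMR over the pre-meal window.

    In the overnight-fasted state near thermoneutrality the resting metabolic
    rate over the final two pre-meal hours approximates BMR. Bins flagged for
    missing data are excluded; fewer than ``min_bins`` clean bins is an error.
    """
    win = _window_bins(binned, window)
    clean = win.loc[~win["flagged"]]
    if len(clean) < min_bins:
        raise ValueError(
            f"only {len(clean)} clean bins in window {window}; need >= {min_bins}"
        )
    return float(clean[column].mean())


def compute_tef(
    binned: pd.DataFrame,
    bmr_w: float,
    meal_energy_kj: float = 60.0,
    column: str = "ree_w",
    window: tuple[float, float] = POST_MEAL_WINDOW_MIN,
) -> tuple[float, float]:
    """Thermic effect of feeding: net post-meal AUC of (RMR - BMR), in kJ.

    Integrates the resting-rate excess over basal across the post-meal window
    by the trapezoidal rule on clean-bin means placed at bin midpoints, with
    the first/last clean values held flat out to the window edges. Negative
    excursions subtract (net AUC). TEF is always computed from absolute,
    un-normalized rates. Returns ``(tef_kj, tef_pct_of_meal)``.
    """
    win = _window_bins(binned, window)
    if len(win) == 0:
        raise ValueError(f"no bins in post-meal window {window}")
    clean = win.loc[~win["flagged"]]
    if len(clean) <= 0.5 * len(win):
        raise ValueError("more than half of the post-meal bins are flagged missing")
    t_min = clean["bin_mid_min"].to_numpy(dtype=float)
    excess_w = clean[column].to_numpy(dtype=float) - bmr_w
    # hold edge values to the window bounds so a constant excess integrates
    # over the full window
    t = np.concatenate(([window[0]], t_min, [window[1]]))
    y = np.concatenate(([excess_w[0]], excess_w, [excess_w[-1]]))
    auc_ws = np.trapezoid(y, t * 60.0)  # Watts * seconds = Joules
    tef_kj = float(auc_ws / 1000.0)
    return tef_kj, 100.0 * tef_kj / meal_energy_kj


def normalize_to_metabolic_mass(value_w: float, ffm_g: float, fm_g: float) -> float:
    """Scale an energy rate to a standard 300 g of metabolic mass.

    Metabolic mass is FFM + 0.2*FM; rates are stated per 300 g to give
    magnitudes comparable to a whole rat. Only BMR/RMR-like quantities are
    ever normalized; TEF, RQs and activity cost are not.
    """
    mm = ffm_g + 0.2 * fm_g
    if not mm > 0:
        raise ValueError("metabolic mass must be positive")
    return value_w * 300.0 / mm


@dataclass(frozen=True)
class DietSpec:
    """Composition of a synthetic diet, g per kg of feed.

    Energy fractions, energy density and food quotient are derived from the
    macronutrient masses with 16.7 kJ/g for carbohydrate (starch + sucrose)
    and protein and 37.7 kJ/g for fat; minerals, vitamins, cellulose and
    choline carry no metabolizable energy. ``from_energy_fractions`` builds a
    spec directly from label energy percentages instead.
    """

    name: str
    protein_g: float = 0.0
    starch_g: float = 0.0
    sucrose_g: float = 0.0
    oil_g: float = 0.0
    minerals_g: float = 0.0
    vitamins_g: float = 0.0
    cellulose_g: float = 0.0
    choline_g: float = 0.0
    # optional override: energy fractions given directly (label values)
    _fractions: tuple[float, float, float] | None = None  # carb, protein, fat
    label_energy_density_kj_g: float | None = None

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_g") and isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        fq = self.food_quotient
        if not 0.7 <= fq <= 1.0:
            raise ValueError(f"food quotient {fq:.3f} outside [0.7, 1.0]")

    @classmethod
    def from_energy_fractions(
        cls, name: str, carbohydrate: float, protein: float, fat: float, **kw
    ) -> "DietSpec":
        # label percentages are rounded to 0.1%, so allow their sum to miss
        # 1 by rounding; fractions are used exactly as given
        total = carbohydrate + protein + fat
        if not math.isclose(total, 1.0, abs_tol=2e-3):
            raise ValueError("energy fractions must sum to 1 (within label rounding)")
        return cls(name=name, _fractions=(carbohydrate, protein, fat), **kw)

    @property
    def carbohydrate_g(self) -> float:
        return self.starch_g + self.sucrose_g

    @property
    def energy_per_kg_kj(self) -> float:
        return (
            self.carbohydrate_g * _KJ_PER_G_CARB
            + self.protein_g * _KJ_PER_G_PROTEIN
            + self.oil_g * _KJ_PER_G_FAT
        )

    @property
    def energy_density_kj_g(self) -> float:
        if self._fractions is not None and self.label_energy_density_kj_g is not None:
            return self.label_energy_density_kj_g
        return self.energy_per_kg_kj / 1000.0

    @property
    def energy_fractions(self) -> tuple[float, float, float]:
        """(carbohydrate, protein, fat) fractions of metabolizable energy."""
        if self._fractions is not None:
            return self._fractions
        tot = self.energy_per_kg_kj
        if tot <= 0:
            raise ValueError("diet has no metabolizable energy")
        return (
            self.carbohydrate_g * _KJ_PER_G_CARB / tot,
            self.protein_g * _KJ_PER_G_PROTEIN / tot,
            self.oil_g * _KJ_PER_G_FAT / tot,
        )

    @property
    def food_quotient(self) -> float:
        """RQ the diet would produce if fully oxidized.

        Energy-fraction weighted sum with weights 1.0 (carbohydrate),
        0.825 (protein) and 0.7 (fat).
        """
        carb, prot, fat = self.energy_fractions
        return _FQ_CARB * carb + _FQ_PROTEIN * prot + _FQ_FAT * fat

    @property
    def computed_energy_density_kj_g(self) -> float:
        """Energy density recomputed from the g/kg recipe, ignoring any label
        override (differs from label values in the third significant figure)."""
        return self.energy_per_kg_kj / 1000.0

    @property
    def computed_food_quotient(self) -> float:
        """Food quotient recomputed from the g/kg recipe, ignoring any label
        energy-fraction override."""
        tot = self.energy_per_kg_kj
        if tot <= 0:
            raise ValueError("diet has no metabolizable energy")
        carb = self.carbohydrate_g * _KJ_PER_G_CARB / tot
        prot = self.protein_g * _KJ_PER_G_PROTEIN / tot
        fat = self.oil_g * _KJ_PER_G_FAT / tot
        return _FQ_CARB * carb + _FQ_PROTEIN * prot + _FQ_FAT * fat

    def meal_mass_g(self, energy_kj: float, density_kj_g: float | None = None) -> float:
        """Mass of a test meal delivering ``energy_kj``, rounded to 0.1 g."""
        d = density_kj_g if density_kj_g is not None else self.energy_density_kj_g
        return round(energy_kj / d, 1)


def diet_metrics(diet: DietSpec, meal_energy_kj: float = 60.0) -> dict:
    """Energy density, food quotient and test-meal mass for a diet.

    When the diet has a g/kg recipe, the recomputed density/FQ are reported
    alongside the label values so the last-digit disagreement stays visible.
    """
    out = {
        "name": diet.name,
        "energy_density_kj_g": diet.energy_density_kj_g,
        "food_quotient": diet.food_quotient,
        "meal_energy_kj": meal_energy_kj,
        "meal_mass_g": diet.meal_mass_g(meal_energy_kj),
    }
    if diet.energy_per_kg_kj > 0:
        out["computed_energy_density_kj_g"] = diet.computed_energy_density_kj_g
        out["computed_food_quotient"] = diet.computed_food_quotient
    return out


# The two synthetic study diets (g/kg). The high-carbohydrate diet (HCD) is a
# starch-based AIN93-like maintenance diet; the high-fat diet (HFD) swaps
# carbohydrate energy for soy oil at matched protein fraction. Both carry the
# label energy fractions and densities alongside the recipe; recomputing from
# the g/kg masses gives densities 15.92/19.80 kJ/g and FQs 0.946/0.846, i.e.
# the labels disagree in the last printed digit (see computed_* properties).
HCD = DietSpec(
    name="HCD",
    protein_g=140.0,
    starch_g=622.4,
    sucrose_g=100.3,
    oil_g=40.0,
    minerals_g=35.0,
    vitamins_g=10.0,
    cellulose_g=50.0,
    choline_g=2.3,
    _fractions=(0.759, 0.147, 0.094),
    label_energy_density_kj_g=HCD_LABEL_ENERGY_DENSITY_KJ_G,
)
HFD = DietSpec(
    name="HFD",
    protein_g=170.0,
    starch_g=436.6,
    sucrose_g=71.1,
    oil_g=225.0,
    minerals_g=35.0,
    vitamins_g=10.0,
    cellulose_g=50.0,
    choline_g=2.3,
    _fractions=(0.429, 0.144, 0.428),
    label_energy_density_kj_g=HFD_LABEL_ENERGY_DENSITY_KJ_G,
)


@dataclass
class SessionSummary:
    """Per-session scalar outcomes of the fasting-refeeding protocol."""

    rat_id: str
    meal_type: str
    bmr_w: float
    bmr_w_per_300g_mm: float | None
    tef_kj: float
    tef_pct_meal: float
    pre_rest_rq: float
    post_rest_rq: float
    pre_act_rq: float
    post_act_rq: float
    pre_activity: float
    post_activity: float
    pre_act_cost_w_per_au: float
    post_act_cost_w_per_au: float
    pre_gox_w: float
    post_gox_w: float
    pre_lox_w: float
    post_lox_w: float
    gox_auc_kj: float
    lox_auc_kj: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _window_mean(binned: pd.DataFrame, column: str, window) -> float:
    win = _window_bins(binned, window)
    clean = win.loc[~win["flagged"], column]
    return float(clean.mean()) if len(clean) else float("nan")


def summarize_session(
    binned: pd.DataFrame,
    rat_id: str,
    meal_type: str,
    meal_energy_kj: float = 60.0,
    ffm_g: float | None = None,
    fm_g: float | None = None,
    pre_window=PRE_MEAL_WINDOW_MIN,
    post_window=POST_MEAL_WINDOW_MIN,
) -> SessionSummary:
    """Reduce a binned decomposed trace to session-level parameters.

    BMR is the clean-bin mean resting rate over the pre-meal window; TEF is
    the net post-meal AUC above BMR (never normalized to body size); all
    pre/post means are clean-bin means over the respective windows. When
    body composition (FFM, FM interpolated to the session day) is supplied,
    BMR is additionally stated per 300 g metabolic mass.
    """
    bmr = compute_bmr(binned, window=pre_window)
    tef_kj, tef_pct = compute_tef(
        binned, bmr, meal_energy_kj=meal_energy_kj, window=post_window
    )
    bmr_norm = (
        normalize_to_metabolic_mass(bmr, ffm_g, fm_g)
        if ffm_g is not None and fm_g is not None
        else None
    )

    # substrate-oxidation AUCs over the post-meal window, relative to basal
    basal_gox = _window_mean(binned, "rest_gox_w", pre_window)
    basal_lox = _window_mean(binned, "rest_lox_w", pre_window)
    post = _window_bins(binned, post_window)
    post = post.loc[~post["flagged"]]
    width_s = (post["bin_end_min"] - post["bin_start_min"]).to_numpy() * 60.0
    gox_auc = float(np.sum((post["rest_gox_w"].to_numpy() - basal_gox) * width_s)) / 1e3
    lox_auc = float(np.sum((post["rest_lox_w"].to_numpy() - basal_lox) * width_s)) / 1e3

    return SessionSummary(
        rat_id=rat_id,
        meal_type=meal_type,
        bmr_w=bmr,
        bmr_w_per_300g_mm=bmr_norm,
        tef_kj=tef_kj,
        tef_pct_meal=tef_pct,
        pre_rest_rq=_window_mean(binned, "rest_rq", pre_window),
        post_rest_rq=_window_mean(binned, "rest_rq", post_window),
        pre_act_rq=_window_mean(binned, "act_rq", pre_window),
        post_act_rq=_window_mean(binned, "act_rq", post_window),
        pre_activity=_window_mean(binned, "activity_au", pre_window),
        post_activity=_window_mean(binned, "activity_au", post_window),
        pre_act_cost_w_per_au=_window_mean(binned, "act_cost_w_per_au", pre_window),
        post_act_cost_w_per_au=_window_mean(binned, "act_cost_w_per_au", post_window),
        pre_gox_w=basal_gox,
        post_gox_w=_window_mean(binned, "rest_gox_w", post_window),
        pre_lox_w=basal_lox,
        post_lox_w=_window_mean(binned, "rest_lox_w", post_window),
        gox_auc_kj=gox_auc,
        lox_auc_kj=lox_auc,
    )
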