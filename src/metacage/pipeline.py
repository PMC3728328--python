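"""End-to-end orchestration: cohort -> sessions -> decomposition ->
session parameters -> classification -> meal-response statistics.

Every stage is seeded from the run's master seed, so a full run is
deterministic: identical configurations produce byte-identical result
files. Any stage failure aborts with an error naming the stage.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bodycomp, inference, parameters
from .decomposition import decompose_trace
from .io import (
    RunConfig,
    provenance_record,
    write_cohort,
    write_json,
    write_summary,
    write_trace,
)
from .synthetic import adiposity_gains, generate_cohort, generate_session

__all__ = ["run_full_pipeline", "PipelineError"]

logger = logging.getLogger("metacage")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.spawn(1)[0].generate_state(1, np.uint32)[0] % (2**31))


@_stage("simulate-cohort")
def _make_cohort(config: RunConfig, master: np.random.SeedSequence):
    cohort_cfg = dataclasses.replace(config.cohort, seed=_child_seed(master))
    return generate_cohort(cohort_cfg)


@_stage("simulate-sessions")
def _make_sessions(config: RunConfig, cohort, gains, master: np.random.SeedSequence):
    rng = np.random.default_rng(master.spawn(1)[0])
    sessions = []
    for rat_id in gains.index:
        day_wk2 = int(rng.integers(8, 14))
        day_wk3 = int(rng.integers(15, 21))
        meals = ["HC", "HF"] if rng.random() < 0.5 else ["HF", "HC"]
        for day, meal in zip((day_wk2, day_wk3), meals):
            ffm, fm = bodycomp.interpolate_composition(cohort, rat_id, day)
            rat = {
                "rat_id": rat_id,
                "adchg": float(gains.loc[rat_id, "hcd_gain_pct"]),
                "ffm_g": ffm,
                "fm_g": fm,
            }
            cfg = dataclasses.replace(
                config.session, seed=_child_seed(master), meal_type=meal
            )
            latent, trace = generate_session(rat, cfg)
            sessions.append(
                dict(
                    rat_id=rat_id,
                    session_id=f"{rat_id}-{meal}",
                    day=day,
                    meal_type=meal,
                    ffm_g=ffm,
                    fm_g=fm,
                    config=cfg,
                    latent=latent,
                    trace=trace,
                )
            )
    return sessions


@_stage("decompose")
def _decompose_all(config: RunConfig, sessions):
    for s in sessions:
        dec, binned = decompose_trace(
            s["trace"], tau_s=s["config"].tau_s, bin_min=config.bin_min
        )
        s["decomposed"] = dec
        s["binned"] = binned
    return sessions


@_stage("summarize")
def _summarize_all(config: RunConfig, sessions):
    summaries = []
    for s in sessions:
        summary = parameters.summarize_session(
            s["binned"],
            rat_id=s["rat_id"],
            meal_type=s["meal_type"],
            meal_energy_kj=s["config"].meal_energy,
            ffm_g=s["ffm_g"],
            fm_g=s["fm_g"],
            pre_window=config.window_pre_min,
            post_window=config.window_post_min,
        )
        row = summary.to_dict()
        row["session_id"] = s["session_id"]
        row["day"] = s["day"]
        summaries.append(row)
    return pd.DataFrame(summaries)


@_stage("classify")
def _classify(gains):
    return bodycomp.classification_table(gains)


@_stage("meal-response")
def _meal_response(config: RunConfig, summaries, gains):
    """Long table + one mixed-model fit per (metabolic parameter, meal, diet)."""
    tables = {}
    fits = {}
    for mp in config.mp_columns:
        rows = []
        for _, r in summaries.iterrows():
            for mealtime in ("pre", "post"):
                rows.append(
                    dict(
                        rat_id=r["rat_id"],
                        session_id=r["session_id"],
                        mealtime=mealtime,
                        meal_type=r["meal_type"],
                        mp=mp,
                        mp_value=r[f"{mealtime}_{mp}"],
                    )
                )
        long = pd.DataFrame(rows)
        for meal, diet in itertools.product(("HC", "HF"), ("hcd", "hfd")):
            sub = long.loc[(long["meal_type"] == meal)].copy()
            sub["adchg"] = sub["rat_id"].map(gains[f"{diet}_gain_pct"])
            tables[(mp, meal, diet)] = sub
            fits[f"{mp}|meal={meal}|adchg={diet}"] = inference.fit_meal_response(
                sub[inference.MEAL_RESPONSE_COLUMNS]
            ).to_dict()
    table = pd.concat(
        [t.assign(mp=mp, adchg_diet=diet) for (mp, meal, diet), t in tables.items()],
        ignore_index=True,
    )
    return table, fits


@_stage("correlations")
def _correlations(gains):
    out = {}
    r, p = inference.pearson_correlation(gains["hcd_gain_pct"], gains["hfd_gain_pct"])
    out["hcd_vs_hfd_adiposity_gain"] = {"r": r, "p": p}
    for diet in ("hcd", "hfd"):
        r, p = inference.pearson_correlation(
            gains[f"bw_gain_{diet}_g"], gains[f"{diet}_gain_pct"]
        )
        out[f"bw_vs_adiposity_gain_{diet}"] = {"r": r, "p": p}
    return out


def run_full_pipeline(config: RunConfig) -> dict:
    """Run the whole synthetic study once; returns the results bundle.

    Bundle keys: cohort, gains, classification, summaries, meal_response,
    fits, correlations, fat_distribution, interpolation_validation,
    diet_metrics, provenance. When ``config.out_dir`` is set the bundle is
    also written there (CSV/JSON; per-session traces only with
    ``write_traces=True``).
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)

    cohort = _make_cohort(config, master)
    gains = adiposity_gains(cohort)
    classification = _classify(gains)
    sessions = _make_sessions(config, cohort, gains, master)
    sessions = _decompose_all(config, sessions)
    summaries = _summarize_all(config, sessions)
    meal_response, fits = _meal_response(config, summaries, gains)
    correlations = _correlations(gains)

    try:
        fat_distribution = bodycomp.fat_distribution_stats(cohort)
        cal_days = {}
        for s in sessions:
            cal_days.setdefault(s["rat_id"], []).append(s["day"])
        interp = bodycomp.validate_interpolation(cohort, cal_days)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("body-composition", exc) from exc

    diet_metrics = {
        d.name: parameters.diet_metrics(d, config.session.meal_energy)
        for d in (parameters.HCD, parameters.HFD)
    }

    bundle = {
        "cohort": cohort,
        "gains": gains,
        "classification": classification,
        "summaries": summaries,
        "meal_response": meal_response,
        "fits": fits,
        "correlations": correlations,
        "fat_distribution": fat_distribution,
        "interpolation_validation": dataclasses.asdict(interp),
        "diet_metrics": diet_metrics,
        "provenance": provenance_record(config),
    }

    if config.out_dir:
        _write_bundle(config, bundle, sessions)
    return bundle


@_stage("write-outputs")
def _write_bundle(config: RunConfig, bundle: dict, sessions) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(bundle["cohort"], out / "cohort.csv")
    bundle["gains"].reset_index().to_csv(out / "gains.csv", index=False, lineterminator="\n")
    bundle["classification"].reset_index().to_csv(
        out / "classification.csv", index=False, lineterminator="\n"
    )
    write_summary(bundle["summaries"], out / "summaries.csv")
    bundle["meal_response"].to_csv(out / "meal_response.csv", index=False, lineterminator="\n")
    write_json(bundle["fits"], out / "fits.json")
    report = {
        "correlations": bundle["correlations"],
        "fat_distribution": {
            "summary": bundle["fat_distribution"]["summary"],
            "wilcoxon_p": {
                f"{a}-{b}": p for (a, b), p in bundle["fat_distribution"]["wilcoxon_p"].items()
            },
        },
        "interpolation_validation": bundle["interpolation_validation"],
        "diet_metrics": bundle["diet_metrics"],
        "provenance": bundle["provenance"],
    }
    write_json(report, out / "report.json")
    if config.write_traces:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for s in sessions:
            write_trace(s["trace"], tdir / f"{s['session_id']}.csv")
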