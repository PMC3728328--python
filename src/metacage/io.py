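"""File formats, run configuration and provenance.

All tabular artifacts are plain RFC-4180 CSV with explicit headers; configs
are YAML; model-fit reports are JSON. Clock times in configs are ISO
"HH:MM"; all internal time is seconds relative to meal delivery. Missing
gas samples round-trip as empty fields with ``missing_flag=1`` — never
zeros.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decomposition import GasTrace
from .synthetic import CohortConfig, SessionConfig

__all__ = [
    "TRACE_COLUMNS",
    "COHORT_COLUMNS",
    "read_trace",
    "write_trace",
    "read_cohort",
    "write_cohort",
    "read_summary",
    "write_summary",
    "RunConfig",
    "provenance_record",
    "SchemaError",
]

TRACE_COLUMNS = ["time_s", "vo2_ml_min", "vco2_ml_min", "activity_au", "missing_flag"]
COHORT_COLUMNS = [
    "rat_id",
    "day",
    "bw_g",
    "ffm_g",
    "fm_g",
    "fm_visc_g",
    "fm_subc_g",
    "mri_session",
]
SUMMARY_COLUMNS = ["rat_id", "meal_type", "bmr_w", "tef_kj", "tef_pct_meal"]


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def write_trace(trace: GasTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "vo2_ml_min": trace.vo2,
            "vco2_ml_min": trace.vco2,
            "activity_au": trace.activity,
            "missing_flag": trace.missing.astype(int),
        }
    )
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")


def read_trace(path) -> GasTrace:
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    missing = df["missing_flag"].astype(int).to_numpy().astype(bool)
    vo2 = df["vo2_ml_min"].to_numpy(dtype=float)
    vco2 = df["vco2_ml_min"].to_numpy(dtype=float)
    # malformed rows: a gas value absent without its missing flag
    bad = np.flatnonzero((np.isnan(vo2) | np.isnan(vco2)) & ~missing)
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise SchemaError(f"{path}: NaN gas values with missing_flag=0 at line(s) {lines}")
    return GasTrace(
        time_s=df["time_s"].to_numpy(dtype=float),
        vo2=vo2,
        vco2=vco2,
        activity=df["activity_au"].to_numpy(dtype=float),
        missing=missing,
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, path)
    return df


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False, lineterminator="\n")


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SUMMARY_COLUMNS, path)
    return df


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    The analysis windows are anchored to meal delivery: the pre-meal window
    (-120..0 min) defines the basal state, the post-meal window (0..300 min)
    the meal response; they must not overlap. ``mp_columns`` lists the
    metabolic parameters carried into the meal-response model.
    """

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    session: SessionConfig = field(default_factory=SessionConfig)
    bin_min: float = 15.0
    window_pre_min: tuple[float, float] = (-120.0, 0.0)
    window_post_min: tuple[float, float] = (0.0, 300.0)
    mp_columns: tuple[str, ...] = ("rest_rq",)
    out_dir: str | None = None
    write_traces: bool = False

    def validate(self) -> None:
        if self.window_pre_min[1] > self.window_post_min[0]:
            raise ValueError("pre- and post-meal windows overlap")
        self.cohort.validate()
        self.session.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        d["session"] = dataclasses.asdict(self.session)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = CohortConfig(**d.pop("cohort", {}))
        session = SessionConfig(**d.pop("session", {}))
        for key in ("window_pre_min", "window_post_min", "mp_columns"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(cohort=cohort, session=session, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Fingerprint of the scientific configuration (paths excluded, so
        re-running into a different directory hashes identically)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("write_traces", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def provenance_record(config: RunConfig) -> dict:
    """Machine-readable record of what produced a results bundle.

    Deliberately excludes wall-clock time so that two runs of the same
    configuration emit byte-identical bundles.
    """
    import scipy
    import statsmodels

    from . import __version__

    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cohort_seed": config.cohort.seed,
        "session_seed": config.session.seed,
        "versions": {
            "metacage": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
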