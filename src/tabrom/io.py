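"""Run-table and result I/O: validated CSV/JSON interchange plus sidecars.

CSV uses dot decimals, UTF-8 and a mandatory header row; configuration is YAML
with a JSON fallback. Every CLI invocation writes a metadata sidecar (seed,
config hash, package version) next to its output so deterministic stages can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rational import ModelCombination
from .reference_models import CampaignTruth
from .selection import FitResult

__all__ = [
    "RUN_TABLE_COLUMNS",
    "load_config",
    "read_run_table",
    "write_run_table",
    "write_ranked_models",
    "write_fitted_params",
    "read_fitted_params",
    "write_metadata",
]

RUN_TABLE_COLUMNS: tuple[str, ...] = (
    "run_id",
    "campaign",
    "concentration_pct",
    "mixing_time_min",
    "turret_rpm",
    "feedframe_rpm",
    "dosing_mm",
    "bulk_density_gcc",
    "true_density_gcc",
    "mean_weight_mg",
    "in_die_thickness_mm",
    "tablet_thickness_mm",
    "tablet_diameter_mm",
    "compaction_force_kN",
    "hardness_N",
)
_NUMERIC = tuple(c for c in RUN_TABLE_COLUMNS if c not in ("run_id", "campaign"))


def load_config(path) -> dict:
    """Load a configuration mapping from YAML (JSON is a YAML subset)."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"config {path} must contain a mapping at top level")
    return payload


def _validate_run_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RUN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"run table missing column(s): {', '.join(missing)}")
    if df["run_id"].duplicated().any():
        dups = df.loc[df["run_id"].duplicated(), "run_id"].tolist()
        raise ValueError(f"duplicate run_id value(s): {dups}")
    for col in _NUMERIC:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ValueError(
                f"non-finite value in column {col!r} at row(s) {bad[:5].tolist()}"
            )
        df[col] = values
    return df


def read_run_table(path) -> pd.DataFrame:
    """Read and validate a run-table CSV; errors name the offending column/row."""
    df = pd.read_csv(path)
    return _validate_run_table(df)


def write_run_table(df: pd.DataFrame, path) -> None:
    _validate_run_table(df.copy())
    df.to_csv(path, index=False, float_format="%.17g")


def write_ranked_models(fits: Sequence[FitResult], path) -> pd.DataFrame:
    """Write a ranked-models CSV (ascending AIC) mirroring the selection output."""
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(fits) + 1),
            "combination": [f.label for f in fits],
            "Np": [f.n_params for f in fits],
            "SSE": [f.sse for f in fits],
            "R2": [f.r2 for f in fits],
            "AIC": [f.aic for f in fits],
            "AIC_ranked": [f.aic if f.aic_ranked is None else f.aic_ranked for f in fits],
            "overfit_flag": [f.overfit for f in fits],
        }
    )
    table.to_csv(path, index=False, float_format="%.6g")
    return table


def _fit_payload(fit: FitResult) -> dict:
    payload = {
        "label": fit.label,
        "theta": fit.theta,
        "sse": fit.sse,
        "r2": fit.r2,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "n_data": fit.n_data,
        "overfit": fit.overfit,
        "seed": fit.seed,
    }
    if fit.combination is not None:
        payload["variant_ids"] = list(fit.combination.variant_ids)
        payload["extra_params"] = list(fit.combination.extra_params)
    if fit.ci is not None:
        payload["ci95"] = {k: list(v) for k, v in fit.ci.items()}
    return payload


def write_fitted_params(best: Mapping[str, FitResult], path,
                        campaign: str = "", c_max: float | None = None) -> None:
    """Write the per-stage fitted parameter sets (with CIs if present) as JSON."""
    payload = {
        "campaign": campaign,
        "c_max": c_max,
        "stages": {stage: _fit_payload(fit) for stage, fit in best.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def read_fitted_params(path) -> CampaignTruth:
    """Reload a fitted-parameters JSON as a campaign truth usable downstream
    (e.g. by the Sobol subcommand or as a simulation ground truth)."""
    payload = json.loads(Path(path).read_text())
    stages: dict[str, dict] = {}
    for stage, entry in payload["stages"].items():
        if stage == "weight":
            theta = entry["theta"]
            stages[stage] = {
                "form": "su_linear" if entry["label"] == "eq21" else "second_order",
                "xi": tuple(theta.get(f"xi{i}", 0.0) for i in range(1, 6)),
                "free": tuple(k for k, v in theta.items() if v != 0.0),
            }
        else:
            stages[stage] = {
                "combination": ModelCombination(
                    stage, tuple(entry["variant_ids"]),
                    extra_params=tuple(entry.get("extra_params", ())),
                ),
                "theta": {k: float(v) for k, v in entry["theta"].items()},
            }
    return CampaignTruth(
        campaign=payload.get("campaign") or "mgst",
        c_max=float(payload["c_max"]) if payload.get("c_max") else 2.0,
        t_max=60.0,
        stages=stages,
    )


def write_metadata(out_path, seed: int, config: Mapping) -> Path:
    """Write the reproducibility sidecar ``<out>.meta.json``."""
    from . import __version__

    config_json = json.dumps(config, sort_keys=True, default=str)
    meta = {
        "seed": seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "package_version": __version__,
    }
    sidecar = Path(str(out_path) + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar
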