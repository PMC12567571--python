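"""First-order Sobol global sensitivity of the integrated stage models.

Inputs are sampled independently and uniformly over stated ranges with a
Saltelli-type plan (via :func:`scipy.stats.sobol_indices`), and the first-order
index of each input — the fraction of output variance attributable to that
input alone — is reported. Inputs the model does not depend on receive an
index of zero up to Monte-Carlo error; a model that is a function of a single
active input concentrates the full variance there (index 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import rom_core
from .rational import RationalParams, eval_rational, get_variant, normalize
from .reference_models import CAMPAIGN_RANGES, CampaignTruth
from .rom_core import TabletGeometry
from .selection import STAGE_FUNCTIONS

__all__ = [
    "SensitivitySpec",
    "sobol_first_order",
    "stage_sensitivity_model",
    "campaign_sobol_table",
]

# extra-input ranges used when a spec does not state them: relative densities
# span the realistic compaction window of the campaigns
DEFAULT_DENSITY_RANGES = {
    "rho_in_die": (0.4, 0.9),
    "rho_tablet": (0.5, 0.9),
    "bulk_density_gcc": (0.25, 0.45),
}


@dataclass(frozen=True)
class SensitivitySpec:
    """Input box and sampling plan for one Sobol analysis.

    ``inputs`` is an ordered mapping name -> (lower, upper); sampling is
    independent uniform on each interval. ``n`` is the Saltelli base sample
    size (a power of two, >= 64).
    """

    inputs: Mapping[str, tuple[float, float]]
    n: int = 2**14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 64:
            raise ValueError("sample size must be >= 64")
        for name, (lo, hi) in self.inputs.items():
            if not np.isfinite([lo, hi]).all() or hi <= lo:
                raise ValueError(f"degenerate or infinite range for input {name!r}")


def sobol_first_order(model: Callable[[np.ndarray], np.ndarray],
                      spec: SensitivitySpec) -> dict[str, float]:
    """First-order Sobol index of each input of ``model``.

    ``model`` maps an array of shape (d, m) — one row per input, in the order
    of ``spec.inputs`` — to an output vector of length m. Deterministic given
    ``spec.seed``.
    """
    dists = [stats.uniform(loc=lo, scale=hi - lo) for lo, hi in spec.inputs.values()]
    res = stats.sobol_indices(
        func=model, n=spec.n, dists=dists, rng=np.random.default_rng(spec.seed)
    )
    return {name: float(s) for name, s in zip(spec.inputs, res.first_order)}


def stage_sensitivity_model(truth: CampaignTruth, stage: str,
                            geom: TabletGeometry | None = None,
                            ) -> tuple[Callable[[np.ndarray], np.ndarray], list[str]]:
    """Vectorized integrated model of one stage plus its ordered input names.

    The upstream inputs are the excipient concentration and mixing time (the
    shear surrogate); stage-specific state variables (in-die or tablet
    relative density, bulk density, speed and fill ratios) complete the list.
    """
    geom = geom or TabletGeometry(8.0, 0.3302)
    entry = truth.stages[stage]

    if stage == "weight":
        xi = entry["xi"]

        def model(x: np.ndarray) -> np.ndarray:
            speed_ratio, fill_ratio, rho_b = x
            eta = rom_core.filling_efficacy(xi, speed_ratio, 1.0, fill_ratio, 1.0)
            # weight in mg at a nominal fill volume scaled by the fill ratio
            v_fill = rom_core.fill_volume(geom, fill_ratio * geom.die_diameter_mm)
            return rom_core.weight_from_efficacy(eta, rho_b, v_fill) * 1e3

        return model, ["speed_ratio", "fill_ratio", "bulk_density_gcc"]

    combination = entry["combination"]
    theta = entry["theta"]

    def functions(c, t):
        X = normalize(c, truth.c_max, theta.get("r_x", 1.0))
        Y = normalize(t, truth.t_max, theta.get("r_y", 1.0))
        out = {}
        for fname, vid in zip(STAGE_FUNCTIONS[stage], combination.variant_ids):
            coefs = {k.split(".", 1)[1]: v for k, v in theta.items()
                     if k.startswith(fname + ".")}
            out[fname] = eval_rational(get_variant(vid), RationalParams.from_dict(coefs), X, Y)
        return out

    if stage == "bulk_density":

        def model(x: np.ndarray) -> np.ndarray:
            c, t = x
            return functions(c, t)["phi"]

        return model, ["concentration_pct", "mixing_time_min"]

    if stage == "compaction":

        def model(x: np.ndarray) -> np.ndarray:
            c, t, rho = x
            f = functions(c, t)
            return rom_core.kawakita_force(rho, f["a"], f["inv_b"], f["rho_c"],
                                           geom.die_diameter_mm, strict=False)

        return model, ["concentration_pct", "mixing_time_min", "rho_in_die"]

    if stage == "elastic_recovery":

        def model(x: np.ndarray) -> np.ndarray:
            c, t, rho = x
            f = functions(c, t)
            eps = rom_core.elastic_recovery(rho, f["eps0"], f["rho_c_eps"],
                                            theta.get("n_exp", 1.0))
            return rom_core.tablet_density(rho, eps)

        return model, ["concentration_pct", "mixing_time_min", "rho_in_die"]

    if stage == "tensile_strength":

        def model(x: np.ndarray) -> np.ndarray:
            c, t, rho = x
            f = functions(c, t)
            return rom_core.leuenberger_tensile(rho, f["sigma0"], f["rho_c_sigma"])

        return model, ["concentration_pct", "mixing_time_min", "rho_tablet"]

    raise ValueError(f"unknown stage {stage!r}")


def _default_ranges(truth: CampaignTruth, names: Sequence[str]) -> dict[str, tuple[float, float]]:
    camp = CAMPAIGN_RANGES[truth.campaign]
    ranges = {}
    for name in names:
        if name in camp:
            lo, hi = camp[name]
            if name == "concentration_pct":
                hi = min(hi, truth.c_max * (1 - 1e-6))  # stay inside the normalization domain
            ranges[name] = (lo, hi)
        elif name == "speed_ratio":
            lo, hi = camp["turret_rpm"]
            ranges[name] = (30.0 / hi, 30.0 / lo)  # nominal feed-frame speed 30 rpm
        elif name == "fill_ratio":
            lo, hi = camp["dosing_mm"]
            d = 8.0
            ranges[name] = (lo / d, hi / d)
        else:
            ranges[name] = DEFAULT_DENSITY_RANGES[name]
    return ranges


def campaign_sobol_table(truth: CampaignTruth, n: int = 2**14, seed: int = 0,
                         ranges: Mapping[str, tuple[float, float]] | None = None,
                         stages: Sequence[str] | None = None) -> pd.DataFrame:
    """First-order Sobol indices of every integrated stage model of a campaign.

    Rows are inputs, columns are stages; entries are blank where a stage does
    not take the input. Ranges default to the campaign's experimental ranges
    (densities to a realistic compaction window) unless overridden.
    """
    stages = list(stages or ("bulk_density", "weight", "compaction",
                             "elastic_recovery", "tensile_strength"))
    table: dict[str, dict[str, float]] = {}
    for k, stage in enumerate(stages):
        model, names = stage_sensitivity_model(truth, stage)
        box = _default_ranges(truth, names)
        if ranges:
            box.update({k2: v for k2, v in ranges.items() if k2 in box})
        spec = SensitivitySpec(inputs={name: box[name] for name in names},
                               n=n, seed=seed + k)
        for name, s1 in sobol_first_order(model, spec).items():
            table.setdefault(name, {})[stage] = s1
    return pd.DataFrame(table).T.reindex(columns=stages)
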