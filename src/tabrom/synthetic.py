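"""Latin-hypercube campaign design and forward simulation of run tables.

The experimental data behind the two reference campaigns are not deposited, so
this module stands in for them: it samples press settings and mixing conditions
by Latin-hypercube design over the stated campaign ranges (20 lubricant runs,
30 glidant runs by default) and pushes them through the published fitted stage
models (:mod:`tabrom.reference_models`) with configurable multiplicative
Gaussian measurement noise.

The forward chain mirrors what the press and the tablet tester would produce:
blend true density (inverse-mass-weighted mixture rule) -> bulk density via the
packing-fraction model -> tablet weight via the filling-efficacy model -> in-die
relative density at the fixed in-die thickness -> Kawakita punch force ->
elastic recovery and out-of-die thickness -> Leuenberger tensile strength,
re-expressed as a hardness reading through the inverse Pitt formula. Each
downstream response is generated from the *measured* (noisy) value of its
upstream predictor, so a zero-noise campaign is an exact fixed point of the
fitting pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import rom_core
from .rational import RationalParams, eval_rational, get_variant, normalize
from .reference_models import CAMPAIGN_RANGES, CampaignTruth, get_truth
from .rom_core import TabletGeometry
from .selection import STAGE_FUNCTIONS

__all__ = [
    "CampaignSpec",
    "DEFAULT_NOISE",
    "COMPONENT_TRUE_DENSITY",
    "DEFAULT_GEOMETRY",
    "IN_DIE_THICKNESS_MM",
    "true_density_mixture",
    "blend_true_density",
    "lhs_design",
    "simulate_campaign",
    "simulate_run",
    "emit_campaign",
]

# per-response coefficient of variation of the multiplicative Gaussian noise
DEFAULT_NOISE: dict[str, float] = {
    "bulk_density": 0.01,
    "weight": 0.01,
    "force": 0.03,
    "tablet_density": 0.01,
    "hardness": 0.05,
}

# component true densities (g/cm^3) of the formulation; configuration values
# for typical excipient grades, overridable per spec
COMPONENT_TRUE_DENSITY: dict[str, float] = {
    "mcc": 1.56,
    "apap": 1.293,
    "mgst": 1.09,
    "cs": 2.2,
}
APAP_MASS_FRACTION = 0.10

# D-type tooling with a shallow cup, pressed to a fixed in-die thickness.
# The thickness is per campaign, chosen so that the whole stated design box
# maps to physical in-die relative densities (< 1) under the reference
# packing-fraction and filling models; see docs/methods.md.
DEFAULT_GEOMETRY = TabletGeometry(die_diameter_mm=8.0, cup_depth_mm=0.3302,
                                  num_die_stations=10)
IN_DIE_THICKNESS_MM: dict[str, float] = {"mgst": 3.2, "cs": 4.0}
DEFAULT_FEEDFRAME_RPM = 30.0  # not varied in the reference campaigns


@dataclass(frozen=True)
class CampaignSpec:
    """Design and noise specification for one synthetic campaign."""

    campaign: str = "mgst"
    n_runs: int | None = None  # default: 20 for mgst, 30 for cs
    ranges: Mapping[str, tuple[float, float]] | None = None
    feedframe_rpm: float = DEFAULT_FEEDFRAME_RPM
    tablets_per_run: int = 50
    noise: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.campaign not in CAMPAIGN_RANGES:
            raise ValueError(f"unknown campaign {self.campaign!r}")
        if self.tablets_per_run < 1:
            raise ValueError("tablets_per_run must be >= 1")
        if any(cv < 0 for cv in self.noise.values()):
            raise ValueError("noise CVs must be >= 0")

    @property
    def resolved_n_runs(self) -> int:
        if self.n_runs is not None:
            return self.n_runs
        return 20 if self.campaign == "mgst" else 30

    @property
    def resolved_ranges(self) -> dict[str, tuple[float, float]]:
        base = dict(CAMPAIGN_RANGES[self.campaign])
        if self.ranges:
            base.update(self.ranges)
        return base

    def without_noise(self) -> "CampaignSpec":
        return replace(self, noise={k: 0.0 for k in self.noise})


def true_density_mixture(mass_fractions: Mapping[str, float],
                         densities: Mapping[str, float] | None = None) -> float:
    """Blend true density (g/cm^3): inverse-mass-weighted harmonic mean.

    1/rho_t = sum_i w_i / rho_i for mass fractions w_i summing to 1.
    """
    densities = densities or COMPONENT_TRUE_DENSITY
    total = sum(mass_fractions.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"mass fractions must sum to 1 (got {total})")
    inv = 0.0
    for name, w in mass_fractions.items():
        if w < 0:
            raise ValueError("mass fractions must be >= 0")
        if w > 0:
            inv += w / densities[name]
    return 1.0 / inv


def blend_true_density(campaign: str, concentration_pct,
                       densities: Mapping[str, float] | None = None) -> np.ndarray:
    """True density of the 10% APAP / MCC / excipient blend at c % w/w."""
    c = np.atleast_1d(np.asarray(concentration_pct, dtype=float)) / 100.0
    out = np.array([
        true_density_mixture(
            {"apap": APAP_MASS_FRACTION, campaign: ci, "mcc": 1.0 - APAP_MASS_FRACTION - ci},
            densities,
        )
        for ci in c
    ])
    return out if out.size > 1 else float(out[0])


def lhs_design(spec: CampaignSpec) -> pd.DataFrame:
    """Latin-hypercube design over the four upstream inputs.

    Each column's values occupy distinct equal-probability strata and lie
    strictly inside the stated range; identical seeds yield identical designs.
    """
    n = spec.resolved_n_runs
    if n < 2:
        raise ValueError("a design needs at least 2 runs")
    cols = ["concentration_pct", "mixing_time_min", "turret_rpm", "dosing_mm"]
    ranges = spec.resolved_ranges
    sampler = qmc.LatinHypercube(d=len(cols), seed=spec.seed)
    u = sampler.random(n)
    lo = np.array([ranges[c][0] for c in cols])
    hi = np.array([ranges[c][1] for c in cols])
    design = pd.DataFrame(qmc.scale(u, lo, hi), columns=cols)
    design.insert(0, "run_id", np.arange(1, n + 1))
    return design


def _truth_functions(truth: CampaignTruth, stage: str, c, t) -> dict[str, np.ndarray]:
    entry = truth.stages[stage]
    theta = entry["theta"]
    X = normalize(c, truth.c_max, theta.get("r_x", 1.0))
    Y = normalize(t, truth.t_max, theta.get("r_y", 1.0))
    out = {}
    for fname, vid in zip(STAGE_FUNCTIONS[stage], entry["combination"].variant_ids):
        coefs = {k.split(".", 1)[1]: v for k, v in theta.items() if k.startswith(fname + ".")}
        out[fname] = eval_rational(get_variant(vid), RationalParams.from_dict(coefs), X, Y)
    return out


def simulate_campaign(spec: CampaignSpec, truth: CampaignTruth | None = None,
                      design: pd.DataFrame | None = None,
                      geom: TabletGeometry = DEFAULT_GEOMETRY,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full campaign; returns (run table, per-tablet table).

    The run table follows the :mod:`tabrom.io` schema. The per-tablet table
    re-samples weight, thickness and hardness around the run-level values with
    the same CVs, so run means reproduce the run-level values within
    CV/sqrt(tablets_per_run).
    """
    truth = truth or get_truth(spec.campaign)
    rng = np.random.default_rng(spec.seed)
    if design is None:
        design = lhs_design(spec)
    c = design["concentration_pct"].to_numpy(float)
    t = design["mixing_time_min"].to_numpy(float)
    nT = design["turret_rpm"].to_numpy(float)
    dosing = design["dosing_mm"].to_numpy(float)
    n = len(design)
    cv = {k: spec.noise.get(k, 0.0) for k in DEFAULT_NOISE}

    def jitter(values, key):
        if cv[key] == 0.0:
            return values
        return values * (1.0 + cv[key] * rng.standard_normal(np.shape(values)))

    rho_t = np.atleast_1d(blend_true_density(spec.campaign, c))

    phi = _truth_functions(truth, "bulk_density", c, t)["phi"]
    rho_b = jitter(phi * rho_t, "bulk_density")  # g/cm^3, measured

    weight_entry = truth.stages["weight"]
    eta = rom_core.filling_efficacy(
        weight_entry["xi"], spec.feedframe_rpm, nT, dosing, geom.die_diameter_mm,
        form=rom_core.FillingForm(weight_entry.get("form", "second_order")),
    )
    v_fill = rom_core.fill_volume(geom, dosing)
    W = jitter(rom_core.weight_from_efficacy(eta, rho_b, v_fill), "weight")  # g

    t_in_die = IN_DIE_THICKNESS_MM[spec.campaign]
    v_in_die = rom_core.tablet_volume(geom, t_in_die)
    rho_in_die = W / (rho_t * v_in_die / 1e3)
    if np.any(rho_in_die >= 1.0) or np.any(rho_in_die <= 0.0):
        raise ValueError("simulated in-die relative density outside (0, 1): "
                         "check design ranges and geometry")

    comp = _truth_functions(truth, "compaction", c, t)
    force = jitter(
        rom_core.kawakita_force(rho_in_die, comp["a"], comp["inv_b"], comp["rho_c"],
                                geom.die_diameter_mm),
        "force",
    )

    rec = _truth_functions(truth, "elastic_recovery", c, t)
    n_exp = truth.theta("elastic_recovery").get("n_exp", 1.0)
    eps = rom_core.elastic_recovery(rho_in_die, rec["eps0"], rec["rho_c_eps"], n_exp)
    rho_tablet = jitter(rom_core.tablet_density(rho_in_die, eps), "tablet_density")
    rho_tablet = np.minimum(rho_tablet, rho_in_die)  # noise keeps physical ordering
    t_tablet = rom_core.thickness_from_volume(geom, W / rho_t / rho_tablet * 1e3)

    ten = _truth_functions(truth, "tensile_strength", c, t)
    sigma_t = rom_core.leuenberger_tensile(rho_tablet, ten["sigma0"], ten["rho_c_sigma"])
    hardness = jitter(
        rom_core.pitt_hardness_from_strength(sigma_t, geom, t_tablet), "hardness"
    )

    runs = pd.DataFrame(
        {
            "run_id": design["run_id"].to_numpy()
            if "run_id" in design
            else np.arange(1, n + 1),
            "campaign": spec.campaign,
            "concentration_pct": c,
            "mixing_time_min": t,
            "turret_rpm": nT,
            "feedframe_rpm": spec.feedframe_rpm,
            "dosing_mm": dosing,
            "bulk_density_gcc": rho_b,
            "true_density_gcc": rho_t,
            "mean_weight_mg": W * 1e3,
            "in_die_thickness_mm": t_in_die,
            "tablet_thickness_mm": t_tablet,
            "tablet_diameter_mm": geom.die_diameter_mm,
            "compaction_force_kN": force,
            "hardness_N": hardness,
        }
    )

    m = spec.tablets_per_run
    rep = runs.loc[runs.index.repeat(m)].reset_index(drop=True)
    tablets = pd.DataFrame(
        {
            "run_id": rep["run_id"],
            "tablet_id": np.tile(np.arange(1, m + 1), n),
            "weight_mg": jitter(rep["mean_weight_mg"].to_numpy(), "weight"),
            "thickness_mm": jitter(rep["tablet_thickness_mm"].to_numpy(), "tablet_density"),
            "diameter_mm": rep["tablet_diameter_mm"],
            "hardness_N": jitter(rep["hardness_N"].to_numpy(), "hardness"),
        }
    )
    return runs, tablets


def simulate_run(inputs: Mapping[str, float], spec: CampaignSpec,
                 truth: CampaignTruth | None = None,
                 geom: TabletGeometry = DEFAULT_GEOMETRY) -> pd.Series:
    """Simulate a single steady-state run from explicit input settings."""
    design = pd.DataFrame([{"run_id": 1, **inputs}])
    ranges = spec.resolved_ranges
    for key, (lo, hi) in ranges.items():
        v = float(design[key].iloc[0])
        if not lo <= v <= hi:
            raise ValueError(f"input {key}={v} outside campaign range [{lo}, {hi}]")
    runs, _ = simulate_campaign(spec, truth=truth, design=design, geom=geom)
    return runs.iloc[0]


def emit_campaign(spec: CampaignSpec, run_path, tablet_path=None,
                  truth: CampaignTruth | None = None) -> pd.DataFrame:
    """Simulate and write a campaign as CSV file(s); returns the run table."""
    from . import io as tabio

    runs, tablets = simulate_campaign(spec, truth=truth)
    tabio.write_run_table(runs, run_path)
    if tablet_path is not None:
        tablets.to_csv(tablet_path, index=False)
    return runs
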