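"""Stage-wise fitting, AICc model selection, overfit flagging and bootstrap.

Selection is a nested optimization: the lower problem estimates, for one model
combination, the rational-function coefficients (and shared normalization
exponents) that minimize the sum of squared errors between the stage ROM
prediction and the run-level data, under mechanistic constraints (positivity,
unit-interval relative quantities, staged onset-density ordering). The upper
problem ranks combinations by the Akaike information criterion with the
small-sample (second-order) correction for n < 30 and picks the lowest.

The lower problem uses a seeded Latin-hypercube multi-start over the
constrained box (positive coefficients explored in log10 space over
(1e-8, 1e4]) followed by trust-region least-squares refinement, so results are
deterministic given the seed. Function-valued bound constraints (a relative
quantity must stay inside [lb, 1] over the whole campaign) enter as smooth
penalty residuals and are exactly zero at any feasible optimum.

The filling-efficacy (weight) stage is linear in its coefficients and is fitted
by ordinary linear least squares over its own small model family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import rom_core
from .rational import (
    ModelCombination,
    RationalBase,
    RationalParams,
    compaction_triple_library,
    eq16_pair_library,
    eval_rational,
    get_variant,
    limit_values,
    normalize,
    param_count,
)
from .rom_core import FillingForm, TabletGeometry

__all__ = [
    "STAGES",
    "STAGE_FUNCTIONS",
    "StageDataset",
    "StageConstraints",
    "FitResult",
    "build_stage_dataset",
    "stage_predict",
    "sse",
    "r_squared",
    "aic",
    "fit_combination",
    "default_library",
    "select_model",
    "overfit_flag",
    "bootstrap_ci",
    "sequential_campaign_fit",
    "WEIGHT_MODELS",
]

STAGE_FUNCTIONS: dict[str, tuple[str, ...]] = {
    "bulk_density": ("phi",),
    "compaction": ("a", "inv_b", "rho_c"),
    "elastic_recovery": ("eps0", "rho_c_eps"),
    "tensile_strength": ("sigma0", "rho_c_sigma"),
}
STAGE_EXTRAS: dict[str, tuple[str, ...]] = {"elastic_recovery": ("n_exp",)}
STAGES = ("bulk_density", "weight", "compaction", "elastic_recovery", "tensile_strength")

# ROM parameters that are relative quantities, bounded to [lb, 1]
_RELATIVE = {"phi", "a", "rho_c", "eps0", "rho_c_eps", "rho_c_sigma"}

# weight-stage model family: name -> (form, free xi names)
WEIGHT_MODELS: dict[str, tuple[FillingForm, tuple[str, ...]]] = {
    "eq21": (FillingForm.SU_LINEAR, ("xi1", "xi2")),
    "second_order": (FillingForm.SECOND_ORDER, ("xi1", "xi2", "xi3", "xi4", "xi5")),
    "second_order_xi1=0": (FillingForm.SECOND_ORDER, ("xi2", "xi3", "xi4", "xi5")),
    "second_order_xi5=0": (FillingForm.SECOND_ORDER, ("xi1", "xi2", "xi3", "xi4")),
    "second_order_xi1=xi5=0": (FillingForm.SECOND_ORDER, ("xi2", "xi3", "xi4")),
}


@dataclass(frozen=True)
class StageDataset:
    """Run-level predictors and response for one fitting stage."""

    stage: str
    predictors: pd.DataFrame
    response: np.ndarray
    x_max: float  # concentration normalization bound (% w/w)
    y_max: float = 60.0  # mixing-time normalization bound (min)
    geom: TabletGeometry | None = None
    response_name: str = ""
    response_unit: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", resp)
        if len(resp) != len(self.predictors):
            raise ValueError("predictors and response length mismatch")
        if len(resp) == 0:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(resp)) or not np.all(np.isfinite(self.predictors.to_numpy(float))):
            raise ValueError("dataset contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.response)

    def subset(self, idx: np.ndarray) -> "StageDataset":
        return replace(
            self,
            predictors=self.predictors.iloc[idx].reset_index(drop=True),
            response=self.response[idx],
        )


@dataclass(frozen=True)
class StageConstraints:
    """Mechanistic constraints for the lower optimization problem.

    ``lower_bounds`` maps a relative-quantity function name to its staged lower
    bound (the onset densities must be ordered rho_c < rho_c_eps <
    rho_c_sigma; sequential fitting feeds each stage the point estimate from
    the stage upstream, minus a small numerical slack).
    """

    lower_bounds: Mapping[str, float] = field(default_factory=dict)
    coef_box: tuple[float, float] = (1e-8, 1e4)
    r_box: tuple[float, float] = (0.05, 10.0)
    n_exp_box: tuple[float, float] = (0.05, 10.0)

    def bound_for(self, fname: str) -> float:
        lb = float(self.lower_bounds.get(fname, 0.0))
        if not 0.0 <= lb < 1.0:
            raise ValueError(f"infeasible staged lower bound {lb} for {fname}")
        return lb


@dataclass
class FitResult:
    """One fitted model combination with its selection metrics."""

    stage: str
    label: str
    theta: dict[str, float]
    sse: float
    r2: float
    n_params: int
    aic: float
    n_data: int
    seed: int
    combination: ModelCombination | None = None
    overfit: bool = False
    converged: bool = True
    ci: dict[str, tuple[float, float]] | None = None
    #: AIC evaluated at the measurement-resolution SSE floor; set by
    #: select_model and used for ordering (ties go to fewer parameters)
    aic_ranked: float | None = None


# ---------------------------------------------------------------------------
# dataset construction from a run table
# ---------------------------------------------------------------------------

def build_stage_dataset(runs: pd.DataFrame, stage: str, geom: TabletGeometry, x_max: float,
                        y_max: float = 60.0) -> StageDataset:
    """Derive the per-stage predictors/response from a validated run table.

    The run table follows the schema of :mod:`tabrom.io` (weights in mg,
    densities in g/cm^3, thicknesses in mm, forces in kN, hardness in N).
    Responses are fitted in: bulk density kg/m^3, filling efficacy
    (dimensionless), compaction force kN, tablet relative density
    (dimensionless), tensile strength MPa.
    """
    W_g = runs["mean_weight_mg"].to_numpy(float) / 1e3
    rho_t = runs["true_density_gcc"].to_numpy(float)
    base = runs[["concentration_pct", "mixing_time_min"]].reset_index(drop=True)

    if stage == "bulk_density":
        pred = base.assign(true_density_gcc=rho_t)
        resp = runs["bulk_density_gcc"].to_numpy(float) * 1e3
        return StageDataset(stage, pred, resp, x_max, y_max, geom, "bulk_density", "kg/m^3")
    if stage == "weight":
        v_fill = rom_core.fill_volume(geom, runs["dosing_mm"].to_numpy(float))
        eta = W_g / (runs["bulk_density_gcc"].to_numpy(float) * v_fill / 1e3)
        pred = pd.DataFrame(
            {
                "speed_ratio": runs["feedframe_rpm"].to_numpy(float)
                / runs["turret_rpm"].to_numpy(float),
                "fill_ratio": runs["dosing_mm"].to_numpy(float) / geom.die_diameter_mm,
            }
        )
        return StageDataset(stage, pred, eta, x_max, y_max, geom, "filling_efficacy", "-")
    if stage == "compaction":
        v_id = rom_core.tablet_volume(geom, runs["in_die_thickness_mm"].to_numpy(float))
        rho_id = W_g / (rho_t * v_id / 1e3)
        pred = base.assign(rho_in_die=rho_id)
        resp = runs["compaction_force_kN"].to_numpy(float)
        return StageDataset(stage, pred, resp, x_max, y_max, geom, "compaction_force", "kN")
    if stage == "elastic_recovery":
        v_id = rom_core.tablet_volume(geom, runs["in_die_thickness_mm"].to_numpy(float))
        v_tab = rom_core.tablet_volume(geom, runs["tablet_thickness_mm"].to_numpy(float))
        pred = base.assign(rho_in_die=W_g / (rho_t * v_id / 1e3))
        resp = W_g / (rho_t * v_tab / 1e3)
        return StageDataset(stage, pred, resp, x_max, y_max, geom, "tablet_density", "-")
    if stage == "tensile_strength":
        v_tab = rom_core.tablet_volume(geom, runs["tablet_thickness_mm"].to_numpy(float))
        pred = base.assign(rho_tablet=W_g / (rho_t * v_tab / 1e3))
        resp = rom_core.pitt_tensile_strength(
            runs["hardness_N"].to_numpy(float), geom, runs["tablet_thickness_mm"].to_numpy(float)
        )
        return StageDataset(stage, pred, resp, x_max, y_max, geom, "tensile_strength", "MPa")
    raise ValueError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _coupled_functions(combination: ModelCombination, theta: Mapping[str, float],
                       X, Y) -> dict[str, np.ndarray]:
    out = {}
    for fname, vid in zip(STAGE_FUNCTIONS[combination.stage], combination.variant_ids):
        coefs = {
            k.split(".", 1)[1]: v for k, v in theta.items() if k.startswith(fname + ".")
        }
        out[fname] = eval_rational(get_variant(vid), RationalParams.from_dict(coefs), X, Y)
    return out


def stage_predict(stage: str, combination: ModelCombination | str,
                  theta: Mapping[str, float], predictors: pd.DataFrame,
                  x_max: float, y_max: float = 60.0,
                  geom: TabletGeometry | None = None, strict: bool = True) -> np.ndarray:
    """Predicted stage response for each run in ``predictors``.

    Composes the coupled rational parameter functions xi(X, Y; theta) with the
    stage ROM equation. ``strict=False`` clamps the Kawakita singularity, which
    the optimizer relies on while exploring infeasible parameter regions.
    """
    if stage == "weight":
        form = WEIGHT_MODELS[combination][0] if isinstance(combination, str) else FillingForm.SECOND_ORDER
        xi = tuple(theta.get(f"xi{i}", 0.0) for i in range(1, 6))
        return np.asarray(
            rom_core.filling_efficacy(
                xi,
                predictors["speed_ratio"].to_numpy(float),
                1.0,
                predictors["fill_ratio"].to_numpy(float),
                1.0,
                form=form,
            )
        )
    assert isinstance(combination, ModelCombination)
    X = normalize(predictors["concentration_pct"].to_numpy(float), x_max, theta.get("r_x", 1.0))
    Y = normalize(predictors["mixing_time_min"].to_numpy(float), y_max, theta.get("r_y", 1.0))
    funcs = _coupled_functions(combination, theta, X, Y)
    if stage == "bulk_density":
        return funcs["phi"] * predictors["true_density_gcc"].to_numpy(float) * 1e3
    if stage == "compaction":
        if geom is None:
            raise ValueError("compaction prediction needs the tooling geometry")
        return np.asarray(
            rom_core.kawakita_force(
                predictors["rho_in_die"].to_numpy(float),
                funcs["a"], funcs["inv_b"], funcs["rho_c"],
                geom.die_diameter_mm, strict=strict,
            )
        )
    if stage == "elastic_recovery":
        rho_id = predictors["rho_in_die"].to_numpy(float)
        eps = rom_core.elastic_recovery(
            rho_id, funcs["eps0"], np.clip(funcs["rho_c_eps"], 0.0, 1.0 - 1e-9),
            max(theta.get("n_exp", 1.0), 1e-6),
        )
        return np.asarray(rom_core.tablet_density(rho_id, np.clip(eps, 0.0, 1.0 - 1e-12)))
    if stage == "tensile_strength":
        return np.asarray(
            rom_core.leuenberger_tensile(
                predictors["rho_tablet"].to_numpy(float),
                np.clip(funcs["sigma0"], 1e-12, None),
                np.clip(funcs["rho_c_sigma"], 0.0, 1.0 - 1e-9),
            )
        )
    raise ValueError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# goodness of fit and the information criterion
# ---------------------------------------------------------------------------

def sse(dataset: StageDataset, combination, theta: Mapping[str, float]) -> float:
    """Sum of squared errors of a combination on a stage dataset."""
    pred = stage_predict(
        dataset.stage, combination, theta, dataset.predictors,
        dataset.x_max, dataset.y_max, dataset.geom, strict=False,
    )
    return float(np.sum((pred - dataset.response) ** 2))


def r_squared(sse_value: float, responses: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST (SST about the mean)."""
    responses = np.asarray(responses, dtype=float)
    sst = float(np.sum((responses - responses.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if sse_value == 0.0 else -math.inf
    return 1.0 - sse_value / sst


def aic(sse_value: float, n: int, n_params: int) -> float:
    """Akaike information criterion, AIC = n ln(SSE/n) + 2 Np.

    For n < 30 the second-order small-sample correction
    2 Np (Np + 1) / (n - Np - 1) is added (the n >= 30 boundary uses the
    uncorrected branch). A perfect fit (SSE = 0) returns -inf, which ranks
    best.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sse_value < 0:
        raise ValueError("SSE must be >= 0")
    if n < 30 and n - n_params - 1 <= 0:
        raise ValueError("small-sample correction needs n > Np + 1")
    if sse_value == 0.0:
        return -math.inf
    value = n * math.log(sse_value / n) + 2 * n_params
    if n < 30:
        value += 2 * n_params * (n_params + 1) / (n - n_params - 1)
    return value


# ---------------------------------------------------------------------------
# lower problem: constrained SSE minimization for one combination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ParamSpec:
    name: str
    kind: str  # 'log' | 'lin'
    lo: float  # internal-space box
    hi: float


def _layout(combination: ModelCombination, constraints: StageConstraints) -> list[_ParamSpec]:
    specs: list[_ParamSpec] = []
    if combination.r_free:
        r_lo, r_hi = constraints.r_box
        specs += [_ParamSpec("r_x", "lin", r_lo, r_hi), _ParamSpec("r_y", "lin", r_lo, r_hi)]
    log_lo = math.log10(constraints.coef_box[0])
    log_hi = math.log10(constraints.coef_box[1])
    for fname, vid in zip(STAGE_FUNCTIONS[combination.stage], combination.variant_ids):
        lb = constraints.bound_for(fname)
        for coef in get_variant(vid).coefficient_names:
            if coef == "p4" and fname in _RELATIVE:
                specs.append(_ParamSpec(f"{fname}.p4", "lin", max(lb, 1e-8), 1.0))
            else:
                specs.append(_ParamSpec(f"{fname}.{coef}", "log", log_lo, log_hi))
    for extra in combination.extra_params:
        lo, hi = constraints.n_exp_box
        specs.append(_ParamSpec(extra, "lin", lo, hi))
    return specs


def _theta_from_internal(z: np.ndarray, specs: Sequence[_ParamSpec],
                         combination: ModelCombination) -> dict[str, float]:
    theta = {
        s.name: (10.0 ** zi if s.kind == "log" else float(zi)) for s, zi in zip(specs, z)
    }
    theta.setdefault("r_x", 1.0)
    theta.setdefault("r_y", 1.0)
    return theta


def _internal_from_theta(theta: Mapping[str, float], specs: Sequence[_ParamSpec]) -> np.ndarray:
    z = np.empty(len(specs))
    for i, s in enumerate(specs):
        v = float(theta[s.name])
        z[i] = math.log10(max(v, 1e-300)) if s.kind == "log" else v
        z[i] = min(max(z[i], s.lo), s.hi)
    return z


def _penalties(combination: ModelCombination, theta: Mapping[str, float],
               dataset: StageDataset, constraints: StageConstraints,
               weight: float) -> list[float]:
    """Violations of the function-valued [lb, 1] bounds for relative quantities."""
    pens: list[float] = []
    relative = [
        (f, v)
        for f, v in zip(STAGE_FUNCTIONS[combination.stage], combination.variant_ids)
        if f in _RELATIVE
    ]
    if not relative:
        return pens
    X = normalize(dataset.predictors["concentration_pct"].to_numpy(float), dataset.x_max,
                  theta.get("r_x", 1.0))
    Y = normalize(dataset.predictors["mixing_time_min"].to_numpy(float), dataset.y_max,
                  theta.get("r_y", 1.0))
    for fname, vid in relative:
        lb = constraints.bound_for(fname)
        coefs = RationalParams.from_dict(
            {k.split(".", 1)[1]: v for k, v in theta.items() if k.startswith(fname + ".")}
        )
        variant = get_variant(vid)
        vals = np.atleast_1d(eval_rational(variant, coefs, X, Y))
        lims = limit_values(variant, coefs)
        lo = min(vals.min(), lims["f(inf,inf)"])
        hi = max(vals.max(), lims["f(inf,inf)"])
        pens.append(weight * max(0.0, lb - lo))
        pens.append(weight * max(0.0, hi - 1.0))
    return pens


def _compiled_residuals(dataset: StageDataset, combination: ModelCombination,
                        constraints: StageConstraints, specs: Sequence[_ParamSpec],
                        pen_w: float):
    """Build a fast residual closure over the internal parameter vector.

    Numerically identical to ``stage_predict`` + ``_penalties`` (pinned by a
    test), but caches predictor arrays, skips re-validation, caches X and Y
    when the normalization exponents are fixed, and reuses the evaluated
    parameter functions for the penalty terms. The optimizer calls this tens
    of thousands of times per stage, so the savings dominate fit time.
    """
    stage = dataset.stage
    fnames = STAGE_FUNCTIONS[stage]
    variants = [get_variant(v) for v in combination.variant_ids]
    pred_df = dataset.predictors
    c = pred_df["concentration_pct"].to_numpy(float)
    tm = pred_df["mixing_time_min"].to_numpy(float)
    resp = dataset.response
    idx = {s.name: i for i, s in enumerate(specs)}
    kinds = [s.kind for s in specs]

    def val(z, name, default=0.0):
        i = idx.get(name)
        if i is None:
            return default
        return 10.0 ** z[i] if kinds[i] == "log" else float(z[i])

    r_free = combination.r_free
    if not r_free:
        X_fix = c / (dataset.x_max - c)
        Y_fix = tm / (dataset.y_max - tm)

    if stage == "bulk_density":
        rho_t = pred_df["true_density_gcc"].to_numpy(float)
    elif stage in ("compaction", "elastic_recovery"):
        rho_arr = pred_df["rho_in_die"].to_numpy(float)
    else:
        rho_arr = pred_df["rho_tablet"].to_numpy(float)
    if stage == "compaction":
        area = math.pi * dataset.geom.die_diameter_mm**2 / 4.0

    lbs = {f: constraints.bound_for(f) for f in fnames if f in _RELATIVE}

    def residuals(z: np.ndarray) -> np.ndarray:
        if r_free:
            X = (c / (dataset.x_max - c)) ** val(z, "r_x", 1.0)
            Y = (tm / (dataset.y_max - tm)) ** val(z, "r_y", 1.0)
        else:
            X, Y = X_fix, Y_fix
        XY = X * Y
        funcs: dict[str, np.ndarray | float] = {}
        pens: list[float] = []
        for fname, variant in zip(fnames, variants):
            p4 = val(z, f"{fname}.p4")
            if variant.base is RationalBase.CONSTANT:
                f, joint = p4, p4
            else:
                p1 = val(z, f"{fname}.p1")
                q1 = val(z, f"{fname}.q1")
                if variant.base is RationalBase.FIRST_DEGREE:
                    lin = val(z, f"{fname}.q2") * X + val(z, f"{fname}.q3") * Y + 1.0
                    joint = p1 / q1 if q1 > 0 else np.inf
                else:
                    q5, q6 = val(z, f"{fname}.q5"), val(z, f"{fname}.q6")
                    lin = q5 * X**2 + q6 * Y**2 + 1.0
                    d = q1 + q5 + q6
                    joint = (p1 + p4 * (q5 + q6)) / d if d > 0 else np.inf
                f = (p1 * XY + p4 * lin) / (q1 * XY + lin)
            funcs[fname] = f
            if fname in lbs:
                vmin = f if np.isscalar(f) else float(np.min(f))
                vmax = f if np.isscalar(f) else float(np.max(f))
                pens.append(pen_w * max(0.0, lbs[fname] - min(vmin, joint)))
                pens.append(pen_w * max(0.0, max(vmax, joint) - 1.0))

        if stage == "bulk_density":
            pred = funcs["phi"] * rho_t * 1e3
        elif stage == "compaction":
            a, inv_b, rho_c = funcs["a"], funcs["inv_b"], funcs["rho_c"]
            den = rho_arr * (np.asarray(a) - 1.0) + rho_c
            singular = (rho_arr > rho_c) & (den <= 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = area * inv_b * (rho_arr - rho_c) / np.where(den > 0, den, 1.0)
            F = np.where(singular, 1e12, F)
            pred = np.where(rho_arr <= rho_c, 0.0, F / rom_core.N_PER_KN)
        elif stage == "elastic_recovery":
            rce = np.clip(funcs["rho_c_eps"], 0.0, 1.0 - 1e-9)
            x = np.clip((rho_arr - rce) / (1.0 - rce), 0.0, None)
            eps = funcs["eps0"] * x ** max(val(z, "n_exp", 1.0), 1e-6)
            pred = rho_arr * (1.0 - np.clip(eps, 0.0, 1.0 - 1e-12))
        else:
            rcs = np.clip(funcs["rho_c_sigma"], 0.0, 1.0 - 1e-9)
            s0 = np.clip(funcs["sigma0"], 1e-12, None)
            sig = s0 * (1.0 - (1.0 - rho_arr) / (1.0 - rcs) * np.exp(rho_arr - rcs))
            pred = np.where(rho_arr <= rcs, 0.0, sig)

        res = pred - resp
        return np.concatenate([res, pens]) if pens else res

    return residuals


def _fit_weight(dataset: StageDataset, model_name: str, seed: int) -> FitResult:
    form, free = WEIGHT_MODELS[model_name]
    s = dataset.predictors["speed_ratio"].to_numpy(float)
    f = dataset.predictors["fill_ratio"].to_numpy(float)
    eta = dataset.response
    if form is FillingForm.SU_LINEAR:
        # eta - 1 = -xi1 (nT/nF) + xi2 (t_fill/D)
        A = np.column_stack([-1.0 / s, f])
        coef, *_ = np.linalg.lstsq(A, eta - 1.0, rcond=None)
        theta = {"xi1": float(coef[0]), "xi2": float(coef[1])}
    else:
        features = {"xi1": np.ones_like(s), "xi2": s, "xi3": f, "xi4": f**2, "xi5": s * f}
        A = np.column_stack([features[name] for name in free])
        coef, *_ = np.linalg.lstsq(A, eta, rcond=None)
        theta = {name: 0.0 for name in features}
        theta.update({name: float(c) for name, c in zip(free, coef)})
    sse_val = sse(dataset, model_name, theta)
    n_par = len(free)
    return FitResult(
        stage="weight", label=model_name, theta=theta, sse=sse_val,
        r2=r_squared(sse_val, eta), n_params=n_par,
        aic=aic(sse_val, dataset.n, n_par), n_data=dataset.n, seed=seed,
    )


def fit_combination(dataset: StageDataset, combination: ModelCombination | str,
                    constraints: StageConstraints | None = None, seed: int = 0,
                    n_starts: int = 32, extra_starts: Iterable[Mapping[str, float]] = (),
                    probes_per_start: int = 24, patience: int | None = None,
                    sse_target: float | None = None) -> FitResult:
    """Estimate theta for one model combination by multi-start least squares.

    The global stage screens ``probes_per_start * n_starts`` Latin-hypercube
    points in the internal (log-transformed) box by raw cost and refines the
    ``n_starts`` best with bounded trust-region least squares, in screening
    order. Refinement stops early once the cost reaches ``sse_target``
    (default: the 1e-12 x SST measurement-resolution floor) or after
    ``patience`` consecutive refinements without meaningful improvement.
    Deterministic given ``seed``. ``extra_starts`` may supply additional
    starting thetas (warm starts from nested fits, or the point estimate when
    refitting bootstrap resamples); they are refined first.
    """
    constraints = constraints or StageConstraints()
    if dataset.stage == "weight":
        if not isinstance(combination, str):
            raise TypeError("weight stage expects a model name from WEIGHT_MODELS")
        return _fit_weight(dataset, combination, seed)
    assert isinstance(combination, ModelCombination)
    if combination.stage != dataset.stage:
        raise ValueError("combination/stage mismatch")
    n_par = param_count(combination)
    if dataset.n < n_par + 2:
        raise ValueError(f"need at least Np + 2 = {n_par + 2} runs to fit {combination.label()}")

    specs = _layout(combination, constraints)
    resp = dataset.response
    sst = float(np.sum((resp - resp.mean()) ** 2))
    scale = float(np.std(resp)) or 1.0
    pen_w = 100.0 * scale
    if sse_target is None:
        sse_target = 1e-12 * sst
    if patience is None:
        patience = max(4, n_starts // 4)

    residuals = _compiled_residuals(dataset, combination, constraints, specs, pen_w)

    lo = np.array([s.lo for s in specs])
    hi = np.array([s.hi for s in specs])
    n_starts = max(n_starts, 1)
    sampler = qmc.LatinHypercube(d=len(specs), seed=seed)
    probes = lo + sampler.random(probes_per_start * n_starts) * (hi - lo)
    costs = np.array([float(np.sum(residuals(z) ** 2)) for z in probes])
    order = np.argsort(costs)[:n_starts]
    starts = [_internal_from_theta(t, specs) for t in extra_starts]
    starts += [probes[i] for i in order]

    best_cost, best_z, converged, stall = np.inf, starts[0], False, 0
    for z0 in starts:
        try:
            sol = least_squares(residuals, z0, bounds=(lo, hi), method="trf",
                                x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=60 * len(specs))
        except Exception:
            continue
        if sol.cost < best_cost * (1.0 - 1e-3):
            stall = 0
        else:
            stall += 1
        if sol.cost < best_cost:
            best_cost, best_z, converged = sol.cost, sol.x, True
        if 2.0 * best_cost <= sse_target or stall >= patience:
            break

    theta = _theta_from_internal(best_z, specs, combination)
    sse_val = sse(dataset, combination, theta)
    fit = FitResult(
        stage=dataset.stage, label=combination.label(), theta=theta, sse=sse_val,
        r2=r_squared(sse_val, resp), n_params=n_par,
        aic=aic(sse_val, dataset.n, n_par), n_data=dataset.n, seed=seed,
        combination=combination, converged=converged,
    )
    fit.overfit = overfit_flag(fit)
    return fit


# ---------------------------------------------------------------------------
# upper problem: ranking over the library
# ---------------------------------------------------------------------------

def default_library(stage: str) -> list:
    """The admissible model library for a stage.

    Bulk density explores all fifteen single variants; compaction the 41
    restricted triples; elastic recovery and tensile strength the 25
    first-degree pairs; weight its own five linear forms.
    """
    if stage == "bulk_density":
        return [ModelCombination(stage, (i,)) for i in range(1, 16)]
    if stage == "weight":
        return list(WEIGHT_MODELS)
    if stage == "compaction":
        return [ModelCombination(stage, t) for t in compaction_triple_library()]
    if stage == "elastic_recovery":
        return [
            ModelCombination(stage, p, extra_params=("n_exp",)) for p in eq16_pair_library()
        ]
    if stage == "tensile_strength":
        return [ModelCombination(stage, p) for p in eq16_pair_library()]
    raise ValueError(f"unknown stage {stage!r}")


def _embed_theta(source: Mapping[str, float], target: ModelCombination) -> dict[str, float]:
    """Re-express a fitted theta of a (nested) simpler combination in the
    parameter space of ``target``, as a warm start.

    A constant f = c embeds exactly into any rational variant via p4 = c,
    p1 = c q1 (the function is then identically c); coefficients absent from
    the source start at the bottom of the positive box, exponents at 1.
    """
    theta: dict[str, float] = {}
    if target.r_free:
        theta["r_x"] = source.get("r_x", 1.0)
        theta["r_y"] = source.get("r_y", 1.0)
    for fname, vid in zip(STAGE_FUNCTIONS[target.stage], target.variant_ids):
        variant = get_variant(vid)
        p4 = source.get(f"{fname}.p4", 0.5)
        for coef in variant.coefficient_names:
            key = f"{fname}.{coef}"
            if key in source:
                theta[key] = source[key]
            elif coef == "p4":
                theta[key] = p4
            elif coef == "p1":
                theta[key] = p4 * source.get(f"{fname}.q1", 1e-8)
            else:
                theta[key] = 1e-8
        if f"{fname}.p1" not in source and f"{fname}.q1" not in source:
            # source function was constant: make the embedding exact
            theta[f"{fname}.q1"] = 1e-4
            theta[f"{fname}.p1"] = p4 * 1e-4
    for extra in target.extra_params:
        theta[extra] = source.get(extra, 1.0)
    return theta


def select_model(dataset: StageDataset, library: Sequence | None = None,
                 constraints: StageConstraints | None = None, seed: int = 0,
                 n_starts: int = 32, sse_floor_rel: float = 1e-10) -> list[FitResult]:
    """Fit every combination in the library and rank by AICc, ascending.

    Combinations are fitted in order of increasing parameter count, each warm
    started from the best already-fitted simpler combinations (a constant
    embeds exactly into every variant), which enforces the nesting property
    that a more general model never fits worse. SSE values below
    ``sse_floor_rel`` x SST are treated as indistinguishable from a perfect
    fit at measurement resolution: their AIC for ranking is computed at the
    floor, so among models that interpolate the data the one with the fewest
    parameters wins the tie (ties broken by smaller Np, then label). Each
    result still stores its exact AIC.
    """
    library = default_library(dataset.stage) if library is None else list(library)
    if not library:
        raise ValueError("empty model library")
    if dataset.stage == "weight":
        fits = [fit_combination(dataset, name, constraints, seed=seed) for name in library]
    else:
        order = sorted(range(len(library)), key=lambda k: (param_count(library[k]), k))
        done: list[FitResult] = []
        fits_by_idx: dict[int, FitResult] = {}
        for k in order:
            combo = library[k]
            sources = sorted(done, key=lambda f: f.sse)[:3]
            warm = [_embed_theta(f.theta, combo) for f in sources]
            fit = fit_combination(dataset, combo, constraints, seed=seed + 17 * k,
                                  n_starts=n_starts, extra_starts=warm)
            fits_by_idx[k] = fit
            done.append(fit)
        fits = [fits_by_idx[k] for k in range(len(library))]
    resp = dataset.response
    sst = float(np.sum((resp - resp.mean()) ** 2))
    floor = sse_floor_rel * max(sst, float(np.sum(resp**2)))
    for fit in fits:
        fit.aic_ranked = aic(max(fit.sse, floor), fit.n_data, fit.n_params)
    return sorted(fits, key=lambda f: (f.aic_ranked, f.n_params, f.label))


def best_fit(ranked: Sequence[FitResult], skip_overfit: bool = True) -> FitResult:
    """Best model of a ranking; overfit-flagged fits are skipped (post hoc rule)
    but remain in the ranked list."""
    for fit in ranked:
        if not (skip_overfit and fit.overfit):
            return fit
    return ranked[0]


def overfit_flag(fit: FitResult, threshold: float = 1e3) -> bool:
    """Flag a fit whose coefficients are excessively large in magnitude.

    True iff any rational coefficient exceeds ``threshold`` x its natural scale
    max(1, |p4|) within its own parameter function. The flagged fit stays in
    the ranked list; only the post hoc best-model choice skips it.
    """
    for fname in STAGE_FUNCTIONS.get(fit.stage, ()):
        p4 = abs(fit.theta.get(f"{fname}.p4", 0.0))
        natural = threshold * max(1.0, p4)
        for key, value in fit.theta.items():
            if key.startswith(fname + ".") and abs(value) > natural:
                return True
    return False


def bootstrap_ci(dataset: StageDataset, best: FitResult, B: int = 1000, seed: int = 0,
                 n_starts: int = 4, level: float = 0.95,
                 constraints: StageConstraints | None = None) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap confidence intervals for the fitted parameters.

    Case resampling of whole runs; each resample is refitted starting from the
    point estimate plus ``n_starts`` fresh multi-starts. ``B = 1`` degenerates
    to a single-resample interval (both ends equal) and is permitted only for
    smoke testing.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    names = [k for k in best.theta]
    draws = {k: [] for k in names}
    combo = best.combination if best.combination is not None else best.label
    for b in range(B):
        idx = rng.integers(0, dataset.n, size=dataset.n)
        try:
            refit = fit_combination(
                dataset.subset(idx), combo, constraints, seed=seed + 1000 + b,
                n_starts=n_starts, extra_starts=[best.theta],
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        for k in names:
            draws[k].append(refit.theta.get(k, np.nan))
    alpha = (1.0 - level) / 2.0
    ci = {}
    for k in names:
        arr = np.asarray(draws[k], dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            ci[k] = (math.nan, math.nan)
        else:
            ci[k] = (float(np.quantile(arr, alpha)), float(np.quantile(arr, 1.0 - alpha)))
    return ci


# ---------------------------------------------------------------------------
# sequential full-campaign fit
# ---------------------------------------------------------------------------

_STAGED_BOUND_SLACK = 0.01


def sequential_campaign_fit(runs: pd.DataFrame, geom: TabletGeometry, x_max: float,
                            y_max: float = 60.0, seed: int = 0, n_starts: int = 32,
                            libraries: Mapping[str, Sequence] | None = None,
                            sse_floor_rel: float = 1e-10,
                            ) -> dict[str, dict]:
    """Fit all five stages in causal order with staged onset-density bounds.

    Order: bulk density -> weight -> compaction -> elastic recovery -> tensile
    strength. The fitted jamming density rho_c (its minimum over the campaign
    runs, minus a small numerical slack for printed-precision robustness)
    lower-bounds rho_c_eps, whose estimate in turn lower-bounds rho_c_sigma.
    A stage failure raises with a stage-naming diagnostic.

    Returns ``{stage: {"ranking": [FitResult...], "best": FitResult}}``.
    """
    libraries = libraries or {}
    results: dict[str, dict] = {}
    lower_bounds: dict[str, float] = {}

    def run_stage(stage: str) -> FitResult:
        dataset = build_stage_dataset(runs, stage, geom, x_max, y_max)
        constraints = StageConstraints(lower_bounds=dict(lower_bounds))
        try:
            ranked = select_model(dataset, libraries.get(stage), constraints,
                                  seed=seed, n_starts=n_starts, sse_floor_rel=sse_floor_rel)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        best = best_fit(ranked)
        results[stage] = {"ranking": ranked, "best": best, "dataset": dataset}
        return best

    run_stage("bulk_density")
    run_stage("weight")

    best_comp = run_stage("compaction")
    lower_bounds["rho_c_eps"] = max(
        0.0, _min_function_value(best_comp, "rho_c") - _STAGED_BOUND_SLACK
    )
    best_rec = run_stage("elastic_recovery")
    lower_bounds.pop("rho_c_eps")
    lower_bounds["rho_c_sigma"] = max(
        0.0, _min_function_value(best_rec, "rho_c_eps") - _STAGED_BOUND_SLACK
    )
    run_stage("tensile_strength")
    return results


def _min_function_value(fit: FitResult, fname: str) -> float:
    """Point estimate of the lower bound of a fitted onset-density function:
    the smaller of its two corner limits, which brackets the monotone
    first-degree family over the whole domain."""
    assert fit.combination is not None
    idx = STAGE_FUNCTIONS[fit.stage].index(fname)
    vid = fit.combination.variant_ids[idx]
    coefs = RationalParams.from_dict(
        {k.split(".", 1)[1]: v for k, v in fit.theta.items() if k.startswith(fname + ".")}
    )
    lims = limit_values(get_variant(vid), coefs)
    return min(lims["f(0,0)"], lims["f(inf,inf)"])
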