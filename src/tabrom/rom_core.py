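"""Tablet geometry, density bookkeeping, and the four-stage tableting ROM equations.

The reduced-order models (ROMs) cover the four stages of powder compaction on a
rotary tablet press:

* die filling      -- filling efficacy eta and tablet weight W,
* main compression -- Kawakita-type punch force as a function of the in-die
                      relative density,
* unloading        -- power-law elastic recovery and out-of-die tablet density,
* tablet strength  -- Leuenberger tensile strength versus tablet density,
                      plus Pitt's diametral-compression formula to convert a
                      measured hardness (breaking force) into a tensile strength
                      for convex (cup-faced) tablets.

Everything here is a plain parameterized equation; the coupling of parameters to
upstream mixing conditions lives in :mod:`tabrom.rational` and
:mod:`tabrom.selection`.

Unit conventions (centralized here, used everywhere else):

* lengths in mm, volumes in mm^3,
* densities in g/cm^3 (relative densities dimensionless),
* masses in g (weights reported in mg at the I/O layer),
* pressures in MPa, forces in kN (mm^2 x MPa = N; divided by 1e3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "TabletGeometry",
    "ThicknessSet",
    "BlendState",
    "StageParameters",
    "FillingForm",
    "tablet_volume",
    "fill_volume",
    "thickness_from_volume",
    "relative_density",
    "pitt_tensile_strength",
    "pitt_hardness_from_strength",
    "filling_efficacy",
    "weight_from_efficacy",
    "kawakita_force",
    "elastic_recovery",
    "tablet_density",
    "leuenberger_tensile",
    "production_rate",
    "N_PER_KN",
]

N_PER_KN = 1e3
MM3_PER_CM3 = 1e3


@dataclass(frozen=True)
class TabletGeometry:
    """Die/punch geometry of the press tooling.

    Parameters
    ----------
    die_diameter_mm : float
        Die diameter D (> 0).
    cup_depth_mm : float
        Depth h of the (spherical-cap) punch cup; 0 for flat-faced tooling.
    num_die_stations : int or None
        Number of die stations Nd on the turret (used for production rate).
    """

    die_diameter_mm: float
    cup_depth_mm: float = 0.0
    num_die_stations: int | None = None

    def __post_init__(self) -> None:
        if self.die_diameter_mm <= 0:
            raise ValueError("die diameter must be > 0")
        if self.cup_depth_mm < 0:
            raise ValueError("cup depth must be >= 0")
        if self.num_die_stations is not None and self.num_die_stations < 1:
            raise ValueError("num_die_stations must be >= 1")

    @property
    def cup_volume_mm3(self) -> float:
        """Volume of the two punch cups, (pi h / 6)(3 D^2 / 4 + h^2)."""
        D, h = self.die_diameter_mm, self.cup_depth_mm
        return math.pi * h / 6.0 * (3.0 * D**2 / 4.0 + h**2)

    @property
    def cross_section_mm2(self) -> float:
        return math.pi * self.die_diameter_mm**2 / 4.0


@dataclass(frozen=True)
class ThicknessSet:
    """Measured band thicknesses (mm) through the compaction cycle."""

    t_fill: float
    t_in_die: float
    t_tablet: float
    t_pc: float | None = None
    cup_depth_mm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t_fill", "t_in_die", "t_tablet"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def overall_thickness(self) -> float:
        """H_tablet = t_tablet + 2h, the convex-tablet overall thickness."""
        return self.t_tablet + 2.0 * self.cup_depth_mm


@dataclass(frozen=True)
class BlendState:
    """Blend-level material state entering the press."""

    true_density: float  # g/cm^3
    bulk_density: float  # g/cm^3
    excipient_concentration: float  # % w/w
    mixing_time: float  # min

    def __post_init__(self) -> None:
        if not 0.0 < self.bulk_density <= self.true_density:
            raise ValueError("require 0 < bulk density <= true density")
        if self.excipient_concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.mixing_time < 0:
            raise ValueError("mixing time must be >= 0")


class FillingForm(str, Enum):
    """Functional form of the filling-efficacy model."""

    SU_LINEAR = "su_linear"  # eta = 1 - xi1 (nT/nF) + xi2 (t_fill/D)
    SECOND_ORDER = "second_order"  # full quadratic form in nF/nT and t_fill/D


@dataclass(frozen=True)
class StageParameters:
    """Plain per-stage ROM parameter set (no upstream coupling).

    Relative quantities (a, eps0, and the three onset densities) live in [0, 1];
    the onsets must be staged: rho_c < rho_c_eps < rho_c_sigma.
    """

    # die filling (second-order form; xi1=xi5=0 recovers the reduced variants)
    xi: tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    # compaction (Kawakita)
    a: float = 0.8
    inv_b: float = 10.0  # MPa
    rho_c: float = 0.2
    # elastic recovery
    eps0: float = 0.1
    rho_c_eps: float = 0.4
    n_exp: float = 1.0
    # tensile strength (Leuenberger)
    sigma0: float = 10.0  # MPa
    rho_c_sigma: float = 0.5

    def __post_init__(self) -> None:
        for name in ("a", "eps0", "rho_c", "rho_c_eps", "rho_c_sigma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not self.rho_c < self.rho_c_eps < self.rho_c_sigma:
            raise ValueError("onset densities must satisfy rho_c < rho_c_eps < rho_c_sigma")
        if self.inv_b <= 0 or self.sigma0 <= 0 or self.n_exp <= 0:
            raise ValueError("inv_b, sigma0 and n_exp must be > 0")


def tablet_volume(geom: TabletGeometry, t: float) -> float:
    """Volume (mm^3) of a convex tablet with band thickness ``t`` (mm).

    V = pi D^2 t / 4 + (pi h / 6)(3 D^2 / 4 + h^2); the second term is the two
    spherical-cap cups and vanishes for flat tooling.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be >= 0")
    v = geom.cross_section_mm2 * t + geom.cup_volume_mm3
    return float(v) if v.ndim == 0 else v


def fill_volume(geom: TabletGeometry, t_fill: float) -> float:
    """Die fill volume (mm^3) at dosing position ``t_fill`` (same formula)."""
    return tablet_volume(geom, t_fill)


def thickness_from_volume(geom: TabletGeometry, volume_mm3: float) -> float:
    """Invert :func:`tablet_volume` for the band thickness (mm)."""
    t = (np.asarray(volume_mm3, dtype=float) - geom.cup_volume_mm3) / geom.cross_section_mm2
    if np.any(t <= 0):
        raise ValueError("volume smaller than the cup volume: no positive thickness")
    return float(t) if t.ndim == 0 else t


def relative_density(weight_g: float, true_density: float, volume_mm3) -> float:
    """Relative density rho = W / (rho_t V) at any point of the cycle.

    ``weight_g`` in g, ``true_density`` in g/cm^3, ``volume_mm3`` in mm^3.
    Values above 1 are unphysical for a real tablet and trigger a warning.
    """
    volume_mm3 = np.asarray(volume_mm3, dtype=float)
    if weight_g <= 0 or true_density <= 0 or np.any(volume_mm3 <= 0):
        raise ValueError("weight, true density and volume must all be > 0")
    rho = weight_g / (true_density * volume_mm3 / MM3_PER_CM3)
    if np.any(rho > 1.0):
        warnings.warn("relative density exceeds 1; check inputs", stacklevel=2)
    return float(rho) if rho.ndim == 0 else rho


def _pitt_denominator(geom: TabletGeometry, t_tablet) -> np.ndarray:
    H = np.asarray(t_tablet, dtype=float) + 2.0 * geom.cup_depth_mm
    D = geom.die_diameter_mm
    return 2.84 * H / D - 0.126 * H / np.asarray(t_tablet, dtype=float) + 3.15 * np.asarray(t_tablet, dtype=float) / D + 0.01


def pitt_tensile_strength(hardness_N, geom: TabletGeometry, t_tablet) -> np.ndarray | float:
    """Tensile strength (MPa) of a convex tablet from the breaking force (N).

    Pitt's diametral-compression formula:
    sigma_t = (10 F / pi D^2) / (2.84 H/D - 0.126 H/t + 3.15 t/D + 0.01),
    with H = t_tablet + 2h the overall thickness and t_tablet the band
    thickness. Lengths in mm, F in N, result in MPa.
    """
    F = np.asarray(hardness_N, dtype=float)
    if np.any(F < 0):
        raise ValueError("hardness must be >= 0")
    if np.any(np.asarray(t_tablet) <= 0):
        raise ValueError("tablet thickness must be > 0")
    den = _pitt_denominator(geom, t_tablet)
    if np.any(den <= 0):
        raise ValueError("degenerate tablet geometry: Pitt denominator <= 0")
    sigma = 10.0 * F / (math.pi * geom.die_diameter_mm**2) / den
    return float(sigma) if sigma.ndim == 0 else sigma


def pitt_hardness_from_strength(sigma_MPa, geom: TabletGeometry, t_tablet) -> np.ndarray | float:
    """Invert :func:`pitt_tensile_strength`: breaking force (N) from sigma_t (MPa)."""
    sigma = np.asarray(sigma_MPa, dtype=float)
    den = _pitt_denominator(geom, t_tablet)
    F = sigma * den * math.pi * geom.die_diameter_mm**2 / 10.0
    return float(F) if F.ndim == 0 else F


def filling_efficacy(xi, nF, nT, t_fill, D, form: FillingForm = FillingForm.SECOND_ORDER):
    """Filling efficacy eta = W / (rho_b V_fill) as a function of press settings.

    ``second_order`` (default):
        eta = xi1 + xi2 (nF/nT) + xi3 (t_fill/D) + xi4 (t_fill/D)^2
              + xi5 (nF/nT)(t_fill/D)
    ``su_linear`` (legacy two-parameter form):
        eta = 1 - xi1 (nT/nF) + xi2 (t_fill/D)

    The raw value is returned un-clipped; clipping to [0, 1] is a reporting
    concern, and fitting uses the raw value.
    """
    nT = np.asarray(nT, dtype=float)
    if np.any(nT <= 0):
        raise ValueError("turret speed nT must be > 0")
    speed_ratio = np.asarray(nF, dtype=float) / nT
    fill_ratio = np.asarray(t_fill, dtype=float) / float(D)
    if form == FillingForm.SU_LINEAR:
        xi1, xi2 = xi[0], xi[1]
        with np.errstate(divide="raise"):
            eta = 1.0 - xi1 / speed_ratio + xi2 * fill_ratio
    else:
        xi1, xi2, xi3, xi4, xi5 = xi
        eta = (
            xi1
            + xi2 * speed_ratio
            + xi3 * fill_ratio
            + xi4 * fill_ratio**2
            + xi5 * speed_ratio * fill_ratio
        )
    eta = np.asarray(eta, dtype=float)
    return float(eta) if eta.ndim == 0 else eta


def weight_from_efficacy(eta, bulk_density, fill_volume_mm3):
    """Tablet weight W (g) = eta rho_b V_fill."""
    W = np.asarray(eta, dtype=float) * np.asarray(bulk_density, dtype=float) * (
        np.asarray(fill_volume_mm3, dtype=float) / MM3_PER_CM3
    )
    return float(W) if W.ndim == 0 else W


def kawakita_force(rho_in_die, a, inv_b, rho_c, D: float, strict: bool = True):
    """Kawakita punch force (kN) at in-die relative density ``rho_in_die``.

    F = (pi D^2 / 4) (1/b) (rho - rho_c) / (rho (a - 1) + rho_c), with ``a`` the
    total compressibility, ``1/b`` (MPa) the mean punch pressure at half-maximal
    compression, and ``rho_c`` the jamming onset. Below rho_c the packing
    transmits no force (returns 0); the degree of compression
    (rho - rho_c)/rho approaching ``a`` is a singularity and raises when
    ``strict`` (with ``strict=False`` the force is clamped to a large finite
    value, which keeps optimizer exploration well-defined).

    The parameters may be arrays (broadcast against ``rho_in_die``), as they are
    when evaluated as rational functions of the mixing conditions per run.
    """
    rho = np.asarray(rho_in_die, dtype=float)
    a = np.asarray(a, dtype=float)
    inv_b = np.asarray(inv_b, dtype=float)
    rho_c = np.asarray(rho_c, dtype=float)
    if np.any(inv_b <= 0):
        raise ValueError("1/b must be > 0")
    den = rho * (a - 1.0) + rho_c
    singular = (rho > rho_c) & (den <= 0)
    if strict and np.any(singular):
        raise ValueError("degree of compression reached the Kawakita limit a: force diverges")
    with np.errstate(divide="ignore", invalid="ignore"):
        F_N = math.pi * D**2 / 4.0 * inv_b * (rho - rho_c) / np.where(den > 0, den, 1.0)
    F_N = np.where(singular, 1e12, F_N)
    F_kN = np.where(rho <= rho_c, 0.0, F_N / N_PER_KN)
    return float(F_kN) if F_kN.ndim == 0 else F_kN


def elastic_recovery(rho_in_die, eps0, rho_c_eps, n_exp):
    """Elastic recovery strain eps = eps0 ((rho - rho_c_eps)/(1 - rho_c_eps))^n.

    Zero below the onset density rho_c_eps; eps0 at full compaction (rho = 1).
    Parameters may be arrays broadcast against ``rho_in_die``.
    """
    eps0 = np.asarray(eps0, dtype=float)
    rho_c_eps = np.asarray(rho_c_eps, dtype=float)
    if np.any(rho_c_eps < 0) or np.any(rho_c_eps >= 1):
        raise ValueError("rho_c_eps must lie in [0, 1)")
    if np.any(np.asarray(n_exp) <= 0):
        raise ValueError("n_exp must be > 0")
    rho = np.asarray(rho_in_die, dtype=float)
    x = np.clip((rho - rho_c_eps) / (1.0 - rho_c_eps), 0.0, None)
    eps = eps0 * x**n_exp
    return float(eps) if eps.ndim == 0 else eps


def tablet_density(rho_in_die, eps_rho):
    """Out-of-die tablet relative density rho_tablet = rho_in_die (1 - eps)."""
    rho = np.asarray(rho_in_die, dtype=float) * (1.0 - np.asarray(eps_rho, dtype=float))
    return float(rho) if rho.ndim == 0 else rho


def leuenberger_tensile(rho_tablet, sigma0, rho_c_sigma):
    """Leuenberger tensile strength (MPa) versus tablet relative density.

    sigma_t = sigma0 [1 - ((1 - rho)/(1 - rho_c)) exp(rho - rho_c)], zero at and
    below the onset density rho_c_sigma and sigma0 at zero porosity (rho = 1).
    Parameters may be arrays broadcast against ``rho_tablet``.
    """
    sigma0 = np.asarray(sigma0, dtype=float)
    rho_c_sigma = np.asarray(rho_c_sigma, dtype=float)
    if np.any(rho_c_sigma < 0) or np.any(rho_c_sigma >= 1):
        raise ValueError("rho_c_sigma must lie in [0, 1)")
    if np.any(sigma0 <= 0):
        raise ValueError("sigma0 must be > 0")
    rho = np.asarray(rho_tablet, dtype=float)
    sigma = sigma0 * (1.0 - (1.0 - rho) / (1.0 - rho_c_sigma) * np.exp(rho - rho_c_sigma))
    sigma = np.where(rho <= rho_c_sigma, 0.0, sigma)
    return float(sigma) if sigma.ndim == 0 else sigma


def production_rate(num_die_stations: int, nT, weight_g):
    """Press throughput m_dot = Nd nT W (g/min for nT in rpm, W in g)."""
    if num_die_stations < 0:
        raise ValueError("number of die stations must be >= 0")
    m = num_die_stations * np.asarray(nT, dtype=float) * np.asarray(weight_g, dtype=float)
    return float(m) if m.ndim == 0 else m
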