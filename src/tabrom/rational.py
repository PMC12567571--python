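"""Constrained bivariate rational functions coupling ROM parameters to mixing.

Upstream mixing conditions — excipient concentration c and mixing time t_mix —
are first normalized onto [0, inf):

    X = (c / (c_max - c))^rX,    Y = (t / (t_max - t))^rY,

so that X = 0 means no lubricant/glidant and Y = 0 means no mixing. Each ROM
parameter xi is then a normalized bivariate rational function f(X, Y) from a
library of fifteen constrained variants built from two base forms,

    first degree :  f = (p1 XY + p4 (q2 X + q3 Y + 1)) / (q1 XY + q2 X + q3 Y + 1)
    second degree:  f = (p1 XY + p4 (q5 X^2 + q6 Y^2 + 1)) / (q1 XY + q5 X^2 + q6 Y^2 + 1)

Both enforce the mechanistic limits f(0, 0) = f(X, 0) = f(0, Y) = p4 (an
unmixed or excipient-free blend behaves like the plain formulation) by the
eliminations p2/q2 = p3/q3 = p4 and p5/q5 = p6/q6 = p4. The first-degree form
is monotone in X and Y; the second-degree form admits interior extrema and is
the route to non-monotonic responses such as over-lubricated bulk density.

Variant ids (1-15) are stable across the library:

====  ============================  =====================  ==============
id    base                          structural constraint  r exponents
====  ============================  =====================  ==============
1     first degree                  —                      free
2     first degree                  —                      rX = rY = 1
3     first degree                  q3 = 0                 free
4     first degree                  q3 = 0                 rX = rY = 1
5     first degree                  q2 = 0                 free
6     first degree                  q2 = 0                 rX = rY = 1
7     first degree                  q2 = q3 = 0            free
8     first degree                  q2 = q3 = 0            rX = rY = 1
9     constant f = p4               all                    rX = rY = 1
10    second degree                 —                      free
11    second degree                 —                      rX = rY = 1
12    second degree                 q6 = 0                 free
13    second degree                 q6 = 0                 rX = rY = 1
14    second degree                 q5 = 0                 free
15    second degree                 q5 = 0                 rX = rY = 1
====  ============================  =====================  ==============
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "RationalBase",
    "RationalVariant",
    "RationalParams",
    "NormalizationSpec",
    "ModelCombination",
    "VARIANTS",
    "get_variant",
    "normalize",
    "eval_rational",
    "limit_values",
    "pair_library",
    "eq16_pair_library",
    "compaction_triple_library",
    "param_count",
    "library_to_json",
]


class RationalBase(str, Enum):
    FIRST_DEGREE = "first_degree"
    SECOND_DEGREE = "second_degree"
    CONSTANT = "constant"


@dataclass(frozen=True)
class RationalVariant:
    """One constrained variant of the normalized bivariate rational family."""

    id: int
    base: RationalBase
    zeroed: frozenset[str] = frozenset()
    r_free: bool = False

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        """Free non-exponent coefficients, in canonical order."""
        if self.base is RationalBase.CONSTANT:
            return ("p4",)
        qs = ("q1", "q2", "q3") if self.base is RationalBase.FIRST_DEGREE else ("q1", "q5", "q6")
        return ("p1", "p4") + tuple(q for q in qs if q not in self.zeroed)

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficient_names)

    @property
    def n_parameters(self) -> int:
        """Free-parameter count including rX, rY when the exponents are free."""
        return self.n_coefficients + (2 if self.r_free else 0)


def _v(i, base, zeroed=(), r_free=False):
    return RationalVariant(i, base, frozenset(zeroed), r_free)


VARIANTS: dict[int, RationalVariant] = {
    1: _v(1, RationalBase.FIRST_DEGREE, (), True),
    2: _v(2, RationalBase.FIRST_DEGREE, ()),
    3: _v(3, RationalBase.FIRST_DEGREE, ("q3",), True),
    4: _v(4, RationalBase.FIRST_DEGREE, ("q3",)),
    5: _v(5, RationalBase.FIRST_DEGREE, ("q2",), True),
    6: _v(6, RationalBase.FIRST_DEGREE, ("q2",)),
    7: _v(7, RationalBase.FIRST_DEGREE, ("q2", "q3"), True),
    8: _v(8, RationalBase.FIRST_DEGREE, ("q2", "q3")),
    9: _v(9, RationalBase.CONSTANT),
    10: _v(10, RationalBase.SECOND_DEGREE, (), True),
    11: _v(11, RationalBase.SECOND_DEGREE, ()),
    12: _v(12, RationalBase.SECOND_DEGREE, ("q6",), True),
    13: _v(13, RationalBase.SECOND_DEGREE, ("q6",)),
    14: _v(14, RationalBase.SECOND_DEGREE, ("q5",), True),
    15: _v(15, RationalBase.SECOND_DEGREE, ("q5",)),
}


def get_variant(variant_id: int) -> RationalVariant:
    try:
        return VARIANTS[int(variant_id)]
    except KeyError:
        raise KeyError(f"unknown rational variant id {variant_id!r}; valid ids are 1-15") from None


@dataclass(frozen=True)
class RationalParams:
    """Coefficients of one constrained rational function.

    Only the coefficients a variant actually uses need be set; the positivity
    constraints p > 0, q >= 0 are validated on construction. Normalization
    exponents are carried separately (they are shared across the coupled
    functions of one stage).
    """

    p1: float = 0.0
    p4: float = 0.0
    q1: float = 0.0
    q2: float = 0.0
    q3: float = 0.0
    q5: float = 0.0
    q6: float = 0.0

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3", "q5", "q6"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "RationalParams":
        return cls(**{k: float(v) for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class NormalizationSpec:
    """Normalization X = (v/(v_max - v))^r of an upstream variable onto [0, inf)."""

    x_max: float  # maximum excipient concentration (% w/w)
    y_max: float = 60.0  # maximum mixing time (min)
    r_x: float = 1.0
    r_y: float = 1.0

    def __post_init__(self) -> None:
        if self.x_max <= 0 or self.y_max <= 0:
            raise ValueError("x_max and y_max must be > 0")
        for r in (self.r_x, self.r_y):
            if not 0.0 < r <= 10.0:
                raise ValueError("normalization exponents must lie in (0, 10]")

    def xy(self, concentration, mixing_time):
        return (
            normalize(concentration, self.x_max, self.r_x),
            normalize(mixing_time, self.y_max, self.r_y),
        )


_SINGULARITY_GUARD = 1e-9


def normalize(v, v_max: float, r: float):
    """Map v in [0, v_max) to X = (v/(v_max - v))^r in [0, inf)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("value to normalize must be >= 0")
    if np.any(v >= v_max - _SINGULARITY_GUARD * v_max):
        raise ValueError(f"value at or above the normalization bound {v_max}: singular")
    x = (v / (v_max - v)) ** r
    return float(x) if x.ndim == 0 else x


def eval_rational(variant: RationalVariant | int, params: RationalParams, X, Y):
    """Evaluate a constrained variant at normalized inputs X, Y >= 0."""
    if isinstance(variant, int):
        variant = get_variant(variant)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(X < 0) or np.any(Y < 0):
        raise ValueError("normalized inputs must be >= 0")
    if variant.base is RationalBase.CONSTANT:
        out = np.broadcast_to(np.asarray(params.p4, dtype=float), np.broadcast_shapes(X.shape, Y.shape)).copy()
        return float(out) if out.ndim == 0 else out
    p1, p4, q1 = params.p1, params.p4, params.q1
    if variant.base is RationalBase.FIRST_DEGREE:
        q2 = 0.0 if "q2" in variant.zeroed else params.q2
        q3 = 0.0 if "q3" in variant.zeroed else params.q3
        lin = q2 * X + q3 * Y + 1.0
        num = p1 * X * Y + p4 * lin
        den = q1 * X * Y + lin
    else:
        q5 = 0.0 if "q5" in variant.zeroed else params.q5
        q6 = 0.0 if "q6" in variant.zeroed else params.q6
        quad = q5 * X**2 + q6 * Y**2 + 1.0
        num = p1 * X * Y + p4 * quad
        den = q1 * X * Y + quad
    out = num / den
    return float(out) if out.ndim == 0 else out


def limit_values(variant: RationalVariant | int, params: RationalParams) -> dict[str, float]:
    """Analytic limits of the constrained form at the corners of [0, inf)^2.

    The eliminations force f(0, 0) = f(inf, 0) = f(0, inf) = p4 for every
    variant. The joint limit along the diagonal X = Y -> inf is p1/q1 for the
    first-degree form and (p1 + p4 (q5 + q6)) / (q1 + q5 + q6) for the
    second-degree form (XY and the squared terms are the same degree there).
    """
    if isinstance(variant, int):
        variant = get_variant(variant)
    p4 = params.p4
    if variant.base is RationalBase.CONSTANT:
        joint = p4
    elif variant.base is RationalBase.FIRST_DEGREE:
        joint = params.p1 / params.q1 if params.q1 > 0 else np.inf
    else:
        q5 = 0.0 if "q5" in variant.zeroed else params.q5
        q6 = 0.0 if "q6" in variant.zeroed else params.q6
        den = params.q1 + q5 + q6
        joint = (params.p1 + p4 * (q5 + q6)) / den if den > 0 else np.inf
    return {"f(0,0)": p4, "f(inf,0)": p4, "f(0,inf)": p4, "f(inf,inf)": joint}


def pair_library() -> list[tuple[int, int]]:
    """The 43 admissible (f_a, f_b) variant pairs for two coupled parameters.

    Variants 1-8 and 10-15 pair with themselves and with the constant variant 9
    (either slot); variant 9 pairs with everything. Ordering is lexicographic.
    """
    pairs = {(i, i) for i in range(1, 16)}
    pairs |= {(i, 9) for i in range(1, 16)}
    pairs |= {(9, j) for j in range(1, 16)}
    return sorted(pairs)


def eq16_pair_library() -> list[tuple[int, int]]:
    """The 25 pairs restricted to first-degree/constant variants (ids 1-9)."""
    return [(a, b) for (a, b) in pair_library() if a <= 9 and b <= 9]


def compaction_triple_library() -> list[tuple[int, int, int]]:
    """Admissible (a, 1/b, rho_c) variant triples for the compaction stage.

    Either the compressibility a or the pressure parameter 1/b is held constant
    (variant 9) while the other, together with rho_c, follows the restricted
    first-degree pair patterns; 41 triples total.
    """
    triples = set()
    for i, j in eq16_pair_library():
        triples.add((9, i, j))  # constant a
        triples.add((i, 9, j))  # constant 1/b
    return sorted(triples)


@dataclass(frozen=True)
class ModelCombination:
    """A stage plus one rational-variant id per coupled ROM parameter."""

    stage: str
    variant_ids: tuple[int, ...]
    extra_params: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for vid in self.variant_ids:
            get_variant(vid)

    @property
    def variants(self) -> tuple[RationalVariant, ...]:
        return tuple(get_variant(v) for v in self.variant_ids)

    @property
    def r_free(self) -> bool:
        return any(v.r_free for v in self.variants)

    def label(self) -> str:
        return "(" + ",".join(str(v) for v in self.variant_ids) + ")"


def param_count(combination: ModelCombination) -> int:
    """Total free-parameter count Np of a model combination.

    Sum of each member variant's non-exponent coefficients, plus the two shared
    normalization exponents iff any member leaves them free, plus one per extra
    stage parameter (e.g. the recovery exponent n, or the constant Kawakita
    member which enters as variant 9 in ``variant_ids``).
    """
    n = sum(v.n_coefficients for v in combination.variants)
    if combination.r_free:
        n += 2
    n += len(combination.extra_params)
    return n


def library_to_json() -> str:
    """Serialize variant definitions and the pair/triple libraries for audit."""
    payload = {
        "variants": [
            {
                "id": v.id,
                "base": v.base.value,
                "zeroed": sorted(v.zeroed),
                "r_free": v.r_free,
                "n_parameters": v.n_parameters,
            }
            for v in VARIANTS.values()
        ],
        "pair_library": pair_library(),
        "eq16_pair_library": eq16_pair_library(),
        "compaction_triple_library": compaction_triple_library(),
    }
    return json.dumps(payload, indent=2)
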