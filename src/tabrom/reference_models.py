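"""Published fitted stage models for the two reference campaigns.

These are the best-fit parameter sets reported for a direct-compression case
study of a 10% w/w acetaminophen / microcrystalline-cellulose formulation with
either magnesium stearate (lubricant, ``mgst``, 0-2% w/w) or colloidal silica
(glidant, ``cs``, 0-0.2% w/w). They serve as the ground truth behind the
synthetic campaign generator and as fixtures for analytic checks; values were
hand-transcribed from the published summary tables and cross-checked twice.

Each stage entry carries the winning model combination (variant ids per coupled
ROM parameter), the shared normalization exponents, and the coefficient values
keyed ``"<function>.<coefficient>"`` exactly as :mod:`tabrom.selection`
represents a fitted theta. The weight stage is a linear filling-efficacy model
and carries its xi vector directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

from .rational import ModelCombination

__all__ = ["CampaignTruth", "REFERENCE_MODELS", "CAMPAIGN_RANGES", "get_truth"]


@dataclass(frozen=True)
class CampaignTruth:
    """Ground-truth fitted models for one campaign, keyed by stage."""

    campaign: str
    c_max: float  # % w/w normalization bound
    t_max: float  # min
    stages: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)

    def combination(self, stage: str) -> ModelCombination:
        return self.stages[stage]["combination"]

    def theta(self, stage: str) -> dict[str, float]:
        return dict(self.stages[stage]["theta"])


_MGST = CampaignTruth(
    campaign="mgst",
    c_max=2.0,
    t_max=60.0,
    stages={
        # packing fraction phi(X, Y): second-degree variant 13 (q6 = 0, r = 1);
        # non-monotone in concentration (over-lubrication bump)
        "bulk_density": {
            "combination": ModelCombination("bulk_density", (13,)),
            "theta": {
                "r_x": 1.0,
                "r_y": 1.0,
                "phi.p1": 14.21,
                "phi.q1": 51.58,
                "phi.p4": 0.17,
                "phi.q5": 0.17,
            },
        },
        # eta = xi2 (nF/nT) + xi3 (t_fill/D) + xi4 (t_fill/D)^2
        "weight": {
            "form": "second_order",
            "xi": (0.0, 0.076, 1.281, -0.533, 0.0),
            "free": ("xi2", "xi3", "xi4"),
        },
        # Kawakita triple (9, 3, 3): constant a; 1/b and rho_c first-degree
        # variant 3 (q3 = 0) with shared free exponents
        "compaction": {
            "combination": ModelCombination("compaction", (9, 3, 3)),
            "theta": {
                "r_x": 0.85,
                "r_y": 8.76,
                "a.p4": 0.735,
                "inv_b.p1": 0.00174,
                "inv_b.q1": 220.6,
                "inv_b.p4": 0.033,
                "inv_b.q2": 0.0034,
                "rho_c.p1": 264.2,
                "rho_c.q1": 915.4,
                "rho_c.p4": 0.365,
                "rho_c.q2": 1.02,
            },
        },
        # recovery pair (6, 9): eps0 variant 6 (q2 = 0, r = 1), constant onset
        "elastic_recovery": {
            "combination": ModelCombination(
                "elastic_recovery", (6, 9), extra_params=("n_exp",)
            ),
            "theta": {
                "r_x": 1.0,
                "r_y": 1.0,
                "n_exp": 2.928,
                "eps0.p1": 14.29,
                "eps0.q1": 117.11,
                "eps0.p4": 9.32e-9,
                "eps0.q3": 4.99e-7,
                "rho_c_eps.p4": 0.288,
            },
        },
        # tensile pair (3, 3): both first-degree variant 3, free exponents
        "tensile_strength": {
            "combination": ModelCombination("tensile_strength", (3, 3)),
            "theta": {
                "r_x": 1.92,
                "r_y": 1.94,
                "sigma0.p1": 335.0,
                "sigma0.q1": 125.1,
                "sigma0.p4": 9.44,
                "sigma0.q2": 0.40,
                "rho_c_sigma.p1": 5.40,
                "rho_c_sigma.q1": 10.85,
                "rho_c_sigma.p4": 0.649,
                "rho_c_sigma.q2": 1.77e-7,
            },
        },
    },
)

_CS = CampaignTruth(
    campaign="cs",
    c_max=0.2,
    t_max=60.0,
    stages={
        # packing fraction: first-degree variant 7 (q2 = q3 = 0, free exponents)
        "bulk_density": {
            "combination": ModelCombination("bulk_density", (7,)),
            "theta": {
                "r_x": 0.325,
                "r_y": 0.222,
                "phi.p1": 0.279,
                "phi.q1": 0.566,
                "phi.p4": 0.242,
            },
        },
        "weight": {
            "form": "second_order",
            "xi": (0.0862, -0.0472, 2.1036, -1.1375, 0.0),
            "free": ("xi1", "xi2", "xi3", "xi4"),
        },
        # compaction (9, 9, 9): force insensitive to the glidant
        "compaction": {
            "combination": ModelCombination("compaction", (9, 9, 9)),
            "theta": {
                "r_x": 1.0,
                "r_y": 1.0,
                "a.p4": 0.824,
                "inv_b.p4": 0.0104,
                "rho_c.p4": 0.1977,
            },
        },
        "elastic_recovery": {
            "combination": ModelCombination(
                "elastic_recovery", (9, 9), extra_params=("n_exp",)
            ),
            "theta": {
                "r_x": 1.0,
                "r_y": 1.0,
                "n_exp": 1.0,
                "eps0.p4": 0.1098,
                "rho_c_eps.p4": 0.446,
            },
        },
        # tensile pair (8, 8): q2 = q3 = 0, r = 1
        "tensile_strength": {
            "combination": ModelCombination("tensile_strength", (8, 8)),
            "theta": {
                "r_x": 1.0,
                "r_y": 1.0,
                "sigma0.p1": 161.0,
                "sigma0.q1": 17.18,
                "sigma0.p4": 10.7,
                "rho_c_sigma.p1": 13.80,
                "rho_c_sigma.q1": 23.80,
                "rho_c_sigma.p4": 0.53,
            },
        },
    },
)

REFERENCE_MODELS: dict[str, CampaignTruth] = {"mgst": _MGST, "cs": _CS}

# experimental input ranges of the two campaigns (lower, upper)
CAMPAIGN_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "mgst": {
        "concentration_pct": (0.0, 2.0),
        "mixing_time_min": (11.0, 30.0),
        "turret_rpm": (11.0, 22.0),
        "dosing_mm": (9.0, 13.0),
    },
    "cs": {
        "concentration_pct": (0.0, 0.2),
        "mixing_time_min": (10.0, 30.0),
        "turret_rpm": (25.0, 35.0),
        "dosing_mm": (7.0, 11.0),
    },
}


def get_truth(campaign: str) -> CampaignTruth:
    try:
        return REFERENCE_MODELS[campaign.lower()]
    except KeyError:
        raise KeyError(f"unknown campaign {campaign!r}; expected 'mgst' or 'cs'") from None
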