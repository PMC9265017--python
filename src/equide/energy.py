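"""Feed-energy arithmetic.

Gross energy (GE) is reconstructed summatively from the proximate
fractions and their heats of combustion; observed digestible energy (DE)
from the digestible nutrient fractions the same way; and DE is predicted
from proximate composition with linear summative equations.

Unit conventions (fixed package-wide): compositions in % of dry matter
(= g/100 g DM), energies in kcal/kg DM. The factor 10 that converts
kcal/100 g to kcal/kg is applied inside the energy functions, never by
callers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .dataset import Dataset, DigestibleFractions, FeedRecord, ProximateComposition

__all__ = [
    "GrossEnergyCoefficients",
    "PredictionEquation",
    "ExtrapolationWarning",
    "DEFAULT_GE",
    "NS_EQUATION",
    "ZK_EQUATION",
    "STANDARD_EQUATIONS",
    "get_equation",
    "load_equations",
    "gross_energy",
    "observed_de_from_digestible",
    "predict_de",
    "predict_dataset",
    "om_digestibility",
    "energy_digestibility",
    "de_per_g_digestible_om",
    "KCAL_TO_MJ",
]

#: 1 kcal = 4.184 kJ (thermochemical calorie); reporting helper only.
KCAL_TO_MJ = 4.184e-3


class ExtrapolationWarning(UserWarning):
    """A composition lies outside the development range of an equation."""


@dataclass(frozen=True)
class GrossEnergyCoefficients:
    """Heats of combustion of the crude nutrients, kcal/g."""

    protein: float = 5.71
    fat: float = 9.51
    fiber: float = 4.80
    nfe: float = 4.18

    def __post_init__(self) -> None:
        for name in ("protein", "fat", "fiber", "nfe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} heat of combustion must be > 0")


#: Heats of combustion recommended for diets of large herbivores.
DEFAULT_GE = GrossEnergyCoefficients()


# Widest published development ranges of the two packaged equations,
# % DM; compositions outside trigger ExtrapolationWarning.
_DEVELOPMENT_RANGES = {
    "cp": (2.7, 70.3),
    "cf": (0.0, 53.3),
    "nfe": (14.2, 89.1),
    "ee": (0.1, 44.7),
}


@dataclass(frozen=True)
class PredictionEquation:
    """Linear summative DE prediction equation.

    DE (kcal/kg DM) = intercept + b_cp*CP + b_cf*CF + b_nfe*NFE + b_ee*EE
    with the nutrients in % DM.
    """

    name: str
    intercept: float
    b_cp: float
    b_cf: float
    b_nfe: float
    b_ee: float

    def coefficients(self) -> np.ndarray:
        return np.array([self.b_cp, self.b_cf, self.b_nfe, self.b_ee])

    def to_dict(self) -> dict:
        return {
            "name": self.name, "intercept": self.intercept,
            "b_cp": self.b_cp, "b_cf": self.b_cf,
            "b_nfe": self.b_nfe, "b_ee": self.b_ee,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionEquation":
        return cls(**{k: d[k] for k in ("name", "intercept", "b_cp", "b_cf", "b_nfe", "b_ee")})


#: Summative equation of Nunez-Sanchez and co-workers (feedstuffs for
#: horses; crude fiber enters negatively because its term folds in the
#: depression of NFE digestion by fiber).
NS_EQUATION = PredictionEquation("ns", -236.0, 48.5, -6.7, 37.3, 90.1)

#: Modified Zeyner-Kienzle equation (mixed feeds and diets; crude fiber
#: enters with a small positive coefficient).
ZK_EQUATION = PredictionEquation("zk", -846.0, 50.0, 2.4, 44.2, 100.4)

STANDARD_EQUATIONS: dict[str, PredictionEquation] = {
    "ns": NS_EQUATION,
    "zk": ZK_EQUATION,
}


def get_equation(name: str) -> PredictionEquation:
    """Look up a packaged equation by name (case-insensitive)."""
    try:
        return STANDARD_EQUATIONS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown equation {name!r}; packaged equations: "
            f"{sorted(STANDARD_EQUATIONS)}"
        ) from None


def load_equations(path: str | Path) -> dict[str, PredictionEquation]:
    """Load user-defined equations from a JSON config file.

    The file holds a list of objects with keys ``name, intercept, b_cp,
    b_cf, b_nfe, b_ee``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    eqs = [PredictionEquation.from_dict(d) for d in raw]
    return {e.name: e for e in eqs}


def gross_energy(
    c: ProximateComposition, g: GrossEnergyCoefficients = DEFAULT_GE
) -> float:
    """Gross energy of a feed, kcal/kg DM, summed from its proximate fractions."""
    return 10.0 * (c.cp * g.protein + c.cf * g.fiber + c.nfe * g.nfe + c.ee * g.fat)


def observed_de_from_digestible(
    d: DigestibleFractions, g: GrossEnergyCoefficients = DEFAULT_GE
) -> float:
    """Digestible energy, kcal/kg DM, from digestible nutrient fractions.

    Each digestible fraction (% DM) contributes its heat of combustion;
    this is the nutrient-wise route to observed DE used when a digestion
    trial reports per-nutrient digestibility.
    """
    if d is None:
        raise ValueError("digestible fractions are absent")
    return 10.0 * (d.dcp * g.protein + d.dcf * g.fiber + d.dnfe * g.nfe + d.dee * g.fat)


def predict_de(c: ProximateComposition, eq: PredictionEquation) -> float:
    """Predicted digestible energy, kcal/kg DM.

    Emits :class:`ExtrapolationWarning` (never an error) when the
    composition lies outside the widest development range of the packaged
    equations.
    """
    outside = [
        name
        for name, (lo, hi) in _DEVELOPMENT_RANGES.items()
        if not (lo <= getattr(c, name) <= hi)
    ]
    if outside:
        warnings.warn(
            f"composition outside equation development range for {outside}; "
            "prediction is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return (
        eq.intercept
        + eq.b_cp * c.cp + eq.b_cf * c.cf + eq.b_nfe * c.nfe + eq.b_ee * c.ee
    )


def predict_dataset(ds: Dataset, eq: PredictionEquation) -> np.ndarray:
    """Vector of DE predictions over a dataset, in record order."""
    return np.array([predict_de(r.composition, eq) for r in ds])


def om_digestibility(c: ProximateComposition, d: DigestibleFractions) -> float:
    """Apparent organic-matter digestibility, fraction in [0, 1]."""
    if d is None:
        raise ValueError("digestible fractions are absent")
    if c.total <= 0:
        raise ValueError("organic matter content is zero")
    return d.total / c.total


def energy_digestibility(de: float, ge: float) -> float:
    """Energy digestibility DE/GE, dimensionless."""
    if ge <= 0:
        raise ValueError(f"gross energy must be > 0, got {ge}")
    return de / ge


def de_per_g_digestible_om(r: FeedRecord) -> float:
    """Observed DE per gram of digestible organic matter, kcal/g."""
    if r.digestible is None:
        raise ValueError(f"record {r.id}: digestible fractions are absent")
    dom_g_per_kg = 10.0 * r.digestible.total  # % DM -> g/kg DM
    if dom_g_per_kg <= 0:
        raise ValueError(f"record {r.id}: digestible organic matter is zero")
    return r.de_observed / dom_g_per_kg
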