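"""Drug-specific pharmacokinetic parameter sets.

Parameters come from the published three-compartment models conventionally
used by TCI systems: Marsh (propofol, weight-proportional), Minto
(remifentanil, covariate model on age/weight/height/sex via James lean body
mass) and Wierda (rocuronium, weight-proportional). Constants live in the
shipped ``pk_parameters.yaml`` registry; the Minto covariate equations are
evaluated here.

Concentration unit conventions used throughout the package:
propofol µg·mL⁻¹ (central amounts in mg), remifentanil ng·mL⁻¹ (amounts in
µg), rocuronium µg·mL⁻¹ (amounts in mg). With V1 in litres, amount/V1 then
lands directly in the drug's concentration unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = ["PKParams", "pk_params", "ideal_body_weight", "load_registry"]

_VALID_DRUGS = ("propofol", "remifentanil", "rocuronium")
_registry_cache: dict | None = None


def load_registry() -> dict:
    """Load (and memoize) the shipped PK parameter registry."""
    global _registry_cache
    if _registry_cache is None:
        text = resources.files("autotiva.pk").joinpath("pk_parameters.yaml").read_text()
        _registry_cache = yaml.safe_load(text)
    return _registry_cache


@dataclass(frozen=True)
class PKParams:
    """Three-compartment + effect-site model constants for one drug.

    Rate constants are per minute; ``v1`` is litres. Compartments 2 and 3
    are expressed as V1-normalised concentrations (amount / V1), so only the
    central volume is needed to run the model.
    """

    drug: str
    v1: float
    k10: float
    k12: float
    k21: float
    k13: float
    k31: float
    ke0: float

    def __post_init__(self) -> None:
        if self.drug not in _VALID_DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {_VALID_DRUGS}")
        for name in ("v1", "k10", "k12", "k21", "k13", "k31", "ke0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def ideal_body_weight(height_cm: float) -> float:
    """Ideal body weight (kg) as the weight giving BMI 22 at this height."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    return 22.0 * (height_cm / 100.0) ** 2


def _james_lbm(weight: float, height: float, sex: str) -> float:
    # James formula; the covariate the Minto model was built on.
    if sex == "male":
        lbm = 1.1 * weight - 128.0 * (weight / height) ** 2
    else:
        lbm = 1.07 * weight - 148.0 * (weight / height) ** 2
    # The James quadratic turns over at high BMI; floor it to stay physical.
    return max(lbm, 0.25 * weight)


def _minto_params(age: float, weight: float, height: float, sex: str) -> PKParams:
    lbm = _james_lbm(weight, height, sex)
    v1 = 5.1 - 0.0201 * (age - 40.0) + 0.072 * (lbm - 55.0)
    v2 = 9.82 - 0.0811 * (age - 40.0) + 0.108 * (lbm - 55.0)
    v3 = 5.42
    cl1 = 2.6 - 0.0162 * (age - 40.0) + 0.0191 * (lbm - 55.0)
    cl2 = 2.05 - 0.0301 * (age - 40.0)
    cl3 = 0.076 - 0.00113 * (age - 40.0)
    ke0 = 0.595 - 0.007 * (age - 40.0)
    return PKParams(
        drug="remifentanil",
        v1=v1,
        k10=cl1 / v1,
        k12=cl2 / v1,
        k21=cl2 / v2,
        k13=cl3 / v1,
        k31=cl3 / v3,
        ke0=ke0,
    )


def pk_params(
    drug: str,
    *,
    age: float = 40.0,
    weight: float = 70.0,
    height: float = 170.0,
    sex: str = "female",
    ke0: float | None = None,
) -> PKParams:
    """Covariate-adjusted parameter set for one drug.

    Marsh (propofol) and Wierda (rocuronium) scale with total body weight
    only; Minto (remifentanil) uses age, weight, height and sex. ``ke0``
    overrides the registry default (several pairings exist in practice).

    Parameters outside the adult range the models were built for trigger a
    warning, not an error.
    """
    if drug not in _VALID_DRUGS:
        raise ValueError(f"unknown drug {drug!r}; expected one of {_VALID_DRUGS}")
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if age < 20:
        warnings.warn(f"age {age} below the adult range these models cover", stacklevel=2)

    reg = load_registry()[drug]
    if drug == "remifentanil":
        p = _minto_params(age, weight, height, sex)
    else:
        p = PKParams(
            drug=drug,
            v1=reg["v1_per_kg"] * weight,
            k10=reg["k10"],
            k12=reg["k12"],
            k21=reg["k21"],
            k13=reg["k13"],
            k31=reg["k31"],
            ke0=float(reg["ke0_default"]),
        )
    if ke0 is not None:
        if ke0 <= 0:
            raise ValueError("ke0 must be > 0")
        p = PKParams(p.drug, p.v1, p.k10, p.k12, p.k21, p.k13, p.k31, ke0)
    return p
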