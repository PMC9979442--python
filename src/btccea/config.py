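"""Model configuration: schema, validation, and the packaged base case.

Every numeric assumption of the analysis lives here — unit prices with their
plausible ranges, utilities, the discount rate, the Weibull survival
parameters per arm and endpoint, body metrics, the charity-assistance policy
and the second-line treatment mix.  Nothing economic is hard-coded in the
computational modules, so scenario sweeps, one-way sensitivity analysis and
the probabilistic sensitivity analysis can all perturb copies of one object.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Iterator, Literal

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Bounded",
    "WeibullParams",
    "SurvivalTable",
    "CostTable",
    "Utilities",
    "CharityPolicy",
    "PatientProfile",
    "SecondLineMix",
    "Regimen",
    "ModelConfig",
    "base_case_config",
    "load_config",
    "save_config",
    "config_hash",
    "iter_bounded",
    "get_bounded",
    "with_value",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class Bounded(_Strict):
    """A scalar parameter with base value, plausible range and PSA distribution."""

    base: float
    lower: float
    upper: float
    distribution: Literal["gamma", "beta", "fixed"] = "fixed"

    @model_validator(mode="after")
    def _ordered(self) -> "Bounded":
        if not (self.lower <= self.base <= self.upper):
            raise ValueError(
                f"bound inversion: lower={self.lower} base={self.base} upper={self.upper}"
            )
        return self


def _g(base: float, lower: float, upper: float) -> Bounded:
    return Bounded(base=base, lower=lower, upper=upper, distribution="gamma")


def _b(base: float, lower: float, upper: float) -> Bounded:
    return Bounded(base=base, lower=lower, upper=upper, distribution="beta")


class WeibullParams(_Strict):
    """Weibull survival law S(t) = exp(-lam * t**gam), t in model cycles."""

    lam: float
    gam: float

    @model_validator(mode="after")
    def _positive(self) -> "WeibullParams":
        if self.lam <= 0 or self.gam <= 0:
            raise ValueError("Weibull parameters must be positive")
        return self


class SurvivalTable(_Strict):
    os_combo: WeibullParams
    os_chemo: WeibullParams
    pfs_combo: WeibullParams
    pfs_chemo: WeibullParams

    def fits(self, arm: str) -> tuple[WeibullParams, WeibullParams]:
        """(pfs, os) parameters for an arm ('combo' or 'chemo')."""
        if arm == "combo":
            return self.pfs_combo, self.os_combo
        if arm == "chemo":
            return self.pfs_chemo, self.os_chemo
        raise ValueError(f"unknown arm {arm!r}")


class CostTable(_Strict):
    """Unit prices in 2021 USD with plausible ranges (95% CI or +/-25%)."""

    durvalumab_per_mg: Bounded = _g(5.61, 4.21, 7.01)
    gemcitabine_per_g: Bounded = _g(52.43, 39.32, 65.54)
    cisplatin_per_30mg: Bounded = _g(3.84, 2.88, 4.80)
    pembrolizumab_per_100mg: Bounded = _g(2777.98, 2083.49, 3472.48)
    dabrafenib_per_pack: Bounded = _g(1718.70, 1289.03, 2148.37)  # 75 mg x 120
    trametinib_per_pack: Bounded = _g(1718.60, 1288.95, 2148.25)  # 2 mg x 30
    paclitaxel_per_100mg: Bounded = _g(108.22, 81.16, 135.27)
    calcium_folinate_per_100mg: Bounded = _g(3.88, 2.91, 4.85)
    regorafenib_per_40mg: Bounded = _g(26.74, 20.06, 33.43)
    oxaliplatin_per_100mg: Bounded = _g(78.54, 58.91, 98.18)
    fluorouracil_per_500mg: Bounded = _g(8.11, 6.08, 10.14)
    terminal: Bounded = _g(4517.85, 3388.39, 5647.31)
    ae_combo: Bounded = _g(603.87, 452.90, 754.84)
    ae_chemo: Bounded = _g(591.20, 443.40, 739.00)
    tests_imaging_per_cycle: Bounded = _g(268.22, 201.16, 335.27)


class Utilities(_Strict):
    pfs: Bounded = _b(0.9, 0.675, 1.125)
    pd: Bounded = _b(0.4, 0.3, 0.5)


class CharityPolicy(_Strict):
    """Pay-k-cycles-then-free durvalumab donation rule.

    The first ``paid_cycles`` durvalumab administrations are paid at list
    price; every later administration is donated until progression.
    """

    paid_cycles: int = 2
    free_until_progression: bool = True

    @model_validator(mode="after")
    def _k(self) -> "CharityPolicy":
        if self.paid_cycles < 1:
            raise ValueError("paid_cycles must be >= 1")
        return self


class PatientProfile(_Strict):
    weight_kg: float = 65.0
    bsa_m2: float = 1.72

    @model_validator(mode="after")
    def _positive(self) -> "PatientProfile":
        if self.weight_kg <= 0 or self.bsa_m2 <= 0:
            raise ValueError("body metrics must be positive")
        return self


class SecondLineMix(_Strict):
    """Proportions of second-line regimens applied to the PD state."""

    folfox: float = 1.0
    ici: float = 0.0
    targeted: float = 0.0
    supportive: float = 0.0

    @model_validator(mode="after")
    def _sums_to_one(self) -> "SecondLineMix":
        total = self.folfox + self.ici + self.targeted + self.supportive
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"second-line proportions sum to {total}, not 1")
        if min(self.folfox, self.ici, self.targeted, self.supportive) < 0:
            raise ValueError("second-line proportions must be nonnegative")
        return self


class Regimen(_Strict):
    induction_cycles: int = 8
    durvalumab_mg: float = 1500.0            # flat, day 1 each cycle
    gemcitabine_mg_per_m2: float = 1000.0    # days 1 and 8
    cisplatin_mg_per_m2: float = 25.0        # days 1 and 8
    maintenance_interval_days: float = 28.0  # durvalumab q4w, combo arm only

    @model_validator(mode="after")
    def _positive(self) -> "Regimen":
        if self.induction_cycles < 1:
            raise ValueError("induction_cycles must be >= 1")
        return self


# Table 1 parameters, time in 21-day model cycles.
_BASE_SURVIVAL = {
    "os_combo": {"lam": 0.0156467, "gam": 1.2807604},
    "os_chemo": {"lam": 0.009309, "gam": 1.5330827},
    "pfs_combo": {"lam": 0.029721, "gam": 1.397684},
    "pfs_chemo": {"lam": 0.0167583, "gam": 1.754329},
}


class ModelConfig(_Strict):
    """Complete base-case configuration of the cost-effectiveness model."""

    cycle_days: float = 21.0
    horizon_years: float = 10.0
    discount: Bounded = _b(0.05, 0.0375, 0.0625)
    wtp_per_qaly: float = 37663.26
    background_mortality_annual: float = 0.00718  # China 2021 crude death rate
    utilities: Utilities = Utilities()
    costs: CostTable = CostTable()
    survival: SurvivalTable = SurvivalTable(**_BASE_SURVIVAL)
    patient: PatientProfile = PatientProfile()
    regimen: Regimen = Regimen()
    charity: CharityPolicy = CharityPolicy()
    second_line_combo: SecondLineMix = SecondLineMix()
    second_line_chemo: SecondLineMix = SecondLineMix()
    tests_imaging_in_pd: bool = True
    half_cycle_correction: bool = False
    accrual: Literal["post", "pre"] = "post"

    @model_validator(mode="after")
    def _valid(self) -> "ModelConfig":
        if not (0 <= self.background_mortality_annual < 1):
            raise ValueError("background mortality must be in [0, 1)")
        if self.wtp_per_qaly <= 0:
            raise ValueError("WTP must be positive")
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")
        return self

    @property
    def horizon_cycles(self) -> int:
        import math

        return math.ceil(self.horizon_years * 365.25 / self.cycle_days)

    def second_line(self, arm: str) -> SecondLineMix:
        if arm == "combo":
            return self.second_line_combo
        if arm == "chemo":
            return self.second_line_chemo
        raise ValueError(f"unknown arm {arm!r}")


def base_case_config() -> ModelConfig:
    """The packaged base case: all published point estimates plus documented
    defaults for the gaps the publication leaves open (background mortality,
    charity ``paid_cycles``, second-line mix, accrual conventions)."""
    return ModelConfig()


def load_config(path: str | Path) -> ModelConfig:
    """Read and schema-validate a YAML configuration file.

    Unknown keys are rejected; missing keys fall back to the packaged base
    case defaults; inverted bounds raise a validation error naming the field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return ModelConfig(**raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def config_hash(config: ModelConfig) -> str:
    """Stable hash of a configuration (invariant to key order)."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Parameter registry: dotted-path access to every Bounded field, used by the
# tornado analysis and the PSA so they perturb exactly the published ranges.
# ---------------------------------------------------------------------------

def iter_bounded(config: ModelConfig) -> Iterator[tuple[str, Bounded]]:
    """Yield (dotted_path, Bounded) for every range-carrying parameter."""
    for field in type(config.costs).model_fields:
        yield f"costs.{field}", getattr(config.costs, field)
    yield "utilities.pfs", config.utilities.pfs
    yield "utilities.pd", config.utilities.pd
    yield "discount", config.discount


def get_bounded(config: ModelConfig, path: str) -> Bounded:
    obj: object = config
    for part in path.split("."):
        obj = getattr(obj, part)
    if not isinstance(obj, Bounded):
        raise TypeError(f"{path} is not a Bounded parameter")
    return obj


def with_value(config: ModelConfig, path: str, value: float) -> ModelConfig:
    """Deep copy of ``config`` with the base value at ``path`` replaced."""
    new = copy.deepcopy(config)
    obj: object = new
    parts = path.split(".")
    for part in parts[:-1]:
        obj = getattr(obj, part)
    bounded: Bounded = getattr(obj, parts[-1])
    replaced = Bounded(
        base=value,
        lower=min(value, bounded.lower),
        upper=max(value, bounded.upper),
        distribution=bounded.distribution,
    )
    setattr(obj, parts[-1], replaced)
    return new
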