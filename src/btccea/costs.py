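"""Drug acquisition, adverse-event, follow-up, second-line and terminal costs.

Dosing follows the trial schedule: 21-day cycles with durvalumab 1500 mg flat
on day 1 (combo arm), gemcitabine 1000 mg/m2 and cisplatin 25 mg/m2 on days 1
and 8, for up to eight induction cycles, then durvalumab maintenance every
4 weeks until progression (prorated into the 21-day model cycle).  Pricing is
linear per mg with no vial rounding.  Costs in the progressed-disease state
come from a configurable second-line regimen mix; a terminal-care cost is
paid once on entry to Death and adverse-event management once at model start.
"""

from __future__ import annotations

import numpy as np

from .cohort import CostStream
from .config import CostTable, ModelConfig, PatientProfile, SecondLineMix

__all__ = [
    "unit_price_per_mg",
    "drug_cost_per_administration",
    "arm_cycle_cost",
    "folfox_cycle_cost",
    "ici_cycle_cost",
    "targeted_cycle_cost",
    "pd_cycle_cost",
    "ae_cost",
    "terminal_cost_event",
    "build_cost_stream",
]

# mg contained in the priced unit of each Table row
_UNIT_MG = {
    "durvalumab_per_mg": 1.0,
    "gemcitabine_per_g": 1000.0,
    "cisplatin_per_30mg": 30.0,
    "pembrolizumab_per_100mg": 100.0,
    "dabrafenib_per_pack": 75.0 * 120,
    "trametinib_per_pack": 2.0 * 30,
    "paclitaxel_per_100mg": 100.0,
    "calcium_folinate_per_100mg": 100.0,
    "regorafenib_per_40mg": 40.0,
    "oxaliplatin_per_100mg": 100.0,
    "fluorouracil_per_500mg": 500.0,
}


def unit_price_per_mg(prices: CostTable, drug: str) -> float:
    """Normalise a price row to $/mg."""
    if drug not in _UNIT_MG:
        raise KeyError(f"no price row for drug {drug!r}")
    return getattr(prices, drug).base / _UNIT_MG[drug]


def drug_cost_per_administration(
    drug: str,
    dose: float,
    dose_rule: str,
    profile: PatientProfile,
    prices: CostTable,
) -> float:
    """Cost of one administration: dose resolved by rule, priced linearly.

    ``dose_rule`` is one of ``flat`` (mg), ``per_m2`` (mg/m2, scaled by body
    surface area) or ``per_kg`` (mg/kg, scaled by weight).
    """
    if dose_rule == "flat":
        mg = dose
    elif dose_rule == "per_m2":
        mg = dose * profile.bsa_m2
    elif dose_rule == "per_kg":
        mg = dose * profile.weight_kg
    else:
        raise ValueError(f"unknown dose rule {dose_rule!r}")
    return mg * unit_price_per_mg(prices, drug)


def _chemo_backbone_cost(config: ModelConfig) -> float:
    """Gemcitabine + cisplatin, two administrations each per 21-day cycle."""
    reg, prof, prices = config.regimen, config.patient, config.costs
    gem = drug_cost_per_administration(
        "gemcitabine_per_g", reg.gemcitabine_mg_per_m2, "per_m2", prof, prices
    )
    cis = drug_cost_per_administration(
        "cisplatin_per_30mg", reg.cisplatin_mg_per_m2, "per_m2", prof, prices
    )
    return 2.0 * (gem + cis)


def _durvalumab_admin_cost(config: ModelConfig) -> float:
    return drug_cost_per_administration(
        "durvalumab_per_mg", config.regimen.durvalumab_mg, "flat",
        config.patient, config.costs,
    )


def arm_cycle_cost(
    arm: str,
    cycle: int,
    config: ModelConfig,
    charity: bool = False,
    include_tests: bool = True,
) -> float:
    """Drug plus follow-up cost for one cycle spent in PFS.

    Induction cycles (1..8) carry the chemotherapy backbone, plus one
    durvalumab administration in the combo arm; later cycles carry only
    maintenance durvalumab (combo arm), prorated from the 4-weekly schedule
    into the 21-day cycle.  Under the charity policy the durvalumab component
    is zeroed after the configured number of paid administrations.  Tests and
    imaging are added for every cycle alive.
    """
    if cycle < 1:
        raise ValueError("cycle index must be >= 1")
    if arm not in ("combo", "chemo"):
        raise ValueError(f"unknown arm {arm!r}")
    reg = config.regimen
    cost = 0.0
    if cycle <= reg.induction_cycles:
        cost += _chemo_backbone_cost(config)
    if arm == "combo":
        durva = _durvalumab_admin_cost(config)
        if cycle > reg.induction_cycles:
            durva *= config.cycle_days / reg.maintenance_interval_days
        if charity and cycle > config.charity.paid_cycles:
            durva = 0.0
        cost += durva
    if include_tests:
        cost += config.costs.tests_imaging_per_cycle.base
    return cost


def folfox_cycle_cost(config: ModelConfig) -> float:
    """FOLFOX drug cost per 21-day cycle.

    Fortnightly dosing — oxaliplatin 85 mg/m2, leucovorin (calcium folinate)
    400 mg/m2, fluorouracil 2800 mg/m2 — prorated by 21/14.
    """
    prof, prices = config.patient, config.costs
    per_q2w = (
        drug_cost_per_administration("oxaliplatin_per_100mg", 85.0, "per_m2", prof, prices)
        + drug_cost_per_administration("calcium_folinate_per_100mg", 400.0, "per_m2", prof, prices)
        + drug_cost_per_administration("fluorouracil_per_500mg", 2800.0, "per_m2", prof, prices)
    )
    return per_q2w * config.cycle_days / 14.0


def ici_cycle_cost(config: ModelConfig) -> float:
    """Pembrolizumab 200 mg every 3 weeks — one administration per cycle."""
    return drug_cost_per_administration(
        "pembrolizumab_per_100mg", 200.0, "flat", config.patient, config.costs
    )


def targeted_cycle_cost(config: ModelConfig) -> float:
    """Targeted therapy per 21-day cycle: mean of dabrafenib + trametinib
    (label daily doses 300 mg and 2 mg) and regorafenib (160 mg/day, 21 days
    on / 7 off, prorated)."""
    prices = config.costs
    dab_tram_daily = (
        300.0 * unit_price_per_mg(prices, "dabrafenib_per_pack")
        + 2.0 * unit_price_per_mg(prices, "trametinib_per_pack")
    )
    dab_tram = dab_tram_daily * config.cycle_days
    rego_28d = 160.0 * unit_price_per_mg(prices, "regorafenib_per_40mg") * 21.0
    rego = rego_28d * config.cycle_days / 28.0
    return 0.5 * (dab_tram + rego)


def pd_cycle_cost(mix: SecondLineMix, config: ModelConfig) -> float:
    """Expected second-line drug cost per 21-day cycle in PD (mix-weighted;
    supportive care carries no drug cost)."""
    return (
        mix.folfox * folfox_cycle_cost(config)
        + mix.ici * ici_cycle_cost(config)
        + mix.targeted * targeted_cycle_cost(config)
        + mix.supportive * 0.0
    )


def ae_cost(
    arm: str,
    config: ModelConfig,
    detailed: list[tuple[float, float]] | None = None,
) -> float:
    """One-time grade-3/4 adverse-event management cost at model start.

    The default returns the published per-arm aggregate; ``detailed`` accepts
    (incidence, unit cost) pairs and returns their weighted sum instead.
    """
    if detailed is not None:
        return float(sum(inc * cost for inc, cost in detailed))
    if arm == "combo":
        return config.costs.ae_combo.base
    if arm == "chemo":
        return config.costs.ae_chemo.base
    raise ValueError(f"unknown arm {arm!r}")


def terminal_cost_event(config: ModelConfig) -> float:
    """End-of-life care cost, paid once on entry to the Death state."""
    return config.costs.terminal.base


def build_cost_stream(
    arm: str,
    config: ModelConfig,
    charity: bool = False,
) -> CostStream:
    """Assemble the full per-cycle cost stream for one arm over the horizon."""
    n = config.horizon_cycles
    pfs = np.array(
        [arm_cycle_cost(arm, i, config, charity=charity) for i in range(1, n + 1)]
    )
    pd_drug = pd_cycle_cost(config.second_line(arm), config)
    pd = np.full(n, pd_drug)
    if config.tests_imaging_in_pd:
        pd += config.costs.tests_imaging_per_cycle.base
    return CostStream(
        pfs=pfs,
        pd=pd,
        death_event=terminal_cost_event(config),
        initial=ae_cost(arm, config),
    )
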