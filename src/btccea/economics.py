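"""Cost-effectiveness comparison, break-even price search, one-way and
probabilistic sensitivity analyses.

The decision problem compares durvalumab plus gemcitabine/cisplatin (combo)
with gemcitabine/cisplatin alone (chemo) by the incremental cost-
effectiveness ratio (ICER), judged against a willingness-to-pay threshold of
three times 2021 Chinese per-capita GDP ($37,663.26/QALY).  The probabilistic
sensitivity analysis samples cost parameters from Gamma and utilities and the
discount rate from Beta distributions, moment-matched to the published
ranges (interpreted as 95% intervals).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Literal

import numpy as np

from .cohort import CohortTrace, run_cohort
from .config import Bounded, ModelConfig, get_bounded, iter_bounded, with_value
from .costs import build_cost_stream
from .survival import ParametricFit
from .transitions import BackgroundMortality, build_matrix_series

logger = logging.getLogger(__name__)

__all__ = [
    "ArmResult",
    "CEComparison",
    "TornadoEntry",
    "CEACCurve",
    "PSAResult",
    "run_arm",
    "evaluate",
    "compare",
    "breakeven_price",
    "one_way_sa",
    "build_psa_distributions",
    "run_psa",
    "default_wtp_grid",
]

ARMS = ("chemo", "combo")


def _fit(lam: float, gam: float) -> ParametricFit:
    """Wrap configured Weibull parameters as a fitted law (no likelihood)."""
    return ParametricFit("weibull", lam, gam, math.nan, math.nan, 0)


def run_arm(config: ModelConfig, arm: str, charity: bool = False) -> CohortTrace:
    """Build transition matrices and cost streams for one arm and run it."""
    pfs_p, os_p = config.survival.fits(arm)
    series = build_matrix_series(
        _fit(pfs_p.lam, pfs_p.gam),
        _fit(os_p.lam, os_p.gam),
        BackgroundMortality(config.background_mortality_annual),
        config.horizon_cycles,
        config.cycle_days,
    )
    stream = build_cost_stream(arm, config, charity=charity)
    return run_cohort(
        series,
        stream,
        u_pfs=config.utilities.pfs.base,
        u_pd=config.utilities.pd.base,
        annual_discount=config.discount.base,
        cycle_days=config.cycle_days,
        half_cycle_correction=config.half_cycle_correction,
        accrual=config.accrual,
    )


@dataclasses.dataclass(frozen=True)
class ArmResult:
    arm: str
    total_cost: float
    total_qaly: float
    total_life_years: float = math.nan
    trace: CohortTrace | None = None


@dataclasses.dataclass(frozen=True)
class CEComparison:
    """Paired-arm comparison: incremental cost, incremental QALY, ICER."""

    reference: ArmResult   # combo
    comparator: ArmResult  # chemo
    wtp: float

    @property
    def incremental_cost(self) -> float:
        return self.reference.total_cost - self.comparator.total_cost

    @property
    def incremental_qaly(self) -> float:
        return self.reference.total_qaly - self.comparator.total_qaly

    @property
    def dominance(self) -> Literal["dominant", "dominated", "undefined", "tradeoff"]:
        dc, de = self.incremental_cost, self.incremental_qaly
        if abs(de) < 1e-12:
            return "undefined" if abs(dc) > 0 else "tradeoff"
        if dc <= 0 and de > 0:
            return "dominant"
        if dc >= 0 and de < 0:
            return "dominated"
        return "tradeoff"

    @property
    def icer(self) -> float:
        """USD per QALY; meaningful only when the comparison is a trade-off."""
        de = self.incremental_qaly
        if abs(de) < 1e-12:
            return math.nan
        return self.incremental_cost / de

    @property
    def cost_effective(self) -> bool:
        return self.net_monetary_benefit(self.wtp) >= 0.0

    def net_monetary_benefit(self, wtp: float) -> float:
        return wtp * self.incremental_qaly - self.incremental_cost


def evaluate(config: ModelConfig, charity: bool = False) -> CEComparison:
    """Run both arms under one configuration and compare them."""
    results = {}
    for arm in ARMS:
        trace = run_arm(config, arm, charity=charity and arm == "combo")
        results[arm] = ArmResult(
            arm, trace.total_cost, trace.total_qaly, trace.total_life_years, trace
        )
    return compare(results["combo"], results["chemo"], config.wtp_per_qaly)


def compare(reference: ArmResult, comparator: ArmResult, wtp: float) -> CEComparison:
    if abs(reference.total_qaly - comparator.total_qaly) < 1e-12 and abs(
        reference.total_cost - comparator.total_cost
    ) > 0:
        logger.info("incremental QALY ~ 0 with nonzero incremental cost: ICER undefined")
    return CEComparison(reference=reference, comparator=comparator, wtp=wtp)


# ---------------------------------------------------------------------------
# Scenario analysis: durvalumab price threshold
# ---------------------------------------------------------------------------

def breakeven_price(
    config: ModelConfig,
    charity: bool = False,
    price_bounds: tuple[float, float] = (0.0, 10.0),
    rel_tol: float = 1e-4,
    max_iter: int = 200,
) -> dict:
    """Bisect on the durvalumab unit price until the ICER meets the WTP.

    The ICER is monotone increasing in the price (all else fixed), so the
    break-even price is the unique root of ICER(price) - WTP inside the
    bracket.  Returns the price, the implied percentage reduction from the
    configured base price, and the ICER at the returned price.
    """
    wtp = config.wtp_per_qaly
    base_price = config.costs.durvalumab_per_mg.base

    def icer_at(price: float) -> float:
        cmp_ = evaluate(
            with_value(config, "costs.durvalumab_per_mg", price), charity=charity
        )
        return cmp_.icer

    lo, hi = price_bounds
    icer_lo, icer_hi = icer_at(lo), icer_at(hi)
    if icer_at(base_price) == wtp:
        lo = hi = base_price
    elif not (icer_lo < wtp < icer_hi):
        raise ValueError(
            f"WTP {wtp} not bracketed: ICER({lo})={icer_lo:.2f}, ICER({hi})={icer_hi:.2f}"
        )
    price, icer = base_price, icer_at(base_price)
    for _ in range(max_iter):
        price = 0.5 * (lo + hi)
        icer = icer_at(price)
        if abs(icer - wtp) <= rel_tol * wtp:
            break
        if icer < wtp:
            lo = price
        else:
            hi = price
    return {
        "price_per_mg": price,
        "reduction_pct": 100.0 * (1.0 - price / base_price),
        "icer": icer,
    }


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_lower: float
    icer_at_upper: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_upper - self.icer_at_lower)


def one_way_sa(
    config: ModelConfig,
    charity: bool = False,
    parameters: list[str] | None = None,
) -> list[TornadoEntry]:
    """Re-run the full pipeline at each parameter's lower and upper bound,
    all else at base; entries are sorted by ICER spread, largest first."""
    names = parameters if parameters is not None else [p for p, _ in iter_bounded(config)]
    entries = []
    for name in names:
        bounded = get_bounded(config, name)
        low = evaluate(with_value(config, name, bounded.lower), charity=charity).icer
        high = evaluate(with_value(config, name, bounded.upper), charity=charity).icer
        entries.append(TornadoEntry(name, low, high))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _moments(bounded: Bounded) -> tuple[float, float]:
    """Mean and SD implied by reading the range as a 95% interval."""
    return bounded.base, (bounded.upper - bounded.lower) / (2.0 * 1.96)


def build_psa_distributions(
    config: ModelConfig,
) -> dict[str, Callable[[np.random.Generator, int], np.ndarray]]:
    """Moment-matched samplers for every range-carrying parameter.

    Gamma for costs (shape = mean^2/sd^2, scale = sd^2/mean); Beta for
    utilities and the discount rate, method-of-moments after truncating the
    mean and bounds into (0, 1).  A zero-width range yields a point mass.
    """
    samplers: dict[str, Callable[[np.random.Generator, int], np.ndarray]] = {}
    for name, bounded in iter_bounded(config):
        samplers[name] = _make_sampler(name, bounded)
    return samplers


def _make_sampler(name: str, bounded: Bounded):
    mean, sd = _moments(bounded)
    if sd == 0 or bounded.distribution == "fixed":
        if sd == 0:
            logger.info("parameter %s has zero-width range: point mass in PSA", name)
        return lambda rng, size, m=mean: np.full(size, m)
    if bounded.distribution == "gamma":
        shape = mean**2 / sd**2
        scale = sd**2 / mean
        return lambda rng, size: rng.gamma(shape, scale, size)
    # Beta: truncate the published mean/bounds into the unit interval first
    # (the PFS-utility upper bound 1.125 exceeds 1 by construction of the
    # +/-25% rule) and log when truncation changes anything.
    lower, upper = bounded.lower, bounded.upper
    t_mean = min(max(mean, 1e-9), 1.0 - 1e-9)
    t_lower = min(max(lower, 0.0), 1.0)
    t_upper = min(max(upper, 0.0), 1.0)
    if (t_mean, t_lower, t_upper) != (mean, lower, upper):
        logger.info(
            "parameter %s: bounds truncated into (0, 1) before moment matching "
            "(%.4g/%.4g/%.4g -> %.4g/%.4g/%.4g)",
            name, lower, mean, upper, t_lower, t_mean, t_upper,
        )
    t_sd = (t_upper - t_lower) / (2.0 * 1.96)
    var = min(t_sd**2, t_mean * (1.0 - t_mean) * 0.999)
    nu = t_mean * (1.0 - t_mean) / var - 1.0
    a, b = t_mean * nu, (1.0 - t_mean) * nu
    return lambda rng, size: rng.beta(a, b, size)


def _config_with_draw(
    config: ModelConfig, names: list[str], values: np.ndarray
) -> ModelConfig:
    """One deep copy of the config with every sampled value substituted.

    Sampled values may legitimately fall outside the published range, so the
    replacement widens the stored bounds rather than re-validating them.
    """
    import copy

    cfg = copy.deepcopy(config)
    for name, value in zip(names, values):
        value = float(value)
        parts = name.split(".")
        obj: object = cfg
        for part in parts[:-1]:
            obj = getattr(obj, part)
        old: Bounded = getattr(obj, parts[-1])
        new = Bounded.model_construct(
            base=value,
            lower=min(value, old.lower),
            upper=max(value, old.upper),
            distribution=old.distribution,
        )
        object.__setattr__(obj, parts[-1], new)
    return cfg


@dataclasses.dataclass(frozen=True)
class CEACCurve:
    """Probability that combo therapy is cost-effective across WTP values."""

    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        if abs(self.wtp[idx] - wtp) > 1e-6:
            raise KeyError(f"WTP {wtp} not on the curve grid")
        return float(self.probability[idx])


@dataclasses.dataclass(frozen=True)
class PSAResult:
    draws: "np.ndarray"            # structured columns via .parameters
    parameters: list[str]
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    ceac: CEACCurve
    seed: int

    @property
    def n(self) -> int:
        return len(self.delta_cost)

    def acceptability(self, wtp: float) -> float:
        """Fraction of draws with nonnegative net monetary benefit at wtp."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost >= 0.0))

    def scatter_frame(self):
        import pandas as pd

        return pd.DataFrame({"dqaly": self.delta_qaly, "dcost": self.delta_cost})


def default_wtp_grid(wtp_threshold: float) -> np.ndarray:
    grid = np.arange(0.0, 150_000.0 + 1.0, 1_500.0)
    return np.unique(np.concatenate([grid, [wtp_threshold]]))


def run_psa(
    config: ModelConfig,
    charity: bool = False,
    n: int = 1000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Monte Carlo PSA: per draw, jointly sample all parameters, re-run both
    arms, and record the incremental cost and QALY.

    The cost-effectiveness acceptability curve evaluates, at each WTP value,
    the fraction of draws with nonnegative net monetary benefit; with two
    strategies the chemotherapy-alone probability is its complement.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samplers = build_psa_distributions(config)
    names = list(samplers)
    draws = np.column_stack([samplers[name](rng, n) for name in names])

    dcost = np.empty(n)
    dqaly = np.empty(n)
    for j in range(n):
        cfg = _config_with_draw(config, names, draws[j])
        cmp_ = evaluate(cfg, charity=charity)
        dcost[j] = cmp_.incremental_cost
        dqaly[j] = cmp_.incremental_qaly

    grid = default_wtp_grid(config.wtp_per_qaly) if wtp_grid is None else np.asarray(wtp_grid)
    prob = np.array([np.mean(w * dqaly - dcost >= 0.0) for w in grid])
    return PSAResult(
        draws=draws,
        parameters=names,
        delta_cost=dcost,
        delta_qaly=dqaly,
        ceac=CEACCurve(grid, prob),
        seed=seed,
    )
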