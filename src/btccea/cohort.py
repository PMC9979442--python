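"""Discrete-time cohort simulation with discounted cost and QALY accrual.

The cohort starts fully in PFS and is pushed through the time-indexed
transition matrices one 21-day cycle at a time.  Rewards (state costs,
utilities) accrue by default on the post-transition occupancy of each cycle;
a pre-transition convention and a half-cycle correction are exposed because
cohort models differ on this and the choice moves totals by up to one
cycle's accrual.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .transitions import DAYS_PER_YEAR, TransitionMatrixSeries

__all__ = ["CostStream", "CohortTrace", "per_cycle_discount_factor", "run_cohort"]


def per_cycle_discount_factor(annual: float, cycle_days: float = 21.0) -> float:
    """Per-cycle discount base (1 + annual)**(-cycle_days / 365.25).

    Cycle i's rewards are discounted by this factor raised to the power i, so
    compounding over one year of cycles reproduces 1 / (1 + annual).
    """
    if annual < 0:
        raise ValueError("discount rate must be nonnegative")
    return (1.0 + annual) ** (-cycle_days / DAYS_PER_YEAR)


@dataclasses.dataclass(frozen=True)
class CostStream:
    """Per-cycle state costs plus event costs for one arm.

    ``pfs`` and ``pd`` hold the cost accrued per full cohort in the state at
    each cycle (length = horizon); ``death_event`` is paid once per cohort
    fraction entering Death; ``initial`` is a one-time cost at model start
    (adverse-event management).
    """

    pfs: np.ndarray
    pd: np.ndarray
    death_event: float = 0.0
    initial: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pfs, dtype=float)
        q = np.asarray(self.pd, dtype=float)
        if p.shape != q.shape or p.ndim != 1:
            raise ValueError("pfs and pd cost streams must be aligned 1-D arrays")
        object.__setattr__(self, "pfs", p)
        object.__setattr__(self, "pd", q)


@dataclasses.dataclass(frozen=True)
class CohortTrace:
    """State occupancy and reward accumulators over the model horizon.

    ``occupancy[i]`` is the (PFS, PD, Death) distribution after cycle i, with
    row 0 the initial distribution (1, 0, 0).
    """

    occupancy: np.ndarray            # (N + 1, 3)
    cost_undiscounted: np.ndarray    # (N,)
    cost_discounted: np.ndarray
    qaly_undiscounted: np.ndarray
    qaly_discounted: np.ndarray
    ly_discounted: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_discounted.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_discounted.sum())

    @property
    def total_life_years(self) -> float:
        return float(self.ly_discounted.sum())

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, 0] + self.occupancy[:, 1]

    def to_frame(self):
        import pandas as pd

        n = len(self.cost_discounted)
        return pd.DataFrame(
            {
                "cycle": np.arange(1, n + 1),
                "pfs": self.occupancy[1:, 0],
                "pd": self.occupancy[1:, 1],
                "death": self.occupancy[1:, 2],
                "cost_disc": self.cost_discounted,
                "qaly_disc": self.qaly_discounted,
            }
        )


def run_cohort(
    series: TransitionMatrixSeries,
    costs: CostStream,
    u_pfs: float,
    u_pd: float,
    annual_discount: float,
    cycle_days: float = 21.0,
    half_cycle_correction: bool = False,
    accrual: str = "post",
) -> CohortTrace:
    """Run the cohort through the matrix series and accrue rewards.

    QALY increment per cycle is occupancy-weighted utility times the cycle
    length in years; state costs follow the same weighting against the cost
    stream; the death-event cost is paid on the newly dead fraction of each
    cycle.  ``accrual`` selects the occupancy the rewards weight: the cycle's
    post-transition distribution (default) or the pre-transition one;
    ``half_cycle_correction`` averages the two.
    """
    n = series.cycles
    if len(costs.pfs) != n:
        raise ValueError(f"cost stream length {len(costs.pfs)} != horizon {n}")
    if accrual not in ("post", "pre"):
        raise ValueError("accrual must be 'post' or 'pre'")

    occ = np.zeros((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for i in range(n):
        occ[i + 1] = occ[i] @ series.matrices[i]

    if half_cycle_correction:
        weight = 0.5 * (occ[:-1] + occ[1:])
    elif accrual == "post":
        weight = occ[1:]
    else:
        weight = occ[:-1]

    beta = per_cycle_discount_factor(annual_discount, cycle_days)
    cycles = np.arange(1, n + 1, dtype=float)
    disc = beta**cycles
    dt_years = cycle_days / DAYS_PER_YEAR

    qaly = (weight[:, 0] * u_pfs + weight[:, 1] * u_pd) * dt_years
    life_years = (weight[:, 0] + weight[:, 1]) * dt_years
    new_deaths = occ[1:, 2] - occ[:-1, 2]
    recurring = weight[:, 0] * costs.pfs + weight[:, 1] * costs.pd + new_deaths * costs.death_event
    cost_undisc = recurring.copy()
    cost_disc = recurring * disc
    cost_undisc[0] += costs.initial  # accrued at model start, discount factor 1
    cost_disc[0] += costs.initial

    return CohortTrace(
        occupancy=occ,
        cost_undiscounted=cost_undisc,
        cost_discounted=cost_disc,
        qaly_undiscounted=qaly,
        qaly_discounted=qaly * disc,
        ly_discounted=life_years * disc,
    )
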