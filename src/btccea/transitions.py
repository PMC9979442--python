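"""Per-cycle transition probabilities for the three-state model.

States are (PFS, PD, Death).  PFS exits follow the fitted progression-free
survival curve; total deaths each cycle are allocated so the modelled alive
fraction tracks the fitted overall-survival curve exactly — the standard
construction of a state-transition model from two survival curves.  Deaths
are drawn first from PFS at the background-mortality rate, then from PD, and
any remainder again from PFS (reducing progressions), with clamping and a
logged warning if the two curves cross under extrapolation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .survival import ParametricFit

logger = logging.getLogger(__name__)

__all__ = [
    "STATES",
    "BackgroundMortality",
    "TransitionMatrixSeries",
    "survival_at",
    "cycle_exit_probability",
    "per_cycle_background_mortality",
    "build_matrix_series",
]

STATES = ("PFS", "PD", "Death")
DAYS_PER_YEAR = 365.25


@dataclasses.dataclass(frozen=True)
class BackgroundMortality:
    """All-cause annual death probability of the general population."""

    annual_probability: float = 0.00718

    def __post_init__(self) -> None:
        if not (0.0 <= self.annual_probability < 1.0):
            raise ValueError("annual probability must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class TransitionMatrixSeries:
    """Row-stochastic 3x3 matrices, one per cycle 1..N (index 0 = cycle 1)."""

    matrices: np.ndarray  # shape (N, 3, 3)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1:] != (3, 3):
            raise ValueError("matrix series must have shape (N, 3, 3)")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(m.sum(axis=2) - 1.0)) > 1e-12:
            raise ValueError("rows must sum to 1")
        object.__setattr__(self, "matrices", m)

    @property
    def cycles(self) -> int:
        return self.matrices.shape[0]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"cycle": i + 1, "from": STATES[a], "to": STATES[b], "p": self.matrices[i, a, b]}
            for i in range(self.cycles)
            for a in range(3)
            for b in range(3)
        ]
        return pd.DataFrame(rows)


def survival_at(fit: ParametricFit, t: float | np.ndarray) -> float | np.ndarray:
    """S(t) = exp(-lam * t**gam) of a fitted law, t in model cycles."""
    return fit.survival(t)


def cycle_exit_probability(fit: ParametricFit, i: int | np.ndarray) -> float | np.ndarray:
    """Conditional probability of leaving the curve's state during cycle i.

    p_i = 1 - S(i)/S(i-1) = 1 - exp(lam*(i-1)**gam - lam*i**gam); with gam = 1
    this reduces to the constant-hazard conversion 1 - exp(-lam) per cycle.
    Returns 1.0 (with a logged warning) where S(i-1) has underflowed to zero.
    """
    i_arr = np.asarray(i, dtype=float)
    if np.any(i_arr < 1):
        raise ValueError("cycle index must be >= 1")
    log_ratio = fit.lam * np.power(i_arr - 1.0, fit.gam) - fit.lam * np.power(i_arr, fit.gam)
    with np.errstate(over="ignore"):
        p = 1.0 - np.exp(log_ratio)
    prev = fit.survival(i_arr - 1.0)
    underflow = np.asarray(prev) <= 0.0
    if np.any(underflow):
        logger.warning("survival underflow at cycle(s) %s; exit probability set to 1", i)
        p = np.where(underflow, 1.0, p)
    return float(p) if np.ndim(i) == 0 else p


def per_cycle_background_mortality(
    bm: BackgroundMortality, cycle_days: float = 21.0
) -> float:
    """Convert an annual death probability to a per-cycle probability:
    1 - (1 - annual)**(cycle_days / 365.25)."""
    return 1.0 - (1.0 - bm.annual_probability) ** (cycle_days / DAYS_PER_YEAR)


def build_matrix_series(
    pfs_fit: ParametricFit,
    os_fit: ParametricFit,
    bm: BackgroundMortality,
    horizon_cycles: int,
    cycle_days: float = 21.0,
) -> TransitionMatrixSeries:
    """Build the time-indexed transition matrices over the horizon.

    Per cycle i (conditioning on state at i-1):

    * PFS exits: ``cycle_exit_probability(pfs_fit, i)``; of these, background
      mortality goes PFS→Death and the remainder progresses PFS→PD.
    * Total deaths are targeted at the OS hazard ``1 - S_OS(i)/S_OS(i-1)``
      applied to the alive cohort; PD→Death is chosen to meet the target
      after PFS deaths, with overflow shifted back to PFS→Death (reducing
      progressions) when PD occupancy is too small.  All probabilities are
      clamped to [0, 1]; an exhausted clamping budget logs a warning.

    When background mortality is 0 the modelled alive fraction equals
    ``S_OS(i)`` to machine precision by construction.
    """
    if horizon_cycles < 1:
        raise ValueError("horizon must be at least one cycle")
    bm_pc = per_cycle_background_mortality(bm, cycle_days)
    cycles = np.arange(1, horizon_cycles + 1)
    pfs_exit_all = np.clip(cycle_exit_probability(pfs_fit, cycles), 0.0, 1.0)
    os_hazard_all = np.clip(cycle_exit_probability(os_fit, cycles), 0.0, 1.0)
    mats = np.zeros((horizon_cycles, 3, 3))
    pfs_occ, pd_occ = 1.0, 0.0
    warned = False
    for i in range(1, horizon_cycles + 1):
        p_exit = float(pfs_exit_all[i - 1])
        os_hazard = float(os_hazard_all[i - 1])
        alive = pfs_occ + pd_occ
        deaths_needed = os_hazard * alive

        p_pfs_death = min(bm_pc, p_exit)
        pfs_deaths = min(pfs_occ * p_pfs_death, deaths_needed)
        p_pfs_death = pfs_deaths / pfs_occ if pfs_occ > 0 else 0.0

        pd_deaths_needed = deaths_needed - pfs_deaths
        pd_deaths = min(pd_deaths_needed, pd_occ)
        p_pd_death = pd_deaths / pd_occ if pd_occ > 0 else 0.0

        shortfall = pd_deaths_needed - pd_deaths
        if shortfall > 1e-15 and pfs_occ > 0:
            # PD cannot supply the OS-implied deaths; take them from PFS exits.
            extra = min(shortfall / pfs_occ, p_exit - p_pfs_death)
            p_pfs_death += extra
            shortfall -= extra * pfs_occ
        if shortfall > 1e-9 and not warned:
            logger.warning(
                "cycle %d: OS curve demands more deaths than PFS/PD can supply "
                "(shortfall %.3e); death flow clamped", i, shortfall,
            )
            warned = True

        p_pfs_pd = max(p_exit - p_pfs_death, 0.0)
        mats[i - 1] = [
            [1.0 - p_pfs_death - p_pfs_pd, p_pfs_pd, p_pfs_death],
            [0.0, 1.0 - p_pd_death, p_pd_death],
            [0.0, 0.0, 1.0],
        ]
        new_pd = pd_occ * (1.0 - p_pd_death) + pfs_occ * p_pfs_pd
        pfs_occ *= 1.0 - p_pfs_death - p_pfs_pd
        pd_occ = new_pd
    return TransitionMatrixSeries(mats)
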