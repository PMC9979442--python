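"""Parametric survival fitting from digitized Kaplan-Meier curves.

Published trial figures are the only survival evidence available for this
model, so the pipeline starts from digitized (time, survival) coordinates:
pseudo individual-patient records are reconstructed by interval allocation,
then Weibull and exponential laws are fitted by right-censored maximum
likelihood and compared by AIC.  All times are in model cycles (21 days)
unless converted at the I/O boundary.

Parameterisation: S(t) = exp(-lam * t**gam) with per-cycle^-gam rate lam > 0
and dimensionless shape gam > 0 (gam = 1 recovers the exponential).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "DigitizedCurve",
    "PseudoIPD",
    "ParametricFit",
    "CurveValidationError",
    "DegenerateInputError",
    "FitConvergenceError",
    "read_digitized_curve",
    "reconstruct_pseudo_ipd",
    "fit_parametric",
    "select_by_aic",
]

DAYS_PER_CYCLE = 21.0
DAYS_PER_MONTH = 30.44

Endpoint = Literal["OS", "PFS"]
Arm = Literal["combo", "chemo"]


class CurveValidationError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


class FitConvergenceError(RuntimeError):
    def __init__(self, message: str, grad_norm: float):
        super().__init__(f"{message} (final gradient norm {grad_norm:.3e})")
        self.grad_norm = grad_norm


@dataclasses.dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (time, survival) coordinates read off a published KM figure."""

    endpoint: str
    arm: str
    times: np.ndarray          # model cycles, strictly increasing, times[0] == 0
    survival: np.ndarray       # non-increasing, in [0, 1], survival[0] == 1
    risk_times: np.ndarray | None = None
    n_at_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1 or len(t) < 2:
            raise CurveValidationError("curve needs >= 2 (time, survival) points")
        if np.any(np.diff(t) <= 0):
            raise CurveValidationError("times must be strictly increasing")
        if np.any((s < -1e-12) | (s > 1 + 1e-12)):
            bad = int(np.argmax((s < -1e-12) | (s > 1 + 1e-12)))
            raise CurveValidationError(
                f"survival outside [0, 1] at row {bad}: S={s[bad]}"
            )
        rises = np.diff(s) > 1e-9
        if np.any(rises):
            bad = int(np.argmax(rises)) + 1
            raise CurveValidationError(
                f"survival increases at row {bad}: "
                f"S({t[bad - 1]})={s[bad - 1]} -> S({t[bad]})={s[bad]}"
            )
        if t[0] != 0.0 or abs(s[0] - 1.0) > 1e-12:
            raise CurveValidationError("curve must be anchored at (0, 1)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", np.clip(s, 0.0, 1.0))


@dataclasses.dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed event/censoring records (time in cycles, event flag)."""

    times: np.ndarray
    events: np.ndarray  # 1 = death/progression, 0 = administratively censored

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be 1-D and aligned")
        if len(t) and t.min() <= 0:
            raise ValueError("all record times must be positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclasses.dataclass(frozen=True)
class ParametricFit:
    """Maximum-likelihood fit of a survival law to pseudo-IPD."""

    family: Literal["weibull", "exponential"]
    lam: float
    gam: float
    log_likelihood: float
    aic: float
    n: int

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return 2 if self.family == "weibull" else 1

    def survival(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be nonnegative")
        out = np.exp(-self.lam * np.power(t, self.gam))
        return float(out) if out.ndim == 0 else out

    def median(self) -> float:
        return (np.log(2.0) / self.lam) ** (1.0 / self.gam)

    def mean(self) -> float:
        from scipy.special import gamma as gamma_fn

        return gamma_fn(1.0 + 1.0 / self.gam) / self.lam ** (1.0 / self.gam)

    def to_record(self, endpoint: str = "", arm: str = "") -> dict:
        return {
            "endpoint": endpoint,
            "arm": arm,
            "family": self.family,
            "lambda": self.lam,
            "gamma": self.gam,
            "loglik": self.log_likelihood,
            "aic": self.aic,
            "n": self.n,
        }


def read_digitized_curve(
    path: str | Path,
    endpoint: str = "OS",
    arm: str = "combo",
    time_unit: Literal["cycle", "day", "month"] = "cycle",
) -> DigitizedCurve:
    """Read a digitized KM curve from CSV with header ``time,survival[,n_risk]``.

    Rows are sorted by time, a (0, 1) anchor is prepended when absent, and the
    optional third column is kept as a numbers-at-risk table.  Times are
    converted from ``time_unit`` to model cycles.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "time" not in cols or "survival" not in cols:
        raise CurveValidationError(f"{path}: expected columns time,survival[,n_risk]")
    if len(df) < 2:
        raise CurveValidationError(f"{path}: need at least 2 rows")
    df = df.sort_values("time").reset_index(drop=True)

    scale = {"cycle": 1.0, "day": 1.0 / DAYS_PER_CYCLE, "month": DAYS_PER_MONTH / DAYS_PER_CYCLE}[
        time_unit
    ]
    t = df["time"].to_numpy(dtype=float) * scale
    s = df["survival"].to_numpy(dtype=float)
    risk_t = risk_n = None
    if "n_risk" in cols:
        mask = df["n_risk"].notna().to_numpy()
        risk_t = t[mask]
        risk_n = df.loc[mask, "n_risk"].to_numpy(dtype=float)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return DigitizedCurve(
        endpoint=endpoint, arm=arm, times=t, survival=s,
        risk_times=risk_t, n_at_risk=risk_n,
    )


def _rescale_to_risk_table(
    events: np.ndarray, upper_times: np.ndarray, n: int,
    risk_times: np.ndarray, n_at_risk: np.ndarray,
) -> np.ndarray:
    """Scale per-interval event counts so the implied numbers at risk match a
    published risk table (within integer rounding).

    With administrative censoring only at follow-up end, the implied number at
    risk just before a risk-table time T is n minus the events allocated to
    intervals ending at or before T; interval counts in each risk-table span
    are rescaled proportionally toward that cumulative target.
    """
    events = events.astype(float).copy()
    prev_target = 0.0
    prev_idx = 0
    for rt, rn in zip(risk_times, n_at_risk):
        if rt <= 0:
            continue
        idx = int(np.searchsorted(upper_times, rt, side="right"))
        target_cum = float(n - rn)
        span = events[prev_idx:idx]
        span_sum = span.sum()
        want = max(target_cum - prev_target, 0.0)
        if span_sum > 0:
            events[prev_idx:idx] = span * want / span_sum
        prev_target = max(target_cum, prev_target)
        prev_idx = idx
    return np.rint(events).astype(int)


def reconstruct_pseudo_ipd(curve: DigitizedCurve, assumed_n: int) -> PseudoIPD:
    """Reconstruct pseudo individual-patient data by interval allocation.

    For each adjacent pair of curve points, ``round(assumed_n * dS)`` event
    records are placed at the interval midpoint; cohort members surviving the
    final point become censored records at that time.  When the curve carries
    a risk table, interval event counts are rescaled to honour it.
    """
    if assumed_n < 10:
        raise DegenerateInputError("assumed_n must be >= 10")
    t, s = curve.times, curve.survival
    drops = s[:-1] - s[1:]
    events_per_interval = np.rint(assumed_n * drops).astype(int)
    if curve.risk_times is not None and curve.n_at_risk is not None:
        events_per_interval = _rescale_to_risk_table(
            events_per_interval, t[1:], assumed_n, curve.risk_times, curve.n_at_risk
        )
    total_events = int(events_per_interval.sum())
    if total_events == 0:
        raise DegenerateInputError(
            f"assumed_n={assumed_n} too small: every interval rounds to zero events"
        )
    midpoints = 0.5 * (t[:-1] + t[1:])
    times = np.repeat(midpoints, events_per_interval)
    events = np.ones_like(times, dtype=int)
    n_censored = assumed_n - total_events
    if n_censored > 0:
        times = np.concatenate([times, np.full(n_censored, t[-1])])
        events = np.concatenate([events, np.zeros(n_censored, dtype=int)])
    order = np.argsort(times, kind="stable")
    return PseudoIPD(times=times[order], events=events[order])


def log_likelihood(lam: float, gam: float, ipd: PseudoIPD) -> float:
    """Right-censored log-likelihood of a Weibull law at (lam, gam):
    sum_events log f(t) + sum_censored log S(t), S(t) = exp(-lam t**gam)."""
    t, e = ipd.times, ipd.events.astype(float)
    log_t = np.log(t)
    return float(
        np.sum(e * (np.log(lam) + np.log(gam) + (gam - 1.0) * log_t))
        - (lam * np.exp(gam * log_t)).sum()
    )


def _neg_loglik_weibull(theta: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    lam, gam = np.exp(theta)
    log_t = np.log(t)
    cum_hazard = lam * np.exp(gam * log_t)
    ll = np.sum(e * (np.log(lam) + np.log(gam) + (gam - 1.0) * log_t)) - cum_hazard.sum()
    return -ll


def fit_parametric(
    ipd: PseudoIPD,
    family: Literal["weibull", "exponential"] = "weibull",
    tol: float = 1e-12,
    fix_gamma: float | None = None,
) -> ParametricFit:
    """Fit a survival law by right-censored maximum likelihood.

    The log-likelihood is sum_events log f(t) + sum_censored log S(t).  The
    exponential MLE is closed-form (lam = events / total time at risk); the
    Weibull is maximised by L-BFGS-B on (log lam, log gam) starting from the
    exponential hazard moment estimate with gam = 1.
    """
    t = ipd.times
    e = ipd.events.astype(float)
    d = float(e.sum())
    if d < 1:
        raise DegenerateInputError("at least one event record is required for a fit")

    if family == "exponential":
        lam = d / t.sum()
        ll = d * np.log(lam) - lam * t.sum()
        return ParametricFit("exponential", lam, 1.0, float(ll), float(2 * 1 - 2 * ll), ipd.n)
    if family != "weibull":
        raise ValueError(f"unknown family {family!r}")
    if fix_gamma is not None:
        # Profile MLE at fixed shape is closed-form: lam = events / sum(t**gam).
        gam = float(fix_gamma)
        lam = d / np.power(t, gam).sum()
        ll = log_likelihood(lam, gam, ipd)
        return ParametricFit("weibull", lam, gam, ll, 2 * 2 - 2 * ll, ipd.n)

    x0 = np.array([np.log(d / t.sum()), 0.0])
    res = minimize(
        _neg_loglik_weibull,
        x0,
        args=(t, e),
        method="L-BFGS-B",
        bounds=[(-30.0, 10.0), (-4.0, 4.0)],
        options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    if not res.success and grad_norm > 1e-4:
        raise FitConvergenceError(f"Weibull MLE did not converge: {res.message}", grad_norm)
    lam, gam = np.exp(res.x)
    ll = -float(res.fun)
    return ParametricFit("weibull", float(lam), float(gam), ll, 2 * 2 - 2 * ll, ipd.n)


def select_by_aic(fits: Sequence[ParametricFit]) -> ParametricFit:
    """Return the fit with minimal AIC; ties go to the fewer-parameter family."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.k))
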