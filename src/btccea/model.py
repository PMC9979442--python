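"""Model/Results interface over the cost-effectiveness pipeline.

``CostEffectivenessModel`` is built from a :class:`~btccea.config.ModelConfig`
(or a YAML file); ``fit()`` runs both treatment arms under both charity
scenarios and returns a :class:`CEResults` carrying totals, incremental
quantities, ICERs and a ``summary()`` table.  Scenario sweeps (break-even
price), the tornado analysis and the probabilistic sensitivity analysis hang
off the model object.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import economics
from .config import ModelConfig, base_case_config, load_config
from .economics import CEComparison, PSAResult, TornadoEntry

__all__ = ["CostEffectivenessModel", "CEResults"]


class CostEffectivenessModel:
    """Three-state Markov cost-effectiveness model of first-line durvalumab
    plus gemcitabine/cisplatin versus gemcitabine/cisplatin alone.

    Parameters
    ----------
    config :
        Complete model configuration; defaults to the packaged base case.

    Examples
    --------
    >>> model = CostEffectivenessModel()
    >>> results = model.fit()
    >>> round(results.comparison(charity=False).icer) > 37663
    True
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config if config is not None else base_case_config()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CostEffectivenessModel":
        return cls(load_config(path))

    def fit(self) -> "CEResults":
        """Run both arms under both charity scenarios."""
        return CEResults(
            model=self,
            no_charity=economics.evaluate(self.config, charity=False),
            with_charity=economics.evaluate(self.config, charity=True),
        )

    def breakeven(self, charity: bool = False, **kwargs) -> dict:
        """Durvalumab price at which the ICER meets the WTP threshold."""
        return economics.breakeven_price(self.config, charity=charity, **kwargs)

    def tornado(self, charity: bool = False) -> list[TornadoEntry]:
        """One-way sensitivity analysis over every range-carrying parameter."""
        return economics.one_way_sa(self.config, charity=charity)

    def psa(self, charity: bool = False, n: int = 1000, seed: int = 0) -> PSAResult:
        """Probabilistic sensitivity analysis with ``n`` Monte Carlo draws."""
        return economics.run_psa(self.config, charity=charity, n=n, seed=seed)


@dataclasses.dataclass(frozen=True)
class CEResults:
    """Fitted base-case results for both charity scenarios."""

    model: CostEffectivenessModel
    no_charity: CEComparison
    with_charity: CEComparison

    def comparison(self, charity: bool) -> CEComparison:
        return self.with_charity if charity else self.no_charity

    @property
    def charity_saving(self) -> float:
        """Total combo-arm cost avoided by the charity donation rule."""
        return (
            self.no_charity.reference.total_cost
            - self.with_charity.reference.total_cost
        )

    def summary(self) -> pd.DataFrame:
        """Base-case table: per-arm totals, increments and ICERs."""
        rows = []
        for label, cmp_ in (("no charity", self.no_charity), ("charity", self.with_charity)):
            rows.append(
                {
                    "scenario": label,
                    "cost_chemo": cmp_.comparator.total_cost,
                    "cost_combo": cmp_.reference.total_cost,
                    "qaly_chemo": cmp_.comparator.total_qaly,
                    "qaly_combo": cmp_.reference.total_qaly,
                    "inc_cost": cmp_.incremental_cost,
                    "inc_qaly": cmp_.incremental_qaly,
                    "icer": cmp_.icer,
                    "cost_effective": cmp_.cost_effective,
                }
            )
        return pd.DataFrame(rows).set_index("scenario")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        wtp = self.model.config.wtp_per_qaly
        lines = ["Cost-effectiveness results (USD, discounted)", "-" * 46]
        for label, cmp_ in (("No charity", self.no_charity), ("Charity", self.with_charity)):
            lines += [
                f"{label}: dCost = {cmp_.incremental_cost:,.2f}, "
                f"dQALY = {cmp_.incremental_qaly:.4f}, ICER = {cmp_.icer:,.2f}/QALY "
                f"({'<=' if cmp_.cost_effective else '>'} WTP {wtp:,.2f})"
            ]
        return "\n".join(lines)
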