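"""Discounted costs, QALYs and incremental cost-effectiveness statistics.

Each cycle of the cohort trace accrues per-state direct medical costs,
annual drug cost for every patient still alive, and utility-weighted
life-years.  Costs are discounted at the table's annual cost rate (3% in
the base case) with cycle 0 undiscounted by default; QALYs are left
undiscounted in the base case (``ModelConfig.discount_outcomes`` enables
discounting at the table's outcome rate).  Death accrues no cost and no
utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CohortTrace, ModelConfig, STATES
from .parameters import ParameterSet

__all__ = [
    "StrategyResult",
    "IncrementalResult",
    "discount_factor",
    "accumulate",
    "evaluate_strategy",
    "icer",
    "net_monetary_benefit",
]


@dataclass(frozen=True)
class StrategyResult:
    """Discounted lifetime cost (IDR) and QALYs for one strategy."""

    strategy: str
    total_cost: float
    total_qaly: float
    per_cycle: pd.DataFrame
    config: ModelConfig

    @property
    def drug_cost(self) -> float:
        """Discounted lifetime drug cost (IDR)."""
        return float(self.per_cycle["disc_drug_cost"].sum())


@dataclass(frozen=True)
class IncrementalResult:
    """Head-to-head comparison of an intervention against a comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    status: str     # "icer", "dominant", "dominated" or "undefined"
    quadrant: str   # NE / NW / SE / SW of the cost-effectiveness plane

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.status == "icer":
            return (
                f"{self.intervention} vs {self.comparator}: "
                f"ICER {self.icer:,.2f} IDR/QALY"
            )
        return f"{self.intervention} vs {self.comparator}: {self.status}"


def discount_factor(rate: float, cycle: int) -> float:
    """End-of-cycle discount factor ``1 / (1 + rate) ** cycle``."""
    if rate < 0.0:
        raise ValueError("discount rate must be >= 0")
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return 1.0 / (1.0 + rate) ** cycle


def _cycle_weights(n: int, half_cycle_correction: bool) -> np.ndarray:
    w = np.ones(n)
    if half_cycle_correction and n > 1:
        w[0] = 0.5
        w[-1] = 0.5
    return w


def accumulate(
    trace: CohortTrace,
    p: ParameterSet,
    strategy: str | None = None,
    cfg: ModelConfig | None = None,
) -> StrategyResult:
    """Tally discounted costs and QALYs over a cohort trace.

    Per cycle: state cost is occupancy-weighted direct medical cost
    (death costing nothing); drug cost is the annual statin price times
    the proportion still alive; QALYs are occupancy-weighted utilities.
    Costs discount at ``drC`` (shifted one year under
    ``discount_timing="end"``); outcomes discount at ``drO`` only when
    ``cfg.discount_outcomes`` is set.  With half-cycle correction the
    first and last cycles carry half weight.
    """
    cfg = cfg or ModelConfig()
    strategy = strategy or trace.strategy
    occ = trace.occupancy
    n = trace.n_cycles

    dmc = np.array([p.dmcRA.mean, p.dmcMI.mean, p.dmcCAr.mean, p.dmcRv.mean, 0.0])
    util = np.array([p.uRA.mean, p.uMI.mean, p.uCAr.mean, p.uRv.mean, 0.0])
    drug_price = p.cHIS.mean if strategy == "HIS" else p.cNHIS.mean

    cycles = np.arange(n)
    w = _cycle_weights(n, cfg.half_cycle_correction)
    shift = 1 if cfg.discount_timing == "end" else 0
    rate_out = p.drO.mean if cfg.discount_outcomes else 0.0
    df_cost = (1.0 + p.drC.mean) ** -(cycles + shift)
    df_out = (1.0 + rate_out) ** -(cycles + shift)

    state_cost = occ @ dmc
    drug_cost = trace.alive * drug_price
    qaly = occ @ util

    disc_state = w * df_cost * state_cost
    disc_drug = w * df_cost * drug_cost
    disc_qaly = w * df_out * qaly

    per_cycle = pd.DataFrame(
        {
            "cycle": cycles,
            "age": trace.ages,
            **{f"occ_{s}": occ[:, i] for i, s in enumerate(STATES)},
            "state_cost": state_cost,
            "drug_cost": drug_cost,
            "qaly": qaly,
            "disc_state_cost": disc_state,
            "disc_drug_cost": disc_drug,
            "disc_qaly": disc_qaly,
        }
    )
    return StrategyResult(
        strategy=strategy,
        total_cost=float(disc_state.sum() + disc_drug.sum()),
        total_qaly=float(disc_qaly.sum()),
        per_cycle=per_cycle,
        config=cfg,
    )


def evaluate_strategy(
    p: ParameterSet, strategy: str, cfg: ModelConfig | None = None
) -> StrategyResult:
    """Run the cohort and accumulate in one step."""
    from .markov import run_cohort

    cfg = cfg or ModelConfig()
    return accumulate(run_cohort(p, strategy, cfg), p, strategy, cfg)


_QALY_TOL = 1e-12


def icer(a: StrategyResult, b: StrategyResult) -> IncrementalResult:
    """Incremental cost-effectiveness of ``a`` (intervention) vs ``b``."""
    if a.config != b.config:
        raise ValueError("cannot compare results from different model configs")
    dc = a.total_cost - b.total_cost
    dq = a.total_qaly - b.total_qaly
    quadrant = ("N" if dc >= 0 else "S") + ("E" if dq >= 0 else "W")
    if dc < 0 and dq > 0:
        status, value = "dominant", None
    elif dc > 0 and dq < 0:
        status, value = "dominated", None
    elif abs(dq) < _QALY_TOL:
        status, value = "undefined", None
    else:
        status, value = "icer", dc / dq
    return IncrementalResult(
        intervention=a.strategy,
        comparator=b.strategy,
        delta_cost=dc,
        delta_qaly=dq,
        icer=value,
        status=status,
        quadrant=quadrant,
    )


def net_monetary_benefit(r: StrategyResult, wtp: float) -> float:
    """``wtp * QALYs - cost``: positive increments mean cost-effective."""
    if wtp < 0.0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    return wtp * r.total_qaly - r.total_cost
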