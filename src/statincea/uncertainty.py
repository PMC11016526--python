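"""Parameter uncertainty: probabilistic and one-way sensitivity analyses.

The probabilistic sensitivity analysis (PSA) redraws the whole parameter
table per iteration — probabilities and utilities from Beta distributions,
costs from Gamma, hazard ratios from Lognormal, each moment-matched to the
table's mean and standard error — and reruns both strategies with the same
sampled table, so treatment effect is the only between-arm difference.
The stay-in-RA probability is the residual of the sampled RA-row events,
keeping that row stochastic by construction.

The one-way analysis (tornado) moves one parameter at a time to its low
and high bound and records the deterministic ICER at each, ranking
parameters by ICER spread.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import StrategyResult, evaluate_strategy, icer
from .markov import ModelConfig
from .parameters import (
    MORTALITY_STATES,
    ParameterSet,
    ParameterValue,
    validate_parameter_set,
)

__all__ = [
    "PsaIteration",
    "PsaResult",
    "TornadoEntry",
    "CeacPoint",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "owsa",
    "export_ce_plane",
]


@dataclass(frozen=True)
class PsaIteration:
    """One Monte Carlo draw and the incremental result it produced."""

    index: int
    sampled: ParameterSet
    cost_his: float
    qaly_his: float
    cost_lmis: float
    qaly_lmis: float

    @property
    def delta_cost(self) -> float:
        return self.cost_his - self.cost_lmis

    @property
    def delta_qaly(self) -> float:
        return self.qaly_his - self.qaly_lmis


@dataclass(frozen=True)
class PsaResult:
    """A full PSA run with its reproducibility metadata."""

    iterations: tuple[PsaIteration, ...]
    seed: int
    resample_count: int

    def __len__(self) -> int:
        return len(self.iterations)

    def __iter__(self):
        return iter(self.iterations)

    @property
    def delta_cost(self) -> np.ndarray:
        return np.array([it.delta_cost for it in self.iterations])

    @property
    def delta_qaly(self) -> np.ndarray:
        return np.array([it.delta_qaly for it in self.iterations])

    def icer_ratio_of_means(self) -> float:
        """Probabilistic ICER as mean incremental cost over mean gain."""
        return float(self.delta_cost.mean() / self.delta_qaly.mean())

    def icer_median_of_ratios(self) -> float:
        return float(np.median(self.delta_cost / self.delta_qaly))


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado: the ICER at a parameter's two bounds."""

    parameter: str
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass(frozen=True)
class CeacPoint:
    """Probability the intervention is cost-effective at one threshold."""

    wtp: float
    probability_cost_effective: float


# --------------------------------------------------------------------------
# Distribution sampling (method of moments)
# --------------------------------------------------------------------------


def _draw_beta(rng: np.random.Generator, mean: float, se: float) -> float:
    nu = mean * (1.0 - mean) / se**2 - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _draw_gamma(rng: np.random.Generator, mean: float, se: float) -> float:
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return float(rng.gamma(shape, scale))


def _draw_lognormal(rng: np.random.Generator, mean: float, se: float) -> float:
    sigma2 = math.log1p((se / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _draw(rng: np.random.Generator, v: ParameterValue) -> float:
    """Sample one parameter; SE of zero or None collapses to the mean."""
    if v.se is None or v.se == 0.0:
        return v.mean
    if v.family in ("probability", "utility"):
        if v.mean in (0.0, 1.0):
            return v.mean
        return _draw_beta(rng, v.mean, v.se)
    if v.family == "cost":
        if v.mean == 0.0:
            return 0.0
        return _draw_gamma(rng, v.mean, v.se)
    if v.family == "hazard_ratio":
        return _draw_lognormal(rng, v.mean, v.se)
    return v.mean  # rates (discount) are fixed in PSA


def sample_parameter_set(p: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """Draw one random parameter table around the base-case table.

    The RA-row event probabilities are sampled and ``tpRA_RA`` is set to
    their residual; if sampled non-stay mass in any row exceeds 1 the
    offending entries are rescaled proportionally so the table stays
    feasible.  Sampled values are point realizations, so they carry no
    standard error of their own.
    """
    new_scalars: dict[str, ParameterValue] = {}
    for name in ParameterSet.SCALAR_FIELDS:
        v: ParameterValue = getattr(p, name)
        if name == "tpRA_RA":
            new_scalars[name] = dataclasses.replace(v, se=None)  # residual, set below
        else:
            new_scalars[name] = dataclasses.replace(v, mean=_draw(rng, v), se=None)

    # RA row: stay probability is the residual of the sampled events.
    ra_events = [new_scalars[k] for k in ("tpRA_MI", "tpRA_CAr", "tpRA_Rv")]
    total = sum(v.mean for v in ra_events)
    if total > 1.0:
        for v in ra_events:
            new_scalars[v.name] = v.with_mean(v.mean / total)
        total = 1.0
    new_scalars["tpRA_RA"] = new_scalars["tpRA_RA"].with_mean(1.0 - total)

    mortality: dict[str, tuple] = {}
    for state in MORTALITY_STATES:
        bands = []
        for band in p.mortality[state]:
            bands.append(
                dataclasses.replace(
                    band,
                    value=dataclasses.replace(
                        band.value, mean=_draw(rng, band.value), se=None
                    ),
                )
            )
        mortality[state] = tuple(bands)

    sampled = dataclasses.replace(p, mortality=mortality, **new_scalars)

    # Event-state rows: rescale stay/switch entries if a band overflows.
    sampled = _rescale_event_rows(sampled)
    return sampled


def _rescale_event_rows(p: ParameterSet) -> ParameterSet:
    worst = {s: max(b.value.mean for b in p.mortality[s]) for s in MORTALITY_STATES}
    updates: dict[str, float] = {}
    for state, names in (("MI", ("tpMI_MI", "tpMI_Rv")), ("Rv", ("tpRv_Rv", "tpRv_MI"))):
        mass = sum(getattr(p, n).mean for n in names)
        if mass + worst[state] > 1.0:
            scale = (1.0 - worst[state]) / mass
            for n in names:
                updates[n] = getattr(p, n).mean * scale
    return p.replace(**updates) if updates else p


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------

_MAX_RESAMPLE = 100


def run_psa(
    p: ParameterSet,
    cfg: ModelConfig | None = None,
    n: int = 1000,
    seed: int = 0,
) -> PsaResult:
    """Monte Carlo over the parameter distributions.

    Iteration ``i`` draws from ``default_rng([seed, i])``, so any subset
    of iterations is reproducible independently of the others.  A draw
    that fails validation is redrawn (counted, capped at 100 attempts).
    """
    cfg = cfg or ModelConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    iters: list[PsaIteration] = []
    resamples = 0
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        for attempt in range(_MAX_RESAMPLE):
            sampled = sample_parameter_set(p, rng)
            if not validate_parameter_set(sampled):
                break
            resamples += 1
        else:  # pragma: no cover - defensive cap
            raise RuntimeError(f"iteration {i}: no feasible draw in {_MAX_RESAMPLE} tries")
        his = evaluate_strategy(sampled, "HIS", cfg)
        lmis = evaluate_strategy(sampled, "LMIS", cfg)
        iters.append(
            PsaIteration(
                index=i,
                sampled=sampled,
                cost_his=his.total_cost,
                qaly_his=his.total_qaly,
                cost_lmis=lmis.total_cost,
                qaly_lmis=lmis.total_qaly,
            )
        )
    return PsaResult(iterations=tuple(iters), seed=seed, resample_count=resamples)


def ceac(psa: PsaResult, thresholds: list[float]) -> list[CeacPoint]:
    """Fraction of iterations with positive incremental net benefit."""
    if len(psa) == 0:
        raise ValueError("CEAC requires at least one PSA iteration")
    dq, dc = psa.delta_qaly, psa.delta_cost
    points = []
    for wtp in thresholds:
        prob = float(np.mean(wtp * dq - dc > 0.0))
        points.append(CeacPoint(wtp=wtp, probability_cost_effective=prob))
    return points


def export_ce_plane(psa: PsaResult, thresholds: list[float] | None = None) -> pd.DataFrame:
    """Cost-effectiveness plane scatter: one row per PSA iteration."""
    df = pd.DataFrame(
        {
            "iteration": [it.index for it in psa],
            "delta_qaly": psa.delta_qaly,
            "delta_cost": psa.delta_cost,
            "cost_his": [it.cost_his for it in psa],
            "qaly_his": [it.qaly_his for it in psa],
            "cost_lmis": [it.cost_lmis for it in psa],
            "qaly_lmis": [it.qaly_lmis for it in psa],
        }
    )
    df.attrs["wtp_thresholds"] = list(thresholds or [])
    return df


# --------------------------------------------------------------------------
# One-way deterministic sensitivity analysis (tornado)
# --------------------------------------------------------------------------

_DOMAIN_BOUNDS = {
    "probability": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "cost": (0.0, math.inf),
    "hazard_ratio": (1e-9, math.inf),
}

#: Discount rates are varied over guideline bounds rather than an SE range.
DISCOUNT_RATE_RANGE = (0.0, 0.05)


def _bounds(v: ParameterValue, range_rule: str) -> tuple[float, float] | None:
    if v.family == "rate":
        return DISCOUNT_RATE_RANGE
    if range_rule == "ci95":
        if v.se is None or v.se == 0.0:
            return None
        lo, hi = v.mean - 1.96 * v.se, v.mean + 1.96 * v.se
    elif range_rule == "pct20":
        lo, hi = 0.8 * v.mean, 1.2 * v.mean
    else:
        raise ValueError(f"unknown range rule {range_rule!r}")
    dom_lo, dom_hi = _DOMAIN_BOUNDS[v.family]
    return max(lo, dom_lo), min(hi, dom_hi)


def _deterministic_icer(p: ParameterSet, cfg: ModelConfig) -> float:
    res = icer(evaluate_strategy(p, "HIS", cfg), evaluate_strategy(p, "LMIS", cfg))
    if res.icer is None:
        # Dominance still needs a position on the tornado axis; the signed
        # ratio preserves direction.
        return res.delta_cost / res.delta_qaly
    return res.icer


def owsa(
    p: ParameterSet,
    cfg: ModelConfig | None = None,
    range_rule: str = "ci95",
) -> list[TornadoEntry]:
    """One-way sensitivity analysis over every uncertain parameter.

    Scalar parameters move to mean +/- 1.96 SE (``ci95``, clipped to their
    domain) or +/- 20% (``pct20``); each age-banded mortality family moves
    all its bands together; the two discount rates sweep 0 to 5%.
    Entries are returned sorted by ICER spread, largest first.
    """
    cfg = cfg or ModelConfig()
    entries: list[TornadoEntry] = []

    def eval_at(modified: ParameterSet) -> float:
        return _deterministic_icer(modified, cfg)

    for name in ParameterSet.SCALAR_FIELDS:
        if name == "tpRA_RA":
            continue  # residual of the RA row, not an independent input
        v: ParameterValue = getattr(p, name)
        b = _bounds(v, range_rule)
        if b is None:
            continue
        lo, hi = b
        icer_lo = eval_at(p.replace(**{name: lo}))
        icer_hi = eval_at(p.replace(**{name: hi}))
        entries.append(TornadoEntry(v.name, lo, hi, icer_lo, icer_hi))

    for state in MORTALITY_STATES:
        bands = p.mortality[state]
        bounds = [_bounds(b.value, range_rule) for b in bands]
        lo_means = [
            lb[0] if lb is not None else b.value.mean for b, lb in zip(bands, bounds)
        ]
        hi_means = [
            lb[1] if lb is not None else b.value.mean for b, lb in zip(bands, bounds)
        ]
        icer_lo = eval_at(p.replace_mortality(state, lo_means))
        icer_hi = eval_at(p.replace_mortality(state, hi_means))
        entries.append(
            TornadoEntry(
                f"tp{state}_D", float(np.mean(lo_means)), float(np.mean(hi_means)),
                icer_lo, icer_hi,
            )
        )

    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries
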