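"""Markov cohort engine: transition matrices and the lifetime state trace.

Five health states: Resolved ACS (RA), Myocardial Infarction (MI), Cardiac
Arrest (CAr), Revascularization (Rv) and Death (D).  The whole cohort
starts in RA at age 30 and is advanced in one-year cycles; Death is
absorbing.  Mortality from the three event states is age-banded in 5-year
bands (30-34 ... 80-84); beyond 84 the last band is held by default.

The high-intensity-statin arm differs from the comparator only through the
three hazard ratios, applied to transitions into MI, CAr and Rv.  Where
the source material leaves a convention open, a :class:`ModelConfig`
switch makes it explicit: where survivors of an event year go
(``residual_rule``), how a hazard ratio acts on a probability
(``hr_transform``), which transitions it acts on (``hr_scope``),
half-cycle correction and the over-84 band rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .parameters import AGE_BANDS, ParameterSet

__all__ = [
    "STATES",
    "STATE_INDEX",
    "ModelConfig",
    "TransitionMatrix",
    "CohortTrace",
    "age_band_for",
    "apply_hazard_ratio",
    "build_transition_matrix",
    "run_cohort",
    "RowRescaleWarning",
]

#: Canonical state order used by every matrix and trace.
STATES: tuple[str, ...] = ("RA", "MI", "CAr", "Rv", "D")
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

_RA, _MI, _CAR, _RV, _D = range(5)

STRATEGIES = ("HIS", "LMIS")


class RowRescaleWarning(UserWarning):
    """A transition row's event mass exceeded 1 and was rescaled."""


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration and modelling-convention switches."""

    start_age: int = 30
    max_age: int = 100
    cycle_length: float = 1.0
    residual_rule: str = "to_RA"          # or "stay"
    hr_transform: str = "multiplicative"  # or "rate_based"
    hr_scope: str = "all_inbound"         # or "from_RA_only"
    half_cycle_correction: bool = False
    over_84_rule: str = "hold_last_band"  # or "truncate"
    #: Whether QALYs are discounted at the table's outcome rate.  The
    #: published base case is reproducible only with outcomes left
    #: undiscounted (see docs/methods.md), so the default is False; set
    #: True for guideline-conformant discounting of both streams.
    discount_outcomes: bool = False
    #: "begin": payments fall at cycle start, cycle 0 undiscounted
    #: (factor (1+r)^-t); "end": payments fall at the end of each cycle
    #: year (factor (1+r)^-(t+1)).
    discount_timing: str = "begin"

    def __post_init__(self) -> None:
        if self.start_age < 30:
            raise ValueError("start_age must be >= 30 (no bands below 30)")
        if self.max_age < self.start_age:
            raise ValueError("max_age must be >= start_age")
        if self.cycle_length != 1.0:
            raise ValueError("only 1-year cycles are supported")
        _check_enum("residual_rule", self.residual_rule, ("to_RA", "stay"))
        _check_enum("hr_transform", self.hr_transform, ("multiplicative", "rate_based"))
        _check_enum("hr_scope", self.hr_scope, ("all_inbound", "from_RA_only"))
        _check_enum("over_84_rule", self.over_84_rule, ("hold_last_band", "truncate"))
        _check_enum("discount_timing", self.discount_timing, ("begin", "end"))

    @property
    def n_cycles(self) -> int:
        """Number of cycles in the trace (cycle 0 .. max_age - start_age)."""
        horizon = self.max_age
        if self.over_84_rule == "truncate":
            horizon = min(horizon, AGE_BANDS[-1][1])
        return horizon - self.start_age + 1


def _check_enum(name: str, value: str, allowed: tuple[str, ...]) -> None:
    if value not in allowed:
        raise ValueError(f"{name} must be one of {allowed}, got {value!r}")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 matrix for one strategy at one age."""

    entries: np.ndarray
    strategy: str
    age: int

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", e)
        if e.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if (e < -1e-12).any():
            raise ValueError("negative transition probability")
        if not np.allclose(e.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")

    def p(self, from_state: str, to_state: str) -> float:
        return float(self.entries[STATE_INDEX[from_state], STATE_INDEX[to_state]])


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state-occupancy proportions, cycle 0 at ``start_age``."""

    occupancy: np.ndarray  # shape (n_cycles, 5)
    ages: np.ndarray       # shape (n_cycles,)
    strategy: str

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def state(self, label: str) -> np.ndarray:
        return self.occupancy[:, STATE_INDEX[label]]

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, _D]


def age_band_for(age: int, over_84_rule: str = "hold_last_band") -> tuple[int, int]:
    """The 5-year mortality band containing ``age``.

    Ages past the last band either reuse it (``hold_last_band``) or raise
    (``truncate``, under which the horizon must not reach such ages).
    """
    if age < AGE_BANDS[0][0]:
        raise ValueError(f"age {age} below the first band {AGE_BANDS[0]}")
    if age > AGE_BANDS[-1][1]:
        if over_84_rule == "hold_last_band":
            return AGE_BANDS[-1]
        raise ValueError(f"age {age} beyond the last band under rule 'truncate'")
    lo = AGE_BANDS[0][0] + 5 * ((age - AGE_BANDS[0][0]) // 5)
    return (lo, lo + 4)


def apply_hazard_ratio(p: float, hr: float, transform: str = "multiplicative") -> float:
    """Apply a hazard ratio to an annual transition probability.

    ``multiplicative`` scales the probability directly (capped at 1);
    ``rate_based`` converts to a constant hazard, scales it, and converts
    back: ``1 - (1 - p) ** hr``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if hr <= 0.0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    if transform == "multiplicative":
        return min(hr * p, 1.0)
    if transform == "rate_based":
        return 1.0 - (1.0 - p) ** hr
    raise ValueError(f"unknown hr transform {transform!r}")


def build_transition_matrix(
    p: ParameterSet, strategy: str, age: int, cfg: ModelConfig | None = None
) -> TransitionMatrix:
    """Assemble the one-cycle transition matrix for a strategy at an age.

    The comparator arm uses the table probabilities directly.  The
    high-intensity arm multiplies transitions into MI, CAr and Rv by the
    corresponding hazard ratio (all such transitions under
    ``hr_scope="all_inbound"``, only those leaving RA under
    ``"from_RA_only"``).  Survivors of an event year either return to the
    resolved state (``residual_rule="to_RA"``) or remain where they are
    (``"stay"``).  If a transformed row's event mass exceeds 1 the event
    entries are rescaled proportionally and a warning is emitted.
    """
    cfg = cfg or ModelConfig()
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    band_lo, _ = age_band_for(age, cfg.over_84_rule)

    his = strategy == "HIS"

    def hr_for(to_state: str, from_ra: bool) -> float:
        if not his:
            return 1.0
        if cfg.hr_scope == "from_RA_only" and not from_ra:
            return 1.0
        return {
            "MI": p.HR_HIS_MI.mean,
            "CAr": p.HR_HIS_CAr.mean,
            "Rv": p.HR_HIS_Rv.mean,
        }[to_state]

    def tp(base: float, to_state: str, from_ra: bool = False) -> float:
        return apply_hazard_ratio(base, hr_for(to_state, from_ra), cfg.hr_transform)

    m = np.zeros((5, 5))

    # RA row: event transitions from the table, residual stays in RA.
    ra_events = {
        _MI: tp(p.tpRA_MI.mean, "MI", from_ra=True),
        _CAR: tp(p.tpRA_CAr.mean, "CAr", from_ra=True),
        _RV: tp(p.tpRA_Rv.mean, "Rv", from_ra=True),
    }
    _fill_row(m, _RA, ra_events, death=0.0, residual_state=_RA)

    # MI row: recurrence, revascularization, banded death.
    mi_events = {
        _MI: tp(p.tpMI_MI.mean, "MI"),
        _RV: tp(p.tpMI_Rv.mean, "Rv"),
    }
    residual = _RA if cfg.residual_rule == "to_RA" else _MI
    _fill_row(m, _MI, mi_events, death=p.death_probability("MI", band_lo),
              residual_state=residual)

    # CAr row: banded death only.
    residual = _RA if cfg.residual_rule == "to_RA" else _CAR
    _fill_row(m, _CAR, {}, death=p.death_probability("CAr", band_lo),
              residual_state=residual)

    # Rv row: repeat revascularization, MI, banded death.
    rv_events = {
        _RV: tp(p.tpRv_Rv.mean, "Rv"),
        _MI: tp(p.tpRv_MI.mean, "MI"),
    }
    residual = _RA if cfg.residual_rule == "to_RA" else _RV
    _fill_row(m, _RV, rv_events, death=p.death_probability("Rv", band_lo),
              residual_state=residual)

    m[_D, _D] = 1.0
    return TransitionMatrix(entries=m, strategy=strategy, age=age)


def _fill_row(
    m: np.ndarray,
    row: int,
    events: dict[int, float],
    death: float,
    residual_state: int,
) -> None:
    """Place event and death mass, rescaling events if they overflow 1."""
    mass = sum(events.values()) + death
    if mass > 1.0:
        if events:
            scale = max((1.0 - death) / sum(events.values()), 0.0)
            warnings.warn(
                f"{STATES[row]} row event mass {mass:.4f} > 1; "
                f"event entries rescaled by {scale:.4f}",
                RowRescaleWarning,
                stacklevel=3,
            )
            events = {k: v * scale for k, v in events.items()}
        death = min(death, 1.0)
        mass = sum(events.values()) + death
    for k, v in events.items():
        m[row, k] += v
    m[row, _D] += death
    m[row, residual_state] += 1.0 - mass


def run_cohort(
    p: ParameterSet, strategy: str, cfg: ModelConfig | None = None
) -> CohortTrace:
    """Advance the whole cohort from start age to the horizon.

    Cycle 0 places the entire cohort in RA.  Occupancy at cycle ``t+1`` is
    occupancy at ``t`` times the matrix for the cohort's age at ``t``;
    matrices are rebuilt whenever the age band changes.
    """
    cfg = cfg or ModelConfig()
    n = cfg.n_cycles
    ages = cfg.start_age + np.arange(n)
    occ = np.zeros((n, 5))
    occ[0, _RA] = 1.0
    cache: dict[tuple[int, int], np.ndarray] = {}
    for t in range(n - 1):
        band = age_band_for(int(ages[t]), cfg.over_84_rule)
        key = (band[0], band[1])
        if key not in cache:
            cache[key] = build_transition_matrix(p, strategy, int(ages[t]), cfg).entries
        occ[t + 1] = occ[t] @ cache[key]
    return CohortTrace(occupancy=occ, ages=ages, strategy=strategy)
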