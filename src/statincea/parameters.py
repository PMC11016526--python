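"""Model parameter table: container, validation, I/O and synthesis.

The cost-utility model is driven entirely by a single parameter table
holding annual transition probabilities, age-banded event-state mortality,
per-state direct medical costs, annual drug costs, treatment hazard ratios,
per-state utilities and the two discount rates.  Each quantity carries a
mean, an optional standard error and a distribution family used by the
probabilistic sensitivity analysis (Beta for probabilities and utilities,
Gamma for costs, Lognormal for hazard ratios; discount rates are fixed).
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import yaml

__all__ = [
    "ParameterValue",
    "AgeBandedProbability",
    "ParameterSet",
    "Violation",
    "builtin_table1",
    "validate_parameter_set",
    "load_parameter_set",
    "write_parameter_set",
    "generate_random_parameter_set",
    "AGE_BANDS",
    "MORTALITY_STATES",
]

Family = Literal["probability", "cost", "utility", "hazard_ratio", "rate"]

#: 5-year age bands covering 30-84 (11 bands) used by the mortality rows.
AGE_BANDS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 4) for lo in range(30, 85, 5)
)

#: Event states that carry age-banded death probabilities.
MORTALITY_STATES: tuple[str, ...] = ("MI", "CAr", "Rv")


@dataclass(frozen=True)
class ParameterValue:
    """A single model quantity: mean, uncertainty and sampling family."""

    name: str
    mean: float
    se: float | None = None
    family: Family = "probability"
    source: str = ""

    def with_mean(self, mean: float) -> "ParameterValue":
        return dataclasses.replace(self, mean=float(mean))


@dataclass(frozen=True)
class AgeBandedProbability:
    """One 5-year age band of a death probability from an event state."""

    from_state: str
    band_start: int
    band_end: int
    value: ParameterValue


@dataclass(frozen=True)
class ParameterSet:
    """The full parameter table for one model run.

    ``mortality`` maps each of the event states ``MI``, ``CAr`` and ``Rv``
    to its 11 age-banded annual death probabilities (ages 30-84).
    """

    drC: ParameterValue
    drO: ParameterValue
    tpRA_RA: ParameterValue
    tpRA_MI: ParameterValue
    tpRA_CAr: ParameterValue
    tpRA_Rv: ParameterValue
    tpMI_MI: ParameterValue
    tpMI_Rv: ParameterValue
    tpRv_Rv: ParameterValue
    tpRv_MI: ParameterValue
    mortality: dict[str, tuple[AgeBandedProbability, ...]]
    dmcRA: ParameterValue
    dmcMI: ParameterValue
    dmcCAr: ParameterValue
    dmcRv: ParameterValue
    cHIS: ParameterValue
    cNHIS: ParameterValue
    HR_HIS_MI: ParameterValue
    HR_HIS_CAr: ParameterValue
    HR_HIS_Rv: ParameterValue
    uRA: ParameterValue
    uMI: ParameterValue
    uCAr: ParameterValue
    uRv: ParameterValue

    SCALAR_FIELDS = (
        "drC", "drO",
        "tpRA_RA", "tpRA_MI", "tpRA_CAr", "tpRA_Rv",
        "tpMI_MI", "tpMI_Rv", "tpRv_Rv", "tpRv_MI",
        "dmcRA", "dmcMI", "dmcCAr", "dmcRv",
        "cHIS", "cNHIS",
        "HR_HIS_MI", "HR_HIS_CAr", "HR_HIS_Rv",
        "uRA", "uMI", "uCAr", "uRv",
    )

    def iter_values(self) -> Iterator[ParameterValue]:
        """All quantities, scalars first, then banded mortality by state."""
        for name in self.SCALAR_FIELDS:
            yield getattr(self, name)
        for state in MORTALITY_STATES:
            for band in self.mortality[state]:
                yield band.value

    def death_probability(self, from_state: str, band_start: int) -> float:
        for band in self.mortality[from_state]:
            if band.band_start == band_start:
                return band.value.mean
        raise KeyError(f"no {from_state} mortality band starting at {band_start}")

    def replace(self, **scalar_means: float) -> "ParameterSet":
        """Copy with the given scalar parameters' means replaced."""
        updates = {
            name: getattr(self, name).with_mean(m)
            for name, m in scalar_means.items()
        }
        return dataclasses.replace(self, **updates)

    def replace_mortality(
        self, state: str, means: "np.ndarray | list[float]"
    ) -> "ParameterSet":
        """Copy with one state's banded death probabilities replaced."""
        bands = tuple(
            dataclasses.replace(b, value=b.value.with_mean(m))
            for b, m in zip(self.mortality[state], means)
        )
        mortality = dict(self.mortality)
        mortality[state] = bands
        return dataclasses.replace(self, mortality=mortality)


@dataclass(frozen=True)
class Violation:
    """One failed structural constraint; data, not an exception."""

    symbol: str
    constraint: str
    value: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.symbol}: {self.constraint} (got {self.value!r})"


def _mortality_band_name(state: str, lo: int, hi: int) -> str:
    return f"tp{state}_D_{lo}to{hi}"


# --------------------------------------------------------------------------
# Built-in parameter table
#
# Annual transition probabilities and hazard ratios from the Taylor et al.
# atorvastatin trial-based model; utilities from Lin et al.; direct medical
# costs from the Indonesian INA-CBGs 2016 tariff (type-B government
# hospital, second-class room); annual statin costs from a 2022 Indonesian
# secondary-hospital price survey.  Costs are in Indonesian rupiah (IDR).
# --------------------------------------------------------------------------

_TAYLOR = "Taylor et al."
_LIN = "Lin et al."
_INACBG = "INA-CBGs 2016"
_HOSP = "Indonesia Secondary Hospital Type B"
_WHO = "WHO 2015"

_MORTALITY_MEANS: dict[str, tuple[tuple[float, float], ...]] = {
    # (mean, se) per 5-year band, ages 30-34 ... 80-84
    "MI": (
        (0.007, 0.001), (0.009, 0.001), (0.014, 0.001), (0.020, 0.002),
        (0.032, 0.003), (0.050, 0.005), (0.084, 0.008), (0.131, 0.013),
        (0.205, 0.021), (0.326, 0.033), (0.508, 0.051),
    ),
    "CAr": (
        (0.004, 0.000), (0.005, 0.001), (0.008, 0.001), (0.012, 0.001),
        (0.018, 0.002), (0.028, 0.003), (0.048, 0.005), (0.074, 0.007),
        (0.116, 0.012), (0.185, 0.019), (0.288, 0.029),
    ),
    "Rv": (
        (0.004, 0.000), (0.005, 0.001), (0.007, 0.001), (0.011, 0.001),
        (0.017, 0.002), (0.027, 0.003), (0.045, 0.005), (0.071, 0.007),
        (0.111, 0.011), (0.176, 0.018), (0.274, 0.027),
    ),
}


def _builtin_mortality() -> dict[str, tuple[AgeBandedProbability, ...]]:
    out: dict[str, tuple[AgeBandedProbability, ...]] = {}
    for state, rows in _MORTALITY_MEANS.items():
        bands = []
        for (lo, hi), (mean, se) in zip(AGE_BANDS, rows):
            bands.append(
                AgeBandedProbability(
                    from_state=state,
                    band_start=lo,
                    band_end=hi,
                    value=ParameterValue(
                        name=_mortality_band_name(state, lo, hi),
                        mean=mean,
                        se=se,
                        family="probability",
                        source=_TAYLOR,
                    ),
                )
            )
        out[state] = tuple(bands)
    return out


def builtin_table1() -> ParameterSet:
    """The packaged base-case parameter table (means and SEs as published)."""
    pv = ParameterValue
    return ParameterSet(
        drC=pv("drC", 0.03, None, "rate", _WHO),
        drO=pv("drO", 0.03, None, "rate", _WHO),
        tpRA_RA=pv("tpRA_RA", 0.952, 0.095, "probability", ""),
        tpRA_MI=pv("tpRA_MI", 0.012, 0.001, "probability", _TAYLOR),
        tpRA_CAr=pv("tpRA_CAr", 0.001, 0.001, "probability", _TAYLOR),
        tpRA_Rv=pv("tpRA_Rv", 0.035, 0.001, "probability", _TAYLOR),
        tpMI_MI=pv("tpMI_MI", 0.049, 0.010, "probability", _TAYLOR),
        tpMI_Rv=pv("tpMI_Rv", 0.027, 0.004, "probability", _TAYLOR),
        tpRv_Rv=pv("tpRv_Rv", 0.135, 0.009, "probability", _TAYLOR),
        tpRv_MI=pv("tpRv_MI", 0.396, 0.024, "probability", _TAYLOR),
        mortality=_builtin_mortality(),
        dmcRA=pv("dmcRA", 19_728_100.0, 197_281.0, "cost", _INACBG),
        dmcMI=pv("dmcMI", 12_118_800.0, 121_188.0, "cost", _INACBG),
        dmcCAr=pv("dmcCAr", 7_041_400.0, 70_414.0, "cost", _INACBG),
        dmcRv=pv("dmcRv", 40_024_100.0, 400_241.0, "cost", _INACBG),
        cHIS=pv("cHIS", 3_908_568.0, 390_856.80, "cost", _HOSP),
        cNHIS=pv("cNHIS", 1_474_656.0, 147_465.60, "cost", _HOSP),
        HR_HIS_MI=pv("HR_HIS_MI", 0.77, 0.07, "hazard_ratio", _TAYLOR),
        HR_HIS_CAr=pv("HR_HIS_CAr", 1.07, 0.11, "hazard_ratio", _TAYLOR),
        HR_HIS_Rv=pv("HR_HIS_Rv", 0.73, 0.04, "hazard_ratio", _TAYLOR),
        uRA=pv("uRA", 0.78, 0.078, "utility", _LIN),
        uMI=pv("uMI", 0.65, 0.065, "utility", _LIN),
        uCAr=pv("uCAr", 0.68, 0.068, "utility", _LIN),
        uRv=pv("uRv", 0.78, 0.078, "utility", _TAYLOR),
    )


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

_ROW_EPS = 1e-9


def _check_value(v: ParameterValue) -> list[Violation]:
    out: list[Violation] = []
    if v.family in ("probability", "utility") and not 0.0 <= v.mean <= 1.0:
        out.append(Violation(v.name, "mean must lie in [0, 1]", v.mean))
    if v.family == "cost" and v.mean < 0.0:
        out.append(Violation(v.name, "cost mean must be >= 0", v.mean))
    if v.family == "hazard_ratio" and v.mean <= 0.0:
        out.append(Violation(v.name, "hazard ratio mean must be > 0", v.mean))
    if v.se is not None and v.se < 0.0:
        out.append(Violation(v.name, "se must be >= 0", v.se))
    if (
        v.se is not None
        and v.se > 0.0
        and v.family in ("probability", "utility")
        and 0.0 < v.mean < 1.0
        and v.se**2 >= v.mean * (1.0 - v.mean)
    ):
        out.append(
            Violation(v.name, "se^2 must be < mean*(1-mean) for Beta sampling", v.se)
        )
    return out


def validate_parameter_set(p: ParameterSet) -> list[Violation]:
    """Check every structural constraint; an empty list means valid."""
    out: list[Violation] = []
    for v in p.iter_values():
        out.extend(_check_value(v))

    ra_sum = (
        p.tpRA_RA.mean + p.tpRA_MI.mean + p.tpRA_CAr.mean + p.tpRA_Rv.mean
    )
    if ra_sum > 1.0 + _ROW_EPS:
        out.append(
            Violation("tpRA_*", "RA row probabilities must sum to <= 1", ra_sum)
        )

    for state in MORTALITY_STATES:
        bands = p.mortality.get(state, ())
        if len(bands) != len(AGE_BANDS) or tuple(
            (b.band_start, b.band_end) for b in bands
        ) != AGE_BANDS:
            out.append(
                Violation(
                    f"tp{state}_D_*",
                    "mortality must cover the 11 five-year bands 30-84",
                    float(len(bands)),
                )
            )
            continue
        for b in bands:
            stay = {
                "MI": p.tpMI_MI.mean + p.tpMI_Rv.mean,
                "CAr": 0.0,
                "Rv": p.tpRv_Rv.mean + p.tpRv_MI.mean,
            }[state]
            total = stay + b.value.mean
            if total > 1.0 + _ROW_EPS:
                out.append(
                    Violation(
                        b.value.name,
                        f"{state} row exceeds 1 in band {b.band_start}-{b.band_end}",
                        total,
                    )
                )
    return out


# --------------------------------------------------------------------------
# File I/O
#
# Two dialects round-trip exactly: a CSV table with columns
# (name, mean, se, family, age_band_start, age_band_end, source) and a YAML
# mapping name -> {mean, se, family, source}.  Numbers always use the
# period decimal separator.
# --------------------------------------------------------------------------

_CSV_COLUMNS = ("name", "mean", "se", "family", "age_band_start", "age_band_end", "source")


class ParameterFileError(ValueError):
    """Raised for structurally invalid parameter files."""


def _expected_names() -> list[str]:
    names = list(ParameterSet.SCALAR_FIELDS)
    for state in MORTALITY_STATES:
        names.extend(_mortality_band_name(state, lo, hi) for lo, hi in AGE_BANDS)
    return names


def _repr_number(x: float) -> str:
    return repr(float(x))


def write_parameter_set(p: ParameterSet, path: str | Path, format: str = "tabular") -> None:
    """Serialize a parameter set to ``tabular`` (CSV) or ``structured-config`` (YAML)."""
    path = Path(path)
    if format == "tabular":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_COLUMNS)
            for name in ParameterSet.SCALAR_FIELDS:
                v = getattr(p, name)
                w.writerow(
                    [v.name, _repr_number(v.mean),
                     "" if v.se is None else _repr_number(v.se),
                     v.family, "", "", v.source]
                )
            for state in MORTALITY_STATES:
                for b in p.mortality[state]:
                    v = b.value
                    w.writerow(
                        [v.name, _repr_number(v.mean),
                         "" if v.se is None else _repr_number(v.se),
                         v.family, b.band_start, b.band_end, v.source]
                    )
    elif format == "structured-config":
        doc = {}
        for v in p.iter_values():
            doc[v.name] = {
                "mean": float(v.mean),
                "se": None if v.se is None else float(v.se),
                "family": v.family,
                "source": v.source,
            }
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        raise ParameterFileError(f"unknown format {format!r}")


def _assemble(records: dict[str, dict]) -> ParameterSet:
    expected = _expected_names()
    missing = [n for n in expected if n not in records]
    if missing:
        raise ParameterFileError(f"missing parameters: {', '.join(missing)}")
    unknown = [n for n in records if n not in expected]
    if unknown:
        raise ParameterFileError(f"unknown parameters: {', '.join(sorted(unknown))}")

    def pv(name: str) -> ParameterValue:
        r = records[name]
        return ParameterValue(
            name=name,
            mean=float(r["mean"]),
            se=None if r.get("se") in (None, "") else float(r["se"]),
            family=r["family"],
            source=r.get("source", "") or "",
        )

    mortality: dict[str, tuple[AgeBandedProbability, ...]] = {}
    for state in MORTALITY_STATES:
        bands = []
        for lo, hi in AGE_BANDS:
            name = _mortality_band_name(state, lo, hi)
            bands.append(
                AgeBandedProbability(
                    from_state=state, band_start=lo, band_end=hi, value=pv(name)
                )
            )
        mortality[state] = tuple(bands)

    scalars = {name: pv(name) for name in ParameterSet.SCALAR_FIELDS}
    p = ParameterSet(mortality=mortality, **scalars)
    violations = validate_parameter_set(p)
    if violations:
        raise ParameterFileError(
        "invalid parameter values: " + "; ".join(str(v) for v in violations)
        )
    return p


def load_parameter_set(path: str | Path, format: str | None = None) -> ParameterSet:
    """Load and validate a parameter table from disk.

    ``format`` is ``tabular`` or ``structured-config``; when omitted it is
    inferred from the file suffix (.yaml/.yml vs anything else).
    """
    path = Path(path)
    if format is None:
        format = "structured-config" if path.suffix in (".yaml", ".yml") else "tabular"
    records: dict[str, dict] = {}
    if format == "tabular":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "name" not in reader.fieldnames:
                raise ParameterFileError(f"{path}: not a parameter table")
            for row in reader:
                records[row["name"]] = row
    elif format == "structured-config":
        doc = yaml.safe_load(path.read_text())
        if not isinstance(doc, dict):
            raise ParameterFileError(f"{path}: expected a mapping of parameters")
        records = {name: dict(rec) for name, rec in doc.items()}
    else:
        raise ParameterFileError(f"unknown format {format!r}")
    return _assemble(records)


# --------------------------------------------------------------------------
# Synthetic parameter tables
# --------------------------------------------------------------------------


def generate_random_parameter_set(
    rng_seed: int, difficulty: str = "typical"
) -> ParameterSet:
    """Draw a random but structurally valid parameter table.

    The synthetic tables mimic the structure the model assumes: each
    from-state row is feasible in every age band, banded death
    probabilities rise monotonically with age, costs are positive,
    utilities lie strictly inside (0, 1) and hazard ratios in (0.3, 1.5).
    ``difficulty="extreme"`` pushes probabilities toward their bounds and
    hazard ratios toward 1 to exercise edge behaviour.  Deterministic in
    ``rng_seed``.
    """
    if difficulty not in ("typical", "extreme"):
        raise ValueError(f"unknown difficulty {difficulty!r}")
    rng = np.random.default_rng(rng_seed)
    extreme = difficulty == "extreme"

    def prob(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    def prob_se(mean: float) -> float:
        # Between 5% and 25% of the mean, capped by Beta feasibility.
        cap = 0.9 * math.sqrt(mean * (1.0 - mean))
        return float(min(rng.uniform(0.05, 0.25) * mean, cap))

    # RA row: small event probabilities; extreme pushes the total near 1.
    if extreme:
        total_events = prob(0.55, 0.92)
        w = rng.dirichlet([1.0, 1.0, 1.0])
        ra_mi, ra_car, ra_rv = (float(total_events * wi) for wi in w)
    else:
        ra_mi = prob(0.005, 0.03)
        ra_car = prob(0.0005, 0.005)
        ra_rv = prob(0.01, 0.06)
    ra_stay = 1.0 - (ra_mi + ra_car + ra_rv)

    # Event-state stay/switch probabilities, leaving room for the worst
    # (oldest-band) death probability.
    death_top = prob(0.55, 0.75) if extreme else prob(0.2, 0.55)
    budget = 1.0 - death_top
    mi_mi = prob(0.01, 0.3 * budget)
    mi_rv = prob(0.01, 0.3 * budget)
    rv_rv = prob(0.05, 0.35 * budget)
    rv_mi = prob(0.05, 0.55 * budget)

    def banded(state: str) -> tuple[AgeBandedProbability, ...]:
        top = float(rng.uniform(0.7, 1.0)) * death_top
        base = float(rng.uniform(0.002, 0.02)) * (0.5 if not extreme else 1.0)
        # Geometric interpolation gives the age-increasing profile seen in
        # published event-survival tables.
        ratio = (top / base) ** (1.0 / (len(AGE_BANDS) - 1))
        means = [base * ratio**i for i in range(len(AGE_BANDS))]
        bands = []
        for (lo, hi), m in zip(AGE_BANDS, means):
            bands.append(
                AgeBandedProbability(
                    from_state=state,
                    band_start=lo,
                    band_end=hi,
                    value=ParameterValue(
                        name=_mortality_band_name(state, lo, hi),
                        mean=m,
                        se=prob_se(m),
                        family="probability",
                        source="synthetic",
                    ),
                )
            )
        return tuple(bands)

    def cost(lo: float, hi: float) -> tuple[float, float]:
        m = float(rng.uniform(lo, hi))
        return m, float(rng.uniform(0.01, 0.2) * m)

    def utility() -> tuple[float, float]:
        m = prob(0.9, 0.995) if extreme else prob(0.4, 0.9)
        return m, prob_se(m)

    def hazard_ratio() -> tuple[float, float]:
        m = float(rng.uniform(0.9, 1.1)) if extreme else float(rng.uniform(0.35, 1.45))
        se = float(rng.uniform(0.03, 0.15) * m)
        return m, se

    pv = ParameterValue
    src = "synthetic"

    def pval(name, mean, se, family):
        return pv(name, float(mean), None if se is None else float(se), family, src)

    dmc = {name: cost(2e6, 5e7) for name in ("dmcRA", "dmcMI", "dmcCAr", "dmcRv")}
    drug_his = cost(1e6, 6e6)
    drug_lmis = cost(2e5, drug_his[0])
    hrs = {name: hazard_ratio() for name in ("HR_HIS_MI", "HR_HIS_CAr", "HR_HIS_Rv")}
    utils = {name: utility() for name in ("uRA", "uMI", "uCAr", "uRv")}

    p = ParameterSet(
        drC=pval("drC", rng.uniform(0.0, 0.05), None, "rate"),
        drO=pval("drO", rng.uniform(0.0, 0.05), None, "rate"),
        tpRA_RA=pval("tpRA_RA", ra_stay, prob_se(ra_stay), "probability"),
        tpRA_MI=pval("tpRA_MI", ra_mi, prob_se(ra_mi), "probability"),
        tpRA_CAr=pval("tpRA_CAr", ra_car, prob_se(ra_car), "probability"),
        tpRA_Rv=pval("tpRA_Rv", ra_rv, prob_se(ra_rv), "probability"),
        tpMI_MI=pval("tpMI_MI", mi_mi, prob_se(mi_mi), "probability"),
        tpMI_Rv=pval("tpMI_Rv", mi_rv, prob_se(mi_rv), "probability"),
        tpRv_Rv=pval("tpRv_Rv", rv_rv, prob_se(rv_rv), "probability"),
        tpRv_MI=pval("tpRv_MI", rv_mi, prob_se(rv_mi), "probability"),
        mortality={state: banded(state) for state in MORTALITY_STATES},
        dmcRA=pval("dmcRA", *dmc["dmcRA"], "cost"),
        dmcMI=pval("dmcMI", *dmc["dmcMI"], "cost"),
        dmcCAr=pval("dmcCAr", *dmc["dmcCAr"], "cost"),
        dmcRv=pval("dmcRv", *dmc["dmcRv"], "cost"),
        cHIS=pval("cHIS", *drug_his, "cost"),
        cNHIS=pval("cNHIS", *drug_lmis, "cost"),
        HR_HIS_MI=pval("HR_HIS_MI", *hrs["HR_HIS_MI"], "hazard_ratio"),
        HR_HIS_CAr=pval("HR_HIS_CAr", *hrs["HR_HIS_CAr"], "hazard_ratio"),
        HR_HIS_Rv=pval("HR_HIS_Rv", *hrs["HR_HIS_Rv"], "hazard_ratio"),
        uRA=pval("uRA", *utils["uRA"], "utility"),
        uMI=pval("uMI", *utils["uMI"], "utility"),
        uCAr=pval("uCAr", *utils["uCAr"], "utility"),
        uRv=pval("uRv", *utils["uRv"], "utility"),
    )
    violations = validate_parameter_set(p)
    if violations:  # pragma: no cover - generator contract
        raise AssertionError(f"synthetic table invalid: {violations}")
    return p
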