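"""Attributable mortality burden and its economic valuation.

Implements the comparative-risk-assessment chain: a potential impact
fraction (PIF) per outcome x sex x age stratum obtained by integrating
the relative-risk curve over the baseline and counterfactual exposure
distributions, deaths prevented or postponed (DPP = PIF x current
deaths), years of life lost (YLL = DPP x residual life expectancy at the
age of death), years of productive life lost between workforce entry and
the pension age, and the corresponding productivity cost under the
human-capital approach (YPLL x mean wage x labor-force participation).

CHD and stroke are modelled independently and summed; no interaction or
competing-risk terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .exposure import (
    DEFAULT_GRID,
    BinGrid,
    ExposureDistribution,
    MarketChannel,
    ScenarioSpec,
    apply_scenario,
    discretize_lognormal,
    pct_energy_from_tfa,
    tfa_intake,
)
from .risk import (
    AGE_GROUPS,
    CHD,
    OUTCOMES,
    SEXES,
    STROKE,
    STROKE_EXCESS,
    RRCurve,
    RRSpec,
    age_band_for,
    build_rr_curve,
    default_rr_table,
    midpoint_age,
)

WORKFORCE_ENTRY_AGE = 15.0


# ---------------------------------------------------------------------------
# input tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MortalityRecord:
    """Annual deaths for one outcome x sex x age-group cell."""

    outcome: str
    sex: str
    age_group: str
    deaths: float

    def __post_init__(self) -> None:
        if self.deaths < 0:
            raise InputError(
                f"{self.outcome}/{self.sex}/{self.age_group}: deaths < 0"
            )


@dataclass(frozen=True)
class LifeTable:
    """Residual life expectancy (years) by age group; non-increasing."""

    expectancy: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = [self.expectancy.get(a) for a in AGE_GROUPS if a in self.expectancy]
        if any(v is None or v <= 0 for v in vals):
            raise InputError("life expectancy must be positive")
        if any(b > a + 1e-9 for a, b in zip(vals, vals[1:])):
            raise InputError("life expectancy must be non-increasing with age")

    def residual(self, age_group: str) -> float:
        try:
            return float(self.expectancy[age_group])
        except KeyError:
            raise ConfigError(f"life table has no entry for {age_group!r}")


@dataclass(frozen=True)
class EconParams:
    """Human-capital costing parameters.

    ``lfpr`` maps (sex, age_group) to the labor-force participation
    fraction; ``pension_age`` maps sex to the statutory pension age.
    """

    mean_annual_wage: float
    lfpr: Mapping[tuple[str, str], float]
    pension_age: Mapping[str, float] = field(
        default_factory=lambda: {"male": 65.0, "female": 60.0}
    )
    workforce_entry_age: float = WORKFORCE_ENTRY_AGE

    def __post_init__(self) -> None:
        if self.mean_annual_wage < 0:
            raise InputError("wage must be >= 0")
        for key, v in self.lfpr.items():
            if not 0.0 <= v <= 1.0:
                raise InputError(f"lfpr{key} outside [0, 1]")
        for sex, p in self.pension_age.items():
            if p <= self.workforce_entry_age:
                raise InputError(
                    f"pension age for {sex} must exceed workforce entry age"
                )

    def participation(self, sex: str, age_group: str) -> float:
        try:
            return float(self.lfpr[(sex, age_group)])
        except KeyError:
            raise ConfigError(f"no labor-force participation for "
                              f"({sex}, {age_group})")


@dataclass(frozen=True)
class StratumBurden:
    """Burden attributable to TFA in one outcome x sex x age cell."""

    outcome: str
    sex: str
    age_group: str
    deaths: float
    pif: float
    dpp: float
    yll: float
    ypll: float
    cost: float


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def pif(
    baseline: ExposureDistribution,
    counterfactual: ExposureDistribution,
    curve: RRCurve,
) -> float:
    """Potential impact fraction for one outcome/age band.

    Discretized form of the PIF integral:
    ``(sum_i RR_i P_i - sum_i RR_i P'_i) / sum_i RR_i P_i`` over the
    exposure bins. The denominator is >= 1 whenever RR >= 1, so the
    ratio is well defined.
    """
    if not (baseline.grid.matches(counterfactual.grid)
            and baseline.grid.matches(curve.grid)):
        raise ConfigError("baseline, counterfactual and RR curve must share "
                          "one bin grid")
    base = float(curve.rr_by_bin @ baseline.prevalence)
    cf = float(curve.rr_by_bin @ counterfactual.prevalence)
    return (base - cf) / base


def dpp(pif_value: float, record: MortalityRecord) -> float:
    """Deaths prevented or postponed: PIF x current deaths."""
    if not 0.0 <= pif_value <= 1.0:
        raise InputError(f"PIF {pif_value} outside [0, 1]")
    return pif_value * record.deaths


def aggregate_paf(strata: Sequence[tuple[float, float]]) -> float:
    """Deaths-weighted mean of stratum PIFs/PAFs.

    ``strata`` is a sequence of (pif, deaths) pairs; the aggregate is
    ``sum(pif * deaths) / sum(deaths)``.
    """
    if not strata:
        raise InputError("at least one stratum is required")
    weights = np.array([d for _, d in strata], dtype=float)
    if np.any(weights < 0):
        raise InputError("deaths must be >= 0")
    total = weights.sum()
    if total == 0:
        raise InputError("aggregate PAF undefined: all strata have 0 deaths")
    pifs = np.array([p for p, _ in strata], dtype=float)
    return float(pifs @ weights / total)


def yll(dpp_value: float, age_group: str, life_table: LifeTable) -> float:
    """Years of life lost: averted deaths x residual life expectancy."""
    if dpp_value < 0:
        raise InputError("DPP must be >= 0")
    return dpp_value * life_table.residual(age_group)


def productive_years(sex: str, age_group: str, econ: EconParams) -> float:
    """Potential working years left at the stratum's representative age."""
    return max(0.0, econ.pension_age[sex] - midpoint_age(age_group))


def ypll_and_cost(
    dpp_value: float, sex: str, age_group: str, econ: EconParams
) -> tuple[float, float]:
    """Years of productive life lost and their human-capital cost.

    Each averted death at representative age ``a`` contributes
    ``max(0, pension_age - a)`` productive years; the cost values those
    years at the mean annual wage times the stratum's labor-force
    participation. Deaths at or above the pension age contribute zero.
    """
    years = dpp_value * productive_years(sex, age_group, econ)
    cost = years * econ.mean_annual_wage * econ.participation(sex, age_group)
    return years, cost


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class InputBundle:
    """Validated model inputs for one country-year.

    ``mean_energy_kcal`` is either one national mean or a mapping from
    (sex, age_group) to stratum-specific energy intake. Per-capita TFA
    mass is identical across strata (market data carry no age/sex
    detail); % of energy may then differ by stratum through the energy
    denominator.
    """

    channels: list[MarketChannel]
    mortality: list[MortalityRecord]
    population: Mapping[tuple[str, str], float]
    life_table: LifeTable
    econ: EconParams
    mean_energy_kcal: float | Mapping[tuple[str, str], float]
    rr_table: Mapping[tuple[str, str], RRSpec] | None = None
    cv: float = 0.5
    grid: BinGrid = field(default_factory=lambda: DEFAULT_GRID)
    tmrel: float = 0.0
    stroke_mode: str = STROKE_EXCESS

    def __post_init__(self) -> None:
        if self.rr_table is None:
            self.rr_table = default_rr_table(
                stroke_mode=self.stroke_mode, tmrel=self.tmrel
            )

    def energy_for(self, sex: str, age_group: str) -> float:
        if isinstance(self.mean_energy_kcal, Mapping):
            try:
                return float(self.mean_energy_kcal[(sex, age_group)])
            except KeyError:
                raise ConfigError(
                    f"no energy intake for ({sex}, {age_group})"
                )
        return float(self.mean_energy_kcal)


@dataclass
class BurdenResult:
    """Per-stratum burdens plus convenience aggregates."""

    scenario_id: str
    strata: pd.DataFrame

    def total(self, column: str = "dpp") -> float:
        return float(self.strata[column].sum())

    def by(self, key: str, column: str = "dpp") -> pd.Series:
        return self.strata.groupby(key)[column].sum()

    @property
    def aggregate_paf(self) -> float:
        rows = list(zip(self.strata["pif"], self.strata["deaths"]))
        return aggregate_paf(rows)

    def premature_share(self, econ: EconParams) -> float:
        """Share of averted deaths below the pension age (derived statistic)."""
        below = [
            row.dpp
            for row in self.strata.itertuples()
            if midpoint_age(row.age_group) < econ.pension_age[row.sex]
        ]
        total = self.total("dpp")
        return float(sum(below) / total) if total > 0 else 0.0

    def summary(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "totals": {
                c: self.total(c) for c in ("dpp", "yll", "ypll", "cost")
            },
            "by_outcome": {
                c: self.by("outcome", c).to_dict()
                for c in ("dpp", "yll", "ypll", "cost")
            },
            "by_sex": {
                c: self.by("sex", c).to_dict()
                for c in ("dpp", "yll", "ypll", "cost")
            },
            "aggregate_paf": self.aggregate_paf,
        }


def _stratum_distributions(
    bundle: InputBundle,
    channels_base: Sequence[MarketChannel],
    channels_cf: Sequence[MarketChannel],
) -> dict[tuple[str, str], tuple[ExposureDistribution, ExposureDistribution]]:
    """Baseline/counterfactual exposure per (sex, age_group).

    With one national energy mean every stratum shares a single pair of
    distributions; with stratum-specific energy each stratum gets its
    own percent-of-energy scale.
    """
    tfa_base = sum(c.tfa_g_per_day for c in channels_base)
    tfa_cf = sum(c.tfa_g_per_day for c in channels_cf)
    cache: dict[float, tuple[ExposureDistribution, ExposureDistribution]] = {}
    out = {}
    for sex in SEXES:
        for age in AGE_GROUPS:
            energy = bundle.energy_for(sex, age)
            if energy not in cache:
                base = discretize_lognormal(
                    pct_energy_from_tfa(tfa_base, energy), bundle.cv,
                    bundle.grid)
                cf = discretize_lognormal(
                    pct_energy_from_tfa(tfa_cf, energy), bundle.cv,
                    bundle.grid)
                cache[energy] = (base, cf)
            out[(sex, age)] = cache[energy]
    return out


def run_model(
    bundle: InputBundle,
    scenario: ScenarioSpec,
    rr_table: Mapping[tuple[str, str], RRSpec] | None = None,
) -> BurdenResult:
    """Run the full point-estimate pipeline for one scenario.

    Deterministic given the inputs. ``rr_table`` overrides the bundle's
    relative risks (used by sensitivity and Monte Carlo re-runs).
    """
    rr_table = rr_table if rr_table is not None else bundle.rr_table
    channels_cf = apply_scenario(bundle.channels, scenario)
    dists = _stratum_distributions(bundle, bundle.channels, channels_cf)

    curves: dict[tuple[str, str], RRCurve] = {}
    rows = []
    for rec in bundle.mortality:
        band = age_band_for(rec.age_group)
        key = (rec.outcome, band)
        if key not in curves:
            try:
                spec = rr_table[key]
            except KeyError:
                raise ConfigError(f"no relative risk for {key}")
            curves[key] = build_rr_curve(spec, bundle.grid)
        base, cf = dists[(rec.sex, rec.age_group)]
        p = pif(base, cf, curves[key])
        # Clamp float noise; a genuinely negative PIF (protective RR after
        # a sensitivity down-scaling) passes through as negative DPP.
        if -1e-12 < p < 0.0:
            p = 0.0
        p = min(p, 1.0)
        d = p * rec.deaths
        y = d * bundle.life_table.residual(rec.age_group)
        py, cost = ypll_and_cost(d, rec.sex, rec.age_group, bundle.econ)
        rows.append(
            StratumBurden(rec.outcome, rec.sex, rec.age_group,
                          rec.deaths, p, d, y, py, cost)
        )
    frame = pd.DataFrame([vars(r) for r in rows])
    return BurdenResult(scenario_id=scenario.scenario_id, strata=frame)
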