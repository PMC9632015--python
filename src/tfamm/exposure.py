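"""Population exposure to industrially produced trans fat.

This module converts partially-hydrogenated-oil (PHO) market volumes into
per-capita TFA intake (g/day and % of dietary energy), models the
population distribution of intake as a log-normal discretized onto a fixed
grid of %-energy bins, and applies counterfactual policy scenarios
(category TFA caps, universal caps, PHO elimination) to the market
channels.

Units: PHO and TFA masses are grams per person per day; energy is
kcal/person/day; exposure is percent of total dietary energy from TFA.
One gram of fat is 9 kcal.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, InputError

KCAL_PER_G_FAT = 9.0
DAYS_PER_YEAR = 365.0
GRAMS_PER_TONNE = 1.0e6

#: Mass-sum tolerance for a discretized distribution.
MASS_TOL = 1e-9


# ---------------------------------------------------------------------------
# bin grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinGrid:
    """Grid of % -energy-from-TFA exposure bins.

    The default reproduces the 25-bin grid used by the model: bins of
    width 0.1 from "<0.1" up to ">2.4", the last bin open-ended with a
    configurable effective midpoint used when evaluating relative risk
    on the open tail.
    """

    width: float = 0.1
    n_bins: int = 25
    top_midpoint: float = 2.45

    def __post_init__(self) -> None:
        if self.width <= 0 or self.n_bins < 2:
            raise ConfigError("bin grid needs positive width and >= 2 bins")
        top_edge = self.width * (self.n_bins - 1)
        if self.top_midpoint <= top_edge:
            raise ConfigError(
                f"top-bin midpoint {self.top_midpoint} must exceed the last "
                f"finite edge {top_edge:g}"
            )

    @property
    def edges(self) -> np.ndarray:
        """Bin edges, length ``n_bins + 1``; the last edge is +inf."""
        finite = self.width * np.arange(self.n_bins)
        return np.concatenate([finite, [np.inf]])

    @property
    def midpoints(self) -> np.ndarray:
        """Bin midpoints, the open top bin at ``top_midpoint``."""
        mids = self.width * (np.arange(self.n_bins) + 0.5)
        mids[-1] = self.top_midpoint
        return mids

    def matches(self, other: "BinGrid") -> bool:
        return (
            self.width == other.width
            and self.n_bins == other.n_bins
            and self.top_midpoint == other.top_midpoint
        )


DEFAULT_GRID = BinGrid()


# ---------------------------------------------------------------------------
# market channels and intake
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarketChannel:
    """One PHO use channel (e.g. bakery, commerce, household oils).

    ``pho_g_per_day`` is PHO grams per capita per day attributed to the
    channel; ``fat_fraction`` the fraction of that mass that is fat
    (default 1: PHO is essentially fat); ``tfa_fraction_of_fat`` the
    fraction of the fat that is trans fat. ``form`` distinguishes solid
    PHO fats (industry and food commerce) from PHO oils, which are
    assumed to be consumed at the household.
    """

    channel_id: str
    pho_g_per_day: float
    tfa_fraction_of_fat: float
    form: str = "fat"
    fat_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.pho_g_per_day < 0:
            raise InputError(f"{self.channel_id}: PHO mass must be >= 0")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise InputError(f"{self.channel_id}: fat_fraction outside [0, 1]")
        if not 0.0 <= self.tfa_fraction_of_fat <= 1.0:
            raise InputError(
                f"{self.channel_id}: tfa_fraction_of_fat outside [0, 1]"
            )
        if self.form not in ("fat", "oil"):
            raise InputError(f"{self.channel_id}: form must be 'fat' or 'oil'")

    @property
    def tfa_g_per_day(self) -> float:
        return self.pho_g_per_day * self.fat_fraction * self.tfa_fraction_of_fat


@dataclass(frozen=True)
class IntakeSummary:
    """Per-capita intake chain: PHO mass, TFA mass, and % of energy."""

    pho_g_per_day: float
    household_pho_g_per_day: float
    tfa_g_per_day: float
    tfa_pct_energy: float
    mean_energy_kcal: float


def per_capita_pho(
    total_pho_mass_per_year: float,
    population: float,
    *,
    unit: str = "g",
) -> float:
    """Annual national PHO volume -> grams per person per day.

    ``unit`` is the unit of ``total_pho_mass_per_year`` ("g" or "tonne").
    Uses a 365-day year.
    """
    if population <= 0:
        raise InputError("population must be positive")
    if total_pho_mass_per_year < 0:
        raise InputError("PHO mass must be >= 0")
    if unit == "tonne":
        total_pho_mass_per_year *= GRAMS_PER_TONNE
    elif unit != "g":
        raise InputError(f"unknown mass unit {unit!r}")
    return total_pho_mass_per_year / population / DAYS_PER_YEAR


def pct_energy_from_tfa(tfa_g_per_day: float, mean_energy_kcal: float) -> float:
    """Percent of total dietary energy contributed by TFA (9 kcal/g)."""
    if mean_energy_kcal <= 0:
        raise InputError("mean energy intake must be positive")
    if tfa_g_per_day < 0:
        raise InputError("TFA intake must be >= 0")
    return 100.0 * tfa_g_per_day * KCAL_PER_G_FAT / mean_energy_kcal


def tfa_intake(
    channels: Sequence[MarketChannel],
    mean_energy_kcal: float,
) -> IntakeSummary:
    """Sum the market channels into a per-capita intake summary.

    Household PHO is the mass in channels with ``form == 'oil'``: market
    PHO oils are assumed to be consumed at the household, while industry
    and commerce use solid PHO fats.
    """
    if not channels:
        raise InputError("at least one market channel is required")
    pho = sum(c.pho_g_per_day for c in channels)
    household = sum(c.pho_g_per_day for c in channels if c.form == "oil")
    tfa = sum(c.tfa_g_per_day for c in channels)
    return IntakeSummary(
        pho_g_per_day=pho,
        household_pho_g_per_day=household,
        tfa_g_per_day=tfa,
        tfa_pct_energy=pct_energy_from_tfa(tfa, mean_energy_kcal),
        mean_energy_kcal=mean_energy_kcal,
    )


# ---------------------------------------------------------------------------
# exposure distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureDistribution:
    """Binned population distribution of % energy from TFA.

    ``prevalence`` is the probability mass per bin (sums to 1);
    ``mean_pct_energy`` and ``cv`` are the arithmetic mean and
    coefficient of variation of the underlying log-normal.
    """

    grid: BinGrid
    prevalence: np.ndarray
    mean_pct_energy: float
    cv: float

    def __post_init__(self) -> None:
        p = np.asarray(self.prevalence, dtype=float)
        object.__setattr__(self, "prevalence", p)
        if p.shape != (self.grid.n_bins,):
            raise ConfigError(
                f"prevalence length {p.shape} does not match the "
                f"{self.grid.n_bins}-bin grid"
            )
        if np.any(p < -MASS_TOL):
            raise InputError("prevalence must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise InputError(f"prevalence sums to {p.sum()}, expected 1")

    @property
    def discretized_mean(self) -> float:
        """Mean of the binned distribution (midpoint rule)."""
        return float(self.grid.midpoints @ self.prevalence)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of ln X for a log-normal with arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def lognormal_bin_masses(
    means: np.ndarray, cv: float, grid: BinGrid = DEFAULT_GRID
) -> np.ndarray:
    """Vectorized bin masses for log-normals with the given means.

    Returns an array of shape ``(len(means), grid.n_bins)``. Rows for a
    zero mean put all mass in the first bin. Used by the Monte Carlo
    engine where thousands of exposure means are discretized at once.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    if np.any(means < 0):
        raise InputError("exposure mean must be >= 0")
    if cv <= 0:
        raise InputError("cv must be positive")
    out = np.zeros((means.size, grid.n_bins))
    zero = means <= 0.0
    out[zero, 0] = 1.0
    if np.any(~zero):
        m = means[~zero]
        sigma2 = np.log1p(cv * cv)
        sigma = np.sqrt(sigma2)
        mu = np.log(m) - sigma2 / 2.0
        edges = grid.edges[:-1]
        with np.errstate(divide="ignore"):
            z = (np.log(edges[None, 1:]) - mu[:, None]) / sigma
        cdf = stats.norm.cdf(z)
        masses = np.empty((m.size, grid.n_bins))
        masses[:, 0] = cdf[:, 0]
        masses[:, 1:-1] = np.diff(cdf, axis=1)
        masses[:, -1] = 1.0 - cdf[:, -1]  # open top bin absorbs the tail
        out[~zero] = masses
    return out


def discretize_lognormal(
    mean_pct_energy: float,
    cv: float,
    grid: BinGrid = DEFAULT_GRID,
) -> ExposureDistribution:
    """Discretize a log-normal intake distribution onto the bin grid.

    The log-normal is parameterized by its arithmetic mean (in % energy)
    and coefficient of variation; bin mass is the CDF increment across
    each bin and the open top bin absorbs the upper tail. A mean of
    exactly zero returns a degenerate distribution with all mass in the
    first bin.
    """
    if mean_pct_energy < 0:
        raise InputError("mean % energy must be >= 0")
    masses = lognormal_bin_masses(np.array([mean_pct_energy]), cv, grid)[0]
    return ExposureDistribution(
        grid=grid, prevalence=masses, mean_pct_energy=mean_pct_energy, cv=cv
    )


# ---------------------------------------------------------------------------
# counterfactual scenarios
# ---------------------------------------------------------------------------

CAP = "cap"
ELIMINATE = "eliminate"


@dataclass(frozen=True)
class ScenarioRule:
    """One policy rule: channels matching ``match`` (a glob pattern) get
    either a cap on the TFA fraction of their fat, or PHO elimination."""

    match: str
    action: str
    limit: float | None = None

    def __post_init__(self) -> None:
        if self.action not in (CAP, ELIMINATE):
            raise ConfigError(f"unknown scenario action {self.action!r}")
        if self.action == CAP:
            if self.limit is None or not 0.0 <= self.limit <= 1.0:
                raise ConfigError("cap rule needs a limit in [0, 1]")

    def applies_to(self, channel: MarketChannel) -> bool:
        return fnmatch.fnmatchcase(channel.channel_id, self.match)


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual policy: an ordered list of rules, first match wins.

    Rule order matters so a specific rule (e.g. household oils) can be
    followed by a ``*`` catch-all; every channel must be matched by at
    least one rule.
    """

    scenario_id: str
    rules: tuple[ScenarioRule, ...]

    def __init__(self, scenario_id: str, rules: Iterable[ScenarioRule]):
        object.__setattr__(self, "scenario_id", scenario_id)
        object.__setattr__(self, "rules", tuple(rules))

    def rule_for(self, channel: MarketChannel) -> ScenarioRule:
        for rule in self.rules:
            if rule.applies_to(channel):
                return rule
        raise ConfigError(
            f"scenario {self.scenario_id!r}: no rule matches channel "
            f"{channel.channel_id!r}"
        )

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioSpec":
        rules = [
            ScenarioRule(
                match=r["match"],
                action=r["action"],
                limit=r.get("limit"),
            )
            for r in data["rules"]
        ]
        return cls(scenario_id=data["scenario_id"], rules=rules)

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "rules": [
                {"match": r.match, "action": r.action}
                | ({"limit": r.limit} if r.limit is not None else {})
                for r in self.rules
            ],
        }


def apply_scenario(
    channels: Sequence[MarketChannel], spec: ScenarioSpec
) -> list[MarketChannel]:
    """Apply a policy scenario to the market channels.

    A cap at limit L sets ``tfa_fraction_of_fat`` to ``min(old, L)``;
    elimination sets it to 0 (PHO replaced by mono/polyunsaturated fat,
    mass unchanged). Channels are otherwise untouched.
    """
    out = []
    for ch in channels:
        rule = spec.rule_for(ch)
        if rule.action == ELIMINATE:
            out.append(replace(ch, tfa_fraction_of_fat=0.0))
        else:
            out.append(
                replace(
                    ch,
                    tfa_fraction_of_fat=min(ch.tfa_fraction_of_fat, rule.limit),
                )
            )
    return out


def null_scenario(scenario_id: str = "baseline") -> ScenarioSpec:
    """A scenario under which no rule binds (cap at 100% of fat)."""
    return ScenarioSpec(scenario_id, [ScenarioRule("*", CAP, 1.0)])
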