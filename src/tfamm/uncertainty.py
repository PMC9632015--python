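"""Monte Carlo uncertainty intervals and deterministic sensitivity.

Uncertainty is forward-propagated: each draw samples (i) every
meta-analytic relative risk from a log-normal whose median is the point
RR and whose spread matches the published 95% CI, one draw per outcome x
age band (perfectly correlated across exposure bins within a band,
independent across bands and outcomes), and (ii) a multiplicative
perturbation of the exposure means, normal around 1 with a configurable
relative standard error, applied jointly to the baseline and
counterfactual means (market-volume error moves both). The full
PIF -> DPP -> YLL/YPLL/cost chain is recomputed per draw and 95%
uncertainty intervals are the 2.5th/97.5th empirical percentiles
(linear interpolation, no bias correction). Point estimates come from
the central parameter values, not the draw mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import BurdenResult, InputBundle, run_model
from .errors import InputError
from .exposure import (
    ScenarioSpec,
    apply_scenario,
    lognormal_bin_masses,
    pct_energy_from_tfa,
)
from .risk import RRSpec, age_band_for, midpoint_age, scale_rr

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class DrawSpec:
    """Monte Carlo configuration: number of draws, seed, exposure error."""

    n_draws: int = 5000
    seed: int = 0
    exposure_rel_se: float = 0.05

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise InputError("n_draws must be >= 1")
        if self.n_draws < 100:
            logger.warning(
                "n_draws=%d is below 100; uncertainty intervals will be "
                "unstable", self.n_draws,
            )
        if self.exposure_rel_se < 0:
            raise InputError("exposure_rel_se must be >= 0")


@dataclass(frozen=True)
class UncertaintyResult:
    """Point estimates with 95% uncertainty intervals per output quantity."""

    scenario_id: str
    draw_spec: DrawSpec
    quantities: Mapping[str, tuple[float, float, float]]  # point, lo, hi

    def point(self, name: str) -> float:
        return self.quantities[name][0]

    def ui(self, name: str) -> tuple[float, float]:
        _, lo, hi = self.quantities[name]
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": k, "point": p, "ui_low": lo, "ui_high": hi}
            for k, (p, lo, hi) in self.quantities.items()
        ]
        return pd.DataFrame(rows)


def rr_sigma(spec: RRSpec) -> float:
    """Log-scale standard error implied by a 95% CI of a ratio measure."""
    if spec.ci_low <= 0 or spec.ci_high <= 0:
        raise InputError("CI bounds must be positive")
    return (np.log(spec.ci_high) - np.log(spec.ci_low)) / (2.0 * Z_95)


def sample_rr(
    spec: RRSpec,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw relative risks from a log-normal fitted to the spec's CI.

    The median of the sampling distribution is the point RR; a
    degenerate CI (low = high = RR) returns the point value exactly.
    """
    sigma = rr_sigma(spec)
    z = rng.standard_normal(size if size is not None else 1)
    draws = spec.rr_per_unit * np.exp(sigma * z)
    return draws if size is not None else float(draws[0])


def _curve_matrix(
    rr_draws: np.ndarray, spec: RRSpec, grid
) -> np.ndarray:
    """RR-by-bin curves for a vector of sampled per-unit RRs.

    Shape (n_draws, n_bins); bins at or below max(y, tmrel) are 1.
    """
    mids = grid.midpoints
    expo = (mids - spec.reference_midpoint_y) / spec.unit_u
    active = mids > max(spec.reference_midpoint_y, spec.tmrel)
    curves = np.ones((rr_draws.size, mids.size))
    curves[:, active] = rr_draws[:, None] ** expo[None, active]
    return curves


def monte_carlo(
    bundle: InputBundle,
    scenario: ScenarioSpec,
    draw_spec: DrawSpec = DrawSpec(),
) -> UncertaintyResult:
    """Propagate RR and exposure uncertainty through the full pipeline.

    Reports 95% UIs for total DPP, YLL, YPLL and cost, plus DPP by
    outcome and by sex. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(draw_spec.seed)
    n = draw_spec.n_draws
    point = run_model(bundle, scenario)

    channels_cf = apply_scenario(bundle.channels, scenario)
    tfa_base = sum(c.tfa_g_per_day for c in bundle.channels)
    tfa_cf = sum(c.tfa_g_per_day for c in channels_cf)

    # joint multiplicative perturbation of baseline and counterfactual means
    factor = np.clip(
        1.0 + draw_spec.exposure_rel_se * rng.standard_normal(n), 0.0, None
    )

    # one RR draw per (outcome, age band) per iteration; sampling order is
    # fixed by sorted keys so results are seed-reproducible
    rr_draws = {
        key: sample_rr(bundle.rr_table[key], rng, size=n)
        for key in sorted(bundle.rr_table)
    }

    # discretize the sampled exposure means once per distinct energy level
    energies = sorted(
        {bundle.energy_for(r.sex, r.age_group) for r in bundle.mortality}
    )
    masses: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for energy in energies:
        base_means = factor * pct_energy_from_tfa(tfa_base, energy)
        cf_means = factor * pct_energy_from_tfa(tfa_cf, energy)
        masses[energy] = (
            lognormal_bin_masses(base_means, bundle.cv, bundle.grid),
            lognormal_bin_masses(cf_means, bundle.cv, bundle.grid),
        )

    # PIF draws per (outcome, band, energy)
    pif_draws: dict[tuple[str, str, float], np.ndarray] = {}
    for (outcome, band), draws in rr_draws.items():
        spec = bundle.rr_table[(outcome, band)]
        curves = _curve_matrix(draws, spec, bundle.grid)
        for energy in energies:
            mb, mc = masses[energy]
            num_base = np.einsum("ij,ij->i", curves, mb)
            num_cf = np.einsum("ij,ij->i", curves, mc)
            pif_draws[(outcome, band, energy)] = (num_base - num_cf) / num_base

    # accumulate output draws over strata
    acc: dict[str, np.ndarray] = {
        k: np.zeros(n)
        for k in (
            "dpp_total", "yll_total", "ypll_total", "cost_total",
            "dpp_chd", "dpp_stroke", "dpp_male", "dpp_female",
        )
    }
    for rec in bundle.mortality:
        band = age_band_for(rec.age_group)
        energy = bundle.energy_for(rec.sex, rec.age_group)
        d = pif_draws[(rec.outcome, band, energy)] * rec.deaths
        life = bundle.life_table.residual(rec.age_group)
        years = max(0.0, bundle.econ.pension_age[rec.sex]
                    - midpoint_age(rec.age_group))
        part = bundle.econ.participation(rec.sex, rec.age_group)
        acc["dpp_total"] += d
        acc["yll_total"] += d * life
        acc["ypll_total"] += d * years
        acc["cost_total"] += d * years * bundle.econ.mean_annual_wage * part
        acc[f"dpp_{rec.outcome}"] += d
        acc[f"dpp_{rec.sex}"] += d

    points = {
        "dpp_total": point.total("dpp"),
        "yll_total": point.total("yll"),
        "ypll_total": point.total("ypll"),
        "cost_total": point.total("cost"),
        "dpp_chd": float(point.by("outcome", "dpp").get("chd", 0.0)),
        "dpp_stroke": float(point.by("outcome", "dpp").get("stroke", 0.0)),
        "dpp_male": float(point.by("sex", "dpp").get("male", 0.0)),
        "dpp_female": float(point.by("sex", "dpp").get("female", 0.0)),
    }
    quantities = {}
    for name, draws in acc.items():
        lo, hi = np.percentile(draws, [2.5, 97.5])
        quantities[name] = (points[name], float(lo), float(hi))
    return UncertaintyResult(
        scenario_id=scenario.scenario_id,
        draw_spec=draw_spec,
        quantities=quantities,
    )


# ---------------------------------------------------------------------------
# deterministic sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityVariant:
    """One deterministic perturbation of the model assumptions.

    ``tmrel`` replaces the theoretical-minimum-risk exposure level;
    ``rr_factor`` scales every relative risk (on the excess-risk scale
    by default, multiplicatively with ``rr_scale_mode='multiplicative'``).
    """

    name: str
    tmrel: float | None = None
    rr_factor: float | None = None


DEFAULT_VARIANTS: tuple[SensitivityVariant, ...] = (
    SensitivityVariant("tmrel_0.2", tmrel=0.2),
    SensitivityVariant("rr_x0.9", rr_factor=0.9),
    SensitivityVariant("rr_x1.1", rr_factor=1.1),
)


def deterministic_sensitivity(
    bundle: InputBundle,
    scenario: ScenarioSpec,
    variants: Sequence[SensitivityVariant] = DEFAULT_VARIANTS,
    rr_scale_mode: str = "excess",
) -> pd.DataFrame:
    """Percent change in total DPP under each assumption variant.

    Returns a frame with columns ``variant``, ``total_dpp`` and
    ``pct_change`` relative to the unmodified model.
    """
    base = run_model(bundle, scenario).total("dpp")
    rows = []
    for variant in variants:
        table = dict(bundle.rr_table)
        for key, spec in table.items():
            if variant.tmrel is not None:
                spec = replace(spec, tmrel=variant.tmrel)
            if variant.rr_factor is not None:
                spec = scale_rr(spec, variant.rr_factor, mode=rr_scale_mode)
            table[key] = spec
        total = run_model(bundle, scenario, rr_table=table).total("dpp")
        change = 100.0 * (total - base) / base if base != 0 else 0.0
        rows.append(
            {"variant": variant.name, "total_dpp": total, "pct_change": change}
        )
    return pd.DataFrame(rows, columns=["variant", "total_dpp", "pct_change"])
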