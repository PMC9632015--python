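"""Relative-risk curves for CHD and stroke mortality by TFA intake.

The dose-response is the standard log-linear form used in comparative
risk assessment: a meta-analytic relative risk ``RR`` per ``u`` percent
of energy from TFA (u = 2 for the bundled CHD meta-analysis) is
exponentiated to any exposure x,

    RR(x) = RR ** ((x - y) / u)   for x above max(y, TMREL), else 1,

where y is the reference exposure (midpoint of the first bin, 0.05% by
default) and TMREL the theoretical-minimum-risk exposure level (0 by
default: any TFA intake carries excess risk). Stroke risk is derived
from CHD risk by halving the excess risk, the conservative convention
for this exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, InputError
from .exposure import DEFAULT_GRID, BinGrid

CHD = "chd"
STROKE = "stroke"
OUTCOMES = (CHD, STROKE)

SEXES = ("male", "female")

#: 5-year age strata covered by the model (adults 25+).
AGE_GROUPS = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

#: Decade bands on which the meta-analytic relative risks are reported.
AGE_BANDS = ("25-34", "35-44", "45-54", "55-64", "65-74", "75+")


def age_band_for(age_group: str) -> str:
    """Map a 5-year age stratum onto its relative-risk decade band."""
    if age_group not in AGE_GROUPS:
        raise InputError(
            f"unknown age group {age_group!r}; the model covers adults 25+ "
            f"in strata {AGE_GROUPS[0]}..{AGE_GROUPS[-1]}"
        )
    idx = AGE_GROUPS.index(age_group)
    return AGE_BANDS[min(idx // 2, len(AGE_BANDS) - 1)]


def midpoint_age(age_group: str) -> float:
    """Representative age of death within a stratum (midpoint; 82.5 for 80+)."""
    if age_group not in AGE_GROUPS:
        raise InputError(f"unknown age group {age_group!r}")
    lower = int(age_group.rstrip("+").split("-")[0])
    return lower + 2.5


@dataclass(frozen=True)
class RRSpec:
    """A meta-analytic relative risk per unit of % energy from TFA."""

    outcome: str
    age_band: str
    rr_per_unit: float
    ci_low: float
    ci_high: float
    unit_u: float = 2.0
    reference_midpoint_y: float = 0.05
    tmrel: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_per_unit <= 0:
            raise InputError("relative risk must be positive")
        if not self.ci_low <= self.rr_per_unit <= self.ci_high:
            raise InputError(
                f"{self.outcome}/{self.age_band}: CI ({self.ci_low}, "
                f"{self.ci_high}) does not bracket RR {self.rr_per_unit}"
            )
        if self.unit_u <= 0:
            raise InputError("unit_u must be positive")


@dataclass(frozen=True)
class RRCurve:
    """Relative risk evaluated at every exposure-bin midpoint."""

    outcome: str
    age_band: str
    grid: BinGrid
    rr_by_bin: np.ndarray

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_by_bin, dtype=float)
        object.__setattr__(self, "rr_by_bin", rr)
        if rr.shape != (self.grid.n_bins,):
            raise ConfigError("rr_by_bin length does not match the bin grid")


def rr_at(x: float, spec: RRSpec) -> float:
    """Relative risk at exposure ``x`` (% energy from TFA).

    Exactly 1 at and below the reference midpoint and below the TMREL
    (zero excess risk, no protective extrapolation).
    """
    if x < 0:
        raise InputError("exposure must be >= 0")
    threshold = max(spec.reference_midpoint_y, spec.tmrel)
    if x <= threshold:
        return 1.0
    return spec.rr_per_unit ** ((x - spec.reference_midpoint_y) / spec.unit_u)


def build_rr_curve(spec: RRSpec, grid: BinGrid = DEFAULT_GRID) -> RRCurve:
    """Evaluate the dose-response at every bin midpoint of ``grid``."""
    mids = grid.midpoints
    threshold = max(spec.reference_midpoint_y, spec.tmrel)
    expo = (mids - spec.reference_midpoint_y) / spec.unit_u
    rr = np.where(mids > threshold, spec.rr_per_unit ** expo, 1.0)
    return RRCurve(outcome=spec.outcome, age_band=spec.age_band, grid=grid,
                   rr_by_bin=rr)


STROKE_EXCESS = "excess"
STROKE_LOG = "log"


def stroke_rr_from_chd(chd: RRSpec, mode: str = STROKE_EXCESS) -> RRSpec:
    """Derive a stroke RR spec from a CHD one by halving the risk.

    ``mode='excess'`` (default) halves the excess risk,
    RR -> 1 + (RR - 1)/2, which keeps RR >= 1 for harmful exposures;
    ``mode='log'`` halves on the log scale, RR -> sqrt(RR). A literal
    RR/2 would turn a harmful exposure protective and is not offered.
    The same transform is applied to both CI bounds.
    """
    if chd.outcome != CHD:
        raise InputError("stroke risk is derived from a CHD spec")
    if mode == STROKE_EXCESS:
        f = lambda r: 1.0 + (r - 1.0) / 2.0
    elif mode == STROKE_LOG:
        f = math.sqrt
    else:
        raise ConfigError(f"unknown stroke-halving mode {mode!r}")
    return replace(
        chd,
        outcome=STROKE,
        rr_per_unit=f(chd.rr_per_unit),
        ci_low=f(chd.ci_low),
        ci_high=f(chd.ci_high),
    )


#: CHD mortality relative risks per 2% of energy from TFA, by age band,
#: with 95% CIs, from the prospective-cohort meta-analysis used by the
#: model (TFA replacing MUFA/PUFA).
WANG_CHD_RR: tuple[RRSpec, ...] = (
    RRSpec(CHD, "25-34", 1.42, 1.28, 1.57),
    RRSpec(CHD, "35-44", 1.40, 1.27, 1.54),
    RRSpec(CHD, "45-54", 1.33, 1.22, 1.45),
    RRSpec(CHD, "55-64", 1.27, 1.18, 1.36),
    RRSpec(CHD, "65-74", 1.22, 1.15, 1.29),
    RRSpec(CHD, "75+", 1.16, 1.11, 1.21),
)


def default_rr_table(
    stroke_mode: str = STROKE_EXCESS,
    tmrel: float = 0.0,
    reference_midpoint_y: float = 0.05,
) -> dict[tuple[str, str], RRSpec]:
    """Bundled RR table: the CHD meta-analytic values plus derived stroke.

    Keys are ``(outcome, age_band)``.
    """
    table: dict[tuple[str, str], RRSpec] = {}
    for spec in WANG_CHD_RR:
        chd = replace(spec, tmrel=tmrel,
                      reference_midpoint_y=reference_midpoint_y)
        table[(CHD, spec.age_band)] = chd
        stroke = stroke_rr_from_chd(chd, mode=stroke_mode)
        table[(STROKE, spec.age_band)] = stroke
    return table


def scale_rr(spec: RRSpec, factor: float, mode: str = "excess") -> RRSpec:
    """Scale a relative risk for sensitivity analysis.

    ``mode='excess'`` scales the excess risk, RR -> 1 + f*(RR - 1);
    ``mode='multiplicative'`` scales the ratio itself, RR -> f*RR.
    CI bounds follow the same transform.
    """
    if mode == "excess":
        g = lambda r: 1.0 + factor * (r - 1.0)
    elif mode == "multiplicative":
        g = lambda r: factor * r
    else:
        raise ConfigError(f"unknown RR scaling mode {mode!r}")
    lo, mid, hi = sorted((g(spec.ci_low), g(spec.rr_per_unit), g(spec.ci_high)))
    return replace(spec, rr_per_unit=mid, ci_low=lo, ci_high=hi)
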