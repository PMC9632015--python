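"""Reading, validating and writing the model's tabular interfaces.

All tables are UTF-8 CSV with a header row and decimal points. Fixture
files written by this package start with a ``#``-comment line flagging
them as calibrated emulations; the readers skip ``#`` comments. Age
labels accept both hyphen and en-dash on input and are written with a
hyphen.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .burden import (
    BurdenResult,
    EconParams,
    InputBundle,
    LifeTable,
    MortalityRecord,
)
from .errors import ConfigError, InputError
from .exposure import BinGrid, DEFAULT_GRID, MarketChannel, ScenarioSpec
from .risk import AGE_BANDS, AGE_GROUPS, OUTCOMES, RRSpec, SEXES
from .uncertainty import UncertaintyResult

FIXTURE_HEADER = (
    "# calibrated emulation of Brazil-2018 model inputs - not official "
    "statistics"
)


def canonical_age(label: str) -> str:
    """Canonicalize an age-group label (en-dash or hyphen in, hyphen out)."""
    return str(label).strip().replace("–", "-").replace("—", "-")


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    table: str
    row: object
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.table}] row {self.row}: {self.rule}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, row, rule: str, message: str) -> None:
        self.violations.append(Violation(table, row, rule, message))

    def __str__(self) -> str:
        if self.ok:
            return "bundle valid: no violations"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  - {v}" for v in self.violations]
        return "\n".join(lines)


def validate_tables(tables: Mapping[str, pd.DataFrame]) -> ValidationReport:
    """Schema, completeness and non-negativity checks; not fail-fast.

    ``tables`` maps table name (market, population, mortality, lifetable,
    econ, optionally rr) to its frame. Returns a report listing every
    violation found.
    """
    report = ValidationReport()
    schemas = {
        "market": {"channel_id", "pho_g_per_day", "form", "fat_fraction",
                   "tfa_fraction_of_fat"},
        "population": {"sex", "age_group", "count"},
        "mortality": {"outcome", "sex", "age_group", "deaths"},
        "lifetable": {"age_group", "life_expectancy"},
        "econ": {"sex", "age_group", "lfpr"},
        "rr": {"outcome", "age_band", "rr", "ci_low", "ci_high",
               "unit_pct_energy"},
    }
    for name, required in schemas.items():
        if name == "rr" and name not in tables:
            continue  # optional: the bundled default table applies
        if name not in tables:
            report.add(name, "-", "missing-table", "table not provided")
            continue
        missing = required - set(tables[name].columns)
        if missing:
            report.add(name, "-", "schema",
                       f"missing column(s) {sorted(missing)}")
    if not report.ok:
        return report  # column checks below need the schema to hold

    value_rules = {
        "market": [("pho_g_per_day", 0.0, None),
                   ("fat_fraction", 0.0, 1.0),
                   ("tfa_fraction_of_fat", 0.0, 1.0)],
        "population": [("count", 0.0, None)],
        "mortality": [("deaths", 0.0, None)],
        "lifetable": [("life_expectancy", 1e-12, None)],
        "econ": [("lfpr", 0.0, 1.0)],
    }
    for table, rules in value_rules.items():
        frame = tables[table]
        for column, lo, hi in rules:
            vals = pd.to_numeric(frame[column], errors="coerce")
            for idx in frame.index[vals.isna()]:
                report.add(table, int(idx), "numeric",
                           f"{column}={frame.loc[idx, column]!r} not numeric")
            bad = vals.notna() & ((vals < lo) | ((vals > hi) if hi is not None
                                                 else False))
            for idx in frame.index[bad]:
                bound = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
                report.add(table, int(idx), "non-negativity",
                           f"{column}={vals[idx]} outside {bound}")

    # stratum completeness: every sex x age group present where required
    def strata_of(frame: pd.DataFrame) -> set[tuple[str, str]]:
        return {
            (str(s), canonical_age(a))
            for s, a in zip(frame["sex"], frame["age_group"])
        }

    full = {(s, a) for s in SEXES for a in AGE_GROUPS}
    for table in ("population", "econ"):
        for s, a in sorted(full - strata_of(tables[table])):
            report.add(table, "-", "completeness", f"missing ({s}, {a})")
    mort = tables["mortality"]
    for outcome in OUTCOMES:
        sub = mort[mort["outcome"] == outcome]
        for s, a in sorted(full - strata_of(sub)):
            report.add("mortality", "-", "completeness",
                       f"missing ({outcome}, {s}, {a})")
    ages = {canonical_age(a) for a in tables["lifetable"]["age_group"]}
    for a in AGE_GROUPS:
        if a not in ages:
            report.add("lifetable", "-", "completeness", f"missing {a}")
    if "rr" in tables:
        have = {(o, canonical_age(b)) for o, b in
                zip(tables["rr"]["outcome"], tables["rr"]["age_band"])}
        for o in OUTCOMES:
            for b in AGE_BANDS:
                if (o, b) not in have:
                    report.add("rr", "-", "completeness",
                               f"missing ({o}, {b})")
    return report


def bundle_to_tables(bundle: InputBundle) -> dict[str, pd.DataFrame]:
    """Serialize an in-memory bundle back to its canonical tables."""
    market = pd.DataFrame(
        [
            {
                "channel_id": c.channel_id,
                "pho_g_per_day": c.pho_g_per_day,
                "form": c.form,
                "fat_fraction": c.fat_fraction,
                "tfa_fraction_of_fat": c.tfa_fraction_of_fat,
            }
            for c in bundle.channels
        ]
    )
    population = pd.DataFrame(
        [
            {"sex": s, "age_group": a, "count": v}
            for (s, a), v in bundle.population.items()
        ]
    )
    mortality = pd.DataFrame(
        [
            {"outcome": r.outcome, "sex": r.sex, "age_group": r.age_group,
             "deaths": r.deaths}
            for r in bundle.mortality
        ]
    )
    lifetable = pd.DataFrame(
        [
            {"age_group": a, "life_expectancy": bundle.life_table.residual(a)}
            for a in AGE_GROUPS
        ]
    )
    econ = pd.DataFrame(
        [
            {"sex": s, "age_group": a, "lfpr": v}
            for (s, a), v in bundle.econ.lfpr.items()
        ]
    )
    rr = pd.DataFrame(
        [
            {
                "outcome": spec.outcome,
                "age_band": spec.age_band,
                "rr": spec.rr_per_unit,
                "ci_low": spec.ci_low,
                "ci_high": spec.ci_high,
                "unit_pct_energy": spec.unit_u,
            }
            for spec in bundle.rr_table.values()
        ]
    )
    return {
        "market": market,
        "population": population,
        "mortality": mortality,
        "lifetable": lifetable,
        "econ": econ,
        "rr": rr,
    }


def validate_bundle(bundle: InputBundle) -> ValidationReport:
    """Validate an in-memory bundle through the same table rules."""
    return validate_tables(bundle_to_tables(bundle))


# ---------------------------------------------------------------------------
# run configuration and bundle loading
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths to the input tables plus model constants.

    The physical constants (9 kcal per gram of fat, 365-day year) are
    recorded in the config for transparency; this build supports them
    only at their standard values.
    """

    market: Path
    population: Path
    mortality: Path
    lifetable: Path
    econ: Path
    scenarios: list[Path]
    rr: Path | None = None
    mean_energy_kcal: float = 2000.0
    wage: float = 0.0
    pension_age_male: float = 65.0
    pension_age_female: float = 60.0
    cv: float = 0.5
    tmrel: float = 0.0
    stroke_mode: str = "excess"
    bin_width: float = 0.1
    n_bins: int = 25
    top_midpoint: float = 2.45
    kcal_per_g_fat: float = 9.0
    days_per_year: float = 365.0

    @property
    def grid(self) -> BinGrid:
        return BinGrid(width=self.bin_width, n_bins=self.n_bins,
                       top_midpoint=self.top_midpoint)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    base = path.parent

    def p(key: str) -> Path:
        try:
            return base / raw[key]
        except KeyError:
            raise ConfigError(f"{path}: missing required key {key!r}")

    cfg = RunConfig(
        market=p("market"),
        population=p("population"),
        mortality=p("mortality"),
        lifetable=p("lifetable"),
        econ=p("econ"),
        scenarios=[base / s for s in raw.get("scenarios", [])],
        rr=(base / raw["rr"]) if raw.get("rr") else None,
        mean_energy_kcal=float(raw.get("mean_energy_kcal", 2000.0)),
        wage=float(raw.get("wage", 0.0)),
        pension_age_male=float(raw.get("pension_age_male", 65.0)),
        pension_age_female=float(raw.get("pension_age_female", 60.0)),
        cv=float(raw.get("cv", 0.5)),
        tmrel=float(raw.get("tmrel", 0.0)),
        stroke_mode=str(raw.get("stroke_mode", "excess")),
        bin_width=float(raw.get("bin_width", 0.1)),
        n_bins=int(raw.get("n_bins", 25)),
        top_midpoint=float(raw.get("top_midpoint", 2.45)),
        kcal_per_g_fat=float(raw.get("kcal_per_g_fat", 9.0)),
        days_per_year=float(raw.get("days_per_year", 365.0)),
    )
    if cfg.kcal_per_g_fat != 9.0 or cfg.days_per_year != 365.0:
        raise ConfigError(
            "kcal_per_g_fat and days_per_year are fixed at 9 and 365 in "
            "this build"
        )
    for f in [cfg.market, cfg.population, cfg.mortality, cfg.lifetable,
              cfg.econ, *cfg.scenarios] + ([cfg.rr] if cfg.rr else []):
        if not Path(f).exists():
            raise ConfigError(f"input file not found: {f}")
    return cfg


def read_scenario(path: str | Path) -> ScenarioSpec:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    try:
        return ScenarioSpec.from_dict(data)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: malformed scenario file ({exc})")


def write_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def load_bundle(
    config: RunConfig,
) -> tuple[InputBundle, dict[str, ScenarioSpec]]:
    """Read, validate and assemble the model inputs.

    Raises :class:`InputError` carrying the validation report if any
    table is invalid.
    """
    tables = {
        "market": _read_csv(config.market),
        "population": _read_csv(config.population),
        "mortality": _read_csv(config.mortality),
        "lifetable": _read_csv(config.lifetable),
        "econ": _read_csv(config.econ),
    }
    if config.rr is not None:
        tables["rr"] = _read_csv(config.rr)
    report = validate_tables(tables)
    if not report.ok:
        raise InputError(str(report))

    channels = [
        MarketChannel(
            channel_id=str(r.channel_id),
            pho_g_per_day=float(r.pho_g_per_day),
            form=str(r.form),
            fat_fraction=float(r.fat_fraction),
            tfa_fraction_of_fat=float(r.tfa_fraction_of_fat),
        )
        for r in tables["market"].itertuples()
    ]
    mortality = [
        MortalityRecord(str(r.outcome), str(r.sex),
                        canonical_age(r.age_group), float(r.deaths))
        for r in tables["mortality"].itertuples()
    ]
    population = {
        (str(r.sex), canonical_age(r.age_group)): float(r.count)
        for r in tables["population"].itertuples()
    }
    life_table = LifeTable(
        {
            canonical_age(r.age_group): float(r.life_expectancy)
            for r in tables["lifetable"].itertuples()
        }
    )
    econ = EconParams(
        mean_annual_wage=config.wage,
        lfpr={
            (str(r.sex), canonical_age(r.age_group)): float(r.lfpr)
            for r in tables["econ"].itertuples()
        },
        pension_age={"male": config.pension_age_male,
                     "female": config.pension_age_female},
    )
    rr_table = None
    if "rr" in tables:
        rr_table = {}
        for r in tables["rr"].itertuples():
            spec = RRSpec(
                outcome=str(r.outcome),
                age_band=canonical_age(r.age_band),
                rr_per_unit=float(r.rr),
                ci_low=float(r.ci_low),
                ci_high=float(r.ci_high),
                unit_u=float(r.unit_pct_energy),
                tmrel=config.tmrel,
            )
            rr_table[(spec.outcome, spec.age_band)] = spec
    bundle = InputBundle(
        channels=channels,
        mortality=mortality,
        population=population,
        life_table=life_table,
        econ=econ,
        mean_energy_kcal=config.mean_energy_kcal,
        rr_table=rr_table,
        cv=config.cv,
        grid=config.grid,
        tmrel=config.tmrel,
        stroke_mode=config.stroke_mode,
    )
    scenarios = {}
    for spath in config.scenarios:
        spec = read_scenario(spath)
        if spec.scenario_id in scenarios:
            raise ConfigError(f"duplicate scenario id {spec.scenario_id!r}")
        scenarios[spec.scenario_id] = spec
    return bundle, scenarios


# ---------------------------------------------------------------------------
# writing fixtures and results
# ---------------------------------------------------------------------------

def _write_table(frame: pd.DataFrame, path: Path, header: str | None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            fh.write(header + "\n")
        frame.to_csv(fh, index=False)


def write_bundle(fixture, out_dir: str | Path) -> None:
    """Write a complete runnable bundle: tables, scenarios, config, report.

    ``fixture`` is a :class:`~tfamm.fixtures.BrazilFixture` or any object
    with ``bundle``, ``scenarios`` and optionally ``report`` attributes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = fixture.bundle
    tables = bundle_to_tables(bundle)
    for name, frame in tables.items():
        _write_table(frame, out / f"{name}.csv", FIXTURE_HEADER)
    scenario_paths = []
    for sid, spec in fixture.scenarios.items():
        fname = f"scenario_{sid.lower()}.yaml"
        write_scenario(spec, out / fname)
        scenario_paths.append(fname)
    energy = bundle.mean_energy_kcal
    config = {
        "market": "market.csv",
        "population": "population.csv",
        "mortality": "mortality.csv",
        "lifetable": "lifetable.csv",
        "econ": "econ.csv",
        "rr": "rr.csv",
        "scenarios": scenario_paths,
        "mean_energy_kcal": float(energy),
        "wage": bundle.econ.mean_annual_wage,
        "pension_age_male": bundle.econ.pension_age["male"],
        "pension_age_female": bundle.econ.pension_age["female"],
        "cv": bundle.cv,
        "tmrel": bundle.tmrel,
        "stroke_mode": bundle.stroke_mode,
        "bin_width": bundle.grid.width,
        "n_bins": bundle.grid.n_bins,
        "top_midpoint": bundle.grid.top_midpoint,
        "kcal_per_g_fat": 9.0,
        "days_per_year": 365.0,
    }
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    report = getattr(fixture, "report", None)
    if report is not None:
        (out / "calibration_report.json").write_text(
            report.to_json(), encoding="utf-8"
        )


def file_checksums(paths: Sequence[str | Path]) -> dict[str, str]:
    """SHA-256 of each input file, for reproducibility logging."""
    out = {}
    for p in paths:
        p = Path(p)
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def round_2_significant(x: float) -> float:
    """Round to 2 significant digits, the convention for headline DPP."""
    if x == 0:
        return 0.0
    from math import floor, log10

    k = 1 - int(floor(log10(abs(x))))
    return round(x, k)


def write_results(
    result: BurdenResult,
    out_dir: str | Path,
    uncertainty: UncertaintyResult | None = None,
    meta: Mapping | None = None,
) -> tuple[Path, Path]:
    """Write results.csv (stratum level) and summary.json (totals + UIs).

    Machine outputs keep full float precision; the summary also carries
    headline DPP rounded to 2 significant digits. The timestamp lives in
    the isolated ``generated_at`` key so two runs with the same inputs
    and seed are otherwise byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_path = out / "results.csv"
    result.strata.to_csv(results_path, index=False)

    summary = result.summary()
    summary["dpp_rounded_2sig"] = round_2_significant(result.total("dpp"))
    if uncertainty is not None:
        summary["uncertainty"] = {
            name: {"point": p, "ui_low": lo, "ui_high": hi}
            for name, (p, lo, hi) in uncertainty.quantities.items()
        }
        summary["draw_spec"] = {
            "n_draws": uncertainty.draw_spec.n_draws,
            "seed": uncertainty.draw_spec.seed,
            "exposure_rel_se": uncertainty.draw_spec.exposure_rel_se,
        }
    if meta:
        summary["meta"] = dict(meta)
    import datetime

    summary["generated_at"] = datetime.datetime.now(
        datetime.timezone.utc
    ).isoformat()
    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    return results_path, summary_path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
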