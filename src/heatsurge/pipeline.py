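"""End-to-end orchestration: fit → reduce/pool → project → bootstrap →
summarize → utilization, with a config file and reproducible seeding.

Stages run in the order of the analysis: (a) county DLNM fits, (b)
present-day expected series, (c) scenario expected series per GCM × SSP,
(d) per-GCM bootstrap of daily differences, (e) combination of GCMs
within each SSP, (f) monthly/regional sums — followed by the
high-utilization-day accounting. All outputs are flat delimited tables
plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .basis import CrossBasisSpec, build_crossbasis
from .curves import export_curve, find_reference, pooled_curve, reduce_to_curve
from .models import (
    MIN_ENROLLEES,
    CountyPanel,
    adjust_counts,
    build_design,
    filter_counties,
    fit_quasipoisson,
)
from .projection import ScenarioTemps, apply_monthly_deltas, project_county
from .synthetic import read_panels, read_region_map, read_scenarios
from .uncertainty import (
    annual_change_pct,
    bootstrap_difference,
    combine_gcms,
    pool_draws,
    substream,
    summarize_region_month,
)
from .utilization import (
    UtilizationReport,
    annual_thresholds,
    count_exceedances,
    exceedance_change_summary,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the analysis' reference values."""

    panels: str = "panels.csv"
    scenarios: str = "scenarios.csv"
    region_map: str = "region_map.csv"
    output_dir: str = "output"
    # crossbasis
    max_lag: int = 5
    knot_percentiles: tuple[float, float, float] = (10.0, 75.0, 90.0)
    grid_step: float = 1.0
    # county model
    df_per_year: int = 8
    adjustment: str = "rescale"
    # bootstrap
    n_draws: int = 250
    seed: int = 0
    # utilization
    utilization_p: float = 0.95

    def to_yaml(self) -> str:
        d = asdict(self)
        d["knot_percentiles"] = list(self.knot_percentiles)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "knot_percentiles" in d:
            d["knot_percentiles"] = tuple(d["knot_percentiles"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def validate_inputs(
    panels_path, scenarios_path, region_map_path
) -> dict[str, list[str]]:
    """Pre-flight checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings_: list[str] = []
    report = {"errors": errors, "warnings": warnings_}
    try:
        df = pd.read_csv(panels_path, parse_dates=["date"])
    except Exception as exc:  # noqa: BLE001 - any unreadable file is blocking
        errors.append(f"cannot read panels: {exc}")
        return report
    try:
        region_map = read_region_map(region_map_path)
    except Exception as exc:  # noqa: BLE001
        errors.append(f"cannot read region map: {exc}")
        return report
    try:
        scen = read_scenarios(scenarios_path)
        for (gcm, ssp), grp in scen.groupby(["gcm", "ssp"]):
            missing = set(range(1, 13)) - set(grp["month"])
            if missing:
                errors.append(f"scenario {gcm}/{ssp} missing months {sorted(missing)}")
    except Exception as exc:  # noqa: BLE001
        errors.append(f"cannot read scenarios: {exc}")

    for county, grp in df.groupby("county"):
        dates = grp["date"].sort_values()
        gaps = dates.diff().dt.days.iloc[1:]
        if (gaps != 1).any():
            where = dates.iloc[int(np.flatnonzero(gaps.to_numpy() != 1)[0])].date()
            errors.append(f"county {county}: date gap after {where}")
        if str(county) not in region_map:
            errors.append(f"county {county}: absent from region map")
        enroll = grp.groupby(grp["date"].dt.year)["enrollees"].first()
        if (enroll <= MIN_ENROLLEES).any():
            warnings_.append(
                f"county {county}: <= {MIN_ENROLLEES} enrollees in some year; "
                "inclusion filter will drop it"
            )
        warnings_.append(f"county {county}: {len(grp)} rows")
    return report


def _fit_one(panel: CountyPanel, spec: CrossBasisSpec, config: PipelineConfig):
    cb = build_crossbasis(panel.tmax, spec)
    design = build_design(panel, cb, df_per_year=config.df_per_year)
    fit = fit_quasipoisson(design)
    return cb, design, fit


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all output tables; returns the artifacts."""
    out = Path(config.output_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)

    region_map = read_region_map(config.region_map)
    panels = read_panels(config.panels, region_map)
    scenarios = read_scenarios(config.scenarios)
    panels = filter_counties(panels)
    if not panels:
        raise RuntimeError("no county passed the enrollment filter")
    panels = [adjust_counts(p, mode=config.adjustment) for p in panels]

    delta_lo = min(0.0, float(scenarios["delta_c"].min()))
    delta_hi = max(0.0, float(scenarios["delta_c"].max()))

    fits, curves_by_region = {}, {}
    projections: dict[str, dict] = {}
    for panel in panels:
        stage = f"fit county {panel.county}"
        try:
            temps = panel.tmax
            spec = CrossBasisSpec.from_temperatures(
                temps,
                future=np.r_[temps + delta_lo, temps + delta_hi],
                max_lag=config.max_lag,
                knot_percentiles=config.knot_percentiles,
            )
            cb, design, fit = _fit_one(panel, spec, config)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        fits[panel.county] = (panel, spec, cb, design, fit)

        grid = np.arange(
            spec.var_boundary[0], spec.var_boundary[1] + config.grid_step / 2, config.grid_step
        )
        curve = find_reference(reduce_to_curve(fit, spec, grid), spec, temps)
        export_curve(curve, out / "curves" / f"county_{panel.county}.csv")
        curves_by_region.setdefault(panel.region, []).append(
            (curve.reduced_coef, curve.reduced_vcov, spec, temps)
        )

    for region, items in curves_by_region.items():
        spec0, temps0 = items[0][2], np.concatenate([it[3] for it in items])
        grid = np.arange(
            spec0.var_boundary[0], spec0.var_boundary[1] + config.grid_step / 2, config.grid_step
        )
        rc = pooled_curve([(c, v) for c, v, _, _ in items], spec0, grid, observed_temps=temps0)
        export_curve(rc, out / "curves" / f"region_{region.replace(' ', '_')}.csv")

    # stages b-d: projections and per-GCM bootstrap
    samples_by_ssp: dict[str, dict[str, list]] = {}
    for county, (panel, spec, cb, design, fit) in fits.items():
        dates = pd.DatetimeIndex(panel.dates)
        present = project_county(fit, design, cb, dates)
        projections[county] = {"present": present, "future": {}}
        for (gcm, ssp), grp in scenarios.groupby(["gcm", "ssp"]):
            stage = f"project county {county} {gcm}/{ssp}"
            try:
                future_tmax = apply_monthly_deltas(dates, panel.tmax, grp)
                scen = ScenarioTemps(gcm=str(gcm), ssp=str(ssp), future_tmax=future_tmax)
                future = project_county(fit, design, cb, dates, scen)
                diff = bootstrap_difference(
                    present,
                    future,
                    n_draws=config.n_draws,
                    rng=substream(config.seed, county, gcm, ssp, "stage1"),
                )
            except Exception as exc:
                raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
            projections[county]["future"][f"{gcm}/{ssp}"] = future
            samples_by_ssp.setdefault(str(ssp), {}).setdefault(county, []).append(diff)

    # stages e-f: combine GCMs and summarize regions/months
    monthly_rows, annual_rows = [], []
    for ssp, by_county in sorted(samples_by_ssp.items()):
        pooled = {c: pool_draws(lst) for c, lst in by_county.items()}
        summary = summarize_region_month(
            pooled, region_map, rng=substream(config.seed, ssp, "region")
        )
        monthly_rows.append(summary.table())
        ann = summary.annual_table()
        present_totals = {
            region_map[c]: 0.0 for c in pooled
        }
        for c in pooled:
            present_totals[region_map[c]] += projections[c]["present"].annual_total()
        present_totals["All"] = sum(
            projections[c]["present"].annual_total() for c in pooled
        )
        ann["pct_change"] = 100.0 * ann["annual_mean_diff"] / ann["region"].map(present_totals)
        ann["pct_lo"] = 100.0 * ann["eci_lo"] / ann["region"].map(present_totals)
        ann["pct_hi"] = 100.0 * ann["eci_hi"] / ann["region"].map(present_totals)
        annual_rows.append(ann)
    monthly_table = pd.concat(monthly_rows, ignore_index=True)
    annual_table = pd.concat(annual_rows, ignore_index=True)
    monthly_table.to_csv(out / "differences_monthly.csv", index=False, float_format="%.6f")
    annual_table.to_csv(out / "annual_change.csv", index=False, float_format="%.6f")

    # utilization accounting on modeled expected series
    reports = []
    county_rows = []
    for county, proj in projections.items():
        present = proj["present"]
        thresholds = annual_thresholds(present.dates, present.expected, config.utilization_p)
        n_present = count_exceedances(present.dates, present.expected, thresholds)
        rep = UtilizationReport(
            county=county, thresholds=thresholds, n_exceed_present=n_present
        )
        for key, fut in proj["future"].items():
            rep.n_exceed_future[key] = count_exceedances(fut.dates, fut.expected, thresholds)
        reports.append(rep)
        for year, thr in thresholds.items():
            county_rows.append(
                {
                    "county": county,
                    "year": year,
                    "threshold": thr,
                    "n_exceed_present": n_present[year],
                }
            )
    pd.DataFrame(county_rows).to_csv(
        out / "utilization_county.csv", index=False, float_format="%.6f"
    )
    util_rows = []
    summaries = {}
    for ssp in sorted(samples_by_ssp):
        summ = exceedance_change_summary(reports, ssp=ssp)
        summaries[ssp] = summ
        for rep, mean_days in zip(reports, summ["mean_future_days"]):
            util_rows.append(
                {
                    "county": rep.county,
                    "ssp": ssp,
                    "mean_future_exceed_days": mean_days,
                    "pct_change": 100.0
                    * (mean_days - rep.mean_present())
                    / max(rep.mean_present(), 1e-12),
                }
            )
    pd.DataFrame(util_rows).to_csv(
        out / "utilization_summary.csv", index=False, float_format="%.6f"
    )

    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_counties": len(panels),
        "versions": {
            "heatsurge": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "fits": fits,
        "projections": projections,
        "monthly": monthly_table,
        "annual": annual_table,
        "utilization_reports": reports,
        "utilization_summaries": summaries,
        "output_dir": out,
    }
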