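"""End-to-end orchestration: events in, report tables out.

``run_pipeline`` wires the stages together -- read and validate events,
assemble visits, apply the institution inclusion rule, annotate
antibiotics, classify appropriateness, estimate rates/ORs, fit the
interrupted time series -- and writes the paper-shaped delimited outputs
plus a run log.  Any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .appropriateness import (APPROPRIATENESS_LEVELS, TierMap, classify_visits,
                              default_tier_map_path, tabulate_appropriateness)
from .catalog import (AntibioticCatalog, annotate_visits, default_catalog_path,
                      tabulate_antibiotic_pattern)
from .data_model import (DEFAULT_WINDOW, assemble_visits, filter_institutions,
                         read_attribute_tables, read_events)
from .estimation import (StandardPopulation, clopper_pearson_ci,
                         fit_inappropriate_or_model, goodman_simultaneous_ci,
                         standardized_rate)
from .its import aggregate_monthly, fit_segmented, seasonal_adjust

log = logging.getLogger(__name__)

STRATIFIERS = ["area_type", "level", "patient_age", "patient_gender",
               "payment", "year", "physician_age", "physician_gender",
               "physician_education"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (12.65 -> 12.7), as report tables print."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def fmt1(x: float) -> str:
    """One-decimal display; em dash for missing."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "—"
    return f"{round_half_away(x, 1):.1f}"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    prescriptions: str
    diagnoses: str
    patients: str | None = None
    physicians: str | None = None
    institutions: str | None = None
    catalog: str | None = None
    tier_map: str | None = None
    outdir: str = "abxaudit_out"
    window: tuple = DEFAULT_WINDOW
    tcm_mode: str = "expert"
    interruption: str = "2020-03"
    min_months: int = 10
    hac_lag: int | None = None
    fit_or_model: bool = True
    stratifiers: list = field(default_factory=lambda: list(STRATIFIERS))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "window" in raw and raw["window"] is not None:
            lo, hi = raw["window"]
            raw["window"] = (dt.date.fromisoformat(str(lo)),
                             dt.date.fromisoformat(str(hi)))
        return cls(**raw)

    @classmethod
    def for_data_dir(cls, data_dir, outdir="abxaudit_out", **kw) -> "RunConfig":
        d = Path(data_dir)
        return cls(prescriptions=str(d / "prescriptions.csv"),
                   diagnoses=str(d / "diagnoses.csv"),
                   patients=str(d / "patients.csv"),
                   physicians=str(d / "physicians.csv"),
                   institutions=str(d / "institutions.csv"),
                   outdir=str(outdir), **kw)

    def validate(self) -> None:
        for name in ["prescriptions", "diagnoses", "patients", "physicians",
                     "institutions", "catalog", "tier_map"]:
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("load")
def _load(config: RunConfig):
    rx, rx_report = read_events(config.prescriptions, "prescription",
                                window=config.window)
    dx, dx_report = read_events(config.diagnoses, "diagnosis",
                                window=config.window)
    patients, physicians, institutions = read_attribute_tables(
        config.patients, config.physicians, config.institutions)
    visits = assemble_visits(rx, dx, patients, physicians, institutions)
    visits, exclusion = filter_institutions(visits, config.min_months)
    return visits, exclusion, rx_report, dx_report


@_stage("classify")
def _classify(visits, config: RunConfig):
    catalog = AntibioticCatalog.from_csv(config.catalog)
    annotate_visits(visits, catalog)
    tier_map = TierMap.from_csv(config.tier_map)
    frame = classify_visits(visits, tier_map, config.tcm_mode)
    return frame, catalog, tier_map


def _table1(frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for strat in STRATIFIERS:
        for level, sub in frame.groupby(strat):
            row = {"characteristic": strat, "level": str(level)}
            for area in ["urban", "rural"]:
                n = int((sub["area_type"] == area).sum())
                denom = int((frame["area_type"] == area).sum())
                row[f"{area}_n"] = n
                row[f"{area}_pct"] = round_half_away(100 * n / denom, 1) \
                    if denom else float("nan")
            row["all_n"] = len(sub)
            row["all_pct"] = round_half_away(100 * len(sub) / len(frame), 1)
            rows.append(row)
    return pd.DataFrame(rows)


def _rates_by_category(frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cat, sub in frame[frame["category"].notna()].groupby("category"):
        est = clopper_pearson_ci(int(sub["has_antibiotic"].sum()), len(sub))
        rows.append({"category": cat, "tier": int(sub["tier"].iloc[0]),
                     "antibiotic_visits": est.x, "visits": est.n,
                     "rate_pct": est.rate, "ci_low": est.ci_low,
                     "ci_high": est.ci_high})
    return pd.DataFrame(rows).sort_values(["tier", "category"]).reset_index(
        drop=True)


def _standardized_rates(frame: pd.DataFrame, stratifiers) -> pd.DataFrame:
    standard = StandardPopulation.from_frame(frame[frame["category"].notna()])
    rows = []
    for strat in stratifiers:
        for level, sub in frame.groupby(strat):
            crude = clopper_pearson_ci(int(sub["has_antibiotic"].sum()),
                                       len(sub))
            per_cat = {
                cat: (int(s["has_antibiotic"].sum()), len(s))
                for cat, s in sub[sub["category"].notna()].groupby("category")}
            std = standardized_rate(per_cat, standard)
            rows.append({
                "stratifier": strat, "level": str(level),
                "crude_rate_pct": crude.rate, "crude_lo": crude.ci_low,
                "crude_hi": crude.ci_high, "standardized_rate_pct": std.rate,
                "standardized_lo": std.ci_low, "standardized_hi": std.ci_high,
                "empty_categories": len(std.flags)})
    return pd.DataFrame(rows)


def _table2(frame: pd.DataFrame, stratifiers, or_model=None) -> pd.DataFrame:
    sections = [("overall", tabulate_appropriateness(frame))]
    for strat in stratifiers:
        tab = tabulate_appropriateness(frame, by=strat)
        tab.insert(0, "stratifier", strat)
        tab = tab.rename(columns={strat: "level"})
        sections.append((strat, tab))
    overall = sections[0][1]
    overall.insert(0, "stratifier", "overall")
    overall.insert(1, "level", "overall")
    out = pd.concat([s[1] for s in sections], ignore_index=True)
    out["level"] = out["level"].astype(str)
    # Goodman simultaneous intervals over the four classes per stratum
    for i, row in out.iterrows():
        counts = [row[level] for level in APPROPRIATENESS_LEVELS]
        if sum(counts) == 0:
            continue
        ci = goodman_simultaneous_ci(counts)
        for j, level in enumerate(APPROPRIATENESS_LEVELS):
            out.loc[i, f"{level}_lo"] = 100 * ci.ci_low[j]
            out.loc[i, f"{level}_hi"] = 100 * ci.ci_high[j]
    if or_model is not None:
        ors = or_model.terms.rename(columns={"term": "stratifier"})
        ors = ors[["stratifier", "level", "or", "ci_low", "ci_high"]].rename(
            columns={"or": "or_inappropriate", "ci_low": "or_lo",
                     "ci_high": "or_hi"})
        out = out.merge(ors, how="left", on=["stratifier", "level"])
    return out


def _its_results(frame: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    rows = []
    for outcome in ["rx_rate", "inappropriate_prop"]:
        series_set = {"overall": aggregate_monthly(frame, outcome)}
        for strat in ["area_type", "level"]:
            for key, s in aggregate_monthly(frame, outcome, by=strat).items():
                series_set[f"{strat}={key}"] = s
        for label, series in series_set.items():
            adj = seasonal_adjust(series)
            fit = fit_segmented(adj.adjusted, series.months,
                                interruption=config.interruption,
                                hac_lag=config.hac_lag, label=label)
            row = {"outcome": outcome}
            row.update(fit.summary_row())
            rows.append(row)
    return pd.DataFrame(rows)


def _sensitivity_tcm(visits, tier_map, config) -> pd.DataFrame:
    rows = []
    for mode in ["expert", "all_tier2", "all_tier3"]:
        frame = classify_visits(visits, tier_map, mode)
        tab = tabulate_appropriateness(frame)
        tab.insert(0, "tcm_mode", mode)
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle to ``config.outdir``.

    Returns the bundle as a dict of DataFrames (plus the run log text).
    """
    config.validate()
    visits, exclusion, rx_report, dx_report = _load(config)
    frame, catalog, tier_map = _classify(visits, config)

    bundle: dict = {}
    bundle["table1_characteristics"] = _table1(frame)
    bundle["fig1_rates_by_category"] = _rates_by_category(frame)
    or_model = None
    if config.fit_or_model:
        try:
            or_model = fit_inappropriate_or_model(frame)
        except Exception as exc:
            raise PipelineError(f"stage 'or_model' failed: {exc}") from exc
    bundle["table2_appropriateness"] = _table2(frame, config.stratifiers,
                                               or_model)
    patterns = []
    for dim in ["spectrum", "aware", "atc4"]:
        tab = tabulate_antibiotic_pattern(visits, dimension=dim)
        tab.insert(0, "dimension", dim)
        tab = tab.rename(columns={dim: "value"})
        patterns.append(tab)
    bundle["pattern_aware_spectrum"] = pd.concat(patterns, ignore_index=True)
    bundle["standardized_rates"] = _standardized_rates(
        frame, [s for s in ["area_type", "level"] if s in config.stratifiers])
    bundle["sensitivity_tcm"] = _sensitivity_tcm(visits, tier_map, config)
    try:
        bundle["its_results"] = _its_results(frame, config)
    except Exception as exc:
        raise PipelineError(f"stage 'its' failed: {exc}") from exc
    bundle["exclusion_report"] = exclusion
    bundle["classified_visits"] = frame.drop(columns=["month"]).assign(
        month=frame["month"].astype(str))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    log_text = _run_log(config, visits, frame, rx_report, dx_report, or_model)
    (outdir / "run_log.txt").write_text(log_text)
    bundle["run_log"] = log_text
    return bundle


def _run_log(config, visits, frame, rx_report, dx_report, or_model) -> str:
    lines = [
        f"abxaudit {__version__}",
        f"run at: {dt.datetime.now().isoformat(timespec='seconds')}",
        f"seed: {config.seed}",
        f"study window: {config.window[0]}..{config.window[1]}",
        f"tcm_mode: {config.tcm_mode}",
        f"interruption month: {config.interruption}",
        f"institution inclusion: >= {config.min_months} months of data",
        f"prescription rows: {rx_report.n_rows} "
        f"(rejected {rx_report.n_rejected}: {dict(rx_report.reasons)})",
        f"diagnosis rows: {dx_report.n_rows} "
        f"(rejected {dx_report.n_rejected}: {dict(dx_report.reasons)})",
        f"visits analysed: {len(visits)}",
        f"antibiotic visits: {int(frame['has_antibiotic'].sum())}",
    ]
    if or_model is not None:
        lines.append(f"random-intercept model: sigma_u={or_model.sigma_u:.3f}"
                     f" over {or_model.n_groups} institutions")
    return "\n".join(lines) + "\n"


def render_summary(bundle: dict) -> str:
    """Human-readable headline report from a pipeline bundle."""
    t2 = bundle["table2_appropriateness"]
    overall = t2[(t2["stratifier"] == "overall")].iloc[0]
    n_abx = int(overall["n_antibiotic_visits"])
    n_visits = len(bundle["classified_visits"])
    rate = clopper_pearson_ci(n_abx, n_visits)
    lines = ["# Antibiotic prescription audit", ""]
    lines.append(f"Visits analysed: {n_visits}; antibiotic prescriptions: "
                 f"{n_abx} ({fmt1(rate.rate)}% "
                 f"[{fmt1(rate.ci_low)}-{fmt1(rate.ci_high)}])")
    lines.append("")
    lines.append("Appropriateness of antibiotic prescriptions:")
    for level in APPROPRIATENESS_LEVELS:
        lines.append(f"  - {level}: {int(overall[level])} "
                     f"({fmt1(overall[f'{level}_pct'])}%)")
    pat = bundle["pattern_aware_spectrum"]
    lines.append("")
    lines.append("Prescribed items:")
    for dim in ["spectrum", "aware"]:
        sub = pat[pat["dimension"] == dim]
        parts = [f"{r['value']} {fmt1(100 * r['proportion'])}%"
                 for _, r in sub.iterrows()]
        lines.append(f"  - by {dim}: " + ", ".join(parts))
    its = bundle["its_results"]
    lines.append("")
    lines.append("Interrupted time series (level change / slope change, "
                 "percentage points):")
    for _, r in its[its["label"] == "overall"].iterrows():
        lines.append(
            f"  - {r['outcome']}: level {fmt1(r['level_change'])} "
            f"[{fmt1(r['level_change_lo'])} to {fmt1(r['level_change_hi'])}], "
            f"slope {fmt1(r['slope_change'])} "
            f"[{fmt1(r['slope_change_lo'])} to {fmt1(r['slope_change_hi'])}]")
    return "\n".join(lines) + "\n"
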