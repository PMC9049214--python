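"""Synthetic outpatient prescription database with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: several years of monthly visit streams over multiple primary
care institutions of four types (urban/rural x center/station), patient
and physician attributes drawn from realistic margins, a diagnosis
spectrum over thirty ICD-10 categories plus TCM codes in three
appropriateness tiers, tier-dependent antibiotic prescribing on the
logit scale with institution-level random intercepts, 12-month
seasonality, and a step-plus-slope change at the interruption month
(March 2020).  Default parameter values are calibrated so the headline
quantities of the emulated study population come out near an overall
prescription rate of ~12.6%, an appropriateness mix of roughly
13/36/51%, and an immediate level drop of about -2.8 percentage points
at the interruption.

Every generated visit's category, tier, prescribing probability and
drawn outcome are recorded, so expected values of all downstream
statistics are available without re-running the generator.

A second entry point, :func:`simulate_monthly_series`, generates monthly
outcome series directly from the segmented-regression data model with
AR(1) noise, bypassing the visit level, for fast estimator testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .appropriateness import TierMap
from .catalog import AntibioticCatalog

# Patient and physician attribute margins of the emulated population.
PATIENT_AGE = {"<6": 0.071, "6-17": 0.063, "18-44": 0.226,
               "45-64": 0.366, ">=65": 0.274}
PATIENT_GENDER = {"male": 0.46, "female": 0.54}
PAYMENT = {"insurance": 0.791, "out_of_pocket": 0.209}
PHYSICIAN_AGE = {"<30": 0.061, "30-39": 0.373, "40-49": 0.290,
                 "50-59": 0.187, ">=60": 0.089}
PHYSICIAN_GENDER = {"male": 0.44, "female": 0.56}
PHYSICIAN_EDUCATION = {"bachelor_or_above": 0.245,
                       "high_school_or_below": 0.755}

#: Visit shares per diagnostic category (sums to 1).  Tier-3 chronic and
#: viral conditions dominate, as in routine outpatient care.
DEFAULT_SPECTRUM = {
    # tier 1
    "pneumonia": 0.004, "urinary_tract_infection": 0.012,
    "skin_soft_tissue_infection": 0.007,
    "sexually_transmitted_infection": 0.001,
    "other_tier1_bacterial_infection": 0.002,
    "tcm_toxin_syndrome": 0.004,
    # tier 2
    "acute_otitis_media": 0.0012, "acute_sinusitis": 0.0004,
    "acute_pharyngitis": 0.009, "acute_tonsillitis": 0.009,
    "copd": 0.012, "infectious_gastroenteritis": 0.014,
    "pelvic_inflammatory_disease": 0.0034,
    "other_respiratory_infection": 0.004, "other_tier2_infection": 0.013,
    "tcm_heat_syndrome": 0.025,
    # tier 3
    "viral_upper_respiratory_infection": 0.117, "acute_bronchitis": 0.017,
    "influenza": 0.0002, "unspecific_fever": 0.0011, "asthma": 0.004,
    "other_viral_infection": 0.008, "non_infectious_gastroenteritis": 0.020,
    "digestive_symptoms": 0.030, "digestive_noninfectious": 0.050,
    "cardiovascular_disease": 0.170, "endocrine_metabolic": 0.110,
    "musculoskeletal_disease": 0.090, "dermatologic_noninfectious": 0.025,
    "genitourinary_noninfectious": 0.015, "symptoms_signs_other": 0.060,
    "other_noninfectious": 0.0607,
    "tcm_exterior_syndrome": 0.101,
}

#: Mixture over catalogue entries for drawn antibiotic items.
DEFAULT_ANTIBIOTIC_MIXTURE = {
    "J01DC02": 0.11, "J01DC04": 0.06, "J01DD04": 0.08, "J01DD01": 0.04,
    "J01DD08": 0.03, "J01DD62": 0.004, "J01DD63": 0.002, "J01MA02": 0.09,
    "J01MA12": 0.07, "J01MA06": 0.03, "J01FA10": 0.04, "J01FA09": 0.02,
    "J01CR02": 0.11, "J01CR05": 0.01, "J01GB03": 0.06, "J01GB06": 0.02,
    "J01GB90": 0.003, "J01DE01": 0.005, "J01CA04": 0.07, "J01CA01": 0.03,
    "J01DB01": 0.05, "J01DB04": 0.03, "J01DB90": 0.004, "J01CE01": 0.008,
    "J01EE01": 0.02, "J01AA02": 0.012, "J01FF01": 0.012, "J01XX01": 0.0003,
    "J01XD01": 0.012, "P01AB01": 0.04, "P01AB03": 0.008,
}

#: Non-antibiotic filler drugs so every visit carries a prescription row.
PLACEBO_DRUGS = [("C09AA01", "enalapril"), ("A02BC01", "omeprazole"),
                 ("N02BE01", "paracetamol"), ("C07AB03", "atenolol"),
                 ("M01AE01", "ibuprofen")]

#: Logit-scale effects of attributes on the prescribing probability.
DEFAULT_COVARIATE_EFFECTS = {
    ("patient_age", "<6"): 0.25, ("patient_age", "6-17"): 0.15,
    ("patient_age", "45-64"): 0.05, ("patient_age", ">=65"): 0.10,
    ("patient_gender", "male"): 0.05,
    ("payment", "out_of_pocket"): 0.05,
    ("physician_education", "high_school_or_below"): 0.15,
    ("area_type", "rural"): 0.60,
    ("level", "CHSC_TH"): 0.40,
}


@dataclass
class SimulationConfig:
    """Parameters of the visit-level generator (logit scale throughout)."""

    seed: int = 20170601
    start: str = "2017-06"
    months: int = 50
    # institutions per (area_type, level) cell
    institutions: dict = field(default_factory=lambda: {
        ("urban", "CHSC_TH"): 2, ("urban", "CHSS_VC"): 5,
        ("rural", "CHSC_TH"): 3, ("rural", "CHSS_VC"): 2})
    monthly_visits: dict = field(default_factory=lambda: {
        "CHSC_TH": 130, "CHSS_VC": 60})
    spectrum: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    #: per-tier prescribing probability at the covariate reference level
    tier_probs: dict = field(default_factory=lambda: {1: 0.56, 2: 0.50, 3: 0.073})
    sigma_u: float = 0.3
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    seasonal_amplitude: float = 0.15      # logit, cosine with January peak
    baseline_slope: float = -0.015        # logit per month
    interruption: str = "2020-03"
    covid_level_change: float = -0.25     # logit step at the interruption
    covid_slope_change: float = 0.025     # logit per month after it
    antibiotic_mixture: dict = field(
        default_factory=lambda: dict(DEFAULT_ANTIBIOTIC_MIXTURE))
    extra_item_prob: float = 0.10         # chance of a second antibiotic item
    p_secondary_diagnosis: float = 0.0    # multi-diagnosis mode off by default
    tcm_fraction_check: float = 0.13      # informational; implied by spectrum

    def validate(self) -> None:
        total = sum(self.spectrum.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"spectrum weights sum to {total}, not 1")
        for t, p in self.tier_probs.items():
            if not 0 < p < 1:
                raise ValueError(f"tier {t} probability {p} outside (0,1)")
        if self.months < 24:
            raise ValueError("need at least 24 months")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")


def _logit(p):
    return np.log(p / (1.0 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _category_tables(tier_map: TierMap, spectrum: dict):
    """Category order, tiers, and validated synthetic code pools."""
    categories = list(spectrum.keys())
    tiers, pools, systems = [], [], []
    for cat in categories:
        rules = [r for r in tier_map.rules if r.category == cat]
        if not rules:
            raise ValueError(f"spectrum category {cat!r} not in tier map")
        tiers.append(rules[0].tier)
        systems.append(rules[0].code_system)
        pool = []
        for rule in rules:
            for suffix in [f"{d}" for d in range(10)] + [
                    f"{d}{e}" for d in range(10) for e in range(10)]:
                code = rule.code_prefix + suffix
                hit = tier_map.match(rule.code_system, code)
                if hit is not None and hit.category == cat:
                    pool.append(code if rule.code_system == "TCM" or
                                len(rule.code_prefix) < 3
                                else f"{rule.code_prefix}.{suffix}")
                if len(pool) >= 3 * len(rules):
                    break
        if not pool:
            raise ValueError(f"no valid synthetic code for category {cat!r}")
        pools.append(pool)
    return categories, np.array(tiers), pools, systems


def _sample_levels(rng, margins: dict, n: int) -> np.ndarray:
    levels = list(margins.keys())
    p = np.array(list(margins.values()), dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(levels, dtype=object), size=n, p=p)


def simulate_frames(config: SimulationConfig | None = None):
    """Run the generator in memory.

    Returns ``(tables, ground_truth)`` where ``tables`` is a dict of the
    five output DataFrames (prescriptions, diagnoses, patients,
    physicians, institutions).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    tier_map = TierMap.from_csv()
    catalog = AntibioticCatalog.from_csv()
    categories, tiers, pools, systems = _category_tables(tier_map,
                                                         config.spectrum)
    weights = np.array([config.spectrum[c] for c in categories])
    weights = weights / weights.sum()

    # --- institutions, physicians, patients -----------------------------
    inst_rows, phys_rows = [], []
    for (area, level), count in sorted(config.institutions.items()):
        for i in range(count):
            iid = f"I{len(inst_rows):03d}"
            inst_rows.append({"institution_id": iid, "area_type": area,
                              "level": level})
    inst = pd.DataFrame(inst_rows)
    inst["u"] = rng.normal(0.0, config.sigma_u, len(inst))
    inst["mean_visits"] = inst["level"].map(config.monthly_visits).astype(float)

    phys_of_inst = []
    for iid in inst["institution_id"]:
        n_p = int(rng.integers(3, 7))
        ids = []
        for k in range(n_p):
            pid = f"D{iid[1:]}{k:02d}"
            phys_rows.append({
                "physician_id": pid,
                "age_group": str(_sample_levels(rng, PHYSICIAN_AGE, 1)[0]),
                "gender": str(_sample_levels(rng, PHYSICIAN_GENDER, 1)[0]),
                "education": str(_sample_levels(rng, PHYSICIAN_EDUCATION, 1)[0]),
            })
            ids.append(pid)
        phys_of_inst.append(ids)
    physicians = pd.DataFrame(phys_rows)
    phys_attr = physicians.set_index("physician_id")

    months = pd.period_range(config.start, periods=config.months, freq="M")
    pool_sizes = (inst["mean_visits"] * config.months / 2).astype(int)
    patient_rows = []
    patient_ids_of_inst = []
    for iid, size in zip(inst["institution_id"], pool_sizes):
        ids = [f"P{iid[1:]}{k:05d}" for k in range(size)]
        patient_ids_of_inst.append(ids)
        patient_rows.append(pd.DataFrame({
            "patient_id": ids,
            "age_group": _sample_levels(rng, PATIENT_AGE, size),
            "gender": _sample_levels(rng, PATIENT_GENDER, size),
            "payment": _sample_levels(rng, PAYMENT, size),
        }))
    patients = pd.concat(patient_rows, ignore_index=True)
    pat_attr = patients.set_index("patient_id")

    # --- visits ----------------------------------------------------------
    cut = pd.Period(config.interruption, freq="M")
    visit_frames = []
    for j, inst_row in inst.iterrows():
        counts = rng.poisson(inst_row["mean_visits"], config.months)
        n_total = int(counts.sum())
        t_idx = np.repeat(np.arange(config.months), counts)
        pat_pool = np.array(patient_ids_of_inst[j], dtype=object)
        pat = pat_pool[rng.integers(0, len(pat_pool), n_total)]
        phys_pool = np.array(phys_of_inst[j], dtype=object)
        phys = phys_pool[rng.integers(0, len(phys_pool), n_total)]
        days_in_month = np.array([m.days_in_month for m in months])
        day = rng.integers(1, days_in_month[t_idx] + 1)
        cat_idx = rng.choice(len(categories), size=n_total, p=weights)
        visit_frames.append(pd.DataFrame({
            "institution_id": inst_row["institution_id"], "t": t_idx,
            "day": day, "patient_id": pat, "physician_id": phys,
            "category_idx": cat_idx, "u": inst_row["u"],
            "area_type": inst_row["area_type"], "level": inst_row["level"],
        }))
    visits = pd.concat(visit_frames, ignore_index=True)
    month_of = months[visits["t"].to_numpy()]
    visits["visit_date"] = pd.to_datetime(
        {"year": month_of.year, "month": month_of.month,
         "day": visits["day"]})
    visits = visits.drop_duplicates(
        subset=["institution_id", "patient_id", "visit_date"],
        keep="first").reset_index(drop=True)
    n = len(visits)

    visits["tier"] = tiers[visits["category_idx"].to_numpy()]
    # optional secondary diagnosis from a different tier
    if config.p_secondary_diagnosis > 0:
        has_second = rng.random(n) < config.p_secondary_diagnosis
        second = rng.choice(len(categories), size=n, p=weights)
        clash = tiers[second] == visits["tier"].to_numpy()
        for _ in range(20):
            if not np.any(clash & has_second):
                break
            redraw = rng.choice(len(categories), size=int(clash.sum()),
                                p=weights)
            second[clash] = redraw
            clash = tiers[second] == visits["tier"].to_numpy()
        has_second &= ~clash
        visits["category2_idx"] = np.where(has_second, second, -1)
    else:
        visits["category2_idx"] = -1

    best_tier = visits["tier"].to_numpy().copy()
    second_mask = visits["category2_idx"].to_numpy() >= 0
    if second_mask.any():
        best_tier[second_mask] = np.minimum(
            best_tier[second_mask],
            tiers[visits.loc[second_mask, "category2_idx"].to_numpy()])
    visits["best_tier"] = best_tier

    # --- prescribing decision -------------------------------------------
    # Covariate and drift terms are centred at their population means so
    # tier_probs keep their meaning as marginal tier-wise rates.
    base = np.array([_logit(config.tier_probs[t]) for t in best_tier])
    eta = base + visits["u"].to_numpy()
    eta += config.baseline_slope * (visits["t"].to_numpy()
                                    - (config.months - 1) / 2.0)
    cal_month = months[visits["t"].to_numpy()].month
    eta += config.seasonal_amplitude * np.cos(2 * np.pi * (cal_month - 1) / 12)
    post = months[visits["t"].to_numpy()] >= cut
    taft_all = np.clip(np.array([(m - cut).n for m in months]), 0, None)
    taft = taft_all[visits["t"].to_numpy()]
    eta += config.covid_level_change * post
    eta += config.covid_slope_change * taft

    volume = {(a, l): c * config.monthly_visits[l]
              for (a, l), c in config.institutions.items()}
    total_volume = sum(volume.values())
    margin_of = {"patient_age": PATIENT_AGE, "patient_gender": PATIENT_GENDER,
                 "payment": PAYMENT, "physician_age": PHYSICIAN_AGE,
                 "physician_gender": PHYSICIAN_GENDER,
                 "physician_education": PHYSICIAN_EDUCATION}
    for (col, level), effect in config.covariate_effects.items():
        if col == "area_type":
            values = visits[col].to_numpy()
            p_level = sum(v for (a, _), v in volume.items()
                          if a == level) / total_volume
        elif col == "level":
            values = visits[col].to_numpy()
            p_level = sum(v for (_, l), v in volume.items()
                          if l == level) / total_volume
        elif col.startswith("patient") or col == "payment":
            attr = {"patient_age": "age_group", "patient_gender": "gender",
                    "payment": "payment"}[col]
            values = pat_attr.loc[visits["patient_id"], attr].to_numpy()
            p_level = margin_of[col][level]
        else:
            attr = {"physician_age": "age_group",
                    "physician_gender": "gender",
                    "physician_education": "education"}[col]
            values = phys_attr.loc[visits["physician_id"], attr].to_numpy()
            p_level = margin_of[col][level]
        eta += effect * ((values == level) - p_level)
    visits["p_prescribe"] = _sigmoid(eta)
    visits["prescribed"] = rng.random(n) < visits["p_prescribe"]

    # --- event tables ----------------------------------------------------
    code_choice = np.array([pools[i][k % len(pools[i])] for i, k in zip(
        visits["category_idx"], rng.integers(0, 64, n))], dtype=object)
    system = np.array([systems[i] for i in visits["category_idx"]],
                      dtype=object)
    dx = pd.DataFrame({
        "institution_id": visits["institution_id"],
        "patient_id": visits["patient_id"],
        "visit_date": visits["visit_date"].dt.date.astype(str),
        "code_system": system, "diagnosis_code": code_choice,
    })
    if second_mask.any():
        sec = visits[second_mask]
        idx2 = sec["category2_idx"].to_numpy()
        code2 = np.array([pools[i][k % len(pools[i])] for i, k in zip(
            idx2, rng.integers(0, 64, len(sec)))], dtype=object)
        dx2 = pd.DataFrame({
            "institution_id": sec["institution_id"],
            "patient_id": sec["patient_id"],
            "visit_date": sec["visit_date"].dt.date.astype(str),
            "code_system": np.array([systems[i] for i in idx2], dtype=object),
            "diagnosis_code": code2,
        })
        dx = pd.concat([dx, dx2], ignore_index=True)

    mix_codes = list(config.antibiotic_mixture.keys())
    mix_p = np.array(list(config.antibiotic_mixture.values()), dtype=float)
    mix_p = mix_p / mix_p.sum()
    name_of = {e.atc_code: e.generic_name for e in catalog.entries}

    rx_parts = []
    presc = visits[visits["prescribed"]]
    n_items = 1 + (rng.random(len(presc)) < config.extra_item_prob)
    rep = np.repeat(np.arange(len(presc)), n_items)
    item_codes = rng.choice(np.array(mix_codes, dtype=object),
                            size=len(rep), p=mix_p)
    routes = np.where(
        pd.Series(item_codes).str.startswith("J01XD"), "parenteral",
        np.where(pd.Series(item_codes).str.startswith("P01AB"), "oral",
                 np.where(rng.random(len(rep)) < 0.15, "parenteral", "oral")))
    rx_parts.append(pd.DataFrame({
        "institution_id": presc["institution_id"].to_numpy()[rep],
        "patient_id": presc["patient_id"].to_numpy()[rep],
        "visit_date": presc["visit_date"].dt.date.astype(str).to_numpy()[rep],
        "drug_code": item_codes,
        "drug_name": [name_of.get(c, c) for c in item_codes],
        "route": routes,
        "physician_id": presc["physician_id"].to_numpy()[rep],
    }))
    nop = visits[~visits["prescribed"]]
    placebo_idx = rng.integers(0, len(PLACEBO_DRUGS), len(nop))
    rx_parts.append(pd.DataFrame({
        "institution_id": nop["institution_id"].to_numpy(),
        "patient_id": nop["patient_id"].to_numpy(),
        "visit_date": nop["visit_date"].dt.date.astype(str).to_numpy(),
        "drug_code": [PLACEBO_DRUGS[i][0] for i in placebo_idx],
        "drug_name": [PLACEBO_DRUGS[i][1] for i in placebo_idx],
        "route": "oral",
        "physician_id": nop["physician_id"].to_numpy(),
    }))
    rx = pd.concat(rx_parts, ignore_index=True)

    sort_cols = ["institution_id", "visit_date", "patient_id"]
    rx = rx.sort_values(sort_cols + ["drug_code"]).reset_index(drop=True)
    dx = dx.sort_values(sort_cols + ["diagnosis_code"]).reset_index(drop=True)

    # --- ground truth ----------------------------------------------------
    item_entries = [catalog.lookup(c) for c in item_codes]
    by_tier = visits.groupby("best_tier")["prescribed"]
    appropriateness_counts = {
        {1: "appropriate", 2: "potentially_appropriate",
         3: "inappropriate"}[t]: int(s)
        for t, s in visits.groupby("best_tier")["prescribed"].sum().items()}
    ground_truth = {
        "seed": config.seed,
        "n_visits": int(n),
        "n_antibiotic_visits": int(visits["prescribed"].sum()),
        "overall_rate_pct": float(100 * visits["prescribed"].mean()),
        "tier_visit_counts": {int(t): int(c) for t, c in
                              visits["best_tier"].value_counts().items()},
        "tier_rx_counts": {int(t): int(s) for t, s in by_tier.sum().items()},
        "tier_rates": {int(t): float(m) for t, m in by_tier.mean().items()},
        "tier_probs": {int(t): p for t, p in config.tier_probs.items()},
        "appropriateness_counts": appropriateness_counts,
        "n_items": int(len(item_codes)),
        "items_by_spectrum": pd.Series(
            [e.spectrum for e in item_entries]).value_counts().to_dict(),
        "items_by_aware": pd.Series(
            [e.aware for e in item_entries]).value_counts().to_dict(),
        "items_by_atc4": pd.Series(
            [e.atc4 for e in item_entries]).value_counts().to_dict(),
        "covid": {"interruption": config.interruption,
                  "level_change_logit": config.covid_level_change,
                  "slope_change_logit": config.covid_slope_change},
        "sigma_u": config.sigma_u,
        "mean_p_prescribe": float(visits["p_prescribe"].mean()),
    }

    tables = {
        "prescriptions": rx,
        "diagnoses": dx,
        "patients": patients,
        "physicians": physicians,
        "institutions": inst[["institution_id", "area_type", "level"]],
    }
    return tables, ground_truth


def simulate_dataset(config: SimulationConfig | None = None, outdir="."):
    """Generate the synthetic database and write it to ``outdir``.

    Emits prescriptions.csv, diagnoses.csv, patients.csv,
    physicians.csv, institutions.csv and ground_truth.json; rerunning
    with the same config yields byte-identical files.
    """
    config = config or SimulationConfig()
    config.validate()          # fail before any file is written
    tables, ground_truth = simulate_frames(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(ground_truth, indent=2, sort_keys=True))
    paths["ground_truth"] = gt_path
    return paths, ground_truth


def simulate_monthly_series(beta=(20.0, -0.2, -2.8, 0.3), T: int = 50,
                            interruption_index: int = 33, rho: float = 0.3,
                            sd: float = 1.0, seasonal=None,
                            replicates: int = 1, seed: int = 0):
    """Monthly outcome series straight from the segmented data model.

    Y_t = b0 + b1 t + b2 Intv_t + b3 taft_t + s_{month(t)} + AR(1) noise,
    with Intv_t = 1 from ``interruption_index`` on and taft_t counting
    months after it (0 at the interruption).  Returns ``(Y, design)``
    with ``Y`` of shape (replicates, T).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(T, dtype=float)
    intv = (t >= interruption_index).astype(float)
    taft = np.clip(t - interruption_index, 0, None)
    b0, b1, b2, b3 = beta
    line = b0 + b1 * t + b2 * intv + b3 * taft
    if seasonal is not None:
        seasonal = np.asarray(seasonal, dtype=float)
        line = line + seasonal[np.arange(T) % 12]
    if sd > 0:
        eps = rng.normal(0.0, sd, size=(replicates, T))
        noise = np.empty((replicates, T))
        noise[:, 0] = eps[:, 0] / np.sqrt(1 - rho ** 2) if abs(rho) < 1 \
            else eps[:, 0]
        for i in range(1, T):
            noise[:, i] = rho * noise[:, i - 1] + eps[:, i]
    else:
        noise = np.zeros((replicates, T))
    design = pd.DataFrame({"const": 1.0, "t0": t, "intv": intv, "taft": taft})
    return line[None, :] + noise, design


def simulate_logistic_clustered(n_clusters: int = 100, cluster_size: int = 50,
                                beta=(-1.0, 0.5), sigma_u: float = 0.3,
                                seed: int = 0):
    """Clustered binary outcomes for testing the random-intercept model.

    Covariates beyond the intercept are i.i.d. Bernoulli(0.5)
    indicators.  Returns ``(y, X, groups)``.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    n = n_clusters * cluster_size
    X = np.column_stack([np.ones(n)] + [
        rng.integers(0, 2, n).astype(float) for _ in range(beta.size - 1)])
    groups = np.repeat(np.arange(n_clusters), cluster_size)
    u = rng.normal(0.0, sigma_u, n_clusters)
    eta = X @ beta + u[groups]
    y = (rng.random(n) < _sigmoid(eta)).astype(float)
    return y, X, groups
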