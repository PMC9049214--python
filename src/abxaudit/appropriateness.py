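"""Diagnosis tiers and visit-level appropriateness of antibiotic use.

Diagnoses are mapped to a three-tier scheme: tier 1 conditions almost
always justify antibiotics (e.g. pneumonia, urinary tract infection),
tier 2 conditions sometimes do (e.g. acute otitis media, sinusitis),
tier 3 conditions almost never do (viral respiratory infections, chronic
non-infectious disease, ...).  ICD-10 codes match the mapping by longest
prefix after stripping punctuation; traditional Chinese medicine (TCM)
codes match a separate expert mapping, or can be forced wholesale to
tier 2 or tier 3 for sensitivity analyses.

A visit that received at least one antibiotic gets a single category by
priority: the best (lowest) tier wins; within a tier an allopathic
(ICD-10) diagnosis beats a TCM one; remaining ties go to the lowest
category index in the shipped mapping file.  The appropriateness label
follows from the best tier:

* tier 1 present            -> appropriate
* tier 2, no tier 1         -> potentially_appropriate
* only tier 3               -> inappropriate
* no classifiable diagnosis -> not_linked
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .data_model import DiagnosisEvent, Visit

log = logging.getLogger(__name__)

TCM_MODES = {"expert", "all_tier2", "all_tier3"}
APPROPRIATENESS_LEVELS = ["appropriate", "potentially_appropriate",
                          "inappropriate", "not_linked"]
#: Umbrella label under which all TCM categories are tabulated.
TCM_UMBRELLA = "tcm"


def default_tier_map_path():
    return resources.files("abxaudit.data") / "tier_map.csv"


@dataclass(frozen=True)
class TierRule:
    code_system: str
    code_prefix: str
    category: str
    tier: int


@dataclass(frozen=True)
class ClassifiedDiagnosis:
    code_system: str
    diagnosis_code: str
    category: str
    tier: int
    category_index: int


class TierMap:
    """Prefix -> (category, tier) mapping for ICD-10 and TCM codes."""

    def __init__(self, rules: list[TierRule]):
        self.rules = list(rules)
        self._by_system: dict[str, dict[str, TierRule]] = {}
        self.categories: list[str] = []
        cat_tier: dict[str, int] = {}
        for r in self.rules:
            if r.tier not in (1, 2, 3):
                raise ValueError(f"prefix {r.code_prefix!r}: tier must be "
                                 f"1, 2 or 3, got {r.tier}")
            table = self._by_system.setdefault(r.code_system, {})
            if r.code_prefix in table:
                raise ValueError(f"duplicate prefix {r.code_prefix!r} in "
                                 f"code system {r.code_system}")
            table[r.code_prefix] = r
            if r.category not in cat_tier:
                cat_tier[r.category] = r.tier
                self.categories.append(r.category)
            elif cat_tier[r.category] != r.tier:
                raise ValueError(f"category {r.category!r} mapped to more "
                                 "than one tier")
        self._category_index = {c: i for i, c in enumerate(self.categories)}

    @classmethod
    def from_csv(cls, path=None) -> "TierMap":
        path = default_tier_map_path() if path is None else path
        df = pd.read_csv(path, dtype=str)
        for col in ["code_system", "code_prefix", "category", "tier"]:
            if col not in df.columns:
                raise ValueError(f"tier map missing column {col!r}")
        rules = [TierRule(r.code_system, r.code_prefix, r.category, int(r.tier))
                 for r in df.itertuples(index=False)]
        return cls(rules)

    def category_index(self, category: str) -> int:
        return self._category_index[category]

    def match(self, code_system: str, code: str) -> TierRule | None:
        """Longest matching prefix within the code system, else None."""
        table = self._by_system.get(code_system)
        if not table:
            return None
        code = _normalise(code)
        for length in range(len(code), 0, -1):
            rule = table.get(code[:length])
            if rule is not None:
                return rule
        return None


def _normalise(code: str) -> str:
    return str(code).replace(".", "").replace("-", "").strip().upper()


def classify_diagnosis(d: DiagnosisEvent, tier_map: TierMap,
                       tcm_mode: str = "expert") -> ClassifiedDiagnosis | None:
    """Map one diagnosis to (category, tier); None when unmatched.

    Under ``all_tier2`` / ``all_tier3`` every TCM code is assigned that
    tier (and the umbrella TCM label) regardless of the expert mapping.
    """
    if tcm_mode not in TCM_MODES:
        raise ValueError(f"unknown tcm_mode {tcm_mode!r}")
    if d.code_system == "TCM" and tcm_mode != "expert":
        tier = 2 if tcm_mode == "all_tier2" else 3
        return ClassifiedDiagnosis(d.code_system, d.diagnosis_code,
                                   TCM_UMBRELLA, tier, len(tier_map.categories))
    rule = tier_map.match(d.code_system, d.diagnosis_code)
    if rule is None:
        return None
    return ClassifiedDiagnosis(d.code_system, d.diagnosis_code, rule.category,
                               rule.tier, tier_map.category_index(rule.category))


@dataclass
class AppropriatenessRecord:
    key: tuple
    matched: list
    n_unmatched: int
    assigned_category: str | None
    assigned_tier: int | None
    appropriateness: str


def _select_best(matched: list[ClassifiedDiagnosis]) -> ClassifiedDiagnosis:
    """Priority: lowest tier, then allopathic over TCM, then lowest
    category index in the mapping file."""
    return min(matched, key=lambda c: (c.tier, c.code_system != "ICD10",
                                       c.category_index))


def assign_visit_appropriateness(visit: Visit, tier_map: TierMap,
                                 tcm_mode: str = "expert") -> AppropriatenessRecord:
    """Classify one antibiotic-prescribing visit."""
    matched, unmatched = [], 0
    for d in visit.diagnoses:
        c = classify_diagnosis(d, tier_map, tcm_mode)
        if c is None:
            unmatched += 1
        else:
            matched.append(c)
    if not matched:
        return AppropriatenessRecord(visit.key, [], unmatched, None, None,
                                     "not_linked")
    best = _select_best(matched)
    label = {1: "appropriate", 2: "potentially_appropriate",
             3: "inappropriate"}[best.tier]
    return AppropriatenessRecord(visit.key, matched, unmatched,
                                 best.category, best.tier, label)


def classify_visits(visits: list[Visit], tier_map: TierMap,
                    tcm_mode: str = "expert") -> pd.DataFrame:
    """Visit-level analysis frame for every visit (antibiotic or not).

    One row per visit with its assigned diagnostic category/tier, its
    appropriateness label (only for antibiotic-prescribing visits), and
    the stratifier covariates used in report tables.  The per-visit
    diagnostic category collapses all TCM categories into the umbrella
    TCM label for rate tabulation.
    """
    rows = []
    n_unmatched_codes = 0
    for v in visits:
        matched = []
        for d in v.diagnoses:
            c = classify_diagnosis(d, tier_map, tcm_mode)
            if c is None:
                n_unmatched_codes += 1
            else:
                matched.append(c)
        if matched:
            best = _select_best(matched)
            category, tier = best.category, best.tier
            label = {1: "appropriate", 2: "potentially_appropriate",
                     3: "inappropriate"}[tier]
            if category.startswith(TCM_UMBRELLA):
                category = TCM_UMBRELLA
        else:
            category, tier, label = None, None, "not_linked"
        rows.append({
            "institution_id": v.institution_id,
            "patient_id": v.patient_id,
            "visit_date": pd.Timestamp(v.visit_date),
            "month": pd.Period(v.visit_date, freq="M"),
            "year": v.visit_date.year,
            "has_antibiotic": v.has_antibiotic,
            "n_antibiotic_items": len(v.antibiotics),
            "category": category,
            "tier": tier,
            "appropriateness": label if v.has_antibiotic else None,
            "area_type": v.institution.area_type,
            "level": v.institution.level,
            "patient_age": v.patient.age_group,
            "patient_gender": v.patient.gender,
            "payment": v.patient.payment,
            "physician_age": v.physician.age_group,
            "physician_gender": v.physician.gender,
            "physician_education": v.physician.education,
        })
    if n_unmatched_codes:
        log.info("%d diagnosis codes matched no tier-map prefix",
                 n_unmatched_codes)
    return pd.DataFrame(rows)


def tabulate_appropriateness(frame: pd.DataFrame,
                             by: str | None = None) -> pd.DataFrame:
    """Counts of the four appropriateness classes per stratum.

    The denominator of every stratum is all its antibiotic-prescribing
    visits, including those not linked to any diagnosis.
    """
    abx = frame[frame["has_antibiotic"]]
    group = [by] if by else []
    rows = []
    for keys, sub in (abx.groupby(group) if group else [((), abx)]):
        counts = sub["appropriateness"].value_counts()
        row = {} if not group else {by: keys[0] if isinstance(keys, tuple) else keys}
        n = len(sub)
        row["n_antibiotic_visits"] = n
        for level in APPROPRIATENESS_LEVELS:
            c = int(counts.get(level, 0))
            row[level] = c
            row[f"{level}_pct"] = 100.0 * c / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
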