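"""Brute-force reference implementations used by several test modules.

These deliberately re-derive results by exhaustive scanning rather than
calling the package's own selection logic.
"""

import datetime as dt

import numpy as np

from abxaudit.data_model import DiagnosisEvent, Visit


def brute_force_match(tier_map, code_system, code):
    """Longest-prefix match by scanning every rule."""
    code = str(code).replace(".", "").replace("-", "").strip().upper()
    best = None
    for rule in tier_map.rules:
        if rule.code_system != code_system:
            continue
        if code.startswith(rule.code_prefix):
            if best is None or len(rule.code_prefix) > len(best.code_prefix):
                best = rule
    return best


def brute_force_appropriateness(tier_map, diagnoses, tcm_mode="expert"):
    """Rule evaluation from first principles for one visit.

    ``diagnoses`` is a list of (code_system, code) pairs.  Returns the
    appropriateness label string.
    """
    tiers = []
    for system, code in diagnoses:
        if system == "TCM" and tcm_mode == "all_tier2":
            tiers.append(2)
        elif system == "TCM" and tcm_mode == "all_tier3":
            tiers.append(3)
        else:
            rule = brute_force_match(tier_map, system, code)
            if rule is not None:
                tiers.append(rule.tier)
    if not tiers:
        return "not_linked"
    if 1 in tiers:
        return "appropriate"
    if 2 in tiers:
        return "potentially_appropriate"
    return "inappropriate"


def random_code_pool(tier_map, rng):
    """Codes spread over every rule of the mapping, plus unmatched ones."""
    pool = []
    for rule in tier_map.rules:
        suffix = str(rng.integers(0, 100))
        pool.append((rule.code_system, rule.code_prefix + suffix))
    pool.append(("ICD10", "9999"))     # matches nothing
    pool.append(("TCM", "QQ123"))      # outside the TCM mapping
    return pool


def make_random_visits(tier_map, n, rng, with_antibiotic=True):
    """Visits with 0-3 random diagnoses each, plus the (system, code)
    lists used by the brute-force oracle."""
    pool = random_code_pool(tier_map, rng)
    date = dt.date(2019, 6, 15)
    visits, raw = [], []
    for i in range(n):
        k = int(rng.integers(0, 4))
        picks = [pool[int(rng.integers(len(pool)))] for _ in range(k)]
        v = Visit("I1", f"P{i}", date)
        v.diagnoses = [DiagnosisEvent("I1", f"P{i}", date, s, c)
                       for s, c in picks]
        if with_antibiotic:
            v.antibiotics = [("event", "entry")]
        visits.append(v)
        raw.append(picks)
    return visits, raw
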