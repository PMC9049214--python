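"""Antibiotic identification and coding.

An item counts as a systemic antibiotic when its ATC code starts with
``J01`` or its generic name is one of the three nitroimidazoles
(metronidazole, tinidazole, ornidazole), which in China are mainly used
against anaerobic bacterial infections and may be coded under ``P01AB``
(oral) as well as ``J01XD`` (parenteral).

Each antibiotic carries three labels:

* **ATC level-4 class** (``atc4``, the first five characters, e.g.
  ``J01MA`` fluoroquinolones);
* **spectrum**: *broad* for second- to fourth-generation cephalosporins,
  fluoroquinolones, macrolides, penicillin combinations, and
  aminoglycosides; *narrow* otherwise;
* **WHO AWaRe category** (Access / Watch / Reserve / Unclassified).
  Fosfomycin is the only Reserve agent here; cefathiamidine,
  cefoperazone/tazobactam, cefoperazone/sulbactam and etimicin fall
  outside the AWaRe lists and are Unclassified.

The catalogue ships as an editable CSV so the drug list is data, not
code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

log = logging.getLogger(__name__)

NITROIMIDAZOLES = {"metronidazole", "tinidazole", "ornidazole"}

#: ATC level-4 classes counted as broad-spectrum.
BROAD_ATC4 = {"J01DC", "J01DD", "J01DE", "J01MA", "J01FA",
              "J01CR", "J01GB", "J01GA"}

AWARE_CATEGORIES = {"Access", "Watch", "Reserve", "Unclassified"}
UNCLASSIFIED_AGENTS = {"cefathiamidine", "cefoperazone/tazobactam",
                       "cefoperazone/sulbactam", "etimicin"}


def default_catalog_path():
    return resources.files("abxaudit.data") / "antibiotic_catalog.csv"


@dataclass(frozen=True)
class AntibioticEntry:
    atc_code: str
    generic_name: str
    atc4: str
    spectrum: str
    aware: str


def is_antibiotic(drug_code: str, generic_name: str = "") -> bool:
    """True iff the code is J01* or the name is a nitroimidazole."""
    if str(drug_code).startswith("J01"):
        return True
    return str(generic_name).strip().lower() in NITROIMIDAZOLES


def classify_spectrum(entry: AntibioticEntry) -> str:
    """Broad iff the ATC level-4 class is in :data:`BROAD_ATC4`."""
    if entry.atc4 in BROAD_ATC4:
        return "broad"
    return "narrow"


class AntibioticCatalog:
    """Lookup table of antibiotic entries keyed by ATC code and name."""

    def __init__(self, entries: list[AntibioticEntry]):
        self.entries = list(entries)
        self._by_code = {e.atc_code: e for e in self.entries}
        self._by_name: dict[str, AntibioticEntry] = {}
        for e in self.entries:
            self._by_name.setdefault(e.generic_name.lower(), e)
        self._validate()

    def _validate(self) -> None:
        if len(self._by_code) != len(self.entries):
            seen, dup = set(), None
            for e in self.entries:
                if e.atc_code in seen:
                    dup = e.atc_code
                seen.add(e.atc_code)
            raise ValueError(f"duplicate ATC code in catalogue: {dup!r}")
        for e in self.entries:
            if e.atc4 != e.atc_code[:5]:
                raise ValueError(f"{e.atc_code}: atc4 {e.atc4!r} is not the "
                                 "first five characters of the code")
            if not is_antibiotic(e.atc_code, e.generic_name):
                raise ValueError(f"{e.atc_code} ({e.generic_name}): neither "
                                 "J01 code nor nitroimidazole")
            if e.spectrum != classify_spectrum(e):
                raise ValueError(f"{e.atc_code}: spectrum {e.spectrum!r} "
                                 "inconsistent with its ATC class")
            if e.aware not in AWARE_CATEGORIES:
                raise ValueError(f"{e.atc_code}: unknown AWaRe {e.aware!r}")
            if e.aware == "Reserve" and e.generic_name != "fosfomycin":
                raise ValueError(f"{e.atc_code}: only fosfomycin is Reserve")
            if (e.aware == "Unclassified"
                    and e.generic_name not in UNCLASSIFIED_AGENTS):
                raise ValueError(f"{e.atc_code}: {e.generic_name!r} is not "
                                 "one of the unclassified agents")

    @classmethod
    def from_csv(cls, path=None) -> "AntibioticCatalog":
        path = default_catalog_path() if path is None else path
        df = pd.read_csv(path, dtype=str)
        for col in ["atc_code", "generic_name", "atc4", "spectrum", "aware"]:
            if col not in df.columns:
                raise ValueError(f"catalogue missing column {col!r}")
        entries = [AntibioticEntry(r.atc_code, r.generic_name, r.atc4,
                                   r.spectrum, r.aware)
                   for r in df.itertuples(index=False)]
        return cls(entries)

    def lookup(self, drug_code: str, generic_name: str = ""):
        """Return the catalogue entry for an antibiotic item, else None."""
        entry = self._by_code.get(str(drug_code).strip())
        if entry is not None:
            return entry
        name = str(generic_name).strip().lower()
        if name in NITROIMIDAZOLES:
            return self._by_name.get(name)
        if is_antibiotic(drug_code, generic_name):
            # antibiotic by the inclusion rule but absent from the table
            log.warning("antibiotic %s (%s) not in catalogue", drug_code,
                        generic_name)
            code = str(drug_code).strip()
            return AntibioticEntry(code, str(generic_name).strip(), code[:5],
                                   "narrow" if code[:5] not in BROAD_ATC4
                                   else "broad", "Unclassified")
        return None

    def classify_aware(self, entry: AntibioticEntry) -> str:
        known = self._by_code.get(entry.atc_code)
        return known.aware if known is not None else "Unclassified"


def annotate_visits(visits, catalog: AntibioticCatalog) -> None:
    """Fill ``visit.antibiotics`` with (event, entry) catalogue matches."""
    for v in visits:
        v.antibiotics = []
        for ev in v.prescriptions:
            entry = catalog.lookup(ev.drug_code, ev.drug_name)
            if entry is not None:
                v.antibiotics.append((ev, entry))


def items_frame(visits, categories: dict | None = None) -> pd.DataFrame:
    """One row per prescribed antibiotic item with its labels.

    ``categories`` optionally maps visit keys to the visit's assigned
    diagnostic category so patterns can be split per category.
    """
    rows = []
    for v in visits:
        cat = categories.get(v.key) if categories else None
        for ev, entry in v.antibiotics:
            rows.append({
                "atc_code": entry.atc_code, "generic_name": entry.generic_name,
                "atc4": entry.atc4, "spectrum": entry.spectrum,
                "aware": entry.aware, "category": cat,
            })
    return pd.DataFrame(rows, columns=["atc_code", "generic_name", "atc4",
                                       "spectrum", "aware", "category"])


def tabulate_antibiotic_pattern(visits, dimension: str = "aware",
                                categories: dict | None = None,
                                per_category: bool = False) -> pd.DataFrame:
    """Counts and proportions of prescribed items along one label axis.

    ``dimension`` is ``atc4``, ``spectrum`` or ``aware``; proportions are
    at the individual-item level, not the visit level.
    """
    if dimension not in {"atc4", "spectrum", "aware"}:
        raise ValueError(f"unknown dimension {dimension!r}")
    items = items_frame(visits, categories)
    group = ["category", dimension] if per_category else [dimension]
    out = items.groupby(group, dropna=False).size().rename("count").reset_index()
    denom = (out.groupby("category")["count"].transform("sum")
             if per_category else out["count"].sum())
    out["proportion"] = out["count"] / denom
    return out
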