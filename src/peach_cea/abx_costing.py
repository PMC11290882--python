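"""Antibiotic micro-costing: free-text name normalization, dose parsing,
two-tier price matching, and per-patient drug + antimicrobial-resistance costs.

Hospital prescribing records carry antibiotic names and doses as free text
(misspellings, shorthand, non-antibiotic medication mixed in).  This module
reduces that text to a canonical lexicon with an ordered rule table, parses
dose strings into (value, unit), and matches each prescription to a two-tier
unit-price table: a primary tier (generic market prices, preferred) and an
indicative tier (list prices, fallback).  A prescribed dose absent from the
table may still be costed as an integer multiple of a listed dose.

Each costed course also accrues a fixed per-prescription surcharge
representing the expected future societal cost of antimicrobial resistance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "NON_ANTIBIOTIC",
    "UNRECOGNIZED",
    "NormalizationRules",
    "PriceTable",
    "PriceMatch",
    "CostedAbx",
    "AbxCostSummary",
    "load_default_rules",
    "load_default_price_table",
    "normalize_abx_name",
    "parse_dose",
    "match_price",
    "cost_antibiotics",
]

#: Sentinel returned for text identified as medication that is not an antibiotic.
NON_ANTIBIOTIC = "non_antibiotic"
#: Sentinel returned for text that cannot be mapped to the lexicon.
UNRECOGNIZED = "unrecognized"

_WS = re.compile(r"\s+")


def _canon_text(raw: str) -> str:
    """Lower-case, strip, and collapse internal whitespace."""
    return _WS.sub(" ", raw.strip().lower())


@dataclass(frozen=True)
class NormalizationRules:
    """Ordered free-text normalization rules plus the canonical lexicon.

    ``rules`` is an ordered list of ``(compiled_pattern, canonical, action)``
    with action ``"map"`` or ``"block"``; first match wins.  ``lexicon`` is the
    set of canonical antibiotic names; ``blocklist_patterns`` is kept only for
    introspection.  Unmatched text falls back to fuzzy recovery against the
    lexicon (unique prefix, then unique edit-distance-1 neighbour) before
    being declared unrecognized.
    """

    rules: tuple = ()
    lexicon: frozenset = frozenset()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NormalizationRules":
        rules = []
        lexicon = set()
        for row in frame.itertuples(index=False):
            action = row.action.strip().lower()
            canonical = "" if pd.isna(row.canonical) else str(row.canonical).strip()
            if action not in ("map", "block"):
                raise ValueError(f"unknown rule action {action!r}")
            if action == "map":
                if not canonical:
                    raise ValueError(f"map rule {row.pattern!r} lacks a canonical name")
                lexicon.add(canonical)
            rules.append((re.compile(row.pattern), canonical, action))
        return cls(rules=tuple(rules), lexicon=frozenset(lexicon))

    @classmethod
    def from_csv(cls, path) -> "NormalizationRules":
        return cls.from_frame(pd.read_csv(path))


@lru_cache(maxsize=1)
def load_default_rules() -> NormalizationRules:
    """Bundled rule table (editable fixture, not a national formulary extract)."""
    with resources.files("peach_cea.data").joinpath("abx_rules.csv").open() as fh:
        return NormalizationRules.from_csv(fh)


def _edit_distance_leq1(a: str, b: str) -> bool:
    """True if Levenshtein distance between a and b is at most 1."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:  # one substitution
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # one insertion into a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def normalize_abx_name(raw: str, rules: NormalizationRules) -> str:
    """Map free text to a canonical antibiotic name.

    Matching is case- and whitespace-insensitive.  Rules are applied in table
    order, first match wins; blocked terms return :data:`NON_ANTIBIOTIC`.
    Text no rule matches is recovered against the lexicon by unique prefix
    (truncated entries, >= 4 characters) and then by unique edit-distance-1
    neighbour (single typos); otherwise :data:`UNRECOGNIZED`.
    """
    text = _canon_text(raw)
    if not text:
        return UNRECOGNIZED
    for pattern, canonical, action in rules.rules:
        if pattern.search(text):
            return NON_ANTIBIOTIC if action == "block" else canonical
    # fuzzy fallback: unique truncation
    if len(text) >= 4:
        prefix_hits = [name for name in rules.lexicon if name.startswith(text)]
        if len(prefix_hits) == 1:
            return prefix_hits[0]
    # fuzzy fallback: unique single-edit typo
    typo_hits = [name for name in rules.lexicon if _edit_distance_leq1(text, name)]
    if len(typo_hits) == 1:
        return typo_hits[0]
    return UNRECOGNIZED


# ---------------------------------------------------------------------------
# dose parsing

_DOSE_RE = re.compile(r"^\s*(\d+(?:[.,]\d+)?)\s*([a-zA-Zµ.]+)\s*$")

_UNIT_SYNONYMS = {
    "mg": ("mg", 1.0),
    "milligram": ("mg", 1.0),
    "milligrams": ("mg", 1.0),
    "g": ("mg", 1000.0),
    "gram": ("mg", 1000.0),
    "grams": ("mg", 1000.0),
    "ml": ("mL", 1.0),
    "millilitre": ("mL", 1.0),
    "millilitres": ("mL", 1.0),
    "milliliter": ("mL", 1.0),
    "milliliters": ("mL", 1.0),
    "unit": ("units", 1.0),
    "units": ("units", 1.0),
    "iu": ("units", 1.0),
    "i.u.": ("units", 1.0),
}


def parse_dose(raw: str) -> Optional[tuple[float, str]]:
    """Parse a free-text dose into ``(value, canonical_unit)``.

    Unit synonyms are folded to mg / mL / units, masses expressed in grams
    are converted to mg ("1 g" -> (1000, "mg")).  Returns ``None`` when the
    text is not a recognizable value+unit pair ("one tablet").
    """
    m = _DOSE_RE.match(raw if isinstance(raw, str) else "")
    if not m:
        return None
    value = float(m.group(1).replace(",", "."))
    unit_raw = m.group(2).lower().rstrip(".") if m.group(2) != "i.u." else "i.u."
    entry = _UNIT_SYNONYMS.get(m.group(2).lower()) or _UNIT_SYNONYMS.get(unit_raw)
    if entry is None:
        return None
    unit, factor = entry
    return value * factor, unit


# ---------------------------------------------------------------------------
# price matching

TIER_ORDER = ("primary", "indicative")


@dataclass(frozen=True)
class PriceTable:
    """Two-tier antibiotic unit-price list.

    Entries are (canonical_name, dose_value, dose_unit, unit_price, tier) with
    tier "primary" (preferred market prices) or "indicative" (list prices).
    """

    frame: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        required = {"canonical_name", "dose_value", "dose_unit", "unit_price_gbp", "tier"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"price table missing columns {sorted(missing)}")
        if (self.frame["unit_price_gbp"] < 0).any():
            raise ValueError("unit_price_gbp must be >= 0")
        bad_tier = set(self.frame["tier"]) - set(TIER_ORDER)
        if bad_tier:
            raise ValueError(f"unknown price tiers {sorted(bad_tier)}")
        dup = self.frame.duplicated(["canonical_name", "dose_value", "dose_unit", "tier"])
        if dup.any():
            raise ValueError("duplicate (name, dose, tier) entries in price table")

    @classmethod
    def from_csv(cls, path) -> "PriceTable":
        return cls(pd.read_csv(path))

    def entries_for(self, name: str, unit: str, tier: str) -> pd.DataFrame:
        f = self.frame
        return f[(f["canonical_name"] == name) & (f["dose_unit"] == unit) & (f["tier"] == tier)]


@lru_cache(maxsize=1)
def load_default_price_table() -> PriceTable:
    """Bundled synthetic two-tier price fixture (not a real eMIT/BNF extract)."""
    with resources.files("peach_cea.data").joinpath("price_table.csv").open() as fh:
        return PriceTable.from_csv(fh)


@dataclass(frozen=True)
class PriceMatch:
    per_dose_cost: float
    tier: str
    multiple: int  # 1 for an exact dose match


def match_price(
    name: str,
    dose_value: float,
    dose_unit: str,
    table: PriceTable,
    rtol: float = 1e-9,
) -> Optional[PriceMatch]:
    """Find a per-dose price for a canonical drug at a prescribed dose.

    The primary tier is searched before the indicative tier.  Within a tier an
    exact dose match is preferred (cheapest entry if several); otherwise the
    prescribed dose may be covered by the smallest integer multiple k >= 2 of
    a listed dose, costing k x unit_price, ties broken by lowest cost.
    Returns ``None`` when no entry fits — an unmatched record is signalled,
    never silently priced at zero.
    """
    for tier in TIER_ORDER:
        entries = table.entries_for(name, dose_unit, tier)
        if entries.empty:
            continue
        exact = entries[abs(entries["dose_value"] - dose_value) <= rtol * max(dose_value, 1.0)]
        if not exact.empty:
            return PriceMatch(float(exact["unit_price_gbp"].min()), tier, 1)
        best: Optional[tuple[int, float]] = None
        for row in entries.itertuples(index=False):
            if row.dose_value <= 0:
                continue
            ratio = dose_value / row.dose_value
            k = round(ratio)
            if k >= 2 and abs(ratio - k) <= rtol * k:
                cand = (k, k * row.unit_price_gbp)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            return PriceMatch(float(best[1]), tier, int(best[0]))
    return None


# ---------------------------------------------------------------------------
# per-patient costing

@dataclass(frozen=True)
class CostedAbx:
    """Costing outcome for a single prescription record."""

    canonical_name: str
    matched: bool
    per_dose_cost: float
    total_drug_cost: float
    n_doses: int


@dataclass(frozen=True)
class AbxCostSummary:
    """Per-patient antibiotic costing totals."""

    total_drug_cost: float
    amr_cost: float
    coverage_fraction: float
    abx_days: float
    n_prescriptions: int
    n_matched: int
    records: tuple = ()


def cost_antibiotics(
    records: Iterable,
    rules: NormalizationRules,
    table: PriceTable,
    amr_cost_per_prescription: float = 2.12,
    amr_unit: str = "per_record",
) -> AbxCostSummary:
    """Cost a patient's antibiotic records.

    ``records`` are objects with ``name_text``, ``dose_text``,
    ``frequency_per_day`` and ``days``.  Text identified as non-antibiotic
    medication is dropped entirely.  Drug cost sums per-dose price x
    frequency x days over matched records; the antimicrobial-resistance
    surcharge accrues per prescription (one record = one course) or, with
    ``amr_unit="per_dose"``, per administered dose.  ``abx_days`` counts days
    on antibiotic treatment, treating courses as consecutive (records carry
    durations, not calendar dates).  Coverage is the matched fraction of
    antibiotic records, 1.0 for a patient with none.
    """
    if amr_unit not in ("per_record", "per_dose"):
        raise ValueError("amr_unit must be 'per_record' or 'per_dose'")
    costed = []
    total_drug = 0.0
    n_abx = 0
    n_matched = 0
    n_doses_total = 0
    abx_days = 0.0
    for rec in records:
        canonical = normalize_abx_name(rec.name_text, rules)
        if canonical == NON_ANTIBIOTIC:
            continue
        n_abx += 1
        abx_days += rec.days
        n_doses = int(rec.frequency_per_day) * int(rec.days)
        n_doses_total += n_doses
        match = None
        if canonical != UNRECOGNIZED:
            dose = parse_dose(rec.dose_text)
            if dose is not None:
                match = match_price(canonical, dose[0], dose[1], table)
        if match is None:
            costed.append(CostedAbx(canonical, False, 0.0, 0.0, n_doses))
        else:
            n_matched += 1
            cost = match.per_dose_cost * n_doses
            total_drug += cost
            costed.append(CostedAbx(canonical, True, match.per_dose_cost, cost, n_doses))
    amr_units = n_abx if amr_unit == "per_record" else n_doses_total
    coverage = 1.0 if n_abx == 0 else n_matched / n_abx
    return AbxCostSummary(
        total_drug_cost=total_drug,
        amr_cost=amr_cost_per_prescription * amr_units,
        coverage_fraction=coverage,
        abx_days=abx_days,
        n_prescriptions=n_abx,
        n_matched=n_matched,
        records=tuple(costed),
    )
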