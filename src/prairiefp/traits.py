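"""Species flowering-trait catalog.

Each species carries a set of calendar months in which published floras
report it to flower, a provenance label (native/exotic per USDA Plants
style classification), a functional group (with C3/C4 photosynthetic
pathway pre-assigned for graminoids — pathway is an input column, never
inferred here), and a lifeform flag used for the exclusion rules: taxa
identified only to genus (e.g. "Carex sp.") and tree seedlings stay in
the catalog but are marked non-includable so downstream filtering lives
in one place.
"""

from __future__ import annotations

import calendar
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

MONTHS = tuple(range(1, 13))
MONTH_ABBR = tuple(calendar.month_abbr[m] for m in MONTHS)  # "Jan".."Dec"

PROVENANCES = ("native", "exotic", "unknown")
FUNCTIONAL_GROUPS = ("C3_graminoid", "C4_graminoid", "forb", "legume", "woody", "other")
LIFEFORMS = ("herbaceous", "tree_seedling", "genus_only_placeholder")

_MONTH_LOOKUP: dict[str, int] = {}
for _m in MONTHS:
    _MONTH_LOOKUP[calendar.month_name[_m].lower()] = _m
    _MONTH_LOOKUP[calendar.month_abbr[_m].lower()] = _m
    _MONTH_LOOKUP[str(_m)] = _m
_MONTH_LOOKUP["sept"] = 9

# en dash, em dash, hyphen, or the words "to"/"through" between two months
_RANGE_SEP = re.compile(r"\s*(?:–|—|-|\bto\b|\bthrough\b)\s*", re.IGNORECASE)
_LIST_SEP = re.compile(r"[,;/]|\band\b", re.IGNORECASE)


def _month_token(token: str) -> int:
    key = token.strip().strip(".").lower()
    if key in _MONTH_LOOKUP:
        return _MONTH_LOOKUP[key]
    raise ValueError(f"unrecognized month token {token.strip()!r}")


def parse_flowering_interval(text: str) -> frozenset[int]:
    """Parse a flora-style flowering interval into a set of month indices.

    Accepts full month names, 3-letter abbreviations, or integers 1-12,
    as delimited lists ("June, July, and August"; "Jun;Jul;Aug") and/or
    inclusive ranges ("Jun-Aug", "May through July"). Ranges may wrap
    the year end: "Nov-Feb" -> {11, 12, 1, 2}.
    """
    if text is None or not str(text).strip():
        raise ValueError("empty flowering interval")
    months: set[int] = set()
    for chunk in _LIST_SEP.split(str(text)):
        chunk = chunk.strip().strip(".")
        if not chunk:
            continue
        parts = [p for p in (q.strip().strip(".") for q in _RANGE_SEP.split(chunk)) if p]
        if len(parts) == 1:
            months.add(_month_token(parts[0]))
        elif len(parts) == 2:
            lo, hi = (_month_token(p) for p in parts)
            if lo <= hi:
                months.update(range(lo, hi + 1))
            else:  # wrap-around range, e.g. Nov-Feb
                months.update(range(lo, 13))
                months.update(range(1, hi + 1))
        else:
            raise ValueError(f"unparseable flowering interval chunk {chunk!r}")
    if not months:
        raise ValueError(f"flowering interval {text!r} yielded no months")
    return frozenset(months)


def months_to_string(months: Iterable[int]) -> str:
    """Serialize a month set to the canonical semicolon-delimited form."""
    ms = sorted(set(months))
    if any(m not in MONTHS for m in ms):
        raise ValueError(f"month indices must lie in 1..12, got {ms}")
    return ";".join(MONTH_ABBR[m - 1] for m in ms)


@dataclass(frozen=True)
class SpeciesTrait:
    """One species' flowering window and classification labels."""

    taxon: str
    flowering_months: frozenset[int] = field(default_factory=frozenset)
    provenance: str = "unknown"
    functional_group: str = "other"
    lifeform: str = "herbaceous"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.taxon or not self.taxon.strip():
            raise ValueError("taxon name must be non-empty")
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"{self.taxon}: provenance {self.provenance!r} not in {PROVENANCES}"
            )
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(
                f"{self.taxon}: functional_group {self.functional_group!r} "
                f"not in {FUNCTIONAL_GROUPS}"
            )
        if self.lifeform not in LIFEFORMS:
            raise ValueError(f"{self.taxon}: lifeform {self.lifeform!r} not in {LIFEFORMS}")
        object.__setattr__(self, "flowering_months", frozenset(self.flowering_months))
        if any(m not in MONTHS for m in self.flowering_months):
            raise ValueError(f"{self.taxon}: flowering months must lie in 1..12")
        if self.includable and not self.flowering_months:
            raise ValueError(
                f"{self.taxon}: includable taxon must have a non-empty flowering window"
            )

    @property
    def includable(self) -> bool:
        """Whether the taxon enters the analysis (herbaceous, fully identified)."""
        return self.lifeform == "herbaceous"


def is_flowering(trait: SpeciesTrait, month: int) -> int:
    """0/1 flowering weight: 1 iff `month` lies in the species' window."""
    if month not in MONTHS:
        raise ValueError(f"month must lie in 1..12, got {month}")
    return int(month in trait.flowering_months)


class TraitCatalog:
    """Validated collection of SpeciesTrait records, keyed by taxon name."""

    def __init__(self, traits: Iterable[SpeciesTrait]):
        self._traits: dict[str, SpeciesTrait] = {}
        for trait in traits:
            if trait.taxon in self._traits:
                raise ValueError(f"duplicate taxon in catalog: {trait.taxon!r}")
            self._traits[trait.taxon] = trait
        self.skipped: list[tuple[str, str]] = []  # (taxon, reason) rows dropped on load

    def __len__(self) -> int:
        return len(self._traits)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._traits

    def __getitem__(self, taxon: str) -> SpeciesTrait:
        try:
            return self._traits[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no trait record") from None

    def __iter__(self) -> Iterator[SpeciesTrait]:
        return iter(self._traits.values())

    @property
    def taxa(self) -> list[str]:
        return list(self._traits)

    def includable_taxa(self) -> list[str]:
        return [t.taxon for t in self if t.includable]

    def flowering_table(self) -> pd.DataFrame:
        """Taxon x month 0/1 indicator table (all 12 months) for vector math."""
        rows = {
            t.taxon: [int(m in t.flowering_months) for m in MONTHS] for t in self
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(MONTHS))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [t.taxon for t in self],
                "flowering_months": [months_to_string(t.flowering_months) for t in self],
                "provenance": [t.provenance for t in self],
                "functional_group": [t.functional_group for t in self],
                "lifeform": [t.lifeform for t in self],
                "source": [t.source for t in self],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


TRAIT_COLUMNS = ("taxon", "flowering_months", "provenance", "functional_group", "lifeform")


def load_trait_catalog(path) -> TraitCatalog:
    """Load and validate a trait CSV.

    Rows violating SpeciesTrait invariants are skipped (recorded on
    ``catalog.skipped`` and logged); duplicate taxa or missing columns
    reject the whole file.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait CSV missing required columns: {missing}")
    dupes = df["taxon"][df["taxon"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate taxon rows in trait CSV: {dupes}")

    traits: list[SpeciesTrait] = []
    skipped: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        months_text = row["flowering_months"].strip()
        try:
            months = parse_flowering_interval(months_text) if months_text else frozenset()
            traits.append(
                SpeciesTrait(
                    taxon=row["taxon"].strip(),
                    flowering_months=months,
                    provenance=row["provenance"].strip(),
                    functional_group=row["functional_group"].strip(),
                    lifeform=row["lifeform"].strip(),
                    source=row.get("source", "").strip() if "source" in df.columns else "",
                )
            )
        except ValueError as err:
            skipped.append((row["taxon"], str(err)))
    catalog = TraitCatalog(traits)
    catalog.skipped = skipped
    for taxon, reason in skipped:
        logger.warning("trait catalog: skipped %r (%s)", taxon, reason)
    logger.info(
        "trait catalog: loaded %d taxa, skipped %d rows", len(catalog), len(skipped)
    )
    return catalog
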