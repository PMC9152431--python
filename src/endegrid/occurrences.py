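"""Parsing, validation, cleaning and checklist summaries for point occurrence records.

Occurrence records are held in a :class:`pandas.DataFrame` with a fixed schema
(:data:`RECORD_COLUMNS`): one row per georeferenced observation of a species,
with provenance/quality flags as boolean columns.  The cleaning step applies an
ordered set of exclusion rules — ex-situ/introduced material, hybrids, doubtful
or incomplete determinations, unusable coordinates, and per-species duplicate
coordinates — so that every removed record has exactly one recorded cause and
the bookkeeping reconciles exactly.

Column names in input files follow Darwin-Core conventions by default
(``decimalLongitude``, ``establishmentMeans``, ...) and can be remapped through
a ``column_map``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "FLAG_COLUMNS",
    "RECORD_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_RULE_ORDER",
    "ColumnMappingError",
    "ChecklistError",
    "OccurrenceRecord",
    "CleaningReport",
    "CleaningResult",
    "ChecklistSummary",
    "parse_occurrences",
    "clean_occurrences",
    "summarize_checklist",
]

#: Provenance / quality flags carried per record, in schema order.
FLAG_COLUMNS = (
    "introduced",
    "ex_situ",
    "hybrid",
    "doubtful_id",
    "incomplete_id",
    "invalid_coordinates",
)

#: Canonical record schema (DataFrame columns, in order).
RECORD_COLUMNS = ("species", "genus", "longitude", "latitude", "country") + FLAG_COLUMNS

#: Logical field -> default (Darwin-Core-style) input column name.
DEFAULT_COLUMN_MAP = {
    "species": "species",
    "genus": "genus",
    "longitude": "decimalLongitude",
    "latitude": "decimalLatitude",
    "country": "country",
    "establishment_means": "establishmentMeans",
    "taxon_rank": "taxonRank",
    "identification_qualifier": "identificationQualifier",
}

#: Fixed rule application order; each record is removed by exactly one rule.
DEFAULT_RULE_ORDER = (
    "introduced_ex_situ",
    "hybrid",
    "doubtful_or_incomplete_id",
    "invalid_coordinates",
    "duplicate_coordinates",
)

_MANDATORY_FIELDS = ("species", "longitude", "latitude")

# establishmentMeans vocabulary mapped onto flags
_INTRODUCED_TERMS = frozenset({"introduced", "invasive", "naturalised", "naturalized"})
_EX_SITU_TERMS = frozenset({"ex situ", "exsitu", "ex-situ", "cultivated", "managed"})
# identificationQualifier tokens that mark a doubtful determination
_DOUBT_TOKENS = ("cf", "cf.", "aff", "aff.", "?", "dubious", "doubtful", "indet", "indet.")
# hybrid markers inside a scientific name
_HYBRID_MARKERS = ("×", " x ")


class ColumnMappingError(KeyError):
    """A mandatory logical column cannot be resolved in the input header."""


class ChecklistError(ValueError):
    """Checklist summary cannot be computed (e.g. records without a country)."""


class OccurrenceRecord(NamedTuple):
    """Row-wise view of one occurrence record."""

    species: str
    genus: str
    longitude: float
    latitude: float
    country: str | None
    flags: frozenset


def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in RECORD_COLUMNS})
    for c in ("longitude", "latitude"):
        df[c] = df[c].astype(float)
    for c in FLAG_COLUMNS:
        df[c] = df[c].astype(bool)
    return df


def iter_records(df: pd.DataFrame) -> Iterable[OccurrenceRecord]:
    """Yield :class:`OccurrenceRecord` views of a record frame."""
    for row in df.itertuples(index=False):
        flags = frozenset(f for f in FLAG_COLUMNS if getattr(row, f))
        yield OccurrenceRecord(
            row.species, row.genus, row.longitude, row.latitude, row.country, flags
        )


def _norm(s: object) -> str:
    return "" if s is None or (isinstance(s, float) and math.isnan(s)) else str(s).strip()


def parse_occurrences(
    source,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read delimited text into the canonical occurrence-record frame.

    Parameters
    ----------
    source
        Path, string of file content is *not* accepted — pass a path or an open
        text stream.  The first row must be a header.
    column_map
        Mapping of logical field names (keys of :data:`DEFAULT_COLUMN_MAP`) to
        the column names used in the file; unspecified fields fall back to the
        Darwin-Core defaults.
    sep
        Field delimiter; sniffed (CSV/TSV) when omitted.

    Unparseable or missing coordinates never raise: the record is kept and
    flagged ``invalid_coordinates`` so the cleaning step can count it.  Row
    order is preserved.

    Raises
    ------
    ColumnMappingError
        If the species, longitude or latitude column cannot be found.
    """
    raw = pd.read_csv(source, sep=sep, engine="python", dtype=str, keep_default_na=False)

    # resolve each logical field: explicit mapping, else the Darwin-Core
    # default, else the canonical schema name itself
    cmap = {}
    for logical, dwc in DEFAULT_COLUMN_MAP.items():
        if column_map and logical in column_map:
            cmap[logical] = column_map[logical]
        elif dwc in raw.columns or logical not in raw.columns:
            cmap[logical] = dwc
        else:
            cmap[logical] = logical
    for logical in _MANDATORY_FIELDS:
        if cmap[logical] not in raw.columns:
            raise ColumnMappingError(
                f"mandatory column for '{logical}' not found: expected "
                f"'{cmap[logical]}' in header {list(raw.columns)}"
            )
    if raw.empty:
        return _empty_frame()

    out = pd.DataFrame(index=raw.index)
    out["species"] = raw[cmap["species"]].map(_norm)

    if cmap["genus"] in raw.columns:
        genus = raw[cmap["genus"]].map(_norm)
    else:
        genus = pd.Series("", index=raw.index)
    # genus is derivable as the first epithet of the binomial
    fallback = out["species"].str.split().str[0].fillna("")
    out["genus"] = genus.where(genus != "", fallback)

    lon = pd.to_numeric(raw[cmap["longitude"]], errors="coerce")
    lat = pd.to_numeric(raw[cmap["latitude"]], errors="coerce")
    out["longitude"] = lon
    out["latitude"] = lat
    out["country"] = (
        raw[cmap["country"]].map(_norm) if cmap["country"] in raw.columns else ""
    )

    means = (
        raw[cmap["establishment_means"]].map(_norm).str.lower()
        if cmap["establishment_means"] in raw.columns
        else pd.Series("", index=raw.index)
    )
    out["introduced"] = means.isin(_INTRODUCED_TERMS)
    out["ex_situ"] = means.isin(_EX_SITU_TERMS)

    name_lower = out["species"].str.lower()
    out["hybrid"] = False
    for marker in _HYBRID_MARKERS:
        out["hybrid"] |= name_lower.str.contains(marker, regex=False)

    qualifier = (
        raw[cmap["identification_qualifier"]].map(_norm).str.lower()
        if cmap["identification_qualifier"] in raw.columns
        else pd.Series("", index=raw.index)
    )
    out["doubtful_id"] = qualifier.apply(
        lambda q: any(tok in q.split() or q == tok for tok in _DOUBT_TOKENS) if q else False
    )

    rank = (
        raw[cmap["taxon_rank"]].map(_norm).str.lower()
        if cmap["taxon_rank"] in raw.columns
        else pd.Series("", index=raw.index)
    )
    epithets = out["species"].str.split()
    mononomial = epithets.str.len() < 2
    sp_placeholder = epithets.str[-1].fillna("").str.lower().isin({"sp", "sp.", "spec."})
    above_species = rank.isin({"genus", "family", "subfamily", "tribe"})
    out["incomplete_id"] = mononomial | sp_placeholder | above_species

    bad_lon = lon.isna() | (lon < -180) | (lon > 180)
    bad_lat = lat.isna() | (lat < -90) | (lat > 90)
    out["invalid_coordinates"] = bad_lon | bad_lat

    # accept pre-computed boolean flag columns when present in the input
    for flag in FLAG_COLUMNS:
        if flag in raw.columns:
            explicit = raw[flag].str.strip().str.lower().isin({"1", "true", "yes", "t"})
            out[flag] |= explicit

    return out[list(RECORD_COLUMNS)]


@dataclass
class CleaningReport:
    """Exact bookkeeping of one cleaning pass.

    Invariant: ``n_input == n_output + sum(n_removed_by_rule.values())``.
    """

    n_input: int
    n_removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_output: int = 0
    n_species_output: int = 0
    n_genera_output: int = 0

    def reconciles(self) -> bool:
        return self.n_input == self.n_output + sum(self.n_removed_by_rule.values())

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


@dataclass
class CleaningResult:
    records: pd.DataFrame
    rejects: pd.DataFrame  # input rows + 'removal_reason' column
    report: CleaningReport

    def __iter__(self):  # allows ``records, report = clean_occurrences(...)`` unpacking
        yield self.records
        yield self.report


def clean_occurrences(
    records: pd.DataFrame,
    rules: Sequence[str] = DEFAULT_RULE_ORDER,
) -> CleaningResult:
    """Apply the ordered exclusion rules and return cleaned records plus a report.

    Rules run in the order given (default: provenance → hybrid → identification
    quality → coordinate validity → per-species duplicate coordinates), so each
    removal has a unique cause.  Duplicate removal keeps the first record of
    each ``(species, longitude, latitude)`` triple at full stored precision.
    Cleaning is total: problems become counted removals, never errors.
    """
    df = records.reset_index(drop=True)
    report = CleaningReport(n_input=len(df))
    reasons = pd.Series("", index=df.index, dtype=object)
    alive = pd.Series(True, index=df.index)

    def _remove(rule: str, mask: pd.Series) -> None:
        hit = mask & alive
        reasons[hit] = rule
        report.n_removed_by_rule[rule] = int(hit.sum())
        alive[hit] = False

    for rule in rules:
        if rule == "introduced_ex_situ":
            _remove(rule, df["introduced"] | df["ex_situ"])
        elif rule == "hybrid":
            _remove(rule, df["hybrid"])
        elif rule == "doubtful_or_incomplete_id":
            _remove(rule, df["doubtful_id"] | df["incomplete_id"])
        elif rule == "invalid_coordinates":
            _remove(rule, df["invalid_coordinates"])
        elif rule == "duplicate_coordinates":
            # only among still-alive rows: the first *surviving* record is kept
            surviving_dup = df[alive].duplicated(
                subset=["species", "longitude", "latitude"], keep="first"
            )
            dup = pd.Series(False, index=df.index)
            dup[surviving_dup.index] = surviving_dup
            _remove(rule, dup)
        else:
            raise ValueError(f"unknown cleaning rule: {rule}")

    clean = df[alive].reset_index(drop=True)
    rejects = df[~alive].copy()
    rejects["removal_reason"] = reasons[~alive]
    rejects = rejects.reset_index(drop=True)

    report.n_output = len(clean)
    report.n_species_output = int(clean["species"].nunique())
    report.n_genera_output = int(clean["genus"].nunique())
    assert report.reconciles()
    return CleaningResult(clean, rejects, report)


@dataclass
class ChecklistSummary:
    """Country-level species/genus bookkeeping for a two-country study area."""

    per_country: dict[str, dict[str, int]]
    n_shared_species: int
    n_union_species: int
    n_union_genera: int
    n_shared_genera: int = 0
    n_shared_endemic_species: int = 0

    def endemic_percent(self, country: str) -> int:
        """Share of a country's species endemic to it, as a rounded percent."""
        c = self.per_country[country]
        return round(100 * c["n_endemic_species"] / c["n_species"]) if c["n_species"] else 0


def summarize_checklist(
    records: pd.DataFrame,
    endemic_species: Iterable[str] | Mapping[str, bool] | None = None,
    *,
    species_country: pd.DataFrame | None = None,
) -> ChecklistSummary:
    """Summarize per-country species and genus checklists from cleaned records.

    Country membership comes from the ``country`` column, or from an explicit
    ``species_country`` table (columns ``species``, ``country``) when supplied.
    Endemism cannot be inferred from records confined to the study area, so
    ``endemic_species`` is an external attribute: species in it (or mapped to
    True) occur nowhere outside the study area.  A species endemic to the study
    area and recorded in a single country counts as endemic to that country;
    endemics recorded in both countries are tallied in
    ``n_shared_endemic_species``.
    """
    if species_country is not None:
        memb = species_country[["species", "country"]].copy()
    else:
        memb = records[["species", "country"]].copy()
    memb["country"] = memb["country"].fillna("").astype(str).str.strip()
    orphans = sorted(memb.loc[memb["country"] == "", "species"].unique())
    if orphans:
        raise ChecklistError(
            "records lack a country and no membership table was supplied for: "
            + ", ".join(orphans[:20])
        )

    if endemic_species is None:
        endemics: set[str] = set()
    elif isinstance(endemic_species, Mapping):
        endemics = {s for s, v in endemic_species.items() if v}
    else:
        endemics = set(endemic_species)

    genus_of = memb["species"].str.split().str[0]
    memb = memb.assign(genus=genus_of)

    countries = sorted(memb["country"].unique())
    sp_sets = {c: set(memb.loc[memb["country"] == c, "species"]) for c in countries}
    gen_sets = {c: set(memb.loc[memb["country"] == c, "genus"]) for c in countries}

    union_sp = set().union(*sp_sets.values()) if sp_sets else set()
    union_gen = set().union(*gen_sets.values()) if gen_sets else set()
    in_many = {s for s in union_sp if sum(s in ss for ss in sp_sets.values()) > 1}
    shared_gen = {g for g in union_gen if sum(g in gs for gs in gen_sets.values()) > 1}

    per_country = {}
    for c in countries:
        only_here = sp_sets[c] - in_many
        per_country[c] = {
            "n_species": len(sp_sets[c]),
            "n_genera": len(gen_sets[c]),
            "n_endemic_species": len(only_here & endemics),
        }

    return ChecklistSummary(
        per_country=per_country,
        n_shared_species=len(in_many),
        n_union_species=len(union_sp),
        n_union_genera=len(union_gen),
        n_shared_genera=len(shared_gen),
        n_shared_endemic_species=len(in_many & endemics),
    )
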