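"""Strain phenotype table: data model, parsing, validation, harmonization.

The schema follows the record structure used by curated strain-description
databases built from IJSEM species descriptions: ancillary data (year, doi,
taxonomy, culture collection), morphology (Gram stain, cell dimensions,
shape, aggregation, motility, flagella, spore and pigment formation),
metabolism free text, environmental preferences (habitat, oxygen
requirement, and range/optimum for pH, temperature and salinity), and
sequence accessions (GC content, 16S rRNA, genome).

Missing information is always represented as absent (``None``), never as a
sentinel numeric, and is distinct from any valid value; summaries report
per-field counts of records with information.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple, Optional

import pandas as pd

__all__ = [
    "EnvRange",
    "StrainRecord",
    "TermMap",
    "ValidationIssue",
    "LoadResult",
    "load_strain_table",
    "write_strain_table",
    "load_term_maps",
    "packaged_term_maps",
    "normalize_term",
    "optimum_from_range",
    "summarize_categorical",
]

SHAPES = ("rod", "coccus", "spiral", "filament", "other")
AGGREGATIONS = ("none", "chain", "clump", "other")
HABITATS = ("soil", "marine", "plant", "freshwater", "host", "other")
OXYGEN = ("aerobe", "anaerobe", "facultative", "microaerophile")
TRISTATE = ("positive", "negative")  # None encodes unknown

TAXON_RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class EnvRange:
    """A reported growth range with an optional explicit optimum.

    The optimum, when present, is allowed to fall outside [min, max] (such
    entries occur in practice) but callers are warned at load time.
    """

    min: Optional[float] = None
    max: Optional[float] = None
    optimum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError(f"range min {self.min} > max {self.max}")

    def is_empty(self) -> bool:
        return self.min is None and self.max is None and self.optimum is None


@dataclass
class StrainRecord:
    """One curated strain entry."""

    strain_id: str
    year: Optional[int] = None
    doi: Optional[str] = None
    taxonomy: dict = field(default_factory=dict)  # rank -> name
    culture_collection: Optional[str] = None
    gram_stain: Optional[str] = None  # positive / negative / None
    cell_length_um: Optional[float] = None
    cell_width_um: Optional[float] = None
    shape: Optional[str] = None
    aggregation: Optional[str] = None
    motility: Optional[str] = None
    flagella: Optional[str] = None
    spore: Optional[str] = None
    pigment: Optional[str] = None
    metabolism: Optional[str] = None
    trait_flags: dict = field(default_factory=dict)  # harmonized trait -> polarity
    habitat: Optional[str] = None
    oxygen: Optional[str] = None
    ph_range: EnvRange = field(default_factory=EnvRange)
    temp_range: EnvRange = field(default_factory=EnvRange)
    salt_range: EnvRange = field(default_factory=EnvRange)
    gc_content: Optional[float] = None
    rrna16s_accession: Optional[str] = None
    genome_accession: Optional[str] = None

    @property
    def ph_optimum(self) -> Optional[float]:
        return optimum_from_range(self.ph_range)

    @property
    def temp_optimum(self) -> Optional[float]:
        return optimum_from_range(self.temp_range)

    @property
    def salt_optimum(self) -> Optional[float]:
        return optimum_from_range(self.salt_range)


@dataclass
class TermMap:
    """Synonym list mapping free-text trait mentions to a canonical trait."""

    canonical_trait: str
    synonyms: list[str]
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative: {self.polarity}")


class ValidationIssue(NamedTuple):
    row: int
    strain_id: str
    fld: str
    message: str


class LoadResult(NamedTuple):
    records: list[StrainRecord]
    issues: list[ValidationIssue]
    duplicated_ids: list[str]


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

_MISSING = {"", "na", "n/a", "nan", "none", "unknown", "not reported", "nr", "-"}

_TRISTATE_SYNONYMS = {
    "positive": "positive", "pos": "positive", "+": "positive", "yes": "positive",
    "y": "positive", "true": "positive", "1": "positive", "present": "positive",
    "motile": "positive",
    "negative": "negative", "neg": "negative", "-": "negative", "no": "negative",
    "n": "negative", "false": "negative", "0": "negative", "absent": "negative",
    "nonmotile": "negative", "non-motile": "negative",
    "variable": None, "unknown": None,
}

COLUMN_ALIASES = {
    "strain_id": {"strain_id", "strain", "id", "strain id"},
    "year": {"year", "yr", "publication_year"},
    "doi": {"doi", "article_doi"},
    "culture_collection": {"culture_collection", "culture collection code"},
    "gram_stain": {"gram_stain", "gram", "gram stain"},
    "cell_length_um": {"cell_length_um", "cell_length", "length_um"},
    "cell_width_um": {"cell_width_um", "cell_width", "width_um"},
    "shape": {"shape", "cell_shape"},
    "aggregation": {"aggregation", "cell_aggregation"},
    "motility": {"motility", "motile"},
    "flagella": {"flagella", "flagellum"},
    "spore": {"spore", "spore_formation", "sporulation"},
    "pigment": {"pigment", "pigment_formation", "pigmentation"},
    "metabolism": {"metabolism", "general_metabolism"},
    "habitat": {"habitat", "habitat_of_isolation", "isolation_source"},
    "oxygen": {"oxygen", "oxygen_requirement"},
    "gc_content": {"gc_content", "gc", "percent_gc"},
    "rrna16s_accession": {"rrna16s_accession", "16s_accession", "accession_16s"},
    "genome_accession": {"genome_accession", "genome"},
}
for _trait in ("ph", "temp", "salt"):
    COLUMN_ALIASES[f"{_trait}_min"] = {f"{_trait}_min", f"{_trait}_range_min"}
    COLUMN_ALIASES[f"{_trait}_max"] = {f"{_trait}_max", f"{_trait}_range_max"}
    COLUMN_ALIASES[f"{_trait}_optimum"] = {
        f"{_trait}_optimum", f"{_trait}_opt", f"optimum_{_trait}",
    }

_BOUNDS = {
    "gc_content": (0.0, 100.0),
    "cell_length_um": (0.0, float("inf")),
    "cell_width_um": (0.0, float("inf")),
    "ph": (0.0, 14.0),
    "temp": (-30.0, 150.0),
    "salt": (0.0, 100.0),
}


def _clean(cell) -> Optional[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip()
    return None if s.lower() in _MISSING else s


def _parse_float(cell) -> Optional[float]:
    s = _clean(cell)
    if s is None:
        return None
    return float(s.replace(",", "."))


def _parse_tristate(cell) -> tuple[Optional[str], bool]:
    """Returns (value, ok); unknown spellings are (None, False)."""
    s = _clean(cell)
    if s is None:
        return None, True
    key = s.lower()
    if key in _TRISTATE_SYNONYMS:
        return _TRISTATE_SYNONYMS[key], True
    return None, False


def _parse_vocab(cell, vocab: tuple[str, ...]) -> tuple[Optional[str], bool]:
    """Controlled vocabulary with 'other' passthrough for novel categories."""
    s = _clean(cell)
    if s is None:
        return None, True
    key = s.lower()
    if key in vocab:
        return key, True
    return ("other", False) if "other" in vocab else (None, False)


def _resolve_columns(columns: Iterable[str]) -> dict[str, str]:
    """Map file header names onto schema field names via aliases."""
    out = {}
    for col in columns:
        key = col.strip().lower().replace(" ", "_")
        if key in TAXON_RANKS:
            out[col] = f"tax:{key}"
            continue
        for fld, aliases in COLUMN_ALIASES.items():
            if key in aliases or key == fld:
                out[col] = fld
                break
    return out


# ---------------------------------------------------------------------------
# load / save
# ---------------------------------------------------------------------------

def load_strain_table(path, sep: str = "\t") -> LoadResult:
    """Parse a delimited strain table into records plus a validation report.

    Every row yields a record; cells that cannot be parsed or that violate a
    field invariant (GC content outside [0, 100], pH outside [0, 14],
    negative dimensions, range min > max) are set absent and reported as
    row-level issues.  Duplicated strain ids are flagged but both rows are
    kept.  A missing ``strain_id`` column is a hard error.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = _resolve_columns(df.columns)
    if "strain_id" not in colmap.values():
        raise ValueError("mandatory column 'strain_id' not found in header")

    records: list[StrainRecord] = []
    issues: list[ValidationIssue] = []

    def issue(row, sid, fld, msg):
        issues.append(ValidationIssue(row, sid, fld, msg))

    for rownum, raw in enumerate(df.itertuples(index=False), start=2):
        row = {colmap[c]: v for c, v in zip(df.columns, raw) if c in colmap}
        sid = _clean(row.get("strain_id"))
        if sid is None:
            issue(rownum, "", "strain_id", "empty strain_id; row skipped")
            continue
        rec = StrainRecord(strain_id=sid)
        for rank in TAXON_RANKS:
            v = _clean(row.get(f"tax:{rank}"))
            if v is not None:
                rec.taxonomy[rank] = v
        for fld in ("doi", "culture_collection", "metabolism",
                    "rrna16s_accession", "genome_accession"):
            setattr(rec, fld, _clean(row.get(fld)))
        y = _clean(row.get("year"))
        if y is not None:
            try:
                rec.year = int(float(y))
            except ValueError:
                issue(rownum, sid, "year", f"unparseable year {y!r}")
        for fld in ("gram_stain", "motility", "flagella", "spore", "pigment"):
            val, ok = _parse_tristate(row.get(fld))
            if not ok:
                issue(rownum, sid, fld, f"unrecognized value {row.get(fld)!r}")
            setattr(rec, fld, val)
        for fld, vocab in (("shape", SHAPES), ("aggregation", AGGREGATIONS),
                           ("habitat", HABITATS), ("oxygen", OXYGEN)):
            val, ok = _parse_vocab(row.get(fld), vocab)
            if not ok and val == "other":
                issue(rownum, sid, fld,
                      f"unknown category {row.get(fld)!r} mapped to 'other'")
            elif not ok:
                issue(rownum, sid, fld, f"unknown category {row.get(fld)!r}")
            setattr(rec, fld, val)
        for fld in ("cell_length_um", "cell_width_um", "gc_content"):
            try:
                v = _parse_float(row.get(fld))
            except ValueError:
                issue(rownum, sid, fld, f"unparseable number {row.get(fld)!r}")
                continue
            if v is None:
                continue
            lo, hi = _BOUNDS[fld]
            if not lo <= v <= hi:
                issue(rownum, sid, fld, f"value {v} outside [{lo}, {hi}]; dropped")
            else:
                setattr(rec, fld, v)
        for trait in ("ph", "temp", "salt"):
            lo, hi = _BOUNDS[trait]
            vals = {}
            for part in ("min", "max", "optimum"):
                fld = f"{trait}_{part}"
                try:
                    v = _parse_float(row.get(fld))
                except ValueError:
                    issue(rownum, sid, fld, f"unparseable number {row.get(fld)!r}")
                    v = None
                if v is not None and not lo <= v <= hi:
                    issue(rownum, sid, fld, f"value {v} outside [{lo}, {hi}]; dropped")
                    v = None
                vals[part] = v
            if (vals["min"] is not None and vals["max"] is not None
                    and vals["min"] > vals["max"]):
                issue(rownum, sid, f"{trait}_range",
                      f"min {vals['min']} > max {vals['max']}; range dropped")
                vals["min"] = vals["max"] = None
            rng = EnvRange(**vals)
            if (rng.optimum is not None and rng.min is not None
                    and rng.max is not None
                    and not rng.min <= rng.optimum <= rng.max):
                issue(rownum, sid, f"{trait}_optimum",
                      f"optimum {rng.optimum} outside reported range "
                      f"[{rng.min}, {rng.max}]")
            setattr(rec, f"{trait}_range", rng)
        records.append(rec)

    seen: dict[str, int] = {}
    for r in records:
        seen[r.strain_id] = seen.get(r.strain_id, 0) + 1
    duplicated = sorted(k for k, v in seen.items() if v > 1)
    for d in duplicated:
        issues.append(ValidationIssue(0, d, "strain_id", "duplicated strain_id"))
    return LoadResult(records, issues, duplicated)


def write_strain_table(records: Iterable[StrainRecord], path, sep: str = "\t") -> None:
    """Write records back to delimited text (round-trips with the loader)."""
    rows = []
    for r in records:
        row = {"strain_id": r.strain_id, "year": r.year, "doi": r.doi,
               "culture_collection": r.culture_collection}
        for rank in TAXON_RANKS:
            row[rank] = r.taxonomy.get(rank)
        for fld in ("gram_stain", "cell_length_um", "cell_width_um", "shape",
                    "aggregation", "motility", "flagella", "spore", "pigment",
                    "metabolism", "habitat", "oxygen", "gc_content",
                    "rrna16s_accession", "genome_accession"):
            row[fld] = getattr(r, fld)
        for trait in ("ph", "temp", "salt"):
            rng = getattr(r, f"{trait}_range")
            row[f"{trait}_min"] = rng.min
            row[f"{trait}_max"] = rng.max
            row[f"{trait}_optimum"] = rng.optimum
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# term harmonization
# ---------------------------------------------------------------------------

def _canon_text(s: str) -> str:
    s = s.strip().lower()
    s = s.translate(str.maketrans("", "", string.punctuation.replace("-", "")))
    return re.sub(r"\s+", " ", s).strip()


def load_term_maps(path, sep: str = "\t") -> list[TermMap]:
    """Read a term-map file (columns: canonical_trait, synonym, polarity)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    maps: dict[tuple[str, str], TermMap] = {}
    for _, row in df.iterrows():
        key = (row["canonical_trait"], row.get("polarity", "positive"))
        maps.setdefault(
            key, TermMap(canonical_trait=key[0], synonyms=[], polarity=key[1])
        ).synonyms.append(row["synonym"])
    out = list(maps.values())
    _check_disjoint(out)
    return out


def packaged_term_maps() -> list[TermMap]:
    """The term maps shipped with the package (metabolic trait synonymy)."""
    with resources.as_file(
        resources.files("traitsignal.data") / "term_maps.tsv"
    ) as p:
        return load_term_maps(p)


def _check_disjoint(maps: list[TermMap]) -> None:
    seen: dict[str, str] = {}
    for m in maps:
        for s in m.synonyms:
            c = _canon_text(s)
            if c in seen and seen[c] != m.canonical_trait:
                raise ValueError(
                    f"synonym {s!r} maps to both {seen[c]} and {m.canonical_trait}"
                )
            seen[c] = m.canonical_trait


def normalize_term(raw: str, maps: list[TermMap]):
    """Match free text against the synonym lists, ignoring case/punctuation.

    Returns ``(canonical_trait, polarity)`` or ``None`` on no match.
    """
    if not maps:
        raise ValueError("no term maps supplied")
    _check_disjoint(maps)
    c = _canon_text(raw)
    hits = [
        (m.canonical_trait, m.polarity)
        for m in maps
        if c in {_canon_text(s) for s in m.synonyms}
        or c == _canon_text(m.canonical_trait)
    ]
    if not hits:
        return None
    traits = {h[0] for h in hits}
    if len(traits) > 1:
        raise ValueError(f"term {raw!r} is ambiguous across {sorted(traits)}")
    return hits[0]


# ---------------------------------------------------------------------------
# derived quantities and summaries
# ---------------------------------------------------------------------------

def optimum_from_range(r: EnvRange) -> Optional[float]:
    """Environmental optimum: the explicit value when reported, otherwise
    the midpoint (min+max)/2 when only a range is available, else absent."""
    if r.optimum is not None:
        return float(r.optimum)
    if r.min is not None and r.max is not None:
        return (float(r.min) + float(r.max)) / 2.0
    return None


_CATEGORICAL_FIELDS = {
    "shape", "aggregation", "habitat", "oxygen",
    "gram_stain", "motility", "flagella", "spore", "pigment",
}


def summarize_categorical(records: list[StrainRecord], fld: str):
    """Count records per category, excluding absent values.

    Returns ``(table, n_reported)`` where the table has columns category,
    count, fraction and fractions sum to 1 over reported categories.
    """
    if fld not in _CATEGORICAL_FIELDS:
        raise ValueError(
            f"{fld!r} is not a categorical field "
            f"(one of {sorted(_CATEGORICAL_FIELDS)})"
        )
    values = [getattr(r, fld) for r in records]
    values = [v for v in values if v is not None]
    n = len(values)
    if n == 0:
        return (
            pd.DataFrame(columns=["category", "count", "fraction"]),
            0,
        )
    counts = pd.Series(values).value_counts()
    table = pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / n,
        }
    ).reset_index(drop=True)
    return table, n


def optima_series(records: list[StrainRecord], trait: str = "ph") -> pd.Series:
    """Per-strain optimum for ``trait`` in {'ph','temp','salt'} (absent
    values dropped), applying the explicit-optimum-else-midpoint rule."""
    if trait not in ("ph", "temp", "salt"):
        raise ValueError("trait must be 'ph', 'temp' or 'salt'")
    out = {}
    for r in records:
        v = optimum_from_range(getattr(r, f"{trait}_range"))
        if v is not None:
            out[r.strain_id] = v
    return pd.Series(out, name=f"{trait}_optimum", dtype=float)
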