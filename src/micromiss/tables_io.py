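"""Data model and TSV I/O for species catalogs, detection matrices and OTU tables.

All tables are UTF-8 TSV with a header row and "." as decimal separator.
Detection matrices accept two dialects, auto-detected from the header:

* long format — columns ``sample_id``, ``group``, ``species``, one row per
  detection event;
* wide format — a ``sample_id`` and ``group`` column followed by one boolean
  (0/1) column per species.

Group labels are fixed to ``case``/``control`` internally; file vocabularies
("kwashiorkor", "healthy", ...) are mapped through a user-supplied alias map.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Novelty",
    "KNOWN",
    "NEW_TAXON_CLASSES",
    "FormatError",
    "ValidationError",
    "SpeciesRecord",
    "SpeciesCatalog",
    "DetectionMatrix",
    "OtuTable",
    "GROUP_CASE",
    "GROUP_CONTROL",
    "GROUPS",
    "normalize_species_name",
    "species_key",
    "classify_novelty",
    "read_species_catalog",
    "write_species_catalog",
    "read_detection_matrix",
    "write_detection_matrix",
    "detection_matrix_from_long",
    "read_otu_tables",
    "write_otu_tables",
    "load_new_taxa",
    "load_new_taxa_catalog",
    "load_missing_repertoire_catalog",
    "load_printed_counts",
    "load_printed_summaries",
]

GROUP_CASE = "case"
GROUP_CONTROL = "control"
GROUPS = (GROUP_CASE, GROUP_CONTROL)

# 16S identity thresholds against the closest validly named neighbour:
# below NEW_SPECIES_IDENTITY the isolate is at least a new species, below
# NEW_GENUS_IDENTITY at least a new genus.
NEW_SPECIES_IDENTITY = 0.9865
NEW_GENUS_IDENTITY = 0.95

KNOWN = "known"


class FormatError(ValueError):
    """A table file is missing required structure (columns, rows)."""


class ValidationError(ValueError):
    """A table file parsed but carries invalid values."""


class Novelty(str, enum.Enum):
    """Novelty class of a species relative to the known human-gut repertoire.

    The three ``new_*`` values are nested refinements: every new genus is also
    a new species, every new family also a new genus.  A catalog stores the
    most specific class.
    """

    KNOWN_GUT = "known_gut"
    KNOWN_HUMAN_NOT_GUT = "known_human_not_gut"
    KNOWN_NOT_HUMAN = "known_not_human"
    NEW_SPECIES = "new_species"
    NEW_GENUS = "new_genus"
    NEW_FAMILY = "new_family"


NEW_TAXON_CLASSES = frozenset(
    {Novelty.NEW_SPECIES, Novelty.NEW_GENUS, Novelty.NEW_FAMILY}
)

_WS = re.compile(r"\s+")


def normalize_species_name(name: str) -> str:
    """Collapse runs of whitespace and strip; preserves case for display."""
    return _WS.sub(" ", str(name)).strip()


def species_key(name: str) -> str:
    """Case-insensitive matching key for a species name."""
    return normalize_species_name(name).casefold()


def classify_novelty(
    identity_to_nearest_named: float,
    *,
    new_species_threshold: float = NEW_SPECIES_IDENTITY,
    new_genus_threshold: float = NEW_GENUS_IDENTITY,
) -> str:
    """Classify a 16S identity fraction against novelty thresholds.

    Returns ``"new_genus"`` below the genus threshold, ``"new_species"``
    below the species threshold, and ``"known"`` otherwise.  Boundary
    semantics follow "under": a value exactly at a threshold is NOT novel at
    that level, so 0.9865 is ``known`` and 0.95 is ``new_species``.  Callers
    refine ``known`` into the ``known_*`` subclasses from catalog metadata.
    """
    identity = float(identity_to_nearest_named)
    if not 0.0 <= identity <= 1.0:
        raise ValidationError(
            f"identity must be a fraction in [0, 1], got {identity!r}"
        )
    if identity < new_genus_threshold:
        return Novelty.NEW_GENUS.value
    if identity < new_species_threshold:
        return Novelty.NEW_SPECIES.value
    return KNOWN


# ---------------------------------------------------------------------------
# Species catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesRecord:
    """Per-species taxonomy and trait metadata."""

    name: str
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    obligate_anaerobe: bool = False
    novelty: Novelty = Novelty.KNOWN_GUT
    probiotic_flag: bool = False
    probiotic_function: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_species_name(self.name))
        object.__setattr__(self, "novelty", Novelty(self.novelty))


class SpeciesCatalog:
    """An ordered collection of :class:`SpeciesRecord` unique by name.

    Genus/name prefix mismatches (reclassified genera, e.g. *Clostridium
    glycolicum* now in *Terrisporobacter*) raise a warning, not an error.
    """

    def __init__(self, entries: Iterable[SpeciesRecord], *, warn_genus: bool = True):
        self.entries: list[SpeciesRecord] = list(entries)
        self._by_key: dict[str, SpeciesRecord] = {}
        for rec in self.entries:
            key = species_key(rec.name)
            if key in self._by_key:
                raise ValidationError(f"duplicate species name in catalog: {rec.name!r}")
            self._by_key[key] = rec
        if warn_genus:
            mismatches = [
                rec.name
                for rec in self.entries
                if rec.genus
                and not species_key(rec.name).startswith(species_key(rec.genus))
            ]
            if mismatches:
                warnings.warn(
                    "genus is not a prefix of the species name for: "
                    + ", ".join(sorted(mismatches)),
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return species_key(name) in self._by_key

    def get(self, name: str) -> SpeciesRecord | None:
        return self._by_key.get(species_key(name))

    def __getitem__(self, name: str) -> SpeciesRecord:
        rec = self.get(name)
        if rec is None:
            raise KeyError(name)
        return rec

    def names(self) -> list[str]:
        return [rec.name for rec in self.entries]

    def subset(self, names: Iterable[str]) -> "SpeciesCatalog":
        keys = {species_key(n) for n in names}
        return SpeciesCatalog(
            [r for r in self.entries if species_key(r.name) in keys],
            warn_genus=False,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.name for r in self.entries],
                "phylum": [r.phylum for r in self.entries],
                "class": [r.class_ for r in self.entries],
                "order": [r.order for r in self.entries],
                "family": [r.family for r in self.entries],
                "genus": [r.genus for r in self.entries],
                "obligate_anaerobe": [int(r.obligate_anaerobe) for r in self.entries],
                "novelty": [r.novelty.value for r in self.entries],
                "probiotic": ["yes" if r.probiotic_flag else "no" for r in self.entries],
                "probiotic_function": [r.probiotic_function for r in self.entries],
            }
        )


_TRUTHY = {"1", "yes", "true", "y"}
_FALSY = {"0", "no", "false", "n", ""}


def _parse_bool(token: object, *, row: object, column: str) -> bool:
    text = str(token).strip().casefold()
    if text in ("nan", "none"):
        text = ""
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValidationError(f"invalid {column} token {token!r} in row {row!r}")


def read_species_catalog(path: str | Path, *, warn_genus: bool = True) -> SpeciesCatalog:
    """Read a species catalog TSV.

    The only required column is ``species``; taxonomy and trait columns are
    optional and default to empty/False/``known_gut``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "species" not in df.columns:
        raise FormatError(f"{path}: missing required column 'species'")
    records = []
    for idx, row in df.iterrows():
        name = row["species"]
        novelty_token = row.get("novelty", "") or Novelty.KNOWN_GUT.value
        try:
            novelty = Novelty(novelty_token)
        except ValueError:
            raise ValidationError(
                f"{path}: unknown novelty token {novelty_token!r} in row "
                f"{idx + 2} ({name!r})"
            ) from None
        anaerobe_token = row.get("obligate_anaerobe", row.get("oxygen_tolerant", "0"))
        anaerobe = _parse_bool(anaerobe_token, row=name, column="oxygen flag")
        if "oxygen_tolerant" in df.columns and "obligate_anaerobe" not in df.columns:
            anaerobe = not anaerobe
        records.append(
            SpeciesRecord(
                name=name,
                phylum=row.get("phylum", ""),
                class_=row.get("class", ""),
                order=row.get("order", ""),
                family=row.get("family", ""),
                genus=row.get("genus", name.split(" ")[0]),
                obligate_anaerobe=anaerobe,
                novelty=novelty,
                probiotic_flag=_parse_bool(
                    row.get("probiotic", "no"), row=name, column="probiotic flag"
                ),
                probiotic_function=row.get("probiotic_function", ""),
            )
        )
    return SpeciesCatalog(records, warn_genus=warn_genus)


def write_species_catalog(catalog: SpeciesCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Detection matrices
# ---------------------------------------------------------------------------

@dataclass
class DetectionMatrix:
    """Boolean sample x species presence matrix for one modality.

    ``presence`` is indexed by sample_id with species columns; ``groups``
    maps sample_id to ``case``/``control``.
    """

    modality: str
    presence: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.modality not in ("culturomics", "metagenomics"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        self.presence = self.presence.astype(bool)
        self.groups = self.groups.reindex(self.presence.index)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValidationError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValidationError(
                f"group labels must be in {GROUPS}, got {sorted(bad)}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return list(self.groups.index[self.groups == group])

    def group_presence(self, group: str) -> pd.DataFrame:
        return self.presence.loc[self.samples_in_group(group)]

    def validate(self) -> None:
        orphan = [c for c in self.presence.columns if not self.presence[c].any()]
        if orphan:
            raise ValidationError(
                f"species columns never detected in any sample: {orphan[:5]}"
            )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for sample in self.presence.index:
            group = self.groups.loc[sample]
            for sp in self.presence.columns[self.presence.loc[sample].to_numpy()]:
                rows.append((sample, group, sp))
        return pd.DataFrame(rows, columns=["sample_id", "group", "species"])


def _map_group(token: str, aliases: Mapping[str, str] | None) -> str:
    label = str(token).strip().casefold()
    if aliases:
        lowered = {str(k).casefold(): v for k, v in aliases.items()}
        label = lowered.get(label, label)
    if label not in GROUPS:
        raise ValidationError(
            f"group token {token!r} not in {GROUPS}; supply an alias map"
        )
    return label


def detection_matrix_from_long(
    df: pd.DataFrame,
    modality: str,
    *,
    group_aliases: Mapping[str, str] | None = None,
) -> DetectionMatrix:
    """Build a matrix from long-format rows; duplicate rows collapse to one."""
    required = {"sample_id", "group", "species"}
    if not required.issubset(df.columns):
        raise FormatError(f"long format requires columns {sorted(required)}")
    if df.empty:
        raise FormatError("empty detection table")
    df = df.copy()
    df["species"] = df["species"].map(normalize_species_name)
    df["group"] = df["group"].map(lambda g: _map_group(g, group_aliases))
    per_sample = df.groupby("sample_id")["group"].nunique()
    if (per_sample > 1).any():
        bad = list(per_sample.index[per_sample > 1])
        raise ValidationError(f"conflicting group labels for samples: {bad}")
    presence = pd.crosstab(df["sample_id"], df["species"]) > 0
    presence = presence.sort_index()
    presence = presence[sorted(presence.columns)]
    groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
    return DetectionMatrix(modality=modality, presence=presence, groups=groups)


def read_detection_matrix(
    path: str | Path,
    modality: str,
    *,
    group_aliases: Mapping[str, str] | None = None,
) -> DetectionMatrix:
    """Read a detection matrix TSV, auto-detecting long vs wide dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty detection table")
    cols = list(df.columns)
    if {"sample_id", "group", "species"}.issubset(cols) and len(cols) == 3:
        return detection_matrix_from_long(df, modality, group_aliases=group_aliases)
    if cols[:2] == ["sample_id", "group"]:
        species_cols = cols[2:]
        if not species_cols:
            raise FormatError(f"{path}: wide matrix with no species columns")
        presence = df[species_cols].map(
            lambda v: _parse_bool(v, row="?", column="presence")
        )
        presence.index = df["sample_id"]
        presence.columns = [normalize_species_name(c) for c in species_cols]
        presence = presence.sort_index()
        presence = presence[sorted(presence.columns)]
        groups = pd.Series(
            [_map_group(g, group_aliases) for g in df["group"]],
            index=df["sample_id"],
        )
        return DetectionMatrix(modality=modality, presence=presence, groups=groups)
    raise FormatError(
        f"{path}: cannot detect dialect from header {cols[:5]}; expected long "
        "(sample_id, group, species) or wide (sample_id, group, <species...>)"
    )


def write_detection_matrix(
    matrix: DetectionMatrix, path: str | Path, *, dialect: str = "long"
) -> None:
    if dialect == "long":
        matrix.to_long_frame().to_csv(path, sep="\t", index=False)
    elif dialect == "wide":
        wide = matrix.presence.astype(int).copy()
        wide.insert(0, "group", matrix.groups)
        wide.insert(0, "sample_id", wide.index)
        wide.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

OTU_COLUMNS = ["otu_id", "read_count", "best_hit_species", "best_hit_identity"]


@dataclass
class OtuTable:
    """Per-sample OTU read counts with best-hit species and identity."""

    sample_id: str
    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=OTU_COLUMNS))

    def __post_init__(self) -> None:
        df = self.rows.copy()
        for col in OTU_COLUMNS:
            if col not in df.columns:
                if col == "best_hit_species":
                    df[col] = None
                elif col == "best_hit_identity":
                    df[col] = np.nan
                else:
                    raise FormatError(f"OTU table missing column {col!r}")
        df = df[OTU_COLUMNS].reset_index(drop=True)
        df["read_count"] = pd.to_numeric(df["read_count"])
        df["best_hit_identity"] = pd.to_numeric(df["best_hit_identity"])
        if (df["read_count"] < 0).any():
            raise ValidationError(f"{self.sample_id}: negative read_count")
        if not (df["read_count"] == df["read_count"].astype(np.int64)).all():
            raise ValidationError(f"{self.sample_id}: non-integer read_count")
        df["read_count"] = df["read_count"].astype(np.int64)
        ident = df["best_hit_identity"]
        if ((ident < 0) | (ident > 1)).any():
            raise ValidationError(f"{self.sample_id}: identity outside [0, 1]")
        if df["otu_id"].duplicated().any():
            dups = list(df.loc[df["otu_id"].duplicated(), "otu_id"].unique())
            raise ValidationError(f"{self.sample_id}: duplicate otu_id {dups[:5]}")
        self.rows = df

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def total_reads(self) -> int:
        return int(self.rows["read_count"].sum())


def read_otu_tables(path: str | Path) -> dict[str, OtuTable]:
    """Read a combined OTU TSV (sample_id, otu_id, read_count, best_hit_species,
    best_hit_identity) into one :class:`OtuTable` per sample."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "otu_id": str})
    required = {"sample_id", "otu_id", "read_count"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: OTU table requires columns {sorted(required)}")
    tables = {}
    for sample_id, sub in df.groupby("sample_id", sort=True):
        tables[str(sample_id)] = OtuTable(sample_id=str(sample_id), rows=sub)
    return tables


def write_otu_tables(tables: Mapping[str, OtuTable] | Iterable[OtuTable], path: str | Path) -> None:
    if isinstance(tables, Mapping):
        tables = tables.values()
    frames = []
    for t in tables:
        df = t.rows.copy()
        df.insert(0, "sample_id", t.sample_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample_id", *OTU_COLUMNS]
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Packaged in-study tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("micromiss").joinpath("data", name))  # type: ignore[arg-type]


def load_new_taxa() -> pd.DataFrame:
    """Putative new taxa isolated by culturomics, with oxygen tolerance,
    origin group (case = kwashiorkor, control = healthy) and novelty class."""
    return pd.read_csv(_data_path("new_taxa.tsv"), sep="\t", dtype=str)


def load_new_taxa_catalog() -> SpeciesCatalog:
    """The new-taxon table as a :class:`SpeciesCatalog` (origin dropped)."""
    df = load_new_taxa()
    records = [
        SpeciesRecord(
            name=row.species,
            family=row.family,
            genus=row.species.split(" ")[0],
            obligate_anaerobe=row.oxygen_tolerant.strip().casefold() == "no",
            novelty=Novelty(row.novelty),
        )
        for row in df.itertuples()
    ]
    return SpeciesCatalog(records)


_GLYCOLICUS_SYNONYMS = {
    "terrisporobacter glycolicus": "clostridium glycolicum",
}


def load_missing_repertoire_catalog() -> SpeciesCatalog:
    """The 45 species found in controls by both modalities but absent from
    cases, with taxonomy, oxygen tolerance, probiotic flag and the literature
    function note for the 12 probiotic candidates."""
    df = pd.read_csv(_data_path("missing_repertoire.tsv"), sep="\t", dtype=str)
    funcs = pd.read_csv(_data_path("probiotic_functions.tsv"), sep="\t", dtype=str)
    notes = {}
    for row in funcs.itertuples():
        key = species_key(row.species)
        key = _GLYCOLICUS_SYNONYMS.get(key, key)
        notes[key] = row.function
    records = []
    for _, row in df.iterrows():
        records.append(
            SpeciesRecord(
                name=row["species"],
                phylum=row["phylum"],
                class_=row["class"],
                order=row["order"],
                family=row["family"],
                genus=row["genus"],
                obligate_anaerobe=bool(int(row["obligate_anaerobe"])),
                novelty=Novelty.KNOWN_GUT,
                probiotic_flag=row["probiotic"].strip().casefold() == "yes",
                probiotic_function=notes.get(species_key(row["species"]), ""),
            )
        )
    with warnings.catch_warnings():
        # the table legitimately contains reclassified genera
        warnings.simplefilter("ignore")
        return SpeciesCatalog(records)


def load_printed_counts() -> pd.DataFrame:
    """Published 2x2 comparison counts (k/N per group) with the test used."""
    return pd.read_csv(_data_path("printed_counts.tsv"), sep="\t")


def load_printed_summaries() -> pd.DataFrame:
    """Published per-group summary statistics (mean, SD, n) with test used."""
    return pd.read_csv(_data_path("printed_summaries.tsv"), sep="\t")
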