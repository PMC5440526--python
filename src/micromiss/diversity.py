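"""Diversity statistics for two-group presence/abundance microbiota data.

Three measures are provided:

* the U/T ratio — a presence/absence beta-diversity statistic: the number of
  species found in exactly one sample of a group (Unique) over all species
  found in that group (Total).  A higher ratio means higher inter-individual
  diversity, and the ratio is comparable across groups of different size;
* the Shannon index H' = -sum p_i log2 p_i in bits, optionally restricted to
  a trait subset (obligate anaerobes / aerotolerant species) with proportions
  renormalized within the subset so the result is itself a Shannon index;
* hitherto-unknown diversity — for culture data, the number of newly isolated
  taxa plus species not previously known from the human gut; for amplicon
  data, the number of unidentified OTUs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    DetectionMatrix,
    NEW_TAXON_CLASSES,
    Novelty,
    SpeciesCatalog,
    ValidationError,
    species_key,
)

__all__ = [
    "UTResult",
    "ShannonResult",
    "UnknownDiversityCount",
    "ut_ratio",
    "shannon_index",
    "unknown_diversity",
    "taxon_frequency_table",
]


@dataclass(frozen=True)
class UTResult:
    """Unique/total species richness of one group."""

    unique_count: int
    total_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.unique_count <= self.total_count:
            raise ValueError("need 0 <= U <= T")
        if self.total_count == 0:
            raise ValueError("U/T ratio undefined for a group with no detections")

    @property
    def ratio(self) -> float:
        return self.unique_count / self.total_count

    def __str__(self) -> str:
        """Render as in published tables, e.g. ``151/335 (45%)``."""
        return f"{self.unique_count}/{self.total_count} ({round(100 * self.ratio)}%)"


@dataclass(frozen=True)
class ShannonResult:
    """Shannon index in bits over a (possibly trait-restricted) composition."""

    h_bits: float
    n_species: int
    scope: str = "all"
    #: False when computed from global (unrenormalized) proportions, in which
    #: case the 0 <= H' <= log2(S) bound need not hold.
    proper: bool = True

    def __post_init__(self) -> None:
        if not self.proper:
            return
        limit = np.log2(self.n_species) if self.n_species else 0.0
        if not -1e-9 <= self.h_bits <= limit + 1e-9:
            raise ValueError(f"H'={self.h_bits} outside [0, log2(S)={limit}]")


@dataclass(frozen=True)
class UnknownDiversityCount:
    """Counts of the hitherto-unknown diversity in one sample or group.

    ``n_new_species`` counts every newly isolated taxon (new species, genus or
    family — the classes are nested, so a new genus is also a new species).
    """

    n_new_species: int = 0
    n_not_known_human: int = 0
    n_known_human_not_gut: int = 0
    n_unidentified_otus: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_new_species",
            "n_not_known_human",
            "n_known_human_not_gut",
            "n_unidentified_otus",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def culturomics_total(self) -> int:
        """New taxa + species not previously known from the human gut."""
        return self.n_new_species + self.n_not_known_human + self.n_known_human_not_gut


def ut_ratio(
    matrix: DetectionMatrix,
    group: str,
    species_subset: Iterable[str] | None = None,
) -> UTResult:
    """Unique/total richness of ``group``; optionally over a species subset.

    "Unique" means present in exactly one sample of this group, regardless of
    the other group.  Raises if the group has no detections (T = 0).
    """
    block = matrix.group_presence(group)
    if len(block) == 0:
        raise ValidationError(f"group {group!r} has no samples")
    if species_subset is not None:
        keys = {species_key(s) for s in species_subset}
        cols = [c for c in block.columns if species_key(c) in keys]
        block = block[cols]
    colsums = block.sum(axis=0)
    total = int((colsums >= 1).sum())
    if total == 0:
        raise ValidationError(
            f"group {group!r} has no detections in the requested species scope"
        )
    unique = int((colsums == 1).sum())
    return UTResult(unique_count=unique, total_count=total)


def _as_series(abundances) -> pd.Series:
    if isinstance(abundances, pd.Series):
        return abundances.astype(float)
    if isinstance(abundances, Mapping):
        return pd.Series(abundances, dtype=float)
    arr = np.asarray(abundances, dtype=float)
    return pd.Series(arr, index=[str(i) for i in range(arr.size)])


def shannon_index(
    abundances,
    scope_filter: Callable[[str], bool] | None = None,
    *,
    scope: str = "all",
    renormalize: bool = True,
) -> ShannonResult:
    """Shannon index H' = -sum p_i log2 p_i of a composition.

    ``abundances`` may be proportions or raw counts (a mapping/Series keyed by
    species, or a plain vector).  ``scope_filter`` restricts to a trait subset
    by species name; with ``renormalize`` (default) proportions are rescaled
    within the subset, which makes the result a proper Shannon index of the
    sub-community.  ``renormalize=False`` keeps global proportions and returns
    the subset's (non-Shannon) contribution, for sensitivity analysis only.
    Zero entries contribute nothing; all-zero input after filtering raises.
    """
    series = _as_series(abundances)
    if (series < 0).any():
        raise ValueError("abundances must be non-negative")
    if scope_filter is not None:
        series = series[[name for name in series.index if scope_filter(name)]]
    series = series[series > 0]
    if series.empty:
        raise ValueError(f"no positive abundances in scope {scope!r}")
    total = series.sum()
    p = series.to_numpy() / total if renormalize else series.to_numpy() / _as_series(abundances).sum()
    h = float(-(p * np.log2(p)).sum())
    if renormalize and series.size == 1:
        h = 0.0
    return ShannonResult(
        h_bits=max(h, 0.0) if renormalize else h,
        n_species=int(series.size),
        scope=scope,
        proper=renormalize,
    )


def unknown_diversity(
    species: Iterable[str] | None,
    catalog: SpeciesCatalog | None,
    modality: str,
    *,
    n_unidentified_otus: int | None = None,
    on_missing: str = "raise",
) -> UnknownDiversityCount:
    """Count the hitherto-unknown diversity of one sample or species set.

    For ``modality="culturomics"`` the species list is resolved in the catalog
    and counted by novelty class; for ``"metagenomics"`` the count is the
    pass-through number of unidentified OTUs and the species list must be
    omitted.  ``on_missing`` controls behaviour for species absent from the
    catalog ("raise" or "warn").
    """
    if modality == "metagenomics":
        if n_unidentified_otus is None or species is not None:
            raise ValidationError(
                "metagenomics unknown diversity needs n_unidentified_otus and no species list"
            )
        return UnknownDiversityCount(n_unidentified_otus=int(n_unidentified_otus))
    if modality != "culturomics":
        raise ValidationError(f"unknown modality {modality!r}")
    if species is None or catalog is None:
        raise ValidationError("culturomics unknown diversity needs species and catalog")
    n_new = n_not_human = n_human_not_gut = 0
    for name in species:
        rec = catalog.get(name)
        if rec is None:
            if on_missing == "warn":
                warnings.warn(f"species {name!r} not in catalog; ignored", stacklevel=2)
                continue
            raise ValidationError(f"species {name!r} not in catalog")
        if rec.novelty in NEW_TAXON_CLASSES:
            n_new += 1
        elif rec.novelty is Novelty.KNOWN_NOT_HUMAN:
            n_not_human += 1
        elif rec.novelty is Novelty.KNOWN_HUMAN_NOT_GUT:
            n_human_not_gut += 1
    return UnknownDiversityCount(
        n_new_species=n_new,
        n_not_known_human=n_not_human,
        n_known_human_not_gut=n_human_not_gut,
    )


_RANK_ATTR = {"phylum": "phylum", "class": "class_", "genus": "genus", "family": "family"}


def taxon_frequency_table(
    species: Iterable[str],
    catalog: SpeciesCatalog,
    rank: str,
    *,
    on_missing: str = "raise",
) -> pd.DataFrame:
    """Per-taxon species counts k/N within a species set at a taxonomic rank.

    Returns a frame with columns ``taxon``, ``count``, ``total``,
    ``proportion``; proportions sum to 1.
    """
    if rank not in _RANK_ATTR:
        raise ValueError(f"rank must be one of {sorted(_RANK_ATTR)}, got {rank!r}")
    attr = _RANK_ATTR[rank]
    taxa: list[str] = []
    for name in species:
        rec = catalog.get(name)
        if rec is None:
            if on_missing == "warn":
                warnings.warn(f"species {name!r} not in catalog; ignored", stacklevel=2)
                continue
            raise ValidationError(f"species {name!r} not in catalog")
        taxa.append(getattr(rec, attr) or "unclassified")
    counts = pd.Series(taxa).value_counts().sort_index()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "taxon": counts.index,
            "count": counts.to_numpy(),
            "total": total,
            "proportion": counts.to_numpy() / total,
        }
    ).reset_index(drop=True)
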