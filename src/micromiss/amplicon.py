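"""Post-processing rules for precomputed 16S OTU tables.

The pipeline consumes OTU read counts with best-hit reference identities and
applies, per sample: removal of OTUs with fewer than 20 reads, species
assignment at >= 97% identity, and the species/OTU accounting used to express
the hitherto-unknown diversity of a sample (unidentified OTUs are counted as
OTUs; the read-level assigned fraction is reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables_io import DetectionMatrix, OtuTable, normalize_species_name

__all__ = [
    "UNIDENTIFIED",
    "AmpliconSummary",
    "filter_low_count_otus",
    "assign_otus",
    "summarize_sample",
    "process_sample",
    "summaries_to_frame",
    "detection_matrix_from_summaries",
]

#: Sentinel assignment for OTUs without a species-level best hit at threshold.
UNIDENTIFIED = "UNIDENTIFIED"

MIN_READS = 20
IDENTITY_THRESHOLD = 0.97


@dataclass(frozen=True)
class AmpliconSummary:
    """Species/OTU accounting for one sample after filtering and assignment.

    Several OTUs may collapse onto one species, so
    ``len(species_detected) + n_unidentified_otus <= n_total_otus_after_filter``.
    """

    sample_id: str
    species_detected: frozenset[str]
    n_unidentified_otus: int
    n_total_otus_after_filter: int
    assigned_read_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.assigned_read_fraction <= 1.0:
            raise ValueError("assigned_read_fraction must be in [0, 1]")
        if len(self.species_detected) + self.n_unidentified_otus > self.n_total_otus_after_filter:
            raise ValueError(
                "species + unidentified OTUs exceed total OTUs after filter"
            )


def filter_low_count_otus(table: OtuTable, min_reads: int = MIN_READS) -> OtuTable:
    """Drop OTUs with ``read_count < min_reads``; row order is preserved."""
    if min_reads < 0:
        raise ValueError(f"min_reads must be non-negative, got {min_reads}")
    kept = table.rows[table.rows["read_count"] >= min_reads]
    return OtuTable(sample_id=table.sample_id, rows=kept)


def assign_otus(
    table: OtuTable, identity_threshold: float = IDENTITY_THRESHOLD
) -> dict[str, str]:
    """Map each OTU to its best-hit species or :data:`UNIDENTIFIED`.

    An OTU is assigned when it has a non-null best hit at identity >= the
    threshold (a hit exactly at the threshold is assigned); a null identity or
    null hit is never assigned.
    """
    assignment: dict[str, str] = {}
    for row in table.rows.itertuples():
        species = row.best_hit_species
        identity = row.best_hit_identity
        if (
            species is not None
            and not (isinstance(species, float) and np.isnan(species))
            and not pd.isna(identity)
            and identity >= identity_threshold
        ):
            assignment[row.otu_id] = normalize_species_name(species)
        else:
            assignment[row.otu_id] = UNIDENTIFIED
    return assignment


def summarize_sample(table: OtuTable, assignment: Mapping[str, str]) -> AmpliconSummary:
    """Collapse an assignment into per-sample species/OTU/read accounting.

    ``assigned_read_fraction`` is the read share of assigned OTUs among all
    reads surviving the filter (0 for an empty table).
    """
    missing = [otu for otu in table.rows["otu_id"] if otu not in assignment]
    if missing:
        raise KeyError(f"assignment missing OTUs: {missing[:5]}")
    species: set[str] = set()
    n_unidentified = 0
    assigned_reads = 0
    total_reads = 0
    for row in table.rows.itertuples():
        label = assignment[row.otu_id]
        total_reads += row.read_count
        if label == UNIDENTIFIED:
            n_unidentified += 1
        else:
            species.add(label)
            assigned_reads += row.read_count
    fraction = assigned_reads / total_reads if total_reads else 0.0
    return AmpliconSummary(
        sample_id=table.sample_id,
        species_detected=frozenset(species),
        n_unidentified_otus=n_unidentified,
        n_total_otus_after_filter=len(table),
        assigned_read_fraction=fraction,
    )


def process_sample(
    table: OtuTable,
    *,
    min_reads: int = MIN_READS,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> AmpliconSummary:
    """Filter, assign and summarize one sample in a single call."""
    filtered = filter_low_count_otus(table, min_reads)
    return summarize_sample(filtered, assign_otus(filtered, identity_threshold))


def summaries_to_frame(summaries: Iterable[AmpliconSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": s.sample_id,
            "n_species": len(s.species_detected),
            "n_unidentified_otus": s.n_unidentified_otus,
            "n_otus_after_filter": s.n_total_otus_after_filter,
            "assigned_read_fraction": s.assigned_read_fraction,
        }
        for s in summaries
    )


def detection_matrix_from_summaries(
    summaries: Iterable[AmpliconSummary],
    groups: Mapping[str, str] | pd.Series,
) -> DetectionMatrix:
    """Assemble a metagenomics detection matrix from per-sample summaries."""
    summaries = list(summaries)
    all_species = sorted(set().union(*(s.species_detected for s in summaries)))
    presence = pd.DataFrame(
        [[sp in s.species_detected for sp in all_species] for s in summaries],
        index=[s.sample_id for s in summaries],
        columns=all_species,
        dtype=bool,
    )
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    return DetectionMatrix(
        modality="metagenomics", presence=presence, groups=groups.reindex(presence.index)
    )
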