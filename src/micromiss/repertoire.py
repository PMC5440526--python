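"""Missing-repertoire identification and probiotic-candidate annotation.

The missing repertoire of a case group is the set of species detected in the
control group by BOTH modalities (culture and 16S amplicon sequencing) but by
NEITHER modality in the case group — viable, demonstrably present organisms
the cases have lost.  Candidate probiotics among them are flagged from the
catalog's literature-derived criteria (healthy-gut commensal, short-chain
fatty acid production, antimicrobial/antioxidant function, no toxic
products); the selection is data, not an algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .tables_io import (
    DetectionMatrix,
    GROUP_CASE,
    GROUP_CONTROL,
    SpeciesCatalog,
    ValidationError,
    species_key,
)

__all__ = ["RepertoireReport", "group_species_set", "missing_repertoire", "annotate_candidates"]


def group_species_set(
    matrix: DetectionMatrix, group: str, *, min_samples: int = 1
) -> set[str]:
    """Species detected in at least ``min_samples`` samples of ``group``."""
    block = matrix.group_presence(group)
    counts = block.sum(axis=0)
    return set(counts.index[counts >= min_samples])


def missing_repertoire(
    cult: DetectionMatrix,
    meta: DetectionMatrix,
    catalog: SpeciesCatalog | None = None,
    *,
    min_control_samples: int = 1,
) -> set[str]:
    """Species seen in controls by both modalities but in cases by neither.

    Computed as ``(cult-control ∩ meta-control) − (cult-case ∪ meta-case)``
    on case-insensitive, whitespace-normalized names.  ``catalog`` (optional)
    only fixes display names.  ``min_control_samples`` raises the bar for
    "identified in controls" above the default of one sample per modality.
    """
    for m, label in ((cult, "culturomics"), (meta, "metagenomics")):
        if not m.samples_in_group(GROUP_CONTROL):
            raise ValidationError(f"{label} matrix has no control samples")

    def keyed(names: set[str]) -> dict[str, str]:
        return {species_key(n): n for n in names}

    cult_ctrl = keyed(group_species_set(cult, GROUP_CONTROL, min_samples=min_control_samples))
    meta_ctrl = keyed(group_species_set(meta, GROUP_CONTROL, min_samples=min_control_samples))
    case_keys = {
        species_key(n)
        for n in group_species_set(cult, GROUP_CASE) | group_species_set(meta, GROUP_CASE)
    }
    missing_keys = (set(cult_ctrl) & set(meta_ctrl)) - case_keys
    out = set()
    for key in missing_keys:
        rec = catalog.get(key) if catalog is not None else None
        out.add(rec.name if rec is not None else cult_ctrl.get(key, meta_ctrl.get(key)))
    return out


@dataclass
class RepertoireReport:
    """Missing-species table with trait annotations and summary counts."""

    per_species: pd.DataFrame
    summary: dict = field(default_factory=dict)

    @property
    def missing_species(self) -> set[str]:
        return set(self.per_species["species"])

    @property
    def candidates(self) -> set[str]:
        return set(self.per_species.loc[self.per_species["candidate"], "species"])


def annotate_candidates(missing: set[str], catalog: SpeciesCatalog) -> RepertoireReport:
    """Annotate a missing-species set against the catalog.

    Species absent from the catalog are kept in the table but excluded from
    candidate evaluation (with a warning).  The summary reports the anaerobe
    share of the missing repertoire and the candidate breakdown by phylum.
    """
    rows = []
    for name in sorted(missing, key=species_key):
        rec = catalog.get(name)
        if rec is None:
            warnings.warn(
                f"species {name!r} missing from catalog; excluded from "
                "candidate evaluation",
                stacklevel=2,
            )
            rows.append(
                {
                    "species": name, "phylum": "", "class": "", "order": "",
                    "family": "", "genus": "", "obligate_anaerobe": False,
                    "candidate": False, "function": "", "in_catalog": False,
                }
            )
            continue
        rows.append(
            {
                "species": rec.name,
                "phylum": rec.phylum,
                "class": rec.class_,
                "order": rec.order,
                "family": rec.family,
                "genus": rec.genus,
                "obligate_anaerobe": rec.obligate_anaerobe,
                "candidate": rec.probiotic_flag,
                "function": rec.probiotic_function,
                "in_catalog": True,
            }
        )
    columns = [
        "species", "phylum", "class", "order", "family", "genus",
        "obligate_anaerobe", "candidate", "function", "in_catalog",
    ]
    df = pd.DataFrame(rows, columns=columns)
    for col in ("obligate_anaerobe", "candidate", "in_catalog"):
        df[col] = df[col].astype(bool)
    n_missing = len(df)
    n_anaerobic = int(df["obligate_anaerobe"].sum())
    candidates = df[df["candidate"]]
    summary = {
        "n_missing": n_missing,
        "n_anaerobic": n_anaerobic,
        "anaerobic_fraction": n_anaerobic / n_missing if n_missing else 0.0,
        "n_candidates": int(len(candidates)),
        "candidates_by_phylum": candidates["phylum"].value_counts().to_dict(),
    }
    return RepertoireReport(per_species=df, summary=summary)
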