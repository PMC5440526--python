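"""Synthetic two-group, two-modality gut-microbiota cohort generator.

Emulates the statistical structure the analysis assumes: a shared species
pool with phylum and oxygen-tolerance traits, independent Bernoulli
presence/absence per species and sample with group- and trait-dependent
detection probabilities (anaerobe depletion and Proteobacteria enrichment in
cases), per-modality detection noise to mimic culture/sequencing
discordance, and 16S read counts drawn log-normal + multinomial and split
into OTUs with best-hit identity scores so that a configurable share of
reads falls below the species-assignment threshold.

Default parameter values mirror the study conditions this generator stands
in for: 10 cases vs 5 controls, roughly 100 detected species per sample,
~3x10^5 16S reads per sample, a strong (0.3x) anaerobe detection depletion
and a 1.6x Proteobacteria enrichment in cases, and unassigned read fractions
of ~5% (cases) vs ~26% (controls).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amplicon
from .tables_io import (
    DetectionMatrix,
    GROUP_CASE,
    GROUP_CONTROL,
    Novelty,
    OtuTable,
    SpeciesCatalog,
    SpeciesRecord,
    ValidationError,
    species_key,
    write_detection_matrix,
    write_otu_tables,
    write_species_catalog,
)

__all__ = ["SynthConfig", "SyntheticDataset", "generate", "ground_truth", "write_dataset"]

_DEFAULT_MIXTURE = {
    "Firmicutes": 0.65,
    "Actinobacteria": 0.15,
    "Proteobacteria": 0.10,
    "Bacteroidetes": 0.08,
    "Fusobacteria": 0.02,
}

_NOVELTY_WEIGHTS = {
    Novelty.KNOWN_GUT: 0.86,
    Novelty.KNOWN_HUMAN_NOT_GUT: 0.04,
    Novelty.KNOWN_NOT_HUMAN: 0.05,
    Novelty.NEW_SPECIES: 0.04,
    Novelty.NEW_GENUS: 0.01,
}


@dataclass
class SynthConfig:
    """Generator parameters; defaults encode the emulated study conditions."""

    n_case: int = 10
    n_control: int = 5
    species_pool: int = 300
    fraction_anaerobic: float = 0.40
    phylum_mixture: dict = field(default_factory=lambda: dict(_DEFAULT_MIXTURE))
    detect_prob_culturomics: float = 0.30
    detect_prob_metagenomics: float = 0.33
    #: multiplier on anaerobe detection probability in cases (1 = no effect)
    anaerobe_depletion_delta: float = 0.3
    #: multiplier on Proteobacteria detection probability in cases
    proteobacteria_enrichment: float = 1.6
    unknown_fraction_control: float = 0.26
    unknown_fraction_case: float = 0.05
    reads_per_sample: int = 300_000
    #: sigma of the log-normal relative-abundance distribution
    read_abundance_dispersion: float = 2.0
    #: probability a species is invisible to one modality entirely
    modality_dropout_culturomics: float = 0.15
    modality_dropout_metagenomics: float = 0.15
    #: species forced to be control-only in both modalities (engineered truth)
    n_forced_control_only: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("need at least one sample per group")
        if self.species_pool < 1:
            raise ValidationError("species_pool must be >= 1")
        total = sum(self.phylum_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"phylum_mixture probabilities sum to {total}, expected 1"
            )
        probs = [
            self.fraction_anaerobic,
            self.detect_prob_culturomics,
            self.detect_prob_metagenomics,
            self.unknown_fraction_control,
            self.unknown_fraction_case,
            self.modality_dropout_culturomics,
            self.modality_dropout_metagenomics,
            *self.phylum_mixture.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must be in [0, 1]")
        if self.anaerobe_depletion_delta <= 0 or self.proteobacteria_enrichment <= 0:
            raise ValidationError("effect multipliers must be > 0")
        if self.reads_per_sample < 1:
            raise ValidationError("reads_per_sample must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SynthConfig
    catalog: SpeciesCatalog
    culturomics: DetectionMatrix
    metagenomics: DetectionMatrix
    otu_tables: dict[str, OtuTable]
    truth: dict


def _species_traits(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.species_pool
    phyla = list(config.phylum_mixture)
    phylum = rng.choice(phyla, size=n, p=[config.phylum_mixture[p] for p in phyla])
    anaerobe = rng.random(n) < config.fraction_anaerobic
    novelty = rng.choice(
        [nv.value for nv in _NOVELTY_WEIGHTS],
        size=n,
        p=list(_NOVELTY_WEIGHTS.values()),
    )
    n_genera = max(n // 3, 1)
    genus_idx = rng.integers(0, n_genera, size=n)
    names = [
        f"Genus{g:03d} species{i:03d}" for i, g in enumerate(genus_idx)
    ]
    return pd.DataFrame(
        {
            "species": names,
            "genus": [f"Genus{g:03d}" for g in genus_idx],
            "phylum": phylum,
            "obligate_anaerobe": anaerobe,
            "novelty": novelty,
        }
    )


def _presence(
    config: SynthConfig,
    traits: pd.DataFrame,
    detectable: np.ndarray,
    base_prob: float,
    groups: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Independent Bernoulli presence with group/trait-modified probabilities."""
    prob = np.full(len(traits), base_prob)
    case_prob = prob.copy()
    case_prob[traits["obligate_anaerobe"].to_numpy()] *= config.anaerobe_depletion_delta
    case_prob[(traits["phylum"] == "Proteobacteria").to_numpy()] *= (
        config.proteobacteria_enrichment
    )
    case_prob = np.clip(case_prob, 0.0, 1.0)
    rows = {}
    for sample_id, group in groups.items():
        p = case_prob if group == GROUP_CASE else prob
        rows[sample_id] = (rng.random(len(traits)) < p) & detectable
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=traits["species"].tolist()
    )


def _sample_otus(
    config: SynthConfig,
    sample_id: str,
    group: str,
    present_species: list[str],
    rng: np.random.Generator,
) -> tuple[OtuTable, float]:
    """Reads for one sample: log-normal abundance, multinomial reads, OTU split.

    Returns the OTU table and the realized below-threshold read fraction.
    """
    if not present_species:
        return OtuTable(sample_id=sample_id, rows=pd.DataFrame(columns=amplicon_columns())), 0.0
    k = len(present_species)
    abundance = rng.lognormal(mean=0.0, sigma=config.read_abundance_dispersion, size=k)
    rel = abundance / abundance.sum()
    reads = rng.multinomial(config.reads_per_sample, rel)
    target_unknown = (
        config.unknown_fraction_case if group == GROUP_CASE else config.unknown_fraction_control
    )
    order = rng.permutation(k)
    unknown = np.zeros(k, dtype=bool)
    acc = 0.0
    for idx in order:
        if acc >= target_unknown:
            break
        unknown[idx] = True
        acc += rel[idx]
    rows = []
    counter = 0
    realized_unknown_reads = 0
    for i, species in enumerate(present_species):
        if reads[i] == 0:
            continue
        n_otus = int(rng.integers(1, 4))
        n_otus = min(n_otus, reads[i])
        split = rng.multinomial(reads[i], np.full(n_otus, 1.0 / n_otus))
        if unknown[i]:
            identity = rng.uniform(0.90, 0.9699)
            realized_unknown_reads += int(reads[i])
        else:
            identity = rng.uniform(0.97, 1.0)
        for part in split:
            if part == 0:
                continue
            rows.append(
                {
                    "otu_id": f"{sample_id}_OTU{counter:04d}",
                    "read_count": int(part),
                    "best_hit_species": species,
                    "best_hit_identity": round(float(identity), 4),
                }
            )
            counter += 1
    table = OtuTable(sample_id=sample_id, rows=pd.DataFrame(rows))
    frac = realized_unknown_reads / max(int(reads.sum()), 1)
    return table, frac


def amplicon_columns() -> list[str]:
    from .tables_io import OTU_COLUMNS

    return list(OTU_COLUMNS)


def generate(config: SynthConfig) -> SyntheticDataset:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    traits = _species_traits(config, rng)

    sample_ids = [f"case{i + 1:02d}" for i in range(config.n_case)] + [
        f"control{i + 1:02d}" for i in range(config.n_control)
    ]
    groups = pd.Series(
        [GROUP_CASE] * config.n_case + [GROUP_CONTROL] * config.n_control,
        index=sample_ids,
    )

    detectable_cult = rng.random(len(traits)) >= config.modality_dropout_culturomics
    detectable_meta = rng.random(len(traits)) >= config.modality_dropout_metagenomics

    cult_presence = _presence(
        config, traits, detectable_cult, config.detect_prob_culturomics, groups, rng
    )
    meta_raw_presence = _presence(
        config, traits, detectable_meta, config.detect_prob_metagenomics, groups, rng
    )

    forced: list[str] = []
    if config.n_forced_control_only:
        eligible = traits.index[detectable_cult & detectable_meta]
        if len(eligible) < config.n_forced_control_only:
            raise ValidationError("not enough dual-detectable species to force control-only")
        chosen = rng.choice(eligible, size=config.n_forced_control_only, replace=False)
        forced = traits.loc[chosen, "species"].tolist()
        case_ids = groups.index[groups == GROUP_CASE]
        ctrl_ids = groups.index[groups == GROUP_CONTROL]
        for df in (cult_presence, meta_raw_presence):
            df.loc[case_ids, forced] = False
            df.loc[ctrl_ids, forced] = True

    # 16S reads are only generated for species the sequencing modality can
    # see; the final metagenomics detection matrix is what survives the OTU
    # filter + assignment rules, so low-abundance or below-threshold species
    # drop out exactly as they would in a real run.
    otu_tables: dict[str, OtuTable] = {}
    unknown_fracs: dict[str, float] = {}
    for sample_id in sample_ids:
        present = meta_raw_presence.columns[meta_raw_presence.loc[sample_id]].tolist()
        table, frac = _sample_otus(config, sample_id, groups[sample_id], present, rng)
        otu_tables[sample_id] = table
        unknown_fracs[sample_id] = frac

    summaries = [amplicon.process_sample(t) for t in otu_tables.values()]
    meta_matrix = amplicon.detection_matrix_from_summaries(summaries, groups)
    # keep forced species detected regardless of abundance draws
    if forced:
        add = [s for s in forced if s not in meta_matrix.presence.columns]
        for s in add:
            meta_matrix.presence[s] = False
        ctrl_ids = groups.index[groups == GROUP_CONTROL]
        meta_matrix.presence.loc[ctrl_ids, forced] = True
        meta_matrix.presence = meta_matrix.presence[sorted(meta_matrix.presence.columns)]

    # never-detected pool species carry no information; drop their columns
    cult_presence = cult_presence.loc[:, cult_presence.any(axis=0)]
    cult_matrix = DetectionMatrix(
        modality="culturomics", presence=cult_presence, groups=groups
    )

    catalog = SpeciesCatalog(
        [
            SpeciesRecord(
                name=row.species,
                genus=row.genus,
                phylum=row.phylum,
                obligate_anaerobe=bool(row.obligate_anaerobe),
                novelty=Novelty(row.novelty),
            )
            for row in traits.itertuples()
        ],
        warn_genus=False,
    )

    def _control_only(cult_m: DetectionMatrix, meta_m: DetectionMatrix) -> set[str]:
        def seen(m, group):
            block = m.group_presence(group)
            return {species_key(c) for c in block.columns[block.any(axis=0)]}

        keys = (seen(cult_m, GROUP_CONTROL) & seen(meta_m, GROUP_CONTROL)) - (
            seen(cult_m, GROUP_CASE) | seen(meta_m, GROUP_CASE)
        )
        return {catalog[k].name for k in keys}

    truth = {
        "anaerobe_depletion_delta": config.anaerobe_depletion_delta,
        "proteobacteria_enrichment": config.proteobacteria_enrichment,
        "unknown_fraction_case": config.unknown_fraction_case,
        "unknown_fraction_control": config.unknown_fraction_control,
        "forced_control_only": sorted(forced),
        "control_only_species": sorted(_control_only(cult_matrix, meta_matrix)),
        "realized_unknown_read_fraction": unknown_fracs,
        "seed": config.seed,
    }
    return SyntheticDataset(
        config=config,
        catalog=catalog,
        culturomics=cult_matrix,
        metagenomics=meta_matrix,
        otu_tables=otu_tables,
        truth=truth,
    )


def ground_truth(dataset: SyntheticDataset) -> dict:
    """The true group effects and realized control-only species set."""
    return dataset.truth


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all tables of a synthetic dataset as TSV (+ truth as JSON)."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": out / "catalog.tsv",
        "culturomics": out / "culturomics.tsv",
        "metagenomics": out / "metagenomics.tsv",
        "otu_tables": out / "otu_tables.tsv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "config.yaml",
    }
    write_species_catalog(dataset.catalog, paths["catalog"])
    write_detection_matrix(dataset.culturomics, paths["culturomics"])
    write_detection_matrix(dataset.metagenomics, paths["metagenomics"])
    write_otu_tables(dataset.otu_tables, paths["otu_tables"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
    dataset.config.to_yaml(paths["config"])
    return paths
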