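"""End-to-end orchestration: load tables, amplicon summaries, diversity,
test battery, missing repertoire, and a reproducible report bundle.

Every p-value in the rendered tables is also appended to a structured log
entry carrying the test name and its exact inputs, so any reported number
can be re-derived by calling the underlying module operation directly.
Outputs carry no timestamps; a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import amplicon, diversity, repertoire, smallstats
from .tables_io import (
    DetectionMatrix,
    GROUP_CASE,
    GROUP_CONTROL,
    SpeciesCatalog,
    read_detection_matrix,
    read_otu_tables,
    read_species_catalog,
)

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run_pipeline", "write_bundle"]

logger = logging.getLogger("micromiss")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    catalog_path: str
    culturomics_path: str
    metagenomics_path: str | None = None
    otu_path: str | None = None
    out_dir: str = "results/run"
    min_reads: int = 20
    identity_threshold: float = 0.97
    new_species_identity: float = 0.9865
    new_genus_identity: float = 0.95
    barnard_max_n: int = 10
    min_expected_cell: float = 5.0
    #: location test for per-sample quantitative comparisons: "t" or "mannwhitney"
    location_test: str = "t"
    group_aliases: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "WARNING"

    def validate(self) -> None:
        if not 0 <= self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in [0, 1]")
        if self.min_reads < 0:
            raise ValueError("min_reads must be non-negative")
        if self.metagenomics_path is None and self.otu_path is None:
            raise ValueError("need metagenomics_path or otu_path")
        if self.location_test not in ("t", "mannwhitney"):
            raise ValueError("location_test must be 't' or 'mannwhitney'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    summary: dict
    log: list[dict]


def _require_file(path: str | None, what: str, stage: str) -> Path:
    if path is None:
        raise PipelineError(stage, f"no {what} path configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"{what} file not found: {p}")
    return p


def _logged_test(
    log: list[dict], table_name: str, row_label: str, result: smallstats.TestResult
) -> float:
    log.append(
        {
            "table": table_name,
            "row": row_label,
            "test": result.test_name,
            "inputs": result.inputs,
            "statistic": result.statistic,
            "p_value": result.p_value,
        }
    )
    logger.info("%s / %s: %s p=%.4g", table_name, row_label, result.test_name, result.p_value)
    return result.p_value


def _beta_diversity_table(
    cult: DetectionMatrix, catalog: SpeciesCatalog, log: list[dict]
) -> pd.DataFrame:
    anaerobes = {r.name for r in catalog if r.obligate_anaerobe}
    aerotolerant = {r.name for r in catalog if not r.obligate_anaerobe}
    scopes = [("all_species", None), ("anaerobic_species", anaerobes),
              ("aerotolerant_species", aerotolerant)]
    rows = []
    for label, subset in scopes:
        try:
            case = diversity.ut_ratio(cult, GROUP_CASE, subset)
            ctrl = diversity.ut_ratio(cult, GROUP_CONTROL, subset)
        except Exception:
            continue
        table = smallstats.Contingency2x2.from_proportions(
            case.unique_count, case.total_count, ctrl.unique_count, ctrl.total_count
        )
        res = smallstats.chi2_uncorrected(table)
        rows.append(
            {
                "scope": label,
                "case": str(case),
                "control": str(ctrl),
                "delta_diversity_pct": round(100 * (ctrl.ratio - case.ratio)),
                "p_value": _logged_test(log, "beta_diversity", label, res),
            }
        )
    return pd.DataFrame(rows)


def _taxon_frequency_tables(
    matrices: Mapping[str, DetectionMatrix],
    catalog: SpeciesCatalog,
    cfg: RunConfig,
    log: list[dict],
) -> pd.DataFrame:
    rows = []
    ranks = {"culturomics": ["phylum"], "metagenomics": ["phylum", "class", "genus"]}
    for modality, matrix in matrices.items():
        case_set = repertoire.group_species_set(matrix, GROUP_CASE)
        ctrl_set = repertoire.group_species_set(matrix, GROUP_CONTROL)
        for rank in ranks.get(modality, ["phylum"]):
            case_tab = diversity.taxon_frequency_table(
                case_set, catalog, rank, on_missing="warn"
            ).set_index("taxon")
            ctrl_tab = diversity.taxon_frequency_table(
                ctrl_set, catalog, rank, on_missing="warn"
            ).set_index("taxon")
            n_case = len(case_set)
            n_ctrl = len(ctrl_set)
            for taxon in sorted(set(case_tab.index) | set(ctrl_tab.index)):
                k_case = int(case_tab["count"].get(taxon, 0))
                k_ctrl = int(ctrl_tab["count"].get(taxon, 0))
                table = smallstats.Contingency2x2.from_proportions(
                    k_case, n_case, k_ctrl, n_ctrl
                )
                test = smallstats.choose_two_proportion_test(
                    table, min_expected_cell=cfg.min_expected_cell
                )
                res = smallstats.run_two_proportion_test(table, test)
                rows.append(
                    {
                        "modality": modality,
                        "rank": rank,
                        "taxon": taxon,
                        "case": f"{k_case}/{n_case}",
                        "control": f"{k_ctrl}/{n_ctrl}",
                        "test": res.test_name,
                        "p_value": _logged_test(
                            log, "taxon_frequency", f"{modality}:{rank}:{taxon}", res
                        ),
                    }
                )
    return pd.DataFrame(rows)


def _shannon_table(
    otu_tables, catalog: SpeciesCatalog, groups: pd.Series, cfg: RunConfig, log: list[dict]
) -> pd.DataFrame:
    """Per-sample Shannon indexes from read-level assigned abundances."""
    anaerobes = {r.name for r in catalog if r.obligate_anaerobe}

    def is_anaerobe(name: str) -> bool:
        return name in anaerobes

    scopes = {
        "all": None,
        "anaerobic": is_anaerobe,
        "aerotolerant": lambda name: not is_anaerobe(name),
    }
    per_sample = []
    for sample_id, table in sorted(otu_tables.items()):
        filtered = amplicon.filter_low_count_otus(table, cfg.min_reads)
        assignment = amplicon.assign_otus(filtered, cfg.identity_threshold)
        abundances: dict[str, int] = {}
        for row in filtered.rows.itertuples():
            label = assignment[row.otu_id]
            if label != amplicon.UNIDENTIFIED:
                abundances[label] = abundances.get(label, 0) + row.read_count
        entry = {"sample_id": sample_id, "group": groups[sample_id]}
        for scope, predicate in scopes.items():
            try:
                entry[f"shannon_{scope}"] = diversity.shannon_index(
                    abundances, predicate, scope=scope
                ).h_bits
            except ValueError:
                entry[f"shannon_{scope}"] = float("nan")
        per_sample.append(entry)
    df = pd.DataFrame(per_sample)
    for scope in scopes:
        col = f"shannon_{scope}"
        x = df.loc[df["group"] == GROUP_CASE, col].dropna()
        y = df.loc[df["group"] == GROUP_CONTROL, col].dropna()
        if len(x) >= 2 and len(y) >= 2:
            if cfg.location_test == "t":
                res = smallstats.pooled_t_from_vectors(x, y)
            else:
                res = smallstats.mann_whitney_two_tailed(x, y)
            _logged_test(log, "shannon", scope, res)
    return df


def _species_presence_tests(
    matrices: Mapping[str, DetectionMatrix], cfg: RunConfig, log: list[dict]
) -> pd.DataFrame:
    """Per-species detection-frequency comparisons (small-sample exact)."""
    rows = []
    for modality, matrix in matrices.items():
        case_block = matrix.group_presence(GROUP_CASE)
        ctrl_block = matrix.group_presence(GROUP_CONTROL)
        n_case, n_ctrl = len(case_block), len(ctrl_block)
        for species in matrix.species:
            k_case = int(case_block[species].sum())
            k_ctrl = int(ctrl_block[species].sum())
            if k_case + k_ctrl == 0 or (k_case == n_case and k_ctrl == n_ctrl):
                continue
            table = smallstats.Contingency2x2.from_proportions(
                k_case, n_case, k_ctrl, n_ctrl
            )
            test = smallstats.choose_two_proportion_test(
                table,
                per_sample=True,
                barnard_max_n=cfg.barnard_max_n,
                min_expected_cell=cfg.min_expected_cell,
            )
            res = smallstats.run_two_proportion_test(table, test)
            rows.append(
                {
                    "modality": modality,
                    "species": species,
                    "case": f"{k_case}/{n_case}",
                    "control": f"{k_ctrl}/{n_ctrl}",
                    "frequency_difference": k_case / n_case - k_ctrl / n_ctrl,
                    "test": res.test_name,
                    "p_value": _logged_test(
                        log, "species_presence", f"{modality}:{species}", res
                    ),
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["p_value", "modality", "species"], kind="mergesort"
        ).reset_index(drop=True)
    return df


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full comparison and return the report bundle."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log: list[dict] = []

    stage = "load"
    catalog = read_species_catalog(
        _require_file(config.catalog_path, "catalog", stage), warn_genus=False
    )
    cult = read_detection_matrix(
        _require_file(config.culturomics_path, "culturomics detection matrix", stage),
        "culturomics",
        group_aliases=config.group_aliases,
    )

    otu_tables = None
    if config.otu_path is not None:
        otu_tables = read_otu_tables(_require_file(config.otu_path, "OTU table", stage))
        try:
            summaries = [
                amplicon.process_sample(
                    t,
                    min_reads=config.min_reads,
                    identity_threshold=config.identity_threshold,
                )
                for t in otu_tables.values()
            ]
            meta = amplicon.detection_matrix_from_summaries(summaries, cult.groups)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("amplicon", str(exc)) from exc
    else:
        meta = read_detection_matrix(
            _require_file(config.metagenomics_path, "metagenomics detection matrix", stage),
            "metagenomics",
            group_aliases=config.group_aliases,
        )
        summaries = None

    tables: dict[str, pd.DataFrame] = {}
    try:
        if summaries is not None:
            tables["amplicon_summaries"] = amplicon.summaries_to_frame(summaries)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("amplicon", str(exc)) from exc

    try:
        tables["beta_diversity"] = _beta_diversity_table(cult, catalog, log)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("beta_diversity", str(exc)) from exc

    try:
        tables["taxon_frequency"] = _taxon_frequency_tables(
            {"culturomics": cult, "metagenomics": meta}, catalog, config, log
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("taxon_frequency", str(exc)) from exc

    if otu_tables is not None:
        try:
            tables["shannon"] = _shannon_table(otu_tables, catalog, cult.groups, config, log)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("shannon", str(exc)) from exc

    try:
        tables["species_presence"] = _species_presence_tests(
            {"culturomics": cult, "metagenomics": meta}, config, log
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("species_presence", str(exc)) from exc

    try:
        missing = repertoire.missing_repertoire(cult, meta, catalog)
        report = repertoire.annotate_candidates(missing, catalog)
        tables["missing_repertoire"] = report.per_species
        repertoire_summary = report.summary
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("repertoire", str(exc)) from exc

    summary = {
        "n_samples": len(cult.samples),
        "n_case": len(cult.samples_in_group(GROUP_CASE)),
        "n_control": len(cult.samples_in_group(GROUP_CONTROL)),
        "n_species_culturomics": len(cult.species),
        "n_species_metagenomics": len(meta.species),
        "repertoire": repertoire_summary,
        "n_tests": len(log),
        "seed": config.seed,
    }
    return ReportBundle(tables=tables, summary=summary, log=log)


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every table as TSV plus summary.json and run_log.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in bundle.tables.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[name] = path
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
    paths["summary"] = out / "summary.json"
    with open(out / "run_log.json", "w") as fh:
        json.dump(bundle.log, fh, indent=2, sort_keys=True)
    paths["run_log"] = out / "run_log.json"
    return paths
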