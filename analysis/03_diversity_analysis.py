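#!/usr/bin/env python
"""Diversity of the simulated cohort: U/T beta-diversity ratios by oxygen
tolerance, per-sample Shannon indexes (all / anaerobic / aerotolerant, from
assigned read abundances), and hitherto-unknown diversity per sample.

Reads results/synthetic/; writes results/beta_diversity.tsv,
results/shannon_per_sample.tsv and results/unknown_diversity.tsv.
"""

from pathlib import Path

import pandas as pd

from micromiss import amplicon, diversity
from micromiss.smallstats import Contingency2x2, chi2_uncorrected
from micromiss.tables_io import (
    read_detection_matrix,
    read_otu_tables,
    read_species_catalog,
)

SYNTH = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    if not SYNTH.exists():
        raise SystemExit(f"{SYNTH} not found - run analysis/01_simulate_cohort.py first")
    catalog = read_species_catalog(SYNTH / "catalog.tsv", warn_genus=False)
    cult = read_detection_matrix(SYNTH / "culturomics.tsv", "culturomics")
    otus = read_otu_tables(SYNTH / "otu_tables.tsv")
    anaerobes = {r.name for r in catalog if r.obligate_anaerobe}

    # U/T beta-diversity by scope, with the uncorrected chi-square
    rows = []
    for label, subset in [
        ("all_species", None),
        ("anaerobic_species", anaerobes),
        ("aerotolerant_species", {r.name for r in catalog} - anaerobes),
    ]:
        case = diversity.ut_ratio(cult, "case", subset)
        ctrl = diversity.ut_ratio(cult, "control", subset)
        p = chi2_uncorrected(
            Contingency2x2.from_proportions(
                case.unique_count, case.total_count,
                ctrl.unique_count, ctrl.total_count,
            )
        ).p_value
        rows.append({"scope": label, "case": str(case), "control": str(ctrl),
                     "p_value": p})
        print(f"U/T {label}: cases {case} vs controls {ctrl} (chi2 p={p:.3g})")
    pd.DataFrame(rows).to_csv(OUT / "beta_diversity.tsv", sep="\t", index=False,
                              float_format="%.6g")

    # per-sample Shannon indexes from assigned read abundances
    shannon_rows = []
    for sample_id, table in sorted(otus.items()):
        filtered = amplicon.filter_low_count_otus(table)
        assignment = amplicon.assign_otus(filtered)
        abundances: dict[str, int] = {}
        for row in filtered.rows.itertuples():
            if assignment[row.otu_id] != amplicon.UNIDENTIFIED:
                abundances[assignment[row.otu_id]] = (
                    abundances.get(assignment[row.otu_id], 0) + row.read_count
                )
        entry = {"sample_id": sample_id}
        for scope, pred in [
            ("all", None),
            ("anaerobic", lambda s: s in anaerobes),
            ("aerotolerant", lambda s: s not in anaerobes),
        ]:
            try:
                entry[f"shannon_{scope}"] = diversity.shannon_index(
                    abundances, pred, scope=scope
                ).h_bits
            except ValueError:
                entry[f"shannon_{scope}"] = float("nan")
        shannon_rows.append(entry)
    sh = pd.DataFrame(shannon_rows)
    sh.to_csv(OUT / "shannon_per_sample.tsv", sep="\t", index=False,
              float_format="%.4f")
    case_h = sh[sh.sample_id.str.startswith("case")]["shannon_anaerobic"].mean()
    ctrl_h = sh[sh.sample_id.str.startswith("control")]["shannon_anaerobic"].mean()
    print(f"mean anaerobic Shannon: cases {case_h:.2f} vs controls {ctrl_h:.2f} bits "
          "(depletion recovered)" if case_h < ctrl_h else
          f"mean anaerobic Shannon: cases {case_h:.2f} vs controls {ctrl_h:.2f} bits")

    # hitherto-unknown diversity per sample (culturomics novelty classes +
    # metagenomics unidentified OTUs)
    unknown_rows = []
    for sample_id in cult.samples:
        species = cult.presence.columns[cult.presence.loc[sample_id]]
        counts = diversity.unknown_diversity(species, catalog, "culturomics")
        table = otus.get(sample_id)
        n_unid = 0
        if table is not None:
            summary = amplicon.process_sample(table)
            n_unid = summary.n_unidentified_otus
        unknown_rows.append(
            {
                "sample_id": sample_id,
                "n_new_taxa": counts.n_new_species,
                "n_not_known_human": counts.n_not_known_human,
                "n_known_human_not_gut": counts.n_known_human_not_gut,
                "culturomics_unknown_total": counts.culturomics_total,
                "n_unidentified_otus": n_unid,
            }
        )
    pd.DataFrame(unknown_rows).to_csv(OUT / "unknown_diversity.tsv", sep="\t",
                                      index=False)
    print(f"wrote beta_diversity.tsv, shannon_per_sample.tsv, unknown_diversity.tsv "
          f"under {OUT}/")


if __name__ == "__main__":
    main()
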