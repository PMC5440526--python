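#!/usr/bin/env python
"""Missing-repertoire screening, twice:

1. on the packaged published table of the 45 species found in controls by
   both modalities but never in cases - reproducing the anaerobe share and
   the 12 probiotic candidates (9 Firmicutes, 2 Bacteroidetes,
   1 Actinobacteria);
2. on the simulated cohort - intersecting both modalities' control
   detections, subtracting everything seen in cases, and checking the result
   against the generator's ground truth.

Writes results/missing_repertoire_published.tsv and
results/missing_repertoire_synthetic.tsv (+ JSON summaries).
"""

import json
from pathlib import Path

from micromiss.repertoire import annotate_candidates, missing_repertoire
from micromiss.tables_io import (
    load_missing_repertoire_catalog,
    read_detection_matrix,
    read_species_catalog,
)

SYNTH = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    # published table
    catalog = load_missing_repertoire_catalog()
    report = annotate_candidates(set(catalog.names()), catalog)
    report.per_species.to_csv(OUT / "missing_repertoire_published.tsv", sep="\t",
                              index=False)
    (OUT / "missing_repertoire_published.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True)
    )
    s = report.summary
    print(f"published repertoire: {s['n_missing']} missing species, "
          f"{s['n_anaerobic']} obligate anaerobes "
          f"({100 * s['anaerobic_fraction']:.0f}%), "
          f"{s['n_candidates']} probiotic candidates {s['candidates_by_phylum']}")

    # simulated cohort
    if not SYNTH.exists():
        raise SystemExit(f"{SYNTH} not found - run analysis/01_simulate_cohort.py first")
    synth_catalog = read_species_catalog(SYNTH / "catalog.tsv", warn_genus=False)
    cult = read_detection_matrix(SYNTH / "culturomics.tsv", "culturomics")
    meta = read_detection_matrix(SYNTH / "metagenomics.tsv", "metagenomics")
    missing = missing_repertoire(cult, meta, synth_catalog)
    synth_report = annotate_candidates(missing, synth_catalog)
    synth_report.per_species.to_csv(OUT / "missing_repertoire_synthetic.tsv",
                                    sep="\t", index=False)
    truth = json.loads((SYNTH / "ground_truth.json").read_text())
    match = missing == set(truth["control_only_species"])
    print(f"synthetic repertoire: {len(missing)} species; matches generator "
          f"ground truth: {match}")
    forced_found = set(truth["forced_control_only"]) <= missing
    print(f"all {len(truth['forced_control_only'])} engineered control-only "
          f"species recovered: {forced_found}")


if __name__ == "__main__":
    main()
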