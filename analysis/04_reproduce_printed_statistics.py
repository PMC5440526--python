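#!/usr/bin/env python
"""Recompute the study's printed test battery from its published counts and
summary statistics (the packaged tables), and compare side by side.

Every 2x2 comparison (U/T ratios, taxon frequencies, small-sample species
presence) is rerun with the test the study used (uncorrected chi-square,
two-tailed Fisher, or Barnard); every mean +/- SD comparison published as a
t-test is rerun from the summary statistics.  Mann-Whitney rows need the raw
per-sample vectors, which were not published, and are carried through with a
recomputed_p of NA.

Writes results/printed_statistics.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from micromiss import smallstats as ss
from micromiss.smallstats import Contingency2x2
from micromiss.tables_io import load_printed_counts, load_printed_summaries

OUT = Path("results/printed_statistics.tsv")


def main() -> None:
    rows = []
    for _, row in load_printed_counts().iterrows():
        table = Contingency2x2.from_proportions(
            int(row.k_case), int(row.n_case), int(row.k_control), int(row.n_control)
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = ss.run_two_proportion_test(table, row.test)
        rows.append(
            {
                "comparison": row.comparison,
                "modality": row.modality,
                "test": result.test_name,
                "published_p": row.printed_p,
                "recomputed_p": f"{result.p_value:.4g}",
            }
        )
    for _, row in load_printed_summaries().iterrows():
        if row.test != "t":
            rows.append(
                {
                    "comparison": row.label,
                    "modality": row.modality,
                    "test": "mann_whitney (raw vectors unpublished)",
                    "published_p": row.printed_p,
                    "recomputed_p": "NA",
                }
            )
            continue
        result = ss.pooled_t_two_tailed(
            row.mean_case, row.sd_case, int(row.n_case),
            row.mean_control, row.sd_control, int(row.n_control),
        )
        rows.append(
            {
                "comparison": row.label,
                "modality": row.modality,
                "test": result.test_name,
                "published_p": row.printed_p,
                "recomputed_p": f"{result.p_value:.4g}",
            }
        )
    frame = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(OUT, sep="\t", index=False)

    def close(pub, rec):
        try:
            pub_f = float(str(pub).lstrip(">"))
            rec_f = float(rec)
        except ValueError:
            return False
        return abs(rec_f - pub_f) <= max(0.1 * pub_f, 0.002)

    recomputable = frame[frame["recomputed_p"] != "NA"]
    agree = sum(close(p, r) for p, r in
                zip(recomputable["published_p"], recomputable["recomputed_p"]))
    print(f"recomputed {len(recomputable)} of {len(frame)} published statistics; "
          f"{agree} agree with the printed value to ~10%")
    print("known divergences (species-count inputs cannot reproduce them): "
          "Streptococcus genus 0.029, Euryarchaeota 0.027, Fusobacteria 0.32 "
          "(the last matches under the tail-doubling Fisher convention)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
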