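# micromiss

Severe acute malnutrition (kwashiorkor) is associated with a collapse of the
anaerobic gut microbiota. Identifying exactly *which* viable organisms are
missing from sick children — and which of them could be given back as
probiotics — requires comparing two complementary inventories of the same
stools: **culturomics** (high-throughput culture, which proves viability) and
**16S metagenomics** (which proves presence). `micromiss` implements that
dual-modality case–control comparison as a tested, reusable library for
microbiome researchers: the presence/absence diversity statistics, the
small-sample exact test battery, the OTU post-processing rules, and the
missing-repertoire / probiotic-candidate screen, exercisable end-to-end on
synthetic or published summary data.

## What it computes

* **U/T ratio** (β-diversity): for a group, U = species found in exactly one
  sample, T = all species found in the group; higher U/T means higher
  inter-individual diversity. Groups are compared with the uncorrected
  Pearson χ² on the (U, T−U) counts.
* **Shannon index** H′ = −Σ pᵢ log₂ pᵢ (bits) from assigned read abundances,
  computed over all species or renormalized within the obligate-anaerobe /
  aerotolerant subsets.
* **Hitherto-unknown diversity**: for culturomics, new taxa (at 16S identity
  < 98.65% to the nearest named species, < 95% for a new genus) plus species
  not previously known from the human gut; for metagenomics, the number of
  OTUs unassigned at ≥ 97% identity.
* **OTU rules**: drop OTUs with < 20 reads, assign species at ≥ 97% best-hit
  identity, account species / unidentified OTUs / assigned read fraction per
  sample.
* **Small-sample test battery**: uncorrected χ², two-tailed point-probability
  Fisher, **Barnard's unconditional exact test** (pooled Wald statistic T,
  p = max over the nuisance success probability π of Σ P(tables with
  |T| ≥ |T_obs|)), pooled-variance Student t (from raw vectors or printed
  mean ± SD summaries), exact-enumeration Mann–Whitney for n₁+n₂ ≤ 12, and
  the normal-theory one-sample binomial test. No multiple-testing correction
  by design.
* **Missing repertoire**: species detected in controls by *both* modalities
  but in cases by *neither* — the viable organisms the cases have lost —
  annotated against a packaged catalog of taxonomy, oxygen tolerance and
  literature-derived probiotic criteria.
* **Synthetic cohorts**: a generator with trait-dependent detection
  probabilities (anaerobe depletion, Proteobacteria enrichment in cases),
  log-normal read abundances and below-threshold identity noise, with full
  ground truth for validation.

## Worked example

Published counts are inputs: 7 of 10 cases vs 0 of 5 controls carried
*Streptococcus gallolyticus*:

```pycon
>>> from micromiss import Contingency2x2, barnard_exact_two_tailed
>>> t = Contingency2x2.from_proportions(7, 10, 0, 5)
>>> r = barnard_exact_two_tailed(t)
>>> round(r.p_value, 6), round(r.statistic, 3)
(0.014709, 2.562)
```

i.e. a two-tailed unconditional exact p ≈ 0.015 — the species is
significantly enriched in cases even at n = 15. The packaged
missing-repertoire screen:

```pycon
>>> from micromiss import load_missing_repertoire_catalog, annotate_candidates
>>> cat = load_missing_repertoire_catalog()
>>> rep = annotate_candidates(set(cat.names()), cat)
>>> rep.summary
{'n_missing': 45, 'n_anaerobic': 23, 'anaerobic_fraction': 0.511...,
 'n_candidates': 12,
 'candidates_by_phylum': {'Firmicutes': 9, 'Bacteroidetes': 2, 'Actinobacteria': 1}}
```

45 species were seen only in healthy controls; 23 (51%) are strict
anaerobes, and 12 meet the probiotic criteria.

The `analysis/` scripts run the same machinery as a narrative: simulate a
cohort (`01`), apply the OTU rules (`02`), compute diversity (`03`),
recompute the published test battery from printed counts (`04`), screen the
missing repertoire (`05`), and run the orchestrated pipeline (`06`), writing
tables under `results/`. A `micromiss` console script exposes
`run`, `synth` and `stat` subcommands, e.g.
`micromiss stat barnard --table 7,3,0,5`.

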