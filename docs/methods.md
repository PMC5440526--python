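# Methods

## Data model

Three containers cover everything the comparison needs. A **species
catalog** holds one record per species: taxonomy (phylum, class, order,
family, genus), an obligate-anaerobe flag, a novelty class, and probiotic
criteria (a flag plus a free-text function note). Novelty takes six values —
`known_gut`, `known_human_not_gut`, `known_not_human`, `new_species`,
`new_genus`, `new_family` — where the three `new_*` values are nested
refinements (a new genus is also a new species); catalogs store the most
specific class, and unknown-diversity counts treat all three as "new taxa".
A **detection matrix** is a boolean sample × species table for one modality
with a `case`/`control` label per sample. An **OTU table** is one sample's
OTU read counts with the best-hit species and identity fraction.

Species names are matched case-insensitively after whitespace collapsing,
because culture-based and sequence-based workflows format the same binomial
differently. Group vocabulary in files ("kwashiorkor", "healthy", …) is
mapped to the internal `case`/`control` labels through a user alias map, so
file vocabulary never leaks into logic. All I/O is UTF-8 TSV; detection
matrices accept a long dialect (`sample_id, group, species`) and a wide 0/1
matrix dialect, auto-detected from the header.

## OTU post-processing

OTUs were clustered and matched upstream; this package applies only the
downstream rules, per sample: remove OTUs with fewer than 20 reads
(boundary: 20 is kept), assign an OTU to its best-hit species when the hit
exists and identity ≥ 0.97 (the boundary is assigned), and count everything
else as *unidentified*. Because several OTUs can map to one species, the
number of distinct species plus unidentified OTUs never exceeds the number
of filtered OTUs — an invariant enforced by the summary type. Unknown
diversity on the sequencing side counts unidentified **OTUs**, not reads;
the read-level assigned fraction is reported separately. Filtering and
assignment are row-wise, so they commute, and the assigned read fraction is
invariant under rescaling all counts. The ≥ 20-read filter is applied to
each table as given; whether to pool samples first is the caller's choice.

## Diversity statistics

**U/T ratio.** For a group, U counts species present in exactly one of the
group's samples ("unique"), T counts species present in at least one; the
ratio U/T estimates inter-individual (β) diversity and is comparable across
groups of different size. "Unique" is judged within the group only. T = 0 is
an error, not a 0/0. Two groups are compared by a χ² on the 2×2 table
(U, T−U) per group; the rendered form is `U/T (round(100·U/T)%)`.

**Shannon index.** H′ = −Σ pᵢ log₂ pᵢ in bits (the sign convention makes H′
non-negative; single-species compositions give exactly 0). Trait-restricted
indexes (anaerobic / aerotolerant diversity) renormalize proportions within
the subset, so the result is a true Shannon index of the sub-community; an
option computes the unrenormalized subset contribution instead for
sensitivity analysis (flagged `proper=False`, since the 0 ≤ H′ ≤ log₂S
bound then need not hold). Inputs are read-level relative abundances of
assigned species; colony-count proportions can be supplied for culture data
if desired.

**Novelty thresholds.** A 16S identity below 0.95 to the nearest named
species indicates a new genus, below 0.9865 a new species; both boundaries
are strict ("under"), so a value exactly at a threshold is not novel at that
level. The classifier returns `known` above both thresholds and callers
refine `known` into the `known_*` subclasses from catalog metadata. The
classifier is monotone: higher identity is never more novel.

## Statistical tests

All tests are two-tailed and report full-precision p-values; display
rounding happens only in reports. No false-discovery-rate correction is
applied anywhere (exploratory design); a caller wanting one can apply
Benjamini–Hochberg to the logged p-values.

* **χ² (uncorrected).** Pearson χ² on the 2×2 table without continuity
  correction, df = 1; algebraically identical to the squared pooled
  two-proportion z (asserted to 1e−10 in tests). A zero column margin is
  degenerate and returns p = 1 with a warning.
* **Fisher (point-probability).** Sums hypergeometric point probabilities
  ≤ that of the observed table (with the usual 1e−7 relative tie guard).
  The tail-doubling convention is available as an option because some
  legacy software reports it.
* **Barnard (unconditional).** Statistic: pooled Wald two-proportion z,
  T = (p̂₁−p̂₂)/√(p̄(1−p̄)(1/n₁+1/n₂)); the two-tailed p-value is the
  supremum over the nuisance success probability π ∈ (0,1) of the null
  probability of {|T| ≥ |T_obs|}, computed on a 2000-point grid with
  bounded local refinement (the tail probability is a polynomial in π, so
  the refinement is a smooth 1-D maximization). Every table's "mirror"
  (n₁−x₁, n₂−x₂) has exactly equal |T|; such exact ties belong to the
  region and a small relative tolerance keeps them there against rounding
  noise. An unpooled (Welch-style) variant is available behind a flag.
  scipy's implementation — which takes table *columns* as the two binomial
  samples — agrees to 1e−7 once the table is transposed accordingly.
* **Pooled t.** Student t with pooled variance, df = n₁+n₂−2, from raw
  vectors or directly from printed mean ± SD summaries (both routes agree
  exactly). Zero variance in both groups degenerates to p = 1 (equal
  means) or p = 0 with a warning.
* **Mann–Whitney.** For n₁+n₂ ≤ 12 the permutation null is enumerated
  exactly over all C(n₁+n₂, n₁) assignments of pooled mid-ranks, with
  p = P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|); ties are handled by mid-ranks.
  Larger samples use the normal approximation with tie correction.
* **One-sample binomial (normal theory).** z = (k/n − p₀)/√(p₀(1−p₀)/n).
  Provided generically; the analysis that motivated it did not publish its
  k, n, p₀, so no specific invocation is reproduced.

**Test auto-selection** in the pipeline mirrors the mixed usage of
small-cohort microbiota studies: per-sample presence comparisons with both
group sizes ≤ 10 get Barnard; other 2×2 tables get Fisher when the minimum
expected cell is < 5 and the uncorrected χ² otherwise. The rule is fully
overridable per comparison.

Two published values deliberately excluded from the reproduction battery:
the genus-level *Streptococcus* χ² (printed 0.029; species counts give
0.153) and the *Euryarchaeota* Fisher (printed 0.027; point-probability
gives 0.041) — no standard convention reproduces them from the printed
species counts, suggesting they were computed on different inputs. The
*Fusobacteria* entry (printed 0.32) matches only the tail-doubling Fisher
convention, which is why that option exists.

## Missing repertoire

The missing repertoire is (culturomics-control ∩ metagenomics-control) −
(culturomics-case ∪ metagenomics-case): species whose viability *and*
presence are both demonstrated in controls, and which no method saw in any
case sample. Subtracting the union is deliberate — a species seen by either
method in cases is demonstrably not missing. Presence in one control sample
per modality suffices by default (a `min_control_samples` knob raises the
bar). Candidate probiotics are flagged from the catalog, not computed: the
selection criteria (persistent viability in a healthy gut, no toxic
products such as lithocholate, symbiosis with resident flora,
butyrate/propionate production, anti-pathogenic bacteriocins) are
literature-based, so they live in a packaged criteria table rather than in
code.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
defaults at the emulated study's scale: 10 cases vs 5 controls; a
300-species pool (≈ 250 detected overall, ≈ 100 per sample at detection
probability ≈ 0.3); 40% obligate anaerobes; a phylum mixture dominated by
Firmicutes (0.65) with Actinobacteria 0.15, Proteobacteria 0.10,
Bacteroidetes 0.08, Fusobacteria 0.02; 3×10⁵ 16S reads per sample;
anaerobe detection multiplied by 0.3 in cases (matching the ≈ 2-bit
anaerobic Shannon gap); Proteobacteria detection multiplied by 1.6 in
cases; and below-assignment-threshold read fractions of 0.05 (cases) vs
0.26 (controls).

Presence is independent Bernoulli per species × sample — the statistics
under test are all presence/count-based and assume no co-occurrence
structure, so none is simulated. Read counts are log-normal relative
abundances (σ = 2) drawn per present species and partitioned
multinomially over the read budget, then split into 1–3 OTUs each;
"unknown" species are accumulated in random order until their abundance
share reaches the group's target and receive identities in [0.90, 0.97).
Each modality independently drops 15% of the pool entirely, emulating
culture/sequencing discordance. The metagenomics detection matrix is
defined as what survives the OTU filter and assignment rules, so
low-abundance species drop out exactly as in a real run. A configurable
number of species can be forced control-only in both modalities to give
the repertoire step an engineered ground truth. Everything is
deterministic given the seed.

What the generator does **not** emulate: phylogenetic or co-occurrence
structure, chimeras and contamination, compositional coupling between
species abundances, strain-level variation, or longitudinal dynamics.
Passing tests on synthetic data therefore validate the *bookkeeping and
inference machinery* under the stated model, not robustness to real-data
artifacts.

## Numerical and design choices

* Barnard's grid has 2000 points plus refinement; 500 points already agree
  with a brute-force double loop to 1e−9 on small tables.
* Published p-values are asserted to within one unit in the last printed
  digit: the source tables' rounding convention is unstated, and the
  Barnard entry printed as 0.014 against a computed 0.014709 is consistent
  only with truncation, so the honest reading of a printed value v with
  last-digit unit u is v ≤ p < v + u (rounding would give |p − v| ≤ u/2);
  the union of both conventions is |p − v| < u.
* The generator's null-calibration check uses equal group sizes: U/T falls
  with sample count, so exchangeability of the two groups under a zero
  effect requires n₁ = n₂. The χ² on U/T counts is mildly conservative
  (the two rows share species), so the asserted property is that the
  empirical size does not exceed the nominal level beyond Monte-Carlo
  error.
* Problem sizes in the test-suite simulations — 200 seeds for
  effect-direction recovery, 10,000 null tables for the Barnard size
  check, exhaustive Fisher-oracle enumeration to N = 40, exact
  Mann–Whitney enumeration to n₁+n₂ = 12 — were chosen so each check's
  Monte-Carlo or enumeration error is far below the margins being
  asserted while the whole suite stays desk-scale.

## Known limitations

* Name reconciliation between culture and sequence inventories is by
  normalized string matching plus a user alias map; no taxonomy service is
  consulted, so true synonyms spelled differently will not merge unless
  aliased.
* The exact Mann–Whitney branch enumerates combinations and is
  intentionally capped at n₁+n₂ = 12.
* The per-sample presence Barnard battery is exact but treats species
  independently; with hundreds of species, individual small-sample
  p-values are exploratory (no FDR correction, by design).
* Raw per-sample species lists behind the published tables were never
  deposited, so group-level statistics that need raw vectors
  (Mann–Whitney rows, per-sample Shannon values) can only be reproduced on
  synthetic data, not recomputed from the publication.
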