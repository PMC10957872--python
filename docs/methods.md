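# Methods

## TLS detection and grading

Input is a table of segmented-cell centroids (µm) with boolean marker calls
per cell; no pixel data is touched. Aggregates are defined graph-
theoretically: cells are vertices, and an edge joins any pair whose
centroid distance is **at most** the contact distance. Aggregates are the
connected components of this graph (computed with a k-d tree and sparse
connected components; a brute-force BFS over the full distance matrix
serves as the test oracle). Output order is fixed by the smallest member
id, so detection is fully deterministic.

**Contact distance.** Histologically, "contact" means a small
membrane-to-membrane gap (~3 µm). Because only centroids are available,
the default centroid threshold is 3 µm + 2 × (nominal cell radius 6 µm) =
**15 µm**; both the gap and the radius are configurable through
`TlsThresholds.contact_distance_um`. A 3 µm *centroid* threshold would be
physically impossible for ~10 µm cells.

**Measurement.** Aggregate size is the maximum Feret diameter — the
largest pairwise centroid distance — matching how a pathologist measures
the extent of a structure. Aggregate area is the convex hull of the member
centroids (µm² → mm²); fewer than three non-collinear members give a
zero-area hull flagged degenerate. Composition counts come from marker
logic (follicular DCs = CD21⁺ ∧ CD23⁺).

**Classification.** An aggregate is a TLS candidate only if *all* of:
`n_cells > 50` (strict, "more than 50"), Feret ≥ 250 µm (inclusive),
CD20⁺ fraction > 0.5 (strict majority), ≥ 1 CD4⁺ and ≥ 1 CD8⁺ cell. With
≥ 1 follicular DC it is mTLS, otherwise eTLS. Every criterion's outcome is
recorded in a rule trace so a call can be audited. All cut-offs live in
`TlsThresholds`.

**Localization.** By aggregate centroid: within the margin band
(default 500 µm, configurable — the width of the invasive margin is a
modelling choice, not a measured quantity) of the core boundary → margin,
regardless of which side; else inside core → core; else inside stroma →
stroma; otherwise unassigned (with a warning if the centroid leaves the
tissue polygon).

## Compartmental densities

Compartments: TME (whole tissue polygon, TLSs included), eTLS and mTLS
(unions of the respective hulls, clipped to tissue for the nTLS remainder),
nTLS (tissue minus all TLS hulls), plus core and stroma region polygons.
TLS compartment membership is **by aggregate membership**, not by
point-in-hull: a cell counts toward the eTLS compartment iff it belongs to
an eTLS aggregate, and nTLS counts are TME counts minus TLS member counts.
This makes the partition identity
`count(TME) = count(nTLS) + count(eTLS) + count(mTLS)` exact by
construction instead of approximately true up to boundary cells. Core and
stroma use point-in-polygon on centroids (boundary inclusive) and sit
outside the partition. Densities are `count / area_mm2`; zero-area
compartments are omitted with a warning. Counts are exact integers; areas
come from shapely polygon arithmetic.

Patient clusters: CL1 = no TLS, CL2 = eTLS only, CL3 = any mTLS. A patient
with mTLS but no eTLS maps to CL3 (maturity dominates); the combination is
biologically unusual but the mapping must be total.

## Panel TMB

The cascade runs in a fixed order; each variant receives exactly one
verdict:

1. **database** — removed if any of the three population allele counts
   (gnomAD exome, gnomAD genome, 1000 Genomes) is ≥ 10. Raw integer allele
   counts, not frequencies.
2. **proximity** — a surviving variant is removed when ≥ 5 of the
   *database-removed* variants share its chromosome with |ΔVAF| ≤ 0.05.
   Decisions are evaluated simultaneously against the frozen
   database-removed set; removals never cascade into further removals. The
   AF tolerance is not fixed by any published value, so it is an explicit
   `TmbConfig` parameter (default 0.05) echoed into output metadata, and
   the comparison uses chromosome + AF only (no genomic-distance window).
3. **high AF** — removed if VAF ≥ 0.90 (likely germline homozygous).
4. **eligibility** — counted if in the coding region, an SNV or indel
   (MNVs excluded), synonymous or nonsynonymous, VAF ≥ 0.05, depth ≥ 50
   and COSMIC count < 50.

`TMB = eligible / effective panel size`, in mut/Mb. The denominator sums
panel intervals with mean coverage **strictly** > 50× that are not flagged
low-confidence. The numerator's coverage rule is inclusive (≥ 50×) while
the denominator's is strict — the asymmetry is preserved deliberately
because the two rules are stated differently. Intervals are 0-based
half-open internally; VCF positions are 1-based at the boundary and the
VCF reader takes a configurable INFO-key mapping for VAF, depth, type,
consequence, database counts and COSMIC.

## Expression QC and signature scoring

Spot/sample QC removes samples with mitochondrial-count fraction
strictly > 0.30 or strictly fewer than 300 detected genes (mitochondrial
genes by prefix `MT-` or explicit list); gene QC drops genes with nonzero
counts in fewer than 5 samples. Both filters are idempotent.

Signature scores are intentionally simple and tagged by method:
`mean_log` = per-sample mean of log1p expression over the signature genes
present; `zmean` = mean of gene-wise z-scores (constant genes contribute
0). For scoring, counts are library-size normalized to counts per 10⁴
(`normalize_cp10k`) and log-transformed; regression-based normalizations
such as SCTransform are published methods outside this package's scope,
so no claim is made of bit-level agreement with them — the method tag
travels with every score. Missing signature genes are reported and only
fatal when *no* gene is present. The 12-chemokine TLS signature is built
in; population marker sets for abundance estimation are user-supplied
configuration. Over-representation uses the hypergeometric upper tail
P(X ≥ overlap).

## Survival and association statistics

Median stratification labels a subject Hi iff its value is strictly above
the cohort median, so "Hi" always means higher-than-median; ties go Lo
(configurable by choosing a different statistic upstream). Kaplan–Meier,
log-rank and Cox fits delegate to lifelines; Cox uses Efron tie handling
(the conventional default) and Wald inference, with CIs computed as
exp(β ± 1.96·SE). A label-permutation log-rank p-value (vectorized over
permutations, seeded) is provided for small cohorts where the chi-square
approximation is doubtful. Mann–Whitney and Wilcoxon use exact enumeration
at small sizes (n+m ≤ 12, n ≤ 15) and the normal approximation otherwise;
Fisher's exact test is always exact; all p-values are two-sided.
Benjamini–Hochberg adjustment is the standard step-up with monotonicity
enforcement, capped at 1. (Note BH is *not* idempotent as a function —
re-adjusting adjusted p-values inflates them — so adjusted values are
clearly labelled in outputs.)

## Synthetic data: what it emulates, and what it does not

The generators produce the statistical *structure* the pipeline consumes,
with recorded ground truth; they do not attempt biological realism beyond
that.

- **Tissue** (`generate_tissue`): background cells are uniform over the
  tissue polygon (simplest null spatial process); each planted aggregate
  sits on a jittered hexagonal lattice clipped to a disc, filled row by
  row from the central row outward. This fill order guarantees that any
  prefix of n cells is connected at the lattice spacing (default 12 µm,
  jitter small enough to keep worst-case neighbor distance under the 15 µm
  contact distance) and that the central row realizes the requested disc
  diameter, so planted aggregates are single components with a controlled
  Feret diameter. Marker roles (B, fDC, CD4, CD8) are assigned to exact
  planned counts and shuffled. Background cells are excluded from a halo
  of two contact distances around each planted disc, and planted discs
  closer than two contact distances to each other are rejected: both rules
  exist so that recorded ground truth can never be corrupted by chance
  adjacency. The intended class and localization of each planted aggregate
  are recorded by running the classification rules on the planted cells
  themselves — ground truth is a construction record, not a separate
  labelling. Real tissue differs in ways that do not matter for testing
  the rules: cells are not lattice-packed, marker calls are noisy, and
  aggregates have irregular shapes; passing tests therefore validate the
  *algorithms*, not segmentation or staining quality.
- **Variants** (`generate_variant_table`): each requested category is
  constructed to be resolved by exactly one rule — database decoys on a
  dedicated chromosome near VAF 0.5, proximity victims placed among them,
  every other category isolated on its own chromosome so no rule fires by
  accident. The cascade re-derives the recorded verdicts exactly (tested).
- **Expression** (`generate_expression`): negative-binomial counts with
  mean 10 and dispersion 0.5 (variance = µ + φµ², overdispersion typical
  of sequencing counts; both configurable), with the signature genes'
  mean multiplied by exp(effect) in a random Hi fraction of samples.
- **Survival** (`generate_survival`): balanced binary covariate,
  exponential event times with baseline hazard ln 2 / 24 months (24-month
  median survival in the reference group) scaled by exp(log HR) in the
  exposed group. Censoring is an *independent* exponential time whose rate
  is solved numerically so the expected censored fraction matches the
  request — coupling the censoring time to the event time would violate
  independent censoring and bias hazard-ratio recovery.

All generators draw every random quantity from one integer seed;
identical spec + seed gives byte-identical output.

## Numerical and design notes

- Proximity-graph edges are inclusive (distance = threshold connects), so
  chains spaced exactly at the contact distance form one component.
- Density tables satisfy `density × area = count` to machine precision;
  written output rounds areas to 6 significant digits.
- The pipeline writes a manifest echoing the full configuration and its
  SHA-256; reruns with identical config and inputs are byte-identical
  (no timestamps in any output).
- Problem sizes in the acceptance script (100 tissues, 1000 variant
  tables, 200 Cox cohorts of n = 300, 20 log-rank cohorts with 10⁵
  permutations each) were chosen to make sampling error small relative to
  the checked tolerances while keeping a single-CPU run in tens of
  seconds.
- The permutation log-rank p includes the observed labelling in the count
  (p ≥ 1/(B+1)), the standard bias-avoiding convention.

## Known limitations

- Marker positivity is consumed as boolean input; intensity thresholding,
  segmentation and registration quality are upstream concerns.
- The convex hull overestimates the area of markedly non-convex
  aggregates; an alpha-shape alternative would need a shape parameter and
  is not currently implemented.
- Aggregates with > 50 cells but under 250 µm are reported as `not_tls`
  with their rule trace; no separate "immune aggregate" grade is assigned.
- Signature scores are not calibrated across datasets; compare within a
  cohort only.
- Multivariate Cox accepts any covariate set from the survival table, but
  no covariate pre-selection or proportional-hazards diagnostics beyond
  lifelines' convergence checks are run.
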