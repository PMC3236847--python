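# Methods

## The model

The input is a gene × organ matrix of expression-tag counts (EST-style:
each tag is one sequencing read attributed to a gene cluster and to the
organ its library came from).  Write `x_ij` for the count of gene *i* in
organ *j*, `K_i = Σ_j x_ij` for the gene total, `M_j = Σ_i x_ij` for the
organ total and `N` for the grand total.

Conditioning on the margins, each of gene *i*'s `K_i` tags is treated as
an independent Bernoulli trial that lands in organ *j* with probability
`p = M_j / N`; under the null hypothesis that gene and organ are
independent, `x_ij ~ Binomial(K_i, p)`.  Per cell the package computes:

- **AE** (absolute expression): the observed count `x_ij`.
- **EE** (expected expression): `K_i · M_j / N`.
- **RE** (relative expression): `AE / EE`, the fold-enrichment over the
  independence expectation.  Convention: an all-zero cell has RE = 0; a
  positive count with EE = 0 is impossible on a consistent matrix and
  raises.
- **p-value**: the exact binomial upper tail
  `P(X ≥ x_ij) = Σ_{k=x}^{K} C(K,k) p^k (1−p)^{K−k}`, with enrichment as
  the one-sided alternative.  Evaluated through the regularized
  incomplete beta function (scipy), which is accurate in the far tail;
  an exhaustive test checks agreement with brute-force exact rational
  summation for all `x, K ≤ 30` to 1e-12 relative error.
- **AZ** (absolute z-score): the binomial standardization
  `(x − Kp) / sqrt(Kp(1−p))` — how many null standard deviations the
  observed count sits above its expectation.
- **RZ** (relative z-score): the standardization of gene *i*'s RE
  profile across organs, `(RE_ij − mean_j RE_i·) / sd_j(RE_i·)`, using
  the population standard deviation.  A flat profile (sd = 0) maps to
  RZ = 0 so ubiquitously expressed genes never look specific.

AZ grows with the sheer amount of evidence (sampling depth), RZ with the
*shape* of the cross-organ profile; the p-value complements RZ with an
exact account of discreteness at small counts.

### The RZ geometry — a hard bound worth knowing

The maximum population z-score within a sample of *n* values is
`sqrt(n − 1)` (attained when one value carries all the variance).  RZ is
therefore bounded by `sqrt(n_organs − 1)` no matter how extreme the
enrichment:

- a single-organ spike over *n* organs has RZ → `sqrt(n − 1)` in
  expectation, independent of the fold;
- a gene split equally over two of 52 organs caps at
  `sqrt(50/2) = 5` exactly — which is why, at RZ ≥ 5, multiple-organ
  (relative) OSGs vanish while single-organ calls survive;
- an RZ ≥ 4 cutoff is reachable only with ≥ 17 organs, and comfortably
  so only well above that.  A 10-organ compendium has max RZ = 3:
  *no* cell can pass RZ ≥ 4, whatever the counts.  The packaged
  10-organ `recovery_fixture` documents this regime; recovery
  demonstrations at the default thresholds use the 52-organ
  `demonstration_fixture`.

## Classification and thresholds

A cell qualifies when all four criteria hold: `p ≤ 1e-5`, `RZ ≥ 4`,
`RE ≥ 4`, `AE ≥ 10` (defaults, all overridable).  A gene qualifying in
exactly one organ is an **absolute** (single-organ) OSG; in two or more,
a **relative** (multiple-organ) OSG.

**Threshold pairing.**  Candidate RZ cutoffs `z` are tied to p-value
cutoffs by rounding the standard-normal upper tail down to a power of
ten: `10^floor(log10(1 − Φ(z)))`.  For z = 2…6 the tails are 2.28e-2,
1.35e-3, 3.17e-5, 2.87e-7, 9.87e-10, giving the ladder (1e-2, 2),
(1e-3, 3), (1e-5, 4), (1e-7, 5), (1e-10, 6).

**Calibration** derives all four cutoffs from the data:

1. `min_AE` = mean AE over all cells, rounded half-up;
2. `min_RE` = mean RE over cells passing the AE cutoff, rounded half-up;
3. among the ladder pairs, the loosest whose absolute-OSG share reaches
   the purity target (default 95%) is selected — "more OSGs is better",
   subject to purity.  If no pair qualifies, calibration fails loudly,
   carrying the per-pair comparison table.

Rounding is half-up (9.56 → 10, 3.85 → 4) rather than banker's, matching
how such cutoffs are conventionally reported.

**Top-gene ranking** within an organ is by RZ descending (RZ is the
specificity axis), ties broken by smaller p-value then lexicographic
gene id; the metric is deliberately simple and documented rather than
clever, and the ranking column can be changed by sorting the score table
differently.

## Ingest

The dump dialect is one row per EST with library metadata columns
("dbEST ID", "EST name", "GenBank Acc", "Lib Name", "Tissue type",
"Organ", optional "Organism" and "Lib ID"); header synonyms are
configurable and '#' lines are comments.  Organ assignment precedence:
wrong organism → explicit drop-list → mixed-library regex markers
(pooled libraries can never be assigned an organ) → direct organ field →
tissue→organ map lookup on the tissue type, then on library-name
unigrams/bigrams → dropped as unresolvable.  Mixed-library detection is
input-driven (drop lists and regex patterns), not heuristic: pooled
libraries are a curation fact, not something to guess from free text.

Organ filtering removes organs with fewer than 100 detected genes
(nonzero cells — "detected", not vocabulary size) **or** fewer than 300
tags; both boundaries are inclusive for retention.  Margins, including
`N`, are recomputed on the surviving submatrix so `p = M/N` stays a
proper probability over retained organs.  The filter is idempotent.

External specificity records (SPM-style scores in [0, 1]) are filtered
at score **strictly greater than** 0.9, the conventional cut for
tissue-specific genes.

## Ordinal (protein-atlas-style) annotations

The eight ordinal labels are digitized on a 0–9 scale — None 0,
Negative 1, Low 2, Weak 3, Medium 5, Moderate 6, High 7, Strong 9 —
strictly increasing along the ordinal ladder, with gaps encoding
perceived distances between adjacent labels.  Digitized scores are
treated as pseudo-counts and passed through the same binomial machinery.
This is an approximation, made explicit: the z-scores (AZ, RZ) are
meaningful rankings on any nonnegative matrix, but exact binomial
p-values presume count sampling, which pseudo-counts are not — treat
those p-values as scores, not calibrated probabilities.  Missing cells
default to 0 ("None"); duplicated cells are an error, not a silent
overwrite.

Concordance between two OSG call sets is sets-based: of the genes called
in both, the fraction whose organ sets intersect.  This sidesteps any
tie-breaking among equally annotated organs.

## Disease linkage

Markers are OSGs with at least one disease associated both with the gene
(gene–disease table) and with the same organ (disease–organ table),
matched on disease identifier only.  Marker records are a subset of OSG
calls by construction.  Disease–organ rows naming organs outside the
working vocabulary are retained with a warning — anatomical
vocabularies are richer than any fixed organ list, and dropping them
would silently lose evidence.  No ontology reasoning or term propagation
is performed; hierarchy exports are consumed flat (both child and parent
identifiers contribute).

## Gene sets

One GMT set per organ with ≥ 1 OSG; relative OSGs appear in every organ
they qualify in.  Random non-specific control sets draw, without
replacement and under a mandatory seed, from genes that are either in
the bottom half of the target organ's RZ ranking ("sufficiently lower
ranked"; the fraction is configurable) or OSGs of other organs only —
never the target's own OSGs.  Control sets default to the target set's
size so downstream normalized-enrichment comparisons are size-matched.
The CLS writer emits the standard "n k 1" header.

## The synthetic-data generator

`simulate_counts` allocates a fixed total of tags multinomially over
cells with rates ∝ `abundance_i × weight_j × fold_ij`, `fold > 1` only
on planted markers.  Multinomial allocation (rather than independent
Poisson cells) matches the fixed-`N`, conditioned-margin structure of
the binomial model.  Gene abundances default to log-normal(0, 1) —
heavy-tailed, as tag counts per gene are in practice; organ weights
default to uniform.  Planted genes are placed on evenly spaced
quantiles of the 30th–90th abundance percentiles so every marker is
comfortably detectable (expected planted counts ≥ 30) without being
uniformly extreme.

What the generator does *not* emulate: library-size overdispersion,
cross-organ correlation of gene programs, mapping ambiguity between
accessions and gene clusters, and curation noise in organ labels.
Passing recovery tests therefore show that the statistics and
classification behave correctly under the stated sampling model — not
that real compendium curation is solved.

Standard fixtures (sizes chosen so the full suite and the acceptance
script run in seconds while keeping planted effects well inside the
detectable regime):

- `recovery_fixture`: 200 genes × 10 organs, 20 markers at fold 20,
  100,000 tags — the RZ-capped regime (see above).
- `demonstration_fixture`: 300 genes × 52 organs, 20 markers at fold
  20, 200,000 tags — recovery at the default thresholds reaches
  sensitivity and precision ≈ 1.
- `calibration_fixture`: 400 genes × 52 organs, 40 single-organ markers
  (fold 20) plus 20 two-organ markers (folds 20/12).  The two-organ
  minor cells sit between the RZ ≥ 3 and RZ ≥ 4 cutoffs by
  construction (expected minor RZ ≈ 3.5), so absolute-OSG purity is
  ~75% at the loose pairs and first reaches 95% at (1e-5, 4) — the pair
  calibration then selects.

Under the null (no planted markers) the empirical distribution of exact
binomial p-values is stochastically ≥ uniform (discreteness makes the
test conservative); a one-sided Kolmogorov–Smirnov check over 50 seeds
guards this.

## Numerical choices

- Binomial tails via `scipy.stats.binom.sf` (incomplete beta): no
  underflow for large `K`, full double precision; displayed at ≥ 6
  significant digits in TSV output.
- Population (ddof = 0) standard deviation for RZ; zero-variance rows
  map to RZ = 0.
- Degenerate cells: organs with `M = 0` (possible only before organ
  filtering) get EE = 0, RE = 0, AZ = 0, p = 1 for their
  necessarily-zero cells; genes with `K = 0` are skipped with a warning
  since all their statistics are undefined.
- Ties in top-gene ranking break deterministically (p-value, then gene
  id) so outputs are byte-reproducible.
- All sampling (simulation, control sets) flows through
  `numpy.random.default_rng(seed)`; no global random state.

## Known limitations

- The RZ bound makes the default thresholds organ-count-dependent;
  compendia with few organs need a lower RZ cutoff (or more organs),
  and the package intentionally does not auto-rescale it.
- Pseudo-count p-values on ordinal data are heuristic (above).
- The gene identifier space is treated as opaque and single; collapsing
  between identifier systems (gene clusters vs. gene ids) is out of
  scope.
- Mixed-library detection relies on supplied patterns/drop lists; there
  is no NLP over library descriptions.
- Enrichment analysis itself (ES/NES/FDR) is external; the package only
  prepares GMT/CLS inputs.
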