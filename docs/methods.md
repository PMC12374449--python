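# Methods

This note documents the statistical procedures the package implements, the
design choices made where the problem was genuinely open, the synthetic
data model used to verify everything, and the limits of what passing tests
demonstrate.

## Unit of observation and populations

The unit throughout is the **spot** — a barcoded capture location holding
several cells, not a single cell. All "per-cell" language from
single-cell workflows maps to per-spot here; load comparisons and risk
tables are reported per spot, which is the resolution the data supports.
Spot-level QC removes spots with a mitochondrial read fraction strictly
above 40% before any analysis. The viability risk screen and the
presence–expression correlations run on CD spots only by default
(controls can be included via `population="all"` for sensitivity
analysis); quantification runs on all groups.

## Decontamination cascade

Four conjunctive per-species rules, with defaults
`min_spatial_reads = 50`, `min_bulk_reads = 50`,
`max_spatial_bulk_ratio = 1.5`, `min_double_survival = 0.02`:

1. total spatial reads `< 50` across all spots of all samples → excluded;
2. total matched bulk metagenome reads `< 50` → excluded (species absent
   from the bulk table count as zero and are logged);
3. spatial read share / bulk read share `> 1.5` → excluded. The share
   ("read percentage") denominator is the total classified bacterial reads
   *within each technology*, pooled across samples — the only basis on
   which the two percentages are commensurable. A per-sample-mean variant
   is available (`percentage_basis="per_sample_mean"`). A species seen
   spatially but absent from bulk has ratio +∞ (excluded); one absent from
   both leaves the ratio undefined and passes this rule, since the floors
   already remove it;
4. double-removal survival `double_total / single_total < 0.02` →
   excluded. Human-read artifacts collapse under a second human-read
   alignment pass; genuine gut species only shrink moderately.

Every inequality is strict exactly as written: 49 reads fail a floor of
50, a ratio of exactly 1.5 and a survival of exactly 0.02 pass. All four
rules are evaluated for every species (no short-circuiting) so the report
is an audit trail; the verdict is their conjunction, which also makes the
retained set independent of evaluation order. Downstream analyses use the
**single-removal** counts of retained species, because double removal also
depresses genuine species. Raising a floor, raising the survival
threshold, or lowering the ratio bound can only shrink the retained set (a
tested monotonicity property).

## Bacterial load and co-localization

Load is CPM: a spot's reads of retained species divided by its total
sequencing reads, ×10⁶. Group and area contrasts use the two-sided
Wilcoxon–Mann–Whitney test; groups are summarised as mean ± SEM
(sd/√n, reported missing for n < 2) with stars at p < 0.05 / 0.005 /
0.0005. The rank-sum implementation uses exact permutation enumeration
(tie-aware, via mid-ranks) when both groups have ≤ 8 observations and the
tie-corrected normal approximation otherwise; the signed normal-scale z is
always reported.

Co-localization of species *s* with cell type *c* is
`w(s,c) = Σᵢ fractions[i,c] · counts[i,s]` over spots; because fraction
rows sum to one, `Σ꜀ w(s,c)` equals the species' total read count exactly
(a tested conservation law). Row-normalising gives a co-localization
probability profile per species (missing for zero-read species). The
beneficial-vs-pathogenic per-cell-type contrast is
`log2(mean beneficial probability / mean pathogenic probability)` with a
half-minimum-nonzero pseudo-probability against zeros, a rank-sum p per
cell type, BH-adjusted across cell types.

Per-patient prognosis summaries are the mean load over the patient's
spots, with Spearman correlations against the Rutgeerts score (all scored
patients) and time to relapse (relapse patients only); fewer than 3 pairs
leaves the correlation not computable. These correlations are a
convenience summary of an ordering, not a causal estimate.

## Viability risk

A spot is damaged when its mitochondrial fraction exceeds 10% (exactly
10% is viable) — the standard stress/viability proxy. Exposure is ≥ 1
read of the species in the spot (configurable). Per species the 2×2
table (a = damaged∧exposed, b = viable∧exposed, c, d unexposed
analogues) gives

- RR = (a/(a+b)) / (c/(c+d));
- 95% CI by the Katz log method, `exp(ln RR ± 1.96·SE)` with
  `SE = √(1/a − 1/(a+b) + 1/c − 1/(c+d))` — chosen for its closed form
  and standard use where no method is otherwise dictated;
- two-sided p from `z = ln RR / SE`, BH-adjusted across evaluable
  species; q < 0.05 defines the beneficial (RR < 1) and pathogenic
  (RR > 1) sets consumed by the expression and PCA stages;
- `PARP = 100 · P(RR−1)/(P(RR−1)+1)` with `P = (a+b)/n` — the share of
  tissue-wide damage attributable to (or, when negative, prevented by)
  the exposure. PARP is 0 at RR = 1, strictly increasing in P for
  RR > 1 and strictly decreasing for RR < 1.

A zero in a or c triggers the Haldane–Anscombe 0.5 correction of all four
cells, flagged in the output; an empty exposed or unexposed margin makes
the species non-evaluable. The screen pools spots across patients without
a patient-level random effect — a deliberate reproduction of the pooled
computation, and a known caveat: within-patient correlation makes the
intervals anticonservative on real data. The strain-level screen is the
identical computation on strain labels, plus a low-exposure flag
(< 10 exposed spots) and the fraction of species reads resolved to
strains.

## Expression response

Expression is depth-normalised to a common target sum (10⁴) and log1p
transformed (scanpy); genes detected in < 10 spots are dropped. The
per-gene test is the two-sided rank test above; "Z-score" means the
signed normal-scale statistic, positive when expression is higher with
exposure. Per comparison, BH runs across genes; a comparison is skipped
when either group has < 10 spots. Consistency across species summarises,
per gene, the fraction of evaluable species with a significant response
(`consistency_rate`) and the share of significant responses on the
majority sign (`direction_agreement`); "consistently up" requires
rate ≥ 0.5, agreement ≥ 0.9 and positive majority — thresholds that are
conventions, exposed in the API and reported in outputs. The
beneficial-vs-pathogenic comparison enumerates all |B|×|P| pairs; for a
pair (b, p) the groups are spots exposed to b-but-not-p versus
p-but-not-b, so doubly-exposed and unexposed spots drop out; positive z
means higher with the beneficial member. Ranked gene lists are exported
as plain TSV for any external enrichment tool; enrichment itself is out
of scope.

## Correlation PCA

`r(s,g)` is the Pearson correlation between the binary presence of
species *s* (same exposure definition as the risk screen, for internal
consistency) and normalised expression of gene *g* across CD spots.
Entries with a constant vector on either side are undefined: they are
masked in the output and imputed as 0 — the no-association neutral
value — before PCA. The matrix is centred gene-wise only (entries are
already on a common correlation scale) and decomposed by full SVD.
Signs are fixed deterministically (largest-|loading| gene positive per
component) so repeated runs are identical. The component separating the
beneficial and pathogenic species sets is found by rank-sum test on the
scores rather than hard-coding a component index, since component order
is data-dependent; the top-k (default 20) genes by |loading| per
component are tabulated.

## Synthetic data model

The generator emulates the statistical structure of the real inputs, not
the reads themselves:

- **Design**: samples cycle control → non-inflamed CD → inflamed CD; a
  non-inflamed/inflamed pair per cycle shares a patient. Patient severity
  (uniform 0.5–1.5, CD only) scales exposure and drives planted Rutgeerts
  scores and relapse times, so prognosis orderings are recoverable.
- **Cell types**: symmetric Dirichlet fractions over 8 default types; a
  planted M-cell stratum (10% of CD spots, Dirichlet concentrated on
  M cells, 2× exposure) gives area-stratified analyses a known maximum.
- **Exposure and counts**: Bernoulli exposure per spot and species, base
  rate 0.15 scaled by group (0.3 / 1.0 / 2.0), severity and stratum;
  exposed spots get 1 + Poisson(3) reads.
- **Damage**: probability = baseline (0.08) × product of per-species
  multipliers over exposed species, capped at 1. `planted_rr` specifies
  each species' **marginal** relative risk in the CD analysis population:
  because heterogeneous exposure rates correlate exposures, raw
  conditional multipliers would attenuate every marginal RR, so the
  multipliers are calibrated by a damped fixed point on the drawn
  exposure matrix (disable with `calibrate_marginal_rr=False` to get the
  plain multiplicative model).
- **Mitochondrial fractions**: Beta(8, 32) for damaged spots (mean 0.20)
  and Beta(8, 192) for viable ones (mean 0.04). The overlap sits almost
  entirely on the damaged side: damaged spots misread as viable shrink
  both arms of an RR proportionally and cancel, whereas viable spots
  misread as damaged would bias every RR toward 1. The 10% rule is the
  downstream classifier, not the generator's rule.
- **Host counts**: per-spot totals negative binomial (mean 2000,
  dispersion 2); the mitochondrial share binomial at the spot's target
  fraction; multinomial over fixed log-normal gene weights, with planted
  (species, gene) log2 fold changes applied multiplicatively in exposed
  spots.
- **Bulk and double removal**: bulk totals are Poisson at equal
  sequencing depth to the spatial totals, so genuine percentage ratios
  sit near 1; double-removal counts are binomial thinnings at survival
  0.5–0.85 for genuine species and < 0.01 for the planted survival-rule
  artifact. Contaminants are constructed to violate exactly one rule
  each while passing the other three, and the violated rule is recorded
  in the ground truth.

Everything is drawn from one seeded generator: identical configs give
byte-identical outputs. The Poisson/negative-binomial/Beta choices are
fixture conventions chosen for realism of the summary statistics each
stage consumes; they are not claims about any particular dataset's
microdistributions. What passing tests show is that the *procedures*
recover *planted* effects at the stated sizes; they do not show that real
tissue satisfies the independence and homogeneity assumptions (notably:
no spatial autocorrelation beyond the planted strata, no patient-level
random effects, no sequencing batch structure).

`worked_fixture()` is a 180-spot, 17-species dataset whose
decontamination block is hand-set with equal spatial and bulk depths
(8 464 reads each), one contaminant per rule at 49 reads / 49 bulk
reads / ratio 1.55 / survival 0.019, and boundary species at exactly 50
reads, ratio 1.50 and survival 0.020 on the retained side.

## Numerical choices and problem sizes

- Exact rank-sum enumeration up to group size 8, tie-corrected normal
  approximation above; no continuity correction on the reported z.
- BH q-values propagate NaN (non-evaluable entries do not count as
  tests).
- PCA reconstruction is exact to 1e-8 at full rank; undefined
  correlations imputed at 0 with the mask preserved.
- Ties in area labelling break lexicographically and are logged.
- The verification script and test suite run planted-truth simulations at
  up to 30 000 spots / 25 species (risk recovery), 5 100 spots / 120
  genes (expression), and 500 replicates of 2 000 spots (CI coverage) —
  sizes at which every planted effect is comfortably within power while
  the whole suite completes in well under a minute of compute.

## Known limitations

- Pooled-spot inference ignores within-patient correlation (see above).
- The exposure threshold (≥ 1 read) makes presence sensitive to
  sequencing depth; the threshold is configurable but no depth-adaptive
  rule is provided.
- The pair comparison conditions on single-membership exposure and
  discards doubly-exposed spots, which loses power when exposures overlap
  heavily.
- Decontamination operates on totals pooled over all samples; a species
  genuinely present in one patient but contaminating others is either
  kept or dropped wholesale.
- No spatial statistics: coordinates are carried through but no
  neighbourhood structure is modelled.
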