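# Methods

This note documents the statistical models, conventions and design choices
behind `mircna`, in the order data flows through the pipeline.

## Coordinates

All genomic spans are 1-based and inclusive at both ends, the convention of
cytogenetic region tables (size = stop − start + 1). BED input (0-based,
half-open) is converted at the I/O boundary by start + 1 with stop
unchanged. Two intervals overlap iff they share ≥ 1 bp; a feature whose
stop equals a region's start − 1 does not overlap it.

## Aberration calling

The caller implements a deterministic run rule rather than a proprietary
segmentation score: a gain (loss) is a maximal run of consecutive probes on
one chromosome whose log₂(test/reference) ratios are *all* ≥ +0.25
(≤ −0.25), with run length ≥ 3 probes. Boundary values count as aberrant
(≥/≤). A single sub-threshold probe terminates a run; there is no gap
tolerance. This is the simplest reading of a "k consecutive probes beyond
threshold" criterion and makes the caller exactly checkable against
exhaustive run enumeration. Orientation is test/reference with gains
positive. The call interval spans the first probe's start to the last
probe's stop; `mean_log2` is the arithmetic mean over the run.

**Parameters.** `min_probes` (default 3), `gain_threshold` (+0.25 log₂),
`loss_threshold` (−0.25 log₂). At these defaults a single-copy gain in a
diploid background (log₂ 3/2 ≈ 0.58, attenuated by tumour-cell purity)
comfortably clears the threshold, while array noise of sd ≈ 0.1 rarely
produces 3 consecutive same-sign excursions.

**Penetrance and recurrent regions.** Per (cytoband, direction), a case
contributes at most once regardless of how many calls overlap the band;
frequency = affected cases / total cases. Bands at or above
`min_frequency` (default 0.19) are kept; genomically adjacent kept bands
with the same direction merge into one region. A merged region reports the
maximum case count/frequency of its member bands (the "most frequently
affected" reading) and their summed probe tally. The per-band probe tally
is the largest number of aberrant probes any single case contributes —
descriptive output only. The frequency denominator is always an explicit
parameter, never hard-coded.

## Count normalization

Three per-sample steps, in the style of hybridization-counting (nCounter)
panels:

1. subtract the sample's negative-control geometric mean from every count,
   flooring at 1 (so log₂ stays defined; standard practice for this assay
   class);
2. scale by (grand mean of per-sample positive-control geometric means) /
   (this sample's positive-control geometric mean);
3. repeat step 2 with all endogenous features as the reference set
   (codeset content normalization).

The step-3 content factor is applied to every row *except* the
positive-control rows. This makes the scaling steps idempotent — after one
pass both reference sets have equal per-sample geometric means, so a second
pass is a no-op (verified to 1e-9) — and leaves the spike-in ladder
interpretable on its own scale. Background subtraction is intentionally not
idempotent and can be skipped (`subtract_background=False`) when re-scaling
already-backgrounded data.

## Differential expression

Per endogenous feature, a two-sample *t*-test on log₂(x + 1) of normalized
counts; log₂ fold change is mean(case) − mean(control), so positive means
higher in TNBC. The default flavour is Student (pooled variance), matching
the array-era tools this stage mirrors; Welch is available and is the
default for the clinical associations. BH-FDR is computed across all
endogenous features; the significant set applies the dual cutoff
*p* < 0.01 ∧ FDR < 0.05. Features with zero variance in both groups and
equal means are assigned *p* = 1. Clustering uses sample–sample distance
1 − Pearson *r* on the significant submatrix with unweighted average
linkage (UPGMA); the dendrogram is serialized as Newick with merge-height
differences as branch lengths.

## Integration

Identifiers are matched after case-folding and stripping the `hsa-`
prefix. Approach 1 joins each significant miRNA to every recurrent region
it overlaps; concordance is (up ∧ gain) ∨ (down ∧ loss). A miRNA spanning
two regions yields one record per region but counts once in `n_mapped`,
and counts as concordant if ≥ 1 of its records is (a case real cohorts
essentially never produce; asserted consistent internally). Approach 2
keeps a gene as a consensus target of a miRNA iff it appears in
≥ `min_dbs` (default 2) of the three prediction tables, unions targeting
miRNAs per gene, intersects with genes resident in recurrent regions, and
sorts by miRNA count descending then gene id. Reported percentages use one
decimal, rounded half away from zero.

## Validation statistics

**ΔΔCt.** Triplicate Cts are averaged per channel; a record is excluded if
the reference mean ≥ 31 cycles or the target mean ≥ 35 (boundary excluded
— the assay's reliability limits). RQ = 2^(−ΔΔCt) with the calibrator
defaulting to the mean ΔCt of the adjacent-non-tumour group, exposed as a
parameter.

**ROC.** AUC is the Mann–Whitney probability that a random tumour sample
outscores a random ANT sample, ties counting ½ (identical to the
trapezoidal area). The 95% CI is the 2.5/97.5 percentile interval over
2,000 seeded bootstrap resamples; single-class resamples are skipped. The
combined multi-miRNA score is the unweighted mean of per-feature z-scores —
deterministic and scale-free; a fitted (logistic) combination would be an
alternative but introduces an estimation step this stage does not need.

**Associations.** Continuous clinical variables are dichotomized at
per-variable cutpoints (age 55.5 y, tumour size 1.7 cm, BMI 28.3, Ki-67 and
p53 10%), overridable; binary variables use their levels. The test is
Welch's unpaired *t* on expression between strata. The multivariate option
is OLS of expression on 0/1-encoded covariates with coefficient *t*-tests;
rank-deficient designs are rejected with the collinear columns named.

**Survival.** High = strictly above the median (ties go low; an all-equal
vector warns). The two-group log-rank statistic is computed from the
observed and hypergeometric-expected event counts over pooled risk sets at
each distinct event time — the per-time table is part of the output — with
a χ²(1) reference; with two groups the "test for trend" reduces to this
ordinary log-rank. KM curves come from the product-limit estimator.

## Synthetic cohort model

The generator fabricates the statistical structure the analysis assumes,
not the biology it summarizes:

- **Genome**: equal-length chromosomes (default 10 Mb) tiled by
  equal-width cytobands named `p{k}…q{m}`; genes (10 kb) and miRNAs
  (100 bp) placed uniformly at random.
- **Array profiles**: probes every 10 kb; step-shaped segments of
  ± amplitude (default 0.5 log₂) spanning 5–15 probes, non-overlapping
  within a case, in Gaussian noise (default sd 0.1). At noise
  sd = amplitude/5 a middle probe of a minimal 5-probe implant dips below
  threshold with small probability, so recovery at the ≥ 50%-reciprocal
  matching rule is near-certain but not structurally guaranteed; the seeded
  tests pin the realized behaviour.
- **Expression**: per-feature baseline log₂ abundance Uniform(5, 12),
  per-sample values Normal(baseline, 1), a per-sample library-scale offset
  Normal(0, 0.25) in log₂ on endogenous and positive-control rows, a
  ± effect mean shift on the case group for the DE subset; Poisson(8)
  negative controls; a 2⁶…2¹¹ positive-control ladder. Log-normal counts
  (not negative binomial) because the downstream statistic is a *t*-test on
  log-transformed normalized values, for which the log-scale Gaussian is
  the matched generative model.
- **Targets**: per miRNA, each drawn candidate gene is either a core
  prediction in all three databases (probability = `db_agreement`) or
  private to one; the recorded consensus truth is the exhaustive 2-of-3
  count over the emitted tables.
- **qPCR**: reference Ct Normal(25, 1); per-sample ΔCt Normal(5, 1.5) in
  ANT shifted down by the driver's log₂ effect in tumour; replicate sd 0.2.
  The 1.5-cycle between-sample spread reflects archival-tissue variability
  and yields moderate (AUC ≈ 0.8–0.95) rather than trivial discrimination.
- **Clinical/survival**: exponential event times with hazard
  baseline × exp(coef × expression), administrative censoring; all other
  covariates drawn independently at marginals typical of a TNBC case
  series (age ≈ 55 ± 11 y, tumour size ≈ 1.9 ± 1.3 cm, BMI ≈ 29 ± 7, ~31%
  recurrence, ~32% distant metastasis, ~71% comorbidity). No joint
  covariate model is implied by the data this emulates, so none is
  simulated.

Every generator is deterministic for a fixed seed, with distinct RNG
substreams per generator so one global seed fans out without correlation.

What passing tests therefore show: the *procedures* are correct (exact
agreement with brute-force oracles) and *well calibrated* under the stated
generative model. What they do not show: robustness to FFPE degradation,
probe GC/wave artefacts, negative-binomial overdispersion, batch structure,
or real target-database biases — none of which the generator emulates.

## Default scenario sizes

The shipped end-to-end scenario uses 4 × 10 Mb chromosomes with 12 bands
each, 400 genes, 200 miRNAs, 24 array cases × 9 segments, 18 vs 32
expression samples, 22 + 12 qPCR samples and 28 patients — sizes chosen so
the full run and the calibration suites (50 null-DE replicates, 200
null-survival replicates) complete in seconds while every stage still has
non-trivial structure to recover. A 2-chromosome genome at these segment
counts saturates every cytoband past the recurrence cutoff, which is why
the pipeline default is wider than the minimal desk-scale genome used in
unit tests.

## Known limitations

- The run-rule caller is not a segmentation algorithm; it will split a true
  segment at any single sub-threshold probe and has no wave/GC correction.
- Content normalization assumes most features are non-differential; with a
  large asymmetric DE fraction it compresses true fold changes.
- The bootstrap ROC CI is percentile-based and degenerate at AUC = 1.
- The log-rank implementation handles exactly two groups.
- Consensus targeting treats the three databases symmetrically and ignores
  prediction scores.
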