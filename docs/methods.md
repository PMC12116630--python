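# Methods

`adlink` implements a desk-scale version of a common analysis chain for
staged anaerobic-digestion (AD) experiments: link the structure of 16S
amplicon communities in acidogenic (1st-stage) and methanogenic (2nd-stage)
reactors to soluble-COD (sCOD) removal performance, screening for
"keystone" genera whose abundance tracks removal. Because the real
sequencing data live in an external repository and require read processing
that is out of scope here, every statistical stage is exercised and
validated on synthetic experiments with planted, machine-readable ground
truth.

## Estimated absolute abundance

Amplicon counts are compositional; to compare genus abundances against an
external variable they are re-scaled to an absolute concentration using a
total-16S qPCR measurement:

* standard curve: ordinary least squares of Cq on log10(copies/reaction)
  over a serial dilution (≥ 3 levels; the generator emits a curve in the
  10⁴–10⁹ copies/reaction range). Amplification efficiency is
  `10^(−1/slope) − 1`; a slope of −log₂10 ≈ −3.3219 is 100%.
* copies per µL template: `10^((mean Cq − intercept)/slope)` divided by
  the template volume per reaction (default 1 µL, configurable).
* normalized copy number: `N = copies/µL × V_t / V_S` (copies per mL of
  reactor sample), with V_t the eluted template volume (µL) and V_S the
  extracted sample volume (mL).
* estimated absolute abundance: `EAA = N × RA`, with RA the per-sample
  relative abundance on **non-rarefied** counts. EAA columns sum to N by
  construction.

Samples whose N falls below the assay detection limit (default 1.6 × 10⁵
copies/mL) are excluded from EAA-based analyses; substituting half the
detection limit is available but off by default, to avoid fabricating
abundance where none was measured.

## Core and unique membership

Per stage, on non-rarefied counts with detection = count ≥ 1:

* **core** genus: detected in at least one sample of *every* reactor of
  the stage, and detected in ≥ 50% of the stage's samples. The prevalence
  condition is evaluated over the stage's pooled samples by default; a
  stricter per-reactor scope (`prevalence_scope="per-reactor"`) is
  provided because the pooled reading is not the only defensible one, and
  the per-reactor result is always a subset of the pooled one.
* **unique** genus: detected under exactly one feed within the stage and
  in no sample of any other feed's reactor of the same stage. Occurrences
  in the other stage are ignored. When a stage contains a single feed,
  uniqueness is not assessable (every genus would be trivially
  "feed-specific") and the unique sets are empty; this also preserves the
  invariant that core and unique sets are disjoint.

Raising the prevalence or detection thresholds can only shrink the core
set. The same is *not* true of unique sets: a genus with a single low
count under a second feed becomes unique once the detection threshold
exceeds that count, because the exclusion condition weakens. Membership
correctness is therefore validated against a brute-force enumeration
rather than a monotonicity law.

## Diversity, ordination, Mantel

* Bray–Curtis dissimilarity `Σ|x−y| / Σ(x+y)` between samples, computed on
  counts rarefied to a common depth (default 3,000 reads; one
  multivariate-hypergeometric draw per sample, samples below the depth
  dropped). Rarefaction is used only here and for Shannon diversity;
  membership and the EAA screen use the raw counts.
* Shannon index `H = −Σ p ln p` (natural log) per rarefied sample.
* Non-metric MDS at k = 4 minimising Kruskal stress-1, via non-metric
  SMACOF with weak-tie monotone regression. Restarts: one Torgerson
  (classical-MDS) warm start plus seeded random configurations, up to
  `trymax` (default 100); the minimum-stress solution is returned,
  centred. `converged` requires the two best restarts to agree (relative
  stress gap < 1e-7 or Procrustes RMSE < 1e-6) or a near-exact embedding;
  like other NMDS implementations, non-convergence is reported, not fatal.
  Stress below 0.2 is conventionally considered a reliable configuration.
* Mantel test: Pearson (default) or Spearman correlation of the strictly
  lower triangles, one-sided upper tail. With n! ≤ the requested
  permutation count the permutation group is enumerated exhaustively and p
  is exact; otherwise p = (1 + #{r_perm ≥ r_obs}) / (1 + permutations)
  with 999 sampled permutations by default. Operational factors are
  encoded as distances: 0/1 mismatch for feed and stage, |Δday| rescaled
  to [0, 1] for time. The factor encoding is a documented package choice;
  other encodings (e.g. Gower) would change r but not the permutation
  logic.

## Performance and screening

* Combined two-stage removal: `100 × (sCOD_in − sCOD_out2)/sCOD_in` per
  sampling day; negative values are reported, not clipped.
* Smoothing: trailing moving average over the current day and the five
  preceding days (window 5), so every observed day keeps a value.
* Spearman's rho: Pearson correlation of average ranks. Two-sided
  p-values: exact by full enumeration of the n! pairings for n ≤ 9
  (enumerated on the linear rank-sum statistic, in vectorised chunks),
  otherwise the t approximation `t = ρ√((n−2)/(1−ρ²))` on n − 2 df.
* Screening: per (stage, feed, genus), EAA samples are paired with the
  feed's smoothed removal on the nearest day within ±3 days (one sampling
  interval); genera with fewer than 6 paired observations or zero variance
  are skipped. Records are labelled core/unique/other and sorted by
  |rho|; the `passed_filter` flag marks p ≤ 0.05 (raw p, no multiplicity
  correction by default — an optional Benjamini–Hochberg step would be a
  trivial extension but is deliberately off to keep the screen a raw
  filter).
* Kruskal–Wallis (tie-corrected, χ² p-value) compares smoothed removal
  across the five feeds.

Because the smoothed removal series is autocorrelated while the screen's
null calibration assumes exchangeable pairs, background genera pass the
raw 0.05 filter slightly above nominal on smoothed series (the acceptance
script reports the realised rate); calibration against i.i.d. removal
values is within [0.03, 0.07], as the test suite asserts.

## Synthetic experiments

The generator emulates the target study design: five feeds (starch-,
protein-, lipid-rich, brewery, dairy wastewater), each feeding a
1st-stage/2nd-stage reactor pair, sampled twice weekly (two visits 3 days
apart) from day 55 to day 185 — 38 dates, 380 samples.

* Removal per pair: logistic ramp from ≈ 40% at day 55 to a feed plateau —
  brewery 96, dairy 92, starch 89, protein 85, lipid 79 percent (the
  bracketing endpoints and their feeds are fixed; the middle values are an
  even spread) — plus AR(1) noise (sd 2 points, φ = 0.5). An optional
  transient dip near day 130 emulates a washout event and is cosmetic.
  Influent sCOD ≈ 8,800 mg/L for the three synthetic feeds and
  ≈ 8,000 mg/L for brewery and dairy.
* Total 16S copies/mL: log-normal (median 10⁹, σ_ln 0.7), independent of
  removal — the biomass-vs-removal Spearman is a planted null. The qPCR
  table carries both the exact copies/µL (V_S = 1.5 mL, V_t = 100 µL) and
  duplicate Cq values generated from a true curve with ≈ 97.6% efficiency
  plus 0.05-cycle replicate noise, so either quantification route can be
  exercised.
* Counts: negative-binomial (gamma–Poisson, size 5) around log-normal
  per-taxon expected fractions of a log-normal sequencing depth (median
  12,000). Defaults: 20 core genera per stage, 8 unique per (stage, feed),
  1 performance correlate per (stage, feed), 120 background genera.
* Membership is guaranteed constructively, not just in expectation:
  unique genera are sampled only in their reactor; background genera
  occupy zero or 2–4 feeds per stage (never exactly one, never all five)
  so they can be neither core nor unique; a deterministic bump-to-
  detection pass enforces per-reactor detection and the 50% prevalence
  floor for planted core genera (and re-enforces them after optional
  detection dropout).
* Correlates are planted on the EAA scale through a Gaussian-copula rank
  link: normal scores of the smoothed-removal ranks are mixed with
  independent noise at latent correlation `2 sin(π ρ_s / 6)`, giving a
  population Spearman of ρ_s (default 0.72) after exponentiation; counts
  are back-computed so that `count × N / depth` reproduces the target EAA.
  For |ρ| = 1 a repair pass enlarges counts minimally so the realised EAA
  is strictly monotone despite integer rounding — zero-noise plantings are
  recovered at exactly 1.0. Correlates also appear as background in three
  of the four other feeds of their stage, so they are classified "other"
  rather than polluting core or unique sets.

What the generator does **not** emulate: reactor dynamics (washout and
reseeding appear only as the optional dip and the dropout rate),
phylogenetic structure among genera, taxon–taxon interactions,
compositional closure effects beyond the shared depth denominator, and
chimeras/contamination. Passing the planted-truth tests therefore shows
the statistics recover the structure they are defined on, not that the
pipeline is robust to every artefact of real amplicon data.

## Numerical and design choices

* Rarefaction is a single draw without replacement; averaging draws would
  shrink variance and is not what the downstream ordination expects.
* Exhaustive Mantel enumeration includes the identity permutation, so the
  exact p is never 0 and agrees with the +1-corrected sampled form.
* Spearman at n > 9 uses the t approximation; at |ρ| = 1 the p-value is
  reported as 0 (the t statistic diverges).
* Ties in the NMDS monotone regression use the weak (primary) treatment.
* Per-stage seeds derive from the master seed by hashing the stage name
  (SHA-256, reduced below 2³¹), so individual stages re-run in isolation
  reproduce their slice of a full run; a fixed master seed makes the whole
  run byte-identical.
* Problem sizes in the test suite and the acceptance script are chosen to
  keep a full validation run to a few minutes: oracle-equivalence checks
  use 500 random ≤ 10 × 20 tables, calibration loops use 400 simulations
  with 199-permutation Mantel tests (at 199 permutations the nominal
  p ≤ 0.05 event has null probability exactly 10/200), rho-recovery uses
  the copula primitive at n = 30 over 200 seeds, and the full-size
  ordination uses 10 SMACOF restarts.

## Known limitations

* The screening pairs abundance and performance by nearest day; it does
  not model temporal autocorrelation, so its p-values are screening
  statistics, not time-series inference.
* The prevalence scope of the core definition (pooled vs per-reactor) is
  genuinely ambiguous in the field's verbal definition; both are
  implemented and the choice is surfaced as a flag rather than guessed.
* NMDS stress values depend mildly on the stress-1 normalisation
  convention (configuration distances vs disparities in the denominator);
  this implementation follows its SMACOF engine's disparity-based form.
* BIOM input is not supported; tab-separated text is the canonical
  interchange format.
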