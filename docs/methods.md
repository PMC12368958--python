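# Methods

## Absolute abundances

Amplicon read counts are compositional; all demographic accounting
therefore works on absolute abundances a_i = r_i · N, where r_i is the
relative abundance of taxon *i* in a sample (row-normalised counts) and N
is an independently measured total community size for the *same* sample.
Three size estimates are supported:

* `fc_total` — flow-cytometry total cell counts (cells g⁻¹ soil).  The
  default for demography, because it is independent of culturing bias.
* `cfu_total` — colony-forming units (CFU g⁻¹).  The default for tracking
  the transplant's summed viable size.
* `dna_conc` — bulk DNA (ng g⁻¹), converted to genome-equivalent cells as
  cells = mass[ng] · 1000 / g_pg, with a mean genome weight per cell g_pg
  of 0.00511 pg for soil-derived (SC) and 0.00292 pg for lake-derived (LC)
  communities, reflecting their different average genome sizes.

The per-sample sum of an absolute-abundance table equals that sample's
chosen total exactly (a tested invariant).  No correction is attempted for
16S copy-number variation or extraction/PCR bias; these biases are shared
between the samples being compared and largely cancel in paired contrasts.

## Interval demography

For a community and an interval (day_a, day_b), each genus's change is
Δa = mean over replicates at day_b minus mean at day_a (cells g⁻¹).
Default intervals are (0, 3), (3, 7), (7, 21): the early bloom, the crash,
and late succession.  Genera are partitioned per interval into the groups
*common increasing/decreasing in both*, *common opposite (A up / B up)*,
*exclusive to A/B increasing/decreasing*, and *unchanged*; "common" means
detected (any nonzero count, any day) in both communities.  Group
contributions split each genus's Δa into its positive part (growth) and
negative part (decline); summed over groups they reconstruct the total
community-size change exactly, which the tests verify to 1e-6 relative.

Two deliberate conventions:

* Deltas are computed as differences of replicate means (not means of
  per-replicate differences).  The two agree for balanced designs with
  complete detection and differ only when a taxon drops out of some
  replicates; the chosen form is the one that conserves total community
  change by construction.
* A common genus with Δa exactly 0 in one community and a nonzero change
  in the other is labelled by the nonzero sign ("increasing/decreasing in
  both", reading 0 as weak agreement); (0, 0) is "unchanged".  Exact zeros
  are measure-null on real data but routine on synthetic data.  Labels
  never affect the contribution sums (a zero delta contributes zero).

## Displacement statistic

The displacement question — which resident ASVs sit at permanently shifted
abundance in the merged community relative to its non-merged control — is
answered by a regression-baseline outlier rule:

1. **Pairing.**  For a replicate pair (one control replicate, one merged
   replicate — or two replicates of the same condition for the noise
   floor) at a given day, transplant ASV reads are removed *first*, each
   sample is then rarefied without replacement (multivariate
   hypergeometric) to D = 100 000 reads, and ASVs with count ≥ 1 in
   **both** samples are paired as (x, y) = log₁₀ counts.  Removing
   transplant reads before rarefaction keeps the resident read depth
   comparable between merged and control samples.  Rarefaction draws are
   keyed per sample, so the same sample is subsampled identically in every
   pair it enters ("equalised datasets").
2. **Baseline.**  An ordinary least-squares line y = β₀ + β₁x is fitted to
   the pooled day-0 pairs of a comparison; at the moment of mixing the
   transplant cannot yet have reshaped the residents, so the day-0
   residual standard deviation σ (n−2 denominator) measures pure replicate
   plus counting variation.  The line is *fixed* at day 0 and reused for
   all later days.
3. **Outliers.**  A paired ASV with |y − (β₀ + β₁x)| > kσ, k = 3 (the
   two-sided 99.7% normal band), is an outlier: enriched if the residual
   is positive (higher in the merged community), depleted if negative.
   The threshold multiplies the *residual dispersion*, not the standard
   error of the mean — an SE-of-mean band would shrink with the number of
   paired ASVs and flag nearly everything; ±3σ is what delivers the stated
   99.7% coverage.  `threshold_basis="prediction_se"` switches to the
   x-dependent OLS standard error of prediction for users who want the
   band to widen at the extremes of the abundance range.
4. **Summaries.**  Per replicate pair, Σ|residual| over all outliers
   across days (log₁₀ units) measures total displacement; group medians
   are compared between merged-vs-control and within-condition pairings.
   Within-condition comparisons use all C(R,2) unordered replicate pairs
   (6 for R = 4); between-condition comparisons use a seeded random
   bijection of replicates (R pairs; 4 for R = 4).  Outliers are also
   profiled per phylum and day by mean log₂ fold change of rarefied counts
   (no pseudocount: pairing already requires presence on both sides) with
   their relative abundance in the merged background as weight.

The rule is exposed as a scikit-learn estimator
(`BaselineOutlierDetector`: `fit` on day-0 pairs; `predict` returns +1/−1;
`decision_function` is positive inside the band), composable with sklearn
tooling; the module functions wrap it into the paired-count workflow.

Degenerate inputs: a baseline needs ≥ 3 pooled points and nonzero x
variance (errors otherwise); σ = 0 with nonzero residuals flags every such
point and emits a warning; fewer than 3 common ASVs in a pairing is an
error; samples that cannot reach the rarefaction depth after exclusion are
an error in pairing (and are dropped with a warning by plain rarefaction).

## Supporting metrics

Shannon index H = −Σ r_i ln r_i (natural log by default, base selectable)
and Bray–Curtis dissimilarity BC = 1 − Σ min(r_a, r_b) on relative
abundances, computed on rarefied counts by default for comparability
across samples.  Ordination, PERMANOVA and repeated-measures testing are
deliberately out of scope — any standard ecology stack consumes the
exported tables.

## Synthetic data generator

`soilmerge.simulate` emulates the two-phase microcosm design so analyses
can be validated against ground truth:

* **Membership.**  Two resident origins share 28% of genus labels but only
  1% of ASV identifiers (shared genera keep the same guild in both
  origins); the transplant has 21 cultured members spanning four phyla,
  one of which is, by default, an ASV also present in both residents — so
  membership inference must flag it as ambiguous.
* **Trajectories.**  Each genus belongs to a guild with a multiplicative
  template: fast bloomers rise ~300× to day 3 then crash ~10× by day 7;
  slow growers rise monotonically; decliners fall monotonically.  Taxon
  weights are guild template × log-normal baseline (σ = 1.0 log₁₀).  The
  community total follows a configured trajectory (default 100× growth by
  day 3, then decline and stabilisation; lake-derived totals reduced
  2.5-fold from day 7; transplant-alone totals 1.5× higher), seeded at
  10⁶ cells g⁻¹.
* **Observation.**  Per sample: log-normal replicate noise (σ = 0.15
  log₁₀ per taxon), multinomial reads at a log-normally drawn depth (mean
  1.2 × 10⁶, CV 0.10), and mean-preserving log-normal noise (CV 0.15) on
  flow-cytometry, CFU (×0.3 culturability for the lake origin) and DNA
  totals.  The read-depth default is set so day-0 merged samples retain
  ≥ 100 000 resident reads after transplant-read removal even when the
  transplant holds 60–80% of reads at mixing.
* **Mergers.**  Phase-II microcosms mix the two grown communities by soil
  mass (default 0.1 + 0.1 into 8 parts sterile soil); the transplant's
  starting share follows from the mixed cell masses (~60–80%) and then
  decays along a configured share trajectory to 0.4% at day 60 — below 1%
  within two months — while its internal composition keeps evolving by
  guild.  Displacement effects multiply chosen resident ASVs by 10^δ from
  an onset day (renormalised within the resident fraction) and are
  recorded as ground truth.  Non-merged controls restart the same
  deterministic composition path, so merged-vs-control pairs differ only
  by replicate/counting noise plus the injected effects.

Everything is deterministic for a fixed scenario seed (per-condition PCG64
streams; per-sample rarefaction streams keyed by CRC32 of the sample id).

**What the generator does not emulate:** mechanistic ecology (no
consumer–resource or Lotka–Volterra dynamics — trajectories are
phenomenological templates), 16S copy-number and PCR bias, chimeras or
contamination, spatial soil structure, and strain-level variation within
ASVs.  Passing recovery tests therefore demonstrates that the estimators
recover what the statistical observation model can expose, not that the
biology of any particular soil behaves this way.

## Validation design and numerical choices

* The displacement-recovery scenario injects |δ| = 5σ effects into 20 of
  400 ASVs, drawing enrichment targets from a low-abundance band
  (relative abundance 1.5–5 × 10⁻⁴) and depletion targets from an abundant
  band (2–10 × 10⁻³).  This keeps the injected read mass at a few percent:
  20-fold enrichment of already-abundant ASVs would move tens of percent
  of resident reads and, through compositional renormalisation, push every
  *unaffected* ASV off the baseline — a property of composition, not of
  the detector.  Sensitivity and false-flag rates are scored per paired
  observation (ASV × replicate pair × day after onset).
* Under the default conditions the measured false-flag rate is typically
  0.4–0.7%, occasionally up to ~1.5% across seeds: multinomial counting
  noise at 1–10 reads is heavy-tailed relative to the pooled Gaussian
  band, so the empirical exceedance of 3σ sits above the nominal 0.27% at
  the low-count margin.  The Gaussian-null calibration (coverage
  99.7 ± 0.1% on ≥ 10⁵ points) isolates the rule itself from this
  observation-model effect.
* Problem sizes used by the test-suite: 400 ASVs / 120 genera per
  community, 4 replicates, days 0/3/7/21/60; the pipeline smoke tests use
  a scaled-down 80-ASV scenario at 30 000-read depth.  These sizes were
  chosen to mirror the emulated design at desk scale.
* Rarefaction uses numpy's multivariate hypergeometric sampler
  (`method="marginals"`); the baseline OLS uses `scipy.stats.linregress`;
  ties and ordering are made deterministic by sorting taxon and replicate
  identifiers before any seeded draw.
* Singletons, for shared-taxa fractions, are taxa with a total count of 1
  within the table under consideration, removed (together with unassigned
  labels) at the rank being compared by default; removal before genus
  aggregation is available via `singletons_at="asv"` since the convention
  is not universal.

## Known limitations

* The day-0 baseline pools all replicate pairs of a comparison; per-pair
  baselines (more conservative when replicates differ systematically) are
  not currently exposed through the CLI.
* The ±3σ band is homoscedastic in log space while counting noise is not;
  very low-abundance ASVs are over-flagged relative to the nominal rate
  (see above).  A variance-stabilised or count-model-based band would
  address this but would no longer be the same statistic.
* Absolute abundances inherit whatever bias the chosen total carries
  (culturability for CFU, staining/gating for flow cytometry); the
  package treats the totals as given.
* Between-condition replicate pairing is a seeded random bijection; with
  n = 4 replicates the displacement summaries retain dependence on that
  pairing, which is why the seed is part of every manifest.
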