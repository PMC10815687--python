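# Methods

## The model

The analysis treats the chr17q21 inversion region as two non-recombining
haplotype classes, H1 and H2, discriminated by a single tag SNV. Variants
fixed for different alleles on the two classes ("haplotype-divergent"
SNVs) are in perfect LD with the tag; everything else segregates
independently. Three statistical questions follow:

1. **Fine-mapping.** Among individuals homozygous for the H2-tagging
   allele, every divergent site should be homozygous too; a site that is
   not marks a historical recombination event on one of the two
   haplotypes. Each tag-homozygote's *consistent segment* is the maximal
   contiguous run of dosage-2 divergent sites around the tag; the minimal
   LD interval is the intersection of all consistent segments. Its
   endpoints are positions of the outermost divergent SNVs consistent in
   every homozygote — not midpoints between sites, so the result is
   reproducible from genotypes alone.
2. **Association against external allele counts.** Cases are compared
   with a control population for which only allele counts are available.
   The allelic model contrasts allele counts directly. Dominant and
   recessive models need control genotype counts, which are derived from
   the control allele frequency p under Hardy–Weinberg equilibrium
   (carrier fraction 1 − (1−p)², homozygote fraction p²) applied to
   total_alleles/2 control individuals; the resulting expected cells are
   fractional, which the Woolf log-OR machinery handles without change.
   This HWE derivation is internally consistent: the same transform of
   the control frequency gives the expected dual-carrier rate used by the
   co-occurrence test.
3. **Dual-carrier co-occurrence.** Under the null, founder-mutation
   carrier status and H2 carrier status are independent, so the expected
   H2-carrier rate among mutation carriers equals the population HWE
   carrier rate. The test contrasts observed carrier odds with this
   expectation, either in closed form (expected cells n·q and n·(1−q)
   among the n observed mutation carriers) or against counts drawn by a
   Monte-Carlo simulation of independent Bernoulli carrier states
   (default 100,000 individuals, seed-controlled). The closed form is the
   large-simulation limit; the MC path also yields empirical variability.
   The two agree in the odds ratio; their confidence intervals differ
   because the simulated expected cells are finite and much larger than
   n, which narrows the interval relative to the closed-form-among-n
   version.

Inference on every 2×2 table uses the Woolf normal approximation on the
log odds ratio (SE = √Σ1/cell, two-sided z test). No continuity
correction is applied; a zero cell raises an error naming the cell so the
caller can decide on a Haldane correction explicitly. The AMSO model is
ordinary least squares of onset age on an H2-carrier indicator
(dominant coding, dosage ≥ 1) and a female indicator, with t-based
confidence intervals and p-values — the standard small-sample OLS choice.

## Quality-control conventions

* Thresholds are strict "lower than": a call with DP 10 and GQ 30 passes
  the default filters (min_depth 10, min_quality 30).
* The canonical order is call filters → variant filters; call rates are
  computed on the post-call-filter matrix. Region extraction happens
  before filtering.
* Coordinates are 1-based inclusive everywhere in memory; only the BED
  writer converts to 0-based half-open.
* Multi-allelic VCF records are split into bi-allelic records at load,
  with dosage counted per split alternate.
* The low-coverage scanner reports maximal runs of positions below a
  depth threshold with a minimum span (default 1000 bp); threshold and
  span are knobs, not claims, since low-coverage calling on real data is
  a judgment about mapping quality.

## The synthetic cohort generator

The generator's defaults describe an Ashkenazi-like PD case cohort:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 1200 | cases |
| `h2_allele_freq` | 0.256 | H2 frequency in the source population |
| `h2_protective_or` | 0.75 | dominant carrier odds ratio targeted by rejection sampling |
| `carrier_freqs` | GBA1 0.196, LRRK2 0.121, dual 0.021, SMPD1 0.007 | founder-mutation subgroup fractions (remainder non-carrier) |
| `amso_mean`, `amso_sd` | 60.5, 11.2 years | onset-age location/scale |
| `female_frac` | 0.396 | cohort sex ratio |
| `n_divergent_snvs` / `n_background_snvs` / `n_indels` | 60 / 120 / 10 | variant layout, scaled down from locus scale so replicate-based tests run in seconds |
| `dp_mean`, `dp_dispersion` | 40, 30 (negative binomial) | per-call depth at well-mapped sites |
| `gq_mean`, `gq_sd` | 80, 10 (clipped Gaussian) | per-call genotype quality |
| `low_dp_mean` | 4 | depth inside the planted low-coverage regions |
| `recombinant_rate` | 0 | per-haplotype recombination probability |

Design choices, made where the scientific description leaves the
mechanism open:

* **Protective effect by rejection sampling.** Case inclusion accepts H2
  carriers with relative probability equal to the target odds ratio, a
  dominant mechanism: the realized case carrier odds equal OR × the HWE
  carrier odds in expectation, so the dominant OR against the generating
  allele frequency is recovered unbiasedly (verified to within 0.03 over
  200 replicates at n = 5000). An allelic mechanism could be swapped in
  by weighting per-haplotype instead of per-carrier.
* **Planted recombinants.** With `plant_recombinants=True`, one clean
  H2/H2 sample receives a proximal-breakpoint recombinant haplotype and a
  second a distal one (breakpoints default to just inside the 4th
  divergent site from each end), while at least one H2/H2 sample stays
  intact. The implied inner block — divergent sites between the two
  breakpoints — is recorded as ground truth, and the fine-mapping chain
  recovers it exactly across seeds.
* **Structured, not i.i.d., coverage noise.** Depth is site-structured:
  well-mapped sites draw from a tight negative binomial whose
  below-threshold probability is ~2 × 10⁻⁵, while two planted flanking
  low-coverage spans (defaults at 1–5% of the region length from each
  end, mirroring the repeat-rich sequence that borders an inversion)
  collapse to mean depth 4 and are eliminated by the call-rate filter.
  An i.i.d. per-call failure rate combined with a call-rate-1.0 filter
  would wipe out every variant at cohort scale, which is not how
  coverage failure behaves; concentrating it in flanking intervals
  reproduces realistic variant attrition while leaving the divergent
  block analyzable.
* **Independence assumptions.** Founder-mutation subgroup, sex and H2
  status are drawn independently (the co-occurrence null itself assumes
  mutation/H2 independence). Mild real-world dependences between sex and
  subgroup are not modeled. GBA1 severity classes (severe/mild/risk at
  0.20/0.55/0.25 among GBA1 carriers, compound-het 4%, N370S-homozygote
  3% of mild) exist only to exercise the AMSO exclusion rule.
* **AMSO.** Onset age is intercept + β_H2·[carrier] + β_sex·[female] +
  N(0, σ), with the intercept solved so the cohort mean hits
  `amso_mean`. Defaults β_H2 = 0 (no onset effect) and β_sex = −1 year
  (a small, plausible sex effect).

What passing tests on this generator do and do not show: they validate
the estimators and the fine-mapping logic against known truth — unbiased
OR recovery, calibrated type-I error, exact interval recovery — but the
generator has no coalescent realism, no LD decay (divergent block versus
independent background only), no genotyping error at the tag, and no
population stratification, so performance on real sequencing data still
depends on upstream calling quality.

## Numerical choices and degenerate inputs

* Composite r² is clipped to [0, 1] against floating-point overshoot and
  is NaN (reported as excluded) for monomorphic partners; a monomorphic
  tag is an error.
* The divergence threshold r² ≥ 0.99 operationalizes "r² ≈ 1" while
  tolerating finite-sample rounding; it is configurable.
* An empty consistent-segment intersection raises (it signals a wrong tag
  or inconsistent genotypes), as does a nominal tag-homozygote with
  dosage < 2 at the tag.
* `dual_carrier_test` requires 0 < k < n; degenerate observed counts are
  an error rather than an infinite odds ratio.
* OLS designs are rejected when a covariate is constant within the
  stratum, naming the column.
* Samples with any missing call among divergent sites are skipped in
  segment detection (the call-rate filter upstream normally guarantees
  completeness).

## Problem sizes

Replicate-based checks use cohorts scaled to keep the full suite fast:
OR recovery at n = 5000 × 200 replicates per generating value
({0.6, 0.75, 1.0}); interval recovery at n = 500 × 20 seeds; AMSO type-I
calibration at n = 1000 × 200 null replicates; null CI coverage at
n = 1500 × 40 replicates. The acceptance script uses 50 replicates for
the OR-recovery summary. These sizes give Monte-Carlo standard errors
well inside the asserted bounds.

## Known limitations

* The r² estimator is the genotypic (composite) correlation, not an
  EM-based haplotype r²; the two coincide on the perfect-LD structure
  that matters here but can differ under partial LD.
* Control genotype expectations assume HWE in the control population;
  deviation from HWE would bias dominant/recessive (not allelic)
  contrasts.
* Observed minimal-interval endpoints are SNV positions; published
  interval bounds for real data may be rounded outward and need not
  match SNV positions exactly.
* The dual-carrier closed-form CI treats the expectation as known among
  the n observed carriers; the MC path's CI depends on the simulated
  population size. Both are reported with their provenance.
* No covariate-adjusted logistic regression, no penetrance modeling, no
  genome-wide scan: the package is a locus-level toolkit.
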