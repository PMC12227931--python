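# Methods

This note documents the models, parameter choices and numerical
conventions behind `mscomorb`, and what the synthetic-data experiments do
and do not demonstrate about real administrative and genetic data.

## Population and archive-event simulator

`SimulationConfig` defines the study conditions. A population of
`n_subjects` is drawn at the reference date (default 2017-12-31, with a
5-full-year lookback window for events):

- **MS status**: Bernoulli at `ms_prevalence`; the default is the
  registry ratio 8850 / 4,274,714 ≈ 2.07 per 1000, and experiments that
  state "2/1000" set it to 0.002 explicitly.
- **AID status**: each of the 14 diseases is conditionally independent
  given MS, with log-odds `logit(baseline) + log(OR_MS)·MS` (an optional
  per-disease female odds ratio can be added). Defaults take the baseline
  prevalence from the published MS-free per-1000 column and the odds
  ratio implied by the two published prevalence columns, so the simulator
  reproduces the registry's marginal disease structure. Pairwise AID–AID
  correlation is deliberately not modelled: each disease is analysed
  marginally downstream.
- **Age**: integer years from a clipped normal (mean 48, SD 19, range
  0–100) — a flat, single-mode stand-in for a regional age pyramid.
- **Hospitalizations**: all-cause 5-year discharge counts are negative
  binomial (dispersion 1) with mean
  `0.6 · 3^MS · 2^anyAID` by default. The multiplicative structure makes
  healthcare contact depend on both MS and comorbidity, which is what
  published per-group contact counts show (overdispersed and
  group-dependent). Note the consequence: in truth-level analyses the
  hospitalization count is a *common effect* of exposure and outcome, so
  fully adjusted ORs sit below crude ORs by construction — the same
  attenuation direction the archive analysis reports. Estimator-validation
  experiments that need an unconfounded target therefore set
  `hosp_rate_ratio_aid = 1`.
- **Event emission**: for each case-finding algorithm and each of its
  streams, a truly affected subject emits the qualifying pattern with the
  per-stream sensitivity and an unaffected subject with 1 − specificity.
  `calibrated_stream_rates(S, Q, k)` inverts the any-stream union
  (sensitivity `1−(1−s)^k`, specificity `q^k`) so that a k-stream union
  algorithm operates at a target point; the default calibrates all four
  streams to the validated MS operating point (95.9% / 99.9%).
  Every subject additionally emits their all-cause discharge events
  (opaque code `ALLCAUSE`), so hospitalization counting works from the
  event tables alone.
- **Surveillance bias** is reproduced by `detection_log_or_per_hosp`:
  a per-subject logit shift of stream sensitivity proportional to the
  hospitalization count. With MS raising contact rates, detected-AID
  prevalence then rises spuriously in the MS group; adjusting for the
  counted hospitalizations attenuates the estimate.

Codes are opaque tokens declared in the algorithm definitions; real
ICD-9-CM/ATC semantics are out of scope, so passing tests say nothing
about the clinical validity of any particular code list — only about the
flagging machinery.

All generators use `numpy.random.default_rng` under a single config seed;
a fixed seed yields byte-identical tables.

## Case finding

A `CaseAlgorithm` is a declarative rule: per-stream code sets, per-stream
minimum counts, an `any`/`all` combination rule (default `any`, matching
multi-source enrichment), a lookback window, and an optional exclusion
rule. Choices where the source design was open:

- The exclusion window is anchored at the subject's **first qualifying
  event**, used as a proxy for the diagnosis date.
- The MS-free comparison population is restricted to the `[min, max]`
  integer-age range of flagged MS subjects — the simplest faithful
  reading of "same age range".
- Subjects vetoed by an exclusion rule are dropped from that disease
  only, not from the cohort.
- Operating characteristics are computed from exact integer 2×2 counts;
  division happens only when a rate is read.

## Association models

- Prevalence per 1000 is exact `1000·k/N`; rounding to 2 decimals happens
  only at display.
- Crude OR: `ad/bc` with Wald 95% CI on the log scale; the
  Haldane–Anscombe 0.5 correction is applied to all cells iff any cell is
  zero, and flagged. Two zero cells on a margin raise.
- Adjusted models: `statsmodels` Logit (Newton/IRLS, tolerance 1e-10,
  100 iterations). Sex is coded female = 1; age and hospitalization count
  enter untransformed. Wald CIs, not profile likelihood, matching
  conventional epidemiological software output. Perfect separation and
  non-convergence are flagged on the result. With no covariates the MS
  coefficient equals the crude log-OR (saturated equivalence, used as an
  oracle in the tests).
- Baseline contrasts: Pearson χ² without continuity correction (samples
  are large throughout) and one-way ANOVA F tests. Degenerate inputs
  raise rather than return NaN. No multiple-testing correction is
  applied, matching the single-table reporting convention it mirrors.

## Genotype QC

Filter order for samples: duplicates → heterozygosity → call rate → sex
check → PC outliers; for variants: call rate → MAF → HWE; post-imputation:
R² → MAF. Each filter is recomputed on the survivors of the previous.
Specifics:

- **Duplicates** use a pairwise identity proportion over best-guess
  genotypes (> 0.95 ⇒ drop the later sample), a deliberate proxy for
  identity-by-descent machinery: the intent (remove genetically identical
  individuals) is testable without KING/PLINK.
- **SD-based filters** (heterozygosity, PC outliers at 3 SD) trim
  *iteratively*, re-estimating mean and SD on survivors until stable.
  This makes the cascade a fixed point of itself — re-running QC on its
  own output removes nothing — at the cost of trimming slightly deeper
  than a single pass on heavy-tailed inputs. Heterozygosity is computed
  on autosomes only, since X heterozygosity is sex-dependent.
- The sample call-rate threshold (0.95) and duplicate threshold (0.95)
  are not published values; they are configurable and recorded in the
  `QcReport`.
- **HWE** is a 1-df χ² goodness-of-fit against expected counts p²N,
  2pqN, q²N — adequate at the 1e-6 threshold for common variants, and a
  documented deviation knob relative to the exact test. Monomorphic
  counts fit trivially (p = 1). Under simulated equilibrium
  (n = 1000, MAF 0.1–0.5) the p-values pass a KS uniformity check.
- **Best-guess conversion** rounds to the nearest of {0, 1, 2}; exact .5
  ties resolve toward the heterozygote (0.5 → 1, 1.5 → 1),
  a deterministic documented convention. MAF is computed from best-guess
  genotypes after conversion.
- **PCs**: each variant centred at 2p and scaled by √(2p(1−p)),
  missing entries mean-imputed, SVD of the standardized matrix; the sign
  convention fixes the largest-magnitude loading positive. Variants are
  used LD-naively (no pruning) — the simulator draws variants
  independently, so pruning would be a no-op there; it is left as a
  future config option for real data.
- The exactly-at-threshold convention is "strict less-than removal":
  R² = 0.6 or MAF = 0.001 survives the post-imputation filter.

## PRS construction

- Scores are **unweighted** risk-allele counts; effect-size weighting is
  out of scope by design.
- Risk alleles may be REF or ALT; counting orients each variant
  accordingly and raises on alleles matching neither.
- **Missing data rule**: post-QC data are expected complete. If a panel
  variant is missing, the default rescales the observed sum by
  n_total/n_observed (keeping the full-panel scale); a strict mode raises
  instead, naming the variant.
- **HLA integration**: the HLA burden is appended to each disease's raw
  score and the denominator enlarged to 2·(n_snps + n_hla). The phrase
  "complemented with the HLA burden, then renormalized" admits a second
  reading (a separately normalized HLA term added per disease); the
  appended-locus reading was chosen because it keeps every disease score
  in [0, 1] and reduces exactly to the non-HLA score when the HLA panel
  is empty. HLA alleles are treated as diallelic carrier loci with counts
  in {0, 1, 2}.
- The generator's default panel sizes span the published 23 (ankylosing
  spondylitis) to 201 (MS) range, with 50 for the unpublished middle; the
  default comorbid enrichment is a per-allele log-odds shift of 0.05 —
  small per locus, but cumulatively detectable at n = 637, which is the
  regime the experiment needs.

## Group comparison

ANCOVA = OLS of the cumulative score on the group indicator + age + sex
(female = 1) + PC1–3; two-sided t-test on the group coefficient. Both
reported covariate sets are always fitted (with and without sex).
Adjusted group means hold covariates at their sample means. Collinear
designs are flagged, not fatal. PC-outlier removal happens in sample QC,
before the comparison.

Calibration checks run at the published group sizes (637 = 65 + 572):
the test's type-I error over 2,000 null replicates must be 0.05 ± 0.01,
and a planted standardized difference of 0.4 is recovered without bias
over 200 replicates. The published significance levels themselves
(p = 0.0078 / 0.015) depend on real genotypes and are not reproduction
targets.

## Problem sizes

The test suite and acceptance script size their simulations to what each
check needs: 200,000 subjects for operating-point recovery (≈400 true MS
cases, giving a ±2.7-point binomial CI around 95.9%), 100,000 × 200
replicates for CI-coverage validation (exposure prevalence raised to 0.2
and outcome baseline to 0.05 there so cell counts keep the Wald
approximation in its comfort zone — this validates the estimator, not the
rare-disease regime), 500,000 for the 14-disease odds-ratio recovery
slope, and 5,000 variants for HWE uniformity.

## Limitations

- Archive codes are opaque tokens; nothing is learned about real code
  lists or their clinical sensitivity.
- Variants are drawn independently: no linkage disequilibrium, no
  population structure beyond what tests plant explicitly, so the PCs of
  default simulated panels are near-isotropic noise.
- AIDs are conditionally independent given MS; real autoimmune
  clustering (shared HLA haplotypes, disease pairs) is not emulated.
- The hospitalization covariate in the default truth-level simulator is
  a common effect of MS and AID status, so fully adjusted truth-level ORs
  are attenuated by construction; the simulator supports switching that
  dependence off for unconfounded targets.
- Mortality, disease onset dynamics and socio-economic covariates are
  out of scope.
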