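# Methods

## Estimation model

All estimators operate on K harmonized instruments, each a quadruple
(β̂ₓₖ, σ̂ₓₖ, β̂ᵧₖ, σ̂ᵧₖ): the SNP's effect on the exposure (SD units per
effect allele) and on the outcome (log-odds per effect allele), with their
standard errors from two non-overlapping GWAS. Throughout, inference on the
pooled slope θ (log-odds of disease per 1-SD exposure increment) conditions
on the SNP-exposure effects being measured without error (the NOME
assumption): the per-SNP Wald standard error is σ̂ᵧₖ/|β̂ₓₖ|, and no
estimator uses σ̂ₓₖ. This matches the standard summary-data MR toolchain;
with strong instruments (the intended use) the neglected exposure-side
noise contributes only a small regression-dilution attenuation, visible in
the synthetic benchmarks when exposure noise is switched on.

* **IVW.** θ̂ = Σβ̂ₓₖβ̂ᵧₖσ̂ᵧₖ⁻² / Σβ̂ₓₖ²σ̂ᵧₖ⁻². The fixed-effect SE is
  (Σβ̂ₓₖ²σ̂ᵧₖ⁻²)^(−1/2); the multiplicative random-effects (MRE) variant
  multiplies it by max(1, √(Q/(K−1))), which equals the residual sigma of
  the weighted through-origin regression, so the MRE SE is never smaller
  than the fixed one and the point estimate is identical. K=1 reduces
  exactly to the Wald ratio. p-values are two-sided normal.
* **Weighted median.** Wald ratios ordered, weighted by se(θ̂ₖ)⁻²; with
  normalized ordered weights w₍ⱼ₎ and cumulative sums Sⱼ, the j-th ratio
  sits at pⱼ = Sⱼ − w₍ⱼ₎/2 and the estimate interpolates θ linearly at
  p = 0.5 (clamped at the extreme ratios). Its SE is a parametric
  bootstrap: β̂ₓₖ and β̂ᵧₖ are resampled from normals at their reported
  SEs, the median recomputed, and the SD over replicates taken
  (default 5000 replicates, always seeded; with a fixed seed the SE is
  bit-reproducible). p two-sided normal.
* **MR-Egger.** Instruments are oriented so all β̂ₓₖ ≥ 0 (negating both
  betas where needed — an allele re-coding, which leaves every slope
  estimator invariant but is required for the intercept to be
  interpretable), then β̂ᵧ is regressed on β̂ₓ with weights σ̂ᵧ⁻² and a
  free intercept. SEs multiply the normal-equation SEs by
  max(1, σ̂_resid) — the residual dispersion is floored at 1, mirroring
  the widely used R implementation, so Egger SEs also never undercut the
  homoscedastic weighted fit. Both quantities get two-sided p from t with
  K−2 df. The intercept estimates the average direct (pleiotropic) effect;
  under the InSIDE assumption the slope remains a consistent causal
  estimate when directional pleiotropy biases IVW.
* **Reporting.** Estimates are exponentiated to odds ratios. Confidence
  intervals are exp(b ± z·se) with the *normal* quantile for every method,
  including Egger — deliberately decoupled from the t reference used for
  Egger p-values, because that asymmetric convention is what the standard
  R tooling prints and is the one published MR tables round-trip against.
  p-values that underflow are floored at the smallest positive double so
  the (0, 1] contract holds.
* **Diagnostics.** Cochran's Q = Σ((θ̂ₖ − θ̂_IVW)/se(θ̂ₖ))² is centred on
  the *fixed-effect* IVW estimate (the convention that pairs Q with the
  IVW table row) and referred to chi-square with K−1 df. Leave-one-out
  recomputes IVW excluding each SNP in turn. Forest, scatter (points
  oriented β̂ₓ ≥ 0, one fitted line per slope method, intercept zero
  except Egger) and funnel tables are emitted as TSVs; figure rendering is
  separated into `mrpipe.plots` so all numerics stay headless.

## Harmonization

Outcome records are re-expressed on the exposure's effect allele: identical
allele pairs pass through; swapped pairs negate the outcome beta and
complement its allele frequency; pairs matching only after strand
complement are complemented first (and then possibly swapped). Palindromic
SNPs (A/T, C/G) carry no strand information in their alleles, so
orientation falls back on allele frequencies: both frequencies must be
present and outside 0.5 ± w (default w = 0.08, configurable) — concordant
sides keep the nominal alignment, discordant sides flip — otherwise the SNP
is dropped as ambiguous. Indels, multi-allelic records and irreconcilable
pairs are dropped as incompatible. Standard errors are never modified. A
per-status audit (kept / allele_flipped / strand_flipped /
dropped_palindromic / dropped_incompatible / absent_from_outcome) is logged
for every pair so the instrument count entering each analysis is fully
accounted for. The conservative drop-when-ambiguous palindromic policy and
the 0.08 window are package choices; source studies rarely disclose theirs,
which is precisely why the audit exists.

Instruments missing from the outcome GWAS may be rescued through a
user-supplied LD-proxy table; a substitution is accepted when r² ≥ 0.8 and
the proxy is present in the outcome, taking the first qualifying map entry
and logging alternatives. LD itself is never computed here — proxy search
belongs to reference-panel tooling.

## Synthetic data generator

`simulate_instruments` draws exactly the generative model the estimators
assume: true strengths γₖ ~ U(0.05, 0.15) (exposure-SD units, bounded away
from zero so weak-instrument artefacts do not contaminate unit tests),
direct effects αₖ = 0 for valid instruments, observed
β̂ₓₖ ~ N(γₖ, se_exposure²) and β̂ᵧₖ ~ N(θγₖ + αₖ, se_outcome²). Default
noise levels se_exposure = 0.01, se_outcome = 0.02 give per-SNP Wald SEs
around 0.2, typical of metabolite instruments against large case-control
outcome GWAS. Pleiotropy regimes: *balanced* (αₖ ~ N(0, τ²) on an invalid
fraction — InSIDE holds, IVW approximately unbiased, Q inflates) and
*directional* (αₖ ~ N(μα, τ²) — IVW biased by roughly
E[α]·E[γ]/E[γ²]). A zero-exposure-noise switch provides the exact-NOME
regime for recovery tests. All randomness flows from a single scenario
seed via `SeedSequence` spawning, one child stream per replicate, so the
full benchmark table is reproducible.

`estimator_benchmark` summarises seeded replicates per method: bias,
empirical SE, CI coverage of the truth, and rejection rate of the method's
null — for the Egger intercept that rejection rate is pleiotropy-detection
power (its bias is measured against the realized mean direct effect), and
a Cochran-Q row reports heterogeneity-detection rate. Benchmarks default
to 100–200 bootstrap replicates per weighted-median fit — enough for rate
estimation across many replicates, versus 5000 for a single reported
analysis.

What the generator does *not* emulate: LD between instruments (the paper's
instruments are pre-clumped, and so are simulated ones), allele-frequency
structure, case-control ascertainment, winner's-curse selection of
instruments, or sample overlap between the two GWAS. Passing benchmarks
therefore demonstrate estimator correctness under the two-sample model,
not robustness to those real-data complications.

Benchmark scenario sizes (1000 replicates for calibration checks, 500 for
pleiotropy regimes, K = 20 instruments) keep the whole suite and the
acceptance script in the seconds-to-minutes range while leaving
Monte-Carlo error well below the effects being asserted. The directional
robustness scenario uses μα = 0.04 (≈ 0.4× the mean instrument strength),
30% invalid instruments; the detection-power scenario makes pleiotropy
pervasive (100% invalid) because the Egger intercept tests the *mean*
direct effect — with a narrow instrument-strength range and a small
invalid minority, the intercept is weakly identified and Q (which sees the
outlying SNPs individually) is the more sensitive detector, a known
trade-off worth remembering when reading real Egger intercepts.

## Multiple-testing tiers

For an m-exposure × n-outcome family the Bonferroni threshold is
α/(m·n) — 0.05/9 ≈ 0.0056 for a 3 × 3 screen. p < threshold is
*significant*, threshold ≤ p < α *suggestive*, otherwise *null*. With a
single test the threshold equals α and the suggestive band is empty; a
threshold exceeding α is rejected as a configuration error.

## Numerical and degenerate-input choices

* β̂ₓₖ = 0 raises a degenerate-instrument error (Wald ratio undefined).
* Zero variance in oriented β̂ₓ makes the Egger design collinear → error.
* Weighted median and Egger require K ≥ 3; Q requires K ≥ 2; MRE-IVW with
  K = 1 falls back to the fixed SE with a warning.
* The weighted-median interpolation clamps at the extreme ratios when half
  the weight lies beyond them.
* Ties in ratios are handled by stable sorting; the estimate is invariant
  to input order.
* Pipeline runs are byte-reproducible for a fixed config and seed; the
  master table rounds ORs/CIs to 3 decimals and p to 3 significant figures
  (publication style), while per-pair TSVs keep full precision.

## Known limitations

Single-exposure models only (no multivariable MR), no MR-PRESSO-style
outlier removal, no mode-based estimators, no reverse-direction analyses,
no LD-aware modelling, and no correction for weak instruments beyond the
design choice of simulating strong ones. The harmonizer matches on variant
ID, not position, so inputs must share an rsID namespace.
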