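# Methods

## Model and assumptions

The pipeline estimates the causal effect θ (log-odds of outcome per SD of
exposure) from summary statistics of two non-overlapping GWAS cohorts.
Each instrument j must satisfy the three instrumental-variable conditions:
relevance (associated with the exposure), independence (not associated
with confounders), and exclusion restriction (no effect on the outcome
except through the exposure). Under those conditions every Wald ratio
Γ_j/γ_j estimates θ, and the estimators differ only in how they pool the
ratios when some instruments are invalid:

- **IVW**: b = Σ w_j r_j / Σ w_j with r_j = Γ_j/γ_j and w_j = 1/se(r_j)²,
  se(r_j) = σ_Γj/|γ_j| (first order). Equivalent to a zero-intercept
  weighted regression of Γ on γ with weights 1/σ_Γj². Unbiased only if
  *all* instruments are valid; the primary method because it is the most
  precise when they are. The default SE is multiplicative random-effects:
  the fixed-effect SE (Σw)^(−1/2) inflated by max(1, √(Q/(J−1))). This is
  conservative under heterogeneity and reduces to fixed-effect when Q is
  small; a `fixed` model is available by configuration.
- **MR-Egger**: weighted regression of Γ on γ with a free intercept,
  instruments oriented to γ ≥ 0. The intercept estimates the average
  directional pleiotropy; the slope is a pleiotropy-adjusted effect,
  consistent under the InSIDE assumption (pleiotropy independent of
  instrument strength). SEs carry the max(1, residual-SE) multiplicative
  inflation; p-values use Student t with J−2 df — this combination makes
  the intercept test exactly calibrated under balanced pleiotropy of any
  magnitude.
- **Weighted/simple median**: the 0.5-crossing of the (half-step
  normalized) cumulative weight over the sorted ratios, with linear
  interpolation; consistent while valid instruments carry > 50% of the
  weight. SE by parametric bootstrap: ratios resampled from
  N(γ_j, σ_γj), N(Γ_j, σ_Γj) with weights held at their observed values,
  SD over draws.
- **Weighted/simple mode**: the maximizer of a Gaussian-kernel density of
  the ratios; consistent when the largest group of instruments sharing one
  ratio is the valid group. Bandwidth is the modified Silverman rule
  0.9·min(SD, 1.4826·MAD)·J^(−1/5) times a configurable factor (default 1).
- **Wald ratio**: the single-instrument degenerate case.

Applicability by instrument count: k = 1 → Wald ratio only; k = 2 → IVW
only (the regression- and quantile-based methods need ≥ 3); k ≥ 3 → all
six. Exposures with k < 3 carry a `low_iv_flag` in the report: their
estimates rest on too few instruments for any internal consistency check,
so they are reported but flagged rather than suppressed.

## Instrument selection

Filters are applied in order: p < 5×10⁻⁶ (strict inequality), greedy LD
clumping, MAF filter (variants with min(eaf, 1−eaf) ≤ 0.01 removed;
variants with no frequency pass with a warning), then the F > 10 screen.
The relaxed p threshold is the convention for microbiome GWAS, whose
per-taxon heritability rarely yields genome-wide-significant hits.

Clumping sorts by ascending p (ties broken by chromosome, position, rsid,
making the kept set invariant to input row order), keeps the best
remaining variant, and discards unkept variants on the same chromosome
within 1 Mb (closed interval) whose r² with it is ≥ 0.001. Variant pairs
absent from the LD source are treated as independent with a warning —
the safe default when no reference panel is bundled.

Variance explained and instrument strength use R² = β²/(β² + SE²) and
F = R²(N−1−K)/((1−R²)K). Per-variant F uses K = 1, which collapses to
(β/SE)²·(N−2)/(N·…) ≈ the squared z-score for large N; the F > 10 screen
is applied per variant, and the reported per-taxon value is the mean over
retained instruments.

## Harmonization

Exposure and outcome rows are joined by rsid. Identical allele pairs are
kept as-is; swapped pairs have the outcome beta negated; palindromic
variants (A/T, C/G) are dropped unconditionally — their strand is
ambiguous between cohorts and frequency-based inference is impossible when
the exposure source omits allele frequencies. No complementary-allele
(strand-flip) rescue is attempted: such records are dropped as mismatches,
trading a few instruments for immunity to silent sign errors. An rsid with
multiple outcome records is dropped as ambiguous. Every input instrument's
fate is recorded as an action label, and the drop tallies are exhaustive
and mutually exclusive by construction.

## Sensitivity battery

- **Cochran's Q** over the ratios with fixed-effect center; p from
  χ²(J−1). Note Q is exactly calibrated only under θ = 0: when θ ≠ 0,
  exposure-side sampling error contributes genuine ratio heterogeneity of
  relative magnitude θ²σ_γ²/σ_Γ², which Q correctly detects.
- **Egger intercept test**: t-test of intercept = 0 (see above).
- **Leave-one-out**: IVW re-estimated excluding each instrument in turn;
  with two instruments each entry degenerates to the other's Wald ratio.
- **MR-PRESSO**: observed statistic Σ_j w_j(Γ_j − θ̂₍₋ⱼ₎γ_j)² with
  leave-one-out IVW slopes; null distribution from parametric simulation
  (γ*, Γ* drawn at their SEs around the fitted model), with the
  leave-one-out slopes recomputed inside each simulated dataset.
  Empirical p-values carry the +1 continuity correction (minimum
  1/(n_sim+1), default n_sim = 1000). Per-variant outlier p-values are
  Bonferroni-adjusted across J and flagged below 0.05; the distortion
  test compares the full and outlier-removed slopes against a null built
  by removing random non-outlier subsets of the same size. MR-PRESSO
  requires ≥ 4 instruments — with 3, the leave-one-out slopes rest on
  pairs and the simulation calibration is meaningless. When outliers are
  flagged, all estimators are recomputed on the corrected set and both
  versions are reported; the raw IVW p remains the FDR input, so outlier
  handling is visible rather than silently folded into the screen.

## Multi-taxon screen and FDR

The Benjamini–Hochberg step-up procedure is applied to the primary
p-values (IVW; Wald ratio when k = 1) of **all taxa attempted within one
run against one outcome cohort** — including null results. The family is
recorded in the run metadata, since q-values are meaningless without it.
Other estimators are reported unadjusted, as sensitivity evidence.
Discoveries are FDR < 0.05. A two-cohort design is two runs with two
separate families. Taxa failing any stage produce a structured skip record
(`no_instruments`, `nothing_to_harmonize`, `estimator_failure`).

## Synthetic-data generator

The generator emulates summary-level GWAS pairs, not genotypes. Per
variant: frequency ~ U(0.05, 0.5); SE = 1/√(2p(1−p)N) — the
standardized-trait approximation, under which, for a case-control outcome,
N must be the *effective* sample size 4/(1/cases + 1/controls). Defaults:
N_exposure = 18,340 (the scale of the largest gut-microbiome GWAS
meta-analysis) and N_outcome = 20,914 (the effective size of a ≈ 5.5k
case / 90k control cohort). Causal effects are drawn |N(0, σ_γ)| with σ_γ
set so the median per-variant F is configurable (default 30 — the typical
strength of instruments passing a 5×10⁻⁶ screen); effect alleles are coded
exposure-increasing so directional pleiotropy is well defined. True
outcome effects are Γ = θγ + α with pleiotropy α ~ N(mean, sd), optionally
correlated with γ (InSIDE violation, ρ = 0.6). Three invalidity flavours
exist because the robust methods are sensitive to different ones: diffuse
pleiotropy (α), gross outliers (α += 10× outcome SE, for MR-PRESSO power),
and correlated pleiotropy (a shared Wald-ratio offset on a fixed fraction
of equal-strength instruments, for breakdown-point studies — equal
strength pins each instrument's share of the inverse-variance weight).

LD is generated at the summary level: variants in a block share an
attenuated index signal (√r²·γ_index) and equicorrelated noise, giving
pairwise summary r² ≈ the configured value, and the pairwise r² table is
exposed for clumping. Palindromic allele pairs and swapped-orientation
outcome rows (negated beta, complemented frequency) exercise
harmonization. Everything is deterministic given the config seed.

What the generator does **not** emulate: genuine genotype-level LD and
population structure, sample overlap between cohorts, winner's-curse from
discovery-and-use of the same exposure GWAS, non-normal effect-size
distributions, and real microbiome taxonomy (taxa are opaque, independent
labels). Passing calibration here therefore shows the statistical
machinery is correct under its stated model, not that real-data biases
are absent.

## Numerical choices

- Wald-ratio SEs are first order (σ_Γ/|γ|); no second-order correction.
- ORs and CIs: OR = exp(b), CI = exp(b ± 1.96·se), so ci_low·ci_high =
  exp(2b) exactly.
- p-values: two-sided normal everywhere except the Egger slope/intercept
  (t, J−2 df). Degenerate zero-SE fits (noise-free data) report p = 1 for
  a zero estimate and p = 0 otherwise.
- Mode search: 512-point grid over the ratio range extended by 3
  bandwidths; density ties resolve to the smallest grid value. When a
  bootstrap draw contains an extreme ratio (near-zero resampled γ), the
  grid is confined to a ±50-bandwidth window around the median so the
  mode stays resolvable; the density maximum of any multi-point cluster
  lies inside that window.
- Bootstraps default to 1000 draws; every stochastic component (bootstrap,
  MR-PRESSO, generator) draws from one run-level seed through fixed
  per-method and per-taxon offsets, so whole-run outputs are byte-identical
  under a repeated seed.
- Results tables are written with 12 significant digits so a write→read
  round trip preserves values to at least 10 significant digits;
  inapplicable cells use the `-` sentinel.
- Monte-Carlo study sizes (1000 replicates for bias/coverage/type-I, 500
  for breakdown, 200 for MR-PRESSO power, 3×50 taxa for the null screen)
  were chosen so each rate is estimated to ~1% precision while the whole
  calibration suite runs in well under a minute.

## Known limitations

- No proxy-SNP search for instruments missing from the outcome, no
  strand-flip rescue, no liftover: variants are used as published or
  dropped.
- The "fewer than three occurrences" cohort-count filter sometimes applied
  to consortium meta-analyses has no operational definition from summary
  files alone and is not implemented; low-instrument exposures are flagged
  instead.
- MR-Egger's slope is reported but is attenuated under weak instruments
  (no SIMEX correction); the intercept test is the calibrated component.
- No multivariable MR, Steiger filtering, reverse-direction analysis, or
  meta-analysis across outcome cohorts.
- Cochran's Q and the IVW random-effects inflation treat exposure-side
  noise as heterogeneity when θ ≠ 0; this is conservative, not biased,
  and disappears as instrument strength grows.
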