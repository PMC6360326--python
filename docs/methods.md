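# Methods

## Model and assumptions

The package estimates the causal effect θ (log-odds of a binary outcome per
1 SD of a quantitative exposure) from two independent GWAS. The structural
assumptions are the usual instrumental-variable triad: each SNP is (i)
associated with the exposure, (ii) independent of confounders of the
exposure–outcome relationship, and (iii) affects the outcome only through
the exposure (exclusion restriction). Under (i)–(iii) each per-SNP Wald
ratio is a consistent estimate of θ, and the estimators differ in how they
combine ratios and in which violations of (iii) they tolerate:

* **IVW (fixed effects)** — precision-weighted mean with weights
  w_j = β̂²_Xj/σ²_Yj; optimal when all instruments are valid. The
  **random-effects** variant multiplies the SE by √max(1, Q/(k−1))
  (multiplicative overdispersion); an additive between-SNP variance
  component is deliberately not implemented.
* **MR-Egger** — weighted regression of β̂_Y on β̂_X with an intercept,
  weights 1/σ²_Yj. The slope is consistent under InSIDE (pleiotropic
  effects independent of instrument strengths) even when all instruments
  are pleiotropic; the intercept estimates the mean directional pleiotropic
  effect and its test is the pleiotropy diagnostic. Because the regression
  is not invariant to allele recoding, instruments are first re-oriented so
  every β̂_X ≥ 0 (both betas negated together). Both SEs carry the same
  overdispersion factor √max(1, RSS_w/(k−2)), floored at 1; the unscaled
  slope SE is reported alongside since published analyses do not always
  scale.
* **Weighted median** — ratios sorted ascending, normalized weights
  accumulated to midpoints s_j = Σ_{i<j} w′_i + w′_j/2, estimate
  interpolated at s = 0.5. Consistent when valid instruments carry ≥ 50% of
  the weight. The SE is a parametric bootstrap (default 10,000 draws of
  (β̂_X, β̂_Y) from normals at their SEs; an explicit seed is required).
* **Multivariable MR** — *joint*: weighted regression of β̂_Y on all
  exposure beta columns without intercept, weights 1/σ²_Yj, SEs from the
  weighted normal equations with the √max(1, RSS_w/(k−m)) floor; with one
  exposure this is algebraically identical to fixed-effects IVW.
  *Residual-based*: the target exposure's betas are residualized on the
  covariate exposures' betas by unweighted OLS with intercept, then
  fixed-effects IVW runs on the residualized betas. The residual regression
  is unweighted because clumped instruments have near-homogeneous exposure
  SEs; with heterogeneous outcome SEs the residual route acquires a small
  weighting bias, which is why the joint route is the primary multivariable
  estimator. Requesting HDL, LDL, TC and TG together is refused up front:
  TC is a near-exact linear combination of the other three, so the design
  is singular by construction. The "LDL controlling for LDL/HDL" analysis
  is realized as joint MVMR over {LDL, HDL}, reporting the LDL coefficient.

All p-values are two-sided from the standard normal (large-sample GWAS
practice; no t reference), and 95% intervals use z = 1.959964. Heterogeneity
uses Cochran's Q = Σ w_j (θ̂_j − θ̂_IVW)² on k−1 df with
I² = max(0, (Q−df)/Q)·100.

## Instrument selection

SNPs passing P ≤ 5×10⁻⁸ are clumped greedily: rank by ascending p (ties
broken lexicographically by SNP id, making the output independent of input
row order), keep the best remaining SNP, discard all others within 1 Mb on
the same chromosome — or, when a caller-supplied r² matrix is given, all
others with r² ≥ 0.001. A distance window stands in for LD-panel clumping
so no reference-panel download is needed; the r² path exists for callers
who have an LD matrix. After harmonization, instruments marginally
associated with the outcome at P < α/k (Bonferroni over the pre-removal k)
are excluded as likely exclusion-restriction violations. Instrument
strength uses the summary-statistics approximation
PVE = β²/(β² + n·se²) and F = PVE(n−2)/(1−PVE); F ≤ 10 triggers a
weak-instrument warning but no automatic removal.

## Harmonization

Exposure and outcome records are matched by SNP id only; positional
disagreement is logged, not fatal, since sources often use different genome
builds. Allele swaps negate the outcome beta; strand flips are resolved by
complementing. Palindromic SNPs (A/T, C/G) default to `drop_ambiguous`:
dropped when either side's effect-allele frequency is missing or within
[0.42, 0.58], otherwise oriented by whether the two frequencies fall on the
same side of 0.5. Records whose reported p disagrees with the two-sided
normal p of beta/se by more than 10% relative on the −log10 scale are
flagged (not dropped) — published tables round aggressively, so the band is
deliberately loose.

## Power

For a binary outcome with case fraction K = n_cases/N, alternative odds
ratio OR per exposure SD and instrument strength R² on the exposure:

    b   = K (OR / (1 + K(OR − 1)) − 1)
    v   = (K(1 − K) − b²) / (N · R²)
    NCP = b² / v
    power = P[ χ²₁(NCP) > χ²₁ quantile at 1 − α ]

Power is reported half-up rounded to whole percent. The transform b(K, OR)
is not exactly symmetric in OR ↔ 1/OR: a protective OR of 0.90 yields
slightly more power than 1.10 (≈7 percentage points at the European design,
< 2 at the East Asian one). Fixed-effect meta-analysis pools per-population
log-OR estimates with weights 1/se²; when only an OR with 95% CI is
published, the SE is recovered as (ln hi − ln lo)/(2·1.959964). A z-test on
the difference of two estimates checks the equal-effect assumption before
pooling.

## Synthetic-data generator

The generator draws, per SNP: a MAF f_j ~ Uniform(0.05, 0.5); a true
exposure effect γ_j = √(R²·s_j / (2 f_j (1−f_j))) where the shares s_j are
equal by default (an exponential-decay alternative is a config switch) —
equal shares make the total instrument R² exactly controllable; a
pleiotropic effect α_j ~ Normal(μ_α, σ²_α), optionally correlated with γ_j
(the InSIDE-violation knob, default off); and observed effects
β̂_Xj ~ N(γ_j, σ²_Xj), β̂_Yj ~ N(θγ_j + α_j, σ²_Yj) with
σ_Xj = (2 f_j(1−f_j) n_X)^(−1/2) and
σ_Yj = (2 f_j(1−f_j) n_Y K(1−K))^(−1/2) — the K(1−K) factor is the
effective-sample-size deflation of a binary trait, matching the power
module's variance algebra. True effects are positive by default so that
directional pleiotropy remains directional after the Egger orientation
step. Loci are spaced 10 Mb apart across 22 chromosomes; optional LD blocks
place groups of adjacent SNPs 10 kb apart within one clump window to
exercise clumping. P-values are computed exactly from beta/se, so generated
records always satisfy the consistency check. Identical configs are
bit-identical (numpy `default_rng(seed)`).

Defaults emulate the European LDL arm of the design the package reproduces:
78 instruments, total R² = 8.75%, exposure GWAS n = 188,577, outcome GWAS
n = 41,689 with case fraction 14,791/41,689. Presets:

| preset | purpose | deviations from defaults |
|---|---|---|
| `null` | type-I error calibration | θ = 0 |
| `causal` | bias/coverage calibration | θ = 0.1 |
| `directional_pleiotropy` | Egger intercept power | θ = 0.1, μ_α = 0.03, σ_α = 0.01 |
| `balanced_pleiotropy` | Q inflation without bias | θ = 0.1, σ_α = 0.02 |
| `heterogeneous` | strong ratio heterogeneity | θ = 0.1, σ_α = 0.05 |
| `weak_instruments` | F ≈ 10 screen | n_X = 20,000, 50 SNPs, R² = 0.025 |

The directional mean 0.03 log-odds was chosen from the analytic Egger
intercept SE at the default design (≈0.009), making the intercept a ~3σ
signal — large enough for a powered test, small enough to be a plausible
pathway effect. The weak-instrument R² puts the per-SNP noncentrality near
10 so observed F statistics straddle the conventional screen.

What the generator does *not* emulate: realistic LD structure (blocks are
positional only, r² is not simulated), allele-frequency differences between
the two GWAS, strand ambiguity (all variants are A/G), sample overlap
between exposure and outcome studies, winner's-curse bias in instrument
effects, and non-normal effect-size distributions. Passing calibration
tests therefore demonstrates correctness of the estimators under the
two-sample summary-data model, not robustness to those real-data
complications.

## Numerical choices and degenerate inputs

* Wald-ratio SE is first-order (outcome noise only), consistent with the
  IVW weights; the second-order exposure-noise term is omitted. The
  resulting weak-instrument attenuation is real: the Egger intercept, in
  particular, absorbs part of the slope attenuation when per-SNP strengths
  have little spread relative to exposure sampling noise, so intercept
  consistency requires strong instruments.
* Zero exposure beta → explicit undefined-ratio error, never silent
  division. k below an estimator's minimum (1 for fixed IVW, 2 for random
  IVW/heterogeneity, 3 for Egger/median/LOO, m+1 for joint MVMR) →
  insufficient-instruments error.
* Q = 0 (identical ratios) gives I² = 0 and p = 1; Q < df truncates I² to 0.
* Overdispersion factors are floored at 1 everywhere, so robust SEs never
  undercut the fixed-effects SE.
* Leave-one-out flags an instrument when its exclusion moves the estimate
  by > 30% of the full-set magnitude or flips significance at 0.05 — a
  numeric stand-in for the visual inspection such plots usually get. The
  effect-size outlier screen defaults to |β̂_X| > 0.40 (per-SD), the scale
  at which large-effect lipid variants start to carry elevated pleiotropy
  risk; both thresholds are configurable.
* Bootstrap SE of exactly 0 (fully degenerate resamples) is replaced by the
  smallest positive float so downstream z-statistics stay finite.

## Problem sizes

The calibration tests run 1,000 replicates for type-I error and 200 each
for coverage and Egger-intercept power at the default 78-SNP design —
enough for binomial 99% bands of width ≈ ±1.8 percentage points around
0.05 — and the oracle comparisons use 100 random instrument sets per
estimator. The full suite completes in a few seconds on one core.

## Known limitations

* No proxy-SNP lookup, liftover, or VCF input; matching is by SNP id.
* Clumping without an LD matrix is purely positional.
* No MR-PRESSO, mode-based or contamination-mixture estimators; no additive
  random-effects meta-analysis; no conditional F statistics for MVMR.
* The mg/dL → mmol/L odds-ratio conversion of published estimates is not
  provided; `to_or_per_unit` rescales per-SD estimates to any mg/dL unit
  given the trait SD (published SDs: HDL 15.1, LDL 39.0, TC 40.6,
  TG 79.3 mg/dL).
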