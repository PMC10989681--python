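# Methods

## Model and estimators

For each exposure/outcome pair the data are GWAS summary statistics: per
SNP *j*, an exposure association γ̂ⱼ with SE s₁ⱼ and an outcome
association Γ̂ⱼ with SE s₂ⱼ, expressed on a shared effect allele. Under
the instrumental-variable assumptions (relevance, independence from
confounders, no direct path to the outcome) each SNP identifies the causal
effect θ through its Wald ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ.

**Ratio SE.** The default is the first-order delta approximation
s₂ⱼ/|γ̂ⱼ|, which ignores exposure-side sampling noise (the NOME
approximation). A second-order variant adding Γ̂ⱼ²s₁ⱼ²/γ̂ⱼ⁴ is available
behind a flag (`wald_ratios(..., second_order=True)`). See *Known
limitations* for when the first-order form is inaccurate.

**IVW.** Fixed-effect: inverse-variance-weighted mean of the ratios,
SE = (Σwⱼ)^(-1/2). This equals the zero-intercept weighted regression of
Γ̂ on γ̂ with weights s₂ⱼ⁻² (tested as an algebraic identity). The
random-effects variant applies multiplicative overdispersion,
SE × max(1, √(Q/(J−1))) — it never deflates below the fixed-effect SE and
leaves the point estimate unchanged. Mode `auto` (the pipeline default)
uses random effects when the Q p-value is below 0.05, fixed otherwise.
Inference is normal; intervals use the multiplier 1.959964.

**MR-Egger.** Instruments are first oriented so γ̂ⱼ ≥ 0 (both betas
negated when γ̂ⱼ < 0), then Γ̂ⱼ is regressed on γ̂ⱼ with an intercept and
weights s₂ⱼ⁻² (statsmodels WLS is the numeric engine). The intercept
estimates the mean directional pleiotropic effect; the slope is the
bias-adjusted causal estimate. SEs carry the same max(1, √(Q/(J−2)))
inflation and p-values use t with J−2 df — the conventional small-J
choice. At least 3 instruments are required.

**Weighted median.** Ratios are sorted; with standardized inverse-variance
weights, the estimate interpolates linearly at the 0.5 crossing of the
centered cumulative weights pⱼ = (Σ_{i≤j} wᵢ − wⱼ/2)/Σwᵢ. Its SE is a
parametric bootstrap: each ratio resampled from Normal(β̂ⱼ, seⱼ) with
weights held fixed, 1000 replicates by default, explicit seed mandatory
in pipeline context. The estimator is consistent while valid instruments
carry > 50% of the weight.

**OR rendering.** Binary-outcome estimates (log odds ratios per 1 SD of
exposure) render as exp(β) with exp(β ± 1.959964·SE), three decimals,
en-dash-separated CI.

## Diagnostics

**Cochran's Q** around the IVW slope (weights = ratio weights, df J−1) or
the Egger fit on the outcome scale (weights s₂ⱼ⁻², df J−2); chi-square
upper-tail p.

**Leave-one-out**: IVW (mode auto) on every J−1 subset, J ≥ 3.

**Pleiotropy residual-sum / outlier test (MR-PRESSO).** Observed statistic
RSS = Σⱼ wⱼ(Γ̂ⱼ − b₍₋ⱼ₎γ̂ⱼ)² with b₍₋ⱼ₎ the leave-one-out IVW slope and
wⱼ = s₂ⱼ⁻². The null distribution comes from parametric replicates
γ*ⱼ ~ N(γ̂ⱼ, s₁ⱼ²), Γ*ⱼ ~ N(b₍₋ⱼ₎γ̂ⱼ, s₂ⱼ²), with the statistic
recomputed identically per replicate; empirical p-values use
(r+1)/(n_sim+1) so they are never zero. Per-SNP outlier p-values are the
empirical tails of the per-SNP weighted residuals, Bonferroni-multiplied
by J; SNPs below α = 0.05 are removed and IVW re-fit as the corrected
estimate (exactly IVW on the remaining subset). Minimum J = 4. The
distortion test is not computed; the result object says so explicitly
rather than silently omitting it.

## Screening and FDR

Per pair: select instruments at p < 1 × 10⁻⁵ (strict inequality), clump
greedily (keep the smallest p, ties by SNP id; discard same-chromosome
SNPs within 10,000 kb that have pairwise r² ≥ 0.001 — with no LD matrix
the distance rule alone applies; the window boundary is inclusive),
harmonize to the exposure's effect allele, drop instruments with F ≤ 10,
then run all estimators and diagnostics. Harmonization resolves swapped
alleles (beta negated, eaf complemented) and strand complements;
palindromic SNPs are aligned by allele frequency only when both eafs lie
outside 0.5 ± 0.08 (configurable), and dropped otherwise — a conservative
standard policy.

BH step-up FDR is applied to the IVW p-values with the family size fixed
at the full panel (m = 41 in the motivating design), one family per
direction × disease screen. Traits yielding zero usable instruments
contribute p = 1 rather than shrinking the family, so the multiplicity
burden does not depend on instrument availability. When fewer p-values
than m are supplied to `bh_adjust`, they are treated as the smallest
ranks of the family; this is equivalent to padding the family with
p = 1 (cross-checked against statsmodels on padded inputs).

Per-pair seeds for the stochastic stages (bootstrap, PRESSO) are derived
by hashing (master seed, exposure name, outcome name), making results
invariant to panel ordering and reproducible bit-for-bit.

## Synthetic data

The generator emulates a cytokine-panel screen: per trait, 8–30
independent instruments (drawn per trait unless fixed), exposure GWAS
sample sizes drawn from 839–8,293 (small population cytokine panels) and
a large outcome GWAS (458,620 by default). MAF ~ U(0.05, 0.5); per-allele
exposure effects are half-normal with SD 0.25 — the effect allele is
reported as the exposure-increasing allele. That orientation convention
matters: with sign-symmetric effects, the γ ≥ 0 orientation used by
MR-Egger flips the sign of half the simulated direct effects, silently
turning directional pleiotropy into balanced pleiotropy; directional
pleiotropy is only defined relative to a fixed orientation. SEs follow
the standard per-allele form (2·maf·(1−maf)·n)^(-1/2); exposure and
outcome noise are independent (non-overlapping samples, the two-sample
assumption). Phenotypic variances are normalized to 1 so effects are in
SD units; binary outcomes are emulated directly on the log-OR scale with
SEs set by the same formula (no liability-scale modeling).

Pleiotropy regimes: `none` (αⱼ = 0), `balanced` (αⱼ ~ N(0, σ²)),
`directional` (αⱼ ~ N(μ, σ²)), and `inside_violating` (αⱼ correlated
with γⱼ at ρ). A configurable fraction of SNPs is palindromic (default
0.1) to exercise the harmonization policy, and a weak fraction draws
effects from a much smaller scale (SD 0.02) to exercise the F filter.
Simulated loci are spaced > 10,000 kb apart so distance clumping is a
no-op on truly independent SNPs.

What the generator does **not** emulate: LD between instruments, sample
overlap, population stratification, winner's-curse selection bias, and
liability-scale attenuation for binary traits. Passing tests therefore
demonstrate correctness of the estimators and pipeline mechanics under
the stated model, not robustness to those real-data complications.

## Calibration checks and problem sizes

The statistical acceptance tests use deliberately scaled designs, chosen
as the smallest sizes at which each property is sharply testable:

- **IVW coverage** (500 replicates, 20 SNPs, θ = 0.1) is evaluated in the
  disease → cytokine regime (exposure n = 458,620, outcome n = 8,293),
  where exposure noise is negligible and the first-order delta SE is
  accurate; measured coverage ≈ 0.95.
- **Null-screen FDR** uses 60 independent 41-trait null panels. Because
  BH under a global null rejects with probability ≈ 1 − e^(−q) ≈ 0.049,
  a raw sample-mean comparison against 0.05 would fail by Monte-Carlo
  noise alone about 40% of the time; the bound is therefore asserted via
  a one-sided exact binomial test (5% false-alarm rate by construction).
- **Pleiotropy recovery** uses 300 replicates of the directional regime
  (μ = 0.05, σ = 0.02): the mean Egger intercept must sit within 3
  standard errors of 0.05 while the mean IVW estimate is detectably
  biased above θ.
- **Outlier correction** uses 200 fixtures of 5 comparable-strength
  instruments (γ ~ U(0.2, 0.4)) with one +10·SE outlier. The fixture
  size follows a power analysis: the outlier shifts the pooled IVW
  estimate by ≈ 10·√(J−1)/J clean-fit SEs, so "corrected estimate closer
  to θ" has per-fixture probability ≈ Φ(5·√(J−1)/J) — about 0.93 at
  J = 10 (structurally below any 95% requirement) but 0.98 at J = 5.
  Small instrument sets are exactly the case where a single pleiotropic
  SNP matters.

## Design choices on genuinely open points

- SNP identity is the rsID, not chromosome/position; positions are
  1-based and used only for the clumping distance rule.
- The pooled instrument-strength F uses k = J, R² = Σr²ⱼ and the
  smallest per-SNP n (the per-trait n is constant in practice).
- The weighted median is the simple (not penalized) variant.
- `bh_adjust` enforces monotonicity only across the supplied ranks; the
  unsupplied larger ranks of the family are assumed non-binding, which
  is exact when the supplied values are truly the smallest of the family.
- Empirical p-values (PRESSO) use the add-one convention, bounding them
  below by 1/(n_sim + 1).

## Known limitations

- **Forward-regime undercoverage.** With a small exposure GWAS
  (n ≈ 800–8,300) against a biobank-scale outcome and a nonzero θ, the
  first-order ratio SE understates the true variance by a factor
  ≈ 1 + θ²·n_outcome/n_exposure; measured IVW coverage in that regime is
  ≈ 0.90 at θ = 0.1. The Q-triggered random-effects inflation absorbs
  part, not all, of this. The second-order SE flag mitigates it at the
  cost of a different (slightly conservative) approximation. This is a
  property of the standard estimator, shared by the common toolchains,
  and is the reason interval calibration is verified in the regime where
  the approximation holds.
- Palindromic SNPs with allele frequencies near 0.5 are dropped, not
  inferred from an LD reference.
- No LD-aware estimation: instruments are assumed independent after
  clumping; the LD matrix input affects pruning only.
- The MR-PRESSO distortion test and mode-based/multivariable estimators
  are out of scope.
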