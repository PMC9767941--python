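# Methods

## Model

For each of M unlinked variants we observe, in K single-trait GWASs, the
summary statistics (β, σ, n, t, p) with t = β/σ and p the upper tail of a
1-df chi-squared at t². Under the global null ("no effect on any trait")
the K-vector t of one variant is modelled as

    t ~ N(0, s ∘ Ψ)

where **Ψ** (the *background correlation*) collects the correlation induced
by sample overlap and non-genetic phenotype correlation — for two studies of
sizes N₁, N₂ sharing N_c individuals with residual phenotype correlation ρ,
ψ = N_c/√(N₁N₂)·ρ — and s = I + 1 is a per-GWAS inflation factor from
stratification or relatedness. True allelic effects δ add a second
covariance component whose genome-wide correlation across GWASs is the
*effect correlation* **Π**, with H_ij = E(δᵢδⱼ).

The package combines the K GWASs into a single genome-wide p-value vector
that is uniform under this null, in two stages:

1. **Iterative effect-based inverse-covariance weighting.** The per-variant
   statistic

       t_E = (h ∘ eᵀ) Ψ⁻¹ t / √((h ∘ eᵀ) Ψ⁻¹ (h ∘ eᵀ)ᵀ),   e = 1/σ,

   is standard normal under the null for *any* effect vector h; h only
   moves power. h = sign(Π−Ψ)_k H projects the expected effect covariance
   and flips the combination direction when the effect correlation falls
   below the background correlation. Special cases recovered exactly (and
   tested): Ψ = I with h ∝ 1 is classical IVW; general Ψ with h ∝ 1 is the
   1-df homogeneous cross-phenotype statistic. Pairs are combined
   iteratively, largest |Π−Ψ| entry first, each combination accepted only
   if it demonstrably beats both the pairwise Wald test and the per-variant
   minimum p (see *Decision rules*), until every remaining entry of
   D = |Π−Ψ| is below F (default 0.05). Pairs with ψ² > 0.5 are combined
   unconditionally to remove near-collinearity before Ψ is inverted at
   larger K.

2. **Truncated Wald scan with empirical calibration.** On the reduced panel,
   each variant is tested with the Wald form tᵀΨ⁻¹t on the nested subsets
   {GWASs with p ≤ r_q}, r_q = 10^(−q/3), q = 1..Q (Q = 18), plus the
   minimum-p singleton. The per-column null distribution is obtained by
   simulation: NS null draws from N(0, Ψ) of the *original* panel are pushed
   through the stored combination weights (so any miscalibration the
   weights introduce is replayed faithfully) and through the identical
   scan. Each column is corrected by Tippett's transform
   1−(1−p)^Neff with Neff fitted per column; the row minima are then mapped
   onto the uniform distribution by a rank-based multiplicative coefficient
   curve c(u) = u / (null quantile at u). The same machinery calibrates the
   naive per-variant minimum p over the K inputs ("MinGWAS") for
   comparison.

## Estimators

**Inflation (s).** t² is fitted as a two-component scale mixture of 1-df
chi-squares: fraction 1−p at scale s, fraction p at scale s+Λ, with
E(t²) = 1+I+pΛ and Var(t²) = 2E(t²)² + 3Λ²p(1−p). For each candidate I the
two moment equations give (Λ, p) in closed form; I minimizes the squared
mismatch between empirical quantiles of t² at levels 0.1–0.5 and the fitted
mixture quantiles. A p→1 effect component is distribution-identical to
inflation, so a 1e-4 penalty on the effect mass pΛ resolves that ridge
toward inflation; identifiable cases are unmoved. The estimate is unbiased
to within ±0.006 at M = 1e5 under 10–20% causal contamination, where the
genomic-control median ratio is biased upward by 0.1–0.2. Statistics are
divided by √s (standard errors absorb the factor, β is untouched).

**Background correlation (ψ).** Starting from the plain correlation of the
two t-vectors, the estimator repeatedly keeps the variants whose 2-df
Mahalanobis chi-squared under the current Ψ₀ is below its median (joint
upper-tail probability > 0.5) and recomputes the correlation on the kept
set, to convergence |Δψ| ≤ 1e-4 (cap 100 iterations). Radial truncation in
the whitened space preserves correlation, so the fixed point is unbiased
even with correlated true effects, which the joint criterion preferentially
excludes. The selection feedback amplifies sampling noise about five-fold
(sd ≈ 0.02 at M = 5e4 versus 0.0045 for a plain correlation); this shrinks
as 1/√M and is the main driver of residual mis-calibration on small panels.
Estimates are clamped to ±0.999; the assembled matrix takes the median over
systematic unlinked-variant subsets (default: up to 100,000 variants,
5 rounds) and is repaired to the nearest unit-diagonal positive-definite
matrix (eigenvalue floor 1e-6) when needed.

**Effect correlation (Π) and effect rule (h).** With Z the uncentered
covariance of the t-columns, H = (Z−Ψ) ∘ σσᵀ and Π is the correlation form
of the σ-free part, entries clamped to [−1, 1]. Three variants:
genome-wide (`all`); significant-stratum (`sig`, Z over Wald-significant
variants at threshold L = 1e-5 against the covariance of the non-significant
ones, falling back to `all` below 100 significant variants); and stabilized
(`stb`, Π ≡ 1 with the rank-one rule built from σ_k√(Z_kk−1)). Mean
chi-squared is floored at 1.001 before H so the Π normalization never
divides by a vanishing diagonal; on genuinely effect-free panels this makes
Π̂ saturate at ±1 — the decision rules below, not Π̂ itself, are what keep
noise combinations out. sign(0) = +1 throughout.

## Decision rules

`optimize` builds the three candidate combinations and returns the one
detecting the most variants at p < 1e-5 among those whose estimated null
variance lies in [0.95, 1.05]; ties keep the stability order all > sig >
stb. The null-variance estimate is the mixture fit above applied to the
combined t_E with the s ≥ 1 clamp released (a truncated-stratum mean would
be biased low by construction). For a symmetric pair the three rules give
nearly identical weights; the distinction matters at larger K and with
asymmetric effects.

`evaluate` accepts a combination only if, at every probe threshold in
{1e-3, 1e-4, 1e-5, 1e-6}, its detection count is at least the count of the
pairwise Wald test and of the Tippett-normalized minimum p, *and* the
improvement at the densest threshold clears a Poisson-scale margin of
2√(count+1). Without the margin, count ties let pure noise through on
effect-free pairs, and the data-fitted weights of such combinations are
exactly what the null replay cannot reproduce; with it, the full pipeline's
final p-values pass Kolmogorov–Smirnov uniformity on 50,000-variant null
panels. Forced (collinearity) combinations bypass `evaluate` entirely.

Tie-breaks are deterministic: the maximal D entry is taken at the
lexicographically smallest index pair, and a rejected pair has its D entry
zeroed rather than re-tried until the next accepted combination refreshes
the matrices.

## Calibration details

- NS defaults to 1e6 at desk scale (the production-scale recommendation is
  ≥100× the independent-variant count, of order 1e8); quantiles below
  10/NS rely on constant extrapolation of the coefficient and are flagged
  in the run report.
- Neff is fitted per column by least squares on a log-spaced quantile grid
  u ∈ [1e-4, 1e-1] so that Tippett's transform maps the simulated null
  column onto the uniform distribution; it is exact (Neff = K) for the
  minimum of K independent uniforms. Columns with too few non-missing
  simulated entries (thresholds so small that the subset is usually empty)
  reuse the last well-estimated Neff — the choice cannot bias the final
  type-I error because real and simulated matrices receive the identical
  transform before the coefficient fit; it only weighs how often such a
  column wins the row minimum.
- The coefficient curve is stored as log c against log u on a grid of ~400
  log-spaced plus 2,000 linear points: the null-min CDF inherits kinks from
  the empty-subset column structure, and a coarse grid leaves
  percent-level calibration error near those kinks. Application is by
  within-vector rank (average ties), clipped to (1e-300, 1], with a running
  maximum along increasing p repairing any local inversion, so significance
  order is preserved.
- Missing scan entries are excluded from the column corrections and the row
  minima in both real and simulated matrices.
- The run report's burdens convert the conventional per-GWAS genome-wide
  threshold onto the combined scale: the effective-test burden is the Neff
  of the minimum-p column and the coefficient burden is c evaluated at the
  corresponding tail quantile; their product times 5e-8 is the study-wide
  threshold (3 significant digits).

## Synthetic data

The summary-level generator draws null T-vectors from N(0, Ψ), adds
optional per-GWAS inflation N(0, I_k), and gives the first ⌊pM⌋ variants an
effect draw from N(0, Π ∘ θθᵀ), so GWAS k has E(χ²) = 1 + pθ_k² (+ I_k);
σ ≡ 1 and n is a nominal constant. Named presets encode the benchmark
configurations (effect patterns over ten GWASs at E(χ²) ∈ {2, 1.6, 1.3,
1.2, 1.1}, p = 0.1; inflation and ψ-recovery benchmarks; a 400-replicate
null study). Non-PSD Π ∘ θθᵀ combinations in extreme corners are repaired
to the nearest PSD matrix with a warning.

The cohort-level generator uses unlinked binomial(2, f) genotypes,
f ~ U(0.05, 0.5), over 20,000 variants and 2,000 individuals by default,
with 1% causal variants scaled so the genetic value explains h² = 0.10 of
the phenotypic variance, and runs per-cohort and union-sample linear
regressions. Three cohort layouts (disjoint, partial, almost-complete
overlap at 1,980/2,000) exercise the ψ = N_c/√(N₁N₂) theory. Unlinked
variants match the summary-level theory being tested; what passing tests do
*not* show is behaviour under LD, allele-frequency-dependent architecture,
or case-control ascertainment — none of which enter the method's own
assumptions, but all of which shape real panels.

The power harness uses oracle weights (true Ψ, Π, θ) for the combination
statistic and shares one simulated-null calibration across replicates, so
its tables isolate the power of the statistics from estimation error.
Problem sizes used by the shipped studies — 50,000 variants, 10 GWASs,
NS = 1e6, 100–400 replicates — keep each study in the minutes range; the
corresponding production-scale runs differ only by these size knobs.

## Known limitations

- The ψ estimator's noise amplification makes single-panel KS uniformity
  of the *fully estimated* pipeline marginal below M ≈ 2e4; the calibration
  itself (known Ψ) is exact to simulation error.
- The null-variance acceptance band [0.95, 1.05] is calibrated for
  M ≳ 2e4; on much smaller panels the band rejects valid combinations at a
  noticeable rate.
- With all traits equally and weakly affected (Π ≈ Ψ, effects spread over
  every GWAS), the truncated scan pays its subset-selection burden without
  a compensating gain and lands a few percent below the plain Wald test —
  the regime where the two are expected to be nearly equivalent.
- The multi-trait-effect score is reported against the asymptotic null
  skewness 2√2; the finite-R sampling skewness of R retained components is
  smaller, so null scores at small R are positively shifted (deliberately
  uncorrected) and a single dominant direction cannot produce a negative
  score below R ≈ 12.
- The combination-weight replay uses one reference weight vector per
  combination (exact when σ is constant across variants, as in the
  simulators; an approximation under strong per-variant heteroskedasticity).
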