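# Methods

## Generative model

Every run simulates `N` virtual participants (default 10,000; the
scaled-down experiment profile uses 4,000) with:

* a true latent ability `g ~ Normal(M = 100, SD = 15)`;
* `k = 15` continuous test scores, score `i` constructed as
  `x_i = M + SD·(r_i z_g + sqrt(1 − r_i²) ε_i)` with `z_g` the
  *population*-standardized g and `ε_i` i.i.d. standard normal. This is
  the simplest construction with exactly the stated marginal moments and
  population correlation `r_i = corr(x_i, g)`; rescaling uses population
  parameters, not sample moments, so per-run correlations are unbiased;
* loadings `r_i ~ Uniform(0.2, 0.9)`; in the traditional paradigm the
  first test (the selection variable) has its loading fixed to 0.1, 0.5
  or 0.9;
* optionally a disturbance `d ~ Beta(α, β)` per person, with
  `(9, 1)` / `(9, 9)` / `(1, 9)` for negatively-skewed / symmetric /
  positively-skewed conditions, multiplied into all of that person's
  scores. Lower `d` means more disturbance. Disturbed scores are not
  re-centered or truncated; only the selection variable is rescaled
  (below).

What the generator deliberately does *not* emulate: item-level
(dichotomous) responses, test-specific disturbance, additive noise
processes, practice/fatigue dynamics, or real test-battery covariance
structures beyond a single common factor. Passing results therefore
demonstrate behaviour of the analysis pipelines under a clean one-factor
world plus multiplicative disturbance — not claims about any empirical
battery.

### Randomness discipline

One master seed feeds `numpy.random.SeedSequence`; each experimental arm
(condition, selection loading) salts the sequence with its label, and
replicates consume spawned children, so every replicate is independently
re-runnable and results are bit-reproducible for a given master seed and
independent of execution order.

## Traditional paradigm

The (possibly disturbed) selection variable is affinely rescaled to
sample mean 100 / SD 15. Ten window centers are equally spaced between
its 5th and 95th percentiles; each subgroup holds everyone within ±10
points of a center, guaranteeing the 20-point within-group range and
overlap between neighbours. The exact windowing used by earlier studies
varies; this policy is exposed in `form_subgroups` so alternatives can be
swapped in — the qualitative trend is robust to it, per-subgroup values
are not. Saturation is the top eigenvalue of the 14 remaining tests'
correlation matrix divided by 14 (correlation, not covariance, because
disturbance induces scale differences that covariance PCA would
conflate). The scalar trend summary per replicate is the Spearman rank
correlation between subgroup mean and saturation; the published analyses
show this trend only graphically, and a rank correlation is a robust
scalar for testing.

## Contemporary criteria

### One-factor CFA

Normal-theory maximum likelihood on the biased (divide-by-n) sample
covariance, minimizing
`F = log|Σ(θ)| + tr(S Σ(θ)⁻¹) − log|S| − k` over k loadings and k
residual variances, with `var(g) = 1` and saturated means (intercepts =
sample means; disturbance shifts means, but all criteria use covariance
structure only). Identification by unit latent variance with a
positive-sum sign convention keeps the squared-loading constraint and
the factor-score metric unambiguous; the criteria depend only on
correlations and signs, which are invariant to this choice.

### Quadratic extension

`Σ = Λ* Φ Λ*' + diag(θ)` with `Λ* = [λ, λ∘λ]` (the squared-loading
constraint is built into the parameterization, so it holds exactly) and
`Φ = [[1, φ], [φ, ψ]]`, `ψ ≥ 0`, `φ` free: two extra parameters. A
variant with `φ` pinned to 0 (orthogonal quadratic factor, one extra
parameter) isolates the latent covariance for a 1-df comparison.

Criterion tests:

* **skewness of ĝ**: regression scores `ĝ = λ'Σ⁻¹(x − μ)`; sample
  skewness `g1 = m₃/m₂^{3/2}` with the exact small-sample null SE
  `sqrt(6n(n−1)/((n−2)(n+1)(n+3)))` and a two-sided normal p. (The
  asymptotic `sqrt(6/n)` variant differs negligibly at these n.)
* **heteroscedastic residuals**: per person, the mean over tests of
  `(x_i − μ_i − λ_i ĝ)²`, floored at 1e−12 before the natural log (so
  degenerate noiseless inputs stay finite), Pearson-correlated with ĝ
  (two-sided t-test). Note the bookkeeping identity: because regression
  scores are shrunken, the grand mean of individual residual variances
  is `mean(θ) − (1 − ρ²)·mean(λ²)` with `ρ² = λ'Σ⁻¹λ`, not `mean(θ)`.
* **quadratic improvement**: 2-df likelihood-ratio test of the full
  quadratic model against the one-factor model, `Δχ² = n·ΔF`. With ψ on
  its boundary under the null the test is mildly conservative
  (chi-bar-square mixture); observed null rejection ≈ 0.035.
* **negative g-by-g² association**: a signed 1-df likelihood-ratio test
  of `φ = 0` vs free (ψ free in both models), fulfilled when significant
  with `φ̂ < 0`. This parameterization-invariant test was chosen after
  examining the alternatives: the fitted `Φ` is typically almost
  singular (`ψ̂ ≈ φ̂²`), which makes Wald standard errors of `φ̂` explode
  and pins the correlation of the two regression-score vectors at ±1
  regardless of the data, so neither a Wald test nor a score-level
  correlation behaves like a test of the association. How the original
  analyses operationalized this parameter's significance is the one
  place where published proportions are not fully recovered (see
  Limitations).

`all_crucial` is the conjunction of the four flags. Non-converged fits
leave their criteria unfulfilled and are counted, never dropped, since
proportions are over all runs.

### Numerical choices

All fitting happens on covariances divided by one global scale (the root
mean diagonal of S) so every free parameter is O(1); the model family is
invariant under this uniform rescaling (ψ and φ absorb the constants)
and estimates are mapped back to the raw metric. Optimization is
L-BFGS-B with analytic gradients (`dF = tr(Σ⁻¹(Σ − S)Σ⁻¹ dΣ)` chained
through the parameterization), residual variances bounded below at 1e−6
(hitting the bound is flagged as a Heywood case), up to 3 jittered
restarts, and each start polished by re-starting from the incumbent
because the quadratic model's discrepancy surface has a long flat valley
along the near-singular ridge of Φ where single L-BFGS-B runs stall on
tiny per-step reductions. Convergence is declared at a projected
gradient below 5e−3: in the flat valley gradient norms plateau around
1e−3 while the discrepancy is stable to ~1e−7, i.e. ~10⁻³ χ² units —
far below anything a significance test could register. The free
quadratic fit is additionally seeded from the φ = 0 solution so the
numerical nesting `F_full ≤ F_orth ≤ F_linear` holds; if the optimizer
cannot beat the restriction the boundary solution itself is returned.
Wald standard errors, where reported, come from the inverse expected
information `I_ij = (n/2)·tr(Σ⁻¹ ∂Σ_i Σ⁻¹ ∂Σ_j)`.

## Experiment profiles

The full published design is 1,000 replicates of N = 10,000 per
condition. The default desk profile is 200 replicates of N = 4,000
(binomial CI on a proportion ≈ ±0.07), which runs in a few minutes on
one CPU; criterion rates were checked to be stable between N = 4,000 and
N = 10,000 under this pipeline. The traditional-paradigm experiment uses
20 replicates per cell, matching the published figure design.

## Limitations

* The g-by-g² significance machinery of the original analyses is not
  identifiable from the publication. Its reported fulfillment rates
  (0.811 / 0.974 / 0.940 across disturbed conditions) are consistent
  with the SEM software refusing factor scores when the fitted latent
  covariance matrix is non-positive-definite — the MLE hugs the singular
  surface `ψ = φ²`, and which side a given optimizer lands on is
  numerical noise. This implementation's signed LRT instead has
  essentially full power in all disturbed conditions at these sample
  sizes, so the conjunction proportion under negative disturbance comes
  out near 1.0 rather than ≈ 0.81. All signs, all other criterion rates,
  and the null-condition behaviour reproduce.
* The chi-bar-square issue of testing ψ on its boundary is flagged, not
  resolved: the 2-df LRT uses the naive reference distribution, which is
  what makes it mildly conservative under the null.
* Scores are continuous one-factor composites; nothing here speaks to
  item-level mechanisms of differentiation.
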