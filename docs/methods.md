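# Methods

## Model and procedure

The generator treats each class of a binary tabular dataset as a sampling
distribution estimated non-parametrically.  On standardized features
(median-imputed, z-scored), the class-conditional density is a Gaussian
kernel mixture with a single scalar bandwidth:

    p̂(x) = 1/(L h^d) Σ_{i=1..L} K((x − x_i)/h),
    K(u) = (2π)^(−d/2) exp(−‖u‖²/2).

Sampling is exact mixture sampling — pick a support point uniformly, add
h-scaled standard normal noise — not MCMC; the mixture is finite, so nothing
approximate is needed.  Two rejection filters then act on each candidate, in
this order:

1. **Utility**: a k-NN classifier trained on the full, imbalanced real
   training set must assign the candidate its intended class.
2. **Privacy**: the candidate's distance to the closest real training record
   must be at least `sigma_multiplier × σ`, where σ is the mean
   nearest-other-record distance among the real training records
   (comparison is strict: kept iff DCR ≥ threshold).

Batches are drawn per class until both per-class targets are met; survivors
beyond a target are truncated in draw order, which keeps runs deterministic.
σ is computed once, before the loop, and never updated.

### Assumptions

- Features are continuous and standardized; the isotropic kernel is only
  sensible because z-scoring makes coordinate scales comparable.
- Both classes have at least two training records (each needs its own KDE).
- The privacy notion is empirical (a distance floor against the training
  set), not differential privacy: it bounds record proximity, not what an
  adversary with side information can infer.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k_neighbors` | 5 | validator neighborhood; matches the k used by the density/coverage metrics, the only k with an established convention here |
| `sigma_multiplier` | 1.0 | privacy threshold in units of σ; 1 means "no synthetic record closer to a real one than real records typically are to each other" |
| `target_positive/negative` | 540 / 540 | balanced output, roughly half the training size per class |
| `batch_size` | = per-class target | one full batch per iteration mirrors "generate the target, filter, top up" |
| `bandwidth_*` | Scott's rule `L^(−1/(d+4))` | standard plug-in rate for Gaussian kernels on unit-scale data; override per class to trade fidelity (small h) against privacy (large h) |
| `kernel_mode` | `isotropic` | the printed model above; `covariance_scaled` uses the support's empirical covariance as kernel shape (equivalent to scipy's `gaussian_kde`) for strongly correlated features |
| `max_iterations` | 100 | loop guard; exhaustion raises a convergence error carrying the partial accounting rather than returning silently short output |

Bandwidth–privacy trade-off: the expected distance from a sample to its
generating support point grows with h (≈ h·√d for standard normal noise), so
mean synthetic DCR is monotone in h — verified as a test property.

## Numerical choices

- Standardization uses sample statistics (ddof = 1), medians over observed
  values only, always fitted on the training split and reused downstream —
  pooled fitting would leak test information.
- Density evaluation uses log-sum-exp; queries 60σ from all support return
  finite log-densities.
- In covariance-scaled mode the support covariance is regularized by ε·I,
  ε = 1e-8·trace/d, then Cholesky-factored; degenerate support fails loudly.
- k-NN ties: neighbors sort by (distance, reference index); an even-k vote
  tie falls back to the single nearest neighbor.  Both rules make
  predictions order-deterministic.
- Nearest-record searches are exact, blockwise (512-row blocks) — at
  N ≈ 10³ correctness is cheap.
- Density/coverage use closed balls and exclude self when computing the
  k-th-neighbor radii, so "synthetic = real ⇒ coverage 1" holds exactly.
- AUC is the rank statistic with average ranks, so ties count ½ exactly.
- Mann–Whitney U is reported as min(U₁, U₂); p-values use the tie-corrected
  normal approximation with continuity correction; Bonferroni adjustment is
  min(1, d·p) with the 0.01 flagging convention.
- Random streams: the generator holds one `numpy` Generator per class,
  constructed as `default_rng([seed, class_label])`, components drawn before
  noise — this makes the "validations off ⇒ raw KDE draws" identity exact.

## The fixture generator

Real ICU sepsis cohorts are not redistributable, so tests and examples run
on generated stand-ins: class-conditional multivariate Gaussians with 27
features, 979 negatives / 296 positives, exchangeable correlation ρ = 0.2,
a mean shift of 0.3 per feature between classes, unit noise and 5% MCAR
missingness.  The defaults were chosen once to emulate a hard clinical
discrimination task (the reference classifier reaches AUC ≈ 0.76 on real
rows) with the imbalance and missingness of a typical ICU table; Gaussians
were chosen over resampled marginals so every downstream moment has a
closed-form target.

What the fixture does **not** emulate: skewed or heavy-tailed lab values,
mixed discrete/continuous features, informative missingness, temporal
structure.  Passing tests therefore demonstrate correctness of the
machinery and the method's internal guarantees — not clinical validity on
real hospital data.

## Observed behavior worth knowing

- **Class-asymmetric rejection.**  The validator is deliberately trained on
  the imbalanced real data, so minority-class candidates near the decision
  boundary are voted down far more often (≈70% utility rejection for the
  minority vs ≈3% for the majority on the default fixture).  This also
  shifts the surviving minority samples away from the boundary — synthetic
  class means sit slightly beyond the real ones.  This is a property of the
  method, reported, not corrected.
- **Privacy costs marginal fidelity.**  The DCR floor plus the fairly wide
  Scott bandwidth at d = 27 (h ≈ 0.8) inflate marginal variances
  (Var ≈ 1 + h²), so per-feature KS tests reject at n ≈ 10³ even though
  TSTR utility is essentially preserved.  Judge synthetic data on the
  metric that matches the use case.

## Scale of the shipped experiments

Tests and the acceptance script run the full pipeline on the default
1275-row, 27-feature fixture (seconds per run), oracle comparisons up to
N = Q = 500, and Monte-Carlo checks at 2·10³–2·10⁴ samples — sizes at which
every stochastic tolerance used has comfortable margin.

## Known limitations

- Binary classes only; no conditional generation on covariates.
- Continuous features only; categorical encoding is out of scope.
- The DCR floor is an empirical privacy proxy; no formal guarantee against
  membership-inference or reconstruction attacks is implied.
- With a large `sigma_multiplier` or tiny bandwidth the acceptance region
  can be empty; the generator then raises after `max_iterations` with full
  accounting instead of looping forever.
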