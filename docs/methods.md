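# Methods

## The measurement model

A forced-oscillation device superimposes pressure oscillations on tidal
breathing and reports respiratory impedance indices. We work with the 10
independent phase measurements — inhaled and exhaled values of R5, R20, X5,
Fres and ALX — and treat the 14 remaining report items as derived:
average = (inhale + exhale)/2, delta = exhale − inhale, and R5−R20
phase-wise. Cohort files are therefore stored canonically as the 10 phase
columns and derived items are recomputed on load; a record can never be
internally inconsistent. Validation tolerance `tau_der` defaults to 1e−6
(synthetic data is exact); real device exports print two decimals, so a
0.015 tolerance is provided for them.

Physiological constraints enforced throughout: R5, R20 and Fres phases are
strictly positive; X5 is typically negative; ALX may be slightly negative
on the delta/exhale items. Records below 16 years are out of scope.

## Reference-interval construction

For one sex stratum and one item with healthy-control sample y₁…yₙ:

1. Fit the Yeo–Johnson shape λ̂ by maximizing the profile log-likelihood
   ℓ(λ) = −(n/2)·log σ̂²(λ) + (λ−1)·Σᵢ sign(yᵢ)·log(|yᵢ|+1),
   with σ̂² the n-denominator variance of ψ(y, λ). Yeo–Johnson rather than
   Box–Cox because reactance items are zero/negative. The search uses
   bounded Brent on [−5, 5] with tolerance 1e−6; an optimum at a bound is
   flagged, not fatal. The forward and inverse maps use log1p/expm1
   formulations, with |λ| (or |2−λ|) < 1e−8 routed to the log branches.
2. Compute μ_t and σ_t (sample SD, n−1) of the transformed values without
   standardization — any affine post-scaling cancels in step 3.
3. Report [ψ⁻¹(μ_t − 2σ_t), ψ⁻¹(μ_t + 2σ_t)] in measurement units. If an
   endpoint falls outside the inverse's attainable interval (possible for
   large |λ̂|), the range becomes one-sided and the corresponding
   `unbounded` flag is set rather than erroring, preserving the screening
   semantics.

Flagging uses strict inequalities: a value exactly on a bound is in range.
The convention is a documented choice (either way moves coverage by a set
of measure zero for continuous data, but matters for 2-decimal device
output). The per-subject count of flagged items (0–24) is the screening
statistic; its ROC uses the full integer cutoff grid 0–25 (classify as
asthma iff count ≥ cutoff) so the curve reaches both corners, AUC by
trapezoid (equal to Mann–Whitney concordance with ties at ½), and the
Youden cutoff takes the smallest maximizer of sens + spec − 1, favouring
sensitivity in a screening context.

Heatmap orderings for the abnormality matrix come from average-linkage
agglomerative clustering on Jaccard distances of the binary rows (columns:
same on the transpose). Distance/linkage for such displays is rarely
reported; Jaccard/average is this package's documented stand-in, checked
against a brute-force agglomeration in the tests. A matrix of identical
rows keeps input order.

The published adult ranges (101 male / 114 female healthy controls) ship as
`reference_ranges.published_ranges()` for flagging real device reports;
they cannot be recomputed from shareable data and are used in tests only as
a flagging fixture, not as a fitting target.

## Synthetic cohorts

The generator emulates the group structure of the published cohorts: per
(sex, group) stratum it stores target measurement-scale mean/SD for each of
the 10 phase dimensions (from the published summary tables), an age
distribution, and a stratum size (101/114 male/female controls, 294/647
male/female patients).

Generative model: latent Z ~ N(0, C); per dimension y = ψ⁻¹(m + s·Z; λ_g).
Defaults λ_g = 0.5 for the positive quantities (R5, R20, Fres, ALX),
giving the right-skewed margins typical of resistance histograms, and
λ_g = 1 (Gaussian) for X5. (m, s) are calibrated by 2-D least-squares
moment matching on a fixed seeded standard-normal sample (n_mc ≥ 1e5,
common random numbers), so realized mean/SD match targets within 2%.
Positivity of R5/R20/Fres draws is enforced by per-subject rejection
sampling (no probability atoms at zero; an acceptance rate below 50%
aborts with advice to revise the spec); ages are normal truncated at 16.

The latent correlation C is separable: a 5×5 cross-quantity block A
(R5–R20 +0.5, R5–Fres +0.5, R5–X5 −0.5, X5–ALX −0.5, Fres–ALX +0.5, zero
otherwise — qualitative respiratory mechanics, not instrument claims)
Kronecker-multiplied by a 2×2 within-breath block with inhale/exhale
correlation 0.8. The separable form was chosen deliberately: zeroing the
cross-phase cross-quantity entries instead makes the matrix strongly
indefinite (smallest eigenvalue ≈ −0.87), and the PSD repair then erodes
the configured 0.8 inhale/exhale coupling to ≈0.57. With the Kronecker
structure the repair (eigenvalue clip at 1e−8, renormalize to unit
diagonal — needed because user-edited matrices may be indefinite) changes
entries by < 0.03. User-supplied matrices are validated for symmetry and
entry range and repaired the same way.

What the generator does **not** emulate: the true inter-item covariance of
the instrument (only marginal moments are published), measurement error,
device rounding, visit-to-visit variation, age/height/weight dependence,
or the overlap structure between patient and control distributions beyond
their first two moments. Synthetic patients and controls are consequently
more separable than clinical groups: both arms of the pipeline score
higher here than published clinical accuracies, and passing tests
demonstrate correctness of the machinery, not clinical performance.

## Classifier arm

Features: either all 24 items or the 10 phase measurements (the derived
items are linear combinations, so the reduced set removes
multicollinearity at no information cost), optionally plus age and sex
(male = 0, female = 1), in that column order. Inputs are standardized with
training-set statistics only; constant columns pass through.

Models:

- `mlp5`: linear(128) → BN → LeakyReLU(0.2) → linear(64) → BN → LeakyReLU
  → linear(32) → BN → LeakyReLU → linear(16) → BN → LeakyReLU → linear(1)
  → sigmoid; 12,769 trainable parameters at input dimension 10.
- `mono`: a single weighted layer plus sigmoid.
- `logreg`: logistic regression by iteratively reweighted least squares
  with ridge 1e−8 so perfectly separable data cannot diverge.

Training (mlp5/mono): Adam, learning rate 1e−3, default moments — recorded
in every report since gradient-training hyperparameters are otherwise
easy to lose; weighted binary cross-entropy; mini-batches of 32 reshuffled
per epoch; rows shuffled once at the start with the trailing 5% held out
for validation history. Batch normalization uses batch statistics in
training and bias-corrected exponential moving averages (momentum 0.99) at
inference — the bias correction matters for short runs, where an
uncorrected average would still lean on its initialization. Default epoch
budget 2500 (supplementary protocol 1000); tests and the acceptance script
use reduced budgets (50–300 epochs) chosen so the loss plateaus on their
problem sizes. He-style initialization from a per-model seed.

Imbalance handling (patients outnumber controls ≈5:1): exact-duplication
oversampling of the minority, SMOTE (k = 5 minority nearest neighbours,
synthetic point uniform on the parent segment; k reduced with a warning
for tiny minorities), or majority undersampling; plus optional balanced
class weights w_c = n_total / (2·n_c) in the loss. Resampling never alters
an existing row.

Evaluation: per repetition, `test_per_group` subjects per class (default
10, supplementary 20) are removed uniformly without replacement; scaler,
resampler, weights and model are fitted strictly on the remainder; the
test set is scored at a probability cutoff of 0.5 ("≥ cutoff ⇒ asthma",
so an exactly-0.5 output counts as a positive call). In Youden mode the
cutoff is instead chosen on validation predictions — never on test rows.
Class-wise accuracy is recall per class; F1 treats asthma as positive;
AUC is pairwise concordance. Aggregates are mean ± SD (n−1) over
repetitions (default 5, supplementary 6). One master seed spawns
independent streams for splitting, resampling and model initialization so
components can be varied in isolation, and identical configurations give
byte-identical reports.

## Numerical and testing notes

- λ-recovery tests generate data through the exact inverse,
  `yj_inverse(N(2, 1); λ_true)`. Applying expm1 to a symmetric Gaussian is
  *not* equivalent for λ = 0 (the log branch covers y ≥ 0 only), and its
  maximum-likelihood shape is ≈ −0.25, not 0 — a useful reminder that the
  transform's two branches differ. N(2, 1) keeps the shape well identified
  across λ ∈ [0, 1.5] (mean absolute error < 0.05 at n = 2000).
- CSV round trips print 17 significant digits and read with pandas'
  `float_precision="round_trip"`; the default parser is off by one ulp.
- Cohort-scale test sizes (n = 5000 for coverage, 60-epoch training runs,
  study-sized protocol smoke runs at 50 epochs) were chosen so each check
  is statistically informative while the whole suite stays quick.

## Known limitations

- The generator's correlation defaults and skew shapes are plausibility
  choices, not estimates; conclusions about the instrument's joint
  distribution cannot be drawn from them.
- Reference ranges assume transformed-space normality; heavy-tailed items
  would need a different interval construction.
- The classifier arm is CPU-oriented and intentionally framework-free;
  it is sized for tabular cohorts (~10³ rows), not larger.
- Pediatric records, device-native export formats, and covariate-adjusted
  (regression-based) reference curves are out of scope.
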