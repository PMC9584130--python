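# Methods

## Setting and data model

The pipeline analyses a two-phase longitudinal design: n subjects measured
on p physiological traits at a baseline phase and again at a chronic phase
after an exposure (the motivating case is a month of high-altitude
residence).  All stages operate on the per-subject change score
Δᵢⱼ = xᵢⱼ(chronic) − xᵢⱼ(baseline); with only two time points this simple
transformation carries all the temporal information, and no mixed-model
machinery is used.  Subjects missing either phase, or any trait in either
phase, are dropped (complete-case) and logged.

## Synthetic cohort generator

No cohort of this kind is publicly deposited, so the generator is the
package's reference input.  It emulates *change scores*, not physiology:

* Trait panel: 28 traits with published baseline means/SDs (e.g. HGB
  150.15 ± 10.05 g/L at baseline, 179.59 ± 13.46 chronic).
* Block structure: the published 14-block composite-phenotype map (six
  blocks are single traits).
* Within-block correlation: one factor per block,
  Δᵢⱼ = μⱼ + σⱼ(√w·f_{b(j),i} + √(1−w)·εᵢⱼ), so any same-block pair has
  correlation w.  w is back-derived from each block's published
  standardized Cronbach's α via r = α/(k − (k−1)α); this spans 0.10
  (liver enzymes, α = 0.25) to 0.89 (platelets, α = 0.94).  Singleton
  blocks use w = 0.5, which only scales their coupling to the background.
* Cross-block correlation: block factors share a weak common background
  factor with coupling 0.1, capping cross-block trait correlations at
  ≈ 0.1·√(wⱼwₖ) — matching the published observation that most
  between-composite correlations are small.
* Hidden subgroups: two groups in ≈ 58:42 proportion; group 2's block
  factors for the red-cell, hemoglobin-concentration and platelet blocks
  are shifted by +1.5 (factor SD units).  Within each group the
  correlation targets hold exactly; marginally, the mixture necessarily
  adds covariance among the shifted blocks (≈ 0.26–0.40 at these
  settings) — a real feature of heterogeneous cohorts, not a bug.
* Change-score SD: the two phase SDs pin the change SD only given the
  (unpublished) baseline–chronic correlation; it is exposed as
  `phase_corr` with default 0.5, a typical test–retest correlation, giving
  σ_Δ = √(σ_b² + σ_c² − 2ρσ_bσ_c).
* Baselines are independent Gaussians on the published moments and
  chronic = baseline + Δ.  Everything is Gaussian; LLS (an integer 0–15
  symptom score) and other discrete traits are modelled continuously.
  Identical configs are bit-identical (single `numpy` Generator per run).

Consequences worth knowing: the published chronic SDs of TBIL/IBIL
(24.90/24.95 against baseline SDs < 2) make those change scores extremely
noisy, so unlike the published table, their phase shifts are *not*
significant at these settings — the screen tests honest effect sizes, not
the printed p-values.

## Block discovery

Similarity is |Spearman ρ| of change scores (average ranks on ties;
constant traits are an error).  The affinity graph keeps edge (j,k) when
either endpoint is among the other's k_nn = 7 most similar traits (union
symmetrization keeps the graph connected at small k; similarity ties
resolve by trait order).  The symmetric normalized Laplacian
L_sym = I − D^{−1/2}WD^{−1/2} is eigendecomposed densely (p ≤ a few
hundred), and the block count is argmax_{k∈{2..p−1}} (γ_{k+1} − γ_k),
ties (within 1e-9) to the smallest k.  Clustering runs k-means (50
restarts, fixed seed) on the row-normalized first-k eigenvectors;
all-zero rows are left unnormalized with a warning; labels are relabelled
contiguously by first occurrence.

A structural caveat, verified on the noise-free population similarity
matrix: under L_sym, a single-trait block can never register as a
spectral community (its indicator mode has eigenvalue ≈ 1 however weak
its edges are, because degree normalization is scale-invariant per
vertex).  With six singleton blocks and a weakest within-block
correlation of 0.10 — equal to the cross-block bound — the eigengap's
population optimum under the generator's calibration is 8 (the
multi-trait blocks), and with the subgroup mixture coupling blocks 5–7 it
drops to 2.  The published 14 on the real cohort is therefore *not*
reproduced by this emulation; recovering it would require similarity
structure (e.g. singleton traits far from everything in a non-uniform
way) that a one-factor equal-correlation model does not produce.  The
random-walk and unnormalized Laplacian variants were examined and do not
change this conclusion.  Tests assert the clean recoverable cases
(disjoint cliques, planted strong blocks) and the pipeline's invariances
(monotone transforms, trait permutation).

## Composite scoring (PLSPM)

Blocks are reflective (mode A).  Before fitting, `align_signs` orients
each block: traits loading negatively on the block's first principal axis
are multiplied by −1 (the published analysis did exactly this for
MCH/MCHC).  With an even split the orientation is ambiguous and the half
containing the block's first trait is flipped; a degenerate top
eigenspace is resolved toward the equal-weight direction.  The operation
is idempotent.

Estimation is the classical alternating algorithm: manifest variables
standardized (population SD, so LV scores have mean 0, SD 1 exactly);
outer weights start at 1; iterate outer estimation Y_b ∝ X_b w_b
(standardized), centroid inner estimation Z_b = Σ_{b′∼b} sign(corr(Y_b,
Y_{b′}))·Y_{b′}, and mode-A update w_b = corr(X_b, Z_b), until
max|Δw| < 1e-6 or 100 iterations (then `converged=False` with a warning).
Single-variable blocks bypass iteration (ξ = the standardized trait,
λ = 1).  LV signs are flipped so most loadings are positive.  The default
inner model is a star: every non-target LV has one arc into the target
(the SpO₂ block) — the same topology as the regression stage, since the
true inner model of the motivating study was never published.  Note that
mode-A weights are correlations with the *inner* estimate, so with a
weakly coupled star the weights need cohort-scale n to stabilize; scores
are composites, whose loadings slightly exceed one-factor loadings (they
mix in unique variance — e.g. 0.89 vs 0.85 planted at 4 indicators).

Unidimensionality diagnostics use the standardized α (mean off-diagonal
correlation after sign alignment), Dillon–Goldstein's ρ from
first-principal-component loadings (a pre-fit check, deliberately not the
converged PLS weights), and the two largest eigenvalues of the block
correlation matrix.  For two indicators these collapse to closed forms in
r (eig = 1 ± r, α = 2r/(1+r)), which is how the published two-variable
cells are verified from their printed α alone.

## Heterogeneity

Subjects are clustered by best-of-50-restart k-means (k-means++ init) on
the LV scores, relabelled by descending size.  A multicollinearity guard
warns when any pairwise LV |r| exceeds 0.5.  The cluster count is a
majority vote of 12 validity indices — silhouette, Calinski–Harabasz,
Davies–Bouldin, Dunn, C-index, point-biserial, McClain–Rao, PBM, gap
statistic (PCA-aligned uniform reference, B = 10, one-SE rule),
Ball–Hall (largest drop), Hartigan (threshold 10), Krzanowski–Lai — the
published analysis used a 26-index roster from a named R package; the
*majority rule* is the method, and the roster is configurable.  Failed
indices abstain; ties go to the smallest k.  Group contrasts use the
two-sided Mann–Whitney test per LV (tie-corrected normal approximation),
and correlation differences use Fisher's z with variance 1/(n−3) per
group; all pairwise comparisons are reported with both unadjusted and
Benjamini–Hochberg p (displays default to unadjusted, matching the
published convention).

## Regression comparison

Model 1: OLS of ΔSpO₂ on the 27 other standardized trait changes (the
response is never its own predictor).  Model 2: OLS on the 13 non-SpO₂ LV
scores.  Aliased predictors are dropped via pivoted QR with a warning.
AIC/BIC use the Gaussian-ML convention aic = n·ln(2π·rss/n) + n + 2(p+2)
(slopes + intercept + error variance), identical for both models so only
differences matter.  Cross-validation uses one seeded random partition
shared by both models (the paired test is only valid on a common
partition); 10-fold errors are per-fold MSEs, leave-one-out errors are
per-observation squared errors computed by exact rank-one downdates of
the normal equations (an actual refit, independent of the PRESS identity
used as the test oracle).  The comparison is a one-sided paired Wilcoxon
signed-rank test of (Model 1 − Model 2) > 0, exact for ≤ 25 informative
untied pairs.  On the synthetic cohorts the 13-predictor composite model
dominates the 27-predictor raw model on all four indices in essentially
every seed — parsimony plus noise suppression, mirroring the published
qualitative result.

## Problem sizes and numerical conventions

Simulation-backed tests and the acceptance script use 20 cohorts of
n = 883 (the published cohort size); unit tests use n = 300 or toy data.
The paired Wilcoxon uses exact enumeration up to 25 untied pairs, else
the continuity-corrected normal approximation; zero differences are
dropped.  Spearman ties get average ranks.  Eigengap and majority-rule
ties resolve to the smallest k.  All seeds are explicit arguments; no
global RNG state is touched.

## Known limitations

* Gaussian everything: no heavy tails, no integer-valued symptom scores,
  no measurement-device artifacts.
* The change-score emulation cannot reproduce selections that depend on
  fine real-data similarity structure (see the eigengap caveat above).
* Mode B (formative) estimation and bootstrap confidence intervals for
  path coefficients are out of scope; the inner model is a documented
  reconstruction, not the published one.
* The paired-test reading of the published "rank-sum (paired)" wording is
  the signed-rank test (the R `wilcox.test(paired=TRUE)` convention); the
  unpaired rank-sum variant is available behind a flag.
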