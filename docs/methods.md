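# Methods

## The data-generating model

The synthetic generator is the canonical input source for validation. It
simulates a placebo-controlled polyphenol supplementation trial with one
plasma sample per subject per phase (Pre, Post, Rec). On the natural-log
scale, for subject *i*, metabolite *j*, phase *t*:

    x_ijt = mu_j + effect_j(arm, t) + u_ij + lam_j(arm) * s_i * [t = Rec] + eps_ijt

* `mu_j` — per-metabolite log baseline (panel defaults span ~5.5–12.5, i.e.
  raw intensities of ~250 to ~270 000 arbitrary units).
* `effect_j(arm, t)` — fixed phase/arm mean shift relative to Pre. Pre is
  always zero in both arms, so baselines overlap by construction. Post
  shifts are shared between arms (a global exercise excursion: purine surge,
  lactate +1.5, GSH depletion). Rec shifts differ by arm: purine catabolites
  and lipid-peroxidation markers stay elevated under placebo and revert
  under supplementation, while polyphenol-derived phenolics appear only in
  the supplemented arm. The uric-acid and hypoxanthine Rec shifts are set
  so that the log UA/HX ratio moves +0.4 under placebo and −0.4 under
  supplementation, emulating a rebound of terminal purine oxidation that
  the intervention suppresses.
* `u_ij ~ N(0, subject_sd²)` — a subject-by-metabolite baseline held fixed
  across phases. It is independent **across metabolites**: a single shared
  per-subject offset would add `subject_sd²` to every between-feature
  covariance and break the closed-form coupling structure below, whereas a
  per-feature offset yields within-subject longitudinal correlation without
  coupling features to one another.
* `s_i ~ N(0,1)` — a latent recovery-stress factor, active only at Rec.
  Purines and lipid-peroxidation markers load positively on it
  (`lam` 0.6–0.8), GSSG positively, GSH negatively. In the polyphenol arm
  every loading is multiplied by the decoupling factor `delta ∈ [0,1]`
  (default 0.2). The induced Rec-phase correlation between coupled
  features a and b is `lam_a·lam_b / sqrt((lam_a²+s²)(lam_b²+s²))` with
  `s² = subject_sd² + residual_sd²`; at the defaults this is ≈0.72 in the
  placebo arm and ≈0.09 in the supplemented arm — the "decoupling"
  observable. One latent factor is deliberately minimal structure: it
  produces the arm-dependent coupling contrast without specifying a full
  covariance matrix.
* `eps ~ N(0, residual_sd²)` — measurement/biological noise.

Defaults: 30 subjects/arm, 4 studies, `subject_sd = 0.3`,
`residual_sd = 0.4`, `delta = 0.2`. Abundances are exported exponentiated
(raw scale). Missingness is applied afterwards: 3% MCAR dropout plus
left-censoring of values strictly below each feature's 5% quantile
(detection-limit behaviour; censored cells are *removed*, not zero-filled,
so the imputer is actually exercised). Total missingness ≈8%, safely below
the 30% filter threshold.

Multi-study generation gives each study a derived seed; study 1 is the
reference platform and studies ≥2 receive per-feature log-baseline offsets
`N(0, 0.5²)` emulating platform heterogeneity. A `SyntheticTruth` record
stores every realized effect, the closed-form coupled-pair correlations and
the geometric-mean UA/HX ratio per arm/phase, and regenerates bit-
identically from (config, seed).

What the generator does **not** emulate: raw spectra, retention-time or
batch drift, diurnal effects, and within-subject crossover dependence (the
two crossover designs are generated as parallel arms). Passing tests
therefore demonstrate correctness of the estimators under a clean
latent-factor world, not robustness to instrument artifacts.

## Preprocessing

Fixed order, recorded in dataset provenance: **filter → impute → log →
Pareto**. The missingness filter removes features missing in strictly more
than 30% of samples, pooled across all samples (the simplest reading;
per-group filtering would be a config extension). Imputation is a
missForest-style iteration (random-forest regression of each feature on all
others, features visited in ascending missingness, per-feature medians as
the starting point), stopping when the relative change of imputed cells
falls below 1e-3, when it increases, or after `rf_max_iter` sweeps. Forest
seeds are fixed per feature so successive sweeps differ only through the
updated imputations — this is what makes the iteration converge and the
result reproducible. Observed cells are never altered. The log transform
adds half the feature's minimum positive value to exact zeros only (a
global pseudo-count would distort observed positives). Pareto scaling
divides centered features by the square root of the sample SD (ddof = 1
throughout the package); constant features are centered, left at zero and
warned about, and a provenance check refuses to scale twice.

The pipeline keeps all four stage matrices because downstream consumers
disagree about scale: multivariate models take the Pareto matrix, fold
changes and Cohen's d the log matrix, and the targeted ratio indices the
raw imputed matrix (a ratio of Pareto-scaled values is meaningless).

## OPLS-DA

Single centered ±1 response; X is centered only (Pareto was applied
upstream; double-scaling is a provenance error). Each orthogonal round
computes PLS weights `w ∝ X'y`, scores `t = Xw`, loadings
`p = X't/(t't)`, extracts the y-orthogonal part of the loadings
`w_o ∝ p − (w'p)w`, and deflates `X ← X − t_o p_o'`; the final predictive
component is fit on the deflated matrix. With zero orthogonal components
the model is exactly one-component PLS1 (asserted against an independent
implementation). One predictive component is the natural choice for a
binary response; "auto" governs orthogonal components only, adding them
while cross-validated Q² improves by more than 0.01, up to 3.

Q² uses stratified 7-fold CV (both classes in every fold) with seeded fold
assignment; the full fit — deflation included — is repeated inside each
fold. The permutation test relabels y uniformly at random, refits with the
orthogonal-component count resolved by the observed fit (re-running the
"auto" search per permutation would multiply cost without changing the
null), and reports `p = (1 + #{Q²_perm ≥ Q²_obs}) / (1 + n_perm)` — the
add-one estimator, which cannot return 0 and degenerates to p = 1 at
`n_perm = 0`. VIP is the predictive-component variant `√J·|w_j|` (mean
VIP² = 1 identically); orthogonal-inclusive VIP variants exist, and the
choice is recorded in model metadata.

## Univariate statistics and selection

The default per-feature test is the two-sided Mann–Whitney U, delegated to
scipy with automatic exact/asymptotic switching: exact for small tie-free
samples (where it matches full enumeration), tie-corrected normal
approximation otherwise. A rank test is consistent with the nonparametric
(Spearman) network branch; Welch's t is available by flag. BH adjustment is
the step-up `q_(i) = min_{j≥i} m·p_(j)/j` capped at 1. Cohen's d uses the
pooled (n−1)-weighted SD. Fold changes are differences of group means on
the log₂ scale (geometric fold changes, since the data are already
log-transformed). Selection is the exact conjunction VIP > 1.0 AND
q < 0.05.

## Networks

Computed on recovery-phase samples per arm, within dataset. Spearman is
implemented as average ranks followed by Pearson on ranks, with two-sided p
from the t approximation on n − 2 df; constant features yield NaN against
every partner and can never form an edge. The matrix is computed directly
(rank-then-correlate) rather than through scipy's matrix wrapper, which
collapses to a scalar NaN when any column is constant; the pairwise results
agree with scipy to numerical precision. Edges require |r| strictly > 0.6
and p strictly < 0.05; isolated nodes are retained. Betweenness is
unnormalized Brandes (networkx) on the unweighted graph — the node set
defaults to the union of discriminant-selected features and the targeted
panel, with a full-panel flag.

Differential statistics follow fixed sign conventions: `delta_r` is
polyphenol minus placebo; `delta_betweenness` is placebo minus polyphenol
(positive = more central under placebo); the strong-edge count uses
|r| > 0.7 applied to the **raw** correlation matrices, independent of the
edge rule. Pathway-pair means average `delta_r` over cross-pathway pairs
(unordered within-pathway pairs for the diagonal). The per-feature p-value
ECDFs summarize within-arm Rec-vs-Pre tests per feature (a documented
choice; the unpaired test is used even though phases share subjects —
see limitations).

## Enrichment

Upper-tail hypergeometric ORA against a pathway annotation (by default the
dataset's own feature pathway labels; any two-column CSV works), BH across
pathways. "Impact" is k/K, the fraction of the pathway hit — a deliberate
simplification of topology-weighted pathway-impact scores, which would
require a pathway graph that is out of scope.

## Multi-study synthesis and demographics

Studies are never pooled at the intensity level; each runs the full
pipeline independently and the run summarizes direction concordance for
three key statistics (recovery UA/HX arm contrast, mean purine ×
lipid-peroxidation `delta_r`, summed targeted-panel betweenness change).
The pooled-demographics helper sums study rows; crossover studies
contribute their unique participants split evenly between arms (each
participant serves both conditions), percentage male and n-weighted mean
BMI are rounded to one decimal, and studies not reporting BMI are excluded
from its weights.

## Numerical and validation choices

* Determinism: every stochastic step (generation, imputation forests, CV
  folds, permutations) is seeded; a full run is byte-reproducible.
* Orthogonality and VIP identities asserted at 1e-8; oracle equivalences
  (Spearman vs brute-force rank-Pearson, betweenness vs path enumeration,
  BH vs hand step-up, ORA vs exhaustive enumeration) at 1e-12 or exactly.
* Monte-Carlo loops (calibration and parameter recovery) run 20–50 seeds at
  the default 30/arm with a reduced imputation forest (30 trees, 2 sweeps);
  imputation accuracy is not the quantity under test there, and relative
  comparisons are insensitive to forest size.
* The closed-form covariance check uses an analytic-SE-aware tolerance for
  the supplemented arm, whose target (delta²·lam_a·lam_b ≈ 0.026) is
  smaller than its own sampling noise at practical n.
* Degenerate inputs are flagged, not silently dropped: undefined ratios
  (zero/missing denominators), zero-variance features in S-plots and
  correlation matrices, identical constant groups in tests (p = 1).

## Known limitations

* Crossover dependence is not simulated and groups are treated as
  independent in all tests; with real crossover data this is conservative
  for between-arm contrasts.
* The recovery UA/HX contrast has a per-seed detection rate of roughly 0.9
  under the default conditions — left-censoring preferentially removes low
  uric-acid values from the supplemented recovery cell, attenuating the
  contrast after imputation — so the 18-of-20-seed recovery count sits
  close to its threshold.
* The ECDF branch applies an unpaired test to paired (same-subject) phases.
* ORA impact ignores pathway topology; correlation networks capture
  association, not causality.
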