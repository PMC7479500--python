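# Methods

`padtrack` implements a longitudinal brain-age analysis for a three-group
familial-risk cohort: controls who remained well (C-well), participants
at high familial risk of mood disorder who remained well (HR-well), and
high-risk participants who developed a mood disorder (HR-MD). The chain
is: synthetic cohort and grey-matter volumes → voxel preprocessing →
PCA + relevance vector regression (RVR) brain-age prediction with
leave-one-participant-out (LOO) evaluation → residuals-corrected
brain-predicted age difference (brain-PAD) → nested random-effects linear
mixed model (LMM) with Holm-corrected pairwise group contrasts.

## Cohort and latent-age model

`simulate_cohort` draws, per group, exactly the design's baseline and
follow-up counts (93/74/35 and 46/47/31 by default); attrition is
assigned by sampling the follow-up subset without replacement so the
printed ns are deterministic. Baseline ages are uniform on 15–28 y;
follow-up intervals are Normal(2.0, 0.25) y truncated positive. High-risk
participants join an existing high-risk family with probability 0.3
(`family_share_prob`), otherwise found a new one; controls are
singletons. HRSD depression scores are negative-binomial with per-group
means (0.8/1.0/3.8 at baseline, 0.8/0.9/6.0 at follow-up, dispersion
0.9), putting the HR-MD group stochastically higher with a rising tail at
follow-up.

The latent "biological brain age" of a scan is

    b = age + delta_g(t) + u_subject + eps_scan

where `delta_g(t)` is the group's baseline offset plus, at follow-up, its
trajectory increment. Default offsets are (0, −0.42, −0.05) y at baseline
with increments (0, −0.28, −0.70) y: an intermediate deceleration for
HR-well and the largest for HR-MD. The noise scales are
`subject_sd = 1.00` y and `noise_sd = 0.50` y. These were derived once
from the study's printed statistics rather than guessed: the reported
interaction standard error (0.14 in z units, about 0.16 y with 31/46
complete cases) implies a within-scan residual sd near 0.49 y, and the
reported group brain-PAD standard deviations (1.0–1.4 y) then imply a
subject-intercept sd near 1.0 y. A family-level variance field
(`family_sd`) exists for experiments but defaults to 0.

## Volume rendering

Volumes are a stand-in for modulated grey-matter maps produced by tissue
segmentation; they make the decoding chain testable, not the anatomy
realistic. A smooth positive template on an ellipsoidal support carries
P = 8 fixed smooth spatial patterns (FWHM 9 mm, unit RMS on the support)
whose amplitudes depend affinely on the latent age:

    V(x) = template(x) + sum_p s_p(x) * (w_p (b − b_ref) + eta_p) + nu(x)

clipped at zero and zeroed outside the ellipsoid. Age slopes `w_p` are
±0.02 density-units/y (random sign, uniform magnitude); `b_ref` = 22.4 y.
The nuisance terms are deliberately small relative to the latent scan
noise — component jitter `eta` sd 0.011 and voxel noise sd 0.01 — because
scan-level measurement error is already modelled by `eps` in the latent
equation; the renderer should encode `b`, not add a second noise floor.
At these scales linear decoding of `b` recovers it to ~0.2 y. The default
grid is 48×56×48 at 1.5 mm (a desk-scale whole-brain stand-in, chosen so
2× downsampling lands on the 3 mm analysis resolution); repeated
end-to-end studies use 24×28×24, which shrinks only the voxel count, not
the construction.

## Preprocessing

Gaussian smoothing uses FWHM in mm (sigma = FWHM/√(8 ln 2), 8 mm default)
with boundary weights renormalised so constants are preserved — the
convolution stays linear and masks cannot bleed intensity off the grid.
Downsampling is 2×2×2 block means (odd dimensions zero-padded), doubling
the voxel size to 3 mm. Each volume is then thresholded at 0.01 and the
common feature space is the union-support mask over the training volumes,
vectorised in fixed row-major order; test scans are projected onto that
mask. The order smooth → downsample → threshold and the union-mask choice
are fixed conventions of this package (thresholding before or after
resampling is not independently determined).

## Brain-age model

The training sample holds one scan per well participant: C-well
contribute follow-up if available else baseline; HR-well with follow-up
are ranked by follow-up age (ties by subject id) and the top half
contributes follow-up, the rest baseline — maximising the covered age
range. PCA (SVD, mean-centred) retains components with covariance
eigenvalue > 1 (Kaiser rule) by default; because that rule is
scale-dependent, a mean-eigenvalue alternative is available via
`ModelOptions.pca_criterion`. At least one component is always kept.

The RVR places one linear-kernel basis per training scan plus an explicit
bias column and iterates the sparse Bayesian updates (posterior
Sigma/m, gamma_i = 1 − alpha_i Sigma_ii, alpha_i ← gamma_i/m_i²,
beta ← (N − Σgamma)/RSS), pruning bases with alpha > 1e9, until the
largest |Δ log alpha| falls below 1e-3 or 1000 iterations. Initialisation
is alpha = 1/N², beta = 10/var(y); the noise precision is capped at 1e12
so exactly realizable targets remain finite. On well-conditioned problems
most bases are pruned; when the kernel is nearly rank-deficient (very few
PCA components) the iteration settles at a dense ridge-like fixed point —
predictions remain correct, only sparsity is lost.

LOO refits the *entire* pipeline (mask, PCA, RVR) with the held-out
participant's training entry removed, then predicts both of that
participant's scans; HR-MD participants are predicted from the model fit
on the complete training sample. Evaluation reports MAE, scaled MAE
(MAE divided by the training age range) and Pearson r with a two-sided
t-transform p on n − 2 df.

## Brain-PAD

Predicted age is regressed on chronological age and sex (coded 0/1) by
ordinary least squares over the reference set — the LOO predictions of
the training-sample scans — and brain-PAD is the residual from those
frozen coefficients, applied unchanged to every other scan. Positive
values mean an older-appearing brain. By construction the reference-set
brain-PAD has mean zero and zero correlation with age and sex. Whether
the original residual fit used baseline-only or mixed-timepoint scans is
not determinable from the study text; the mixed-timepoint reference set
used here is a documented package choice.

## Mixed model

The trajectory model is brain-PAD ~ Timepoint × Group with nested random
intercepts for family and subject-within-family, estimated by REML. The
two variance ratios (family and subject variance over residual) are
profiled: for fixed ratios the GLS coefficients and residual variance are
closed-form, leaving a 2-parameter Nelder-Mead search on the log scale
(non-negativity by construction, tolerance 1e-8); families with identical
row/subject structure share one covariance factorisation, so a fit costs
tens of milliseconds and thousand-repetition calibration studies are
practical. The fit records the objective trace, a finite-difference
gradient norm at the solution, and a convergence flag.

Degrees of freedom follow the containment (inner-outer) rule: each fixed
term is assigned the innermost grouping level at which it varies, with
df = N_level − N_parent − (non-intercept terms at that level). For the
design's 326 observations and 202 subjects with 3 within-subject terms
this gives 121 for the timepoint and interaction terms; group terms get
the subject-within-family df and the intercept the family-level df.

Z-scoring the outcome (and age, where it is a covariate) yields
standardised coefficients; estimates are also reported in years by
rescaling with the outcome sd. The t statistics and p values of slope
terms are identical on either scale (verified to 1e-6).

Contrasts: at baseline the three pairwise group differences come from the
group main effects (subject-level df); the trajectory stage contrasts the
interaction coefficients and the follow-up stage the sums of group and
interaction terms (observation-level df, the innermost level entering the
contrast). Each stage's three p values are Holm-corrected. The
exploratory difference model regresses the z-scored within-subject
brain-PAD change on z-scored baseline age × group over complete cases
with a family random intercept only (one row per subject, so the subject
level collapses into the residual); if the change score is constant the
model falls back to the year scale, where z-scoring is undefined.

## Demographic machinery

Kruskal–Wallis (tie-corrected, via scipy) with Dunn's pairwise z tests on
pooled ranks (unadjusted p by default; an adjustment can be applied by
the caller) for skewed variables; chi-squared tests for categorical
tables, with Yates continuity correction on every 2×2 table — this
reproduces the design's attrition chi-squares (14.6/6.2/2.8) — and plain
Pearson for r×c tables. Subclinical depression is a score strictly above
7 on the HRSD.

## Calibration studies and problem sizes

`padtrack.studies` packages three repeated-run studies used by the tests
and the acceptance script: (1) 200 repetitions of the default latent-only
simulation recover the −0.70 y HR-MD trajectory effect with 95% CI
coverage checked against the 0.90–0.99 band; (2) 1000 null repetitions
(all offsets zero) bound the Holm familywise error at 0.05 per stage;
(3) 20 seeded end-to-end runs at the 24×28×24 grid check that the HR-MD
trajectory contrast is negative and the groups order as configured
(HR-MD < HR-well < C-well) in at least 90% of runs. The latent-only
studies bypass rendering (the latent b is a noise-free prediction), which
is what makes their repetition counts affordable; the end-to-end study
keeps every stage, at the smaller grid.

## What the synthetic data do and do not show

The generator reproduces the design's sampling structure, attrition,
family nesting and effect sizes, and encodes brain age affinely in
smooth spatial patterns. It does not emulate real neuroanatomy, scanner
artifacts, segmentation error, non-linear age effects, or the
feature-to-age relationship of real grey-matter maps — so passing tests
demonstrate the correctness and calibration of the *machinery*, not the
real-data performance figures, which depend on data that cannot be
redistributed. The printed real-data anchors (MAE 2.21 y, r = 0.40)
appear only in worked examples of the arithmetic, never as synthetic
targets.

## Known limitations

* The Kaiser rule's eigenvalue-greater-than-one cut-off interacts with
  the synthetic feature scale; very small grids can retain a single
  component (the mean-eigenvalue switch is the remedy).
* Containment dfs are the only supported df method (no Satterthwaite or
  Kenward-Roger), matching the nested-intercept design.
* No random slopes, crossed random effects, or alternative age-bias
  corrections (slope scaling, quadratic age) are implemented.
* The RVR loses sparsity in near-rank-deficient kernel regimes (see
  above); predictions are unaffected.
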