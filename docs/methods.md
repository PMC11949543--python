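# Methods

`statedyn` implements a sliding-window dynamic functional-connectivity (DFC)
brain-state analysis for intensive single-subject fMRI designs — many
meditation runs traversing ordered altered-state stages (access concentration
AC, jhana stages J1–J5, merged J6–8, afterglow) plus non-meditative control
runs — together with a synthetic-study generator that plants known brain
states so every stage of the pipeline can be validated end to end.

## Pipeline

1. **Signal conditioning** (optional). Nuisance regression (OLS with an
   intercept, residuals exactly orthogonal to the regressors), a zero-phase
   Butterworth band-pass (default 0.01–0.1 Hz, order 4, forward–backward),
   and soft despiking `y' = μ + cσ·tanh((y−μ)/(cσ))` with `c = 3` — linear
   within 3 SDs of the column mean, bounded beyond. The tanh realization of
   the "squashing" despike and the Butterworth family are our choices; the
   steps and their order (regress, then filter, then despike, no scrubbing,
   no global-signal regression) follow standard practice for DFC denoising.
2. **Static connectivity**. Whole-run Pearson correlations per node pair,
   Fisher-z transformed with the correlation clamped at ±(1 − 1e−7) so
   degenerate inputs stay finite. The meditation-vs-control contrast averages
   control-run matrices into one reference value per edge and applies a
   two-sided one-sample t test over meditation runs with Bonferroni
   correction over the N(N−1)/2 unique edges (two-sided because the contrast
   reports signed differences).
3. **Windowed connectivity**. Tapered windows of 16 TRs (46.4 s at
   TR = 2.9 s): a rectangle of the window length convolved with a Gaussian of
   scale σ = 3 TRs, truncated and peak-normalized — the convention of the
   standard dFNC toolboxes. Per window, a weighted Pearson correlation
   (weights = taper), Fisher z, strict upper triangle in a fixed row-major
   (i<j) edge order shared by all runs. Step = 1 TR, so window positions are
   quoted interchangeably with TRs; windows never span runs, and each window
   is indexed by its center TR (start + length//2).
4. **State clustering**. Windows from all runs and both conditions are
   pooled. K is selected by the elbow of the best-of-replicates
   within-cluster dispersion curve, operationalized as the k maximizing the
   ratio of successive dispersion drops; a near-flat curve (total relative
   drop < 10%) has no elbow and falls back to the smallest k with a warning.
   States are fit by k-means with L1 (city-block) distance — median centroid
   updates, greedy spread-out seeding, 20 seeded replicates, lowest cost kept
   (squared-Euclidean available by config). Noise states are pruned iff all
   their meditation windows come from exactly one meditation run *and* the
   centroid roughness (SD of first differences along the canonical edge
   ordering) exceeds 1.5× the median roughness of all states; runs left with
   no retained windows are excluded, and removed-state windows in surviving
   runs are reassigned to the nearest retained centroid.
5. **Dynamic measures**. Per run and state: proportion of window positions,
   episode count (maximal constant runs), mean dwell time (undefined — never
   0 — for absent states), switch proportion (switches / (length − 1);
   a /length convention is available), and row-stochastic transition matrices
   with self-transitions on the diagonal and NaN rows where a state has no
   outgoing steps. The contrast mirrors the static one (averaged-control
   reference, one-sample t) with Benjamini–Hochberg FDR across the measure
   family.
6. **Trajectory models**. The dominant (modal) state per meditation run and
   jhana stage (AC and afterglow excluded; ties broken by earliest first
   occurrence, logged); k-modes clustering of those categorical trajectories
   (simple-matching dissimilarity, seeded Huang-style initialization,
   best of 10 replicates, elbow on the mismatch-cost curve); and
   mixed-effects logistic models of state presence (≥1 window in the
   run-stage) with stage ordinal 1–6 (merged J6–8 coded 6) or a
   form/formless contrast as the fixed effect and run as the random
   intercept, BH-FDR across states.
7. **Phenomenology coupling**. Pearson correlations between ratings and
   dynamic measures at three levels (run-global, per-stage local,
   form/formless), raw p only by default — the states' proportions are not
   independent, so multiplicity correction is deliberately not applied (a
   config flag adds BH for reuse). Canonical correlation analysis between
   global ratings and state proportions via SVD of the whitened
   cross-covariance, with Hotelling's trace Σρᵢ²/(1−ρᵢ²) and its classical
   F approximation; proportions summing to one make that side rank-deficient
   by construction, and the redundant dimension is dropped with a warning.

## Mixed logistic fitting

The random-intercept logistic model is fit by direct marginal maximum
likelihood: the intercept integral is evaluated with 25-node Gauss–Hermite
quadrature (ample for a one-dimensional integral; agrees with `lme4::glmer`
to ~1e−3 on matched data) under box bounds on log σᵤ, so a vanishing
random-intercept variance degrades gracefully to plain logistic regression.
The reported standard error is the Wald SE from the numerically
differentiated Hessian; the slope p-value is the likelihood-ratio test
against the slope-free model, which stays calibrated at a few dozen runs
where the Wald test is noticeably conservative (null rejection ≈ 1% instead
of 5% in our simulations). Constant outcomes and diverging slopes raise an
explicit separation error rather than returning a silent estimate.

## The synthetic study generator

The generator emulates the study geometry: 49 nodes at TR = 2.9 s, 27
meditation runs of 176 TRs (≈ 512 s, eight equal stage segments) and 4
control runs of 166 TRs (≈ 8 min), with three planted connectivity states
styled on the reported ones:

* *DMN-anticorrelated*: high background correlation (r = 0.5) with a 10-node
  sub-network at r = 0.5 internally and −0.35 to the rest;
* *hyperconnected*: uniform r = 0.6;
* *sparsely connected*: weak background (r = 0.1) with one small weak block.

Requested block patterns are repaired to the nearest positive-definite
unit-diagonal correlation matrix by eigenvalue clipping (floor 1e−6) and
diagonal rescaling, iterated to convergence; a pattern whose repair moves it
beyond a tolerance raises an explicit error, as do templates closer than the
separation floor (Frobenius 1.0). The sparse state is given a weak positive
background rather than exactly zero correlations deliberately: a template
that is essentially the zero vector has no recoverable direction, so
centroid–template angles would be dominated by estimation noise for any
method.

Latent dynamics are a stage-conditioned sticky Markov chain: within a stage
the state persists with probability 0.98 per TR and otherwise redraws from
the stage's target weights (their stationary distribution). At stage
boundaries the state is updated by the **maximal coupling** of the two
stages' weight vectors — it switches only with probability equal to the
total-variation distance between successive stage distributions. This keeps
stage-marginal occupancies exactly on schedule while making transitions
gradual, emulating the continuous prevalence trajectories the analysis is
designed to detect (rather than wholesale state resets at each button
press). The default schedule moves state 1 up (0.20 → 0.85 across J1…J6–8)
and state 2 down (0.52 → 0.03), with the sparse state 3 dominating control
runs (0.90); the resulting switch proportions (~0.02–0.04 per window
position) and dwell times (tens of TRs) sit at the scale such analyses
report for real runs. Observations are zero-mean multivariate normal draws
from the active template plus isotropic noise (SD 0.2 against unit signal
variance, a realistic scale for denoised ROI-mean BOLD).

Ratings couple to the latent dynamics: width of attention
= 8 − 6·(run occupancy of state 2) + N(0, 0.75²), physical sensations in the
formless stages = 2 + 0.15·(state-2 mean dwell in formless TRs) + noise, all
clipped (not resampled) to the 1–10 scale to preserve the monotone coupling;
out-of-range noiseless expectations trigger a clipping warning. Remaining
items carry weak, uncoupled structure. With these defaults the
width/occupancy coupling yields r ≈ −0.7 at n = 27, detectable in well over
80% of replicates.

For scoring window-level recovery, a window's ground-truth label is the
taper-weighted modal latent label over its span — the state that dominates
the signal the window actually measures.

### What the generator does not emulate

No hemodynamic convolution, no voxel-level spatial structure, no
physiological noise or motion artifacts, no drift or scanner trends, and
stage durations are equal by default (real stage durations vary; a custom
stage plan hook exists). Passing recovery tests on this generator
demonstrates the pipeline's correctness and statistical behavior under the
assumed state-switching covariance model, not robustness to the full noise
structure of real 7-T BOLD data.

## Validation experiments and problem sizes

The built-in experiments (also run by `scripts/acceptance.py`) use these
sizes, chosen to finish on one CPU in minutes:

* planted-state recovery: the full default study (31 runs, ~4,950 windows of
  1,176 edges), K searched over 2–8 with 5 dispersion replicates;
* mixed-logistic recovery: presence data drawn from the model itself
  (27 runs × 6 stages), 100 replicates at slope +0.5, 150–300 under the
  null;
* coupling detection: 100 regenerated studies, Pearson test at n = 27;
* type-I calibration: both conditions drawn from one covariance at 16 nodes.
  The static arm uses 12 meditation runs against 1,000 equal-length control
  runs — equal lengths cancel the small-sample bias of the Fisher z estimate
  between conditions, and the large control pool makes the averaged
  reference effectively noise-free (its residual variance inflates t by
  √(1 + n/m)); the dynamics arm uses the study-realistic 27 meditation runs
  against 216 controls with k-means forced to 3 states.

## Known limitations

* Band-passing is only near-identity for signals already confined to the
  0.01–0.1 Hz analysis band. The synthetic generator draws temporally white
  observations, so applying the band-pass to raw synthetic data removes
  roughly half the signal variance and autocorrelates the residual, which
  measurably degrades windowed state recovery (ARI drops by ~0.1–0.2). Real
  denoised BOLD is band-limited, which is the regime the conditioning chain
  is built for; the pipeline-order test therefore checks near-identity on
  band-limited study data.

* The one-sample contrast treats the averaged control reference as a fixed
  value. When control data are scarce (the real design has 4 control runs
  against 27 meditation runs), the reference's own sampling noise inflates
  the t statistics by roughly √(1 + n_meditation/m_control) — nearly a
  factor of 2.8 at 27 vs 4 — so the contrast is anti-conservative exactly
  where the design is weakest. The calibration experiments therefore use
  large control pools; results from few-control designs should be read as
  descriptive.
* Dwell-time and episode-count measures are skewed, small-count quantities
  at run level; one-sample t tests on them have a family-wise false-positive
  rate somewhat above nominal even with a noise-free reference, which is why
  the null-calibration check on the FDR family carries a binomial tolerance
  rather than a sharp bound.
* Dominant-state ties and stages with no windows are logged, not silently
  resolved; k-modes on very few complete trajectories is fragile and
  degenerates with a warning when all trajectories coincide.
* Reported degrees of freedom for correlations are always n − 2 with n
  logged explicitly.
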