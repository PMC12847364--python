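# Methods

## Scope

`sibci` implements a complete, leakage-safe decoding analysis for a
seven-task imagery protocol (four motor-imagery tasks, two
singing-imagery variants, rest) together with a synthetic EEG generator
that emulates the protocol and provides ground truth for every
downstream claim.  This note documents the generative model, the
analysis pipeline's numerical choices, the defaults and why they were
chosen, and what the synthetic results do and do not establish about
real EEG.

## Synthetic session model

### Protocol

A session has `n_blocks` blocks (default 7); within each block every
task appears `trials_per_task_per_block` times (default 10) in an
independently shuffled order, giving 490 trials by default.  Trial
timing follows the emulated protocol: a blank screen for a uniform
0.5–1.5 s, "Ready!" and "GO!" screens of 0.5 s each, then a 4-s imagery
window.  The event marker sits on the first sample of the imagery
window with integer codes 1–7 in task order (the original marker scheme
is not published; this is our convention, stated in the file sidecars).
Recording starts and ends with 2 s of padding.

### Signal

The continuous recording is a linear instantaneous mixture of
band-limited Gaussian sources over a 1/f background:

    x(t) = Σ_s a_s · topo_s · gain_s(t) · s_s(t) + alpha + noise

* **Sources.** One rhythmic source per imagery task — right/left
  sensorimotor (C4 / C3) for the hand tasks, midline-central (Cz) for
  feet, bilateral inferior-temporal (T7+T8) for tongue, bilateral
  inferior-frontal (F7+F8) for the singing-imagery-specific source —
  plus a task-independent posterior alpha source (Oz).  Each rhythmic
  source is a mu (8–12 Hz) plus beta (18–26 Hz) pair of unit-variance
  band-limited Gaussian signals, scaled to `source_amp_uv` (default
  6 µV) at its peak electrode.
* **Topographies.** Gaussian kernels (width 0.35 head-radius units) on
  an azimuthal-equidistant 2-D projection of the standard 10-10
  positions.  The naive (x, y) projection was rejected because it
  collapses the lateral ring onto the central strip (T7 lands ~0.2
  units from C3); the azimuthal projection preserves arc distance from
  the vertex, keeping temporal and central sources distinct.  Reduced
  montages are chosen by greedy farthest-point sampling seeded with
  C3/C4/Cz so that any channel count keeps bilateral sensorimotor
  coverage.
* **Task gating (ERD).** During a trial of task t, the variance of t's
  own source in band b is multiplied by `1 + g·e_i·m_b`, floored at
  0.01 (total suppression is the physical limit).  Defaults
  `m_mu = −0.7`, `m_beta = −0.5` emulate event-related
  desynchronization; `g` is the global effect size and `e_i` a
  per-trial multiplier.  REST gates nothing — its signature is the
  absence of desynchronization.  At `g = 0` all task-conditional
  distributions are identical by construction, which makes the
  generator a leakage detector for the cross-validation.
* **Confusability knobs.** `overlap_alpha` mixes the SI_Kin topography
  convexly toward the tongue topography (identical at 1.0);
  `sinokin_depth` scales SI_noKin's modulation depth (REST-like at 0).
  With `overlap_alpha` high and `sinokin_depth` low, the 6-class
  confusion concentrates on (T, SI_Kin) and (REST, SI_noKin)
  respectively — the qualitative pattern such studies report.
* **Noise.** Independent per-channel 1/f noise (power exponent 1.0,
  flattened below 1 Hz, 4 µV) plus the common posterior alpha source
  (4 µV).  The effect-free SNR was fixed once at these values as a
  plausible resting-EEG ratio of rhythmic to broadband power.

### Subjective data

Per trial, a self-evaluation category (correct / not correct / correct
but not well) is drawn with probabilities `self_eval_probs` (default
0.7/0.15/0.15).  In **informative** mode the flags are causal: flagged
trials are synthesized with reduced effect (`flag_effect`, default 0.0
for "not correct", 0.5 for "not well").  In **uninformative** mode the
flags are drawn identically but the signal ignores them.  These two
modes bracket the scientific question behind the discard analysis:
whether self-evaluation marks genuinely degraded brain patterns.
KVIQ-style questionnaire scores are two 5–25 subscales; the kinesthetic
subscale correlates with the participant's effect-size multiplier
(default r = 0.6) to feed the correlation analyses.  Per-participant
effect multipliers are lognormal (σ = 0.3).

### What the generator does not emulate

No volume-conduction/leadfield realism, no ocular or muscular
artifacts, no nonstationary drifts, no inter-channel noise correlation.
Consequently, passing tests demonstrate that the *pipeline* recovers
CSP-compatible band-power structure without leakage and with correct
statistical calibration; they do not establish performance levels on
real recordings.

## Analysis pipeline

* **Preprocessing order** is fixed: polyphase resample 500→250 Hz
  (event indices rescaled with round-half-even), average re-reference,
  epoch −0.5…4.0 s (half-open sample windows, onset at t = 0, 1125
  samples), baseline = subtract the whole-epoch mean per trial and
  channel.  The whole-epoch rule is the emulated analysis's stated
  rule; a conventional pre-stimulus baseline is available as an
  explicit non-default (`prestim_baseline`).
* **Filter bank**: nine non-overlapping 4-Hz bands, 4–40 Hz,
  windowed-sinc (Hamming) FIR, 251 taps at 250 Hz, single-pass
  convolution with exact group-delay compensation and reflect padding.
  Forward–backward filtering would square the magnitude response and is
  deliberately not used.  At 4-Hz bandwidths the ~3.3-Hz transition
  bands mean the bank captures ~82 % of the ideal flat 4–40 Hz power;
  tests therefore check band variances against the exact
  frequency-response integral, not the flat partition.
* **Covariance window**: features and covariances use 0…4 s
  post-onset; the −0.5 s pre-onset segment serves only as filter edge
  padding.  Covariances are per-trial sample covariances,
  trace-normalized, averaged per class.  Average-referenced EEG is
  exactly rank n−1, so CSP problems are solved on the principal
  subspace of the composite/pooled covariance; an error suggesting
  diagonal loading (`diag_loading`, default off) is raised only when
  the rank cannot supply the requested filter count.
* **Binary CSP**: generalized eigenproblem Σ₁w = λ(Σ₁+Σ₂)w; filters
  scaled so wᵀ(Σ₁+Σ₂)w = 1; 5 pairs (top/bottom eigenvalues) per band;
  sign fixed by making the largest-magnitude coefficient positive.
* **Multiclass CSP**: whiten by the pooled covariance, then orthogonal
  approximate joint diagonalization of the whitened class covariances
  by Jacobi sweeps with closed-form (Cardoso–Souloumiac) angles.
  Convergence: all rotation sines < 1e−8 (commuting sets reach this
  quadratically) or per-sweep objective decrease < 1e−4 of the current
  off-diagonal energy (non-commuting sets plateau with remaining
  rotations far below covariance estimation noise); cap 200 sweeps,
  beyond which an error reports the residual energy.  Components are
  ranked by a Gaussian information surrogate,
  score_j = −½ Σ_c π_c log(s_cj/s̄_j), which is ≥ 0 and zero iff the
  component's variance is class-independent; ties break to the lower
  component index.  Ten filters per band are kept in every scenario so
  the 90-feature dimensionality holds throughout.
* **Features**: log of the raw projected variance (the normalized
  variance-fraction variant is a non-default switch).
* **mRMR-MID**: plug-in mutual information on per-column
  equal-frequency 5-bin discretization (edges learned on training data
  and reused on held-out data); first pick maximizes I(f; y), later
  picks maximize I(f; y) − mean_s I(f; s); ties go to the lower index;
  top 25 of 90 kept.
* **Classifier**: random forest, 100 trees, Gini, unlimited depth,
  bootstrap, √p candidate features per split — the standard default
  configuration of the emulated analysis.
* **Cross-validation**: stratified k-fold (k = 10), 5 repeats,
  balanced accuracy in percent (equal to plain accuracy under the
  protocol's exact class balance).  The filter bank itself is
  label-independent and applied once; CSP, discretization, mRMR and
  the forest are refit inside each training fold.  A "fit mRMR once
  per scenario" literal mode exists (`mrmr_outside_cv`) and is off by
  default: on zero-effect data the fold-fitted pipeline stays at
  chance while full-data fitting inflates a 2-class null to ~100 %.
  The pooled confusion matrix is averaged over repeats, so rows sum to
  per-class trial counts.
* **Scenarios**: all task pairs (21, including SI_Kin vs SI_noKin);
  4- and 5-subsets with at most one SI variant (25, 11); the two
  6-class sets {L,R,F,T,REST}+SI (2).
* **Statistics**: inverse-binomial-CDF thresholds (reported to one
  decimal); label-permutation nulls re-running the entire pipeline per
  permutation with add-one empirical p (never zero, floor
  1/(n_perm+1)) plus the one-sample t comparison of the null
  distribution against the observed scalar (reported but flagged as
  statistically unconventional); paired t/Cohen's d and product-moment
  correlation (rank correlation as an option); no multiple-testing
  correction, matching the per-comparison α = 0.05 convention and
  noted in report footers.  Under the exact rule the 5-class threshold
  for n = 350 is 82/350 = 23.4 %; published tables for this protocol
  print 23.3 %, which the exact inverse CDF cannot produce — the
  package reports the exact value.
* **Discard analysis**: one arm removes self-flagged trials (two
  modes: "not correct" only, or also "not well"); the control arm
  removes the same number of randomly chosen trials, count-matched per
  class (a fully random variant is a switch); both arms re-run the
  scenario cross-validation.  When nothing is flagged the arms are the
  same dataset and are evaluated once.

## Seeding

Every stochastic stage derives its stream as
`derive_seed(global_seed, *tags)` = first four bytes of
SHA-256("seed/tag1/tag2/…") mod 2³¹, so adding a participant, scenario
or permutation never perturbs the other streams, and a single `--seed`
reproduces a whole study bit-identically.

## Problem sizes used by the test and acceptance suites

The full protocol (490 trials × 64 channels) is exercised for plan
structure and I/O; pipeline-level properties run at reduced sizes
chosen once as the package's own test conditions:

* null calibration: 10 trials/class, 16 channels, 2 CV repeats, mean
  over 4 independent sessions, compared against the unchanged
  single-session 95 % binomial band (a single session's null CV mean
  has ≈11 % SD, so averaging tames Monte-Carlo noise without touching
  the band);
* 6-class recovery: g = 1, 20 trials/class, 16 channels, 10 seeds,
  compared against the n = 120 threshold (22.5 %);
* discard comparison: 20 trials/class, 8 channels, 4 + 2 CSP filters
  per band, 5 folds, 20 seeds per self-evaluation mode;
* confusion structure: `overlap_alpha` = 0.95, `sinokin_depth` = 0.2,
  24 channels (the smallest montage containing both temporal
  electrodes), two pooled sessions.

## Known limitations

* The multiclass information score is the first-order Gaussian
  surrogate; the exact criterion used by existing library
  implementations varies and is checked here only for its documented
  properties (non-negativity, zero at class-equality, deterministic
  tie-break).
* Orthogonal AJD after whitening cannot represent non-orthogonal joint
  diagonalizers; for class covariances sharing the pooled-covariance
  whitening this is the standard construction, but residual
  off-diagonal energy is genuinely non-zero on real (non-commuting)
  data.
* Equal-frequency discretization with 25 selected features is a
  pragmatic plug-in MI estimator; no bias correction is applied.
* BrainVision support is deliberately a single dialect (multiplexed
  IEEE float32, µV) with a bit-exact round trip; other dialects are
  rejected with a named error rather than approximated.
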