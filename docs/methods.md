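# Methods

This note documents the models, algorithms and numerical choices behind
`kinstyle`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Kinematic preprocessing (`kinfeat`)

Marker trajectories (six hand markers, mm, fixed rate) pass through a
zero-phase Butterworth low-pass filter (order 2, cutoff 6 Hz by default,
applied forward-backward so the effective magnitude response is the
squared single-pass response and onsets are not delayed). Wrist speed is
the Euclidean norm of central finite differences of the filtered wrist
position — second-order accurate with no phase lag.

**Reach segmentation.** Onset is the first sample whose speed exceeds the
threshold (20 mm/s default) *and stays above it* for the refractory window
(100 ms default); offset is the first later sample at or below the
threshold not followed by a renewed excursion within the refractory
window. Both guards exist for the same reason: on a noisy speed estimate a
fixed threshold crosses spuriously, while a real movement crosses
sustainedly. Trials whose speed never exceeds the threshold, or never
drops back, raise typed signals and are dropped (with the reason logged)
during batch feature extraction rather than aborting the batch.

**Variables.** Four lab-frame variables (wrist velocity, wrist height = z,
wrist horizontal trajectory = x, grip aperture = thumb-tip-to-index-tip
distance) and twelve hand-frame variables. The hand frame has its origin
at the wrist marker, X toward the index metacarpal, Z along
X × (little_mcp − wrist), Y completing a right-handed set; the exact
construction is a documented convention — any rigid-motion-invariant frame
built from the same markers gives equivalent clustering inputs. The twelve
local variables are the thumb-tip and index-tip coordinates, the unit
normal of the finger plane (through the two tips and the midpoint of the
thumb-trapezium and index-metacarpal markers — the midpoint is the one
choice that uses only recorded markers and degenerates only if the fingers
collapse onto a line), and the unit normal of the dorsum plane. Because
the dorsum plane is spanned by the same three markers that define the
frame, its normal expressed in that frame is identically (0, 0, ±1); the
columns are kept for structural completeness and carry no variance, which
the design-matrix builder records by marking them constant (sd 0) instead
of amplifying float rounding into pseudo-variance. Normal signs are fixed
non-negative-z at onset and tracked continuously to avoid sign flips.

**Normalization.** Each variable is linearly interpolated at P equally
spaced points of normalized movement time (default P = 10 at 0.1, …, 1.0;
a zero-inclusive grid is available), then each of the 16·P columns is
z-scored across trials. Z-scoring (rather than min-max) is the default
because the clustering distance below assumes roughly unit-scale
dimensions; it is configurable in effect through the `global_variances`
argument of the clustering.

## Two-step clustering (`stylecluster`)

Clustering operates on cluster-feature (CF) statistics only — point count
N, per-dimension linear sum LS and squared sum SS — which are sufficient
for every distance and criterion used. The log-likelihood merge distance
for entries A, B is

    d(A, B) = ξ_A + ξ_B − ξ_{A∪B},
    ξ_C = −N_C · Σ_k ½ · log(σ̂²_{Ck} + σ̂²_k),

where σ̂²_{Ck} is the entry's per-dimension variance from (N, LS, SS) and
σ̂²_k is the *global* per-dimension variance of the data (1 on z-scored
columns; the fit computes actual column variances, floored at 1e-6 so
constant columns stay finite). The global-variance term matters: it is
what makes a structureless Gaussian un-splittable under the
classification-style likelihood (a tiny additive constant instead would
let any split of correlated columns "pay", and no-structure data would
never select one cluster).

The pre-cluster pass inserts points sequentially: a point joins the
nearest entry if the merge distance is at or below the threshold
(default 0, i.e. exact mode with singleton sub-clusters), else seeds a new
entry; when the entry count exceeds `max_subclusters` (default 512) the
threshold is raised and entries are re-inserted (CF-tree rebuild). The
cluster step merges the two closest entries greedily down to one cluster,
recording the minimum inter-cluster distance consumed at every level.

**Cluster-count selection.** BIC(k) = −2 Σ ξ + 2·k·d·log n over the
agglomeration levels, k = 1…k_max (default 15).

1. If BIC(2) ≥ BIC(1) there is no structure: k = 1.
2. Otherwise the coarse estimate k₀ is the smallest k whose successive
   BIC change, relative to the first change, falls below 0.04. When no
   change falls below it — the usual case with clear structure, because
   past the true k the BIC rises at roughly the penalty rate — the whole
   range stays in play.
3. Refinement: among 2 ≤ k ≤ k₀, pick the k maximizing
   d_min(k) / d_min(k+1), the ratio of successive minimum merge
   distances; ties go to the smaller k; flat ratios mean no refinement
   signal and k₀ is returned with a warning.

Final labels are reported 1…k in order of descending cluster size so that
"cluster 1" is always the most prevalent style.

**Predictor importance.** Per column, a one-way ANOVA F-test of cluster
mean differences gives p_i; PI_i = −log10(p_i) / max_j(−log10 p_j), with
p floored at 1e-300. The best column scores exactly 1.
`importance_by_variable` aggregates columns to the 16 variables by the
maximum over time points.

## Representative-movement selection (`stimselect`)

Two-class Fisher LDA: w ∝ (S_w + εI)⁻¹(μ₁ − μ₀) with pooled within-class
covariance S_w and ridge ε = 1e-6 (the feature count can exceed the trial
count). Distances are measured on the discriminant axis — the "mean
variate score" of a class is its centroid — so the selection is invariant
to any affine rescaling of the axis. Counts are first equated across the
two intents (default: the smaller intent count) and then the n nearest
trials per intent are kept, ties broken by trial id. The cluster profile
of a selection reports per-cluster share (%), distinct contributing
participants and movements per participant.

## Drift-diffusion model (`ddm`)

**Density.** First-passage density of a Wiener process with unit
diffusion, drift v, absorbing boundaries {0, a} and start w·a (w fixed at
0.5), shifted by the non-decision time t. Evaluated through the standard
small-time and large-time series of the normalized (a=1, v=0) density,
choosing per evaluation whichever series needs fewer terms for truncation
error 1e-10. Trials with rt ≤ t have zero density (−∞ log density), a
contract the sampler handles by rejection rather than an exception.
Accuracy coding: a correct response is an upper-boundary crossing. No
bias or inter-trial-variability parameters (sz, sv, st) are modeled.

**Simulation.** Euler–Maruyama with default dt = 1e-3 s and a
continuity correction: discrete monitoring misses crossings between grid
points, biasing the effective boundary upward, so both barriers are moved
inward by 0.5826·√dt. With the correction, 1e5 simulated paths match the
analytic density to a KS distance of ~0.002–0.008 and the closed-form
choice probability to <0.01 even at dt = 1e-3; without it, fitted
boundary separations on simulated data are visibly biased upward. The
inner loop uses an inline xorshift64* / Box–Muller stream (deterministic
given the seed) for speed.

**Hierarchy.** Subject-level parameters: drift v_{s,c} per stimulus
cluster (or one v_s in the null model), boundary a_s > 0, non-decision
t_s ≥ 0, with group-level normals
v_{s,c} ~ N(μ_{v,c}, σ_v), a_s ~ N(μ_a, σ_a), t_s ~ N(μ_t, σ_t).
Priors are weakly informative on the empirical scale of ~1 s decisions:
μ_v ~ N(0, 2²), μ_a ~ N(1.5, 1²) truncated positive, μ_t ~ N(0.3, 0.3²)
truncated non-negative, group sds half-normal(1).

**Sampler.** Metropolis-within-Gibbs with vectorized blocks: all
subject×cluster drifts propose and accept independently in one density
evaluation, likewise all boundaries and all non-decision times; the
cluster-mean drifts have a conjugate Gibbs update and the remaining group
parameters scalar Metropolis steps. Proposal scales adapt toward ~0.4
acceptance during burn-in only. Defaults: 1500 iterations, 500 burn-in,
2 chains — the blocked updates mix fast (split R-hat < 1.05 on the study
designs used here), and the small default keeps replicate-based
validation runs at desk scale; all settings are configurable. Fits with
any split R-hat above 1.1 are flagged, never suppressed. The deviance
−2 log L is recorded at every retained draw.

**Model comparison and tests.** DIC = D̄ + p_D with
p_D = D̄ − D(θ̄), where θ̄ is the posterior mean of the subject-level
parameters (the focus of the hierarchy). A difference above 10 selects
the lower-DIC model; below the margin the comparison is inconclusive.
Posterior ordering tests use P_p|D(A < B), the fraction of retained draws
(paired across iterations and chains) where the A-draw is below the
B-draw or a constant; values below 0.05 or above 0.95 are significant.

## Synthetic data (`synthkin`)

The generator emulates a motion-capture study of reach-to-grasp with
three intents (pour, drink, place) and an observer study of two-choice
intention discrimination.

*Movement model.* Minimum-jerk wrist transport over a 46 cm reach (peak
speed 1.875·D/T, so a 20 mm/s threshold is crossed exactly twice between
rest paddings of 0.15 s), a sin² wrist-lift profile, a beta-shaped grip
aperture peaking at 70% of movement time, and a rigid hand template with
progressive pronation. Intent-specific base values (lift, peak aperture,
roll, mean duration) separate pour/drink/place; within a condition,
durations scatter with ~8% CV around the intent mean, clipped to the
overall 0.72–1.64 s range.

*Styles.* A participant's style is a constant offset on peak grip
aperture (mm) and on the tilt of the fingertip assembly about the hand's
long axis (the same length expressed at an 80 mm fingertip lever arm).
Style-group mean offsets are spaced by `separation × noise_sd`;
participants scatter around their group mean by 0.5 × noise_sd. The tilt
is applied to the fingertips rather than to the whole hand because all
hand-local variables are rigid-motion invariant: only a *shape* change is
observable, and it surfaces in the finger-plane normal and tip
coordinates. These, plus grip aperture, are the ground-truth
style-driving variables recorded for importance tests.

*Trial noise.* Two components. (1) Motor variability `noise_sd`
(default 2.5 mm): each trial perturbs peak aperture, finger tilt and
wrist lift by a smooth random function of normalized time (a constant
component with weight 0.35 plus three low-order sinusoids, pointwise
scale noise_sd). A pure constant perturbation would make every
aperture-linked column a copy of one latent variable — an artefactual
one-factor structure that real repeated movements do not show and that a
classification-likelihood criterion would split. (2) Marker measurement
noise (0.4 mm i.i.d. per coordinate sample), the scale of optical
tracking error plus soft-tissue jitter of skin-mounted hand markers.

*Observer model.* Each simulated observer gets one drift *ability*
offset (sd 0.4 evidence/s) added to every cluster's group drift — so
equally readable clusters remain equally readable within an observer —
plus subject-level boundary (sd 0.1) and non-decision time (sd 0.05).
Choices/RTs come from the Euler simulator; censored paths (none at
realistic drifts before the 10 s cap) are dropped.

*What passing tests do and do not show.* The generator produces clean
segmentable movements with known style structure and a well-specified
observer model. Recovery results therefore demonstrate the correctness of
the estimators, not robustness to marker dropout, soft-tissue artefact
structure, non-minimum-jerk transport, within-session learning, RT
contaminants (lapses, fast guesses) or model misspecification — none of
which are modeled.

## Validation design

Every quantitative claim is backed by an independent oracle: CF-based
distances against raw-point computation; greedy agglomeration against an
exhaustive best-merge search on ≤ 8 points; the analytic density against
quadrature (normalization), a closed-form hitting probability, and
1e5-path simulation (KS < 0.02); the Fisher axis against scikit-learn's
LDA; the Rand index against scikit-learn; split R-hat against arviz; and
parameter recovery against generator ground truth at the study scale (18
observers × ~400 trials; 17 actors × 10 trials per intent). Replicated
stochastic checks (cluster-count selection, DIC model selection,
overlap-pattern recovery) use 10 fixed-seed replicates with majority
thresholds. Validation runs use 800–1000 sampler iterations rather than
the 1500 default; the blocked sampler's R-hats stay below 1.05 there.

## Known limitations

- The TwoStep variant implements the all-continuous case only: no
  categorical variables and no outlier sub-cluster handling.
- Classification-style BIC plus greedy agglomeration can split strong
  continuous latent factors into spurious clusters; the zero-separation
  control quantifies this on the generator (k = 1 in ~9/10 replicates)
  but real data with dominant one-dimensional structure deserve a check
  of the merge-distance trace.
- The diffusion model fixes the start point at 0.5 and omits inter-trial
  variability; DIC is computed with the plug-in deviance at the
  subject-parameter posterior mean, which is standard but focus-dependent.
- Group-level truncations (a > 0, t ≥ 0) are enforced by rejection, not
  by renormalized truncated densities; at the parameter scales used the
  truncated mass is negligible.
- With 18 observers, group drifts are estimated with a sampling error of
  σ_v/√18 ≈ 0.09 that shifts all clusters jointly; drift-vs-zero tests on
  a truly at-chance cluster are therefore non-significant in ~90% of
  replicates, not always — the calibrated behavior of a 95% interval.
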