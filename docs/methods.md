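# Methods

## The signalling model

The model tracks seven species in arbitrary simulated concentration units
(C_s): inactive c-Jun, phosphorylated c-Jun (pJun), c-Jun mRNA, a generic
target-gene mRNA, active JNK, DUSP1 mRNA and DUSP1 protein. A binary
stimulus c(t) ∈ {0, 1} (an abstraction of agonist addition and washout)
drives JNK activation; active JNK is removed by first-order turnover and by
a saturating, DUSP1-dependent dephosphorylation term, and DUSP1 is itself
induced through pJun — a delayed negative feedback that shapes pulse
kinetics. c-Jun phosphorylation is a Hill function of active JNK
(coefficient n = 4, half-maximum T = 1 C_s); pJun feeds back on c-Jun mRNA
(autoregulation) and drives both DUSP1 and the target gene. The target
gene appears in no other equation, a structural fact exploited throughout
(below).

Three variants alter only the target production term:

- **mass_action** — β_t + β_tj·[pJun];
- **hill** — β_t + β_tj·[pJun]ⁿ/(Kⁿ + [pJun]ⁿ), with promoter affinity K
  (C_s) and cooperativity n_target;
- **delay** versions of either, using pJun(t − τ) with constant
  pre-simulation history.

Hill terms are defined as 0 at a zero numerator (continuity at the origin).

### Parameters

Defaults (units h⁻¹ unless noted): β_j = β_jp = β_tj = 3, α_j = 0.5,
n = 4, T = 1 C_s, α_junp = α_jm = α_dusp = 2.1 (20-min half-lives),
β_jmi = β_t = β_dusp = 1, β_mj = 1.5, β_jnkp = 10 C_s h⁻¹, α_jnkp = 7.5,
α_djnkp = 50, Td = 0.2 C_s, β_md = 0.25, α_dp = 0.693 (1-h half-life).
α_m, the target mRNA turnover, is the analysis variable; its package
default is 0.693 h⁻¹ (1-h half-life) and scans cover 0.02–1.4 h⁻¹
(half-lives 36 h to 30 min). For the Hill variants the package defaults
are n_target = 1.8 (a modest transcription-factor cooperativity; 1.8 and 4
are the two values the analyses compare) and K = 0.5 C_s (mid-range of the
scanned 0.01–3 C_s, comparable to peak pJun ≈ 1.3 C_s so neither limit of
the Hill curve is presumed). τ defaults to 0.

Sensitivity ranges span the 20 kinetic parameters (each uniform; e.g.
n ∈ [1, 10], T ∈ [0.1, 2] C_s, α_m ∈ [0.02, 1.4] h⁻¹, α_djnkp ∈ [30, 70]
h⁻¹). Td's range is 0.01–1 C_s (it is a concentration).

### Stimulus programs and initial conditions

`make_stimulus` builds the three canonical programs: sustained (on from
t = 0), transient (on for 1 h), pulsed (on 0–1 h and again 4–5 h), plus a
null program. Simulations start from the analytic resting (c = 0) fixed
point — active JNK, pJun and the DUSP1 pair at zero, c-Jun mRNA at
β_jmi/α_jm, inactive c-Jun at β_j·mRNA/α_j, target at β_t/α_m — because
cells are unstimulated before treatment; the fixed point is verified to
‖rhs‖∞ < 1e−8 at construction.

One deliberate exception: the *expression-pattern shape* checks
(short-lived vs long-lived target under pulsed input) initialise the
target gene at zero expression, keeping every other species at rest. From
basal steady state a 5-h mRNA shows two shallow local maxima (scaled
prominences 0.12 and 0.21); from zero it integrates the two pulses into a
single rising-then-falling curve, the "cumulative" shape these comparisons
are about, while a 30-min mRNA tracks both pulses either way. Fits and
steady-state analyses keep the resting initial condition.

## Numerics

- **Single simulations** use LSODA (rtol 1e−8, atol 1e−10), restarted at
  every stimulus switch time so discontinuities of c(t) are exact; output
  on a uniform grid, default step 0.05 h over an 8-h horizon (the span of
  the imaging and RNA timepoints).
- **Target-gene integration** exploits the decoupling: the six upstream
  species are solved once, pJun and its exact model derivative are stored
  on a 1-ms-resolution grid (10⁻³ h), and the linear target ODE
  dG/dt = P(t) − α·G is advanced with its exact exponential-integrator
  update, reconstructing P(t) per step as a cubic Hermite polynomial. The
  scheme is unconditionally stable and agrees with full joint simulation
  to < 1e−6; it is what makes 200×200 parameter scans cheap. Delay
  variants evaluate P at pJun(t − τ) from the stored interpolant with
  constant pre-simulation history — exact for this model structure, and
  equivalent to the method of steps without its bookkeeping.
- **Sensitivity-analysis evaluations** use a fixed-step RK4 integrator
  vectorised across all parameter samples (step 0.005 h; the system is
  non-stiff over the sampled ranges, fastest rate ≈ 80 h⁻¹). At default
  parameters it matches LSODA to ~5e−9 relative.
- Species non-negativity is asserted to −1e−9 on stored trajectories
  (tiny solver undershoot is clipped to zero); the right-hand side guards
  against states below −1e−6, a looser bound because adaptive solvers
  probe trial points before rejecting steps.

## Sobol sensitivity analysis

Saltelli radial sampling: two base matrices A and B from a scrambled
Sobol' sequence in 2k dimensions, plus the k cross matrices AB_i, giving
n_base·(k + 2) model evaluations (n_base = 1000 by default, k = 20).
First-order indices use the Saltelli estimator, total-order indices the
Jansen estimator; no second-order indices. The analysed output is the
target-gene value at 0.5-h steps over 0–8 h.

The scalar per-parameter summary is the **mean** index over output
timepoints. A median was considered and rejected: under sustained
stimulation the late-time output is heavy-tailed (1/α_m amplification
down to α_m = 0.02 h⁻¹), per-time indices there are estimator noise near
zero, and a median over timepoints degenerates to that noise, making the
parameter ranking seed-dependent. The mean keeps the informative early
timepoints in play without privileging any single one; with it, α_m ranks
first under all three stimulus programs for every seed tested. Negative
estimates (estimator noise) are retained raw and clipped to [0, 1] only
at reporting time. Index *magnitudes* remain noisy across seeds because
the output distribution is heavy-tailed; only the ranking is treated as a
stable conclusion.

## Grid-scan RMSE fitting

Profiles are scaled 0–8 h time courses at the RNA timepoints
{0, 2, 4, 6, 8} h (cluster means or single genes). Scans evaluate the
model on uniform, endpoint-inclusive grids — 200 α_m values on
[0.02, 1.4] h⁻¹, 200 K values on [0.01, 3] C_s, 25 delays on [0.01, 1] h —
and report the RMSE-minimising coordinates plus the implied half-life
t½ = ln 2/α_m. Ties break toward the smallest α_m, then K, then τ.

**Comparison metric.** The model is sampled at the profile's own
timepoints, both sides are min–max scaled over those shared observation
times, and both are linearly interpolated (never splined — the timepoints
are too sparse) onto a dense 0.1-h grid before the RMSE. Sampling the
model *densely* instead was tried and rejected: the dense-side RMSE is
then dominated by the mismatch between the model's curvature and the
piecewise-linear experimental interpolant, which biases the scans toward
smoother dynamics (a noiseless α_m = 0.2 profile fit at 0.186, and a
τ = 0.8 h profile at τ ≈ 0.09 h). With the symmetric treatment, noiseless
generator/scan round trips are exact. The standalone `profile_rmse`
utility keeps the general dense-curve-vs-interpolated-profile contract
for users comparing full trajectories.

**Identifiability.** The (α_m, K) surface has a shallow ridge (lower α_m
trades off against higher K); noiseless profiles generated *on* the scan
grids are recovered exactly, but off-grid truths can slide several K
steps along the ridge at an RMSE floor of ~1e−3. Five timepoints carry
limited information: a 3-grid-step change in α_m moves the scaled profile
values by ≤ 0.03 (and ≤ 0.007 for α_m ≳ 1 h⁻¹), so single-profile
estimates under additive noise of sd 0.05 scatter by ~5–25 grid steps at
mid-to-high decay rates, and noise clipped to [0, 1] adds a small upward
bias where the likelihood is flat. Cluster-level estimates are therefore
preferred: `scan_decay_profiles` minimises the gene-averaged RMSE curve
and `predict_cluster_halflife` averages per-gene half-lives (± SEM);
both are accurate in the informative regime (α_m ≲ 0.5 h⁻¹) and the
short-vs-long-lived *ordering* is robust everywhere.

A `lag` option shifts the model's sampling times to emulate the
transcription lag built into RNA sampling designs; it defaults to 0 and no
analysis here turns it on.

## KTR trace quantification

The baseline is the mean C/N ratio of the 4 frames immediately preceding
treatment (10-min frames; ~30 min of pre-imaging), per cell by default
with a shared-baseline option. A pulse is a strict post-treatment local
maximum at or above 1.5× baseline (50% above baseline); plateaus of equal
values count once at their leftmost frame and series endpoints are never
peaks. No prominence or minimum spacing is applied by default — the
height rule is the stated criterion — but a `min_distance_frames` option
exists because with frame-independent noise every jittered frame near a
broad pulse top is a strict local maximum (at 5% multiplicative noise,
height-only counting recovers 0/100 programmed counts; with a 1-h minimum
spacing, 100/100). Activity duration is the number of frames at or above
the threshold times the frame interval, optionally windowed (e.g. the
first 3 h); the area above threshold is exported as a secondary metric.

## Expression clustering

Genes pass the significance filter with FDR < 0.05, |log2FC| > 1 at ≥ 1 of
the 2/4/6/8-h timepoints, max group mean > 1 and a protein-coding biotype.
Profiles anchor t = 0 at fold change 0 and are min–max scaled per gene
(constant rows map to zeros, so the scaled peak timepoint is preserved).
Clustering is Euclidean k-means (k-means++ initialisation, best of 10
restarts, seeded); k is chosen from silhouette score, within-cluster SS
(elbow) and cluster-size dispersion, recommending the silhouette argmax
among k whose smallest cluster holds ≥ 5% of genes — advisory, never
forced. Cluster labels are renumbered by descending peak time of the
cluster-mean profile (sustained/late clusters first; ties by size), a
stable convention for cross-condition comparisons. Overlaps between
cluster gene sets report intersection size, Jaccard, both directional
fractions and — as the headline — the shared fraction of the smaller set.
Half-life cross-referencing reports per-(cluster, study) means and match
counts; genes absent from a study are counted, never imputed, and empty
cells are missing rather than zero.

## Synthetic data

The generators produce every input the pipeline reads, with serialised
ground truth sufficient to regenerate outputs bit-identically.

- *Expression profiles* come from the model itself (known α_m per gene,
  optionally K/n_target/τ), sampled at the RNA timepoints, scaled, with
  additive Gaussian noise clipped to [0, 1].
- *KTR traces* rescale the model's own active-JNK trajectory to C/N units
  (baseline 1.0, programmed peak multiple), so trace fixtures inherit
  realistic rise and decay shapes; a cheap double-sigmoid alternative is
  available. Non-responders stay at baseline; noise is multiplicative per
  frame. Defaults — 90% responders, 2.5× peak height, 5% noise, 10-min
  frames, 4 baseline frames, 8.5-h span — mirror a strongly synchronised
  agonist-dosing experiment.
- *DEG tables* assign pass/fail per filter criterion independently
  (Bernoulli), yielding an exactly known filtered set.

What the generators do **not** emulate: count-based measurement noise and
gene-gene correlation in RNA data, cell-cycle and tracking artefacts in
imaging, desynchronised or heterogeneous pulse timing across cells, and
any absolute expression scale (everything downstream is min–max scaled).
Passing round-trip tests therefore demonstrates correctness of the
estimators under the model's own assumptions, not robustness to real-data
artefacts.

## Known limitations

- The model predicts *scaled dynamics* only; promoter strength and
  absolute expression changes are out of scope by construction.
- At default parameters the second pJun pulse under the pulsed program is
  ~9% higher than the first: autoregulation (β_mj = 1.5) grows the
  inactive c-Jun pool between pulses. Active JNK — what a KTR reporter
  measures — shows the opposite, physiological ordering (second ≤ first).
- Decay-rate estimates from 5-timepoint profiles are reliable at the
  cluster level and for α_m ≲ 0.5 h⁻¹; single noisy genes at faster
  turnover are close to unidentifiable (see Grid-scan fitting).
- Sobol index magnitudes (not rankings) are unstable across seeds for
  heavy-tailed outputs such as the sustained program's late timepoints.
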