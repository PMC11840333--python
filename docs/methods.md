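# Methods

`synlink` implements a multimodal analysis chain that asks whether regional
presynaptic terminal density, measured with [11C]UCB-J PET, co-varies with
task-evoked BOLD activity and with executive task performance across
subjects. Because subject-level data for this kind of study are typically
request-only, the package pairs every analysis stage with a synthetic-cohort
generator whose ground truth is fully recorded, so each stage can be
validated by parameter recovery.

## PET kinetic model

Regional time-activity curves (TACs) follow the one-tissue-compartment
model against a metabolite-corrected arterial plasma input C_p(t):

    dC_T/dt = K1 C_p(t) − k2 C_T(t)
    C_PET(t) = (1 − V_B) C_T(t) + V_B C_wb(t)

with influx K1 (mL·cm⁻³·min⁻¹), efflux k2 (min⁻¹), fixed fractional blood
volume V_B = 0.05, whole-blood activity C_wb = C_p / (plasma-to-whole-blood
ratio), and total distribution volume V_T = K1/k2 (mL/cm³). Regional V_T is
normalised by the centrum semiovale (white matter with minimal specific
SV2A binding) to give DVRcs; the reference region has DVRcs = 1 identically.

Numerical choices:

* The input function is piecewise linear between samples and its
  convolution with e^(−k2·t) is evaluated in closed form per linear
  segment; frame values are exact time-averages of the continuous model
  over each frame (via ∫C_T = (K1∫C_p − ΔC_T)/k2). There is no quadrature
  error in the forward model, so fit accuracy is limited only by the
  optimiser.
* Fitting is bounded weighted nonlinear least squares over (K1, k2) with
  K1 ∈ (1e-4, 2], k2 ∈ (1e-4, 1] per-minute, V_B held fixed, frame weights
  proportional to frame duration (a proxy for count statistics), four fixed
  starting points, and 1e-12 termination tolerances. Non-convergence and
  all-zero inputs return flagged failure results rather than raising.
* Inputs are assumed decay-corrected and metabolite-corrected; the default
  frame schedule is 26 frames over 90 min (8×15 s, 3×60 s, 5×120 s,
  5×300 s, 5×600 s).

## Task designs and first-level GLM

Two in-scanner tasks are modelled. The N-back working-memory task is a
block design: 0-, 1- and 2-back blocks, six of each in seeded pseudorandom
order, each block ten 2-s trials followed by 10 s rest — 540 s, acquired as
270 volumes at TR 2 s. The switching task is event-related: 150 trials at
3.5-s spacing whose cue colour changes on exactly 42 trials ("switch") and
repeats on 108 ("no-switch"); the first trial has no predecessor and counts
as no-switch; 180 volumes at TR 3 s.

The GLM uses a gamma HRF with mean lag 6 s and SD 3 s (shape 4,
scale 1.5 s), truncated at 30 s and normalised to unit area so parameter
estimates are in signal units per unit regressor. Condition boxcars are
convolved on a 0.01-s grid and sampled at volume midpoints; each condition
gets an (unorthogonalised) finite-difference temporal-derivative column.
High-pass filtering with a 100-s cut-off is implemented as exact projection
onto the complement of a discrete-cosine low-frequency basis — a projection,
hence idempotent and testable, rather than FSL's Gaussian-weighted running
line. The filter is applied identically to data, task, derivative and
motion-nuisance columns (motion columns are never convolved); the intercept
is retained. Estimation is OLS per series with an optional single-pass
AR(1) Cochrane–Orcutt refinement; spatially regularised prewhitening is out
of scope. Contrasts: working-memory load "1&2-back>0-back" with weights
(−1, +0.5, +0.5) — the named contrast does not fix its weights, these make
it a mean comparison summing to zero — and "switch>no-switch" with (−1, +1).

Behavioural summaries: block accuracy is 100 × correct/responded (responded
trials only), the N-back outcome is the mean of the 1-back and 2-back
condition accuracies, and switch cost is mean RT(switch) − mean
RT(no-switch) in seconds. QC excludes subjects scoring below the group mean
− 2.5 sample SD, and subjects whose mean relative RMS displacement exceeds
0.5 mm when the above-threshold condition also persists for more than 30
consecutive volumes.

## PLS and inference

Both modalities yield a subjects × ROIs matrix (six task-relevant ROIs).
PLS-CA (canonical mode) standardises columns to zero mean and unit variance
(ddof 1), then extracts per component unit weight vectors maximising the
covariance of the block scores, by power iteration on the cross-covariance
matrix (tolerance 1e-6, max 500 iterations; if the spectrum is too
degenerate for the iteration to settle, the dominant eigenpair — the
iteration's fixed point — is computed directly). Each block is deflated by
its own scores (canonical deflation), which keeps within-block scores
orthogonal across components. Reported per component: canonical correlation
r_i and score covariance Cov_i. Sign convention: the largest-magnitude
X-weight is positive and the Y sign makes the covariance non-negative.
Column standardisation makes results invariant to affine rescaling of any
input column; whether the original study standardised is not stated, so the
step is exposed as a `scale` flag (default on, matching the cited software
family's default).

The permutation test shuffles the rows of the fMRI block while holding the
PET block fixed, refits fully, and takes the two-tailed p per component as
the proportion of permuted |r_i| strictly greater than the observed |r_i|
(1000 permutations by default). The strict rule can return p = 0; an
optional (b+1)/(m+1) smoothing is available behind a flag. Row shuffling
leaves column means and SDs unchanged, so refitting on the standardised
blocks is exact, not an approximation.

PLS-R regresses a single behavioural outcome on the PET block (two
components by default; y deflated by x-scores), reporting in-sample
R² = 1 − SS_res/SS_tot and RMSE in outcome units — no cross-validation, as
the emulated analysis evaluates predicted-vs-observed on the fitted cohort.
Its permutation test shuffles y and is one-sided on R² (only large values
argue against the null). Exploratory per-ROI associations use Pearson's r
with the two-sided t-based p (n − 2 dof), uncorrected.

Power utilities use the Fisher-z approximation:
power = Φ(√(n−3)·|atanh r| − z_{1−α/tails}) plus the negligible far tail, and
required n = ⌈((z_{1−α/tails} + z_power)/atanh r)² + 3⌉. The approximation
neglects the small-sample bias of atanh r (≈ r/(2(n−1))), which shifts true
power by about 0.015 at n = 25 — quoted powers at such n are approximate to
that order.

## Synthetic cohorts

`generate_paired_matrices` plants X = Σ_j t_j p_jᵀ + E_x,
Y = Σ_j u_j q_jᵀ + E_y, with per-component latent pairs (t_j, u_j)
bivariate standard normal at correlation ρ_j (Cholesky of the 2×2
correlation matrix), components independent, and i.i.d. Gaussian feature
noise. Default planted structure mirrors the estimated cross-modal
components of the emulated study cohort: a dominant component with loading
norms 2×2 and ρ = 0.28, and a smaller one with norms 1×1 and ρ = 0.63.

Loading directions, when not supplied explicitly, are variance-balanced
orthogonal vectors: a uniform flat-magnitude vector and a seeded balanced
±1 pattern (QR-orthonormal fallback beyond two components or for odd ROI
counts). Equal per-column planted variance matters: the PLS preprocessing
standardises columns, and under loadings with unequal per-column variance
that standardisation distorts and mixes the planted components, so the
planted ρ_j would not be recoverable even at n = 5000. With balanced
loadings the standardisation is a uniform rescaling and recovery is clean
(observed |r̂_2 − ρ_2| < 0.011 across seeds at n = 5000, noise SD 0.01).

Behaviour is linearly coupled to a PET latent score:
outcome = intercept + scale·t_j + e, with residual SD
|scale|·√((1−R²)/R²) so the population R² hits its target (default 0.45).
Defaults for switch cost — intercept 0.100 s, scale 0.055 s — give a
realistic ~60 ms RMSE at R² = 0.45. Trial-level records subtract the
sampling variance of the trial-mean difference (42 switch/108 no-switch
trials, RT SD 0.15 s) from the subject-level residual variance, so the
cohort-level coupling keeps its target R² after trial noise.

Raw-signal generation: TACs come from the 1TC forward model with
per-subject kinetic parameters drawn from per-ROI ranges (grey matter
V_T ≈ 10–27 mL/cm³; centrum semiovale at the low-V_T end, ≈ 3–6) and
multiplicative frame noise with SD ∝ 1/√(frame duration) (60-s reference
frame) mimicking count statistics — the emulated study does not
characterise either modality's within-ROI noise, so these magnitudes are
free parameters of the generator, not estimates of the study's noise.
BOLD runs are design matrix × planted amplitudes plus slow drift built
from low-frequency DCT modes (periods snapped to the filter's basis, so
the 100-s high-pass removes the drift exactly by construction) plus white
noise. In the raw-level pipeline the planted matrices are mapped to
physical units (DVR = 3 + 0.1·standardised X; PE = 0.2·standardised Y),
which leaves all correlation-based results unchanged by affine invariance.

What the generator does not emulate: scanner physics, head motion and
registration error, physiological noise structure (the BOLD noise is
white), metabolite kinetics, and any spatial correlation between ROIs
beyond the planted components. Passing recovery tests therefore shows the
estimators are correct under the stated generative model, not that real
data meet that model.

## Reproducibility and problem sizes

Identical cohort specifications (including the seed) reproduce every byte.
The pipeline fans one global seed into per-stage seeds by stable hashing of
stage names, so stages are independently reproducible; every reported
random result carries its seed.

Validation problem sizes were chosen as the smallest that make the checks
sharp: planted-structure recovery uses n = 5000 subjects (Monte-Carlo error
of a correlation ≈ 0.01 there); permutation calibration uses 500 null
cohorts of n = 25 with 1000 permutations each (binomial SE ≈ 0.01 on the
type-I rate, against an acceptance band of 0.03–0.07); kinetic-fit closure
uses a 3×3 (K1, k2) grid spanning realistic grey/white-matter values.

## Known limitations

* PLS-CA weights are reported per deflated block (standard NIPALS
  convention); they are not back-rotated to the original variables beyond
  the first component.
* The voxelwise path (maps + masks) is intended for toy grids; there is no
  volumetric parametric imaging at realistic sizes, registration, or
  group-level cluster inference.
* The strict permutation p-value has resolution 1/m and can be exactly 0.
* The Fisher-z power utilities describe the z-test; for n below ~50 they
  understate true power by up to ~0.02.
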