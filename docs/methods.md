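# Methods

`infantpress` implements a continuous (field-level) analysis of infant
foot–ground interaction on a pressure platform: centre-of-pressure (CoP)
trajectories placed in a cohort-wide reference system, pedobarographic
image registration, and statistics over whole curves and whole images
rather than region summaries.  Because no infant pressure recordings are
distributed with the package, every stage is exercised on synthetic
footstep data whose generator is itself a first-class, tested component.
This note documents the models, the parameters that matter, and the
design choices made where more than one reasonable construction exists.

## Platform grid and conventions

Frames are 36 × 25 matrices of pressures (kPa) at 0.5 cm sensor pitch
(4 sensors/cm²), sampled at 100 Hz.  Rows index the anterior–posterior
(AP) axis; after vertical rotation the row index increases toward the
toes.  Columns index the medio-lateral (ML) axis; after mirroring left
steps onto the right-foot convention the column index increases
medially.  Physical coordinates are 0-based pixel centres
(`coordinate = index × pitch`).  The maximum pressure picture (MPP) of a
step is the pixelwise maximum over its frames.

## Synthetic cohort

Anthropometrics for the two walking stages (*new*: first 3–5 independent
steps; *confident*: 10–15 steps with navigation and carrying) are drawn
from a componentwise-truncated multivariate normal whose per-stage
means, SDs and ranges are the package defaults
(`synthetic.DEFAULT_ANTHROPOMETRICS`), e.g. new-stage mass
10.3 ± 1.3 kg on [8.0, 13.8], foot length 11.4 ± 0.7 cm.  Four pairwise
Pearson correlations are imposed (height–age 0.53, height–mass 0.63,
mass–foot length 0.50, experience–age 0.59); unspecified pairs are 0 and
the matrix is projected to the nearest positive-definite correlation
matrix.  Componentwise truncation attenuates correlations, so the
generator calibrates the latent matrix once (a short fixed-seed
Monte-Carlo fixed point) so that the *realized* correlations match the
targets; with that calibration the sampled height–mass correlation is
0.61–0.63 at n = 5000.

Visits are comonotone: each infant keeps one latent z-score per growth
variable across stages, so confident-stage age, mass, height and foot
size always exceed the new-stage values while each stage retains its own
marginals.  Walking experience defaults to cumulative days since the
first-walking milestone (guaranteed monotone across visits); the
alternative per-visit "days since the most recent milestone" reading is
available as `experience_mode="since_milestone"`, since the underlying
definition is ambiguous.

## Synthetic footstep (rollover) model

A step is rendered by evaluating a continuous pressure field at the
(posed) pixel centres, for 30 frames (0.3 s of stance at 100 Hz; the
pipeline time-normalizes, so the count only sets temporal resolution).
The field is built from, in foot coordinates (u medial, v from the
heel):

- a **two-lobed silhouette**: a smooth half-width profile (fraction of
  W/2) with a wide heel (~0.8), narrowed midfoot (~0.52), widest
  forefoot (1.0), tapering to zero at both ends, with a parabolic
  pressure cross-section;
- a **contact wave**: a Gaussian activation along v whose centre runs
  piecewise-linearly from the stage's `contact_onset_frac` of foot
  length (default 0.50 for new walkers, 0.30 for confident walkers)
  through a common convergence knot (62% of foot length at 38% of
  stance) to toe-off at 82%.  After the convergence knot the path is
  *identical for every onset*, so stage differences are confined to
  early stance, the way infant AP trajectories merge in mid-stance;
- **zone gains** setting peak pressures per anatomical region (heel 160,
  midfoot 60, forefoot 140, toes 90 kPa — infant-scale magnitudes);
- a **medial ridge**: a sustained, low-amplitude (0.25×) copy of the
  cross-section shifted medially (nominally `medial_offset × W`, default
  0.22, scaled with the local half-width), broad along v (0.30 L) and
  gated by a stage-independent reference load envelope.  Because the
  ridge's peak stays below the base peak, it barely moves the pixelwise
  *maximum* image, while it shifts every *frame's* centroid medially —
  this is what makes the instantaneous CoP medial to the MPP's
  longitudinal axis at essentially every stance node, without tilting
  the image's principal axis.  (A naive "shift the activation medially"
  construction fails: the MPP centroid then shifts with the CoP and the
  two cancel.)
- a **contact floor** (5 kPa) of light whole-sole pressure, so the MPP
  support spans the full silhouette and the most posterior contact point
  stays at the anatomical heel even when the CoP starts mid-foot;
- an envelope `sin(πt)^0.7` making total load rise from and return to
  zero (frames 0 and 29 are exactly unloaded), a 0.5 kPa cutoff giving
  compact support, and additive Gaussian sensor noise (SD 3 kPa)
  applied only inside the loaded region.

The onset knot is calibrated per step (two fixed-point iterations on a
fine off-grid lattice) so the first loaded frame's pressure centroid
sits at `contact_onset_frac × L` exactly; only the pre-convergence part
of the path moves.  The pose is a uniform in-plane rotation (default
≤ 20°) and a translation drawn uniformly from the feasible region that
keeps all nonzero pixels at least one pixel inside the border; pose,
per-frame true CoP (computed on a fine sub-pixel lattice) and the onset
are recorded as ground truth.  Left feet are the exact mirror
construction of right feet.

What the generator does *not* emulate: toe individuation, double
support, turning or squatting steps, inter-step variability of the
rollover profile beyond sensor noise, and any forward dynamics.  Tests
passing on these data therefore validate the *pipeline machinery*
(geometry, references, statistics) and its calibration targets, not
claims about real infant gait.

## Pre-processing

The visual step-selection criteria used on real recordings are replaced
by programmatic proxies (`validate_step`): no nonzero pixel on an MPP
border row/column; first and last frames unloaded with a loaded
interior; MPP contact area ≥ 50% of foot length × width (skipped when
foot dimensions are unknown).

Vertical rotation aligns the pressure-weighted principal axis of the MPP
with the AP axis.  Heel/toe disambiguation compares the centroid of the
earliest-loaded 20% of frames with that of the latest-loaded 20% (the
rollover travels heel→toe); this is robust even when initial contact is
at mid-foot, where a "posterior half" rule would be ambiguous.  The
content is recentred on the *occupancy* (support) centroid rather than
the pressure centroid: the pressure centroid moves with the loading
pattern (stage-dependent), which would leak stage differences into the
posterior-contact reference K.  Resampling is bilinear with negatives
clipped; because a rigid motion conserves total load exactly, each frame
is renormalized to its pre-rotation total (plain bilinear interpolation
loses up to ~8% on frames with few loaded pixels).  Residual rotation
error on noise-free synthetic steps is ≤ ~1°; a second application
changes the angle by < 0.1°.

## CoP trajectories and the common reference system

Per loaded frame (total load > 1 kPa, the assumed platform noise floor)
the CoP is the pressure-weighted centroid of pixel centres.  Stance time
is normalized uniformly over loaded frames and the path is resampled to
101 nodes by cubic spline (endpoints preserved exactly; linear fallback
below 4 support points).

Two scalar references per step place all trajectories in one frame:
K, the minimum AP coordinate among MPP pixels above threshold (most
posterior contact), and J, the ML coordinate of the MPP's longitudinal
axis (pressure-weighted centroid after rotation).  Both are aggregated
hierarchically — arithmetic mean over an infant's steps per visit
(K_WS, J_WS), then mean over infants and visits (K_BS, J_BS); the
statistic is configurable since only "estimated" behaviour is required.
Re-referencing subtracts the between-infant values elementwise
(`AP − K_BS`, `ML − J_BS`); ML is signed so positive is medial.
Trajectories are finally normalized to percent of foot length / width.
On default cohorts the mean normalized AP origin is ≈ 51% (new) and
≈ 31% (confident) of foot length, recovering the generator's stage
profiles; the noise-free end-to-end chain reproduces the generator's
true CoP path to < 0.1 cm at every node.

## Registration

MPPs above 1 kPa become point clouds (one point per pixel centre,
pressures carried by point identity — registration moves coordinates,
never deforms pressures).

*Within infant*: step clouds are rigidly aligned by ICP (nearest
neighbour + least-squares Procrustes, two initializations — centroid and
centroid + principal axis — keeping the better basin; known in-plane
transforms up to 20° are recovered to < 1e-4 cm mean residual on
noise-free clouds).  The reference is the medoid step cloud (minimum
summed symmetric NN distance after centering), and for each reference
point the matched points' coordinates and pressures are averaged.

*Between infants*: mean clouds are non-rigidly moved to an unbiased
template — the medoid mean cloud — by coherent point drift (Gaussian
mixture EM with a motion-coherence kernel).  Defaults are
`beta = 0.75 cm`, `lambda = 2`, `max_iter = 300`, `tol = 1e-8` (relative
objective change).  The kernel width was chosen against the 0.5 cm
sensor lattice: a much wider kernel (e.g. 2 cm) cannot represent the
sub-lattice corrections that remain after the smooth shape difference is
absorbed, and plateaus near ~0.5 mm mean overlap error, above the
documented registration quality of this methodology (< 0.4 mm); at
0.75 cm the kernel is still 1.5 pixels wide (coherent at footprint
scale) and the chain reaches ~0.25–0.35 mm on cohort-range feet with
smooth warps up to 5%.  The EM objective is non-increasing and σ² is
floored at 1e-10 to avoid degenerate collapse.

Aligned clouds are resampled onto the template's pixel lattice by linear
scattered-data interpolation inside the convex hull (the valid-data
mask), with nearest-neighbour fill on hull-boundary lattice points.

## Statistics

All paired tests are two-tailed at α = 0.05 (both directions of change
are of interest).

**1D (101-node curves).**  Node-wise paired t statistics; residual
smoothness summarized as the FWHM implied by the mean squared gradient
of unit-normalized residuals; the family-wise critical threshold is the
smallest t whose expected-Euler-characteristic tail probability over
`resels = 100 / FWHM` is ≤ α/2, clamped between the single-comparison
and Bonferroni quantiles.  Suprathreshold clusters are reported as node
intervals with the EC tail probability at the cluster peak (no
cluster-extent calibration).  On a smooth Gaussian null (20 pairs,
FWHM 10) the empirical family-wise error is 0.050 ± 0.007 over 1000
replicates.  Normality screening uses the node-wise D'Agostino–Pearson
K² statistic on residuals against an RFT-corrected χ²₂ threshold;
residuals (not raw curves) are tested, matching what the t-test assumes.

**2D (template-aligned images).**  The analysis mask keeps pixels with
valid data in ≥ 90% of images (remaining gaps count as 0 kPa).  The
paired test flips the signs of per-pair difference images — exhaustively
when 2ⁿ fits in the permutation budget (default 10 000), otherwise
sampled with the observed labelling included — and thresholds |t| at the
(1 − α) quantile of the max-|t| distribution (pixel-level inference; no
cluster statistics, since single-pixel effects are meaningful at this
resolution).

**Predictor screening.**  Pairwise Pearson correlations among candidate
predictors; pairs with |r| ≥ 0.5 and p < 0.001 are flagged and the
lower-priority member dropped.  The default priority keeps walking
experience, mass and the foot-width variables and drops age (a
chronological, not developmental, variable) and height (redundant with
mass).  Normalised foot width is width/length × 100 (the percent scale
of the cohort table, ≈ 45.6 for new walkers).

**Pixel-level regression.**  Per pixel, OLS of pressure on all retained
predictors plus intercept; per-predictor inference by Freedman–Lane
permutation (permute residuals of the reduced model, refit the full
model) with max-|t| family-wise control, deterministic given the seed.
Rank-deficient designs are rejected naming the collinear columns.

## Problem sizes

The shipped benchmarks use 1000 null replicates for the 1D error-rate
calibration, 20 infants × 3 steps for the registration chain, and the
full 39-infant × 2-stage × 2-foot × 3-step design (468 steps) for the
trajectory pipeline — the cohort-scale design throughout, which keeps a
complete run in the tens of seconds on one CPU.

## Known limitations

- The reference-system scatter (K per step minus K_BS) adds ~2% of foot
  length of between-step noise to trajectory origins; only cohort means
  are calibrated quantities.
- CPD at sub-lattice kernel widths willingly interpolates sensor noise;
  the overlap error metric rewards this.  Pressure *values* are never
  deformed, so downstream pixel statistics are unaffected beyond the
  correspondence itself.
- RFT thresholds assume smooth, stationary Gaussian residual fields; the
  permutation procedures are the fallback wherever that is doubtful.
- The greedy screen resolves correlated predictor pairs by a fixed
  priority; with different priorities a different retained set (and
  different regression maps) results.
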