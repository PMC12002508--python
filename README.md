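# infantpress

Continuous analysis of infant foot–ground interaction from plantar
pressure recordings: centre-of-pressure (CoP) trajectories in a
cohort-wide reference system, pedobarographic image registration, and
field-level statistics over whole curves and whole pressure images —
exercised end to end on synthetic footstep data that emulates a cohort
of infants observed at two stages of walking development (*new*: first
3–5 independent steps; *confident*: 10–15 steps with navigation and
carrying).

It is written for movement scientists who analyse pressure-platform
data and want the continuous (per-node / per-pixel) treatment instead
of region-of-interest averages, and for methodologists who need a
fully synthetic, ground-truthed testbed for that pipeline.

## What it computes

**Trajectories.** Steps are 36 × 25 pressure-frame sequences (0.5 cm
pitch, 100 Hz).  Each step is vertically rotated by PCA of its maximum
pressure picture (MPP), left feet are mirrored onto the right-foot
convention, and the per-frame CoP (pressure-weighted centroid) is
resampled to 101 stance nodes by cubic spline.  Trajectories are placed
in a common frame built from the most posterior contact point K and the
longitudinal-axis coordinate J of each MPP, aggregated within infants
(K_WS, J_WS) then between infants (K_BS, J_BS):

    AP_it = AP_t − K_BS        ML_it = ML_t − J_BS

with ML signed positive = medial, and finally normalized to percent of
foot length / width.

**Registration.** MPPs become pressure-bearing point clouds; steps are
rigidly aligned within infant (iterative closest point) and averaged
into one mean cloud per infant, mean clouds are non-rigidly aligned to
an unbiased medoid template (coherent point drift), and the aligned
clouds are resampled onto the template lattice for pixelwise
comparison.

**Statistics.** Node-wise paired t-tests over the 101 nodes with
random-field-theory family-wise thresholds (statistical parametric
mapping for 1D data, plus a node-wise normality check); pixel-wise
paired tests on aligned images with sign-flip permutation max-|t|
thresholds; Pearson screening of correlated predictors (|r| ≥ 0.5,
p < 0.001); and pixel-level linear regression of pressure on
developmental predictors (body mass, foot width, normalised foot
width = width/length × 100, walking experience) with Freedman–Lane
permutation inference.

**Synthetic data.** `infantpress.synthetic` draws cohorts whose
anthropometrics match published per-stage summary statistics (means,
SDs, ranges, pairwise correlations) and renders footsteps from a
two-lobed foot silhouette with a stage-dependent rollover: initial
contact at 50% of foot length for new walkers vs 30% for confident
walkers, a medially biased CoP, visit-level rollover variability, and a
random pose on the platform.  Every step carries its generator truth
(CoP path, pose, onset), so the whole pipeline is tested by parameter
recovery.  See `docs/methods.md` for the model details.

## Worked example

```python
from infantpress import pipeline, synthetic

cfg = pipeline.PipelineConfig(
    cohort=synthetic.CohortConfig(n_infants=10, steps_per_foot_per_stage=2, seed=0),
    n_perm=500, seed=0,
)
report = pipeline.run_pipeline(cfg)

print({k: round(v["mean"], 1) for k, v in report.ap_origin_percent.items()})
print(report.spm1d["AP"]["clusters"])
print(report.registration_error_mm["cpd_mean"])
```

prints (exactly reproducible with this config):

```
{'new': 51.3, 'confident': 31.7}
[[0, 33, 8.680231382223886e-13]]
0.31272712790064866
```

Reading: the mean AP trajectory origin is at ~51% of foot length for
new walkers and ~32% for confident walkers — new walkers first touch
the ground with the mid-foot, confident walkers near the heel.  The
paired 1D test flags a suprathreshold cluster over stance nodes 0–33
(early stance, where the two rollovers genuinely differ) and nothing
later, where the trajectories merge.  The mean point-overlap error of
the between-infant registration is ≈ 0.31 mm, i.e. well below the
sensor pitch.  The same run also writes `report.json`,
`trajectories.csv`, the reference-system values and the aligned images
when `outdir` is set, and reports the 2D paired pressure comparison and
the per-predictor regression maps with significant-pixel counts per
anatomical zone.

The same pipeline is available from a shell:

```sh
infantpress run-all --seed 0 --out results/run0
infantpress simulate --seed 1 --out data/   # just the synthetic dataset
```

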