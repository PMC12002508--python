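"""Self-contained benchmark routines for the pipeline's headline numbers.

Each routine generates its own synthetic inputs (cohorts, footstep
clouds, smooth null curves), runs the relevant part of the pipeline from
scratch, and returns the measured quantity.  They are used both by the
test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import cop, registration as reg, synthetic
from .io import compute_mpp, mirror_to_common_side, pca_vertical_rotate
from .spm import PairedSPM1D

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def smooth_gaussian_curves(n_curves: int, n_nodes: int, fwhm: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise curves smoothed to the given FWHM
    (circular convolution keeps the field stationary)."""
    white = rng.standard_normal((n_curves, n_nodes))
    smooth = gaussian_filter1d(white, fwhm * FWHM_TO_SIGMA, axis=1, mode="wrap")
    return smooth / smooth.std()


def fwer_paired_1d(
    n_replicates: int = 1000,
    n_pairs: int = 20,
    n_nodes: int = 101,
    fwhm: float = 10.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical family-wise false-positive rate of the parametric paired
    1D test under a smooth Gaussian null (zero true difference)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        a = smooth_gaussian_curves(n_pairs, n_nodes, fwhm, rng)
        b = smooth_gaussian_curves(n_pairs, n_nodes, fwhm, rng)
        hits += PairedSPM1D(a, b, alpha=alpha).fit().h0_rejected
    return hits / n_replicates


def registration_pipeline_error(
    n_infants: int = 20,
    steps_per_infant: int = 3,
    warp_frac: float = 0.05,
    seed: int = 0,
    stage: str = "new",
) -> dict:
    """Mean pixel-overlap error (mm) of the registration chain.

    Synthetic infants' step clouds (random in-plane poses, sensor noise,
    per-infant smooth shape warps up to ``warp_frac`` of the footprint)
    are ICP-registered within infant and coordinate-averaged; the mean
    clouds are CPD-registered to the medoid template.  Returns the mean
    symmetric nearest-neighbour error over all registered pairs, plus the
    within- (ICP) and between-infant (CPD) components.
    """
    cfg = synthetic.CohortConfig(n_infants=n_infants, seed=seed)
    profiles = synthetic.sample_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 4]))
    icp_errors: list[float] = []
    mean_clouds: list[reg.PressureCloud] = []
    for i, profile in enumerate(profiles):
        clouds = []
        for k in range(steps_per_infant):
            step_seed = int(rng.integers(0, 2**31 - 1))
            ss = synthetic.synthesize_step(profile, stage, seed=step_seed)
            rotated, _ = pca_vertical_rotate(ss.step)
            cloud = reg.mpp_to_cloud(compute_mpp(rotated), 1.0)
            # per-infant smooth shape warp (same warp for each of the
            # infant's steps: it is a property of the foot, not the step)
            warped = reg.apply_smooth_warp(cloud.points, warp_frac, seed=1000 + i)
            clouds.append(cloud.replace(points=warped))
        mean_cloud = reg.within_subject_mean(clouds)
        mean_clouds.append(mean_cloud)
        for c in clouds:
            _, aligned, _ = reg.icp_align(c, mean_cloud)
            icp_errors.append(reg.registration_error(aligned, mean_cloud))
    template = reg.select_template(mean_clouds)
    cpd_errors = []
    for cloud in mean_clouds:
        res = reg.cpd_nonrigid(cloud, template)
        cpd_errors.append(reg.registration_error(cloud.replace(points=res.displaced), template))
    all_errors = icp_errors + cpd_errors
    return {
        "mean_mm": float(np.mean(all_errors)),
        "icp_mean_mm": float(np.mean(icp_errors)),
        "cpd_mean_mm": float(np.mean(cpd_errors)),
        "n_pairs": len(all_errors),
    }


def ap_origin_by_stage(
    n_infants: int = 39,
    steps_per_foot_per_stage: int = 3,
    seed: int = 0,
) -> dict:
    """Mean AP-trajectory origin (% foot length) per stage, computed by
    the full chain: generate, rotate, mirror, CoP, 101-node resampling,
    K/J reference construction, re-referencing and normalization."""
    cfg = synthetic.CohortConfig(
        n_infants=n_infants, steps_per_foot_per_stage=steps_per_foot_per_stage, seed=seed
    )
    steps = synthetic.generate_dataset(cfg, compute_truth=False)
    per_step_refs = []
    paths = []
    meta = []
    for s in steps:
        rotated, _ = pca_vertical_rotate(s.step)
        st = mirror_to_common_side(rotated)
        mpp = compute_mpp(st)
        per_step_refs.append(
            (st.infant_id, st.stage, cop.compute_K(mpp, 1.0), cop.compute_J(mpp))
        )
        paths.append(cop.resample_101(cop.compute_cop_path(st, 1.0)))
        meta.append((st.stage, s.foot_length_cm, s.foot_width_cm))
    refs = cop.aggregate_reference(per_step_refs)
    origins: dict[str, list[float]] = {}
    for (stage, L, W), p in zip(meta, paths):
        traj = cop.normalise_trajectory(cop.rereference(p, refs), L, W)
        origins.setdefault(stage, []).append(cop.ap_origin_percent(traj))
    return {stage: float(np.mean(v)) for stage, v in origins.items()}


def cohort_mass_mean(n_infants: int = 39, seed: int = 0, stage: str = "new") -> float:
    """Sample mean body mass (kg) of a default synthetic cohort."""
    cfg = synthetic.CohortConfig(n_infants=n_infants, seed=seed)
    profiles = synthetic.sample_cohort(cfg)
    return float(np.mean([p.stages[stage].mass_kg for p in profiles]))
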