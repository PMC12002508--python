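"""End-to-end pipeline: simulate -> preprocess -> CoP -> register -> stats.

``run_pipeline`` executes every stage on a synthetic cohort, writes the
intermediate artifacts (ASCII images, CSV tables, JSON reports) to the
output directory, and returns a machine-readable :class:`RunReport`.
The entire run is a pure function of (config, seed): rerunning with the
same configuration reproduces the report bit for bit (timestamps are
deliberately excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cop, registration as reg, synthetic
from .grid import N_COLS_ML, N_ROWS_AP, PITCH_CM
from .io import compute_mpp, mirror_to_common_side, pca_vertical_rotate, validate_step, write_grid_ascii
from .spm import (
    PairedPermutationSPM2D,
    PairedSPM1D,
    PixelRegression,
    correlation_screen,
    normalised_foot_width,
)

log = logging.getLogger("infantpress")

#: fractional AP bands (of the mask bounding box, heel at low AP index)
ZONE_AP_BANDS = {"heel": (0.0, 0.30), "midfoot": (0.30, 0.60), "forefoot": (0.60, 0.85), "toes": (0.85, 1.001)}
#: ML thirds; the column index increases medially
ZONE_ML_BANDS = {"lateral": (0.0, 1 / 3), "central": (1 / 3, 2 / 3), "medial": (2 / 3, 1.001)}


@dataclasses.dataclass
class PipelineConfig:
    cohort: synthetic.CohortConfig = dataclasses.field(default_factory=synthetic.CohortConfig)
    load_threshold: float = 1.0
    area_ratio_min: float = 0.5
    icp_max_iter: int = 100
    icp_tol: float = 1e-8
    cpd_beta: float = 0.75
    cpd_lambda: float = 2.0
    cpd_max_iter: int = 300
    cpd_tol: float = 1e-8
    alpha: float = 0.05
    n_perm: int = 1000
    r_thresh: float = 0.5
    p_thresh: float = 0.001
    priority: list | None = None
    outdir: str | None = None
    seed: int = 0

    def validate(self):
        self.cohort.validate()
        if not 0.0 < self.alpha < 1.0:
            raise synthetic.ConfigurationError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = {
            "n_infants": self.cohort.n_infants,
            "stages": list(self.cohort.stages),
            "steps_per_foot_per_stage": self.cohort.steps_per_foot_per_stage,
            "experience_mode": self.cohort.experience_mode,
            "seed": self.cohort.seed,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.cohort = synthetic.CohortConfig(**cohort_raw)
        return cfg


@dataclasses.dataclass
class RunReport:
    counts: dict
    references: dict
    ap_origin_percent: dict
    ml_medial_fraction: dict
    spm1d: dict
    spm2d: dict
    regression: dict
    registration_error_mm: dict
    provenance: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_zones(significant: np.ndarray, mask: np.ndarray, pitch_cm: float = PITCH_CM) -> pd.DataFrame:
    """Counts of significant pixels per anatomical zone.

    Zones are fractional AP/ML bands of the template mask's bounding box:
    heel 0-30% of length, midfoot 30-60%, forefoot 60-85%, toes 85-100%;
    medial / central / lateral thirds of the width (column index
    increases medially).  Zone counts partition the significant pixels.
    """
    sig = np.asarray(significant, bool)
    m = np.asarray(mask, bool)
    rows_idx, cols_idx = np.nonzero(m)
    out = []
    if rows_idx.size == 0:
        for zap in ZONE_AP_BANDS:
            for zml in ZONE_ML_BANDS:
                out.append(dict(ap_zone=zap, ml_zone=zml, n_significant=0))
        return pd.DataFrame(out)
    r0, r1 = rows_idx.min(), rows_idx.max()
    c0, c1 = cols_idx.min(), cols_idx.max()
    rr, cc = np.nonzero(sig & m)
    fr = (rr - r0) / max(r1 - r0, 1)
    fc = (cc - c0) / max(c1 - c0, 1)
    for zap, (a0, a1) in ZONE_AP_BANDS.items():
        for zml, (b0, b1) in ZONE_ML_BANDS.items():
            n = int(np.sum((fr >= a0) & (fr < a1) & (fc >= b0) & (fc < b1)))
            out.append(dict(ap_zone=zap, ml_zone=zml, n_significant=n))
    return pd.DataFrame(out)


def _zone_table_dict(sig, mask):
    df = summarize_zones(sig, mask)
    return {f"{r.ap_zone}_{r.ml_zone}": int(r.n_significant) for r in df.itertuples()}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and return the report."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- simulate -------------------------------------------------------
    log.info("stage 1/5: simulate")
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    profiles = synthetic.sample_cohort(cohort_cfg)
    prof_by_id = {p.infant_id: p for p in profiles}
    steps = synthetic.generate_dataset(cohort_cfg, compute_truth=False)
    counts = {"generated": len(steps), "valid": 0, "excluded": 0, "excluded_reasons": {}}

    # ---- preprocess -----------------------------------------------------
    log.info("stage 2/5: preprocess (validate, rotate, mirror)")
    processed = []  # (SyntheticStep, rotated+mirrored StepRecord)
    for s in steps:
        rep = validate_step(
            s.step,
            area_ratio_min=config.area_ratio_min,
            foot_length_cm=s.foot_length_cm,
            foot_width_cm=s.foot_width_cm,
            load_threshold=config.load_threshold,
        )
        if not rep.is_valid:
            counts["excluded"] += 1
            for flag in ("within_borders", "full_cycle", "no_omission"):
                if not getattr(rep, flag):
                    counts["excluded_reasons"][flag] = counts["excluded_reasons"].get(flag, 0) + 1
            continue
        rotated, _ = pca_vertical_rotate(s.step, load_threshold=config.load_threshold)
        processed.append((s, mirror_to_common_side(rotated)))
        counts["valid"] += 1

    report_empty = RunReport(
        counts=counts, references={}, ap_origin_percent={}, ml_medial_fraction={},
        spm1d={}, spm2d={}, regression={}, registration_error_mm={},
        provenance=_provenance(config),
    )
    if not processed:
        if outdir:
            report_empty.to_json(outdir / "report.json")
        return report_empty

    # ---- CoP ------------------------------------------------------------
    log.info("stage 3/5: CoP trajectories and reference system")
    per_step_refs = []
    paths101 = []
    for s, st in processed:
        mpp = compute_mpp(st)
        per_step_refs.append(
            (st.infant_id, st.stage, cop.compute_K(mpp, config.load_threshold), cop.compute_J(mpp))
        )
        paths101.append(cop.resample_101(cop.compute_cop_path(st, config.load_threshold)))
    refs = cop.aggregate_reference(per_step_refs)
    trajectories = []
    for (s, st), p101 in zip(processed, paths101):
        tr = cop.rereference(p101, refs, side=st.side, mirrored=True,
                             infant_id=st.infant_id, stage=st.stage)
        tr.side = st.side
        trajectories.append(cop.normalise_trajectory(tr, s.foot_length_cm, s.foot_width_cm))

    ap_origin = {}
    ml_medial = {}
    for stage in config.cohort.stages:
        vals = [cop.ap_origin_percent(t) for t in trajectories if t.stage == stage]
        mls = [np.mean(t.ml_101 > 0) for t in trajectories if t.stage == stage]
        if vals:
            ap_origin[stage] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0, "n": len(vals)}
            ml_medial[stage] = float(np.mean(mls))
    if outdir:
        cop.trajectories_to_frame(trajectories).to_csv(outdir / "trajectories.csv", index=False)
        Path(outdir / "references.json").write_text(json.dumps(
            {"K_BS": refs.K_BS, "J_BS": refs.J_BS,
             "K_WS": {f"{k[0]}/{k[1]}": v for k, v in refs.K_WS.items()},
             "J_WS": {f"{k[0]}/{k[1]}": v for k, v in refs.J_WS.items()}},
            indent=2, sort_keys=True))

    # ---- registration ---------------------------------------------------
    log.info("stage 4/5: registration (ICP within, CPD between)")
    groups: dict[tuple[str, str], list] = {}
    for s, st in processed:
        groups.setdefault((st.infant_id, st.stage), []).append(st)
    mean_clouds = {}
    for (iid, stage), sts in groups.items():
        clouds = [reg.mpp_to_cloud(compute_mpp(st), config.load_threshold) for st in sts]
        mean_clouds[(iid, stage)] = reg.within_subject_mean(clouds)
    template = reg.select_template(list(mean_clouds.values()))
    aligned = {}
    cpd_errors = []
    for key, cloud in mean_clouds.items():
        res = reg.cpd_nonrigid(cloud, template, beta=config.cpd_beta, lam=config.cpd_lambda,
                               max_iter=config.cpd_max_iter, tol=config.cpd_tol)
        moved = cloud.replace(points=res.displaced)
        cpd_errors.append(reg.registration_error(moved, template))
        aligned[key] = reg.resample_to_template_grid(
            res.displaced, cloud.pressures, infant_id=key[0], stage=key[1]
        )
    reg_err = {"cpd_mean": float(np.mean(cpd_errors)), "cpd_max": float(np.max(cpd_errors))}
    if outdir:
        for (iid, stage), img in aligned.items():
            write_grid_ascii(img.grid, outdir / f"aligned_{iid}_{stage}.txt",
                             {"infant_id": iid, "stage": stage})

    # ---- statistics -----------------------------------------------------
    log.info("stage 5/5: statistics")
    spm1d_out, spm2d_out, regression_out = {}, {}, {}
    stages = list(config.cohort.stages)
    if len(stages) >= 2:
        s_a, s_b = stages[0], stages[1]
        ids = sorted({iid for (iid, _) in mean_clouds})
        # per-infant mean normalized curves per stage
        def stage_curves(stage, comp):
            rows = []
            for iid in ids:
                cs = [getattr(t, comp) for t in trajectories if t.infant_id == iid and t.stage == stage]
                rows.append(np.mean(cs, axis=0) if cs else None)
            return rows

        for comp, label in (("ap_101", "AP"), ("ml_101", "ML")):
            ca, cb = stage_curves(s_a, comp), stage_curves(s_b, comp)
            keep = [i for i in range(len(ids)) if ca[i] is not None and cb[i] is not None]
            if len(keep) >= 3:
                res = PairedSPM1D(np.array([cb[i] for i in keep]), np.array([ca[i] for i in keep]),
                                  alpha=config.alpha).fit()
                spm1d_out[label] = {
                    "t_critical": res.t_critical, "fwhm": res.fwhm, "df": res.df,
                    "clusters": [[int(i0), int(i1), p] for (i0, i1, p) in res.clusters],
                }
        pairs = [iid for iid in ids if (iid, s_a) in aligned and (iid, s_b) in aligned]
        if len(pairs) >= 5:
            A = np.stack([aligned[(i, s_b)].grid for i in pairs])
            B = np.stack([aligned[(i, s_a)].grid for i in pairs])
            MA = np.stack([aligned[(i, s_b)].mask for i in pairs])
            MB = np.stack([aligned[(i, s_a)].mask for i in pairs])
            res2 = PairedPermutationSPM2D(
                A, B, alpha=config.alpha, n_perm=config.n_perm,
                seed=int(np.random.SeedSequence([config.seed, 21]).generate_state(1)[0]),
                masks_a=MA, masks_b=MB,
            ).fit()
            spm2d_out = {
                "t_critical": res2.t_critical,
                "n_significant": res2.n_significant,
                "n_permutations": res2.n_permutations,
                "zones": _zone_table_dict(res2.suprathreshold, res2.mask),
            }

    # regression over all aligned images (one row per infant per stage)
    keys = sorted(aligned)
    if len(keys) >= 8:
        imgs = np.stack([aligned[k].grid for k in keys])
        rows = []
        for iid, stage in keys:
            r = prof_by_id[iid].stages[stage]
            rows.append(dict(
                age_months=r.age_months, height_cm=r.height_cm, mass_kg=r.mass_kg,
                foot_length_cm=r.foot_length_cm, foot_width_cm=r.foot_width_cm,
                normalised_foot_width=normalised_foot_width(r.foot_width_cm, r.foot_length_cm),
                experience_days=r.experience_days,
            ))
        table = pd.DataFrame(rows)
        screen = correlation_screen(table, r_thresh=config.r_thresh,
                                    p_thresh=config.p_thresh, priority=config.priority)
        design = table[screen.retained]
        res3 = PixelRegression(
            imgs, design, alpha=config.alpha, n_perm=config.n_perm,
            seed=int(np.random.SeedSequence([config.seed, 22]).generate_state(1)[0]),
        ).fit()
        regression_out = {
            "retained": screen.retained,
            "flagged_pairs": [[a, b, r] for a, b, r, _ in screen.flagged_pairs],
            "per_predictor": {
                name: {"t_critical": res3.t_critical[name],
                       "n_significant": res3.n_significant(name),
                       "zones": _zone_table_dict(res3.suprathreshold[name], res3.mask)}
                for name in res3.predictors
            },
        }

    report = RunReport(
        counts=counts,
        references={"K_BS_cm": refs.K_BS, "J_BS_cm": refs.J_BS},
        ap_origin_percent=ap_origin,
        ml_medial_fraction=ml_medial,
        spm1d=spm1d_out,
        spm2d=spm2d_out,
        regression=regression_out,
        registration_error_mm=reg_err,
        provenance=_provenance(config),
    )
    if outdir:
        report.to_json(outdir / "report.json")
    return report


def _provenance(config: PipelineConfig) -> dict:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "grid": f"{N_ROWS_AP}x{N_COLS_ML}@{PITCH_CM}cm",
    }
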