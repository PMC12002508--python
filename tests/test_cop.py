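"""CoP extraction, 101-node resampling, K/J references and normalization."""

import numpy as np
import pytest

from infantpress import cop
from infantpress.grid import GRID_SHAPE, PITCH_CM
from infantpress.io import InputError, MaxPressurePicture, StepRecord, compute_mpp


def step_from_blocks(*pixel_lists):
    """Build a step whose frames carry the given (row, col, value) pixels."""
    frames = np.zeros((len(pixel_lists) + 2,) + GRID_SHAPE)
    for t, pixels in enumerate(pixel_lists, start=1):
        for r, c, v in pixels:
            frames[t, r, c] = v
    return StepRecord(frames)


class TestComputeCoPPath:
    def test_point_mass_cop_at_pixel_center(self):
        step = step_from_blocks([(8, 5, 10.0)], [(20, 7, 10.0)])
        path = cop.compute_cop_path(step, 1.0)
        np.testing.assert_allclose(path.ap, [8 * PITCH_CM, 20 * PITCH_CM])
        np.testing.assert_allclose(path.ml, [5 * PITCH_CM, 7 * PITCH_CM])
        np.testing.assert_allclose(path.stance_fraction, [0.0, 1.0])

    def test_weighted_mean_of_two_pixels(self):
        # pressures 1 and 3 at ML coordinates 0 cm and 1 cm (same row)
        step = step_from_blocks([(10, 0, 1.0), (10, 2, 3.0)], [(11, 0, 1.0), (11, 2, 3.0)])
        path = cop.compute_cop_path(step, load_threshold=0.5)
        np.testing.assert_allclose(path.ml, [0.75, 0.75])

    def test_uniform_patch_cop_at_geometric_center(self):
        patch = [(r, c, 7.0) for r in range(10, 14) for c in range(6, 9)]
        path = cop.compute_cop_path(step_from_blocks(patch, patch), 1.0)
        np.testing.assert_allclose(path.ap, 11.5 * PITCH_CM)
        np.testing.assert_allclose(path.ml, 7.0 * PITCH_CM)

    def test_too_few_loaded_frames_raises(self):
        step = step_from_blocks([(8, 5, 10.0)])
        with pytest.raises(InputError):
            cop.compute_cop_path(step, 1.0)


class TestResample101:
    def test_always_101_nodes_and_linear_reproduction(self):
        t = np.linspace(0, 1, 17)
        path = cop.CoPPath(ap=2.0 + 3.0 * t, ml=1.0 - t, stance_fraction=t)
        out = cop.resample_101(path)
        assert out.ap.size == out.ml.size == 101
        nodes = np.linspace(0, 1, 101)
        np.testing.assert_allclose(out.ap, 2.0 + 3.0 * nodes, atol=1e-9)
        np.testing.assert_allclose(out.ml, 1.0 - nodes, atol=1e-9)

    def test_identity_at_existing_nodes(self):
        nodes = np.linspace(0, 1, 101)
        path = cop.CoPPath(ap=np.sin(nodes * 3), ml=np.cos(nodes * 2), stance_fraction=nodes)
        out = cop.resample_101(path)
        np.testing.assert_allclose(out.ap, path.ap, atol=1e-12)

    def test_endpoints_preserved_exactly(self):
        t = np.linspace(0, 1, 9)
        path = cop.CoPPath(ap=np.random.default_rng(0).normal(5, 1, 9), ml=np.zeros(9), stance_fraction=t)
        out = cop.resample_101(path)
        assert out.ap[0] == path.ap[0] and out.ap[-1] == path.ap[-1]

    def test_duplicate_stance_fraction_rejected(self):
        t = np.array([0.0, 0.5, 0.5, 1.0])
        with pytest.raises(InputError):
            cop.CoPPath(ap=t, ml=t, stance_fraction=t)


class TestReferences:
    def make_mpp(self, pixels):
        g = np.zeros(GRID_SHAPE)
        for r, c, v in pixels:
            g[r, c] = v
        return MaxPressurePicture(g)

    def test_K_is_most_posterior_contact(self):
        mpp = self.make_mpp([(4, 10, 30.0), (8, 10, 50.0)])
        assert cop.compute_K(mpp, 1.0) == 4 * PITCH_CM == 2.0

    def test_K_translation_equivariance(self):
        base = [(4, 10, 30.0), (9, 11, 40.0)]
        shifted = [(r + 2, c, v) for r, c, v in base]
        assert cop.compute_K(self.make_mpp(shifted), 1.0) == cop.compute_K(self.make_mpp(base), 1.0) + 1.0

    def test_K_matches_true_heel_on_clean_step(self, clean_step):
        # identity pose with heel end at y = 2.0 cm; the silhouette tapers
        # to zero width at the anatomical heel point, so the most posterior
        # loaded pixel sits within one pixel anterior of it
        K = cop.compute_K(compute_mpp(clean_step.step), 1.0)
        assert 0.0 <= K - 2.0 <= 2 * PITCH_CM

    def test_J_symmetric_and_invariances(self):
        sym = self.make_mpp([(10, 10, 20.0), (10, 14, 20.0), (12, 12, 40.0)])
        assert cop.compute_J(sym) == 12 * PITCH_CM
        doubled = self.make_mpp([(10, 10, 40.0), (10, 14, 40.0), (12, 12, 80.0)])
        assert cop.compute_J(doubled) == cop.compute_J(sym)
        mirrored = MaxPressurePicture(sym.grid[:, ::-1])
        assert cop.compute_J(mirrored) == pytest.approx(24 * PITCH_CM - cop.compute_J(sym))

    def test_empty_mpp_raises(self):
        with pytest.raises(InputError):
            cop.compute_K(self.make_mpp([]), 1.0)
        with pytest.raises(InputError):
            cop.compute_J(self.make_mpp([]))


class TestAggregation:
    def test_singleton(self):
        refs = cop.aggregate_reference([("a", "new", 2.0, 5.0)])
        assert refs.K_BS == 2.0 and refs.J_BS == 5.0
        assert refs.K_WS[("a", "new")] == 2.0

    def test_mean_of_two_infants(self):
        refs = cop.aggregate_reference(
            [("a", "new", 2.0, 4.0), ("b", "new", 3.0, 6.0)]
        )
        assert refs.K_BS == 2.5 and refs.J_BS == 5.0

    def test_order_invariance_and_bracketing(self):
        per_step = [("a", "new", 2.0, 4.0), ("b", "new", 3.5, 6.0), ("c", "confident", 2.5, 5.0)]
        r1 = cop.aggregate_reference(per_step)
        r2 = cop.aggregate_reference(per_step[::-1])
        assert r1.K_BS == r2.K_BS and r1.J_BS == r2.J_BS
        assert min(r1.K_WS.values()) <= r1.K_BS <= max(r1.K_WS.values())
        assert min(r1.J_WS.values()) <= r1.J_BS <= max(r1.J_WS.values())

    def test_empty_raises(self):
        with pytest.raises(InputError):
            cop.aggregate_reference([])


class TestRereferenceAndNormalize:
    def path101(self, ap=5.0, ml=3.0):
        nodes = np.linspace(0, 1, 101)
        return cop.CoPPath(ap=np.full(101, ap), ml=np.full(101, ml), stance_fraction=nodes)

    def test_zero_references_identity(self):
        refs = cop.ReferenceSystem({}, {}, {}, {}, 0.0, 0.0)
        traj = cop.rereference(self.path101(), refs)
        assert np.all(traj.ap_101 == 5.0) and np.all(traj.ml_101 == 3.0)

    def test_constant_subtraction(self):
        refs = cop.ReferenceSystem({}, {}, {}, {}, 2.0, 0.0)
        traj = cop.rereference(self.path101(ap=5.0), refs)
        np.testing.assert_allclose(traj.ap_101, 3.0)

    def test_path_on_longitudinal_axis(self):
        # a path lying exactly on the axis at ML 3.0 with J_BS = 3.5
        refs = cop.ReferenceSystem({}, {}, {}, {}, 0.0, 3.5)
        traj = cop.rereference(self.path101(ml=3.0), refs)
        np.testing.assert_allclose(traj.ml_101, -0.5)

    def test_unmirrored_left_step_flips_ml_sign(self):
        refs = cop.ReferenceSystem({}, {}, {}, {}, 0.0, 0.0)
        traj = cop.rereference(self.path101(ml=3.0), refs, side="left", mirrored=False)
        np.testing.assert_allclose(traj.ml_101, -3.0)

    def test_normalization_and_inverse(self):
        refs = cop.ReferenceSystem({}, {}, {}, {}, 0.0, 0.0)
        traj = cop.rereference(self.path101(ap=5.7, ml=0.0), refs)
        pct = cop.normalise_trajectory(traj, foot_length_cm=11.4, foot_width_cm=5.0)
        assert pct.units == "percent"
        np.testing.assert_allclose(pct.ap_101, 50.0)
        np.testing.assert_allclose(pct.ml_101, 0.0)
        np.testing.assert_allclose(pct.ap_101 * 11.4 / 100.0, traj.ap_101)
        assert cop.ap_origin_percent(pct) == pytest.approx(50.0)

    def test_nonpositive_dimensions_rejected(self):
        refs = cop.ReferenceSystem({}, {}, {}, {}, 0.0, 0.0)
        traj = cop.rereference(self.path101(), refs)
        with pytest.raises(InputError):
            cop.normalise_trajectory(traj, 0.0, 5.0)


class TestPipelineProperties:
    def test_translation_equivariance_of_rereferencing(self, profiles):
        """Shifting every step by the same whole-pixel offset is absorbed
        by the between-infant references."""
        from infantpress import synthetic

        steps = [
            synthetic.synthesize_step(profiles[i % 2], "new", seed=i, compute_truth=False).step
            for i in range(4)
        ]

        def run(shift):
            per, paths = [], []
            for i, st in enumerate(steps):
                frames = np.roll(st.frames, shift, axis=(1, 2)) if shift else st.frames
                sr = StepRecord(frames, infant_id=f"i{i}", stage="new")
                mpp = compute_mpp(sr)
                per.append((sr.infant_id, "new", cop.compute_K(mpp, 1.0), cop.compute_J(mpp)))
                paths.append(cop.resample_101(cop.compute_cop_path(sr, 1.0)))
            refs = cop.aggregate_reference(per)
            return [cop.rereference(p, refs) for p in paths]

        base = run((0, 0))
        moved = run((2, 1))
        for a, b in zip(base, moved):
            np.testing.assert_allclose(a.ap_101, b.ap_101, atol=1e-9)
            np.testing.assert_allclose(a.ml_101, b.ml_101, atol=1e-9)

    def test_noise_free_chain_recovers_truth_within_1mm(self, clean_step):
        """rotate -> CoP -> resample reproduces the generator CoP path."""
        from infantpress.io import pca_vertical_rotate
        from .conftest import grid_centroid_shift

        rotated, _ = pca_vertical_rotate(clean_step.step)
        path = cop.compute_cop_path(rotated, 1.0)
        dx, dy = grid_centroid_shift(clean_step.step.frames)
        truth = clean_step.truth_cop_xy
        assert np.abs(path.ap - (truth[:, 1] + dy)).max() < 0.1
        assert np.abs(path.ml - (truth[:, 0] + dx)).max() < 0.1

    def test_medial_sign_convention_majority_medial(self, profiles):
        from infantpress import synthetic
        from infantpress.io import pca_vertical_rotate

        fracs = []
        for seed in range(4):
            ss = synthetic.synthesize_step(profiles[seed % 2], "new", seed=seed)
            rotated, _ = pca_vertical_rotate(ss.step)
            mpp = compute_mpp(rotated)
            path = cop.resample_101(cop.compute_cop_path(rotated, 1.0))
            refs = cop.aggregate_reference(
                [("x", "new", cop.compute_K(mpp, 1.0), cop.compute_J(mpp))]
            )
            traj = cop.rereference(path, refs)
            fracs.append(np.mean(traj.ml_101 > 0))
        assert np.mean(fracs) > 0.5
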