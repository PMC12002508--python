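"""Field statistics: RFT thresholds, paired tests, screening, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from infantpress.benchmarks import smooth_gaussian_curves
from infantpress.io import InputError
from infantpress.spm import (
    PairedPermutationSPM2D,
    PairedSPM1D,
    PixelRegression,
    correlation_screen,
    estimate_fwhm,
    normalised_foot_width,
    normality_test_1d,
    paired_t_statistic,
    rft_threshold_1d,
)
from infantpress.spm.paired import ConfigurationError
from infantpress.spm.regression import ConfigurationError as RegressionConfigError


class TestPairedTStatistic:
    def test_matches_closed_form_to_1e10(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.3, 1.2, (14, 101))
        t = paired_t_statistic(d)
        n = d.shape[0]
        oracle = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(n))
        np.testing.assert_allclose(t, oracle, rtol=1e-10)
        # agrees with the generic paired t-test at every node
        sm = stats.ttest_rel(d + 1.0, np.ones_like(d), axis=0).statistic
        np.testing.assert_allclose(t, sm, rtol=1e-10)


class TestRFTThreshold:
    @pytest.mark.parametrize("df", [5, 12, 19, 40])
    @pytest.mark.parametrize("fwhm", [0.4, 2.0, 8.0, 25.0, 300.0])
    def test_bracketed_by_single_and_bonferroni(self, df, fwhm):
        tc = rft_threshold_1d(df, fwhm, 101, 0.05)
        lo = stats.t.isf(0.025, df)
        hi = stats.t.isf(0.025 / 101, df)
        assert lo - 1e-12 <= tc <= hi + 1e-12

    def test_one_resel_limit_approaches_single_quantile(self):
        tc = rft_threshold_1d(19, 1e4, 101, 0.05)
        assert tc == pytest.approx(stats.t.isf(0.025, 19), rel=0.02)

    def test_tiny_fwhm_hits_bonferroni(self):
        tc = rft_threshold_1d(19, 0.3, 101, 0.05)
        assert tc == pytest.approx(stats.t.isf(0.025 / 101, 19), rel=1e-9)

    def test_strictly_decreasing_in_alpha(self):
        ts = [rft_threshold_1d(19, 10.0, 101, a) for a in (0.01, 0.05, 0.1, 0.2)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_invalid_alpha_rejected(self):
        from infantpress.spm.rft import ConfigurationError as RFTConfigError

        with pytest.raises(RFTConfigError):
            rft_threshold_1d(19, 10.0, 101, 1.5)

    def test_fwhm_estimator_recovers_known_smoothness(self):
        rng = np.random.default_rng(1)
        R = smooth_gaussian_curves(2000, 101, 10.0, rng)
        assert estimate_fwhm(R) == pytest.approx(10.0, rel=0.1)


class TestPairedSPM1D:
    def test_identical_sets_give_null_field(self):
        rng = np.random.default_rng(2)
        a = smooth_gaussian_curves(10, 101, 8.0, rng) + 3.0
        res = PairedSPM1D(a, a.copy() + 1e-300).fit()
        assert np.all(res.t[np.isfinite(res.t)] == 0)
        assert res.clusters == []

    def test_planted_early_stance_shift_found_only_early(self, profiles):
        """Two conditions differing only in contact onset (0.50 vs 0.30)
        produce a suprathreshold cluster in early stance and none after
        40% where the rollover converges."""
        from infantpress import cop, synthetic
        from infantpress.io import compute_mpp, pca_vertical_rotate

        hits = []
        for rep in range(2):
            curves = {0.50: [], 0.30: []}
            per_refs, paths = [], []
            for i in range(12):
                prof = profiles[i % len(profiles)]
                for onset in (0.50, 0.30):
                    rp = synthetic.RolloverParams(contact_onset_frac=onset)
                    ss = synthetic.synthesize_step(prof, "new", rollover=rp, seed=1000 * rep + 2 * i + int(onset * 10))
                    rotated, _ = pca_vertical_rotate(ss.step)
                    mpp = compute_mpp(rotated)
                    per_refs.append((f"i{i}", "s", cop.compute_K(mpp, 1.0), cop.compute_J(mpp)))
                    paths.append((onset, i, cop.resample_101(cop.compute_cop_path(rotated, 1.0)), ss.foot_length_cm))
            refs = cop.aggregate_reference(per_refs)
            for onset, i, p, L in paths:
                traj = cop.normalise_trajectory(cop.rereference(p, refs), L, 5.0)
                curves[onset].append(traj.ap_101)
            res = PairedSPM1D(np.array(curves[0.50]), np.array(curves[0.30])).fit()
            early = any(i0 <= 25 for i0, i1, _ in res.clusters)
            late = any(i1 > 40 for i0, i1, _ in res.clusters)
            hits.append(early and not late)
        assert sum(hits) >= 1

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(InputError):
            PairedSPM1D(np.zeros((5, 101)), np.zeros((6, 101)))


class TestNormality1D:
    def test_smooth_gaussian_null_not_rejected(self):
        rng = np.random.default_rng(3)
        curves = smooth_gaussian_curves(50, 101, 10.0, rng)
        res = normality_test_1d(curves)
        assert not res.h0_rejected

    def test_skewed_node_detected(self):
        rng = np.random.default_rng(4)
        curves = smooth_gaussian_curves(200, 101, 10.0, rng)
        curves[:, 50] = rng.exponential(1.0, 200)  # heavy skew at one node
        res = normality_test_1d(curves)
        assert res.suprathreshold[50]

    def test_constant_curves_rejected(self):
        with pytest.raises(InputError):
            normality_test_1d(np.ones((10, 101)))


def footprint_images(n, rng, forefoot_boost=None):
    """Synthetic template-aligned pressure images: a 20x12 footprint with
    lognormal texture; optional per-image forefoot increase."""
    imgs = np.zeros((n, 36, 25))
    base = np.zeros((36, 25))
    base[8:28, 7:19] = 60.0
    for i in range(n):
        img = base * rng.lognormal(0.0, 0.25, base.shape)
        if forefoot_boost is not None:
            img[20:28, 7:19] *= 1.0 + forefoot_boost[i]
        imgs[i] = np.where(base > 0, img, 0.0)
    return imgs


class TestPairedPermutation2D:
    def test_identical_sets_no_suprathreshold(self):
        rng = np.random.default_rng(5)
        A = footprint_images(8, rng)
        res = PairedPermutationSPM2D(A, A, n_perm=200, seed=0).fit()
        assert res.n_significant == 0

    def test_exhaustive_enumeration_matches_oracle_and_ignores_seed(self):
        rng = np.random.default_rng(6)
        n = 8
        A = footprint_images(n, rng)
        B = footprint_images(n, rng)
        res1 = PairedPermutationSPM2D(A, B, n_perm=10_000, seed=11).fit()
        res2 = PairedPermutationSPM2D(A, B, n_perm=10_000, seed=99).fit()
        assert res1.exhaustive and res1.n_permutations == 2**n
        assert res1.t_critical == res2.t_critical
        D = (np.where(res1.mask, A, 0) - np.where(res1.mask, B, 0))[:, res1.mask]
        maxts = [
            np.abs(paired_t_statistic(np.array(s)[:, None] * D)).max()
            for s in itertools.product((1.0, -1.0), repeat=n)
        ]
        assert res1.t_critical == pytest.approx(np.quantile(maxts, 0.95))

    def test_planted_forefoot_increase_detected_in_forefoot(self):
        rng = np.random.default_rng(7)
        found = 0
        for rep in range(5):
            A = footprint_images(39, rng)
            B = footprint_images(39, rng, forefoot_boost=np.full(39, 0.30))
            res = PairedPermutationSPM2D(B, A, n_perm=500, seed=rep).fit()
            rows = np.nonzero(res.suprathreshold)[0]
            # detections concentrate in the boosted forefoot band (a lone
            # stray pixel elsewhere is the alpha-level family-wise error)
            if rows.size > 0 and np.mean(rows >= 20) >= 0.9:
                found += 1
        assert found >= 5 * 0.9

    def test_low_permutation_count_rejected(self):
        rng = np.random.default_rng(8)
        A = footprint_images(6, rng)
        with pytest.raises(ConfigurationError):
            PairedPermutationSPM2D(A, A, n_perm=50)

    def test_disjoint_masks_rejected(self):
        A = np.zeros((6, 36, 25))
        A[:, 2:5, 2:5] = 10.0
        B = np.zeros((6, 36, 25))
        B[:, 20:23, 20:23] = 10.0
        with pytest.raises(InputError):
            PairedPermutationSPM2D(A, B, n_perm=200, min_coverage=0.9).fit()


class TestCorrelationScreen:
    def test_identical_columns_flagged_with_unit_r(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 100)
        table = pd.DataFrame({"a": x, "b": x, "c": rng.normal(0, 1, 100)})
        screen = correlation_screen(table, priority=["a", "b", "c"])
        assert any(set(p[:2]) == {"a", "b"} and p[2] == pytest.approx(1.0) for p in screen.flagged_pairs)
        assert screen.retained == ["a", "c"]

    def test_cohort_mass_foot_length_correlation_near_half(self, big_cohort_table):
        new = big_cohort_table[big_cohort_table.stage == "new"]
        r = np.corrcoef(new.mass_kg, new.foot_length_cm)[0, 1]
        assert r == pytest.approx(0.50, abs=0.05)

    def test_default_priority_keeps_developmental_predictors(self, big_cohort_table):
        new = big_cohort_table[big_cohort_table.stage == "new"].copy()
        new["normalised_foot_width"] = normalised_foot_width(
            new.foot_width_cm.to_numpy(), new.foot_length_cm.to_numpy()
        )
        table = new[
            ["age_months", "height_cm", "mass_kg", "foot_length_cm",
             "foot_width_cm", "normalised_foot_width", "experience_days"]
        ]
        screen = correlation_screen(table)
        assert "age_months" not in screen.retained
        assert "height_cm" not in screen.retained
        assert {"mass_kg", "foot_width_cm", "experience_days"} <= set(screen.retained)

    def test_independent_columns_rarely_flagged(self):
        rng = np.random.default_rng(10)
        flagged_reps = 0
        for _ in range(20):
            table = pd.DataFrame(rng.normal(0, 1, (200, 4)), columns=list("abcd"))
            if correlation_screen(table).flagged_pairs:
                flagged_reps += 1
        assert flagged_reps <= 1

    def test_constant_column_reported_undefined_not_flagged(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({"a": rng.normal(0, 1, 50), "b": np.ones(50)})
        screen = correlation_screen(table)
        assert np.isnan(screen.r_matrix.loc["a", "b"])
        assert screen.flagged_pairs == []


class TestPixelRegression:
    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(12)
        n = 25
        imgs = rng.gamma(2.0, 10.0, (n, 6, 5)) + 1.0
        X = pd.DataFrame({"u": rng.normal(0, 1, n), "v": rng.normal(3, 2, n)})
        res = PixelRegression(imgs, X, n_perm=100, seed=0).fit()
        Xd = np.column_stack([np.ones(n), X.to_numpy()])
        y = imgs[:, 3, 2]
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        resid = y - Xd @ beta
        s2 = resid @ resid / (n - 3)
        se = np.sqrt(np.diag(np.linalg.inv(Xd.T @ Xd)) * s2)
        np.testing.assert_allclose(res.t_images["u"][3, 2], (beta / se)[1], rtol=1e-8)

    def test_t_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(13)
        imgs = rng.gamma(2.0, 10.0, (30, 6, 5)) + 1.0
        X = pd.DataFrame({"u": rng.normal(0, 1, 30)})
        r1 = PixelRegression(imgs, X, n_perm=100, seed=1).fit()
        r2 = PixelRegression(imgs, X * 10.0, n_perm=100, seed=1).fit()
        np.testing.assert_allclose(r1.t_images["u"], r2.t_images["u"], atol=1e-10)

    def test_noise_predictor_controls_false_positives(self):
        rng = np.random.default_rng(14)
        hits = 0
        for rep in range(20):
            imgs = footprint_images(30, rng)
            X = pd.DataFrame({"noise": rng.normal(0, 1, 30)})
            res = PixelRegression(imgs, X, n_perm=200, seed=rep).fit()
            hits += res.n_significant("noise") > 0
        assert hits <= 3  # ~alpha-level false positive rate over the mask

    def test_planted_experience_effect_recovered_in_forefoot(self):
        """Forefoot pressure generated with a positive linear dependence on
        walking experience is flagged there in >= 90% of replicates."""
        rng = np.random.default_rng(15)
        found = 0
        n_rep = 10
        for rep in range(n_rep):
            n = 39
            exp_days = rng.uniform(5, 60, n)
            boost = 0.015 * (exp_days - exp_days.mean())
            imgs = footprint_images(n, rng, forefoot_boost=boost)
            X = pd.DataFrame({"experience_days": exp_days, "mass_kg": rng.normal(10.3, 1.3, n)})
            res = PixelRegression(imgs, X, n_perm=300, seed=rep).fit()
            sig = res.suprathreshold["experience_days"] & (res.t_images["experience_days"] > 0)
            rows = np.nonzero(sig.any(axis=1))[0]
            if sig.sum() > 0 and rows.min() >= 20:
                found += 1
        assert found >= 0.9 * n_rep

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(16)
        x = rng.normal(0, 1, 20)
        imgs = rng.gamma(2.0, 10.0, (20, 4, 4)) + 1.0
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(RegressionConfigError, match="collinear"):
            PixelRegression(imgs, X, n_perm=100)


class TestNormalisedFootWidth:
    def test_reference_values(self):
        assert normalised_foot_width(5.1, 11.4) == pytest.approx(44.7, abs=0.05)
        assert normalised_foot_width(7.0, 7.0) == 100.0

    def test_cohort_mean_matches_table_scale(self, big_cohort_table):
        new = big_cohort_table[big_cohort_table.stage == "new"]
        vals = normalised_foot_width(new.foot_width_cm.to_numpy(), new.foot_length_cm.to_numpy())
        assert np.mean(vals) == pytest.approx(45.6, abs=2.0)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InputError):
            normalised_foot_width(5.0, 0.0)
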