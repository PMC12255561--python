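import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairasl.fair_model import (
    FAIRSeries,
    FitBounds,
    InversionRecoveryParams,
    LN2,
    fair_signal,
    fit_series,
    fit_voxel,
    initial_guess,
)
from fairasl.gridfit import GridFitTable


class TestFairSignal:
    def test_null_point_of_full_inversion(self):
        p = InversionRecoveryParams(s0=1000.0, alpha=1.0, t1=1500.0)
        assert fair_signal(p, 1500.0 * LN2) == pytest.approx(0.0, abs=1e-9)

    def test_ti_zero_full_inversion_returns_s0(self):
        p = InversionRecoveryParams(s0=1000.0, alpha=1.0, t1=800.0)
        assert fair_signal(p, 0.0) == pytest.approx(1000.0)

    def test_full_recovery_at_long_ti(self):
        p = InversionRecoveryParams(s0=1000.0, alpha=1.0, t1=800.0)
        assert fair_signal(p, 1e7) == pytest.approx(1000.0, rel=1e-9)

    @given(
        t1=st.floats(min_value=100.0, max_value=5000.0),
        alpha=st.floats(min_value=0.5, max_value=1.0),
    )
    @settings(deadline=None)
    def test_continuity_at_null_point(self, t1, alpha):
        """The magnitude fold must not jump at the zero crossing."""
        p = InversionRecoveryParams(s0=1000.0, alpha=alpha, t1=t1)
        ti_null = t1 * np.log(2 * alpha)
        eps = 1e-6 * t1
        left = fair_signal(p, max(ti_null - eps, 0.0))
        right = fair_signal(p, ti_null + eps)
        assert abs(left - right) < 1e-2  # both within slope*2eps of zero

    def test_rejects_negative_ti(self):
        p = InversionRecoveryParams(s0=1.0, alpha=1.0, t1=100.0)
        with pytest.raises(ValueError):
            fair_signal(p, -1.0)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"s0": 0.0, "alpha": 1.0, "t1": 100.0},
            {"s0": 1.0, "alpha": 1.5, "t1": 100.0},
            {"s0": 1.0, "alpha": -0.1, "t1": 100.0},
            {"s0": 1.0, "alpha": 1.0, "t1": 0.0},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            InversionRecoveryParams(**kwargs)


class TestInitialGuess:
    def test_null_point_seeds_t1(self):
        # blood-like T1 of 2430 ms nulls at 2430*ln2 = 1684 ms
        t1_true = 2430.0
        tis = np.linspace(100, 6000, 24)
        y = fair_signal(InversionRecoveryParams(1000.0, 1.0, t1_true), tis)
        guess = initial_guess(y, tis)
        assert guess.t1 == pytest.approx(t1_true, rel=0.1)
        assert guess.alpha == 1.0
        assert guess.s0 == pytest.approx(float(np.max(y)))

    def test_monotone_curve_clamps_to_bounds(self):
        # small alpha: signal minimum sits at the earliest TI
        tis = np.array([100.0, 500.0, 2000.0, 5000.0])
        y = fair_signal(InversionRecoveryParams(1000.0, 0.1, 1500.0), tis)
        bounds = FitBounds(t1_min=400.0)
        guess = initial_guess(y, tis, bounds)
        assert guess.t1 == bounds.t1_min  # 100/ln2 = 144 clamped up to 400

    def test_constant_signals_fall_back_to_mid_bound(self):
        bounds = FitBounds()
        guess = initial_guess([5.0, 5.0, 5.0, 5.0], [100, 200, 300, 400], bounds)
        assert guess.t1 == pytest.approx(np.sqrt(bounds.t1_min * bounds.t1_max))


class TestFitVoxel:
    def test_noiseless_round_trip(self, schedule14):
        tis = np.array(schedule14.tis_ms)
        truth = InversionRecoveryParams(s0=1000.0, alpha=1.0, t1=1500.0)
        y = fair_signal(truth, tis)
        params, resid, mse = fit_voxel(y, tis)
        assert params.s0 == pytest.approx(truth.s0, rel=1e-3)
        assert params.alpha == pytest.approx(truth.alpha, rel=1e-3)
        assert params.t1 == pytest.approx(truth.t1, rel=1e-3)
        assert mse <= 1e-10

    def test_partial_inversion_recovered(self, schedule14):
        tis = np.array(schedule14.tis_ms)
        truth = InversionRecoveryParams(s0=800.0, alpha=0.8, t1=1200.0)
        params, _, _ = fit_voxel(fair_signal(truth, tis), tis)
        assert 0.0 <= params.alpha <= 1.0
        assert params.alpha == pytest.approx(0.8, abs=0.02)

    def test_beats_or_ties_grid_oracle(self, schedule14):
        """Bounded LS residual norm <= dense-grid oracle norm on random noisy
        voxels (the grid solves s0 exactly per (alpha, T1) grid point)."""
        tis = np.array(schedule14.tis_ms)
        table = GridFitTable(tis)
        rng = np.random.default_rng(7)
        wins, total = 0, 25
        for _ in range(total):
            truth = (
                rng.uniform(500, 2000),
                rng.uniform(0.6, 1.0),
                rng.uniform(300, 3000),
            )
            y = np.abs(
                fair_signal(truth, tis) + rng.normal(0, 0.02 * truth[0], len(tis))
            )
            _, resid, _ = fit_voxel(y, tis)
            fit_norm = float(np.sqrt(np.sum(resid**2)))
            *_, grid_norm = table.fit(y)
            if fit_norm <= grid_norm * (1 + 1e-12):
                wins += 1
            else:
                assert fit_norm <= 1.01 * grid_norm
        assert wins >= total - 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_voxel([1.0, 2.0], [100.0, 200.0])


class TestFitSeries:
    def test_uniform_noiseless_phantom_constant_t1(self, clean_series_small,
                                                   clean_fits_small, small_truth):
        fit = clean_fits_small["control"]
        liver = small_truth.liver_mask & (small_truth.labels != 7)
        t1s = fit.t1_map[liver]
        assert np.nanmax(np.abs(t1s - small_truth.spec.t1_liver_ms)) < 1e-3 * 1400

    def test_excluding_redundant_ti_leaves_noiseless_fit_unchanged(
        self, clean_series_small, clean_fits_small
    ):
        full = clean_fits_small["label"]
        dropped = fit_series(clean_series_small, "label", exclude_tis=[5])
        m = full.converged_mask & dropped.converged_mask
        assert np.allclose(full.t1_map[m], dropped.t1_map[m], rtol=1e-5)
        assert np.all(dropped.n_points_map[m] == 13)

    def test_bit_stable_rerun(self, noisy_series_small):
        a = fit_series(noisy_series_small, "label")
        b = fit_series(noisy_series_small, "label")
        assert np.array_equal(a.t1_map, b.t1_map, equal_nan=True)
        assert np.array_equal(a.mse_map, b.mse_map, equal_nan=True)

    def test_nonfitted_voxels_are_nan_not_zero(self, clean_fits_small, small_truth):
        fit = clean_fits_small["label"]
        background = ~small_truth.tissue_mask
        assert np.all(np.isnan(fit.t1_map[background]))
        assert not fit.converged_mask[background].any()

    def test_over_exclusion_rejected(self, clean_series_small):
        with pytest.raises(ValueError):
            fit_series(clean_series_small, "label",
                       exclude_tis=list(range(12)))

    def test_mse_nonnegative_where_fitted(self, clean_fits_small):
        for fit in clean_fits_small.values():
            assert np.all(fit.mse_map[fit.converged_mask] >= 0)


class TestFAIRSeriesValidation:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FAIRSeries(
                label_stack=np.ones((3, 4, 4)),
                control_stack=np.ones((3, 4, 5)),
                tis_ms=[100, 200, 300],
            )

    def test_ti_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FAIRSeries(
                label_stack=np.ones((3, 4, 4)),
                control_stack=np.ones((3, 4, 4)),
                tis_ms=[100, 200],
            )

    def test_negative_signal_rejected(self):
        stack = np.ones((3, 4, 4))
        bad = stack.copy()
        bad[1, 2, 2] = -1.0
        with pytest.raises(ValueError):
            FAIRSeries(label_stack=bad, control_stack=stack, tis_ms=[1, 2, 3])
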