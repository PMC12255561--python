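import json

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from fairasl.fair_model import fit_series
from fairasl.phantom import (
    LABEL_NAMES,
    PhantomSpec,
    build_phantom,
    simulate_series,
    through_plane_events,
    _area_mask,
)
from fairasl.qa import (
    QAReport,
    edge_overlay,
    exclude_and_refit,
    flag_corrupted_tis,
    qa_report,
)
from fairasl.quant import histogram_fwhm, perfusion_map
from fairasl.scheduler import plan_motion_free_tis


@pytest.fixture(scope="module")
def corrupted_series_small(small_truth, schedule14):
    return simulate_series(
        small_truth, schedule14, noise_sigma=0.02, seed=11,
        corruptions=through_plane_events(),
    )


@pytest.fixture(scope="module")
def corrupted_label_fit(corrupted_series_small):
    return fit_series(corrupted_series_small, "label")


class TestFlagCorruptedTis:
    def test_clean_noiseless_phantom_flags_nothing(
        self, clean_series_small, clean_fits_small
    ):
        res = flag_corrupted_tis(clean_series_small, clean_fits_small["label"])
        assert res.flagged == ()

    def test_standard_corruption_flags_exactly_9_and_12(
        self, corrupted_series_small, corrupted_label_fit
    ):
        res = flag_corrupted_tis(corrupted_series_small, corrupted_label_fit)
        assert res.flagged == (9, 12)

    def test_vanishing_amplitude_clears_flags(self, small_truth, schedule14):
        series = simulate_series(
            small_truth, schedule14, noise_sigma=0.02, seed=11,
            corruptions=through_plane_events(magnitude=0.02),
        )
        fit = fit_series(series, "label")
        res = flag_corrupted_tis(series, fit)
        assert res.flagged == ()

    def test_refuses_fewer_than_four_tis(self, small_truth, model):
        sched = plan_motion_free_tis(model, 3, 100, 3000)
        series = simulate_series(small_truth, sched, noise_sigma=0.0)
        fit = fit_series(series, "label")
        with pytest.raises(ValueError):
            flag_corrupted_tis(series, fit)

    def test_detection_sensitivity_over_random_phantoms(self, schedule14):
        """A single corrupted TI should attain the maximum per-TI score in
        nearly every randomly drawn phantom."""
        from fairasl.qa import _pass_scores

        rng = np.random.default_rng(2024)
        hits = 0
        n_trials = 20
        for trial in range(n_trials):
            spec = PhantomSpec(shape=(48, 48), seed=trial)
            truth = build_phantom(spec)
            ti_idx = int(rng.integers(5, 15))  # 1-based, away from shortest TIs
            mag = float(rng.uniform(0.3, 0.7))
            series = simulate_series(
                truth, schedule14, noise_sigma=0.02, seed=trial,
                corruptions=through_plane_events(
                    ti_indices=(ti_idx,), magnitude=mag, area="full"
                ),
            )
            fit = fit_series(series, "label")
            scores = _pass_scores(series, fit, voxel_quantile=75.0)
            if max(scores, key=scores.get) == ti_idx:
                hits += 1
        assert hits >= 18

    def test_mse_separates_corrupted_from_clean_voxels(
        self, small_truth, corrupted_label_fit
    ):
        """Rank-based AUC of corrupted-region vs clean-region voxel MSE."""
        liver = small_truth.liver_mask
        area = _area_mask("upper_half", small_truth.labels.shape)
        mse = corrupted_label_fit.mse_map
        corrupted = mse[liver & area & np.isfinite(mse)]
        clean = mse[liver & ~area & np.isfinite(mse)]
        u = mannwhitneyu(corrupted, clean, alternative="greater")
        auc = u.statistic / (len(corrupted) * len(clean))
        assert auc >= 0.9


class TestExcludeAndRefit:
    def test_corrupted_exclusion_reduces_liver_mse_tenfold(
        self, small_truth, corrupted_series_small, corrupted_label_fit
    ):
        fits = {
            "label": corrupted_label_fit,
            "control": fit_series(corrupted_series_small, "control"),
        }
        res = exclude_and_refit(
            corrupted_series_small, (9, 12), fits_before=fits
        )
        liver = small_truth.liver_mask
        before = np.nanmedian(fits["label"].mse_map[liver])
        after = np.nanmedian(res.fit_label.mse_map[liver])
        assert before / after >= 10.0

    def test_never_increases_mse_over_retained_points(
        self, corrupted_series_small, corrupted_label_fit
    ):
        fits = {
            "label": corrupted_label_fit,
            "control": fit_series(corrupted_series_small, "control"),
        }
        res = exclude_and_refit(corrupted_series_small, (9, 12), fits_before=fits)
        keep = res.fit_label.used_ti_indices
        both = fits["label"].converged_mask & res.fit_label.converged_mask
        r_before = fits["label"].residual_stack[keep][:, both]
        mse_before_retained = np.mean(r_before**2, axis=0)
        assert np.all(res.fit_label.mse_map[both] <= mse_before_retained + 1e-9)

    def test_excluding_clean_ti_from_noiseless_data_keeps_t1(
        self, clean_series_small, clean_fits_small
    ):
        res = exclude_and_refit(
            clean_series_small, (5,), fits_before=clean_fits_small
        )
        before = clean_fits_small["label"].t1_map
        after = res.fit_label.t1_map
        m = np.isfinite(before) & np.isfinite(after)
        assert np.allclose(after[m], before[m], rtol=1e-6)

    def test_histogram_spread_roughly_preserved(
        self, small_truth, corrupted_series_small, corrupted_label_fit
    ):
        """Exclusion shifts the perfusion distribution (accuracy) without
        drastically changing its width (precision)."""
        fits = {
            "label": corrupted_label_fit,
            "control": fit_series(corrupted_series_small, "control"),
        }
        pmap_before = perfusion_map(fits["label"], fits["control"])
        res = exclude_and_refit(corrupted_series_small, (9, 12), fits_before=fits)
        # tissue voxels outside both the corrupted area and the vessel peak:
        # their distribution width is the precision of the measurement
        clean_half = (
            small_truth.liver_mask
            & ~small_truth.vessel_mask
            & ~_area_mask("upper_half", small_truth.labels.shape)
        )
        vals_b = pmap_before.values[clean_half]
        vals_a = res.perfusion.values[clean_half]
        bw = 20.0  # common bin width so the two FWHMs are comparable
        fwhm_b, _ = histogram_fwhm(vals_b[np.isfinite(vals_b)], bin_width=bw)
        fwhm_a, _ = histogram_fwhm(vals_a[np.isfinite(vals_a)], bin_width=bw)
        assert abs(fwhm_a - fwhm_b) <= 0.25 * fwhm_b

    def test_over_exclusion_rejected(self, corrupted_series_small):
        with pytest.raises(ValueError):
            exclude_and_refit(corrupted_series_small, tuple(range(1, 13)))


class TestEdgeOverlay:
    def test_identical_frames_give_zero_displacement(self, clean_series_small):
        res = edge_overlay(clean_series_small, reference_ti_index=1)
        assert not res.empty_edges
        # compare frames of similar contrast: displacement must be 0 where
        # the estimator is well posed (every frame here is motion-free)
        for d in res.displacements:
            assert d["displacement_px"] == 0.0

    def test_shifted_frame_displacement_estimated(self, small_truth, schedule14):
        from fairasl.phantom import CorruptionEvent

        ev = CorruptionEvent(ti_index=12, mode="both", kind="in_plane_shift",
                             shift=(6, 0))
        series = simulate_series(small_truth, schedule14, noise_sigma=0.01,
                                 seed=4, corruptions=[ev])
        res = edge_overlay(series, reference_ti_index=1)
        d12 = res.displacements[11]
        assert d12["displacement_px"] == pytest.approx(6.0, abs=1.0)
        others = [d["displacement_px"] for d in res.displacements
                  if d["index"] not in (12,)]
        assert max(others) <= 1.0

    def test_uniform_image_flagged_empty(self, schedule14):
        from fairasl.fair_model import FAIRSeries

        n = len(schedule14.tis_ms)
        flat = np.ones((n, 16, 16))
        series = FAIRSeries(label_stack=flat, control_stack=flat,
                            tis_ms=np.array(schedule14.tis_ms))
        res = edge_overlay(series)
        assert res.empty_edges
        assert not res.edge_map.any()


@pytest.fixture(scope="module")
def clean_report(clean_series_small, clean_fits_small, small_truth):
    pmap = perfusion_map(clean_fits_small["label"], clean_fits_small["control"])
    return qa_report(
        clean_series_small, clean_fits_small, pmap, small_truth.labels,
        roi_names=dict(LABEL_NAMES),
    )


class TestQAReport:
    def test_clean_phantom_yields_no_flags_and_low_negativity(self, clean_report):
        for mode in ("label", "control"):
            assert clean_report.flagged_tis[mode]["flagged"] == []
        assert clean_report.negativity_fraction < 0.01

    def test_serialization_round_trip(self, clean_report):
        restored = QAReport.from_json(clean_report.to_json())
        assert restored.to_json() == clean_report.to_json()
        assert json.loads(clean_report.to_json())["negativity_fraction"] == \
            clean_report.negativity_fraction

    def test_corrupted_mse_histogram_right_shifted(
        self, small_truth, clean_fits_small, corrupted_series_small,
        corrupted_label_fit, clean_series_small
    ):
        clean_med = np.nanmedian(
            clean_fits_small["label"].mse_map[small_truth.liver_mask]
        )
        corrupt_med = np.nanmedian(
            corrupted_label_fit.mse_map[small_truth.liver_mask]
        )
        assert corrupt_med > clean_med
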