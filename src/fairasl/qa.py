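"""Residual-based quality assessment of multi-TI FAIR acquisitions.

The per-voxel mean squared residual (MSE) of the T1 fit is the central
quality metric: respiration-corrupted acquisitions leave localized, per-TI
residual structure that survey statistics pick up reliably.  This module
scores each inversion time for corruption, excludes flagged TIs and refits,
estimates in-plane displacement from edge maps, and aggregates everything
into a serializable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from fairasl.fair_model import FAIRSeries, FitBounds, T1FitResult, fit_series
from fairasl.quant import PerfusionMap, QuantConfig, perfusion_map

__all__ = [
    "TIFlagResult",
    "RefitResult",
    "EdgeOverlayResult",
    "QAReport",
    "flag_corrupted_tis",
    "exclude_and_refit",
    "edge_overlay",
    "qa_report",
]


@dataclass
class TIFlagResult:
    """Per-TI corruption scores and the flagged (1-based) indices."""

    scores: dict[int, float]  # 1-based TI index -> robust outlier score
    flagged: tuple[int, ...]
    threshold_z: float
    mode: str

    def to_dict(self) -> dict:
        return {
            "scores": {str(k): v for k, v in self.scores.items()},
            "flagged": list(self.flagged),
            "threshold_z": self.threshold_z,
            "mode": self.mode,
        }


def _pass_scores(
    series: FAIRSeries, fit: T1FitResult, voxel_quantile: float
) -> dict[int, float]:
    """One scoring pass: robustly standardized |residual| per TI, summarized
    across masked voxels at the given quantile."""
    used = fit.used_ti_indices
    mask = series.effective_mask() & fit.converged_mask
    if not mask.any():
        raise ValueError("no converged voxels to score")
    resid = fit.residual_stack[used][:, mask]  # (n_used, n_voxels)
    med = np.median(resid, axis=0)
    mad = np.median(np.abs(resid - med), axis=0)
    scale = 1.4826 * mad
    # floor the scale at a tiny fraction of the voxel's equilibrium signal:
    # residual structure below ~1e-6 of s0 is numerical, not physical, and
    # must not produce scores on noiseless data
    s0 = fit.s0_map[mask]
    floor = 1e-6 * np.where(np.isfinite(s0), np.abs(s0), 1.0) + 1e-12
    scale = np.maximum(scale, floor)
    z = np.abs(resid) / scale[None, :]
    per_ti = np.percentile(z, voxel_quantile, axis=1)
    return {int(used[i]) + 1: float(per_ti[i]) for i in range(len(used))}


def flag_corrupted_tis(
    series: FAIRSeries,
    fit: T1FitResult,
    threshold_z: float = 3.0,
    voxel_quantile: float = 75.0,
    bounds: FitBounds | None = None,
) -> TIFlagResult:
    """Score each fitted TI for corruption and flag outliers.

    For every masked, converged voxel the residuals are standardized by a
    robust per-voxel scale (1.4826 x median absolute deviation of that
    voxel's residuals, floored to avoid zero division on noiseless data); the
    per-TI score summarizes the standardized |r_k| across voxels at the upper
    quartile.  The quartile keeps a small minority of high-residual voxels
    (vessel pulsation) from raising scores, while staying sensitive to
    respiratory corruption, which is regional and typically covers a large
    part of the liver.

    Detection is greedy-sequential: the highest-scoring TI above
    ``threshold_z`` is flagged, the series is refitted without the flagged
    TIs, and scoring repeats until no TI exceeds the threshold.  The refit
    step matters because a least-squares fit partially absorbs a corrupted
    point into its parameters, masking a second, weaker corruption; removing
    the dominant outlier first restores the contrast of the remaining ones.
    Reported scores are from the pass at which each TI was flagged (final
    pass for unflagged TIs).

    Requires at least 4 fitted TIs (with 3, an outlier cannot be separated
    from the 3-parameter trend); flagging stops while 4 TIs remain.
    """
    if len(fit.used_ti_indices) < 4:
        raise ValueError(
            f"need at least 4 fitted TIs to score outliers, got "
            f"{len(fit.used_ti_indices)}"
        )
    flagged: list[int] = []
    scores: dict[int, float] = {}
    current = fit
    while True:
        scores.update(_pass_scores(series, current, voxel_quantile))
        candidates = {
            k: v for k, v in scores.items()
            if k not in flagged and v > threshold_z
        }
        if not candidates or len(current.used_ti_indices) <= 4:
            break
        worst = max(candidates, key=lambda k: (candidates[k], -k))
        flagged.append(worst)
        current = fit_series(
            series, fit.mode, exclude_tis=[k - 1 for k in flagged], bounds=bounds
        )
    return TIFlagResult(
        scores=scores,
        flagged=tuple(sorted(flagged)),
        threshold_z=threshold_z,
        mode=fit.mode,
    )


@dataclass
class RefitResult:
    """Outcome of excluding flagged TIs and refitting both modes."""

    fit_label: T1FitResult
    fit_control: T1FitResult
    perfusion: PerfusionMap
    excluded: tuple[int, ...]  # 1-based
    mse_summary: dict


def exclude_and_refit(
    series: FAIRSeries,
    flagged: Sequence[int],
    bounds: FitBounds | None = None,
    config: QuantConfig | None = None,
    fits_before: Mapping[str, T1FitResult] | None = None,
) -> RefitResult:
    """Refit both inversion modes without the flagged (1-based) TIs.

    Per voxel the refit never increases the MSE evaluated over the retained
    points: where the bounded optimizer lands worse than the original
    parameters restricted to the retained points (possible from a different
    start), the original parameters are kept.  The summary reports, per mode,
    the masked-voxel median MSE before (all points), before restricted to the
    retained points, and after the refit.
    """
    bounds = bounds or FitBounds()
    config = config or QuantConfig()
    excl0 = sorted(set(int(k) - 1 for k in flagged))  # to 0-based
    if any(k < 0 or k >= series.n_ti for k in excl0):
        raise ValueError(f"flagged TI outside schedule 1..{series.n_ti}: {flagged}")
    if series.n_ti - len(excl0) < 3:
        raise ValueError(
            f"excluding {len(excl0)} of {series.n_ti} TIs leaves fewer than "
            "3 points per voxel"
        )

    if fits_before is None:
        fits_before = {
            mode: fit_series(series, mode, bounds=bounds)
            for mode in ("label", "control")
        }
    keep = np.array([i for i in range(series.n_ti) if i not in excl0], dtype=int)

    refits: dict[str, T1FitResult] = {}
    summary: dict[str, dict] = {}
    mask = series.effective_mask()
    for mode in ("label", "control"):
        before = fits_before[mode]
        after = fit_series(series, mode, exclude_tis=excl0, bounds=bounds)

        # MSE of the *original* parameters over the retained points only
        r_before = before.residual_stack[keep]
        n_finite = np.sum(np.isfinite(r_before), axis=0)
        mse_before_retained = np.where(
            n_finite > 0,
            np.nansum(r_before**2, axis=0) / np.maximum(n_finite, 1),
            np.nan,
        )

        # keep the better of the two parameter sets per voxel
        worse = (
            before.converged_mask
            & after.converged_mask
            & (after.mse_map > mse_before_retained)
        )
        if worse.any():
            for attr in ("t1_map", "s0_map", "alpha_map"):
                getattr(after, attr)[worse] = getattr(before, attr)[worse]
            after.mse_map[worse] = mse_before_retained[worse]
            after.residual_stack[np.ix_(keep, *np.nonzero(worse))] = before.residual_stack[
                np.ix_(keep, *np.nonzero(worse))
            ]
        refits[mode] = after

        sel = mask & before.converged_mask & after.converged_mask
        summary[mode] = {
            "median_mse_before": float(np.median(before.mse_map[sel])),
            "median_mse_before_retained": float(np.median(mse_before_retained[sel])),
            "median_mse_after": float(np.median(after.mse_map[sel])),
            "n_voxels": int(sel.sum()),
        }

    pmap = perfusion_map(refits["label"], refits["control"], config)
    return RefitResult(
        fit_label=refits["label"],
        fit_control=refits["control"],
        perfusion=pmap,
        excluded=tuple(int(k) for k in sorted(set(flagged))),
        mse_summary=summary,
    )


@dataclass
class EdgeOverlayResult:
    """Edge map of the reference TI and per-TI displacement estimates."""

    reference_index: int  # 1-based
    edge_map: np.ndarray  # boolean edges of the reference frame
    displacements: list[dict]  # per TI: index, dy, dx, displacement_px, flat
    empty_edges: bool = False

    def max_displacement(self) -> float:
        vals = [d["displacement_px"] for d in self.displacements
                if np.isfinite(d["displacement_px"])]
        return max(vals) if vals else float("nan")


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    return np.hypot(gy, gx)


def _circular_shift(ref: np.ndarray, moved: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) maximizing the circular cross-correlation of two
    zero-mean images: the translation that maps ``ref`` onto ``moved``."""
    a = ref - ref.mean()
    b = moved - moved.mean()
    corr = np.real(np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))))
    dy, dx = np.unravel_index(np.argmax(corr), corr.shape)
    if dy > ref.shape[0] // 2:
        dy -= ref.shape[0]
    if dx > ref.shape[1] // 2:
        dx -= ref.shape[1]
    return int(dy), int(dx)


def edge_overlay(
    series: FAIRSeries,
    reference_ti_index: int = 1,
    mode: str = "label",
    edge_percentile: float = 90.0,
) -> EdgeOverlayResult:
    """Edge map of the reference TI frame and in-plane displacement per TI.

    The reference frame's gradient magnitude is thresholded at the given
    percentile to produce the overlay edges (the 'find edges over the first
    TI' inspection); displacement of every other frame is the integer shift
    maximizing the circular cross-correlation of the two gradient-magnitude
    maps.  A flat reference yields a flagged empty-edge result; flat frames
    get NaN displacement.
    """
    stack = series.stack(mode)
    n_ti = series.n_ti
    if not (1 <= reference_ti_index <= n_ti):
        raise ValueError(f"reference TI index {reference_ti_index} outside 1..{n_ti}")
    ref = stack[reference_ti_index - 1]

    if np.ptp(ref) == 0:
        return EdgeOverlayResult(
            reference_index=reference_ti_index,
            edge_map=np.zeros(ref.shape, dtype=bool),
            displacements=[
                {"index": k + 1, "dy": 0, "dx": 0,
                 "displacement_px": float("nan"), "flat": True}
                for k in range(n_ti)
            ],
            empty_edges=True,
        )

    grad_ref = _gradient_magnitude(ref)
    edges = grad_ref > np.percentile(grad_ref, edge_percentile)

    displacements = []
    for k in range(n_ti):
        frame = stack[k]
        if np.ptp(frame) == 0:
            displacements.append(
                {"index": k + 1, "dy": 0, "dx": 0,
                 "displacement_px": float("nan"), "flat": True}
            )
            continue
        dy, dx = _circular_shift(grad_ref, _gradient_magnitude(frame))
        displacements.append(
            {"index": k + 1, "dy": dy, "dx": dx,
             "displacement_px": float(np.hypot(dy, dx)), "flat": False}
        )
    return EdgeOverlayResult(
        reference_index=reference_ti_index,
        edge_map=edges,
        displacements=displacements,
        empty_edges=False,
    )


@dataclass
class QAReport:
    """Aggregated quality metrics of one FAIR perfusion run."""

    mse_histograms: dict  # mode -> {"edges": [...], "counts": [...], "median": x}
    roi_mean_mse: dict  # mode -> {roi name -> mean MSE}
    flagged_tis: dict  # mode -> {"scores": {...}, "flagged": [...]}
    flagged_voxel_fraction: dict  # mode -> fraction of high-MSE voxels
    negativity_fraction: float
    edge_displacement: list  # per TI summary from the label stack

    def to_dict(self) -> dict:
        return {
            "mse_histograms": self.mse_histograms,
            "roi_mean_mse": self.roi_mean_mse,
            "flagged_tis": self.flagged_tis,
            "flagged_voxel_fraction": self.flagged_voxel_fraction,
            "negativity_fraction": self.negativity_fraction,
            "edge_displacement": self.edge_displacement,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "QAReport":
        d = json.loads(text)
        return cls(**d)


def qa_report(
    series: FAIRSeries,
    fits: Mapping[str, T1FitResult],
    perfusion: PerfusionMap,
    masks: np.ndarray,
    roi_names: Mapping[int, str] | None = None,
    threshold_z: float = 3.0,
    high_mse_k_mad: float = 5.0,
) -> QAReport:
    """Assemble the QA metrics for one run.

    Selective and global modes are assessed independently.  The flagged-voxel
    fraction counts masked voxels whose MSE exceeds the robust threshold
    median + ``high_mse_k_mad`` x MAD of the masked MSE distribution.
    """
    masks = np.asarray(masks)
    mask_any = masks > 0
    mse_histograms: dict = {}
    roi_mean_mse: dict = {}
    flagged: dict = {}
    flagged_frac: dict = {}

    for mode, fit in fits.items():
        mse = fit.mse_map
        vals = mse[mask_any & np.isfinite(mse)]
        if len(vals):
            counts, edges = np.histogram(vals, bins=min(64, max(8, len(vals) // 50)))
            med = float(np.median(vals))
            mad = float(np.median(np.abs(vals - med)))
            frac = float((vals > med + high_mse_k_mad * mad).sum() / len(vals))
        else:
            counts, edges, med, frac = np.array([]), np.array([]), float("nan"), float("nan")
        mse_histograms[mode] = {
            "edges": [float(e) for e in edges],
            "counts": [int(c) for c in counts],
            "median": med,
        }
        flagged_frac[mode] = frac
        per_roi = {}
        for label in sorted(int(v) for v in np.unique(masks) if v != 0):
            name = (roi_names or {}).get(label, f"roi_{label}")
            roi_vals = mse[(masks == label) & np.isfinite(mse)]
            per_roi[name] = float(np.mean(roi_vals)) if len(roi_vals) else float("nan")
        roi_mean_mse[mode] = per_roi
        try:
            res = flag_corrupted_tis(series, fit, threshold_z=threshold_z)
            flagged[mode] = res.to_dict()
        except ValueError as exc:
            flagged[mode] = {"error": str(exc)}

    overlay = edge_overlay(series, reference_ti_index=1, mode="label")
    edge_summary = [
        {"index": d["index"], "displacement_px": d["displacement_px"]}
        for d in overlay.displacements
    ]

    return QAReport(
        mse_histograms=mse_histograms,
        roi_mean_mse=roi_mean_mse,
        flagged_tis=flagged,
        flagged_voxel_fraction=flagged_frac,
        negativity_fraction=perfusion.negativity_fraction,
        edge_displacement=edge_summary,
    )
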