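"""Magnitude inversion-recovery signal model and per-voxel T1 fitting.

A FAIR acquisition alternates a slice-selective inversion (label) with a
global inversion (control).  For each mode the magnitude signal at inversion
time ``TI`` follows

    S(TI) = | S0 * (1 - 2 * alpha * exp(-TI / T1)) |

with equilibrium signal ``S0``, inversion efficiency ``alpha`` in [0, 1] and
longitudinal relaxation time ``T1``.  Blood delivered to the slice only in the
control condition shortens the apparent T1 of the label series, and the pair
of fitted T1 maps encodes perfusion (see :mod:`fairasl.quant`).

Fitting is a bounded three-parameter least-squares on the magnitude model
directly (no polarity restoration), with the per-voxel mean squared residual
``MSE = sum(r_k**2) / n`` retained as the quality metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FAIRSeries",
    "InversionRecoveryParams",
    "FitBounds",
    "T1FitResult",
    "fair_signal",
    "initial_guess",
    "fit_voxel",
    "fit_series",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class InversionRecoveryParams:
    """One voxel's inversion-recovery parameters.

    s0 : equilibrium signal (arbitrary units, > 0)
    alpha : inversion efficiency in [0, 1]
    t1 : longitudinal relaxation time in ms (> 0)
    """

    s0: float
    alpha: float
    t1: float

    def __post_init__(self) -> None:
        if not (self.s0 > 0):
            raise ValueError(f"s0 must be > 0, got {self.s0}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (self.t1 > 0):
            raise ValueError(f"t1 must be > 0 ms, got {self.t1}")


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the three-parameter fit.

    Defaults span tissue and blood T1 at 9.4 T (blood ~2430 ms) with
    headroom; the s0 ceiling is expressed as a multiple of the voxel's
    maximum observed signal.
    """

    t1_min: float = 50.0
    t1_max: float = 10000.0
    alpha_min: float = 0.0
    alpha_max: float = 1.0
    s0_max_factor: float = 10.0

    def s0_bounds(self, signals: np.ndarray) -> tuple[float, float]:
        top = self.s0_max_factor * float(np.max(signals))
        if top <= 0:
            top = 1.0
        return (1e-12, top)


@dataclass
class FAIRSeries:
    """Paired label/control image stacks indexed by TI.

    ``label_stack`` and ``control_stack`` are ``(n_TI, rows, cols)`` arrays of
    non-negative magnitude signals; ``tis_ms`` is the shared ascending TI
    list; ``mask`` optionally restricts which voxels are fitted.
    """

    label_stack: np.ndarray
    control_stack: np.ndarray
    tis_ms: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.label_stack = np.asarray(self.label_stack, dtype=float)
        self.control_stack = np.asarray(self.control_stack, dtype=float)
        self.tis_ms = np.asarray(self.tis_ms, dtype=float)
        if self.label_stack.shape != self.control_stack.shape:
            raise ValueError(
                f"label and control stacks differ in shape: "
                f"{self.label_stack.shape} vs {self.control_stack.shape}"
            )
        if self.label_stack.ndim != 3:
            raise ValueError("stacks must be 3D (n_TI, rows, cols)")
        if len(self.tis_ms) != self.label_stack.shape[0]:
            raise ValueError(
                f"{len(self.tis_ms)} TIs but {self.label_stack.shape[0]} frames"
            )
        if np.any(np.diff(self.tis_ms) <= 0):
            raise ValueError("tis_ms must be strictly increasing")
        for name, stack in (("label", self.label_stack), ("control", self.control_stack)):
            if not np.all(np.isfinite(stack)):
                raise ValueError(f"{name} stack contains non-finite values")
            if np.any(stack < 0):
                raise ValueError(f"{name} stack contains negative magnitudes")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != grid {self.grid_shape}"
                )

    @property
    def n_ti(self) -> int:
        return len(self.tis_ms)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.label_stack.shape[1:]

    def stack(self, mode: str) -> np.ndarray:
        if mode == "label":
            return self.label_stack
        if mode == "control":
            return self.control_stack
        raise ValueError(f"mode must be 'label' or 'control', got {mode!r}")

    def effective_mask(self) -> np.ndarray:
        if self.mask is not None:
            return self.mask
        return np.ones(self.grid_shape, dtype=bool)


@dataclass
class T1FitResult:
    """Per-voxel fit maps for one inversion mode.

    Non-fitted and non-converged voxels are NaN in the parameter maps and
    False in ``converged_mask`` — never silently zero.  ``residual_stack``
    keeps the raw residuals r_k (model - data) in ascending-TI order of the
    *full* acquisition; TIs excluded from the fit hold NaN so downstream QA
    can align residuals with acquisition indices.
    """

    t1_map: np.ndarray
    s0_map: np.ndarray
    alpha_map: np.ndarray
    mse_map: np.ndarray
    converged_mask: np.ndarray
    n_points_map: np.ndarray
    residual_stack: np.ndarray
    tis_ms: np.ndarray
    used_ti_indices: np.ndarray  # 0-based indices into tis_ms used by the fit
    mode: str = "label"

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.t1_map.shape


def fair_signal(
    params: InversionRecoveryParams | tuple[float, float, float],
    ti: float | np.ndarray,
) -> np.ndarray | float:
    """Magnitude inversion-recovery signal ``|s0 (1 - 2 alpha exp(-ti/t1))|``.

    Accepts a scalar or array of TIs (ms, >= 0).
    """
    if isinstance(params, InversionRecoveryParams):
        s0, alpha, t1 = params.s0, params.alpha, params.t1
    else:
        s0, alpha, t1 = params
    ti = np.asarray(ti, dtype=float)
    if np.any(ti < 0):
        raise ValueError("ti must be >= 0 ms")
    out = np.abs(s0 * (1.0 - 2.0 * alpha * np.exp(-ti / t1)))
    return float(out) if out.ndim == 0 else out


def initial_guess(
    signals: Sequence[float],
    tis_ms: Sequence[float],
    bounds: FitBounds | None = None,
) -> InversionRecoveryParams:
    """Starting parameters from the signal null point.

    Full inversion nulls the magnitude at ``TI_null = T1 * ln 2``, so the TI
    of the minimum observed signal seeds T1 as ``TI_min_signal / ln 2``.
    s0 starts at the maximum signal and alpha at 1 (full adiabatic
    inversion).  Degenerate (all-equal) signals fall back to the geometric
    mid-bound T1.
    """
    bounds = bounds or FitBounds()
    y = np.asarray(signals, dtype=float)
    tis = np.asarray(tis_ms, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 points for an initial guess")
    s0 = float(np.max(y))
    if s0 <= 0:
        s0 = 1.0
    if np.allclose(y, y[0]):
        t1 = float(np.sqrt(bounds.t1_min * bounds.t1_max))
    else:
        t1 = float(tis[int(np.argmin(y))]) / LN2
    t1 = float(np.clip(t1, bounds.t1_min, bounds.t1_max))
    s0 = float(np.clip(s0, *bounds.s0_bounds(y)))
    return InversionRecoveryParams(s0=s0, alpha=1.0, t1=t1)


def fit_voxel(
    signals: Sequence[float],
    tis_ms: Sequence[float],
    bounds: FitBounds | None = None,
    initial: InversionRecoveryParams | None = None,
) -> tuple[InversionRecoveryParams | None, np.ndarray, float]:
    """Bounded three-parameter least-squares fit of one voxel.

    Minimises ``sum((model - signal)**2)`` over (s0, alpha, t1) subject to the
    box constraints.  Returns ``(params, residuals, mse)`` where residuals are
    model minus data in TI order and ``mse = sum(r_k**2) / n``.  A fit that
    fails to converge returns ``(None, nan_residuals, nan)`` rather than
    raising.

    When no explicit ``initial`` is given the fit is multi-started: the
    null-point guess (alpha = 1) first and, unless that already lands at a
    near-exact solution, a second start with reduced inversion efficiency
    (alpha = 0.7) and a correspondingly later null point.  The magnitude
    model folds the recovery curve at zero, which creates local minima when
    alpha is well below 1; the second start covers that basin.
    """
    bounds = bounds or FitBounds()
    y = np.asarray(signals, dtype=float)
    tis = np.asarray(tis_ms, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 finite points to fit 3 parameters")
    if len(y) != len(tis):
        raise ValueError("signals and tis_ms lengths differ")

    if initial is None:
        first = initial_guess(y, tis, bounds)
        out = _fit_voxel_single(y, tis, bounds, first)
        # near-exact solution: no second basin worth exploring
        if out[0] is not None and out[2] <= (1e-6 * max(np.max(y), 1.0)) ** 2:
            return out
        ti_min_sig = float(tis[int(np.argmin(y))])
        second = InversionRecoveryParams(
            s0=first.s0,
            alpha=0.7,
            t1=float(np.clip(ti_min_sig / np.log(1.4), bounds.t1_min, bounds.t1_max)),
        )
        alt = _fit_voxel_single(y, tis, bounds, second)
        if out[0] is None:
            return alt
        if alt[0] is not None and alt[2] < out[2]:
            return alt
        return out
    return _fit_voxel_single(y, tis, bounds, initial)


def _fit_voxel_single(
    y: np.ndarray,
    tis: np.ndarray,
    bounds: FitBounds,
    initial: InversionRecoveryParams,
) -> tuple[InversionRecoveryParams | None, np.ndarray, float]:
    s0_lo, s0_hi = bounds.s0_bounds(y)
    x0 = np.array(
        [
            np.clip(initial.s0, s0_lo, s0_hi),
            np.clip(initial.alpha, bounds.alpha_min, bounds.alpha_max),
            np.clip(initial.t1, bounds.t1_min, bounds.t1_max),
        ]
    )
    lo = np.array([s0_lo, bounds.alpha_min, bounds.t1_min])
    hi = np.array([s0_hi, bounds.alpha_max, bounds.t1_max])

    def resid(x: np.ndarray) -> np.ndarray:
        s0, alpha, t1 = x
        return np.abs(s0 * (1.0 - 2.0 * alpha * np.exp(-tis / t1))) - y

    def jac(x: np.ndarray) -> np.ndarray:
        s0, alpha, t1 = x
        e = np.exp(-tis / t1)
        u = s0 * (1.0 - 2.0 * alpha * e)
        sgn = np.where(u >= 0, 1.0, -1.0)  # subgradient at the null point
        return np.column_stack(
            [
                sgn * (1.0 - 2.0 * alpha * e),
                sgn * (-2.0 * s0 * e),
                sgn * (-2.0 * s0 * alpha * e * tis / t1**2),
            ]
        )

    try:
        sol = least_squares(
            resid, x0, jac=jac, bounds=(lo, hi), method="trf", x_scale="jac"
        )
    except Exception:
        return None, np.full_like(y, np.nan), float("nan")
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return None, np.full_like(y, np.nan), float("nan")

    params = InversionRecoveryParams(
        s0=float(sol.x[0]), alpha=float(sol.x[1]), t1=float(sol.x[2])
    )
    r = resid(sol.x)
    mse = float(np.sum(r**2) / len(r))
    return params, r, mse


def fit_series(
    series: FAIRSeries,
    mode: str,
    exclude_tis: Sequence[int] | None = None,
    bounds: FitBounds | None = None,
) -> T1FitResult:
    """Fit every masked voxel of one inversion mode.

    ``exclude_tis`` are 0-based indices into ``series.tis_ms`` dropped from
    the fit (e.g. motion-corrupted acquisitions); the per-voxel MSE then uses
    the post-exclusion point count.  Deterministic for fixed inputs.
    """
    bounds = bounds or FitBounds()
    stack = series.stack(mode)
    mask = series.effective_mask()
    if not mask.any():
        raise ValueError("mask selects no voxels")

    n_ti = series.n_ti
    excl = sorted(set(int(i) for i in (exclude_tis or [])))
    if any(i < 0 or i >= n_ti for i in excl):
        raise ValueError(f"exclude_tis out of range 0..{n_ti - 1}: {excl}")
    keep = np.array([i for i in range(n_ti) if i not in excl], dtype=int)
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} TIs remain after excluding {len(excl)}; "
            "need at least 3 to fit"
        )

    tis = series.tis_ms[keep]
    shape = series.grid_shape
    t1_map = np.full(shape, np.nan)
    s0_map = np.full(shape, np.nan)
    alpha_map = np.full(shape, np.nan)
    mse_map = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)
    n_points = np.zeros(shape, dtype=int)
    residual_stack = np.full((n_ti,) + shape, np.nan)

    rows, cols = np.nonzero(mask)
    for r_idx, c_idx in zip(rows, cols):
        y = stack[keep, r_idx, c_idx]
        params, resid, mse = fit_voxel(y, tis, bounds=bounds)
        n_points[r_idx, c_idx] = len(keep)
        if params is None:
            continue
        t1_map[r_idx, c_idx] = params.t1
        s0_map[r_idx, c_idx] = params.s0
        alpha_map[r_idx, c_idx] = params.alpha
        mse_map[r_idx, c_idx] = mse
        converged[r_idx, c_idx] = True
        residual_stack[keep, r_idx, c_idx] = resid

    return T1FitResult(
        t1_map=t1_map,
        s0_map=s0_map,
        alpha_map=alpha_map,
        mse_map=mse_map,
        converged_mask=converged,
        n_points_map=n_points,
        residual_stack=residual_stack,
        tis_ms=series.tis_ms.copy(),
        used_ti_indices=keep,
        mode=mode,
    )
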