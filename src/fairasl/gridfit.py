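"""Exhaustive grid reference fit for the inversion-recovery model.

A deliberately simple, derivative-free cross-check of the bounded
least-squares fit: T1 and alpha are enumerated on a dense grid and, for each
grid point, the optimal s0 has the closed form of a 1-D linear least-squares
problem (the model is linear in s0 once |1 - 2 alpha exp(-ti/T1)| is fixed).
The returned residual norm is a certified upper bound on the global optimum
over the grid, which the trust-region fit is expected to beat or tie.
"""

from __future__ import annotations

import numpy as np

from fairasl.fair_model import FitBounds

__all__ = ["grid_fit_voxel", "GridFitTable"]


class GridFitTable:
    """Precomputed |model shape| table over a (alpha, T1) grid for one TI
    list, reusable across voxels."""

    def __init__(
        self,
        tis_ms: np.ndarray,
        bounds: FitBounds | None = None,
        t1_step: float = 10.0,
        alpha_step: float = 0.01,
    ) -> None:
        bounds = bounds or FitBounds()
        self.bounds = bounds
        tis = np.asarray(tis_ms, dtype=float)
        self.t1_grid = np.arange(bounds.t1_min, bounds.t1_max + t1_step / 2, t1_step)
        self.alpha_grid = np.arange(
            bounds.alpha_min, bounds.alpha_max + alpha_step / 2, alpha_step
        )
        e = np.exp(-tis[None, :] / self.t1_grid[:, None])  # (n_t1, n_ti)
        g = 1.0 - 2.0 * self.alpha_grid[:, None, None] * e[None, :, :]
        self.abs_g = np.abs(g)  # (n_alpha, n_t1, n_ti)
        self.den = np.sum(self.abs_g**2, axis=-1)  # (n_alpha, n_t1)

    def fit(self, signals: np.ndarray) -> tuple[float, float, float, float]:
        """Best (s0, alpha, t1, residual_norm) over the grid for one voxel."""
        y = np.asarray(signals, dtype=float)
        num = self.abs_g @ y  # (n_alpha, n_t1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s0 = num / self.den
        s0_lo, s0_hi = self.bounds.s0_bounds(y)
        s0 = np.clip(np.nan_to_num(s0, nan=s0_lo), s0_lo, s0_hi)
        rss = np.sum((s0[..., None] * self.abs_g - y[None, None, :]) ** 2, axis=-1)
        ia, it = np.unravel_index(np.argmin(rss), rss.shape)
        return (
            float(s0[ia, it]),
            float(self.alpha_grid[ia]),
            float(self.t1_grid[it]),
            float(np.sqrt(rss[ia, it])),
        )


def grid_fit_voxel(
    signals: np.ndarray,
    tis_ms: np.ndarray,
    bounds: FitBounds | None = None,
    t1_step: float = 10.0,
    alpha_step: float = 0.01,
) -> tuple[float, float, float, float]:
    """One-shot grid fit of a single voxel; see :class:`GridFitTable`."""
    table = GridFitTable(tis_ms, bounds=bounds, t1_step=t1_step, alpha_step=alpha_step)
    return table.fit(signals)
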