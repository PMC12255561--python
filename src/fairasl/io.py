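"""Readers/writers and run configuration.

Image stacks and maps travel as NIfTI with spatial dimensions first
(``rows x cols x n_TI`` on disk, transposed to ``n_TI x rows x cols`` in
memory); the JSON sidecar is the single source of truth for the TI values,
inversion-mode labels and acquisition metadata — NIfTI headers carry geometry
only.  Grids are row-major and 0-based internally; user-facing TI indices are
1-based.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from fairasl.fair_model import FAIRSeries, FitBounds, T1FitResult
from fairasl.quant import QuantConfig
from fairasl.scheduler import RespirationModel

__all__ = [
    "RunConfig",
    "read_fair_series",
    "write_fair_series",
    "read_map",
    "write_map",
    "write_fit_result",
    "write_provenance",
]

log = logging.getLogger("fairasl")


@dataclass
class RunConfig:
    """Bundled defaults for a full pipeline run.

    Numeric defaults follow the reference protocol where one exists
    (lambda 0.95 ml/g, blood T1 2430 ms, rate 45 bpm, I:E 1:2, readout 50 ms,
    trigger window 10 ms); every value is overridable.
    """

    quant: QuantConfig = field(default_factory=QuantConfig)
    respiration: RespirationModel = field(default_factory=RespirationModel)
    bounds: FitBounds = field(default_factory=FitBounds)
    qa_threshold_z: float = 3.0
    vessel_k_mad: float = 5.0
    vessel_min_cluster: int = 4
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        return {
            "quant": self.quant.to_dict(),
            "respiration": self.respiration.to_dict(),
            "bounds": {
                "t1_min": self.bounds.t1_min,
                "t1_max": self.bounds.t1_max,
                "alpha_min": self.bounds.alpha_min,
                "alpha_max": self.bounds.alpha_max,
                "s0_max_factor": self.bounds.s0_max_factor,
            },
            "qa_threshold_z": self.qa_threshold_z,
            "vessel_k_mad": self.vessel_k_mad,
            "vessel_min_cluster": self.vessel_min_cluster,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            quant=QuantConfig(**d.get("quant", {})),
            respiration=RespirationModel.from_dict(d.get("respiration", {})),
            bounds=FitBounds(**d.get("bounds", {})),
            qa_threshold_z=d.get("qa_threshold_z", 3.0),
            vessel_k_mad=d.get("vessel_k_mad", 5.0),
            vessel_min_cluster=d.get("vessel_min_cluster", 4),
            seed=d.get("seed", 0),
            verbosity=d.get("verbosity", 1),
        )


def _to_disk_order(stack: np.ndarray) -> np.ndarray:
    """(n_TI, rows, cols) in memory -> (rows, cols, n_TI) on disk."""
    return np.transpose(np.asarray(stack), (1, 2, 0))


def _from_disk_order(vol: np.ndarray) -> np.ndarray:
    return np.transpose(np.asarray(vol), (2, 0, 1))


def write_map(arr: np.ndarray, path: str | Path) -> Path:
    """Write a 2D map or 3D stack (TI-first) as NIfTI."""
    arr = np.asarray(arr)
    data = _to_disk_order(arr) if arr.ndim == 3 else arr
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_map(path: str | Path, ti_first: bool = False) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).get_fdata())
    if ti_first and data.ndim == 3:
        return _from_disk_order(data)
    return data


def write_fair_series(
    series: FAIRSeries,
    label_path: str | Path,
    control_path: str | Path,
    sidecar_path: str | Path,
    extra_metadata: dict | None = None,
) -> None:
    """Write the two stacks as NIfTI and the TI list/metadata as JSON."""
    write_map(series.label_stack, label_path)
    write_map(series.control_stack, control_path)
    sidecar = {
        "tis_ms": [float(t) for t in series.tis_ms],
        "modes": {"label": str(Path(label_path).name),
                  "control": str(Path(control_path).name)},
    }
    if extra_metadata:
        sidecar.update(extra_metadata)
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_fair_series(
    label_path: str | Path,
    control_path: str | Path,
    sidecar_path: str | Path,
    mask: np.ndarray | None = None,
) -> FAIRSeries:
    """Load and validate a FAIR series.

    The sidecar's TI list is authoritative; if it is not ascending the frames
    of both stacks are reordered to ascending TI and the permutation is
    logged.
    """
    for p in (label_path, control_path, sidecar_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input file: {p}")
    sidecar = json.loads(Path(sidecar_path).read_text())
    if "tis_ms" not in sidecar:
        raise ValueError(f"sidecar {sidecar_path} lacks required field 'tis_ms'")
    tis = np.asarray(sidecar["tis_ms"], dtype=float)

    label = read_map(label_path, ti_first=True)
    control = read_map(control_path, ti_first=True)
    if label.shape != control.shape:
        raise ValueError(
            f"label stack {label.shape} and control stack {control.shape} "
            "differ in shape"
        )
    if label.shape[0] != len(tis):
        raise ValueError(
            f"sidecar lists {len(tis)} TIs but stacks hold {label.shape[0]} frames"
        )

    order = np.argsort(tis, kind="stable")
    if not np.array_equal(order, np.arange(len(tis))):
        log.info("sidecar TIs not ascending; reordering frames with permutation %s",
                 order.tolist())
        tis = tis[order]
        label = label[order]
        control = control[order]
    return FAIRSeries(label_stack=label, control_stack=control, tis_ms=tis, mask=mask)


def write_fit_result(fit: T1FitResult, out_dir: str | Path, prefix: str) -> dict:
    """Write the per-voxel maps of one fit; returns the path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (
        ("t1", fit.t1_map),
        ("s0", fit.s0_map),
        ("alpha", fit.alpha_map),
        ("mse", fit.mse_map),
    ):
        p = out / f"{prefix}_{name}.nii"
        write_map(arr, p)
        paths[name] = str(p)
    sidecar = {
        "mode": fit.mode,
        "tis_ms": [float(t) for t in fit.tis_ms],
        "used_ti_indices_1based": [int(i) + 1 for i in fit.used_ti_indices],
        "maps": paths,
    }
    sc = out / f"{prefix}_fit.json"
    sc.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = str(sc)
    return paths


def write_provenance(out_path: str | Path, config: RunConfig, **extras) -> None:
    """Machine-readable record of how an output was produced."""
    from fairasl import __version__

    record = {
        "package": "fairasl",
        "version": __version__,
        "python": sys.version.split()[0],
        "argv": sys.argv,
        "config": config.to_dict(),
    }
    record.update(extras)
    Path(out_path).write_text(json.dumps(record, indent=2))
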