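# fairasl

Respiration-aware multi-TI FAIR arterial-spin-labeling (ASL) perfusion
quantification for preclinical liver MRI, with residual-based quality
assurance and a synthetic phantom for end-to-end validation.

## The problem

Pulsed ASL of the rodent liver measures perfusion without contrast agents by
comparing two inversion-recovery experiments: a slice-selective inversion
(*label*), in which unlabeled blood flowing into the slice accelerates the
apparent longitudinal relaxation, and a global inversion (*control*), in which
it does not. The difficulty is respiration: the inversion pulse and the image
readout are separated by the inversion time TI, which may span several breaths,
and if the liver moves in between, the inverted slab and the imaged slice no
longer coincide. That through-plane mismatch corrupts the label signal in a
way no registration can repair.

Under mechanical ventilation the respiratory cycle is strictly periodic, so
the entire multi-TI experiment can be *planned*: a short (~10 ms) trigger
window at the onset of the end-expiration plateau fixes the inversion instant,
and TIs are chosen so that the delayed EPI readout (~50 ms) also lands inside
a motion-free plateau — even 4 breaths later. This package implements that
planning, the quantification that follows, and the quality metrics that tell
you when it failed.

## The model

Each voxel's magnitude signal at inversion time TI follows the
inversion-recovery curve

    S(TI) = | S0 · (1 − 2 α e^(−TI/T1)) |

with equilibrium signal S0, inversion efficiency α ∈ [0, 1] and relaxation
time T1. A bounded three-parameter least-squares fit per voxel and per
inversion mode yields T1_selective and T1_global maps, and perfusion follows as

    f = λ · (T1_global / T1_blood) · (1/T1_selective − 1/T1_global)

with λ = 0.95 ml/g (liver blood–tissue partition coefficient) and
T1_blood = 2430 ms at 9.4 T, expressed in ml/100 g tissue/min. Fit quality is
tracked voxel-wise by the mean squared residual MSE = Σ r_k²/n, and ROI
variability by the coefficient of variation CV = σ/μ × 100%.

## Worked example

```python
import numpy as np
from fairasl import (
    RespirationModel, plan_motion_free_tis, validate_schedule,
    PhantomSpec, build_phantom, simulate_series,
    fit_series, perfusion_map, roi_stats,
)
from fairasl.phantom import LABEL_NAMES, through_plane_events
from fairasl.qa import flag_corrupted_tis, exclude_and_refit

# 1. plan a motion-free TI schedule for 45 bpm ventilation
model = RespirationModel(rate=45)
schedule = plan_motion_free_tis(model, n=14, ti_min=100, ti_max=5500)
print("TIs (ms):", [int(t) for t in schedule.tis_ms])
print("motion-free failures:", validate_schedule(schedule, model).n_failures)

# 2. simulate a phantom acquisition with through-plane corruption (2% noise)
truth = build_phantom(PhantomSpec(shape=(48, 48), seed=0))
series = simulate_series(truth, schedule, noise_sigma=0.02, seed=1,
                         corruptions=through_plane_events())

# 3. fit both inversion modes and quantify perfusion
fits = {m: fit_series(series, m) for m in ("label", "control")}
pmap = perfusion_map(fits["label"], fits["control"])

# 4. QA: flag corrupted TIs, exclude them, refit
flags = flag_corrupted_tis(series, fits["label"])
print("flagged TIs:", flags.flagged)
refit = exclude_and_refit(series, flags.flagged, fits_before=fits)
liver = truth.liver_mask
print("liver median MSE before: %.0f  after: %.0f" % (
    np.nanmedian(fits["label"].mse_map[liver]),
    np.nanmedian(refit.fit_label.mse_map[liver])))

# 5. per-lobe statistics of the repaired perfusion map
for s in roi_stats(refit.perfusion, truth.labels, roi_names=LABEL_NAMES):
    print(f"{s.roi_name:>7s}: mean {s.mean:6.1f}  CV {s.cv_percent:5.1f}%  (n={s.n_voxels})")
```

Output:

```
TIs (ms): [100, 140, 190, 250, 340, 460, 470, 480, 1340, 1600, 1810, 2970, 4040, 5500]
motion-free failures: 0
flagged TIs: (9, 12)
liver median MSE before: 7045  after: 302
    RML: mean  137.5  CV  47.2%  (n=155)
    LML: mean  142.0  CV  48.0%  (n=160)
     RL: mean  136.8  CV  53.6%  (n=162)
     CL: mean  151.9  CV  51.1%  (n=161)
    LLL: mean  151.1  CV  53.3%  (n=104)
 muscle: mean  117.1  CV  75.5%  (n=203)
vessels: mean  456.4  CV  22.1%  (n=56)
```

Every planned TI keeps the readout inside an end-expiration plateau of the
1333 ms ventilation cycle. The QA stage identifies exactly the two TIs whose
label frames were simulated with a slab/slice mismatch, and excluding them
drops the liver median fit MSE by more than 20×. Lobe means recover the
phantom's true 140 ml/100 g/min within per-lobe sampling noise; the planted
vessel clusters stand out at ~3× tissue perfusion.

The same stages are available from the shell:

```
fairasl plan-ti --rate 45 --n 14 --ti-min 100 --ti-max 5500 --out schedule.json
fairasl simulate --preset through-plane-corrupt --seed 7 --out sim/
fairasl qa --label sim/label.nii --control sim/control.nii \
           --tis sim/series.json --labels sim/labels.nii --out qa/
fairasl roi-stats --map qa/perfusion.nii --labels sim/labels.nii
```

## Layout

- `fairasl.scheduler` — ventilation cycle model, motion-free windows, TI planners
- `fairasl.fair_model` — magnitude inversion-recovery model and per-voxel fitting
- `fairasl.quant` — perfusion map, ROI statistics, histogram FWHM/peaks, vessel mask
- `fairasl.qa` — per-TI corruption scores, exclusion-and-refit, edge overlays, QA report
- `fairasl.phantom` — synthetic rat-liver cross-section with ground truth and corruption events
- `fairasl.gridfit` — exhaustive grid reference fit (validation oracle)
- `fairasl.io` / `fairasl.cli` — NIfTI + JSON sidecar I/O, run configuration, CLI

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
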