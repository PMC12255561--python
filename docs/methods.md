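# Methods

## Respiration model and TI planning

A mechanically ventilated breathing cycle is modeled as strictly periodic with
period P = 60000/rate ms. The period is kept as an exact real and never
pre-rounded: at 45 bpm the exact period is 1333.33… ms, and a TI of 5500 ms
spans more than four cycles, so rounding the period to 1333 ms would misplace
the readout by more than a millisecond per cycle and misclassify long TIs.
Rounding happens only in the display helper.

The trigger instant (t = 0) is modeled as the onset of the end-expiration
plateau with zero jitter — the prospective trigger window is shortened to
~10 ms and sits at the plateau onset, so the inversion time point is
effectively deterministic under ventilation. Free-breathing trigger jitter is
not part of the scheduler; irregular breathing effects are emulated in the
phantom module instead, where they belong.

The usable plateau defaults to 40% of the cycle (≈533 ms at 45 bpm, inside the
500–550 ms range observed for ventilated rats) and is overridable, as is a
guard margin subtracted from the plateau end. A TI is motion-free when the
whole readout interval [TI, TI + 50 ms] fits inside one plateau window, i.e.
(TI mod P) ≤ plateau − guard − readout.

`plan_motion_free_tis` places candidates on a 10 ms grid (the scale of the
trigger window), distributes n targets log-uniformly over [ti_min, ti_max]
(log spacing samples the recovery curve densely at short TIs, like the
geometric series used for free breathing), and snaps each target to the
nearest unused valid instant, ties toward the earlier instant. The planner is
deterministic and raises a descriptive infeasibility error naming the binding
constraint when fewer than n valid instants exist. Note the protocol's
published TI range end (5150 ms) is not motion-free under the default plateau
model; the model is configurable rather than force-fitted, and the planners
accept any range.

All user-facing TI indices are 1-based ("the 9th TI"); internal storage is
0-based ascending.

## Signal model and fitting

The magnitude inversion-recovery model S(TI) = |S0(1 − 2α e^(−TI/T1))| is
fitted directly — no polarity restoration — with `scipy.optimize.least_squares`
(trust-region reflective, analytic Jacobian using the sign of the folded
residual as subgradient at the null point). Bounds: α ∈ [0, 1],
T1 ∈ [50, 10000] ms (spanning tissue and blood at 9.4 T with headroom),
S0 ∈ (0, 10 × max signal].

Initialization uses the signal null point: full inversion nulls the magnitude
at TI_null = T1·ln 2, so T1 starts at (TI of the minimum signal)/ln 2, S0 at
the maximum signal, α at 1. Because the magnitude fold creates a second basin
when α is well below 1 (the curve may never cross zero), the fit is
multi-started: if the first start does not land at a near-exact solution, a
second start with α = 0.7 and a correspondingly later null point is tried and
the lower-cost solution kept. On 100 random noisy voxels this ties or beats an
exhaustive (T1 × α) grid with per-grid-point closed-form S0 (the `gridfit`
reference) in every case we test.

Non-convergent voxels are recorded as NaN with a false `converged_mask` entry,
never as silent zeros. Per-voxel residuals are kept in ascending-TI order for
the QA stage, and MSE = Σ r_k²/n uses the post-exclusion point count n.

## Perfusion quantification

f = unit_factor · λ · (T1_global/T1_blood) · (1/T1_selective − 1/T1_global),
with λ = 0.95 ml/g, T1_blood = 2430 ms, and unit_factor = 6×10⁶ converting
ml·g⁻¹·ms⁻¹ to ml/100 g tissue/min (×60000 ms→min, ×100 g→100 g). The factor
is explicit configuration so alternative unit conventions are auditable.
Negative perfusion (selective T1 above global T1) diagnoses poor fits and is
reported — counted in the QA negativity fraction — never clipped.

ROI statistics use the sample standard deviation (n−1): ROI voxels are treated
as a sample when forming CV = σ/μ × 100%. Histograms default to
Freedman–Diaconis bin widths; FWHM is measured on the tallest peak by linear
interpolation at half maximum, and degenerate (single-valued) input returns
the bin width with a flag. Peak counting (mono- vs biphasic classification)
uses `scipy.signal.find_peaks` with a prominence of 15% of the tallest bin.

Vessel exclusion replaces the visual identification of bright vessel clusters
with a stated rule: voxels above median + k·MAD (k = 5) of the valid map,
kept only in 4-connected components of ≥ 4 voxels. Both constants are exposed
in configuration.

## Quality assurance

Per-TI corruption scoring standardizes each voxel's residuals by a robust
per-voxel scale, 1.4826 × MAD of that voxel's residual vector. The MAD
(rather than the voxel's RMSE) matters: with two corrupted TIs out of
fourteen, the corrupted points dominate the RMSE and cap their own
standardized score near √(n/2), below any usable threshold, while the MAD
ignores a minority of outliers. The scale is floored at 10⁻⁶ of the voxel's
S0 — residual structure below that is numerical, not physical — so noiseless
data produce near-zero scores rather than ratios of rounding errors.

The per-TI score summarizes standardized |r_k| across masked voxels at the
75th percentile. Respiratory corruption is regional (often half the organ or
more), whereas vessel-pulsation residuals affect a small minority of voxels;
the upper quartile is sensitive to the former and robust to the latter, while
a median can sit exactly at the boundary of a half-field artifact and dilute
it.

Detection is greedy-sequential: flag the highest-scoring TI above the
threshold (default z = 3), refit without the flagged TIs, rescore, repeat.
The refit step is essential because least squares partially absorbs a
corrupted point into the parameters; with a dominant outlier at one TI and a
weaker one at another, the weaker one only becomes distinct after the dominant
one is removed. Flagging stops while four fitted TIs remain (with three
points, an outlier is indistinguishable from the three-parameter trend).
Selective and global modes are scored independently.

`exclude_and_refit` refits both modes without the flagged TIs and guarantees,
per voxel, that the MSE over the retained points never increases: where the
bounded optimizer lands worse than the original parameters restricted to the
retained points (possible from a different start), the original parameters are
kept. The summary reports the masked median MSE before (all points), before
(retained points only) and after.

Edge inspection computes a Sobel gradient magnitude of the reference TI frame,
thresholds at a percentile (default 90) for the overlay, and estimates per-TI
in-plane displacement as the integer shift maximizing the circular
cross-correlation of the gradient maps. The contract is the displacement
estimate, not edge aesthetics; any gradient operator would serve. Flat frames
are flagged rather than fitted.

## Synthetic phantom

The phantom emulates a single axial rat-liver cross-section on the 96 × 96
acquisition grid (625 μm in-plane pixels): five lobes (RML, LML, RL, CL, LLL)
drawn as wedge sectors of an ellipse separated by thin background clefts, a
muscle band below the liver, and circular vessel clusters planted in one host
lobe. The geometry is procedural, not anatomical — downstream code needs
topology (distinct labeled ROIs, compact vessel clusters, a non-liver
reference tissue), not anatomy.

Defaults are the study conditions: tissue perfusion 140 ml/100 g/min (inside
the 100–185 range reported for healthy ventilated rats), muscle 120, vessels
3× tissue; vessels occupy 30% of the host lobe so that the lobe mean with
vessels exceeds the mean without by a factor of 1.6, inside the observed
1.5–2 range. Global-inversion T1: liver 1400 ms (a configuration choice —
rat liver T1 at 9.4 T is not pinned by a published value here), blood 2430 ms,
muscle 1800 ms. The selective-inversion T1 map is constructed from the true
perfusion by the exact algebraic inverse of the perfusion equation, so the
forward identity holds to machine precision on every voxel and the
simulate→fit→quantify round trip has an exact reference.

Corruption events are injected per TI: `through_plane_mismatch` multiplies the
effective α of the selective stack by (1 − magnitude) over a configurable
area (full / upper half / lower half — real respiratory corruption is
regionally confined); `in_plane_shift` translates a frame by whole pixels
(at 625 μm pixels, the 2 mm / 3.5 mm diaphragm displacements reported for free
breathing correspond to ~3 / ~6 px); `pulsation` jitters α inside a 2-pixel
annulus around the vessels. The standard corrupted preset applies
through-plane events of magnitude 0.5 at the 9th and 12th TIs over the upper
half of the field of view.

Noise is added last. Gaussian noise (default, σ as a fraction of the voxel's
S0, default 2%) is added to the magnitude and re-magnitudized; Rician noise is
the magnitude of the signal plus complex Gaussian and exhibits the expected
positive floor at the recovery null. Identical seeds give bit-identical
stacks.

What the phantom does *not* emulate: EPI artifacts (ghosting, distortion,
blurring), B0/B1 inhomogeneity, partial-volume mixtures at region boundaries,
the dual (portal/arterial) blood supply, cardiac waveforms, and free-breathing
trigger jitter as a continuous process. Passing tests therefore demonstrate
the correctness and sensitivity of the planning/fitting/QA machinery under
the stated corruption mechanisms, not performance on real acquisitions.

## Problem sizes and numerical choices

Unit tests run on a 48 × 48 phantom (same topology, ~900 tissue voxels);
end-to-end checks and the acceptance script use the full 96 × 96 grid with 14
planned TIs. A voxel fit costs ~2 ms, so a full two-mode fit is ~30–45 s.
The exhaustive grid reference uses 10 ms T1 steps and 0.01 α steps over the
fit bounds. Fits are deterministic for fixed inputs (fixed starts, no
stochastic optimizer), so reruns are bit-stable; all simulation randomness
flows through explicit seeds.

## Known limitations

- One frame per TI per mode, single slice; no averaging or multi-slice logic.
- The per-TI flagging rule is a stated surrogate for what was historically a
  visual judgment; its threshold (z = 3) and quantile (75%) are defaults, not
  universal constants, and regionally tiny artifacts (well under a quarter of
  the organ) will not raise per-TI scores — they surface in the MSE map
  instead.
- The vessel mask assumes vessels are hyper-perfused relative to a unimodal
  tissue background; it will under-select in maps dominated by fit failures.
- Perfusion negativity and CV are reported as diagnostics; no automatic
  re-scan decision is made.
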