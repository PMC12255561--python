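"""Respiration-aware inversion-time (TI) scheduling.

Mechanical ventilation makes the respiratory cycle strictly periodic, so a
multi-TI FAIR acquisition can be planned such that both the inversion pulse
(delivered at a respiratory trigger) and the EPI readout that follows the TI
delay fall inside motion-free end-expiration plateaus — even when the TI spans
several breaths.  This module models the ventilated cycle and plans/validates
TI lists against it.

Timing convention: t = 0 is the trigger instant, which coincides with the
onset of the first end-expiration plateau.  All times are in milliseconds.
The usable part of plateau k is the half-open interval
``[k*P, k*P + plateau_ms - guard_ms)`` where ``P = 60000/rate`` is the exact
(unrounded) cycle period.  A TI is motion-free when the whole readout interval
``[ti, ti + readout_ms]`` fits inside one such window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "RespirationModel",
    "TISchedule",
    "ScheduleValidation",
    "InfeasibleScheduleError",
    "cycle_period",
    "display_period_ms",
    "motion_free_windows",
    "is_ti_motion_free",
    "plan_motion_free_tis",
    "plan_geometric_tis",
    "validate_schedule",
]

#: granularity (ms) at which candidate TIs are placed; matches the scale of
#: the prospective trigger window.
TI_GRANULARITY_MS = 10.0

#: fraction of the cycle occupied by the usable end-expiration plateau when
#: no explicit plateau length is given (observed 500-550 ms at 45 bpm,
#: i.e. about 40% of the 1333 ms cycle).
DEFAULT_PLATEAU_FRACTION = 0.40


class InfeasibleScheduleError(ValueError):
    """Raised when a motion-free TI schedule cannot be constructed."""


def cycle_period(rate: float) -> float:
    """Exact respiratory cycle period in ms for a ventilation rate in
    breaths per minute.

    The period is kept as an exact real (45 bpm -> 1333.333... ms); rounding
    happens only in :func:`display_period_ms`.  Pre-rounding would misjudge
    TIs several cycles out (e.g. 5500 ms spans >4 periods and lands in a
    different cycle phase under a rounded period).
    """
    if not math.isfinite(rate) or rate <= 0:
        raise ValueError(f"ventilation rate must be > 0 bpm, got {rate!r}")
    return 60000.0 / rate


def display_period_ms(rate: float) -> int:
    """Cycle period floored to integer ms, for display only."""
    return int(math.floor(cycle_period(rate)))


@dataclass(frozen=True)
class RespirationModel:
    """Timing description of a mechanically ventilated breathing cycle.

    Parameters
    ----------
    rate :
        Ventilation rate in breaths per minute (> 0).
    ie_ratio :
        Inspiration:expiration duration ratio as a pair of positive reals.
        The protocol default is 1:2.
    plateau_ms :
        Usable motion-free window length starting at the trigger point.
        Defaults to 40% of the cycle period, matching the observed 500-550 ms
        end-expiration plateau at 45 bpm.
    trigger_window_ms :
        Prospective trigger window length; shortened to ~10 ms and placed at
        the plateau onset so the inversion instant is well defined.
    readout_ms :
        Single-shot EPI acquisition duration (~50 ms).
    guard_ms :
        Safety margin subtracted from the end of each plateau.
    """

    rate: float = 45.0
    ie_ratio: tuple[float, float] = (1.0, 2.0)
    plateau_ms: float | None = None
    trigger_window_ms: float = 10.0
    readout_ms: float = 50.0
    guard_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if len(self.ie_ratio) != 2 or min(self.ie_ratio) <= 0:
            raise ValueError(f"ie_ratio must be two positive reals, got {self.ie_ratio}")
        if self.plateau_ms is None:
            object.__setattr__(
                self, "plateau_ms", DEFAULT_PLATEAU_FRACTION * self.period_ms
            )
        if self.plateau_ms < 0:
            raise ValueError(f"plateau_ms must be >= 0, got {self.plateau_ms}")
        if self.plateau_ms >= self.period_ms:
            raise ValueError(
                f"plateau_ms ({self.plateau_ms}) must be shorter than the "
                f"cycle period ({self.period_ms:.2f} ms)"
            )
        if self.trigger_window_ms < 0 or self.readout_ms < 0 or self.guard_ms < 0:
            raise ValueError("trigger_window_ms, readout_ms and guard_ms must be >= 0")

    @property
    def period_ms(self) -> float:
        return cycle_period(self.rate)

    @property
    def usable_plateau_ms(self) -> float:
        """Plateau length after the guard margin, clipped at zero."""
        return max(self.plateau_ms - self.guard_ms, 0.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ie_ratio"] = list(self.ie_ratio)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RespirationModel":
        d = dict(d)
        if "ie_ratio" in d:
            d["ie_ratio"] = tuple(d["ie_ratio"])
        return cls(**d)


@dataclass
class TISchedule:
    """An ordered list of inversion times with its provenance.

    ``mode`` is one of ``geometric`` (log-spaced, free-breathing protocol),
    ``motion_free`` (planned against a :class:`RespirationModel`) or
    ``explicit`` (user supplied).
    """

    tis_ms: tuple[float, ...]
    mode: str = "explicit"
    readout_ms: float = 50.0
    provenance: str = ""

    def __post_init__(self) -> None:
        tis = tuple(float(t) for t in self.tis_ms)
        if len(tis) < 2:
            raise ValueError("a TI schedule needs at least 2 inversion times")
        if any(t <= 0 for t in tis):
            raise ValueError("all TIs must be > 0 ms")
        if any(b <= a for a, b in zip(tis, tis[1:])):
            raise ValueError("TIs must be strictly increasing")
        self.tis_ms = tis

    def __len__(self) -> int:
        return len(self.tis_ms)

    def to_json(self, **model_fields) -> str:
        payload = {
            "tis_ms": list(self.tis_ms),
            "mode": self.mode,
            "readout_ms": self.readout_ms,
            "provenance": self.provenance,
        }
        payload.update(model_fields)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TISchedule":
        d = json.loads(text)
        return cls(
            tis_ms=tuple(d["tis_ms"]),
            mode=d.get("mode", "explicit"),
            readout_ms=d.get("readout_ms", 50.0),
            provenance=d.get("provenance", ""),
        )


def motion_free_windows(
    model: RespirationModel, horizon_ms: float
) -> list[tuple[float, float]]:
    """Half-open motion-free intervals ``[start, end)`` within the horizon.

    Window k starts at ``k * period`` (the plateau onset, which for k = 0 is
    the trigger/inversion instant) and ends ``plateau_ms - guard_ms`` later.
    Windows whose usable length is zero are returned empty (start == end) so
    callers can still see the cycle structure.
    """
    if horizon_ms <= 0:
        raise ValueError(f"horizon_ms must be > 0, got {horizon_ms}")
    p = model.period_ms
    usable = model.usable_plateau_ms
    windows = []
    k = 0
    while k * p < horizon_ms:
        start = k * p
        windows.append((start, start + usable))
        k += 1
    return windows


def is_ti_motion_free(ti: float, model: RespirationModel) -> bool:
    """True iff the readout ``[ti, ti + readout_ms]`` lies wholly inside a
    motion-free plateau window.

    Equivalent to ``(ti mod period) <= plateau - guard - readout`` with the
    exact (unrounded) period.
    """
    if ti <= 0:
        return False
    budget = model.usable_plateau_ms - model.readout_ms
    if budget < 0:
        return False
    phase = math.fmod(ti, model.period_ms)
    return phase <= budget


def plan_geometric_tis(n: int, ti_min: float, ti_max: float) -> TISchedule:
    """Geometric TI series ``TI_k = ti_min * r**(k-1)`` with
    ``r = (ti_max/ti_min)**(1/(n-1))``.

    This is the vendor-default free-breathing series: dense sampling at short
    TIs where the recovery curve changes fastest, with the first and last TI
    hitting the requested endpoints exactly.
    """
    _check_plan_args(n, ti_min, ti_max)
    ratio = (ti_max / ti_min) ** (1.0 / (n - 1))
    tis = [ti_min * ratio ** k for k in range(n)]
    tis[0], tis[-1] = float(ti_min), float(ti_max)  # exact endpoints
    return TISchedule(
        tis_ms=tuple(tis),
        mode="geometric",
        provenance=f"geometric series n={n}, {ti_min}-{ti_max} ms, ratio={ratio:.6g}",
    )


def plan_motion_free_tis(
    model: RespirationModel,
    n: int,
    ti_min: float,
    ti_max: float,
    spacing: str = "log",
) -> TISchedule:
    """Plan ``n`` motion-free TIs in ``[ti_min, ti_max]``.

    Candidate instants are placed on a 10 ms grid and kept only where the
    readout fits inside a plateau window.  ``n`` target TIs are distributed
    log-uniformly (or uniformly for ``spacing='linear'``) across the range and
    each is snapped to the nearest unused valid instant, ties broken toward
    the earlier instant.  The result is deterministic for fixed inputs.

    Raises
    ------
    InfeasibleScheduleError
        If fewer than ``n`` valid 10 ms-grid instants exist in the range; the
        message names the binding constraint.
    """
    _check_plan_args(n, ti_min, ti_max)
    if spacing not in ("log", "linear"):
        raise ValueError(f"unknown spacing policy {spacing!r}")

    budget = model.usable_plateau_ms - model.readout_ms
    if budget < 0:
        raise InfeasibleScheduleError(
            f"readout ({model.readout_ms} ms) plus guard ({model.guard_ms} ms) "
            f"exceeds the plateau ({model.plateau_ms:.1f} ms): no TI can be "
            "motion-free under this model"
        )

    g = TI_GRANULARITY_MS
    lo = math.ceil(ti_min / g) * g
    grid = np.arange(lo, ti_max + 0.5 * g, g)
    grid = grid[(grid >= ti_min) & (grid <= ti_max)]
    valid = np.array([t for t in grid if is_ti_motion_free(t, model)])
    if len(valid) < n:
        raise InfeasibleScheduleError(
            f"only {len(valid)} motion-free instants at {g:.0f} ms granularity "
            f"in [{ti_min}, {ti_max}] ms (plateau {model.plateau_ms:.1f} ms, "
            f"readout {model.readout_ms} ms, period {model.period_ms:.2f} ms); "
            f"{n} requested"
        )

    if spacing == "log":
        targets = np.geomspace(max(ti_min, g), ti_max, n)
    else:
        targets = np.linspace(ti_min, ti_max, n)

    chosen: list[float] = []
    remaining = list(valid)
    for target in targets:
        dists = [abs(t - target) for t in remaining]
        best = min(range(len(remaining)), key=lambda i: (dists[i], remaining[i]))
        chosen.append(remaining.pop(best))
    chosen.sort()

    return TISchedule(
        tis_ms=tuple(chosen),
        mode="motion_free",
        readout_ms=model.readout_ms,
        provenance=(
            f"motion-free plan n={n}, {ti_min}-{ti_max} ms, {spacing} spacing, "
            f"rate={model.rate} bpm, plateau={model.plateau_ms:.1f} ms, "
            f"readout={model.readout_ms} ms, guard={model.guard_ms} ms"
        ),
    )


@dataclass
class ScheduleValidation:
    """Per-TI motion-free verdicts for a schedule under a respiration model."""

    entries: list[dict] = field(default_factory=list)

    @property
    def n_failures(self) -> int:
        return sum(not e["motion_free"] for e in self.entries)

    @property
    def n_tis(self) -> int:
        return len(self.entries)

    @property
    def all_valid(self) -> bool:
        return self.n_failures == 0

    def to_dict(self) -> dict:
        return {
            "n_tis": self.n_tis,
            "n_failures": self.n_failures,
            "all_valid": self.all_valid,
            "entries": self.entries,
        }


def validate_schedule(
    schedule: TISchedule, model: RespirationModel
) -> ScheduleValidation:
    """Check every TI of a schedule against the respiration model.

    Reports, per TI (1-based index), its cycle offset (phase within the
    respiratory period) and whether the readout fits a motion-free window.
    Inputs are not mutated.
    """
    entries = []
    for idx, ti in enumerate(schedule.tis_ms, start=1):
        entries.append(
            {
                "index": idx,
                "ti_ms": float(ti),
                "cycle_offset_ms": math.fmod(ti, model.period_ms),
                "motion_free": is_ti_motion_free(ti, model),
            }
        )
    return ScheduleValidation(entries=entries)


def _check_plan_args(n: int, ti_min: float, ti_max: float) -> None:
    if n < 2:
        raise ValueError(f"need at least 2 TIs, got n={n}")
    if not (0 < ti_min < ti_max):
        raise ValueError(f"require 0 < ti_min < ti_max, got {ti_min}, {ti_max}")
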