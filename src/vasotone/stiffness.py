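"""Arterial stiffness index β from pressures and a pulsatile diameter waveform.

The stiffness parameter

    β = ln(Ps / Pd) / ((Ds − Dd) / Dd)

relates the log pressure ratio (systolic over diastolic, mmHg) to the
fractional pulse change in arterial diameter (Ds and Dd are the per-cycle
maximum and minimum diameters, mm).  A higher β indicates a stiffer artery.
β is dimensionless and invariant to the unit the diameters are expressed in.

Systolic/diastolic pressures are treated as cycle-constant scalars (they are
measured once per session with a sphygmomanometer, not beat-to-beat).  Ds and
Dd are averaged across at least three cardiac cycles before a single β is
computed — mirroring the clinical caliper procedure — while per-cycle β
values are also reported so the spread is visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "HemodynamicTrace",
    "BetaResult",
    "beta_point",
    "extract_extrema",
    "beta_from_trace",
]


@dataclass
class HemodynamicTrace:
    """Arterial diameter waveform (mm) plus the session's cuff pressures (mmHg)."""

    diameter: np.ndarray
    fs: float
    Ps: float
    Pd: float
    heart_rate: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, dtype=float).ravel()
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not (self.Ps > self.Pd > 0):
            raise ValueError(
                f"require Ps > Pd > 0, got Ps={self.Ps}, Pd={self.Pd}"
            )
        if np.any(self.diameter <= 0):
            raise ValueError("diameter must be positive everywhere")

    @property
    def duration(self) -> float:
        return self.diameter.size / self.fs


@dataclass
class BetaResult:
    beta: float
    Ds: float
    Dd: float
    n_cycles: int
    per_cycle_beta: np.ndarray

    def __post_init__(self) -> None:
        if self.n_cycles < 3:
            raise ValueError(
                f"a reportable β needs >= 3 cardiac cycles, got {self.n_cycles}"
            )
        if not math.isfinite(self.beta):
            raise ValueError("β must be finite")


def beta_point(Ps: float, Pd: float, Ds: float, Dd: float) -> float:
    """Closed-form stiffness index from scalar pressures and diameters.

    Raises on the degenerate inputs (zero strain Ds == Dd, or a pressure
    ratio at or below 1) where β is undefined; in the Ps → Pd⁺ limit β → 0.
    """
    if not (Ps > Pd > 0):
        raise ValueError(f"require Ps > Pd > 0, got Ps={Ps}, Pd={Pd}")
    if Dd <= 0:
        raise ValueError("Dd must be positive")
    if Ds == Dd:
        raise ValueError("Ds == Dd: zero pulse strain, β undefined")
    return math.log(Ps / Pd) / ((Ds - Dd) / Dd)


def extract_extrema(
    trace: HemodynamicTrace,
    min_cycles: int = 3,
    prominence_frac: float = 0.25,
) -> dict:
    """Per-cardiac-cycle diameter extrema via prominence-based peak detection.

    Peaks (systolic maxima) and valleys (diastolic minima) are found with a
    prominence floor of ``prominence_frac`` times the waveform's peak-to-peak
    excursion; Ds and Dd are the means of the per-cycle extreme values.

    Returns ``{"Ds", "Dd", "n_cycles", "peak_values", "valley_values"}``.
    Raises if fewer than ``min_cycles`` full cycles are detected (e.g. a
    constant trace has no cycles at all).
    """
    d = trace.diameter
    span = float(np.ptp(d))
    if span <= 0:
        raise ValueError("constant diameter trace: no cardiac cycles detected")
    prom = prominence_frac * span
    if trace.heart_rate:
        dist = max(1, int(round(0.5 * 60.0 / trace.heart_rate * trace.fs)))
    else:
        dist = 1
    peaks, _ = sps.find_peaks(d, prominence=prom, distance=dist)
    valleys, _ = sps.find_peaks(-d, prominence=prom, distance=dist)
    n_cycles = int(min(peaks.size, valleys.size))
    if n_cycles < min_cycles:
        raise ValueError(
            f"detected {n_cycles} cardiac cycles, need at least {min_cycles}"
        )
    return {
        "Ds": float(d[peaks].mean()),
        "Dd": float(d[valleys].mean()),
        "n_cycles": n_cycles,
        "peak_values": d[peaks],
        "valley_values": d[valleys],
    }


def beta_from_trace(trace: HemodynamicTrace, min_cycles: int = 3) -> BetaResult:
    """Stiffness index from a diameter waveform: extrema extraction + Eq. form.

    Ds/Dd are averaged over cycles before the single reported β is evaluated;
    per-cycle β values (pairing the k-th peak with the k-th valley) are
    returned alongside to expose the beat-to-beat spread.
    """
    ext = extract_extrema(trace, min_cycles=min_cycles)
    beta = beta_point(trace.Ps, trace.Pd, ext["Ds"], ext["Dd"])
    n = ext["n_cycles"]
    pk = ext["peak_values"][:n]
    vl = ext["valley_values"][:n]
    per_cycle = np.array(
        [beta_point(trace.Ps, trace.Pd, p, v) for p, v in zip(pk, vl)]
    )
    return BetaResult(
        beta=beta, Ds=ext["Ds"], Dd=ext["Dd"], n_cycles=n, per_cycle_beta=per_cycle
    )
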