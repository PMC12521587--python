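"""Synthetic vascular electrophysiology (VE) recordings and hemodynamic traces.

The generator is phenomenological: it emulates the statistical structure the
analysis pipeline assumes, not smooth-muscle biophysics.  Its components:

* broadband Gaussian background noise, rescaled post hoc so that its RMS
  *after the analysis band-pass* (fourth-order Butterworth, 0.5–50 Hz,
  forward–backward) equals the configured ``noise_rms`` — the in-vivo preset
  is 2.63 μV, matching the noise floor reported for chronically implanted
  interfaces;
* a low-frequency vasomotor oscillation built from asymmetric piecewise-linear
  cycles whose per-cycle rise/fall time ratio t_r/t_f is state-dependent
  (constriction rises faster than it falls, dilation the opposite);
* monotone dose scaling of the oscillation amplitude, g(d) = 1 + κ·d;
* amplitude suppression for denervated and stented states;
* an optional common-mode mains sinusoid to exercise the notch stage;
* a per-channel phase gradient along the electrode array's axial (row)
  direction, modelling a propagating vasomotor wave — this is what keeps the
  oscillation visible after common-average referencing;
* pulsatile arterial diameter waveforms consistent with a configured
  stiffness index, for the hemodynamic cross-check.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import enum
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import signal as sps

from .recording import MultichannelRecording, default_grid
from .stiffness import HemodynamicTrace, beta_point

__all__ = [
    "VasomotorState",
    "GenConfig",
    "HemodynamicPreset",
    "StatePreset",
    "STATE_PRESETS",
    "POST_STENT_PRESET",
    "POST_STIM_PRESET",
    "INVIVO_NOISE_RMS",
    "dose_gain",
    "generate_baseline",
    "generate_vasomotor",
    "generate_hemodynamics",
]

#: In-band RMS noise floor (μV) measured in vivo for the implanted interface.
INVIVO_NOISE_RMS = 2.63

#: Slope of the dose→amplitude gain law g(d) = 1 + KAPPA * d.
KAPPA = 1.0

ANALYSIS_BAND = (0.5, 50.0)


class VasomotorState(str, enum.Enum):
    """Ground-truth vasomotor state attached to every generated segment."""

    BASELINE = "baseline"
    CONSTRICTION = "constriction"
    DILATION = "dilation"
    DENERVATED = "denervated"
    STENTED_ACUTE = "stented_acute"
    STENTED_CHRONIC = "stented_chronic"
    POST_STIM = "post_stim"


@dataclass(frozen=True)
class StatePreset:
    """Per-state defaults: cycle asymmetry and amplitude suppression."""

    rise_fall_ratio: float
    power_suppression: float = 0.0


# Constriction rises faster than it falls (ratio < 1), dilation the opposite;
# denervation suppresses vasomotor drive most strongly, stent dysfunction
# progressively, and post-stimulation segments are nearly recovered.
STATE_PRESETS: dict[VasomotorState, StatePreset] = {
    VasomotorState.CONSTRICTION: StatePreset(rise_fall_ratio=0.6),
    VasomotorState.DILATION: StatePreset(rise_fall_ratio=1.6),
    VasomotorState.DENERVATED: StatePreset(1.0, power_suppression=0.8),
    VasomotorState.STENTED_ACUTE: StatePreset(1.0, power_suppression=0.4),
    VasomotorState.STENTED_CHRONIC: StatePreset(1.0, power_suppression=0.6),
    VasomotorState.POST_STIM: StatePreset(1.0, power_suppression=0.1),
}


@dataclass
class GenConfig:
    """Configuration for synthetic VE recordings.

    ``rise_fall_ratio`` and ``power_suppression`` default to ``None``,
    meaning "use the state preset"; setting them overrides the preset.
    ``osc_amp`` is half the peak-to-valley excursion of the noiseless cycle,
    in μV.  ``phase_gradient_cycles`` is the total phase advance of the
    vasomotor wave across the electrode grid's rows, in cycles.
    """

    n_channels: int = 64
    fs: float = 4000.0
    duration: float = 10.0
    noise_rms: float = INVIVO_NOISE_RMS
    osc_freq: float = 1.2
    osc_amp: float = 25.0
    rise_fall_ratio: float | None = None
    dose_scale: float = 0.0
    power_suppression: float | None = None
    mains_freq: float = 50.0
    mains_amp: float = 5.0
    phase_gradient_cycles: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not self.fs > 2 * ANALYSIS_BAND[1]:
            raise ValueError(
                f"fs must exceed {2 * ANALYSIS_BAND[1]} Hz to carry the "
                f"0.5-50 Hz analysis band, got {self.fs}"
            )
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")
        if self.rise_fall_ratio is not None and not self.rise_fall_ratio > 0:
            raise ValueError("rise_fall_ratio must be > 0")
        if self.dose_scale < 0:
            raise ValueError("dose_scale must be >= 0")
        if self.power_suppression is not None and not (
            0 <= self.power_suppression <= 1
        ):
            raise ValueError("power_suppression must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def dose_gain(dose_scale: float) -> float:
    """Strictly increasing dose→amplitude gain, g(0) = 1."""
    return 1.0 + KAPPA * dose_scale


def _calibrated_noise(
    rng: np.random.Generator, shape: tuple[int, int], fs: float, target_rms: float
) -> np.ndarray:
    """White Gaussian noise rescaled so each channel's in-band RMS is exact.

    "In-band" is defined operationally: RMS after the analysis band-pass
    (4th-order Butterworth 0.5-50 Hz, zero-phase), the same filter the
    pipeline applies, because the in-vivo noise figure is quoted after that
    band-pass.
    """
    if target_rms == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    # Parseval route to the post-band-pass RMS: weight the realization's
    # spectrum by the zero-phase filter's squared magnitude (|H|^2 per pass,
    # applied twice).  Equivalent to time-domain sosfiltfilt up to edge
    # transients, and much cheaper on long multichannel records.
    n = shape[-1]
    sos = sps.butter(4, ANALYSIS_BAND, btype="bandpass", fs=fs, output="sos")
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
    w4 = np.abs(h) ** 4
    spec_pow = np.abs(np.fft.rfft(white, axis=-1)) ** 2
    weights = np.full(n // 2 + 1, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    ms = (spec_pow * (w4 * weights)).sum(axis=-1) / n**2
    rms = np.sqrt(ms)[..., None]
    return white * (target_rms / rms)


def asymmetric_cycle_wave(
    t: np.ndarray, freq: float, rise_fall_ratio: float, phase: float = 0.0
) -> np.ndarray:
    """Unit-amplitude periodic cycle: linear rise over t_r, fall over t_f.

    One period is partitioned as t_r + t_f = 1/freq with
    t_r / t_f = ``rise_fall_ratio``; the waveform runs valley (−1) → peak
    (+1) → valley.  ``phase`` is in cycles; phase 0 starts at a valley.
    """
    frac = np.mod(np.asarray(t, dtype=float) * freq + phase, 1.0)
    rise_frac = rise_fall_ratio / (1.0 + rise_fall_ratio)
    out = np.empty_like(frac)
    rising = frac < rise_frac
    out[rising] = -1.0 + 2.0 * frac[rising] / rise_frac
    out[~rising] = 1.0 - 2.0 * (frac[~rising] - rise_frac) / (1.0 - rise_frac)
    return out


def _mains(cfg: GenConfig, t: np.ndarray) -> np.ndarray:
    if cfg.mains_amp == 0:
        return np.zeros_like(t)
    return cfg.mains_amp * np.sin(2 * np.pi * cfg.mains_freq * t)


def _assemble(cfg: GenConfig, osc: np.ndarray | None, state: VasomotorState):
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    data = _calibrated_noise(rng, (cfg.n_channels, n), cfg.fs, cfg.noise_rms)
    if osc is not None:
        data += osc
    data += _mains(cfg, t)[None, :]  # common-mode across channels
    meta = {"state": state.value, "config": asdict(cfg)}
    return MultichannelRecording(data=data, fs=cfg.fs, metadata=meta)


def generate_baseline(cfg: GenConfig) -> MultichannelRecording:
    """Baseline recording: calibrated background noise (+ optional mains), no
    vasomotor oscillation."""
    return _assemble(cfg, None, VasomotorState.BASELINE)


def generate_vasomotor(
    cfg: GenConfig, state: VasomotorState | str
) -> MultichannelRecording:
    """Recording for a given vasomotor state.

    The oscillation is a state-asymmetric cycle train at ``osc_freq`` with
    amplitude ``osc_amp * g(dose_scale) * (1 − power_suppression)`` (the
    suppression factor applies only to denervated/stented/post-stim states).
    Each channel sees the same wave advanced in phase along the array's rows
    (propagating vasomotor wave); calibrated noise and mains are added as in
    :func:`generate_baseline`.  The ground-truth state label is stored in the
    recording metadata.
    """
    state = VasomotorState(state)
    if state is VasomotorState.BASELINE:
        return generate_baseline(cfg)

    preset = STATE_PRESETS[state]
    ratio = (
        cfg.rise_fall_ratio if cfg.rise_fall_ratio is not None else preset.rise_fall_ratio
    )
    supp = (
        cfg.power_suppression
        if cfg.power_suppression is not None
        else preset.power_suppression
    )
    amp = cfg.osc_amp * dose_gain(cfg.dose_scale) * (1.0 - supp)

    t = np.arange(cfg.n_samples) / cfg.fs
    coords = default_grid(cfg.n_channels)
    rows = np.array([rc[0] for rc in coords], dtype=float)
    n_rows = rows.max() + 1 if rows.size else 1
    phases = cfg.phase_gradient_cycles * rows / max(n_rows, 1)
    osc = np.empty((cfg.n_channels, t.size))
    # channels on the same row share a phase; compute each distinct phase once
    for ph in np.unique(phases):
        wave = amp * asymmetric_cycle_wave(t, cfg.osc_freq, ratio, phase=ph)
        osc[phases == ph] = wave
    rec = _assemble(cfg, osc, state)
    rec.metadata.update(
        {
            "rise_fall_ratio": float(ratio),
            "power_suppression": float(supp),
            "osc_amplitude": float(amp),
        }
    )
    return rec


# ---------------------------------------------------------------------------
# hemodynamics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HemodynamicPreset:
    """Scalar hemodynamic condition: cuff pressures (mmHg), per-cycle diameter
    extremes (mm), and heart rate (beats/min; 220 is a typical anesthetized
    rabbit rate)."""

    Ps: float
    Pd: float
    Dd: float
    Ds: float
    heart_rate: float = 220.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.Ps > self.Pd > 0):
            raise ValueError(f"require Ps > Pd > 0, got Ps={self.Ps}, Pd={self.Pd}")
        if not (self.Ds > self.Dd > 0):
            raise ValueError(f"require Ds > Dd > 0, got Ds={self.Ds}, Dd={self.Dd}")

    @property
    def beta(self) -> float:
        """The stiffness index this preset encodes, by direct evaluation."""
        return beta_point(self.Ps, self.Pd, self.Ds, self.Dd)


#: Post-stent (pre-stimulation) condition: diameters built by inverting the
#: stiffness relation at the printed index (β ≈ 18.83) for Ps/Pd = 110/85.
POST_STENT_PRESET = HemodynamicPreset(Ps=110.0, Pd=85.0, Dd=3.0, Ds=3.0411)

#: Post-stimulation condition: same pressures, β ≈ 14.06.
POST_STIM_PRESET = HemodynamicPreset(Ps=110.0, Pd=85.0, Dd=3.0, Ds=3.0550)


def generate_hemodynamics(
    preset: HemodynamicPreset,
    duration: float,
    noise_sd: float = 0.0,
    fs: float = 500.0,
) -> HemodynamicTrace:
    """Pulsatile diameter waveform oscillating between Dd and Ds once per
    cardiac cycle (raised-cosine pulse at ``heart_rate``), with optional
    additive Gaussian measurement noise (mm).

    With ``duration >= 3 * (60 / heart_rate)`` the trace contains at least
    three full cycles, enough for a reportable stiffness estimate.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    f_hr = preset.heart_rate / 60.0
    t = np.arange(int(round(duration * fs))) / fs
    # start mid-rise (quarter-cycle phase) so a duration of k cardiac cycles
    # contains k interior systolic peaks and k interior diastolic valleys
    d = preset.Dd + (preset.Ds - preset.Dd) * 0.5 * (
        1 - np.cos(2 * np.pi * f_hr * t - np.pi / 2)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(preset.seed)
        d = d + rng.normal(0.0, noise_sd, size=d.shape)
        d = np.clip(d, 1e-6, None)  # diameters stay physical
    return HemodynamicTrace(
        diameter=d,
        fs=fs,
        Ps=preset.Ps,
        Pd=preset.Pd,
        heart_rate=preset.heart_rate,
        metadata={"preset": asdict(preset), "noise_sd": noise_sd},
    )


def with_seed(cfg: GenConfig, seed: int) -> GenConfig:
    """Convenience: the same generation condition under a different seed."""
    return replace(cfg, seed=int(seed))
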