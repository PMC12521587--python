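"""Preprocessing chain for multichannel VE recordings.

Stage order follows the standard extracellular workflow: corrupted-channel
removal, mains notch, common average reference (CAR), band-pass to the
0.5–50 Hz analysis band with a fourth-order Butterworth, and a 100-ms
sliding-window RMS envelope.

All filters are applied forward–backward (zero-phase), so cycle-morphology
features downstream are not skewed by phase delay; note the effective filter
order doubles.  Masked channels propagate untouched through every filter and
are excluded from the CAR mean.  Operations never mutate their input.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .recording import Envelope, MultichannelRecording

__all__ = [
    "remove_bad_channels",
    "notch",
    "car",
    "bandpass",
    "sliding_rms",
    "preprocess_chain",
    "channel_rms",
]

logger = logging.getLogger(__name__)

#: Recorder full-scale range (μV) used by the saturation criterion.
DEFAULT_SAT_LEVEL = 5000.0


def remove_bad_channels(
    rec: MultichannelRecording,
    flat_tol: float = 0.1,
    sat_frac: float = 0.01,
    sat_level: float = DEFAULT_SAT_LEVEL,
) -> MultichannelRecording:
    """Mask flat and saturated channels.

    A channel is *flat* when its peak-to-peak excursion is below ``flat_tol``
    μV, and *saturated* when more than ``sat_frac`` of its samples sit at or
    beyond ``sat_level`` μV in magnitude.  Channels are masked, never
    deleted, so grid geometry is preserved.  Raises when nothing is left.
    """
    ptp = np.ptp(rec.data, axis=1)
    flat = ptp < flat_tol
    sat = np.mean(np.abs(rec.data) >= sat_level, axis=1) > sat_frac
    bad = flat | sat
    new_mask = rec.mask & ~bad
    if not new_mask.any():
        raise ValueError("all channels masked as corrupted: nothing to analyze")
    n_new = int((rec.mask & bad).sum())
    if n_new:
        logger.info("masked %d corrupted channel(s): flat=%d saturated=%d",
                    n_new, int((rec.mask & flat).sum()), int((rec.mask & sat).sum()))
    return rec.with_mask(new_mask, n_masked=int((~new_mask).sum()))


def _apply_to_valid(rec: MultichannelRecording, fn) -> np.ndarray:
    """Apply a samples-axis filter to unmasked rows; copy masked rows as-is."""
    out = rec.data.copy()
    if rec.mask.any():
        out[rec.mask] = fn(rec.data[rec.mask])
    return out


def notch(
    rec: MultichannelRecording,
    mains_freq: float = 50.0,
    n_harmonics: int = 2,
    Q: float = 30.0,
) -> MultichannelRecording:
    """Zero-phase IIR notch at the mains frequency and its harmonics.

    Harmonics at or above Nyquist are skipped silently; a fundamental at or
    above Nyquist is a configuration error.
    """
    if mains_freq >= rec.fs / 2:
        raise ValueError(
            f"mains_freq {mains_freq} Hz is at/above Nyquist ({rec.fs / 2} Hz)"
        )
    sections = []
    for h in range(1, n_harmonics + 1):
        f0 = h * mains_freq
        if f0 >= rec.fs / 2:
            break
        b, a = sps.iirnotch(f0, Q, fs=rec.fs)
        sections.append(sps.tf2sos(b, a))
    sos = np.vstack(sections)  # cascade all harmonics in one zero-phase pass
    # pad ~5 ring-down time constants of the narrowest notch so edge
    # transients settle (scipy's default pad is far too short for high Q)
    padlen = int(min(rec.n_samples - 1, 5 * rec.fs * Q / (np.pi * mains_freq)))
    return rec.with_data(
        _apply_to_valid(rec, lambda x: sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen))
    )


def car(rec: MultichannelRecording) -> MultichannelRecording:
    """Common average reference: subtract the per-sample mean across unmasked
    channels from every unmasked channel."""
    if rec.n_valid < 2:
        raise ValueError("CAR needs at least 2 unmasked channels")
    out = rec.data.copy()
    ref = rec.data[rec.mask].mean(axis=0)
    out[rec.mask] = rec.data[rec.mask] - ref
    return rec.with_data(out)


def bandpass(
    rec: MultichannelRecording,
    lo: float = 0.5,
    hi: float = 50.0,
    order: int = 4,
) -> MultichannelRecording:
    """Zero-phase Butterworth band-pass (second-order sections for stability)."""
    if lo <= 0:
        raise ValueError("low cut-off must be > 0")
    if lo >= hi:
        raise ValueError(f"require lo < hi, got {lo} >= {hi}")
    if hi >= rec.fs / 2:
        raise ValueError(f"high cut-off {hi} Hz is at/above Nyquist ({rec.fs / 2} Hz)")
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=rec.fs, output="sos")
    # pad ~3 periods of the low cut-off so the high-pass edge transient
    # settles; scipy's default pad is far too short for 0.5 Hz at 4 kHz
    padlen = int(min(rec.n_samples - 1, 3 * rec.fs / lo))
    return rec.with_data(
        _apply_to_valid(rec, lambda x: sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen))
    )


def sliding_rms(
    rec: MultichannelRecording, window: float = 0.1, hop: float = 0.05
) -> Envelope:
    """Per-channel RMS in a sliding window (100 ms / 50% hop by default).

    The partial trailing window is dropped.
    """
    wlen = int(round(window * rec.fs))
    hlen = max(1, int(round(hop * rec.fs)))
    if wlen > rec.n_samples:
        raise ValueError(
            f"window of {wlen} samples exceeds recording length {rec.n_samples}"
        )
    frames = np.lib.stride_tricks.sliding_window_view(rec.data, wlen, axis=-1)
    frames = frames[:, ::hlen, :]
    values = np.sqrt(np.mean(frames**2, axis=-1))
    starts = np.arange(values.shape[1]) * hlen / rec.fs
    return Envelope(
        values=values, window_len=wlen / rec.fs, hop=hlen / rec.fs,
        start_times=starts, mask=rec.mask.copy(),
    )


def preprocess_chain(
    rec: MultichannelRecording,
    mains_freq: float = 50.0,
    n_harmonics: int = 2,
    Q: float = 30.0,
    lo: float = 0.5,
    hi: float = 50.0,
    order: int = 4,
    flat_tol: float = 0.1,
    sat_frac: float = 0.01,
    apply_car: bool = True,
) -> MultichannelRecording:
    """Full standard chain: bad-channel removal → notch → CAR → band-pass."""
    rec = remove_bad_channels(rec, flat_tol=flat_tol, sat_frac=sat_frac)
    rec = notch(rec, mains_freq=mains_freq, n_harmonics=n_harmonics, Q=Q)
    if apply_car:
        rec = car(rec)
    rec = bandpass(rec, lo=lo, hi=hi, order=order)
    rec.metadata["preprocessing"] = {
        "mains_freq": mains_freq, "n_harmonics": n_harmonics, "Q": Q,
        "lo": lo, "hi": hi, "order": order, "car": apply_car,
    }
    return rec


def channel_rms(rec: MultichannelRecording, edge_guard: float = 0.0) -> np.ndarray:
    """RMS (μV) of each unmasked channel.

    ``edge_guard`` (seconds) excludes that much signal at both ends.  After
    zero-phase band-passing with a near-DC low edge, the first and last few
    low-frequency periods carry boundary ringing whose power is an artifact
    of filtering a finite record; steady-state noise measurements should skip
    them (a guard of ~3 periods of the low cut-off is enough).
    """
    g = int(round(edge_guard * rec.fs))
    if 2 * g >= rec.n_samples:
        raise ValueError("edge guard leaves no samples to measure")
    x = rec.valid_data()[:, g : rec.n_samples - g if g else None]
    return np.sqrt(np.mean(x**2, axis=-1))
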