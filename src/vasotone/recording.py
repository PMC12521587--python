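"""In-memory containers for multichannel vascular electrophysiology data.

A :class:`MultichannelRecording` is the object every pipeline stage consumes
and produces: a channels x samples voltage matrix in microvolts, a sampling
rate, per-channel labels with 2-D electrode-grid coordinates (8 x 8 for the
default 64-channel layout, row-major, 0-based), a per-channel validity mask,
and free-form metadata (ground-truth state label, provenance, stage log).

All pipeline operations are non-mutating: they return new recordings and
leave their input untouched.  Channels flagged invalid in ``mask`` are
excluded from every downstream computation but are carried along so channel
indexing and grid geometry stay stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MultichannelRecording", "Envelope", "default_grid"]


def default_grid(n_channels: int) -> list[tuple[int, int]]:
    """Row-major (row, col) coordinates on the squarest grid holding ``n_channels``.

    64 channels map onto the 8 x 8 electrode array; other counts fall back to
    an ``n_rows x 8`` layout (last row possibly partial) so axial (row)
    subsampling remains meaningful.
    """
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    n_cols = 8 if n_channels >= 8 else n_channels
    return [(i // n_cols, i % n_cols) for i in range(n_channels)]


@dataclass
class MultichannelRecording:
    """Channels x samples voltage matrix (μV) with sampling rate and metadata."""

    data: np.ndarray
    fs: float
    channel_ids: list[str] | None = None
    coords: list[tuple[int, int]] | None = None
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n_ch = self.data.shape[0]
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i + 1:02d}" for i in range(n_ch)]
        if len(self.channel_ids) != n_ch:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {n_ch} channels"
            )
        if self.coords is None:
            self.coords = default_grid(n_ch)
        if len(self.coords) != n_ch:
            raise ValueError(f"{len(self.coords)} grid coords for {n_ch} channels")
        self.coords = [tuple(int(v) for v in rc) for rc in self.coords]
        if self.mask is None:
            self.mask = np.ones(n_ch, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n_ch,):
            raise ValueError("mask must be a 1-D boolean array, one flag per channel")

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) / self.fs

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_data(self) -> np.ndarray:
        """Rows of unmasked channels only."""
        return self.data[self.mask]

    # -- functional update ----------------------------------------------
    def with_data(self, data: np.ndarray, **meta_updates) -> "MultichannelRecording":
        """New recording sharing this one's geometry, with replaced samples."""
        md = {**self.metadata, **meta_updates}
        return replace(self, data=np.asarray(data, dtype=float), metadata=md)

    def with_mask(self, mask: np.ndarray, **meta_updates) -> "MultichannelRecording":
        md = {**self.metadata, **meta_updates}
        return replace(self, mask=np.asarray(mask, dtype=bool), metadata=md)

    def copy(self) -> "MultichannelRecording":
        return replace(
            self,
            data=self.data.copy(),
            mask=self.mask.copy(),
            metadata=dict(self.metadata),
        )


@dataclass
class Envelope:
    """Sliding-window RMS values (μV), one row per channel, one column per window."""

    values: np.ndarray
    window_len: float
    hop: float
    start_times: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("RMS values must be non-negative")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.start_times is None:
            self.start_times = np.arange(self.values.shape[1]) * self.hop

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]
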