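import numpy as np
import pytest

from vasotone import GenConfig, generate_vasomotor


def sine(freq: float, fs: float, duration: float, amp: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t)


@pytest.fixture
def clean_cfg():
    """Noiseless, mains-free single-channel generator config."""
    def make(**overrides):
        defaults = dict(
            n_channels=1, fs=1000.0, duration=20.0,
            noise_rms=0.0, mains_amp=0.0, seed=0,
        )
        defaults.update(overrides)
        return GenConfig(**defaults)

    return make


@pytest.fixture
def constriction_signal(clean_cfg):
    """Noiseless constriction-state trace (rise/fall ratio 0.6)."""
    cfg = clean_cfg()
    rec = generate_vasomotor(cfg, "constriction")
    return rec.data[0], cfg.fs
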