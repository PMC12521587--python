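# vasotone

Vasomotor electrophysiology analysis at desk scale.

Arteries constrict and dilate under autonomic control, and that vasomotor
activity has an electrophysiological signature: slow, low-frequency voltage
oscillations recordable from the vessel wall with a multichannel (64-site)
interface.  Stent implantation, denervation and vasoactive drugs all change
this signature — its amplitude, its band power, and the within-cycle
rise/fall asymmetry.  `vasotone` implements the full analysis workflow for
such recordings, plus the two companion computations that anchor it
clinically: the ultrasound-derived arterial stiffness index β and a
closed-loop controller that detects vasomotor dysfunction from the signal
and triggers charge-balanced electrical stimulation to restore it.

Because the package is aimed at method development and validation rather
than hardware, it ships a synthetic-data generator that emulates the
statistical structure of in-vivo recordings (calibrated noise floor,
state-dependent oscillation morphology, dose-dependent amplitude,
suppression under denervation/stenting, pulsatile diameter waveforms).
Every pipeline stage is validated by parameter recovery against generator
ground truth.  See `docs/methods.md` for the model details.

## Core quantities

* **Rhythm ratio** — each vasomotor cycle is a valley → peak → valley
  triplet with rise time t_r and fall time t_f; the per-cycle ratio
  t_r/t_f distinguishes constriction (< 1) from dilation (> 1).
* **Relative power / amplitude** — within-subject post/pre ratios of mean
  0.5–50 Hz band power (100-ms Hann windows, 50% overlap) and mean cycle
  amplitude; dimensionless, monotone in drug dose.
* **Stiffness index** — β = ln(P_s/P_d) / ((D_s − D_d)/D_d) from cuff
  pressures (mmHg) and per-cycle diameter extrema (mm); higher β = stiffer
  artery.
* **Separability** — silhouette score of t-SNE-embedded feature vectors
  against ground-truth vasomotor state labels.

## Worked example

```python
import vasotone as vt

# a constricting artery, 64 channels, 4 kHz, in-vivo noise floor
cfg = vt.GenConfig(duration=20.0, seed=7)
rec = vt.generate_vasomotor(cfg, "constriction")

clean = vt.preprocess_chain(rec)            # notch -> CAR -> 0.5-50 Hz
cycles = vt.detect_cycles(clean.data[0], clean.fs)
print(vt.rhythm_ratio(cycles)["mean"])      # 0.600 +/- 0.01  (preset 0.6)

# stiffness before and after stimulation, from the documented presets
from vasotone.synthgen import POST_STENT_PRESET, POST_STIM_PRESET
for preset in (POST_STENT_PRESET, POST_STIM_PRESET):
    trace = vt.generate_hemodynamics(preset, duration=2.0)
    print(round(vt.beta_from_trace(trace).beta, 2))
# 18.82   <- post-stent: stiff, dysfunctional
# 14.06   <- post-stimulation: elasticity restored

# closed loop: chronically stented vessel at 40% of healthy power
ref = vt.HealthyReference(mean_power=cfg.osc_amp**2 / 2)
loop_cfg = vt.GenConfig(n_channels=1, noise_rms=0.0, mains_amp=0.0)
log = vt.run_closed_loop(loop_cfg, ref, state="stented_chronic")
print(log.n_stimulations, log.recovered)    # 2 True
```

The rhythm ratio recovers the generator's constriction preset; the two β
values reproduce the stiff post-stent artery and its recovery after
stimulation; the closed-loop session detects the power deficit and restores
it into the healthy band with exactly two 300 μA / 100 μs charge-balanced
pulse trains.

A command-line interface mirrors the library:

```sh
vasotone simulate --state dilation --duration 10 --seed 3 --out rec.csv
vasotone preprocess --in rec.csv --out clean.csv
vasotone features --in clean.csv --out features.csv
vasotone embed --in features.csv --out embedding.csv
vasotone stiffness --diameter trace.csv --ps 110 --pd 85 --out beta.json
vasotone closedloop --preset stented_chronic --out session.json
vasotone run --config config.yaml            # full pipeline from YAML
```

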