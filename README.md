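# vokr

Quantification of optokinetic and vestibulo-ocular eye movements in
larval zebrafish from dual-camera video-oculography, together with a
calibrated synthetic-data generator.

Larval zebrafish stabilize gaze with the optokinetic response (OKR;
slow-phase following of large-field visual motion, reset by quick-phase
saccades) and the vestibulo-ocular reflex (VOR; compensatory eye
movements driven by head motion).  A dual-camera setup — one camera
above the fish, one in front — tracks the horizontal (yaw) and vertical
(roll) eye position simultaneously by fitting an ellipse to the
binarized eye image and reading the angle between its major axis and the
body axis.  This package implements the full analysis chain for such
recordings:

* stimulus protocols (constant rotation, sinusoidal velocity envelope,
  vestibular roll) and their kinematics;
* trace conditioning (rolling-mean, median, Wiener filters; detrending;
  derivatives);
* multi-step saccade detection with plane-specific thresholds (1 deg
  minimum deflection; peak velocity 30/10 deg s⁻¹ and mean velocity
  20/10 deg s⁻¹ for horizontal/vertical), endpoint refinement, saccade
  removal, and classification of coincident events into the four
  direction clusters;
* outcome measures: the VOR score (Fourier amplitude of eye position at
  the head-rotation frequency, `2|Σ x e^{−iωt}|/N` in degrees),
  stimulus-triggered averages (STA) with outlier-period rejection, sine
  plus linear fits `A sin(2πft+φ) + c + mt` with plateau exclusion,
  gain (`2πfA/v_a` for the VOR; eye/stimulus peak-to-peak position for
  the OKR), cross-correlation and top-of-descent phase lags, 4-s
  constant-rotation gain and amplitude, dynamic range, cumulative
  averages and tuning grids over spatial frequency × angular velocity;
* a synthetic generator producing dual-camera recordings with known
  ground truth, including the projection artifact by which large
  horizontal eye rotations corrupt the front camera's apparent vertical
  angle, plus an eye-image renderer and a moment-based ellipse tracker.

The model, parameter defaults and the design rationale are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a vertical-VOR experiment (eight full body rolls per phase at
90, 45 and 22.5 deg s⁻¹, both directions, calibrated so the pipeline
recovers a 15.9 deg VOR score) and score it:

```python
import numpy as np
from vokr import build_protocol, get_preset
from vokr.synthetic import generate_vvor_dataset
from vokr.pipelines import vvor_metrics

config = get_preset("vvor-90-score", seed=42)
protocol = build_protocol("vvor", seed=42)
dataset = generate_vvor_dataset(config, protocol)
records = vvor_metrics(dataset)

for velocity in (90.0, 45.0, 22.5):
    rows = [r for r in records if r["angular_velocity"] == velocity]
    score = np.mean([r["vor_score"] for r in rows])
    rng = np.mean([r["dynamic_range"] for r in rows])
    lag = np.mean([r["phase_lag_deg"] for r in rows])
    print(f"{velocity:5.1f} deg/s  VOR score {score:5.2f} deg   "
          f"dynamic range {rng:5.2f} deg   phase lag {lag:+5.2f} deg")
```

```
 90.0 deg/s  VOR score 16.19 deg   dynamic range 31.92 deg   phase lag +0.02 deg
 45.0 deg/s  VOR score 15.91 deg   dynamic range 31.79 deg   phase lag +0.00 deg
 22.5 deg/s  VOR score 15.90 deg   dynamic range 31.82 deg   phase lag +0.02 deg
```

The VOR score sits at the configured 15.9 deg (the 90 deg s⁻¹ value runs
~2% high from smoothing-window edge effects), the dynamic range is twice
the score — eye position is locked to head position — and the
cross-correlation phase lag is essentially zero, i.e. the pipeline
introduces no spurious lag.

The same workflow is available from the shell:

```sh
vokr simulate --preset vvor-90-score --seed 42 --out runs/vvor
vokr vvor --run runs/vvor
vokr report --dir runs
```

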