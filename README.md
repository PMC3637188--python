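# cibeam

Dual-microphone delay-and-subtract beamforming for cochlear-implant (CI)
front ends, with a low-complexity compensation algorithm for the
low-frequency roll-off that first-order differential arrays impose on
broadband speech.

## The problem

CI users need better signal-to-noise ratios than normal-hearing listeners,
and a two-microphone differential array (the only geometry that fits a CI
headpiece, with microphones about 1 cm apart) provides directional noise
suppression.  Its narrowband magnitude response to a far-field plane wave at
incidence angle θ is

    |H(θ, f)| = |1 − β·e^{−j2πf(d·cosθ/c + τ)}|
              = √(1 + β² − 2β·cos(2πf(d·cosθ/c + τ)))

with inter-microphone distance d, sound speed c, algorithm delay τ
(τ = 0, 0.342·d/c, d/c give the dipole, supercardioid and cardioid
patterns) and subtraction weight β.  At low frequency the response falls
toward |1 − β| — zero for the common β = 1 — so the array attenuates
exactly the band where speech energy concentrates.

## The method

Over the speech band [0, 6000] Hz the on-axis f→H curves form a nearly
linear family in β.  The package builds the two-segment linear model

    H_eva(β, f) = (1 − β) + slope(β)·f

whose 0 Hz intercept is exact and whose 6 kHz endpoint interpolates
piecewise linearly in β between H₁ = 1 (β = 0), H₂ (at the turning weight
β ≈ 0.45 minimizing the endpoint response) and H₃ (β = 1).  For the default
CI geometry the slopes reduce to the numeric form

    H_eva = (1 − β) + 1.278e−4·β·f             for β ≤ 0.45
    H_eva = (1 − β) + (2.145e−4·β − 3.897e−5)·f  for β > 0.45

Model accuracy is quantified by relative, energy-normalized and per-weight
average errors; the compensation itself is one scalar gain per channel of
the 8-band CI filter bank, referenced to the channel near 1000 Hz.  An
evaluation chain (filter bank → envelopes → CIS sinusoidal modulation →
Welch PSD) and a synthetic two-microphone scene simulator close the loop:
the simulator validates the closed form, and the CIS line spectra show the
gains restoring the original spectral balance.

## Worked example

```python
import numpy as np
from cibeam import (ArrayConfig, BeamParams, LinearizedModel, SceneConfig,
                    channel_gains, run_end_to_end)

array = ArrayConfig()                    # d = 1 cm, c = 340 m/s
model = LinearizedModel.from_array(array)
print(model.beta_turn, round(model.H2, 4), round(model.H3, 4))
# 0.45 0.8952 1.0529

gains = channel_gains(1.0, mode="ideal", model=model)
print(np.round(gains.gains, 3))
# [3.663 1.94  1.32  1.    0.689 0.426 0.265 0.169]

result = run_end_to_end(scene=SceneConfig(duration=2.0), array=array,
                        params=BeamParams.dipolar(beta=1.0))
print(result.to_frame().round(2).to_string(index=False))
```

```
 channel  center_hz  uncompensated_db  linearized_db  ideal_db
       1      274.0            -19.78           0.23      0.13
       2      517.5            -14.31           0.14      0.04
       3      761.0            -11.11           0.04     -0.05
       4     1005.0             -8.67           0.06     -0.03
       5     1462.0             -5.42           0.05     -0.03
       6     2376.0             -1.25           0.00     -0.02
       7     3869.0              2.87          -0.11     -0.02
       8     6276.0              6.77          -0.42     -0.03
```

The uncompensated dipolar beamformer loses ~20 dB in the lowest CIS channel
and gains ~7 dB in the highest; both the linearized and ideal channel gains
restore every line to within half a decibel of the omnidirectional
reference.

The same computations are available from the shell:

```
cibeam beampattern --beta 0.5 --out pattern
cibeam errors --out errors
cibeam evaluate --duration 2 --out eval
```

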